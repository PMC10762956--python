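"""Synthetic molecule libraries with planted structure-property rules.

The generator emulates the statistical shape of a quantum-chemistry-derived
organic semiconductor library: polycyclic aromatic cores (the 11 registered
conjugated fragments) decorated at random aromatic CH positions with
substituents, each substituent carrying exactly one functional group from
the 15-entry SMARTS library. A continuous property (a HOMO-like orbital
energy in eV) is planted as a group-additive linear rule plus Gaussian
noise, so that downstream classifiers have a recoverable signal whose
ground truth is known exactly.

No attempt is made to match real HOMO/LUMO distributions numerically; the
point is a controllable, fully reproducible stand-in with the same *kinds*
of structure (families sharing conjugated fragments, properties driven by
functional-group content).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from rdkit import Chem

from .errors import ConfigurationError, GenerationExhaustedError
from .groups import (
    count_groups,
    family_tags,
    load_fragment_library,
    load_group_library,
)
from .smiles import canonicalize, mol_from_smiles

#: Default substituent SMILES, one per functional group of the library.
#: Attachment is always through atom 0 of the parsed fragment.
DEFAULT_SUBSTITUENTS: dict[str, str] = {
    "nitrile": "C#N",
    "nitro": "[N+](=O)[O-]",
    "imine": "C=NC",
    "enamine": "N(C)C",
    "ketone": "C(C)=O",
    "carbonyl_with_nitrogen": "C(N)=O",
    "carbonyl_with_oxygen": "C(=O)OC",
    "thiol": "S",
    "thiocarbonyl": "C(C)=S",
    "sulfone": "S(C)(=O)=O",
    "sulfonic_acid": "S(=O)(=O)O",
    "sulfonate": "S(=O)(=O)OC",
    "sulfonamide": "S(N)(=O)=O",
    "acetylene": "C#C",
    "halogens": "Cl",
}


def default_core_smiles() -> list[str]:
    """SMILES of the 11 registered conjugated cores, in registry order."""
    return [f.smiles for f in load_fragment_library().values()]


def child_seed(root_seed: int, counter: int) -> int:
    """Derive an independent per-subtask seed from a root seed.

    Counter-based spawning keeps stages reproducible when re-run
    independently of one another.
    """
    ss = np.random.SeedSequence(root_seed, spawn_key=(counter,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class GeneratorConfig:
    """Structural parameters of the synthetic library.

    ``max_substituents`` is the per-molecule cap; the actual number is
    drawn uniformly from 0..max_substituents (clipped to the number of
    free aromatic CH positions on the chosen core).
    """

    n_molecules: int
    core_fragments: tuple[str, ...] = None
    substituent_groups: tuple[str, ...] = None
    max_substituents: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.core_fragments is None:
            object.__setattr__(self, "core_fragments", tuple(default_core_smiles()))
        else:
            object.__setattr__(self, "core_fragments", tuple(self.core_fragments))
        if self.substituent_groups is None:
            object.__setattr__(
                self, "substituent_groups", tuple(DEFAULT_SUBSTITUENTS.values())
            )
        else:
            object.__setattr__(
                self, "substituent_groups", tuple(self.substituent_groups)
            )
        if self.n_molecules < 1:
            raise ConfigurationError("n_molecules must be positive")
        if self.max_substituents < 0:
            raise ConfigurationError("max_substituents must be >= 0")
        for smi in self.core_fragments:
            if Chem.MolFromSmiles(smi) is None:
                raise ConfigurationError(f"invalid core fragment SMILES: {smi!r}")
        for smi in self.substituent_groups:
            if Chem.MolFromSmiles(smi) is None:
                raise ConfigurationError(f"invalid substituent SMILES: {smi!r}")


@dataclass(frozen=True)
class PlantedRule:
    """Group-additive linear property rule: intercept + sum(coef * count).

    Units are eV throughout (intercept, per-occurrence coefficients, and
    the Gaussian noise standard deviation).
    """

    intercept: float
    group_coefficients: Mapping[str, float]
    noise_sd: float = 0.0
    property_name: str = "homo"

    def __post_init__(self):
        object.__setattr__(
            self, "group_coefficients", dict(self.group_coefficients)
        )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not any(c != 0 for c in self.group_coefficients.values()):
            raise ConfigurationError("at least one group coefficient must be nonzero")
        known = set(load_group_library())
        unknown = set(self.group_coefficients) - known
        if unknown:
            raise ConfigurationError(
                f"unknown group name(s) in rule: {sorted(unknown)}"
            )

    def mean_value(self, group_counts: Mapping[str, int]) -> float:
        """Noise-free property value for the given group counts."""
        return self.intercept + sum(
            coef * group_counts.get(name, 0)
            for name, coef in self.group_coefficients.items()
        )


#: Default planted rule: a HOMO-like energy around -5.5 eV, lowered by
#: electron-withdrawing groups and raised by the donor amine, with 0.15 eV
#: of Gaussian scatter standing in for conformational/method noise.
DEFAULT_RULE = PlantedRule(
    intercept=-5.5,
    group_coefficients={
        "nitro": -0.45,
        "nitrile": -0.35,
        "carbonyl_with_oxygen": -0.20,
        "enamine": 0.30,
        "halogens": -0.10,
    },
    noise_sd=0.15,
)


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: canonical SMILES, properties, and annotations.

    ``family_tags`` is exactly the set of registered conjugated fragments
    contained as substructures; ``group_counts`` is the SMARTS match count
    of every library group.
    """

    id: str
    smiles: str
    properties: Mapping[str, float]
    family_tags: frozenset[str]
    group_counts: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "properties", dict(self.properties))
        object.__setattr__(self, "family_tags", frozenset(self.family_tags))
        object.__setattr__(self, "group_counts", dict(self.group_counts))


def make_record(
    mol_id: str,
    smiles: str,
    rule: PlantedRule | None = None,
    noise: float = 0.0,
) -> MoleculeRecord:
    """Annotate a SMILES string into a full record (canonicalizing it)."""
    canonical = canonicalize(smiles)
    mol = mol_from_smiles(canonical)
    counts = count_groups(mol)
    props = {}
    if rule is not None:
        props[rule.property_name] = rule.mean_value(counts) + noise
    return MoleculeRecord(
        id=mol_id,
        smiles=canonical,
        properties=props,
        family_tags=family_tags(mol),
        group_counts=counts,
    )


def _aromatic_ch_positions(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _assemble(
    core: Chem.Mol,
    sites: Sequence[int],
    substituents: Sequence[Chem.Mol],
) -> str | None:
    """Attach each substituent (via its atom 0) at the paired core site.

    Returns canonical SMILES, or None if the assembly fails sanitization.
    """
    combo = Chem.RWMol(core)
    for site, sub in zip(sites, substituents):
        offset = combo.GetNumAtoms()
        combo.InsertMol(sub)
        combo.AddBond(site, offset, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def generate_dataset(
    config: GeneratorConfig,
    rule: PlantedRule | None = None,
    id_prefix: str = "mol",
    retry_factor: int = 200,
) -> list[MoleculeRecord]:
    """Generate ``config.n_molecules`` distinct valid molecules.

    Assembly picks a random core, a random number of substituents
    (0..max_substituents) and distinct random aromatic CH attachment
    positions. Molecules are deduplicated on canonical SMILES. Property
    values follow ``rule`` (default :data:`DEFAULT_RULE`) with Gaussian
    noise drawn from a stream independent of the structural one, so the
    structural sequence is unaffected by the noise level.

    Deterministic given (config, rule). Raises
    :class:`GenerationExhaustedError` if the retry budget
    (``retry_factor * n_molecules`` attempts) is exhausted before
    ``n_molecules`` distinct molecules are found.
    """
    rule = rule if rule is not None else DEFAULT_RULE
    ss = np.random.SeedSequence(config.seed)
    struct_ss, noise_ss = ss.spawn(2)
    rng = np.random.default_rng(struct_ss)
    noise_rng = np.random.default_rng(noise_ss)

    cores = [mol_from_smiles(s, "core fragment") for s in config.core_fragments]
    core_sites = [_aromatic_ch_positions(m) for m in cores]
    subs = [mol_from_smiles(s, "substituent") for s in config.substituent_groups]

    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    budget = retry_factor * config.n_molecules
    for _ in range(budget):
        if len(records) == config.n_molecules:
            break
        ci = int(rng.integers(len(cores)))
        sites_avail = core_sites[ci]
        n_sub = int(rng.integers(config.max_substituents + 1))
        n_sub = min(n_sub, len(sites_avail))
        if n_sub > 0 and subs:
            sites = [int(i) for i in rng.choice(len(sites_avail), n_sub, replace=False)]
            sites = [sites_avail[i] for i in sites]
            chosen = [subs[int(rng.integers(len(subs)))] for _ in range(n_sub)]
        else:
            sites, chosen = [], []
        smiles = _assemble(cores[ci], sites, chosen)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        noise = float(noise_rng.normal(0.0, rule.noise_sd)) if rule.noise_sd > 0 else 0.0
        records.append(
            make_record(f"{id_prefix}_{len(records):05d}", smiles, rule, noise)
        )
    if len(records) < config.n_molecules:
        raise GenerationExhaustedError(
            f"only {len(records)} of {config.n_molecules} distinct molecules "
            f"generated within {budget} attempts; enlarge the core/substituent "
            "pools or lower n_molecules"
        )
    return records


#: Small neutral molecules containing exactly one occurrence of each
#: library group (used as deterministic positive fixtures).
_POSITIVE_FIXTURES: dict[str, str] = {
    "nitrile": "CC#N",
    "nitro": "O=[N+]([O-])c1ccccc1",
    "imine": "CC=NC",
    "enamine": "CN(C)c1ccccc1",
    "ketone": "CC(C)=O",
    "carbonyl_with_nitrogen": "CNC(C)=O",
    "carbonyl_with_oxygen": "COC(C)=O",
    "thiol": "CCS",
    "thiocarbonyl": "CC(C)=S",
    "sulfone": "CS(C)(=O)=O",
    "sulfonic_acid": "CS(=O)(=O)O",
    "sulfonate": "COS(C)(=O)=O",
    "sulfonamide": "CNS(C)(=O)=O",
    "acetylene": "CC#C",
    "halogens": "CCCl",
}


def fixture_set(rule: PlantedRule | None = None) -> list[MoleculeRecord]:
    """Deterministic fixture molecules covering every group and fragment.

    Contains, for each of the 15 library groups, one molecule with exactly
    one occurrence of that group; benzene as a universal negative fixture
    (zero matches for every group); and each of the 11 registered
    conjugated fragments as a bare molecule. Property values, when a rule
    is given, are noise-free.
    """
    records = [
        make_record(f"fixture_{name}", smi, rule)
        for name, smi in _POSITIVE_FIXTURES.items()
    ]
    records.append(make_record("fixture_benzene", "c1ccccc1", rule))
    for name, frag in load_fragment_library().items():
        records.append(make_record(f"fixture_fragment_{name}", frag.smiles, rule))
    return records


# ---------------------------------------------------------------------------
# I/O

def write_records_csv(records: Iterable[MoleculeRecord], destination) -> None:
    """Write records as CSV: id, smiles, one column per property,
    semicolon-joined family_tags."""
    records = list(records)
    prop_names = sorted({p for r in records for p in r.properties})

    def _write(fh):
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", *prop_names, "family_tags"])
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.smiles,
                    *[f"{r.properties[p]:.6f}" if p in r.properties else "" for p in prop_names],
                    ";".join(sorted(r.family_tags)),
                ]
            )

    if hasattr(destination, "write"):
        _write(destination)
    else:
        with open(destination, "w", newline="", encoding="utf-8") as fh:
            _write(fh)


def read_records_csv(source) -> list[MoleculeRecord]:
    """Read records written by :func:`write_records_csv`.

    Group counts and family tags are recomputed from the SMILES via the
    libraries, so a round-trip restores the full annotation."""
    if hasattr(source, "read"):
        rows = list(csv.reader(source.read().splitlines()))
    else:
        with open(source, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
    header = rows[0]
    prop_names = [c for c in header if c not in ("id", "smiles", "family_tags")]
    records = []
    for row in rows[1:]:
        d = dict(zip(header, row))
        props = {p: float(d[p]) for p in prop_names if d[p] != ""}
        records.append(
            MoleculeRecord(
                id=d["id"],
                smiles=d["smiles"],
                properties=props,
                family_tags=family_tags(d["smiles"]),
                group_counts=count_groups(d["smiles"]),
            )
        )
    return records


def load_config(source) -> tuple[GeneratorConfig, PlantedRule]:
    """Read a generator configuration and planted rule from a YAML file.

    Expected layout::

        generator:
          n_molecules: 1000
          max_substituents: 3
          seed: 1
          # core_fragments / substituent_groups optional (defaults used)
        rule:
          intercept: -5.5
          noise_sd: 0.15
          property_name: homo
          group_coefficients:
            nitro: -0.45
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "generator" not in doc:
        raise ConfigurationError("config file must have a 'generator' section")
    gen = dict(doc["generator"])
    config = GeneratorConfig(
        n_molecules=int(gen["n_molecules"]),
        core_fragments=tuple(gen["core_fragments"]) if "core_fragments" in gen else None,
        substituent_groups=(
            tuple(gen["substituent_groups"]) if "substituent_groups" in gen else None
        ),
        max_substituents=int(gen.get("max_substituents", 3)),
        seed=int(gen.get("seed", 0)),
    )
    if "rule" in doc:
        r = dict(doc["rule"])
        rule = PlantedRule(
            intercept=float(r["intercept"]),
            group_coefficients={k: float(v) for k, v in r["group_coefficients"].items()},
            noise_sd=float(r.get("noise_sd", 0.0)),
            property_name=str(r.get("property_name", "homo")),
        )
    else:
        rule = DEFAULT_RULE
    return config, rule
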