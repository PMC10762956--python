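"""SMARTS chemical-group library and conjugated-fragment registry.

The group library is the fixed 15-entry set of functional-group SMARTS
patterns used by the ablation probes (nitrile, nitro, imine, enamine,
ketone, the two carbonyl environments, the sulfur groups, acetylene and the
halogens). The fragment registry holds the 11 polycyclic conjugated cores
(naphthalene through perylenetetracarboxylic diimide) that define molecule
families for the "unknown molecule" holdout splits.

Both ship as two-column TSV data files so they can be inspected or swapped
without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping

from rdkit import Chem

from .errors import SmartsPatternError
from .smiles import mol_from_smiles


@dataclass(frozen=True)
class SmartsGroup:
    """A named functional group defined by a SMARTS pattern."""

    name: str
    smarts: str
    # compiled query, derived from `smarts`; excluded from equality
    query: Chem.Mol = field(compare=False, repr=False, default=None)

    def __post_init__(self):
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise SmartsPatternError(
                f"invalid SMARTS for group {self.name!r}: {self.smarts!r}"
            )
        object.__setattr__(self, "query", patt)


@dataclass(frozen=True)
class Fragment:
    """A named conjugated fragment used for family tagging and holdouts."""

    name: str
    smiles: str
    query: Chem.Mol = field(compare=False, repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "query", mol_from_smiles(self.smiles, f"fragment {self.name!r}")
        )


def _read_tsv(name: str) -> list[tuple[str, str]]:
    text = resources.files("molprobe.data").joinpath(name).read_text("utf-8")
    rows = []
    for line in text.splitlines():
        if not line.strip():
            continue
        key, value = line.split("\t", 1)
        rows.append((key, value))
    return rows


@lru_cache(maxsize=1)
def load_group_library() -> dict[str, SmartsGroup]:
    """The 15-entry functional-group SMARTS library, keyed by group name."""
    return {n: SmartsGroup(n, s) for n, s in _read_tsv("smarts_groups.tsv")}


@lru_cache(maxsize=1)
def load_fragment_library() -> dict[str, Fragment]:
    """The 11 conjugated fragments, keyed by fragment name."""
    return {n: Fragment(n, s) for n, s in _read_tsv("fragments.tsv")}


def _as_mol(molecule: str | Chem.Mol) -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    return mol_from_smiles(molecule)


def group_matches(
    molecule: str | Chem.Mol, group: SmartsGroup
) -> list[frozenset[int]]:
    """All distinct matches of ``group`` in a molecule as atom-index sets.

    Overlapping matches of the same pattern that cover the same atoms (e.g.
    a symmetric match traversed in both directions) are deduplicated by
    atom-index set; order of first occurrence is preserved. ``molecule``
    may be a SMILES string or a parsed RDKit Mol.
    """
    mol = _as_mol(molecule)
    seen: list[frozenset[int]] = []
    for match in mol.GetSubstructMatches(group.query, uniquify=True):
        s = frozenset(match)
        if s not in seen:
            seen.append(s)
    return seen


def count_groups(
    molecule: str | Chem.Mol, library: Mapping[str, SmartsGroup] | None = None
) -> dict[str, int]:
    """Number of distinct matches of every library group in a molecule."""
    library = library if library is not None else load_group_library()
    mol = _as_mol(molecule)
    return {name: len(group_matches(mol, g)) for name, g in library.items()}


def family_tags(
    molecule: str | Chem.Mol, fragments: Mapping[str, Fragment] | None = None
) -> frozenset[str]:
    """Names of all registry fragments contained in a molecule."""
    fragments = fragments if fragments is not None else load_fragment_library()
    mol = _as_mol(molecule)
    return frozenset(
        name for name, frag in fragments.items() if mol.HasSubstructMatch(frag.query)
    )
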