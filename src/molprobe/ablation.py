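"""Perturbation probes for SMILES classifiers.

Three families of perturbation are generated, all as token-level edits of
the parent string:

* single-atom ablation - every non-hydrogen, non-carbon atom is replaced,
  one at a time, by the reserved ``<missing>`` token;
* single-group ablation - every distinct SMARTS match of a functional group
  has all of its atoms replaced by ``<missing>``, one match at a time;
* random mutation - every atom of one chosen match is replaced by an
  independently drawn element from a fixed 12-element list.

Because the edits are purely lexical (bonds, ring-closure digits,
parentheses and everything outside the replaced atom tokens are untouched),
the resulting strings are generally NOT valid SMILES. They are treated as
plain text prompts throughout; validity is never claimed or repaired.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import NoMatchError
from .groups import SmartsGroup, group_matches
from .smiles import MISSING_TOKEN, mol_from_smiles, tokenize

#: Elements drawn from in the mutation probe (the heteroatoms occurring in
#: the organic-semiconductor data this pipeline emulates, plus boron).
MUTATION_ELEMENTS = ("B", "N", "O", "F", "Si", "P", "S", "Cl", "As", "Se", "Br", "I")


@dataclass(frozen=True)
class AblationVariant:
    """One perturbed SMILES string linked to its parent and edit site.

    ``site`` holds 0-based atom indices in the parent's canonical atom
    order (which coincides with atom-token reading order of the parent
    string). ``replacement`` is ``<missing>`` for ablations or the tuple of
    substituted element symbols for mutations, aligned with ``site``.
    """

    parent_id: str
    kind: str  # "atom" | "group" | "mutation"
    site: tuple[int, ...]
    group_name: str | None
    variant_text: str
    replacement: str | tuple[str, ...]


def _atom_token_positions(smiles: str) -> tuple:
    """Token sequence of ``smiles`` plus positions of its atom tokens.

    The i-th atom token corresponds to RDKit atom index i of the molecule
    parsed from the same string, because RDKit assigns indices in order of
    appearance.
    """
    seq = tokenize(smiles)
    return seq, seq.atom_positions()


def heteroatom_positions(smiles: str) -> list[tuple[int, str]]:
    """All non-hydrogen, non-carbon atoms as (atom index, element symbol).

    Aromatic lowercase atoms and bracket atoms count by their element, so
    ``[nH]`` is a nitrogen and ``[O-]`` an oxygen. Indices follow the
    atom-token reading order of the string.
    """
    mol = mol_from_smiles(smiles)
    return [
        (atom.GetIdx(), atom.GetSymbol())
        for atom in mol.GetAtoms()
        if atom.GetSymbol() not in ("C", "H")
    ]


def single_atom_variants(smiles: str, parent_id: str = "") -> list[AblationVariant]:
    """One ``<missing>``-ablated variant per heteroatom of the molecule."""
    seq, atom_pos = _atom_token_positions(smiles)
    variants = []
    for idx, element in heteroatom_positions(smiles):
        edited = seq.replaced([atom_pos[idx]], MISSING_TOKEN)
        variants.append(
            AblationVariant(
                parent_id=parent_id,
                kind="atom",
                site=(idx,),
                group_name=None,
                variant_text=edited.text,
                replacement=MISSING_TOKEN,
            )
        )
    return variants


def single_group_variants(
    smiles: str, group: SmartsGroup, parent_id: str = ""
) -> list[AblationVariant]:
    """One variant per distinct match of ``group``, ablating one match at a
    time; every atom of the match becomes its own ``<missing>`` token."""
    seq, atom_pos = _atom_token_positions(smiles)
    variants = []
    for match in group_matches(smiles, group):
        site = tuple(sorted(match))
        edited = seq.replaced([atom_pos[i] for i in site], MISSING_TOKEN)
        variants.append(
            AblationVariant(
                parent_id=parent_id,
                kind="group",
                site=site,
                group_name=group.name,
                variant_text=edited.text,
                replacement=MISSING_TOKEN,
            )
        )
    return variants


def mutate_group_variants(
    smiles: str,
    group: SmartsGroup,
    n_variants: int = 100,
    seed: int = 0,
    parent_id: str = "",
) -> list[AblationVariant]:
    """Randomly mutated variants of one functional-group occurrence.

    For each of the ``n_variants`` strings, one match of ``group`` is
    chosen (uniformly, when several exist) and every atom of that match is
    independently replaced by a uniformly random element from
    :data:`MUTATION_ELEMENTS`, written as a bare element symbol. Which
    match was mutated is recorded in ``site``. Deterministic given ``seed``.
    """
    matches = group_matches(smiles, group)
    if not matches:
        raise NoMatchError(
            f"group {group.name!r} has no match in {smiles!r}"
        )
    seq, atom_pos = _atom_token_positions(smiles)
    rng = np.random.default_rng(seed)
    variants = []
    for _ in range(n_variants):
        match = matches[int(rng.integers(len(matches)))]
        site = tuple(sorted(match))
        elements = tuple(
            MUTATION_ELEMENTS[int(rng.integers(len(MUTATION_ELEMENTS)))]
            for _ in site
        )
        mapping = {atom_pos[i]: el for i, el in zip(site, elements)}
        edited = seq.replaced(mapping.keys(), mapping)
        variants.append(
            AblationVariant(
                parent_id=parent_id,
                kind="mutation",
                site=site,
                group_name=group.name,
                variant_text=edited.text,
                replacement=elements,
            )
        )
    return variants


def write_variants_csv(variants: Iterable[AblationVariant], destination) -> None:
    """Export variants as CSV (parent_id, kind, group_name, site, variant_text)."""

    def _write(fh):
        writer = csv.writer(fh)
        writer.writerow(["parent_id", "kind", "group_name", "site", "variant_text"])
        for v in variants:
            writer.writerow(
                [
                    v.parent_id,
                    v.kind,
                    v.group_name or "",
                    ";".join(str(i) for i in v.site),
                    v.variant_text,
                ]
            )

    if hasattr(destination, "write"):
        _write(destination)
    else:
        with open(destination, "w", newline="", encoding="utf-8") as fh:
            _write(fh)
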