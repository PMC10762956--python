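"""Ablation and mutation probes, checked against independent oracles."""

import re

import numpy as np
import pytest

import molprobe as mp
from molprobe.errors import NoMatchError
from molprobe.smiles import is_atom_token

# ---------------------------------------------------------------------------
# Independent oracles (no SMARTS, no shared code paths with the probes)

_ELEMENT_RE = re.compile(r"^\[?\d*([A-Za-z][a-z]?)")


def token_scan_heteroatom_count(smiles: str) -> int:
    """Linear scan over atom tokens counting elements other than C and H."""
    count = 0
    for tok in mp.tokenize(smiles):
        if not is_atom_token(tok) or tok == "*":
            continue
        m = _ELEMENT_RE.match(tok)
        element = m.group(1)
        if element.islower() and len(element) == 1:
            element = element.upper()
        if element not in ("C", "H"):
            count += 1
    return count


def graph_scan_nitrile_count(smiles: str) -> int:
    """Count C#N units by walking the molecular graph directly."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.TRIPLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        for nitrogen, carbon in ((a, b), (b, a)):
            if (
                nitrogen.GetSymbol() == "N"
                and nitrogen.GetDegree() + nitrogen.GetTotalNumHs() == 1
                and carbon.GetSymbol() == "C"
                and carbon.GetDegree() + carbon.GetTotalNumHs() == 2
            ):
                n += 1
    return n


def graph_scan_halogen_count(smiles: str) -> int:
    """Count terminal F/Cl/Br/I atoms by walking the molecular graph."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    return sum(
        1
        for atom in mol.GetAtoms()
        if atom.GetSymbol() in ("F", "Cl", "Br", "I") and atom.GetDegree() == 1
    )


# ---------------------------------------------------------------------------


class TestHeteroatomPositions:
    def test_benzene_has_none(self):
        assert mp.heteroatom_positions("c1ccccc1") == []

    def test_ethanol_oxygen(self):
        assert mp.heteroatom_positions("CCO") == [(2, "O")]

    def test_two_oxygen_two_chlorine_one_nitrogen(self):
        # 2 O + 2 Cl + 1 N -> five single-atom ablation tests
        smiles = "OC(=O)c1cc(Cl)cc(Cl)c1N"
        positions = mp.heteroatom_positions(smiles)
        assert len(positions) == 5
        assert sorted(el for _, el in positions) == ["Cl", "Cl", "N", "O", "O"]

    def test_bracket_and_aromatic_atoms_count_by_element(self):
        positions = mp.heteroatom_positions("c1cc[nH]c1")
        assert [el for _, el in positions] == ["N"]


class TestSingleAtomVariants:
    def test_ethanol(self):
        (variant,) = mp.single_atom_variants("CCO")
        assert variant.variant_text == "CC<missing>"
        assert variant.site == (2,)
        assert variant.kind == "atom"

    def test_benzene_empty(self):
        assert mp.single_atom_variants("c1ccccc1") == []

    def test_variant_count_matches_token_scan_oracle(self, default_records):
        for r in default_records[:200]:
            assert len(mp.single_atom_variants(r.smiles)) == token_scan_heteroatom_count(
                r.smiles
            )

    def test_site_locality(self, default_records):
        for r in default_records[:30]:
            parent = mp.tokenize(r.smiles)
            for v in mp.single_atom_variants(r.smiles, r.id):
                child = mp.tokenize(v.variant_text)
                assert len(child) == len(parent)
                diffs = [i for i, (a, b) in enumerate(zip(parent, child)) if a != b]
                assert len(diffs) == len(v.site) == 1
                assert child.tokens[diffs[0]] == "<missing>"


class TestGroupVariants:
    def test_nitrile_tokens(self, group_library):
        (variant,) = mp.single_group_variants("CC#N", group_library["nitrile"])
        assert list(mp.tokenize(variant.variant_text)) == [
            "C", "<missing>", "#", "<missing>",
        ]

    def test_one_at_a_time_leaves_other_occurrence_intact(self, group_library):
        variants = mp.single_group_variants("N#CCC#N", group_library["nitrile"])
        assert len(variants) == 2
        for v in variants:
            assert "#" in v.variant_text
            assert v.variant_text.count("<missing>") == 2
            # exactly one intact nitrile remains
            assert ("C#N" in v.variant_text) or ("N#C" in v.variant_text)

    def test_three_fluorines_three_variants(self, group_library):
        variants = mp.single_group_variants(
            "FC(F)(F)c1ccccc1", group_library["halogens"]
        )
        assert len(variants) == 3

    def test_counts_match_graph_scan_oracles(self, default_records, group_library):
        for r in default_records[:200]:
            assert len(
                mp.single_group_variants(r.smiles, group_library["nitrile"])
            ) == graph_scan_nitrile_count(r.smiles)
            assert len(
                mp.single_group_variants(r.smiles, group_library["halogens"])
            ) == graph_scan_halogen_count(r.smiles)


class TestMutation:
    def test_nitrile_mutation_form(self, group_library):
        variants = mp.mutate_group_variants(
            "CC#N", group_library["nitrile"], 100, seed=4
        )
        assert len(variants) == 100
        elements = "|".join(mp.MUTATION_ELEMENTS)
        pattern = re.compile(f"^C({elements})#({elements})$")
        for v in variants:
            assert pattern.match(v.variant_text), v.variant_text
            assert v.kind == "mutation"
            assert len(v.replacement) == len(v.site) == 2

    def test_deterministic_given_seed(self, group_library):
        a = mp.mutate_group_variants("CC#N", group_library["nitrile"], 5, seed=1)
        b = mp.mutate_group_variants("CC#N", group_library["nitrile"], 5, seed=1)
        assert [v.variant_text for v in a] == [v.variant_text for v in b]

    def test_element_frequencies_uniform(self, group_library):
        variants = mp.mutate_group_variants(
            "CC#N", group_library["nitrile"], 6000, seed=0
        )
        replacements = [el for v in variants for el in v.replacement]
        assert len(replacements) == 12_000
        counts = np.array(
            [replacements.count(el) for el in mp.MUTATION_ELEMENTS]
        )
        n, p = 12_000, 1 / 12
        se = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) <= 4 * se)

    def test_no_match_raises(self, group_library):
        with pytest.raises(NoMatchError):
            mp.mutate_group_variants("c1ccccc1", group_library["nitrile"], 10, seed=0)

    def test_one_match_mutated_per_variant(self, group_library):
        variants = mp.mutate_group_variants(
            "N#CCC#N", group_library["nitrile"], 50, seed=2
        )
        sites = {v.site for v in variants}
        assert len(sites) == 2  # both matches get chosen across variants
        for v in variants:
            assert len(v.site) == 2


def test_variant_count_conservation(default_records, group_library):
    """Total variants over a dataset equals total heteroatom/match counts."""
    subset = default_records[:100]
    total_atom_variants = sum(len(mp.single_atom_variants(r.smiles)) for r in subset)
    total_heteroatoms = sum(len(mp.heteroatom_positions(r.smiles)) for r in subset)
    assert total_atom_variants == total_heteroatoms

    group = group_library["nitro"]
    total_group_variants = sum(
        len(mp.single_group_variants(r.smiles, group)) for r in subset
    )
    total_matches = sum(len(mp.group_matches(r.smiles, group)) for r in subset)
    assert total_group_variants == total_matches


def test_variants_csv_export(tmp_path, group_library):
    variants = mp.single_group_variants("CC#N", group_library["nitrile"], "m1")
    path = tmp_path / "variants.csv"
    mp.ablation.write_variants_csv(variants, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "parent_id,kind,group_name,site,variant_text"
    assert lines[1].startswith("m1,group,nitrile,")
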