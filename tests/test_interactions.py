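"""Interaction detectors: boundary behavior, oracle equivalence,
planted-interaction recovery and structural invariants."""

import numpy as np
import pytest

from thermofold.interactions import (
    CATEGORIES,
    InteractionConfig,
    find_aromatic_aromatic,
    find_aromatic_sulfur,
    find_cation_pi,
    find_disulfide,
    find_hbonds,
    find_hydrophobic,
    find_ionic,
    summarize_interactions,
)
from thermofold.structure_io import Structure, parse_structure
from thermofold.synthetic import (
    PlantedStructureSpec,
    make_ideal_helix,
    make_paired_structures,
    make_planted_structure,
)

from conftest import make_residue, make_structure, oracle_hbond_pairs, oracle_pairs

CFG = InteractionConfig()


def hexagon(center, z=0.0, radius=1.39):
    pts = {}
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    for k, n in enumerate(names):
        ang = np.pi * k / 3.0
        pts[n] = (center[0] + radius * np.cos(ang),
                  center[1] + radius * np.sin(ang), center[2] + z)
    return pts


def phe(seq_id, center):
    atoms = {"CA": (center[0], center[1] - 4.0, center[2])}
    atoms.update(hexagon(center))
    return make_residue("F", "PHE", seq_id, atoms)


class TestIonic:
    def test_pair_below_cutoff_detected(self, lys_glu_pair):
        found = find_ionic(lys_glu_pair(3.5), CFG)
        assert len(found) == 1
        assert found[0].distance == pytest.approx(3.5)

    def test_pair_above_cutoff_rejected(self, lys_glu_pair):
        assert find_ionic(lys_glu_pair(6.5), CFG) == []

    def test_boundary_inclusive(self, lys_glu_pair):
        assert len(find_ionic(lys_glu_pair(6.0), CFG)) == 1

    def test_minimal_atom_distance_reported_once_per_pair(self):
        arg = make_residue("R", "ARG", "1", {
            "CA": (0, 0, 9), "NH1": (0, 0, 5.9), "NH2": (0.9, 0, 6.4), "NE": (0, 1, 8)})
        asp = make_residue("D", "ASP", "30", {
            "CA": (3, 0, 0), "OD1": (20, 0, 0), "OD2": (0, 0, 0)})
        s = make_structure([arg, asp])
        found = find_ionic(s, CFG)
        assert len(found) == 1
        assert found[0].distance == pytest.approx(5.9)

    def test_missing_sidechain_atoms_skipped(self):
        lys = make_residue("K", "LYS", "1", {"CA": (0, 0, 0)})  # no NZ
        glu = make_residue("E", "GLU", "20", {"CA": (3, 0, 0), "OE1": (1, 0, 0)})
        assert find_ionic(make_structure([lys, glu]), CFG) == []


class TestAromaticAromatic:
    @pytest.mark.parametrize("d, expected", [(5.5, 1), (4.0, 0), (7.5, 0),
                                             (4.5, 1), (7.0, 1)])
    def test_centroid_window(self, d, expected):
        s = make_structure([phe("1", (0, 0, 0)), phe("21", (0, 0, d))])
        assert len(find_aromatic_aromatic(s, CFG)) == expected

    def test_incomplete_ring_skipped(self):
        broken = make_residue("F", "PHE", "1", {"CA": (0, 0, 0), "CG": (1, 0, 0)})
        s = make_structure([broken, phe("21", (0, 0, 5.5))])
        assert find_aromatic_aromatic(s, CFG) == []


class TestCationPi:
    @pytest.mark.parametrize("d, expected", [(4.8, 1), (6.2, 0)])
    def test_lys_nz_to_centroid(self, d, expected):
        lys = make_residue("K", "LYS", "1", {"CA": (5, 5, d), "NZ": (0, 0, d)})
        s = make_structure([lys, phe("21", (0, 0, 0))])
        assert len(find_cation_pi(s, CFG)) == expected

    def test_arg_cz_reference(self):
        arg = make_residue("R", "ARG", "1", {"CA": (4, 4, 5), "CZ": (0, 0, 5)})
        s = make_structure([arg, phe("21", (0, 0, 0))])
        found = find_cation_pi(s, CFG)
        assert len(found) == 1 and found[0].distance == pytest.approx(5.0)


class TestAromaticSulfur:
    def test_met_sd_within_cutoff(self):
        met = make_residue("M", "MET", "1", {"CA": (4, 0, 4.9), "SD": (0, 0, 4.9)})
        s = make_structure([met, phe("21", (0, 0, 0))])
        found = find_aromatic_sulfur(s, CFG)
        assert len(found) == 1 and found[0].distance == pytest.approx(4.9)

    def test_strictly_above_cutoff_rejected(self):
        cys = make_residue("C", "CYS", "1", {"CA": (4, 0, 5.31), "SG": (0, 0, 5.31)})
        s = make_structure([cys, phe("21", (0, 0, 0))])
        assert find_aromatic_sulfur(s, CFG) == []

    def test_no_sulfur_residues_empty(self):
        s = make_structure([phe("1", (0, 0, 0)), phe("21", (0, 0, 5.5))])
        assert find_aromatic_sulfur(s, CFG) == []


class TestDisulfide:
    @pytest.mark.parametrize("d, expected", [(2.05, 1), (3.5, 0)])
    def test_sg_sg_distance(self, d, expected):
        c1 = make_residue("C", "CYS", "1", {"CA": (2, 0, 0), "SG": (0, 0, 0)})
        c2 = make_residue("C", "CYS", "30", {"CA": (2, 0, d), "SG": (0, 0, d)})
        assert len(find_disulfide(make_structure([c1, c2]), CFG)) == expected

    def test_three_cysteines_no_double_counting(self):
        # 1-2 bonded, 3 isolated: exactly one bond, each SG pair counted once
        c1 = make_residue("C", "CYS", "1", {"SG": (0, 0, 0)})
        c2 = make_residue("C", "CYS", "10", {"SG": (0, 0, 2.05)})
        c3 = make_residue("C", "CYS", "20", {"SG": (0, 0, 30.0)})
        found = find_disulfide(make_structure([c1, c2, c3]), CFG)
        assert len(found) == 1


class TestHbonds:
    def test_helix_has_mc_mc_bonds(self):
        s = parse_structure(make_ideal_helix(12), "helix")
        cats = {it.category for it in find_hbonds(s, CFG)}
        assert "hbond_mc_mc" in cats

    def test_ser_asp_sc_sc(self):
        ser = make_residue("S", "SER", "1", {"CA": (2, 0, 0), "OG": (0, 0, 0)})
        asp = make_residue("D", "ASP", "20", {"CA": (2, 0, 2.8), "OD1": (0, 0, 2.8),
                                              "OD2": (1.5, 1.5, 4.0)})
        found = find_hbonds(make_structure([ser, asp]), CFG)
        assert [it.category for it in found] == ["hbond_sc_sc"]
        assert found[0].distance == pytest.approx(2.8)

    def test_adjacent_mc_mc_excluded(self):
        r1 = make_residue("A", "ALA", "1", {"N": (0, 0, 0), "O": (1.2, 0, 0)})
        r2 = make_residue("A", "ALA", "2", {"N": (1.2, 0, 2.3), "O": (3.0, 0, 2.3)})
        found = [it for it in find_hbonds(make_structure([r1, r2]), CFG)
                 if it.category == "hbond_mc_mc"]
        assert found == []

    def test_salt_bridge_pair_not_reported_as_hbond(self, lys_glu_pair):
        s = lys_glu_pair(3.4)
        assert find_ionic(s, CFG)
        assert all(it.category.startswith("hbond") is False
                   for it in find_hbonds(s, CFG))


class TestHydrophobic:
    def build(self, d, seq_b="20"):
        leu = make_residue("L", "LEU", "1", {"CA": (3, 0, 0), "CD1": (0, 0, 0)})
        val = make_residue("V", "VAL", seq_b, {"CA": (3, 0, d), "CG1": (0, 0, d)})
        return make_structure([leu, val])

    @pytest.mark.parametrize("d, expected", [(4.2, 1), (5.6, 0)])
    def test_carbon_contact(self, d, expected):
        assert len(find_hydrophobic(self.build(d), CFG)) == expected

    def test_sequence_adjacent_pair_excluded(self):
        assert find_hydrophobic(self.build(4.2, seq_b="2"), CFG) == []


class TestSummarize:
    def test_normalized_counts_are_counts_over_length(self):
        spec = PlantedStructureSpec(
            residues=["K", "E", "F", "F"],
            planted_interactions=[("ionic", (0, 1), 3.5),
                                  ("aromatic_aromatic", (2, 3), 5.5)])
        s = parse_structure(make_planted_structure(spec), "p")
        iset = summarize_interactions(s, CFG)
        assert iset.residue_count == 4
        for cat in CATEGORIES:
            n = iset.normalized_counts[cat] * iset.residue_count
            assert n == pytest.approx(round(n))
        assert iset.counts["ionic"] == 1
        assert iset.normalized_counts["ionic"] == pytest.approx(0.25)

    def test_empty_structure_all_zero(self):
        gly = make_residue("G", "GLY", "1", {"CA": (0, 0, 0)})
        iset = summarize_interactions(make_structure([gly]), CFG)
        assert all(v == 0 for v in iset.counts.values())


PLANT_BATTERY = [
    ("ionic", 3.5, ["K", "E"]),
    ("ionic", 5.9, ["R", "D"]),
    ("ionic", 4.5, ["H", "E"]),
    ("aromatic_aromatic", 5.5, ["F", "Y"]),
    ("aromatic_aromatic", 6.9, ["W", "F"]),
    ("cation_pi", 4.8, ["K", "Y"]),
    ("cation_pi", 5.0, ["R", "W"]),
    ("aromatic_sulfur", 4.9, ["M", "F"]),
    ("aromatic_sulfur", 5.0, ["C", "Y"]),
    ("disulfide", 2.05, ["C", "C"]),
    ("hydrophobic", 4.2, ["L", "V"]),
    ("hydrophobic", 4.8, ["I", "A"]),
    ("hbond_sc_sc", 2.8, ["S", "D"]),
]


@pytest.mark.parametrize("cat, target, aas", PLANT_BATTERY,
                         ids=[f"{c}-{'-'.join(a)}" for c, _, a in PLANT_BATTERY])
def test_planted_interaction_recovered_exactly(cat, target, aas):
    spec = PlantedStructureSpec(residues=aas,
                                planted_interactions=[(cat, (0, 1), target)])
    s = parse_structure(make_planted_structure(spec), "p")
    iset = summarize_interactions(s, CFG)
    nonzero = {c for c, v in iset.counts.items() if v}
    assert nonzero == {cat}
    assert iset.counts[cat] == 1


def _battery_structures():
    structures = []
    for cat, target, aas in PLANT_BATTERY:
        spec = PlantedStructureSpec(residues=aas,
                                    planted_interactions=[(cat, (0, 1), target)])
        structures.append(parse_structure(make_planted_structure(spec), "p"))
    a, b, _ = make_paired_structures(n_residues=30, seed=7, noise_sd=0.1,
                                     identity_target=0.7)
    structures.append(parse_structure(a, "pa"))
    structures.append(parse_structure(b, "pb"))
    structures.append(parse_structure(make_ideal_helix(12), "helix"))
    return structures


def test_detectors_match_bruteforce_oracle_on_small_structures():
    """Every detector equals an exhaustive all-pairs scan (residue-pair level)."""
    finders = {"ionic": find_ionic, "aromatic_aromatic": find_aromatic_aromatic,
               "cation_pi": find_cation_pi, "aromatic_sulfur": find_aromatic_sulfur,
               "disulfide": find_disulfide, "hydrophobic": find_hydrophobic}
    for s in _battery_structures():
        assert s.length <= 50
        for cat, fn in finders.items():
            got = {frozenset(((it.partner_a[0], it.partner_a[1]),
                              (it.partner_b[0], it.partner_b[1])))
                   for it in fn(s, CFG)}
            assert got == oracle_pairs(s, cat, CFG), (s.id, cat)
        want_hb = oracle_hbond_pairs(s, CFG)
        hb = find_hbonds(s, CFG)
        for cat in ("hbond_mc_mc", "hbond_mc_sc", "hbond_sc_sc"):
            got = {frozenset(((it.partner_a[0], it.partner_a[1]),
                              (it.partner_b[0], it.partner_b[1])))
                   for it in hb if it.category == cat}
            assert got == want_hb[cat], (s.id, cat)


def test_detectors_invariant_to_residue_order_reversal():
    a, b, _ = make_paired_structures(n_residues=30, seed=11, noise_sd=0.1)
    s = parse_structure(a, "fwd")
    rev = Structure(id="rev", chains={"A": list(reversed(s.chains["A"]))})
    fwd_set = {(it.category, it.residue_pair(), round(it.distance, 9))
               for it in summarize_interactions(s, CFG).interactions}
    rev_set = {(it.category, it.residue_pair(), round(it.distance, 9))
               for it in summarize_interactions(rev, CFG).interactions}
    assert fwd_set == rev_set


def test_cutoff_monotonicity():
    """Enlarging any cutoff never decreases the corresponding count."""
    a, _, _ = make_paired_structures(n_residues=40, seed=13, noise_sd=0.1)
    s = parse_structure(a, "mono")
    grown = {
        "ionic": ("ionic_cutoff", 8.0), "cation_pi": ("cation_pi_cutoff", 8.0),
        "aromatic_sulfur": ("aromatic_sulfur_cutoff", 7.0),
        "disulfide": ("disulfide_cutoff", 4.0),
        "hydrophobic": ("hydrophobic_cutoff", 6.5),
        "aromatic_aromatic": ("aromatic_max", 9.0),
    }
    base = summarize_interactions(s, CFG).counts
    for cat, (field, value) in grown.items():
        cfg2 = InteractionConfig(**{field: value})
        assert summarize_interactions(s, cfg2).counts[cat] >= base[cat], cat
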