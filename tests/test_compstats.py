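"""Composition profiles, t-tests against a high-precision oracle, and the
significance screens on planted cohorts."""

import numpy as np
import pytest

from thermofold.compstats import (
    CompositionProfile,
    EnvironmentProfile,
    composition_profile,
    environment_preference_screen,
    environment_profile,
    significance_screen,
    t_test_unpaired,
)
from thermofold.environment import ResidueEnvironment
from thermofold.synthetic import CohortSpec, make_cohort

from conftest import welch_p_highprec


class TestCompositionProfile:
    def test_single_amino_acid(self):
        p = composition_profile("AAAA")
        assert p.freq["A"] == 1.0
        assert sum(v for k, v in p.freq.items() if k != "A") == 0.0

    def test_uniform_four(self):
        p = composition_profile("ACDE")
        for aa in "ACDE":
            assert p.freq[aa] == 0.25

    def test_length_normalization(self):
        seq = "R" * 10 + "A" * 90
        p = composition_profile(seq)
        assert p.freq["R"] == pytest.approx(0.10)
        assert p.length == 100

    def test_x_removed_before_normalizing(self):
        p = composition_profile("AXXA")
        assert p.freq["A"] == 1.0 and p.length == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            composition_profile("XXX")

    def test_frequencies_sum_to_one_validated(self):
        with pytest.raises(ValueError):
            CompositionProfile("bad", {"A": 0.7}, 10)


class TestTTest:
    def test_identical_lists_give_p_one(self):
        a = [0.05, 0.06, 0.055]
        t, df, p = t_test_unpaired(a, a)
        assert t == 0.0 and p == 1.0

    def test_welch_matches_high_precision_oracle(self):
        a = [0.05, 0.06, 0.055]
        b = [0.03, 0.035, 0.032]
        _, _, p = t_test_unpaired(a, b, variant="welch")
        assert p == pytest.approx(welch_p_highprec(a, b), abs=1e-10)

    def test_oracle_agreement_on_random_samples(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            na, nb = rng.integers(3, 9, size=2)
            a = rng.normal(0.0, 1.0, na)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2.0), nb)
            _, _, p = t_test_unpaired(a, b, variant="welch")
            assert p == pytest.approx(welch_p_highprec(a, b), abs=1e-10)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=5), rng.normal(1.0, 2.0, size=7)
        t1, _, p1 = t_test_unpaired(a, b)
        t2, _, p2 = t_test_unpaired(b, a)
        assert p1 == pytest.approx(p2)
        assert t1 == pytest.approx(-t2)

    def test_pooled_variant_df(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0]
        _, df, _ = t_test_unpaired(a, b, variant="pooled")
        assert df == 5.0

    def test_zero_variance_degenerate(self):
        t, _, p = t_test_unpaired([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0
        _, _, p = t_test_unpaired([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test_unpaired([1.0], [1.0, 2.0])


class TestSignificanceScreen:
    def test_planted_arg_effect_detected(self):
        th, me, truth = make_cohort(CohortSpec(n_thermo=8, n_meso=8,
                                               effects={"R": 0.03}, seed=5))
        assert truth["R"] == 0.03
        table = significance_screen(th, me)
        row = table[table["feature"] == "R"].iloc[0]
        assert row["significant"]
        assert row["enriched_in"] == "thermophile"

    def test_identical_profiles_nothing_significant(self):
        th, _, _ = make_cohort(CohortSpec(n_thermo=4, n_meso=4, seed=6))
        table = significance_screen(th, list(th))
        assert not table["significant"].any()
        assert set(table["enriched_in"]) == {"none"}

    def test_order_invariance_within_groups(self):
        th, me, _ = make_cohort(CohortSpec(n_thermo=5, n_meso=5, seed=7))
        t1 = significance_screen(th, me)
        t2 = significance_screen(list(reversed(th)), list(reversed(me)))
        assert np.allclose(t1["p_value"], t2["p_value"])

    def test_absent_feature_flagged_p_one(self):
        def flat(sid):
            return CompositionProfile(sid, {"A": 0.5, "G": 0.5, "W": 0.0}, 10)
        table = significance_screen([flat("t1"), flat("t2")],
                                    [flat("m1"), flat("m2")], features=["W"])
        row = table.iloc[0]
        assert row["p_value"] == 1.0 and row["flag"] == "absent_in_all"

    def test_power_monotone_in_effect_size(self):
        """Detection rate is non-decreasing over three planted effect sizes."""
        rates = []
        for effect in (0.005, 0.015, 0.03):
            hits = 0
            for rep in range(200):
                th, me, _ = make_cohort(CohortSpec(
                    n_thermo=8, n_meso=8, effects={"R": effect}, seed=50_000 + rep))
                table = significance_screen(th, me, features=["R"])
                hits += bool(table.iloc[0]["significant"])
            rates.append(hits / 200)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]

    def test_family_averaged_mode_runs(self):
        th, me, _ = make_cohort(CohortSpec(n_thermo=6, n_meso=6, seed=8,
                                           n_families=3))
        table = significance_screen(th, me, aggregate="family_averaged")
        assert (table["n_thermo"] == 3).all()


def _env_profile(sid, aa_class_fracs):
    """aa_class_fracs: {(aa, ss3 class): frac}; acc left uniform."""
    p = EnvironmentProfile(structure_id=sid)
    p.ss3 = dict(aa_class_fracs)
    for aa in {a for a, _ in aa_class_fracs}:
        p.acc = {**p.acc, (aa, "buried"): 0.3, (aa, "intermediate"): 0.4,
                 (aa, "exposed"): 0.3}
    return p


class TestEnvironmentPreferenceScreen:
    def test_planted_sheet_preference_detected(self):
        # thermophiles carry Pro only in sheets, mesophiles only in loops
        th = [_env_profile(f"t{i}", {("P", "sheet"): 1.0 - 0.01 * i,
                                     ("P", "loop"): 0.01 * i,
                                     ("P", "helix"): 0.0}) for i in range(4)]
        me = [_env_profile(f"m{i}", {("P", "sheet"): 0.01 * i,
                                     ("P", "loop"): 1.0 - 0.01 * i,
                                     ("P", "helix"): 0.0}) for i in range(4)]
        table = environment_preference_screen(th, me, focus_aas=["P"])
        sheet = table[(table["aa"] == "P") & (table["class"] == "sheet")].iloc[0]
        assert sheet["significant"] and sheet["enriched_in"] == "thermophile"
        loop = table[(table["aa"] == "P") & (table["class"] == "loop")].iloc[0]
        assert loop["enriched_in"] == "mesophile"

    def test_empty_focus_list_gives_empty_table(self):
        table = environment_preference_screen([], [], focus_aas=[])
        assert len(table) == 0

    def test_identical_groups_nothing_significant(self):
        profs = [_env_profile(f"p{i}", {("A", "helix"): 0.5 + 0.01 * i,
                                        ("A", "sheet"): 0.5 - 0.01 * i,
                                        ("A", "loop"): 0.0}) for i in range(4)]
        table = environment_preference_screen(profs, list(profs), focus_aas=["A"])
        assert not table["significant"].any()

    def test_protein_missing_aa_omitted_from_row(self):
        th = [_env_profile(f"t{i}", {("W", "helix"): 1.0, ("W", "sheet"): 0.0,
                                     ("W", "loop"): 0.0}) for i in range(3)]
        me = [_env_profile(f"m{i}", {("W", "helix"): 0.5, ("W", "sheet"): 0.5,
                                     ("W", "loop"): 0.0}) for i in range(2)]
        me.append(EnvironmentProfile(structure_id="no_trp"))  # lacks W entirely
        table = environment_preference_screen(th, me, focus_aas=["W"])
        helix = table[(table["aa"] == "W") & (table["class"] == "helix")].iloc[0]
        assert helix["n_meso"] == 2


class TestEnvironmentProfileBuilder:
    def test_fractions_sum_to_one_per_amino_acid(self):
        envs = [
            ResidueEnvironment(("A", "1", "L"), "H", "helix", 10.0, 0.05, "buried"),
            ResidueEnvironment(("A", "2", "L"), "E", "sheet", 80.0, 0.40, "exposed"),
            ResidueEnvironment(("A", "3", "G"), " ", "loop", 50.0, 0.48, "exposed"),
            ResidueEnvironment(("A", "4", "X"), " ", "loop", 50.0, None, None),
        ]
        p = environment_profile(envs, "s")
        assert sum(v for (aa, _), v in p.ss3.items() if aa == "L") == pytest.approx(1.0)
        assert sum(v for (aa, _), v in p.acc.items() if aa == "L") == pytest.approx(1.0)
        assert p.ss3[("L", "helix")] == 0.5
        assert not any(aa == "X" for aa, _ in p.ss3)
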