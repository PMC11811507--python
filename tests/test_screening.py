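"""Statistical engine: rank tests, BH adjustment, panel screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bh_formula_oracle, ks_enumeration_oracle, mw_enumeration_oracle
from metaboreg.errors import ConfigurationError
from metaboreg.profiles import MetaboliteProfileSet
from metaboreg.screening import (
    bh_adjust,
    ks_two_sample,
    mann_whitney,
    screen_panel,
)


class TestMannWhitney:
    @pytest.mark.parametrize(
        "x, y, u_expected, p_expected",
        [
            # fully separated samples: U=0, 2/20 of assignments as extreme
            ([1, 2, 3], [4, 5, 6], 0.0, 0.1),
            # U at the null centre: two-sided p caps at 1
            ([1, 4], [2, 3], 2.0, 1.0),
        ],
    )
    def test_exact_small_sample_values(self, x, y, u_expected, p_expected):
        res = mann_whitney(x, y)
        assert res.method == "exact"
        assert res.statistic == pytest.approx(u_expected)
        assert res.pvalue == pytest.approx(p_expected, abs=1e-12)

    def test_degenerate_all_identical(self):
        res = mann_whitney([3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.degenerate
        assert res.pvalue == 1.0

    def test_ties_fall_back_to_asymptotic(self):
        res = mann_whitney([1, 2, 2, 3], [2, 4, 5, 6])
        assert res.method == "asymptotic"
        assert 0 <= res.pvalue <= 1

    def test_too_few_observations_rejected(self):
        with pytest.raises(ConfigurationError):
            mann_whitney([1.0], [2.0, 3.0])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n1, n2 = rng.integers(2, 7, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(loc=rng.normal(), size=n2)
            u_o, p_o = mw_enumeration_oracle(x, y)
            res = mann_whitney(x, y)
            assert res.statistic == pytest.approx(u_o)
            assert res.pvalue == pytest.approx(p_o, abs=1e-12)


class TestKolmogorovSmirnov:
    def test_identical_samples_have_zero_distance(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0

    def test_disjoint_supports_have_unit_distance(self):
        res = ks_two_sample([1, 2], [3, 4])
        assert res.statistic == 1.0

    def test_interleaved_thirds(self):
        d_o, p_o = ks_enumeration_oracle([1, 3, 5], [2, 4, 6])
        res = ks_two_sample([1, 3, 5], [2, 4, 6])
        assert res.statistic == pytest.approx(1 / 3)
        assert d_o == pytest.approx(1 / 3)
        assert res.pvalue == pytest.approx(p_o, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n1, n2 = rng.integers(2, 7, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(loc=rng.normal(), size=n2)
            d_o, p_o = ks_enumeration_oracle(x, y)
            res = ks_two_sample(x, y)
            assert res.statistic == pytest.approx(d_o, abs=1e-12)
            assert res.pvalue == pytest.approx(p_o, abs=1e-12)


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([0.02], [0.02]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.0, 0.0, 0.0], [0.0, 0.0, 0.0]),
        ],
    )
    def test_step_up_examples(self, raw, expected):
        assert bh_adjust(raw) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigurationError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ConfigurationError):
            bh_adjust([-0.1])

    def test_matches_formula_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), bh_formula_oracle(p),
                                       atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_permutation_invariance_and_bounds(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-12)


def _panel_with_shifts(effect_a, effect_b, n_mets=6, shift=3.0, cv=0.2, seed=5):
    rng = np.random.default_rng(seed)
    mets = [f"Met{i}" for i in range(n_mets)]
    sizes = {"diseaseA": 9, "diseaseB": 9, "control": 17}
    rows, sample_ids, groups = [], [], []
    for g, n in sizes.items():
        for k in range(n):
            mu = np.zeros(n_mets)
            if g == "diseaseA":
                mu[list(effect_a)] = shift
            elif g == "diseaseB":
                mu[list(effect_b)] = shift
            rows.append(np.exp(mu + cv * rng.normal(size=n_mets)))
            sample_ids.append(f"{g}{k}")
            groups.append(g)
    conc = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"),
                        columns=mets)
    classes = pd.Series("amino_acid", index=conc.columns)
    return MetaboliteProfileSet(conc, pd.Series(groups, index=conc.index),
                                classes)


class TestScreenPanel:
    def test_planted_shifts_classified_specific_and_shared(self):
        """m0 planted in A only, m1 in both, m2 in B only."""
        panel = _panel_with_shifts(effect_a=[0, 1], effect_b=[1, 2])
        res = screen_panel(panel)
        assert res.classified("A_specific") == ["Met0"]
        assert res.classified("shared") == ["Met1"]
        assert res.classified("B_specific") == ["Met2"]

    def test_classification_partitions_metabolites(self):
        panel = _panel_with_shifts(effect_a=[0], effect_b=[0, 2])
        res = screen_panel(panel)
        labels = res.classification
        assert set(labels.index) == set(panel.metabolite_ids)
        assert set(labels.unique()) <= {"A_specific", "B_specific", "shared", "none"}

    def test_adjusted_p_dominates_raw(self):
        panel = _panel_with_shifts(effect_a=[0], effect_b=[1])
        t = screen_panel(panel).table
        assert (t["mw_p_adj"] >= t["mw_p"] - 1e-15).all()
        assert (t["ks_p_adj"] >= t["ks_p"] - 1e-15).all()
        assert (t["mw_p_adj"] <= 1).all() and (t["ks_p_adj"] <= 1).all()

    def test_rule_either_is_at_least_as_permissive_as_both(self):
        panel = _panel_with_shifts(effect_a=[0, 1], effect_b=[2])
        both = set(screen_panel(panel, rule="both").significant("diseaseA"))
        either = set(screen_panel(panel, rule="either").significant("diseaseA"))
        assert both <= either

    def test_missing_control_group_rejected(self):
        panel = _panel_with_shifts(effect_a=[0], effect_b=[1])
        no_ctrl = MetaboliteProfileSet(
            panel.concentrations[panel.groups != "control"],
            panel.groups[panel.groups != "control"],
            panel.classes,
        )
        with pytest.raises(ConfigurationError, match="control"):
            screen_panel(no_ctrl)

    def test_missing_values_excluded_pairwise(self):
        panel = _panel_with_shifts(effect_a=[0], effect_b=[1])
        conc = panel.concentrations.copy()
        conc.iloc[0, 0] = np.nan
        panel2 = MetaboliteProfileSet(conc, panel.groups, panel.classes)
        res = screen_panel(panel2)
        assert np.isfinite(
            res.table.loc[res.table["metabolite"] == "Met0", "mw_p"]
        ).all()
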