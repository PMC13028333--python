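"""Test selection, omnibus statistics, effect sizes and post-hoc procedures."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

import kinanthro as ka
from kinanthro.groupstats import DegenerateDataError


def _normal_groups(rng, k=7, n=25, mean=0.0, sd=1.0):
    return {f"g{i}": rng.normal(mean, sd, n) for i in range(k)}


class TestSelectTest:
    def test_all_normal_homoscedastic_gives_anova(self):
        rng = np.random.default_rng(11)
        sel = ka.select_test(_normal_groups(rng))
        assert sel.test == "anova"
        assert sel.levene_p is not None

    def test_exponential_group_gives_kruskal(self):
        rng = np.random.default_rng(11)
        groups = _normal_groups(rng, k=6)
        groups["skewed"] = rng.exponential(1.0, 40)
        assert ka.select_test(groups).test == "kruskal_wallis"

    def test_heteroscedastic_normals_give_welch(self):
        rng = np.random.default_rng(11)
        groups = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40),
                  "c": rng.normal(0, 10, 40)}
        assert ka.select_test(groups).test == "welch"

    def test_tiny_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            ka.select_test({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0, 4.0]})


class TestOmnibus:
    def test_eta_squared_matches_hand_sums_of_squares(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        # grand mean 3.5; SSB = 3*1.5^2*2 = 13.5; SST = 17.5
        assert ka.eta_squared(groups) == pytest.approx(13.5 / 17.5, rel=1e-14)

    def test_f_conversion_identity(self):
        assert ka.eta_squared_from_f_effect(1.0) == pytest.approx(0.5)

    def test_eta_squared_from_ss_equals_f_route(self):
        """SS-based eta^2 equals the Cohen-f conversion via the sample F."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            groups = {f"g{i}": rng.normal(rng.normal(), 1.0, rng.integers(5, 30))
                      for i in range(4)}
            es = ka.eta_squared(groups)
            n = sum(len(v) for v in groups.values())
            g = len(groups)
            f_stat, _, _ = ka.omnibus(groups, "anova")
            f2 = f_stat * (g - 1) / (n - g)  # sample Cohen's f^2
            assert es == pytest.approx(ka.eta_squared_from_f_effect(np.sqrt(f2)),
                                       abs=1e-12)

    def test_identical_groups_zero_effect(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        _, p, es = ka.omnibus(groups, "anova")
        assert es == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_constant_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            ka.omnibus({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]}, "anova")

    def test_epsilon_squared_bounds_and_maximal_at_separation(self):
        """epsilon^2 stays in [0, 1] and, over every assignment of the pooled
        sample into the given block sizes, is maximized by perfect rank
        separation (brute force, n = 6)."""
        values = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
        sizes = (2, 2, 2)
        best = None
        separated = None
        seen = set()
        for perm in permutations(values):
            if perm in seen:
                continue
            seen.add(perm)
            groups = {"a": perm[0:2], "b": perm[2:4], "c": perm[4:6]}
            h, _, es = ka.omnibus(groups, "kruskal_wallis")
            assert 0.0 <= es <= 1.0
            if best is None or es > best:
                best = es
            if perm == values:
                separated = es
        assert separated == pytest.approx(best, abs=1e-12)


class TestEffectLabel:
    @pytest.mark.parametrize("value,label", [
        (0.621, "large"), (0.188, "large"), (0.07, "medium"), (0.005, "small"),
    ])
    def test_threshold_labels(self, value, label):
        assert ka.effect_label(value) == label


class TestGamesHowell:
    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 30)
        p = ka.games_howell({"a": x, "b": x.copy()})
        assert p.loc["a", "b"] > 0.99

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(3)
        p = ka.games_howell({"a": rng.normal(0, 1, 30), "b": rng.normal(5, 1, 30)})
        assert p.loc["a", "b"] < 0.001

    def test_symmetric_in_pair_order(self):
        rng = np.random.default_rng(3)
        groups = _normal_groups(rng, k=4, n=15)
        p = ka.games_howell(groups)
        assert np.allclose(p.to_numpy(), p.to_numpy().T)

    def test_matches_reference_implementation(self):
        """Agree with the pingouin Games-Howell p-values on random data."""
        import pingouin as pg
        import pandas as pd

        rng = np.random.default_rng(8)
        groups = {"a": rng.normal(0, 1, 20), "b": rng.normal(0.8, 2, 25),
                  "c": rng.normal(-0.5, 0.5, 15)}
        mine = ka.games_howell(groups)
        long = pd.DataFrame({
            "value": np.concatenate(list(groups.values())),
            "group": np.repeat(list(groups), [len(v) for v in groups.values()]),
        })
        ref = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        for row in ref.itertuples():
            assert mine.loc[row.A, row.B] == pytest.approx(row.pval, abs=1e-8)


class TestDunn:
    def test_identical_trio_nonsignificant(self):
        x = np.arange(1.0, 16.0)
        p = ka.dunn({"a": x, "b": x.copy(), "c": x.copy()})
        assert (p.to_numpy() > 0.9).all()

    def test_separated_trio_significant(self):
        p = ka.dunn({"a": np.arange(10.0), "b": np.arange(20.0, 30.0),
                     "c": np.arange(40.0, 50.0)})
        assert p.to_numpy()[np.triu_indices(3, 1)].min() < 0.01

    def test_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(4)
        groups = _normal_groups(rng, k=4, n=12)
        raw = ka.dunn(groups, adjust="none")
        holm = ka.dunn(groups, adjust="holm")
        assert (holm.to_numpy() >= raw.to_numpy() - 1e-12).all()


class TestCompareAll:
    def test_synthetic_cohort_reproduces_positional_pattern(self, cohort189):
        """Body mass separates positions with a large effect and offensive
        linemen on top; the cormic index does not separate them."""
        df = cohort189.to_dataframe()
        body = ka.compare_all(df, ["body_mass"])[0]
        assert body.p_value < 0.05
        assert body.effect_label == "large"
        assert max(body.group_means, key=body.group_means.get) == "OL"
        assert body.ordering.startswith("OL")
        assert body.posthoc_method in ("games_howell", "dunn")

        idx = ka.index_table(cohort189)
        cormic = ka.compare_all(idx, ["cormic"])[0]
        assert cormic.p_value > 0.05
        assert cormic.effect_label == "small"
        assert cormic.ordering == "ns"

    def test_null_single_distribution_not_significant(self):
        rng = np.random.default_rng(12)
        df = None
        import pandas as pd
        df = pd.DataFrame({
            "position": np.repeat(list("ABCDEFG"), 25),
            "v": rng.normal(50, 5, 175),
        })
        comp = ka.compare_all(df, ["v"])[0]
        assert comp.p_value > 0.05
        assert comp.ordering == "ns"

    def test_posthoc_matches_test_family(self, cohort189):
        df = cohort189.to_dataframe()
        for comp in ka.compare_all(df, ["body_mass", "stretch_stature"]):
            if comp.posthoc_method is None:
                continue
            if comp.test_used == "kruskal_wallis":
                assert comp.posthoc_method == "dunn"
            else:
                assert comp.posthoc_method == "games_howell"


class TestOrderingString:
    def test_blocks_and_rest_rendering(self):
        import pandas as pd
        means = {"OL": 120.0, "DL": 110.0, "LB": 95.0, "DB": 85.0, "QB": 84.0,
                 "RB": 83.0}
        names = list(means)
        p = pd.DataFrame(1.0, index=names, columns=names)
        for a in names:
            for b in names:
                if a != b:
                    p.loc[a, b] = 0.001
        # LB vs DB, DB/QB/RB mutually indistinct
        for a, b in (("DB", "QB"), ("DB", "RB"), ("QB", "RB")):
            p.loc[a, b] = p.loc[b, a] = 0.8
        assert ka.ordering_string(means, p) == "OL>DL>LB>Rest"
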