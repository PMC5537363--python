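import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sporecyte as sc

from conftest import scene_spec


def permutation_p_pooled(a, b):
    """Exact two-sided permutation p-value for the pooled t statistic."""

    def t_stat(x, y):
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
        if sp2 == 0:
            return 0.0 if np.mean(x) == np.mean(y) else math.inf
        return (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / nx + 1 / ny))

    pooled = np.asarray(list(a) + list(b))
    t_obs = abs(t_stat(np.asarray(a), np.asarray(b)))
    n_a = len(a)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        t = abs(t_stat(pooled[mask], pooled[~mask]))
        count += t >= t_obs - 1e-12
        total += 1
    return count / total


class TestGrowthRate:
    def test_identity(self):
        t = sc.GrowthRecord(3.0, 4.0)
        c = sc.GrowthRecord(3.0, 4.0)
        assert sc.growth_rate(t, c) == pytest.approx(1.0)

    def test_ten_percent_growth(self):
        # treated grew 0.1 cm against 1.0 cm in seawater → ratio 0.1
        assert sc.growth_rate(
            sc.GrowthRecord(3.0, 3.1), sc.GrowthRecord(3.0, 4.0)
        ) == pytest.approx(0.1)

    def test_no_growth_floors_to_zero(self):
        assert sc.growth_rate(sc.GrowthRecord(3.0, 3.0), sc.GrowthRecord(3.0, 4.0)) == 0.0
        # shrinkage also floors at zero growth
        assert sc.growth_rate(sc.GrowthRecord(3.0, 2.5), sc.GrowthRecord(3.0, 4.0)) == 0.0

    def test_zero_control_growth_rejected(self):
        with pytest.raises(ValueError, match="control"):
            sc.growth_rate(sc.GrowthRecord(3.0, 4.0), sc.GrowthRecord(3.0, 3.0))


class TestTwoGroupTest:
    def test_identical_groups(self):
        res = sc.two_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.stars == ""

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(8)
        a = 0.0 + rng.normal(0, 1e-3, 4)
        b = 1.0 + rng.normal(0, 1e-3, 4)
        res = sc.two_group_test(a, b)
        assert res.p < 0.001
        assert res.stars == "**"

    def test_zero_variance_conventions(self):
        same = sc.two_group_test([2.0, 2.0], [2.0, 2.0])
        assert (same.t, same.p) == (0.0, 1.0)
        diff = sc.two_group_test([2.0, 2.0], [3.0, 3.0])
        assert diff.p == 0.0 and diff.t == -math.inf

    def test_pooled_df(self):
        res = sc.two_group_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0])
        assert res.df == 5

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            sc.two_group_test([1.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1.9, 2.3, 2.0, 1.8, 2.1], [3.1, 2.4, 2.2, 2.5]),
            ([2.1, 2.0, 1.5], [2.8, 2.5, 2.4, 2.5, 3.3]),
            ([2.4, 1.2, 1.9, 1.9, 1.6], [2.1, 2.0, 2.4, 2.0, 2.8]),
            ([1.9, 1.2, 2.0, 1.7], [2.0, 2.1, 1.8, 1.9, 2.1]),
        ],
    )
    def test_pooled_p_matches_exact_permutation_oracle(self, a, b):
        # agreement holds away from the far tail, where the permutation
        # distribution's lattice resolution (1/C(n, n_a)) becomes the limit
        res = sc.two_group_test(a, b, variant="pooled")
        assert res.p == pytest.approx(permutation_p_pooled(a, b), abs=0.02)

    @given(
        a=st.lists(st.floats(-10, 10), min_size=2, max_size=6),
        b=st.lists(st.floats(-10, 10), min_size=2, max_size=6),
    )
    @settings(max_examples=40, derandomize=True)
    def test_symmetry(self, a, b):
        """Swapping groups negates t and preserves p."""
        r1 = sc.two_group_test(a, b)
        r2 = sc.two_group_test(b, a)
        assert r1.p == pytest.approx(r2.p, nan_ok=True)
        if math.isfinite(r1.t):
            assert r1.t == pytest.approx(-r2.t)

    def test_welch_variant_runs_with_satterthwaite_df(self):
        res = sc.two_group_test([1.0, 2.0, 3.0], [10.0, 30.0, 50.0, 70.0], variant="welch")
        assert 0 < res.df < 5

    def test_stars_convention(self):
        assert sc.significance_stars(0.02) == ""
        assert sc.significance_stars(0.005) == "*"
        assert sc.significance_stars(0.0005) == "**"

    def test_bonferroni(self):
        assert sc.bonferroni([0.01, 0.4]) == [0.02, 0.8]


class TestDoseResponseTable:
    def rec(self, biocide, conc, values, rep=1):
        return sc.AssayRecord(biocide, conc, rep, tuple(values))

    def test_single_record(self):
        tab = sc.dose_response_table([self.rec("CuPT", 50.0, [2.0, 4.0])])
        assert len(tab) == 1
        assert tab.loc[0, "mean"] == pytest.approx(3.0)
        assert tab.loc[0, "n"] == 2

    def test_control_first_concentrations_ascending(self):
        recs = [
            self.rec("CuPT", 150.0, [1.0]),
            self.rec("CuPT", 0.0, [10.0]),
            self.rec("CuPT", 50.0, [5.0]),
        ]
        tab = sc.dose_response_table(recs)
        assert tab["concentration_ppb"].tolist() == [0.0, 50.0, 150.0]

    def test_mixed_biocides_grouped_with_labels(self):
        recs = [self.rec("CuPT", 10.0, [1.0]), self.rec("ZnPT", 10.0, [2.0])]
        tab = sc.dose_response_table(recs)
        assert set(tab["biocide"]) == {"CuPT", "ZnPT"}

    def test_means_are_convex_combinations(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 100, size=12)
        tab = sc.dose_response_table([self.rec("EC", 10.0, vals)])
        assert vals.min() <= tab.loc[0, "mean"] <= vals.max()

    def test_monotone_effect_recovered_from_synthetic_assay(self):
        effect = {0.0: 0.8, 10.0: 0.5, 100.0: 0.1}
        df, _ = sc.generate_assay(
            effect,
            n_fields=4,
            spec=scene_spec(field_um=(600.0, 450.0), n_spores=80, pixel_size_um=1.5),
            seed=17,
        )
        tab = sc.dose_response_table(sc.records_from_frame(df))
        means = tab.sort_values("concentration_ppb")["mean"].to_numpy()
        assert (np.diff(means) < 0).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sc.dose_response_table([])

    def test_control_record_requires_zero_concentration(self):
        with pytest.raises(ValueError, match="concentration 0"):
            sc.AssayRecord("control", 10.0, 1, (1.0,))


class TestAssayIO:
    def test_csv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "biocide": ["CuPT"] * 3 + ["control"] * 3,
                "concentration_ppb": [50.0] * 3 + [0.0] * 3,
                "replicate": [1, 1, 2, 1, 1, 1],
                "field_id": [0, 1, 0, 0, 1, 2],
                "value": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                "kind": ["corrected_count"] * 6,
            }
        )
        path = tmp_path / "assay.csv"
        df.to_csv(path, index=False)
        recs = sc.read_assay_csv(path)
        assert len(recs) == 3  # (CuPT,50,1), (CuPT,50,2), (control,0,1)
        control = [r for r in recs if r.biocide == "control"][0]
        assert control.measurements == (10.0, 11.0, 12.0)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            sc.records_from_frame(pd.DataFrame({"biocide": ["x"]}))
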