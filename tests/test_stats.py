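"""Mann-Whitney, Bonferroni and Spearman behavior against oracles."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata

import urimir as u


def u_statistic_oracle(x, y):
    """Pair-counting U of x over y, ties counted one half."""
    u_x = 0.0
    for xi in x:
        for yj in y:
            u_x += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u_x


def exact_p_oracle(x, y):
    """Two-sided permutation p-value by full enumeration of labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)
    center = n1 * len(y) / 2
    observed = abs(u_statistic_oracle(x, y) - center)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_statistic_oracle(xs, ys) - center) >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestMannWhitney:
    def test_identical_samples(self):
        stat, p = u.mann_whitney([1, 2, 3], [1, 2, 3])
        assert stat == pytest.approx(4.5)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_complete_separation_exact(self):
        stat, p = u.mann_whitney([4, 5, 6], [1, 2, 3])
        assert stat == 9
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings

    @pytest.mark.parametrize("x, y", [
        ([1, 3], [2]),
        ([1, 4, 6], [2, 3, 5]),
        ([10, 20], [15, 25, 30]),
    ])
    def test_matches_enumeration_oracle(self, x, y):
        stat, p = u.mann_whitney(x, y)
        assert stat == pytest.approx(u_statistic_oracle(x, y))
        assert p == pytest.approx(exact_p_oracle(x, y))

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            u.mann_whitney([], [1.0])

    def test_symmetry_and_complement(self, rng):
        for _ in range(20):
            x = rng.integers(0, 10, size=rng.integers(2, 15)).astype(float)
            y = rng.integers(0, 10, size=rng.integers(2, 15)).astype(float)
            ux, px = u.mann_whitney(x, y)
            uy, py = u.mann_whitney(y, x)
            assert ux + uy == pytest.approx(len(x) * len(y))
            assert px == pytest.approx(py)


class TestBonferroni:
    def test_examples(self):
        assert u.bonferroni(0.005) == pytest.approx(0.045)
        assert u.bonferroni(0.2) == 1.0
        assert u.bonferroni(0.0) == 0.0

    def test_monotone_and_capped(self):
        grid = np.linspace(0, 1, 101)
        adj = [u.bonferroni(p) for p in grid]
        assert all(a <= b for a, b in zip(adj, adj[1:]))
        assert max(adj) <= 1.0


class TestSpearman:
    def test_perfect_monotone(self):
        assert u.spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0
        assert u.spearman([1, 2, 3, 4], [40, 30, 20, 10])[0] == -1.0

    def test_rank_formula_oracle(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        r, _ = u.spearman(x, y)
        d2 = ((rankdata(x) - rankdata(y)) ** 2).sum()
        n = len(x)
        assert r == pytest.approx(1 - 6 * d2 / (n * (n ** 2 - 1)))
        assert r == pytest.approx(0.8)

    def test_constant_input_signaled(self):
        with pytest.raises(ValueError):
            u.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        r0, p0 = u.spearman(x, y)
        r1, p1 = u.spearman(np.exp(x), y ** 3)
        assert r1 == pytest.approx(r0)
        assert p1 == pytest.approx(p0)


class TestGroupComparisons:
    def test_invariants_on_default_cohort(self, analysis):
        for c in analysis.comparisons:
            assert 0.0 <= c.p_raw <= c.p_adjusted <= 1.0
            assert (c.direction == "not_different") == (c.p_adjusted >= 0.05)

    def test_recovers_configured_regulation(self, analysis, default_spec):
        directions = {c.miRNA: c.direction for c in analysis.comparisons}
        # the strongly shifted markers keep their configured direction
        for name in ("hsa-miR-125b", "hsa-miR-145", "hsa-miR-183",
                     "hsa-miR-221"):
            assert directions[name] == default_spec.marker(name).direction


class TestStageGradeCorrelations:
    def test_strictly_decreasing_in_stage_gives_minus_one(self, analysis,
                                                          default_cohort):
        import pandas as pd
        from urimir.stats import STAGE_CODE, stage_grade_correlations
        cases = [r for r in default_cohort if r.is_case]
        expr = pd.DataFrame(
            {m: [5.0 - STAGE_CODE[r.stage] for r in cases]
             for m in u.MIRNAS},
            index=pd.Index([r.sample_id for r in cases], name="sample_id"))
        res = stage_grade_correlations(expr, cases)
        stage_rs = {r.pair[0]: r.r_s for r in res if r.pair[1] == "stage"}
        assert all(v == pytest.approx(-1.0) for v in stage_rs.values())

    def test_configured_stage_trend_detected(self, analysis):
        rows = {r.pair: r for r in analysis.stage_grade_correlations}
        r = rows[("hsa-miR-125b", "stage")]
        assert r.r_s < 0

    def test_trend_marker_significant_at_500_tumors(self):
        import warnings
        spec = u.default_paper_spec(seed=21)
        spec.n_cases, spec.n_controls = 500, 20
        records = u.generate_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expr, _ = u.normalize_cohort(records)
        res = u.stage_grade_correlations(expr, records)
        r = next(x for x in res if x.pair == ("hsa-miR-125b", "stage"))
        assert r.r_s < 0 and r.p < 0.01

    def test_stage_independent_marker_is_null(self, rng):
        """200 replicates of a stage-independent marker at n=500: the mean
        Spearman coefficient with stage stays near zero."""
        rs = []
        for _ in range(200):
            codes = rng.integers(1, 5, size=500).astype(float)
            values = rng.normal(size=500)
            rs.append(u.spearman(values, codes)[0])
        assert abs(np.mean(rs)) < 0.05
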