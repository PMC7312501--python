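"""ROC curves, AUC identities and Youden cutoff selection."""

import numpy as np
import pytest

import urimir as u

CASE, CTRL = "BCa", "control"


def labels_for(n_cases, n_controls):
    return np.array([CASE] * n_cases + [CTRL] * n_controls)


def brute_force_youden(values, labels, direction):
    """Independent exhaustive threshold scan with the documented tie-break
    (max J, then max specificity, then distance from the median, then the
    larger threshold)."""
    values = np.asarray(values, dtype=float)
    case = np.asarray(labels) == CASE
    pos, neg = values[case], values[~case]
    uniq = sorted(set(values))
    candidates = ([-np.inf] + [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]
                  + [np.inf])
    med = float(np.median(values))
    best = None
    for t in candidates:
        if direction == "up":
            sens = sum(v >= t for v in pos) / len(pos)
            spec = sum(v < t for v in neg) / len(neg)
        else:
            sens = sum(v <= t for v in pos) / len(pos)
            spec = sum(v > t for v in neg) / len(neg)
        j = sens + spec - 1
        dist = abs(t - med) if np.isfinite(t) else np.inf
        key = (j, spec, dist, t)
        if best is None or key > best:
            best = key
    return best


def pair_counting_auc(cases, controls):
    wins = sum(1.0 if c > k else (0.5 if c == k else 0.0)
               for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


class TestRoc:
    def test_perfect_separation(self):
        r = u.roc([4, 5, 6, 1, 2, 3], labels_for(3, 3), "up")
        assert r.auc == pytest.approx(1.0)

    def test_ties_counted_half(self):
        r = u.roc([3, 4, 5, 1, 2, 3], labels_for(3, 3), "up")
        assert r.auc == pytest.approx(8.5 / 9)

    def test_orientation_symmetry_without_ties(self, rng):
        values = rng.normal(size=30)
        labels = labels_for(14, 16)
        up = u.roc(values, labels, "up")
        down = u.roc(values, labels, "down")
        assert down.auc == pytest.approx(1.0 - up.auc)

    def test_points_monotone_and_anchored(self, analysis):
        for r in analysis.roc_results.values():
            pts = r.points
            assert tuple(pts[0]) == (0.0, 0.0)
            assert tuple(pts[-1]) == (1.0, 1.0)
            assert (np.diff(pts[:, 0]) >= 0).all()
            assert (np.diff(pts[:, 1]) >= 0).all()

    def test_auc_is_trapezoid_of_points(self, analysis):
        for r in analysis.roc_results.values():
            area = np.trapezoid(r.points[:, 1], r.points[:, 0])
            assert abs(area - r.auc) < 1e-12

    def test_auc_equals_u_over_n1n2(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 20, size=2)
            values = rng.integers(0, 8, size=n1 + n2).astype(float)
            labels = labels_for(n1, n2)
            r = u.roc(values, labels, "up")
            stat, _ = u.mann_whitney(values[:n1], values[n1:])
            assert abs(r.auc - stat / (n1 * n2)) < 1e-12

    def test_auc_invariant_under_monotone_transform(self, rng):
        values = rng.normal(size=40)
        labels = labels_for(18, 22)
        a0 = u.roc(values, labels, "up").auc
        a1 = u.roc(np.exp(values), labels, "up").auc
        assert a1 == pytest.approx(a0, abs=1e-12)

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score
        values = rng.normal(size=60) + np.r_[np.full(25, 0.8), np.zeros(35)]
        labels = labels_for(25, 35)
        ours = u.roc(values, labels, "up").auc
        theirs = roc_auc_score((labels == CASE).astype(int), values)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            u.roc([1.0, 2.0], np.array([CASE, CASE]), "up")


class TestYoudenCutoff:
    def test_specificity_tie_break(self):
        cut = u.youden_cutoff([2, 3, 4, 0, 1, 2], labels_for(3, 3), "up")
        assert cut.cutoff == pytest.approx(2.5)
        assert cut.youden_j == pytest.approx(2 / 3)
        assert cut.sens_at_cutoff == pytest.approx(2 / 3)
        assert cut.spec_at_cutoff == pytest.approx(1.0)

    def test_perfect_separation_reaches_j_one(self):
        cut = u.youden_cutoff([4, 5, 6, 1, 2, 3], labels_for(3, 3), "up")
        assert cut.youden_j == pytest.approx(1.0)

    def test_j_is_sens_plus_spec_minus_one(self, analysis):
        for cut in analysis.cutoffs.values():
            assert cut.youden_j == pytest.approx(
                cut.sens_at_cutoff + cut.spec_at_cutoff - 1.0)

    def test_j_matches_roc_curve_maximum(self, analysis):
        for mirna, r in analysis.roc_results.items():
            j_roc = float(np.max(r.points[:, 1] - r.points[:, 0]))
            assert abs(j_roc - analysis.cutoffs[mirna].youden_j) < 1e-12

    @pytest.mark.parametrize("direction", ["up", "down"])
    def test_matches_brute_force(self, rng, direction):
        for _ in range(100):
            n1, n2 = rng.integers(2, 16, size=2)
            values = rng.integers(0, 10, size=n1 + n2).astype(float)
            labels = labels_for(n1, n2)
            cut = u.youden_cutoff(values, labels, direction)
            j, spec, _, t = brute_force_youden(values, labels, direction)
            assert cut.youden_j == pytest.approx(j, abs=1e-12)
            assert cut.spec_at_cutoff == pytest.approx(spec, abs=1e-12)
            assert cut.cutoff == pytest.approx(t) or (
                np.isinf(cut.cutoff) and np.isinf(t))

    def test_null_labels_never_give_negative_j(self, rng):
        js = []
        for _ in range(200):
            values = rng.normal(size=100)
            labels = rng.permutation(labels_for(50, 50))
            js.append(u.youden_cutoff(values, labels, "up").youden_j)
        assert min(js) >= 0.0
        assert np.mean(js) > 0.0  # resubstitution optimism


def test_infer_direction(rng):
    values = np.r_[rng.normal(2.0, 1.0, 30), rng.normal(0.0, 1.0, 30)]
    labels = labels_for(30, 30)
    assert u.infer_direction(values, labels) == "up"
    assert u.infer_direction(-values, labels) == "down"
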