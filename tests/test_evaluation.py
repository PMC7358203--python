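import numpy as np
import pytest

from hbadeals.evaluation import (
    isoform_proportions,
    mean_pr_curve,
    ostp_curve,
    pr_curve,
    t_test_de_scores,
    welch_t,
    PRCurve,
)
from hbadeals.io_normalize import CASE, CONTROL, CountMatrix


def _cm(counts, genes, n_control=2):
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[1]
    return CountMatrix(
        isoform_ids=[f"i{r}" for r in range(counts.shape[0])],
        gene_ids=genes,
        counts=counts,
        sample_ids=[f"s{j}" for j in range(n)],
        condition_labels=[CONTROL] * n_control + [CASE] * (n - n_control),
    )


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_pr(scores, flags):
    """Enumerate every score cutpoint; return operating points and area.

    Independent of the implementation: thresholds are the distinct scores,
    the area integrates the best precision at each distinct recall over
    recall, with a flat extension down to recall zero.
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    pts = set()
    for t in np.unique(scores):
        called = scores >= t
        tp = int((called & flags).sum())
        pts.add((tp / flags.sum(), tp / called.sum()))
    by_recall = {}
    for r, p in pts:
        by_recall[r] = max(by_recall.get(r, 0.0), p)
    rs = sorted(by_recall)
    ps = [by_recall[r] for r in rs]
    if rs[0] > 0:
        rs = [0.0] + rs
        ps = [ps[0]] + ps
    area = sum((rs[k + 1] - rs[k]) * (ps[k + 1] + ps[k]) / 2 for k in range(len(rs) - 1))
    return pts, area


def brute_force_ostp(props, is_control, flags):
    """Exhaustive |t| threshold enumeration with max-TP-per-FP envelope."""
    tstats = []
    for row in range(props.shape[0]):
        x = props[row, is_control]
        y = props[row, ~is_control]
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if len(x) < 2 or len(y) < 2 or (x.var(ddof=1) == 0 and y.var(ddof=1) == 0):
            tstats.append(np.nan)
            continue
        tstats.append(
            (x.mean() - y.mean())
            / np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
        )
    tstats = np.abs(np.array(tstats))
    ok = np.isfinite(tstats)
    t_ok, f_ok = tstats[ok], np.asarray(flags, bool)[ok]
    best = {}
    for thr in np.unique(t_ok):
        called = t_ok >= thr
        fp = int((called & ~f_ok).sum())
        tp = int((called & f_ok).sum())
        best[fp] = max(best.get(fp, -1), tp)
    pts = set()
    for fp, tp in best.items():
        if tp + fp:
            pts.add((tp / flags.sum(), tp / (tp + fp)))
    return pts


# ---------------------------------------------------------------------------
# isoform proportions
# ---------------------------------------------------------------------------

class TestIsoformProportions:
    def test_equal_counts_give_unit_ratios(self):
        cm = _cm([[2, 2, 2, 2], [2, 2, 2, 2]], ["g", "g"])
        props, keep = isoform_proportions(cm)
        np.testing.assert_array_equal(props, 1.0)
        assert keep.all()

    def test_zero_complement_is_undefined(self):
        cm = _cm([[0, 1, 1, 1], [5, 1, 1, 1]], ["g", "g"])
        with pytest.warns(UserWarning, match="zero complement"):
            props, _ = isoform_proportions(cm)
        assert props[0, 0] == 0.0 and np.isnan(props[1, 0])

    def test_single_isoform_genes_excluded(self):
        cm = _cm([[1, 1, 1, 1], [2, 2, 2, 2], [3, 3, 3, 3]], ["g1", "g1", "g2"])
        _, keep = isoform_proportions(cm)
        np.testing.assert_array_equal(keep, [True, True, False])

    def test_row_permutation_permutes_output(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(6, 4)).astype(float)
        genes = ["a", "a", "a", "b", "b", "b"]
        base, _ = isoform_proportions(_cm(counts, genes))
        perm = [2, 0, 1, 5, 3, 4]       # permutes within genes
        out, _ = isoform_proportions(_cm(counts[perm], [genes[i] for i in perm]))
        np.testing.assert_allclose(out, base[perm])


# ---------------------------------------------------------------------------
# PR machinery
# ---------------------------------------------------------------------------

class TestPRCurve:
    def test_perfect_scores_reach_unit_area(self):
        flags = np.array([True, False, True, False, False, True])
        curve = pr_curve(flags.astype(float), flags)
        assert curve.auprc == pytest.approx(1.0)

    def test_six_item_hand_enumeration(self):
        scores = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.1])
        flags = np.array([1, 1, 0, 1, 0, 0], dtype=bool)
        curve = pr_curve(scores, flags)
        pts, area = brute_force_pr(scores, flags)
        got = set(zip(curve.recall[np.isfinite(curve.precision)],
                      curve.precision[np.isfinite(curve.precision)]))
        assert pts <= got
        assert curve.auprc == pytest.approx(area, abs=1e-12)

    def test_identical_scores_give_prevalence_precision(self):
        flags = np.array([True] * 3 + [False] * 7)
        curve = pr_curve(np.full(10, 0.5), flags)
        finite = np.isfinite(curve.precision)
        assert set(np.round(curve.precision[finite], 12)) == {0.3}
        assert curve.auprc == pytest.approx(0.3)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(8)
        grid = np.linspace(0.0, 1.0, 10_001)
        for rep in range(5):
            n = int(rng.integers(10, 100))
            scores = grid[rng.integers(0, grid.size, size=n)]
            flags = rng.random(n) < 0.3
            if not flags.any():
                flags[0] = True
            curve = pr_curve(scores, flags)
            pts, area = brute_force_pr(scores, flags)
            finite = np.isfinite(curve.precision)
            got = set(zip(curve.recall[finite], curve.precision[finite]))
            assert pts <= got
            assert curve.auprc == pytest.approx(area, abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="no truth positives"):
            pr_curve(np.array([0.5, 0.5]), np.array([False, False]))


class TestOSTP:
    def test_perfect_separation_reaches_precision_one(self):
        rng = np.random.default_rng(1)
        n_iso = 20
        props = np.empty((n_iso, 10))
        flags = np.zeros(n_iso, dtype=bool)
        flags[:5] = True
        for r in range(n_iso):
            base = rng.uniform(0.5, 1.5)
            noise = 0.01 * rng.standard_normal(10)
            props[r] = base + noise
            if flags[r]:
                props[r, 5:] += 2.0          # |t| huge for true positives
        curve = ostp_curve(props, np.array([True] * 5 + [False] * 5), flags)
        at_full = curve.precision[np.isclose(curve.recall, 1.0)]
        assert at_full.max() == pytest.approx(1.0)
        assert curve.auprc == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_enumeration_on_toy(self):
        rng = np.random.default_rng(2)
        props = rng.uniform(0.1, 2.0, size=(10, 8))
        props[2, 4:] += 1.0
        props[7, 4:] += 0.5
        flags = np.zeros(10, dtype=bool)
        flags[[2, 7]] = True
        is_control = np.array([True] * 4 + [False] * 4)
        curve = ostp_curve(props, is_control, flags)
        pts = brute_force_ostp(props, is_control, flags)
        got = set(zip(curve.recall, curve.precision))
        assert got == pts

    def test_permuted_labels_give_prevalence_precision(self):
        rng = np.random.default_rng(3)
        precisions = []
        for rep in range(20):
            props = rng.uniform(0.5, 1.5, size=(60, 10))
            flags = rng.random(60) < 0.25
            if not flags.any():
                flags[0] = True
            curve = ostp_curve(props, np.array([True] * 5 + [False] * 5), flags)
            # average achievable precision at mid recall
            mid = np.abs(curve.recall - 0.5).argmin()
            precisions.append(curve.precision[mid])
        # with no signal the oracle still overfits slightly upward of
        # prevalence, but stays well below strong-signal levels
        assert 0.1 < np.mean(precisions) < 0.6


class TestMeanPRCurve:
    def _curve(self, r, p):
        return PRCurve(recall=np.asarray(r, float), precision=np.asarray(p, float),
                       auprc=float("nan"))

    def test_identical_inputs_average_to_themselves(self):
        r = np.linspace(0, 1, 21)
        p = np.clip(1.0 - 0.5 * r, 0, 1)
        mean = mean_pr_curve([self._curve(r, p), self._curve(r, p)])
        expected = np.interp(mean.recall, r, p)
        np.testing.assert_allclose(mean.precision, expected, atol=0.05)

    def test_reflected_curves_average_to_half(self):
        r = np.linspace(0, 1, 21)
        up = 0.5 + 0.4 * r
        down = 0.5 - 0.4 * r
        mean = mean_pr_curve([self._curve(r, up), self._curve(r, down)])
        np.testing.assert_allclose(mean.precision, 0.5, atol=0.05)

    def test_missing_precision_carried_from_lower_recall(self):
        # one curve is only defined up to recall 0.8
        full = self._curve(np.linspace(0, 1, 6), [1.0, 0.9, 0.8, 0.7, 0.6, 0.5])
        partial = self._curve([0.0, 0.4, 0.8], [1.0, 1.0, 1.0])
        mean = mean_pr_curve([full, partial], grid_points=11)
        at_09 = mean.precision[np.isclose(mean.recall, 0.9)][0]
        # the partial curve contributes its recall-0.8 value (1.0) at 0.9
        expected = (np.interp(0.9, full.recall, full.precision) + 1.0) / 2
        assert at_09 == pytest.approx(expected, abs=0.05)

    def test_requires_two_curves(self):
        with pytest.raises(ValueError):
            mean_pr_curve([self._curve([0, 1], [1, 1])])


class TestTTestBaseline:
    def test_shifted_gene_scores_higher_than_null(self):
        rng = np.random.default_rng(4)
        null = rng.poisson(200, size=(30, 10)).astype(float)
        shifted = np.column_stack([rng.poisson(150, size=(10, 5)),
                                   rng.poisson(600, size=(10, 5))]).astype(float)
        counts = np.vstack([null, shifted])
        genes = [f"g{r}" for r in range(40)]
        cm = _cm(counts, genes, n_control=5)
        ids, scores = t_test_de_scores(cm)
        assert scores[30:].min() > scores[:30].mean()
        assert np.all((scores >= 0) & (scores <= 1))

    def test_welch_t_degenerate_rows_are_nan(self):
        vals = np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        t = welch_t(vals, np.array([True, True, False, False]))
        assert np.isnan(t[0]) and np.isfinite(t[1])
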