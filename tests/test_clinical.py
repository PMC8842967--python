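"""Event post-processing, clinical metrics, and ICC agreement."""

import numpy as np
import pytest

from fogdetect import (
    WalkExampleSeries,
    classify_icc,
    compute_clinical_metrics,
    ground_truth_metrics,
    icc_1_1,
    optimize_threshold,
    postprocess_events,
    threshold_labels,
)
from fogdetect.clinical import THRESHOLD_GRID


def runlength_oracle(binary):
    """Regex-style oracle: merge single gaps to fixed point, drop singletons."""
    import re

    s = "".join("1" if b else "0" for b in binary)
    while True:
        merged = re.sub(r"(?<=1)0(?=1)", "1", s)
        if merged == s:
            break
        s = merged
    events = []
    for m in re.finditer(r"1+", s):
        if m.end() - m.start() > 1:
            events.append((m.start(), m.end()))
    return events


class TestThreshold:
    def test_basic(self):
        assert list(threshold_labels([0.2, 0.8], 0.5)) == [False, True]

    def test_threshold_one_all_false(self):
        assert not threshold_labels([0.3, 1.0, 0.9], 1.0).any()

    def test_strictly_above(self):
        assert list(threshold_labels([0.5], 0.5)) == [False]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_labels([0.5], 1.5)


class TestPostprocessEvents:
    def test_traced_merge_then_delete(self):
        # runs at 1, 3-4 merge across the single gap; singleton at 7 deleted
        assert postprocess_events([0, 1, 0, 1, 1, 0, 0, 1, 0]) == [(1, 5)]

    def test_two_gap_not_merged(self):
        assert postprocess_events([1, 1, 0, 0, 1, 1]) == [(0, 2), (4, 6)]

    def test_isolated_singleton_deleted(self):
        assert postprocess_events([0, 1, 0]) == []

    def test_merge_iterates_to_fixed_point(self):
        # 1,0,1,0,1: first merge creates a longer run, second merge extends it
        assert postprocess_events([1, 0, 1, 0, 1]) == [(0, 5)]

    def test_matches_runlength_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(1, 61))
            binary = rng.uniform(size=n) < rng.uniform(0.1, 0.9)
            assert postprocess_events(binary) == runlength_oracle(binary)


def _series(probs, truth, walk="w0"):
    return WalkExampleSeries(walk, "P01", 2.0, np.asarray(probs, dtype=float),
                             np.asarray(truth, dtype=bool))


class TestClinicalMetrics:
    def test_simple_event(self):
        probs = np.zeros(50)
        probs[10:20] = 0.9
        m = compute_clinical_metrics(_series(probs, np.zeros(50)), 0.5)
        assert m.percent_time_fog == pytest.approx(20.0)
        assert m.n_fog_events == 1

    def test_all_zero_probabilities(self):
        m = compute_clinical_metrics(_series(np.zeros(10), np.zeros(10)), 0.5)
        assert m.percent_time_fog == 0.0
        assert m.n_fog_events == 0

    def test_traced_sequence_percent(self):
        probs = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        m = compute_clinical_metrics(_series(probs, np.zeros(9)), 0.5)
        # one merged event of 4 examples (8 s) in a 9-example (18 s) walk
        assert m.n_fog_events == 1
        assert m.percent_time_fog == pytest.approx(100 * 4 / 9, abs=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            _series(np.array([]), np.array([]))


class TestGroundTruthMetrics:
    @pytest.mark.parametrize(
        "truth,pct,events",
        [([1, 1, 0, 1], 75.0, 2), ([0, 0, 0], 0.0, 0), ([1, 1, 1], 100.0, 1)],
    )
    def test_examples(self, truth, pct, events):
        m = ground_truth_metrics(_series(np.zeros(len(truth)), truth))
        assert m.percent_time_fog == pytest.approx(pct)
        assert m.n_fog_events == events

    def test_no_postprocessing_applied(self):
        # a singleton human-rated event is kept (unlike model output)
        m = ground_truth_metrics(_series(np.zeros(5), [0, 1, 0, 1, 0]))
        assert m.n_fog_events == 2


def anova_icc_oracle(x):
    """Explicit sum-of-squares one-way ANOVA ICC(1,1)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_between = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ss_within = sum((x[i, j] - x[i].mean()) ** 2 for i in range(n) for j in range(k))
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestIcc:
    def test_identical_columns(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert icc_1_1(x).estimate == 1.0

    def test_matches_anova_oracle(self):
        x = np.array([[1, 2], [3, 4], [5, 6], [7, 8]], dtype=float)
        assert abs(icc_1_1(x).estimate - anova_icc_oracle(x)) < 1e-10

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n, k = int(rng.integers(3, 12)), int(rng.integers(2, 5))
            x = rng.standard_normal((n, k)) + rng.standard_normal((n, 1))
            assert abs(icc_1_1(x).estimate - anova_icc_oracle(x)) < 1e-10

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal((1000, 2))
        assert abs(icc_1_1(x).estimate) < 0.08

    def test_symmetric_under_rater_swap(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((10, 2))
        assert icc_1_1(x).estimate == pytest.approx(
            icc_1_1(x[:, ::-1]).estimate, abs=1e-12
        )

    def test_degenerate_identical_ratings(self):
        res = icc_1_1(np.full((5, 2), 3.0))
        assert res.estimate == 1.0
        assert res.ci95 == (1.0, 1.0)
        assert res.degenerate

    def test_ci_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        x = rng.standard_normal((12, 2)) + 2 * rng.standard_normal((12, 1))
        res = icc_1_1(x)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile(["a", "b"], 12),
                "scores": x.ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="scores"
        )
        ref = table[table["Type"] == "ICC(1,1)"].iloc[0]
        assert res.estimate == pytest.approx(ref["ICC"], abs=1e-9)
        # pingouin prints the CI rounded to two decimals
        assert res.ci95[0] == pytest.approx(ref["CI95"][0], abs=6e-3)
        assert res.ci95[1] == pytest.approx(ref["CI95"][1], abs=6e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc_1_1(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            icc_1_1(np.zeros((5, 1)))
        with pytest.raises(ValueError):
            icc_1_1(np.array([[1.0, np.nan], [2, 3], [4, 5]]))


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "ci,expected",
        [
            ((0.91, 0.97), "excellent"),
            ((0.82, 0.93), "good to excellent"),
            ((0.10, 0.40), "poor"),
            ((0.55, 0.70), "moderate"),
            ((0.40, 0.95), "poor to excellent"),
        ],
    )
    def test_bands(self, ci, expected):
        assert classify_icc(ci) == expected


class TestOptimizeThreshold:
    def _perfect_series(self, rng, n_walks=5):
        """Truth with episode-like runs (>= 2 long, gaps >= 2) so the
        merge/delete post-processing is a no-op on perfect predictions."""
        out = []
        for i in range(n_walks):
            truth = np.zeros(30, dtype=bool)
            pos = 2
            while pos < 26:
                run = int(rng.integers(2, 6))
                truth[pos:pos + run] = True
                pos += run + int(rng.integers(2, 8))
            out.append(WalkExampleSeries(f"w{i}", "P01", 2.0,
                                         truth.astype(float), truth))
        return out

    def test_perfect_predictor_reaches_icc_one(self, rng):
        series = self._perfect_series(rng)
        thr, icc = optimize_threshold(series, "percent_time")
        assert icc.estimate > 0.999

    def test_grid_evaluated_once_per_threshold(self, rng, monkeypatch):
        import fogdetect.clinical as clin

        series = self._perfect_series(rng)
        calls = []
        original = clin.icc_1_1

        def counting(x):
            calls.append(1)
            return original(x)

        monkeypatch.setattr(clin, "icc_1_1", counting)
        clin.optimize_threshold(series, "percent_time")
        assert len(calls) == len(THRESHOLD_GRID) == 101

    def test_tie_breaks_to_lower_threshold(self):
        # constant predictions: every threshold below 0.6 gives the same
        # metrics, so the first (lowest) winning threshold must be returned
        series = [
            WalkExampleSeries(f"w{i}", "P", 2.0, np.full(10, 0.6),
                              np.arange(10) < i + 2)
            for i in range(4)
        ]
        thr, _ = optimize_threshold(series, "percent_time")
        assert thr in (0.0, 0.6)  # first threshold of its equivalence class

    def test_too_few_walks_rejected(self, rng):
        with pytest.raises(ValueError, match="3 walks"):
            optimize_threshold(self._perfect_series(rng, n_walks=2))

    def test_all_degenerate_rejected(self):
        series = [
            WalkExampleSeries(f"w{i}", "P", 2.0, np.zeros(10), np.zeros(10, bool))
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            optimize_threshold(series, "percent_time")
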