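"""Color-class assignment rules, training curation, and exact 1-D k-means."""

import itertools

import numpy as np
import pytest

from agndesign.curation import (
    GAP,
    ColorClass,
    CurationConfig,
    classify_peak,
    curate_training,
    evaluate_design_outcome,
    kmeans_cutoffs,
)

CFG = CurationConfig()  # bright threshold 0.2
BRIGHT = 1.0
DIM = 0.05


class TestClassifyPeak:
    @pytest.mark.parametrize(
        "lam,expected",
        [
            (550, ColorClass.GREEN),
            (590, GAP),
            (630, ColorClass.RED),
            (700, ColorClass.FARRED),
            (1041, ColorClass.NIR),  # longest-wavelength emitter known
            (579.999, ColorClass.GREEN),
            (580.0, GAP),
            (600.0, GAP),
            (660.0, ColorClass.RED),
            (800.0, ColorClass.FARRED),
            (800.001, ColorClass.NIR),
        ],
    )
    def test_interval_membership(self, lam, expected):
        assert classify_peak(lam, CFG) == expected

    def test_nonpositive_wavelength_rejected(self):
        with pytest.raises(ValueError):
            classify_peak(0.0, CFG)

    def test_boundaries_must_increase(self):
        with pytest.raises(ValueError):
            CurationConfig(red_max=900.0)


class TestCurateTraining:
    def test_labeling_rules(self):
        rows = [
            ("AAAAAAAAAA", [(630.0, BRIGHT)]),  # Red
            ("CCCCCCCCCC", [(630.0, BRIGHT), (850.0, BRIGHT)]),  # multiclass
            ("GGGGGGGGGG", []),  # Dark
            ("TTTTTTTTTT", [(590.0, BRIGHT)]),  # gap
            ("ACACACACAC", [(630.0, 0.15)]),  # mediocre band [0.1, 0.2)
            ("AGAGAGAGAG", [(630.0, DIM)]),  # dim only -> Dark
            ("ATATATATAT", [(545.0, BRIGHT), (560.0, 2 * BRIGHT)]),  # same class twice
        ]
        result = curate_training(rows, CFG)
        labels = {r.sequence: r.label for r in result.labeled}
        reasons = dict(result.exclusions)
        assert labels["AAAAAAAAAA"] is ColorClass.RED
        assert labels["GGGGGGGGGG"] is ColorClass.DARK
        assert labels["AGAGAGAGAG"] is ColorClass.DARK
        assert labels["ATATATATAT"] is ColorClass.GREEN
        assert reasons["CCCCCCCCCC"] == "multiclass"
        assert reasons["TTTTTTTTTT"] == "gap"
        assert reasons["ACACACACAC"] == "mediocre"

    def test_partition_property(self, rng):
        from tests.conftest import random_sequences

        seqs = random_sequences(rng, 200)
        rows = []
        for s in seqs:
            n_peaks = int(rng.integers(0, 3))
            rows.append(
                (s, [(float(rng.uniform(450, 1000)), float(rng.uniform(0, 2))) for _ in range(n_peaks)])
            )
        result = curate_training(rows, CFG)
        assert len(result.labeled) + len(result.exclusions) == len(rows)

    def test_determinism(self):
        rows = [("ACGTACGTAC", [(630.0, BRIGHT), (545.0, 0.5)])] * 3
        r1 = curate_training(rows, CFG)
        r2 = curate_training(rows, CFG)
        assert [(l.sequence, l.label) for l in r1.labeled] == [
            (l.sequence, l.label) for l in r2.labeled
        ]

    def test_nir_override_flag(self):
        rows = [("ACGTACGTAC", [(630.0, BRIGHT), (850.0, BRIGHT)])]
        default = curate_training(rows, CFG)
        assert default.exclusions[0][1] == "multiclass"
        override = curate_training(rows, CurationConfig(nir_overrides_training=True))
        assert override.labeled[0].label is ColorClass.NIR

    def test_duplicate_conflicting_rows_flagged_and_kept(self):
        rows = [
            ("ACGTACGTAC", [(630.0, BRIGHT)]),
            ("ACGTACGTAC", [(545.0, BRIGHT)]),
        ]
        result = curate_training(rows, CFG)
        assert len(result.labeled) == 2
        assert result.duplicates == ["ACGTACGTAC"]


class TestDesignOutcome:
    def test_nir_target_dual_label(self):
        ok, labels = evaluate_design_outcome(
            [(545.0, BRIGHT), (900.0, BRIGHT)], ColorClass.NIR, CFG
        )
        assert ok
        assert labels == {ColorClass.NIR, ColorClass.GREEN}

    def test_visible_target_brightest_rules(self):
        ok, labels = evaluate_design_outcome(
            [(545.0, BRIGHT), (640.0, 2 * BRIGHT)], ColorClass.GREEN, CFG
        )
        assert not ok
        assert labels == {ColorClass.RED}

    def test_no_peaks_is_dark_failure(self):
        ok, labels = evaluate_design_outcome([], ColorClass.FARRED, CFG)
        assert not ok
        assert labels == {ColorClass.DARK}

    def test_nir_does_not_compete_with_visible_for_brightest(self):
        # a brighter NIR peak must not steal a Far Red success
        ok, labels = evaluate_design_outcome(
            [(700.0, BRIGHT), (900.0, 3 * BRIGHT)], ColorClass.FARRED, CFG
        )
        assert ok
        assert labels == {ColorClass.FARRED, ColorClass.NIR}


def dp_oracle_1d_kmeans(values, k):
    """Exhaustive oracle: try every split of the sorted values into k runs."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    best, best_centroids = np.inf, None
    for splits in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *splits, n)
        cost = 0.0
        centroids = []
        for a, b in zip(bounds, bounds[1:]):
            seg = x[a:b]
            centroids.append(seg.mean())
            cost += float(((seg - seg.mean()) ** 2).sum())
        if cost < best - 1e-12:
            best, best_centroids = cost, centroids
    return np.array(best_centroids), best


class TestKmeansCutoffs:
    def test_two_point_masses(self):
        values = [500.0] * 6 + [900.0] * 6
        r = kmeans_cutoffs(values, k=2)
        assert np.allclose(r.centroids, [500.0, 900.0])
        assert np.allclose(r.midpoints, [700.0])

    def test_matches_exhaustive_oracle(self, rng):
        for k in (2, 3, 4):
            values = rng.uniform(450, 1000, size=12)
            r = kmeans_cutoffs(values, k=k)
            oracle_centroids, oracle_cost = dp_oracle_1d_kmeans(values, k)
            assert np.allclose(r.centroids, oracle_centroids)
            assert r.inertia == pytest.approx(oracle_cost, abs=1e-8)

    def test_centroids_ascending_midpoints_interleave(self, rng):
        values = np.concatenate(
            [rng.normal(c, 20, 60) for c in (550, 640, 690, 800)]
        )
        r = kmeans_cutoffs(values, k=4)
        assert np.all(np.diff(r.centroids) > 0)
        for i, mid in enumerate(r.midpoints):
            assert r.centroids[i] < mid < r.centroids[i + 1]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            kmeans_cutoffs([1.0, 2.0, 3.0], k=1)
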