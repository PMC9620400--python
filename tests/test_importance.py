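"""Shadow-feature importance (MISA), selection rules, and net importance."""

import numpy as np
import pytest

from agndesign.curation import ColorClass
from agndesign.ensemble import class_pairs
from agndesign.features import feature_names
from agndesign.importance import (
    ImportanceRecord,
    NisTable,
    class_frequencies,
    net_importance,
    select_important,
    shadow_importance,
    top_features,
)

PAIR_GR = (ColorClass.GREEN, ColorClass.RED)
PAIR_FN = (ColorClass.FARRED, ColorClass.NIR)


class TestShadowImportance:
    def test_planted_feature_beats_all_shadows(self, rng):
        X = rng.integers(0, 3, size=(200, 144)).astype(float)
        y = np.array([1] * 100 + [0] * 100)
        X[:, 17] = np.where(y == 1, 6.0, 0.0)
        recs = shadow_importance(X, y, PAIR_GR, n_repeats=5, seed=2)
        planted = next(r for r in recs if r.feature == feature_names()[17])
        assert planted.misa_mean > planted.max_shadow
        assert planted.selected
        others = [r.misa_mean for r in recs if r.feature != planted.feature]
        assert planted.misa_mean > max(others)

    def test_pure_noise_selects_almost_nothing(self, rng):
        X = rng.integers(0, 3, size=(200, 144)).astype(float)
        y = rng.integers(0, 2, size=200)
        recs = shadow_importance(X, y, PAIR_GR, n_repeats=5, seed=4)
        assert sum(r.selected for r in recs) <= 2

    def test_constant_labels_rejected(self, rng):
        X = rng.integers(0, 3, size=(50, 144)).astype(float)
        with pytest.raises(ValueError, match="degenerate"):
            shadow_importance(X, np.ones(50, dtype=int), PAIR_GR)


class TestSelectionRules:
    def _rec(self, pair, mean, sd, shadow):
        return ImportanceRecord("G_0G", pair, mean, sd, shadow, selected=False)

    def test_standard_rule(self):
        assert select_important([self._rec(PAIR_GR, 0.9, 0.0, 0.5)]) == {"G_0G"}
        assert select_important([self._rec(PAIR_GR, 0.45, 0.1, 0.5)]) == set()

    def test_nir_exception_within_one_sd(self):
        # mean 0.45 + sd 0.1 >= shadow 0.5 -> selected only for NIR pairs
        assert select_important([self._rec(PAIR_FN, 0.45, 0.1, 0.5)]) == {"G_0G"}
        assert select_important([self._rec(PAIR_GR, 0.45, 0.1, 0.5)]) == set()


def _uniform_records(misa=0.5):
    """Identical MISA for every feature and pair."""
    return {
        pair: [
            ImportanceRecord(f, pair, misa, 0.0, 0.4, True) for f in feature_names()
        ]
        for pair in class_pairs()
    }


class TestNetImportance:
    def test_sign_arithmetic(self):
        records = _uniform_records(misa=0.5)
        names = feature_names()
        freqs = np.ones((5, 144))
        f_idx = names.index("G_0G")
        # G_0G more frequent in NIR than in every other class
        freqs[4, f_idx] = 3.0
        freq_df = class_frequencies(
            np.vstack([np.tile(freqs[i], (2, 1)) for i in range(5)]),
            [c for c in ColorClass for _ in range(2)],
        )
        nis = net_importance(records, freq_df)
        # all four pairs add +0.5 for NIR; all other classes get one -0.5
        assert nis.scores.loc["G_0G", "NIR"] == pytest.approx(2.0)
        for c in ("Dark", "Green", "Red", "FarRed"):
            assert nis.scores.loc["G_0G", c] == pytest.approx(-0.5)

    def test_equal_frequencies_give_zero(self):
        records = _uniform_records()
        X = np.ones((10, 144))
        labels = [c for c in ColorClass for _ in range(2)]
        nis = net_importance(records, class_frequencies(X, labels))
        assert np.allclose(nis.scores.to_numpy(), 0.0)

    def test_triangle_bound(self, rng):
        records = {
            pair: [
                ImportanceRecord(f, pair, float(rng.uniform(0, 1)), 0.0, 0.4, True)
                for f in feature_names()
            ]
            for pair in class_pairs()
        }
        X = rng.integers(0, 4, size=(50, 144)).astype(float)
        labels = [list(ColorClass)[i % 5] for i in range(50)]
        nis = net_importance(records, class_frequencies(X, labels))
        by_pair = {p: {r.feature: r.misa_mean for r in rs} for p, rs in records.items()}
        from agndesign.ensemble import canonical_pair

        for f in feature_names():
            for c in ColorClass:
                bound = sum(
                    by_pair[canonical_pair((c, o))[0]][f] for o in ColorClass if o is not c
                )
                assert abs(nis.scores.loc[f, c.value]) <= bound + 1e-12

    def test_missing_pair_reported(self):
        records = _uniform_records()
        del records[(ColorClass.DARK, ColorClass.GREEN)]
        X = np.ones((10, 144))
        labels = [c for c in ColorClass for _ in range(2)]
        with pytest.raises(ValueError, match="Dark vs Green"):
            net_importance(records, class_frequencies(X, labels))

    def test_planted_nir_motif_recovered(self, features_and_labels):
        """On the planted-rule dataset, G_0G favors NIR and disfavors Dark."""
        X, labels = features_and_labels
        y = np.array([l.value for l in labels])
        records = {}
        for i, pair in enumerate(class_pairs()):
            mask = np.isin(y, [pair[0].value, pair[1].value])
            records[pair] = shadow_importance(
                X[mask],
                (y[mask] == pair[0].value).astype(int),
                pair,
                n_repeats=3,
                seed=100 + i,
            )
        nis = net_importance(records, class_frequencies(X, labels))
        assert nis.scores.loc["G_0G", "NIR"] > 0
        assert nis.scores.loc["G_0G", "Dark"] < 0
        # every planted positively-weighted motif appears in the selected union
        union = set()
        for pair, recs in records.items():
            union |= select_important(recs)
        assert {"C_0C", "G_0G", "G_0C", "C_0G", "G_1G"} <= union


class TestTopFeatures:
    def _table(self, rng):
        scores = rng.normal(0, 1, size=(144, 5))
        import pandas as pd

        df = pd.DataFrame(scores, index=feature_names(), columns=[c.value for c in ColorClass])
        return NisTable(scores=df, frequencies=df)

    def test_returns_n_rows_sorted(self, rng):
        nis = self._table(rng)
        top = top_features(nis, 15)
        assert len(top) == 15
        assert list(top["max_abs_nis"]) == sorted(top["max_abs_nis"], reverse=True)

    def test_scale_invariance_of_ranking(self, rng):
        nis = self._table(rng)
        scaled = NisTable(scores=nis.scores * 7.5, frequencies=nis.frequencies)
        assert list(top_features(nis, 20).index) == list(top_features(scaled, 20).index)

    def test_ties_break_on_feature_name(self):
        import pandas as pd

        df = pd.DataFrame(
            1.0, index=feature_names(), columns=[c.value for c in ColorClass]
        )
        top = top_features(NisTable(scores=df, frequencies=df), 5)
        assert list(top.index) == sorted(feature_names())[:5]
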