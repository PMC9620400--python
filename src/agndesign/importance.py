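"""Shadow-feature importance (MISA) and per-class Net Importance Scores.

Which staple motifs actually drive color selection?  Following the Boruta
idea, every real feature column is duplicated as a randomly permuted
"shadow" column carrying the same marginal distribution but no label
information; a random-forest classifier is fit on the augmented table and
a real feature is deemed important for a class pair only if its
importance beats the best-scoring shadow.  To wash out subsampling noise
the procedure is repeated over several balanced subsamples per pair
(MISA = importance score compared against the shadow maximum, averaged
over repeats).

Per-feature attribution uses the forest's mean-decrease-in-impurity
importances.  The selection contract is attribution-agnostic: a feature
is selected when its mean MISA exceeds the (mean) maximum shadow
importance; for pairs involving NIR — whose tiny class size inflates the
subsampling variance — a feature within one standard deviation of that
bar is also selected.

The Net Importance Score folds the four pairwise scores of a class into
one signed number: NIS(f, c) = sum over the four pairs (c, o) of
±misa_mean(f, pair), adding when feature f occurs more frequently (mean
count per sequence) in class c than in o, subtracting when less, and
contributing zero on exact ties.  NIS > 0 marks motifs that favor the
class, NIS < 0 motifs that select against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .curation import CLASS_ORDER, ColorClass
from .ensemble import balanced_subsamples, class_pairs, canonical_pair
from .features import feature_names

__all__ = [
    "ImportanceRecord",
    "NisTable",
    "shadow_importance",
    "select_important",
    "net_importance",
    "class_frequencies",
    "top_features",
]


@dataclass(frozen=True)
class ImportanceRecord:
    """MISA summary for one (feature, class pair)."""

    feature: str
    pair: tuple[ColorClass, ColorClass]
    misa_mean: float
    misa_sd: float
    max_shadow: float
    selected: bool


@dataclass
class NisTable:
    """Signed per-(feature, class) net importance scores.

    ``scores`` is a features × classes DataFrame; ``frequencies`` holds the
    per-class mean feature counts that set the signs.
    """

    scores: pd.DataFrame
    frequencies: pd.DataFrame


def shadow_importance(
    X: np.ndarray,
    y: np.ndarray,
    pair: tuple[ColorClass, ColorClass],
    n_repeats: int = 10,
    n_trees: int = 100,
    seed: int = 0,
    feature_names_: list[str] | None = None,
) -> list[ImportanceRecord]:
    """Score every feature against shuffled shadow copies for one class pair.

    Parameters
    ----------
    X : numpy.ndarray, shape (n, n_features)
        Feature rows of *both* classes of the pair.
    y : array-like of {0, 1}
        1 marks the pair's first class.
    pair : (ColorClass, ColorClass)
        The class pair, used for the NIR selection exception.
    n_repeats : int
        Balanced subsample / shadow-shuffle repeats.
    n_trees : int
        Trees per random forest.

    Returns
    -------
    list of ImportanceRecord
        One record per feature, with the selection flag already applied.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("degenerate input: both classes must be present")
    names = feature_names_ or feature_names()
    if X.shape[1] != len(names):
        raise ValueError(f"X has {X.shape[1]} columns but {len(names)} feature names")
    pair = (ColorClass(pair[0]), ColorClass(pair[1]))

    rng = np.random.default_rng(seed)
    idx_a = np.flatnonzero(y == 1)
    idx_b = np.flatnonzero(y == 0)
    n_feat = X.shape[1]
    real = np.empty((n_repeats, n_feat))
    shadow_max = np.empty(n_repeats)
    for r in range(n_repeats):
        ra, rb = balanced_subsamples(idx_a, idx_b, 1, rng)[0]
        rows = np.concatenate([ra, rb])
        Xr, yr = X[rows], y[rows]
        # one shadow per real feature, re-shuffled each repeat
        shadow = np.empty_like(Xr)
        for j in range(n_feat):
            shadow[:, j] = rng.permutation(Xr[:, j])
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
        )
        clf.fit(np.hstack([Xr, shadow]), yr)
        imp = clf.feature_importances_
        real[r] = imp[:n_feat]
        shadow_max[r] = imp[n_feat:].max()

    misa_mean = real.mean(axis=0)
    misa_sd = real.std(axis=0)
    bar = float(shadow_max.mean())
    nir_pair = ColorClass.NIR in pair
    records = []
    for j, name in enumerate(names):
        if nir_pair:
            sel = misa_mean[j] + misa_sd[j] >= bar
        else:
            sel = misa_mean[j] > bar
        records.append(
            ImportanceRecord(
                feature=name,
                pair=pair,
                misa_mean=float(misa_mean[j]),
                misa_sd=float(misa_sd[j]),
                max_shadow=bar,
                selected=bool(sel),
            )
        )
    return records


def select_important(records: list[ImportanceRecord], pair=None) -> set[str]:
    """Features passing the shadow bar for a pair.

    Standard rule: ``misa_mean > max_shadow``.  Pairs containing NIR use
    the relaxed rule ``misa_mean + misa_sd >= max_shadow`` (the NIR class
    is small, so subsample-to-subsample MISA variance is large).
    """
    if pair is not None:
        pair = (ColorClass(pair[0]), ColorClass(pair[1]))
        records = [r for r in records if set(r.pair) == set(pair)]
    out = set()
    for r in records:
        if ColorClass.NIR in r.pair:
            if r.misa_mean + r.misa_sd >= r.max_shadow:
                out.add(r.feature)
        elif r.misa_mean > r.max_shadow:
            out.add(r.feature)
    return out


def class_frequencies(X: np.ndarray, labels, feature_names_: list[str] | None = None) -> pd.DataFrame:
    """Mean per-sequence feature counts within each class (classes × features)."""
    names = feature_names_ or feature_names()
    labels = [ColorClass(l) for l in labels]
    X = np.asarray(X, dtype=float)
    rows = {}
    for c in CLASS_ORDER:
        mask = np.array([l is c for l in labels])
        if mask.any():
            rows[c.value] = X[mask].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


def net_importance(
    records_by_pair: dict[tuple[ColorClass, ColorClass], list[ImportanceRecord]],
    frequencies: pd.DataFrame,
) -> NisTable:
    """Aggregate pairwise MISA scores into per-class Net Importance Scores.

    Parameters
    ----------
    records_by_pair : dict
        Importance records for all 10 canonical class pairs.
    frequencies : pandas.DataFrame
        Classes × features mean counts (see :func:`class_frequencies`).

    Raises
    ------
    ValueError
        If any pair needed for a class is missing, listing the gaps.
    """
    canon = {}
    for pair, recs in records_by_pair.items():
        key, _ = canonical_pair((ColorClass(pair[0]), ColorClass(pair[1])))
        canon[key] = {r.feature: r for r in recs}
    missing = [p for p in class_pairs() if p not in canon]
    if missing:
        raise ValueError(
            "incomplete input: missing pairs "
            + ", ".join(f"{a.value} vs {b.value}" for a, b in missing)
        )
    features = list(frequencies.columns)
    scores = pd.DataFrame(0.0, index=features, columns=[c.value for c in CLASS_ORDER])
    for c in CLASS_ORDER:
        for o in CLASS_ORDER:
            if o is c:
                continue
            key, _ = canonical_pair((c, o))
            recs = canon[key]
            for f in features:
                diff = frequencies.loc[c.value, f] - frequencies.loc[o.value, f]
                scores.loc[f, c.value] += float(np.sign(diff)) * recs[f].misa_mean
    return NisTable(scores=scores, frequencies=frequencies)


def top_features(nis: NisTable, n: int = 15) -> pd.DataFrame:
    """Rank features by the largest |NIS| across classes.

    Deterministic: ties in |NIS| break on feature name.  Returns at most
    ``n`` rows, with the per-class signed scores alongside the ranking key.
    """
    if nis.scores.empty:
        raise ValueError("NIS table is empty")
    key = nis.scores.abs().max(axis=1)
    df = nis.scores.copy()
    df.insert(0, "max_abs_nis", key)
    # descending |NIS|, ties broken by feature name ascending
    order = sorted(range(len(df)), key=lambda i: (-df["max_abs_nis"].iloc[i], df.index[i]))
    return df.iloc[order].head(n)


def plot_top_features(nis: NisTable, n: int = 15, path=None):
    """Grouped bar chart of the top-n |NIS| features (one bar per class)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = top_features(nis, n).drop(columns=["max_abs_nis"])
    colors = {"Dark": "black", "Green": "green", "Red": "red", "FarRed": "darkred", "NIR": "blue"}
    ax = df.plot.bar(color=[colors[c] for c in df.columns], figsize=(10, 4))
    ax.set_ylabel("Net importance score")
    ax.set_xlabel("Staple feature")
    ax.axhline(0, color="gray", lw=0.5)
    fig = ax.get_figure()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
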