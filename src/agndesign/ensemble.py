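"""One-versus-one SVM ensemble with balanced subsampling.

The color-class training data are small and heavily imbalanced (roughly
ten times fewer NIR than Far Red sequences), so a single multiclass
classifier would be dominated by the abundant classes.  The model here is
an ensemble of 100 linear classifiers: one set of 10 L1-regularized
linear SVMs for each of the C(5,2) = 10 unordered pairs of the classes
{Dark, Green, Red, FarRed, NIR}.  Within a pair the majority class is
randomly subsampled 10 times to the minority-class size and one SVM is
trained per balanced subsample; the pair's probability is the mean of its
members' calibrated probabilities, and the consensus class of a sequence
is the class whose *minimum* pairwise probability over its four pairs is
largest (the same min-of-four score used by the design screen).

Margins are mapped to probabilities through the logistic function
``p = 1 / (1 + exp(-d))`` (parameter-free, monotone in the margin); Platt
scaling with an inner logistic refit is available via
``TrainingConfig.calibration = "platt"``.  Features enter as raw staple
counts (0-9) without scaling so the L1 weights stay interpretable;
standardization is available behind a flag.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .curation import CLASS_ORDER, ColorClass
from .features import feature_names

__all__ = [
    "TrainingConfig",
    "PairMember",
    "PairModel",
    "EnsembleModel",
    "CvReport",
    "class_pairs",
    "balanced_subsamples",
    "train_ensemble",
    "pair_probability",
    "predict_class",
    "cross_validate",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the ensemble.

    ``c`` is the L1 regularization strength of every linear SVM (small c =
    strong regularization = sparse weights); ``n_subsamples`` members are
    trained per class pair; cross-validation uses ``n_cv_folds`` folds
    repeated over ``n_cv_repeats`` independent subsample/fold draws.
    """

    c: float = 0.1
    penalty: str = "l1"
    n_subsamples: int = 10
    n_cv_folds: int = 10
    n_cv_repeats: int = 100
    seed: int = 0
    calibration: str = "sigmoid"  # "sigmoid" (raw margin) or "platt" (inner refit)
    standardize: bool = False
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise ValueError("regularization strength c must be positive")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if self.calibration not in ("sigmoid", "platt"):
            raise ValueError(f"unknown calibration {self.calibration!r}")


@dataclass
class PairMember:
    """One linear classifier of a pair set: w·x + b > 0 favors the first class."""

    weights: np.ndarray
    bias: float
    subsample_index: int
    platt_a: float = 1.0  # p = sigmoid(a·d + b_platt)
    platt_b: float = 0.0

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def probability(self, X: np.ndarray) -> np.ndarray:
        """Calibrated probability of the pair's first class."""
        d = self.platt_a * self.decision(X) + self.platt_b
        return _sigmoid(d)


@dataclass
class PairModel:
    """The set of balanced-subsample classifiers for one unordered class pair."""

    pair: tuple[ColorClass, ColorClass]  # canonical order (CLASS_ORDER)
    members: list[PairMember]

    def probability_first(self, X: np.ndarray) -> np.ndarray:
        """Mean member probability of the pair's first class."""
        return np.mean([m.probability(X) for m in self.members], axis=0)


@dataclass
class EnsembleModel:
    """Full 10-pair × n-member ensemble plus training metadata."""

    pair_models: dict[tuple[ColorClass, ColorClass], PairModel]
    feature_names: list[str]
    config: TrainingConfig
    classes: tuple[ColorClass, ...] = CLASS_ORDER
    data_fingerprint: str = ""
    standardize_mean: np.ndarray | None = None
    standardize_scale: np.ndarray | None = None

    @property
    def n_members(self) -> int:
        return sum(len(pm.members) for pm in self.pair_models.values())

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature vector length {X.shape[1]} != model's {len(self.feature_names)}"
            )
        if self.standardize_mean is not None:
            X = (X - self.standardize_mean) / self.standardize_scale
        return X

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "agndesign-ensemble-v1",
            "classes": [c.value for c in self.classes],
            "feature_names": self.feature_names,
            "config": asdict(self.config),
            "data_fingerprint": self.data_fingerprint,
            "standardize_mean": None
            if self.standardize_mean is None
            else self.standardize_mean.tolist(),
            "standardize_scale": None
            if self.standardize_scale is None
            else self.standardize_scale.tolist(),
            "pairs": [
                {
                    "pair": [pm.pair[0].value, pm.pair[1].value],
                    "members": [
                        {
                            "weights": m.weights.tolist(),
                            "bias": m.bias,
                            "subsample_index": m.subsample_index,
                            "platt_a": m.platt_a,
                            "platt_b": m.platt_b,
                        }
                        for m in pm.members
                    ],
                }
                for pm in self.pair_models.values()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        if d.get("format") != "agndesign-ensemble-v1":
            raise ValueError("not an agndesign ensemble model file")
        pair_models = {}
        for p in d["pairs"]:
            pair = (ColorClass(p["pair"][0]), ColorClass(p["pair"][1]))
            members = [
                PairMember(
                    weights=np.asarray(m["weights"], dtype=float),
                    bias=float(m["bias"]),
                    subsample_index=int(m["subsample_index"]),
                    platt_a=float(m["platt_a"]),
                    platt_b=float(m["platt_b"]),
                )
                for m in p["members"]
            ]
            pair_models[pair] = PairModel(pair=pair, members=members)
        return cls(
            pair_models=pair_models,
            feature_names=list(d["feature_names"]),
            config=TrainingConfig(**d["config"]),
            classes=tuple(ColorClass(c) for c in d["classes"]),
            data_fingerprint=d.get("data_fingerprint", ""),
            standardize_mean=None
            if d.get("standardize_mean") is None
            else np.asarray(d["standardize_mean"], dtype=float),
            standardize_scale=None
            if d.get("standardize_scale") is None
            else np.asarray(d["standardize_scale"], dtype=float),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CvReport:
    """Per-pair repeated cross-validation accuracies (mean ± sd over repeats)."""

    entries: dict[tuple[ColorClass, ColorClass], tuple[float, float]]
    n_folds: int
    n_repeats: int

    def as_rows(self) -> list[dict]:
        return [
            {
                "class_a": a.value,
                "class_b": b.value,
                "mean_accuracy": m,
                "sd_accuracy": s,
            }
            for (a, b), (m, s) in self.entries.items()
        ]


def _sigmoid(d: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(d, dtype=float)
    pos = d >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    e = np.exp(d[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def class_pairs(classes: tuple[ColorClass, ...] = CLASS_ORDER) -> list[tuple[ColorClass, ColorClass]]:
    """All unordered class pairs in canonical order (first class ranks lower)."""
    return [
        (classes[i], classes[j])
        for i in range(len(classes))
        for j in range(i + 1, len(classes))
    ]


def canonical_pair(pair: tuple[ColorClass, ColorClass]) -> tuple[tuple[ColorClass, ColorClass], bool]:
    """Return (canonical pair, flipped) where flipped means the input was reversed."""
    a, b = pair
    if CLASS_ORDER.index(a) <= CLASS_ORDER.index(b):
        return (a, b), False
    return (b, a), True


def balanced_subsamples(
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``n`` class-balanced index sets for one pair.

    The minority class is used in full in every draw; the majority class
    is subsampled without replacement to the minority size, independently
    per draw.  Returns ``n`` tuples ``(rows_a, rows_b)``.
    """
    idx_a = np.asarray(idx_a)
    idx_b = np.asarray(idx_b)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError(
            f"insufficient data: class sizes {idx_a.size} and {idx_b.size} (need >= 2 each)"
        )
    size = min(idx_a.size, idx_b.size)
    out = []
    for _ in range(n):
        a = idx_a if idx_a.size == size else rng.choice(idx_a, size=size, replace=False)
        b = idx_b if idx_b.size == size else rng.choice(idx_b, size=size, replace=False)
        out.append((np.sort(a), np.sort(b)))
    return out


def _fit_member(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainingConfig,
    subsample_index: int,
    seed: int,
) -> PairMember:
    """Fit one L1 linear SVM; y = 1 marks the pair's first class."""
    clf = LinearSVC(
        penalty=cfg.penalty,
        loss="squared_hinge",
        dual=False,
        C=cfg.c,
        max_iter=cfg.max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rare non-convergence on tiny folds
        clf.fit(X, y)
    # sklearn orders classes_ ascending; decision > 0 favors classes_[1] == 1
    w = clf.coef_[0].astype(float)
    b = float(clf.intercept_[0])
    member = PairMember(weights=w, bias=b, subsample_index=subsample_index)
    if cfg.calibration == "platt":
        member.platt_a, member.platt_b = _platt_fit(X @ w + b, y)
    return member


def _platt_fit(d: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """1-D logistic refit of margins onto labels (Platt scaling)."""
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1e6)
    lr.fit(d.reshape(-1, 1), y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def _fingerprint(X: np.ndarray, y: list[ColorClass]) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(",".join(c.value for c in y).encode())
    return h.hexdigest()[:16]


def train_ensemble(
    X: np.ndarray,
    labels,
    config: TrainingConfig | None = None,
    feature_names_: list[str] | None = None,
) -> EnsembleModel:
    """Train the full one-versus-one ensemble.

    Parameters
    ----------
    X : numpy.ndarray, shape (n, n_features)
        Staple-count matrix (raw integer counts).
    labels : sequence of ColorClass (or their string values)
        One label per row; all five classes must have >= 2 members.
    config : TrainingConfig, optional
    feature_names_ : list of str, optional
        Column labels; defaults to the canonical 144 staple names.

    Returns
    -------
    EnsembleModel
        ``C(n_classes, 2) * n_subsamples`` linear classifiers (100 for the
        default five classes and 10 subsamples).
    """
    cfg = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    labels = [ColorClass(l) for l in labels]
    if X.shape[0] != len(labels):
        raise ValueError("X rows and labels must align")
    names = feature_names_ or feature_names()
    if X.shape[1] != len(names):
        raise ValueError(f"X has {X.shape[1]} columns but {len(names)} feature names")

    mean = scale = None
    X_fit = X
    if cfg.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X_fit = (X - mean) / scale

    by_class = {c: np.flatnonzero([l is c for l in labels]) for c in CLASS_ORDER}
    for c, idx in by_class.items():
        if idx.size < 2:
            raise ValueError(f"class {c.value} has {idx.size} members; need >= 2")

    root = np.random.SeedSequence(cfg.seed)
    pair_list = class_pairs()
    pair_seeds = root.spawn(len(pair_list))
    pair_models: dict[tuple[ColorClass, ColorClass], PairModel] = {}
    for (a, b), ss in zip(pair_list, pair_seeds):
        rng = np.random.default_rng(ss)
        member_seed = int(rng.integers(2**31 - 1))
        draws = balanced_subsamples(by_class[a], by_class[b], cfg.n_subsamples, rng)
        members = []
        for si, (ra, rb) in enumerate(draws):
            rows = np.concatenate([ra, rb])
            y = np.concatenate([np.ones(ra.size, dtype=int), np.zeros(rb.size, dtype=int)])
            members.append(_fit_member(X_fit[rows], y, cfg, si, member_seed))
        pair_models[(a, b)] = PairModel(pair=(a, b), members=members)

    return EnsembleModel(
        pair_models=pair_models,
        feature_names=list(names),
        config=cfg,
        data_fingerprint=_fingerprint(X, labels),
        standardize_mean=mean,
        standardize_scale=scale,
    )


def pair_probability(
    model: EnsembleModel,
    pair: tuple[ColorClass, ColorClass],
    features: np.ndarray,
) -> np.ndarray | float:
    """Ensemble-average probability that ``features`` belongs to ``pair[0]``.

    The complement identity ``P(A vs B) + P(B vs A) = 1`` holds exactly.
    Accepts a single feature vector or a matrix; returns a scalar or a
    vector accordingly.
    """
    pair = (ColorClass(pair[0]), ColorClass(pair[1]))
    canon, flipped = canonical_pair(pair)
    if canon not in model.pair_models:
        raise KeyError(f"unknown class pair {pair[0].value} vs {pair[1].value}")
    single = np.asarray(features).ndim == 1
    X = model._prepare(features)
    p = model.pair_models[canon].probability_first(X)
    if flipped:
        p = 1.0 - p
    return float(p[0]) if single else p


def class_probability_table(model: EnsembleModel, features: np.ndarray) -> dict:
    """Per-(class, pair) average probabilities for one feature vector."""
    table: dict[ColorClass, dict[ColorClass, float]] = {}
    for c in model.classes:
        table[c] = {}
        for o in model.classes:
            if o is c:
                continue
            table[c][o] = pair_probability(model, (c, o), features)
    return table


def predict_class(
    model: EnsembleModel, features: np.ndarray
) -> tuple[ColorClass, dict, bool]:
    """Consensus prediction for one sequence's feature vector.

    The winning class maximizes the minimum of its four pairwise average
    probabilities.  Ties are broken by canonical class order (Dark <
    Green < Red < FarRed < NIR) and flagged in the returned boolean.

    Returns ``(class, per-pair probability table, tie_flag)``.
    """
    table = class_probability_table(model, features)
    scores = {c: min(table[c].values()) for c in model.classes}
    best = max(scores.values())
    winners = [c for c in model.classes if scores[c] == best]
    return winners[0], table, len(winners) > 1


def predict_classes(model: EnsembleModel, X: np.ndarray) -> list[ColorClass]:
    """Vectorized consensus prediction for a feature matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    score = np.full((len(model.classes), n), np.inf)
    for ci, c in enumerate(model.classes):
        for o in model.classes:
            if o is c:
                continue
            p = pair_probability(model, (c, o), X)
            score[ci] = np.minimum(score[ci], p)
    win = np.argmax(score, axis=0)  # argmax takes first max -> canonical tie-break
    return [model.classes[i] for i in win]


def cross_validate(
    X: np.ndarray,
    labels,
    config: TrainingConfig | None = None,
) -> CvReport:
    """Repeated stratified k-fold cross-validation of every pair classifier.

    For each pair and each of ``n_cv_repeats`` repeats, one balanced
    subsample is drawn, split into ``n_cv_folds`` stratified folds, and a
    fresh SVM is trained on 9 folds and scored on the held-out fold; the
    repeat's accuracy is the mean over folds.  The report carries the mean
    and standard deviation over repeats.  Pairs whose minority class is
    smaller than the fold count are skipped with a warning.
    """
    cfg = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    labels = [ColorClass(l) for l in labels]
    by_class = {c: np.flatnonzero([l is c for l in labels]) for c in CLASS_ORDER}
    present = [c for c in CLASS_ORDER if by_class[c].size > 0]

    root = np.random.SeedSequence(cfg.seed)
    pair_list = [
        (a, b) for (a, b) in class_pairs() if a in present and b in present
    ]
    pair_seeds = root.spawn(len(pair_list))
    entries = {}
    for (a, b), ss in zip(pair_list, pair_seeds):
        size = min(by_class[a].size, by_class[b].size)
        if size < cfg.n_cv_folds:
            warnings.warn(
                f"skipping pair {a.value} vs {b.value}: minority class size {size} "
                f"< {cfg.n_cv_folds} folds"
            )
            continue
        rng = np.random.default_rng(ss)
        repeat_acc = np.empty(cfg.n_cv_repeats)
        for r in range(cfg.n_cv_repeats):
            (ra, rb) = balanced_subsamples(by_class[a], by_class[b], 1, rng)[0]
            rows = np.concatenate([ra, rb])
            y = np.concatenate([np.ones(ra.size, dtype=int), np.zeros(rb.size, dtype=int)])
            skf = StratifiedKFold(
                n_splits=cfg.n_cv_folds,
                shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            fold_acc = []
            for tr, te in skf.split(rows.reshape(-1, 1), y):
                member = _fit_member(X[rows[tr]], y[tr], cfg, 0, seed=0)
                pred = (member.decision(X[rows[te]]) > 0).astype(int)
                fold_acc.append(float(np.mean(pred == y[te])))
            repeat_acc[r] = float(np.mean(fold_acc))
        entries[(a, b)] = (float(repeat_acc.mean()), float(repeat_acc.std()))
    return CvReport(entries=entries, n_folds=cfg.n_cv_folds, n_repeats=cfg.n_cv_repeats)
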