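"""Synthetic sequence-color datasets with planted staple-motif rules.

Real AgN-DNA training data are expensive well-plate experiments; this
module fabricates datasets with the same statistical shape so every
pipeline stage can be exercised and verified against known ground truth.
Class membership is generated by a *linear* rule over staple-feature
counts — class c scores a sequence as ``w_c . staple_counts + b_c`` and
the noiseless label is the argmax — matching the representational
capacity of the linear classifier ensemble, so perfect recovery is
achievable at zero label noise.  Labels are then flipped to a uniformly
chosen other class with probability ``label_noise``.

The default rule set mirrors the chemistry qualitatively: consecutive Gs
(G_0G, G_1G) drive the long-wavelength Far Red / NIR classes, C-rich
motifs (C_0C) drive fluorescence generally, mixed G/C adjacency (G_0C,
C_0G) drives Red, and motif-poor sequences stay Dark.  Default class
proportions mirror the experimental library: Dark and Far Red dominate,
Green and Red are moderate, and NIR is rare (~4%, about a tenth of Far
Red).  An "xor" stress profile with a non-linearly separable rule is
included to document the linear model's expected failure mode.

Synthetic emission spectra (1 Gaussian peak in the class's wavelength
interval, flat noise for Dark) let the spectral-fitting and curation
stages be round-tripped end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import CLASS_ORDER, ColorClass
from .features import (
    BASES,
    decode,
    feature_index,
    feature_names,
    parse_feature_name,
    staple_count_matrix,
)
from .spectra import EmissionSpectrum, HC_EV_NM

__all__ = [
    "PlantedRuleSet",
    "SyntheticDataset",
    "default_rules",
    "xor_stress_rules",
    "generate_dataset",
    "generate_spectra",
    "imbalance_profile",
    "CLASS_WAVELENGTH_INTERVALS",
]


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the requested rules."""


#: lambda_p intervals (nm) used when synthesizing spectra per class.
CLASS_WAVELENGTH_INTERVALS: dict[ColorClass, tuple[float, float]] = {
    ColorClass.GREEN: (460.0, 575.0),
    ColorClass.RED: (605.0, 655.0),
    ColorClass.FARRED: (665.0, 795.0),
    ColorClass.NIR: (805.0, 990.0),
}


@dataclass(frozen=True)
class PlantedRuleSet:
    """Linear class-scoring rules over staple features.

    ``motifs`` maps each class to (feature name, weight) pairs; every
    class must carry at least one motif.  The noiseless label of a
    sequence is the argmax over classes of ``sum(w * count) + intercept``.
    """

    motifs: dict[ColorClass, tuple[tuple[str, float], ...]]
    intercepts: dict[ColorClass, float]
    label_noise: float = 0.0
    proportions: dict[ColorClass, float] = field(
        default_factory=lambda: {
            ColorClass.DARK: 0.30,
            ColorClass.GREEN: 0.08,
            ColorClass.RED: 0.20,
            ColorClass.FARRED: 0.38,
            ColorClass.NIR: 0.04,
        }
    )

    def __post_init__(self) -> None:
        for c in CLASS_ORDER:
            if not self.motifs.get(c):
                raise ValueError(f"class {c.value} must have at least one planted motif")
            for name, w in self.motifs[c]:
                parse_feature_name(name)  # validates
                if not np.isfinite(w):
                    raise ValueError(f"non-finite weight for motif {name}")
        if not (0 <= self.label_noise < 1):
            raise ValueError("label_noise must be in [0, 1)")
        total = sum(self.proportions.get(c, 0.0) for c in CLASS_ORDER)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")

    def weight_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (n_classes, 144) weights and (n_classes,) intercepts."""
        names = feature_names()
        W = np.zeros((len(CLASS_ORDER), len(names)))
        b = np.zeros(len(CLASS_ORDER))
        for ci, c in enumerate(CLASS_ORDER):
            b[ci] = self.intercepts.get(c, 0.0)
            for name, w in self.motifs[c]:
                x, y, m = parse_feature_name(name)
                W[ci, feature_index(x, y, m)] += w
        return W, b

    def noiseless_labels(self, X: np.ndarray) -> list[ColorClass]:
        """Bayes labels of staple-count rows under the planted rule."""
        W, b = self.weight_matrix()
        scores = np.asarray(X, dtype=float) @ W.T + b
        return [CLASS_ORDER[i] for i in np.argmax(scores, axis=1)]

    def to_dict(self) -> dict:
        return {
            "motifs": {c.value: list(map(list, self.motifs[c])) for c in CLASS_ORDER},
            "intercepts": {c.value: self.intercepts.get(c, 0.0) for c in CLASS_ORDER},
            "label_noise": self.label_noise,
            "proportions": {c.value: self.proportions.get(c, 0.0) for c in CLASS_ORDER},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedRuleSet":
        return cls(
            motifs={
                ColorClass(c): tuple((n, float(w)) for n, w in v)
                for c, v in d["motifs"].items()
            },
            intercepts={ColorClass(c): float(v) for c, v in d["intercepts"].items()},
            label_noise=float(d["label_noise"]),
            proportions={ColorClass(c): float(v) for c, v in d["proportions"].items()},
        )


@dataclass
class SyntheticDataset:
    """Generated records plus full generator truth for downstream assertions."""

    sequences: list[str]
    labels: list[ColorClass]  # observed labels (after noise flips)
    true_labels: list[ColorClass]  # noiseless argmax labels
    rules: PlantedRuleSet
    seed: int

    def __len__(self) -> int:
        return len(self.sequences)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sequence": self.sequences, "label": [l.value for l in self.labels]}
        )


def default_rules(label_noise: float = 0.0) -> PlantedRuleSet:
    """The standard planted rule set (linear, recoverable by the ensemble)."""
    return PlantedRuleSet(
        motifs={
            ColorClass.DARK: (("A_0A", 0.1),),
            ColorClass.GREEN: (("C_0C", 1.0), ("G_0G", -1.0)),
            ColorClass.RED: (("G_0C", 1.0), ("C_0G", 1.0), ("G_0G", -0.5)),
            ColorClass.FARRED: (("C_0C", 0.8), ("G_0G", 0.8)),
            ColorClass.NIR: (("G_0G", 1.5), ("G_1G", 0.5)),
        },
        intercepts={
            ColorClass.DARK: 0.5,
            ColorClass.GREEN: 0.0,
            ColorClass.RED: 0.0,
            ColorClass.FARRED: 0.0,
            ColorClass.NIR: -1.0,
        },
        label_noise=label_noise,
    )


def xor_stress_rules(label_noise: float = 0.0) -> PlantedRuleSet:
    """A stress profile whose Green/Red distinction is XOR-like.

    Green and Red both reward C_0C and G_0C but with opposite pairings, so
    no single linear margin on the two motifs separates them cleanly.
    Used to document the linear ensemble's failure mode; not a default.
    """
    return PlantedRuleSet(
        motifs={
            ColorClass.DARK: (("A_0A", 0.1),),
            ColorClass.GREEN: (("C_0C", 1.0), ("G_0C", 1.0), ("C_3G", -2.0)),
            ColorClass.RED: (("C_0C", 1.0), ("G_0C", 1.0), ("C_3G", 2.0), ("A_0T", -3.0)),
            ColorClass.FARRED: (("C_0C", 0.8), ("G_0G", 0.8)),
            ColorClass.NIR: (("G_0G", 1.5), ("G_1G", 0.5)),
        },
        intercepts={
            ColorClass.DARK: 0.5,
            ColorClass.GREEN: 0.0,
            ColorClass.RED: -1.0,
            ColorClass.FARRED: 0.0,
            ColorClass.NIR: -1.0,
        },
        label_noise=label_noise,
    )


def _allocate_counts(n: int, proportions: dict[ColorClass, float]) -> dict[ColorClass, int]:
    """Largest-remainder allocation of n records to classes."""
    raw = {c: n * proportions.get(c, 0.0) for c in CLASS_ORDER}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(CLASS_ORDER, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _propose_batch(
    c: ColorClass,
    rules: PlantedRuleSet,
    batch: int,
    L: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random sequences biased toward class c by planting one of its motifs."""
    codes = rng.integers(0, 4, size=(batch, L), dtype=np.int8)
    positive = [(n, w) for n, w in rules.motifs[c] if w > 0]
    if positive:
        # plant one positively weighted motif per proposal at a random offset
        pick = rng.integers(0, len(positive), size=batch)
        for mi, (name, _) in enumerate(positive):
            x, y, m = parse_feature_name(name)
            rows = np.flatnonzero(pick == mi)
            if rows.size == 0 or m > L - 2:
                continue
            pos = rng.integers(0, L - 1 - m, size=rows.size)
            codes[rows, pos] = BASES.index(x)
            codes[rows, pos + m + 1] = BASES.index(y)
    return codes


def generate_dataset(
    rules: PlantedRuleSet | None = None,
    n: int = 5000,
    seed: int = 0,
    L: int = 10,
    max_rounds: int = 60,
) -> SyntheticDataset:
    """Generate ``n`` labeled sequences under a planted rule set.

    Sequences are drawn class-conditionally: for each class, random
    sequences (biased by planting one of the class's motifs) are accepted
    when the class wins the noiseless argmax, until the class quota —
    set by the rule set's proportions — is filled.  Observed labels are
    then flipped to a uniform other class with probability
    ``rules.label_noise``.  Identical seeds reproduce the dataset exactly.

    Raises
    ------
    GenerationError
        If a class quota cannot be filled within ``max_rounds`` proposal
        rounds (motifs too rare / proportions unsatisfiable).
    """
    rules = rules or default_rules()
    if n < 1:
        raise ValueError("n must be >= 1")
    if L < 10:
        raise ValueError("planted rules live on the 144-feature layout; L must be >= 10")
    rng = np.random.default_rng(seed)
    counts = _allocate_counts(n, rules.proportions)
    W, b = rules.weight_matrix()

    seq_codes: list[np.ndarray] = []
    true_labels: list[ColorClass] = []
    for ci, c in enumerate(CLASS_ORDER):
        need = counts[c]
        got: list[np.ndarray] = []
        rounds = 0
        while need > 0:
            rounds += 1
            if rounds > max_rounds:
                raise GenerationError(
                    f"could not generate {counts[c]} sequences of class {c.value} "
                    f"within {max_rounds} proposal rounds"
                )
            batch = max(4 * need, 256)
            codes = _propose_batch(c, rules, batch, L, rng)
            scores = staple_count_matrix(codes).astype(float) @ W.T + b
            # require a unique argmax equal to c
            win = np.argmax(scores, axis=1) == ci
            top = np.sort(scores, axis=1)
            unique = top[:, -1] > top[:, -2]
            ok = np.flatnonzero(win & unique)[:need]
            got.extend(codes[ok])
            need -= ok.size
        seq_codes.extend(got)
        true_labels.extend([c] * counts[c])

    order = rng.permutation(len(seq_codes))
    seq_codes = [seq_codes[i] for i in order]
    true_labels = [true_labels[i] for i in order]

    labels = list(true_labels)
    if rules.label_noise > 0:
        flip = rng.random(len(labels)) < rules.label_noise
        for i in np.flatnonzero(flip):
            others = [c for c in CLASS_ORDER if c is not true_labels[i]]
            labels[i] = others[int(rng.integers(len(others)))]

    return SyntheticDataset(
        sequences=[decode(c) for c in seq_codes],
        labels=labels,
        true_labels=true_labels,
        rules=rules,
        seed=seed,
    )


def generate_spectra(
    dataset: SyntheticDataset,
    noise_sd: float = 0.002,
    grid: np.ndarray | None = None,
    seed: int = 0,
    bright_area: float = 0.5,
) -> tuple[list[EmissionSpectrum], list[dict]]:
    """Synthesize one emission spectrum per record, consistent with its label.

    Each non-Dark record receives a single Gaussian peak (in energy) whose
    lambda_p is drawn uniformly in the record's class interval and whose
    area (``bright_area`` in control-normalized units) is well above the
    default bright threshold; Dark records get flat noise.  Returns the
    spectra and a truth dict per record (lambda_p, area, sigma).
    """
    if grid is None:
        grid = np.arange(400.0, 1000.0, 2.0)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    energy = HC_EV_NM / grid
    spectra, truths = [], []
    for i, (seq, label) in enumerate(zip(dataset.sequences, dataset.labels)):
        intens = rng.normal(0.0, noise_sd, size=grid.size) if noise_sd > 0 else np.zeros(grid.size)
        truth: dict = {"sequence": seq, "label": label.value, "lambda_p": None, "area": 0.0}
        if label is not ColorClass.DARK:
            lo, hi = CLASS_WAVELENGTH_INTERVALS[label]
            lam = float(rng.uniform(lo, hi))
            sigma = float(rng.uniform(0.04, 0.06))  # eV
            center = HC_EV_NM / lam
            intens = intens + bright_area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
                -0.5 * ((energy - center) / sigma) ** 2
            )
            truth.update({"lambda_p": lam, "area": bright_area, "sigma": sigma})
        spectra.append(EmissionSpectrum(grid, intens, well_id=f"well{i:05d}"))
        truths.append(truth)
    return spectra, truths


def imbalance_profile(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per-class counts and ratios relative to the largest class."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    counts = {c.value: 0 for c in CLASS_ORDER}
    for l in dataset.labels:
        counts[l.value] += 1
    biggest = max(counts.values())
    return pd.DataFrame(
        {
            "count": counts,
            "fraction": {k: v / len(dataset) for k, v in counts.items()},
            "ratio_to_largest": {k: v / biggest for k, v in counts.items()},
        }
    )
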