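"""Exhaustive sequence design: score all 4^L templates for a target color.

The trained ensemble is cheap enough to score the entire 10-base design
space (4^10 = 1,048,576 sequences).  A sequence's score for a target
class is the *minimum* of its four pairwise average probabilities — the
probability of the target class against each of the other four classes —
so top-ranked sequences are those unlikely to fall into *any* undesired
class.  The default selection size of 124 sequences fills one 384-well
synthesis plate three targets at a time with 10 control wells left over.

Enumeration streams in fixed-size blocks so memory stays bounded
regardless of L; ranking ties are broken lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .curation import ColorClass
from .ensemble import EnsembleModel, pair_probability
from .features import decode, staple_count_matrix

__all__ = [
    "DesignScore",
    "DesignRun",
    "enumerate_space",
    "enumerate_code_blocks",
    "score_sequence",
    "design_top_k",
]

_L_MAX = 12  # guard against accidental 4^L blowup


@dataclass(frozen=True)
class DesignScore:
    """Score of one sequence for one target class."""

    sequence: str
    target: ColorClass
    score: float  # = min(per_pair.values())
    per_pair: dict  # other class -> average probability of target


@dataclass
class DesignRun:
    """Result of a full design screen for one target class."""

    target: ColorClass
    model_fingerprint: str
    k: int
    ranking: pd.DataFrame  # rank, sequence, score, per-pair probabilities
    enumeration_size: int


def _check_length(L: int) -> None:
    if not (1 <= L <= _L_MAX):
        raise ValueError(
            f"sequence length {L} outside [1, {_L_MAX}]; 4^{L} = {4**L:,} "
            "sequences would be enumerated"
        )


def enumerate_space(L: int = 10) -> Iterator[str]:
    """Yield every DNA sequence of length L once, in lexicographic order.

    A, C, G, T ordering; 4^L sequences total ("AA..A" first, "TT..T" last).
    """
    _check_length(L)
    for block in enumerate_code_blocks(L):
        for row in block:
            yield decode(row)


def enumerate_code_blocks(L: int, block_size: int = 65536) -> Iterator[np.ndarray]:
    """Stream the design space as (block, L) int8 code arrays, lexicographic."""
    _check_length(L)
    total = 4**L
    place = 4 ** np.arange(L - 1, -1, -1, dtype=np.int64)
    for start in range(0, total, block_size):
        stop = min(start + block_size, total)
        ids = np.arange(start, stop, dtype=np.int64)
        yield ((ids[:, None] // place) % 4).astype(np.int8)


def _model_m_max(model: EnsembleModel) -> int:
    """Gap bound implied by the model's feature count (16 features per gap)."""
    n = len(model.feature_names)
    if n % 16 != 0 or n == 0:
        raise ValueError(f"model feature count {n} is not a staple-feature layout")
    return n // 16 - 1


def _target_pair_probs(model: EnsembleModel, target: ColorClass, X: np.ndarray):
    """Average target-class probability against each other class; (others, matrix)."""
    others = [c for c in model.classes if c is not target]
    probs = np.stack([pair_probability(model, (target, o), X) for o in others])
    return others, probs


def score_sequence(model: EnsembleModel, seq: str, target: ColorClass) -> DesignScore:
    """Min-of-four-pairs design score for a single sequence."""
    target = ColorClass(target)
    if target not in model.classes:
        raise KeyError(f"target {target} not among model classes")
    from .features import encode

    X = staple_count_matrix(encode(seq)[None, :], m_max=_model_m_max(model)).astype(float)
    others, probs = _target_pair_probs(model, target, X)
    per_pair = {o: float(probs[i, 0]) for i, o in enumerate(others)}
    return DesignScore(
        sequence=seq, target=target, score=min(per_pair.values()), per_pair=per_pair
    )


def design_top_k(
    model: EnsembleModel,
    target: ColorClass,
    k: int = 124,
    L: int = 10,
    block_size: int = 65536,
    exclude: set[str] | None = None,
) -> DesignRun:
    """Screen the full 4^L space and return the top-k candidates.

    Parameters
    ----------
    model : EnsembleModel
    target : ColorClass
        Desired color class.
    k : int
        Number of candidates to keep (124 fits one 384-well plate per
        three targets plus controls).
    L : int
        Template length (the model is trained on L = 10).
    block_size : int
        Sequences scored per streamed block; memory scales with this, not
        with 4^L.
    exclude : set of str, optional
        Sequences (e.g. the training library) to drop before ranking.

    Returns
    -------
    DesignRun
        Ranking sorted by descending score, ties broken lexicographically.
    """
    target = ColorClass(target)
    if target not in model.classes:
        raise KeyError(f"target {target} not among model classes")
    total = 4**L
    if k > total:
        raise ValueError(f"k={k} exceeds the design space size 4^{L} = {total}")
    exclude = exclude or set()
    m_max = _model_m_max(model)
    if m_max > L - 2:
        raise ValueError(
            f"model expects gaps up to m={m_max} but length-{L} sequences "
            f"only support m <= {L - 2}"
        )
    others = [c for c in model.classes if c is not target]

    # rolling top-k buffer; blocks arrive in lexicographic order and the
    # stable sort keeps earlier (lexicographically smaller) rows on ties
    buf_scores = np.empty(0)
    buf_probs = np.empty((len(others), 0))
    buf_codes = np.empty((0, L), dtype=np.int8)

    for codes in enumerate_code_blocks(L, block_size=block_size):
        X = staple_count_matrix(codes, m_max=m_max).astype(float)
        _, probs = _target_pair_probs(model, target, X)
        scores = probs.min(axis=0)
        buf_scores = np.concatenate([buf_scores, scores])
        buf_probs = np.concatenate([buf_probs, probs], axis=1)
        buf_codes = np.concatenate([buf_codes, codes], axis=0)
        order = np.argsort(-buf_scores, kind="stable")[: max(k + len(exclude), k)]
        buf_scores = buf_scores[order]
        buf_probs = buf_probs[:, order]
        buf_codes = buf_codes[order]

    seqs = [decode(row) for row in buf_codes]
    keep = [i for i, s in enumerate(seqs) if s not in exclude][:k]
    rows = {
        "rank": np.arange(1, len(keep) + 1),
        "sequence": [seqs[i] for i in keep],
        "score": buf_scores[keep],
    }
    for j, o in enumerate(others):
        rows[f"p_vs_{o.value}"] = buf_probs[j, keep]
    return DesignRun(
        target=target,
        model_fingerprint=model.data_fingerprint,
        k=k,
        ranking=pd.DataFrame(rows),
        enumeration_size=total,
    )
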