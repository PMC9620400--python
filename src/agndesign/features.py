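"""Staple-motif and positional featurization of DNA template sequences.

Fluorescent silver nanoclusters templated by single-stranded DNA
(Ag\\ :sub:`N`-DNAs) are stabilized by pairs of nucleobases that bridge
surface silver atoms, in analogy with the thiolate "staple motifs" of
monolayer-protected metal clusters.  A *staple feature* ``X_mY`` is an
ordered pair of nucleobases X and Y separated by ``m`` arbitrary bases,
read 5'→3'; for 10-base templates with gaps ``m = 0..8`` there are
``4 × 4 × 9 = 144`` distinct features, and every 10-mer contains exactly
``sum(9 - m for m in 0..8) = 45`` staple occurrences.

This module converts sequences into

* integer count vectors over the 144 staple features (the representation
  used by the classifier ensemble and the design screen), and
* position-resolved one-hot vectors of length ``4 L`` (a baseline
  representation that discards relative-position information).

The canonical feature order is X-major, Y-minor, gap innermost with bases
ordered A, C, G, T — i.e. ``A_0A, A_1A, ..., A_8A, A_0C, ...`` — and is
fixed across the package (models, importance tables, CSV headers).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BASES",
    "DEFAULT_LENGTH",
    "DEFAULT_M_MAX",
    "InvalidSequenceError",
    "validate_sequence",
    "encode",
    "decode",
    "feature_names",
    "feature_index",
    "parse_feature_name",
    "staple_features",
    "staple_count_matrix",
    "one_hot",
    "decode_one_hot",
    "featurize",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Template length used for all training and design in this package.
DEFAULT_LENGTH = 10
#: Largest gap considered between the two bases of a staple (L - 2 for L = 10).
DEFAULT_M_MAX = 8


class InvalidSequenceError(ValueError):
    """Raised for sequences containing characters outside {A, C, G, T}."""


def validate_sequence(seq: str, length: int | None = None) -> str:
    """Uppercase and validate a DNA sequence.

    RNA-style ``U`` is rejected rather than silently mapped to ``T`` so that
    accidental RNA input fails loudly.

    Parameters
    ----------
    seq : str
        Raw sequence.
    length : int, optional
        If given, the sequence must have exactly this length.

    Returns
    -------
    str
        The validated, uppercased sequence.
    """
    s = str(seq).strip().upper()
    for pos, ch in enumerate(s):
        if ch not in _BASE_INDEX:
            raise InvalidSequenceError(
                f"invalid base {ch!r} at position {pos} in sequence {s!r}; "
                "allowed alphabet is A, C, G, T"
            )
    if length is not None and len(s) != length:
        raise InvalidSequenceError(
            f"sequence {s!r} has length {len(s)}, expected {length}"
        )
    if len(s) < 2:
        raise InvalidSequenceError(
            f"sequence {s!r} is too short: at least 2 bases are required "
            "for staple features to exist"
        )
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a validated sequence as int8 base codes (A=0, C=1, G=2, T=3)."""
    s = validate_sequence(seq)
    return np.fromiter((_BASE_INDEX[c] for c in s), dtype=np.int8, count=len(s))


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(BASES[int(c)] for c in codes)


def feature_names(m_max: int = DEFAULT_M_MAX) -> list[str]:
    """Ordered labels ``"X_mY"`` for the canonical staple-feature order.

    Length is ``16 * (m_max + 1)``; the order is X-major, Y-minor, m
    innermost and is stable across runs.
    """
    if m_max < 0:
        raise ValueError("m_max must be >= 0")
    return [f"{x}_{m}{y}" for x in BASES for y in BASES for m in range(m_max + 1)]


def feature_index(x: str, y: str, m: int, m_max: int = DEFAULT_M_MAX) -> int:
    """Position of staple ``X_mY`` in the canonical feature order."""
    if not (0 <= m <= m_max):
        raise ValueError(f"gap m={m} outside [0, {m_max}]")
    try:
        xi, yi = _BASE_INDEX[x.upper()], _BASE_INDEX[y.upper()]
    except KeyError as exc:
        raise InvalidSequenceError(f"invalid base {exc.args[0]!r} in feature name") from None
    return (xi * 4 + yi) * (m_max + 1) + m


def parse_feature_name(name: str, m_max: int = DEFAULT_M_MAX) -> tuple[str, str, int]:
    """Parse ``"X_mY"`` into ``(x, y, m)``."""
    x, rest = name[0], name[1:]
    if not rest.startswith("_") or len(rest) < 3:
        raise ValueError(f"malformed staple feature name {name!r}")
    m, y = int(rest[1:-1]), rest[-1]
    feature_index(x, y, m, m_max)  # validates
    return x.upper(), y.upper(), m


def staple_features(seq: str, m_max: int = DEFAULT_M_MAX) -> np.ndarray:
    """Count staple-motif occurrences ``X_mY`` in one sequence.

    Component ``(X, Y, m)`` of the returned vector equals the number of
    positions ``i`` with ``seq[i] == X`` and ``seq[i + m + 1] == Y``.

    Parameters
    ----------
    seq : str
        DNA sequence over {A, C, G, T}, length ``L >= 2``.
    m_max : int
        Largest gap, must satisfy ``m_max <= L - 2``.

    Returns
    -------
    numpy.ndarray
        Integer vector of length ``16 * (m_max + 1)`` in canonical order.
    """
    codes = encode(seq)
    if m_max > codes.size - 2:
        raise ValueError(
            f"m_max={m_max} too large for sequence of length {codes.size} "
            f"(must be <= {codes.size - 2})"
        )
    return staple_count_matrix(codes[None, :], m_max=m_max)[0]

def staple_count_matrix(codes: np.ndarray, m_max: int = DEFAULT_M_MAX) -> np.ndarray:
    """Vectorized staple counts for a batch of encoded sequences.

    Parameters
    ----------
    codes : numpy.ndarray, shape (B, L)
        Integer base codes (A=0 .. T=3).
    m_max : int
        Largest gap; ``m_max <= L - 2``.

    Returns
    -------
    numpy.ndarray, shape (B, 16 * (m_max + 1))
        Integer count matrix in canonical feature order.
    """
    codes = np.asarray(codes)
    if codes.ndim != 2:
        raise ValueError("codes must be a 2-D array of base codes")
    n, L = codes.shape
    if m_max > L - 2:
        raise ValueError(f"m_max={m_max} must be <= L - 2 = {L - 2}")
    n_feat = 16 * (m_max + 1)
    if n == 0:
        return np.zeros((0, n_feat), dtype=np.int16)
    row = np.arange(n, dtype=np.intp) * n_feat
    flat_parts = []
    c = codes.astype(np.intp)
    for m in range(m_max + 1):
        for i in range(L - 1 - m):
            idx = (c[:, i] * 4 + c[:, i + m + 1]) * (m_max + 1) + m
            flat_parts.append(row + idx)
    flat = np.concatenate(flat_parts)
    counts = np.bincount(flat, minlength=n * n_feat)
    return counts.reshape(n, n_feat).astype(np.int16)


def one_hot(seq: str) -> np.ndarray:
    """Position-resolved one-hot encoding, length ``4 L``.

    Slot ``4 * p + b`` is 1 iff position ``p`` carries base ``b`` (A=0..T=3);
    exactly ``L`` entries are 1.
    """
    codes = encode(seq)
    vec = np.zeros(4 * codes.size, dtype=np.int8)
    vec[4 * np.arange(codes.size) + codes] = 1
    return vec


def decode_one_hot(vec: np.ndarray) -> str:
    """Recover the sequence from a one-hot vector (round-trip of :func:`one_hot`)."""
    vec = np.asarray(vec)
    if vec.size % 4 != 0:
        raise ValueError("one-hot vector length must be a multiple of 4")
    mat = vec.reshape(-1, 4)
    if not np.all(mat.sum(axis=1) == 1):
        raise ValueError("each position must have exactly one active base slot")
    return decode(np.argmax(mat, axis=1))


def featurize(
    seqs: Iterable[str],
    m_max: int = DEFAULT_M_MAX,
    length: int | None = DEFAULT_LENGTH,
) -> tuple[np.ndarray, list[str]]:
    """Staple-count matrix for a collection of sequences.

    Returns ``(matrix, validated_sequences)``; rows follow input order.
    """
    validated = [validate_sequence(s, length=length) for s in seqs]
    if not validated:
        return np.zeros((0, 16 * (m_max + 1)), dtype=np.int16), []
    codes = np.stack([encode(s) for s in validated])
    return staple_count_matrix(codes, m_max=m_max), validated
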