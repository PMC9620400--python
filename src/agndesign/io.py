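"""File schemas: sequence lists, training tables, spectra, peaks, models.

All tables are comma-separated UTF-8 CSV with a required header and "."
decimals.  A training-table row holds one sequence together with its
fitted peak list; peak wavelength and brightness lists within a cell are
semicolon-delimited (wide experimental tables are normalized to this
long-ish format on load).  Sequences travel as plain text (one per line)
or FASTA.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import LabeledRecord
from .features import InvalidSequenceError, validate_sequence
from .spectra import EmissionSpectrum, PeakSet

__all__ = [
    "TrainingTableError",
    "read_sequences",
    "write_fasta",
    "load_training_table",
    "save_training_table",
    "read_spectra_csv",
    "write_peaks_csv",
    "write_labeled_csv",
    "write_exclusions_csv",
]

TRAINING_COLUMNS = ("sequence", "lambda_p", "brightness")


class TrainingTableError(ValueError):
    """Raised for malformed training tables; carries per-line errors."""

    def __init__(self, message: str, line_errors: list[str] | None = None):
        self.line_errors = line_errors or []
        details = ("\n  " + "\n  ".join(self.line_errors)) if self.line_errors else ""
        super().__init__(message + details)


def read_sequences(path) -> list[str]:
    """Read sequences from FASTA or plain one-per-line text, validated."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return [validate_sequence(str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    return [validate_sequence(line) for line in text.splitlines() if line.strip()]


def write_fasta(sequences, path, ids=None) -> None:
    """Write sequences as FASTA (ids default to seq1, seq2, ...)."""
    ids = ids or [f"seq{i + 1}" for i in range(len(sequences))]
    records = [SeqRecord(Seq(s), id=i, description="") for s, i in zip(sequences, ids)]
    SeqIO.write(records, str(path), "fasta")


def _parse_float_list(cell: str) -> list[float]:
    cell = cell.strip()
    if not cell:
        return []
    return [float(tok) for tok in cell.split(";")]


def load_training_table(path) -> list[tuple[str, list[tuple[float, float]]]]:
    """Load a (sequence, lambda_p list, brightness list) training CSV.

    Returns ``(sequence, [(lambda_p, brightness), ...])`` rows ready for
    :func:`agndesign.curation.curate_training`.  Malformed rows are
    collected and reported together with their line numbers; an empty
    table is an explicit error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise TrainingTableError(f"{path}: empty input file")
    header = [h.strip().lower() for h in rows[0]]
    if tuple(header[:3]) != TRAINING_COLUMNS:
        raise TrainingTableError(
            f"{path}: header {rows[0]!r} does not match schema {TRAINING_COLUMNS}"
        )
    if len(rows) == 1:
        raise TrainingTableError(f"{path}: no data rows")
    records = []
    errors = []
    for lineno, row in enumerate(rows[1:], start=2):
        try:
            seq = validate_sequence(row[0])
            lams = _parse_float_list(row[1]) if len(row) > 1 else []
            brs = _parse_float_list(row[2]) if len(row) > 2 else []
            if len(lams) != len(brs):
                raise ValueError(
                    f"{len(lams)} wavelengths but {len(brs)} brightness values"
                )
            records.append((seq, list(zip(lams, brs))))
        except (InvalidSequenceError, ValueError, IndexError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise TrainingTableError(f"{path}: {len(errors)} malformed row(s)", errors)
    return records


def save_training_table(records, path, comment: str | None = None) -> None:
    """Write (sequence, [(lambda_p, brightness), ...]) rows to the training CSV schema."""
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        w = csv.writer(fh)
        w.writerow(TRAINING_COLUMNS)
        for seq, peaks in records:
            w.writerow(
                [
                    seq,
                    ";".join(repr(float(l)) for l, _ in peaks),
                    ";".join(repr(float(b)) for _, b in peaks),
                ]
            )


def read_spectra_csv(path) -> list[EmissionSpectrum]:
    """Read spectra from CSV: two-column (wavelength_nm, intensity) or a
    wide plate table (first column wavelength, one column per well)."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least wavelength and one intensity column")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    if df.shape[1] == 2:
        return [EmissionSpectrum(wl, df.iloc[:, 1].to_numpy(dtype=float), well_id=str(df.columns[1]))]
    return [
        EmissionSpectrum(wl, df[c].to_numpy(dtype=float), well_id=str(c))
        for c in df.columns[1:]
    ]


def write_peaks_csv(peaksets: list[PeakSet], path, comment: str | None = None) -> None:
    """Peak table: one row per fitted peak (well_id, lambda_p, area, brightness, n)."""
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        w = csv.writer(fh)
        w.writerow(["well_id", "lambda_p", "area", "normalized_brightness", "n_components"])
        for ps in peaksets:
            if not ps.peaks:
                w.writerow([ps.well_id, "", "", "", 0])
            for p in ps.peaks:
                w.writerow(
                    [ps.well_id, p.center_wavelength, p.area, p.normalized_brightness, len(ps)]
                )


def write_labeled_csv(labeled: list[LabeledRecord], path, comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        w = csv.writer(fh)
        w.writerow(["sequence", "label"])
        for rec in labeled:
            w.writerow([rec.sequence, rec.label.value])


def write_exclusions_csv(exclusions, path, comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        w = csv.writer(fh)
        w.writerow(["sequence", "reason"])
        for seq, reason in exclusions:
            w.writerow([seq, reason])
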