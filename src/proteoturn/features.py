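"""Proteoform abundance and N-terminal sequence features.

Abundance is estimated from MS/MS spectral counting: per-proteoform counts
are averaged over the timepoints where the proteoform was identified, then
length-normalised into NSAF values (SpC/L renormalised to sum to one over
the dataset).  N-terminal hydrophobicity is the grand average of hydropathy
(GRAVY) of the first 2 or 10 residues on the Kyte-Doolittle scale.
Intrinsic-disorder percentages and ubiquitination evidence are pass-through
input columns (computed upstream by dedicated predictors/databases).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .errors import ValidationError

__all__ = ["mean_spectral_counts", "nsaf", "gravy", "feature_table"]


def mean_spectral_counts(counts: Sequence[float] | Mapping) -> float:
    """Arithmetic mean spectral count over identified timepoints.

    Timepoints where the proteoform was not identified are excluded from
    the mean, not zero-filled; pass only observed counts (NaNs dropped).
    """
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts,
        dtype=float,
    )
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValidationError("no identified timepoints: mean undefined")
    return float(values.mean())


def nsaf(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Normalised spectral abundance factors.

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j), with L the mature
    proteoform length in residues.  Sums to one over the dataset.
    """
    c = np.asarray(counts, dtype=float)
    length = np.asarray(lengths, dtype=float)
    if c.shape != length.shape:
        raise ValidationError("counts and lengths must align")
    if np.any(length <= 0):
        raise ValidationError("lengths must be positive")
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    saf = c / length
    total = saf.sum()
    if total <= 0:
        raise ValidationError("all spectral counts are zero")
    return saf / total


def gravy(sequence: str, n_residues: int = 10) -> float:
    """Grand average of hydropathy of the proteoform's N-terminal window.

    Mean Kyte-Doolittle hydropathy over the first ``n_residues`` residues
    (2 or 10 in practice); positive scores are more hydrophobic.
    """
    seq = sequence.upper()
    if n_residues < 1:
        raise ValidationError("n_residues must be >= 1")
    if len(seq) < n_residues:
        raise ValidationError(
            f"sequence of length {len(seq)} shorter than window {n_residues}"
        )
    window = seq[:n_residues]
    try:
        return float(sum(KYTE_DOOLITTLE[a] for a in window) / n_residues)
    except KeyError as exc:
        raise ValidationError(f"invalid residue {exc.args[0]!r}") from exc


def feature_table(
    records: pd.DataFrame,
    count_cols: Sequence[str] | None = None,
    sequence_col: str = "proteoform_sequence",
) -> pd.DataFrame:
    """Append mean SpC, NSAF and GRAVY-2/10 columns to a proteoform table.

    ``records`` needs a ``length`` column (mature proteoform length), the
    N-terminal sequence in ``sequence_col``, and per-timepoint spectral
    counts either in ``count_cols`` (NaN = not identified) or a single
    ``spectral_count`` column.
    """
    out = records.copy()
    if count_cols:
        out["mean_spc"] = [
            mean_spectral_counts(row) for row in out[count_cols].to_numpy()
        ]
    elif "mean_spc" not in out.columns:
        if "spectral_count" not in out.columns:
            raise ValidationError("no spectral-count columns found")
        out["mean_spc"] = out["spectral_count"].astype(float)
    out["nsaf"] = nsaf(out["mean_spc"].to_numpy(), out["length"].to_numpy())
    out["gravy2"] = [gravy(s, 2) for s in out[sequence_col]]
    out["gravy10"] = [
        gravy(s, 10) if len(s) >= 10 else np.nan for s in out[sequence_col]
    ]
    return out
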