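"""Translation-initiation-site calling from ribosome-profiling tracks.

Lactimidomycin (LTM) arrests initiating ribosomes, so LTM P-site density
peaks at translation-initiation sites; cycloheximide (CHX) arrests
elongating ribosomes and serves as background.  A position is called a TIS
when its LTM read count, its local-maximum status within a 7-nt window
(one codon either side) and the library-normalised LTM-CHX difference
R_LTM-CHX all clear category-specific thresholds:

======================  =========  =========
category                min count  min R
======================  =========  =========
annotated start             5        0.01
CDS downstream             15        0.15
5'UTR / 3'UTR / ncRNA      10        0.05
======================  =========  =========

Coordinates are transcript-local, 0-based, half-open; the annotated start
is the first nucleotide of the start codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import ProteoformRecord
from .errors import ValidationError

__all__ = [
    "RiboTrack",
    "TISCall",
    "TISThresholds",
    "psite_offset",
    "r_ltm_chx",
    "call_tis",
    "match_peptides_to_tis",
]

MIN_READ_LENGTH = 26
MAX_READ_LENGTH = 34


@dataclass
class RiboTrack:
    """Paired CHX/LTM P-site count vectors over one transcript."""

    transcript: str
    chx: np.ndarray
    ltm: np.ndarray
    cds_start: int | None  # 0-based; None for non-coding transcripts
    cds_end: int | None  # half-open
    chx_total: float
    ltm_total: float

    def __post_init__(self) -> None:
        self.chx = np.asarray(self.chx)
        self.ltm = np.asarray(self.ltm)
        if self.chx.shape != self.ltm.shape or self.chx.ndim != 1:
            raise ValidationError("CHX and LTM tracks must align")
        if np.any(self.chx < 0) or np.any(self.ltm < 0):
            raise ValidationError("negative P-site counts")
        if self.coding:
            if not (0 <= self.cds_start < self.cds_end <= len(self)):
                raise ValidationError(
                    f"CDS [{self.cds_start}, {self.cds_end}) outside "
                    f"track of length {len(self)}"
                )

    def __len__(self) -> int:
        return self.chx.size

    @property
    def coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    @property
    def annotated_start(self) -> int | None:
        return self.cds_start

    def position_category(self, pos: int) -> str:
        if not 0 <= pos < len(self):
            raise ValidationError(f"position {pos} outside track")
        if not self.coding:
            return "non-coding"
        if pos == self.cds_start:
            return "annotated"
        if self.cds_start < pos < self.cds_end:
            return "CDS-downstream"
        if pos < self.cds_start:
            return "5UTR"
        return "3UTR"


@dataclass
class TISCall:
    transcript: str
    position: int
    category: str
    ltm_count: int
    r_value: float
    passed: bool


@dataclass(frozen=True)
class TISThresholds:
    """Per-category calling thresholds and the normalisation constant."""

    count_annotated: int = 5
    count_cds: int = 15
    count_other: int = 10
    r_annotated: float = 0.01
    r_cds: float = 0.15
    r_other: float = 0.05
    scale: float = 1e7
    window: int = 7  # local-maximum window, one codon up- and downstream
    local_max_all_categories: bool = True

    def __post_init__(self) -> None:
        numeric = (
            self.count_annotated,
            self.count_cds,
            self.count_other,
            self.r_annotated,
            self.r_cds,
            self.r_other,
            self.scale,
        )
        if any(v <= 0 for v in numeric):
            raise ValidationError("thresholds and scale must be positive")
        if self.window < 1 or self.window % 2 == 0:
            raise ValidationError("window must be a positive odd width")

    def for_category(self, category: str) -> tuple[int, float]:
        if category == "annotated":
            return self.count_annotated, self.r_annotated
        if category == "CDS-downstream":
            return self.count_cds, self.r_cds
        return self.count_other, self.r_other


def psite_offset(read_length: int) -> int:
    """5'-end-to-P-site offset as a function of read length.

    Reads of <= 30 nt shift by +12, 31-33 nt by +13, 34 nt by +14;
    lengths outside the retained 26-34 nt range are rejected.
    """
    if not MIN_READ_LENGTH <= read_length <= MAX_READ_LENGTH:
        raise ValidationError(
            f"read length {read_length} outside retained range "
            f"{MIN_READ_LENGTH}-{MAX_READ_LENGTH}"
        )
    if read_length <= 30:
        return 12
    if read_length <= 33:
        return 13
    return 14


def r_ltm_chx(
    ltm_count: float,
    chx_count: float,
    ltm_total: float,
    chx_total: float,
    scale: float = 1e7,
) -> float:
    """Library-normalised LTM minus CHX signal at one position.

    R = scale * ltm/ltm_total - scale * chx/chx_total.
    """
    if ltm_total <= 0 or chx_total <= 0:
        raise ValidationError("library totals must be positive")
    if ltm_count < 0 or chx_count < 0:
        raise ValidationError("counts must be non-negative")
    return scale * ltm_count / ltm_total - scale * chx_count / chx_total


def _is_local_max(counts: np.ndarray, pos: int, window: int) -> bool:
    """Local maximum within the window; ties break toward the 5' end."""
    half = window // 2
    lo = max(0, pos - half)
    hi = min(counts.size, pos + half + 1)
    seg = counts[lo:hi]
    peak = seg.max()
    if counts[pos] < peak:
        return False
    return int(lo + np.argmax(seg)) == pos


def call_tis(
    track: RiboTrack,
    thresholds: TISThresholds | None = None,
    return_all: bool = False,
) -> list[TISCall]:
    """Evaluate every position of a track against the TIS-calling rules.

    Returns passing calls (or every nonzero-LTM candidate when
    ``return_all``); a call passes when its LTM count and R_LTM-CHX meet
    its category's thresholds and the position is an LTM local maximum
    within the configured window.
    """
    thresholds = thresholds or TISThresholds()
    calls: list[TISCall] = []
    ltm = track.ltm
    for pos in np.flatnonzero(ltm > 0):
        pos = int(pos)
        category = track.position_category(pos)
        min_count, min_r = thresholds.for_category(category)
        r_val = r_ltm_chx(
            ltm[pos],
            track.chx[pos],
            track.ltm_total,
            track.chx_total,
            thresholds.scale,
        )
        need_local_max = (
            thresholds.local_max_all_categories or category == "annotated"
        )
        passed = (
            ltm[pos] >= min_count
            and r_val >= min_r
            and (
                not need_local_max
                or _is_local_max(ltm, pos, thresholds.window)
            )
        )
        if passed or return_all:
            calls.append(
                TISCall(
                    transcript=track.transcript,
                    position=pos,
                    category=category,
                    ltm_count=int(ltm[pos]),
                    r_value=float(r_val),
                    passed=bool(passed),
                )
            )
    return calls


def _initiator_met_position(record: ProteoformRecord) -> int:
    """1-based residue index of the Met codon initiating this N-terminus."""
    if record.imet_status == "processed":
        return record.start - 1
    return record.start


def match_peptides_to_tis(
    records: Iterable[ProteoformRecord],
    calls: Iterable[TISCall],
    codon_map: Mapping[str, tuple[str, int]],
) -> pd.DataFrame:
    """Flag proteoforms whose initiating Met codon carries a passing TIS.

    ``codon_map`` maps protein accession -> (transcript id, 0-based CDS
    start nucleotide); residue r of the annotated protein then sits at
    nucleotide ``cds_start + 3*(r-1)``.  For iMet-processed N-termini the
    relevant codon is that of the Met immediately preceding the observed
    start residue (position-2 peptides are supported through codon 1).
    """
    passing: dict[tuple[str, int], TISCall] = {
        (c.transcript, c.position): c for c in calls if c.passed
    }
    rows = []
    for rec in records:
        if rec.accession not in codon_map:
            raise ValidationError(
                f"accession {rec.accession!r} has no transcript mapping"
            )
        transcript, cds_start = codon_map[rec.accession]
        met_residue = _initiator_met_position(rec)
        nt = cds_start + 3 * (met_residue - 1)
        call = passing.get((transcript, nt))
        rows.append(
            {
                "accession": rec.accession,
                "start": rec.start,
                "category": rec.category,
                "transcript": transcript,
                "tis_nt_position": nt,
                "riboseq_supported": call is not None,
                "r_ltm_chx": call.r_value if call else np.nan,
            }
        )
    return pd.DataFrame(rows)
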