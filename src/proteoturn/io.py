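"""Readers and writers for the pipeline's table and track formats.

Interchange formats are deliberately plain: TSV (UTF-8, header row, "Inf"
for infinite half-lives, empty cell for missing) for tables, FASTA for
protein sequences, bedGraph (0-based, half-open) for per-nucleotide P-site
count tracks plus a small TSV annotation table for transcript geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AMINO_ACIDS, ImetConfig
from .errors import SchemaError, ValidationError
from .kinetics import KineticsConfig
from .ribo import RiboTrack, TISThresholds

__all__ = [
    "PipelineConfig",
    "read_peptide_table",
    "write_table",
    "read_table",
    "read_fasta",
    "write_fasta",
    "read_tracks",
    "write_tracks",
]

_PEPTIDE_KEY_COLS = ["peptide", "accession", "gene", "start", "timepoint_h"]


@dataclass
class PipelineConfig:
    """All configurable constants of a pipeline run."""

    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    tis: TISThresholds = field(default_factory=TISThresholds)
    imet: ImetConfig = field(default_factory=ImetConfig)
    alpha: float = 0.05
    enrichment_alpha: float = 0.01
    seed: int = 0
    fasta: str | None = None
    peptides: str | None = None
    chx_track: str | None = None
    ltm_track: str | None = None
    track_annotation: str | None = None
    outdir: str = "proteoturn_out"

    def __post_init__(self) -> None:
        for a in (self.alpha, self.enrichment_alpha):
            if not 0 < a < 1:
                raise ValidationError("significance levels must be in (0,1)")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["imet"]["cleavable_residues"] = "".join(
            sorted(self.imet.cleavable_residues)
        )
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "kinetics" in d:
            d["kinetics"] = KineticsConfig(**d["kinetics"])
        if "tis" in d:
            d["tis"] = TISThresholds(**d["tis"])
        if "imet" in d:
            imet = d["imet"]
            if isinstance(imet, Mapping):
                imet = imet.get("cleavable_residues", "AVSTCGP")
            d["imet"] = ImetConfig(frozenset(str(imet)))
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a peptide quantification TSV.

    Requires peptide, accession, gene, start, timepoint_h columns plus
    either ratio columns (ratio_ML, ratio_HL) or intensity columns
    (intensity_L/M/H), from which ratios are derived on read.  Duplicate
    (proteoform, timepoint) rows and non-numeric quantities are rejected
    with row context.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PEPTIDE_KEY_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_ratios = {"ratio_ML", "ratio_HL"}.issubset(df.columns)
    has_intens = {"intensity_L", "intensity_M", "intensity_H"}.issubset(
        df.columns
    )
    if not has_ratios and not has_intens:
        raise SchemaError(
            "need ratio_ML/ratio_HL or intensity_L/intensity_M/intensity_H"
        )
    numeric_cols = ["start", "timepoint_h"] + (
        ["ratio_ML", "ratio_HL"] if has_ratios
        else ["intensity_L", "intensity_M", "intensity_H"]
    )
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric value in column {col!r} at data row(s) "
                f"{[int(i) + 2 for i in bad[:5]]} (1-based incl. header)"
            )
        df[col] = parsed
    if not has_ratios:
        if (df["intensity_L"] <= 0).any():
            raise SchemaError("intensity_L must be positive to form ratios")
        df["ratio_ML"] = df["intensity_M"] / df["intensity_L"]
        df["ratio_HL"] = df["intensity_H"] / df["intensity_L"]
    if "proteoform_id" not in df.columns:
        df["proteoform_id"] = (
            df["accession"].astype(str) + "_" + df["start"].astype(int).astype(str)
        )
    dup = df.duplicated(subset=["proteoform_id", "timepoint_h"])
    if dup.any():
        raise SchemaError(
            f"duplicate (proteoform, timepoint) rows at data row(s) "
            f"{[int(i) + 2 for i in df.index[dup][:5]]}"
        )
    if "acetylation_evidence" in df.columns:
        df["acetylation_evidence"] = df["acetylation_evidence"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with 'Inf' for infinities and empty cells for missing."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda v: "Inf" if v == math.inf
                else ("-Inf" if v == -math.inf else v)
            )
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` ('Inf' -> inf)."""
    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if df[col].dtype == object:
            vals = df[col].dropna().unique()
            if len(vals) and all(
                v in ("Inf", "-Inf") or _is_number(v) for v in vals
            ):
                df[col] = df[col].replace(
                    {"Inf": math.inf, "-Inf": -math.inf}
                ).astype(float)
    return df


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences: first header token = accession, upper-cased.

    Duplicate accessions and residues outside the standard 20-letter
    alphabet are rejected.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split()[0]
        if acc in sequences:
            raise ValidationError(f"duplicate accession {acc!r} in FASTA")
        seq = str(rec.seq).upper()
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"invalid residue(s) {sorted(bad)} in {acc!r}"
            )
        sequences[acc] = seq
    if not sequences:
        raise ValidationError(f"no FASTA records in {path}")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _read_bedgraph(path: str | Path, lengths: Mapping[str, int]) -> dict:
    """Parse a bedGraph into dense per-nucleotide count vectors."""
    vectors = {
        tx: np.zeros(n, dtype=np.int64) for tx, n in lengths.items()
    }
    covered = {tx: np.zeros(n, dtype=bool) for tx, n in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValidationError(
                    f"{path}:{lineno}: expected 4 bedGraph columns"
                )
            tx, start, end, value = parts
            if tx not in vectors:
                raise ValidationError(
                    f"{path}:{lineno}: transcript {tx!r} not in annotation"
                )
            start, end = int(start), int(end)
            val = float(value)
            if val < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            if not 0 <= start < end <= lengths[tx]:
                raise ValidationError(
                    f"{path}:{lineno}: interval [{start},{end}) outside "
                    f"{tx} (length {lengths[tx]})"
                )
            if covered[tx][start:end].any():
                raise ValidationError(
                    f"{path}:{lineno}: overlapping interval on {tx}"
                )
            covered[tx][start:end] = True
            vectors[tx][start:end] = int(round(val))
    return vectors


def read_tracks(
    chx_path: str | Path,
    ltm_path: str | Path,
    annotation_path: str | Path,
) -> list[RiboTrack]:
    """Read paired CHX/LTM bedGraphs plus the transcript annotation TSV.

    The annotation needs transcript, length, cds_start, cds_end columns
    (empty cds = non-coding) and may carry chx_total/ltm_total library
    sizes; absent totals default to the summed track counts.
    """
    ann = pd.read_csv(annotation_path, sep="\t")
    required = {"transcript", "length", "cds_start", "cds_end"}
    missing = required - set(ann.columns)
    if missing:
        raise SchemaError(
            f"annotation missing column(s): {', '.join(sorted(missing))}"
        )
    lengths = {
        str(r["transcript"]): int(r["length"]) for _, r in ann.iterrows()
    }
    chx = _read_bedgraph(chx_path, lengths)
    ltm = _read_bedgraph(ltm_path, lengths)
    chx_total_default = float(sum(v.sum() for v in chx.values()))
    ltm_total_default = float(sum(v.sum() for v in ltm.values()))
    tracks = []
    for _, row in ann.iterrows():
        tx = str(row["transcript"])
        cds_start = (
            None if pd.isna(row["cds_start"]) else int(row["cds_start"])
        )
        cds_end = None if pd.isna(row["cds_end"]) else int(row["cds_end"])
        tracks.append(
            RiboTrack(
                transcript=tx,
                chx=chx[tx],
                ltm=ltm[tx],
                cds_start=cds_start,
                cds_end=cds_end,
                chx_total=float(
                    row.get("chx_total", chx_total_default)
                    if "chx_total" in ann.columns
                    else chx_total_default
                ),
                ltm_total=float(
                    row.get("ltm_total", ltm_total_default)
                    if "ltm_total" in ann.columns
                    else ltm_total_default
                ),
            )
        )
    return tracks


def _write_bedgraph(
    vectors: Mapping[str, np.ndarray], path: str | Path
) -> None:
    """Run-length-encode dense count vectors into bedGraph lines."""
    with open(path, "w") as fh:
        for tx in vectors:
            v = vectors[tx]
            if v.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [v.size]])
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{tx}\t{s}\t{e}\t{int(v[s])}\n")


def write_tracks(
    tracks: Iterable[RiboTrack],
    chx_path: str | Path,
    ltm_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write RiboTracks as paired bedGraphs plus the annotation TSV."""
    tracks = list(tracks)
    _write_bedgraph({t.transcript: t.chx for t in tracks}, chx_path)
    _write_bedgraph({t.transcript: t.ltm for t in tracks}, ltm_path)
    ann = pd.DataFrame(
        {
            "transcript": [t.transcript for t in tracks],
            "length": [len(t) for t in tracks],
            "cds_start": [t.cds_start for t in tracks],
            "cds_end": [t.cds_end for t in tracks],
            "chx_total": [t.chx_total for t in tracks],
            "ltm_total": [t.ltm_total for t in tracks],
        }
    )
    ann.to_csv(annotation_path, sep="\t", index=False)
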