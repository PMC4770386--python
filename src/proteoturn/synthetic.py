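"""Synthetic data with known ground truth for the whole pipeline.

Emulates the structure of a pulsed-SILAC N-terminomics study of a dividing
human cell line: proteomes in which a subset of genes expresses both the
annotated N-terminus (dbTIS) and a downstream alternative one (aTIS,
median start offset ~52 residues), deterministic initiator-Met processing
by the second-residue rule, 7-timepoint label-swap ratio time courses
following m(t) = exp(B t) at a ~24 h doubling time, LTM/CHX ribosome
footprint tracks with peaks planted at the true initiation codons, and
protein complexes carrying planted turnover outliers.

Every generator takes an explicit integer seed and owns a private
``numpy.random.Generator``; no global random state is touched, and equal
seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import CLEAVABLE_RESIDUES
from .errors import ValidationError
from .kinetics import LN2
from .ribo import RiboTrack

__all__ = [
    "NoiseModel",
    "SyntheticTruth",
    "generate_proteome",
    "simulate_psilac",
    "simulate_ribotracks",
    "generate_complexes",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# rough human proteome residue frequencies (uniform is unrealistically flat)
_AA_FREQ = np.array(
    [8.3, 1.4, 5.4, 6.8, 3.9, 7.1, 2.6, 4.4, 5.8, 9.7,
     2.4, 4.1, 6.3, 4.6, 5.5, 8.3, 5.4, 6.9, 1.2, 2.9]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

UTR5_LENGTH = 60
UTR3_LENGTH = 30

#: geometry of the planted aTIS start offsets (median ~52 residues)
ATIS_OFFSET_MEDIAN = 52
ATIS_OFFSET_SIGMA = 0.35

#: lognormal geometry of true 50% turnover times (hours)
TURNOVER_MEDIAN_H = 16.0
TURNOVER_SIGMA = 0.8
TURNOVER_RANGE_H = (0.5, 60.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters of the pSILAC simulator.

    sigma is the lognormal standard deviation applied multiplicatively to
    each intensity channel; missingness is the per-timepoint dropout
    probability; nonexponential_fraction of profiles are replaced by
    monotone logistic-shaped decays (to exercise the linear fallback);
    intensity_floor sets the light-channel baseline in arbitrary units.
    """

    sigma: float = 0.1
    missingness: float = 0.1
    nonexponential_fraction: float = 0.02
    intensity_floor: float = 1000.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        for p in (self.missingness, self.nonexponential_fraction):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated study.

    ``proteoforms`` has one row per observable N-terminus with the true
    decay parameter B (= -k_deg - ln2/t_cc), category and iMet status;
    ``tis_positions`` lists planted initiation codons in transcript
    coordinates (0-based); ``transcripts`` the synthetic transcript
    geometry.
    """

    proteoforms: pd.DataFrame
    sequences: dict[str, str]
    transcripts: pd.DataFrame
    tis_positions: pd.DataFrame
    t_cc: float
    seed: int
    complex_outliers: set[str] = field(default_factory=set)

    def validate(self) -> None:
        b_expected = -self.proteoforms["k_deg"] - LN2 / self.t_cc
        if not np.allclose(self.proteoforms["B"], b_expected, atol=1e-12):
            raise ValidationError("B != -k_deg - ln2/t_cc in truth table")
        lengths = self.transcripts.set_index("transcript")["length"]
        for _, row in self.tis_positions.iterrows():
            if not 0 <= row["position"] < lengths[row["transcript"]]:
                raise ValidationError(
                    f"planted TIS at {row['position']} outside "
                    f"{row['transcript']}"
                )


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    seq = list(rng.choice(_AA, size=length, p=_AA_FREQ))
    seq[0] = "M"
    return seq


def generate_proteome(
    n_genes: int,
    atis_fraction: float = 0.3,
    seed: int = 0,
    t_cc: float = 24.0,
    atis_abundance_factor: float = 0.5,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate protein sequences and the truth table of their N-termini.

    Each gene gets a random sequence of 50-1000 residues; a fraction of
    genes carries a downstream aTIS whose Met sits at a lognormally
    distributed offset (median ~52).  Second residues follow realistic
    frequencies, so both iMet-cleavable and iMet-retaining N-termini
    occur, and the observable N-terminus of every start is derived
    deterministically from the processing rule.  True turnover times are
    lognormal (median 16 h, spanning <1 h to >48 h); aTIS proteoforms get
    a lower mean spectral-count abundance (factor 0.5 by default).
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if not 0 <= atis_fraction <= 1:
        raise ValidationError("atis_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    sequences: dict[str, str] = {}
    rows = []
    tis_rows = []
    tx_rows = []
    n_atis_genes = int(round(atis_fraction * n_genes))
    has_atis = np.zeros(n_genes, dtype=bool)
    has_atis[:n_atis_genes] = True
    rng.shuffle(has_atis)

    for i in range(n_genes):
        acc = f"P{i:05d}"
        gene = f"GENE{i:05d}"
        transcript = f"TX{i:05d}"
        length = int(rng.integers(50, 1001))
        seq = _random_protein(rng, length)

        starts: list[tuple[int, str]] = [(1, "dbTIS")]  # (Met position, cat)
        if has_atis[i]:
            offset = int(
                round(
                    math.exp(
                        rng.normal(math.log(ATIS_OFFSET_MEDIAN),
                                   ATIS_OFFSET_SIGMA)
                    )
                )
            )
            offset = int(np.clip(offset, 3, length - 20))
            seq[offset - 1] = "M"
            starts.append((offset, "aTIS"))
        sequences[acc] = "".join(seq)

        cds_len = 3 * (length + 1)  # includes the stop codon
        tx_rows.append(
            {
                "transcript": transcript,
                "accession": acc,
                "length": UTR5_LENGTH + cds_len + UTR3_LENGTH,
                "cds_start": UTR5_LENGTH,
                "cds_end": UTR5_LENGTH + cds_len,
            }
        )

        for met_pos, category in starts:
            second = sequences[acc][met_pos] if met_pos < length else "L"
            processed = second in CLEAVABLE_RESIDUES
            obs_start = met_pos + 1 if processed else met_pos
            imet = "processed" if processed else "retained"
            t_turn = float(
                np.clip(
                    math.exp(
                        rng.normal(math.log(TURNOVER_MEDIAN_H),
                                   TURNOVER_SIGMA)
                    ),
                    *TURNOVER_RANGE_H,
                )
            )
            B = math.log(0.5) / t_turn
            k_deg = -B - LN2 / t_cc
            abundance = float(math.exp(rng.normal(math.log(20.0), 0.8)))
            if category == "aTIS":
                abundance *= atis_abundance_factor
            rows.append(
                {
                    "proteoform_id": f"{acc}_{obs_start}",
                    "accession": acc,
                    "gene": gene,
                    "transcript": transcript,
                    "start": obs_start,
                    "category": category,
                    "imet_status": imet,
                    "met_position": met_pos,
                    "B": B,
                    "k_deg": k_deg,
                    "t_turn": t_turn,
                    "mean_spc": abundance,
                    "length": length - obs_start + 1,
                }
            )
            tis_rows.append(
                {
                    "transcript": transcript,
                    "position": UTR5_LENGTH + 3 * (met_pos - 1),
                    "category": "annotated" if category == "dbTIS"
                    else "CDS-downstream",
                }
            )

    truth = SyntheticTruth(
        proteoforms=pd.DataFrame(rows),
        sequences=sequences,
        transcripts=pd.DataFrame(tx_rows),
        tis_positions=pd.DataFrame(tis_rows),
        t_cc=t_cc,
        seed=seed,
    )
    truth.validate()
    return sequences, truth


def _logistic_profile(t: np.ndarray, t50: float) -> np.ndarray:
    """Monotone descending sigmoid crossing 0.5 at t50 (non-exponential)."""
    return 1.0 / (1.0 + np.exp((t - t50) / (t50 / 6.0)))


def simulate_psilac(
    truth: SyntheticTruth,
    timepoints: Sequence[float] = (0.5, 1.5, 4, 8, 12, 24, 48),
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the peptide quantification table of a label-swap pSILAC run.

    Per proteoform and timepoint, channel intensities satisfy
    E[M/L] = exp(B t) and E[H/L] = 1 - exp(B t) with multiplicative
    lognormal noise per channel; timepoints drop out independently with
    the configured missingness, a configured fraction of profiles follows
    a monotone logistic (non-exponential) shape, and spectral counts are
    Poisson around the proteoform's true mean abundance.
    """
    noise = noise or NoiseModel()
    t = np.asarray(timepoints, dtype=float)
    if t.size == 0:
        raise ValidationError("timepoint list is empty")
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValidationError("timepoints must be positive and ascending")
    rng = np.random.default_rng(seed)

    n = len(truth.proteoforms)
    nonexp = rng.random(n) < noise.nonexponential_fraction
    mu = -noise.sigma**2 / 2.0  # mean-one lognormal noise

    rows = []
    for j, (_, p) in enumerate(truth.proteoforms.iterrows()):
        if nonexp[j]:
            m_true = _logistic_profile(t, p["t_turn"])
        else:
            m_true = np.exp(p["B"] * t)
        seq = truth.sequences[p["accession"]]
        peptide = seq[p["start"] - 1 : p["start"] - 1 + 10]
        base = noise.intensity_floor * p["mean_spc"]
        for i, ti in enumerate(t):
            if rng.random() < noise.missingness:
                continue
            noise3 = (
                np.exp(rng.normal(mu, noise.sigma, size=3))
                if noise.sigma > 0
                else np.ones(3)
            )
            light = base * noise3[0]
            med = base * m_true[i] * noise3[1]
            heavy = base * (1.0 - m_true[i]) * noise3[2]
            rows.append(
                {
                    "proteoform_id": p["proteoform_id"],
                    "peptide": peptide,
                    "accession": p["accession"],
                    "gene": p["gene"],
                    "start": int(p["start"]),
                    "timepoint_h": float(ti),
                    "intensity_L": light,
                    "intensity_M": med,
                    "intensity_H": heavy,
                    "ratio_ML": med / light,
                    "ratio_HL": heavy / light,
                    "spectral_count": int(rng.poisson(p["mean_spc"])),
                    "acetylation_evidence": bool(rng.random() < 0.7),
                    "nonexponential_truth": bool(nonexp[j]),
                }
            )
    return pd.DataFrame(rows)


def simulate_ribotracks(
    truth: SyntheticTruth,
    background_rate: float = 0.1,
    peak_height: int = 50,
    ltm_background_factor: float = 0.1,
    library_total: float = 1e9,
    seed: int = 0,
) -> list[RiboTrack]:
    """Simulate paired CHX/LTM P-site tracks with peaks at the true TIS.

    CHX is Poisson background over the CDS (elongating ribosomes); LTM is
    a tenth of that background plus a deterministic peak of
    ``peak_height`` reads at every planted initiation codon.  Library
    totals default to 1e9 mapped P-sites per treatment, standing for the
    full library of which these transcripts are a small part.
    """
    if background_rate < 0:
        raise ValidationError("background_rate must be >= 0")
    if peak_height < 0:
        raise ValidationError("peak_height must be >= 0")
    rng = np.random.default_rng(seed)
    tis_by_tx = truth.tis_positions.groupby("transcript")["position"]
    tis_map = {tx: pos.to_numpy() for tx, pos in tis_by_tx}

    tracks = []
    for _, tx in truth.transcripts.iterrows():
        length = int(tx["length"])
        cds_start, cds_end = int(tx["cds_start"]), int(tx["cds_end"])
        chx = np.zeros(length, dtype=np.int64)
        chx[cds_start:cds_end] = rng.poisson(
            background_rate, cds_end - cds_start
        )
        ltm = rng.poisson(
            background_rate * ltm_background_factor, length
        ).astype(np.int64)
        for pos in tis_map.get(tx["transcript"], ()):
            ltm[int(pos)] += peak_height
        tracks.append(
            RiboTrack(
                transcript=tx["transcript"],
                chx=chx,
                ltm=ltm,
                cds_start=cds_start,
                cds_end=cds_end,
                chx_total=library_total,
                ltm_total=library_total,
            )
        )
    return tracks


def generate_complexes(
    accessions: Sequence[str],
    n_complexes: int,
    outlier_shift: float = 20.0,
    seed: int = 0,
    outlier_fraction: float = 0.5,
    within_complex_sd: float = 1.0,
    size_range: tuple[int, int] = (3, 10),
) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """Generate CORUM-style complexes with planted turnover outliers.

    Returns ``(membership, turnover, outliers)``: a two-column membership
    table (complex_id, accession), a turnover time per member (tight
    around a complex-level baseline, sd ``within_complex_sd`` hours) and
    the set of planted outlier accessions, each shifted upward by
    ``outlier_shift`` hours in a fraction of complexes.
    """
    lo, hi = size_range
    if lo < 3:
        raise ValidationError("complexes need at least 3 members")
    rng = np.random.default_rng(seed)
    accessions = list(accessions)
    sizes = rng.integers(lo, hi + 1, size=n_complexes)
    if sizes.sum() > len(accessions):
        raise ValidationError(
            f"need {int(sizes.sum())} accessions for {n_complexes} "
            f"complexes, got {len(accessions)}"
        )
    pool = list(accessions)
    rng.shuffle(pool)
    rows, turnover, outliers = [], {}, set()
    cursor = 0
    for c, size in enumerate(sizes):
        members = pool[cursor : cursor + size]
        cursor += size
        base = rng.uniform(8.0, 30.0)
        values = base + rng.normal(0.0, within_complex_sd, size)
        plant = rng.random() < outlier_fraction and outlier_shift != 0
        out_idx = int(rng.integers(size)) if plant else None
        for k, acc in enumerate(members):
            val = values[k] + (outlier_shift if k == out_idx else 0.0)
            rows.append({"complex_id": f"CPX{c:04d}", "accession": acc})
            turnover[acc] = max(val, 0.1)
            if k == out_idx:
                outliers.add(acc)
    membership = pd.DataFrame(rows)
    return membership, pd.Series(turnover, name="t_turn"), outliers
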