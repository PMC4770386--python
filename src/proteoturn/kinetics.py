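"""Turnover kinetics of N-terminal proteoforms from pulsed-SILAC time courses.

A label swap at t = 0 splits each proteoform's signal into a pre-existing
(medium, M), newly synthesised (heavy, H) and reference (light, L) channel.
Under conservation (M + H = L) the normalised ratios m = (M/L)/(M/L + H/L)
and h = 1 - m trace degradation and synthesis; first-order decay plus
dilution by cell division gives

    m(t) = exp(B t),   B = -k_deg - ln(2)/t_cc,

so the 50% turnover time (where the degradation and synthesis curves cross,
m = h = 1/2) is t_turn = ln(1/2)/B, and the division-corrected half-life is
t_half = ln(2)/k_deg for k_deg > 0, infinite otherwise (dilution alone).

The module implements the fitting cascade used throughout the package:
single-parameter exponential least squares in ratio space gated on R^2, a
linear-interpolation fallback for monotone non-exponential profiles, and a
minimum-timepoint filter.  A statsmodels-style :class:`TurnoverModel` /
:class:`TurnoverResults` pair wraps the cascade for whole cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateFitError, NoCrossingError, ValidationError

LN2 = math.log(2.0)

__all__ = [
    "KineticsConfig",
    "NormalizedTimeCourse",
    "TurnoverFit",
    "TurnoverModel",
    "TurnoverResults",
    "normalize_ratios",
    "fit_exponential",
    "turnover_from_B",
    "linear_crossing",
    "half_life",
    "compute_turnover",
    "subsample_turnover",
    "doubling_time",
]


@dataclass(frozen=True)
class KineticsConfig:
    """Tunable constants of the turnover cascade.

    Parameters
    ----------
    t_cc : float
        Cell doubling time in hours (default 24, Jurkat-like growth).
    r2_threshold : float
        Minimum coefficient of determination for an exponential fit to be
        accepted (default 0.8).
    min_timepoints : int
        Minimum number of quantified timepoints per proteoform (default 3).
    """

    t_cc: float = 24.0
    r2_threshold: float = 0.8
    min_timepoints: int = 3

    def __post_init__(self) -> None:
        if not self.t_cc > 0:
            raise ValidationError(f"t_cc must be positive, got {self.t_cc}")
        if not 0 < self.r2_threshold <= 1:
            raise ValidationError(
                f"r2_threshold must be in (0, 1], got {self.r2_threshold}"
            )
        if self.min_timepoints < 2:
            raise ValidationError("min_timepoints must be >= 2")


@dataclass
class NormalizedTimeCourse:
    """Normalised degradation (m) and synthesis (h) fractions over time.

    ``m + h == 1`` at every timepoint by construction; ``qc_flags`` marks
    timepoints where the raw channels departed strongly from the M + H = L
    conservation assumption (|(M+H)/L - 1| > 0.5) before normalisation.
    """

    accession: str
    timepoints: np.ndarray
    m: np.ndarray
    h: np.ndarray
    qc_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if not (self.timepoints.shape == self.m.shape == self.h.shape):
            raise ValidationError("timepoints, m and h must share a shape")
        if self.timepoints.size and np.any(np.diff(self.timepoints) <= 0):
            order = np.argsort(self.timepoints)
            self.timepoints = self.timepoints[order]
            self.m = self.m[order]
            self.h = self.h[order]

    @classmethod
    def from_ratios(
        cls,
        accession: str,
        timepoints: Sequence[float],
        ratio_ml: Sequence[float],
        ratio_hl: Sequence[float],
    ) -> "NormalizedTimeCourse":
        """Build from raw M/L and H/L ratios, normalising each timepoint."""
        t = np.asarray(timepoints, dtype=float)
        ml = np.asarray(ratio_ml, dtype=float)
        hl = np.asarray(ratio_hl, dtype=float)
        pairs = [normalize_ratios(a, b) for a, b in zip(ml, hl)]
        m = np.array([p[0] for p in pairs])
        h = np.array([p[1] for p in pairs])
        qc = np.abs(ml + hl - 1.0) > 0.5
        return cls(accession, t, m, h, qc_flags=qc)

    def __len__(self) -> int:
        return self.timepoints.size


@dataclass
class TurnoverFit:
    """Result of the turnover cascade for one proteoform."""

    accession: str
    method: str  # 'exponential' | 'linear' | 'invalid'
    n_timepoints: int
    B: float = math.nan
    r2: float = math.nan
    t_turn: float = math.nan
    k_deg: float = math.nan
    t_half: float = math.nan

    @property
    def valid(self) -> bool:
        return self.method in ("exponential", "linear")


def normalize_ratios(ml: float, hl: float) -> tuple[float, float]:
    """Normalise an (M/L, H/L) ratio pair so the fractions sum to one.

    Returns ``(m, h) = (ml, hl) / (ml + hl)``; raises for negative input or
    a zero sum, where no normalisation exists.
    """
    if ml < 0 or hl < 0:
        raise ValidationError(f"ratios must be non-negative, got ({ml}, {hl})")
    total = ml + hl
    if total <= 0:
        raise ValidationError("cannot normalise: M/L + H/L is zero")
    return ml / total, hl / total


def fit_exponential(
    tc: NormalizedTimeCourse | None = None,
    *,
    timepoints: Sequence[float] | None = None,
    m: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Least-squares fit of m(t) = exp(B t) to the degradation fraction.

    The single parameter B is found by nonlinear least squares in ratio
    space (not log space, which would reweight the noise), initialised from
    the log-linear slope over positive m values.  Returns ``(B, r2)`` with
    R^2 = 1 - SS_res/SS_tot about the mean of the observed m.

    Raises
    ------
    DegenerateFitError
        Fewer than two distinct timepoints, or constant m (SS_tot = 0).
    """
    if tc is not None:
        t = np.asarray(tc.timepoints, dtype=float)
        y = np.asarray(tc.m, dtype=float)
    else:
        t = np.asarray(timepoints, dtype=float)
        y = np.asarray(m, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if np.unique(t).size < 2:
        raise DegenerateFitError("need >= 2 distinct timepoints")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateFitError("constant m values: SS_tot = 0")

    pos = y > 0
    if pos.sum() >= 2 and np.unique(t[pos]).size >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        b0 = float(np.clip(slope, -20.0, 20.0))
    else:
        b0 = -0.1

    def residuals(b: np.ndarray) -> np.ndarray:
        return np.exp(np.clip(b[0] * t, -700, 700)) - y

    sol = optimize.least_squares(residuals, x0=[b0], method="lm")
    # lm can stall on a poor start; refine with a second start if needed
    if not sol.success or sol.cost > 1e3:
        alt = optimize.least_squares(residuals, x0=[-0.05], method="lm")
        if alt.cost < sol.cost:
            sol = alt
    B = float(sol.x[0])
    ss_res = float(np.sum(residuals(sol.x) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return B, r2


def turnover_from_B(B: float) -> float:
    """50% turnover time t_turn = ln(1/2)/B for a descending profile (B < 0)."""
    if not np.isfinite(B) or B >= 0:
        raise NoCrossingError(
            f"profile with B = {B} never crosses 50%: no turnover time"
        )
    return math.log(0.5) / B


def _descending_trend(tc: NormalizedTimeCourse) -> bool:
    """Spearman correlation of m versus t is negative (monotone decrease)."""
    if len(tc) < 2:
        return False
    rho = stats.spearmanr(tc.timepoints, tc.m).statistic
    return bool(np.isfinite(rho) and rho < 0)


def linear_crossing(tc: NormalizedTimeCourse) -> float:
    """Turnover time from linear interpolation at the m/h crossing point.

    Uses the earliest pair of consecutive observed timepoints bracketing
    m = 0.5 (m_i >= 0.5 >= m_{i+1}); the chords through the two m points
    and the two h points intersect where the interpolated m equals 1/2
    because h = 1 - m.  A descending overall trend is required.
    """
    if len(tc) < 2:
        raise NoCrossingError("need >= 2 timepoints for linear interpolation")
    if not _descending_trend(tc):
        raise NoCrossingError("no descending trend in m(t)")
    t, m = tc.timepoints, tc.m
    for i in range(len(t) - 1):
        if m[i] == 0.5:
            return float(t[i])
        if m[i] > 0.5 and m[i + 1] <= 0.5:
            frac = (m[i] - 0.5) / (m[i] - m[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    if m[-1] == 0.5:
        return float(t[-1])
    raise NoCrossingError("no consecutive pair brackets the 50% crossing")


def half_life(B: float, config: KineticsConfig | None = None) -> tuple[float, float]:
    """Degradation constant and division-corrected half-life from B.

    k_deg = -B - ln(2)/t_cc; for k_deg > 0, t_half = ln(2)/k_deg, otherwise
    loss is dilution-dominated and the half-life is reported as infinite.
    """
    config = config or KineticsConfig()
    if not np.isfinite(B):
        raise ValidationError("B must be finite")
    k_deg = -B - LN2 / config.t_cc
    t_half = LN2 / k_deg if k_deg > 0 else math.inf
    return k_deg, t_half


def compute_turnover(
    tc: NormalizedTimeCourse, config: KineticsConfig | None = None
) -> TurnoverFit:
    """Run the full decision cascade for one proteoform.

    1. fewer than ``min_timepoints`` observations -> invalid;
    2. exponential fit with R^2 >= threshold and B < 0 -> exponential;
    3. otherwise, a descending profile with a bracketing pair -> linear;
    4. otherwise invalid (excluded from analysis).

    k_deg and t_half are derived from the exponential B whenever that fit
    produced one, even when the turnover time itself comes from the linear
    fallback.
    """
    config = config or KineticsConfig()
    n = len(tc)
    fit = TurnoverFit(accession=tc.accession, method="invalid", n_timepoints=n)
    if n < config.min_timepoints:
        return fit
    try:
        B, r2 = fit_exponential(tc)
        fit.B, fit.r2 = B, r2
    except DegenerateFitError:
        B, r2 = math.nan, math.nan
    if np.isfinite(B):
        fit.k_deg, fit.t_half = half_life(B, config)
    if np.isfinite(r2) and r2 >= config.r2_threshold and B < 0:
        fit.method = "exponential"
        fit.t_turn = turnover_from_B(B)
        return fit
    try:
        fit.t_turn = linear_crossing(tc)
        fit.method = "linear"
    except NoCrossingError:
        fit.method = "invalid"
        fit.t_turn = math.nan
    return fit


def subsample_turnover(
    tc: NormalizedTimeCourse, k: int = 3, config: KineticsConfig | None = None
) -> list[float]:
    """Turnover times from exponential fits to every k-point subset.

    Fits each of the C(n, k) timepoint subsets, keeps those with
    R^2 >= threshold and B < 0, and returns their turnover times (a
    box-plot-ready multiset assessing how few observations suffice).
    """
    config = config or KineticsConfig()
    if len(tc) < k:
        raise ValidationError(f"time course has {len(tc)} < k = {k} points")
    out: list[float] = []
    idx = np.arange(len(tc))
    for subset in combinations(idx, k):
        sub = np.array(subset)
        try:
            B, r2 = fit_exponential(
                timepoints=tc.timepoints[sub], m=tc.m[sub]
            )
        except DegenerateFitError:
            continue
        if r2 >= config.r2_threshold and B < 0:
            out.append(turnover_from_B(B))
    return out


def doubling_time(
    densities: Sequence[float], times: Sequence[float]
) -> float:
    """Cell doubling time from a growth curve: t_cc = ln(2)/r.

    The growth rate r is the least-squares slope of ln(density) versus
    time; requires at least two positive densities and net growth.
    """
    d = np.asarray(densities, dtype=float)
    t = np.asarray(times, dtype=float)
    if d.size != t.size or d.size < 2:
        raise ValidationError("need >= 2 paired density/time measurements")
    if np.any(d <= 0):
        raise ValidationError("densities must be positive")
    r = np.polyfit(t, np.log(d), 1)[0]
    if r <= 0:
        raise ValidationError(f"non-positive growth rate r = {r}")
    return LN2 / float(r)


# ---------------------------------------------------------------------------
# Cohort-level model / results objects
# ---------------------------------------------------------------------------


class TurnoverModel:
    """Exponential turnover model for a cohort of pSILAC time courses.

    Built from a long-format table with one row per proteoform and
    timepoint; ``fit()`` runs the per-proteoform cascade and returns a
    :class:`TurnoverResults`.

    Parameters
    ----------
    timecourses : list of NormalizedTimeCourse
    config : KineticsConfig, optional
    """

    def __init__(
        self,
        timecourses: Iterable[NormalizedTimeCourse],
        config: KineticsConfig | None = None,
    ) -> None:
        self.timecourses = list(timecourses)
        self.config = config or KineticsConfig()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        config: KineticsConfig | None = None,
        accession_col: str = "accession",
        time_col: str = "timepoint_h",
        ml_col: str = "ratio_ML",
        hl_col: str = "ratio_HL",
    ) -> "TurnoverModel":
        """Build from a long-format ratio table (one row per timepoint)."""
        for col in (accession_col, time_col, ml_col, hl_col):
            if col not in data.columns:
                raise ValidationError(f"missing required column {col!r}")
        tcs = []
        for acc, grp in data.groupby(accession_col, sort=True):
            grp = grp.sort_values(time_col)
            tcs.append(
                NormalizedTimeCourse.from_ratios(
                    str(acc),
                    grp[time_col].to_numpy(),
                    grp[ml_col].to_numpy(),
                    grp[hl_col].to_numpy(),
                )
            )
        return cls(tcs, config=config)

    def fit(self) -> "TurnoverResults":
        fits = [compute_turnover(tc, self.config) for tc in self.timecourses]
        return TurnoverResults(self, fits)


@dataclass
class TurnoverResults:
    """Per-proteoform turnover estimates with cohort summaries."""

    model: TurnoverModel
    fits: list[TurnoverFit] = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": [f.accession for f in self.fits],
                "n_timepoints": [f.n_timepoints for f in self.fits],
                "method": [f.method for f in self.fits],
                "B": [f.B for f in self.fits],
                "R2": [f.r2 for f in self.fits],
                "t_turn_h": [f.t_turn for f in self.fits],
                "k_deg_per_h": [f.k_deg for f in self.fits],
                "t_half_h": [f.t_half for f in self.fits],
            }
        )

    def funnel(self) -> dict[str, int]:
        """Filter-funnel counts: identified -> enough timepoints -> valid."""
        cfg = self.model.config
        n_all = len(self.fits)
        n_enough = sum(f.n_timepoints >= cfg.min_timepoints for f in self.fits)
        n_valid = sum(f.valid for f in self.fits)
        return {
            "identified": n_all,
            "min_timepoints": n_enough,
            "valid_turnover": n_valid,
        }

    def summary(self) -> str:
        tab = self.table
        valid = tab[tab["method"] != "invalid"]
        fun = self.funnel()
        lines = [
            "Proteoform turnover model (m(t) = exp(B t))",
            "=" * 46,
            f"proteoforms identified     : {fun['identified']}",
            f">= {self.model.config.min_timepoints} timepoints            "
            f": {fun['min_timepoints']}",
            f"valid turnover assigned    : {fun['valid_turnover']}",
            f"  exponential (R2 >= {self.model.config.r2_threshold:.2f}) "
            f" : {(tab['method'] == 'exponential').sum()}",
            f"  linear fallback          : {(tab['method'] == 'linear').sum()}",
        ]
        if len(valid):
            lines += [
                f"median t_turn [h]          : {valid['t_turn_h'].median():.2f}",
                f"median R2 (exponential)    : "
                f"{tab.loc[tab['method'] == 'exponential', 'R2'].median():.3f}",
            ]
            finite_half = valid["t_half_h"][np.isfinite(valid["t_half_h"])]
            if len(finite_half):
                lines.append(
                    f"median finite t_half [h]   : {finite_half.median():.2f}"
                )
        return "\n".join(lines)

    def plot_fit(self, accession: str, ax=None):
        """Plot one proteoform's m/h data with its fitted decay curve."""
        import matplotlib.pyplot as plt

        tc = next(
            t for t in self.model.timecourses if t.accession == accession
        )
        fit = next(f for f in self.fits if f.accession == accession)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(tc.timepoints, tc.m, "o", label="m (degradation)")
        ax.plot(tc.timepoints, tc.h, "s", label="h (synthesis)")
        if np.isfinite(fit.B):
            tt = np.linspace(0, tc.timepoints.max(), 200)
            ax.plot(tt, np.exp(fit.B * tt), "-", label=f"exp(Bt), B={fit.B:.3g}")
        if np.isfinite(fit.t_turn):
            ax.axvline(fit.t_turn, ls=":", color="grey")
            ax.axhline(0.5, ls=":", color="grey")
        ax.set_xlabel("time after label swap [h]")
        ax.set_ylabel("normalised fraction")
        ax.set_title(f"{accession} ({fit.method})")
        ax.legend()
        return ax
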