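"""Comparative statistics for proteoform turnover, abundance and disorder.

Nonparametric throughout: one-sided Mann-Whitney U for independent groups,
one-sided Wilcoxon signed-rank for paired dbTIS/aTIS data, Kruskal-Wallis
over N-terminal residue groups with two post-hoc procedures (the
critical-difference-of-mean-ranks multiple comparison and uncorrected
pairwise Wilcoxon), a pairwise-difference Mann-Whitney dispersion test for
members of macromolecular complexes, Spearman/Pearson correlation, and a
simplified 1D category-enrichment operation with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "ComplexDispersionResult",
    "compare_groups",
    "residue_group_analysis",
    "kruskal_with_posthoc",
    "complex_dispersion",
    "ubiquitination_comparison",
    "correlate",
    "enrichment_1d",
    "extreme_decile_analysis",
]

EXACT_MAX_N = 25  # exact rank-test p-values up to this size when tie-free
PERM_MAX_N = 8  # exact permutation p-values for tied samples up to this size


def _mw_exact_permutation(
    a: np.ndarray, b: np.ndarray, alternative: str
) -> float:
    """Exact MW p for tied samples: permute group labels over mid-ranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    obs = ranks[: a.size].sum()
    hits = total = 0
    for idx in combinations(range(pooled.size), a.size):
        r = ranks[list(idx)].sum()
        total += 1
        if alternative == "less":
            hits += r <= obs
        elif alternative == "greater":
            hits += r >= obs
    if alternative == "two-sided":
        return min(
            1.0,
            2.0
            * min(
                _mw_exact_permutation(a, b, "less"),
                _mw_exact_permutation(a, b, "greater"),
            ),
        )
    return hits / total


def _wsr_exact_permutation(diffs: np.ndarray, alternative: str) -> float:
    """Exact signed-rank p for tied |differences|: enumerate sign flips."""
    from itertools import product as iproduct

    ranks = sps.rankdata(np.abs(diffs))
    obs = ranks[diffs > 0].sum()
    hits = total = 0
    for signs in iproduct((False, True), repeat=diffs.size):
        w = ranks[np.array(signs)].sum() if any(signs) else 0.0
        total += 1
        if alternative == "less":
            hits += w <= obs
        elif alternative == "greater":
            hits += w >= obs
    if alternative == "two-sided":
        return min(
            1.0,
            2.0
            * min(
                _wsr_exact_permutation(diffs, "less"),
                _wsr_exact_permutation(diffs, "greater"),
            ),
        )
    return hits / total


@dataclass
class ComparisonResult:
    """Outcome of one two-group comparison."""

    variable: str
    test: str
    alternative: str
    p_value: float
    n_a: int
    n_b: int
    statistic: float = math.nan
    alpha: float = 0.05
    conclusion: str = ""

    def __post_init__(self) -> None:
        if not self.conclusion:
            if math.isnan(self.p_value):
                self.conclusion = "degenerate"
            elif self.p_value <= self.alpha:
                self.conclusion = f"significant ({self.alternative})"
            else:
                self.conclusion = "not significant"

    @property
    def significant(self) -> bool:
        return (
            not math.isnan(self.p_value) and self.p_value <= self.alpha
        )


@dataclass
class ComplexDispersionResult:
    """Per-complex outcome of the pairwise-difference outlier test."""

    complex_id: str
    members: list[str]
    turnover: list[float]
    p_values: list[float]
    outlier_flags: list[bool]

    @property
    def label(self) -> str:
        return "has-outliers" if any(self.outlier_flags) else "consistent"

    @property
    def outliers(self) -> list[str]:
        return [m for m, f in zip(self.members, self.outlier_flags) if f]


def _has_ties(*samples: np.ndarray) -> bool:
    pooled = np.concatenate(samples)
    return np.unique(pooled).size < pooled.size


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
    alternative: str = "two-sided",
    variable: str = "custom",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-group nonparametric comparison.

    Independent groups use the Mann-Whitney U test, paired groups the
    Wilcoxon signed-rank test; ``alternative`` ('less', 'greater',
    'two-sided') states the direction of A relative to B.  P-values are
    exact for tie-free samples of up to 25 and for tied samples of
    up to 8 per group (full mid-rank permutation), normal-approximated with
    tie correction otherwise.  Identical paired samples yield no signed
    ranks; the result is flagged degenerate (p = NaN) rather than raised.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    if paired:
        if a.size != b.size:
            raise ValidationError("paired samples must have equal lengths")
        diffs = a - b
        if np.all(diffs == 0):
            return ComparisonResult(
                variable, "wilcoxon-signed-rank", alternative,
                math.nan, a.size, b.size, alpha=alpha,
            )
        nz = diffs[diffs != 0]
        if nz.size <= PERM_MAX_N and _has_ties(np.abs(nz)):
            return ComparisonResult(
                variable, "wilcoxon-signed-rank", alternative,
                _wsr_exact_permutation(nz, alternative),
                a.size, b.size, alpha=alpha,
            )
        method = (
            "exact"
            if nz.size <= EXACT_MAX_N and not _has_ties(np.abs(nz))
            else "approx"
        )
        res = sps.wilcoxon(
            a, b, alternative=alternative, method=method,
            zero_method="wilcox",
        )
        return ComparisonResult(
            variable, "wilcoxon-signed-rank", alternative,
            float(res.pvalue), a.size, b.size,
            statistic=float(res.statistic), alpha=alpha,
        )
    if max(a.size, b.size) <= PERM_MAX_N and _has_ties(a, b):
        return ComparisonResult(
            variable, "mann-whitney", alternative,
            _mw_exact_permutation(a, b, alternative),
            a.size, b.size, alpha=alpha,
        )
    method = (
        "exact"
        if max(a.size, b.size) <= EXACT_MAX_N and not _has_ties(a, b)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return ComparisonResult(
        variable, "mann-whitney", alternative,
        float(res.pvalue), a.size, b.size,
        statistic=float(res.statistic), alpha=alpha,
    )


@dataclass
class KruskalResult:
    """Kruskal-Wallis outcome with both post-hoc procedures."""

    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    critical_difference_pairs: list[tuple[str, str]] = field(
        default_factory=list
    )
    pairwise_wilcoxon: dict[tuple[str, str], float] = field(
        default_factory=dict
    )

    @property
    def deviating_pairs_wilcoxon(self) -> list[tuple[str, str]]:
        return [k for k, p in self.pairwise_wilcoxon.items() if p < 0.05]


def kruskal_with_posthoc(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> KruskalResult:
    """Kruskal-Wallis H test plus the two post-hoc procedures.

    The multiple-comparison procedure declares groups i, j different when
    |mean_rank_i - mean_rank_j| exceeds the critical difference
    z_{1 - alpha/(k(k-1))} * sqrt(N(N+1)/12 * (1/n_i + 1/n_j)), computed
    on pooled mid-ranks (Siegel & Castellan construction).  Pairwise
    Wilcoxon rank-sum p-values are reported without multiple-testing
    correction.
    """
    names = sorted(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if len(samples) < 2:
        raise ValidationError("need at least two groups")
    if any(s.size < 2 for s in samples):
        raise ValidationError("every group needs >= 2 members")
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            H, p = sps.kruskal(*samples)
    if math.isnan(H):  # all values identical across groups
        H, p = 0.0, 1.0

    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    sizes = np.array([s.size for s in samples])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = {
        g: ranks[bounds[i] : bounds[i + 1]].mean()
        for i, g in enumerate(names)
    }
    N = pooled.size
    k = len(names)
    z = sps.norm.ppf(1.0 - alpha / (k * (k - 1)))
    cd_pairs = []
    pw: dict[tuple[str, str], float] = {}
    for (i, gi), (j, gj) in combinations(enumerate(names), 2):
        cd = z * math.sqrt(
            N * (N + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        if abs(mean_ranks[gi] - mean_ranks[gj]) > cd:
            cd_pairs.append((gi, gj))
        pw[(gi, gj)] = compare_groups(
            samples[i], samples[j], alternative="two-sided"
        ).p_value
    return KruskalResult(
        statistic=float(H),
        p_value=float(p),
        group_sizes={g: int(s) for g, s in zip(names, sizes)},
        critical_difference_pairs=cd_pairs,
        pairwise_wilcoxon=pw,
    )


def residue_group_analysis(
    records: pd.DataFrame,
    value_col: str = "t_turn_h",
    n_residues: int = 1,
    sequence_col: str = "peptide",
    imet_col: str = "imet_status",
    min_group_size: int = 2,
    alpha: float = 0.05,
) -> KruskalResult:
    """Effect of the N-terminal residue(s) and iMet processing on turnover.

    Proteoforms are grouped by their first ``n_residues`` residue(s), with
    iMet-susceptible N-termini split into Met-retaining and Met-cleaved
    subgroups, and compared with Kruskal-Wallis plus post-hoc procedures.
    """
    df = records.dropna(subset=[value_col])
    groups: dict[str, list[float]] = {}
    for _, row in df.iterrows():
        key = str(row[sequence_col])[:n_residues].upper()
        status = row.get(imet_col, "not-applicable")
        if status in ("retained", "processed"):
            key = f"{key}-{status}"
        groups.setdefault(key, []).append(float(row[value_col]))
    groups = {
        g: v for g, v in groups.items() if len(v) >= min_group_size
    }
    if len(groups) < 2:
        raise ValidationError(
            "fewer than two residue groups with enough members"
        )
    return kruskal_with_posthoc(groups, alpha=alpha)


def complex_dispersion(
    turnover: Mapping[str, float] | pd.Series,
    complexes: pd.DataFrame,
    alpha: float = 0.05,
    min_members: int = 3,
) -> list[ComplexDispersionResult]:
    """Detect turnover outliers within macromolecular complexes.

    For each member i of a complex, the absolute turnover differences
    {|t_i - t_j|, j != i} are compared against the pairwise differences
    among the remaining members with a one-sided Mann-Whitney test
    (greater); members with p <= alpha are flagged.  Complexes with fewer
    than ``min_members`` quantified members are skipped with a log entry.
    """
    if isinstance(turnover, pd.Series):
        turnover = turnover.to_dict()
    results = []
    for cid, grp in complexes.groupby("complex_id", sort=True):
        members = [
            a for a in grp["accession"] if a in turnover
            and np.isfinite(turnover[a])
        ]
        if len(members) < min_members:
            logger.info(
                "complex %s skipped: %d quantified members (< %d)",
                cid, len(members), min_members,
            )
            continue
        values = np.array([turnover[a] for a in members])
        n = len(members)
        pvals, flags = [], []
        for i in range(n):
            others = np.delete(values, i)
            test_set = np.abs(values[i] - others)
            ref_set = np.array(
                [
                    abs(x - y)
                    for x, y in combinations(others, 2)
                ]
            )
            res = compare_groups(
                test_set, ref_set, alternative="greater"
            )
            pvals.append(res.p_value)
            flags.append(res.p_value <= alpha)
        results.append(
            ComplexDispersionResult(
                complex_id=str(cid),
                members=members,
                turnover=[float(v) for v in values],
                p_values=pvals,
                outlier_flags=flags,
            )
        )
    return results


def ubiquitination_comparison(
    records: pd.DataFrame,
    value_col: str = "t_turn_h",
    lysine_col: str = "lysine_count",
    evidence_col: str = "ubiquitination_evidence",
    category_col: str = "category",
    alternative: str = "less",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Stability of ubiquitinated versus non-ubiquitinated dbTIS N-termini.

    Group A: dbTIS proteoforms with at least one detected ubiquitination
    site; group B: dbTIS with at least one lysine but no evidence.  The
    default one-sided alternative tests whether ubiquitinated proteoforms
    turn over faster (smaller turnover times).
    """
    db = records[records[category_col] == "dbTIS"]
    a = db.loc[db[evidence_col].astype(bool), value_col].dropna()
    b = db.loc[
        (~db[evidence_col].astype(bool)) & (db[lysine_col] >= 1), value_col
    ].dropna()
    if a.empty or b.empty:
        raise ValidationError(
            "empty comparison group (need ubiquitinated and "
            "lysine-bearing unmodified dbTIS)"
        )
    return compare_groups(
        a, b, alternative=alternative, variable="turnover-ubiquitination",
        alpha=alpha,
    )


def label_pair_delta(delta_turnover: float, threshold: float = 2.0) -> str:
    """Label a per-pair turnover difference against the relevance threshold."""
    if abs(delta_turnover) < threshold:
        return f"irrelevant difference (<{threshold:g} h)"
    return "destabilised" if delta_turnover < 0 else "stabilised"


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "rank"
) -> float:
    """Spearman ('rank') or Pearson ('linear') correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal lengths")
    if x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if method == "rank":
        return float(sps.spearmanr(x, y).statistic)
    if method == "linear":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValidationError("constant input: Pearson r undefined")
        return float(sps.pearsonr(x, y).statistic)
    raise ValidationError(f"unknown method {method!r}")


def enrichment_1d(
    assignments: Mapping[str, Sequence[bool]] | pd.DataFrame,
    values: Sequence[float],
    two_sided: bool = True,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Simplified 1D enrichment of categorical terms in a numeric variable.

    For every category, members' values are compared against
    non-members' with a Mann-Whitney test (two-sided by default);
    Benjamini-Hochberg FDR is computed across testable categories and a
    direction label states whether the category prefers larger or smaller
    values.  Categories with fewer than two members or two non-members
    are skipped with a log entry.
    """
    vals = np.asarray(values, dtype=float)
    if isinstance(assignments, pd.DataFrame):
        assignments = {
            str(c): assignments[c].to_numpy() for c in assignments.columns
        }
    rows = []
    for cat in sorted(assignments):
        mask = np.asarray(assignments[cat], dtype=bool)
        if mask.size != vals.size:
            raise ValidationError(
                f"category {cat!r} mask does not match values"
            )
        inside, outside = vals[mask], vals[~mask]
        if inside.size < 2 or outside.size < 2:
            logger.info("category %s skipped: too few members", cat)
            continue
        res = compare_groups(
            inside, outside,
            alternative="two-sided" if two_sided else "greater",
        )
        direction = (
            "larger"
            if np.median(inside) >= np.median(outside)
            else "smaller"
        )
        rows.append(
            {
                "category": cat,
                "n_in": inside.size,
                "n_out": outside.size,
                "p_value": res.p_value,
                "direction": direction,
            }
        )
    if not rows:
        raise ValidationError("no testable categories")
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] <= alpha
    return out


def extreme_decile_analysis(
    turnover: Sequence[float],
    feature: Sequence[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Are the most and least stable deciles enriched for a feature?

    Flags the bottom and top 10% of proteoforms by turnover time and runs
    the 1D enrichment of each decile against the feature values, with
    BH-FDR over the two tests.
    """
    t = np.asarray(turnover, dtype=float)
    f = np.asarray(feature, dtype=float)
    if t.size != f.size:
        raise ValidationError("turnover and feature must align")
    if t.size < 20:
        raise ValidationError("need >= 20 records for decile analysis")
    lo, hi = np.quantile(t, [0.1, 0.9])
    assignments = {
        "unstable_decile": t <= lo,
        "stable_decile": t >= hi,
    }
    out = enrichment_1d(assignments, f, two_sided=True, alpha=alpha)
    return out
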