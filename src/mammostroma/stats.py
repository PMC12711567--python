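"""Assay arithmetic and the shared nonparametric/parametric statistics.

Covers mammosphere-forming efficiency, clonogenic colony metrics, lobule
morphometry, the paired Wilcoxon signed-rank test (exact by rank-sum
enumeration when there are no ties, tie-corrected normal approximation
otherwise), within-subject one-way repeated-measures ANOVA with Sidak
multiple-comparison adjustment, paired correlations, and the
round-half-away-from-zero percentage arithmetic used in reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SphereAssay",
    "ColonyAssay",
    "LobuleMorphometry",
    "PairedTestResult",
    "AnovaResult",
    "mfe_percent",
    "colony_metrics",
    "morphometry_summary",
    "wilcoxon_signed_rank",
    "sidak_adjust",
    "rm_anova",
    "paired_correlation",
    "category_fraction",
]

EXACT_N_MAX = 25  # largest n for which the exact signed-rank distribution is used


# --------------------------------------------------------------------------
# assay containers and arithmetic
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereAssay:
    """A mammosphere well: seeded cell count and measured sphere diameters."""

    n_cells_seeded: int
    sphere_diameters_um: tuple[float, ...]
    diameter_threshold_um: float = 50.0
    seeding_density_per_cm2: float = 1000.0  # metadata only


def mfe_percent(assay: SphereAssay) -> float:
    """Mammosphere-forming efficiency: spheres of at least the threshold
    diameter per cell seeded, as a percentage (threshold inclusive)."""
    if assay.n_cells_seeded <= 0:
        raise ValueError("n_cells_seeded must be positive")
    n = sum(1 for d in assay.sphere_diameters_um if d >= assay.diameter_threshold_um)
    return 100.0 * n / assay.n_cells_seeded


@dataclass(frozen=True)
class ColonyAssay:
    cluster_sizes: tuple[int, ...]
    colony_min_cells: int = 50
    type_counts: dict | None = None  # {"luminal": k, "mixed": k, "basal": k}


def colony_metrics(assay: ColonyAssay) -> dict:
    """Colony count (clusters of >= colony_min_cells, inclusive) and type
    proportions in percent of typed colonies."""
    if any(s < 0 for s in assay.cluster_sizes):
        raise ValueError("cluster sizes must be nonnegative")
    n_colonies = sum(1 for s in assay.cluster_sizes if s >= assay.colony_min_cells)
    out = {"n_colonies": n_colonies}
    if assay.type_counts is not None:
        total = sum(assay.type_counts.values())
        if total == 0:
            raise ValueError("type proportions undefined: no typed colonies")
        out["type_percent"] = {
            k: 100.0 * v / total for k, v in assay.type_counts.items()
        }
    return out


@dataclass(frozen=True)
class LobuleMorphometry:
    lobule_area: float
    epithelial_area: float
    acinus_areas: tuple[float, ...] = ()

    def epithelial_fraction(self) -> float:
        if self.lobule_area <= 0:
            raise ValueError("lobule area must be positive")
        if self.epithelial_area > self.lobule_area:
            raise ValueError("epithelial area exceeds lobule area")
        return self.epithelial_area / self.lobule_area


def morphometry_summary(lobules, min_lobules: int = 3) -> dict:
    """Participant-level means of per-lobule epithelial (acinar-to-lobular)
    fraction and mean acinus area; warns below ``min_lobules`` lobules."""
    if not lobules:
        raise ValueError("at least one lobule required")
    if len(lobules) < min_lobules:
        warnings.warn(
            f"only {len(lobules)} lobules; at least {min_lobules} recommended",
            stacklevel=2,
        )
    fracs = [lb.epithelial_fraction() for lb in lobules]
    acinus = [np.mean(lb.acinus_areas) for lb in lobules if lb.acinus_areas]
    return {
        "n_lobules": len(lobules),
        "mean_epithelial_fraction": float(np.mean(fracs)),
        "mean_acinus_area": float(np.mean(acinus)) if acinus else float("nan"),
    }


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    statistic: float          # W, sum of positive ranks
    p_value: float
    method: str               # "exact" | "tie_corrected_normal"
    n_effective: int          # non-zero differences used


def _signed_rank_counts(n: int) -> np.ndarray:
    """counts[w] = number of sign assignments over ranks 1..n with positive-rank
    sum w; the standard convolution recursion for the null distribution."""
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return counts


def wilcoxon_signed_rank(differences) -> PairedTestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped.  With no ties and n <= 25 the exact null
    distribution of W (sum of positive ranks) is used; otherwise a normal
    approximation with tie-corrected variance
    ``var = n(n+1)(2n+1)/24 - sum(t^3 - t)/48``.
    """
    d = np.asarray(differences, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    if n < 2:
        raise ValueError("need at least 2 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n

    if not has_ties and n <= EXACT_N_MAX:
        counts = _signed_rank_counts(n)
        total = counts.sum()
        w = int(round(w_pos))
        p_le = counts[: w + 1].sum() / total
        p_ge = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return PairedTestResult(w_pos, float(p), "exact", n)

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts.astype(float) ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise ValueError("degenerate variance: all differences tied at one value")
    z = (w_pos - mu) / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return PairedTestResult(w_pos, p, "tie_corrected_normal", n)


# --------------------------------------------------------------------------
# Sidak adjustment and repeated-measures ANOVA
# --------------------------------------------------------------------------

def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment p_adj = 1 - (1 - p)^m."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.clip(1.0 - np.power(1.0 - p, m), 0.0, 1.0)


@dataclass
class AnovaResult:
    """Within-subject one-way RM-ANOVA with Sidak-adjusted pairwise contrasts."""

    f_statistic: float
    p_value: float
    df_condition: int
    df_error: int
    n_subjects: int
    conditions: tuple[str, ...]
    contrasts: pd.DataFrame = field(repr=False)  # cond_a, cond_b, t, p, p_sidak

    def summary(self) -> str:
        lines = [
            f"Repeated-measures one-way ANOVA: F({self.df_condition}, "
            f"{self.df_error}) = {self.f_statistic:.4f}, p = {self.p_value:.4g}, "
            f"n = {self.n_subjects} subjects, {len(self.conditions)} conditions",
            "Pairwise contrasts (paired t, Sidak-adjusted):",
        ]
        for _, r in self.contrasts.iterrows():
            lines.append(
                f"  {r.cond_a} vs {r.cond_b}: t = {r.t:.3f}, "
                f"p = {r.p:.4g}, p_sidak = {r.p_sidak:.4g}"
            )
        return "\n".join(lines)


def rm_anova(frame: pd.DataFrame, subject: str = "participant",
             condition: str = "condition", value: str = "value") -> AnovaResult:
    """One-way repeated-measures ANOVA on a long table.

    Subjects with incomplete blocks are excluded with a warning; fewer than
    three complete subjects is an error.  Pairwise condition contrasts use
    paired t-tests with Sidak adjustment over the number of contrasts.
    """
    wide = frame.pivot_table(index=subject, columns=condition, values=value)
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"excluding subjects with incomplete blocks: {list(incomplete)}",
            stacklevel=2,
        )
        wide = wide.dropna()
    n, k = wide.shape
    if n < 3:
        raise ValueError("repeated-measures ANOVA requires >= 3 complete subjects")
    if k < 2:
        raise ValueError("need at least 2 conditions")

    x = wide.to_numpy(float)
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_c, df_e = k - 1, (k - 1) * (n - 1)
    f = (ss_cond / df_c) / (ss_err / df_e)
    p = float(sps.f.sf(f, df_c, df_e))

    pairs = list(combinations(wide.columns, 2))
    rows = []
    for a, b in pairs:
        t, pt = sps.ttest_rel(wide[a], wide[b])
        rows.append({"cond_a": a, "cond_b": b, "t": float(t), "p": float(pt)})
    contrasts = pd.DataFrame(rows)
    contrasts["p_sidak"] = sidak_adjust(contrasts["p"], m=len(pairs))
    return AnovaResult(float(f), p, df_c, df_e, n, tuple(wide.columns), contrasts)


# --------------------------------------------------------------------------
# correlations and reporting fractions
# --------------------------------------------------------------------------

def paired_correlation(x, y, method: str = "pearson"):
    """Product-moment or Spearman rank correlation with two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r = sps.pearsonr(x, y)
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def category_fraction(k: int, n: int, rounding: str = "one_decimal") -> float:
    """Percentage 100*k/n rounded half-away-from-zero to the reporting
    precision (``one_decimal`` or ``integer``)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    pct = Decimal(100 * k) / Decimal(n)
    q = Decimal("0.1") if rounding == "one_decimal" else Decimal("1")
    if rounding not in ("one_decimal", "integer"):
        raise ValueError(f"unknown rounding {rounding!r}")
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def fraction_from_flags(flags, rounding: str = "one_decimal") -> float:
    flags = list(flags)
    return category_fraction(sum(bool(f) for f in flags), len(flags), rounding)
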