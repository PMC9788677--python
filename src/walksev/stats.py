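"""The evaluation statistics battery.

Association of the continuous severity outcome with clinician-rated EDSS
(Pearson r, Spearman ρ, least-squares line), a Kruskal–Wallis test of median
severity across the three strata, and the before/after event battery: a
Brown–Forsythe test by medians gates the choice between Student's and
Welch's t-test, and a Mann–Whitney U test compares medians.  All tests are
two-sided; no multiple-testing correction is applied by default (a Holm
option is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class AssociationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    r_squared: float
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class BeforeAfterResult:
    """Variance-gated before/after battery.

    ``welch_applied`` is True iff the Brown–Forsythe (by medians) p-value
    falls below ``alpha``, in which case the t-test is Welch's rather than
    Student's.  The Mann–Whitney U test is always computed.
    """

    bf_stat: float
    bf_p: float
    t_stat: float
    t_p: float
    welch_applied: bool
    u_stat: float
    u_p: float
    n_before: int
    n_after: int
    alpha: float = 0.05
    computable: bool = True
    reason: str = ""


def associate_with_edss(severity, edss) -> AssociationResult:
    """Pearson and Spearman association between per-subject mean severity
    and per-subject mean EDSS, with the least-squares line."""
    x = np.asarray(edss, dtype=float)
    y = np.asarray(severity, dtype=float)
    if len(x) != len(y):
        raise ValueError("severity and EDSS must be the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in severity or EDSS")
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    fit = sps.linregress(x, y)
    r = float(pr.statistic)
    return AssociationResult(
        pearson_r=r, pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        r_squared=r * r,
        slope=float(fit.slope), intercept=float(fit.intercept), n=len(x))


def group_test(groups: dict[str, np.ndarray] | list[np.ndarray]):
    """Kruskal–Wallis H (rank-based, tie-corrected) across severity groups.

    Returns (H, p) with the chi-square p-value."""
    samples = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for g in samples:
        if len(g) < 1:
            raise ValueError("empty group")
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def brown_forsythe(a, b) -> tuple[float, float]:
    """Brown–Forsythe homogeneity-of-variance test: the Levene-type
    statistic on absolute deviations from the group *median*."""
    stat, p = sps.levene(np.asarray(a, float), np.asarray(b, float),
                         center="median")
    return float(stat), float(p)


def before_after_tests(before, after, alpha: float = 0.05) -> BeforeAfterResult:
    """Run the full before/after battery on two samples of daily severities.

    Degenerate input (both sides constant) is reported as not-computable
    rather than as NaN statistics."""
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each side needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        equal = a[0] == b[0]
        return BeforeAfterResult(
            bf_stat=np.nan, bf_p=np.nan, t_stat=np.nan,
            t_p=1.0 if equal else np.nan, welch_applied=False,
            u_stat=np.nan, u_p=1.0 if equal else np.nan,
            n_before=len(a), n_after=len(b), alpha=alpha,
            computable=False,
            reason="both sides constant; tests degenerate")
    with warnings.catch_warnings():
        # scipy warns about precision loss when one side is near-constant;
        # legitimate here (severity often saturates at a scale endpoint)
        warnings.filterwarnings("ignore", message=".*[Pp]recision loss.*",
                                category=RuntimeWarning)
        bf_stat, bf_p = brown_forsythe(a, b)
        welch = bool(bf_p < alpha)
        t = sps.ttest_ind(a, b, equal_var=not welch)
        # exact Mann-Whitney null for small tie-free samples, otherwise the
        # normal approximation with tie and continuity correction
        small = max(len(a), len(b)) <= 8
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (small and not ties) else "asymptotic"
        u = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return BeforeAfterResult(
        bf_stat=bf_stat, bf_p=bf_p,
        t_stat=float(t.statistic), t_p=float(t.pvalue), welch_applied=welch,
        u_stat=float(u.statistic), u_p=float(u.pvalue),
        n_before=len(a), n_after=len(b), alpha=alpha)


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default in every
    pipeline path)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(p_values, float), method="holm")[1]
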