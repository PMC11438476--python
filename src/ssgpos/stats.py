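"""Repeated-measures inference on bout-level summaries.

The analysis chain mirrors standard practice in experimental sports science:
a Shapiro-Wilk normality gate routes each variable either to parametric
repeated-measures tests (one-way rm-ANOVA; one-way MANOVA with Pillai's
trace when several responses enter jointly) with Bonferroni-adjusted
pairwise post hocs, or to Friedman's rank test with Dunn's post hoc.
Effect sizes are partial eta squared, labelled by the four-class taxonomy
(no effect < 0.04 <= minimum < 0.25 <= moderate < 0.64 <= strong).
Observer-agreement analyses use ICC(3,1): two-way mixed, consistency,
single measure.

All test statistics are computed from first principles (rank sums, sums of
squares, SSCP matrices); only distribution functions come from scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import BalanceError, DegenerateVarianceError, SSGPosError


@dataclass(frozen=True)
class EffectTaxonomy:
    """Thresholds partitioning partial eta squared into labels."""

    minimum: float = 0.04
    moderate: float = 0.25
    strong: float = 0.64

    def label(self, eta2p: float) -> str:
        if not 0.0 <= eta2p <= 1.0:
            raise ValueError(f"eta2p must lie in [0, 1], got {eta2p}")
        if eta2p < self.minimum:
            return "no effect"
        if eta2p < self.moderate:
            return "minimum effect"
        if eta2p < self.strong:
            return "moderate effect"
        return "strong effect"


DEFAULT_TAXONOMY = EffectTaxonomy()


def effect_label(eta2p: float, taxonomy: EffectTaxonomy = DEFAULT_TAXONOMY) -> str:
    """Classify a partial eta squared; boundaries are lower-inclusive."""
    return taxonomy.label(eta2p)


@dataclass
class TestResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    eta2p: float | None = None
    effect: str | None = None
    extras: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None


def _as_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise BalanceError("expected a units x conditions matrix")
    if np.any(~np.isfinite(m)):
        raise BalanceError("matrix has missing cells")
    return m


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------


def normality_gate(values_by_condition: dict[str, np.ndarray], alpha: float = 0.05) -> str:
    """Shapiro-Wilk per condition; 'nonparametric' if any condition rejects.

    Constant samples (Shapiro-Wilk undefined) are flagged nonparametric with
    a warning rather than silently passed.
    """
    if not values_by_condition:
        raise SSGPosError("no samples to gate")
    for cond, vals in values_by_condition.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3:
            raise SSGPosError(
                f"condition {cond!r} has {v.size} observations; Shapiro-Wilk needs >= 3"
            )
        if np.ptp(v) == 0:
            warnings.warn(
                f"condition {cond!r} is constant; flagging nonparametric",
                stacklevel=2,
            )
            return "nonparametric"
        if sps.shapiro(v).pvalue < alpha:
            return "nonparametric"
    return "parametric"


# ---------------------------------------------------------------------------
# Friedman + Dunn
# ---------------------------------------------------------------------------


def _midranks(row: np.ndarray) -> np.ndarray:
    return sps.rankdata(row, method="average")


def friedman_test(matrix: np.ndarray, posthoc: bool = True) -> TestResult:
    """Friedman rank test across k >= 3 repeated conditions.

    Mid-ranks within each unit; the chi-square statistic carries the
    standard tie correction.  Dunn's post hoc compares condition mean ranks
    with the normal approximation, Bonferroni-adjusted over the k(k-1)/2
    pairs (adjusted p capped at 1).
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    if k < 3:
        raise BalanceError("Friedman needs k >= 3 conditions")
    if n < 2:
        raise BalanceError("Friedman needs >= 2 units")
    ranks = np.apply_along_axis(_midranks, 1, m)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction: per unit, sum of (t^3 - t) over tie groups
    tie_sum = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if denom <= 0:
        raise DegenerateVarianceError("all values tied within every unit")
    chi2 /= denom
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))

    ph = None
    if posthoc:
        mean_ranks = rank_sums / n
        se = np.sqrt(k * (k + 1) / (6.0 * n))
        n_pairs = k * (k - 1) // 2
        recs = []
        for i, j in combinations(range(k), 2):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            raw = 2.0 * float(sps.norm.sf(abs(z)))
            recs.append(
                {
                    "i": i,
                    "j": j,
                    "z": z,
                    "p_raw": raw,
                    "p_adj": min(1.0, raw * n_pairs),
                }
            )
        ph = pd.DataFrame(recs)
    # Kendall's W as a convenient companion effect measure for ranks
    w = chi2 / (n * (k - 1))
    return TestResult(
        test="friedman",
        statistic=float(chi2),
        df=(float(df),),
        p_value=p,
        extras={"kendall_w": float(w), "mean_ranks": rank_sums / n},
        posthoc=ph,
    )


# ---------------------------------------------------------------------------
# One-way repeated-measures ANOVA
# ---------------------------------------------------------------------------


def rm_anova(matrix: np.ndarray, posthoc: bool = True) -> TestResult:
    """One-way repeated-measures ANOVA on a units x k matrix.

    F = MS_condition / MS_(condition x unit); partial eta squared uses
    SS_condition / (SS_condition + SS_error).  No sphericity correction by
    default; the Greenhouse-Geisser epsilon is reported in ``extras`` so a
    corrected p can be formed when wanted.  Pairwise paired t tests are
    Bonferroni-adjusted.
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    if k < 2:
        raise BalanceError("rm-ANOVA needs k >= 2 conditions")
    if n < 2:
        raise BalanceError("rm-ANOVA needs >= 2 units")
    grand = m.mean()
    cond_means = m.mean(axis=0)
    unit_means = m.mean(axis=1)
    ss_total = float(np.sum((m - grand) ** 2))
    ss_cond = float(n * np.sum((cond_means - grand) ** 2))
    ss_unit = float(k * np.sum((unit_means - grand) ** 2))
    ss_error = ss_total - ss_cond - ss_unit
    df_cond = k - 1
    df_error = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_error = ss_error / df_error
    if ms_error <= 0:
        raise DegenerateVarianceError("zero residual variance")
    f_stat = ms_cond / ms_error
    p = float(sps.f.sf(f_stat, df_cond, df_error))
    eta2p = ss_cond / (ss_cond + ss_error)

    # Greenhouse-Geisser epsilon from the double-centered covariance
    cov = np.cov(m, rowvar=False, ddof=1)
    centered = cov - cov.mean(axis=0, keepdims=True) - cov.mean(axis=1, keepdims=True) + cov.mean()
    eig_ok = np.trace(centered) ** 2
    gg = float(eig_ok / ((k - 1) * np.sum(centered**2))) if np.sum(centered**2) > 0 else 1.0

    ph = None
    if posthoc:
        n_pairs = k * (k - 1) // 2
        recs = []
        for i, j in combinations(range(k), 2):
            t_res = sps.ttest_rel(m[:, i], m[:, j])
            recs.append(
                {
                    "i": i,
                    "j": j,
                    "t": float(t_res.statistic),
                    "p_raw": float(t_res.pvalue),
                    "p_adj": min(1.0, float(t_res.pvalue) * n_pairs),
                }
            )
        ph = pd.DataFrame(recs)
    return TestResult(
        test="rm_anova",
        statistic=float(f_stat),
        df=(float(df_cond), float(df_error)),
        p_value=p,
        eta2p=float(eta2p),
        effect=effect_label(float(eta2p)),
        extras={
            "ss_condition": ss_cond,
            "ss_subject": ss_unit,
            "ss_error": ss_error,
            "ss_total": ss_total,
            "gg_epsilon": gg,
        },
        posthoc=ph,
    )


# ---------------------------------------------------------------------------
# One-way MANOVA, Pillai's trace
# ---------------------------------------------------------------------------


def manova_pillai(responses: np.ndarray, groups: np.ndarray) -> TestResult:
    """One-way MANOVA on condition groups; Pillai's trace with its standard F.

    ``responses`` is (N, p); ``groups`` labels each row's condition.
    V = trace(H (H + E)^-1) from the between (H) and within (E) SSCP
    matrices; the multivariate partial eta squared is V / s with
    s = min(p, k - 1).
    """
    x = np.asarray(responses, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    groups = np.asarray(groups)
    if x.shape[0] != groups.shape[0]:
        raise BalanceError("responses and groups disagree in length")
    labels = np.unique(groups)
    k = labels.size
    n_total, p = x.shape
    if k < 2:
        raise BalanceError("MANOVA needs >= 2 groups")
    if n_total - k < p:
        raise DegenerateVarianceError("fewer residual df than response variables")
    grand = x.mean(axis=0)
    h = np.zeros((p, p))
    e = np.zeros((p, p))
    for lab in labels:
        sub = x[groups == lab]
        mu = sub.mean(axis=0)
        diff = (mu - grand)[:, None]
        h += sub.shape[0] * (diff @ diff.T)
        resid = sub - mu
        e += resid.T @ resid
    try:
        v = float(np.trace(h @ np.linalg.solve(h + e, np.eye(p))))
    except np.linalg.LinAlgError as exc:
        raise DegenerateVarianceError("singular H + E SSCP matrix") from exc

    s = min(p, k - 1)
    m_par = (abs(k - 1 - p) - 1) / 2.0
    n_par = (n_total - k - p - 1) / 2.0
    df1 = s * (2 * m_par + s + 1)
    df2 = s * (2 * n_par + s + 1)
    if s - v <= 0:
        f_stat = np.inf
    else:
        f_stat = (df2 / df1) * (v / (s - v))
    p_val = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    eta2p = v / s
    return TestResult(
        test="manova_pillai",
        statistic=float(v),
        df=(float(df1), float(df2)),
        p_value=p_val,
        eta2p=float(eta2p),
        effect=effect_label(float(eta2p)),
        extras={"F": float(f_stat), "s": s, "H": h, "E": e},
    )


# ---------------------------------------------------------------------------
# ICC(3,1)
# ---------------------------------------------------------------------------


def icc_3_1(ratings: np.ndarray, ci: float = 0.95) -> TestResult:
    """ICC(3,1): two-way mixed effects, consistency, single measure.

    ``ratings`` is targets x raters.  ICC = (MS_T - MS_E) / (MS_T + (k-1)
    MS_E) from the two-way ANOVA without replication; F = MS_T / MS_E on
    (n-1, (n-1)(k-1)) df, and the confidence bounds follow from scaling F by
    the F-distribution quantiles.
    """
    m = _as_matrix(ratings)
    n, k = m.shape
    if n < 2 or k < 2:
        raise BalanceError("ICC needs >= 2 targets and >= 2 raters")
    grand = m.mean()
    target_means = m.mean(axis=1)
    rater_means = m.mean(axis=0)
    ss_total = float(np.sum((m - grand) ** 2))
    ss_target = float(k * np.sum((target_means - grand) ** 2))
    ss_rater = float(n * np.sum((rater_means - grand) ** 2))
    ss_error = ss_total - ss_target - ss_rater
    df_t, df_e = n - 1, (n - 1) * (k - 1)
    ms_t = ss_target / df_t
    ms_e = ss_error / df_e
    if ms_t <= 0 and ms_e <= 0:
        raise DegenerateVarianceError("constant ratings: ICC undefined")
    if ms_e == 0:
        icc = 1.0
        f_stat = np.inf
        lo = hi = 1.0
        p = 0.0
    else:
        icc = (ms_t - ms_e) / (ms_t + (k - 1) * ms_e)
        f_stat = ms_t / ms_e
        p = float(sps.f.sf(f_stat, df_t, df_e))
        alpha = 1.0 - ci
        fl = f_stat / sps.f.ppf(1 - alpha / 2, df_t, df_e)
        fu = f_stat * sps.f.ppf(1 - alpha / 2, df_e, df_t)
        lo = (fl - 1) / (fl + (k - 1))
        hi = (fu - 1) / (fu + (k - 1))
    return TestResult(
        test="icc_3_1",
        statistic=float(icc),
        df=(float(df_t), float(df_e)),
        p_value=p,
        extras={"F": float(f_stat), "ci": (float(lo), float(hi)), "level": ci},
    )


# ---------------------------------------------------------------------------
# Driver over a condition dataset
# ---------------------------------------------------------------------------


def analyze_condition_dataset(
    dataset: pd.DataFrame,
    variables: list[str],
    conditions: tuple[str, ...] | None = None,
    alpha: float = 0.05,
) -> dict[str, TestResult]:
    """Gate each variable on normality, then run the matching omnibus test.

    Parametric variables go to rm-ANOVA, non-normal ones to Friedman, the
    routing the published analysis plan prescribes for bout-level summaries.
    """
    from .synthetic import condition_matrix  # local import to avoid a cycle

    results: dict[str, TestResult] = {}
    conditions = conditions or tuple(sorted(dataset["condition"].unique()))
    for var in variables:
        mat, _ = condition_matrix(dataset, var, conditions)
        by_cond = {c: mat[:, i] for i, c in enumerate(conditions)}
        route = normality_gate(by_cond, alpha)
        res = rm_anova(mat) if route == "parametric" else friedman_test(mat)
        res.extras["route"] = route
        res.extras["conditions"] = conditions
        results[var] = res
    return results
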