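"""Reaction-time statistics and questionnaire correlations.

The RT analysis works on per-participant medians: valid trials (correct
response, 250–2000 ms) are split by congruency, each participant
contributes the median RT per condition, and the cohort of
congruent-minus-incongruent differences is tested with a paired t-test,
a one-sided Wilcoxon signed-rank test (congruent faster), Cohen's d and
a JZS Bayes factor (Cauchy scale 0.707). Hypotheses are directional, so
tests default to one-sided; the sidedness is always recorded in the
result. Pearson and Spearman correlations are always reported side by
side — their disagreement on non-normal data is part of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

RT_MIN_MS = 250.0
RT_MAX_MS = 2000.0
JZS_CAUCHY_SCALE = 0.707


def jzs_bayes_factor(t: float, n: int, r: float = JZS_CAUCHY_SCALE,
                     alternative: str = "two-sided") -> float:
    """JZS Bayes factor BF10 for a one-sample/paired t statistic.

    The marginal likelihood under H1 integrates the noncentral-t
    likelihood over a Cauchy(0, r) prior on the standardized effect
    size δ; for a directional hypothesis the prior is the half-Cauchy on
    the hypothesized side (density doubled). H0 is δ = 0.
    """
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * sqrt_n) * stats.cauchy.pdf(delta, scale=r)

    null = stats.t.pdf(t, df)
    if alternative == "two-sided":
        m1, _ = integrate.quad(integrand, -np.inf, np.inf)
    elif alternative == "less":
        m1 = 2.0 * integrate.quad(integrand, -np.inf, 0.0)[0]
    elif alternative == "greater":
        m1 = 2.0 * integrate.quad(integrand, 0.0, np.inf)[0]
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(m1 / null)


@dataclass(frozen=True)
class PairedTestResult:
    wilcoxon_statistic: float
    wilcoxon_p: float
    t_statistic: float
    t_p: float
    cohens_d: float
    bf10: float
    n: int
    sidedness: str            # "one" (congruent < incongruent) or "two"
    wilcoxon_method: str      # "exact" or "approx"


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    x_label: str = "x"
    y_label: str = "y"


def filter_valid(log: pd.DataFrame) -> tuple:
    """Keep correctly-classified trials with RT in [250, 2000] ms
    (inclusive bounds). Returns (valid log, exclusion counts per reason).
    """
    required = {"rt_ms", "response", "target_valence"}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"behavioural log missing columns: {sorted(missing)}")
    correct = log["response"] == log["target_valence"]
    too_fast = log["rt_ms"] < RT_MIN_MS
    too_slow = log["rt_ms"] > RT_MAX_MS
    valid = correct & ~too_fast & ~too_slow
    counts = {
        "wrong_response": int((~correct).sum()),
        "too_fast": int((correct & too_fast).sum()),
        "too_slow": int((correct & ~too_fast & too_slow).sum()),
        "retained": int(valid.sum()),
    }
    return log[valid].reset_index(drop=True), counts


def rt_contrast(valid: pd.DataFrame) -> pd.DataFrame:
    """Per-participant condition medians and their difference
    (congruent − incongruent). Participants missing a condition are
    excluded and flagged in the ``excluded`` column of the returned frame.
    """
    rows = []
    for pid, grp in valid.groupby("participant"):
        cong = grp.loc[grp["congruent"], "rt_ms"].to_numpy()
        incong = grp.loc[~grp["congruent"], "rt_ms"].to_numpy()
        if len(cong) == 0 or len(incong) == 0:
            rows.append({"participant": pid, "excluded": True,
                         "median_congruent": np.nan, "median_incongruent": np.nan,
                         "difference": np.nan,
                         "n_valid_congruent": len(cong),
                         "n_valid_incongruent": len(incong)})
            continue
        mc, mi = float(np.median(cong)), float(np.median(incong))
        rows.append({"participant": pid, "excluded": False,
                     "median_congruent": mc, "median_incongruent": mi,
                     "difference": mc - mi,
                     "n_valid_congruent": len(cong),
                     "n_valid_incongruent": len(incong)})
    return pd.DataFrame(rows)


def paired_tests(differences: np.ndarray, sided: str = "one",
                 exact_max_n: int = 25) -> PairedTestResult:
    """Test the cohort of per-participant median differences against zero.

    One-sided means H1: differences < 0 (congruent faster). The Wilcoxon
    test discards zero differences (Wilcoxon's original rule), uses the
    exact null for n ≤ ``exact_max_n`` and a continuity-corrected normal
    approximation above. The Bayes factor is JZS with Cauchy scale
    0.707, matched to the test's sidedness.
    """
    d = np.asarray(differences, dtype=float)
    if len(d) < 5:
        raise ValueError(f"need at least 5 participants, got {len(d)}")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    alternative = "less" if sided == "one" else "two-sided"

    nonzero = d[d != 0]
    if len(nonzero) == 0:
        raise ValueError("all differences are zero: Wilcoxon signed-rank undefined")
    method = "exact" if len(nonzero) <= exact_max_n else "approx"
    try:
        w = stats.wilcoxon(d, zero_method="wilcox", alternative=alternative,
                           method=method, correction=(method == "approx"))
    except ValueError:
        # exact null unavailable (e.g. tied ranks in older backends)
        method = "approx"
        w = stats.wilcoxon(d, zero_method="wilcox", alternative=alternative,
                           method="approx", correction=True)

    t = stats.ttest_1samp(d, 0.0, alternative=alternative)
    sd = d.std(ddof=1)
    cohens_d = float(d.mean() / sd) if sd > 0 else 0.0
    bf10 = jzs_bayes_factor(float(t.statistic), len(d), alternative=alternative)

    return PairedTestResult(
        wilcoxon_statistic=float(w.statistic), wilcoxon_p=float(w.pvalue),
        t_statistic=float(t.statistic), t_p=float(t.pvalue),
        cohens_d=cohens_d, bf10=bf10, n=len(d), sidedness=sided,
        wilcoxon_method=method,
    )


def holm_correct(pvals) -> np.ndarray:
    """Bonferroni–Holm step-down adjusted p-values (capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def correlate(x, y, x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Pearson and Spearman correlation (two-sided p), reported together."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired observations with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(f"correlation undefined: zero variance in "
                         f"{x_label if np.std(x) == 0 else y_label}")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        x_label=x_label, y_label=y_label,
    )
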