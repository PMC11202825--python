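"""Diagnostic-accuracy statistics for separating MFS from non-MFS.

Implements the evaluation stage: Welch group comparisons, empirical ROC
AUC (Mann-Whitney estimator, ties counted half) with DeLong 95%
confidence intervals, closed-form AUC under binormal or moment-matched
lognormal score models, Youden-optimal cut-offs with sensitivity /
specificity / predictive values, and exact-binomial McNemar comparison
of two paired dichotomous classifications.  Positivity direction is
fixed throughout as "higher score implies MFS".
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "RocCurve",
    "AucEstimate",
    "CutoffPerformance",
    "McNemarResult",
    "welch_t",
    "roc_curve",
    "auc_empirical",
    "auc_closed_form",
    "youden_cutoff",
    "mcnemar",
    "evaluate_table2",
    "table2_frame",
]

_LEVELS_DSDR = ("L1", "L2", "L3", "L4", "L5", "S1")
_LEVELS_DSVR = ("L3", "L4", "L5", "S1")


@dataclass
class GroupComparison:
    variable: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


@dataclass
class AucEstimate:
    auc: float
    ci_low: float
    ci_high: float
    method: str  # empirical_delong | closed_form_normal | closed_form_lognormal

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.auc <= self.ci_high <= 1.0):
            raise ValueError("AUC/CI ordering violated")


@dataclass
class CutoffPerformance:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float


@dataclass
class McNemarResult:
    b: int
    c: int
    statistic: float
    p: float
    method: str  # exact_binomial | chi2_cc


def welch_t(values_a, values_b, variable: str = "") -> GroupComparison:
    """Welch two-sample t test (Satterthwaite df, two-sided)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.array_equal(a, b) and a.std() == 0 and b.std() == 0:
        t, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        if np.isnan(t):  # both groups constant and equal
            t, p = 0.0, 1.0
    return GroupComparison(variable=variable,
                           mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                           mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
                           t=t, p=p)


def roc_curve(scores_cases, scores_controls) -> RocCurve:
    """Empirical ROC over all observed thresholds ("score >= t" positive)."""
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    thr = np.unique(np.concatenate([cases, controls]))[::-1]
    sens = np.array([(cases >= t).mean() for t in thr])
    spec = np.array([(controls < t).mean() for t in thr])
    return RocCurve(thresholds=thr, sensitivity=sens, specificity=spec)


def _delong(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney AUC and its DeLong variance (midrank algorithm)."""
    m, n = len(cases), len(controls)
    both = np.concatenate([cases, controls])
    r_all = stats.rankdata(both)
    r_cases = stats.rankdata(cases)
    r_controls = stats.rankdata(controls)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    if m < 2 or n < 2:
        return float(auc), 0.0
    v10 = (r_all[:m] - r_cases) / n  # placements of cases among controls
    v01 = 1.0 - (r_all[m:] - r_controls) / m
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return float(auc), float(var)


def auc_empirical(scores_cases, scores_controls) -> AucEstimate:
    """Empirical AUC (ties count one half) with DeLong 95% CI.

    Equivalent to counting concordant pairs over all case-control pairs.
    With a degenerate group (size < 2) or perfect separation the
    variance collapses and the interval degenerates to the point value.
    """
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    auc, var = _delong(cases, controls)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    lo = min(max(auc - half, 0.0), auc)
    hi = max(min(auc + half, 1.0), auc)
    return AucEstimate(auc=auc, ci_low=lo, ci_high=hi, method="empirical_delong")


def auc_closed_form(mean1: float, sd1: float, mean0: float, sd0: float,
                    family: str = "normal") -> float:
    """Model-based AUC from group moments.

    Binormal: Phi((mu1 - mu0) / sqrt(sd1^2 + sd0^2)).  Lognormal:
    the same expression after moment-matching each group to a lognormal
    (exact when scores are lognormal, since log scores are then normal
    and AUC is rank-invariant).
    """
    if sd1 <= 0 or sd0 <= 0:
        raise ValueError("standard deviations must be positive")
    if family == "normal":
        mu1, s1, mu0, s0 = mean1, sd1, mean0, sd0
    elif family == "lognormal":
        if mean1 <= 0 or mean0 <= 0:
            raise ValueError("lognormal family needs positive means")
        v1 = np.log1p((sd1 / mean1) ** 2)
        v0 = np.log1p((sd0 / mean0) ** 2)
        mu1, s1 = np.log(mean1) - v1 / 2, np.sqrt(v1)
        mu0, s0 = np.log(mean0) - v0 / 2, np.sqrt(v0)
    else:
        raise ValueError(f"invalid family {family!r}")
    return float(stats.norm.cdf((mu1 - mu0) / np.hypot(s1, s0)))


def youden_cutoff(scores_cases, scores_controls) -> CutoffPerformance:
    """Youden-optimal threshold for the rule "score >= cutoff => MFS".

    Scans every observed score; ties in J break toward the lowest
    cutoff.  PPV/NPV use the sample prevalence; an undefined predictive
    value (empty predicted class) is returned as NaN.
    """
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    candidates = np.unique(np.concatenate([cases, controls]))
    best = None
    for t in candidates:  # ascending, first strict improvement wins => lowest tie
        sens = float((cases >= t).mean())
        spec = float((controls < t).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    j, t, sens, spec = best
    tp = int((cases >= t).sum())
    fp = int((controls >= t).sum())
    fn = len(cases) - tp
    tn = len(controls) - fp
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return CutoffPerformance(cutoff=float(t), sensitivity=sens, specificity=spec,
                             ppv=ppv, npv=npv, youden_j=j)


def mcnemar(b: int, c: int, method: str = "exact_binomial") -> McNemarResult:
    """McNemar test on discordant counts b, c.

    Exact: p = min(1, 2 P(Bin(b+c, 1/2) <= min(b, c))).  The chi-square
    variant applies the continuity correction (|b-c|-1)^2 / (b+c).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    n = b + c
    if method == "exact_binomial":
        stat = float(min(b, c))
        p = 1.0 if n == 0 else min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
    elif method == "chi2_cc":
        if n == 0:
            stat, p = 0.0, 1.0
        else:
            stat = (abs(b - c) - 1) ** 2 / n if abs(b - c) > 1 else 0.0
            p = float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return McNemarResult(b=int(b), c=int(c), statistic=stat, p=float(p), method=method)


def evaluate_table2(cohort) -> dict[str, dict]:
    """Per-level ROC evaluation of DSVR and DSDR on a cohort table.

    ``cohort`` is a CohortTable or DataFrame with a ``group`` column
    (values "MFS"/"nonMFS") and ``dsvr_<level>`` / ``dsdr_<level>``
    columns.  For each level present, returns the empirical AUC with
    DeLong CI and the Youden cut-off performance for each index, and —
    where both indices exist — an exact McNemar test comparing the
    correctness of their Youden-dichotomized classifications against
    the true group.
    """
    df = cohort.table if hasattr(cohort, "table") else cohort
    if "group" not in df.columns:
        raise ValueError("cohort table lacks a 'group' column")
    is_case = (df["group"] == "MFS").to_numpy()
    if not is_case.any() or is_case.all():
        raise ValueError("cohort must contain both groups")

    def _cols(prefix):
        return [f"{prefix}_{lvl}" for lvl in _LEVELS_DSDR if f"{prefix}_{lvl}" in df.columns]

    if not _cols("dsvr") and not _cols("dsdr"):
        raise ValueError("cohort table lacks dsvr_*/dsdr_* columns")

    out: dict[str, dict] = {}
    for lvl in _LEVELS_DSDR:
        entry: dict = {}
        preds: dict[str, np.ndarray] = {}
        for key in ("dsvr", "dsdr"):
            col = f"{key}_{lvl}"
            if col not in df.columns:
                continue
            scores = df[col].to_numpy(dtype=float)
            cases, controls = scores[is_case], scores[~is_case]
            entry[f"auc_{key}"] = auc_empirical(cases, controls)
            cut = youden_cutoff(cases, controls)
            entry[f"cutoff_{key}"] = cut
            preds[key] = scores >= cut.cutoff
        if "dsvr" in preds and "dsdr" in preds:
            correct_v = preds["dsvr"] == is_case
            correct_d = preds["dsdr"] == is_case
            b = int(np.sum(correct_v & ~correct_d))
            c = int(np.sum(~correct_v & correct_d))
            entry["mcnemar"] = mcnemar(b, c)
        if entry:
            out[lvl] = entry
    return out


def table2_frame(results: dict[str, dict], ndigits: int = 3) -> pd.DataFrame:
    """Flatten evaluate_table2 output into a report table."""
    rows = []
    for lvl, entry in results.items():
        row: dict = {"level": lvl}
        for key in ("dsvr", "dsdr"):
            est = entry.get(f"auc_{key}")
            if est is not None:
                row[f"auc_{key}"] = round(est.auc, ndigits)
                row[f"auc_{key}_ci_low"] = round(est.ci_low, ndigits)
                row[f"auc_{key}_ci_high"] = round(est.ci_high, ndigits)
                cut = entry[f"cutoff_{key}"]
                row[f"cutoff_{key}"] = round(cut.cutoff, ndigits)
                row[f"sens_{key}"] = round(cut.sensitivity, ndigits)
                row[f"spec_{key}"] = round(cut.specificity, ndigits)
        mc = entry.get("mcnemar")
        if mc is not None:
            row["mcnemar_b"] = mc.b
            row["mcnemar_c"] = mc.c
            row["mcnemar_p"] = round(mc.p, ndigits)
        rows.append(row)
    return pd.DataFrame(rows)
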