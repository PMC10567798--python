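"""Clinical validation statistics for urinary miRNA biomarkers.

Covers the quantification and statistics used to relate urinary exosomal
miRNA levels to kidney function and disease progression in an IgA
nephropathy cohort:

* 2^-ddCt relative qPCR quantification, normalized to urine creatinine and
  log10-transformed (log10 copies/mg Cr);
* the 2009 CKD-EPI creatinine equation for eGFR;
* the progressor / non-progressor classification rule (>50% eGFR loss
  within five years or renal replacement therapy, vs <10% change over more
  than five years);
* Spearman correlation, Mann-Whitney / Kruskal-Wallis group comparisons,
  ROC AUC with the Hanley-McNeil confidence interval, and univariate Cox
  proportional-hazards regression (Breslow ties).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

PROGRESSOR = "progressor"
NON_PROGRESSOR = "non_progressor"
INDETERMINATE = "indeterminate"


# ---------------------------------------------------------------------------
# qPCR quantification

def relative_level(ct_target: float, ct_calibrator: float,
                   urine_creatinine: float, ct_reference: float | None = None,
                   ct_reference_calibrator: float | None = None) -> float:
    """Creatinine-normalized log10 relative miRNA level from qPCR Ct values.

    Relative expression is 2^-ddCt with ddCt = dCt_sample - dCt_calibrator.
    With an endogenous reference assay, dCt = Ct_target - Ct_reference for
    both sample and calibrator; without one (the default), dCt is the raw
    Ct and the calibrator Ct anchors the scale.  The relative quantity is
    divided by urine creatinine and log10-transformed (log10 per mg Cr).
    """
    if urine_creatinine is None or not np.isfinite(urine_creatinine) or urine_creatinine <= 0:
        raise ValueError("urine creatinine must be positive")
    if ct_target is None or not np.isfinite(ct_target):
        raise ValueError("missing target Ct")
    if ct_calibrator is None or not np.isfinite(ct_calibrator):
        raise ValueError("missing calibrator Ct")
    dct_sample = ct_target - (ct_reference if ct_reference is not None else 0.0)
    dct_cal = ct_calibrator - (ct_reference_calibrator
                               if ct_reference_calibrator is not None else 0.0)
    ddct = dct_sample - dct_cal
    rel = 2.0 ** (-ddct)
    return float(np.log10(rel / urine_creatinine))


# ---------------------------------------------------------------------------
# eGFR

_CKD_EPI = {
    "female": {"kappa": 0.7, "alpha": -0.329, "sex_factor": 1.018},
    "male": {"kappa": 0.9, "alpha": -0.411, "sex_factor": 1.0},
}


def ckd_epi_egfr(serum_creatinine, age, sex: str, race_black: bool = False):
    """2009 CKD-EPI creatinine eGFR in mL/min/1.73 m^2.

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age
           * 1.018 [female] (* 1.159 if the published race term is enabled).

    The race coefficient is off by default and available behind
    ``race_black`` for strict replication of the original equation.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("serum creatinine and age must be positive")
    key = str(sex).strip().lower()
    key = {"f": "female", "m": "male"}.get(key, key)
    if key not in _CKD_EPI:
        raise ValueError(f"unknown sex {sex!r}")
    c = _CKD_EPI[key]
    ratio = scr / c["kappa"]
    egfr = (141.0 * np.minimum(ratio, 1.0) ** c["alpha"]
            * np.maximum(ratio, 1.0) ** -1.209
            * 0.993 ** age * c["sex_factor"])
    if race_black:
        egfr = egfr * 1.159
    return float(egfr) if egfr.ndim == 0 else egfr


def invert_ckd_epi(egfr: float, age: float, sex: str) -> float:
    """Serum creatinine (mg/dL) whose CKD-EPI eGFR equals the given value."""
    key = str(sex).strip().lower()
    key = {"f": "female", "m": "male"}.get(key, key)
    c = _CKD_EPI[key]
    g = egfr / (141.0 * 0.993 ** age * c["sex_factor"])
    # low-creatinine branch (Scr <= kappa): g = (Scr/kappa)^alpha
    scr = c["kappa"] * g ** (1.0 / c["alpha"])
    if scr > c["kappa"]:
        scr = c["kappa"] * g ** (-1.0 / 1.209)
    return float(scr)


# ---------------------------------------------------------------------------
# progression classification

def classify_progression(egfr_baseline: float,
                         egfr_trajectory: Sequence[tuple[float, float]],
                         rrt: bool, followup_years: float) -> str:
    """Progressor / non-progressor / indeterminate label for one patient.

    Progressor: renal replacement therapy (dominates all other evidence),
    or any observed eGFR below half the baseline within five years of
    diagnosis.  Non-progressor: more than five years of follow-up with
    every observed eGFR within 10% of baseline.  Everything else — e.g. a
    30% decline, or a short follow-up without progression — is
    indeterminate and excluded from progression analyses.
    """
    if egfr_baseline <= 0:
        raise ValueError("baseline eGFR must be positive")
    if rrt:
        return PROGRESSOR
    points = [(float(t), float(e)) for t, e in egfr_trajectory]
    if any(t <= 5.0 and e < 0.5 * egfr_baseline for t, e in points):
        return PROGRESSOR
    if (followup_years > 5.0 and points
            and all(abs(e - egfr_baseline) / egfr_baseline < 0.10 for _, e in points)):
        return NON_PROGRESSOR
    return INDETERMINATE


# ---------------------------------------------------------------------------
# nonparametric statistics

def _paired_finite(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties);
    missing pairs are dropped; at least three complete pairs are required
    and either variable being constant in ranks is an error.
    """
    x, y = _paired_finite(x, y)
    if len(x) < 3:
        raise ValueError("spearman needs >=3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant variable")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def group_compare(*groups: Iterable[float]) -> tuple[float, float]:
    """Two-sided nonparametric comparison of two or more groups.

    Two groups: Mann-Whitney U (exact when the combined sample is at most
    twelve and untied, otherwise the tie- and continuity-corrected normal
    approximation).  More than two: Kruskal-Wallis H with tie correction.
    Returns (statistic, p).
    """
    cleaned = []
    for g in groups:
        arr = np.asarray(list(g), dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) == 0:
            raise ValueError("every group must be non-empty")
        cleaned.append(arr)
    if len(cleaned) < 2:
        raise ValueError("need at least two groups")
    if len(cleaned) == 2:
        a, b = cleaned
        combined = np.concatenate([a, b])
        no_ties = len(np.unique(combined)) == len(combined)
        method = "exact" if (len(combined) <= 12 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*cleaned)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(scores: Iterable[float], labels: Iterable[int]) -> tuple[float, float, float]:
    """ROC AUC by concordant-pair counting with a Hanley-McNeil 95% CI.

    AUC = (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg) over all
    positive/negative pairs.  The confidence interval uses the
    Hanley-McNeil variance approximation and is clipped to [0, 1].
    """
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels))
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be paired")
    labels = labels.astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    diff = pos[:, None] - neg[None, :]
    auc = float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    n1, n0 = len(pos), len(neg)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc)
           + (n0 - 1) * (q2 - auc * auc)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)
    return auc, lo, hi


# ---------------------------------------------------------------------------
# univariate Cox proportional hazards (Breslow ties)

@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit: hazard ratio, Wald CI and p, convergence state."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool
    reason: str = ""
    n: int = 0
    n_events: int = 0


def _breslow_quantities(beta: float, t: np.ndarray, d: np.ndarray,
                        x: np.ndarray, last: np.ndarray):
    """Breslow log partial likelihood, score and information at beta.

    Inputs are sorted by descending time; ``last[i]`` is the final index of
    subject i's tie group, so cumulative sums through it cover the risk set
    {l : t_l >= t_i}.
    """
    exb = np.exp(beta * x)
    s0 = np.cumsum(exb)[last]
    s1 = np.cumsum(x * exb)[last]
    s2 = np.cumsum(x * x * exb)[last]
    ev = d.astype(bool)
    loglik = float(np.sum(beta * x[ev] - np.log(s0[ev])))
    r1 = s1[ev] / s0[ev]
    score = float(np.sum(x[ev] - r1))
    info = float(np.sum(s2[ev] / s0[ev] - r1 * r1))
    return loglik, score, info


def cox_univariate(times: Iterable[float], events: Iterable[int],
                   covariate: Iterable[float], tol: float = 1e-8,
                   max_iter: int = 50) -> CoxResult:
    """Fit a single-covariate Cox proportional-hazards model.

    The Breslow-ties partial log-likelihood is maximized by Newton-Raphson
    with step-halving; convergence is declared when |score| < tol.  Returns
    the hazard ratio exp(beta) with Wald 95% CI and two-sided p.  A
    constant covariate or a monotone likelihood (complete separation,
    diverging beta) yields a flagged non-converged result with no estimate.
    """
    t = np.asarray(list(times), dtype=float)
    d = np.asarray(list(events), dtype=float)
    x = np.asarray(list(covariate), dtype=float)
    if not (t.shape == d.shape == x.shape):
        raise ValueError("times, events, covariate must be aligned")
    keep = np.isfinite(t) & np.isfinite(d) & np.isfinite(x)
    t, d, x = t[keep], d[keep], x[keep]
    n, n_events = len(t), int(d.sum())
    if n_events < 1:
        raise ValueError("at least one event is required")

    def flagged(reason: str) -> CoxResult:
        logger.info("cox fit flagged: %s", reason)
        return CoxResult(beta=math.nan, se=math.nan, hr=math.nan,
                         ci_low=math.nan, ci_high=math.nan, p=math.nan,
                         converged=False, reason=reason, n=n, n_events=n_events)

    order = np.argsort(-t, kind="mergesort")
    t, d, x = t[order], d[order], x[order]
    # last index of each tie group in the descending-time ordering
    last = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        last[i:j + 1] = j
        i = j + 1

    # information content requires covariate variation within risk sets
    if np.ptp(x) == 0:
        return flagged("constant covariate")

    beta = 0.0
    loglik, score, info = _breslow_quantities(beta, t, d, x, last)
    if info <= 0:
        return flagged("covariate constant among subjects at risk")
    converged_flag = False
    for _ in range(max_iter):
        if abs(score) < tol:
            converged_flag = True
            break
        step = score / info
        # near machine precision the likelihood plateaus while the score
        # carries rounding noise: a vanishing Newton step means convergence
        if abs(step) < 1e-7 * (1.0 + abs(beta)):
            converged_flag = True
            break
        new_beta = beta + step
        new_ll, new_score, new_info = _breslow_quantities(new_beta, t, d, x, last)
        halvings = 0
        while new_ll < loglik and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _breslow_quantities(new_beta, t, d, x, last)
            halvings += 1
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > 50 or info <= 0:
            return flagged("monotone likelihood (complete separation)")
    else:
        converged_flag = abs(score) < tol
    if not converged_flag:
        return flagged("no convergence within iteration limit")

    se = 1.0 / math.sqrt(info)
    if abs(beta) > 30 or se > 30:
        return flagged("monotone likelihood (complete separation)")
    zcrit = 1.959963984540054
    zstat = beta / se
    p = 2.0 * stats.norm.sf(abs(zstat))
    return CoxResult(beta=beta, se=se, hr=math.exp(beta),
                     ci_low=math.exp(beta - zcrit * se),
                     ci_high=math.exp(beta + zcrit * se),
                     p=float(p), converged=True, n=n, n_events=n_events)
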