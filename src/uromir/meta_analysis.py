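"""Random-effects meta-analysis of case/control expression with permutation FDR.

Per gene and dataset a bias-corrected standardized mean difference (SMD) is
computed; the per-dataset effects y_i are then combined under the
random-effects model

    y_i ~ N(theta_i, s_i^2),    theta_i ~ N(mu, tau^2)

with the DerSimonian-Laird moment estimator for the between-study variance
tau^2.  The pooled effect mu_hat, standardized by its standard error, gives
a per-gene z-score.  Significance is assessed SAM-style: case/control
labels are permuted within each dataset, the full pipeline is recomputed,
and the false discovery rate at threshold t = |z_g| is the mean number of
null z-scores at least as extreme, divided by the observed count, made
monotone in t.  Genes with permutation FDR < 0.05 and geometric-mean fold
change > 1.5 in either direction are called significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import DatasetCollection

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 1000
DEFAULT_FDR = 0.05
DEFAULT_FC = 1.5


@dataclass(frozen=True)
class EffectSize:
    """Bias-corrected SMD for one gene in one dataset."""

    y: float
    s2: float
    n_case: int
    n_control: int


@dataclass(frozen=True)
class MetaCombination:
    mu_hat: float
    se_mu: float
    tau2: float
    z: float


class UnusableEffect(ValueError):
    """Raised when a gene/dataset cell carries no usable effect size."""


# ---------------------------------------------------------------------------
# effect sizes

def _group_stats(values: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """n, mean, sample variance per row over the given columns (NaN-aware)."""
    sub = values[:, cols]
    if np.isnan(sub).any():
        n = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(sub, axis=1)
            mean = np.where(n > 0, mean, np.nan)
            var = np.full(sub.shape[0], np.nan)
            ok = n >= 2
            if ok.any():
                centered = sub - mean[:, None]
                ss = np.nansum(centered * centered, axis=1)
                var[ok] = ss[ok] / (n[ok] - 1)
    else:
        n = np.full(sub.shape[0], sub.shape[1])
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
    return n, mean, var


def effect_sizes_matrix(values: np.ndarray, case_cols: np.ndarray,
                        control_cols: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized bias-corrected SMDs for every gene of one dataset.

    Returns ``(y, s2, diff)`` arrays; ``y`` and ``s2`` are NaN where the
    gene is unusable in this dataset (fewer than two non-missing values in
    either group, or zero pooled variance), ``diff`` is the case-minus-
    control mean difference on the log2 scale (NaN-aware, used for fold
    change).
    """
    n1, m1, v1 = _group_stats(values, case_cols)
    n2, m2, v2 = _group_stats(values, control_cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.where(df > 0, df, np.nan)
        usable = (n1 >= 2) & (n2 >= 2) & (sp2 > 0)
        d = (m1 - m2) / np.sqrt(sp2)
        ntot = n1 + n2
        y = d * (1.0 - 3.0 / (4.0 * ntot - 9.0))
        s2 = 1.0 / n1 + 1.0 / n2 + y * y / (2.0 * ntot)
    y = np.where(usable, y, np.nan)
    s2 = np.where(usable, s2, np.nan)
    diff = m1 - m2
    return y, s2, diff


def effect_size(case_values, control_values) -> EffectSize:
    """Bias-corrected SMD (case minus control) for one gene in one dataset.

    y = d * (1 - 3/(4N - 9)) with d the plain SMD and N the total sample
    count; its sampling variance is 1/n1 + 1/n2 + y^2/(2N).  Raises
    :class:`UnusableEffect` when either group has fewer than two finite
    values or the pooled standard deviation is zero.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    case = case[np.isfinite(case)]
    control = control[np.isfinite(control)]
    if len(case) < 2 or len(control) < 2:
        raise UnusableEffect("each group needs >=2 finite observations")
    values = np.concatenate([case, control])[None, :]
    y, s2, _ = effect_sizes_matrix(values, np.arange(len(case)),
                                   np.arange(len(case), len(case) + len(control)))
    if np.isnan(y[0]):
        raise UnusableEffect("zero pooled standard deviation")
    return EffectSize(y=float(y[0]), s2=float(s2[0]),
                      n_case=len(case), n_control=len(control))


# ---------------------------------------------------------------------------
# DerSimonian-Laird combination

def dersimonian_laird(y: np.ndarray, s2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized DL combination over a genes x datasets effect array.

    NaN cells mark unusable gene/dataset pairs.  Returns per-gene
    ``(mu_hat, se_mu, tau2, z)``; genes usable in no dataset come back NaN.
    For a single usable effect mu_hat = y, tau2 = 0.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    s2 = np.atleast_2d(np.asarray(s2, dtype=float))
    usable = ~np.isnan(y) & ~np.isnan(s2)
    k = usable.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(usable, 1.0 / s2, 0.0)
        sw = w.sum(axis=1)
        sw2 = (w * w).sum(axis=1)
        ybar = np.where(sw > 0, (w * np.where(usable, y, 0.0)).sum(axis=1) / sw, np.nan)
        q = (w * (np.where(usable, y, 0.0) - ybar[:, None]) ** 2 * usable).sum(axis=1)
        c = sw - np.where(sw > 0, sw2 / sw, 0.0)
        tau2 = np.where(k >= 2, np.maximum(0.0, (q - (k - 1)) / np.where(c > 0, c, np.nan)), 0.0)
        tau2 = np.where(k >= 1, tau2, np.nan)
        wstar = np.where(usable, 1.0 / (s2 + tau2[:, None]), 0.0)
        sws = wstar.sum(axis=1)
        mu = np.where(sws > 0, (wstar * np.where(usable, y, 0.0)).sum(axis=1) / sws, np.nan)
        se = np.where(sws > 0, 1.0 / np.sqrt(sws), np.nan)
        z = mu / se
    return mu, se, tau2, z


def random_effects_combine(effects: list[EffectSize]) -> MetaCombination:
    """Combine one gene's per-dataset effects under the random-effects model."""
    if not effects:
        raise UnusableEffect("no usable effects to combine")
    y = np.array([[e.y for e in effects]])
    s2 = np.array([[e.s2 for e in effects]])
    mu, se, tau2, z = dersimonian_laird(y, s2)
    return MetaCombination(mu_hat=float(mu[0]), se_mu=float(se[0]),
                           tau2=float(tau2[0]), z=float(z[0]))


# ---------------------------------------------------------------------------
# whole-collection pipeline

def _collection_arrays(collection: DatasetCollection):
    """Extract per-dataset ndarrays and group column indices once."""
    out = []
    for ds in collection.datasets:
        vals = ds.values.to_numpy(dtype=float)
        cols = {s: i for i, s in enumerate(ds.values.columns)}
        case = np.array([cols[s] for s in ds.case_samples])
        control = np.array([cols[s] for s in ds.control_samples])
        out.append((vals, case, control))
    return out


def collection_effects(collection: DatasetCollection):
    """Per-gene effect arrays (genes x datasets) and log2 mean differences."""
    arrays = _collection_arrays(collection)
    ys, s2s, diffs = [], [], []
    for vals, case, control in arrays:
        y, s2, diff = effect_sizes_matrix(vals, case, control)
        ys.append(y)
        s2s.append(s2)
        diffs.append(diff)
    return np.column_stack(ys), np.column_stack(s2s), np.column_stack(diffs)


def _mean_log2_diff(usable: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    """Mean log2 difference over usable datasets; NaN when none usable."""
    count = usable.sum(axis=1)
    total = np.where(usable, diffs, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def observed_z(collection: DatasetCollection) -> np.ndarray:
    y, s2, _ = collection_effects(collection)
    return dersimonian_laird(y, s2)[3]


def overall_fold_change(collection: DatasetCollection) -> np.ndarray:
    """Per-gene geometric-mean fold change across usable datasets.

    fc = 2 ** mean(log2 case-control differences), averaged over datasets
    where the gene supports an effect size; genes usable nowhere are NaN.
    """
    y, _, diffs = collection_effects(collection)
    return np.power(2.0, _mean_log2_diff(~np.isnan(y), diffs))


def permutation_fdr(collection: DatasetCollection, observed: np.ndarray,
                    n_permutations: int = DEFAULT_PERMUTATIONS,
                    seed: int = 1) -> np.ndarray:
    """SAM-style permutation FDR for per-gene z-scores.

    For each of B permutations, case/control labels are shuffled
    independently within each dataset (group sizes preserved, one shuffle
    shared by all genes of that dataset) and the full effect-size ->
    DerSimonian-Laird -> z pipeline is recomputed.  For a gene with
    threshold t = |z_g|,

        q(g) = [ mean_b #{ |z^null_b| >= t } ] / #{ |z^obs| >= t }

    clipped to [0, 1] and made monotone non-increasing in t.  The null is
    pooled across genes (two-sided in |z|).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    arrays = _collection_arrays(collection)

    null_abs_parts = []
    for _ in range(n_permutations):
        ys, s2s = [], []
        for vals, case, control in arrays:
            n_case = len(case)
            all_cols = np.concatenate([case, control])
            perm = rng.permutation(all_cols)
            y, s2, _ = effect_sizes_matrix(vals, perm[:n_case], perm[n_case:])
            ys.append(y)
            s2s.append(s2)
        z_null = dersimonian_laird(np.column_stack(ys), np.column_stack(s2s))[3]
        null_abs_parts.append(np.abs(z_null[~np.isnan(z_null)]))

    null_abs = np.sort(np.concatenate(null_abs_parts))
    obs_abs = np.abs(observed)
    tested = ~np.isnan(obs_abs)
    t = obs_abs[tested]
    obs_sorted = np.sort(t)

    # counts >= t via binary search on the sorted pools
    n_null_ge = len(null_abs) - np.searchsorted(null_abs, t, side="left")
    n_obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, t, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (n_null_ge / n_permutations) / n_obs_ge
    raw = np.clip(raw, 0.0, 1.0)

    # q(g) = min over thresholds t' <= t(g) of the raw FDR: running minimum
    # over genes ordered by increasing |z|.
    order = np.argsort(t, kind="mergesort")
    q_sorted = np.minimum.accumulate(raw[order])
    q_tested = np.empty_like(raw)
    q_tested[order] = q_sorted

    q = np.full(observed.shape, np.nan)
    q[tested] = q_tested
    return q


def meta_analyze(collection: DatasetCollection,
                 n_permutations: int = DEFAULT_PERMUTATIONS, seed: int = 1,
                 fdr_threshold: float = DEFAULT_FDR,
                 fc_threshold: float = DEFAULT_FC) -> pd.DataFrame:
    """Run the full per-gene meta-analysis over a harmonized collection.

    Returns a DataFrame indexed by gene with columns mu_hat, se_mu, tau2,
    z, q, fc and the boolean ``significant`` flag
    (q < fdr_threshold and max(fc, 1/fc) > fc_threshold).
    Genes unusable in every dataset are excluded (logged).
    """
    y, s2, diffs = collection_effects(collection)
    mu, se, tau2, z = dersimonian_laird(y, s2)
    q = permutation_fdr(collection, z, n_permutations=n_permutations, seed=seed)
    fc = np.power(2.0, _mean_log2_diff(~np.isnan(y), diffs))

    df = pd.DataFrame({
        "mu_hat": mu, "se_mu": se, "tau2": tau2, "z": z, "q": q, "fc": fc,
    }, index=pd.Index(collection.gene_universe, name="gene"))
    excluded = df.index[df["z"].isna()]
    if len(excluded):
        logger.info("excluding %d genes with no usable dataset", len(excluded))
        df = df.drop(index=excluded)
    extreme_fc = np.maximum(df["fc"], 1.0 / df["fc"])
    df["significant"] = (df["q"] < fdr_threshold) & (extreme_fc > fc_threshold)
    return df


def select_significant(results: pd.DataFrame,
                       fdr_threshold: float = DEFAULT_FDR,
                       fc_threshold: float = DEFAULT_FC) -> tuple[set[str], dict]:
    """Select genes with q < FDR threshold and |fold change| beyond the cut.

    The fold-change filter is direction-agnostic: max(fc, 1/fc) >
    fc_threshold, so both up- and down-regulated genes qualify.  Returns
    the gene set and a report with per-direction counts.
    """
    extreme_fc = np.maximum(results["fc"], 1.0 / results["fc"])
    selected = results[(results["q"] < fdr_threshold) & (extreme_fc > fc_threshold)]
    up = selected[selected["fc"] > 1.0]
    report = {
        "n_tested": int(len(results)),
        "n_selected": int(len(selected)),
        "n_up": int(len(up)),
        "n_down": int(len(selected) - len(up)),
        "fdr_threshold": fdr_threshold,
        "fc_threshold": fc_threshold,
    }
    return set(selected.index), report
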