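"""Calibration and recovery experiments for the whole pipeline.

Each function runs a self-contained study on synthetic data with known
ground truth and returns the measured quantity: exactness of the
elementary statistics against independent oracles (integer-arithmetic
hypergeometric enumeration, brute-force pair counting, loop-based
DerSimonian-Laird evaluation), false-discovery calibration of the
permutation FDR under a label-exchangeable null, recovery of implanted
pooled effects and enriched miRNAs, Wald-interval coverage of the Cox
estimator, and byte-level determinism of the file pipeline.

Replicate seeds are always drawn from a master ``numpy`` generator so a
single integer reproduces every experiment.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path

import numpy as np

from . import clinical_validation as cv
from . import meta_analysis as ma
from .pipeline import RunConfig, run_discovery, run_simulate, run_validation
from .synthetic_data import gen_expression_collection, gen_target_databases
from .target_enrichment import (build_consensus, enrich_all, fisher_enrichment,
                                rank_and_select)


def _subseeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# oracle agreement

def hypergeom_exactness(max_n: int = 60) -> float:
    """Max |p - exact| of the enrichment tail over all margins with N <= max_n.

    The oracle enumerates every table with the given margins in exact
    integer arithmetic (binomial coefficients), summing the upper tail.
    """
    from scipy.stats import hypergeom

    worst = 0.0
    for N in range(1, max_n + 1):
        for n in range(1, N + 1):
            for m in range(1, N + 1):
                kmax = min(n, m)
                kmin = max(0, n + m - N)
                terms = [math.comb(m, j) * math.comb(N - m, n - j)
                         for j in range(kmin, kmax + 1)]
                denom = math.comb(N, n)
                # suffix sums: exact upper-tail P(X >= k) for every k
                suffix = np.cumsum(terms[::-1])[::-1]
                ks = np.arange(kmin, kmax + 1)
                exact = suffix / denom
                ours = hypergeom.sf(ks - 1, N, m, n)
                worst = max(worst, float(np.max(np.abs(ours - exact))))
    return worst


def fisher_glue_exactness(seed: int = 1, n_instances: int = 50) -> float:
    """Max |p - exact| of :func:`fisher_enrichment` on random gene sets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        N = int(rng.integers(5, 61))
        universe = [f"g{i}" for i in range(N)]
        n = int(rng.integers(1, N + 1))
        m = int(rng.integers(1, N + 1))
        sig = set(rng.choice(universe, size=n, replace=False))
        targets = set(rng.choice(universe, size=m, replace=False))
        rec = fisher_enrichment(sig, targets, universe, "x")
        kmax = min(n, m)
        num = sum(math.comb(m, j) * math.comb(N - m, n - j)
                  for j in range(rec.k, kmax + 1))
        worst = max(worst, abs(rec.p - num / math.comb(N, n)))
    return worst


def roc_auc_exactness(seed: int = 1, n_instances: int = 200) -> float:
    """Max AUC deviation from brute-force positive/negative pair counting."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_instances:
        n = int(rng.integers(4, 51))
        scores = np.round(rng.normal(size=n), 1)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        auc, _, _ = cv.roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = 0.0
        for p in pos:
            for q in neg:
                conc += 1.0 if p > q else (0.5 if p == q else 0.0)
        worst = max(worst, abs(auc - conc / (len(pos) * len(neg))))
        done += 1
    return worst


def spearman_exactness(seed: int = 1, n_instances: int = 200) -> float:
    """Max |rho - Pearson-on-midranks| over random tied instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_instances:
        n = int(rng.integers(4, 60))
        x = np.round(rng.normal(size=n), 1)
        y = np.round(rng.normal(size=n), 1)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, _ = cv.spearman(x, y)
        # independent mid-rank oracle
        def midranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(n)
            i = 0
            while i < n:
                j = i
                while j + 1 < n and v[order[j + 1]] == v[order[i]]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks
        rx, ry = midranks(x), midranks(y)
        num = np.sum((rx - rx.mean()) * (ry - ry.mean()))
        den = math.sqrt(np.sum((rx - rx.mean()) ** 2)
                        * np.sum((ry - ry.mean()) ** 2))
        worst = max(worst, abs(rho - num / den))
        done += 1
    return worst


def _dl_loop_oracle(y, s2):
    """Plain-loop DerSimonian-Laird evaluation (independent of the package)."""
    k = len(y)
    w = [1.0 / v for v in s2]
    sw = sum(w)
    ybar = sum(wi * yi for wi, yi in zip(w, y)) / sw
    q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y))
    c = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (q - (k - 1)) / c) if k > 1 else 0.0
    ws = [1.0 / (v + tau2) for v in s2]
    sws = sum(ws)
    mu = sum(wi * yi for wi, yi in zip(ws, y)) / sws
    se = 1.0 / math.sqrt(sws)
    return mu, se, tau2, mu / se


def dl_exactness(seed: int = 1, n_instances: int = 200) -> float:
    """Max deviation of the vectorized DL combination from the loop oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    # hand-checkable homogeneous and heterogeneous cases first
    cases = [([1.0, 1.0], [0.5, 0.5]), ([0.0, 2.0], [1.0, 1.0]),
             ([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])]
    for _ in range(n_instances):
        k = int(rng.integers(2, 6))
        cases.append((rng.normal(0, 1, k).tolist(),
                      rng.uniform(0.05, 1.0, k).tolist()))
    for y, s2 in cases:
        mine = ma.random_effects_combine(
            [ma.EffectSize(a, b, 5, 5) for a, b in zip(y, s2)])
        mu, se, tau2, z = _dl_loop_oracle(y, s2)
        worst = max(worst, abs(mine.mu_hat - mu), abs(mine.se_mu - se),
                    abs(mine.tau2 - tau2), abs(mine.z - z))
    return worst


# ---------------------------------------------------------------------------
# statistical calibration and recovery

def null_fdp(seed: int = 1, n_seeds: int = 20, n_genes: int = 2000,
             n_datasets: int = 5, n_per_group: int = 10,
             n_permutations: int = 200) -> float:
    """Mean realized false-discovery proportion under a global null.

    Every collection is generated with no group effect at all; any gene
    passing q < 0.05 is a false discovery, so the per-replicate FDP is
    V / max(R, 1).
    """
    fdps = []
    for s in _subseeds(seed, n_seeds):
        coll, _ = gen_expression_collection(
            n_datasets=n_datasets, n_genes=n_genes, n_case=n_per_group,
            n_control=n_per_group, de_fraction=0.0, tau=0.0, seed=int(s))
        res = ma.meta_analyze(coll, n_permutations=n_permutations, seed=int(s))
        r = int((res["q"] < 0.05).sum())
        fdps.append(r / max(r, 1))
    return float(np.mean(fdps))


def parameter_recovery(seed: int = 1, n_reps: int = 5, n_genes: int = 2000,
                       n_de: int = 500, mu: float = 1.0, tau: float = 0.3,
                       ) -> tuple[float, float]:
    """Mean sign-aligned pooled effect and mean tau2 over implanted genes."""
    mus, taus = [], []
    for s in _subseeds(seed, n_reps):
        coll, truth = gen_expression_collection(
            n_datasets=5, n_genes=n_genes, n_case=10, n_control=10,
            de_fraction=n_de / n_genes, mu=mu, tau=tau, seed=int(s))
        y, s2, _ = ma.collection_effects(coll)
        mu_hat, _, tau2, _ = ma.dersimonian_laird(y, s2)
        idx = {g: i for i, g in enumerate(coll.gene_universe)}
        ii = np.array([idx[g] for g in truth.de_genes])
        signs = np.sign(np.array(list(truth.de_genes.values())))
        mus.append(np.nanmean(mu_hat[ii] * signs))
        taus.append(np.nanmean(tau2[ii]))
    return float(np.mean(mus)), float(np.mean(taus))


def enrichment_recovery(seed: int = 1, n_seeds: int = 20,
                        n_genes: int = 10_000, de_fraction: float = 0.10,
                        n_mirnas: int = 200, n_enriched: int = 5,
                        overlap_odds: float = 5.0,
                        n_permutations: int = 100) -> tuple[float, float]:
    """Recovery of implanted enriched miRNAs through the full discovery arm.

    For each replicate the significant gene set is recovered by the
    meta-analysis (not taken from the truth), target databases are
    implanted at the stated odds against the true DE genes, and
    BH-selected miRNAs are compared with the implanted set.  Returns
    (mean true positives, mean false positives).
    """
    tps, fps = [], []
    for s in _subseeds(seed, n_seeds):
        coll, truth = gen_expression_collection(
            n_datasets=5, n_genes=n_genes, n_case=10, n_control=10,
            de_fraction=de_fraction, mu=1.0, tau=0.3, seed=int(s))
        res = ma.meta_analyze(coll, n_permutations=n_permutations, seed=int(s))
        sig, _ = ma.select_significant(res)
        frames, ttruth = gen_target_databases(
            n_mirnas=n_mirnas, gene_universe=coll.gene_universe,
            enriched_mirnas=n_enriched, overlap_odds=overlap_odds,
            agreement=0.6, de_genes=sorted(truth.de_genes), seed=int(s))
        cmap = build_consensus(frames)
        _, candidates = rank_and_select(
            enrich_all(cmap, sig, coll.gene_universe))
        implanted = set(ttruth.enriched_mirnas)
        tps.append(len(set(candidates) & implanted))
        fps.append(len(set(candidates) - implanted))
    return float(np.mean(tps)), float(np.mean(fps))


def cox_recovery(seed: int = 1, n_reps: int = 200, n: int = 200,
                 log_hr: float = 0.7) -> tuple[float, float]:
    """Wald CI coverage at the true log-HR and null bias of the Cox fit.

    Event times follow an exponential proportional-hazards model with a
    binary covariate; censoring times are tuned to ~30% censoring.
    Returns (coverage, |mean null log-HR|).
    """
    rng = np.random.default_rng(seed)
    covered = 0
    fitted = 0
    for _ in range(n_reps):
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.1 * np.exp(log_hr * x)))
        c = rng.exponential(2.2 / 0.1, n)
        res = cv.cox_univariate(np.minimum(t, c), (t <= c).astype(int), x)
        if res.converged:
            fitted += 1
            if math.log(res.ci_low) <= log_hr <= math.log(res.ci_high):
                covered += 1
    betas = []
    for _ in range(n_reps):
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10.0, n)
        c = rng.exponential(22.0, n)
        res = cv.cox_univariate(np.minimum(t, c), (t <= c).astype(int), x)
        if res.converged:
            betas.append(res.beta)
    return covered / max(fitted, 1), abs(float(np.mean(betas)))


# ---------------------------------------------------------------------------
# determinism

def _digest_tree(path: Path) -> dict[str, str]:
    return {str(p.relative_to(path)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(Path(path).rglob("*")) if p.is_file()}


def pipeline_determinism(workdir: str | Path, seed: int = 1) -> bool:
    """Run simulate + discover + validate twice; True iff outputs are
    byte-identical."""
    workdir = Path(workdir)
    sim_cfg = {
        "seed": seed, "permutations": 50,
        "simulate": {
            "expression": {"glomerulus": {
                "n_datasets": 3, "n_genes": 400, "n_case": 8, "n_control": 8,
                "de_fraction": 0.1, "mu": 1.2}},
            "targets": {"n_mirnas": 40, "enriched_mirnas": 2,
                        "overlap_odds": 8.0},
            "cohort": {"n_igan": 40, "n_disease_control": 5, "n_normal": 8},
        },
    }
    sim = workdir / "inputs"
    run_simulate(RunConfig.from_dict({**sim_cfg, "out_dir": str(sim)}))
    digests = []
    for run in ("run1", "run2"):
        out = workdir / run
        cfg = RunConfig(
            out_dir=str(out / "discovery"), seed=seed, permutations=50,
            compartments={"glomerulus": {
                "expression": [str(sim / "glomerulus" / f"DS{i:02d}.tsv")
                               for i in (1, 2, 3)],
                "annotation": str(sim / "glomerulus" / "annotation.tsv")}},
            target_dbs=[str(sim / "targets" / f"DB{i}.tsv") for i in (1, 2, 3)],
        )
        run_discovery(cfg)
        vcfg = RunConfig(out_dir=str(out / "validation"),
                         cohort=str(sim / "cohort" / "cohort.tsv"),
                         measurements=str(sim / "cohort" / "measurements.tsv"))
        run_validation(vcfg)
        digests.append(_digest_tree(out))
    return digests[0] == digests[1]
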