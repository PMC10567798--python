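"""Consensus miRNA-target maps and hypergeometric target-set enrichment.

miRNA-target interaction databases (e.g. miRTarBase, TargetScan, miRDB
exports) are merged into a consensus map keeping only (miRNA, gene) pairs
supported by at least ``min_support`` distinct sources.  Each miRNA's
consensus target set is then tested for over-representation among the
significant genes of the expression meta-analysis, against the universe N
of genes actually measured, with the one-sided (upper tail) hypergeometric
test — the Fisher exact test on the 2x2 table

    [ k, n-k, m-k, N-n-m+k ]

where n = significant genes, m = in-universe targets, k = their overlap.
miRNA-level FDR is Benjamini-Hochberg over the tested miRNAs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 2
DEFAULT_FDR = 0.05


@dataclass
class ConsensusTargetMap:
    """miRNA -> consensus target-gene sets with provenance."""

    targets: Mapping[str, frozenset[str]]
    min_support: int
    sources: list[str]
    n_pairs_input: int = 0
    n_pairs_retained: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.n_pairs_retained = sum(len(s) for s in self.targets.values())

    @property
    def n_mirnas(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class EnrichmentRecord:
    """Contingency counts and hypergeometric p for one miRNA."""

    mirna: str
    k: int
    n: int
    m: int
    N: int
    p: float


def read_target_db(path: str | Path, source: str | None = None) -> pd.DataFrame:
    """Read one miRNA-target TSV into (mirna, gene, source) rows.

    Columns ``mirna`` and ``gene`` are required; ``source`` defaults to the
    file stem when absent.  A file with no parsable pair is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"mirna", "gene"} <= set(df.columns):
        raise ValueError(f"{path.name}: expected columns 'mirna' and 'gene'")
    out = df[["mirna", "gene"]].apply(lambda s: s.str.strip())
    out = out.dropna()
    out = out[(out["mirna"] != "") & (out["gene"] != "")]
    if out.empty:
        raise ValueError(f"{path.name}: no parsable miRNA-target pairs")
    if "source" in df.columns:
        out["source"] = df.loc[out.index, "source"].str.strip()
    else:
        out["source"] = path.stem
    return out.reset_index(drop=True)


def build_consensus(db_files: Sequence[str | Path | pd.DataFrame],
                    min_support: int = DEFAULT_MIN_SUPPORT) -> ConsensusTargetMap:
    """Merge target databases, retaining multi-source pairs only.

    Pairs are deduplicated within each source first, so repeats inside one
    database never count as independent support; a pair survives iff it
    appears in at least ``min_support`` distinct sources.
    """
    if len(db_files) < 2:
        raise ValueError("build_consensus requires >=2 source databases")
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    frames = []
    for f in db_files:
        frames.append(f if isinstance(f, pd.DataFrame) else read_target_db(f))
    pairs = pd.concat(frames, ignore_index=True)
    n_input = len(pairs)
    pairs = pairs.drop_duplicates(["mirna", "gene", "source"])
    support = pairs.groupby(["mirna", "gene"], sort=False)["source"].nunique()
    kept = support[support >= min_support].reset_index()

    targets: dict[str, frozenset[str]] = {}
    for mirna, grp in kept.groupby("mirna", sort=True):
        targets[mirna] = frozenset(grp["gene"])
    sources = sorted(pairs["source"].unique())
    cmap = ConsensusTargetMap(targets=targets, min_support=min_support,
                              sources=sources, n_pairs_input=n_input)
    logger.info("consensus map: %d miRNAs, %d pairs retained of %d input",
                cmap.n_mirnas, cmap.n_pairs_retained, n_input)
    return cmap


def fisher_enrichment(sig_genes: Iterable[str], targets: Iterable[str],
                      universe: Iterable[str], mirna: str = "") -> EnrichmentRecord:
    """One-sided hypergeometric enrichment of a target set in the significant set.

    Targets are intersected with the universe before counting, so m counts
    only measured genes; p = P(X >= k) for X ~ Hypergeom(N, m, n).  Raises
    ``ValueError`` when no target lies in the universe (the caller skips
    such miRNAs).
    """
    universe = set(universe)
    sig = set(sig_genes)
    if not sig <= universe:
        raise ValueError("significant genes must be a subset of the universe")
    in_univ = set(targets) & universe
    if not in_univ:
        raise ValueError(f"miRNA {mirna!r}: no target in the measured universe")
    k = len(sig & in_univ)
    n = len(sig)
    m = len(in_univ)
    N = len(universe)
    p = float(hypergeom.sf(k - 1, N, m, n))
    return EnrichmentRecord(mirna=mirna, k=k, n=n, m=m, N=N, p=min(p, 1.0))


def enrich_all(cmap: ConsensusTargetMap, sig_genes: Iterable[str],
               universe: Iterable[str]) -> pd.DataFrame:
    """Enrichment records for every consensus miRNA with in-universe targets."""
    universe = set(universe)
    sig = set(sig_genes) & universe
    records = []
    skipped = 0
    for mirna in sorted(cmap.targets):
        try:
            rec = fisher_enrichment(sig, cmap.targets[mirna], universe, mirna=mirna)
        except ValueError:
            skipped += 1
            logger.info("miRNA %s skipped: no target in universe", mirna)
            continue
        records.append(rec)
    if skipped:
        logger.info("skipped %d miRNAs without in-universe targets", skipped)
    return pd.DataFrame([r.__dict__ for r in records])


def rank_and_select(records: pd.DataFrame,
                    fdr_threshold: float = DEFAULT_FDR) -> tuple[pd.DataFrame, list[str]]:
    """Benjamini-Hochberg FDR over tested miRNAs and candidate selection.

    Adds a ``q`` column (BH step-up) and a ``selected`` flag (q < threshold);
    the candidate list is ordered by ascending p, ties broken by miRNA id.
    """
    if records is None or len(records) == 0:
        warnings.warn("no enrichment records: empty candidate list", stacklevel=2)
        empty = pd.DataFrame(columns=["mirna", "k", "n", "m", "N", "p", "q", "selected"])
        return empty, []
    out = records.copy()
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["selected"] = out["q"] < fdr_threshold
    out = out.sort_values(["p", "mirna"], kind="mergesort").reset_index(drop=True)
    candidates = out.loc[out["selected"], "mirna"].tolist()
    return out, candidates
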