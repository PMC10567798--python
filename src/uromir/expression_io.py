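"""Reading, validation, probe collapse, and harmonization of expression datasets.

Case/control microarray datasets arrive as log2 expression matrices
(probesets or genes in rows, samples in columns).  Before meta-analysis the
datasets are made comparable:

1. each probeset matrix is collapsed to one row per gene symbol, keeping the
   probeset with the largest sample variance for genes measured by several
   probesets;
2. the collapsed matrices are restricted to the genes shared by every
   dataset of a tissue compartment (the *gene universe*), which later also
   serves as the background for miRNA target enrichment.

Expression values are assumed to be already log2-transformed indices; no
re-normalization is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")
COMPARTMENTS = ("glomerulus", "tubulointerstitium")


@dataclass
class LoadReport:
    """Bookkeeping for one expression TSV load."""

    path: str
    n_rows: int
    n_dropped_all_missing: int


@dataclass
class ProbesetMatrix:
    """Probeset-level log2 expression for one dataset.

    ``values`` is a probeset x sample DataFrame; ``probe_to_gene`` maps
    probeset id to gene symbol (many-to-one allowed, unmapped probesets are
    simply absent from the map).
    """

    dataset_id: str
    values: pd.DataFrame
    probe_to_gene: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate probeset id {dup!r}"
            )
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate sample id {dup!r}"
            )


@dataclass
class GeneMatrix:
    """Gene-level log2 expression with one row per gene symbol.

    ``provenance`` records, for each gene, the probeset chosen to represent
    it (the maximal-variance probeset within this dataset).
    """

    dataset_id: str
    values: pd.DataFrame
    provenance: Mapping[str, str] = field(default_factory=dict)


@dataclass
class HarmonizedDataset:
    """One member of a :class:`DatasetCollection`, restricted to the universe."""

    dataset_id: str
    values: pd.DataFrame  # gene_universe x samples, row order == universe
    case_samples: list[str]
    control_samples: list[str]


@dataclass
class DatasetCollection:
    """Harmonized multi-dataset expression: the meta-analysis substrate."""

    compartment: str
    gene_universe: list[str]
    datasets: list[HarmonizedDataset]

    def __post_init__(self) -> None:
        if not self.gene_universe:
            raise ValueError("empty gene universe")
        for ds in self.datasets:
            if list(ds.values.index) != list(self.gene_universe):
                raise ValueError(
                    f"dataset {ds.dataset_id!r} rows differ from the gene universe"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_universe)


def _clean_index(idx: Iterable) -> pd.Index:
    return pd.Index([str(x).strip() for x in idx])


def read_expression_tsv(path: str | Path, dataset_id: str) -> tuple[ProbesetMatrix, LoadReport]:
    """Parse a log2 expression TSV into a :class:`ProbesetMatrix`.

    The file has a header row of sample ids, a first column of probeset (or
    gene) ids, and numeric cells; missing values are empty cells or ``NA``.
    Lines starting with ``#`` are ignored.  Rows whose values are all
    missing are dropped and counted in the returned :class:`LoadReport`.

    Raises ``ValueError`` naming the offending id for duplicate row ids, and
    with (row, column) coordinates for non-numeric cells.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, comment="#", dtype=str,
        keep_default_na=False,
    )
    df.index = _clean_index(df.index)
    df.columns = _clean_index(df.columns)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path.name}: duplicate probeset id {dup!r}")

    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col].str.strip()
        raw = raw.mask(raw.isin(["", "NA", "nan", "NaN"]))
        try:
            numeric[col] = pd.to_numeric(raw)
        except (ValueError, TypeError):
            for row_id, cell in raw.dropna().items():
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path.name}: non-numeric value {cell!r} at "
                        f"row {row_id!r}, column {col!r}"
                    ) from None
            raise
    numeric = numeric.replace([np.inf, -np.inf], np.nan)

    all_missing = numeric.isna().all(axis=1)
    n_dropped = int(all_missing.sum())
    if n_dropped:
        logger.info("%s: dropped %d all-missing rows", path.name, n_dropped)
        numeric = numeric.loc[~all_missing]
    report = LoadReport(path=str(path), n_rows=numeric.shape[0],
                        n_dropped_all_missing=n_dropped)
    return ProbesetMatrix(dataset_id=dataset_id, values=numeric), report


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probeset_id -> gene_symbol TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{Path(path).name}: probe map needs two columns")
    probes = df.iloc[:, 0].str.strip()
    genes = df.iloc[:, 1].str.strip()
    keep = genes.notna() & (genes != "")
    return dict(zip(probes[keep], genes[keep]))


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read the sample annotation TSV (sample_id, dataset_id, group, compartment)."""
    ann = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "dataset_id", "group", "compartment"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    for col in required:
        ann[col] = ann[col].str.strip()
    bad_group = set(ann["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    bad_comp = set(ann["compartment"]) - set(COMPARTMENTS)
    if bad_comp:
        raise ValueError(f"unknown compartments: {sorted(bad_comp)}")
    dup = ann["sample_id"][ann["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"sample {dup.iloc[0]!r} annotated more than once")
    return ann


def collapse_probesets(pm: ProbesetMatrix) -> GeneMatrix:
    """Collapse a probeset matrix to one row per gene symbol.

    For genes measured by several probesets, the probeset with the largest
    sample variance (ddof=1, missing values excluded) represents the gene;
    exact variance ties are broken toward the lexicographically smaller
    probeset id.  Unmapped probesets are discarded; probesets with fewer
    than two non-missing values carry no variance and a gene is dropped
    (and logged) if none of its probesets is usable.
    """
    mapped = [p for p in pm.values.index if p in pm.probe_to_gene]
    if not mapped:
        raise ValueError(f"dataset {pm.dataset_id!r}: no probeset maps to a gene")
    sub = pm.values.loc[mapped]
    variances = sub.var(axis=1, ddof=1, skipna=True)  # NaN when <2 observations
    cand = pd.DataFrame({
        "probeset": sub.index,
        "gene": [pm.probe_to_gene[p] for p in sub.index],
        "variance": variances.to_numpy(),
    })
    usable = cand[cand["variance"].notna()]
    dropped_genes = set(cand["gene"]) - set(usable["gene"])
    for g in sorted(dropped_genes):
        logger.info("dataset %s: gene %s dropped (no probeset with >=2 values)",
                    pm.dataset_id, g)
    # lexicographic probeset order first, then a stable sort on variance
    # descending, makes the first row per gene the winner with the tie-break.
    usable = usable.sort_values("probeset", kind="mergesort")
    usable = usable.sort_values("variance", ascending=False, kind="mergesort")
    winners = usable.drop_duplicates("gene", keep="first")
    winners = winners.sort_values("gene")
    values = sub.loc[winners["probeset"]].copy()
    values.index = winners["gene"].to_numpy()
    provenance = dict(zip(winners["gene"], winners["probeset"]))
    return GeneMatrix(dataset_id=pm.dataset_id, values=values, provenance=provenance)


def harmonize(matrices: Sequence[GeneMatrix], annotation: pd.DataFrame) -> DatasetCollection:
    """Merge gene matrices on their common genes into a :class:`DatasetCollection`.

    The gene universe is the sorted intersection of all member gene lists;
    every matrix is reindexed to it.  All datasets must belong to one
    compartment and each must contribute at least two case and two control
    samples.
    """
    if len(matrices) < 2:
        raise ValueError("harmonize requires at least 2 datasets")
    ids = [m.dataset_id for m in matrices]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset ids")

    compartments = set()
    members: list[HarmonizedDataset] = []
    universe: set[str] | None = None
    for gm in matrices:
        ann = annotation[annotation["dataset_id"] == gm.dataset_id]
        if ann.empty:
            raise ValueError(f"dataset {gm.dataset_id!r} absent from annotation")
        compartments.update(ann["compartment"].unique())
        known = [s for s in ann["sample_id"] if s in gm.values.columns]
        missing = set(ann["sample_id"]) - set(known)
        if missing:
            raise ValueError(
                f"dataset {gm.dataset_id!r}: annotated samples not in matrix: "
                f"{sorted(missing)[:3]}"
            )
        grp = dict(zip(ann["sample_id"], ann["group"]))
        case = [s for s in gm.values.columns if grp.get(s) == "case"]
        control = [s for s in gm.values.columns if grp.get(s) == "control"]
        if len(case) < 2 or len(control) < 2:
            raise ValueError(
                f"dataset {gm.dataset_id!r} needs >=2 case and >=2 control "
                f"samples (has {len(case)}/{len(control)})"
            )
        members.append(HarmonizedDataset(gm.dataset_id, gm.values[case + control],
                                         case, control))
        genes = set(gm.values.index)
        universe = genes if universe is None else universe & genes

    if len(compartments) > 1:
        raise ValueError(f"datasets span multiple compartments: {sorted(compartments)}")
    if not universe:
        raise ValueError("no genes common to all datasets")
    ordered = sorted(universe)
    for ds in members:
        ds.values = ds.values.loc[ordered]
    return DatasetCollection(compartment=compartments.pop(),
                             gene_universe=ordered, datasets=members)
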