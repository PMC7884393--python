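"""Brain expression cohorts staged by Braak score.

Postmortem brain RNA-seq cohorts (e.g. the AMP-AD studies) annotate each
specimen with a Braak stage, a 0-6 neuropathological score of neurofibrillary
tangle spread.  For stage prediction the seven Braak stages are grouped into
three ordered severity categories::

    A (early)        Braak 0-2
    B (intermediate) Braak 3-4
    C (late)         Braak 5-6

This module reads expression matrices and sample metadata, restricts the
feature space to a protein-coding gene universe, and constructs the binary
classification tasks (A-vs-B, B-vs-C, A-vs-C) that the stage predictors are
trained on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Severity categories in increasing order of disease progression.
STAGE_ORDER: dict[str, int] = {"A": 0, "B": 1, "C": 2}

_BRAAK_TO_STAGE = {0: "A", 1: "A", 2: "A", 3: "B", 4: "B", 5: "C", 6: "C"}

REQUIRED_META_COLUMNS = ("sample_id", "braak", "age", "dataset", "region")


class CohortError(ValueError):
    """Fatal problem with cohort inputs (bad metadata, empty intersections...)."""


def map_braak_to_stage(braak: int) -> str:
    """Map a Braak score (0-6) to its severity category A/B/C.

    Raises :class:`CohortError` for scores outside 0-6.
    """
    b = int(braak)
    if b != braak or b not in _BRAAK_TO_STAGE:
        raise CohortError(f"Braak score must be an integer in 0..6, got {braak!r}")
    return _BRAAK_TO_STAGE[b]


def parse_age(value) -> float:
    """Parse an age field; censored ages like ``"90+"`` map to their prefix."""
    if isinstance(value, str):
        value = value.strip()
        if value.endswith("+"):
            value = value[:-1]
    age = float(value)
    if not age > 0:
        raise CohortError(f"age must be positive, got {value!r}")
    return age


@dataclass
class StagedCohort:
    """Expression matrix with per-sample Braak category and age.

    Parameters
    ----------
    expr
        Genes x samples matrix of log-scale normalized abundance.  Values are
        consumed as provided; no re-normalization is applied.
    braak
        Per-sample integer Braak score in 0..6, indexed like ``expr.columns``.
    age
        Per-sample age in years (censored ages already resolved), same index.
    dataset_id, region_id
        Labels for the study and brain region this cohort came from.
    """

    expr: pd.DataFrame
    braak: pd.Series
    age: pd.Series
    dataset_id: str = "dataset"
    region_id: str = "region"

    def __post_init__(self) -> None:
        dup = self.expr.index[self.expr.index.duplicated()]
        if len(dup):
            raise CohortError(f"duplicate gene symbol(s): {sorted(set(dup))}")
        if self.expr.columns.duplicated().any():
            raise CohortError("duplicate sample identifiers in expression matrix")
        if not (self.expr.columns.equals(self.braak.index) and self.expr.columns.equals(self.age.index)):
            raise CohortError("braak/age index must match expression columns")
        bad = self.braak[~self.braak.isin(range(7))]
        if len(bad):
            raise CohortError(f"Braak scores outside 0..6 for samples {list(bad.index)}")
        if not (self.age > 0).all():
            raise CohortError("all ages must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def stage(self) -> pd.Series:
        """Per-sample severity category derived from the Braak score."""
        return self.braak.map(_BRAAK_TO_STAGE).rename("stage")

    def label(self) -> str:
        return f"{self.dataset_id}/{self.region_id}"


@dataclass
class BinaryTask:
    """A two-class stage discrimination problem (e.g. A-vs-C) on a cohort.

    ``labels`` assigns 0 to the earlier (``lo_class``) and 1 to the later
    (``hi_class``) category; ``sample_ids`` index into the parent cohort.
    """

    cohort: StagedCohort
    lo_class: str
    hi_class: str
    sample_ids: pd.Index = field(repr=False)
    labels: np.ndarray = field(repr=False)

    @property
    def name(self) -> str:
        return f"{self.lo_class}-vs-{self.hi_class}"

    @property
    def ages(self) -> pd.Series:
        return self.cohort.age.loc[self.sample_ids]

    def expression(self, genes: Iterable[str]) -> np.ndarray:
        """Samples x genes feature matrix restricted to ``genes``."""
        return self.cohort.expr.loc[list(genes), self.sample_ids].to_numpy().T


def build_binary_task(cohort: StagedCohort, lo: str, hi: str) -> BinaryTask:
    """Select the samples of two severity categories and label them 0/1.

    Requires ``lo < hi`` in the A < B < C order and at least two samples per
    class (age-matched pairing is impossible otherwise).
    """
    for c in (lo, hi):
        if c not in STAGE_ORDER:
            raise CohortError(f"unknown stage category {c!r}")
    if not STAGE_ORDER[lo] < STAGE_ORDER[hi]:
        raise CohortError(f"lo class must precede hi class, got {lo} vs {hi}")
    stage = cohort.stage
    mask = stage.isin([lo, hi])
    sample_ids = cohort.samples[mask.to_numpy()]
    labels = (stage.loc[sample_ids] == hi).to_numpy().astype(int)
    n_lo, n_hi = int((labels == 0).sum()), int((labels == 1).sum())
    if n_lo < 2 or n_hi < 2:
        raise CohortError(
            f"task {lo}-vs-{hi} needs >=2 samples per class, got {n_lo} ({lo}) and {n_hi} ({hi})"
        )
    return BinaryTask(cohort, lo, hi, sample_ids, labels)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_names(path: Path) -> list[str]:
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def read_expression(expr_path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix from TSV or MatrixMarket.

    TSV: first column holds gene symbols, header row holds sample IDs.
    MatrixMarket: ``<stem>.mtx`` with sidecar ``<stem>.rownames.txt`` (genes)
    and ``<stem>.colnames.txt`` (samples), one name per line.
    """
    expr_path = Path(expr_path)
    if expr_path.suffix == ".mtx":
        from scipy.io import mmread

        m = mmread(str(expr_path))
        if hasattr(m, "toarray"):
            m = m.toarray()
        stem = expr_path.with_suffix("")
        genes = _read_names(Path(str(stem) + ".rownames.txt"))
        samples = _read_names(Path(str(stem) + ".colnames.txt"))
        if np.shape(m) != (len(genes), len(samples)):
            raise CohortError(
                f"matrix shape {np.shape(m)} does not match {len(genes)} rownames x {len(samples)} colnames"
            )
        return pd.DataFrame(np.asarray(m), index=genes, columns=samples)
    return pd.read_csv(expr_path, sep="\t", index_col=0)


def read_cohort(
    expr_path: str | Path,
    meta_path: str | Path,
    *,
    log2_cpm: bool = False,
    alias_map: Mapping[str, str] | None = None,
) -> StagedCohort:
    """Read an expression matrix and sample metadata into a :class:`StagedCohort`.

    Metadata is TSV with required columns ``sample_id, braak, age, dataset,
    region``.  Samples are intersected between the two files (metadata order
    wins); samples with missing braak or age are dropped with a warning.
    Set ``log2_cpm`` for raw counts to apply a log2(CPM+1) transform.
    ``alias_map`` optionally renames gene symbols before duplicate checking.
    """
    expr = read_expression(expr_path)
    if alias_map:
        expr.index = [alias_map.get(g, g) for g in expr.index]
    dup = expr.index[expr.index.duplicated()]
    if len(dup):
        raise CohortError(f"duplicate gene symbol(s) in {expr_path}: {sorted(set(dup))}")

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise CohortError(f"metadata {meta_path} is missing required column(s): {missing}")

    n0 = len(meta)
    meta = meta.dropna(subset=["braak", "age"])
    if len(meta) < n0:
        log.warning("dropped %d sample(s) with missing braak or age", n0 - len(meta))
    meta = meta.set_index("sample_id")

    shared = [s for s in meta.index if s in set(expr.columns)]
    n_meta_only = len(meta) - len(shared)
    n_expr_only = expr.shape[1] - len(shared)
    if n_meta_only or n_expr_only:
        log.warning(
            "sample intersection dropped %d metadata-only and %d expression-only sample(s)",
            n_meta_only,
            n_expr_only,
        )
    if not shared:
        raise CohortError("zero overlapping samples between expression and metadata")
    expr = expr.loc[:, shared]
    meta = meta.loc[shared]

    if log2_cpm:
        totals = expr.sum(axis=0)
        expr = np.log2(expr.div(totals, axis=1) * 1e6 + 1.0)

    braak = meta["braak"].astype(int).rename("braak")
    for b in braak:
        map_braak_to_stage(b)  # validates range, error names offending value
    age = meta["age"].map(parse_age).rename("age")

    dataset = str(meta["dataset"].iloc[0]) if meta["dataset"].nunique() == 1 else "mixed"
    region = str(meta["region"].iloc[0]) if meta["region"].nunique() == 1 else "mixed"
    cohort = StagedCohort(expr, braak, age, dataset_id=dataset, region_id=region)
    cohort._meta = meta  # retained for region splitting
    log.info("read cohort %s: %d genes x %d samples", cohort.label(), *expr.shape)
    return cohort


def write_cohort(cohort: StagedCohort, expr_path: str | Path, meta_path: str | Path) -> None:
    """Write a cohort back to TSV (inverse of :func:`read_cohort` on TSV input)."""
    expr_path, meta_path = Path(expr_path), Path(meta_path)
    out = cohort.expr.copy()
    out.index.name = "gene"
    out.to_csv(expr_path, sep="\t", float_format="%.10g")
    meta = pd.DataFrame(
        {
            "sample_id": cohort.samples,
            "braak": cohort.braak.to_numpy(),
            "age": cohort.age.to_numpy(),
            "dataset": cohort.dataset_id,
            "region": cohort.region_id,
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False, float_format="%.10g")


def split_by_region(cohort: StagedCohort) -> Iterator[StagedCohort]:
    """Yield one single-region cohort per (dataset, region) present.

    Useful when a metadata file spans several brain regions; age matching and
    background nulls are computed within a single region.
    """
    meta = getattr(cohort, "_meta", None)
    if meta is None or ("dataset" not in meta.columns):
        yield cohort
        return
    for (ds, rg), sub in meta.groupby(["dataset", "region"], sort=True):
        ids = sub.index
        yield StagedCohort(
            cohort.expr.loc[:, ids],
            cohort.braak.loc[ids],
            cohort.age.loc[ids],
            dataset_id=str(ds),
            region_id=str(rg),
        )


def read_universe(path: str | Path) -> list[str]:
    """Read a gene universe: one symbol per line, blanks ignored."""
    symbols = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not symbols:
        raise CohortError(f"gene universe {path} is empty")
    return symbols


def restrict_to_universe(cohort: StagedCohort, universe: Iterable[str]) -> StagedCohort:
    """Restrict the cohort's genes to those in ``universe`` (row order kept).

    Symbols are matched case-sensitively.  An empty intersection is fatal.
    """
    uni = set(universe)
    if not uni:
        raise CohortError("gene universe is empty")
    keep = [g for g in cohort.genes if g in uni]
    if not keep:
        raise CohortError("no cohort genes found in the supplied universe")
    dropped = cohort.n_genes - len(keep)
    if dropped:
        log.info("universe restriction dropped %d of %d genes", dropped, cohort.n_genes)
    out = StagedCohort(
        cohort.expr.loc[keep],
        cohort.braak,
        cohort.age,
        dataset_id=cohort.dataset_id,
        region_id=cohort.region_id,
    )
    if hasattr(cohort, "_meta"):
        out._meta = cohort._meta
    return out
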