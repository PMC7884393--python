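"""Drug-associated gene lists (DGLs) from perturbational count data.

A DGL is the set of genes significantly differentially expressed when neural
cell cultures are exposed to a drug, relative to vehicle (DMSO) controls.
The list-derivation contract is: keep genes at FDR < 0.05 and cap the result
at the top 300 genes.  Differential expression itself is a pluggable step —
any procedure that yields per-gene (logFC, p, FDR) can stand behind
:class:`DeResult`, and precomputed lists can always be supplied directly.
The built-in test is a per-gene Welch t-test on log2(CPM + 0.5) with
Benjamini-Hochberg adjustment across all tested genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_FDR = 0.05
DEFAULT_CAP = 300
#: Prior count added to CPM before the log2 transform, keeping logFC finite.
CPM_PRIOR = 0.5


@dataclass
class GeneList:
    """A named, ordered, duplicate-free list of gene symbols.

    ``source`` records whether the list was derived from a differential
    expression contrast or supplied externally (literature list, GMT entry).
    An empty gene list is a sentinel for "no significant perturbation":
    downstream evaluation skips it rather than aborting a screen.
    """

    name: str
    genes: list[str] = field(default_factory=list)
    source: str = "supplied"
    experiment_id: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dups = sorted({g for g in self.genes if g in seen or seen.add(g)})
            raise ValueError(f"gene list {self.name!r} contains duplicates: {dups}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def is_empty(self) -> bool:
        return not self.genes


def log2_cpm(counts: pd.DataFrame, lib_sizes: Sequence[float] | None = None) -> pd.DataFrame:
    """log2(counts-per-million + prior) with per-column library-size scaling.

    ``lib_sizes`` overrides the default per-column totals; useful when a
    matrix slice must keep the library sizes of the full experiment.
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        lib_sizes = np.where(lib_sizes <= 0, 1.0, lib_sizes)
    cpm = counts.to_numpy(dtype=float) / lib_sizes * 1e6
    return pd.DataFrame(np.log2(cpm + CPM_PRIOR), index=counts.index, columns=counts.columns)


def differential_expression(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    *,
    treated_lib_sizes: Sequence[float] | None = None,
    control_lib_sizes: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-gene treated-vs-control test on log2 CPM; returns logFC, p, FDR.

    Both matrices are genes x replicates with identical gene rows and at
    least two replicate columns each.  Genes with zero counts everywhere are
    reported (p = 1, logFC = 0), not dropped.  BH adjustment runs across all
    tested genes.
    """
    if not treated.index.equals(control.index):
        raise ValueError("treated and control matrices must share identical gene rows")
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need >= 2 replicate columns per arm")

    lt = log2_cpm(treated, treated_lib_sizes).to_numpy()
    lc = log2_cpm(control, control_lib_sizes).to_numpy()

    logfc = lt.mean(axis=1) - lc.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(lt, lc, axis=1, equal_var=False)
    pval = np.where(np.isfinite(pval), pval, 1.0)

    all_zero = (treated.to_numpy().sum(axis=1) == 0) & (control.to_numpy().sum(axis=1) == 0)
    logfc = np.where(all_zero, 0.0, logfc)
    pval = np.where(all_zero, 1.0, pval)

    fdr = multipletests(pval, method="fdr_bh")[1]
    return pd.DataFrame({"logFC": logfc, "p": pval, "fdr": fdr}, index=treated.index)


def derive_gene_list(
    de: pd.DataFrame,
    *,
    fdr_threshold: float = DEFAULT_FDR,
    cap: int = DEFAULT_CAP,
    name: str = "derived",
    experiment_id: str | None = None,
) -> GeneList:
    """Significant genes (FDR < threshold), ranked and truncated to ``cap``.

    Ranking for truncation: ascending FDR, ties by descending \\|logFC\\|,
    then ascending symbol — fully deterministic.  No significant genes
    yields the empty sentinel with a warning.
    """
    if de.empty:
        raise ValueError("differential expression result is empty")
    sig = de[de["fdr"] < fdr_threshold].copy()
    if sig.empty:
        log.warning("gene list %r: no genes at FDR < %g; emitting empty sentinel", name, fdr_threshold)
        return GeneList(name, [], source="derived", experiment_id=experiment_id)
    sig["_abs_lfc"] = sig["logFC"].abs()
    sig["_symbol"] = sig.index.astype(str)
    sig = sig.sort_values(["fdr", "_abs_lfc", "_symbol"], ascending=[True, False, True])
    genes = list(sig.index[:cap].astype(str))
    return GeneList(name, genes, source="derived", experiment_id=experiment_id)


# ---------------------------------------------------------------------------
# Count-matrix manifests and contrasts
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("sample", "drug", "dose", "replicate", "experiment_id", "is_control")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples integer count matrix from TSV (first column = gene)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV mapping count-matrix columns to (drug, dose, replicate...)."""
    man = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {missing}")
    man["is_control"] = man["is_control"].astype(bool)
    return man


def derive_all_gene_lists(
    counts: pd.DataFrame,
    manifest: pd.DataFrame,
    *,
    fdr_threshold: float = DEFAULT_FDR,
    cap: int = DEFAULT_CAP,
) -> list[GeneList]:
    """One DGL per (drug, dose, experiment) contrast against that experiment's DMSO arm.

    The list is named after the drug so downstream ranking joins directly
    with drug-target binding tables; dose is folded into ``experiment_id``
    (``"EXP1:10uM"``), so a drug profiled at several doses or in several
    experiments has its per-contrast evidence merged by the geometric mean
    at ranking time.  Library sizes are taken from the full count matrix so
    CPM normalization is unaffected by subsetting columns to one contrast.
    """
    lib = counts.sum(axis=0)
    lists: list[GeneList] = []
    for exp_id, exp_man in manifest.groupby("experiment_id", sort=True):
        ctrl_cols = list(exp_man.loc[exp_man["is_control"], "sample"])
        if len(ctrl_cols) < 2:
            raise ValueError(f"experiment {exp_id!r} has fewer than 2 control columns")
        treated_man = exp_man[~exp_man["is_control"]]
        for (drug, dose), grp in treated_man.groupby(["drug", "dose"], sort=True):
            cols = list(grp["sample"])
            if len(cols) < 2:
                log.warning("contrast %s@%s in %s has <2 replicates; skipped", drug, dose, exp_id)
                continue
            de = differential_expression(
                counts[cols],
                counts[ctrl_cols],
                treated_lib_sizes=lib[cols],
                control_lib_sizes=lib[ctrl_cols],
            )
            lists.append(
                derive_gene_list(
                    de,
                    fdr_threshold=fdr_threshold,
                    cap=cap,
                    name=str(drug),
                    experiment_id=f"{exp_id}:{dose}",
                )
            )
    return lists


# ---------------------------------------------------------------------------
# Gene-list I/O (GMT and one-symbol-per-line text)
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a plain-text gene list (one symbol per line)."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return GeneList(name or path.stem, genes, source="supplied")


def read_gmt(path: str | Path) -> list[GeneList]:
    """Read gene lists from GMT (tab-separated: name, description, genes...)."""
    lists = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line: {ln!r}")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        exp = desc if desc and desc != "na" else None
        lists.append(GeneList(name, genes, source="supplied", experiment_id=exp))
    return lists


def write_gmt(lists: Iterable[GeneList], path: str | Path) -> None:
    """Write gene lists as GMT; experiment_id is stored in the description field."""
    with open(path, "w") as fh:
        for gl in lists:
            desc = gl.experiment_id if gl.experiment_id else "na"
            fh.write("\t".join([gl.name, desc, *gl.genes]) + "\n")
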