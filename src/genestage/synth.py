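"""Seeded synthetic fixtures with known ground truth.

Three generators emulate the pipeline's three external inputs:

* a staged brain expression cohort, with a chosen subset of "informative"
  genes whose log-scale mean shifts monotonically across the A -> B -> C
  severity categories;
* perturbational count matrices (drug vs. DMSO), negative-binomial counts
  with a planted fold change on each drug's responsive genes;
* a drug-target binding-record table constructed so that TAS resolution
  reproduces a known truth table exactly.

Every generator emits a machine-readable truth record, so parameter-recovery
tests elsewhere consume only generator outputs plus truth.  Outputs are
byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import StagedCohort

#: Braak scores available within each severity category.
_CATEGORY_BRAAK = {"A": (0, 1, 2), "B": (3, 4), "C": (5, 6)}


@dataclass
class CohortSpec:
    """Parameters of the synthetic staged cohort.

    ``effect_size`` is the mean log-expression shift per category step
    (A -> B and B -> C) planted in the informative genes; ``noise_sd`` is the
    per-gene Gaussian noise on the same log scale.  Age ranges overlap
    across categories so age matching is informative but non-degenerate.
    """

    n_per_stage: tuple[int, int, int] = (34, 33, 33)
    n_genes: int = 2000
    n_informative: int = 50
    effect_size: float = 1.0
    noise_sd: float = 1.0
    age_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (60.0, 85.0), "B": (65.0, 90.0), "C": (70.0, 95.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")


def generate_cohort(spec: CohortSpec) -> tuple[StagedCohort, dict]:
    """Generate a staged cohort; returns (cohort, truth).

    ``truth['informative_genes']`` lists the genes with the planted stage
    effect.  Baseline per-gene means are N(6, 1) on the log scale; for
    informative genes the category index (A=0, B=1, C=2) times
    ``effect_size`` is added, and N(0, noise_sd) noise covers all genes.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    informative = sorted(rng.choice(genes, size=spec.n_informative, replace=False).tolist())
    informative_set = set(informative)

    stages = [s for s, n in zip("ABC", spec.n_per_stage) for _ in range(n)]
    n_samples = len(stages)
    samples = [f"S{i:04d}" for i in range(n_samples)]

    baseline = rng.normal(6.0, 1.0, size=spec.n_genes)
    stage_idx = np.array([{"A": 0, "B": 1, "C": 2}[s] for s in stages])
    info_mask = np.array([g in informative_set for g in genes])

    expr = np.tile(baseline[:, None], (1, n_samples))
    expr[info_mask, :] += spec.effect_size * stage_idx[None, :]
    expr += rng.normal(0.0, spec.noise_sd, size=expr.shape)

    braak = np.array([rng.choice(_CATEGORY_BRAAK[s]) for s in stages])
    age = np.array(
        [rng.uniform(*spec.age_ranges[s]) for s in stages]
    ).round(1)

    cohort = StagedCohort(
        pd.DataFrame(expr, index=genes, columns=samples),
        pd.Series(braak, index=samples, name="braak"),
        pd.Series(age, index=samples, name="age"),
        dataset_id="synthetic",
        region_id="sim",
    )
    truth = {
        "informative_genes": informative,
        "effect_size": spec.effect_size,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return cohort, truth


@dataclass
class PerturbationSpec:
    """Parameters of the synthetic drug-perturbation count experiment.

    ``dispersion`` is the negative-binomial overdispersion (variance =
    mu + dispersion * mu^2); ``library_size`` is the expected total count
    per column.  ``fold_change`` multiplies the responsive genes' means in
    treated arms.
    """

    n_genes: int = 2000
    n_responsive: int = 50
    fold_change: float = 4.0
    dispersion: float = 0.005
    n_replicates: int = 3
    library_size: float = 1e7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_responsive", "fold_change", "dispersion", "n_replicates", "library_size"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_responsive > self.n_genes:
            raise ValueError("n_responsive cannot exceed n_genes")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    # gamma-poisson mixture: var = mu + dispersion * mu^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def generate_perturbation_counts(
    spec: PerturbationSpec,
    drug_names: list[str],
    experiment_id: str = "EXP1",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate counts, a column manifest, and per-drug responsive-gene truth.

    The experiment has one DMSO control arm plus one treated arm per drug
    (single dose, ``n_replicates`` columns each).  Responsive genes are
    drawn independently per drug; half are up-regulated by ``fold_change``
    and half down-regulated by its reciprocal, so the perturbation is
    roughly composition-neutral and non-responsive genes stay null on the
    CPM scale.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]

    # baseline relative abundance: lognormal, normalized to library size
    rel = rng.lognormal(0.0, 1.0, size=spec.n_genes)
    base_mu = rel / rel.sum() * spec.library_size

    columns: dict[str, np.ndarray] = {}
    manifest_rows = []
    for r in range(spec.n_replicates):
        col = f"DMSO_r{r + 1}"
        columns[col] = _nb_counts(rng, base_mu, spec.dispersion)
        manifest_rows.append(
            {"sample": col, "drug": "DMSO", "dose": "0", "replicate": r + 1,
             "experiment_id": experiment_id, "is_control": True}
        )

    truth: dict[str, list[str]] = {}
    for drug in drug_names:
        responsive = sorted(rng.choice(genes, size=spec.n_responsive, replace=False).tolist())
        truth[drug] = responsive
        n_up = spec.n_responsive // 2 + spec.n_responsive % 2
        up = set(rng.choice(responsive, size=n_up, replace=False).tolist())
        down = set(responsive) - up
        factor = np.array(
            [spec.fold_change if g in up else 1.0 / spec.fold_change if g in down else 1.0 for g in genes]
        )
        mu = base_mu * factor
        mu = mu / mu.sum() * spec.library_size
        for r in range(spec.n_replicates):
            col = f"{drug}_r{r + 1}"
            columns[col] = _nb_counts(rng, mu, spec.dispersion)
            manifest_rows.append(
                {"sample": col, "drug": drug, "dose": "10uM", "replicate": r + 1,
                 "experiment_id": experiment_id, "is_control": False}
            )

    counts = pd.DataFrame(columns, index=genes)
    manifest = pd.DataFrame(manifest_rows)
    return counts, manifest, {"responsive_genes": truth, "seed": spec.seed}


def generate_binding_table(
    drugs: list[str],
    targets: list[str],
    density: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate binding records plus the truth TAS table they resolve to.

    Each drug-target pair is populated with probability ``density``.  A
    truth TAS value in {1, 2, 3, 10} is drawn, then evidence consistent with
    it is constructed: TAS 1 and 3 require dose-response records; TAS 2 and
    10 use a random evidence kind, sometimes with additional conflicting
    lower-precedence records (resolution must still recover the truth).
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    truth_rows = []

    affinity_bands = {1: (1.0, 99.0), 2: (100.0, 999.0), 3: (1000.0, 10000.0), 10: (10001.0, 100000.0)}

    for drug in drugs:
        for target in targets:
            if rng.uniform() > density:
                continue
            tas = int(rng.choice([1, 2, 3, 10], p=[0.15, 0.25, 0.2, 0.4]))
            if tas in (1, 3):
                kind = "dose_response"
            else:
                kind = str(rng.choice(["dose_response", "single_dose", "literature"]))

            if kind == "dose_response":
                lo, hi = affinity_bands[tas]
                n_meas = int(rng.integers(1, 4))
                # all measurements inside the band -> first quartile stays in band
                for _ in range(n_meas):
                    records.append(_record(drug, target, "dose_response", affinity=rng.uniform(lo, hi)))
                # occasionally add a conflicting lower-precedence record
                if rng.uniform() < 0.3:
                    records.append(
                        _record(drug, target, "literature",
                                assertion="negative" if tas != 10 else "confirming")
                    )
            elif kind == "single_dose":
                conc = float(rng.choice([100.0, 1000.0, 10000.0]))
                lo_cut, hi_cut = {100.0: (25.0, 75.0), 1000.0: (1.0, 90.0), 10000.0: (0.1, 75.0)}[conc]
                percent = rng.uniform(0, lo_cut) if tas == 2 else rng.uniform(hi_cut, 100.0)
                records.append(_record(drug, target, "single_dose", conc=conc, percent=percent))
            else:
                records.append(
                    _record(drug, target, "literature",
                            assertion="confirming" if tas == 2 else "negative")
                )
            truth_rows.append({"drug": drug, "target": target, "tas": tas})

    records_df = pd.DataFrame(
        records,
        columns=["drug", "target", "evidence_kind", "affinity_nM", "assay_conc_nM", "percent", "assertion"],
    )
    truth_df = pd.DataFrame(truth_rows, columns=["drug", "target", "tas"])
    if not truth_df.empty:
        truth_df = truth_df.sort_values(["drug", "target"]).reset_index(drop=True)
    return records_df, truth_df


def _record(drug, target, kind, affinity=None, conc=None, percent=None, assertion=None) -> dict:
    return {
        "drug": drug,
        "target": target,
        "evidence_kind": kind,
        "affinity_nM": affinity,
        "assay_conc_nM": conc,
        "percent": percent,
        "assertion": assertion,
    }


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
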