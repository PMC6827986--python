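"""Synthetic pharmacogenomic panels and clinical cohorts with known truth.

The generator emulates the statistical skeleton of the real screening inputs:
several partially overlapping cell-line panels, each with its own expression
platform, a drug-response table per panel, and a handful of "planted" genes
whose expression drives the response of every drug in their affected classes.
The clinical generator produces cohorts where expression improves survival
only in chemotherapy-treated patients, and shifts the odds of tumor response.

Screen model
------------
Within each panel, every gene's expression is ``mu_g + N(0, 1)`` with a
gene-specific mean ``mu_g`` shared across panels; panels draw their
expression independently (each platform re-measures the biology). The
response of drug ``d`` (class ``c``) for a line is

    response = sum over planted genes g affecting c of s_g * beta_g * (expr_g - mu_g)
               + N(0, noise_sd)

with ``s_g = -1`` for sensitizers (higher expression => lower AUC / ln IC50)
and ``+1`` for resistance genes. Null genes never enter any response.

Clinical model
--------------
``expr ~ N(0, 1)``; survival time is exponential with hazard
``lambda0 * exp(-gamma * expr)`` for treated patients and ``lambda0``
otherwise, so ``gamma > 0`` makes high expression protective only under
chemotherapy. Censoring is an independent exponential calibrated to the
requested censoring rate in expectation. Response labels for treated
patients follow ``Bernoulli(logistic(a + b * expr))``.

All generators are pure functions of their configuration: the same seed
yields bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    DrugClass,
    DrugClassMap,
    DrugResponseTable,
    ExpressionMatrix,
    ResponseMetric,
    ScreenDataset,
)
from .clinical import ClinicalCohort, Response
from .consensus import Direction

__all__ = [
    "PlantedGene",
    "SyntheticScreenConfig",
    "SyntheticClinicalConfig",
    "SyntheticTruth",
    "generate_screen_panels",
    "generate_clinical_cohort",
    "write_panels",
]

#: the four DNA-damage classes a pan-class sensitizer affects by default
DNA_DAMAGE_CLASSES = (
    DrugClass.ALKYLATING,
    DrugClass.ANTIMETABOLITE,
    DrugClass.ANTITUMOR_ANTIBIOTIC,
    DrugClass.TOPOISOMERASE,
)

_CLASS_ABBREV = {
    DrugClass.ALKYLATING: "ALK",
    DrugClass.ANTIMETABOLITE: "AMB",
    DrugClass.ANTITUMOR_ANTIBIOTIC: "ATA",
    DrugClass.MICROTUBULE: "MTI",
    DrugClass.TOPOISOMERASE: "TOP",
}


@dataclass(frozen=True)
class PlantedGene:
    """One gene with a real effect on the drugs of its affected classes."""

    gene_id: str
    classes: tuple[DrugClass, ...]
    beta: float  # effect size per SD of latent expression, >= 0
    direction: Direction = Direction.SENSITIVITY

    @property
    def sign(self) -> float:
        # sensitizers push the response metric down as expression rises
        return -1.0 if Direction(self.direction) is Direction.SENSITIVITY else 1.0


def _default_planted() -> tuple[PlantedGene, ...]:
    return (
        PlantedGene(
            gene_id="PLANTED_SENS",
            classes=DNA_DAMAGE_CLASSES,
            beta=1.5,
            direction=Direction.SENSITIVITY,
        ),
    )


@dataclass
class SyntheticScreenConfig:
    """Study conditions for the multi-panel screen simulation.

    Defaults mirror the screening scenario the pipeline is designed around:
    three databases of 60 solid-tumor lines with half the lines shared, 500
    null transcripts plus one planted pan-class sensitizer (beta = 1.5,
    response noise SD 1), and six drugs per class per database (the real
    chemotherapeutic inventories average ~6 drugs per class per panel).
    """

    n_databases: int = 3
    n_genes: int = 501  # total universe, planted genes included
    n_lines_per_db: int = 60
    line_overlap_fraction: float = 0.5
    drugs_per_class: int = 6
    planted_genes: tuple[PlantedGene, ...] = field(default_factory=_default_planted)
    noise_sd: float = 1.0
    expression_mean_center: float = 7.0  # RMA-like log2 intensity scale
    lineages: tuple[str, ...] = ("breast", "lung", "ovary")
    lineage_gene: str | None = None
    lineage_offsets: tuple[float, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_databases < 1:
            raise ValueError("need at least one database")
        if not 0.0 <= self.line_overlap_fraction <= 1.0:
            raise ValueError("line_overlap_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_genes < len(self.planted_genes):
            raise ValueError("gene universe smaller than planted gene list")
        n_shared = round(self.line_overlap_fraction * self.n_lines_per_db)
        if self.line_overlap_fraction > 0 and n_shared == 0:
            raise ValueError(
                "n_lines_per_db too small for the requested overlap fraction"
            )
        for pg in self.planted_genes:
            if pg.beta < 0:
                raise ValueError(f"planted gene {pg.gene_id!r} has negative beta")
        if self.lineage_gene is not None and len(self.lineage_offsets) != len(
            self.lineages
        ):
            raise ValueError("lineage_offsets must match lineages in length")


@dataclass
class SyntheticClinicalConfig:
    """Study conditions for one simulated patient cohort.

    Survival times are on a monthly scale (baseline hazard 0.05/month gives a
    ~14-month median). ``gamma`` is the log-hazard reduction per SD of
    expression, applied only to chemotherapy-treated patients.
    """

    n_patients: int = 150
    chemo_fraction: float = 0.5
    baseline_hazard: float = 0.05
    gamma: float = 1.0
    censoring_rate: float = 0.2
    response_intercept: float = -0.5
    response_slope: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError("need at least 4 patients")
        if not 0.0 <= self.chemo_fraction <= 1.0:
            raise ValueError("chemo_fraction must be in [0, 1]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside generated data, enough to score recovery."""

    planted_genes: tuple[PlantedGene, ...] = ()
    null_genes: tuple[str, ...] = ()
    drug_classes: DrugClassMap | None = None
    clinical_gamma: float | None = None
    response_slope: float | None = None
    config: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_genes": [
                {
                    "gene_id": pg.gene_id,
                    "classes": [c.value for c in pg.classes],
                    "beta": pg.beta,
                    "direction": Direction(pg.direction).value,
                }
                for pg in self.planted_genes
            ],
            "null_genes": list(self.null_genes),
            "drug_classes": (
                {d: c.value for d, c in self.drug_classes.items()}
                if self.drug_classes is not None
                else None
            ),
            "clinical_gamma": self.clinical_gamma,
            "response_slope": self.response_slope,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _line_names(cfg: SyntheticScreenConfig) -> list[list[str]]:
    """Per-database line lists with a shared pool of the requested size."""
    n_shared = round(cfg.line_overlap_fraction * cfg.n_lines_per_db)
    shared = [f"CL-SH{i:04d}" for i in range(n_shared)]
    panels = []
    for k in range(cfg.n_databases):
        unique = [
            f"CL-DB{k + 1}U{i:04d}" for i in range(cfg.n_lines_per_db - n_shared)
        ]
        panels.append(shared + unique)
    return panels


def generate_screen_panels(
    cfg: SyntheticScreenConfig,
) -> tuple[list[ScreenDataset], SyntheticTruth]:
    """Simulate ``cfg.n_databases`` panels plus the planted-gene ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    planted_ids = [pg.gene_id for pg in cfg.planted_genes]
    n_null = cfg.n_genes - len(planted_ids)
    null_ids = [f"G{i:05d}" for i in range(n_null)]
    genes = planted_ids + null_ids

    panels_lines = _line_names(cfg)
    all_lines = sorted({ln for panel in panels_lines for ln in panel})
    lineage_of = {ln: cfg.lineages[i % len(cfg.lineages)] for i, ln in enumerate(all_lines)}

    # gene-specific means are shared biology; each panel re-measures
    # expression independently around them
    gene_means = cfg.expression_mean_center + rng.normal(0.0, 1.0, size=len(genes))
    offsets = dict(zip(cfg.lineages, cfg.lineage_offsets))

    metrics = [ResponseMetric.AUC, ResponseMetric.LN_IC50]
    datasets = []
    class_map = DrugClassMap()
    for k, lines in enumerate(panels_lines):
        db_id = f"DB{k + 1}"
        centered = rng.normal(0.0, 1.0, size=(len(lines), len(genes)))
        if cfg.lineage_gene is not None:
            gi = genes.index(cfg.lineage_gene)
            centered[:, gi] += np.array([offsets[lineage_of[ln]] for ln in lines])
        observed = gene_means[None, :] + centered
        expr = ExpressionMatrix(
            dataset_id=db_id,
            data=pd.DataFrame(observed, index=lines, columns=genes),
        )

        drug_ids = []
        resp_cols = {}
        for cls in DrugClass:
            effect = np.zeros(len(lines))
            for pg in cfg.planted_genes:
                if cls in pg.classes:
                    gi = genes.index(pg.gene_id)
                    effect = effect + pg.sign * pg.beta * centered[:, gi]
            for j in range(cfg.drugs_per_class):
                drug = f"{db_id}-{_CLASS_ABBREV[cls]}{j + 1:02d}"
                class_map[drug] = cls
                resp_cols[drug] = effect + rng.normal(0.0, cfg.noise_sd, size=len(lines))
                drug_ids.append(drug)
        resp = DrugResponseTable(
            dataset_id=db_id,
            metric=metrics[k % len(metrics)],
            data=pd.DataFrame(resp_cols, index=lines, columns=drug_ids),
        )
        datasets.append(
            ScreenDataset(
                expression=expr,
                response=resp,
                lineage={ln: lineage_of[ln] for ln in lines},
            )
        )

    truth = SyntheticTruth(
        planted_genes=tuple(cfg.planted_genes),
        null_genes=tuple(null_ids),
        drug_classes=class_map,
        config={
            k: v
            for k, v in asdict(cfg).items()
            if k not in ("planted_genes",)
        },
    )
    return datasets, truth


def generate_clinical_cohort(
    cfg: SyntheticClinicalConfig, cohort_id: str = "synthetic-cohort"
) -> tuple[ClinicalCohort, SyntheticTruth]:
    """Simulate one patient cohort under the exponential-hazard model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    expr = rng.normal(0.0, 1.0, size=n)
    chemo = rng.random(n) < cfg.chemo_fraction

    hazard = cfg.baseline_hazard * np.exp(-cfg.gamma * expr * chemo)
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        # exponential censoring with rate chosen so that, against the baseline
        # hazard, the expected censored fraction equals censoring_rate
        cens_rate = cfg.baseline_hazard * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        censor_time = rng.exponential(1.0 / cens_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    logit = cfg.response_intercept + cfg.response_slope * expr
    p_resp = 1.0 / (1.0 + np.exp(-logit))
    resp_draw = rng.random(n) < p_resp
    response = np.where(
        chemo,
        np.where(resp_draw, Response.RESPONDER.value, Response.NON_RESPONDER.value),
        None,
    )

    data = pd.DataFrame(
        {
            "patient_id": [f"PT{i:04d}" for i in range(n)],
            "expr": expr,
            "time": time,
            "event": event,
            "chemo": chemo,
            "response": response,
        }
    )
    cohort = ClinicalCohort(cohort_id=cohort_id, data=data)
    truth = SyntheticTruth(
        clinical_gamma=cfg.gamma,
        response_slope=cfg.response_slope,
        config=asdict(cfg),
    )
    return cohort, truth


def write_panels(
    datasets: Sequence[ScreenDataset],
    truth: SyntheticTruth,
    outdir: str | Path,
) -> None:
    """Write panels in the delimited formats the readers consume, plus truth."""
    from .core import write_expression, write_response

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        did = ds.dataset_id
        write_expression(ds.expression, outdir / f"{did}.expression.tsv")
        write_response(ds.response, outdir / f"{did}.response.tsv")
        if ds.lineage:
            pd.DataFrame(
                sorted(ds.lineage.items()), columns=["cell_line", "lineage"]
            ).to_csv(outdir / f"{did}.lineage.tsv", sep="\t", index=False)
    if truth.drug_classes is not None:
        pd.DataFrame(
            sorted((d, c.value) for d, c in truth.drug_classes.items()),
            columns=["drug", "class"],
        ).to_csv(outdir / "drug_classes.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
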