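"""End-to-end orchestration: config parsing, stage execution, run manifest.

A run is described by a single YAML config. Panels come either from
delimited-text files on disk or from the synthetic generator (``simulate:``
section). The screen stage chains correlation -> consensus -> concordance
and writes every stage table as TSV together with a ``manifest.json``
recording inputs, thresholds, seed and per-stage record counts; rerunning an
identical config reproduces byte-identical outputs.

No multiple-testing correction is applied to the screen; the manifest
records how many gene-drug hypotheses were attempted so readers can judge
the burden themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import concordance as conc
from . import consensus as cons
from . import screen as scr
from .clinical import ClinicalCohort, compare_responders, read_cohort, validate_cohort
from .core import (
    FLOAT_FORMAT,
    DrugClassMap,
    ScreenDataset,
    read_drug_classes,
    read_expression,
    read_lineages,
    read_response,
    summarize_overlap,
)
from .simulate import (
    SyntheticClinicalConfig,
    SyntheticScreenConfig,
    generate_clinical_cohort,
    generate_screen_panels,
    write_panels,
)

__all__ = ["PipelineConfig", "run_screen", "run_validation", "run_all"]

VALID_ANALYSES = ("aggregate", "chemo_only", "responder")


@dataclass
class Thresholds:
    r_threshold: float = cons.R_THRESHOLD
    min_fraction: float = cons.MIN_FRACTION
    min_databases: int = cons.MIN_DATABASES
    min_n: int = scr.MIN_VALID_N

    def validate(self) -> None:
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must be in (0, 1]")
        if not 0 <= self.min_fraction < 1:
            raise ValueError("min_fraction must be in [0, 1)")
        if self.min_databases < 1:
            raise ValueError("min_databases must be >= 1")
        if self.min_n < 3:
            raise ValueError("min_n must be >= 3")


@dataclass
class DatasetEntry:
    dataset_id: str
    expression: str
    response: str
    metric: str
    lineage: str | None = None


@dataclass
class CohortEntry:
    cohort_id: str
    path: str
    analyses: tuple[str, ...] = ("aggregate", "chemo_only")


@dataclass
class PipelineConfig:
    output_dir: str = "chemoscreen-out"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    datasets: list[DatasetEntry] = field(default_factory=list)
    drug_classes: str | None = None
    simulate_screen: dict | None = None
    simulate_clinical: dict | None = None
    concordance_genes: list[str] = field(default_factory=list)
    concordance_top_k: int = 1
    cohorts: list[CohortEntry] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = Thresholds(**raw.get("thresholds", {}))
        datasets = [DatasetEntry(**d) for d in raw.get("datasets", [])]
        cohorts = []
        for c in raw.get("cohorts", []):
            c = dict(c)
            if "analyses" in c:
                c["analyses"] = tuple(c["analyses"])
            cohorts.append(CohortEntry(**c))
        sim = raw.get("simulate", {}) or {}
        return cls(
            output_dir=raw.get("output_dir", "chemoscreen-out"),
            seed=int(raw.get("seed", 0)),
            thresholds=thresholds,
            datasets=datasets,
            drug_classes=raw.get("drug_classes"),
            simulate_screen=sim.get("screen"),
            simulate_clinical=sim.get("clinical"),
            concordance_genes=list(raw.get("concordance_genes", [])),
            concordance_top_k=int(raw.get("concordance_top_k", 1)),
            cohorts=cohorts,
        )

    def validate_for_screen(self, n_databases: int) -> None:
        self.thresholds.validate()
        for a in (a for c in self.cohorts for a in c.analyses):
            if a not in VALID_ANALYSES:
                raise ValueError(f"unknown analysis {a!r}; expected {VALID_ANALYSES}")
        if self.thresholds.min_databases > n_databases:
            raise ValueError(
                f"min_databases={self.thresholds.min_databases} exceeds the "
                f"{n_databases} configured database(s)"
            )


def _portable_path(path: str, outdir: Path) -> str:
    """Record run-directory-internal paths relative to it, for reproducible manifests."""
    try:
        return str(Path(path).relative_to(outdir))
    except ValueError:
        return str(path)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA")


def _load_datasets(
    config: PipelineConfig, outdir: Path
) -> tuple[list[ScreenDataset], DrugClassMap]:
    if config.simulate_screen is not None:
        sim_raw = dict(config.simulate_screen)
        sim_raw.setdefault("seed", config.seed)
        cfg = SyntheticScreenConfig(**sim_raw)
        datasets, truth = generate_screen_panels(cfg)
        simdir = outdir / "simulated"
        write_panels(datasets, truth, simdir)
        return datasets, truth.drug_classes
    if not config.datasets:
        raise ValueError("config defines neither datasets nor a simulate section")
    if config.drug_classes is None:
        raise ValueError("config must point at a drug-class annotation table")
    classes = read_drug_classes(config.drug_classes)
    datasets = []
    for entry in config.datasets:
        expr = read_expression(entry.expression, entry.dataset_id)
        resp = read_response(entry.response, entry.dataset_id, entry.metric)
        lineage = read_lineages(entry.lineage) if entry.lineage else None
        datasets.append(ScreenDataset(expression=expr, response=resp, lineage=lineage))
    return datasets, classes


def run_screen(config: PipelineConfig, outdir: str | Path | None = None) -> Path:
    """Correlation screen -> consensus selection -> concordance; returns outdir."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets, classes = _load_datasets(config, outdir)
    n_databases = len({cons.database_of(ds.dataset_id) for ds in datasets})
    config.validate_for_screen(n_databases)
    th = config.thresholds

    manifest: dict[str, Any] = {
        "seed": config.seed,
        "thresholds": vars(th),
        "datasets": {
            ds.dataset_id: {
                "n_genes": len(ds.expression.gene_ids),
                "n_drugs": len(ds.response.drug_ids),
                "n_lines": len(ds.shared_samples),
                "metric": ds.response.metric.value,
                "attempted_correlations": len(ds.expression.gene_ids)
                * len(ds.response.drug_ids),
            }
            for ds in datasets
        },
        "stages": {},
    }

    screen = scr.screen_datasets(datasets, min_n=th.min_n)
    _write_tsv(screen, outdir / "screen.tsv")
    manifest["stages"]["screen"] = {
        "records": int(len(screen)),
        "valid_records": int(screen["valid"].sum()),
        "hypotheses_tested_no_correction": int(len(screen)),
    }

    if len(datasets) >= 2:
        genes_ov, lines_ov = summarize_overlap(datasets)
        _write_tsv(genes_ov.to_frame(), outdir / "overlap_genes.tsv")
        _write_tsv(lines_ov.to_frame(), outdir / "overlap_lines.tsv")

    fractions = cons.compute_class_fractions(screen, classes, threshold=th.r_threshold)
    _write_tsv(fractions, outdir / "class_fractions.tsv")
    consensus = cons.consensus_select(
        fractions, min_fraction=th.min_fraction, min_databases=th.min_databases
    )
    _write_tsv(consensus, outdir / "consensus.tsv")
    _write_tsv(cons.selected_counts(consensus), outdir / "selected_counts.tsv")
    _write_tsv(cons.selected_gene_table(consensus), outdir / "selected_genes.tsv")
    multiclass = cons.flag_multiclass_genes(consensus)
    _write_tsv(multiclass, outdir / "multiclass_genes.tsv")
    manifest["stages"]["consensus"] = {
        "fraction_records": int(len(fractions)),
        "consensus_records": int(len(consensus)),
        "selected": int(consensus["selected"].sum()) if len(consensus) else 0,
    }

    # concordance for explicitly requested genes, else top pan-class candidates
    candidates = list(config.concordance_genes)
    if not candidates and len(multiclass):
        sens = multiclass[multiclass["direction"] == cons.Direction.SENSITIVITY.value]
        ranked = sens.sort_values(["n_classes", "gene_id"], ascending=[False, True])
        candidates = list(ranked["gene_id"].head(config.concordance_top_k))
    conc_rows = []
    if len(datasets) >= 2:
        for gene in candidates:
            for i in range(len(datasets)):
                for j in range(i + 1, len(datasets)):
                    try:
                        cc = conc.gene_concordance(gene, datasets[i], datasets[j])
                    except (KeyError, ValueError):
                        continue
                    conc_rows.append(
                        {
                            "gene_id": cc.gene_id,
                            "dataset_a": cc.dataset_a,
                            "dataset_b": cc.dataset_b,
                            "n_shared_lines": cc.n_shared_lines,
                            "r": cc.r,
                            "p": cc.p,
                            "slope": cc.slope,
                            "intercept": cc.intercept,
                        }
                    )
    conc_df = pd.DataFrame(
        conc_rows,
        columns=[
            "gene_id", "dataset_a", "dataset_b", "n_shared_lines",
            "r", "p", "slope", "intercept",
        ],
    )
    _write_tsv(conc_df, outdir / "concordance.tsv")

    lin_rows = []
    for gene in candidates:
        for ds in datasets:
            if ds.lineage is None or gene not in ds.expression.gene_ids:
                continue
            for s in conc.lineage_summaries(ds, gene):
                lin_rows.append(vars(s) | {"gene_id": gene})
    lin_df = pd.DataFrame(
        lin_rows, columns=["gene_id", "dataset_id", "lineage", "n_lines", "mean", "sd"]
    )
    _write_tsv(lin_df, outdir / "lineage_summaries.tsv")
    manifest["stages"]["concordance"] = {
        "candidate_genes": candidates,
        "pairs": int(len(conc_df)),
        "lineage_rows": int(len(lin_df)),
    }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _load_cohorts(config: PipelineConfig, outdir: Path) -> list[tuple[CohortEntry, ClinicalCohort]]:
    if config.simulate_clinical is not None:
        sim_raw = dict(config.simulate_clinical)
        sim_raw.setdefault("seed", config.seed)
        cfg = SyntheticClinicalConfig(**sim_raw)
        cohort, truth = generate_clinical_cohort(cfg)
        simdir = outdir / "simulated"
        simdir.mkdir(parents=True, exist_ok=True)
        from .clinical import write_cohort

        write_cohort(cohort, simdir / "cohort.tsv")
        truth.to_json(simdir / "clinical_truth.json")
        entry = CohortEntry(
            cohort_id=cohort.cohort_id,
            path=str(simdir / "cohort.tsv"),
            analyses=("aggregate", "chemo_only", "responder"),
        )
        return [(entry, cohort)]
    return [
        (entry, read_cohort(entry.path, entry.cohort_id)) for entry in config.cohorts
    ]


def run_validation(config: PipelineConfig, outdir: str | Path | None = None) -> Path:
    """Survival and responder analyses for every configured cohort."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = _load_cohorts(config, outdir)
    if not pairs:
        raise ValueError("config defines neither cohorts nor a clinical simulate section")

    surv_rows, resp_rows = [], []
    for entry, cohort in pairs:
        for analysis in entry.analyses:
            if analysis not in VALID_ANALYSES:
                raise ValueError(f"unknown analysis {analysis!r}")
            if analysis == "responder":
                if "response" not in cohort.data.columns:
                    raise ValueError(
                        f"cohort {cohort.cohort_id!r}: responder analysis "
                        "requested but column 'response' is absent"
                    )
                resp_rows.append(
                    compare_responders(cohort) .to_row() | {"analysis": analysis}
                )
            else:
                comp = validate_cohort(cohort, subset_chemo_only=analysis == "chemo_only")
                surv_rows.append(comp.to_row() | {"analysis": analysis})
                stem = f"{entry.cohort_id}.{analysis}"
                _write_tsv(comp.km_high.to_frame(), outdir / f"{stem}.km_high.tsv")
                _write_tsv(comp.km_low.to_frame(), outdir / f"{stem}.km_low.tsv")

    surv_df = pd.DataFrame(
        surv_rows,
        columns=["cohort_id", "analysis", "n_high", "n_low", "logrank_chisq", "p", "hr_low_vs_high"],
    )
    _write_tsv(surv_df, outdir / "survival_comparisons.tsv")
    resp_df = pd.DataFrame(
        resp_rows,
        columns=[
            "cohort_id", "analysis", "n_responder", "n_non_responder",
            "mean_z_responder", "mean_z_non_responder", "t", "welch_df", "p",
        ],
    )
    _write_tsv(resp_df, outdir / "response_comparisons.tsv")

    manifest_path = outdir / "validation_manifest.json"
    manifest_path.write_text(
        json.dumps(
            {
                "seed": config.seed,
                "cohorts": {
                    e.cohort_id: {
                        "path": _portable_path(e.path, outdir),
                        "analyses": list(e.analyses),
                    }
                    for e, _ in pairs
                },
                "survival_rows": int(len(surv_df)),
                "response_rows": int(len(resp_df)),
            },
            indent=2,
            sort_keys=True,
        )
    )
    return outdir


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> Path:
    outdir = Path(outdir or config.output_dir)
    run_screen(config, outdir)
    run_validation(config, outdir)
    return outdir
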