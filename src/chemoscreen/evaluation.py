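"""Replicate-level calibration and recovery benchmarks for the pipeline.

These helpers run the full screen -> consensus -> validation machinery on
freshly simulated data and summarize how well planted truths are recovered
and how well null inputs are calibrated. They are used by the test suite and
the reproduction script; problem sizes are arguments, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .clinical import validate_cohort
from .consensus import (
    Direction,
    compute_class_fractions,
    consensus_select,
    flag_multiclass_genes,
)
from .screen import screen_dataset, screen_datasets
from .simulate import (
    SyntheticClinicalConfig,
    SyntheticScreenConfig,
    generate_clinical_cohort,
    generate_screen_panels,
)

__all__ = [
    "PanClassReplicate",
    "pan_class_recovery",
    "screen_null_p_rate",
    "logrank_null_rejection_rate",
    "chemo_only_power",
    "survival_lnhr_estimates",
]


def _seed(base: int, i: int) -> int:
    return (int(base) * 1009 + i) % (2**31 - 1)


@dataclass
class PanClassReplicate:
    """Outcome of one planted-sensitizer replicate at the pan-class query."""

    seed: int
    planted_n_classes: int
    n_null_pan_class: int  # null genes reaching >= min_classes in sensitivity

    def unique(self, min_classes: int = 4) -> bool:
        return self.planted_n_classes >= min_classes and self.n_null_pan_class == 0


def pan_class_recovery(
    n_replicates: int = 20,
    base_seed: int = 0,
    min_classes: int = 4,
    config: SyntheticScreenConfig | None = None,
) -> list[PanClassReplicate]:
    """Run the screen + consensus on replicated panels with one planted sensitizer.

    For each replicate, reports how many classes selected the planted gene in
    the sensitivity direction and how many null genes reached the
    ``min_classes`` pan-class bar.
    """
    base_cfg = config or SyntheticScreenConfig()
    out = []
    for i in range(n_replicates):
        cfg = replace(base_cfg, seed=_seed(base_seed, i))
        panels, truth = generate_screen_panels(cfg)
        screen = screen_datasets(panels)
        fractions = compute_class_fractions(screen, truth.drug_classes)
        consensus = consensus_select(fractions)
        counts = flag_multiclass_genes(consensus)
        sens = counts[counts["direction"] == Direction.SENSITIVITY.value]
        planted_id = truth.planted_genes[0].gene_id
        planted_rows = sens[sens["gene_id"] == planted_id]
        planted_n = int(planted_rows["n_classes"].iloc[0]) if len(planted_rows) else 0
        null_pan = int(
            (
                sens[sens["gene_id"] != planted_id]["n_classes"] >= min_classes
            ).sum()
        )
        out.append(
            PanClassReplicate(
                seed=cfg.seed, planted_n_classes=planted_n, n_null_pan_class=null_pan
            )
        )
    return out


def screen_null_p_rate(
    seed: int = 0, n_genes: int = 100, n_drugs_total: int = 20, n_lines: int = 60
) -> tuple[float, int]:
    """Fraction of screen p-values <= 0.05 on a panel with no planted effects."""
    drugs_per_class = max(1, n_drugs_total // 5)
    cfg = SyntheticScreenConfig(
        n_databases=1,
        n_genes=n_genes,
        n_lines_per_db=n_lines,
        drugs_per_class=drugs_per_class,
        planted_genes=(),
        seed=seed,
    )
    panels, _ = generate_screen_panels(cfg)
    df = screen_dataset(panels[0])
    return float((df["p"] <= 0.05).mean()), int(len(df))


def logrank_null_rejection_rate(
    n_seeds: int = 100, base_seed: int = 0, n_patients: int = 150
) -> float:
    """Chemo-only log-rank rejection rate when expression has no effect."""
    rej = 0
    for i in range(n_seeds):
        cohort, _ = generate_clinical_cohort(
            SyntheticClinicalConfig(
                n_patients=n_patients, gamma=0.0, seed=_seed(base_seed, i)
            )
        )
        comp = validate_cohort(cohort, subset_chemo_only=True)
        rej += comp.p <= 0.05
    return rej / n_seeds


def chemo_only_power(
    n_seeds: int = 20, base_seed: int = 0, n_patients: int = 150, gamma: float = 1.0
) -> float:
    """Power of the chemo-only log-rank test under a planted treated-only benefit."""
    hits = 0
    for i in range(n_seeds):
        cohort, _ = generate_clinical_cohort(
            SyntheticClinicalConfig(
                n_patients=n_patients, gamma=gamma, seed=_seed(base_seed, i)
            )
        )
        comp = validate_cohort(cohort, subset_chemo_only=True)
        hits += comp.p <= 0.05
    return hits / n_seeds


def survival_lnhr_estimates(
    n_seeds: int = 20, base_seed: int = 0, n_patients: int = 200, gamma: float = 1.0
) -> np.ndarray:
    """ln(HR) estimates (LOW vs HIGH) over replicated fully-treated cohorts."""
    out = []
    for i in range(n_seeds):
        cohort, _ = generate_clinical_cohort(
            SyntheticClinicalConfig(
                n_patients=n_patients,
                chemo_fraction=1.0,
                gamma=gamma,
                seed=_seed(base_seed, i),
            )
        )
        comp = validate_cohort(cohort)
        out.append(np.log(comp.hr))
    return np.asarray(out)
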