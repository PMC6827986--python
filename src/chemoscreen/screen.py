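"""Stage 1: transcriptome-wide Pearson correlation of expression vs drug response.

For every (gene, drug) pair within a panel, the sample Pearson coefficient is
computed over pairwise-complete observations. Because the response metric is
oriented so that lower values mean greater sensitivity, a *negative* r means
higher expression is associated with sensitization, and a positive r with
resistance.

Two-sided p-values come from the exact t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` against Student's t with ``n - 2``
degrees of freedom. Pairs with fewer than ``min_n`` complete observations or
with a constant vector are emitted flagged invalid rather than dropped, so the
attempted-combination count |genes| x |drugs| is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DrugClassMap, ScreenDataset

__all__ = [
    "MIN_VALID_N",
    "CorrelationResult",
    "correlate_gene_drug",
    "screen_dataset",
    "screen_datasets",
    "rank_transcripts_for_drug",
    "drug_class_summary",
    "significance_tier",
    "waterfall_table",
]

#: minimum pairwise-complete sample count for a correlation to be valid
MIN_VALID_N = 10

#: long-format column order shared by every screen output
SCREEN_COLUMNS = ["gene_id", "drug_id", "dataset_id", "n", "r", "p", "valid"]


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int
    valid: bool


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t transform; |r| = 1 handled as the p -> 0 limit."""
    r = np.clip(r, -1.0, 1.0)
    p = np.full(r.shape, np.nan)
    ok = np.isfinite(r) & (n >= 3)
    sat = ok & (np.abs(r) >= 1.0)
    p[sat] = 0.0
    reg = ok & ~sat
    if reg.any():
        t = r[reg] * np.sqrt((n[reg] - 2) / (1.0 - r[reg] ** 2))
        p[reg] = 2.0 * stats.t.sf(np.abs(t), n[reg] - 2)
    return p


def correlate_gene_drug(
    expr: Sequence[float], resp: Sequence[float], min_n: int = MIN_VALID_N
) -> CorrelationResult:
    """Pearson r/p for one expression vector vs one response vector.

    Vectors must be index-aligned by sample; pairs where either value is
    missing are dropped (pairwise-complete). Results with fewer than
    ``min_n`` complete pairs or a constant vector are flagged invalid with
    NaN statistics.
    """
    x = np.asarray(expr, dtype=float)
    y = np.asarray(resp, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_n:
        return CorrelationResult(np.nan, np.nan, n, False)
    xv, yv = x[mask], y[mask]
    if xv.max() == xv.min() or yv.max() == yv.min():
        return CorrelationResult(np.nan, np.nan, n, False)
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    p = float(_pearson_p(np.array([r]), np.array([n]))[0])
    return CorrelationResult(r, p, n, True)


def screen_dataset(ds: ScreenDataset, min_n: int = MIN_VALID_N) -> pd.DataFrame:
    """Correlate every gene with every drug in one panel.

    Returns a long-format frame with one row per attempted (gene, drug)
    combination: columns gene_id, drug_id, dataset_id, n, r, p, valid.
    Invalid combinations (insufficient n, constant input) carry NaN r/p and
    valid=False; they are never silently dropped.
    """
    samples = ds.shared_samples
    E = ds.expression.data.loc[samples].to_numpy(dtype=float)  # lines x genes
    R = ds.response.data.reindex(samples).to_numpy(dtype=float)  # lines x drugs
    genes = ds.expression.gene_ids
    drugs = ds.response.drug_ids
    e_fin = np.isfinite(E)
    E0 = np.where(e_fin, E, 0.0)

    frames = []
    for j, drug in enumerate(drugs):
        y = R[:, j]
        y_fin = np.isfinite(y)
        V = e_fin & y_fin[:, None]  # lines x genes validity mask
        n = V.sum(axis=0)
        y0 = np.where(y_fin, y, 0.0)

        sx = (E0 * V).sum(axis=0)
        sxx = (E0 * E0 * V).sum(axis=0)
        sy = y0 @ V
        syy = (y0 * y0) @ V
        # E0 and y0 are zero wherever their side is missing, so the product
        # only accumulates over pairwise-complete entries
        sxy = E0.T @ y0

        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy - sx * sy / np.where(n > 0, n, 1)
            varx = sxx - sx * sx / np.where(n > 0, n, 1)
            vary = syy - sy * sy / np.where(n > 0, n, 1)
            r = cov / np.sqrt(varx * vary)
        r = np.clip(r, -1.0, 1.0)

        # constant-vector detection uses exact range on the valid entries
        ex_max = np.where(V, E, -np.inf).max(axis=0)
        ex_min = np.where(V, E, np.inf).min(axis=0)
        y_max = np.where(V, y[:, None], -np.inf).max(axis=0)
        y_min = np.where(V, y[:, None], np.inf).min(axis=0)
        const = (ex_max == ex_min) | (y_max == y_min)

        valid = (n >= min_n) & ~const & np.isfinite(r)
        r = np.where(valid, r, np.nan)
        p = _pearson_p(r, n)
        p = np.where(valid, p, np.nan)

        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "drug_id": drug,
                    "dataset_id": ds.dataset_id,
                    "n": n.astype(int),
                    "r": r,
                    "p": p,
                    "valid": valid,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[SCREEN_COLUMNS]


def screen_datasets(
    datasets: Sequence[ScreenDataset], min_n: int = MIN_VALID_N
) -> pd.DataFrame:
    """Run :func:`screen_dataset` over several panels and stack the results."""
    return pd.concat(
        [screen_dataset(ds, min_n=min_n) for ds in datasets], ignore_index=True
    )


def rank_transcripts_for_drug(records: pd.DataFrame) -> pd.DataFrame:
    """Rank all transcripts for one drug, ascending by r.

    Rank 1 is the most negative (most sensitizing) transcript. Ties break by
    gene_id lexicographic order; invalid records sort to the bottom.
    """
    if records["drug_id"].nunique() > 1:
        raise ValueError(
            f"mixed drug_ids in ranking input: {sorted(records['drug_id'].unique())}"
        )
    if records["dataset_id"].nunique() > 1:
        raise ValueError("mixed dataset_ids in ranking input")
    out = records.sort_values(
        ["r", "gene_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def significance_tier(p: float) -> str:
    """Display tier for a correlation p-value; boundaries are inclusive."""
    if not np.isfinite(p):
        return "invalid"
    if p <= 0.001:
        return "p<=0.001"
    if p <= 0.05:
        return "p<=0.05"
    return "p>0.05"


@dataclass
class ClassSummary:
    """Per-class view of one gene's drug correlations (mean +/- SEM display)."""

    drug_class: str
    drugs: pd.DataFrame  # columns drug_id, r, p, tier
    mean_r: float
    sem_r: float


def drug_class_summary(
    records: pd.DataFrame, classes: DrugClassMap
) -> dict[str, ClassSummary]:
    """Summarize one gene's correlations by drug class.

    ``records`` must be the per-gene subset of a screen frame. Every drug must
    be annotated in ``classes``; a missing drug is an error naming it. Only
    valid records enter the summaries.
    """
    if records["gene_id"].nunique() > 1:
        raise ValueError("drug_class_summary expects records for a single gene")
    for drug in records["drug_id"].unique():
        if drug not in classes:
            raise KeyError(f"drug {drug!r} has no class annotation")
    valid = records[records["valid"]].copy()
    valid["class"] = [classes[d].value for d in valid["drug_id"]]
    valid["tier"] = [significance_tier(p) for p in valid["p"]]
    out: dict[str, ClassSummary] = {}
    for cls, grp in valid.groupby("class", sort=True):
        rvals = grp["r"].to_numpy()
        sem = float(rvals.std(ddof=1) / np.sqrt(len(rvals))) if len(rvals) > 1 else np.nan
        out[cls] = ClassSummary(
            drug_class=cls,
            drugs=grp[["drug_id", "r", "p", "tier"]].reset_index(drop=True),
            mean_r=float(rvals.mean()),
            sem_r=sem,
        )
    return out


def waterfall_table(
    records: pd.DataFrame, classes: DrugClassMap
) -> pd.DataFrame:
    """Plot-ready (drug, class, r) table for one gene+dataset, sorted by r."""
    valid = records[records["valid"]].copy()
    valid["class"] = [classes.class_of(d).value for d in valid["drug_id"]]
    return (
        valid[["drug_id", "class", "r"]]
        .sort_values(["r", "drug_id"], kind="mergesort")
        .reset_index(drop=True)
    )
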