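"""Stage 3: cross-dataset expression reproducibility and lineage summaries.

Different panels profile overlapping cell lines on different platforms under
divergent naming conventions ("MDA-MB-231" vs "MDAMB231"). Lines are matched
by a normalized identifier (uppercased, spaces/hyphens/periods stripped), and
a candidate gene's expression is correlated across the shared lines. A
least-squares fit is returned alongside r/p for regression-style display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ScreenDataset
from .screen import correlate_gene_drug

__all__ = [
    "normalize_line_name",
    "CrossDatasetConcordance",
    "gene_concordance",
    "LineageSummary",
    "lineage_summaries",
]

MIN_SHARED_LINES = 3

_STRIP = str.maketrans("", "", " -.")


def normalize_line_name(name: str) -> str:
    """Canonical cell-line key: uppercase with spaces, hyphens, periods removed."""
    return str(name).upper().translate(_STRIP)


def _normalized_index(ds: ScreenDataset) -> dict[str, str]:
    """Map normalized name -> original sample id; refuses to merge distinct lines."""
    out: dict[str, str] = {}
    for s in ds.expression.sample_ids:
        key = normalize_line_name(s)
        if key in out and out[key] != s:
            raise ValueError(
                f"dataset {ds.dataset_id!r}: lines {out[key]!r} and {s!r} "
                f"collide under name normalization ({key!r})"
            )
        out[key] = s
    return out


@dataclass
class CrossDatasetConcordance:
    """Agreement of one gene's expression between two panels' shared lines."""

    gene_id: str
    dataset_a: str
    dataset_b: str
    n_shared_lines: int
    r: float
    p: float
    slope: float
    intercept: float
    paired: pd.DataFrame  # columns line, expr_a, expr_b


def gene_concordance(
    gene_id: str, ds_a: ScreenDataset, ds_b: ScreenDataset
) -> CrossDatasetConcordance:
    """Pearson concordance of ``gene_id`` expression across two panels.

    Shared lines are matched by normalized identifier; fewer than 3 complete
    shared observations is an error. The regression line is least squares of
    b on a.
    """
    ea = ds_a.expression.gene_values(gene_id)
    eb = ds_b.expression.gene_values(gene_id)
    idx_a = _normalized_index(ds_a)
    idx_b = _normalized_index(ds_b)
    shared = sorted(set(idx_a) & set(idx_b))
    pairs = []
    for key in shared:
        va = float(ea[idx_a[key]])
        vb = float(eb[idx_b[key]])
        if np.isfinite(va) and np.isfinite(vb):
            pairs.append((idx_a[key], va, vb))
    if len(pairs) < MIN_SHARED_LINES:
        raise ValueError(
            f"gene {gene_id!r}: only {len(pairs)} shared line(s) between "
            f"{ds_a.dataset_id!r} and {ds_b.dataset_id!r} "
            f"(need >= {MIN_SHARED_LINES})"
        )
    paired = pd.DataFrame(pairs, columns=["line", "expr_a", "expr_b"])
    res = correlate_gene_drug(paired["expr_a"], paired["expr_b"], min_n=MIN_SHARED_LINES)
    slope, intercept = np.polyfit(paired["expr_a"], paired["expr_b"], deg=1)
    return CrossDatasetConcordance(
        gene_id=gene_id,
        dataset_a=ds_a.dataset_id,
        dataset_b=ds_b.dataset_id,
        n_shared_lines=len(paired),
        r=res.r,
        p=res.p,
        slope=float(slope),
        intercept=float(intercept),
        paired=paired,
    )


@dataclass
class LineageSummary:
    dataset_id: str
    lineage: str
    n_lines: int
    mean: float
    sd: float  # NaN when n < 2 (sample SD undefined)


def lineage_summaries(ds: ScreenDataset, gene_id: str) -> list[LineageSummary]:
    """Per-lineage n/mean/SD of one gene's expression, ordered by descending mean.

    SD uses the n-1 denominator and is reported as NaN for single-line
    lineages. Requires the dataset to carry lineage annotations.
    """
    if ds.lineage is None:
        raise ValueError(f"dataset {ds.dataset_id!r} has no lineage annotations")
    expr = ds.expression.gene_values(gene_id)
    groups: dict[str, list[float]] = {}
    for sample, value in expr.items():
        lin = ds.lineage.get(sample)
        if lin is None or not np.isfinite(value):
            continue
        groups.setdefault(lin, []).append(float(value))
    out = []
    for lin, vals in groups.items():
        arr = np.asarray(vals)
        out.append(
            LineageSummary(
                dataset_id=ds.dataset_id,
                lineage=lin,
                n_lines=len(arr),
                mean=float(arr.mean()),
                sd=float(arr.std(ddof=1)) if len(arr) >= 2 else float("nan"),
            )
        )
    out.sort(key=lambda s: (-s.mean, s.lineage))
    return out
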