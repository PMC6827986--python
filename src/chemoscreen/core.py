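"""Domain containers and delimited-text I/O for pharmacogenomic screen data.

The screen operates on per-database pairs of a normalized expression matrix
(genes x cell lines, log-scale values as produced by RMA-style pipelines)
and a drug-response table (cell lines x drugs, AUC or natural-log IC50).
Lower response values always mean greater sensitivity; that orientation is a
contract of the input files, never guessed from the data.

Matrices are stored sample-major internally (rows = cell lines) regardless
of the on-disk orientation, so that every downstream operation aligns on
sample identifiers the same way.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMetric",
    "DrugClass",
    "DRUG_CLASSES",
    "ExpressionMatrix",
    "DrugResponseTable",
    "DrugClassMap",
    "ScreenDataset",
    "OverlapSummary",
    "read_expression",
    "write_expression",
    "read_response",
    "write_response",
    "read_drug_classes",
    "bundled_drug_classes",
    "read_lineages",
    "summarize_overlap",
    "count_gene_drug_combinations",
]

#: strings accepted as missing values in delimited inputs (plus empty cells)
NA_VALUES = ["", "NA"]

#: float format used by every writer, so reruns are byte-identical
FLOAT_FORMAT = "%.10g"


class ResponseMetric(str, enum.Enum):
    """Drug-response summary metric. Lower value = more sensitive line."""

    AUC = "AUC"
    LN_IC50 = "LN_IC50"


class DrugClass(str, enum.Enum):
    """Closed vocabulary of chemotherapeutic classes used by the screen."""

    ALKYLATING = "ALKYLATING"
    ANTIMETABOLITE = "ANTIMETABOLITE"
    ANTITUMOR_ANTIBIOTIC = "ANTITUMOR_ANTIBIOTIC"
    MICROTUBULE = "MICROTUBULE"
    TOPOISOMERASE = "TOPOISOMERASE"


DRUG_CLASSES = tuple(DrugClass)


def _sniff_delimiter(path: Path) -> str:
    """Pick tab vs comma from the header line; ties break toward tab."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_delimiter(path)
    # pandas silently renames duplicate header fields, so check them raw
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "column")
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=NA_VALUES,
        keep_default_na=False,
        dtype=str,
    )
    df.index.name = None
    df.columns.name = None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    # non-numeric cells become missing rather than poisoning the column dtype
    return df.apply(pd.to_numeric, errors="coerce")


def _check_unique(labels: Iterable[str], kind: str) -> list[str]:
    labels = [str(x) for x in labels]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {kind} identifier: {lab!r}")
        seen.add(lab)
    return labels


@dataclass
class ExpressionMatrix:
    """Normalized log-scale expression for one panel, stored samples x genes."""

    dataset_id: str
    data: pd.DataFrame  # index = sample_ids, columns = gene_ids

    def __post_init__(self) -> None:
        _check_unique(self.data.columns, "gene")
        _check_unique(self.data.index, "sample")
        vals = self.data.to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError("empty expression matrix")
        bad = ~(np.isfinite(vals) | np.isnan(vals))
        if bad.any():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def gene_values(self, gene_id: str) -> pd.Series:
        if gene_id not in self.data.columns:
            raise KeyError(f"gene {gene_id!r} not in dataset {self.dataset_id!r}")
        return self.data[gene_id]


@dataclass
class DrugResponseTable:
    """Drug-response summaries for one panel, stored samples x drugs."""

    dataset_id: str
    metric: ResponseMetric
    data: pd.DataFrame  # index = sample_ids, columns = drug_ids

    def __post_init__(self) -> None:
        self.metric = ResponseMetric(self.metric)
        _check_unique(self.data.columns, "drug")
        _check_unique(self.data.index, "sample")
        vals = self.data.to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError("empty response table")
        bad = ~(np.isfinite(vals) | np.isnan(vals))
        if bad.any():
            raise ValueError("response table contains non-finite values")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


class DrugClassMap(dict):
    """Mapping drug_id -> DrugClass with a closed class vocabulary."""

    def __setitem__(self, drug: str, cls: DrugClass) -> None:
        cls = DrugClass(cls)
        if drug in self and self[drug] != cls:
            raise ValueError(
                f"drug {drug!r} assigned conflicting classes "
                f"{self[drug].value} and {cls.value}"
            )
        super().__setitem__(drug, cls)

    def drugs_in_class(self, cls: DrugClass) -> list[str]:
        cls = DrugClass(cls)
        return [d for d, c in self.items() if c == cls]

    def class_of(self, drug: str) -> DrugClass:
        if drug not in self:
            raise KeyError(f"drug {drug!r} has no class annotation")
        return self[drug]


@dataclass
class ScreenDataset:
    """One cell-line panel: expression + response + optional lineage labels."""

    expression: ExpressionMatrix
    response: DrugResponseTable
    lineage: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.shared_samples:
            raise ValueError(
                f"dataset {self.dataset_id!r}: no cell lines shared between "
                "expression matrix and response table"
            )

    @property
    def dataset_id(self) -> str:
        return self.expression.dataset_id

    @property
    def shared_samples(self) -> list[str]:
        """Correlation-eligible lines: in expression AND response, expression order."""
        resp = set(self.response.sample_ids)
        return [s for s in self.expression.sample_ids if s in resp]


@dataclass
class OverlapSummary:
    """Set-intersection bookkeeping across >= 2 panels, for genes and lines."""

    set_sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    all_way: int
    in_at_least_two: int

    def to_frame(self) -> pd.DataFrame:
        rows = [(f"|{k}|", v) for k, v in self.set_sizes.items()]
        rows += [(f"|{a} & {b}|", v) for (a, b), v in self.pairwise.items()]
        rows.append(("|all datasets|", self.all_way))
        rows.append(("in >=2 datasets", self.in_at_least_two))
        return pd.DataFrame(rows, columns=["set_description", "count"])


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path, dataset_id: str) -> ExpressionMatrix:
    """Read a genes-x-samples delimited file (first column = gene IDs).

    Non-numeric cells (including empty and "NA") are recorded as missing.
    Duplicate gene or sample identifiers are a hard error naming the label.
    """
    df = _read_table(path)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    return ExpressionMatrix(dataset_id=dataset_id, data=df.T)


def write_expression(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    out = matrix.data.T.rename_axis("gene")
    out.to_csv(path, sep=sep, float_format=FLOAT_FORMAT, na_rep="NA")


def read_response(
    path: str | Path, dataset_id: str, metric: ResponseMetric | str
) -> DrugResponseTable:
    """Read a cell-lines-x-drugs delimited file. ``metric`` must be AUC or LN_IC50."""
    try:
        metric = ResponseMetric(metric)
    except ValueError:
        valid = ", ".join(m.value for m in ResponseMetric)
        raise ValueError(f"unknown response metric {metric!r}; expected one of {valid}")
    df = _read_table(path)
    _check_unique(df.columns, "drug")
    _check_unique(df.index, "sample")
    return DrugResponseTable(dataset_id=dataset_id, metric=metric, data=df)


def write_response(table: DrugResponseTable, path: str | Path, sep: str = "\t") -> None:
    out = table.data.copy()
    out.index.name = "cell_line"
    out.to_csv(path, sep=sep, float_format=FLOAT_FORMAT, na_rep="NA")


def read_drug_classes(path: str | Path) -> DrugClassMap:
    """Read a two-column (drug, class) annotation table.

    Unknown class labels and conflicting duplicate assignments are errors;
    duplicate rows with a consistent class are tolerated.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (drug, class)")
    cmap = DrugClassMap()
    for drug, cls in zip(df.iloc[:, 0], df.iloc[:, 1]):
        try:
            cls_enum = DrugClass(cls)
        except ValueError:
            valid = ", ".join(c.value for c in DrugClass)
            raise ValueError(
                f"unknown drug class {cls!r} for drug {drug!r}; expected one of {valid}"
            )
        cmap[str(drug)] = cls_enum
    if not cmap:
        raise ValueError(f"{path}: no drug annotations found")
    return cmap


def bundled_drug_classes() -> DrugClassMap:
    """The packaged chemotherapeutic inventory (56 drugs, 5 classes)."""
    with resources.as_file(
        resources.files("chemoscreen.data") / "drug_classes.tsv"
    ) as p:
        return read_drug_classes(p)


def read_lineages(path: str | Path) -> dict[str, str]:
    """Read a two-column (cell_line, lineage) annotation table."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (cell_line, lineage)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# bookkeeping operations


def _overlap(sets: dict[str, set[str]]) -> tuple[dict, int, int]:
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(sets, 2)
    }
    all_way = len(set.intersection(*sets.values()))
    in_ge2: set[str] = set()
    for a, b in combinations(sets, 2):
        in_ge2 |= sets[a] & sets[b]
    return pairwise, all_way, len(in_ge2)


def summarize_overlap(
    datasets: Sequence[ScreenDataset],
) -> tuple[OverlapSummary, OverlapSummary]:
    """Gene and cell-line overlap counts across panels.

    Returns ``(gene_summary, line_summary)``. The "in >= 2 datasets" count is
    the size of the union of all pairwise intersections, matching how shared
    membership across unequal panels is usually reported.
    """
    if len(datasets) < 2:
        raise ValueError("overlap summary requires at least 2 datasets")
    ids = [ds.dataset_id for ds in datasets]
    _check_unique(ids, "dataset")
    gene_sets = {ds.dataset_id: set(ds.expression.gene_ids) for ds in datasets}
    line_sets = {ds.dataset_id: set(ds.shared_samples) for ds in datasets}
    summaries = []
    for sets in (gene_sets, line_sets):
        pairwise, all_way, in_ge2 = _overlap(sets)
        summaries.append(
            OverlapSummary(
                set_sizes={k: len(v) for k, v in sets.items()},
                pairwise=pairwise,
                all_way=all_way,
                in_at_least_two=in_ge2,
            )
        )
    return summaries[0], summaries[1]


def count_gene_drug_combinations(
    drug_counts: Sequence[int], gene_counts: Sequence[int]
) -> int:
    """Total attempted gene-drug pairs across panels: sum_i drugs_i * genes_i."""
    if len(drug_counts) != len(gene_counts):
        raise ValueError(
            f"length mismatch: {len(drug_counts)} drug counts vs "
            f"{len(gene_counts)} gene counts"
        )
    if any(d <= 0 for d in drug_counts) or any(g <= 0 for g in gene_counts):
        raise ValueError("counts must be positive")
    return int(sum(int(d) * int(g) for d, g in zip(drug_counts, gene_counts)))
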