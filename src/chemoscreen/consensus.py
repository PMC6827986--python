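"""Stage 2: cross-database consensus nomination of sensitizing/resistance transcripts.

A gene is nominated for a drug class and direction when, in at least
``min_databases`` (default 2) of the databases screened, the fraction of that
class's drugs whose correlation passes the magnitude threshold exceeds
``min_fraction`` (default 0.5, strict). Direction SENSITIVITY counts drugs
with r <= -threshold (inclusive boundary); RESISTANCE counts r >= +threshold.

Databases that report both AUC and ln(IC50) contribute two screened tables
whose dataset_id shares a database prefix before ``:`` (e.g. "GDSC:AUC",
"GDSC:LN_IC50"). They are collapsed to database level before the >=2 rule:
passing in either metric table counts the database once, so a dual-metric
database can never satisfy the multi-database requirement by itself.

A database abstains for a gene/class when it has no valid correlation record
there (class not tested, gene unmeasured, or all records invalid); abstention
counts neither for nor against.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DrugClassMap

__all__ = [
    "Direction",
    "R_THRESHOLD",
    "MIN_FRACTION",
    "MIN_DATABASES",
    "ClassFraction",
    "database_of",
    "class_fraction",
    "compute_class_fractions",
    "consensus_select",
    "selected_counts",
    "selected_gene_table",
    "flag_multiclass_genes",
    "compare_gene_sets",
]

R_THRESHOLD = 0.2
MIN_FRACTION = 0.5
MIN_DATABASES = 2


class Direction(str, enum.Enum):
    SENSITIVITY = "SENSITIVITY"  # r <= -threshold: high expression, low AUC/IC50
    RESISTANCE = "RESISTANCE"  # r >= +threshold


def database_of(dataset_id: str) -> str:
    """Collapse a metric-suffixed dataset id ("GDSC:AUC") to its database ("GDSC")."""
    return dataset_id.split(":", 1)[0]


@dataclass(frozen=True)
class ClassFraction:
    """Fraction of one class's drugs passing the threshold, for one gene+database."""

    gene_id: str
    drug_class: str
    database: str
    direction: Direction
    n_drugs_in_class: int
    n_drugs_beyond_threshold: int

    @property
    def fraction(self) -> float:
        return self.n_drugs_beyond_threshold / self.n_drugs_in_class


def _passes(r: np.ndarray, direction: Direction, threshold: float) -> np.ndarray:
    if Direction(direction) is Direction.SENSITIVITY:
        return r <= -threshold
    return r >= threshold


def class_fraction(
    records: pd.DataFrame,
    direction: Direction,
    threshold: float = R_THRESHOLD,
) -> ClassFraction | None:
    """Threshold-passing fraction for one gene/class/database subset.

    Invalid records are excluded from numerator and denominator. Returns
    ``None`` when no valid record remains (the database abstains).
    """
    for col in ("gene_id", "dataset_id"):
        if records[col].nunique() > 1:
            raise ValueError(f"records mix multiple values of {col}")
    valid = records[records["valid"]]
    if valid.empty:
        return None
    r = valid["r"].to_numpy(dtype=float)
    hits = int(_passes(r, direction, threshold).sum())
    return ClassFraction(
        gene_id=str(records["gene_id"].iloc[0]),
        drug_class=str(records["class"].iloc[0]) if "class" in records else "",
        database=database_of(str(records["dataset_id"].iloc[0])),
        direction=Direction(direction),
        n_drugs_in_class=len(valid),
        n_drugs_beyond_threshold=hits,
    )


def compute_class_fractions(
    screen: pd.DataFrame,
    classes: DrugClassMap,
    threshold: float = R_THRESHOLD,
) -> pd.DataFrame:
    """Database-level passing fractions for every gene x class x direction.

    ``screen`` is the long-format output of the correlation stage (possibly
    stacked over datasets). Drugs without a class annotation are an error.
    Metric-suffixed tables of one database are collapsed by taking, per
    direction, the *maximum* fraction over that database's tables — so the
    database passes iff either metric view passes.

    Returns a frame with columns gene_id, class, database, direction,
    n_drugs, n_beyond, fraction; gene/class/database triples with no valid
    record are absent (abstention).
    """
    unknown = set(screen["drug_id"].unique()) - set(classes)
    if unknown:
        raise KeyError(f"drugs without class annotation: {sorted(unknown)}")
    valid = screen[screen["valid"]].copy()
    if valid.empty:
        return pd.DataFrame(
            columns=["gene_id", "class", "database", "direction", "n_drugs", "n_beyond", "fraction"]
        )
    valid["class"] = valid["drug_id"].map({d: c.value for d, c in classes.items()})
    valid["database"] = [database_of(d) for d in valid["dataset_id"]]
    r = valid["r"].to_numpy(dtype=float)
    valid["SENSITIVITY"] = r <= -threshold
    valid["RESISTANCE"] = r >= threshold

    keys = ["gene_id", "class", "database", "dataset_id"]
    agg = (
        valid.groupby(keys, sort=True)
        .agg(
            n_drugs=("r", "size"),
            SENSITIVITY=("SENSITIVITY", "sum"),
            RESISTANCE=("RESISTANCE", "sum"),
        )
        .reset_index()
    )
    tbl = agg.melt(
        id_vars=keys + ["n_drugs"],
        value_vars=[d.value for d in Direction],
        var_name="direction",
        value_name="n_beyond",
    )
    tbl["fraction"] = tbl["n_beyond"] / tbl["n_drugs"]
    # collapse metric-suffixed tables to database level: best fraction wins
    idx = tbl.groupby(["gene_id", "class", "database", "direction"], sort=True)[
        "fraction"
    ].idxmax()
    out = (
        tbl.loc[idx]
        .drop(columns=["dataset_id"])
        .sort_values(["gene_id", "class", "database", "direction"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out[
        ["gene_id", "class", "database", "direction", "n_drugs", "n_beyond", "fraction"]
    ]


def consensus_select(
    fractions: pd.DataFrame,
    min_fraction: float = MIN_FRACTION,
    min_databases: int = MIN_DATABASES,
) -> pd.DataFrame:
    """Apply the multi-database consensus rule to class fractions.

    A database passes a gene/class/direction iff fraction > ``min_fraction``
    (strict). A gene/class/direction is selected iff the number of passing
    databases is >= ``min_databases``. Abstaining databases are simply absent
    from ``fractions`` and count neither way, but the bar of
    ``min_databases`` is absolute.

    Returns one row per gene/class/direction present, with columns gene_id,
    class, direction, n_databases_reporting, n_databases_passing, selected,
    and per-database pass flags in ``databases_passing`` (comma-joined).
    """
    n_db = fractions["database"].nunique() if len(fractions) else 0
    if min_databases > n_db:
        raise ValueError(
            f"min_databases={min_databases} exceeds the {n_db} database(s) screened"
        )
    keys = ["gene_id", "class", "direction"]
    out = (
        fractions.groupby(keys, sort=True)["database"]
        .nunique()
        .rename("n_databases_reporting")
        .reset_index()
    )
    passing = fractions[fractions["fraction"] > min_fraction]
    n_pass = passing.groupby(keys)["database"].nunique().rename("n_databases_passing")
    dbs_pass = (
        passing.groupby(keys)["database"]
        .apply(lambda s: ",".join(sorted(s.unique())))
        .rename("databases_passing")
    )
    out = out.merge(n_pass, on=keys, how="left").merge(dbs_pass, on=keys, how="left")
    out["n_databases_passing"] = out["n_databases_passing"].fillna(0).astype(int)
    out["databases_passing"] = out["databases_passing"].fillna("")
    out["selected"] = out["n_databases_passing"] >= min_databases
    return out[
        [
            "gene_id",
            "class",
            "direction",
            "n_databases_reporting",
            "n_databases_passing",
            "databases_passing",
            "selected",
        ]
    ]


def selected_counts(consensus: pd.DataFrame) -> pd.DataFrame:
    """Per-class selected-gene tallies in each direction (the summary-figure numbers)."""
    sel = consensus[consensus["selected"]]
    return (
        sel.groupby(["class", "direction"], sort=True)["gene_id"]
        .nunique()
        .rename("n_genes")
        .reset_index()
    )


def selected_gene_table(consensus: pd.DataFrame) -> pd.DataFrame:
    """Gene-list table: one row per class x direction with a comma-joined gene list."""
    sel = consensus[consensus["selected"]]
    return (
        sel.groupby(["class", "direction"], sort=True)["gene_id"]
        .apply(lambda g: ",".join(sorted(g.unique())))
        .rename("genes")
        .reset_index()
    )


def flag_multiclass_genes(consensus: pd.DataFrame) -> pd.DataFrame:
    """Count, per gene and direction, how many classes selected it.

    Supports the query "genes selected in >= k classes" used to nominate
    pan-class biomarkers.
    """
    sel = consensus[consensus["selected"]]
    counts = (
        sel.groupby(["gene_id", "direction"], sort=True)["class"]
        .nunique()
        .rename("n_classes")
        .reset_index()
    )
    return counts


def compare_gene_sets(
    selected: list[str] | set[str], reference: list[str] | set[str]
) -> tuple[int, list[str]]:
    """Exact intersection of a selected gene list with a reference list."""
    inter = sorted(set(selected) & set(reference))
    return len(inter), inter
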