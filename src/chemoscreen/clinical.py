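"""Stage 4: clinical validation of a candidate biomarker.

Patients are dichotomized at the median of the query gene's tumor expression
(computed on the analyzed subset, after any chemotherapy-only filtering):
expression strictly above the median is HIGH, at or below is LOW. The two
groups are compared by the Kaplan-Meier product-limit estimator, the
log-rank (Mantel-Cox) test, and a Mantel-Haenszel hazard ratio reported as
hazard in the LOW group relative to HIGH — so HR > 1 means low expression is
the higher-risk group.

Responder analyses (pathologic complete response, or the "highly sensitive"
relapse-free class) compare z-scored expression between responders and
non-responders with Welch's unequal-variance t-test.

All estimators here are implemented directly from their defining formulas;
the test suite cross-checks them against independent survival/statistics
libraries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import FLOAT_FORMAT, _sniff_delimiter

__all__ = [
    "Response",
    "ClinicalCohort",
    "read_cohort",
    "write_cohort",
    "median_dichotomize",
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "SurvivalComparison",
    "validate_cohort",
    "zscore",
    "ResponseComparison",
    "compare_responders",
]

HIGH, LOW = "HIGH", "LOW"

REQUIRED_COLUMNS = ("patient_id", "expr", "time", "event", "chemo")


class Response(str, enum.Enum):
    RESPONDER = "RESPONDER"
    NON_RESPONDER = "NON_RESPONDER"


@dataclass
class ClinicalCohort:
    """Patient-level table: expression of the query gene, survival, treatment.

    ``data`` columns: patient_id, expr (tumor mRNA level), time (overall
    survival in any consistent unit), event (death observed), chemo
    (received cytotoxic chemotherapy), and optionally response
    (RESPONDER / NON_RESPONDER).
    """

    cohort_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(
                f"cohort {self.cohort_id!r} missing required column(s): "
                + ", ".join(missing)
            )
        df = self.data
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValueError(f"duplicate patient identifier: {dup!r}")
        if (df["time"].to_numpy(dtype=float) < 0).any():
            raise ValueError("negative survival time")
        if not np.isfinite(df["expr"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite expression value")

    @property
    def has_response(self) -> bool:
        return "response" in self.data.columns and self.data["response"].notna().any()

    def subset_chemo(self) -> "ClinicalCohort":
        sub = self.data[self.data["chemo"].astype(bool)].reset_index(drop=True)
        if sub.empty:
            raise ValueError(
                f"cohort {self.cohort_id!r}: no chemotherapy-treated patients"
            )
        return ClinicalCohort(cohort_id=f"{self.cohort_id}:chemo", data=sub)


_BOOL_MAP = {
    "1": True, "0": False, "true": True, "false": False, "yes": True, "no": False,
}


def _to_bool(series: pd.Series, col: str) -> pd.Series:
    def conv(v):
        s = str(v).strip().lower()
        if s not in _BOOL_MAP:
            raise ValueError(f"column {col!r}: cannot interpret {v!r} as boolean")
        return _BOOL_MAP[s]

    return series.map(conv)


def read_cohort(path: str | Path, cohort_id: str | None = None) -> ClinicalCohort:
    """Read a delimited patient table.

    Required columns: patient_id, expr, time, event, chemo; optional column
    response with values RESPONDER / NON_RESPONDER (blank = unknown).
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): " + ", ".join(missing))
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "expr": pd.to_numeric(df["expr"]),
            "time": pd.to_numeric(df["time"]),
            "event": _to_bool(df["event"], "event"),
            "chemo": _to_bool(df["chemo"], "chemo"),
        }
    )
    if "response" in df.columns:
        out["response"] = [
            Response(v).value if v not in ("", "NA") else np.nan
            for v in df["response"]
        ]
    return ClinicalCohort(cohort_id=cohort_id or path.stem, data=out)


def write_cohort(cohort: ClinicalCohort, path: str | Path, sep: str = "\t") -> None:
    df = cohort.data.copy()
    for col in ("event", "chemo"):
        df[col] = df[col].astype(bool).astype(int)
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT, na_rep="")


def median_dichotomize(expr: Sequence[float]) -> np.ndarray:
    """Label each patient HIGH (expr > median) or LOW (expr <= median).

    The median is taken over the analyzed cohort; ties at the median fall in
    the LOW group. Requires >= 4 patients and non-constant expression.
    """
    x = np.asarray(expr, dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 patients to dichotomize, got {x.size}")
    if x.max() == x.min():
        raise ValueError("all expression values identical; cannot stratify")
    med = float(np.median(x))
    return np.where(x > med, HIGH, LOW)


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate: S(t) right-continuous step function."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored observations decrement the risk set without producing a step.
    Ties between events and censorings at the same time follow the standard
    convention that events happen first.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = len(t)
    surv, at_risk, d_out = [], [], []
    s = 1.0
    for ti in event_times:
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & e).sum())
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        d_out.append(d_i)
        surv.append(s)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        n_at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(d_out, dtype=int),
    )


def _logrank_tables(
    labels: Sequence[str], times: Sequence[float], events: Sequence[bool]
) -> tuple[float, float, float, float, float]:
    """Observed/expected/variance tabulation for the two-group log-rank test.

    Returns (O1, E1, O2, E2, V) where group 1 = LOW and group 2 = HIGH.
    """
    lab = np.asarray(labels)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (lab.shape == t.shape == e.shape):
        raise ValueError("labels, times and events must have equal length")
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 non-empty groups, got {list(groups)}")
    # deterministic ordering: LOW first if present, else lexicographic
    if LOW in groups:
        g1 = LOW
    else:
        g1 = sorted(groups)[0]
    in1 = lab == g1
    O1 = O2 = E1 = E2 = V = 0.0
    for ti in np.unique(t[e]):
        at_risk = t >= ti
        n_i = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d_i = int(((t == ti) & e).sum())
        d1 = int(((t == ti) & e & in1).sum())
        O1 += d1
        O2 += d_i - d1
        E1 += d_i * n1 / n_i
        E2 += d_i * (n_i - n1) / n_i
        if n_i > 1:
            V += d_i * (n1 / n_i) * (1 - n1 / n_i) * (n_i - d_i) / (n_i - 1)
    return O1, E1, O2, E2, V


def logrank_test(
    labels: Sequence[str], times: Sequence[float], events: Sequence[bool]
) -> tuple[float, float]:
    """Two-group log-rank (Mantel-Cox) test.

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation; chisq = (O1 - E1)^2 / V against
    chi-square with 1 df. Returns (chisq, p).
    """
    O1, E1, _, _, V = _logrank_tables(labels, times, events)
    if V <= 0:
        return 0.0, 1.0
    chisq = (O1 - E1) ** 2 / V
    p = float(stats.chi2.sf(chisq, df=1))
    return float(chisq), p


def hazard_ratio(
    labels: Sequence[str], times: Sequence[float], events: Sequence[bool]
) -> float:
    """Mantel-Haenszel hazard ratio HR = (O1/E1) / (O2/E2), group 1 = LOW.

    HR > 1 means the LOW-expression group carries the higher hazard, i.e.
    high expression is protective. Returns NaN when either group has zero
    expected events (undefined).
    """
    O1, E1, O2, E2, _ = _logrank_tables(labels, times, events)
    if E1 <= 0 or E2 <= 0:
        return float("nan")
    if O2 == 0:
        return float("inf") if O1 > 0 else float("nan")
    return (O1 / E1) / (O2 / E2)


@dataclass
class SurvivalComparison:
    """Median-dichotomized survival contrast for one cohort analysis."""

    cohort_id: str
    n_high: int
    n_low: int
    logrank_chisq: float
    p: float
    hr: float  # hazard in LOW relative to HIGH
    km_high: KMCurve
    km_low: KMCurve
    labels: np.ndarray

    def to_row(self) -> dict:
        return {
            "cohort_id": self.cohort_id,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "logrank_chisq": self.logrank_chisq,
            "p": self.p,
            "hr_low_vs_high": self.hr,
        }


def validate_cohort(
    cohort: ClinicalCohort, subset_chemo_only: bool = False
) -> SurvivalComparison:
    """Median dichotomization -> KM per group -> log-rank -> hazard ratio.

    With ``subset_chemo_only`` the cohort is first restricted to patients who
    received chemotherapy, and the dichotomization median is computed on that
    subset (each analysis stratifies its own analyzed population).
    """
    analyzed = cohort.subset_chemo() if subset_chemo_only else cohort
    df = analyzed.data
    labels = median_dichotomize(df["expr"].to_numpy(dtype=float))
    t = df["time"].to_numpy(dtype=float)
    e = df["event"].to_numpy(dtype=bool)
    chisq, p = logrank_test(labels, t, e)
    hr = hazard_ratio(labels, t, e)
    return SurvivalComparison(
        cohort_id=analyzed.cohort_id,
        n_high=int((labels == HIGH).sum()),
        n_low=int((labels == LOW).sum()),
        logrank_chisq=chisq,
        p=p,
        hr=hr,
        km_high=km_estimate(t[labels == HIGH], e[labels == HIGH]),
        km_low=km_estimate(t[labels == LOW], e[labels == LOW]),
        labels=labels,
    )


def zscore(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector cannot be z-scored")
    return (x - x.mean()) / sd


@dataclass
class ResponseComparison:
    """Welch t contrast of z-scored expression, responders vs non-responders."""

    cohort_id: str
    n_responder: int
    n_non_responder: int
    mean_responder: float
    mean_non_responder: float
    t: float
    df: float  # Welch-Satterthwaite
    p: float

    def to_row(self) -> dict:
        return {
            "cohort_id": self.cohort_id,
            "n_responder": self.n_responder,
            "n_non_responder": self.n_non_responder,
            "mean_z_responder": self.mean_responder,
            "mean_z_non_responder": self.mean_non_responder,
            "t": self.t,
            "welch_df": self.df,
            "p": self.p,
        }


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t: returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def compare_responders(cohort: ClinicalCohort) -> ResponseComparison:
    """Compare z-scored expression between responders and non-responders.

    Expression is z-scored across all labeled patients before splitting.
    Each response group must contain >= 2 patients.
    """
    if "response" not in cohort.data.columns:
        raise ValueError(f"cohort {cohort.cohort_id!r} has no response column")
    df = cohort.data[cohort.data["response"].notna()]
    z = zscore(df["expr"].to_numpy(dtype=float))
    is_resp = df["response"].to_numpy() == Response.RESPONDER.value
    a, b = z[is_resp], z[~is_resp]
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"cohort {cohort.cohort_id!r}: each response group needs >= 2 "
            f"patients (got {a.size} responders, {b.size} non-responders)"
        )
    t, dof, p = welch_t(a, b)
    return ResponseComparison(
        cohort_id=cohort.cohort_id,
        n_responder=int(a.size),
        n_non_responder=int(b.size),
        mean_responder=float(a.mean()),
        mean_non_responder=float(b.mean()),
        t=t,
        df=dof,
        p=p,
    )
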