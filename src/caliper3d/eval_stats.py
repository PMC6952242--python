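"""Study statistics: accuracy/precision summaries, inter-tool agreement,
paired t-tests, and intra-user variability.

All functions accept either a list of
:class:`~caliper3d.study_sim.MeasurementRecord` or the equivalent pandas
DataFrame (columns user, tool, dataset, measurement, value_mm, valid).
Invalid records are dropped pairwise.  Sample statistics use the n-1
denominator throughout; zero spread is representable (a tool whose coarse
display precision makes every reader report the same value has SD exactly
0), while an SD over fewer than two values is reported as NaN and flagged
rather than invented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .study_sim import records_to_dataframe

__all__ = [
    "AgreementStats",
    "TTestResult",
    "IntraUserVariability",
    "summarize_phantom",
    "paired_values",
    "agreement",
    "paired_ttest",
    "paired_ttest_records",
    "intra_user_variability",
    "full_report",
]

_PAIR_KEY = ["user", "dataset", "measurement"]


def _valid(records) -> pd.DataFrame:
    df = records_to_dataframe(records)
    return df[df["valid"]].copy()


# ---------------------------------------------------------------------------
# Phantom accuracy / precision summary
# ---------------------------------------------------------------------------

def _parse_phantom_measurement(name: str) -> tuple[float, str]:
    # protocol naming convention: "cyst <size> mm <H|V> diameter"
    tokens = name.split()
    try:
        return float(tokens[1]), tokens[3]
    except (IndexError, ValueError):
        raise ValueError(
            f"cannot parse phantom measurement name {name!r}; expected "
            "'cyst <size> mm <H|V> diameter'") from None


def summarize_phantom(records, truth: dict[str, float] | None = None,
                      phantom_dataset: str = "phantom") -> pd.DataFrame:
    """Per (insert size, axis, tool) accuracy and precision across readers.

    Returns one row per cell with the number of records, the mean, the
    sample SD (NaN when fewer than two records) and the signed error of the
    mean versus truth.  Within each (size, axis) row the tool with the
    smallest absolute mean error is flagged ``best_accuracy`` and the tool
    with the smallest SD ``best_precision``.

    ``truth`` maps measurement name to the true length; by default it is
    parsed from the protocol's measurement names.
    """
    df = _valid(records)
    df = df[df["dataset"] == phantom_dataset]
    if df.empty:
        raise ValueError("no valid phantom records to summarise")

    parsed = df["measurement"].map(_parse_phantom_measurement)
    df = df.assign(size_mm=[p[0] for p in parsed],
                   axis=[p[1] for p in parsed])
    if truth is None:
        df["truth_mm"] = df["size_mm"]
    else:
        df["truth_mm"] = df["measurement"].map(truth)
        if df["truth_mm"].isna().any():
            missing = df.loc[df["truth_mm"].isna(), "measurement"].unique()
            raise ValueError(f"truth missing for {list(missing)}")

    grouped = df.groupby(["size_mm", "axis", "tool"], sort=True)
    out = grouped.agg(
        n=("value_mm", "size"),
        mean_mm=("value_mm", "mean"),
        sd_mm=("value_mm", lambda v: v.std(ddof=1)),  # NaN for n < 2
        truth_mm=("truth_mm", "first"),
    ).reset_index()
    out["error_mm"] = out["mean_mm"] - out["truth_mm"]

    out["best_accuracy"] = False
    out["best_precision"] = False
    for _, idx in out.groupby(["size_mm", "axis"]).groups.items():
        cell = out.loc[idx]
        out.loc[cell["error_mm"].abs().idxmin(), "best_accuracy"] = True
        if cell["sd_mm"].notna().any():
            out.loc[cell["sd_mm"].idxmin(), "best_precision"] = True
    return out


# ---------------------------------------------------------------------------
# Agreement versus a reference tool
# ---------------------------------------------------------------------------

@dataclass
class AgreementStats:
    """Pairwise agreement of one tool against the reference tool."""

    tool: str
    reference: str
    n_pairs: int
    mean_diff_mm: float
    sd_diff_mm: float
    n_within_threshold: int
    threshold_mm: float
    slope: float
    intercept: float
    correlation: float
    n_dropped: int = 0
    degenerate_regression: bool = False


def paired_values(records, tool: str, reference_tool: str
                  ) -> tuple[np.ndarray, np.ndarray, int]:
    """Values of ``tool`` and ``reference_tool`` paired on
    (user, dataset, measurement); returns (tool values, reference values,
    number of unpaired/invalid records dropped)."""
    df = records_to_dataframe(records)
    df = df[df["tool"].isin([tool, reference_tool])]
    total = len(df)
    df = df[df["valid"]]
    wide = df.pivot_table(index=_PAIR_KEY, columns="tool",
                          values="value_mm", aggfunc="mean")
    if tool not in wide.columns or reference_tool not in wide.columns:
        return np.array([]), np.array([]), total
    wide = wide[[tool, reference_tool]].dropna()
    return (wide[tool].to_numpy(), wide[reference_tool].to_numpy(),
            total - 2 * len(wide))


def agreement(records, tool: str, reference_tool: str,
              threshold_mm: float = 2.0) -> AgreementStats:
    """Differences ``tool - reference`` over paired measurements.

    Reports the mean and sample SD of the differences, the count of pairs
    strictly within ``threshold_mm``, and an ordinary least-squares
    regression of the tool on the reference (flagged degenerate when the
    reference values are constant).
    """
    a, b, n_dropped = paired_values(records, tool, reference_tool)
    n = len(a)
    if n == 0:
        raise ValueError(
            f"no pairable records between {tool!r} and {reference_tool!r}")
    diffs = a - b
    mean_diff = float(np.mean(diffs))
    sd_diff = float(np.std(diffs, ddof=1)) if n > 1 else math.nan
    n_within = int(np.sum(np.abs(diffs) < threshold_mm))

    degenerate = n < 2 or np.ptp(b) == 0
    if degenerate:
        slope = intercept = corr = math.nan
    else:
        fit = stats.linregress(b, a)
        slope, intercept, corr = float(fit.slope), float(fit.intercept), float(fit.rvalue)

    return AgreementStats(
        tool=tool, reference=reference_tool, n_pairs=n,
        mean_diff_mm=mean_diff, sd_diff_mm=sd_diff,
        n_within_threshold=n_within, threshold_mm=threshold_mm,
        slope=slope, intercept=intercept, correlation=corr,
        n_dropped=n_dropped, degenerate_regression=degenerate,
    )


# ---------------------------------------------------------------------------
# Paired t-test
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    """Two-sided paired-samples t-test with per-sample summaries.

    ``status`` is ``"ok"``, ``"no_variation"`` (all differences are zero:
    t is undefined and reported as NaN) or ``"infinite"`` (identical
    nonzero differences: |t| diverges).
    """

    t: float
    df: int
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    status: str = "ok"


def paired_ttest(a, b) -> TTestResult:
    """Paired t-test of ``a`` versus ``b`` (two-sided).

    ``t = mean(d) / (SD(d) / sqrt(n))`` with ``d = a - b`` and
    ``df = n - 1``.  Pairs containing NaN are dropped; at least two complete
    pairs are required.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test requires at least 2 complete pairs")
    d = a - b
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    summary = dict(mean_a=float(np.mean(a)), sd_a=float(np.std(a, ddof=1)),
                   mean_b=float(np.mean(b)), sd_b=float(np.std(b, ddof=1)))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return TTestResult(t=math.nan, df=df, p=math.nan,
                               status="no_variation", **summary)
        return TTestResult(t=math.copysign(math.inf, mean_d), df=df, p=0.0,
                           status="infinite", **summary)
    t = mean_d / (sd_d / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p, **summary)


def paired_ttest_records(records, tool: str, reference_tool: str) -> TTestResult:
    """Paired t-test of a tool against the reference over all paired records."""
    a, b, _ = paired_values(records, tool, reference_tool)
    return paired_ttest(a, b)


# ---------------------------------------------------------------------------
# Intra-user variability
# ---------------------------------------------------------------------------

@dataclass
class IntraUserVariability:
    """Per (user, tool) spread of deviations from the cross-tool mean.

    ``table`` has one row per (user, tool) with the number of contributing
    deviations and their sample SD (NaN when fewer than two).
    ``n_excluded`` counts (user, dataset, measurement) combinations dropped
    because only one tool measured them.
    """

    table: pd.DataFrame
    n_excluded: int


def intra_user_variability(records) -> IntraUserVariability:
    """For each record, the deviation from the mean over all tools of the
    same (user, dataset, measurement); per (user, tool), the sample SD of
    those deviations."""
    df = _valid(records)
    if df.empty:
        raise ValueError("no valid records")
    counts = df.groupby(_PAIR_KEY)["tool"].transform("nunique")
    excluded = df[counts < 2]
    n_excluded = excluded.groupby(_PAIR_KEY).ngroups
    df = df[counts >= 2].copy()
    df["deviation_mm"] = df["value_mm"] - df.groupby(_PAIR_KEY)[
        "value_mm"].transform("mean")
    table = df.groupby(["user", "tool"], sort=True).agg(
        n=("deviation_mm", "size"),
        sd_mm=("deviation_mm", lambda v: v.std(ddof=1)),
    ).reset_index()
    return IntraUserVariability(table=table, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# One-call report
# ---------------------------------------------------------------------------

def full_report(records, reference_tool: str = "QLAB",
                threshold_mm: float = 2.0) -> dict:
    """Phantom summary, agreement and t-test per non-reference tool, and
    intra-user variability, as one dictionary (the CLI's ``evaluate``)."""
    df = records_to_dataframe(records)
    tools = [t for t in df["tool"].unique() if t != reference_tool]
    report: dict = {"reference_tool": reference_tool}
    if (df["dataset"] == "phantom").any():
        report["phantom_summary"] = summarize_phantom(df)
    report["agreement"] = {t: agreement(df, t, reference_tool, threshold_mm)
                           for t in tools}
    report["t_tests"] = {t: paired_ttest_records(df, t, reference_tool)
                         for t in tools}
    report["intra_user"] = intra_user_variability(df)
    return report
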