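"""Dual-luciferase readthrough quantification and small assay statistics.

The dual-luciferase readthrough assay places firefly luciferase (FLuc)
downstream of a test stop codon and Renilla luciferase (RLuc) upstream;
RLuc is expressed constitutively, so the per-replicate FLuc/RLuc ratio is
the transfection-normalized readthrough signal. Efficiency is expressed
against a "no-stop" construct in which FLuc is constitutive:

    %TCR = 100 * mean(FLuc/RLuc, with-stop) / mean(FLuc/RLuc, no-stop)

i.e. mean of per-replicate ratios within each construct, then the quotient
of the two construct means. Percentages are displayed to one decimal.

Also here: the Welch/Student/paired t-tests used throughout, the qPCR
delta-delta-Ct fold change, and densitometry normalization to a loading
control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

LUCIFERASE_COLUMNS = ("construct", "replicate", "fluc", "rluc")


@dataclass(frozen=True)
class ReadthroughEstimate:
    """Percent readthrough and the construct means behind it."""

    percent_tcr: float
    with_stop_mean: float
    no_stop_mean: float
    n_with: int
    n_no: int

    def __str__(self) -> str:
        return f"{format_percent(self.percent_tcr)}%"


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class DdctRecord:
    """Cycle thresholds for target and reference gene in two conditions."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    @property
    def ddct(self) -> float:
        return (self.ct_target_treated - self.ct_reference_treated) - (
            self.ct_target_control - self.ct_reference_control
        )

    @property
    def fold_change(self) -> float:
        return 2.0 ** (-self.ddct)


def read_luciferase_tsv(path: Union[Path, str]) -> pd.DataFrame:
    """Load a per-replicate luminescence table.

    Expects TSV columns ``construct``, ``replicate``, ``fluc``, ``rluc``
    (``#`` comments allowed). Rows with non-positive RLuc are rejected:
    RLuc is the transfection normalizer and a zero reading means the ratio
    is undefined for that replicate.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = set(LUCIFERASE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"luciferase table missing columns: {sorted(missing)}")
    if (table["rluc"] <= 0).any():
        bad = table.loc[table["rluc"] <= 0, "replicate"].tolist()
        raise ValueError(f"non-positive RLuc reading in replicates {bad}")
    if (table["fluc"] < 0).any():
        raise ValueError("negative FLuc readings")
    return table


def fluc_rluc_ratios(table: pd.DataFrame, construct: str) -> np.ndarray:
    """Per-replicate FLuc/RLuc ratios for one construct, in table order."""
    rows = table[table["construct"] == construct]
    if rows.empty:
        raise KeyError(f"construct {construct!r} not in table")
    rluc = rows["rluc"].to_numpy(dtype=float)
    if (rluc <= 0).any():
        raise ValueError(f"non-positive RLuc reading for construct {construct!r}")
    return rows["fluc"].to_numpy(dtype=float) / rluc


def percent_tcr(
    with_stop: Sequence[float],
    no_stop: Sequence[float],
    background: Optional[Sequence[float]] = None,
) -> ReadthroughEstimate:
    """Percent readthrough from with-stop and no-stop replicate ratios.

    ``100 * mean(with_stop) / mean(no_stop)`` with arithmetic means;
    rounding happens only at display. If ``background`` ratios from a
    vector-only construct are supplied, their mean is subtracted from both
    construct means first (off by default: the standard calculation does
    not background-subtract).
    """
    with_stop = np.asarray(with_stop, dtype=float)
    no_stop = np.asarray(no_stop, dtype=float)
    if with_stop.size == 0 or no_stop.size == 0:
        raise ValueError("both constructs need at least one replicate ratio")
    with_mean = float(with_stop.mean())
    no_mean = float(no_stop.mean())
    if background is not None:
        bg = float(np.mean(np.asarray(background, dtype=float)))
        with_mean -= bg
        no_mean -= bg
    if no_mean <= 0:
        raise ValueError("no-stop construct mean must be positive")
    return ReadthroughEstimate(
        percent_tcr=100.0 * with_mean / no_mean,
        with_stop_mean=with_mean,
        no_stop_mean=no_mean,
        n_with=int(with_stop.size),
        n_no=int(no_stop.size),
    )


def welch_ttest(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    equal_var: bool = False,
) -> TTestResult:
    """Two-sided t-test between two groups.

    Unpaired by default with Welch's correction (Welch–Satterthwaite
    degrees of freedom); ``equal_var=True`` selects the pooled-variance
    Student variant; ``paired=True`` reduces to a one-sample t-test on the
    differences. Groups with no variability and equal means return
    ``t=0, p=1`` (a no-signal result, where the textbook statistic is 0/0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        diffs = a - b
        df = float(a.size - 1)
        if np.allclose(diffs.std(ddof=1), 0.0) and np.allclose(diffs.mean(), 0.0):
            return TTestResult(0.0, df, 1.0)
        res = stats.ttest_rel(a, b)
        return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))
    if (
        np.allclose(a.std(ddof=1), 0.0)
        and np.allclose(b.std(ddof=1), 0.0)
        and np.allclose(a.mean(), b.mean())
    ):
        return TTestResult(0.0, float(a.size + b.size - 2), 1.0)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def ddct_fold_change(record: DdctRecord) -> float:
    """Relative expression by the delta-delta-Ct method, ``2**(-ddCt)``."""
    return record.fold_change


def densitometry_normalize(band: float, loading: float) -> float:
    """Band density relative to a loading control (e.g. actin)."""
    if loading <= 0:
        raise ValueError("loading-control density must be positive")
    if band < 0:
        raise ValueError("band density must be non-negative")
    return band / loading


def format_percent(value: float) -> str:
    """Display convention for percentages: one decimal, truncated.

    Truncation toward zero (not round-half) is used because it is the only
    one-decimal convention consistent with all three published example
    calculations this formula reproduces: 0.0705/0.6347 -> 11.1,
    0.0273/0.3748 -> 7.2 (7.2839 would round to 7.3), 0.0576/0.3488 ->
    16.5. Full precision is kept everywhere upstream; truncation happens
    only at display.
    """
    import math

    return f"{math.floor(round(value * 10, 6)) / 10:.1f}"
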