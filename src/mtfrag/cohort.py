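"""Cohort-level statistics for mt-cfDNA length and tumor burden.

Group contrasts use Welch's unequal-variance two-tailed t-test (the safe
choice when group sizes are as lopsided as 46 cancer vs 4 healthy
samples); burden associations use Pearson correlation with
pairwise-complete observations; cohorts can be dichotomized at a ctDNA
percentage threshold (default 5%); and per-patient longitudinal series
report signed between-timepoint changes and direction reversals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

COHORT_COLUMNS = [
    "sample_id", "patient_id", "group", "timepoint", "mean_mt_length",
    "ctdna_percent", "tumor_size", "ctdna_concentration", "disease_state",
]


@dataclass(frozen=True)
class GroupComparison:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    df: float
    p_value: float
    defined: bool = True

    def as_dict(self) -> dict:
        return {
            "n_a": self.n_a, "n_b": self.n_b,
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "t": self.t_statistic, "df": self.df, "p_value": self.p_value,
            "defined": self.defined,
        }


@dataclass(frozen=True)
class CorrelationResult:
    variable_x: str
    variable_y: str
    r: float
    n: int
    p_value: float

    def as_dict(self) -> dict:
        return {
            "pair": f"{self.variable_x}:{self.variable_y}",
            "r": self.r, "n": self.n, "p_value": self.p_value,
        }


@dataclass(frozen=True)
class LongitudinalSeries:
    patient_id: str
    timepoints: tuple[int, ...]
    mean_mt_lengths: tuple[float, ...]
    disease_states: tuple[str, ...]
    directions: tuple[int, ...]  # sign of each between-timepoint change
    has_reversal: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "timepoint": self.timepoints,
                "mean_mt_length": self.mean_mt_lengths,
                "disease_state": self.disease_states,
            }
        )


def welch_t_test(group_a, group_b) -> GroupComparison:
    """Welch's two-tailed t-test (unequal variances)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():  # identical constants: no evidence
            return GroupComparison(a.size, b.size, float(a.mean()), float(b.mean()),
                                   0.0, float(a.size + b.size - 2), 1.0, defined=False)
        raise ValueError("both groups have zero variance with different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        n_a=int(a.size), n_b=int(b.size),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        t_statistic=float(res.statistic), df=float(res.df), p_value=float(res.pvalue),
    )


def pearson_correlation(x, y, variable_x: str = "x", variable_y: str = "y") -> CorrelationResult:
    """Sample Pearson r with two-sided p; missing values dropped pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in a variable")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        variable_x=variable_x, variable_y=variable_y,
        r=float(res.statistic), n=int(x.size), p_value=float(res.pvalue),
    )


def dichotomize_by_ctdna(
    samples: pd.DataFrame, threshold: float = 5.0
) -> tuple[pd.DataFrame, pd.DataFrame, GroupComparison | None]:
    """Split at ctDNA percentage strictly above ``threshold``; compare mt length.

    Returns (high, low, comparison); the comparison is ``None`` when a
    group is empty or too small for the test.
    """
    known = samples[samples["ctdna_percent"].notna()]
    high = known[known["ctdna_percent"] > threshold]
    low = known[known["ctdna_percent"] <= threshold]
    if len(high) < 2 or len(low) < 2:
        return high, low, None
    cmp = welch_t_test(high["mean_mt_length"], low["mean_mt_length"])
    return high, low, cmp


def track_patient(samples: pd.DataFrame) -> LongitudinalSeries:
    """Order one patient's samples by timepoint; flag direction reversals."""
    patients = samples["patient_id"].unique()
    if len(patients) != 1:
        raise ValueError("track_patient expects samples from exactly one patient")
    if len(samples) < 2:
        raise ValueError("need >= 2 timepoints")
    s = samples.sort_values("timepoint")
    tps = s["timepoint"].to_numpy()
    if np.unique(tps).size != tps.size:
        raise ValueError("duplicate timepoint")
    vals = s["mean_mt_length"].to_numpy(dtype=float)
    diffs = np.diff(vals)
    directions = tuple(int(np.sign(d)) for d in diffs)
    nonzero = [d for d in directions if d != 0]
    has_reversal = any(a != b for a, b in zip(nonzero, nonzero[1:]))
    return LongitudinalSeries(
        patient_id=str(patients[0]),
        timepoints=tuple(int(t) for t in tps),
        mean_mt_lengths=tuple(float(v) for v in vals),
        disease_states=tuple(str(x) for x in s["disease_state"]),
        directions=directions,
        has_reversal=has_reversal,
    )


def group_series(samples: pd.DataFrame, group_col: str = "group", value_col: str = "mean_mt_length"):
    """Map group label -> value array (NaNs dropped)."""
    out = {}
    for g, grp in samples.groupby(group_col, observed=True):
        vals = grp[value_col].to_numpy(dtype=float)
        out[str(g)] = vals[~np.isnan(vals)]
    return out


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg (default) adjustment; off by default upstream."""
    return multipletests(np.asarray(pvalues, dtype=float), method=method)[1]


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Cohort TSV: one row per sample, columns as in COHORT_COLUMNS."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "patient_id", "mean_mt_length") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    return df
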