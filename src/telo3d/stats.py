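"""Cohort-level statistics for two-phase telomere architecture comparison.

The central test is a nested factorial analysis of variance: disease phase is
a fixed effect, patient is a random effect nested within phase, and nuclei
are replicates within patient.  The phase effect is therefore tested against
the patient-within-phase mean square, honouring both patient-to-patient and
cell-to-cell variation.  Distributions are compared with a Pearson
chi-square on binned counts.  No multiple-testing correction is applied
across the telomere parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profiles import PROFILE_PARAMETERS

COMPARE_PARAMETERS = (
    "n_telomeres",
    "total_intensity",
    "mean_signal_intensity",
    "n_aggregates",
    "ac_ratio",
    "nuclear_volume_um3",
)


@dataclass(frozen=True)
class NestedAnovaResult:
    """Phase effect tested against patient-within-phase variation."""

    f_phase: float
    df: tuple[int, int]
    p_value: float
    ss_phase: float
    ss_patient: float
    ss_within: float
    degenerate: bool = False
    balanced: bool = True

    @property
    def ss_total(self) -> float:
        return self.ss_phase + self.ss_patient + self.ss_within


def nested_anova(values, patient_ids, phase_ids) -> NestedAnovaResult:
    """Nested factorial ANOVA of ``values`` ~ phase / patient / replicate.

    Balanced designs use the exact sums-of-squares decomposition with
    F = MS_phase / MS_patient(phase) on (g - 1, n_patients - g) degrees of
    freedom.  Unbalanced designs conservatively collapse to patient means and
    run a one-way ANOVA across phases (with a warning).  All-identical values
    are flagged degenerate.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(list(values), dtype=float),
            "patient": list(patient_ids),
            "phase": list(phase_ids),
        }
    ).dropna(subset=["y"])
    if df.empty:
        raise ValueError("no finite values for nested ANOVA")

    phase_of_patient = df.groupby("patient")["phase"].nunique()
    if (phase_of_patient > 1).any():
        bad = phase_of_patient[phase_of_patient > 1].index.tolist()
        raise ValueError(f"patients assigned to more than one phase: {bad}")

    phases = df["phase"].unique()
    g = len(phases)
    if g < 2:
        raise ValueError("nested ANOVA needs at least 2 phases")
    patients_per_phase = df.groupby("phase")["patient"].nunique()
    if (patients_per_phase < 2).any():
        raise ValueError(
            f"nested ANOVA needs >= 2 patients per phase, got {patients_per_phase.to_dict()}"
        )

    cells_per_patient = df.groupby("patient").size()
    balanced = (
        cells_per_patient.nunique() == 1 and patients_per_phase.nunique() == 1
    )

    if not balanced:
        warnings.warn(
            "unbalanced nested design: collapsing to patient means and running "
            "one-way ANOVA across phases",
            stacklevel=2,
        )
        pm = df.groupby(["phase", "patient"])["y"].mean().reset_index()
        groups = [sub["y"].to_numpy() for _, sub in pm.groupby("phase")]
        grand = pm["y"].mean()
        ss_phase = float(sum(len(v) * (v.mean() - grand) ** 2 for v in groups))
        ss_patient = float(sum(((v - v.mean()) ** 2).sum() for v in groups))
        n_pat = len(pm)
        df1, df2 = g - 1, n_pat - g
        if ss_patient <= 0 and ss_phase <= 0:
            return NestedAnovaResult(
                float("nan"), (df1, df2), float("nan"), 0.0, 0.0, 0.0, True, False
            )
        f = (ss_phase / df1) / (ss_patient / df2)
        p = float(sps.f.sf(f, df1, df2))
        return NestedAnovaResult(float(f), (df1, df2), p, ss_phase, ss_patient, 0.0, False, False)

    grand = df["y"].mean()
    phase_means = df.groupby("phase")["y"].mean()
    phase_sizes = df.groupby("phase").size()
    ss_phase = float((phase_sizes * (phase_means - grand) ** 2).sum())

    pat = df.groupby(["phase", "patient"])["y"].agg(["mean", "size"])
    pat = pat.join(phase_means.rename("phase_mean"), on="phase")
    ss_patient = float((pat["size"] * (pat["mean"] - pat["phase_mean"]) ** 2).sum())

    cell_means = df.merge(
        pat["mean"].rename("patient_mean"), left_on=["phase", "patient"], right_index=True
    )
    ss_within = float(((cell_means["y"] - cell_means["patient_mean"]) ** 2).sum())

    n_patients = len(pat)
    df1, df2 = g - 1, n_patients - g
    ms_patient = ss_patient / df2 if df2 > 0 else float("nan")
    if not np.isfinite(ms_patient) or ms_patient <= 0:
        degenerate = ss_phase <= 0
        f = float("inf") if ss_phase > 0 else float("nan")
        p = 0.0 if ss_phase > 0 else float("nan")
        return NestedAnovaResult(f, (df1, df2), p, ss_phase, ss_patient, ss_within, degenerate)
    f = (ss_phase / df1) / ms_patient
    p = float(sps.f.sf(f, df1, df2))
    return NestedAnovaResult(float(f), (df1, df2), p, ss_phase, ss_patient, ss_within)


def summarize_phase(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Mean +/- SD of one parameter per phase, over nuclei and over patient means.

    Single-observation SDs are reported as NaN rather than zero.
    """
    if parameter not in table.columns:
        raise KeyError(
            f"unknown parameter {parameter!r}; expected one of {sorted(set(PROFILE_PARAMETERS) | set(table.columns))}"
        )
    if table.empty:
        raise ValueError("empty cohort table")
    rows = []
    for phase, sub in table.groupby("phase", sort=False):
        vals = sub[parameter].dropna()
        pmeans = sub.groupby("patient_id")[parameter].mean().dropna()
        rows.append(
            {
                "phase": phase,
                "parameter": parameter,
                "n_nuclei": int(len(vals)),
                "mean": float(vals.mean()) if len(vals) else float("nan"),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "n_patients": int(len(pmeans)),
                "patient_mean": float(pmeans.mean()) if len(pmeans) else float("nan"),
                "patient_sd": float(pmeans.std(ddof=1)) if len(pmeans) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def merge_small_bins(hist_a: np.ndarray, hist_b: np.ndarray, min_expected: float = 5.0):
    """Pool adjacent bins until every expected count reaches ``min_expected``."""
    a = np.asarray(hist_a, dtype=float).copy()
    b = np.asarray(hist_b, dtype=float).copy()
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("histograms must be 1D with identical binning")

    def expected(a, b):
        total = a.sum() + b.sum()
        col = a + b
        return np.outer([a.sum(), b.sum()], col) / total

    while a.size > 1:
        exp = expected(a, b)
        if exp.min() >= min_expected:
            break
        j = int(np.argmin(exp.min(axis=0)))
        k = j + 1 if j + 1 < a.size else j - 1
        lo, hi = sorted((j, k))
        a[lo] += a[hi]
        b[lo] += b[hi]
        a = np.delete(a, hi)
        b = np.delete(b, hi)
    return a, b


def chi_square_distributions(hist_a, hist_b, min_expected: float = 5.0):
    """Pearson chi-square comparing two binned distributions.

    Bins with expected counts below ``min_expected`` are pooled with a
    neighbour first.  Returns ``(statistic, df, p_value)`` with
    df = (number of bins after merging) - 1.
    """
    a = np.asarray(hist_a, dtype=float)
    b = np.asarray(hist_b, dtype=float)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("all-zero histogram")
    a, b = merge_small_bins(a, b, min_expected)
    if a.size < 2:
        raise ValueError("fewer than 2 bins remain after merging")
    stat, p, dof, _ = sps.chi2_contingency(np.vstack([a, b]), correction=False)
    return float(stat), int(dof), float(p)


def equal_probability_histograms(values_a, values_b, n_bins: int = 10):
    """Histograms on ``n_bins`` equal-probability bins of the pooled distribution."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    pooled = np.concatenate([a, b])
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    edges = np.unique(edges)
    return np.histogram(a, bins=edges)[0], np.histogram(b, bins=edges)[0]


def compare_cohorts(
    table: pd.DataFrame, parameters: tuple[str, ...] = COMPARE_PARAMETERS
) -> pd.DataFrame:
    """Phase-comparison report: per-phase mean +/- SD and nested-ANOVA p per parameter,
    plus a chi-square comparison of the signal-intensity distribution.

    P-values are reported uncorrected across parameters.
    """
    phases = list(table["phase"].unique())
    if len(phases) != 2:
        raise ValueError(f"expected exactly 2 phases, got {phases}")
    rows = []
    for param in parameters:
        summary = summarize_phase(table, param).set_index("phase")
        sub = table.dropna(subset=[param])
        try:
            res = nested_anova(sub[param], sub["patient_id"], sub["phase"])
            p_val, f_val = res.p_value, res.f_phase
        except ValueError:
            p_val, f_val = float("nan"), float("nan")
        row = {"parameter": param, "F_phase": f_val, "p_value": p_val}
        for ph in phases:
            row[f"mean_{ph}"] = summary.loc[ph, "mean"]
            row[f"sd_{ph}"] = summary.loc[ph, "sd"]
        rows.append(row)

    a = table.loc[table["phase"] == phases[0], "mean_signal_intensity"]
    b = table.loc[table["phase"] == phases[1], "mean_signal_intensity"]
    try:
        ha, hb = equal_probability_histograms(a, b)
        stat, dof, p = chi_square_distributions(ha, hb)
        rows.append(
            {
                "parameter": "intensity_distribution_chi2",
                "F_phase": stat,
                "p_value": p,
                f"mean_{phases[0]}": float(np.nanmean(a)),
                f"sd_{phases[0]}": float(np.nanstd(a, ddof=1)),
                f"mean_{phases[1]}": float(np.nanmean(b)),
                f"sd_{phases[1]}": float(np.nanstd(b, ddof=1)),
            }
        )
    except ValueError:
        pass
    return pd.DataFrame(rows)
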