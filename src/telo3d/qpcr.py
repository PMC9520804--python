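"""Comparative-Ct (2^-ddCt) relative quantification for aurora kinase qPCR.

For each sample, technical replicates are averaged on the Ct scale, the
target gene is normalised to the GAPDH reference (dCt = Ct_target - Ct_ref),
and expression is reported relative to the mean dCt of the healthy-donor
calibrator group: ddCt = dCt_sample - mean(dCt_calibrator), fold = 2^-ddCt.
Amplification efficiency is taken as exactly 2 (no efficiency correction).

Group summaries are arithmetic mean +/- SD of the per-sample fold changes;
groups are compared with one-way ANOVA and Bonferroni-adjusted pairwise
t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

REQUIRED_COLUMNS = ("sample_id", "group", "gene", "replicate", "ct_target", "ct_reference")


@dataclass
class ExpressionResult:
    """Per-sample and per-group relative expression for one gene."""

    gene: str
    calibrator_group: str
    per_sample: pd.DataFrame  # sample_id, group, delta_ct, delta_delta_ct, fold_change
    group_summary: pd.DataFrame  # group, n, mean, sd, sem

    def folds(self, group: str) -> np.ndarray:
        return self.per_sample.loc[self.per_sample["group"] == group, "fold_change"].to_numpy()


def delta_delta_ct(
    records: pd.DataFrame, gene: str, calibrator_group: str = "healthy"
) -> ExpressionResult:
    """Comparative-Ct quantification of one gene against a calibrator group."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    sub = records[records["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no Ct records for gene {gene!r}")
    if sub[["ct_target", "ct_reference"]].isna().any().any():
        bad = sub.loc[sub[["ct_target", "ct_reference"]].isna().any(axis=1), "sample_id"]
        raise ValueError(f"missing Ct values for samples: {sorted(set(bad))}")
    if (sub[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")

    # technical replicates averaged on the Ct scale
    per_sample = (
        sub.groupby(["sample_id", "group"], as_index=False)[["ct_target", "ct_reference"]]
        .mean()
        .assign(delta_ct=lambda d: d["ct_target"] - d["ct_reference"])
    )
    cal = per_sample.loc[per_sample["group"] == calibrator_group, "delta_ct"]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples for {gene}")
    per_sample["delta_delta_ct"] = per_sample["delta_ct"] - cal.mean()
    per_sample["fold_change"] = 2.0 ** (-per_sample["delta_delta_ct"])

    group_summary = (
        per_sample.groupby("group")["fold_change"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
        .assign(sem=lambda d: d["sd"] / np.sqrt(d["n"]))
    )
    return ExpressionResult(gene, calibrator_group, per_sample, group_summary)


def group_comparison(result: ExpressionResult) -> tuple[float, dict[tuple[str, str], float]]:
    """One-way ANOVA across groups plus Bonferroni-adjusted pairwise t-tests.

    Raw pairwise p-values are multiplied by the number of comparisons and
    capped at 1.  Degenerate (constant, or < 2 samples) groups are rejected.
    """
    canonical = ("healthy", "chronic", "accelerated_blast")
    groups = sorted(
        result.per_sample["group"].unique(),
        key=lambda g: canonical.index(g) if g in canonical else len(canonical),
    )
    if len(groups) < 2:
        raise ValueError("group comparison needs at least 2 groups")
    arrays = {g: result.folds(g) for g in groups}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if all(np.ptp(v) == 0 for v in arrays.values()) and len({v[0] for v in arrays.values()}) == 1:
        raise ValueError("all groups are constant and identical: ANOVA undefined")
    anova_p = float(sps.f_oneway(*arrays.values()).pvalue)
    n_comp = len(list(combinations(groups, 2)))
    pairwise = {}
    for g1, g2 in combinations(groups, 2):
        p_raw = float(sps.ttest_ind(arrays[g1], arrays[g2]).pvalue)
        pairwise[(g1, g2)] = min(p_raw * n_comp, 1.0)
    return anova_p, pairwise


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table {path} is missing columns: {missing}")
    return df
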