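"""Per-nucleus telomere architecture profiles.

Condenses the detected signals of one nucleus into the six-parameter record
used to compare disease phases: number of telomere signals, total and mean
signal intensity (a proxy for telomere length), number of telomere
aggregates, the a/c ratio of the telomere point cloud (a flatness measure
that tracks cell-cycle stage), nuclear volume, and the radial position of
each signal.  Also provides the short/intermediate/long partition of a
pooled intensity distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import NucleusMask, TelomereSignal

PROFILE_PARAMETERS = (
    "n_telomeres",
    "total_intensity",
    "mean_signal_intensity",
    "n_aggregates",
    "ac_ratio",
    "nuclear_volume_um3",
    "mean_radial_position",
)


@dataclass
class NucleusProfile:
    """Six-parameter telomere architecture record for one nucleus."""

    patient_id: str
    sample_id: str
    nucleus_id: str
    phase: str
    n_telomeres: int
    total_intensity: float
    n_aggregates: int
    ac_ratio: float  # NaN when undefined (< 4 signals or degenerate cloud)
    nuclear_volume_um3: float
    radial_positions: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_aggregates > self.n_telomeres:
            raise ValueError("n_aggregates cannot exceed n_telomeres")
        if self.nuclear_volume_um3 <= 0:
            raise ValueError("nuclear volume must be positive")

    @property
    def mean_signal_intensity(self) -> float:
        if self.n_telomeres == 0:
            return float("nan")
        return self.total_intensity / self.n_telomeres

    @property
    def mean_radial_position(self) -> float:
        finite = [r for r in self.radial_positions if np.isfinite(r)]
        return float(np.mean(finite)) if finite else float("nan")

    @property
    def telomeres_per_volume(self) -> float:
        """Telomere signals per unit nuclear volume (signals / um^3)."""
        return self.n_telomeres / self.nuclear_volume_um3

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "sample_id": self.sample_id,
            "nucleus_id": self.nucleus_id,
            "phase": self.phase,
            "n_telomeres": self.n_telomeres,
            "total_intensity": self.total_intensity,
            "mean_signal_intensity": self.mean_signal_intensity,
            "n_aggregates": self.n_aggregates,
            "ac_ratio": self.ac_ratio,
            "nuclear_volume_um3": self.nuclear_volume_um3,
            "mean_radial_position": self.mean_radial_position,
            "telomeres_per_volume": self.telomeres_per_volume,
        }


def compute_ac_ratio(positions_nm: np.ndarray, min_signals: int = 4) -> float:
    """Extreme principal-axis ratio of a 3D point cloud, sqrt(l_max / l_min).

    Rotation- and translation-invariant by construction.  Returns NaN for
    fewer than ``min_signals`` points or a degenerate (rank < 3) cloud.
    """
    pts = np.asarray(positions_nm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array")
    if pts.shape[0] < min_signals:
        return float("nan")
    cov = np.cov(pts.T)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-9 * max(eigvals[-1], 1e-300):
        return float("nan")
    return float(np.sqrt(eigvals[-1] / eigvals[0]))


def build_profile(
    nucleus: NucleusMask,
    signals: list[TelomereSignal],
    n_aggregates: int,
    patient_id: str = "",
    sample_id: str = "",
    nucleus_id: str = "",
    phase: str = "",
) -> NucleusProfile:
    """Assemble the per-nucleus profile from quantification output."""
    positions = np.array([s.centroid_nm for s in signals]).reshape(len(signals), 3)
    return NucleusProfile(
        patient_id=patient_id,
        sample_id=sample_id or patient_id,
        nucleus_id=nucleus_id,
        phase=phase,
        n_telomeres=len(signals),
        total_intensity=float(sum(s.integrated_intensity for s in signals)),
        n_aggregates=n_aggregates,
        ac_ratio=compute_ac_ratio(positions) if len(signals) else float("nan"),
        nuclear_volume_um3=nucleus.volume_um3,
        radial_positions=[s.radial_position for s in signals],
    )


def profiles_to_frame(profiles: list[NucleusProfile]) -> pd.DataFrame:
    """CohortTable: one row per nucleus, keyed by (phase, patient, sample, nucleus)."""
    return pd.DataFrame([p.to_row() for p in profiles])


@dataclass(frozen=True)
class IntensityPartition:
    """Short/intermediate/long split of an intensity distribution."""

    thresholds: tuple[float, float]
    counts: tuple[int, int, int]

    @property
    def total(self) -> int:
        return sum(self.counts)


def _kmeans_cuts(values: np.ndarray, n_iter: int = 100) -> tuple[float, float]:
    """Deterministic 1D 3-means on log intensity; returns the two midpoints."""
    x = np.log(np.clip(values, 1e-12, None))
    centers = np.quantile(x, [1 / 6, 3 / 6, 5 / 6])
    for _ in range(n_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [x[assign == k].mean() if (assign == k).any() else centers[k] for k in range(3)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    centers = np.sort(centers)
    return float(np.exp((centers[0] + centers[1]) / 2)), float(
        np.exp((centers[1] + centers[2]) / 2)
    )


def partition_intensities(
    intensities,
    method: str = "tertile",
    thresholds: tuple[float, float] | None = None,
) -> IntensityPartition:
    """Partition signal intensities into short / intermediate / long.

    The default cuts at the 33.3rd and 66.7th percentiles of the pooled
    distribution; ``method="kmeans"`` places the cut points between three
    1D k-means clusters of log-intensity (recovers unequal subpopulation
    weights when the components are well separated); ``method="fixed"`` uses
    caller-supplied thresholds.  Degenerate (all-equal) input yields equal
    thresholds, every value in the first class, and a warning.
    """
    values = np.asarray(list(intensities), dtype=float)
    if values.size < 3:
        raise ValueError(f"need at least 3 intensities to partition, got {values.size}")
    if method == "tertile":
        t1, t2 = np.percentile(values, [100 / 3.0, 200 / 3.0])
    elif method == "kmeans":
        t1, t2 = _kmeans_cuts(values)
    elif method == "fixed":
        if thresholds is None:
            raise ValueError("fixed method requires explicit thresholds")
        t1, t2 = thresholds
    else:
        raise ValueError(f"unknown partition method {method!r}")
    if not t1 <= t2:
        raise ValueError("thresholds must be non-decreasing")
    if t1 == t2:
        warnings.warn("degenerate intensity partition: thresholds coincide", stacklevel=2)
        short = int((values <= t1).sum())
        long_ = int((values > t2).sum())
    else:
        short = int((values <= t1).sum())
        long_ = int((values > t2).sum())
    inter = int(values.size - short - long_)
    return IntensityPartition(thresholds=(float(t1), float(t2)), counts=(short, inter, long_))
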