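"""Synthetic 3D Q-FISH data with ground truth.

This module emulates the raw material of a two-phase CML telomere study:

* multi-channel 3D image stacks of single CD34+ interphase nuclei — a DAPI
  ellipsoid, a Cy3 channel with PSF-blurred telomere signals (three intensity
  subpopulations: short / intermediate / long telomeres, plus unresolvable
  telomere aggregates), and a FITC channel encoding CD34 status;
* qPCR Ct tables for AURKA/AURKB against a GAPDH reference with configured
  group-level 2^-ddCt fold changes.

Every draw is made through a seeded :class:`numpy.random.Generator`, so a
fixed configuration and seed reproduce output byte for byte.  Ground truth
(spot positions, intensities, aggregate memberships, nuclear volume, cloud
flattening) is returned alongside every rendered nucleus and is the oracle
for the quantification tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .stacks import ImageStack3D, VoxelSpacing, write_stack

PHASES = ("chronic", "accelerated_blast")
GENES = ("AURKA", "AURKB")
GROUPS = ("healthy", "chronic", "accelerated_blast")


# ---------------------------------------------------------------------------
# nucleus-level configuration


@dataclass(frozen=True)
class IntensityMixture:
    """Three-component lognormal mixture for telomere signal intensities.

    Components are ordered short / intermediate / long.  ``log_means`` are the
    means of log-intensity, ``log_sds`` the log-scale dispersions.
    """

    weights: tuple[float, float, float] = (0.20, 0.55, 0.25)
    log_means: tuple[float, float, float] = (
        float(np.log(1000.0) - 0.005),
        float(np.log(1200.0) - 0.005),
        float(np.log(1500.0) - 0.005),
    )
    log_sds: tuple[float, float, float] = (0.10, 0.10, 0.10)

    def __post_init__(self) -> None:
        if len(self.weights) != 3 or len(self.log_means) != 3 or len(self.log_sds) != 3:
            raise ValueError("intensity mixture must have exactly 3 components")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {self.weights}")
        if any(w < 0 for w in self.weights) or any(s < 0 for s in self.log_sds):
            raise ValueError("mixture weights and log-sds must be non-negative")

    @property
    def component_means(self) -> np.ndarray:
        mu = np.asarray(self.log_means)
        sd = np.asarray(self.log_sds)
        return np.exp(mu + sd**2 / 2.0)

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw n intensities; returns (intensities, component indices)."""
        comp = rng.choice(3, size=n, p=np.asarray(self.weights) / sum(self.weights))
        log_i = rng.normal(np.asarray(self.log_means)[comp], np.asarray(self.log_sds)[comp])
        return np.exp(log_i), comp


@dataclass(frozen=True)
class SynthNucleusConfig:
    """Generative model for one nucleus.

    Distances are nm, intensities arbitrary units.  ``semi_axes`` is the
    nuclear ellipsoid (a >= b >= c); ``flattening`` divides the axial spread
    of the telomere point cloud (not the nucleus itself) so the cloud's
    principal-axis a/c ratio is ``flattening * a/c`` analytically.
    """

    semi_axes: tuple[float, float, float] = (4430.0, 3740.0, 2770.0)
    n_telomeres: tuple[float, float] = (39.45, 6.46)  # (mean, sd) of signal count
    intensity_mixture: IntensityMixture = field(default_factory=IntensityMixture)
    n_aggregates: tuple[float, float] = (3.37, 1.04)
    aggregate_multiplicity: tuple[tuple[int, float], ...] = ((2, 0.3), (3, 0.5), (4, 0.2))
    flattening: float = 1.0
    psf_sigma: tuple[float, float, float] = (150.0, 150.0, 300.0)  # (x, y, z) nm
    background_level: float = 20.0
    noise_sd: float = 2.0
    cd34_positive: bool = True
    dapi_level: float = 100.0
    fitc_positive_level: float = 60.0
    fitc_negative_level: float = 6.0
    # 4x the PSF sigma per axis: the elliptical constraint then guarantees a
    # uniform 4-sigma separation in PSF units, so distinct signals never fuse
    min_separation: tuple[float, float] = (600.0, 1200.0)  # lateral/axial nm between signals
    # member offset radii chosen so pairwise member distances stay below half
    # the (200, 500) nm resolution limit: aggregates render as one object
    aggregate_spread: tuple[float, float] = (45.0, 112.0)  # lateral/axial nm

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError(f"semi_axes must satisfy a >= b >= c > 0, got {self.semi_axes}")
        if any(k < 2 for k, _ in self.aggregate_multiplicity):
            raise ValueError("aggregate multiplicity must be >= 2 spots per aggregate")
        if abs(sum(p for _, p in self.aggregate_multiplicity) - 1.0) > 1e-9:
            raise ValueError("aggregate multiplicity probabilities must sum to 1")
        if self.flattening < 1.0:
            raise ValueError("flattening must be >= 1")
        if self.n_telomeres[0] < 0 or self.n_telomeres[1] < 0:
            raise ValueError("n_telomeres mean and sd must be non-negative")

    @property
    def nuclear_volume_um3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c * 1e-9

    @property
    def ac_ratio_true(self) -> float:
        """Analytic a/c of the flattened telomere point cloud."""
        a, _, c = self.semi_axes
        return self.flattening * a / c


@dataclass
class GroundTruth:
    """Per-nucleus generative truth used as test oracle."""

    member_positions: np.ndarray  # (n_members, 3) nm, (z, y, x)
    member_intensities: np.ndarray
    member_signal_id: np.ndarray  # which rendered signal each member belongs to
    member_component: np.ndarray  # mixture component of each member
    signal_is_aggregate: np.ndarray  # (n_signals,) bool
    nuclear_volume_um3: float
    ac_ratio: float
    semi_axes: tuple[float, float, float]
    cd34_positive: bool

    @property
    def n_signals(self) -> int:
        return int(self.signal_is_aggregate.size)

    @property
    def n_aggregates(self) -> int:
        return int(self.signal_is_aggregate.sum())

    @property
    def signal_positions(self) -> np.ndarray:
        """Intensity-weighted centroid of each signal's members, (n_signals, 3) nm."""
        out = np.zeros((self.n_signals, 3))
        for sid in range(self.n_signals):
            sel = self.member_signal_id == sid
            w = self.member_intensities[sel]
            out[sid] = (self.member_positions[sel] * w[:, None]).sum(0) / w.sum()
        return out

    @property
    def signal_intensities(self) -> np.ndarray:
        return np.bincount(
            self.member_signal_id, weights=self.member_intensities, minlength=self.n_signals
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "signal_id": self.member_signal_id,
                "z_nm": self.member_positions[:, 0],
                "y_nm": self.member_positions[:, 1],
                "x_nm": self.member_positions[:, 2],
                "intensity": self.member_intensities,
                "component": self.member_component,
                "is_aggregate": self.signal_is_aggregate[self.member_signal_id],
            }
        )


# ---------------------------------------------------------------------------
# geometry helpers


def _sample_in_ellipsoid(rng: np.random.Generator, n: int, semi_axes_zyx: np.ndarray) -> np.ndarray:
    """Uniform points in an ellipsoid centred at the origin, (n, 3) in (z,y,x)."""
    u = rng.normal(size=(n, 3))
    u /= np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-300)
    r = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return u * r * semi_axes_zyx


def _scaled_dist2(p: np.ndarray, q: np.ndarray, lateral: float, axial: float) -> np.ndarray:
    """Squared anisotropy-scaled distance: < 1 means closer than (lateral, axial)."""
    d = p - q
    return (d[..., 0] / axial) ** 2 + (d[..., 1] / lateral) ** 2 + (d[..., 2] / lateral) ** 2


def _place_signals(
    rng: np.random.Generator, config: SynthNucleusConfig, n_signals: int
) -> np.ndarray:
    """Signal centres inside the (flattened-cloud) nucleus with min pairwise separation."""
    a, b, c = config.semi_axes
    margin = max(config.aggregate_spread) + 50.0
    axes = np.array([c, b, a]) - margin  # (z, y, x) order
    if np.any(axes <= 0):
        raise ValueError("nucleus too small to place telomere signals")
    lat, ax = config.min_separation
    placed: list[np.ndarray] = []
    attempts = 0
    max_attempts = 5000 * max(n_signals, 1)
    while len(placed) < n_signals:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n_signals} signals with separation {config.min_separation} nm "
                f"inside semi-axes {config.semi_axes} nm"
            )
        attempts += 1
        p = _sample_in_ellipsoid(rng, 1, axes)[0]
        p[0] /= config.flattening  # flatten the cloud axially
        if placed and np.any(_scaled_dist2(np.array(placed), p, lat, ax) < 1.0):
            continue
        placed.append(p)
    return np.array(placed).reshape(n_signals, 3)


def _render_spots(
    shape: tuple[int, int, int],
    spacing: VoxelSpacing,
    positions: np.ndarray,
    intensities: np.ndarray,
    psf_sigma_xyz: tuple[float, float, float],
) -> np.ndarray:
    """Sum of integrated-intensity Gaussians evaluated at voxel centres."""
    img = np.zeros(shape, dtype=np.float64)
    sig_vox = np.array([psf_sigma_xyz[2], psf_sigma_xyz[1], psf_sigma_xyz[0]]) / spacing.zyx
    half = np.ceil(4.0 * sig_vox).astype(int)
    for pos, inten in zip(positions, intensities):
        pos_vox = pos / spacing.zyx
        lo = np.maximum(np.floor(pos_vox).astype(int) - half, 0)
        hi = np.minimum(np.floor(pos_vox).astype(int) + half + 2, shape)
        if np.any(lo >= hi):
            continue
        axes = [
            np.exp(-0.5 * ((np.arange(lo[d], hi[d]) - pos_vox[d]) / sig_vox[d]) ** 2)
            / (np.sqrt(2 * np.pi) * sig_vox[d])
            for d in range(3)
        ]
        patch = inten * axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += patch
    return img


def _ellipsoid_interior(
    shape: tuple[int, int, int], spacing: VoxelSpacing, center: np.ndarray, semi_axes: tuple
) -> np.ndarray:
    a, b, c = semi_axes
    axes_zyx = np.array([c, b, a])
    zz = ((np.arange(shape[0]) * spacing.dz - center[0]) / axes_zyx[0]) ** 2
    yy = ((np.arange(shape[1]) * spacing.dy - center[1]) / axes_zyx[1]) ** 2
    xx = ((np.arange(shape[2]) * spacing.dx - center[2]) / axes_zyx[2]) ** 2
    return (zz[:, None, None] + yy[None, :, None] + xx[None, None, :]) <= 1.0


# ---------------------------------------------------------------------------
# single-nucleus generation


def generate_nucleus(
    config: SynthNucleusConfig,
    spacing: VoxelSpacing | None = None,
    seed: int | np.random.SeedSequence = 0,
    shape: tuple[int, int, int] = (60, 128, 128),
    render_fitc: bool = True,
    render: bool = True,
) -> tuple[dict[str, ImageStack3D], GroundTruth]:
    """Render one nucleus as per-channel stacks plus its ground truth.

    The nucleus is centred in the stack.  The Cy3 channel is the sum of
    PSF-blurred Gaussian spots over a flat background with Gaussian noise;
    the stack is already "deconvolved-like" (no aberrations are modelled).
    """
    spacing = spacing or VoxelSpacing()
    rng = np.random.default_rng(seed)
    a, b, c = config.semi_axes
    extent = (np.array(shape) - 1) * spacing.zyx
    center = extent / 2.0
    if 2 * a > extent[2] or 2 * b > extent[1] or 2 * c > extent[0]:
        raise ValueError(
            f"nuclear semi-axes {config.semi_axes} nm do not fit in a {shape} stack "
            f"at spacing ({spacing.dx}, {spacing.dy}, {spacing.dz}) nm"
        )

    n_signals = max(int(round(rng.normal(*config.n_telomeres))), 0)
    n_agg = max(int(round(rng.normal(*config.n_aggregates))), 0)
    n_agg = min(n_agg, n_signals)

    if n_signals > 0:
        centres = _place_signals(rng, config, n_signals) + center
    else:
        centres = np.zeros((0, 3))

    ks, ps = zip(*config.aggregate_multiplicity)
    mult = rng.choice(np.array(ks), size=n_agg, p=np.array(ps)) if n_agg else np.zeros(0, int)

    member_pos: list[np.ndarray] = []
    member_sid: list[int] = []
    lat_r, ax_r = config.aggregate_spread
    for sid in range(n_signals):
        if sid < n_agg:
            k = int(mult[sid])
            # members within a small ellipsoid => pairwise closer than the
            # resolution limit, rendering as one unresolvable object
            offsets = _sample_in_ellipsoid(rng, k, np.array([ax_r, lat_r, lat_r]) / 2.0)
            for off in offsets:
                member_pos.append(centres[sid] + off)
                member_sid.append(sid)
        else:
            member_pos.append(centres[sid])
            member_sid.append(sid)
    member_pos_arr = np.array(member_pos).reshape(len(member_sid), 3)
    member_sid_arr = np.array(member_sid, dtype=int)
    intensities, components = config.intensity_mixture.sample(rng, len(member_sid))

    truth = GroundTruth(
        member_positions=member_pos_arr,
        member_intensities=intensities,
        member_signal_id=member_sid_arr,
        member_component=components,
        signal_is_aggregate=np.arange(n_signals) < n_agg,
        nuclear_volume_um3=config.nuclear_volume_um3,
        ac_ratio=config.ac_ratio_true,
        semi_axes=config.semi_axes,
        cd34_positive=config.cd34_positive,
    )

    if not render:  # ground-truth-only draws, e.g. for design/power checks
        return {}, truth

    interior = _ellipsoid_interior(shape, spacing, center, config.semi_axes)

    dapi = np.where(interior, config.dapi_level, 0.0)
    dapi = ndi.gaussian_filter(dapi, sigma=1.0)
    if config.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, config.noise_sd, size=shape)

    cy3 = _render_spots(shape, spacing, member_pos_arr, intensities, config.psf_sigma)
    cy3 += config.background_level
    if config.noise_sd > 0:
        cy3 = cy3 + rng.normal(0.0, config.noise_sd, size=shape)

    stacks = {
        "DAPI": ImageStack3D(np.clip(dapi, 0, None).astype(np.float32), spacing, "DAPI"),
        "Cy3": ImageStack3D(np.clip(cy3, 0, None).astype(np.float32), spacing, "Cy3"),
    }
    if render_fitc:
        level = config.fitc_positive_level if config.cd34_positive else config.fitc_negative_level
        fitc = np.where(interior, level, 1.0)
        if config.noise_sd > 0:
            fitc = fitc + rng.normal(0.0, config.noise_sd, size=shape)
        stacks["FITC"] = ImageStack3D(np.clip(fitc, 0, None).astype(np.float32), spacing, "FITC")
    return stacks, truth


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortConfig:
    """One disease-phase cohort: patients x nuclei drawn around a base nucleus model.

    Patient-level heterogeneity enters as Gaussian shifts of the per-nucleus
    count means and a lognormal rescaling of the nuclear radii; nucleus-level
    dispersion stays in :class:`SynthNucleusConfig`.
    """

    phase_label: str = "chronic"
    n_patients: int = 18
    n_nuclei_per_sample: int = 30
    nucleus: SynthNucleusConfig = field(default_factory=SynthNucleusConfig)
    patient_telomere_sd: float = 0.5
    patient_aggregate_sd: float = 0.5
    patient_radius_log_sd: float = 0.03
    nucleus_radius_log_sd: float = 0.06
    rng_seed: int = 0
    shape: tuple[int, int, int] = (60, 128, 128)

    def __post_init__(self) -> None:
        if self.phase_label not in PHASES:
            raise ValueError(f"phase_label must be one of {PHASES}, got {self.phase_label!r}")
        if self.n_nuclei_per_sample < 1:
            raise ValueError("n_nuclei_per_sample must be >= 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")


def iter_cohort(config: CohortConfig):
    """Yield ``(patient_id, nucleus_id, nucleus_config, child_seed)`` deterministically.

    The same iterator backs in-memory pipelines and on-disk cohorts, so both
    see identical nuclei for a given configuration.
    """
    root = np.random.SeedSequence(config.rng_seed)
    patient_seeds = root.spawn(config.n_patients)
    for p in range(config.n_patients):
        pseed = patient_seeds[p]
        prng = np.random.default_rng(pseed)
        telo_shift = prng.normal(0.0, config.patient_telomere_sd)
        agg_shift = prng.normal(0.0, config.patient_aggregate_sd)
        radius_patient = np.exp(
            np.clip(prng.normal(0.0, config.patient_radius_log_sd), -2 * config.patient_radius_log_sd, 2 * config.patient_radius_log_sd)
            if config.patient_radius_log_sd > 0
            else 0.0
        )
        nucleus_seeds = pseed.spawn(config.n_nuclei_per_sample)
        for i in range(config.n_nuclei_per_sample):
            nrng = np.random.default_rng(nucleus_seeds[i])
            radius = radius_patient * np.exp(
                np.clip(
                    nrng.normal(0.0, config.nucleus_radius_log_sd),
                    -2 * config.nucleus_radius_log_sd,
                    2 * config.nucleus_radius_log_sd,
                )
                if config.nucleus_radius_log_sd > 0
                else 0.0
            )
            base = config.nucleus
            ncfg = dataclasses.replace(
                base,
                semi_axes=tuple(ax * radius for ax in base.semi_axes),
                n_telomeres=(base.n_telomeres[0] + telo_shift, base.n_telomeres[1]),
                n_aggregates=(base.n_aggregates[0] + agg_shift, base.n_aggregates[1]),
            )
            yield f"{config.phase_label}_P{p + 1:02d}", f"N{i + 1:03d}", ncfg, nucleus_seeds[i].spawn(1)[0]


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write a cohort to disk: per-nucleus TIFF set + ground-truth CSV + manifest.

    Returns the manifest (one row per nucleus) that is also written as
    ``manifest.csv``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    spacing = VoxelSpacing()
    rows = []
    for patient_id, nucleus_id, ncfg, seed in iter_cohort(config):
        stacks, truth = generate_nucleus(ncfg, spacing, seed=seed, shape=config.shape)
        paths = {}
        for channel, stack in stacks.items():
            path = out_dir / f"{patient_id}_{nucleus_id}_{channel}.tif"
            try:
                write_stack(stack, path)
            except OSError as exc:
                raise OSError(f"failed writing {path}: {exc}") from exc
            paths[channel] = path.name
        gt_path = out_dir / f"{patient_id}_{nucleus_id}_truth.csv"
        truth.to_frame().to_csv(gt_path, index=False)
        rows.append(
            {
                "patient_id": patient_id,
                "sample_id": patient_id,
                "nucleus_id": nucleus_id,
                "phase": config.phase_label,
                "true_n_telomeres": truth.n_signals,
                "true_n_aggregates": truth.n_aggregates,
                "true_volume_um3": truth.nuclear_volume_um3,
                "truth_csv": gt_path.name,
                **{f"{ch.lower()}_tif": name for ch, name in paths.items()},
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "sample_id",
            "nucleus_id",
            "phase",
            "true_n_telomeres",
            "true_n_aggregates",
            "true_volume_um3",
            "truth_csv",
            "dapi_tif",
            "cy3_tif",
            "fitc_tif",
        ],
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# configuration files


_NUCLEUS_KEYS = {f.name for f in dataclasses.fields(SynthNucleusConfig)}
_COHORT_KEYS = {f.name for f in dataclasses.fields(CohortConfig)}
_MIXTURE_KEYS = {f.name for f in dataclasses.fields(IntensityMixture)}


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(_tuplify(v) for v in obj)
    return obj


def cohort_config_from_dict(raw: dict) -> CohortConfig:
    raw = dict(raw)
    unknown = set(raw) - _COHORT_KEYS
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    if "nucleus" in raw:
        nraw = dict(raw["nucleus"])
        unknown = set(nraw) - _NUCLEUS_KEYS
        if unknown:
            raise ValueError(f"unknown nucleus config keys: {sorted(unknown)}")
        if "intensity_mixture" in nraw:
            mraw = dict(nraw["intensity_mixture"])
            unknown = set(mraw) - _MIXTURE_KEYS
            if unknown:
                raise ValueError(f"unknown intensity mixture keys: {sorted(unknown)}")
            nraw["intensity_mixture"] = IntensityMixture(
                **{k: _tuplify(v) for k, v in mraw.items()}
            )
        raw["nucleus"] = SynthNucleusConfig(**{k: _tuplify(v) for k, v in nraw.items()})
    raw = {k: _tuplify(v) for k, v in raw.items()}
    return CohortConfig(**raw)


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Load a cohort configuration from YAML (or JSON) with strict keys."""
    text = Path(path).read_text()
    return cohort_config_from_dict(yaml.safe_load(text))


def packaged_cohort_config(phase: str) -> CohortConfig:
    """The packaged chronic / accelerated_blast cohort calibrations."""
    from importlib.resources import files

    name = {"chronic": "chronic.yaml", "accelerated_blast": "blast.yaml"}[phase]
    return cohort_config_from_dict(yaml.safe_load(files("telo3d.configs").joinpath(name).read_text()))


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass(frozen=True)
class GroupFold:
    """Target 2^-ddCt mean and between-sample SD (fold scale) for one group."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("fold-change mean must be > 0")
        if self.sd < 0:
            raise ValueError("fold-change sd must be >= 0")


@dataclass(frozen=True)
class CtGeneratorConfig:
    """Generator for comparative-Ct tables.

    Per-sample fold changes are drawn on the 2^-ddCt scale, converted to a
    target-gene ddCt offset over a gene-specific baseline dCt, and emitted as
    technical duplicates against a GAPDH reference around ``baseline_ref_ct``.
    """

    folds: dict[str, dict[str, GroupFold]] = field(
        default_factory=lambda: {
            "AURKA": {
                "healthy": GroupFold(1.0, 0.10),
                "chronic": GroupFold(2.85, 0.20),
                "accelerated_blast": GroupFold(4.12, 0.22),
            },
            "AURKB": {
                "healthy": GroupFold(1.0, 0.08),
                "chronic": GroupFold(2.62, 0.12),
                "accelerated_blast": GroupFold(3.02, 0.21),
            },
        }
    )
    reference_gene: str = "GAPDH"
    n_samples_per_group: int = 8
    baseline_ref_ct: float = 20.0
    baseline_delta_ct: dict[str, float] = field(
        default_factory=lambda: {"AURKA": 5.0, "AURKB": 6.0}
    )
    ref_ct_sd: float = 0.3
    technical_sd: float = 0.05
    n_replicates: int = 2
    rng_seed: int = 42

    def __post_init__(self) -> None:
        for gene, groups in self.folds.items():
            if gene not in GENES:
                raise ValueError(f"unknown gene {gene!r}; expected one of {GENES}")
            for group in groups:
                if group not in GROUPS:
                    raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        if self.n_replicates < 1:
            raise ValueError("need at least one technical replicate")


def generate_ct_table(config: CtGeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Emit a long-format Ct table (one row per sample x gene x replicate).

    With fold sd = 0 and technical_sd = 0 the recovered per-sample 2^-ddCt is
    exactly the configured group mean; otherwise the expected group mean
    equals the configured fold change.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    rows = []
    for gene in sorted(config.folds):
        base_dct = config.baseline_delta_ct.get(gene, 5.0)
        for group in sorted(config.folds[gene], key=GROUPS.index):
            fold_cfg = config.folds[gene][group]
            for s in range(config.n_samples_per_group):
                fold = fold_cfg.mean if fold_cfg.sd == 0 else rng.normal(fold_cfg.mean, fold_cfg.sd)
                fold = max(fold, 1e-3)
                ddct = -np.log2(fold)
                ref_ct = config.baseline_ref_ct + (
                    rng.normal(0.0, config.ref_ct_sd) if config.ref_ct_sd > 0 else 0.0
                )
                dct = base_dct + ddct
                for rep in range(config.n_replicates):
                    tnoise = (
                        rng.normal(0.0, config.technical_sd, size=2)
                        if config.technical_sd > 0
                        else np.zeros(2)
                    )
                    rows.append(
                        {
                            "sample_id": f"{group}_{s + 1:02d}",
                            "group": group,
                            "gene": gene,
                            "replicate": rep + 1,
                            "ct_target": ref_ct + dct + tnoise[0],
                            "ct_reference": ref_ct + tnoise[1],
                        }
                    )
    return pd.DataFrame(rows)


def packaged_ct_config() -> CtGeneratorConfig:
    """Default qPCR fixture: folds calibrated to the reported AURKA/AURKB values."""
    return CtGeneratorConfig()
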