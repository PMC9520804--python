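"""Segmentation, CD34 gating, spot detection, aggregates, radial position."""

from __future__ import annotations

import numpy as np
import pytest

from telo3d.quantify import (
    NoNucleusError,
    NucleusMask,
    SpotDetectionParams,
    TelomereSignal,
    call_aggregates,
    classify_cd34,
    detect_spots,
    radial_position,
    segment_nucleus,
)
from telo3d.simulate import VoxelSpacing, _ellipsoid_interior, _render_spots, generate_nucleus
from telo3d.stacks import ImageStack3D

from conftest import clean_nucleus_config, single_component_mixture

SPACING = VoxelSpacing()


def ellipsoid_stack(semi_axes, shape=(60, 128, 128), level=100.0, channel="DAPI"):
    center = (np.array(shape) - 1) * SPACING.zyx / 2
    interior = _ellipsoid_interior(shape, SPACING, center, semi_axes)
    return ImageStack3D(np.where(interior, level, 0.0).astype(np.float32), SPACING, channel)


def spot_stack(positions_nm, intensities, shape=(60, 128, 128), background=20.0):
    img = _render_spots(shape, SPACING, np.asarray(positions_nm, float),
                        np.asarray(intensities, float), (150.0, 150.0, 300.0))
    return ImageStack3D((img + background).astype(np.float32), SPACING, "Cy3")


def full_mask(shape=(60, 128, 128)):
    return NucleusMask(np.ones(shape, bool), SPACING)


class TestSegmentNucleus:
    @pytest.mark.parametrize(
        "semi_axes,shape",
        [
            ((5000.0, 4000.0, 3000.0), (60, 128, 128)),
            ((2000.0, 2000.0, 2000.0), (60, 128, 128)),
            ((8000.0, 6000.0, 4000.0), (90, 176, 176)),
        ],
    )
    def test_volume_within_5pct_of_analytic_ellipsoid(self, semi_axes, shape):
        a, b, c = semi_axes
        analytic = 4 / 3 * np.pi * a * b * c * 1e-9
        mask = segment_nucleus(ellipsoid_stack(semi_axes, shape))
        assert mask.volume_um3 == pytest.approx(analytic, rel=0.05)

    def test_all_zero_stack_raises_no_nucleus(self):
        stack = ImageStack3D(np.zeros((20, 32, 32), np.float32), SPACING, "DAPI")
        with pytest.raises(NoNucleusError, match="no nucleus found"):
            segment_nucleus(stack)

    def test_two_blobs_keeps_the_larger(self):
        shape = (60, 200, 128)
        img = np.zeros(shape, np.float32)
        big = _ellipsoid_interior(shape, SPACING, np.array([6000.0, 5000.0, 6500.0]),
                                  (4000.0, 3000.0, 2500.0))
        small = _ellipsoid_interior(shape, SPACING, np.array([6000.0, 15000.0, 6500.0]),
                                    (3175.0, 2381.0, 1984.0))  # half the volume
        img[big] = 100.0
        img[small] = 100.0
        mask = segment_nucleus(ImageStack3D(img, SPACING, "DAPI"))
        frac_small = (mask.mask & small).sum() / small.sum()
        assert (mask.mask & big).sum() / big.sum() > 0.95
        assert frac_small < 0.01

    def test_noisy_simulated_nucleus_volume_matches_truth(self):
        cfg = clean_nucleus_config(noise_sd=2.0)
        stacks, truth = generate_nucleus(cfg, seed=11)
        mask = segment_nucleus(stacks["DAPI"])
        assert mask.volume_um3 == pytest.approx(truth.nuclear_volume_um3, rel=0.05)


class TestClassifyCd34:
    def test_boundary_is_inclusive(self):
        stack = ImageStack3D(np.full((10, 16, 16), 30.0, np.float32), SPACING, "FITC")
        assert classify_cd34(stack, full_mask((10, 16, 16)), threshold=30.0)

    def test_zero_fitc_is_negative(self):
        stack = ImageStack3D(np.zeros((10, 16, 16), np.float32), SPACING, "FITC")
        assert not classify_cd34(stack, full_mask((10, 16, 16)), threshold=5.0)

    @pytest.mark.parametrize("positive", [True, False])
    def test_simulated_pair_classified_correctly(self, positive):
        cfg = clean_nucleus_config(cd34_positive=positive)
        stacks, _ = generate_nucleus(cfg, seed=12)
        mask = segment_nucleus(stacks["DAPI"])
        assert classify_cd34(stacks["FITC"], mask, threshold=30.0) is positive


def grid_positions(n, shape=(60, 128, 128), spacing_nm=2500.0):
    """Well-separated lattice positions in the stack interior."""
    extent = (np.array(shape) - 1) * SPACING.zyx
    pos = []
    per_axis = int(np.ceil(n ** (1 / 3)))
    for i in range(per_axis):
        for j in range(per_axis):
            for k in range(per_axis):
                if len(pos) < n:
                    pos.append(
                        extent / 2
                        + (np.array([i, j, k]) - (per_axis - 1) / 2) * spacing_nm
                    )
    return np.array(pos)


class TestDetectSpots:
    def test_ten_spots_at_snr10_all_found_within_one_voxel(self):
        pos = grid_positions(10)
        stack = spot_stack(pos, np.full(10, 1000.0))
        noisy = ImageStack3D(
            np.clip(stack.voxels + np.random.default_rng(0).normal(0, 2.0, stack.shape), 0, None
                    ).astype(np.float32),
            SPACING, "Cy3",
        )
        signals = detect_spots(noisy, full_mask())
        assert len(signals) == 10
        found = np.array([s.centroid_nm for s in signals])
        for p in pos:
            d = np.abs(found - p).min(axis=0)
            assert np.all(np.abs(found - p).sum(1).min() < 300)
            nearest = found[np.linalg.norm(found - p, axis=1).argmin()]
            assert np.all(np.abs(nearest - p) <= SPACING.zyx)

    def test_blank_channel_yields_no_detections(self):
        stack = ImageStack3D(np.full((60, 128, 128), 20.0, np.float32), SPACING, "Cy3")
        assert detect_spots(stack, full_mask()) == []

    def test_intensity_ratio_two_to_one_within_5pct(self):
        pos = np.array([[6000.0, 4000.0, 4000.0], [6000.0, 9000.0, 9000.0]])
        stack = spot_stack(pos, [1000.0, 2000.0])
        signals = detect_spots(stack, full_mask())
        assert len(signals) == 2
        ii = sorted(s.integrated_intensity for s in signals)
        assert ii[1] / ii[0] == pytest.approx(2.0, rel=0.05)

    def test_measured_intensity_linear_in_truth(self):
        ladder = np.array([250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0])
        pos = grid_positions(len(ladder), spacing_nm=3500.0)
        stack = spot_stack(pos, ladder)
        signals = detect_spots(stack, full_mask())
        assert len(signals) == len(ladder)
        measured = np.array(sorted(s.integrated_intensity for s in signals))
        r = np.corrcoef(measured, np.sort(ladder))[0, 1]
        assert r**2 >= 0.99

    def test_lateral_axis_permutation_leaves_outputs_unchanged(self):
        cfg = clean_nucleus_config(
            semi_axes=(3500.0, 3500.0, 2500.0), n_telomeres=(15, 0.0), noise_sd=0.0
        )
        stacks, _ = generate_nucleus(cfg, seed=13)
        mask = segment_nucleus(stacks["DAPI"])
        sig = detect_spots(stacks["Cy3"], mask)
        swapped = ImageStack3D(
            np.ascontiguousarray(stacks["Cy3"].voxels.transpose(0, 2, 1)), SPACING, "Cy3"
        )
        mask_sw = NucleusMask(np.ascontiguousarray(mask.mask.transpose(0, 2, 1)), SPACING)
        sig_sw = detect_spots(swapped, mask_sw)
        assert len(sig) == len(sig_sw)
        a = sorted(round(s.integrated_intensity, 3) for s in sig)
        b = sorted(round(s.integrated_intensity, 3) for s in sig_sw)
        assert a == pytest.approx(b, rel=1e-5)


class TestCallAggregates:
    def test_unresolvable_pair_flagged_via_intensity(self):
        # one pair 150 nm apart plus 8 context singles: the fused detection
        # carries twice the median intensity and is called an aggregate
        singles = grid_positions(8, spacing_nm=3200.0)
        pair_center = np.array([3000.0, 2500.0, 2500.0])
        members = [pair_center + [0, 0, -75.0], pair_center + [0, 0, 75.0]]
        stack = spot_stack(np.vstack([singles, members]), np.full(10, 1000.0))
        signals = detect_spots(stack, full_mask())
        signals, n_agg = call_aggregates(signals)
        assert len(signals) == 9
        assert n_agg == 1
        brightest = max(signals, key=lambda s: s.integrated_intensity)
        assert brightest.is_aggregate
        assert np.abs(np.array(brightest.centroid_nm) - pair_center).max() < 300

    def test_well_separated_unit_spots_have_no_aggregates(self):
        signals = [
            TelomereSignal((0.0, 0.0, i * 2000.0), 1.0) for i in range(6)
        ]
        flagged, n_agg = call_aggregates(signals)
        assert n_agg == 0
        assert not any(s.is_aggregate for s in flagged)

    def test_simulated_nucleus_recovers_four_aggregates(self):
        cfg = clean_nucleus_config(
            n_telomeres=(20, 0.0), n_aggregates=(4, 0.0), noise_sd=2.0
        )
        stacks, truth = generate_nucleus(cfg, seed=14)
        assert truth.n_aggregates == 4
        mask = segment_nucleus(stacks["DAPI"])
        signals = detect_spots(stacks["Cy3"], mask)
        _, n_agg = call_aggregates(signals)
        assert abs(n_agg - 4) <= 1

    def test_empty_input(self):
        assert call_aggregates([]) == ([], 0)


class TestRadialPosition:
    def test_center_is_zero_and_boundary_is_one(self):
        iso = VoxelSpacing(100.0, 100.0, 100.0)
        shape = (81, 81, 81)
        center = (np.array(shape) - 1) * iso.zyx / 2
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        r2 = ((zz - 40) ** 2 + (yy - 40) ** 2 + (xx - 40) ** 2) * 100.0**2
        mask = NucleusMask(r2 <= 3500.0**2, iso)
        at_center = TelomereSignal(tuple(center), 1.0)
        assert radial_position(at_center, mask) == 0.0
        near_edge = TelomereSignal(tuple(center + [0.0, 0.0, 3400.0]), 1.0)
        assert radial_position(near_edge, mask) == pytest.approx(1.0, abs=0.05)

    def test_outside_mask_is_an_error(self):
        iso = VoxelSpacing(100.0, 100.0, 100.0)
        mask = NucleusMask(np.zeros((21, 21, 21), bool), iso)
        mask.mask[8:13, 8:13, 8:13] = True
        with pytest.raises(ValueError, match="outside"):
            radial_position(TelomereSignal((100.0, 100.0, 100.0), 1.0), mask)

    def test_uniform_ball_mean_radial_is_three_quarters(self):
        # E[r/R] = 3/4 for uniform points in a ball (integral of 3r^3 dr)
        iso = VoxelSpacing(100.0, 100.0, 100.0)
        shape = (81, 81, 81)
        center = (np.array(shape) - 1) * iso.zyx / 2
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        r2 = ((zz - 40) ** 2 + (yy - 40) ** 2 + (xx - 40) ** 2) * 100.0**2
        mask = NucleusMask(r2 <= 3600.0**2, iso)
        rng = np.random.default_rng(15)
        u = rng.normal(size=(500, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = center + u * (rng.uniform(size=(500, 1)) ** (1 / 3)) * 3500.0
        vals = [radial_position(TelomereSignal(tuple(p), 1.0), mask) for p in pts]
        assert np.mean(vals) * 3600.0 / 3500.0 == pytest.approx(0.75, abs=0.03)


class TestRecallPrecision:
    def test_detection_recall_and_precision_on_synthetic_nuclei(self):
        """>= 0.95 recall and precision at SNR >= 8 with well-separated spots."""
        hits = total_true = total_det = 0
        for seed in range(6):
            cfg = clean_nucleus_config(
                n_telomeres=(30, 0.0),
                intensity_mixture=single_component_mixture(850.0),  # peak ~ 16.6, SNR ~ 8.3
                noise_sd=2.0,
            )
            stacks, truth = generate_nucleus(cfg, seed=seed)
            mask = segment_nucleus(stacks["DAPI"])
            signals = detect_spots(stacks["Cy3"], mask)
            det = np.array([s.centroid_nm for s in signals]).reshape(-1, 3)
            total_true += truth.n_signals
            total_det += len(det)
            for p in truth.signal_positions:
                if len(det) and np.linalg.norm(det - p, axis=1).min() < 300.0:
                    hits += 1
        assert hits / total_true >= 0.95
        assert hits / max(total_det, 1) >= 0.95
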