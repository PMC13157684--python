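import numpy as np
import pytest

from fmripulse.io import FMRIScan, ROIMask, slice_offsets_from_params
from fmripulse.hypersample import (
    build_timing_table,
    detrend_linear,
    hypersample_roi,
    interleave,
    slice_group_signals,
)
from fmripulse.phantom import generate_phantom
from fmripulse.spectra import alias_frequency, periodogram_psd
from conftest import single_component_spec


class TestTimingTable:
    @pytest.mark.parametrize(
        "n_slices,mb,expected", [(72, 8, 9), (40, 8, 5), (16, 16, 1)]
    )
    def test_n_time_is_slices_over_mb(self, n_slices, mb, expected):
        table = build_timing_table(n_slices=n_slices, mb_factor=mb, tr_s=0.8)
        assert table.n_time == expected
        assert table.dt_s == pytest.approx(0.8 / expected)
        assert table.nyquist_hz == pytest.approx(expected / 1.6)

    def test_non_divisible_parameters_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_timing_table(n_slices=40, mb_factor=7, tr_s=0.8)

    def test_groups_from_scan_offsets_with_tolerance(self):
        offsets = slice_offsets_from_params(8, 2, 0.8)
        offsets = offsets + np.tile([0.0, 0.0004], 4)  # sub-tolerance jitter
        scan = FMRIScan(
            data=np.zeros((2, 2, 8, 4)), tr_s=0.8, slice_offsets_s=offsets
        )
        table = build_timing_table(scan)
        assert table.n_time == 4
        assert np.all(np.bincount(table.group_of_slice) == 2)

    def test_unequal_group_sizes_warn_not_error(self):
        offsets = np.array([0.0, 0.0, 0.0, 0.4])
        scan = FMRIScan(
            data=np.zeros((1, 1, 4, 4)), tr_s=0.8, slice_offsets_s=offsets
        )
        with pytest.warns(UserWarning, match="unequal"):
            table = build_timing_table(scan)
        assert table.n_time == 2


class TestDetrend:
    def test_line_maps_to_zeros(self):
        t = np.arange(50.0)
        np.testing.assert_allclose(detrend_linear(2 + 3 * t), 0.0, atol=1e-9)

    def test_integer_period_sinusoid_essentially_unchanged(self):
        n = 200
        # a cosine even about the sampling midpoint is discretely orthogonal
        # to both the constant and the ramp, so detrend is an exact no-op
        centered = np.cos(2 * np.pi * 5 * (np.arange(n) - (n - 1) / 2) / n)
        np.testing.assert_allclose(detrend_linear(centered), centered, atol=1e-9)
        # at arbitrary phase detrending removes exactly a straight line
        x = np.sin(2 * np.pi * 5 * np.arange(n) / n)
        removed = x - detrend_linear(x)
        np.testing.assert_allclose(np.diff(removed, 2), 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        t = np.arange(101.0)
        x = np.sin(0.3 * t) + 0.05 * t + rng.normal(size=t.size)
        design = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(design.T @ design, design.T @ x)
        np.testing.assert_allclose(
            detrend_linear(x), x - design @ beta, atol=1e-9
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            detrend_linear(np.array([1.0, 2.0]))


class TestSliceGroupSignals:
    def test_single_voxel_roi(self):
        spec = single_component_spec(1.0, noise_sd=0.3, n_volumes=32)
        scan, _, _, _ = generate_phantom(spec)
        table = build_timing_table(scan)
        mask = np.zeros(spec.shape, dtype=bool)
        mask[1, 2, 5] = True
        signals, valid, counts = slice_group_signals(
            scan, ROIMask(mask, "custom"), table
        )
        g = table.group_of_slice[5]
        np.testing.assert_allclose(
            signals[g], detrend_linear(scan.data[1, 2, 5].astype(float)), atol=1e-12
        )
        assert valid.sum() == 1 and counts[g] == 1

    def test_noiseless_phantom_matches_generative_formula(self):
        spec = single_component_spec(0.7, slice_baseline=0.0, n_volumes=48)
        scan, _, _, _ = generate_phantom(spec)
        table = build_timing_table(scan)
        mask = ROIMask(np.ones(spec.shape, bool), "custom")
        signals, valid, _ = slice_group_signals(scan, mask, table)
        k = np.arange(spec.n_volumes)
        for g in range(table.n_time):
            expected = detrend_linear(
                np.sin(2 * np.pi * 0.7 * (k * spec.tr_s + table.offsets_s[g]))
            )
            np.testing.assert_allclose(signals[g], expected, atol=1e-9)

    def test_constant_offset_between_voxels_vanishes(self):
        spec = single_component_spec(1.0, n_volumes=24)
        scan, _, _, _ = generate_phantom(spec)
        scan.data[0, 0, 0] += 17.0  # add constant c to one voxel
        table = build_timing_table(scan)
        mask = np.zeros(spec.shape, dtype=bool)
        mask[0, 0, 0] = mask[0, 1, 0] = True
        signals, _, _ = slice_group_signals(scan, ROIMask(mask, "custom"), table)
        g = table.group_of_slice[0]
        np.testing.assert_allclose(
            signals[g],
            detrend_linear(scan.data[0, 1, 0].astype(float)),
            atol=1e-9,
        )

    def test_empty_roi_rejected(self):
        spec = single_component_spec(1.0, n_volumes=8)
        scan, _, _, _ = generate_phantom(spec)
        with pytest.raises(ValueError):
            ROIMask(np.zeros(spec.shape, bool), "custom")


class TestInterleave:
    def test_degenerate_n_time_one_is_roi_mean(self):
        spec = single_component_spec(0.4, mb_factor=8, n_volumes=32)
        scan, _, masks, _ = generate_phantom(spec)
        table = build_timing_table(scan)
        assert table.n_time == 1
        sig = hypersample_roi(scan, masks["roi"], table)
        expected = detrend_linear(scan.data[masks["roi"].mask].mean(axis=0))
        np.testing.assert_allclose(sig.values, expected, atol=1e-9)
        assert sig.fs_hz == pytest.approx(1 / spec.tr_s)

    def test_sample_placement_volume_major(self):
        table = build_timing_table(n_slices=6, mb_factor=2, tr_s=0.6)
        groups = np.arange(12, dtype=float).reshape(3, 4)  # group j, volume k
        sig = interleave(groups, table)
        expected = groups.T.reshape(-1)  # k*n_time + j ordering
        np.testing.assert_array_equal(sig.values, expected)
        assert sig.valid.all() and sig.coverage == 3

    def test_unaliasing_above_per_volume_nyquist(self, hcp_cardiac_phantom):
        spec, scan, _, masks, _ = hcp_cardiac_phantom
        table = build_timing_table(scan)
        sig = hypersample_roi(scan, masks["roi"], table)
        hyper = periodogram_psd(sig.values, sig.fs_hz)
        f_peak = hyper.freqs_hz[np.argmax(hyper.psd)]
        assert f_peak == pytest.approx(1.1, abs=hyper.df_hz)
        # per-volume sampling aliases the same oscillation
        volume_series = detrend_linear(scan.data[masks["roi"].mask].mean(axis=0))
        pervol = periodogram_psd(volume_series, 1 / spec.tr_s)
        f_alias = pervol.freqs_hz[np.argmax(pervol.psd)]
        assert f_alias == pytest.approx(
            alias_frequency(1.1, 1 / spec.tr_s), abs=pervol.df_hz
        )

    def test_nonuniform_offsets_warn(self):
        offsets = np.array([0.0, 0.15, 0.4, 0.6])  # 0.15 deviates from 0.2 grid
        scan = FMRIScan(
            data=np.random.default_rng(0).normal(size=(1, 1, 4, 8)),
            tr_s=0.8,
            slice_offsets_s=offsets,
        )
        table = build_timing_table(scan)
        with pytest.warns(UserWarning, match="deviate"):
            hypersample_roi(scan, ROIMask(np.ones((1, 1, 4), bool), "custom"), table)


class TestHypersampleRoi:
    def _nine_group_scan(self, covered_groups):
        spec = single_component_spec(
            1.0, shape=(2, 2, 72), tr_s=0.8, n_volumes=40, mb_factor=8
        )
        scan, _, _, _ = generate_phantom(spec)
        table = build_timing_table(scan)
        mask = np.zeros(spec.shape, dtype=bool)
        for g in covered_groups:
            mask[:, :, np.flatnonzero(table.group_of_slice == g)[0]] = True
        return scan, table, ROIMask(mask, "artery")

    def test_four_of_nine_groups_is_insufficient_coverage(self):
        scan, table, mask = self._nine_group_scan(range(4))
        with pytest.raises(ValueError, match="insufficient slice-timing coverage"):
            hypersample_roi(scan, mask, table)

    def test_five_of_nine_groups_interpolates_gaps(self):
        scan, table, mask = self._nine_group_scan(range(5))
        sig = hypersample_roi(scan, mask, table, gap_policy="interpolate")
        assert sig.coverage == 5 and sig.interpolated
        assert not sig.valid.all()
        # gap values equal explicit linear interpolation over valid samples
        idx = np.arange(sig.values.size)
        expected = np.interp(
            idx[~sig.valid], idx[sig.valid], sig.values[sig.valid]
        )
        np.testing.assert_allclose(sig.values[~sig.valid], expected, atol=1e-12)

    def test_strict_policy_errors_on_gaps(self):
        scan, table, mask = self._nine_group_scan(range(5))
        with pytest.raises(ValueError, match="strict"):
            hypersample_roi(scan, mask, table, gap_policy="strict")

    def test_zero_policy_fills_zeros(self):
        scan, table, mask = self._nine_group_scan(range(5))
        sig = hypersample_roi(scan, mask, table, gap_policy="zero")
        assert np.all(sig.values[~sig.valid] == 0)

    def test_full_coverage_identical_to_interleave(self):
        spec = single_component_spec(1.0, noise_sd=0.1, n_volumes=24)
        scan, _, masks, _ = generate_phantom(spec)
        table = build_timing_table(scan)
        signals, valid, _ = slice_group_signals(scan, masks["roi"], table)
        np.testing.assert_array_equal(
            hypersample_roi(scan, masks["roi"], table).values,
            interleave(signals, table, valid).values,
        )


class TestAlgebraicProperties:
    def test_linearity_of_hypersampling(self):
        spec1 = single_component_spec(1.0, noise_sd=0.2, seed=1, n_volumes=24)
        spec2 = single_component_spec(0.3, noise_sd=0.2, seed=2, n_volumes=24)
        s1, _, masks, _ = generate_phantom(spec1)
        s2, _, _, _ = generate_phantom(spec2)
        table = build_timing_table(s1)
        combined = FMRIScan(
            data=2.0 * s1.data - 0.5 * s2.data,
            tr_s=s1.tr_s,
            slice_offsets_s=s1.slice_offsets_s,
        )
        h1 = hypersample_roi(s1, masks["roi"], table).values
        h2 = hypersample_roi(s2, masks["roi"], table).values
        hc = hypersample_roi(combined, masks["roi"], table).values
        np.testing.assert_allclose(hc, 2.0 * h1 - 0.5 * h2, atol=1e-9)

    def test_detrend_commutes_with_averaging(self):
        rng = np.random.default_rng(5)
        voxels = rng.normal(size=(30, 100)) + np.linspace(0, 3, 100)
        mean_then_detrend = detrend_linear(voxels.mean(axis=0))
        detrend_then_mean = detrend_linear(voxels).mean(axis=0)
        np.testing.assert_allclose(mean_then_detrend, detrend_then_mean, atol=1e-9)

    def test_incoherent_phases_are_suppressed_by_averaging(self):
        # each voxel gets an independent uniform phase: every stitched sample
        # averages the V/n_time voxels of one timing group, so the retained
        # power is ~1/(V/n_time) of the coherent case in expectation
        shape, tr, n_vol, mb = (6, 6, 8), 0.8, 128, 2
        offsets = slice_offsets_from_params(shape[2], mb, tr)
        k = np.arange(n_vol)
        table = None
        variances = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            data = np.empty(shape + (n_vol,))
            for x, y, z in np.ndindex(*shape):
                phi = rng.uniform(0, 2 * np.pi)
                data[x, y, z] = np.sin(2 * np.pi * 1.0 * (k * tr + offsets[z]) - phi)
            scan = FMRIScan(data=data, tr_s=tr, slice_offsets_s=offsets)
            table = build_timing_table(scan)
            mask = ROIMask(np.ones(shape, bool), "custom")
            variances.append(np.var(hypersample_roi(scan, mask, table).values))
        incoherent = np.mean(variances)
        coherent_spec = single_component_spec(
            1.0, shape=shape, tr_s=tr, n_volumes=n_vol, mb_factor=mb
        )
        cscan, _, cmasks, _ = generate_phantom(coherent_spec)
        coherent = np.var(hypersample_roi(cscan, cmasks["roi"], table).values)
        voxels_per_group = np.prod(shape) / table.n_time
        assert incoherent < coherent / 20.0  # strong suppression
        assert incoherent == pytest.approx(coherent / voxels_per_group, rel=1.0)
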