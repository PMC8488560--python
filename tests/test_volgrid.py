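"""Voxel-grid core: MRC round-trips, filtering, profiles, masks, FSC."""

import numpy as np
import pytest
from scipy import ndimage

from cryodiff import (
    MaskSpec,
    VoxelGrid,
    fsc,
    lowpass_filter,
    make_mask,
    radial_amplitude_profile,
    read_map,
    scale_to_reference,
    write_map,
)
from cryodiff.volgrid import MapFormatError, _ball


# --------------------------------------------------------------------------
# independent oracles

def brute_radial_profile(data, voxel_size):
    """Loop over Fourier voxels grouping by integer-rounded radius."""
    n = data.shape[0]
    ft = np.fft.fftn(data)
    shells = {}
    for i in range(n):
        for j in range(n):
            for k in range(n):
                fi = i if i <= n // 2 else i - n
                fj = j if j <= n // 2 else j - n
                fk = k if k <= n // 2 else k - n
                s = int(round(np.sqrt(fi * fi + fj * fj + fk * fk)))
                if s <= n // 2:
                    shells.setdefault(s, []).append(abs(ft[i, j, k]))
    mean = np.zeros(n // 2 + 1)
    for s, vals in shells.items():
        mean[s] = np.mean(vals)
    return mean


def brute_lowpass(data, voxel_size, cutoff_A, edge_shells):
    """Explicit DFT-multiply-inverse with an independently built multiplier."""
    n = data.shape[0]
    j = np.arange(n)
    w = np.exp(-2j * np.pi * np.outer(j, j) / n)
    ft = np.einsum("ia,jb,kc,abc->ijk", w, w, w, data)
    r_c = n * voxel_size / cutoff_A
    h = np.zeros((n, n, n))
    for i in range(n):
        for jj in range(n):
            for k in range(n):
                fi = i if i <= n // 2 else i - n
                fj = jj if jj <= n // 2 else jj - n
                fk = k if k <= n // 2 else k - n
                r = round(np.sqrt(fi * fi + fj * fj + fk * fk))
                if r <= r_c:
                    h[i, jj, k] = 1.0
                elif r < r_c + edge_shells:
                    h[i, jj, k] = 0.5 * (1 + np.cos(np.pi * (r - r_c) / edge_shells))
    winv = np.conj(w) / n
    return np.einsum("ia,jb,kc,abc->ijk", winv, winv, winv, ft * h).real


# --------------------------------------------------------------------------
# VoxelGrid basics and MRC I/O

class TestVoxelGrid:
    def test_stats_degenerate(self):
        g = VoxelGrid(np.zeros((4, 4, 4)), 1.0)
        assert g.mean == 0.0 and g.sigma == 0.0

    def test_stats_single_hot_voxel(self):
        data = np.zeros((2, 2, 2))
        data[0, 0, 0] = 1.0
        g = VoxelGrid(data, 1.0)
        assert g.mean == pytest.approx(0.125)
        assert g.sigma == pytest.approx(np.sqrt(0.125 - 0.125**2), abs=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            VoxelGrid(np.zeros((4, 4)), 1.0)
        with pytest.raises(ValueError):
            VoxelGrid(np.zeros((4, 4, 4)), -1.0)
        with pytest.raises(ValueError):
            VoxelGrid(np.full((4, 4, 4), np.nan), 1.0)

    def test_mrc_roundtrip(self, tmp_path, rng):
        data = rng.standard_normal((8, 8, 8)).astype(np.float32)
        g = VoxelGrid(data, 2.0, origin=(4.0, -2.0, 8.0))
        path = tmp_path / "g.mrc"
        write_map(g, path)
        back = read_map(path)
        # bit-compatible for float32 volumes
        np.testing.assert_array_equal(back.data, data.astype(np.float64))
        assert back.voxel_size == pytest.approx(2.0)
        np.testing.assert_allclose(back.origin, g.origin)

    def test_mrc_roundtrip_nonconstant_shape(self, tmp_path, rng):
        data = rng.standard_normal((6, 8, 10))
        g = VoxelGrid(data, 1.5)
        write_map(g, tmp_path / "g.mrc")
        back = read_map(tmp_path / "g.mrc")
        np.testing.assert_allclose(back.data, data, atol=1e-6)
        assert back.shape == (6, 8, 10)

    def test_read_rejects_garbage(self, tmp_path):
        bad = tmp_path / "bad.mrc"
        bad.write_bytes(b"not an mrc file")
        with pytest.raises(MapFormatError):
            read_map(bad)


# --------------------------------------------------------------------------
# low-pass filter

class TestLowpass:
    def test_constant_grid_unchanged(self):
        g = VoxelGrid(np.full((16, 16, 16), 3.5), 2.0)
        out = lowpass_filter(g, 11.0)
        np.testing.assert_allclose(out.data, g.data, atol=1e-9)

    def test_high_frequency_removed(self):
        # pure sinusoid of 4 A wavelength on a 2 A grid; cutoff 11 A
        n, vs = 32, 1.0
        x = np.arange(n) * vs
        wave = np.sin(2 * np.pi * x / 4.0)
        g = VoxelGrid(np.broadcast_to(wave[:, None, None], (n, n, n)).copy(), vs)
        out = lowpass_filter(g, 11.0)
        assert np.abs(out.data).max() <= 1e-6 * np.abs(g.data).max()

    def test_matches_brute_force_dft(self, blob_grid):
        out = lowpass_filter(blob_grid, 12.0, edge_width_shells=3.0)
        expected = brute_lowpass(blob_grid.data, blob_grid.voxel_size, 12.0, 3.0)
        np.testing.assert_allclose(out.data, expected, atol=1e-8)

    def test_mean_preserved(self, random_grid):
        out = lowpass_filter(random_grid, 10.0)
        assert out.mean == pytest.approx(random_grid.mean, abs=1e-10)

    def test_rejects_cutoff_beyond_nyquist(self, random_grid):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(random_grid, 3.9)  # Nyquist is 4.0 A here


# --------------------------------------------------------------------------
# radial amplitude profile and scaling

class TestRadialProfile:
    def test_zero_grid(self):
        p = radial_amplitude_profile(VoxelGrid(np.zeros((8, 8, 8)), 1.0))
        assert np.all(p.mean_amplitude == 0)
        assert p.shell_count[0] == 1

    def test_constant_grid_dc_only(self):
        c, n = 2.5, 8
        p = radial_amplitude_profile(VoxelGrid(np.full((n, n, n), c), 1.0))
        assert p.mean_amplitude[0] == pytest.approx(c * n**3)
        assert np.all(p.mean_amplitude[1:] < 1e-9)

    def test_matches_brute_force_shells(self, rng):
        data = rng.standard_normal((8, 8, 8))
        g = VoxelGrid(data, 2.0)
        p = radial_amplitude_profile(g)
        expected = brute_radial_profile(data, 2.0)
        np.testing.assert_allclose(p.mean_amplitude, expected, atol=1e-8)

    def test_shell_frequencies(self):
        g = VoxelGrid(np.zeros((16, 16, 16)), 2.0)
        p = radial_amplitude_profile(g)
        assert p.n_shells == 9
        assert p.shell_frequency[1] == pytest.approx(1.0 / 32.0)


class TestScaleToReference:
    def test_self_scaling_identity(self, blob_grid):
        p = radial_amplitude_profile(blob_grid)
        out = scale_to_reference(blob_grid, p)
        np.testing.assert_allclose(out.data, blob_grid.data,
                                   atol=1e-6 * np.abs(blob_grid.data).max())

    def test_double_amplitude_halved(self, blob_grid):
        ref_profile = radial_amplitude_profile(blob_grid)
        doubled = blob_grid.with_data(2.0 * blob_grid.data)
        out = scale_to_reference(doubled, ref_profile)
        np.testing.assert_allclose(out.data, blob_grid.data,
                                   atol=1e-6 * np.abs(blob_grid.data).max())

    def test_restores_attenuated_profile(self, blob_grid):
        from cryodiff import apply_radial_attenuation

        ref_profile = radial_amplitude_profile(blob_grid)
        attenuated = apply_radial_attenuation(blob_grid, 200.0)
        rescaled = scale_to_reference(attenuated, ref_profile)
        out_profile = radial_amplitude_profile(rescaled)
        scaled = ~np.isin(np.arange(out_profile.n_shells),
                          getattr(rescaled, "scaling_skipped", []))
        np.testing.assert_allclose(
            out_profile.mean_amplitude[scaled],
            ref_profile.mean_amplitude[scaled],
            rtol=1e-6,
        )

    def test_fixed_factors_commute_with_lowpass(self, random_grid, rng):
        # with the per-shell factors held fixed, scaling and filtering are
        # both radial Fourier multipliers and commute exactly
        from cryodiff.volgrid import apply_shell_factors

        factors = rng.uniform(0.5, 2.0, size=9)
        a = lowpass_filter(apply_shell_factors(random_grid, factors), 10.0)
        b = apply_shell_factors(lowpass_filter(random_grid, 10.0), factors)
        np.testing.assert_allclose(a.data, b.data, atol=1e-6)

    def test_geometry_mismatch_rejected(self, blob_grid):
        p = radial_amplitude_profile(blob_grid)
        small = VoxelGrid(np.zeros((8, 8, 8)), 2.0)
        with pytest.raises(ValueError, match="mismatch"):
            scale_to_reference(small, p)


# --------------------------------------------------------------------------
# masks

class TestMakeMask:
    def test_threshold_above_max_empty(self, blob_grid):
        k = (blob_grid.data.max() - blob_grid.mean) / blob_grid.sigma + 1.0
        mask = make_mask(blob_grid, MaskSpec(sigma_threshold=k, extend_px=0,
                                             soften_px=0))
        assert np.all(mask.data == 0)

    def test_threshold_below_min_full(self, blob_grid):
        k = (blob_grid.data.min() - blob_grid.mean) / blob_grid.sigma - 1.0
        mask = make_mask(blob_grid, MaskSpec(sigma_threshold=k, extend_px=0,
                                             soften_px=0))
        assert np.all(mask.data == 1)

    def test_dilation_matches_set_oracle(self, blob_grid):
        spec = MaskSpec(sigma_threshold=3.0, extend_px=2, soften_px=0)
        mask = make_mask(blob_grid, spec)
        # brute force: threshold then mark every voxel within radius 2
        level = blob_grid.mean + 3.0 * blob_grid.sigma
        binary = blob_grid.data >= level
        expected = ndimage.binary_dilation(binary, structure=_ball(2))
        hand = np.zeros_like(binary)
        idx = np.argwhere(binary)
        for c in idx:
            for dx in range(-2, 3):
                for dy in range(-2, 3):
                    for dz in range(-2, 3):
                        if dx * dx + dy * dy + dz * dz <= 4:
                            p = c + (dx, dy, dz)
                            if np.all(p >= 0) and np.all(p < 16):
                                hand[tuple(p)] = True
        assert (mask.data > 0).sum() == hand.sum()
        np.testing.assert_array_equal(mask.data > 0, expected)

    def test_soft_weights_in_unit_interval(self, blob_grid):
        mask = make_mask(blob_grid, MaskSpec(3.0, 2, 9))
        assert mask.data.min() >= 0.0 and mask.data.max() <= 1.0
        # soft edge voxels strictly between 0 and 1 exist
        assert np.any((mask.data > 0) & (mask.data < 1))

    @pytest.mark.parametrize("k_lo,k_hi", [(1.0, 2.0), (2.0, 3.0)])
    def test_monotone_in_threshold(self, blob_grid, k_lo, k_hi):
        lo = make_mask(blob_grid, MaskSpec(k_lo, 0, 0)).data > 0
        hi = make_mask(blob_grid, MaskSpec(k_hi, 0, 0)).data > 0
        assert np.all(hi <= lo)


# --------------------------------------------------------------------------
# FSC

class TestFSC:
    def test_self_correlation_is_one(self, blob_grid):
        curve = fsc(blob_grid, blob_grid)
        powered = ~np.isnan(curve.correlation)
        np.testing.assert_allclose(curve.correlation[powered], 1.0, atol=1e-10)

    def test_negated_correlation_is_minus_one(self, blob_grid):
        neg = blob_grid.with_data(-blob_grid.data)
        curve = fsc(blob_grid, neg)
        powered = ~np.isnan(curve.correlation)
        np.testing.assert_allclose(curve.correlation[powered], -1.0, atol=1e-10)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(77)
        a = VoxelGrid(rng.standard_normal((32, 32, 32)), 1.0)
        b = VoxelGrid(rng.standard_normal((32, 32, 32)), 1.0)
        curve = fsc(a, b)
        from cryodiff.volgrid import _shell_index

        _, n_shells = _shell_index(a, "test")
        counts = radial_amplitude_profile(a).shell_count
        vals = curve.correlation[1:]  # DC shell has 1 voxel, skip
        # FSC of independent noise has per-shell SD ~ 1/sqrt(shell voxels)
        bound = 5.0 / np.sqrt(counts[1:])
        assert np.all(np.abs(vals) < bound)
        assert abs(np.nanmean(vals)) < 0.05

    def test_symmetric_and_scale_invariant(self, blob_grid, random_grid):
        c1 = fsc(blob_grid, random_grid).correlation
        c2 = fsc(random_grid, blob_grid).correlation
        np.testing.assert_allclose(c1, c2, atol=1e-12)
        scaled = fsc(
            blob_grid.with_data(3.0 * blob_grid.data),
            random_grid.with_data(3.0 * random_grid.data),
        ).correlation
        np.testing.assert_allclose(c1, scaled, atol=1e-9)

    def test_resolution_estimate_sensible(self):
        # identical signal + independent noise: resolution finite, > voxel size
        rng = np.random.default_rng(3)
        n, vs = 32, 2.0
        ax = (np.arange(n) - n / 2) * vs
        d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        signal = 10 * np.exp(-0.5 * d2 / 8.0**2)
        a = VoxelGrid(signal + rng.standard_normal((n, n, n)), vs)
        b = VoxelGrid(signal + rng.standard_normal((n, n, n)), vs)
        res = fsc(a, b).resolution
        assert 2 * vs <= res < n * vs

    def test_geometry_mismatch_rejected(self, blob_grid):
        other = VoxelGrid(np.zeros((8, 8, 8)), 2.0)
        with pytest.raises(ValueError, match="mismatch"):
            fsc(blob_grid, other)
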