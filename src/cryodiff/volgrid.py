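"""Voxel-grid data model and reciprocal-space utilities for cryo-EM maps.

This module provides the core 3D scalar-field container (:class:`VoxelGrid`),
MRC2014 input/output through gemmi, Fourier low-pass filtering, radial
amplitude profiles and profile-based rescaling, soft sigma-contour masks,
and Fourier shell correlation (FSC).

Conventions
-----------
* Voxels are isotropic; anisotropic sampling is rejected rather than
  silently resampled.
* Fourier shells are indexed by the integer-rounded voxel radius of each
  Fourier coefficient; shell ``s`` on an ``N``-cube corresponds to spatial
  frequency ``s / (N * voxel_size)`` in 1/A.
* Radial operations (profiles, scaling, FSC) require a cubic grid so that
  a single shell index is well defined.
* Map statistics (mean, sigma) are computed over the whole box; contour
  levels are expressed as ``mean + k * sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "RadialProfile",
    "FSCCurve",
    "MaskSpec",
    "read_map",
    "write_map",
    "lowpass_filter",
    "radial_amplitude_profile",
    "scale_to_reference",
    "make_mask",
    "fsc",
]

# relative tolerance for declaring voxel sampling isotropic
ISOTROPY_RTOL = 1e-3


class MapFormatError(ValueError):
    """Raised when an MRC volume cannot be interpreted as a VoxelGrid."""


@dataclass
class VoxelGrid:
    """A 3D scalar density field with physical sampling metadata.

    Parameters
    ----------
    data
        3D array of density values (arbitrary intensity units).
    voxel_size
        Isotropic sampling in Angstrom per voxel.
    origin
        Physical position (A) of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("empty grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("grid contains non-finite values")
        self.voxel_size = float(self.voxel_size)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def nx(self) -> int:
        return self.data.shape[0]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nz(self) -> int:
        return self.data.shape[2]

    @property
    def mean(self) -> float:
        """Mean over the whole box (recomputed on access)."""
        return float(self.data.mean())

    @property
    def sigma(self) -> float:
        """Population standard deviation over the whole box."""
        return float(self.data.std())

    @property
    def is_cubic(self) -> bool:
        return self.nx == self.ny == self.nz

    def require_cubic(self, what: str) -> int:
        if not self.is_cubic:
            raise ValueError(f"{what} requires a cubic grid, got {self.shape}")
        return self.nx

    def same_geometry(self, other: "VoxelGrid", rtol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.voxel_size, other.voxel_size, rtol=rtol)
            and np.allclose(self.origin, other.origin, atol=1e-3)
        )

    def check_geometry(self, other: "VoxelGrid"):
        if not self.same_geometry(other):
            raise ValueError(
                "grid geometry mismatch: "
                f"{self.shape}@{self.voxel_size} A (origin {self.origin}) vs "
                f"{other.shape}@{other.voxel_size} A (origin {other.origin})"
            )

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """New grid sharing this grid's geometry."""
        return VoxelGrid(data, self.voxel_size, self.origin.copy())

    def contour_level(self, sigma_threshold: float) -> float:
        """Density value of the ``mean + k * sigma`` isosurface."""
        return self.mean + sigma_threshold * self.sigma


@dataclass
class RadialProfile:
    """Mean Fourier amplitude per integer-radius shell.

    ``shell_frequency[s] = s / (N * voxel_size)`` (1/A); shell 0 is the DC
    coefficient.  Amplitudes use the unnormalized numpy forward-FFT
    convention (DC amplitude of a constant map c is ``c * N**3``).
    """

    shell_frequency: np.ndarray
    mean_amplitude: np.ndarray
    shell_count: np.ndarray

    def __post_init__(self):
        self.shell_frequency = np.asarray(self.shell_frequency, dtype=np.float64)
        self.mean_amplitude = np.asarray(self.mean_amplitude, dtype=np.float64)
        self.shell_count = np.asarray(self.shell_count, dtype=np.int64)
        if np.any(self.mean_amplitude < 0):
            raise ValueError("amplitudes must be nonnegative")
        if np.any(np.diff(self.shell_frequency) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")

    @property
    def n_shells(self) -> int:
        return len(self.mean_amplitude)

    def to_table(self, path):
        import pandas as pd

        pd.DataFrame(
            {
                "shell_frequency": self.shell_frequency,
                "mean_amplitude": self.mean_amplitude,
                "shell_count": self.shell_count,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class FSCCurve:
    """Fourier shell correlation between two maps.

    ``correlation`` may contain NaN for shells without power in both maps.
    """

    shell_frequency: np.ndarray
    correlation: np.ndarray
    cutoff_criterion: float = 0.143

    @property
    def resolution(self) -> float:
        """Resolution (A) at the first crossing below the cutoff.

        Linearly interpolated between the bracketing shells; ``inf``
        frequency (i.e. Nyquist) is never extrapolated — if the curve
        never crosses, the Nyquist resolution is returned.
        """
        freq = self.shell_frequency
        corr = self.correlation
        for s in range(1, len(corr)):
            if np.isnan(corr[s]):
                continue
            if corr[s] < self.cutoff_criterion:
                # interpolate between previous valid shell and this one
                prev = s - 1
                while prev > 0 and np.isnan(corr[prev]):
                    prev -= 1
                c0, c1 = corr[prev], corr[s]
                f0, f1 = freq[prev], freq[s]
                if np.isnan(c0) or c1 == c0:
                    fc = f1
                else:
                    fc = f0 + (c0 - self.cutoff_criterion) * (f1 - f0) / (c0 - c1)
                return 1.0 / fc
        return 1.0 / freq[-1]

    def to_table(self, path):
        import pandas as pd

        pd.DataFrame(
            {"shell_frequency": self.shell_frequency, "correlation": self.correlation}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class MaskSpec:
    """Threshold / dilate / soften recipe for a density mask.

    The mask is binarized at ``mean + sigma_threshold * sigma``, dilated by
    ``extend_px`` voxels and given a cosine fall-off from 1 to 0 over
    ``soften_px`` voxels outside the binary edge.
    """

    sigma_threshold: float = 3.0
    extend_px: int = 2
    soften_px: int = 9

    def __post_init__(self):
        if self.extend_px < 0 or self.soften_px < 0:
            raise ValueError("extend_px and soften_px must be nonnegative")


# --------------------------------------------------------------------------
# MRC input/output (gemmi, MRC2014 mode-2 float volumes)

def read_map(path) -> VoxelGrid:
    """Read an MRC2014 volume into a :class:`VoxelGrid`.

    The voxel size is derived from the cell dimensions divided by the
    sampling counts; the origin is taken from the ORIGIN header words.
    Anisotropic sampling (beyond a relative tolerance of 1e-3) is rejected.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC volume {path}: {exc}") from exc
    # normalize axis order to X,Y,Z fastest-to-slowest (mapc/mapr/maps)
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = ccp4.grid
    sx, sy, sz = grid.spacing
    if sx <= 0:
        raise MapFormatError(
            "non-positive voxel size derived from CELLA/NXYZ header fields"
        )
    mean_s = (sx + sy + sz) / 3.0
    if max(abs(sx - mean_s), abs(sy - mean_s), abs(sz - mean_s)) > ISOTROPY_RTOL * mean_s:
        raise MapFormatError(
            f"anisotropic voxel size ({sx:.4f}, {sy:.4f}, {sz:.4f}) A from "
            "CELLA/NXYZ header fields; isotropic sampling is required"
        )
    data = np.array(grid, copy=True)
    if data.ndim != 3:
        raise MapFormatError("MRC file is not a 3D volume (MODE/NXYZ headers)")
    if not np.all(np.isfinite(data)):
        raise MapFormatError("MRC volume contains non-finite densities")
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    return VoxelGrid(data, mean_s, origin)


def write_map(grid: VoxelGrid, path) -> None:
    """Write a :class:`VoxelGrid` as an MRC2014 mode-2 (float32) volume."""
    fg = gemmi.FloatGrid(grid.nx, grid.ny, grid.nz)
    fg.set_unit_cell(
        gemmi.UnitCell(
            grid.nx * grid.voxel_size,
            grid.ny * grid.voxel_size,
            grid.nz * grid.voxel_size,
            90.0,
            90.0,
            90.0,
        )
    )
    np.array(fg, copy=False)[...] = grid.data.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = fg
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))


# --------------------------------------------------------------------------
# Fourier-space helpers

def _voxel_radius(shape: tuple[int, int, int]) -> np.ndarray:
    """Fourier radius of each coefficient in voxel (cycles-per-box) units."""
    fx = np.fft.fftfreq(shape[0]) * shape[0]
    fy = np.fft.fftfreq(shape[1]) * shape[1]
    fz = np.fft.fftfreq(shape[2]) * shape[2]
    return np.sqrt(
        fx[:, None, None] ** 2 + fy[None, :, None] ** 2 + fz[None, None, :] ** 2
    )


def _shell_index(grid: VoxelGrid, what: str) -> tuple[np.ndarray, int]:
    """Integer-rounded shell index per Fourier voxel, and shell count."""
    n = grid.require_cubic(what)
    r = _voxel_radius(grid.shape)
    idx = np.rint(r).astype(np.int64)
    n_shells = n // 2 + 1
    return idx, n_shells


def lowpass_filter(
    grid: VoxelGrid, cutoff_A: float, edge_width_shells: float = 3.0
) -> VoxelGrid:
    """Low-pass Fourier filter with a raised-cosine edge.

    Amplitudes are kept up to the cutoff frequency ``1 / cutoff_A`` and
    rolled off to zero over ``edge_width_shells`` Fourier shells beyond it.
    The DC term (map mean) is always preserved.

    The multiplier is constant within each integer-rounded shell (the same
    shell convention as :func:`radial_amplitude_profile`), which makes the
    filter commute exactly with profile-based rescaling.

    Parameters
    ----------
    cutoff_A
        Filter cutoff as a real-space distance in Angstrom; must be above
        the Nyquist limit ``2 * voxel_size``.
    edge_width_shells
        Width of the cosine roll-off in shell (voxel-radius) units.
    """
    n = grid.require_cubic("lowpass_filter")
    nyquist_A = 2.0 * grid.voxel_size
    if cutoff_A <= nyquist_A:
        raise ValueError(
            f"cutoff {cutoff_A} A is at or beyond Nyquist ({nyquist_A} A)"
        )
    r = np.rint(_voxel_radius(grid.shape))
    r_c = n * grid.voxel_size / cutoff_A  # cutoff radius in voxel units
    w = float(edge_width_shells)
    if w <= 0:
        h = (r <= r_c).astype(np.float64)
    else:
        h = np.where(
            r <= r_c,
            1.0,
            np.where(
                r >= r_c + w, 0.0, 0.5 * (1.0 + np.cos(np.pi * (r - r_c) / w))
            ),
        )
    out = np.fft.ifftn(np.fft.fftn(grid.data) * h)
    return grid.with_data(out.real)


def radial_amplitude_profile(grid: VoxelGrid) -> RadialProfile:
    """Mean Fourier amplitude (modulus) per integer-radius shell."""
    idx, n_shells = _shell_index(grid, "radial_amplitude_profile")
    amp = np.abs(np.fft.fftn(grid.data))
    keep = idx < n_shells
    flat_idx = idx[keep].ravel()
    flat_amp = amp[keep].ravel()
    counts = np.bincount(flat_idx, minlength=n_shells)
    sums = np.bincount(flat_idx, weights=flat_amp, minlength=n_shells)
    mean_amp = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    n = grid.nx
    freqs = np.arange(n_shells) / (n * grid.voxel_size)
    # shell 0 is the single DC coefficient; make frequencies strictly increasing
    return RadialProfile(freqs, mean_amp, counts)


def scale_to_reference(
    target: VoxelGrid,
    reference_profile: RadialProfile,
    amplitude_floor: float = 1e-12,
) -> VoxelGrid:
    """Rescale a map's radial amplitude profile onto a reference profile.

    Every Fourier coefficient in shell ``s`` is multiplied by
    ``reference_amplitude[s] / target_amplitude[s]``; phases are unchanged.
    Coefficients in the box corners (radius beyond Nyquist) reuse the
    Nyquist-shell factor.  Shells where the target amplitude falls below
    ``amplitude_floor * DC_amplitude`` are passed through unscaled (their
    indices are recorded on the returned grid as ``scaling_skipped``).
    """
    idx, n_shells = _shell_index(target, "scale_to_reference")
    if reference_profile.n_shells != n_shells:
        raise ValueError(
            f"profile has {reference_profile.n_shells} shells but grid needs "
            f"{n_shells}: geometry mismatch"
        )
    ft = np.fft.fftn(target.data)
    amp = np.abs(ft)
    keep = idx < n_shells
    flat_idx = idx[keep].ravel()
    counts = np.bincount(flat_idx, minlength=n_shells)
    sums = np.bincount(flat_idx, weights=amp[keep].ravel(), minlength=n_shells)
    tgt_amp = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    floor = amplitude_floor * max(tgt_amp[0], 1e-300)
    usable = tgt_amp > floor
    factors = np.ones(n_shells)
    factors[usable] = reference_profile.mean_amplitude[usable] / tgt_amp[usable]
    out = apply_shell_factors(target, factors)
    out.scaling_skipped = np.flatnonzero(~usable)
    return out


def apply_shell_factors(grid: VoxelGrid, factors: np.ndarray) -> VoxelGrid:
    """Multiply every Fourier coefficient by its shell's factor.

    This is the application half of :func:`scale_to_reference` with the
    per-shell factors held fixed; as a pure radial Fourier multiplier it
    commutes with :func:`lowpass_filter` (whereas re-estimating factors on
    an already-filtered map does not).  Corner coefficients beyond Nyquist
    reuse the Nyquist-shell factor.
    """
    idx, n_shells = _shell_index(grid, "apply_shell_factors")
    factors = np.asarray(factors, dtype=np.float64)
    if len(factors) != n_shells:
        raise ValueError(
            f"expected {n_shells} shell factors, got {len(factors)}"
        )
    mult = factors[np.minimum(idx, n_shells - 1)]
    ft = np.fft.fftn(grid.data)
    return grid.with_data(np.fft.ifftn(ft * mult).real)


def make_mask(grid: VoxelGrid, spec: MaskSpec) -> VoxelGrid:
    """Soft mask: binarize at a sigma contour, dilate, cosine-soften.

    Returns a grid of weights in [0, 1].  A threshold above the map maximum
    yields the all-zero mask.
    """
    level = grid.contour_level(spec.sigma_threshold)
    binary = grid.data >= level
    if spec.extend_px > 0 and binary.any():
        binary = ndimage.binary_dilation(
            binary, structure=_ball(spec.extend_px), iterations=1
        )
    weights = binary.astype(np.float64)
    if spec.soften_px > 0 and binary.any() and not binary.all():
        # Euclidean distance (in voxels) from outside voxels to the binary edge
        dist = ndimage.distance_transform_edt(~binary)
        ramp = (dist > 0) & (dist <= spec.soften_px)
        weights[ramp] = 0.5 * (1.0 + np.cos(np.pi * dist[ramp] / spec.soften_px))
    return grid.with_data(weights)


def _ball(radius: int) -> np.ndarray:
    """Spherical structuring element of the given voxel radius."""
    r = int(radius)
    zyx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (zyx**2).sum(axis=0) <= r * r


def fsc(a: VoxelGrid, b: VoxelGrid, mask: VoxelGrid | None = None,
        cutoff_criterion: float = 0.143) -> FSCCurve:
    """Fourier shell correlation between two maps on the same grid.

    If a soft ``mask`` is given, both maps are multiplied by it before
    transforming.  Shells where either map has zero power are reported as
    NaN.  The curve's :attr:`FSCCurve.resolution` is the real-space
    distance of the first crossing below ``cutoff_criterion``.
    """
    a.check_geometry(b)
    da, db = a.data, b.data
    if mask is not None:
        a.check_geometry(mask)
        da = da * mask.data
        db = db * mask.data
    idx, n_shells = _shell_index(a, "fsc")
    fa = np.fft.fftn(da)
    fb = np.fft.fftn(db)
    keep = idx < n_shells
    flat_idx = idx[keep].ravel()
    cross = np.bincount(
        flat_idx, weights=(fa * np.conj(fb)).real[keep].ravel(), minlength=n_shells
    )
    pa = np.bincount(flat_idx, weights=(np.abs(fa) ** 2)[keep].ravel(), minlength=n_shells)
    pb = np.bincount(flat_idx, weights=(np.abs(fb) ** 2)[keep].ravel(), minlength=n_shells)
    denom = np.sqrt(pa * pb)
    corr = np.full(n_shells, np.nan)
    ok = denom > 0
    corr[ok] = cross[ok] / denom[ok]
    n = a.nx
    freqs = np.arange(n_shells) / (n * a.voxel_size)
    return FSCCurve(freqs, corr, cutoff_criterion)
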