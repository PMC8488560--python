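"""Global difference analysis between two ensembles of reconstructions.

Given two sets of independent reconstructions of the same structure under
two conditions (for example, a macromolecular assembly with and without a
bound ligand), this module computes per-voxel Student's t statistics and
probabilities for the difference between the condition means, classifies
voxels into significance bands, and drives the full pipeline:

1. estimate a radial amplitude scaling profile from the reference
   condition's mean map,
2. rescale every member of the other condition onto that profile (removing
   global amplitude/B-factor differences that would otherwise appear as
   false density differences),
3. low-pass filter all members,
4. compute per-condition mean and unbiased variance,
5. compute the pooled two-sample t and p per voxel,
6. classify voxels into ordered significance bands.

The per-voxel test is the classical map-comparison convention: pooled
variance, df = n_A + n_B - 2, two-tailed probabilities by default.  A
Welch option is provided.  No multiple-testing correction is applied; the
run report instead states the expected false-positive voxel count in the
weakest band under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .volgrid import (
    MaskSpec,
    VoxelGrid,
    lowpass_filter,
    radial_amplitude_profile,
    scale_to_reference,
)

__all__ = [
    "MapEnsemble",
    "SignificanceMap",
    "PipelineConfig",
    "ensemble_stats",
    "difference_map",
    "voxel_t_map",
    "classify_significance",
    "run_difference_pipeline",
    "CLASS_UNDETERMINED",
    "CLASS_NOT_SIGNIFICANT",
]

# ordinal class codes used in the integer class map
CLASS_UNDETERMINED = -1
CLASS_NOT_SIGNIFICANT = 0
# bands 1..k correspond to the ordered probability thresholds


@dataclass
class MapEnsemble:
    """n same-geometry maps treated as independent reconstructions."""

    members: list[VoxelGrid]
    label: str = ""

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError(
                f"ensemble '{self.label}' needs at least 2 members, "
                f"got {len(self.members)}"
            )
        ref = self.members[0]
        for m in self.members[1:]:
            ref.check_geometry(m)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def geometry(self) -> VoxelGrid:
        return self.members[0]

    def stack(self) -> np.ndarray:
        return np.stack([m.data for m in self.members])

    def map_members(self, fn) -> "MapEnsemble":
        return MapEnsemble([fn(m) for m in self.members], self.label)


@dataclass
class SignificanceMap:
    """Per-voxel t, p, degrees of freedom and significance classes."""

    t: VoxelGrid
    p: VoxelGrid
    df: int
    classes: VoxelGrid
    thresholds: tuple[float, ...]
    undetermined: np.ndarray  # boolean, True where the test was not run

    @property
    def band_counts(self) -> dict[int, int]:
        """Voxel count per band (cumulative sets: band k = p < thresholds[k-1])."""
        c = self.classes.data.astype(int)
        out = {}
        for band in range(1, len(self.thresholds) + 1):
            out[band] = int((c >= band).sum())
        return out

    def band_fraction(self, band: int) -> float:
        defined = (~self.undetermined).sum()
        if defined == 0:
            return float("nan")
        return self.band_counts[band] / defined


@dataclass
class PipelineConfig:
    """Parameters of the difference pipeline.

    Attributes
    ----------
    lowpass_A
        Low-pass filter cutoff in Angstrom (typical choices: 11 for whole
        assemblies, 12 for sub-volumes).
    thresholds
        Strictly decreasing probability cutoffs defining the significance
        bands.  The last (most stringent) band is the one interpreted as
        direct density difference.
    tails
        1 or 2; tailedness of the per-voxel probability.
    variance_floor
        Voxels whose pooled variance falls below
        ``variance_floor * mean(pooled variance)`` are labelled
        undetermined and excluded from classification (solvent / padding).
    welch
        Use the Welch (unequal-variance) t statistic instead of the pooled
        one.
    scaling
        Enable radial amplitude-profile scaling of the non-reference
        condition onto the reference condition.
    scaling_reference
        Which ensemble ("A" or "B") anchors the amplitude scaling.
    mask
        Optional mask recipe applied when reporting statistics (the test
        itself is always run on the full box).
    """

    lowpass_A: float = 11.0
    thresholds: tuple[float, ...] = (0.05, 0.0005, 0.0001)
    tails: int = 2
    variance_floor: float = 1e-9
    welch: bool = False
    scaling: bool = True
    scaling_reference: str = "A"
    mask: MaskSpec | None = None

    def __post_init__(self):
        th = tuple(float(t) for t in self.thresholds)
        if any(b >= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly decreasing")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.scaling_reference not in ("A", "B"):
            raise ValueError("scaling_reference must be 'A' or 'B'")
        self.thresholds = th


def ensemble_stats(ens: MapEnsemble) -> tuple[VoxelGrid, VoxelGrid]:
    """Per-voxel sample mean and unbiased sample variance (divisor n-1)."""
    stack = ens.stack()
    mean = stack.mean(axis=0)
    var = stack.var(axis=0, ddof=1)
    geo = ens.geometry
    return geo.with_data(mean), geo.with_data(var)


def difference_map(mean_B: VoxelGrid, mean_A: VoxelGrid) -> VoxelGrid:
    """Plain voxel-wise difference B - A (inputs already scaled/filtered)."""
    mean_B.check_geometry(mean_A)
    return mean_B.with_data(mean_B.data - mean_A.data)


def voxel_t_map(
    ens_A: MapEnsemble,
    ens_B: MapEnsemble,
    config: PipelineConfig | None = None,
) -> SignificanceMap:
    """Per-voxel two-sample Student's t test between two ensembles.

    The statistic is ``t = (mean_A - mean_B) / SE`` with the pooled
    standard error and ``df = n_A + n_B - 2`` (or the Welch form when
    ``config.welch``).  Voxels with pooled variance below the relative
    variance floor are labelled undetermined.
    """
    config = config or PipelineConfig()
    ens_A.geometry.check_geometry(ens_B.geometry)
    nA, nB = ens_A.n, ens_B.n
    mA, vA = ensemble_stats(ens_A)
    mB, vB = ensemble_stats(ens_B)

    if config.welch:
        seA = vA.data / nA
        seB = vB.data / nB
        pooled = seA + seB
        with np.errstate(divide="ignore", invalid="ignore"):
            df_map = pooled**2 / (
                seA**2 / max(nA - 1, 1) + seB**2 / max(nB - 1, 1)
            )
        df_scalar = int(np.round(np.nanmedian(df_map)))
        se2 = pooled
        floor_ref = np.mean(se2)
        undetermined = se2 <= config.variance_floor * floor_ref
        df_arr = df_map
    else:
        df_scalar = nA + nB - 2
        sp2 = ((nA - 1) * vA.data + (nB - 1) * vB.data) / df_scalar
        floor_ref = np.mean(sp2)
        undetermined = sp2 <= config.variance_floor * floor_ref
        se2 = sp2 * (1.0 / nA + 1.0 / nB)
        df_arr = np.full(se2.shape, float(df_scalar))

    t = np.zeros(se2.shape)
    ok = ~undetermined
    t[ok] = (mA.data[ok] - mB.data[ok]) / np.sqrt(se2[ok])
    p = np.full(se2.shape, np.nan)
    sf = stats.t.sf(np.abs(t[ok]), df_arr[ok])
    p[ok] = config.tails * sf
    np.clip(p, 0.0, 1.0, out=p)

    geo = ens_A.geometry
    sig = SignificanceMap(
        t=geo.with_data(t),
        p=geo.with_data(np.where(ok, p, 1.0)),
        df=df_scalar,
        classes=geo.with_data(np.zeros(se2.shape)),
        thresholds=config.thresholds,
        undetermined=undetermined,
    )
    sig.classes = classify_significance(sig, config.thresholds)
    return sig


def classify_significance(
    sig: SignificanceMap, thresholds: Sequence[float]
) -> VoxelGrid:
    """Assign each defined voxel the most stringent band its p falls below.

    Band ``k`` (1-based) means ``p < thresholds[k-1]``; thresholds must be
    strictly decreasing, so higher bands are subsets of lower ones.
    Undetermined voxels are coded -1, not-significant voxels 0.
    """
    th = tuple(float(t) for t in thresholds)
    if any(b >= a for a, b in zip(th, th[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    p = sig.p.data
    classes = np.zeros(p.shape, dtype=np.int64)
    for band, cutoff in enumerate(th, start=1):
        classes[p < cutoff] = band
    classes[sig.undetermined] = CLASS_UNDETERMINED
    return sig.p.with_data(classes.astype(np.float64))


@dataclass
class PipelineResult:
    """All stage outputs of the difference pipeline."""

    mean_A: VoxelGrid
    mean_B: VoxelGrid
    difference: VoxelGrid
    significance: SignificanceMap
    ensemble_A: MapEnsemble
    ensemble_B: MapEnsemble
    report: dict = field(default_factory=dict)


def run_difference_pipeline(
    ens_A: MapEnsemble,
    ens_B: MapEnsemble,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Scale, filter, and statistically compare two reconstruction ensembles.

    The scaling profile is always estimated from the *unfiltered* mean of
    the reference condition and applied identically to every member of the
    other condition; filtering follows.  Returns the filtered condition
    means, the plain difference map (non-reference minus reference), the
    significance map, and a run report.
    """
    config = config or PipelineConfig()
    ens_A.geometry.check_geometry(ens_B.geometry)

    ref_ens, other_ens = (ens_A, ens_B) if config.scaling_reference == "A" else (
        ens_B,
        ens_A,
    )
    skipped_shells = 0
    if config.scaling:
        ref_mean, _ = ensemble_stats(ref_ens)
        ref_profile = radial_amplitude_profile(ref_mean)
        skipped: set[int] = set()

        def rescale(m):
            out = scale_to_reference(m, ref_profile)
            skipped.update(int(s) for s in getattr(out, "scaling_skipped", ()))
            return out

        other_ens = other_ens.map_members(rescale)
        skipped_shells = len(skipped)

    if config.scaling_reference == "A":
        ens_A_s, ens_B_s = ref_ens, other_ens
    else:
        ens_A_s, ens_B_s = other_ens, ref_ens

    lp = lambda m: lowpass_filter(m, config.lowpass_A)
    ens_A_f = ens_A_s.map_members(lp)
    ens_B_f = ens_B_s.map_members(lp)

    mean_A, _ = ensemble_stats(ens_A_f)
    mean_B, _ = ensemble_stats(ens_B_f)
    diff = difference_map(mean_B, mean_A)
    sig = voxel_t_map(ens_A_f, ens_B_f, config)

    defined = int((~sig.undetermined).sum())
    report = {
        "n_A": ens_A.n,
        "n_B": ens_B.n,
        "df": sig.df,
        "lowpass_A": config.lowpass_A,
        "tails": config.tails,
        "scaling": config.scaling,
        "scaling_reference": config.scaling_reference,
        "scaling_skipped_shells": skipped_shells,
        "thresholds": list(config.thresholds),
        "voxels_total": int(np.prod(ens_A.geometry.shape)),
        "voxels_defined": defined,
        "voxels_undetermined": int(sig.undetermined.sum()),
        "band_counts": sig.band_counts,
        "band_fractions": {
            b: sig.band_fraction(b) for b in range(1, len(config.thresholds) + 1)
        },
        # raw per-voxel probabilities are reported uncorrected; under the
        # null, band 1 is expected to contain this many voxels by chance
        "expected_false_positives_band1": config.thresholds[0] * defined,
    }
    return PipelineResult(
        mean_A=mean_A,
        mean_B=mean_B,
        difference=diff,
        significance=sig,
        ensemble_A=ens_A_f,
        ensemble_B=ens_B_f,
        report=report,
    )


def write_report(report: dict, path) -> None:
    """Tab-separated key/value run report."""
    import json

    with open(path, "w") as fh:
        for key, value in report.items():
            if isinstance(value, (dict, list)):
                value = json.dumps(value)
            fh.write(f"{key}\t{value}\n")
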