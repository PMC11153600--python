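"""Areal densities, depth calibration, weighted depth profiles, group tests.

Corrected molecule counts become areal densities (molecules per um^2 of
segmented area) with Poisson counting errors.  A uniform "synthetic biofilm"
calibration sample — bacteria embedded homogeneously in agarose — measures the
depth-dependent detection bias of the optical system; its per-depth densities,
normalized to the coverslip value, divide the biofilm densities plane by
plane.  Depth profiles aggregate the FOVs at each depth with an
inverse-variance weighted mean, and groups (e.g. biofilm maturation
timepoints) are compared with Student's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DensityMeasurement:
    """Corrected areal density of one FOV."""

    fov_id: str
    depth_um: float
    raw_count: float
    predicted_spurious: float
    corrected_count: float
    area_um2: float
    density: float = 0.0
    density_error: float = 0.0
    grid_x_um: float = 0.0
    grid_y_um: float = 0.0
    replicate: int = 0
    valid: bool = True
    #: relative systematic error shared by all FOVs of a depth (set by the
    #: calibration step); kept out of the statistical weights and folded into
    #: the aggregated error in quadrature.
    systematic_rel_error: float = 0.0
    flags: list[str] = field(default_factory=list)


def compute_density(corrected_count: float, area_um2: float) -> tuple[float, float]:
    """Density (count / area) with Poisson counting error sqrt(count) / area.

    Raises on non-positive area; callers should flag such measurements
    invalid and exclude them from aggregation.
    """
    if area_um2 <= 0:
        raise ValueError("segmented area must be > 0 to compute a density")
    if corrected_count < 0:
        raise ValueError("corrected_count must be >= 0")
    density = corrected_count / area_um2
    error = float(np.sqrt(corrected_count)) / area_um2
    return float(density), error


def make_measurement(
    fov_id: str,
    depth_um: float,
    raw_count: float,
    predicted_spurious: float,
    corrected_count: float,
    area_um2: float,
    **kwargs,
) -> DensityMeasurement:
    """Build a measurement, flagging it invalid when the area is zero."""
    m = DensityMeasurement(
        fov_id=fov_id,
        depth_um=float(depth_um),
        raw_count=float(raw_count),
        predicted_spurious=float(predicted_spurious),
        corrected_count=float(corrected_count),
        area_um2=float(area_um2),
        **kwargs,
    )
    if area_um2 <= 0:
        m.valid = False
        m.flags.append("zero_area")
        return m
    m.density, m.density_error = compute_density(corrected_count, area_um2)
    return m


def _weights(errors: np.ndarray) -> np.ndarray:
    """Inverse-variance weights; zero-error entries get the largest finite
    weight present (or equal weights when no error is positive)."""
    errors = np.asarray(errors, float)
    if np.all(errors <= 0):
        return np.ones_like(errors)
    floor = errors[errors > 0].min()
    safe = np.where(errors > 0, errors, floor)
    return 1.0 / safe**2


def weighted_mean(
    values: Sequence[float], errors: Sequence[float]
) -> tuple[float, float]:
    """Inverse-variance weighted mean and its error ``sqrt(1 / sum(w))``."""
    values = np.asarray(values, float)
    w = _weights(np.asarray(errors, float))
    mean = float(np.sum(w * values) / np.sum(w))
    return mean, float(np.sqrt(1.0 / np.sum(w)))


@dataclass
class CalibrationProfile:
    """Depth-dependent detection factors, normalized to 1 at the coverslip."""

    depths_um: tuple[float, ...]
    factors: tuple[float, ...]
    factor_errors: tuple[float, ...]

    def factor_at(self, depth_um: float) -> tuple[float, float]:
        try:
            i = self.depths_um.index(float(depth_um))
        except ValueError:
            raise KeyError(
                f"depth {depth_um} um not present in calibration profile "
                f"(depths: {self.depths_um})"
            ) from None
        return self.factors[i], self.factor_errors[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_um": self.depths_um,
                "factor": self.factors,
                "factor_error": self.factor_errors,
            }
        )


def _group_by_depth(
    measurements: Iterable[DensityMeasurement],
) -> dict[float, list[DensityMeasurement]]:
    groups: dict[float, list[DensityMeasurement]] = {}
    for m in measurements:
        if m.valid:
            groups.setdefault(float(m.depth_um), []).append(m)
    return dict(sorted(groups.items()))


def build_calibration(
    measurements: Iterable[DensityMeasurement],
) -> CalibrationProfile:
    """Normalize uniform-sample densities to the coverslip (depth 0) value.

    Per depth, FOVs (pooled across replicates) are combined with an
    inverse-variance weighted mean; the factor at depth z is
    ``mean(z) / mean(0)`` with errors propagated in quadrature on the ratio.
    """
    groups = _group_by_depth(measurements)
    if 0.0 not in groups:
        raise ValueError("calibration measurements must include depth 0")
    means = {
        z: weighted_mean([m.density for m in ms], [m.density_error for m in ms])
        for z, ms in groups.items()
    }
    m0, e0 = means[0.0]
    if m0 <= 0:
        raise ValueError("weighted mean density at depth 0 must be > 0")
    depths, factors, errors = [], [], []
    for z, (mz, ez) in means.items():
        f = mz / m0
        if f <= 0:
            raise ValueError(f"non-positive calibration factor at depth {z} um")
        ef = f * float(np.hypot(ez / mz if mz else 0.0, e0 / m0))
        depths.append(z)
        factors.append(f)
        errors.append(ef)
    return CalibrationProfile(tuple(depths), tuple(factors), tuple(errors))


def calibrate(
    measurements: Iterable[DensityMeasurement], profile: CalibrationProfile
) -> list[DensityMeasurement]:
    """Divide each density by the calibration factor of its plane.

    The statistical (counting) error scales with the density, ``e -> e / f``;
    the factor's own uncertainty is shared by every FOV of the plane, so it
    is carried as a relative *systematic* error and folded into the
    aggregated depth mean in quadrature rather than into the per-FOV
    weights (which would both distort the weighting and spuriously shrink a
    shared error).  A measurement at a depth absent from the profile raises
    ``KeyError`` naming the depth.
    """
    out = []
    for m in measurements:
        factor, factor_err = profile.factor_at(m.depth_um)
        new = replace(m, flags=list(m.flags))
        if m.valid:
            new.density = m.density / factor
            new.density_error = m.density_error / factor
            new.systematic_rel_error = float(
                np.hypot(m.systematic_rel_error, factor_err / factor)
            )
            new.flags.append("calibrated")
        out.append(new)
    return out


@dataclass
class DepthProfile:
    """Weighted per-depth aggregation of FOV densities."""

    depths_um: tuple[float, ...]
    mean_density: tuple[float, ...]
    mean_error: tuple[float, ...]
    n_fov: tuple[int, ...]
    n_replicates: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_um": self.depths_um,
                "mean_density_per_um2": self.mean_density,
                "mean_error_per_um2": self.mean_error,
                "n_fov": self.n_fov,
                "n_replicates": self.n_replicates,
            }
        )

    def normalized(self) -> "DepthProfile":
        """Profile divided by its depth-0 mean (ratio errors in quadrature)."""
        try:
            i0 = self.depths_um.index(0.0)
        except ValueError:
            raise ValueError("profile has no depth-0 entry to normalize on") from None
        m0, e0 = self.mean_density[i0], self.mean_error[i0]
        if m0 <= 0:
            raise ValueError("depth-0 mean must be > 0 for normalization")
        means, errs = [], []
        for m, e in zip(self.mean_density, self.mean_error):
            r = m / m0
            re = abs(r) * float(np.hypot(e / m if m else 0.0, e0 / m0)) if m else e / m0
            means.append(r)
            errs.append(re)
        return DepthProfile(
            self.depths_um, tuple(means), tuple(errs), self.n_fov, self.n_replicates
        )


def aggregate_profile(
    measurements: Iterable[DensityMeasurement], weighting: str = "inverse_variance"
) -> DepthProfile:
    """Per-depth weighted mean of FOV densities.

    ``weighting`` is ``"inverse_variance"`` (default; error of the weighted
    mean is ``sqrt(1/sum w)``), ``"area"`` (segmented-area weights) or
    ``"equal"`` (arithmetic mean with standard error of the mean).
    """
    groups = _group_by_depth(measurements)
    if not groups:
        raise ValueError("no valid measurements to aggregate")
    depths, means, errs, nfov, nrep = [], [], [], [], []
    for z, ms in groups.items():
        d = np.asarray([m.density for m in ms])
        e = np.asarray([m.density_error for m in ms])
        if weighting == "inverse_variance":
            mean, err = weighted_mean(d, e)
        elif weighting == "area":
            w = np.asarray([m.area_um2 for m in ms])
            mean = float(np.sum(w * d) / np.sum(w))
            err = float(np.sqrt(np.sum((w / np.sum(w)) ** 2 * e**2)))
        elif weighting == "equal":
            mean = float(d.mean())
            err = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else float(e[0])
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        sys_rel = max(m.systematic_rel_error for m in ms)
        if sys_rel > 0:
            err = float(np.hypot(err, abs(mean) * sys_rel))
        depths.append(z)
        means.append(mean)
        errs.append(err)
        nfov.append(len(ms))
        nrep.append(len({m.replicate for m in ms}))
    return DepthProfile(
        tuple(depths), tuple(means), tuple(errs), tuple(nfov), tuple(nrep)
    )


def compare_groups(
    densities_a: Sequence[float],
    densities_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test (Welch with ``equal_var=False``).

    Returns ``(t, p)``; identical groups give ``t = 0, p = 1``.
    """
    a = np.asarray(densities_a, float)
    b = np.asarray(densities_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    if np.array_equal(a, b) and np.all(a == a[0]):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


MEASUREMENT_COLUMNS = [
    "fov_id",
    "grid_x_um",
    "grid_y_um",
    "depth_um",
    "replicate",
    "raw_count",
    "predicted_spurious",
    "corrected_count",
    "area_um2",
    "density_per_um2",
    "density_error_per_um2",
    "systematic_rel_error",
    "valid",
    "flags",
]


def measurements_to_frame(
    measurements: Iterable[DensityMeasurement],
) -> pd.DataFrame:
    rows = [
        {
            "fov_id": m.fov_id,
            "grid_x_um": m.grid_x_um,
            "grid_y_um": m.grid_y_um,
            "depth_um": m.depth_um,
            "replicate": m.replicate,
            "raw_count": m.raw_count,
            "predicted_spurious": m.predicted_spurious,
            "corrected_count": m.corrected_count,
            "area_um2": m.area_um2,
            "density_per_um2": m.density,
            "density_error_per_um2": m.density_error,
            "systematic_rel_error": m.systematic_rel_error,
            "valid": m.valid,
            "flags": ";".join(m.flags),
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def measurements_from_frame(df: pd.DataFrame) -> list[DensityMeasurement]:
    out = []
    for _, r in df.iterrows():
        out.append(
            DensityMeasurement(
                fov_id=str(r["fov_id"]),
                depth_um=float(r["depth_um"]),
                raw_count=float(r["raw_count"]),
                predicted_spurious=float(r["predicted_spurious"]),
                corrected_count=float(r["corrected_count"]),
                area_um2=float(r["area_um2"]),
                density=float(r["density_per_um2"]),
                density_error=float(r["density_error_per_um2"]),
                grid_x_um=float(r.get("grid_x_um", 0.0)),
                grid_y_um=float(r.get("grid_y_um", 0.0)),
                replicate=int(r.get("replicate", 0)),
                valid=bool(r["valid"]),
                systematic_rel_error=float(r.get("systematic_rel_error", 0.0)),
                flags=[f for f in str(r.get("flags", "")).split(";") if f and f != "nan"],
            )
        )
    return out


def plot_profile(profile: DepthProfile, path: str | Path, normalized: bool = True):
    """Bar chart of the depth profile with error bars (optional figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prof = profile.normalized() if normalized else profile
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(
        range(len(prof.depths_um)),
        prof.mean_density,
        yerr=prof.mean_error,
        capsize=3,
        color="#d95f02",
    )
    ax.set_xticks(range(len(prof.depths_um)))
    ax.set_xticklabels([f"{z:g}" for z in prof.depths_um])
    ax.set_xlabel("depth below coverslip (um)")
    ax.set_ylabel("relative density" if normalized else "density (um$^{-2}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
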