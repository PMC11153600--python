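"""Inclined light-sheet geometry and acquisition-grid planning.

A single-objective light sheet is produced by focusing the excitation beam
off the optical axis of a high-NA objective; refraction at the
coverslip/sample interface inclines the sheet by

    theta_r = asin(d / (n_sample * f_obj))

where ``d`` is the off-axis displacement of the focused beam, ``n_sample``
the sample refractive index and ``f_obj`` the objective focal length.  The
acquisition plan tiles the sample with a lateral grid of FOV positions, each
imaged as a stack of depths, ordered so that no yet-to-be-imaged FOV sits
between the already-imaged region and the current one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def refraction_angle(d: float, n_sample: float, f_obj: float) -> float:
    """Sheet inclination in degrees for off-axis displacement ``d``.

    ``d`` and ``f_obj`` share any length unit (typically mm); ``n_sample``
    is dimensionless.  Raises on ``|d| >= n_sample * f_obj``, where the
    geometry has no refracted solution.
    """
    if n_sample <= 0 or f_obj <= 0:
        raise ValueError("n_sample and f_obj must be positive")
    s = d / (n_sample * f_obj)
    if abs(s) >= 1.0:
        raise ValueError(
            f"|d| = {abs(d)} must be smaller than n_sample * f_obj = "
            f"{n_sample * f_obj}"
        )
    return math.degrees(math.asin(s))


@dataclass(frozen=True)
class FovSpec:
    """One planned acquisition: lateral position, depth, and order index."""

    order: int
    ix: int
    iy: int
    x_um: float
    y_um: float
    depth_um: float

    @property
    def fov_id(self) -> str:
        return f"x{self.ix}y{self.iy}z{self.depth_um:g}"


@dataclass
class AcquisitionPlan:
    """Grid of FOVs: ``nx x ny`` lateral positions times ``nz`` depths.

    Defaults reproduce the 3 x 3 x 4 scheme (36 FOVs) with 100 um lateral and
    4.5 um axial spacing and 10 x 40 um^2 FOVs; plane depths are
    ``{0, axial_spacing, ..., (nz-1) * axial_spacing}``.
    """

    nx: int = 3
    ny: int = 3
    nz: int = 4
    lateral_spacing_um: float = 100.0
    axial_spacing_um: float = 4.5
    fov_width_um: float = 10.0
    fov_height_um: float = 40.0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid counts must be >= 1")
        if self.lateral_spacing_um <= 0 or self.axial_spacing_um <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_fovs(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def plane_depths_um(self) -> tuple[float, ...]:
        return tuple(round(k * self.axial_spacing_um, 9) for k in range(self.nz))


def plan_acquisition(plan: AcquisitionPlan) -> list[FovSpec]:
    """Ordered FOV list: outward lateral traversal, full depth stack first.

    Lateral positions are visited from the grid center outward (sorted by
    squared distance from the center, ties by angle), and each position's
    complete depth stack is acquired before moving on; illuminated regions
    therefore never lie beyond a pending position on the way out.
    """
    cx = (plan.nx - 1) / 2.0
    cy = (plan.ny - 1) / 2.0
    positions = [(ix, iy) for ix in range(plan.nx) for iy in range(plan.ny)]
    positions.sort(
        key=lambda p: (
            round((p[0] - cx) ** 2 + (p[1] - cy) ** 2, 9),
            round(math.atan2(p[1] - cy, p[0] - cx), 9),
        )
    )
    specs: list[FovSpec] = []
    order = 0
    for ix, iy in positions:
        for z in plan.plane_depths_um:
            specs.append(
                FovSpec(
                    order=order,
                    ix=ix,
                    iy=iy,
                    x_um=ix * plan.lateral_spacing_um,
                    y_um=iy * plan.lateral_spacing_um,
                    depth_um=z,
                )
            )
            order += 1
    return specs
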