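"""Seeded synthetic acquisitions with known ground truth.

Emulates the quantitative-PALM experiment on rod-shaped bacteria so the whole
analysis pipeline can be exercised end to end without microscope data:

* a *scene* places spherocylindrical cells in a 2D field of view (FOV) at each
  imaging depth.  At the coverslip (depth 0) cells lie horizontally; deeper in
  the sample an increasing fraction is oriented isotropically, which shortens
  the projected footprint (the geometric effect that lowers apparent areal
  density at the base layer of a uniform sample);
* each cell carries a Poisson number of labelled molecules, uniform over its
  projected footprint;
* an acquisition is a pair of consecutive videos sharing one frame counter:
  a *pre-activation* video containing only photoactivation-independent
  ("spurious") localizations whose per-frame rate decays exponentially, and an
  *activation* video in which each molecule may photoactivate once
  (irreversibly, no dark-state blinking), emit over a geometric number of
  frames, and be localized with isotropic Gaussian error.  The spurious decay
  continues across the video boundary;
* a small fraction of cells are "torches": cells producing a high, constant,
  activation-independent localization rate, which downstream segmentation must
  exclude;
* detection efficiency decreases with depth, emulating the loss of
  signal-to-background deep in the sample that the uniform calibration sample
  is designed to measure.

Every emitter carries a hidden ground-truth identity, returned alongside the
tables (and writable as a sidecar file, never inside the CSV), so recovery of
molecule counts by the filter/merge/correction chain can be tested exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .io import LocalizationTable, TableMeta, write_table

DepthFunction = Callable[[float], float]


def as_depth_function(spec) -> DepthFunction:
    """Normalize a scalar / mapping / callable into ``f(depth_um) -> value``.

    A mapping must be keyed by depth in um and is looked up exactly (the
    acquisition visits a fixed depth grid, so no interpolation is needed).
    """
    if callable(spec):
        return spec
    if isinstance(spec, Mapping):
        table = {float(k): float(v) for k, v in spec.items()}

        def lookup(z: float) -> float:
            try:
                return table[float(z)]
            except KeyError:
                raise KeyError(f"no value tabulated for depth {z} um") from None

        return lookup
    value = float(spec)
    return lambda z: value


def _default_horizontal_fraction(z: float) -> float:
    # fully horizontal at the coverslip, isotropic from ~10 um down
    return max(0.0, 1.0 - z / 10.0)


def _default_detection_efficiency(z: float) -> float:
    return float(np.exp(-z / 20.0))


def _default_loc_sigma(z: float) -> float:
    # localization error grows mildly with depth (nm)
    return 23.0 + 0.08 * z


@dataclass
class SceneParams:
    """Geometry and content of a synthetic sample.

    Defaults mirror the acquisition this package targets: 10 x 40 um^2 FOVs
    imaged at depths (0, 4.5, 9, 13.5) um, rod-shaped cells of 2 x 1 um.
    ``molecule_density`` is the true number of labelled molecules per um^2 of
    projected cell footprint and may depend on depth (a biofilm-like gradient)
    or be constant (a uniform calibration sample).
    """

    fov_width_um: float = 10.0
    fov_height_um: float = 40.0
    plane_depths_um: tuple[float, ...] = (0.0, 4.5, 9.0, 13.5)
    n_cells_per_plane: int = 180
    cell_length_um: float = 2.0
    cell_width_um: float = 1.0
    horizontal_fraction: object = None
    molecule_density: object = 40.0
    torch_fraction: float = 0.05
    free_background_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fov_width_um, self.fov_height_um) <= 0:
            raise ValueError("FOV dimensions must be positive")
        if self.cell_length_um <= 0 or self.cell_width_um <= 0:
            raise ValueError("cell dimensions must be positive")
        if self.cell_width_um > self.cell_length_um:
            raise ValueError("cell_width_um must not exceed cell_length_um")
        if not 0.0 <= self.torch_fraction <= 1.0:
            raise ValueError("torch_fraction must be in [0, 1]")
        if not 0.0 <= self.free_background_fraction <= 1.0:
            raise ValueError("free_background_fraction must be in [0, 1]")
        depths = tuple(float(z) for z in self.plane_depths_um)
        if any(z < 0 for z in depths) or any(
            b <= a for a, b in zip(depths, depths[1:])
        ):
            raise ValueError("plane_depths_um must be non-negative and strictly increasing")
        self.plane_depths_um = depths
        if self.horizontal_fraction is None:
            self.horizontal_fraction = _default_horizontal_fraction

    @property
    def horizontal_fraction_fn(self) -> DepthFunction:
        return as_depth_function(self.horizontal_fraction)

    @property
    def molecule_density_fn(self) -> DepthFunction:
        return as_depth_function(self.molecule_density)


@dataclass
class PhotokineticsParams:
    """Emitter photokinetics and camera/quality-field model.

    ``activation_rate`` is the per-frame activation probability of an inactive
    molecule under 405 nm light; at the default it keeps only ~0-2 fluorophores
    per cell active at any moment, the sparsity regime molecular counting
    requires.  ``mean_on_frames`` is the mean emission duration in frames
    (geometric, memoryless; activation is irreversible and followed by
    permanent bleaching, with no reversible blinking).  ``spurious_amplitude``
    and ``spurious_decay`` parameterize the photoactivation-independent
    localization rate ``A * exp(-decay * frame)`` shared by both videos.
    Quality fields are drawn uniformly inside the filter-passing ranges except
    for an ``outlier_fraction`` of rows that violate one randomly chosen
    filter condition.
    """

    n_pre_frames: int = 1000
    n_act_frames: int = 1000
    activation_rate: float = 0.005
    mean_on_frames: float = 3.0
    detection_efficiency: object = None
    loc_sigma_nm: object = None
    spurious_amplitude: float = 10.0
    spurious_decay: float = 0.005
    torch_rate: float = 2.0
    outlier_fraction: float = 0.05
    offset_range: tuple[float, float] = (1.0, 5.0)
    sigma_range: tuple[float, float] = (120.0, 250.0)
    intensity_range: tuple[float, float] = (50.0, 350.0)
    bkgstd_range: tuple[float, float] = (0.6, 2.0)
    uncertainty_range: tuple[float, float] = (8.0, 45.0)

    def __post_init__(self) -> None:
        if self.n_pre_frames < 0 or self.n_act_frames <= 0:
            raise ValueError("frame counts must be positive")
        if not 0.0 < self.activation_rate <= 1.0:
            raise ValueError("activation_rate must be in (0, 1]")
        if self.mean_on_frames < 1.0:
            raise ValueError("mean_on_frames must be >= 1")
        if self.spurious_decay <= 0:
            raise ValueError("spurious_decay must be > 0")
        if self.spurious_amplitude < 0 or self.torch_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.detection_efficiency is None:
            self.detection_efficiency = _default_detection_efficiency
        if self.loc_sigma_nm is None:
            self.loc_sigma_nm = _default_loc_sigma

    @property
    def detection_efficiency_fn(self) -> DepthFunction:
        return as_depth_function(self.detection_efficiency)

    @property
    def loc_sigma_fn(self) -> DepthFunction:
        return as_depth_function(self.loc_sigma_nm)


@dataclass
class Cell:
    """A spherocylinder projected onto the imaging plane.

    The projected footprint is a 2D capsule: a segment of half-length
    ``seg_half_nm`` (shortened by out-of-plane tilt) dilated by radius
    ``radius_nm``.
    """

    cx_nm: float
    cy_nm: float
    phi: float            # in-plane orientation, radians
    tilt: float           # out-of-plane tilt, radians; 0 = horizontal
    depth_um: float
    length_um: float
    width_um: float
    is_torch: bool = False

    @property
    def radius_nm(self) -> float:
        return self.width_um * 1000.0 / 2.0

    @property
    def seg_half_nm(self) -> float:
        cyl = (self.length_um - self.width_um) * 1000.0
        return 0.5 * cyl * float(np.cos(self.tilt))

    @property
    def endpoints_nm(self) -> tuple[np.ndarray, np.ndarray]:
        u = np.array([np.cos(self.phi), np.sin(self.phi)])
        c = np.array([self.cx_nm, self.cy_nm])
        return c - self.seg_half_nm * u, c + self.seg_half_nm * u

    @property
    def area_um2(self) -> float:
        """Projected footprint area in um^2."""
        r = self.radius_nm
        a_nm2 = 2.0 * r * 2.0 * self.seg_half_nm + np.pi * r**2
        return float(a_nm2) / 1e6

    def contains(self, x_nm: np.ndarray, y_nm: np.ndarray) -> np.ndarray:
        p0, p1 = self.endpoints_nm
        d = p1 - p0
        L2 = float(d @ d)
        px = np.asarray(x_nm) - p0[0]
        py = np.asarray(y_nm) - p0[1]
        if L2 == 0.0:
            dist2 = px**2 + py**2
        else:
            t = np.clip((px * d[0] + py * d[1]) / L2, 0.0, 1.0)
            dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2
        return dist2 <= self.radius_nm**2

    def sample_points(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Exactly uniform samples over the capsule footprint (nm)."""
        r = self.radius_nm
        h = self.seg_half_nm
        rect_area = 4.0 * r * h
        cap_area = np.pi * r**2
        in_rect = rng.random(n) < rect_area / (rect_area + cap_area)
        ax = np.empty(n)
        perp = np.empty(n)
        k = int(in_rect.sum())
        ax[in_rect] = rng.uniform(-h, h, k)
        perp[in_rect] = rng.uniform(-r, r, k)
        m = n - k
        # uniform in a disk; positive axial half attaches to +end cap
        rr = r * np.sqrt(rng.random(m))
        th = rng.uniform(0.0, 2.0 * np.pi, m)
        dx, dy = rr * np.cos(th), rr * np.sin(th)
        ax[~in_rect] = np.where(dx >= 0, h + dx, -h + dx)
        perp[~in_rect] = dy
        u = np.array([np.cos(self.phi), np.sin(self.phi)])
        v = np.array([-u[1], u[0]])
        x = self.cx_nm + ax * u[0] + perp * v[0]
        y = self.cy_nm + ax * u[1] + perp * v[1]
        return x, y


@dataclass
class SyntheticScene:
    """Ground truth for one lateral position: cells and their molecules."""

    params: SceneParams
    cells: list[Cell]
    mol_x_nm: np.ndarray
    mol_y_nm: np.ndarray
    mol_depth_um: np.ndarray
    mol_cell: np.ndarray  # index into ``cells``

    def cells_at(self, depth_um: float) -> list[Cell]:
        return [c for c in self.cells if c.depth_um == float(depth_um)]

    def cell_indices_at(self, depth_um: float) -> np.ndarray:
        return np.asarray(
            [i for i, c in enumerate(self.cells) if c.depth_um == float(depth_um)],
            dtype=int,
        )

    def molecule_indices_at(self, depth_um: float) -> np.ndarray:
        return np.flatnonzero(self.mol_depth_um == float(depth_um))

    def n_molecules_at(self, depth_um: float) -> int:
        return int(self.molecule_indices_at(depth_um).size)

    def footprint_area_um2(self, depth_um: float) -> float:
        return float(sum(c.area_um2 for c in self.cells_at(depth_um)))

    def ground_truth_density(self, depth_um: float) -> float:
        """True molecules per um^2 of cell footprint requested at this depth."""
        return float(self.params.molecule_density_fn(float(depth_um)))


def generate_scene(params: SceneParams, seed: int | None = None) -> SyntheticScene:
    """Place cells and molecules for every imaging depth of one position.

    Cells may overlap (dense biofilms do); centers keep a half-length margin
    from the FOV edge so footprints, and hence molecules, stay inside the FOV.
    Per-cell molecule counts are Poisson with mean
    ``molecule_density(depth) * footprint_area``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    h_fn = params.horizontal_fraction_fn
    rho_fn = params.molecule_density_fn
    W = params.fov_width_um * 1000.0
    H = params.fov_height_um * 1000.0
    margin = params.cell_length_um * 1000.0 / 2.0
    if 2 * margin >= min(W, H):
        raise ValueError("cell length does not fit inside the FOV")

    cells: list[Cell] = []
    xs, ys, zs, owners = [], [], [], []
    for z in params.plane_depths_um:
        h = float(np.clip(h_fn(z), 0.0, 1.0))
        rho = float(rho_fn(z))
        if rho < 0:
            raise ValueError("molecule_density must be non-negative")
        for _ in range(params.n_cells_per_plane):
            horizontal = rng.random() < h
            # isotropic axis orientation: sin(tilt) uniform in [0, 1)
            tilt = 0.0 if horizontal else float(np.arcsin(rng.random()))
            cell = Cell(
                cx_nm=float(rng.uniform(margin, W - margin)),
                cy_nm=float(rng.uniform(margin, H - margin)),
                phi=float(rng.uniform(0.0, 2.0 * np.pi)),
                tilt=tilt,
                depth_um=float(z),
                length_um=params.cell_length_um,
                width_um=params.cell_width_um,
                is_torch=bool(rng.random() < params.torch_fraction),
            )
            idx = len(cells)
            cells.append(cell)
            n_mol = int(rng.poisson(rho * cell.area_um2))
            if n_mol:
                mx, my = cell.sample_points(rng, n_mol)
                xs.append(mx)
                ys.append(my)
                zs.append(np.full(n_mol, float(z)))
                owners.append(np.full(n_mol, idx, dtype=int))

    cat = lambda parts, dtype=float: (
        np.concatenate(parts) if parts else np.empty(0, dtype=dtype)
    )
    return SyntheticScene(
        params=params,
        cells=cells,
        mol_x_nm=cat(xs),
        mol_y_nm=cat(ys),
        mol_depth_um=cat(zs),
        mol_cell=cat(owners, dtype=int).astype(int),
    )


@dataclass
class FovTruth:
    """Hidden ground truth for one simulated FOV (sidecar, not in the CSV)."""

    depth_um: float
    n_molecules: int            # molecules present at this depth
    n_detected: int             # activated within the window and detected
    pre_source: np.ndarray      # per pre-table row: "spurious" | "torch"
    act_source: np.ndarray      # per act-table row: + "molecule"
    act_emitter_id: np.ndarray  # molecule index, -1 for non-molecule rows
    pre_outlier: np.ndarray     # rows given filter-violating quality values
    act_outlier: np.ndarray

    @property
    def n_distinct_act_emitters(self) -> int:
        ids = self.act_emitter_id
        return int(np.unique(ids[ids >= 0]).size)


def _quality_fields(
    rng: np.random.Generator, n: int, kin: PhotokineticsParams
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Uniform in filter-passing ranges, with an outlier fraction violating
    exactly one randomly chosen filter condition each."""
    q = {
        "sigma [nm]": rng.uniform(*kin.sigma_range, n),
        "intensity [photon]": rng.uniform(*kin.intensity_range, n),
        "offset [photon]": rng.uniform(*kin.offset_range, n),
        "bkgstd [photon]": rng.uniform(*kin.bkgstd_range, n),
        "uncertainty [nm]": rng.uniform(*kin.uncertainty_range, n),
    }
    outlier = rng.random(n) < kin.outlier_fraction
    kinds = rng.integers(0, 6, n)
    viol = {
        0: ("offset [photon]", 0.25),   # offset <= 0.5
        1: ("offset [photon]", 7.0),    # offset >= 6
        2: ("sigma [nm]", 350.0),       # sigma >= 300
        3: ("uncertainty [nm]", 80.0),  # uncertainty >= 60
        4: ("bkgstd [photon]", 3.0),    # bkgstd >= 2.3
        5: ("intensity [photon]", 500.0),  # intensity >= 400
    }
    for k, (col, value) in viol.items():
        sel = outlier & (kinds == k)
        q[col][sel] = value
    return q, outlier


def simulate_fov(
    scene: SyntheticScene,
    kinetics: PhotokineticsParams,
    depth_um: float,
    seed: int | np.random.Generator,
) -> tuple[LocalizationTable, LocalizationTable, FovTruth]:
    """Simulate the paired pre-activation / activation videos for one depth.

    The pre video spans frames ``1..n_pre`` and contains only spurious and
    torch localizations; the activation video spans the following
    ``n_act`` frames and adds molecule emission.  The spurious exponential
    decays continuously across the boundary.
    """
    depth_um = float(depth_um)
    if depth_um not in scene.params.plane_depths_um:
        raise ValueError(
            f"depth {depth_um} um is not one of the scene planes "
            f"{scene.params.plane_depths_um}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_pre, n_act = kinetics.n_pre_frames, kinetics.n_act_frames
    n_total = n_pre + n_act
    W = scene.params.fov_width_um * 1000.0
    H = scene.params.fov_height_um * 1000.0
    cells = scene.cells_at(depth_um)
    areas = np.asarray([c.area_um2 for c in cells])

    frames: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    sources: list[np.ndarray] = []
    emitters: list[np.ndarray] = []

    # --- spurious (photoactivation-independent) localizations -------------
    f_all = np.arange(1, n_total + 1)
    rate = kinetics.spurious_amplitude * np.exp(-kinetics.spurious_decay * f_all)
    counts = rng.poisson(rate)
    n_spur = int(counts.sum())
    if n_spur:
        sp_frames = np.repeat(f_all, counts)
        sx = np.empty(n_spur)
        sy = np.empty(n_spur)
        free = rng.random(n_spur) < scene.params.free_background_fraction
        if len(cells) == 0:
            free[:] = True
        n_free = int(free.sum())
        sx[free] = rng.uniform(0.0, W, n_free)
        sy[free] = rng.uniform(0.0, H, n_free)
        n_in = n_spur - n_free
        if n_in:
            probs = areas / areas.sum()
            pick = rng.choice(len(cells), size=n_in, p=probs)
            ix = np.empty(n_in)
            iy = np.empty(n_in)
            for ci in np.unique(pick):
                sel = pick == ci
                ix[sel], iy[sel] = cells[ci].sample_points(rng, int(sel.sum()))
            sx[~free] = ix
            sy[~free] = iy
        frames.append(sp_frames)
        xs.append(sx)
        ys.append(sy)
        sources.append(np.full(n_spur, "spurious"))
        emitters.append(np.full(n_spur, -1, dtype=int))

    # --- torch cells: constant activation-independent rate ----------------
    for cell in cells:
        if not cell.is_torch or kinetics.torch_rate <= 0:
            continue
        t_counts = rng.poisson(kinetics.torch_rate, n_total)
        n_t = int(t_counts.sum())
        if n_t == 0:
            continue
        tx, ty = cell.sample_points(rng, n_t)
        frames.append(np.repeat(f_all, t_counts))
        xs.append(tx)
        ys.append(ty)
        sources.append(np.full(n_t, "torch"))
        emitters.append(np.full(n_t, -1, dtype=int))

    # --- molecules: single irreversible activation ------------------------
    mol_idx = scene.molecule_indices_at(depth_um)
    n_mol = mol_idx.size
    eff = float(np.clip(kinetics.detection_efficiency_fn(depth_um), 0.0, 1.0))
    sig = float(kinetics.loc_sigma_fn(depth_um))
    n_detected = 0
    if n_mol:
        detected = rng.random(n_mol) < eff
        t_act = rng.geometric(kinetics.activation_rate, n_mol)  # offset in act video
        within = t_act <= n_act
        if kinetics.mean_on_frames <= 1.0:
            dur = np.ones(n_mol, dtype=int)
        else:
            dur = rng.geometric(1.0 / kinetics.mean_on_frames, n_mol)
        active = detected & within
        n_detected = int(active.sum())
        for m in np.flatnonzero(active):
            gid = int(mol_idx[m])
            f0 = n_pre + int(t_act[m])
            f1 = min(f0 + int(dur[m]) - 1, n_total)
            ff = np.arange(f0, f1 + 1)
            k = ff.size
            mx = scene.mol_x_nm[gid] + rng.normal(0.0, sig, k)
            my = scene.mol_y_nm[gid] + rng.normal(0.0, sig, k)
            frames.append(ff)
            xs.append(np.clip(mx, 0.0, W))
            ys.append(np.clip(my, 0.0, H))
            sources.append(np.full(k, "molecule"))
            emitters.append(np.full(k, gid, dtype=int))

    if frames:
        frame_arr = np.concatenate(frames)
        x_arr = np.concatenate(xs)
        y_arr = np.concatenate(ys)
        src_arr = np.concatenate(sources)
        emit_arr = np.concatenate(emitters)
    else:
        frame_arr = np.empty(0, dtype=int)
        x_arr = y_arr = np.empty(0)
        src_arr = np.empty(0, dtype=object)
        emit_arr = np.empty(0, dtype=int)

    order = np.argsort(frame_arr, kind="stable")
    frame_arr, x_arr, y_arr = frame_arr[order], x_arr[order], y_arr[order]
    src_arr, emit_arr = src_arr[order], emit_arr[order]

    quality, outlier = _quality_fields(rng, frame_arr.size, kinetics)

    def build(mask: np.ndarray, role: str, frange: tuple[int, int]) -> LocalizationTable:
        df = pd.DataFrame(
            {
                "frame": frame_arr[mask].astype(np.int64),
                "x [nm]": x_arr[mask],
                "y [nm]": y_arr[mask],
                "sigma [nm]": quality["sigma [nm]"][mask],
                "intensity [photon]": quality["intensity [photon]"][mask],
                "offset [photon]": quality["offset [photon]"][mask],
                "bkgstd [photon]": quality["bkgstd [photon]"][mask],
                "uncertainty [nm]": quality["uncertainty [nm]"][mask],
            }
        )
        meta = TableMeta(depth_um=depth_um, role=role, frame_range=frange)
        return LocalizationTable(df, meta=meta)

    pre_mask = frame_arr <= n_pre
    act_mask = ~pre_mask
    pre = build(pre_mask, "pre", (1, n_pre))
    act = build(act_mask, "activation", (n_pre + 1, n_total))
    truth = FovTruth(
        depth_um=depth_um,
        n_molecules=int(n_mol),
        n_detected=n_detected,
        pre_source=src_arr[pre_mask],
        act_source=src_arr[act_mask],
        act_emitter_id=emit_arr[act_mask],
        pre_outlier=outlier[pre_mask],
        act_outlier=outlier[act_mask],
    )
    return pre, act, truth


def write_fov(
    pre: LocalizationTable,
    act: LocalizationTable,
    truth: FovTruth,
    directory: str | Path,
    stem: str,
) -> dict[str, Path]:
    """Write ``<stem>_pre.csv``, ``<stem>_act.csv`` and a ground-truth sidecar.

    The sidecar ``<stem>_truth.tsv`` is tab-separated with columns
    ``video`` (pre|act), ``row`` (0-based row in that CSV), ``source``
    (molecule|spurious|torch), ``emitter_id`` (-1 for non-molecule rows) and
    ``outlier`` (0/1: quality fields drawn to violate the filter).  A JSON
    summary ``<stem>_truth.json`` records the per-FOV counts.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "pre": directory / f"{stem}_pre.csv",
        "act": directory / f"{stem}_act.csv",
        "truth": directory / f"{stem}_truth.tsv",
        "summary": directory / f"{stem}_truth.json",
    }
    write_table(pre, paths["pre"])
    write_table(act, paths["act"])
    rows = pd.DataFrame(
        {
            "video": ["pre"] * len(pre) + ["act"] * len(act),
            "row": list(range(len(pre))) + list(range(len(act))),
            "source": np.concatenate([truth.pre_source, truth.act_source]),
            "emitter_id": np.concatenate(
                [np.full(len(pre), -1, dtype=int), truth.act_emitter_id]
            ),
            "outlier": np.concatenate(
                [truth.pre_outlier, truth.act_outlier]
            ).astype(int),
        }
    )
    rows.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    with open(paths["summary"], "w") as fh:
        json.dump(
            {
                "depth_um": truth.depth_um,
                "n_molecules": truth.n_molecules,
                "n_detected": truth.n_detected,
                "n_distinct_act_emitters": truth.n_distinct_act_emitters,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return paths
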