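"""Localization-table I/O, quality filtering and overcounting merge.

Tables follow the ThunderSTORM CSV export dialect: a quoted header row

    "frame","x [nm]","y [nm]","sigma [nm]","intensity [photon]",
    "offset [photon]","bkgstd [photon]","uncertainty [nm]"

followed by one row per fitted localization.  A PALM acquisition yields one
such table per video; each field of view (FOV) has a *pre-activation* video
(readout laser only, capturing photoactivation-independent signal) and an
*activation* video (readout plus 405 nm activation light) whose frames
continue the pre-video's frame counter.

The quality filter removes outlier fits using strict inequalities on the
fitted offset, PSF sigma, localization uncertainty, background standard
deviation and intensity.  The merge step corrects overcounting caused by a
fluorophore emitting across several camera frames: localizations closer than
a radius in consecutive-frame windows are counted as a single molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

THUNDERSTORM_COLUMNS: tuple[str, ...] = (
    "frame",
    "x [nm]",
    "y [nm]",
    "sigma [nm]",
    "intensity [photon]",
    "offset [photon]",
    "bkgstd [photon]",
    "uncertainty [nm]",
)

#: Short attribute name -> ThunderSTORM column name.
_FIELD_TO_COLUMN = {
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "sigma": "sigma [nm]",
    "intensity": "intensity [photon]",
    "offset": "offset [photon]",
    "bkgstd": "bkgstd [photon]",
    "uncertainty": "uncertainty [nm]",
}


class TableFormatError(ValueError):
    """A localization file does not conform to the expected dialect."""


class TableParseError(ValueError):
    """A localization file contains a cell that cannot be parsed."""


@dataclass
class TableMeta:
    """Provenance of one localization table.

    Parameters
    ----------
    fov_id:
        Identifier of the field of view this video belongs to.
    depth_um:
        Imaging-plane depth below the coverslip/sample interface, in um.
    role:
        ``"pre"`` for the pre-activation video, ``"activation"`` for the
        photoactivation video.
    frame_range:
        Inclusive (first, last) frame indices of the video.  The activation
        video continues the pre-video's counter (default 1-1000 then
        1001-2000).
    """

    fov_id: str = ""
    depth_um: float = 0.0
    role: str = "activation"
    frame_range: tuple[int, int] | None = None


class LocalizationTable:
    """One video's localizations, sorted by frame.

    Wraps a :class:`pandas.DataFrame` holding the canonical ThunderSTORM
    columns; any extra columns found in a file are preserved, row-aligned,
    in :attr:`extra`.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        meta: TableMeta | None = None,
        extra: pd.DataFrame | None = None,
    ) -> None:
        missing = [c for c in THUNDERSTORM_COLUMNS if c not in df.columns]
        if missing:
            raise TableFormatError(f"missing mandatory column(s): {missing}")
        core = df.loc[:, list(THUNDERSTORM_COLUMNS)].reset_index(drop=True)
        if extra is None:
            extra_cols = [c for c in df.columns if c not in THUNDERSTORM_COLUMNS]
            extra = df.loc[:, extra_cols].reset_index(drop=True)
        else:
            extra = extra.reset_index(drop=True)
        order = np.argsort(core["frame"].to_numpy(), kind="stable")
        self.df = core.iloc[order].reset_index(drop=True)
        self.df["frame"] = self.df["frame"].astype(np.int64)
        self.extra = extra.iloc[order].reset_index(drop=True)
        self.meta = meta if meta is not None else TableMeta()

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LocalizationTable(n={len(self)}, fov={self.meta.fov_id!r}, "
            f"role={self.meta.role!r}, depth={self.meta.depth_um} um)"
        )

    def _col(self, name: str) -> np.ndarray:
        return self.df[_FIELD_TO_COLUMN[name]].to_numpy()

    @property
    def frame(self) -> np.ndarray:
        return self._col("frame")

    @property
    def x(self) -> np.ndarray:
        return self._col("x")

    @property
    def y(self) -> np.ndarray:
        return self._col("y")

    @property
    def sigma(self) -> np.ndarray:
        return self._col("sigma")

    @property
    def intensity(self) -> np.ndarray:
        return self._col("intensity")

    @property
    def offset(self) -> np.ndarray:
        return self._col("offset")

    @property
    def bkgstd(self) -> np.ndarray:
        return self._col("bkgstd")

    @property
    def uncertainty(self) -> np.ndarray:
        return self._col("uncertainty")

    def take(self, mask_or_indices) -> "LocalizationTable":
        """Row subset preserving order, metadata and extra columns."""
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        sub = self.df.iloc[idx]
        ext = self.extra.iloc[idx] if len(self.extra.columns) else pd.DataFrame(
            index=range(len(sub))
        )
        return LocalizationTable(sub.reset_index(drop=True), meta=replace(self.meta),
                                 extra=ext.reset_index(drop=True))


def read_table(path: str | Path, meta: TableMeta | None = None) -> LocalizationTable:
    """Read a ThunderSTORM-dialect CSV into a :class:`LocalizationTable`.

    Raises
    ------
    TableFormatError
        If a mandatory column is missing (the error names it).
    TableParseError
        If a cell in a mandatory column is not numeric (the error gives the
        1-based data row number).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip().strip('"') for c in df.columns]
    for col in THUNDERSTORM_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f'missing mandatory column "{col}" in {path}')
    for col in THUNDERSTORM_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TableParseError(
                f'non-numeric value in column "{col}", data row {row} of {path}'
            )
        df[col] = numeric
    return LocalizationTable(df, meta=meta)


def write_table(table: LocalizationTable, path: str | Path) -> None:
    """Write a table in the ThunderSTORM CSV dialect (quoted header).

    Numeric formatting uses the shortest round-trip representation, so a
    read/write cycle is byte-stable.
    """
    path = Path(path)
    cols = list(THUNDERSTORM_COLUMNS) + list(table.extra.columns)
    header = ",".join(f'"{c}"' for c in cols)
    out = table.df.copy()
    for c in table.extra.columns:
        out[c] = table.extra[c].to_numpy()
    with open(path, "w", newline="\n") as fh:
        fh.write(header + "\n")
        out.to_csv(fh, header=False, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Quality filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """Strict-inequality outlier filter on fit-quality fields.

    Defaults reproduce the empirically determined ThunderSTORM filter
    ``offset > 0.5 & offset < 6 & sigma < 300 & uncertainty < 60 &
    bkgstd < 2.3 & intensity < 400`` (photons / nm as per column units).
    """

    offset_min: float = 0.5
    offset_max: float = 6.0
    sigma_max: float = 300.0
    uncertainty_max: float = 60.0
    bkgstd_max: float = 2.3
    intensity_max: float = 400.0

    def __post_init__(self) -> None:
        if not self.offset_min < self.offset_max:
            raise ValueError("offset_min must be < offset_max")

    def mask(self, table: LocalizationTable) -> np.ndarray:
        """Boolean keep-mask; every inequality is strict, as printed."""
        return (
            (table.offset > self.offset_min)
            & (table.offset < self.offset_max)
            & (table.sigma < self.sigma_max)
            & (table.uncertainty < self.uncertainty_max)
            & (table.bkgstd < self.bkgstd_max)
            & (table.intensity < self.intensity_max)
        )


def apply_quality_filter(
    table: LocalizationTable, spec: FilterSpec | None = None
) -> LocalizationTable:
    """Drop records violating any strict filter inequality; order preserved."""
    spec = spec if spec is not None else FilterSpec()
    return table.take(np.flatnonzero(spec.mask(table)))


# ---------------------------------------------------------------------------
# Overcounting merge
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergeSpec:
    """Spatio-temporal linking rule for the overcounting merge.

    Two localizations may belong to one molecule iff their Euclidean
    distance is <= ``radius_nm`` and their frame gap is between 1 and
    ``max_frame_gap`` (localizations in the same frame are never the same
    molecule).
    """

    radius_nm: float = 30.0
    max_frame_gap: int = 10

    def __post_init__(self) -> None:
        if self.radius_nm <= 0 or self.max_frame_gap < 1:
            raise ValueError("radius_nm must be > 0 and max_frame_gap >= 1")


@dataclass
class Molecule:
    """A merged emitter: mean position over its linked appearances."""

    x: float
    y: float
    first_frame: int
    last_frame: int
    n_appearances: int
    row_indices: tuple[int, ...] = field(default_factory=tuple, repr=False)


class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def merge_localizations(
    table: LocalizationTable, spec: MergeSpec | None = None
) -> list[Molecule]:
    """Merge multi-frame appearances of single emitters into molecules.

    Linking is single-linkage over the relation *distance <= radius and
    1 <= frame gap <= max_frame_gap*: any chain of linked appearances is one
    molecule, so a fluorophore re-detected every few frames is counted once.
    Same-frame localizations are never linked directly (two simultaneous
    emitters are two molecules), though they may end up in one molecule via
    a shared earlier appearance.  Returned molecules are ordered by first
    frame, then by first row index; positions are appearance means.
    """
    spec = spec if spec is not None else MergeSpec()
    n = len(table)
    if n == 0:
        return []
    frames = table.frame
    pts = np.column_stack([table.x, table.y])
    dsu = _DisjointSet(n)

    # Rows grouped by frame (frames are sorted already).
    uniq_frames, starts = np.unique(frames, return_index=True)
    groups: dict[int, np.ndarray] = {}
    bounds = list(starts) + [n]
    for k, f in enumerate(uniq_frames):
        groups[int(f)] = np.arange(bounds[k], bounds[k + 1])

    for f in uniq_frames:
        f = int(f)
        prev_idx = [groups[g] for g in range(f - spec.max_frame_gap, f) if g in groups]
        if not prev_idx:
            continue
        prev = np.concatenate(prev_idx)
        tree = cKDTree(pts[prev])
        cur = groups[f]
        hits = tree.query_ball_point(pts[cur], r=spec.radius_nm)
        for i, neigh in zip(cur, hits):
            for j in neigh:
                dsu.union(int(i), int(prev[j]))

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(dsu.find(i), []).append(i)

    molecules = []
    for rows in comps.values():
        rows_arr = np.asarray(rows)
        molecules.append(
            Molecule(
                x=float(pts[rows_arr, 0].mean()),
                y=float(pts[rows_arr, 1].mean()),
                first_frame=int(frames[rows_arr].min()),
                last_frame=int(frames[rows_arr].max()),
                n_appearances=len(rows),
                row_indices=tuple(int(r) for r in rows),
            )
        )
    molecules.sort(key=lambda m: (m.first_frame, m.row_indices[0]))
    return molecules


def molecule_positions(molecules: Sequence[Molecule]) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) arrays in nm for a list of merged molecules."""
    if len(molecules) == 0:
        return np.empty(0), np.empty(0)
    return (
        np.asarray([m.x for m in molecules]),
        np.asarray([m.y for m in molecules]),
    )


def write_molecules(molecules: Sequence[Molecule], path: str | Path) -> None:
    """Write merged molecules as CSV.

    Header: ``x [nm],y [nm],first_frame,last_frame,n_appearances``.
    """
    df = pd.DataFrame(
        {
            "x [nm]": [m.x for m in molecules],
            "y [nm]": [m.y for m in molecules],
            "first_frame": [m.first_frame for m in molecules],
            "last_frame": [m.last_frame for m in molecules],
            "n_appearances": [m.n_appearances for m in molecules],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")
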