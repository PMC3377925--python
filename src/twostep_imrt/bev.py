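"""Beam and MLC geometry: gantry angles and beam's-eye-view projections.

Conventions
-----------
Patient coordinates are in mm with the isocenter at the origin: ``x`` is
lateral, ``y`` anterior (towards the gantry at angle 0), ``z`` the patient
longitudinal axis.  Gantry angles follow IEC 61217: 0 deg means the beam
enters from anterior, angles increase clockwise when viewed from the
patient's feet.  Beams are coplanar; MLC leaf pairs stack along ``z`` and
travel in the axial plane, so the BEV travel axis ``u`` lies in the axial
plane and the stacking axis ``v`` is parallel to ``z``.

All projections are divergent (point source at distance SAD from the
isocenter) onto the isocenter plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Beam",
    "MLCModel",
    "BEVMask",
    "mlc_preset",
    "equidistant_angles",
    "project_structure",
]


@dataclass(frozen=True)
class Beam:
    """One coplanar treatment beam.

    Parameters
    ----------
    gantry_angle_deg:
        IEC 61217 gantry angle; normalized into [0, 360).
    isocenter:
        Isocenter position in patient coordinates (mm).
    sad:
        Source-axis distance in mm (default 1000).
    """

    gantry_angle_deg: float
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sad: float = 1000.0

    def __post_init__(self) -> None:
        if self.sad <= 0:
            raise ValueError("sad must be positive")
        object.__setattr__(self, "gantry_angle_deg", float(self.gantry_angle_deg) % 360.0)

    @property
    def source_position(self) -> np.ndarray:
        """Source location in patient coordinates (mm)."""
        th = np.deg2rad(self.gantry_angle_deg)
        iso = np.asarray(self.isocenter, dtype=float)
        return iso + self.sad * np.array([np.sin(th), np.cos(th), 0.0])

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from source towards the isocenter."""
        th = np.deg2rad(self.gantry_angle_deg)
        return -np.array([np.sin(th), np.cos(th), 0.0])

    @property
    def travel_axis(self) -> np.ndarray:
        """BEV ``u`` unit vector (leaf travel direction, axial plane)."""
        th = np.deg2rad(self.gantry_angle_deg)
        return np.array([np.cos(th), -np.sin(th), 0.0])

    @property
    def stack_axis(self) -> np.ndarray:
        """BEV ``v`` unit vector (leaf stacking direction, +z)."""
        return np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class MLCModel:
    """Multi-leaf collimator description at the isocenter plane.

    ``leaf_width`` is the projected leaf width in mm; leaf pair rows are
    centred on ``v = 0``.  ``max_field_extent`` is the half-extent of leaf
    travel in mm, i.e. leaves may open anywhere within
    [-max_field_extent, +max_field_extent].
    """

    leaf_width: float
    n_leaf_pairs: int
    max_field_extent: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.leaf_width <= 0:
            raise ValueError("leaf_width must be positive")
        if self.n_leaf_pairs < 1:
            raise ValueError("need at least one leaf pair")
        if self.max_field_extent <= 0:
            raise ValueError("max_field_extent must be positive")

    def row_centers(self) -> np.ndarray:
        """``v`` coordinates (mm) of leaf pair row centres."""
        n = self.n_leaf_pairs
        return (np.arange(n) - (n - 1) / 2.0) * self.leaf_width


#: MLC presets: a 4 mm leaf collimator and a 10 mm leaf collimator, the two
#: leaf widths used in the planning study.
_MLC_PRESETS = {
    "s4": MLCModel(leaf_width=4.0, n_leaf_pairs=40, max_field_extent=160.0, name="s4"),
    "s10": MLCModel(leaf_width=10.0, n_leaf_pairs=40, max_field_extent=200.0, name="s10"),
}


def mlc_preset(name: str) -> MLCModel:
    """Return a named MLC preset (``s4`` = 4 mm leaves, ``s10`` = 10 mm)."""
    try:
        return _MLC_PRESETS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown MLC preset {name!r}; choose from {sorted(_MLC_PRESETS)}")


@dataclass
class BEVMask:
    """Beam's-eye-view occupancy raster of one structure.

    Rows correspond to MLC leaf pairs (stacking axis ``v``), columns to the
    travel axis ``u`` at ``resolution`` mm.  ``mask[r, c]`` is True when the
    ray from the source through cell centre ``(u[c], v[r])`` on the
    isocenter plane intersects the structure.
    """

    mask: np.ndarray          # (n_rows, n_cols) bool
    u: np.ndarray             # column centres, mm
    v: np.ndarray             # row centres, mm
    resolution: float         # mm along u
    leaf_width: float         # mm along v

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.resolution * self.leaf_width

    def row_extent(self, row: int) -> tuple[float, float] | None:
        """Return (min, max) occupied cell-centre ``u`` in a row, or None."""
        cols = np.nonzero(self.mask[row])[0]
        if cols.size == 0:
            return None
        return float(self.u[cols[0]]), float(self.u[cols[-1]])


def equidistant_angles(n: int, start_deg: float = 0.0, arc_deg: float = 360.0) -> np.ndarray:
    """Equidistant gantry angles over a full circle or partial arc.

    For a full circle the spacing is ``arc/n`` (no duplicate beam at
    start+360); for a partial arc the ``n`` beams span the arc inclusively
    with spacing ``arc/(n-1)``.  All angles are normalized to [0, 360).
    """
    if n < 1:
        raise ValueError("need at least one beam")
    if not 0 < arc_deg <= 360:
        raise ValueError("arc_deg must be in (0, 360]")
    if arc_deg == 360:
        ang = start_deg + np.arange(n) * (arc_deg / n)
    elif n == 1:
        ang = np.array([start_deg], dtype=float)
    else:
        ang = start_deg + np.arange(n) * (arc_deg / (n - 1))
    return np.mod(ang, 360.0)


# ---------------------------------------------------------------------------
# projection


def _voxel_coords(case) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre coordinate vectors (mm) for each grid axis."""
    out = []
    for n, dv in zip(case.grid_shape, case.voxel_size):
        out.append((np.arange(n) - (n - 1) / 2.0) * dv)
    return tuple(out)


def _mask_bbox_corners(case, mask: np.ndarray) -> np.ndarray:
    """Corners (8, 3) in mm of the voxel-centre bounding box of a mask."""
    idx = np.nonzero(mask)
    xs, ys, zs = _voxel_coords(case)
    los = [xs[idx[0].min()], ys[idx[1].min()], zs[idx[2].min()]]
    his = [xs[idx[0].max()], ys[idx[1].max()], zs[idx[2].max()]]
    corners = np.array(
        [[a, b, c] for a in (los[0], his[0]) for b in (los[1], his[1]) for c in (los[2], his[2])]
    )
    return corners


def _project_points(points: np.ndarray, beam: Beam) -> tuple[np.ndarray, np.ndarray]:
    """Project points (N, 3) through the source onto the isocenter plane."""
    src = beam.source_position
    rel = points - src
    t = rel @ beam.axis
    u = beam.sad * (rel @ beam.travel_axis) / t
    v = beam.sad * (rel @ beam.stack_axis) / t
    return u, v


def project_structure(
    case,
    structure: str,
    beam: Beam,
    mlc: MLCModel,
    resolution: float = 1.0,
) -> BEVMask:
    """Divergent BEV projection of a structure onto the isocenter plane.

    A BEV cell is occupied iff the ray from the source through the cell
    centre intersects the structure mask (sampled at half the smallest voxel
    size along the ray).  Deterministic for fixed inputs.
    """
    if resolution > mlc.leaf_width / 2:
        raise ValueError("BEV resolution must be <= leaf_width / 2")
    k = mlc.leaf_width / resolution
    if abs(k - round(k)) > 1e-9:
        raise ValueError("BEV resolution must divide the leaf width")
    mask3d = case.structures[structure]

    v_rows = mlc.row_centers()
    n_cols = 2 * int(np.ceil(mlc.max_field_extent / resolution)) + 1
    u_cols = (np.arange(n_cols) - (n_cols - 1) / 2.0) * resolution
    bev = np.zeros((v_rows.size, u_cols.size), dtype=bool)
    out = BEVMask(mask=bev, u=u_cols, v=v_rows, resolution=resolution, leaf_width=mlc.leaf_width)
    if not mask3d.any():
        return out

    # Restrict candidate cells using the projected bounding box of the mask:
    # the perspective image of a box is contained in the convex hull of its
    # projected corners.
    corners = _mask_bbox_corners(case, mask3d)
    cu, cv = _project_points(corners, beam)
    margin = max(case.voxel_size) + resolution
    cand_c = np.nonzero((u_cols >= cu.min() - margin) & (u_cols <= cu.max() + margin))[0]
    cand_r = np.nonzero((v_rows >= cv.min() - mlc.leaf_width) & (v_rows <= cv.max() + mlc.leaf_width))[0]
    if cand_c.size == 0 or cand_r.size == 0:
        return out

    src = beam.source_position
    iso = np.asarray(beam.isocenter, dtype=float)
    rr, cc = np.meshgrid(cand_r, cand_c, indexing="ij")
    plane_pts = (
        iso[None, :]
        + u_cols[cc].ravel()[:, None] * beam.travel_axis[None, :]
        + v_rows[rr].ravel()[:, None] * beam.stack_axis[None, :]
    )
    dirs = plane_pts - src[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    center = corners.mean(axis=0)
    radius = float(np.linalg.norm(corners - center, axis=1).max())
    dist_c = float(np.linalg.norm(center - src))
    step = min(case.voxel_size) / 2.0
    tvals = np.arange(dist_c - radius - step, dist_c + radius + step, step)

    shape = np.asarray(case.grid_shape)
    voxel = np.asarray(case.voxel_size, dtype=float)
    half = (shape - 1) / 2.0
    hit = np.zeros(dirs.shape[0], dtype=bool)
    # chunk over samples to bound memory
    for t0 in range(0, tvals.size, 64):
        ts = tvals[t0 : t0 + 64]
        pts = src[None, None, :] + ts[:, None, None] * dirs[None, :, :]
        idx = np.rint(pts / voxel + half).astype(np.int64)
        ok = np.all((idx >= 0) & (idx < shape), axis=2)
        flat = (idx[..., 0] * shape[1] + idx[..., 1]) * shape[2] + idx[..., 2]
        flat[~ok] = 0
        inside = mask3d.ravel()[flat] & ok
        hit |= inside.any(axis=0)
        if hit.all():
            break
    bev[rr.ravel()[hit], cc.ravel()[hit]] = True
    return out
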