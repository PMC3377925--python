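"""Synthetic voxel phantoms and per-case objective templates.

Three presets stand in for the study geometries:

``quasimodo``
    A horseshoe-shaped PTV partially enclosing a central cylindrical OAR
    inside an elliptical water-equivalent body — a hard test of the dose
    gradient between a concave target and the organ it wraps around.
``sib``
    Nested PTVs (outer target plus an inner simultaneous-integrated-boost
    volume) with a dominant OAR indenting the outer PTV, prostate/rectum or
    spine/cord like.
``tangent``
    A crescent (breast-like) PTV hugging the body surface next to a large
    lateral lung-like OAR, intended for partial-arc planning.

All phantoms are 3D voxel grids with a small longitudinal extent: the
planning problems are effectively 2.5D (structures are uniform along z), so
coplanar-beam planning is meaningful while staying cheap.  Masks are
voxel-centre rasterizations of analytic shapes, which keeps them testable
against closed-form volumes and distances.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optimize import ObjectiveTerm

__all__ = [
    "CaseGeometry",
    "ObjectiveTemplate",
    "QuasimodoParams",
    "SIBParams",
    "TangentParams",
    "make_phantom",
    "make_objective_template",
    "structure_volume",
    "save_case",
]


class PhantomError(ValueError):
    """Raised for inadmissible phantom parameters."""


@dataclass
class CaseGeometry:
    """Voxel grid, labelled structure masks and prescription levels.

    ``structures`` maps names to boolean masks on the grid; ``prescription``
    maps PTV names to the dose (Gy per fraction) that defines 100% for that
    target.  The grid is centred on the isocenter.
    """

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    structures: dict[str, np.ndarray]
    prescription: dict[str, float]
    case_name: str = "case"

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def reference_dose(self) -> float:
        """Primary prescription (Gy): the 'ptv' level if present, else max."""
        if "ptv" in self.prescription:
            return self.prescription["ptv"]
        return max(self.prescription.values())

    def validate(self) -> None:
        body = self.structures.get("body")
        if body is None:
            raise PhantomError("phantom must define a 'body' mask")
        for name, mask in self.structures.items():
            if mask.shape != tuple(self.grid_shape):
                raise PhantomError(f"mask {name!r} does not match the grid")
            if name != "body" and np.any(mask & ~body):
                raise PhantomError(f"structure {name!r} is not a subset of body")
        if "ptv" in self.structures and "oar_primary" in self.structures:
            if np.any(self.structures["ptv"] & self.structures["oar_primary"]):
                raise PhantomError("ptv and oar_primary overlap")
        if "ptv_boost" in self.structures:
            if np.any(self.structures["ptv_boost"] & ~self.structures["ptv"]):
                raise PhantomError("ptv_boost is not a subset of ptv")


@dataclass
class ObjectiveTemplate:
    """A per-case set of DVH objectives (see :class:`~.optimize.ObjectiveTerm`)."""

    objectives: list[ObjectiveTerm]

    @property
    def count(self) -> int:
        return len(self.objectives)

    def validate(self, case: CaseGeometry) -> None:
        for term in self.objectives:
            if term.structure not in case.structures:
                raise PhantomError(f"objective references unknown structure {term.structure!r}")
            if not 0.1 <= term.weight <= 100:
                raise PhantomError("objective weights must lie in [0.1, 100]")
        for ptv in case.prescription:
            kinds = [t.kind for t in self.objectives if t.structure == ptv]
            if kinds.count("lower") < 2 or kinds.count("upper") < 2:
                raise PhantomError(f"PTV {ptv!r} needs >=2 lower and >=2 upper objectives")


# ---------------------------------------------------------------------------
# geometry helpers


def _grids(grid_shape, voxel_size):
    nx, ny, _ = grid_shape
    dx, dy, _ = voxel_size
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    return np.meshgrid(x, y, indexing="ij")


def _extrude(mask2d: np.ndarray, nz: int) -> np.ndarray:
    return np.repeat(mask2d[:, :, None], nz, axis=2)


def dilate_mm(mask: np.ndarray, radius_mm: float, voxel_size) -> np.ndarray:
    """Dilate a mask by a Euclidean radius in mm."""
    if radius_mm <= 0:
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask, sampling=voxel_size)
    return d <= radius_mm


def erode_mm(mask: np.ndarray, radius_mm: float, voxel_size) -> np.ndarray:
    """Erode a mask by a Euclidean radius in mm."""
    if radius_mm <= 0:
        return mask.copy()
    d = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    return d > radius_mm


def _sector(xx, yy, center, dir_deg, half_deg):
    """Angular sector around direction ``dir_deg`` (0 = +y, clockwise to +x)."""
    ang = np.degrees(np.arctan2(xx - center[0], yy - center[1]))
    diff = (ang - dir_deg + 180.0) % 360.0 - 180.0
    return np.abs(diff) <= half_deg


# ---------------------------------------------------------------------------
# presets


@dataclass(frozen=True)
class QuasimodoParams:
    """Horseshoe phantom parameters (mm / deg).

    The published phantom's exact dimensions live in its own report; these
    defaults are documented approximations: an elliptical body of
    300 x 200 mm, a 25 mm radius central OAR, a 20 mm thick PTV annulus at a
    5 mm gap with a 90 deg posterior opening.
    """

    body_semiaxes: tuple[float, float] = (150.0, 100.0)
    oar_radius: float = 25.0
    gap_mm: float = 5.0
    ptv_thickness: float = 20.0
    opening_deg: float = 90.0
    opening_dir_deg: float = 180.0
    oar_center: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class SIBParams:
    """Nested-PTV (simultaneous integrated boost) phantom parameters (mm)."""

    core_center: tuple[float, float] = (0.0, 20.0)
    core_radius: float = 24.0
    margin_mm: float = 10.0
    boost_margin_mm: float = 5.0
    oar_center: tuple[float, float] = (0.0, -22.0)
    oar_radius: float = 14.0
    oar_margin_mm: float = 4.0
    secondary_center: tuple[float, float] = (34.0, 42.0)
    secondary_radius: float = 9.0
    body_semiaxes: tuple[float, float] = (150.0, 100.0)


@dataclass(frozen=True)
class TangentParams:
    """Breast-like crescent PTV next to a large lateral OAR (mm / deg)."""

    body_semiaxes: tuple[float, float] = (150.0, 100.0)
    lung_center: tuple[float, float] = (45.0, -15.0)
    lung_radius: float = 55.0
    gap_mm: float = 5.0
    ptv_thickness: float = 22.0
    sector_dir_deg: float = 35.0
    sector_half_deg: float = 70.0
    heart_center: tuple[float, float] = (-25.0, -40.0)
    heart_radius: float = 24.0
    contra_lung_center: tuple[float, float] = (-62.0, -15.0)
    contra_lung_radius: float = 28.0


def _check_gap(gap_mm: float, voxel_size) -> None:
    if gap_mm < 2.0 * max(voxel_size[0], voxel_size[1]):
        raise PhantomError(
            f"grid too coarse: PTV-OAR gap {gap_mm} mm is below two in-plane voxels"
        )


def _quasimodo(params: QuasimodoParams, grid_shape, voxel_size):
    a, b = params.body_semiaxes
    r_in = params.oar_radius + params.gap_mm
    r_out = r_in + params.ptv_thickness
    cx, cy = params.oar_center
    if not 0 < params.opening_deg < 180:
        raise PhantomError("opening_deg must lie in (0, 180) for a horseshoe PTV")
    if np.hypot(cx, cy) + params.oar_radius > r_in:
        raise PhantomError("inconsistent radii: OAR is not inside the PTV concavity")
    if r_out > min(a, b) - 2.0:
        raise PhantomError("inconsistent radii: PTV annulus does not fit inside the body")
    _check_gap(params.gap_mm, voxel_size)

    xx, yy = _grids(grid_shape, voxel_size)
    body = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    rr = np.hypot(xx - cx, yy - cy)
    oar = rr <= params.oar_radius
    annulus = (rr >= r_in) & (rr <= r_out)
    opening = _sector(xx, yy, (cx, cy), params.opening_dir_deg, params.opening_deg / 2.0)
    ptv = annulus & ~opening & body
    neck = annulus & opening & body
    nz = grid_shape[2]
    structures = {
        "body": _extrude(body, nz),
        "oar_primary": _extrude(oar & body, nz),
        "ptv": _extrude(ptv, nz),
        "neck_help": _extrude(neck, nz),
    }
    return structures, {"ptv": 2.0}


def _sib(params: SIBParams, grid_shape, voxel_size):
    if params.boost_margin_mm >= params.margin_mm:
        raise PhantomError("boost margin must be smaller than the outer PTV margin")
    _check_gap(params.oar_margin_mm, voxel_size)
    a, b = params.body_semiaxes
    xx, yy = _grids(grid_shape, voxel_size)
    body = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    core = np.hypot(xx - params.core_center[0], yy - params.core_center[1]) <= params.core_radius
    oar = np.hypot(xx - params.oar_center[0], yy - params.oar_center[1]) <= params.oar_radius
    d_core = np.hypot(xx - params.core_center[0], yy - params.core_center[1]) - params.core_radius
    d_oar = np.hypot(xx - params.oar_center[0], yy - params.oar_center[1]) - params.oar_radius
    avoid = d_oar <= params.oar_margin_mm
    ptv = (d_core <= params.margin_mm) & ~avoid & body
    boost = (d_core <= params.boost_margin_mm) & ~avoid & body
    sec = (
        np.hypot(xx - params.secondary_center[0], yy - params.secondary_center[1])
        <= params.secondary_radius
    )
    if not (ptv & ~boost).any():
        raise PhantomError("outer PTV collapsed onto the boost volume")
    nz = grid_shape[2]
    structures = {
        "body": _extrude(body, nz),
        "ptv": _extrude(ptv, nz),
        "ptv_boost": _extrude(boost, nz),
        "oar_primary": _extrude(oar & body, nz),
        "oar_secondary": _extrude(sec & body, nz),
    }
    return structures, {"ptv": 1.8, "ptv_boost": 2.2}


def _tangent(params: TangentParams, grid_shape, voxel_size):
    _check_gap(params.gap_mm, voxel_size)
    a, b = params.body_semiaxes
    xx, yy = _grids(grid_shape, voxel_size)
    body = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    d_lung = np.hypot(xx - params.lung_center[0], yy - params.lung_center[1]) - params.lung_radius
    lung = (d_lung <= 0) & body
    ring = (d_lung >= params.gap_mm) & (d_lung <= params.gap_mm + params.ptv_thickness)
    sector = _sector(xx, yy, params.lung_center, params.sector_dir_deg, params.sector_half_deg)
    ptv = ring & sector & body
    heart = (
        np.hypot(xx - params.heart_center[0], yy - params.heart_center[1]) <= params.heart_radius
    ) & body
    contra_lung = (
        np.hypot(xx - params.contra_lung_center[0], yy - params.contra_lung_center[1])
        <= params.contra_lung_radius
    ) & body
    contra_breast = ptv[::-1, :] & body  # mirrored crescent on the contralateral side
    if not ptv.any():
        raise PhantomError("tangent PTV is empty for these parameters")
    nz = grid_shape[2]
    structures = {
        "body": _extrude(body, nz),
        "ptv": _extrude(ptv, nz),
        "oar_primary": _extrude(lung, nz),
        "oar_secondary": _extrude(heart, nz),
        "lung_contra": _extrude(contra_lung, nz),
        "oar_contra": _extrude(contra_breast & ~ptv, nz),
    }
    return structures, {"ptv": 2.0}


_PRESETS = {"quasimodo": (_quasimodo, QuasimodoParams), "sib": (_sib, SIBParams), "tangent": (_tangent, TangentParams)}


def make_phantom(
    preset: str,
    params=None,
    grid_shape: tuple[int, int, int] = (256, 256, 16),
    voxel_size=2.0,
) -> CaseGeometry:
    """Build a synthetic :class:`CaseGeometry` for a named preset.

    Parameters may be given as the preset's dataclass or as keyword dict.
    Raises :class:`PhantomError` for inadmissible parameters (e.g. an OAR
    that does not fit inside the PTV concavity, or a grid too coarse to
    resolve the PTV-OAR gap with at least two voxels).
    """
    if preset not in _PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    builder, cls = _PRESETS[preset]
    if params is None:
        params = cls()
    elif isinstance(params, dict):
        params = cls(**params)
    grid_shape = tuple(int(n) for n in grid_shape)
    if any(n < 1 for n in grid_shape):
        raise PhantomError("grid_shape must be positive")
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    voxel_size = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in voxel_size):
        raise PhantomError("voxel_size must be positive")

    structures, prescription = builder(params, grid_shape, voxel_size)
    for name, mask in structures.items():
        if not mask.any():
            raise PhantomError(f"generated structure {name!r} is empty; grid too small?")
    case = CaseGeometry(
        grid_shape=grid_shape,
        voxel_size=voxel_size,
        structures=structures,
        prescription=prescription,
        case_name=preset,
    )
    case.validate()
    return case


def structure_volume(case: CaseGeometry, name: str) -> float:
    """Volume of a structure in cm^3 (voxel count x voxel volume)."""
    if name not in case.structures:
        raise KeyError(f"unknown structure {name!r}")
    return float(case.structures[name].sum()) * case.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# objective templates


def _ensure_derived(case: CaseGeometry, name: str, build) -> None:
    if name not in case.structures:
        mask = build()
        if not mask.any():
            raise PhantomError(f"derived structure {name!r} is empty on this grid")
        case.structures[name] = mask


def _add_common_derived(case: CaseGeometry, plateau_erosion_mm: float = 6.0) -> None:
    vox = case.voxel_size
    ptv = case.structures["ptv"]
    body = case.structures["body"]

    def plateau():
        r = plateau_erosion_mm
        m = erode_mm(ptv, r, vox)
        while not m.any() and r > 0:  # very small PTVs: fall back gracefully
            r -= 1.0
            m = erode_mm(ptv, r, vox)
        return m

    _ensure_derived(case, "ptv_plateau", plateau)
    _ensure_derived(case, "ptv_ring", lambda: dilate_mm(ptv, 10.0, vox) & ~dilate_mm(ptv, 2.0, vox) & body)
    _ensure_derived(case, "ptv_ring2", lambda: dilate_mm(ptv, 25.0, vox) & ~dilate_mm(ptv, 12.0, vox) & body)

    def healthy():
        m = body & ~dilate_mm(ptv, 2.0, vox)
        for name in ("oar_primary", "oar_secondary"):
            if name in case.structures:
                m &= ~case.structures[name]
        return m

    _ensure_derived(case, "healthy", healthy)


def _ptv_block(structure: str, w_min=50.0, w_max=30.0):
    return [
        ObjectiveTerm(structure, "lower", 100, 95.0, w_min),
        ObjectiveTerm(structure, "lower", 98, 97.0, w_min),
        ObjectiveTerm(structure, "upper", 2, 102.0, w_max),
        ObjectiveTerm(structure, "upper", 0, 104.0, w_max),
    ]


def _plateau_block(structure: str, w=10.0):
    return [
        ObjectiveTerm(structure, "lower", 50, 98.0, w),
        ObjectiveTerm(structure, "upper", 50, 101.0, w),
    ]


def make_objective_template(case: CaseGeometry, preset: str) -> ObjectiveTemplate:
    """Build the per-case objective set.

    The per-case objective *pattern* and *count* follow the study design
    (quasimodo 14, sib-prostate 21, sib-spine 28, tangent 25 terms; each PTV
    with two lower objectives near the minimum dose, D_100 > 95 and
    D_98 > 97, and two upper objectives, D_02 < 102 and D_00 < 104, plus a
    central-plateau window).  The numeric OAR levels and weights are this
    package's defaults; all weights lie in [0.1, 100] and every term is
    configurable after construction.

    Derived helper structures (plateau, envelopes, healthy tissue, GTV) are
    rasterized on demand and added to ``case.structures``.
    """
    vox = case.voxel_size
    if "ptv" not in case.structures:
        raise PhantomError("case has no 'ptv' structure")

    if preset == "quasimodo":
        for req in ("oar_primary", "neck_help"):
            if req not in case.structures:
                raise PhantomError(f"quasimodo template requires structure {req!r}")
        _add_common_derived(case)
        terms = (
            _ptv_block("ptv")
            + _plateau_block("ptv_plateau")
            + [
                ObjectiveTerm("oar_primary", "upper", 0, 45.0, 20.0),
                ObjectiveTerm("oar_primary", "upper", 10, 35.0, 10.0),
                ObjectiveTerm("oar_primary", "upper", 50, 25.0, 5.0),
                ObjectiveTerm("ptv_ring", "upper", 5, 95.0, 5.0),
                ObjectiveTerm("ptv_ring", "upper", 50, 80.0, 2.0),
                ObjectiveTerm("healthy", "upper", 5, 70.0, 2.0),
                ObjectiveTerm("healthy", "upper", 50, 40.0, 1.0),
                ObjectiveTerm("neck_help", "upper", 50, 60.0, 1.0),
            ]
        )
    elif preset == "sib-prostate":
        for req in ("ptv_boost", "oar_primary", "oar_secondary"):
            if req not in case.structures:
                raise PhantomError(f"sib-prostate template requires structure {req!r}")
        _add_common_derived(case)
        boost = case.structures["ptv_boost"]
        _ensure_derived(case, "boost_plateau", lambda: erode_mm(boost, 4.0, vox))
        terms = (
            _ptv_block("ptv")
            + _plateau_block("ptv_plateau")
            + _ptv_block("ptv_boost")
            + _plateau_block("boost_plateau")
            + [
                ObjectiveTerm("oar_primary", "upper", 0, 75.0, 20.0),
                ObjectiveTerm("oar_primary", "upper", 20, 60.0, 10.0),
                ObjectiveTerm("oar_primary", "upper", 50, 40.0, 5.0),
                ObjectiveTerm("oar_secondary", "upper", 0, 105.0, 5.0),
                ObjectiveTerm("oar_secondary", "upper", 50, 90.0, 2.0),
                ObjectiveTerm("ptv_ring", "upper", 5, 95.0, 5.0),
                ObjectiveTerm("ptv_ring", "upper", 50, 80.0, 2.0),
                ObjectiveTerm("healthy", "upper", 5, 70.0, 2.0),
                ObjectiveTerm("healthy", "upper", 50, 40.0, 1.0),
            ]
        )
    elif preset == "sib-spine":
        for req in ("ptv_boost", "oar_primary", "oar_secondary"):
            if req not in case.structures:
                raise PhantomError(f"sib-spine template requires structure {req!r}")
        _add_common_derived(case)
        boost = case.structures["ptv_boost"]
        _ensure_derived(case, "gtv", lambda: erode_mm(boost, 4.0, vox))
        terms = (
            _ptv_block("gtv")
            + _ptv_block("ptv_boost")
            + _ptv_block("ptv")
            + _plateau_block("ptv_plateau")
            + [
                ObjectiveTerm("oar_primary", "upper", 0, 55.0, 30.0),
                ObjectiveTerm("oar_primary", "upper", 10, 45.0, 10.0),
                ObjectiveTerm("oar_primary", "upper", 50, 30.0, 5.0),
                ObjectiveTerm("oar_secondary", "upper", 0, 80.0, 5.0),
                ObjectiveTerm("oar_secondary", "upper", 10, 60.0, 2.0),
                ObjectiveTerm("oar_secondary", "upper", 50, 40.0, 1.0),
                ObjectiveTerm("ptv_ring", "upper", 0, 103.0, 5.0),
                ObjectiveTerm("ptv_ring", "upper", 5, 95.0, 5.0),
                ObjectiveTerm("ptv_ring", "upper", 50, 80.0, 2.0),
                ObjectiveTerm("ptv_ring2", "upper", 0, 95.0, 2.0),
                ObjectiveTerm("ptv_ring2", "upper", 5, 80.0, 1.0),
                ObjectiveTerm("ptv_ring2", "upper", 50, 60.0, 1.0),
                ObjectiveTerm("healthy", "upper", 5, 70.0, 2.0),
                ObjectiveTerm("healthy", "upper", 50, 40.0, 1.0),
            ]
        )
    elif preset == "tangent":
        for req in ("oar_primary", "oar_secondary", "lung_contra", "oar_contra"):
            if req not in case.structures:
                raise PhantomError(f"tangent template requires structure {req!r}")
        _add_common_derived(case)
        terms = (
            _ptv_block("ptv")
            + _plateau_block("ptv_plateau")
            + [
                ObjectiveTerm("oar_primary", "upper", 5, 60.0, 10.0),
                ObjectiveTerm("oar_primary", "upper", 20, 40.0, 5.0),
                ObjectiveTerm("oar_primary", "upper", 50, 20.0, 2.0),
                ObjectiveTerm("lung_contra", "upper", 0, 20.0, 2.0),
                ObjectiveTerm("lung_contra", "upper", 50, 10.0, 1.0),
                ObjectiveTerm("oar_secondary", "upper", 0, 50.0, 5.0),
                ObjectiveTerm("oar_secondary", "upper", 10, 35.0, 2.0),
                ObjectiveTerm("oar_secondary", "upper", 50, 15.0, 1.0),
                ObjectiveTerm("oar_contra", "upper", 0, 30.0, 2.0),
                ObjectiveTerm("oar_contra", "upper", 50, 10.0, 1.0),
                ObjectiveTerm("ptv_ring", "upper", 0, 103.0, 5.0),
                ObjectiveTerm("ptv_ring", "upper", 5, 95.0, 5.0),
                ObjectiveTerm("ptv_ring", "upper", 50, 80.0, 2.0),
                ObjectiveTerm("ptv_ring2", "upper", 0, 95.0, 2.0),
                ObjectiveTerm("ptv_ring2", "upper", 5, 80.0, 1.0),
                ObjectiveTerm("ptv_ring2", "upper", 50, 60.0, 1.0),
                ObjectiveTerm("healthy", "upper", 0, 105.0, 2.0),
                ObjectiveTerm("healthy", "upper", 5, 70.0, 2.0),
                ObjectiveTerm("healthy", "upper", 50, 40.0, 1.0),
            ]
        )
    else:
        raise KeyError(f"unknown objective preset {preset!r}")

    template = ObjectiveTemplate(objectives=terms)
    template.validate(case)
    return template


# ---------------------------------------------------------------------------
# export


def save_case(case: CaseGeometry, out_dir) -> None:
    """Write structure masks as NIfTI files plus a YAML sidecar."""
    import pathlib

    import nibabel as nib
    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(case.voxel_size) + [1.0])
    for name, mask in case.structures.items():
        img = nib.Nifti1Image(mask.astype(np.uint8), affine)
        nib.save(img, out / f"{name}.nii")
    meta = {
        "case_name": case.case_name,
        "grid_shape": list(case.grid_shape),
        "voxel_size_mm": list(case.voxel_size),
        "prescription_gy": dict(case.prescription),
        "structures": sorted(case.structures),
    }
    (out / "case.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
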