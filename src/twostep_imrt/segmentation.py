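"""Construction of S0/S1/S2 apertures and assembly of step-and-shoot plans.

The method analyses the BEV topology of the PTV and the dominant OAR per
gantry angle and builds up to three deliverable MLC aperture types:

* **S0** — PTV-conformal: each leaf pair opens over the full PTV shadow in
  its row (per-row convex hull), ignoring the OAR.
* **S1** — PTV-covering with the OAR blocked: the open interval is the
  chosen-side portion of the PTV row strictly outside the margin-expanded
  OAR shadow; rows fully covered by the OAR shadow are closed.
* **S2** — a narrow strip immediately beside the expanded OAR shadow,
  saturating the PTV rim that S1 leaves underdosed; rows without OAR shadow
  stay closed.

Single-segment-per-beam ("Fast") plans distribute segments of alternating
order over many gantry angles, e.g. ``{S1 S2}^m`` or ``{S0 S1 S2}^m``.
Beams with no valid segment of their assigned order are discarded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .bev import Beam, BEVMask, MLCModel, equidistant_angles, project_structure

__all__ = [
    "SegmentOrder",
    "Aperture",
    "Segment",
    "Plan",
    "SegmentationParams",
    "EmptyPlanError",
    "make_s0",
    "make_s1",
    "make_s2",
    "make_aperture",
    "assign_order_pattern",
    "build_fast_plan",
    "build_multisegment_plan",
]


class SegmentOrder(str, enum.Enum):
    """Segment order: conformal (S0), OAR-blocking (S1), rim strip (S2)."""

    S0 = "S0"
    S1 = "S1"
    S2 = "S2"


class EmptyPlanError(RuntimeError):
    """Raised when every beam of a plan was discarded."""


@dataclass
class Aperture:
    """One deliverable MLC shape: at most one open interval per leaf pair.

    ``x_left``/``x_right`` are interval edges in mm on the isocenter plane
    for rows where ``open_`` is True (``x_left < x_right``); closed rows
    carry zeros.  ``valid`` is False for structurally impossible shapes
    (e.g. an S2 requested where no OAR shadow exists).
    """

    x_left: np.ndarray
    x_right: np.ndarray
    open_: np.ndarray
    v: np.ndarray            # row centres, mm
    leaf_width: float
    valid: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.open_.any():
            bad = self.open_ & ~(self.x_left < self.x_right)
            if bad.any():
                raise ValueError("open rows must have x_left < x_right")

    @property
    def area_cm2(self) -> float:
        widths = np.where(self.open_, self.x_right - self.x_left, 0.0)
        return float(widths.sum() * self.leaf_width / 100.0)

    def copy(self) -> "Aperture":
        return Aperture(
            self.x_left.copy(), self.x_right.copy(), self.open_.copy(),
            self.v.copy(), self.leaf_width, self.valid, self.note,
        )

    def mirrored(self) -> "Aperture":
        """Mirror the aperture across u = 0 (left/right bank exchange)."""
        ap = self.copy()
        ap.x_left, ap.x_right = -self.x_right.copy(), -self.x_left.copy()
        return ap


@dataclass
class Segment:
    """One beam angle, one aperture, one weight in MU_eff."""

    beam: Beam
    aperture: Aperture
    order: SegmentOrder
    weight_mu: float = 0.0

    def __post_init__(self) -> None:
        if self.weight_mu < 0:
            raise ValueError("segment weight must be >= 0")


@dataclass
class Plan:
    """Ordered collection of segments grouped by beam.

    ``n_beams`` counts gantry angles with at least one segment,
    ``n_segments`` the total segment number; for Fast plans these are equal
    (one segment per retained angle).
    """

    segments: list[Segment]
    name: str = "plan"
    discard_log: list[str] = field(default_factory=list)

    @property
    def angles(self) -> list[float]:
        seen: dict[float, None] = {}
        for s in self.segments:
            seen.setdefault(s.beam.gantry_angle_deg, None)
        return list(seen)

    @property
    def n_beams(self) -> int:
        return len(self.angles)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def segments_per_angle(self) -> dict[float, int]:
        out: dict[float, int] = {}
        for s in self.segments:
            out[s.beam.gantry_angle_deg] = out.get(s.beam.gantry_angle_deg, 0) + 1
        return out

    @property
    def total_mu(self) -> float:
        return float(sum(s.weight_mu for s in self.segments))

    @property
    def angle_spacing_deg(self) -> float:
        """Spacing between consecutive beams (uniform for equidistant sets)."""
        ang = sorted(self.angles)
        if len(ang) < 2:
            return 0.0
        diffs = np.diff(ang + [ang[0] + 360.0])
        return float(np.median(diffs))


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the aperture construction.

    ``oar_margin_mm`` expands the OAR shadow before blocking (penumbra
    allowance).  ``s2_width_mm`` fixes the S2 strip width; when None the
    width follows a geometric rule: a quarter of the chosen-side PTV extent
    beyond the OAR edge in the central row, clamped to [5, 30] mm.
    ``min_open_area_cm2`` is the validity threshold below which a segment is
    discarded; the default rejects degenerate slivers while keeping the
    narrow S2 strips of the slab-like phantoms (whose longitudinal extent is
    an order of magnitude below a clinical field's) valid.  ``side`` selects
    the leaf bank relative to the dominant OAR shadow; keeping one side for
    all beams minimizes inter-beam leaf travel.
    """

    oar_margin_mm: float = 3.0
    s2_width_mm: float | None = None
    min_open_area_cm2: float = 0.5
    side: str = "left"

    def __post_init__(self) -> None:
        if self.oar_margin_mm < 0:
            raise ValueError("oar_margin_mm must be >= 0")
        if self.s2_width_mm is not None and self.s2_width_mm <= 0:
            raise ValueError("s2_width_mm must be > 0")
        if self.min_open_area_cm2 <= 0:
            raise ValueError("min_open_area_cm2 must be > 0")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


def _closed(bev: BEVMask, valid: bool, note: str = "") -> Aperture:
    n = bev.v.size
    return Aperture(
        x_left=np.zeros(n), x_right=np.zeros(n), open_=np.zeros(n, dtype=bool),
        v=bev.v.copy(), leaf_width=bev.leaf_width, valid=valid, note=note,
    )


def make_s0(ptv_bev: BEVMask, mlc: MLCModel | None = None) -> Aperture:
    """PTV-conformal aperture: per-row [min, max] hull of the PTV shadow."""
    ap = _closed(ptv_bev, valid=not ptv_bev.is_empty,
                 note="" if not ptv_bev.is_empty else "empty PTV shadow")
    if not ap.valid:
        return ap
    half = ptv_bev.resolution / 2.0
    for r in range(ptv_bev.v.size):
        ext = ptv_bev.row_extent(r)
        if ext is None:
            continue
        ap.open_[r] = True
        ap.x_left[r] = ext[0] - half
        ap.x_right[r] = ext[1] + half
    return ap


def _oar_interval(oar_bev: BEVMask, row: int, margin: float) -> tuple[float, float] | None:
    """Margin-expanded hull [left, right] of the OAR shadow in a row (mm)."""
    ext = oar_bev.row_extent(row)
    if ext is None:
        return None
    half = oar_bev.resolution / 2.0
    return ext[0] - half - margin, ext[1] + half + margin


def make_s1(
    ptv_bev: BEVMask,
    oar_bev: BEVMask,
    params: SegmentationParams,
    mlc: MLCModel | None = None,
) -> Aperture:
    """OAR-blocking aperture on the chosen side of the expanded OAR shadow.

    Rows without OAR shadow fall back to the S0 row; rows whose chosen side
    contains no PTV are closed.  The aperture never overlaps the expanded
    OAR shadow.
    """
    mirror = params.side == "right"
    if mirror:
        ptv_bev, oar_bev = _mirror_bev(ptv_bev), _mirror_bev(oar_bev)
    ap = _closed(ptv_bev, valid=not ptv_bev.is_empty,
                 note="" if not ptv_bev.is_empty else "empty PTV shadow")
    if ap.valid:
        half = ptv_bev.resolution / 2.0
        for r in range(ptv_bev.v.size):
            ext = ptv_bev.row_extent(r)
            if ext is None:
                continue
            oiv = _oar_interval(oar_bev, r, params.oar_margin_mm)
            if oiv is None:
                ap.open_[r] = True
                ap.x_left[r], ap.x_right[r] = ext[0] - half, ext[1] + half
                continue
            # PTV cells strictly left of the expanded OAR interval
            cells = np.nonzero(ptv_bev.mask[r] & (ptv_bev.u < oiv[0]))[0]
            if cells.size == 0:
                continue
            left = ptv_bev.u[cells[0]] - half
            right = min(ptv_bev.u[cells[-1]] + half, oiv[0])
            if right > left:
                ap.open_[r] = True
                ap.x_left[r], ap.x_right[r] = left, right
        if not ap.open_.any():
            ap.valid = False
            ap.note = "no PTV on the chosen side of the OAR"
    return ap.mirrored() if mirror else ap


def s2_strip_width(
    ptv_bev: BEVMask, oar_bev: BEVMask, params: SegmentationParams
) -> float:
    """Resolve the S2 strip width in mm.

    With ``s2_width_mm`` unset, take a quarter of the chosen-side PTV extent
    beyond the expanded OAR edge in the central row (the row with both PTV
    and OAR shadow closest to v = 0), clamped to [5, 30] mm.
    """
    if params.s2_width_mm is not None:
        return params.s2_width_mm
    mirror = params.side == "right"
    if mirror:
        ptv_bev, oar_bev = _mirror_bev(ptv_bev), _mirror_bev(oar_bev)
    rows = [
        r
        for r in range(ptv_bev.v.size)
        if ptv_bev.row_extent(r) is not None and oar_bev.row_extent(r) is not None
    ]
    if not rows:
        return 5.0
    r = min(rows, key=lambda r: abs(ptv_bev.v[r]))
    oiv = _oar_interval(oar_bev, r, params.oar_margin_mm)
    ext = ptv_bev.row_extent(r)
    extent_beyond = max(oiv[0] - (ext[0] - ptv_bev.resolution / 2.0), 0.0)
    return float(np.clip(0.25 * extent_beyond, 5.0, 30.0))


def make_s2(
    ptv_bev: BEVMask,
    oar_bev: BEVMask,
    params: SegmentationParams,
    mlc: MLCModel | None = None,
) -> Aperture:
    """Rim-strip aperture beside the expanded OAR shadow.

    Per row with OAR shadow: a strip of the resolved S2 width immediately on
    the chosen side of the expanded OAR edge, intersected with the S0 row
    interval.  Rows without OAR shadow stay closed; if no row carries both
    PTV and OAR shadow the aperture is invalid (driving beam discard).
    """
    width = s2_strip_width(ptv_bev, oar_bev, params)
    mirror = params.side == "right"
    if mirror:
        ptv_bev, oar_bev = _mirror_bev(ptv_bev), _mirror_bev(oar_bev)
    if ptv_bev.is_empty or oar_bev.is_empty:
        ap = _closed(ptv_bev, valid=False, note="S2 needs both PTV and OAR shadow")
        return ap.mirrored() if mirror else ap
    ap = _closed(ptv_bev, valid=True)
    half = ptv_bev.resolution / 2.0
    any_overlap_row = False
    for r in range(ptv_bev.v.size):
        ext = ptv_bev.row_extent(r)
        oiv = _oar_interval(oar_bev, r, params.oar_margin_mm)
        if ext is None or oiv is None:
            continue
        any_overlap_row = True
        s0_left, s0_right = ext[0] - half, ext[1] + half
        left = max(oiv[0] - width, s0_left)
        right = min(oiv[0], s0_right)
        if right > left:
            ap.open_[r] = True
            ap.x_left[r], ap.x_right[r] = left, right
    if not any_overlap_row:
        ap.valid = False
        ap.note = "no row with both PTV and OAR shadow"
    elif not ap.open_.any():
        ap.valid = False
        ap.note = "S2 strip empty on the chosen side"
    return ap.mirrored() if mirror else ap


def _mirror_bev(bev: BEVMask) -> BEVMask:
    """Mirror a BEV mask across u = 0 (requires a symmetric column frame)."""
    return BEVMask(
        mask=bev.mask[:, ::-1].copy(), u=bev.u.copy(), v=bev.v.copy(),
        resolution=bev.resolution, leaf_width=bev.leaf_width,
    )


def make_aperture(
    order: SegmentOrder,
    ptv_bev: BEVMask,
    oar_bev: BEVMask,
    params: SegmentationParams,
    mlc: MLCModel | None = None,
) -> Aperture:
    """Dispatch S0/S1/S2 construction by segment order."""
    order = SegmentOrder(order)
    if order is SegmentOrder.S0:
        return make_s0(ptv_bev, mlc)
    if order is SegmentOrder.S1:
        return make_s1(ptv_bev, oar_bev, params, mlc)
    return make_s2(ptv_bev, oar_bev, params, mlc)


def assign_order_pattern(n_angles: int, pattern) -> list[SegmentOrder]:
    """Cyclically repeat an order pattern over ``n_angles`` gantry angles."""
    if n_angles < 1:
        raise ValueError("need at least one angle")
    pattern = [SegmentOrder(p) for p in pattern]
    if not pattern:
        raise ValueError("pattern must be non-empty")
    return [pattern[i % len(pattern)] for i in range(n_angles)]


def _project_pair(case, angle, mlc, resolution, ptv_name, oar_name):
    beam = Beam(gantry_angle_deg=angle)
    ptv_bev = project_structure(case, ptv_name, beam, mlc, resolution)
    if oar_name in case.structures:
        oar_bev = project_structure(case, oar_name, beam, mlc, resolution)
    else:
        oar_bev = BEVMask(
            mask=np.zeros_like(ptv_bev.mask), u=ptv_bev.u, v=ptv_bev.v,
            resolution=ptv_bev.resolution, leaf_width=ptv_bev.leaf_width,
        )
    return beam, ptv_bev, oar_bev


def build_fast_plan(
    case,
    n: int,
    arc_deg: float = 360.0,
    pattern=(SegmentOrder.S1, SegmentOrder.S2),
    params: SegmentationParams = SegmentationParams(),
    mlc: MLCModel | None = None,
    start_deg: float = 0.0,
    bev_resolution: float = 1.0,
    ptv_name: str = "ptv",
    oar_name: str = "oar_primary",
    name: str = "fast",
) -> Plan:
    """Build a single-segment-per-beam plan with alternating segment orders.

    Each retained gantry angle carries exactly one segment of its assigned
    order; beams whose aperture is invalid or below the minimum open area
    are discarded (logged in ``plan.discard_log``).  Initial weights are
    uniform (1 MU) pending optimization.
    """
    from .bev import mlc_preset

    mlc = mlc or mlc_preset("s4")
    angles = equidistant_angles(n, start_deg, arc_deg)
    orders = assign_order_pattern(len(angles), pattern)
    segments: list[Segment] = []
    log: list[str] = []
    for angle, order in zip(angles, orders):
        beam, ptv_bev, oar_bev = _project_pair(case, angle, mlc, bev_resolution, ptv_name, oar_name)
        ap = make_aperture(order, ptv_bev, oar_bev, params, mlc)
        if not ap.valid:
            log.append(f"beam {angle:.1f} deg ({order.value}) discarded: {ap.note}")
            continue
        if ap.area_cm2 < params.min_open_area_cm2:
            log.append(
                f"beam {angle:.1f} deg ({order.value}) discarded: open area "
                f"{ap.area_cm2:.2f} cm2 below {params.min_open_area_cm2} cm2"
            )
            continue
        segments.append(Segment(beam=beam, aperture=ap, order=order, weight_mu=1.0))
    if not segments:
        raise EmptyPlanError("all beams were discarded")
    return Plan(segments=segments, name=name, discard_log=log)


def build_multisegment_plan(
    case,
    n: int,
    arc_deg: float = 360.0,
    orders_per_beam=(SegmentOrder.S0, SegmentOrder.S1, SegmentOrder.S2),
    params: SegmentationParams = SegmentationParams(),
    mlc: MLCModel | None = None,
    both_sides: bool = False,
    start_deg: float = 0.0,
    bev_resolution: float = 1.0,
    ptv_name: str = "ptv",
    oar_name: str = "oar_primary",
    name: str = "two-step",
) -> Plan:
    """Build a conventional multi-segment plan (every valid order per beam).

    With ``both_sides`` the S1/S2 orders are generated for both leaf banks,
    roughly doubling the segment count on symmetric geometries.  Invalid
    apertures are skipped with a log entry.
    """
    from .bev import mlc_preset

    mlc = mlc or mlc_preset("s4")
    if not orders_per_beam:
        raise ValueError("orders_per_beam must be non-empty")
    orders = [SegmentOrder(o) for o in orders_per_beam]
    angles = equidistant_angles(n, start_deg, arc_deg)
    segments: list[Segment] = []
    log: list[str] = []
    for angle in angles:
        beam, ptv_bev, oar_bev = _project_pair(case, angle, mlc, bev_resolution, ptv_name, oar_name)
        for order in orders:
            sides = ["left"]
            if both_sides and order is not SegmentOrder.S0:
                sides = ["left", "right"]
            for side in sides:
                p = SegmentationParams(
                    oar_margin_mm=params.oar_margin_mm,
                    s2_width_mm=params.s2_width_mm,
                    min_open_area_cm2=params.min_open_area_cm2,
                    side=side,
                )
                ap = make_aperture(order, ptv_bev, oar_bev, p, mlc)
                if not ap.valid or ap.area_cm2 < params.min_open_area_cm2:
                    log.append(f"beam {angle:.1f} deg ({order.value}/{side}) skipped: {ap.note or 'area below threshold'}")
                    continue
                segments.append(Segment(beam=beam, aperture=ap, order=order, weight_mu=1.0))
    if not segments:
        raise EmptyPlanError("no valid segment on any beam")
    return Plan(segments=segments, name=name, discard_log=log)
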