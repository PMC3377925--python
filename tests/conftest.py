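"""Shared fixtures: small synthetic cases that keep the suite fast."""

import numpy as np
import pytest

import twostep_imrt as ts


@pytest.fixture(scope="session")
def small_quasimodo() -> ts.CaseGeometry:
    """Down-scaled horseshoe phantom (96x96x4 at 2 mm)."""
    return ts.make_phantom(
        "quasimodo",
        dict(body_semiaxes=(80, 60), oar_radius=12, gap_mm=5, ptv_thickness=14),
        grid_shape=(96, 96, 4),
        voxel_size=2.0,
    )


@pytest.fixture(scope="session")
def small_mlc() -> ts.MLCModel:
    return ts.MLCModel(leaf_width=4.0, n_leaf_pairs=12, max_field_extent=80.0)


@pytest.fixture(scope="session")
def seg_params() -> ts.SegmentationParams:
    """Validity threshold scaled to the small fixture's 8 mm height."""
    return ts.SegmentationParams(min_open_area_cm2=0.3)


def make_slab_case(ny: int = 151, depth_face_mm: float = 100.0, voxel: float = 2.0):
    """Water slab whose surface sits ``depth_face_mm`` above the isocenter
    for a beam from anterior (gantry 0): central-axis quantities are then
    closed-form."""
    nx = nz = 9
    ys = (np.arange(ny) - (ny - 1) / 2.0) * voxel
    sel = (ys <= depth_face_mm) & (ys >= -160.0)
    body = np.zeros((nx, ny, nz), dtype=bool)
    body[:, sel, :] = True
    return ts.CaseGeometry(
        grid_shape=(nx, ny, nz),
        voxel_size=(voxel, voxel, voxel),
        structures={"body": body, "ptv": body.copy()},
        prescription={"ptv": 2.0},
        case_name="slab",
    )


def open_field_aperture(half_mm: float = 50.0, leaf_width: float = 10.0, n_rows: int = 12):
    """Square open field of edge 2*half_mm centred on the axis."""
    v = (np.arange(n_rows) - (n_rows - 1) / 2.0) * leaf_width
    sel = np.abs(v) <= half_mm  # rows fully inside the field
    return ts.Aperture(
        x_left=np.where(sel, -half_mm, 0.0),
        x_right=np.where(sel, half_mm, 0.0),
        open_=sel,
        v=v,
        leaf_width=leaf_width,
    )
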