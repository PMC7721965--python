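import numpy as np
import pydicom
import pytest

from lidckit.geometry import ScanGeometry, build_geometry
from lidckit.synthetic import (
    NoduleSpec,
    PhantomSpec,
    generate_annotations,
    generate_ct_series,
)


def make_geometry(
    n_slices=5,
    pixel_spacing=(1.0, 1.0),
    slice_step=1.0,
    image_shape=(64, 64),
    origin=(0.0, 0.0, 0.0),
):
    """Axial identity-orientation geometry for unit tests."""
    positions = tuple(origin[2] + k * slice_step for k in range(n_slices))
    return ScanGeometry(
        pixel_spacing=pixel_spacing,
        slice_positions=positions,
        origin=origin,
        orientation=(1, 0, 0, 0, 1, 0),
        slice_table={f"1.2.3.{k}": k for k in range(n_slices)},
        image_shape=image_shape,
        frame_of_reference_uid="1.2.3.4.5",
        series_instance_uid="1.2.3.4.6",
        sop_class_uid="1.2.840.10008.5.1.4.1.1.2",
        slice_origins=tuple((origin[0], origin[1], z) for z in positions),
    )


def square_ring(x0, y0, n):
    """Closed ring of the border pixels of an n-by-n block at (x0, y0)."""
    pts = []
    for x in range(x0, x0 + n):
        pts.append((x, y0))
    for y in range(y0 + 1, y0 + n):
        pts.append((x0 + n - 1, y))
    for x in range(x0 + n - 2, x0 - 1, -1):
        pts.append((x, y0 + n - 1))
    for y in range(y0 + n - 2, y0, -1):
        pts.append((x0, y))
    return pts


def random_star_polygon(rng, center=(10, 10), r_min=2, r_max=8, n_min=4, n_max=12):
    """Random simple (star-shaped) integer polygon around a center."""
    for _ in range(50):
        n = int(rng.integers(n_min, n_max + 1))
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
        radii = rng.uniform(r_min, r_max, size=n)
        xs = np.rint(center[0] + radii * np.cos(angles)).astype(int)
        ys = np.rint(center[1] + radii * np.sin(angles)).astype(int)
        pts = list(dict.fromkeys(zip(xs.tolist(), ys.tolist())))
        if len(pts) < 3:
            continue
        arr = np.asarray(pts)
        # reject fully collinear sets
        v = arr - arr[0]
        if np.all(v[:, 0] * v[1, 1] - v[:, 1] * v[1, 0] == 0):
            continue
        # integer rounding can rarely break simplicity; keep only simple polygons
        from shapely.geometry import Polygon

        if not Polygon(pts).is_valid:
            continue
        return pts
    raise AssertionError("could not generate a polygon")


STANDARD_PHANTOM = PhantomSpec(
    image_shape=(128, 128),
    pixel_spacing=(0.7, 0.7),
    slice_step=2.5,
    n_slices=20,
    nodules=(
        NoduleSpec(center_mm=(30.0, 30.0, 20.0), radius_mm=8.0, n_readers=3, jitter_mm=0.5),
        NoduleSpec(center_mm=(62.0, 62.0, 30.0), radius_mm=6.0, n_readers=3, jitter_mm=0.5),
    ),
    center_only_marks=((45.0, 20.0, 25.0),),
    seed=7,
)


@pytest.fixture(scope="session")
def phantom_scan(tmp_path_factory):
    """Synthetic 2-nodule, 3-reader scan with one center-only mark."""
    root = tmp_path_factory.mktemp("phantom")
    ct_dir = root / "ct"
    truth = generate_ct_series(STANDARD_PHANTOM, ct_dir)
    geometry = build_geometry(ct_dir)
    xml_path = root / "annotations.xml"
    _, annotations = generate_annotations(STANDARD_PHANTOM, geometry, xml_path)
    return {
        "spec": STANDARD_PHANTOM,
        "root": root,
        "ct_dir": ct_dir,
        "xml_path": xml_path,
        "geometry": geometry,
        "annotations": annotations,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def sphere_scans(tmp_path_factory):
    """Single-sphere scans at 1 mm isotropic voxels, radii 5/8/12 mm."""
    root = tmp_path_factory.mktemp("spheres")
    scans = {}
    for r in (5.0, 8.0, 12.0):
        spec = PhantomSpec(
            image_shape=(64, 64),
            pixel_spacing=(1.0, 1.0),
            slice_step=1.0,
            n_slices=40,
            nodules=(NoduleSpec(center_mm=(32.0, 32.0, 20.0), radius_mm=r, n_readers=1),),
            seed=int(r),
        )
        ct_dir = root / f"r{int(r)}"
        generate_ct_series(spec, ct_dir)
        geometry = build_geometry(ct_dir)
        _, annotations = generate_annotations(spec, geometry)
        scans[r] = {"spec": spec, "geometry": geometry, "annotations": annotations}
    return scans


@pytest.fixture(scope="session")
def ct_context(phantom_scan):
    from lidckit.seg_writer import composite_context_from

    first = sorted(phantom_scan["ct_dir"].glob("*.dcm"))[0]
    return composite_context_from(pydicom.dcmread(str(first), stop_before_pixels=True))
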