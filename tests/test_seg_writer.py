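import numpy as np
import pytest

from lidckit.geometry import build_geometry
from lidckit.lidc_xml import select_volumetric
from lidckit.rasterize import build_mask
from lidckit.seg_writer import (
    DISPLAY_PALETTE,
    SegConventions,
    SegDecodeError,
    SegEncodeError,
    annotation_color,
    cielab16_to_rgb,
    decode_seg,
    encode_seg,
    rgb_to_cielab16,
    seg_semantics,
)
from lidckit.uid import UidFactory
from lidckit.validation import validate_seg


@pytest.fixture(scope="module")
def encoded(phantom_scan, ct_context):
    g = phantom_scan["geometry"]
    ann = select_volumetric(phantom_scan["annotations"])[0]
    mask = build_mask(ann, g)
    conv = SegConventions(
        nodule_number=1,
        annotation_id=ann.annotation_id,
        tracking_uid="1.2.826.0.1.3680043.8.498.1.77.1",
        display_color=annotation_color(0),
    )
    ct_refs = {idx: uid for uid, idx in g.slice_table.items()}
    seg = encode_seg(mask, conv, ct_refs, ct_context, uid_factory=UidFactory(seed=5))
    return {"mask": mask, "conv": conv, "seg": seg, "g": g, "ct_refs": ct_refs}


class TestCielab:
    def test_white_and_black_poles(self):
        assert rgb_to_cielab16((255, 255, 255)) == (0xFFFF, 0x8080, 0x8080)
        assert rgb_to_cielab16((0, 0, 0)) == (0x0000, 0x8080, 0x8080)

    def test_gray_axis_stays_neutral(self):
        for v in (32, 128, 200):
            _, a16, b16 = rgb_to_cielab16((v, v, v))
            assert a16 == 0x8080 and b16 == 0x8080

    def test_primary_red_against_independent_colorimetry(self):
        # independent oracle: sRGB -> XYZ(D65) -> Bradford D50 -> Lab, written
        # from the published matrices, kept separate from the implementation
        def oracle(rgb):
            c = np.array(rgb) / 255.0
            lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
            m_xyz = np.array(
                [
                    [0.4124564, 0.3575761, 0.1804375],
                    [0.2126729, 0.7151522, 0.0721750],
                    [0.0193339, 0.1191920, 0.9503041],
                ]
            )
            bradford = np.array(
                [
                    [0.8951, 0.2664, -0.1614],
                    [-0.7502, 1.7135, 0.0367],
                    [0.0389, -0.0685, 1.0296],
                ]
            )
            w65 = np.array([0.95047, 1.0, 1.08883])
            w50 = np.array([0.96422, 1.0, 0.82521])
            xyz = m_xyz @ lin
            cone = bradford @ xyz
            cone *= (bradford @ w50) / (bradford @ w65)
            xyz50 = np.linalg.solve(bradford, cone)
            t = xyz50 / w50
            f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
            L = 116 * f[1] - 16
            a = 500 * (f[0] - f[1])
            b = 200 * (f[1] - f[2])
            return (
                round(L * 65535 / 100),
                round((np.clip(a, -128, 127) + 128) * 65535 / 255),
                round((np.clip(b, -128, 127) + 128) * 65535 / 255),
            )

        for rgb in [(255, 0, 0), (0, 255, 0), (0, 0, 255), (230, 25, 75)]:
            got = rgb_to_cielab16(rgb)
            expected = oracle(rgb)
            assert all(abs(g - e) <= 1 for g, e in zip(got, expected)), (rgb, got, expected)

    def test_inverse_recovers_palette_colors(self):
        for rgb in DISPLAY_PALETTE:
            assert cielab16_to_rgb(rgb_to_cielab16(rgb)) == rgb

    def test_out_of_range_component_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_cielab16((256, 0, 0))


class TestEncode:
    def test_one_frame_per_nonempty_slice_only(self, encoded):
        n_nonempty = len(encoded["mask"].nonempty_slices)
        assert int(encoded["seg"].NumberOfFrames) == n_nonempty
        assert n_nonempty < encoded["g"].n_slices  # slices away from the nodule omitted

    def test_naming_convention(self, encoded):
        conv = encoded["conv"]
        seg = encoded["seg"]
        expected = f"Nodule 1 - Annotation {conv.annotation_id}"
        assert str(seg.SeriesDescription) == expected
        assert str(seg.SegmentSequence[0].SegmentLabel) == expected
        assert str(seg.SegmentSequence[0].TrackingID) == expected

    def test_segment_semantics_codes(self, encoded):
        category, seg_type, anatomy = seg_semantics(encoded["seg"])
        assert (category.value, category.scheme) == ("M-01000", "SRT")
        assert (seg_type.value, seg_type.scheme) == ("M-03010", "SRT")
        assert (anatomy.value, anatomy.scheme) == ("T-28000", "SRT")

    def test_sct_scheme_option(self, encoded, ct_context):
        seg = encode_seg(
            encoded["mask"],
            encoded["conv"],
            encoded["ct_refs"],
            ct_context,
            uid_factory=UidFactory(seed=6),
            code_scheme="SCT",
        )
        category, seg_type, anatomy = seg_semantics(seg)
        assert [c.value for c in (category, seg_type, anatomy)] == [
            "49755003",
            "27925004",
            "39607008",
        ]

    def test_composite_context_copied(self, encoded, ct_context):
        assert str(encoded["seg"].PatientID) == str(ct_context.PatientID)
        assert str(encoded["seg"].StudyInstanceUID) == str(ct_context.StudyInstanceUID)

    def test_each_frame_references_its_source_slice(self, encoded):
        g, seg = encoded["g"], encoded["seg"]
        uid_by_index = {idx: uid for uid, idx in g.slice_table.items()}
        normal = g.slice_normal
        for fg in seg.PerFrameFunctionalGroupsSequence:
            ipp = np.array([float(v) for v in fg.PlanePositionSequence[0].ImagePositionPatient])
            k = g.slice_index_for_position(float(ipp @ normal))
            ref = fg.DerivationImageSequence[0].SourceImageSequence[0]
            assert str(ref.ReferencedSOPInstanceUID) == uid_by_index[k]

    def test_missing_ct_ref_rejected(self, encoded, ct_context):
        with pytest.raises(SegEncodeError, match="ct_refs"):
            encode_seg(encoded["mask"], encoded["conv"], {}, ct_context)

    def test_conformance_zero_errors(self, encoded):
        result = validate_seg(encoded["seg"])
        assert result.ok, [str(f) for f in result.errors]


class TestDecode:
    def test_round_trip_voxel_identity(self, encoded):
        mask, conv = decode_seg(encoded["seg"], encoded["g"])
        assert np.array_equal(mask.voxels, encoded["mask"].voxels)
        assert mask.nonempty_slices == encoded["mask"].nonempty_slices

    def test_conventions_recovered(self, encoded):
        _, conv = decode_seg(encoded["seg"], encoded["g"])
        assert conv.tracking_uid == encoded["conv"].tracking_uid
        assert conv.nodule_number == 1
        assert conv.annotation_id == encoded["conv"].annotation_id
        assert conv.display_color == encoded["conv"].display_color

    def test_foreign_frame_of_reference_rejected(self, encoded):
        import copy

        seg = copy.deepcopy(encoded["seg"])
        seg.FrameOfReferenceUID = "1.2.840.99999.1"
        with pytest.raises(SegDecodeError, match="frame of reference"):
            decode_seg(seg, encoded["g"])

    def test_non_seg_object_rejected(self, encoded, phantom_scan):
        import pydicom

        ct = pydicom.dcmread(str(sorted(phantom_scan["ct_dir"].glob("*.dcm"))[0]))
        with pytest.raises(SegDecodeError):
            decode_seg(ct, encoded["g"])


def test_palette_cycles_distinct_colors():
    colors = [annotation_color(i) for i in range(len(DISPLAY_PALETTE))]
    assert len(set(colors)) == len(colors)
    assert annotation_color(len(DISPLAY_PALETTE)) == colors[0]
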