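import pytest

from lidckit.codes import load_dictionary
from lidckit.sr_writer import (
    MeasurementGroup,
    SrDecodeError,
    SrEncodeError,
    decode_sr,
    encode_sr,
    flatten_evaluations,
)
from lidckit.uid import UidFactory
from lidckit.validation import validate_sr

DICT = load_dictionary()


def make_group(tracking_uid="1.2.3.77.1", nodule=1, ann_id="101", skip=None):
    evaluations = []
    for attr in (
        "subtlety",
        "internalStructure",
        "calcification",
        "sphericity",
        "margin",
        "lobulation",
        "spiculation",
        "texture",
        "malignancy",
    ):
        if attr == skip:
            continue
        evaluations.append(DICT.evaluation_code(attr, 3 if attr != "internalStructure" else 1))
    measurements = []
    for name, value in (("diameter", 16.0), ("surface_area", 854.37), ("volume", 2107.0)):
        concept, unit = DICT.measurement_codes(name)
        measurements.append((concept, value, unit))
    return MeasurementGroup(
        tracking_id=f"Nodule {nodule} - Annotation {ann_id}",
        tracking_uid=tracking_uid,
        referenced_segment_uid="1.2.3.88.1",
        referenced_segment_number=1,
        referenced_source_series="1.2.3.99.1",
        evaluations=tuple(evaluations),
        measurements=tuple(measurements),
    )


@pytest.fixture(scope="module")
def encoded(ct_context):
    group = make_group()
    sr = encode_sr(group, ct_context, uid_factory=UidFactory(seed=9))
    return {"group": group, "sr": sr}


class TestEncode:
    def test_nine_evaluations_three_measurements(self, encoded):
        group = decode_sr(encoded["sr"])
        assert len(group.evaluations) == 9
        assert len(group.measurements) == 3

    def test_missing_internal_structure_gives_eight(self, ct_context):
        group = make_group(skip="internalStructure")
        sr = encode_sr(group, ct_context)
        decoded = decode_sr(sr)
        assert len(decoded.evaluations) == 8
        concepts = {c.meaning for c, _ in decoded.evaluations}
        assert "Internal structure" not in concepts

    def test_tracking_pair_embedded(self, encoded):
        group = decode_sr(encoded["sr"])
        assert group.tracking_uid == encoded["group"].tracking_uid
        assert group.tracking_id == encoded["group"].tracking_id

    def test_template_is_tid_1500(self, encoded):
        t = encoded["sr"].ContentTemplateSequence[0]
        assert str(t.TemplateIdentifier).strip() == "1500"
        assert str(t.MappingResource) == "DCMR"

    def test_missing_segment_reference_rejected(self, ct_context):
        group = make_group()
        object.__setattr__(group, "referenced_segment_uid", "")
        with pytest.raises(SrEncodeError, match="SEG"):
            encode_sr(group, ct_context)

    def test_non_ucum_unit_rejected(self, ct_context):
        from lidckit.codes import CodedConcept

        concept, _ = DICT.measurement_codes("volume")
        bad_unit = CodedConcept("mm3", "SRT", "cubic millimeter")
        group = MeasurementGroup(
            tracking_id="Nodule 1 - Annotation 1",
            tracking_uid="1.2.3",
            referenced_segment_uid="1.2.3.88.1",
            referenced_segment_number=1,
            referenced_source_series="1.2.3.99.1",
            measurements=((concept, 5.0, bad_unit),),
        )
        with pytest.raises(SrEncodeError, match="UCUM"):
            encode_sr(group, ct_context)

    def test_nonpositive_measurement_rejected(self):
        concept, unit = DICT.measurement_codes("volume")
        with pytest.raises(ValueError):
            MeasurementGroup(
                tracking_id="t",
                tracking_uid="1.2.3",
                referenced_segment_uid="1.2.3.88.1",
                referenced_segment_number=1,
                referenced_source_series="1.2.3.99.1",
                measurements=((concept, 0.0, unit),),
            )

    def test_conformance_zero_errors(self, encoded):
        result = validate_sr(encoded["sr"])
        assert result.ok, [str(f) for f in result.errors]


class TestDecode:
    def test_round_trip_equality(self, encoded):
        assert decode_sr(encoded["sr"]) == encoded["group"]

    def test_round_trip_on_random_groups(self, ct_context):
        import numpy as np

        rng = np.random.default_rng(4)
        from lidckit.lidc_xml import CHARACTERISTIC_RANGES

        for trial in range(10):
            evaluations = []
            for attr, (lo, hi) in CHARACTERISTIC_RANGES.items():
                if rng.random() < 0.8:
                    evaluations.append(
                        DICT.evaluation_code(attr, int(rng.integers(lo, hi + 1)))
                    )
            measurements = []
            for name in ("diameter", "surface_area", "volume"):
                concept, unit = DICT.measurement_codes(name)
                measurements.append((concept, float(np.round(rng.uniform(0.1, 3000), 3)), unit))
            group = MeasurementGroup(
                tracking_id=f"Nodule {trial} - Annotation {trial}",
                tracking_uid=f"1.2.3.{trial}",
                referenced_segment_uid="1.2.3.88.1",
                referenced_segment_number=1,
                referenced_source_series="1.2.3.99.1",
                evaluations=tuple(evaluations),
                measurements=tuple(measurements),
            )
            assert decode_sr(encode_sr(group, ct_context)) == group

    def test_surface_area_unit_recovered(self, encoded):
        group = decode_sr(encoded["sr"])
        units = {c.value: u for c, _v, u in group.measurements}
        assert (units["C0JK"].value, units["C0JK"].scheme) == ("mm2", "UCUM")

    def test_document_without_measurement_group_rejected(self, encoded, ct_context):
        import copy

        sr = copy.deepcopy(encoded["sr"])
        # remove the Imaging Measurements container
        sr.ContentSequence = [
            item
            for item in sr.ContentSequence
            if str(item.ConceptNameCodeSequence[0].CodeValue) != "126010"
        ]
        with pytest.raises(SrDecodeError, match="Imaging Measurements"):
            decode_sr(sr)

    def test_non_sr_object_rejected(self, phantom_scan):
        import pydicom

        ct = pydicom.dcmread(str(sorted(phantom_scan["ct_dir"].glob("*.dcm"))[0]))
        with pytest.raises(SrDecodeError):
            decode_sr(ct)


class TestFlatten:
    def test_one_row_per_annotation(self, ct_context):
        srs = [
            encode_sr(make_group(tracking_uid=f"1.2.3.{i}", nodule=i, ann_id=str(i)), ct_context)
            for i in range(1, 5)
        ]
        table = flatten_evaluations(srs)
        assert len(table) == 4
        assert list(table["annotation_id"]) == ["1", "2", "3", "4"]
        assert (table["volume"] == 2107.0).all()

    def test_absent_evaluation_yields_null_cell(self, ct_context):
        sr = encode_sr(make_group(skip="internalStructure"), ct_context)
        table = flatten_evaluations([sr])
        assert table["internalStructure"].isna().all()
        assert table["malignancy"].notna().all()

    def test_flatten_reproduces_group_values(self, ct_context):
        group = make_group()
        table = flatten_evaluations([encode_sr(group, ct_context)])
        row = table.iloc[0]
        assert row["diameter"] == 16.0
        assert row["surface_area"] == 854.37
        assert "3 out of 5" in row["malignancy"]
        assert row["tracking_uid"] == group.tracking_uid

    def test_duplicate_tracking_pair_rejected(self, ct_context):
        sr = encode_sr(make_group(), ct_context)
        with pytest.raises(ValueError, match="duplicate"):
            flatten_evaluations([sr, sr])
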