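import numpy as np
import pytest

from conftest import make_geometry, square_ring
from lidckit.cluster import annotation_distance, cluster_annotations
from lidckit.lidc_xml import ContourRoi, NoduleAnnotation
from lidckit.uid import UidFactory
from oracles import union_find_clusters


def point_ann(aid, x, y, k=0):
    return NoduleAnnotation(aid, (ContourRoi(f"1.2.3.{k}", float(k), True, ((x, y),)),))


def ring_ann(aid, x0, y0, n=5, k=0):
    return NoduleAnnotation(
        aid, (ContourRoi(f"1.2.3.{k}", float(k), True, tuple(square_ring(x0, y0, n))),)
    )


class TestDistance:
    def test_identical_annotation_distance_zero(self):
        g = make_geometry()
        a = ring_ann("a", 5, 5)
        assert annotation_distance(a, a, g) == 0.0

    def test_three_four_five(self):
        g = make_geometry(pixel_spacing=(1.0, 1.0))
        assert annotation_distance(point_ann("a", 0, 0), point_ann("b", 3, 4), g) == 5.0

    def test_spacing_enters_the_metric(self):
        g = make_geometry(pixel_spacing=(1.0, 0.7))
        d = annotation_distance(point_ann("a", 0, 0), point_ann("b", 10, 0), g)
        assert d == pytest.approx(7.0)

    def test_symmetry_on_random_fixtures(self):
        g = make_geometry(n_slices=6)
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = point_ann("a", int(rng.integers(0, 60)), int(rng.integers(0, 60)), int(rng.integers(0, 6)))
            b = point_ann("b", int(rng.integers(0, 60)), int(rng.integers(0, 60)), int(rng.integers(0, 6)))
            assert annotation_distance(a, b, g) == annotation_distance(b, a, g)

    def test_annotation_without_points_rejected(self):
        g = make_geometry()
        bad = NoduleAnnotation("a", ())
        with pytest.raises(ValueError):
            annotation_distance(bad, point_ann("b", 1, 1), g)


class TestClustering:
    def test_four_overlapping_annotations_one_cluster(self):
        g = make_geometry()
        anns = [ring_ann(str(i), 5, 5) for i in range(4)]
        clusters = cluster_annotations(anns, g, tol=1.0)
        assert len(clusters) == 1
        assert clusters[0].size == 4
        assert clusters[0].nodule_number == 1

    def test_chain_merges_under_single_linkage(self):
        # A-B at 1, B-C at 1, A-C far: one cluster {A, B, C}
        g = make_geometry(pixel_spacing=(1.0, 1.0), image_shape=(64, 64))
        a = point_ann("A", 10, 10)
        b = point_ann("B", 11, 10)
        c = point_ann("C", 12, 10)
        far = point_ann("D", 50, 50)
        clusters = cluster_annotations([a, b, c, far], g, tol=2.0)
        member_sets = {frozenset(m.annotation_id for m in cl.members) for cl in clusters}
        assert member_sets == {frozenset("ABC"), frozenset("D")}

    def test_cluster_sizes_above_four_are_permitted(self):
        g = make_geometry()
        anns = [ring_ann(str(i), 5 + i, 5) for i in range(6)]
        clusters = cluster_annotations(anns, g, tol=3.0)
        assert len(clusters) == 1 and clusters[0].size == 6

    def test_matches_union_find_oracle_on_random_fixtures(self):
        g = make_geometry(n_slices=8, image_shape=(80, 80))
        rng = np.random.default_rng(42)
        for trial in range(15):
            n = int(rng.integers(2, 9))
            anns = [
                point_ann(
                    str(i),
                    int(rng.integers(0, 80)),
                    int(rng.integers(0, 80)),
                    int(rng.integers(0, 8)),
                )
                for i in range(n)
            ]
            tol = float(rng.uniform(0.5, 15))
            clusters = cluster_annotations(anns, g, tol=tol)
            expected = union_find_clusters(
                n, lambda i, j: annotation_distance(anns[i], anns[j], g), tol
            )
            got = {
                frozenset(int(m.annotation_id) for m in cl.members) for cl in clusters
            }
            assert got == expected, f"trial {trial} (tol={tol})"

    def test_tolerance_monotonicity(self):
        g = make_geometry(image_shape=(80, 80))
        rng = np.random.default_rng(7)
        anns = [
            point_ann(str(i), int(rng.integers(0, 80)), int(rng.integers(0, 80)))
            for i in range(10)
        ]
        counts = [
            len(cluster_annotations(anns, g, tol=t)) for t in (0.5, 2, 5, 10, 40)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_numbering_follows_first_appearance(self):
        g = make_geometry(image_shape=(64, 64))
        anns = [point_ann("x", 50, 50), point_ann("y", 5, 5), point_ann("z", 50, 51)]
        clusters = cluster_annotations(anns, g, tol=2.0)
        assert [c.nodule_number for c in clusters] == [1, 2]
        assert {m.annotation_id for m in clusters[0].members} == {"x", "z"}

    def test_member_sets_invariant_to_input_order(self):
        g = make_geometry(image_shape=(80, 80))
        rng = np.random.default_rng(13)
        anns = [
            point_ann(str(i), int(rng.integers(0, 80)), int(rng.integers(0, 80)))
            for i in range(8)
        ]
        ref = {
            frozenset(m.annotation_id for m in c.members)
            for c in cluster_annotations(anns, g, tol=6.0)
        }
        for seed in range(3):
            perm = list(np.random.default_rng(seed).permutation(len(anns)))
            got = {
                frozenset(m.annotation_id for m in c.members)
                for c in cluster_annotations([anns[i] for i in perm], g, tol=6.0)
            }
            assert got == ref

    def test_tracking_uids_shared_within_and_distinct_across(self):
        g = make_geometry(image_shape=(64, 64))
        anns = [
            point_ann("a", 5, 5),
            point_ann("b", 6, 5),
            point_ann("c", 50, 50),
        ]
        clusters = cluster_annotations(
            anns, g, tol=2.0, uid_factory=UidFactory(seed=0)
        )
        uids = [c.tracking_uid for c in clusters]
        assert len(set(uids)) == len(uids)
        for c in clusters:
            assert c.tracking_uid  # every member shares the cluster's single UID

    def test_default_tolerance_is_slice_step(self, phantom_scan):
        from lidckit.lidc_xml import select_volumetric

        g = phantom_scan["geometry"]
        anns = select_volumetric(phantom_scan["annotations"])
        default = cluster_annotations(anns, g)
        explicit = cluster_annotations(anns, g, tol=g.slice_step)
        assert [
            {m.annotation_id for m in c.members} for c in default
        ] == [{m.annotation_id for m in c.members} for c in explicit]
        assert len(default) == 2  # the phantom's two nodules

    def test_negative_tolerance_rejected(self):
        g = make_geometry()
        with pytest.raises(ValueError):
            cluster_annotations([point_ann("a", 1, 1)], g, tol=-1.0)
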