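import numpy as np
import pandas as pd
import pytest

from ciliaxis.contacts import (
    ContactParams,
    SkeletonSet,
    associate_puncta,
    build_cilium_table,
    ciliary_fraction,
    cilium_length,
    classify_contacts,
    distance_on_skeleton,
    filter_cilia,
    percent_of,
    skeletonize_instances,
)
from ciliaxis.puncta import PunctaSet
from ciliaxis.segmentation import BinaryMask
from ciliaxis.volumes import VoxelVolume

SP = (1.0, 1.0, 1.0)


def tube_mask(shape, p0, p1, radius, spacing=1.0):
    grids = np.indices(shape).astype(float) * spacing
    pts = np.stack(grids, axis=-1)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    t = np.clip(((pts - p0) @ d) / (d @ d), 0, 1)
    return np.linalg.norm(pts - (p0 + t[..., None] * d), axis=-1) <= radius


class TestSkeletonize:
    def test_thin_line_is_its_own_skeleton(self):
        m = np.zeros((5, 12, 5), dtype=bool)
        m[2, 1:11, 2] = True
        skels = skeletonize_instances(BinaryMask(m, SP))
        assert len(skels) == 1
        assert len(skels.instances[0]) == 10
        assert skels.to_mask()[m].all()

    def test_cylinder_gives_single_path_spanning_ends(self):
        m = tube_mask((12, 60, 12), (6, 5, 6), (6, 55, 6), 3.0)
        skels = skeletonize_instances(BinaryMask(m, SP))
        assert len(skels) == 1
        ys = skels.instances[0][:, 1]
        assert ys.min() <= 7 and ys.max() >= 53

    def test_two_disjoint_tubes_give_two_instances(self):
        m = tube_mask((10, 40, 20), (5, 3, 5), (5, 36, 5), 1.5)
        m |= tube_mask((10, 40, 20), (5, 3, 14), (5, 36, 14), 1.5)
        from scipy import ndimage

        _, n_comp = ndimage.label(m, structure=np.ones((3, 3, 3)))
        skels = skeletonize_instances(BinaryMask(m, SP))
        assert len(skels) == n_comp == 2

    def test_anisotropic_input_refused(self):
        m = BinaryMask(np.ones((4, 4, 4), dtype=bool), (0.3, 0.1, 0.1))
        with pytest.raises(ValueError, match="resample"):
            skeletonize_instances(m)

    def test_even_thickness_bar_survives_thinning_collapse(self):
        # symmetric 2x6 bars defeat parity-based thinning; the centerline
        # fallback must still recover a full-length instance
        m = np.zeros((12, 50, 12), dtype=bool)
        m[3:9, 4:44, 3:5] = True
        skels = skeletonize_instances(BinaryMask(m, SP))
        assert len(skels) == 1
        ys = skels.instances[0][:, 1]
        assert ys.max() - ys.min() >= 35


class TestCiliumLength:
    def test_straight_ten_voxel_axis(self):
        inst = np.stack([np.full(10, 2), np.arange(10), np.full(10, 2)], axis=1)
        assert cilium_length(inst, (0.2, 0.2, 0.2)) == pytest.approx(1.8)

    def test_diagonal_line_matches_analytic_arc_length(self):
        n = 15
        inst = np.stack([np.arange(n)] * 3, axis=1)
        est = cilium_length(inst, (0.2, 0.2, 0.2))
        assert est == pytest.approx((n - 1) * 0.2 * np.sqrt(3), rel=0.05)

    def test_planted_tube_lengths_recovered(self, contact_scene, contact_pipeline):
        from conftest import match_instances_to_curves

        _, truth = contact_scene
        skels = skeletonize_instances(
            BinaryMask(truth.masks["cilia"], (0.189,) * 3))
        matched = match_instances_to_curves(skels, truth.curves)
        errs = []
        for inst, k in zip(skels.instances, matched):
            est = cilium_length(inst, skels.spacing, mask=truth.masks["cilia"])
            errs.append(abs(est - truth.cilia.length[k]))
        tol = np.maximum(0.05 * truth.cilia.length[matched].values, 2 * 0.189)
        assert (np.asarray(errs) <= tol).mean() >= 0.9

    def test_empty_instance_raises(self):
        with pytest.raises(ValueError):
            cilium_length(np.empty((0, 3)), SP)


class TestDistanceOnSkeleton:
    def brute_force(self, cilia_vox, target_vox, spacing):
        c = np.asarray(cilia_vox) * spacing
        t = np.asarray(target_vox) * spacing
        return np.sqrt(((c[:, None, :] - t[None, :, :]) ** 2).sum(-1)).min(axis=1)

    def test_coincident_voxel_distance_zero(self):
        inst = np.array([[2, 2, 2]])
        skels = SkeletonSet([inst], SP, (5, 5, 5))
        target = np.zeros((5, 5, 5), dtype=bool)
        target[2, 2, 2] = True
        per_voxel, minima = distance_on_skeleton(skels, BinaryMask(target, SP))
        assert minima[0] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_all_pairs_scan(self, seed):
        rng = np.random.default_rng(seed)
        shape = (20, 20, 20)
        target = rng.random(shape) < 0.02
        target[10, 10, 10] = True
        inst = np.unique(rng.integers(0, 20, (30, 3)), axis=0)
        skels = SkeletonSet([inst], SP, shape)
        per_voxel, minima = distance_on_skeleton(skels, BinaryMask(target, SP))
        expected = self.brute_force(inst, np.argwhere(target), 1.0)
        np.testing.assert_allclose(per_voxel[0], expected, atol=1e-9)

    def test_empty_target_gives_infinite_distances(self):
        skels = SkeletonSet([np.array([[1, 1, 1]])], SP, (4, 4, 4))
        _, minima = distance_on_skeleton(
            skels, BinaryMask(np.zeros((4, 4, 4), dtype=bool), SP))
        assert np.isinf(minima[0])


class TestClassifyContacts:
    def _table(self, distances):
        return pd.DataFrame({
            "id": range(len(distances)),
            "excluded": [False] * len(distances),
            "min_axon_distance": distances,
        })

    def test_cutoff_is_inclusive(self):
        out = classify_contacts(self._table([0.5, 2.0, 2.001]))
        assert list(out.contacting) == [True, True, False]

    def test_planted_distances_classify_as_expected(self):
        out = classify_contacts(self._table([0.5, 1.5, 2.5, 3.5]))
        assert list(out.contacting) == [True, True, False, False]

    def test_contact_count_monotone_in_cutoff(self):
        distances = [0.3, 0.9, 1.7, 2.2, 2.8, 3.5]
        counts = [
            int(classify_contacts(self._table(distances),
                                  ContactParams(contact_cutoff=c)).contacting.sum())
            for c in (0.5, 1.0, 2.0, 3.0, 4.0)
        ]
        assert counts == sorted(counts)

    def test_unpopulated_distances_raise(self):
        with pytest.raises(ValueError):
            classify_contacts(pd.DataFrame({"id": [0], "excluded": [False]}))


class TestFilterCilia:
    def _setup(self):
        shape = (20, 30, 30)
        layer = np.zeros(shape, dtype=bool)
        layer[5:15, 5:25, 5:25] = True
        centers = np.array([[10.0, 10.0, 10.0], [2.0, 27.0, 27.0]])  # in / out of layer
        return shape, BinaryMask(layer, SP), centers

    def test_boundary_cilium_excluded(self):
        shape, layer, centers = self._setup()
        inst = np.stack([np.zeros(5, int), np.arange(10, 15), np.full(5, 10)], axis=1)
        table = filter_cilia(SkeletonSet([inst], SP, shape), layer, centers)
        assert table.excluded[0]
        assert table.exclusion_reason[0] == "boundary"

    def test_non_layer_nucleus_excluded(self):
        shape, layer, centers = self._setup()
        inst = np.stack([np.full(5, 4), np.arange(24, 29), np.full(5, 27)], axis=1)
        table = filter_cilia(SkeletonSet([inst], SP, shape), layer, centers)
        assert table.excluded[0]
        assert table.exclusion_reason[0] == "non_layer_nucleus"

    def test_interior_cilium_with_layer_nucleus_retained(self):
        shape, layer, centers = self._setup()
        inst = np.stack([np.full(5, 10), np.arange(10, 15), np.full(5, 10)], axis=1)
        table = filter_cilia(SkeletonSet([inst], SP, shape), layer, centers)
        assert not table.excluded[0]
        assert table.exclusion_reason[0] == "none"


class TestAssociatePuncta:
    def _axon(self):
        inst = np.stack([np.full(20, 5), np.arange(20), np.full(20, 5)], axis=1)
        return SkeletonSet([inst], (0.5, 0.5, 0.5), (11, 20, 11))

    def test_near_and_far_puncta(self):
        ps = PunctaSet([[2.5, 5.0, 2.8], [2.5, 5.0, 4.0]], [1.0, 1.0])
        out = associate_puncta(ps, self._axon())
        assert list(out.association) == [True, False]

    def test_matches_brute_force_nearest_neighbor(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 5, (50, 3))
        ps = PunctaSet(coords, np.ones(50))
        axon = self._axon()
        out = associate_puncta(ps, axon)
        skel_um = axon.instances[0] * 0.5
        d = np.sqrt(((coords[:, None] - skel_um[None]) ** 2).sum(-1)).min(axis=1)
        np.testing.assert_array_equal(out.association, d <= 1.0)

    def test_empty_skeleton_all_unassociated(self):
        ps = PunctaSet([[1.0, 1.0, 1.0]], [1.0])
        out = associate_puncta(ps, SkeletonSet([], SP, (4, 4, 4)))
        assert not out.association.any()


class TestPercentOf:
    @pytest.mark.parametrize("count,total,expected", [
        (426, 1209, 35),
        (18, 27, 67),
        (0, 10, 0),
        (10, 10, 100),
    ])
    def test_reported_ratios(self, count, total, expected):
        assert percent_of(count, total) == expected

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            percent_of(1, 0)
        with pytest.raises(ValueError):
            percent_of(5, 3)


class TestCiliaryFraction:
    def _mask(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[4:6, 2:8, 4:6] = True
        return BinaryMask(m, SP)

    def test_all_signal_inside_gives_one(self):
        mask = self._mask()
        rec = np.where(mask.values, 100.0, 0.0)
        assert ciliary_fraction(VoxelVolume(rec, SP), mask) == 1.0

    def test_no_signal_inside_gives_zero(self):
        mask = self._mask()
        rec = np.zeros((10, 10, 10))
        rec[0, 0, 0] = 100.0
        assert ciliary_fraction(VoxelVolume(rec, SP), mask) == 0.0

    def test_subthreshold_signal_ignored_in_total(self):
        mask = self._mask()
        rec = np.where(mask.values, 100.0, 0.0)
        rec[0, 0, :] = 19.0  # below the 20-count cutoff
        assert ciliary_fraction(VoxelVolume(rec, SP), mask) == 1.0

    def test_planted_split_recovered_on_blur_free_scene(self):
        from ciliaxis import segmentation as sg
        from ciliaxis import synth

        params = synth.ContactSceneParams(
            receptor_ciliary_fraction=0.6, psf_sigma=None, poisson_noise=False,
            read_noise=0.0, seed=3)
        mc, truth = synth.make_contact_scene(params)
        cil = sg.close_and_filter(sg.otsu_mask(mc["cilia"]), 0.4, 0.05)
        frac = ciliary_fraction(mc["receptor"], cil)
        assert frac == pytest.approx(0.60, abs=0.02)


class TestPipelineOnScene:
    def test_contact_labels_match_planted_truth(self, contact_scene, contact_pipeline):
        from conftest import match_instances_to_curves

        _, truth = contact_scene
        pipe = contact_pipeline
        table = pipe["table"]
        matched = match_instances_to_curves(pipe["cilia_skels"], truth.curves)
        active = ~table.excluded.values
        got = table.contacting.values[active].astype(bool)
        expected = truth.cilia.contact.values[np.asarray(matched)[active]]
        np.testing.assert_array_equal(got, expected)

    def test_min_axon_distances_close_to_planted(self, contact_scene, contact_pipeline):
        from conftest import match_instances_to_curves

        _, truth = contact_scene
        pipe = contact_pipeline
        matched = match_instances_to_curves(pipe["cilia_skels"], truth.curves)
        planted = truth.cilia.axon_distance.values[matched]
        got = pipe["table"].min_axon_distance.values
        # within one voxel diagonal of the planted axis-to-axis distance
        assert np.abs(got - planted).max() <= np.sqrt(3) * 0.189
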