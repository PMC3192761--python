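import numpy as np
import pytest

import histo3d as h
from histo3d.segmentation import LabelSpec, LabelVolume

from .oracles import bfs_reachable_components, flood_fill_components

DARK = LabelSpec("stain", (160, 80, 20), 100, "dark")


def label_volume_from(mask, spacing=(1, 1, 1), physical=None):
    return LabelVolume(
        mask.astype(np.int32), {1: DARK}, spacing=spacing, physical_spacing_um=physical
    )


class TestThresholdLabel:
    def test_white_stack_selects_nothing(self):
        vol = h.threshold_label(np.full((3, 5, 5), 255, np.uint8), [DARK])
        assert (vol.labels == 0).all()

    def test_black_stack_selects_everything(self):
        vol = h.threshold_label(np.zeros((3, 5, 5), np.uint8), [DARK])
        assert (vol.labels == 1).all()

    def test_phantom_stain_dice_against_ground_truth(self, clean_sections):
        sections, masks = clean_sections
        gray = np.stack([h.to_grayscale(s) for s in sections])
        # threshold at the stain/background luma midpoint
        vol = h.threshold_label(gray, [LabelSpec("stain", (0, 0, 0), 164, "dark")])
        truth = np.stack([m["stain"] for m in masks])
        pred = vol.labels == 1
        dice = 2 * (pred & truth).sum() / (pred.sum() + truth.sum())
        assert dice >= 0.90

    def test_first_matching_spec_wins(self):
        gray = np.full((1, 2, 2), 50, np.uint8)
        vol = h.threshold_label(
            gray, [LabelSpec("a", (0, 0, 0), 100, "dark"), LabelSpec("b", (0, 0, 0), 100, "dark")]
        )
        assert (vol.labels == 1).all()

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            h.threshold_label(np.zeros((1, 2, 2), np.uint8), [DARK, DARK])

    def test_dark_threshold_monotone(self, rng):
        gray = rng.integers(0, 256, (4, 8, 8)).astype(np.uint8)
        lo = h.threshold_label(gray, [LabelSpec("s", (0, 0, 0), 80, "dark")]).labels == 1
        hi = h.threshold_label(gray, [LabelSpec("s", (0, 0, 0), 120, "dark")]).labels == 1
        assert (hi | ~lo).all()  # raising the cut never unselects

    def test_deterministic(self, rng):
        gray = rng.integers(0, 256, (4, 8, 8)).astype(np.uint8)
        a = h.threshold_label(gray, [DARK]).labels
        b = h.threshold_label(gray, [DARK]).labels
        np.testing.assert_array_equal(a, b)


class TestManualMasks:
    def test_empty_mask_is_identity(self, rng):
        vol = label_volume_from(rng.random((3, 6, 6)) < 0.3)
        out = h.apply_manual_masks(vol, {1: np.zeros((6, 6), bool)}, 1, "add")
        np.testing.assert_array_equal(out.labels, vol.labels)

    def test_add_then_erase_restores(self):
        vol = label_volume_from(np.zeros((2, 5, 5), bool))
        mask = np.zeros((5, 5), bool)
        mask[1:3, 1:3] = True
        added = h.apply_manual_masks(vol, {0: mask}, 1, "add")
        assert added.labels[0][mask].all()
        back = h.apply_manual_masks(added, {0: mask}, 1, "erase")
        np.testing.assert_array_equal(back.labels, vol.labels)

    def test_correcting_false_negative_raises_dice(self, clean_sections):
        sections, masks = clean_sections
        gray = np.stack([h.to_grayscale(s) for s in sections])
        # deliberately conservative threshold leaves false negatives
        vol = h.threshold_label(gray, [LabelSpec("stain", (0, 0, 0), 60, "dark")])
        truth = np.stack([m["stain"] for m in masks])

        def dice(v):
            pred = v.labels == 1
            return 2 * (pred & truth).sum() / (pred.sum() + truth.sum())

        missed = truth[4] & ~(vol.labels[4] == 1)
        assert missed.any()
        fixed = h.apply_manual_masks(vol, {4: missed}, 1, "add")
        assert dice(fixed) > dice(vol)

    def test_dimension_mismatch_rejected(self):
        vol = label_volume_from(np.zeros((2, 5, 5), bool))
        with pytest.raises(ValueError):
            h.apply_manual_masks(vol, {0: np.zeros((4, 4), bool)}, 1, "add")


class TestComponents:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        comps = h.components_3d(label_volume_from(mask), 1)
        assert comps.n_components == 1
        assert comps.sizes.tolist() == [1]

    def test_diagonal_voxels_split_by_connectivity(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        vol = label_volume_from(mask)
        assert h.components_3d(vol, 1, connectivity=26).n_components == 1
        assert h.components_3d(vol, 1, connectivity=6).n_components == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        mask = rng.random((10, 20, 20)) < 0.25
        comps = h.components_3d(label_volume_from(mask), 1, connectivity)
        _, oracle_sizes = flood_fill_components(mask, connectivity)
        assert comps.n_components == len(oracle_sizes)
        assert sorted(comps.sizes.tolist()) == sorted(oracle_sizes.tolist())

    def test_sizes_partition_the_label(self, rng):
        mask = rng.random((6, 12, 12)) < 0.3
        comps = h.components_3d(label_volume_from(mask), 1)
        assert comps.sizes.sum() == mask.sum()

    def test_physical_sizes_use_spacing(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        comps = h.components_3d(label_volume_from(mask, physical=(0.5, 0.5, 5.0)), 1)
        assert comps.sizes_um3[0] == pytest.approx(1.25)

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            h.components_3d(label_volume_from(np.zeros((2, 2, 2), bool)), 7)


class TestConnectivityQuery:
    def make_volume(self):
        labels = np.zeros((4, 10, 10), np.int32)
        labels[:, 4:6, 4:6] = 2  # reference duct
        labels[:, 6, 4] = 1  # stain touching the duct
        labels[1, 1, 1] = 1  # isolated speck
        table = {1: DARK, 2: LabelSpec("duct", (80, 80, 255), 250, "bright")}
        return LabelVolume(labels, table, spacing=(1, 1, 1))

    def test_overlapping_and_isolated_components(self):
        rep = h.connectivity_query(self.make_volume(), 1, 2)
        assert rep.n_connected == 1
        assert rep.n_isolated == 1

    def test_verdicts_match_bfs_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            labels = np.zeros((6, 12, 12), np.int32)
            labels[(r.random((6, 12, 12)) < 0.15)] = 1
            labels[:, 5:7, 5:7] = 2
            vol = LabelVolume(
                labels, {1: DARK, 2: LabelSpec("ref", (0, 0, 255), 250, "bright")},
                spacing=(1, 1, 1),
            )
            rep = h.connectivity_query(vol, 1, 2, connectivity=26)
            _, sizes, touched = bfs_reachable_components(labels == 1, labels == 2, 26)
            assert rep.n_connected == len(touched)
            assert rep.n_isolated == len(sizes) - len(touched)

    def test_seed_mask_reference(self):
        vol = self.make_volume()
        seed = vol.labels == 2
        rep = h.connectivity_query(vol, 1, seed)
        assert rep.n_connected == 1 and rep.n_isolated == 1

    def test_empty_reference_rejected(self):
        vol = self.make_volume()
        with pytest.raises(ValueError):
            h.connectivity_query(vol, 1, np.zeros_like(vol.labels, dtype=bool))

    def test_verdict_counts_invariant_under_component_relabeling(self, rng):
        # permuting which component gets which id never changes the totals
        labels = np.zeros((4, 10, 10), np.int32)
        labels[0, 1, 1] = 1
        labels[2, 5, 5] = 1
        labels[:, 8, 8] = 2
        vol = LabelVolume(
            labels, {1: DARK, 2: LabelSpec("ref", (0, 0, 255), 250, "bright")},
            spacing=(1, 1, 1),
        )
        flipped = labels[::-1].copy()  # reverses discovery order of components
        vol2 = LabelVolume(flipped, dict(vol.table), spacing=(1, 1, 1))
        r1 = h.connectivity_query(vol, 1, 2)
        r2 = h.connectivity_query(vol2, 1, 2)
        assert (r1.n_connected, r1.n_isolated) == (r2.n_connected, r2.n_isolated)


class TestFilterSmall:
    def test_min_one_is_identity(self, rng):
        vol = label_volume_from(rng.random((4, 8, 8)) < 0.2)
        out = h.filter_small(vol, 1, 1)
        np.testing.assert_array_equal(out.labels, vol.labels)

    def test_small_component_removed(self):
        mask = np.zeros((3, 8, 8), bool)
        mask[1, 1:3, 1:3] = True  # 4 voxels
        vol = label_volume_from(mask)
        out = h.filter_small(vol, 1, 10)
        assert (out.labels == 0).all()

    def test_survivor_census_matches_oracle(self, rng):
        mask = rng.random((6, 14, 14)) < 0.2
        vol = label_volume_from(mask)
        out = h.filter_small(vol, 1, 5)
        _, oracle_sizes = flood_fill_components(mask, 26)
        survivors = sorted(s for s in oracle_sizes if s >= 5)
        got = h.components_3d(out, 1)
        assert sorted(got.sizes.tolist()) == survivors
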