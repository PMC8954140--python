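"""Voting oracle, post-processing semantics, ensemble selection."""

import numpy as np
import pytest

from lgeseg.inference import (VoteStack, classify_patient, default_quorum,
                              majority_vote, postprocess, select_ensemble)
from lgeseg.io import MVO, MYOCARDIUM, SCAR, LabelMap, check_topology


def vote_oracle(members, anatomical, quorum):
    """Per-voxel brute-force re-implementation of the fusion rule."""
    shape = members[0].shape
    out = anatomical.copy()
    for idx in np.ndindex(shape):
        votes = [m[idx] for m in members]
        n_scar = votes.count(SCAR)
        n_mvo = votes.count(MVO)
        if n_scar + n_mvo >= quorum:
            out[idx] = SCAR if n_scar >= n_mvo else MVO
    return out


class TestMajorityVote:
    def test_unanimous_members(self, random_labelmap):
        lm = random_labelmap(seed=0)
        stack = VoteStack([lm.labels.copy() for _ in range(5)], quorum=3,
                          anatomical=np.full(lm.shape, MYOCARDIUM, np.uint8))
        fused = majority_vote(stack)
        # pathological voxels agree with any member; the rest follow anatomy
        path = lm.labels >= SCAR
        np.testing.assert_array_equal(fused.labels[path], lm.labels[path])
        assert (fused.labels[~path] == MYOCARDIUM).all()

    def test_three_of_eight_scar_beats_five_myocardium(self):
        shape = (4, 4, 2)
        anatomical = np.full(shape, MYOCARDIUM, np.uint8)
        members = [np.full(shape, MYOCARDIUM, np.uint8) for _ in range(8)]
        for m in members[:3]:
            m[1, 1, 0] = SCAR
        fused = majority_vote(VoteStack(members, quorum=3,
                                        anatomical=anatomical))
        assert fused.labels[1, 1, 0] == SCAR

    def test_two_of_eight_below_quorum(self):
        shape = (4, 4, 2)
        anatomical = np.full(shape, MYOCARDIUM, np.uint8)
        members = [np.full(shape, MYOCARDIUM, np.uint8) for _ in range(8)]
        for m in members[:2]:
            m[1, 1, 0] = SCAR
        fused = majority_vote(VoteStack(members, quorum=3,
                                        anatomical=anatomical))
        assert fused.labels[1, 1, 0] == MYOCARDIUM

    def test_tie_between_scar_and_mvo_goes_to_scar(self):
        shape = (2, 2, 1)
        anatomical = np.full(shape, MYOCARDIUM, np.uint8)
        members = [np.full(shape, MYOCARDIUM, np.uint8) for _ in range(4)]
        members[0][0, 0, 0] = SCAR
        members[1][0, 0, 0] = SCAR
        members[2][0, 0, 0] = MVO
        members[3][0, 0, 0] = MVO
        fused = majority_vote(VoteStack(members, quorum=3,
                                        anatomical=anatomical))
        assert fused.labels[0, 0, 0] == SCAR

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_vote_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        members = [rng.integers(0, 5, (12, 12, 3)).astype(np.uint8)
                   for _ in range(8)]
        anatomical = rng.integers(0, 3, (12, 12, 3)).astype(np.uint8)
        stack = VoteStack(members, quorum=3, anatomical=anatomical)
        fused = majority_vote(stack)
        np.testing.assert_array_equal(
            fused.labels, vote_oracle(members, anatomical, 3))

    def test_member_order_invariance(self, rng):
        members = [rng.integers(0, 5, (10, 10, 2)).astype(np.uint8)
                   for _ in range(6)]
        anatomical = rng.integers(0, 3, (10, 10, 2)).astype(np.uint8)
        a = majority_vote(VoteStack(members, 3, anatomical=anatomical)).labels
        b = majority_vote(VoteStack(members[::-1], 3,
                                    anatomical=anatomical)).labels
        np.testing.assert_array_equal(a, b)

    def test_stack_validation(self, rng):
        with pytest.raises(ValueError):
            VoteStack([])
        with pytest.raises(ValueError, match="quorum"):
            VoteStack([np.zeros((2, 2, 2), np.uint8)], quorum=2)
        with pytest.raises(ValueError, match="grids"):
            VoteStack([np.zeros((2, 2, 2), np.uint8),
                       np.zeros((3, 3, 3), np.uint8)])


def test_default_quorum_scaling():
    assert default_quorum(8) == 3
    assert default_quorum(3) == 1
    assert default_quorum(1) == 1
    assert default_quorum(16) == 3  # capped at the published quorum


def wall_with_blob(blob_voxels, shape=(20, 20, 6)):
    """Myocardium-filled map with a cubic-ish scar blob of a given size."""
    arr = np.full(shape, MYOCARDIUM, np.uint8)
    placed = 0
    for z in range(4):
        for r in range(4):
            for c in range(4):
                if placed < blob_voxels:
                    arr[8 + r, 8 + c, 1 + z] = SCAR
                    placed += 1
    return arr


class TestPostprocess:
    def test_63_voxel_component_removed(self):
        out = postprocess(wall_with_blob(63))
        assert not (out.labels == SCAR).any()

    def test_64_voxel_component_retained(self):
        out = postprocess(wall_with_blob(64))
        assert (out.labels == SCAR).sum() == 64

    def test_all_myocardium_unchanged(self):
        arr = np.full((10, 10, 4), MYOCARDIUM, np.uint8)
        np.testing.assert_array_equal(postprocess(arr).labels, arr)

    def test_removed_voxels_become_myocardium(self):
        out = postprocess(wall_with_blob(63))
        assert (out.labels == MYOCARDIUM).all()

    def test_orphan_mvo_relabelled_to_scar(self):
        arr = np.full((20, 20, 6), MYOCARDIUM, np.uint8)
        arr[4:12, 4:12, 1:4] = MVO  # large MVO blob with no scar anywhere
        out = postprocess(arr)
        assert not (out.labels == MVO).any()
        assert (out.labels == SCAR).any()
        assert check_topology(out).mvo_without_scar == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_idempotent_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 5, (24, 24, 6)).astype(np.uint8)
        once = postprocess(arr)
        twice = postprocess(once)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_spacing_preserved(self):
        lm = LabelMap(wall_with_blob(64), spacing=(1.5, 1.5, 8.0))
        assert postprocess(lm).spacing == (1.5, 1.5, 8.0)


class TestClassifyPatient:
    def test_surviving_scar_means_infarcted(self):
        assert classify_patient(postprocess(wall_with_blob(64))) == "infarcted"

    def test_pathology_free_map_is_normal(self):
        arr = np.full((8, 8, 4), MYOCARDIUM, np.uint8)
        assert classify_patient(arr) == "normal"

    def test_subthreshold_scar_cleaned_to_normal(self):
        assert classify_patient(postprocess(wall_with_blob(63))) == "normal"


class TestSelectEnsemble:
    def test_single_candidate(self):
        assert select_ensemble([(0,)], [0.7]) == (0,)

    def test_argmax_by_dsc(self):
        assert select_ensemble([(0,), (1,)], [0.7, 0.8]) == (1,)

    def test_tie_prefers_smaller_ensemble(self):
        assert select_ensemble([(0, 1, 2), (0, 1)], [0.8, 0.8]) == (0, 1)

    def test_matches_exhaustive_scan(self, rng):
        import itertools

        members = list(range(4))
        candidates = [c for r in range(1, 5)
                      for c in itertools.combinations(members, r)]
        scores = list(rng.random(len(candidates)))
        best = select_ensemble(candidates, scores)
        expect = min(zip(candidates, scores, range(len(scores))),
                     key=lambda t: (-t[1], len(t[0]), t[2]))[0]
        assert best == expect
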