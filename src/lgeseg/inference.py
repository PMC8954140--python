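"""Test-time prediction, ensemble fusion, post-processing, classification.

Prediction is hierarchical: the anatomical network labels background /
cavity / wall; each pathological ensemble member then relabels wall voxels
among {myocardium, scar, MVO}.  Member maps are fused by majority voting —
a voxel becomes pathological when at least `quorum` members vote any
infarct class (MVO votes count toward the quorum, MVO being a subclass of
MI), the winning class being the plurality of pathological votes with ties
resolved to scar.  Post-processing opens the infarct region slice-wise
(3×3), drops 3D components below 64 voxels and reattaches orphan MVO, and
is iterated to a fixed point so it is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import BACKGROUND, CAVITY, MVO, MYOCARDIUM, SCAR, LabelMap
from .preprocess import (CavityNotFoundError, PreprocessRecord,
                         locate_lv_centroid, preprocess_volume)
from .training import PATH_TO_LABEL, TrainConfig

DEFAULT_QUORUM = 3


def default_quorum(n_members: int) -> int:
    """Quorum of 3 for the full 8-member roster, scaled proportionally
    (never below 1) for smaller rosters.

    For a 3-member roster this is 1 — a union over members — which is the
    published 3/8 fraction rounded; the 64-voxel component floor in
    post-processing is what controls the union's false positives."""
    return min(DEFAULT_QUORUM, max(1, round(DEFAULT_QUORUM * n_members / 8)))


@dataclass
class VoteStack:
    """Ensemble member predictions over a shared grid."""

    member_preds: list
    quorum: int = DEFAULT_QUORUM
    anatomical: np.ndarray | None = None

    def __post_init__(self):
        if not self.member_preds:
            raise ValueError("empty vote stack")
        arrays = [m.labels if isinstance(m, LabelMap) else np.asarray(m)
                  for m in self.member_preds]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"member grids differ: {shapes}")
        if self.quorum > len(arrays):
            raise ValueError("quorum exceeds member count")
        self.member_preds = arrays


def sliding_window_probs(net, channels: np.ndarray,
                         patch: tuple[int, int, int]) -> np.ndarray:
    """Overlap-averaged softmax probabilities over a whole volume.

    Windows of `patch` are tiled with half-window stride (clamped at the
    far edge); per-voxel probabilities are averaged over covering windows
    and renormalised.
    """
    _, R, C, S = channels.shape
    patch = tuple(min(p, s) for p, s in zip(patch, (R, C, S)))
    out_classes = net.cfg.out_classes
    acc = np.zeros((out_classes, R, C, S), dtype=np.float64)
    cover = np.zeros((R, C, S), dtype=np.float64)

    def starts(extent, p):
        if extent == p:
            return [0]
        stride = max(p // 2, 1)
        pos = list(range(0, extent - p, stride)) + [extent - p]
        return sorted(set(pos))

    for r0 in starts(R, patch[0]):
        for c0 in starts(C, patch[1]):
            for z0 in starts(S, patch[2]):
                win = (slice(r0, r0 + patch[0]), slice(c0, c0 + patch[1]),
                       slice(z0, z0 + patch[2]))
                x = channels[(slice(None),) + win][None].astype(np.float32)
                probs = net(x).data[0]
                acc[(slice(None),) + win] += probs
                cover[win] += 1.0
    acc /= cover[None]
    acc /= acc.sum(axis=0, keepdims=True)
    return acc


@dataclass
class CasePrediction:
    """Everything predict_case produces for one volume."""

    anatomical: LabelMap
    stack: VoteStack
    record: PreprocessRecord
    member_probs: list = field(default_factory=list)
    raw_member_maps: list = field(default_factory=list)


def predict_case(volume, anatomical_net, members, cfg: TrainConfig,
                 quorum: int | None = None) -> CasePrediction:
    """Two-stage prediction of one (unpreprocessed) volume.

    A first anatomical pass on a centre-cropped copy locates the cavity
    centroid (image centre if no cavity is found); the properly cropped
    volume is then segmented anatomically, and each pathological member
    relabels the predicted wall.  `raw_member_maps` keep each member's
    unmasked argmax (mapped to report labels) for topology diagnostics.
    """
    from .training import predict_anatomical

    nlm = {"h": cfg.denoise_h} if cfg.denoise_h is not None else {}
    first, first_rec = preprocess_volume(volume, None, target=cfg.target_shape,
                                         nlm=nlm, allow_z_crop=True)
    try:
        centroid_local = locate_lv_centroid(
            predict_anatomical(anatomical_net, first.data))
        centroid = (centroid_local[0] + first_rec.crop_offset[0],
                    centroid_local[1] + first_rec.crop_offset[1])
    except CavityNotFoundError:
        centroid = None
    pre, rec = preprocess_volume(volume, centroid, target=cfg.target_shape,
                                 nlm=nlm, allow_z_crop=True)
    anat = predict_anatomical(anatomical_net, pre.data)
    anat_labels = anat.copy()
    wall = anat_labels == 2
    mask = wall.astype(np.float32)

    channels = np.stack([pre.data, mask])
    member_maps, member_probs, raw_maps = [], [], []
    for net in members:
        probs = sliding_window_probs(net, channels, cfg.patch_size)
        raw_maps.append(PATH_TO_LABEL[np.argmax(probs, axis=0)])
        mm = anat_labels.copy()
        within = np.argmax(probs[1:], axis=0) + 1  # 1 myo, 2 scar, 3 mvo
        mm[wall] = PATH_TO_LABEL[within][wall]
        member_maps.append(mm)
        member_probs.append(probs)
    q = quorum if quorum is not None else default_quorum(len(members))
    stack = VoteStack(member_preds=member_maps, quorum=q,
                      anatomical=anat_labels)
    return CasePrediction(anatomical=LabelMap(anat_labels,
                                              spacing=volume.spacing),
                          stack=stack, record=rec,
                          member_probs=member_probs,
                          raw_member_maps=raw_maps)


def majority_vote(stack: VoteStack) -> LabelMap:
    """Fuse member maps: pathological iff ≥ quorum infarct votes; winning
    class by plurality of pathological votes (ties → scar); otherwise the
    anatomical label (or the member plurality when no anatomical map)."""
    preds = np.stack(stack.member_preds)  # (M, R, C, S)
    scar_votes = (preds == SCAR).sum(axis=0)
    mvo_votes = (preds == MVO).sum(axis=0)
    path_votes = scar_votes + mvo_votes
    pathological = path_votes >= stack.quorum

    if stack.anatomical is not None:
        base = np.asarray(stack.anatomical).copy()
    else:
        counts = np.stack([(preds == c).sum(axis=0)
                           for c in (BACKGROUND, CAVITY, MYOCARDIUM)])
        base = np.argmax(counts, axis=0).astype(np.uint8)
    out = base.astype(np.uint8)
    out[pathological & (scar_votes >= mvo_votes)] = SCAR
    out[pathological & (scar_votes < mvo_votes)] = MVO
    return LabelMap(out)


def _open_slicewise(mask: np.ndarray) -> np.ndarray:
    opened = np.zeros_like(mask)
    se = np.ones((3, 3), dtype=bool)
    for s in range(mask.shape[2]):
        opened[:, :, s] = ndimage.binary_opening(mask[:, :, s], structure=se)
    return opened


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def postprocess(labels: LabelMap | np.ndarray, min_size: int = 64,
                max_rounds: int = 4) -> LabelMap:
    """Morphological cleanup of the fused map, iterated to a fixed point.

    Each round: slice-wise 3×3 opening of the infarct region (scar ∪ MVO,
    removed voxels become myocardium), removal of 3D infarct components
    (26-connectivity) below `min_size` voxels (relabelled to myocardium,
    preserving the anatomical shell), and relabelling to scar of MVO
    components with no adjacent scar.
    """
    arr = (labels.labels if isinstance(labels, LabelMap)
           else np.asarray(labels)).copy()
    spacing = labels.spacing if isinstance(labels, LabelMap) else (1.0,) * 3
    for _ in range(max_rounds):
        before = arr.copy()
        infarct = arr >= SCAR
        opened = _open_slicewise(infarct)
        arr[infarct & ~opened] = MYOCARDIUM
        comp, n = ndimage.label(opened, structure=_CONN26)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                       np.arange(1, n + 1))
            small = np.isin(comp, np.arange(1, n + 1)[sizes < min_size])
            arr[small] = MYOCARDIUM
        mcomp, mn = ndimage.label(arr == MVO, structure=_CONN26)
        for i in range(1, mn + 1):
            cm = mcomp == i
            halo = ndimage.binary_dilation(cm, structure=_CONN26)
            if not (halo & (arr == SCAR)).any():
                arr[cm] = SCAR
        if np.array_equal(arr, before):
            break
    return LabelMap(arr, spacing=spacing)


def classify_patient(final: LabelMap | np.ndarray) -> str:
    """Patient verdict from the post-processed map: infarcted iff any
    scar or MVO voxels survive."""
    arr = final.labels if isinstance(final, LabelMap) else np.asarray(final)
    return "infarcted" if (arr >= SCAR).any() else "normal"


def select_ensemble(candidates, train_dscs):
    """Pick the candidate member-subset with the highest mean training DSC
    over pathological classes; ties go to the smaller ensemble, then the
    earlier candidate."""
    if len(candidates) != len(train_dscs):
        raise ValueError("one DSC per candidate required")
    if not candidates:
        raise ValueError("no candidates")
    best, best_key = None, None
    for i, (cand, score) in enumerate(zip(candidates, train_dscs)):
        key = (-float(score), len(cand), i)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    return best
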