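"""Region-, surface- and volume-based segmentation evaluation.

Implements the challenge-style suite: Dice similarity coefficient,
Hausdorff distance on 6-connectivity boundary voxels (directed and
symmetric), absolute volume difference and its rate relative to the manual
myocardium volume, MVO presence accuracy at case and slice level, the
patient-classification confusion metrics, and Bland–Altman summaries.

Conventions: DSC of two empty masks is 1 (perfect agreement on absence);
an empty mask makes the Hausdorff distance undefined (reported as NaN in
tables, never 0); AVDR is in percent of the manual wall volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import MVO, SCAR, WALL_CLASSES, LabelMap

STRUCTURES = {"myocardium": WALL_CLASSES, "scar": (SCAR,), "mvo": (MVO,)}


class UndefinedMetricError(ValueError):
    """A metric has no value on this input (e.g. HD of an empty mask)."""


@dataclass
class VolumeMeasurements:
    """Automatic vs manual structure volumes (mm³) for one case.

    ``v_myo`` is the manual myocardial-wall volume (healthy muscle + scar +
    MVO), the denominator of the AVDR.
    """

    v_auto: float
    v_manual: float
    v_myo: float

    def __post_init__(self):
        if min(self.v_auto, self.v_manual, self.v_myo) < 0:
            raise ValueError("volumes must be >= 0")

    @classmethod
    def from_maps(cls, pred, gt, class_id: int, spacing
                  ) -> "VolumeMeasurements":
        p, g = _as_array(pred), _as_array(gt)
        vox = float(np.prod(spacing))
        return cls(v_auto=int(_mask(p, class_id).sum()) * vox,
                   v_manual=int(_mask(g, class_id).sum()) * vox,
                   v_myo=int(_mask(g, WALL_CLASSES).sum()) * vox)

    def avd(self) -> float:
        return abs(self.v_auto - self.v_manual)

    def avdr(self) -> float:
        return (float("nan") if self.v_myo == 0
                else 100.0 * self.avd() / self.v_myo)


def _as_array(x) -> np.ndarray:
    return x.labels if isinstance(x, LabelMap) else np.asarray(x)


def _mask(arr: np.ndarray, class_set) -> np.ndarray:
    if np.isscalar(class_set):
        class_set = (class_set,)
    return np.isin(arr, np.asarray(class_set))


def dsc(pred, gt, class_set) -> float:
    """Dice similarity coefficient 2|P∩G| / (|P|+|G|); both-empty → 1."""
    p, g = _as_array(pred), _as_array(gt)
    if p.shape != g.shape:
        raise ValueError(f"grid mismatch {p.shape} vs {g.shape}")
    pm, gm = _mask(p, class_set), _mask(g, class_set)
    denom = int(pm.sum()) + int(gm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pm & gm).sum()) / denom


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary = mask minus its 6-connectivity erosion (edges count)."""
    return mask & ~ndimage.binary_erosion(mask, structure=_STRUCT6)


def hausdorff(pred, gt, class_set, spacing, mode: str = "symmetric") -> float:
    """Hausdorff distance (mm) between boundary voxel sets.

    ``directed`` is max over predicted boundary points of the distance to
    the closest manual boundary point; ``symmetric`` takes the max of both
    directions (the reporting default).
    """
    p, g = _as_array(pred), _as_array(gt)
    if p.shape != g.shape:
        raise ValueError(f"grid mismatch {p.shape} vs {g.shape}")
    pm, gm = _mask(p, class_set), _mask(g, class_set)
    if not pm.any() or not gm.any():
        raise UndefinedMetricError("Hausdorff undefined for an empty mask")
    sp = np.asarray(spacing, dtype=np.float64)
    a = np.argwhere(boundary_voxels(pm)) * sp
    m = np.argwhere(boundary_voxels(gm)) * sp

    def directed(src, dst):
        d, _ = cKDTree(dst).query(src, k=1)
        return float(d.max())

    if mode == "directed":
        return directed(a, m)
    if mode == "symmetric":
        return max(directed(a, m), directed(m, a))
    raise ValueError(f"unknown mode {mode!r}")


def avd_avdr(pred, gt, class_id: int, spacing) -> tuple[float, float]:
    """Absolute volume difference (mm³) and its rate (% of manual wall).

    AVD = |V_A − V_M|; AVDR = 100·AVD / V_MYO with V_MYO the manual
    myocardial-wall volume (healthy muscle + scar + MVO).  AVDR is NaN when
    the manual wall is empty.
    """
    vm = VolumeMeasurements.from_maps(pred, gt, class_id, spacing)
    return vm.avd(), vm.avdr()


def mvo_presence_accuracy(preds, gts, level: str = "case") -> float:
    """Percent agreement of predicted vs true MVO presence.

    ``case``: one verdict per volume; ``slice``: short-axis slices of all
    volumes pooled.
    """
    hits = total = 0
    for pred, gt in zip(preds, gts, strict=True):
        p, g = _as_array(pred), _as_array(gt)
        if level == "case":
            hits += int((p == MVO).any() == (g == MVO).any())
            total += 1
        elif level == "slice":
            for s in range(p.shape[2]):
                hits += int((p[:, :, s] == MVO).any() == (g[:, :, s] == MVO).any())
                total += 1
        else:
            raise ValueError(f"unknown level {level!r}")
    if total == 0:
        raise UndefinedMetricError("no cases supplied")
    return 100.0 * hits / total


def classification_metrics(pred_labels, true_labels
                           ) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, precision, accuracy) in percent.

    Labels are binary with infarcted = positive = 1 (string labels
    "infarcted"/"normal" accepted).  Ratios with an empty denominator are
    NaN (reported missing).
    """
    def binarise(seq):
        return np.array([1 if str(x) in ("1", "infarcted", "True") else 0
                         for x in seq])

    p, t = binarise(pred_labels), binarise(true_labels)
    if p.shape != t.shape:
        raise ValueError("label lists differ in length")
    tp = int(((p == 1) & (t == 1)).sum())
    tn = int(((p == 0) & (t == 0)).sum())
    fp = int(((p == 1) & (t == 0)).sum())
    fn = int(((p == 0) & (t == 1)).sum())

    def ratio(num, den):
        return float("nan") if den == 0 else 100.0 * num / den

    return (ratio(tp, tp + fn), ratio(tn, tn + fp),
            ratio(tp, tp + fp), ratio(tp + tn, len(p)))


@dataclass
class BlandAltman:
    bias: float
    lower: float
    upper: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(vol_pred, vol_manual) -> BlandAltman:
    """Bias and 95% limits of agreement of automatic − manual volumes."""
    a = np.asarray(vol_pred, dtype=np.float64)
    m = np.asarray(vol_manual, dtype=np.float64)
    if a.shape != m.shape:
        raise ValueError("volume lists differ in length")
    diffs = a - m
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd,
                       (a + m) / 2.0, diffs)


def plot_bland_altman(ba: BlandAltman, ax=None, title: str = ""):
    """Standard Bland–Altman scatter with bias and limit lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.means, ba.diffs, s=12)
    ax.axhline(ba.bias, color="tab:blue", ls="--", label="bias")
    ax.axhline(ba.lower, color="tab:red", ls="--")
    ax.axhline(ba.upper, color="tab:red", ls="--")
    ax.set_xlabel("mean of volumes (mm³)")
    ax.set_ylabel("automatic − manual (mm³)")
    if title:
        ax.set_title(title)
    return ax


def evaluate_cases(preds, gts, spacing, case_ids=None,
                   hd_mode: str = "symmetric") -> pd.DataFrame:
    """Per-case metric table over the three reported structures.

    One row per case with DSC / HD / AVD / AVDR per structure, plus a final
    ``mean`` row.  Undefined entries (empty masks for HD, empty wall for
    AVDR) are NaN and excluded from the mean.
    """
    rows = []
    ids = case_ids if case_ids is not None else range(len(list(preds)))
    for cid, pred, gt in zip(ids, preds, gts, strict=True):
        row = {"case": cid}
        for name, classes in STRUCTURES.items():
            row[f"{name}_dsc"] = dsc(pred, gt, classes)
            try:
                row[f"{name}_hd"] = hausdorff(pred, gt, classes, spacing,
                                              mode=hd_mode)
            except UndefinedMetricError:
                row[f"{name}_hd"] = float("nan")
            avd, avdr = avd_avdr(pred, gt, classes[0] if len(classes) == 1
                                 else WALL_CLASSES[0], spacing)
            if len(classes) > 1:  # wall: pool all wall classes
                p, g = _as_array(pred), _as_array(gt)
                vox = float(np.prod(spacing))
                va = int(_mask(p, WALL_CLASSES).sum()) * vox
                vm = int(_mask(g, WALL_CLASSES).sum()) * vox
                avd = abs(va - vm)
                avdr = float("nan") if vm == 0 else 100.0 * avd / vm
            row[f"{name}_avd"] = avd
            row[f"{name}_avdr"] = avdr
        rows.append(row)
    df = pd.DataFrame(rows).set_index("case")
    df.loc["mean"] = df.mean(axis=0, skipna=True)
    return df
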