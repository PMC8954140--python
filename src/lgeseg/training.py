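"""Training orchestration for both stages and the CVAE shape prior.

The anatomical stage fits a 3-class U-Net (background / cavity / wall) with
cross-entropy + Dice under Adam and a polynomially decayed learning rate,
optionally as five-fold cross-validation.  The pathological stage fits a
4-class U-Net (outside-wall / healthy myocardium / scar / MVO) on windows
sampled around the myocardial wall, under the composite objective
L_seg + λ_IC·L_IC + λ_CC·L_CC, one model per (λ_IC, λ_CC) pair of the
ensemble roster.  The CVAE prior is pretrained on ground-truth one-hot
shapes and frozen.

All loops are seed-reproducible; divergence (non-finite loss) aborts with
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from ._layers import Adam, polynomial_lr
from .losses import (LossWeights, kl_divergence, loss_anatomical, loss_ce,
                     loss_dice, loss_final, onehot_encode)
from .metrics import dsc
from .networks import (CVAE, NetConfig, anatomical_config, build_net,
                       pathological_config)
from .preprocess import crop_labels, locate_lv_centroid, preprocess_volume

#: anatomical-stage class remap: wall = myocardium ∪ scar ∪ MVO
ANAT_REMAP = np.array([0, 1, 2, 2, 2], dtype=np.uint8)
#: pathological-stage remap: {bg ∪ cavity, myocardium, scar, MVO}
PATH_REMAP = np.array([0, 0, 1, 2, 3], dtype=np.uint8)
#: inverse of PATH_REMAP channels back to report labels
PATH_TO_LABEL = np.array([0, 2, 3, 4], dtype=np.uint8)


@dataclass
class TrainConfig:
    """Optimisation and scale settings for all three training loops.

    Full-scale defaults follow the published protocol (Adam, initial
    anatomical rate 3e-4 with polynomial decay, pathological rate 1e-4,
    12³ patches, batch 4, up to 200k iterations, 5 folds); the
    :func:`fast_dev` profile scales the same pipeline to a single CPU.
    """

    lr_anatomical: float = 3e-4
    lr_pathological: float = 1e-4
    lr_cvae: float = 1e-3
    poly_power: float = 0.9
    patch_size: tuple[int, int, int] = (12, 12, 12)
    batch_size: int = 4
    max_iters: int = 200_000
    anatomical_steps: int = 200_000
    pathological_steps: int = 200_000
    cvae_steps: int = 2000
    folds: int = 5
    seed: int = 0
    target_shape: tuple[int, int, int] = (96, 96, 16)
    depth: int = 3
    base_channels: int = 16
    cvae_base_channels: int = 8
    cvae_latent: int = 64
    cvae_kl_weight: float = 1e-3
    anatomical_batch: int = 2
    denoise_h: float | None = None   # None → σ-scaled; 0 disables

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        for lr in (self.lr_anatomical, self.lr_pathological, self.lr_cvae):
            if lr <= 0:
                raise ValueError("learning rates must be > 0")


def fast_dev_config(seed: int = 0) -> TrainConfig:
    """Desk-scale profile: 48×48×8 grids, small nets, few hundred steps.

    Learning rates are raised in proportion to the shortened schedules so
    the scaled runs traverse a comparable optimisation distance.
    """
    return TrainConfig(
        lr_anatomical=3e-3, lr_pathological=1e-3, lr_cvae=2e-3,
        patch_size=(16, 16, 8), batch_size=4,
        anatomical_steps=220, pathological_steps=600, cvae_steps=1200,
        target_shape=(48, 48, 8), depth=2, base_channels=8,
        cvae_base_channels=8, seed=seed, denoise_h=0.0,
    )


@dataclass
class LambdaGrid:
    """The (λ_IC, λ_CC) roster: grid values and the paired-member ensemble."""

    values: list[float]
    pairs: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if not self.pairs:
            self.pairs = [(v, v) for v in self.values]


def lambda_grid(start: float = 1e-2, step: float = 7e-2,
                ceiling: float = 5e-1) -> LambdaGrid:
    """λ values from 10⁻² to 5×10⁻¹ in increments of 7×10⁻²."""
    values = []
    v = start
    while v <= ceiling + 1e-12:
        values.append(round(v, 10))
        v += step
    return LambdaGrid(values=values)


def make_folds(cases, k: int = 5, seed: int = 0, strata=None):
    """Deterministic stratified k-fold partition; returns (train, val) index
    lists with every case in exactly one validation fold."""
    n = len(cases)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} cases")
    if strata is None:
        strata = [getattr(c, "category", getattr(c, "patient_label", ""))
                  for c in cases]
    rng = np.random.default_rng(seed)
    buckets: dict = {}
    for i, s in enumerate(strata):
        buckets.setdefault(s, []).append(i)
    assignment = np.empty(n, dtype=int)
    offset = 0
    for key in sorted(buckets, key=str):
        idx = np.array(buckets[key])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            assignment[i] = (j + offset) % k
        offset += len(idx)
    folds = []
    for f in range(k):
        val = [i for i in range(n) if assignment[i] == f]
        train = [i for i in range(n) if assignment[i] != f]
        folds.append((train, val))
    return folds


# ---------------------------------------------------------------------------
# case preparation

@dataclass
class PreparedCase:
    """A case after the deterministic pre-processing chain."""

    case_id: str
    image: np.ndarray          # (rows, cols, slices), float32 in [0, 1]
    labels: np.ndarray         # cropped GT labels, uint8, or None
    record: object
    patient_label: int         # 1 infarcted / 0 normal
    category: str = ""


def prepare_cohort(cohort, cfg: TrainConfig) -> list[PreparedCase]:
    """Crop each case around its GT cavity centroid and normalise contrast."""
    out = []
    nlm = {"h": cfg.denoise_h} if cfg.denoise_h is not None else {}
    for case in cohort:
        try:
            centroid = locate_lv_centroid(case.labels)
        except Exception:
            centroid = None
        vol, rec = preprocess_volume(case.volume, centroid,
                                     target=cfg.target_shape, nlm=nlm)
        lab = crop_labels(case.labels, rec).labels if case.labels is not None \
            else None
        patient = int(case.patient_label == "infarcted") \
            if isinstance(case.patient_label, str) else int(case.patient_label)
        out.append(PreparedCase(case_id=case.case_id, image=vol.data,
                                labels=lab, record=rec, patient_label=patient,
                                category=getattr(case, "category", "")))
    return out


class DivergenceError(RuntimeError):
    pass


def _check_finite(loss_val: float, step: int, stage: str):
    if not np.isfinite(loss_val):
        raise DivergenceError(
            f"{stage} training diverged at step {step}: loss={loss_val}")


# ---------------------------------------------------------------------------
# anatomical stage

def fit_anatomical(train_cases: list[PreparedCase], cfg: TrainConfig,
                   seed: int, steps: int | None = None,
                   loss_log: list | None = None):
    """Fit one anatomical U-Net on prepared cases; returns the model."""
    steps = steps or cfg.anatomical_steps
    rng = np.random.default_rng(seed)
    net_cfg = anatomical_config(depth=cfg.depth,
                                base_channels=cfg.base_channels,
                                in_channels=1, out_classes=3)
    net = build_net(net_cfg, rng)
    opt = Adam(net.parameters(), lr=cfg.lr_anatomical)
    images = np.stack([c.image for c in train_cases])[:, None]  # (M,1,...)
    targets = np.stack([ANAT_REMAP[c.labels] for c in train_cases])
    m = len(train_cases)
    for step in range(steps):
        idx = rng.choice(m, size=min(cfg.anatomical_batch, m), replace=False)
        x = images[idx]
        oh = onehot_encode(targets[idx], 3)
        probs = net(x)
        loss = loss_anatomical(probs, oh)
        _check_finite(loss.item(), step, "anatomical")
        if loss_log is not None:
            loss_log.append(loss.item())
        opt.lr = polynomial_lr(cfg.lr_anatomical, step, steps, cfg.poly_power)
        opt.zero_grad()
        loss.backward()
        opt.step()
    net.eval()
    return net


def predict_anatomical(net, image: np.ndarray) -> np.ndarray:
    """Whole-volume anatomical labels {0 bg, 1 cavity, 2 wall}."""
    probs = net(image[None, None].astype(np.float32))
    return np.argmax(probs.data[0], axis=0).astype(np.uint8)


def train_anatomical(cohort, cfg: TrainConfig, prepared=None):
    """Five-fold cross-validated anatomical training.

    Returns (per-fold models, metrics table with one row per fold plus
    mean and SD rows: wall DSC / AVD / HD).
    """
    from .metrics import UndefinedMetricError, hausdorff

    cases = prepared if prepared is not None else prepare_cohort(cohort, cfg)
    folds = make_folds(cases, k=cfg.folds, seed=cfg.seed,
                       strata=[c.category or str(c.patient_label)
                               for c in cases])
    spacing = cases[0].record.spacing
    vox = float(np.prod(spacing))
    models, rows = [], []
    for f, (train_idx, val_idx) in enumerate(folds):
        net = fit_anatomical([cases[i] for i in train_idx], cfg,
                             seed=cfg.seed * 1000 + f)
        dscs, avds, hds = [], [], []
        for i in val_idx:
            pred = predict_anatomical(net, cases[i].image)
            gt = ANAT_REMAP[cases[i].labels]
            dscs.append(dsc(pred, gt, (2,)))
            avds.append(abs(int((pred == 2).sum()) - int((gt == 2).sum())) * vox)
            try:
                hds.append(hausdorff(pred, gt, (2,), spacing))
            except UndefinedMetricError:
                hds.append(np.nan)
        models.append(net)
        rows.append({"fold": f, "myocardium_dsc": float(np.mean(dscs)),
                     "myocardium_avd": float(np.mean(avds)),
                     "myocardium_hd": float(np.nanmean(hds))})
    table = pd.DataFrame(rows).set_index("fold")
    table.loc["mean"] = table.mean()
    table.loc["sd"] = table.iloc[:-1].std()
    return models, table


# ---------------------------------------------------------------------------
# CVAE shape prior

def pretrain_cvae(gt_onehots, cfg: TrainConfig, seed: int = 0,
                  loss_log: list | None = None) -> tuple[CVAE, float]:
    """Pretrain the shape prior on one-hot GT shapes and freeze it.

    Returns (frozen model, mean reconstruction Dice over foreground classes
    present in each training shape, decoded from the latent mean).
    """
    shapes = np.stack([np.asarray(o, dtype=np.float32) for o in gt_onehots])
    n, k = shapes.shape[:2]
    rng = np.random.default_rng(seed)
    net_cfg = NetConfig(kind="cvae", base_channels=cfg.cvae_base_channels,
                        in_channels=k, latent_dim=cfg.cvae_latent,
                        input_shape=tuple(shapes.shape[2:]),
                        kl_weight=cfg.cvae_kl_weight)
    cvae = build_net(net_cfg, rng)
    opt = Adam(cvae.parameters(), lr=cfg.lr_cvae)
    batch = min(4, n)
    for step in range(cfg.cvae_steps):
        idx = rng.choice(n, size=batch, replace=False)
        x = shapes[idx]
        recon, mu, logvar = cvae(Tensor(x), sample=True, rng=rng)
        loss = (loss_ce(recon, x) + loss_dice(recon, x)
                + cfg.cvae_kl_weight * kl_divergence(mu, logvar))
        _check_finite(loss.item(), step, "cvae")
        if loss_log is not None:
            loss_log.append(loss.item())
        opt.zero_grad()
        loss.backward()
        opt.step()
    cvae.freeze()
    dice = cvae_reconstruction_dice(cvae, shapes)
    return cvae, dice


def cvae_reconstruction_dice(cvae: CVAE, shapes: np.ndarray) -> float:
    """Mean Dice of mean-latent reconstructions vs inputs, over foreground
    classes present in each shape."""
    scores = []
    for i in range(shapes.shape[0]):
        recon, _, _ = cvae(Tensor(shapes[i][None]))
        rec_lab = np.argmax(recon.data[0], axis=0)
        in_lab = np.argmax(shapes[i], axis=0)
        per_class = [dsc(rec_lab, in_lab, (c,))
                     for c in range(1, shapes.shape[1])
                     if (in_lab == c).any()]
        if per_class:
            scores.append(float(np.mean(per_class)))
    return float(np.mean(scores)) if scores else float("nan")


# ---------------------------------------------------------------------------
# pathological stage

def _clamp_window(center, size, bound):
    lo = int(center) - size // 2
    lo = max(0, min(lo, bound - size))
    return lo


def sample_patch_origin(mask: np.ndarray, patch: tuple[int, int, int],
                        rng: np.random.Generator,
                        voxels: np.ndarray | None = None):
    """Origin of a patch window guaranteed to overlap the wall mask.

    A wall voxel is drawn uniformly and the window is centred on it, clamped
    inside the grid — the sampled voxel stays inside the window, so every
    patch overlaps the mask by construction.
    """
    if voxels is None:
        voxels = np.argwhere(mask)
    if len(voxels) == 0:
        raise ValueError("empty wall mask")
    center = voxels[rng.integers(len(voxels))]
    return tuple(_clamp_window(center[d], patch[d], mask.shape[d])
                 for d in range(3))


def train_pathological(cases: list[PreparedCase], masks, cvae: CVAE,
                       weights: LossWeights, cfg: TrainConfig, seed: int = 0,
                       loss_log: list | None = None):
    """Fit one pathological U-Net under L_seg + λ_IC·L_IC + λ_CC·L_CC.

    `masks` are the pre-segmented wall masks (one bool grid per case); cases
    whose mask is empty are skipped with a warning.  The patient label for
    the class constraint is per case: infarcted iff GT has scar/MVO voxels.
    """
    import warnings

    rng = np.random.default_rng(seed)
    usable, wall_voxels, path_voxels = [], [], []
    for case, mask in zip(cases, masks, strict=True):
        vox = np.argwhere(mask)
        if len(vox) == 0:
            warnings.warn(f"case {case.case_id}: empty wall mask, skipped")
            continue
        usable.append((case, mask.astype(np.float32)))
        wall_voxels.append(vox)
        pv = np.argwhere(case.labels >= 3) if case.labels is not None else vox
        path_voxels.append(pv if len(pv) else vox)
    if not usable:
        raise ValueError("no case has a non-empty wall mask")

    net_cfg = pathological_config(depth=cfg.depth,
                                  base_channels=cfg.base_channels)
    net = build_net(net_cfg, rng)
    opt = Adam(net.parameters(), lr=cfg.lr_pathological)
    patch = cfg.patch_size
    use_cvae = cvae is not None and weights.lambda_ic > 0
    for step in range(cfg.pathological_steps):
        xs, ys, labels = [], [], []
        for _ in range(cfg.batch_size):
            ci = int(rng.integers(len(usable)))
            case, mask = usable[ci]
            # half the windows are centred on pathology voxels (when the
            # case has any) to counter the heavy class imbalance
            pool = path_voxels[ci] if rng.random() < 0.5 else wall_voxels[ci]
            r0, c0, z0 = sample_patch_origin(mask, patch, rng, pool)
            win = (slice(r0, r0 + patch[0]), slice(c0, c0 + patch[1]),
                   slice(z0, z0 + patch[2]))
            xs.append(np.stack([case.image[win], mask[win]]))
            ys.append(PATH_REMAP[case.labels[win]])
            labels.append(case.patient_label)
        x = np.stack(xs).astype(np.float32)
        oh = onehot_encode(np.stack(ys), 4)
        probs, scores = net(x, return_scores=True)
        rp = rg = None
        if use_cvae:
            rp, _, _ = cvae(probs)
            rg_t, _, _ = cvae(Tensor(oh))
            rg = rg_t.detach()
        loss = loss_final(probs, oh, rp, rg, scores, labels, weights,
                          normalize_ic=True)
        _check_finite(loss.item(), step, "pathological")
        if loss_log is not None:
            loss_log.append(loss.item())
        opt.zero_grad()
        loss.backward()
        opt.step()
    net.eval()
    return net


def train_pathological_ensemble(cases, masks, cvae, roster, cfg: TrainConfig,
                                seed: int = 0):
    """One model per (λ_IC, λ_CC) pair of the roster."""
    members = []
    for j, (lic, lcc) in enumerate(roster):
        w = LossWeights(lambda_ic=lic, lambda_cc=lcc)
        members.append(train_pathological(cases, masks, cvae, w, cfg,
                                          seed=seed * 100 + j))
    return members
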