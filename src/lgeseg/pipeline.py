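"""Model/Results interface over the two-stage pipeline, plus the scaled
end-to-end experiment used by the CLI and the reproduction script.

The classes follow the estimator convention of statistical modelling
packages: a model object is built from data and configuration, ``fit()``
performs the training and returns a results object carrying the fitted
networks, the evaluation tables and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import (classify_patient, default_quorum, majority_vote,
                        postprocess, predict_case)
from .io import check_topology
from .losses import onehot_encode
from .metrics import classification_metrics, evaluate_cases, \
    mvo_presence_accuracy
from .phantom import generate_cohort
from .preprocess import restore_geometry
from .training import (PATH_REMAP, PreparedCase, TrainConfig,
                       fast_dev_config, fit_anatomical, lambda_grid,
                       make_folds, predict_anatomical, prepare_cohort,
                       pretrain_cvae, sample_patch_origin, train_anatomical,
                       train_pathological_ensemble)

#: fast_dev ensemble roster: three paired (λ_IC, λ_CC) values off the grid
FAST_DEV_ROSTER = [(0.01, 0.01), (0.08, 0.08), (0.15, 0.15)]


# ---------------------------------------------------------------------------
# anatomical stage

class AnatomicalSegmentation:
    """First-stage model: background / LV cavity / myocardial wall."""

    def __init__(self, cohort, config: TrainConfig | None = None):
        self.cohort = cohort
        self.config = config or TrainConfig()
        self._prepared = None

    @property
    def prepared(self) -> list[PreparedCase]:
        if self._prepared is None:
            self._prepared = prepare_cohort(self.cohort, self.config)
        return self._prepared

    def fit(self, cross_validate: bool = False) -> "AnatomicalResults":
        if cross_validate:
            models, table = train_anatomical(self.cohort, self.config,
                                             prepared=self.prepared)
            return AnatomicalResults(self, models, cv_table=table)
        net = fit_anatomical(self.prepared, self.config,
                             seed=self.config.seed)
        return AnatomicalResults(self, [net])


@dataclass
class AnatomicalResults:
    model_spec: AnatomicalSegmentation
    models: list
    cv_table: pd.DataFrame | None = None

    @property
    def net(self):
        return self.models[0]

    def predict_labels(self, image: np.ndarray) -> np.ndarray:
        return predict_anatomical(self.net, image)

    def wall_mask(self, case: PreparedCase) -> np.ndarray:
        return self.predict_labels(case.image) == 2

    def summary(self) -> str:
        lines = ["Anatomical segmentation (cavity/wall U-Net)",
                 f"  folds trained: {len(self.models)}"]
        if self.cv_table is not None:
            lines.append(self.cv_table.to_string(float_format="%.3f"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# CVAE shape prior

class ShapePrior:
    """Frozen CVAE over one-hot pathology-stage shapes (window-sized)."""

    def __init__(self, shapes, config: TrainConfig | None = None):
        self.shapes = [np.asarray(s, dtype=np.float32) for s in shapes]
        self.config = config or TrainConfig()

    @classmethod
    def from_cases(cls, cases: list[PreparedCase], config: TrainConfig,
                   per_case: int = 3, seed: int = 0) -> "ShapePrior":
        """Window-sized one-hot GT shapes sampled around each case's wall."""
        rng = np.random.default_rng(seed)
        patch = config.patch_size
        shapes = []
        for case in cases:
            wall = case.labels >= 2
            if not wall.any():
                continue
            vox = np.argwhere(wall)
            for _ in range(per_case):
                r0, c0, z0 = sample_patch_origin(wall, patch, rng, vox)
                win = (slice(r0, r0 + patch[0]), slice(c0, c0 + patch[1]),
                       slice(z0, z0 + patch[2]))
                shapes.append(onehot_encode(PATH_REMAP[case.labels[win]], 4))
        return cls(shapes, config)

    def fit(self, seed: int = 0) -> "ShapePriorResults":
        model, dice = pretrain_cvae(self.shapes, self.config, seed=seed)
        return ShapePriorResults(model=model, reconstruction_dice=dice,
                                 n_shapes=len(self.shapes))


@dataclass
class ShapePriorResults:
    model: object
    reconstruction_dice: float
    n_shapes: int

    def summary(self) -> str:
        return ("CVAE shape prior\n"
                f"  shapes: {self.n_shapes}\n"
                f"  mean reconstruction Dice: {self.reconstruction_dice:.3f}")


# ---------------------------------------------------------------------------
# pathological stage

class PathologySegmentation:
    """Second-stage model: scar / MVO within the pre-segmented wall."""

    def __init__(self, cases: list[PreparedCase], masks, prior,
                 roster=None, config: TrainConfig | None = None):
        self.cases = cases
        self.masks = masks
        self.prior = prior
        self.config = config or TrainConfig()
        self.roster = roster if roster is not None else lambda_grid().pairs

    def fit(self, seed: int = 0) -> "PathologyResults":
        cvae = self.prior.model if hasattr(self.prior, "model") else self.prior
        members = train_pathological_ensemble(self.cases, self.masks, cvae,
                                              self.roster, self.config,
                                              seed=seed)
        return PathologyResults(members=members, roster=list(self.roster),
                                config=self.config)


@dataclass
class PathologyResults:
    members: list
    roster: list
    config: TrainConfig

    def summary(self) -> str:
        pairs = ", ".join(f"({a:g},{b:g})" for a, b in self.roster)
        return (f"Pathological ensemble: {len(self.members)} members\n"
                f"  (λ_IC, λ_CC) roster: {pairs}\n"
                f"  fusion quorum: {default_quorum(len(self.members))}")


# ---------------------------------------------------------------------------
# end-to-end experiment

@dataclass
class ExperimentReport:
    """Everything the scaled end-to-end run measures on held-out phantoms."""

    metrics: pd.DataFrame
    classification: tuple
    mvo_case_accuracy: float
    mvo_slice_accuracy: float
    topology_violations_final: int
    raw_topology_violations: int
    cvae_reconstruction_dice: float
    anatomical: AnatomicalResults = None
    pathology: PathologyResults = None
    predictions: list = field(default_factory=list)

    def summary(self) -> str:
        mean = self.metrics.loc["mean"]
        sens, spec, prec, acc = self.classification
        lines = [
            "Held-out evaluation (phantom cohort)",
            f"  myocardium DSC: {mean['myocardium_dsc']:.3f}"
            f"   scar DSC: {mean['scar_dsc']:.3f}"
            f"   MVO DSC: {mean['mvo_dsc']:.3f}",
            f"  patient classification: acc {acc:.1f}%  sens {sens:.1f}%"
            f"  spec {spec:.1f}%  prec {prec:.1f}%",
            f"  MVO presence accuracy: case {self.mvo_case_accuracy:.1f}%"
            f"  slice {self.mvo_slice_accuracy:.1f}%",
            f"  pathology-outside-wall voxels (final maps): "
            f"{self.topology_violations_final}",
            f"  CVAE reconstruction Dice: {self.cvae_reconstruction_dice:.3f}",
        ]
        return "\n".join(lines)


def split_cohort(cohort, n_test: int, seed: int):
    """Stratified train/test split using the fold machinery."""
    k = max(2, round(len(cohort) / n_test))
    folds = make_folds(cohort, k=k, seed=seed)
    train_idx, test_idx = folds[0]
    return [cohort[i] for i in train_idx], [cohort[i] for i in test_idx]


def run_experiment(seed: int = 0, n: int = 40,
                   stratification: tuple[int, int, int] = (13, 11, 16),
                   n_test: int = 10,
                   config: TrainConfig | None = None,
                   roster=None) -> ExperimentReport:
    """Simulate → train (both stages + prior) → predict → evaluate.

    Cohort stratification defaults to the training-split proportions
    (33/27/40 per hundred) scaled to `n`.  Returns the full report; all
    randomness derives from `seed`.
    """
    cfg = config or fast_dev_config(seed)
    roster = roster if roster is not None else FAST_DEV_ROSTER

    cohort = generate_cohort(n, stratification, seed=seed)
    train_cases, test_cases = split_cohort(cohort, n_test=n_test, seed=seed)

    anat_model = AnatomicalSegmentation(train_cases, cfg)
    anat = anat_model.fit()
    prepared = anat_model.prepared

    prior = ShapePrior.from_cases(prepared, cfg, seed=seed + 1).fit(
        seed=seed + 1)

    # training-time wall masks from ground truth (teacher forcing)
    masks = [c.labels >= 2 for c in prepared]
    path_model = PathologySegmentation(prepared, masks, prior, roster, cfg)
    path = path_model.fit(seed=seed + 2)

    preds, gts, pred_patients, true_patients = [], [], [], []
    topo_final = 0
    topo_raw = 0
    predictions = []
    for case in test_cases:
        cp = predict_case(case.volume, anat.net, path.members, cfg)
        fused = majority_vote(cp.stack)
        final = postprocess(fused)
        restored = restore_geometry(final, cp.record)
        predictions.append((case.case_id, cp, restored))
        preds.append(restored.labels)
        gts.append(case.labels.labels)
        pred_patients.append(classify_patient(restored))
        true_patients.append(case.patient_label)
        topo_final += check_topology(restored).pathology_outside_wall
        for raw in cp.raw_member_maps:
            topo_raw += check_topology(raw).pathology_outside_wall

    spacing = test_cases[0].volume.spacing
    table = evaluate_cases(preds, gts, spacing,
                           case_ids=[c.case_id for c in test_cases])
    cls = classification_metrics(pred_patients, true_patients)
    return ExperimentReport(
        metrics=table,
        classification=cls,
        mvo_case_accuracy=mvo_presence_accuracy(preds, gts, level="case"),
        mvo_slice_accuracy=mvo_presence_accuracy(preds, gts, level="slice"),
        topology_violations_final=topo_final,
        raw_topology_violations=topo_raw,
        cvae_reconstruction_dice=prior.reconstruction_dice,
        anatomical=anat, pathology=path, predictions=predictions,
    )


def run_inclusion_ablation(seed: int = 0, n: int = 21,
                           stratification: tuple[int, int, int] = (7, 7, 7),
                           n_test: int = 5,
                           lambda_ic: float = 0.15,
                           config: TrainConfig | None = None) -> dict:
    """Paired runs with and without the inclusion constraint (same seed).

    Trains two pathological networks differing only in λ_IC (class
    constraint off in both) and compares the summed pathology-outside-wall
    count of the raw (unmasked) network predictions on held-out phantoms.
    """
    from .losses import LossWeights
    from .training import train_pathological

    cfg = config or fast_dev_config(seed)
    if config is None:
        # direction check only: shorter schedules than the headline run
        cfg.anatomical_steps = 120
        cfg.pathological_steps = 400
    cohort = generate_cohort(n, stratification, seed=seed)
    train_cases, test_cases = split_cohort(cohort, n_test=n_test, seed=seed)
    anat_model = AnatomicalSegmentation(train_cases, cfg)
    anat = anat_model.fit()
    prepared = anat_model.prepared
    prior = ShapePrior.from_cases(prepared, cfg, seed=seed + 1).fit(
        seed=seed + 1)
    masks = [c.labels >= 2 for c in prepared]

    counts = {}
    for name, lic in (("without_ic", 0.0), ("with_ic", lambda_ic)):
        net = train_pathological(prepared, masks, prior.model,
                                 LossWeights(lambda_ic=lic, lambda_cc=0.0),
                                 cfg, seed=seed + 3)
        total = 0
        for case in test_cases:
            cp = predict_case(case.volume, anat.net, [net], cfg, quorum=1)
            total += check_topology(cp.raw_member_maps[0]
                                    ).pathology_outside_wall
        counts[name] = total
    return counts
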