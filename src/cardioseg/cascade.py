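"""The coarse-to-fine cascade: training, inference, fusion, experiments.

Stage 1 trains LS-Net on the coarse-group (CG) structures.  Stage 2
freezes LS-Net, produces its CG masks for every slice, one-hot encodes
them (one binary channel per CG structure) and concatenates them with
the normalized slice to train SS-Net on the fine-group (FG)
structures: the predicted large-structure masks act as anatomical
priors that encode position, shape and scale.  At inference the two
stage outputs are fused into a single 10-structure label map, with the
coarse stage taking precedence on conflicting voxels (its structures
constrain the area in which fine structures may appear).

Training follows the protocol the framework was developed with: Adam,
initial learning rate 1e-4, batch of 12 slices, up to 300 epochs, and
a plateau schedule that halves the learning rate whenever the
validation loss fails to decrease for ten consecutive epochs.  Cases
are split 6:2:2 into train/validation/test, with optional five-fold
cross-validation over the non-test cases.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imageio import LabelMap, Volume
from .losses import LossConfig, distance_map_stack, hybrid_loss_grad, one_hot
from .metrics import aggregate_reports, evaluate_case
from .nets import NetSpec, UNet2D, build_lsnet, build_ssnet, load_network, save_network
from .preprocess import AugmentSpec, augment_case, normalize_hu
from .registry import GroupingScheme, get_grouping, invert_remap, remap_labels

__all__ = [
    "TrainConfig",
    "CascadeModel",
    "Split",
    "PlateauScheduler",
    "derive_seed",
    "split_dataset",
    "train_stage",
    "train_cascade",
    "train_single",
    "predict_case",
    "predict_single",
    "fuse_predictions",
    "run_experiment",
    "small_structure_dsc",
    "grouping_sweep",
]


def derive_seed(seed: int, name: str) -> int:
    """Stable component seed below 2**31 from a master seed and a label."""
    digest = hashlib.blake2s(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run (both stages share them)."""

    learning_rate: float = 1e-4
    batch_size: int = 12
    max_epochs: int = 300
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    folds: int = 5
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    grouping: str = "group2"
    prior_source: str = "predicted"  # "predicted" | "gold"
    augment: AugmentSpec | None = None
    # network hyperparameters (channel counts derive from the grouping)
    base_width: int = 64
    depth: int = 4
    dropout_rate: float = 0.5
    batch_norm: bool = True
    transposed_up: bool = False
    foreground_only: bool = False
    # optional convergence stop: halt once the mean foreground DSC on
    # the training slices reaches stop_train_dsc AND no single class is
    # below stop_train_dsc_min (checked every stop_check_every epochs);
    # None trains to max_epochs.  stop_train_dsc_coarse, when set,
    # overrides the mean threshold for the first (coarse) stage only.
    stop_train_dsc: float | None = None
    stop_train_dsc_min: float | None = None
    stop_train_dsc_coarse: float | None = None
    stop_check_every: int = 5
    # plateau/val loss may be evaluated on every val_slice_stride-th
    # validation slice (1 = all slices)
    val_slice_stride: int = 1

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if min(self.learning_rate, self.batch_size, self.plateau_patience) <= 0:
            raise ValueError("learning_rate, batch_size, plateau_patience must be positive")
        if not 0 < self.plateau_factor <= 1:
            raise ValueError("plateau_factor must be in (0, 1]")
        if self.prior_source not in ("predicted", "gold"):
            raise ValueError(f"prior_source must be 'predicted' or 'gold', got {self.prior_source!r}")


@dataclass
class Split:
    train: list
    val: list
    test: list
    folds: list[tuple[list, list]]


def split_dataset(case_ids: list, cfg: TrainConfig) -> Split:
    """Random 6:2:2 split plus k-fold assignments over the non-test cases.

    Deterministic for a fixed ``cfg.seed``; no case appears in more
    than one of train/val/test, and the folds partition train+val.
    """
    ids = list(case_ids)
    if len(ids) < cfg.folds:
        raise ValueError(f"need at least folds={cfg.folds} cases, got {len(ids)}")
    rng = np.random.default_rng(derive_seed(cfg.seed, "split"))
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(order)
    n_train = int(round(cfg.split[0] * n))
    n_val = int(round(cfg.split[1] * n))
    train, val = order[:n_train], order[n_train : n_train + n_val]
    test = order[n_train + n_val :]
    if not train or not val or not test:
        raise ValueError(f"split {cfg.split} leaves an empty partition for {n} cases")
    dev = train + val
    folds = []
    for k in range(cfg.folds):
        val_k = dev[k :: cfg.folds]
        train_k = [c for c in dev if c not in val_k]
        folds.append((train_k, val_k))
    return Split(train, val, test, folds)


class PlateauScheduler:
    """Halve (×factor) the learning rate after ``patience`` consecutive
    epochs without a strict decrease of the validation loss."""

    def __init__(self, optimizer, patience: int = 10, factor: float = 0.5):
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.best = np.inf
        self.bad_epochs = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, val_loss: float) -> bool:
        """Register one epoch's validation loss; True if the LR was reduced."""
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs >= self.patience:
            self.optimizer.lr *= self.factor
            self.bad_epochs = 0
            return True
        return False


@dataclass
class StageData:
    """Slice-wise training material for one network stage."""

    images: list[np.ndarray]  # (H, W) normalized float32
    targets: list[np.ndarray]  # (H, W) dense class labels
    priors: list[np.ndarray] | None  # per-slice (K, H, W) mask channels
    spacing_inplane: tuple[float, float]

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int | None = None


def _stack_inputs(data: StageData, idx: list[int]) -> np.ndarray:
    xs = []
    for i in idx:
        chans = [data.images[i][None]]
        if data.priors is not None:
            chans.append(data.priors[i])
        xs.append(np.concatenate(chans, axis=0))
    return np.stack(xs).astype(np.float32)


def _batch_loss_grad(probs, targets, dmaps, cfg_loss):
    """Hybrid loss and gradient over a (B, C, H, W) batch."""
    b, c, h, w = probs.shape
    p = np.moveaxis(probs, 1, 0).reshape(c, -1)
    g = np.moveaxis(targets, 1, 0).reshape(c, -1)
    d = np.moveaxis(dmaps, 1, 0).reshape(c, -1)
    value, grad = hybrid_loss_grad(p, g, d, cfg_loss)
    return value, np.moveaxis(grad.reshape(c, b, h, w), 0, 1)


def _epoch_tables(data: StageData, n_classes: int, augment, epoch_seed):
    """Per-epoch slice tensors: inputs already augmented, one-hot gold,
    distance maps (2D, physical in-plane spacing, recomputed because the
    augmented gold changes)."""
    images, targets, priors = data.images, data.targets, data.priors
    if augment is not None:
        aug_im, aug_tg, aug_pr = [], [], []
        for i in range(len(data)):
            img, lab, pri = augment_case(
                images[i], targets[i], priors[i] if priors is not None else None,
                augment, derive_seed(epoch_seed, f"aug{i}"),
            )
            aug_im.append(img)
            aug_tg.append(lab)
            aug_pr.append(pri)
        images, targets = aug_im, aug_tg
        priors = aug_pr if data.priors is not None else None
    onehots = [one_hot(t, n_classes) for t in targets]
    dmaps = [distance_map_stack(t, n_classes, data.spacing_inplane) for t in targets]
    return StageData(images, targets, priors, data.spacing_inplane), onehots, dmaps


def _eval_loss(net, data: StageData, onehots, dmaps, cfg: TrainConfig) -> float:
    total, count = 0.0, 0
    for start in range(0, len(data), cfg.batch_size):
        idx = list(range(start, min(start + cfg.batch_size, len(data))))
        x = _stack_inputs(data, idx)
        probs = net.forward(x, train=False)
        g = np.stack([onehots[i] for i in idx])
        d = np.stack([dmaps[i] for i in idx])
        value, _ = _batch_loss_grad(probs, g, d, cfg.loss)
        total += value * len(idx)
        count += len(idx)
    return total / max(count, 1)


def _train_dsc(net, data: StageData, cfg: TrainConfig) -> tuple[float, float]:
    """Mean and minimum foreground Dice of argmax predictions over the
    given slices."""
    from .metrics import dsc as _dsc

    preds = []
    for start in range(0, len(data), cfg.batch_size):
        idx = list(range(start, min(start + cfg.batch_size, len(data))))
        probs = net.forward(_stack_inputs(data, idx), train=False)
        preds.extend(list(probs.argmax(axis=1)))
    scores = []
    n_classes = net.spec.out_classes
    gold3d = np.stack(data.targets)
    pred3d = np.stack(preds)
    for c in range(1, n_classes):
        if (gold3d == c).any():
            scores.append(_dsc(gold3d == c, pred3d == c))
    if not scores:
        return float("nan"), float("nan")
    return float(np.mean(scores)), float(np.min(scores))


def train_stage(
    net: UNet2D,
    train_data: StageData,
    val_data: StageData,
    cfg: TrainConfig,
    seed: int | None = None,
) -> TrainHistory:
    """Train one network stage with Adam + plateau LR schedule.

    Keeps the weights of the lowest-validation-loss epoch.  Fully
    deterministic for a fixed seed.  Raises on non-finite loss.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(derive_seed(seed, "batches"))
    optimizer = net.make_optimizer(cfg.learning_rate)
    scheduler = PlateauScheduler(optimizer, cfg.plateau_patience, cfg.plateau_factor)
    history = TrainHistory()
    n_classes = net.spec.out_classes

    val_fixed, val_onehots, val_dmaps = _epoch_tables(val_data, n_classes, None, 0)
    best_val = np.inf
    best_state = net.state_dict()

    static_tables = None
    if cfg.augment is None:
        # gold is static without augmentation: one-hot targets and
        # distance maps can be computed once for the whole run
        static_tables = _epoch_tables(train_data, n_classes, None, 0)

    for epoch in range(1, cfg.max_epochs + 1):
        ep_seed = derive_seed(seed, f"epoch{epoch}")
        if static_tables is not None:
            data, onehots, dmaps = static_tables
        else:
            data, onehots, dmaps = _epoch_tables(train_data, n_classes, cfg.augment, ep_seed)
        order = rng.permutation(len(data))
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = [int(i) for i in order[start : start + cfg.batch_size]]
            x = _stack_inputs(data, idx)
            probs = net.forward(x, train=True)
            if not np.all(np.isfinite(probs)):
                raise RuntimeError(
                    f"non-finite network output at epoch {epoch}; "
                    "the weights have diverged — lower the learning rate"
                )
            g = np.stack([onehots[i] for i in idx])
            d = np.stack([dmaps[i] for i in idx])
            value, grad = _batch_loss_grad(probs, g, d, cfg.loss)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss ({value}) at epoch {epoch}; "
                    "lower the learning rate or check the inputs"
                )
            optimizer.zero_grad()
            net.backward(grad)
            optimizer.step()
            epoch_loss += value * len(idx)
            seen += len(idx)
        val_loss = _eval_loss(net, val_fixed, val_onehots, val_dmaps, cfg)
        history.train_loss.append(epoch_loss / max(seen, 1))
        history.val_loss.append(float(val_loss))
        scheduler.step(float(val_loss))
        history.lr.append(float(optimizer.lr))
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.state_dict()
            history.best_epoch = epoch
        if cfg.stop_train_dsc is not None and epoch % cfg.stop_check_every == 0:
            mean_dsc, min_dsc = _train_dsc(net, train_data, cfg)
            if mean_dsc >= cfg.stop_train_dsc and (
                cfg.stop_train_dsc_min is None or min_dsc >= cfg.stop_train_dsc_min
            ):
                history.stopped_epoch = epoch
                # converged by the training-Dice criterion: keep current weights
                best_state = net.state_dict()
                break
    net.load_state_dict(best_state)
    return history


# --- dataset plumbing ----------------------------------------------------


def _normalized(vol: Volume) -> np.ndarray:
    if vol.intensity_kind == "HU":
        return normalize_hu(vol).data
    return vol.data


def _case_slices(volumes, labelmaps, keep_codes, foreground_only=False):
    """Slice-wise (image, dense target) pairs plus the dense code table."""
    images, targets = [], []
    table = None
    for vol, lab in zip(volumes, labelmaps):
        img = _normalized(vol).astype(np.float32)
        dense, table = remap_labels(lab.data, keep_codes)
        for z in range(img.shape[0]):
            if foreground_only and not dense[z].any():
                continue
            images.append(img[z])
            targets.append(dense[z].astype(np.int16))
    return images, targets, table


def _prior_channels(dense_cg: np.ndarray, n_cg: int) -> np.ndarray:
    """One-hot prior channels (background omitted) from dense CG labels."""
    return np.stack([(dense_cg == c).astype(np.float32) for c in range(1, n_cg + 1)])


def _predict_dense(net: UNet2D, images: list[np.ndarray], priors, batch: int) -> list[np.ndarray]:
    data = StageData(images, [np.zeros_like(images[0], dtype=np.int16)] * len(images), priors, (1.0, 1.0))
    out = []
    for start in range(0, len(images), batch):
        idx = list(range(start, min(start + batch, len(images))))
        probs = net.forward(_stack_inputs(data, idx), train=False)
        out.extend(list(probs.argmax(axis=1).astype(np.int16)))
    return out


@dataclass
class CascadeModel:
    """Trained two-stage model plus everything needed to reproduce it."""

    lsnet: UNet2D
    ssnet: UNet2D
    grouping: GroupingScheme
    cg_table: dict[int, int]
    fg_table: dict[int, int]
    with_priors: bool = True
    fingerprint: dict = field(default_factory=dict)
    history: dict = field(default_factory=dict)

    def save(self, rundir: str | os.PathLike) -> None:
        rundir = os.fspath(rundir)
        os.makedirs(rundir, exist_ok=True)
        save_network(self.lsnet, os.path.join(rundir, "lsnet"))
        save_network(self.ssnet, os.path.join(rundir, "ssnet"))
        meta = {
            "grouping": self.grouping.name,
            "cg_table": {str(k): v for k, v in self.cg_table.items()},
            "fg_table": {str(k): v for k, v in self.fg_table.items()},
            "with_priors": self.with_priors,
            "fingerprint": self.fingerprint,
        }
        with open(os.path.join(rundir, "cascade.json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, rundir: str | os.PathLike) -> "CascadeModel":
        rundir = os.fspath(rundir)
        with open(os.path.join(rundir, "cascade.json")) as fh:
            meta = json.load(fh)
        return cls(
            lsnet=load_network(os.path.join(rundir, "lsnet")),
            ssnet=load_network(os.path.join(rundir, "ssnet")),
            grouping=get_grouping(meta["grouping"]),
            cg_table={int(k): v for k, v in meta["cg_table"].items()},
            fg_table={int(k): v for k, v in meta["fg_table"].items()},
            with_priors=meta["with_priors"],
            fingerprint=meta.get("fingerprint", {}),
        )


def _netspec(cfg: TrainConfig, in_channels: int, out_classes: int) -> NetSpec:
    return NetSpec(
        in_channels=in_channels,
        out_classes=out_classes,
        base_width=cfg.base_width,
        depth=cfg.depth,
        dropout_rate=cfg.dropout_rate,
        batch_norm=cfg.batch_norm,
        transposed_up=cfg.transposed_up,
    )


def train_cascade(
    dataset: list[tuple[Volume, LabelMap]],
    cfg: TrainConfig,
    split: Split | None = None,
    with_priors: bool = True,
    lsnet: UNet2D | None = None,
) -> CascadeModel:
    """Train LS-Net on the CG targets, then SS-Net on the FG targets.

    With ``with_priors`` (the framework proper), SS-Net's input
    concatenates the slice with the one-hot CG masks — predicted by the
    frozen LS-Net (``cfg.prior_source='predicted'``) or taken from the
    gold labels (``'gold'``, an ablation).  With ``with_priors=False``
    the second stage sees the image alone (the plain two-stage
    comparator).  An already-trained ``lsnet`` may be passed in to
    share the first stage between runs whose stage-1 task is identical
    (e.g. the two-stage and full-cascade experiment arms).
    """
    grouping = get_grouping(cfg.grouping)
    if split is None:
        split = split_dataset(list(range(len(dataset))), cfg)
    spacing = dataset[0][0].spacing
    inplane = (spacing[1], spacing[2])

    def subset(ids):
        return [dataset[i][0] for i in ids], [dataset[i][1] for i in ids]

    tr_vols, tr_labs = subset(split.train)
    va_vols, va_labs = subset(split.val)

    # --- stage 1: LS-Net on coarse-group targets
    n_cg = len(grouping.coarse)
    tr_img, tr_cg, cg_table = _case_slices(tr_vols, tr_labs, grouping.coarse, cfg.foreground_only)
    va_img, va_cg, _ = _case_slices(va_vols, va_labs, grouping.coarse)
    va_img = va_img[:: cfg.val_slice_stride]
    va_cg = va_cg[:: cfg.val_slice_stride]
    if lsnet is None:
        cfg_ls = cfg
        if cfg.stop_train_dsc_coarse is not None:
            cfg_ls = replace(cfg, stop_train_dsc=cfg.stop_train_dsc_coarse)
        lsnet = build_lsnet(_netspec(cfg, 1, n_cg + 1), seed=derive_seed(cfg.seed, "lsnet-init"))
        ls_hist = train_stage(
            lsnet,
            StageData(tr_img, tr_cg, None, inplane),
            StageData(va_img, va_cg, None, inplane),
            cfg_ls,
            seed=derive_seed(cfg.seed, "lsnet"),
        )
    else:
        if lsnet.spec.out_classes != n_cg + 1:
            raise ValueError(
                f"shared LS-Net predicts {lsnet.spec.out_classes} classes, "
                f"grouping {grouping.name} needs {n_cg + 1}"
            )
        ls_hist = TrainHistory()

    # --- stage 2: SS-Net on fine-group targets, priors from stage 1
    n_fg = len(grouping.fine)
    _, tr_fg, fg_table = _case_slices(tr_vols, tr_labs, grouping.fine, cfg.foreground_only)
    _, va_fg, _ = _case_slices(va_vols, va_labs, grouping.fine)
    va_fg = va_fg[:: cfg.val_slice_stride]
    if with_priors:
        if cfg.prior_source == "gold":
            tr_pri = [_prior_channels(t, n_cg) for t in tr_cg]
            va_pri = [_prior_channels(t, n_cg) for t in va_cg]
        else:
            tr_pri = [_prior_channels(p, n_cg) for p in _predict_dense(lsnet, tr_img, None, cfg.batch_size)]
            va_pri = [_prior_channels(p, n_cg) for p in _predict_dense(lsnet, va_img, None, cfg.batch_size)]
        ssnet = build_ssnet(
            _netspec(cfg, 1 + n_cg, n_fg + 1), n_cg, seed=derive_seed(cfg.seed, "ssnet-init")
        )
    else:
        tr_pri = va_pri = None
        ssnet = UNet2D(_netspec(cfg, 1, n_fg + 1), seed=derive_seed(cfg.seed, "ssnet-init"))
    ss_hist = train_stage(
        ssnet,
        StageData(tr_img, tr_fg, tr_pri, inplane),
        StageData(va_img, va_fg, va_pri, inplane),
        cfg,
        seed=derive_seed(cfg.seed, "ssnet"),
    )

    fingerprint = {
        "config": _config_fingerprint(cfg),
        "grouping": grouping.name,
        "n_cases": len(dataset),
        "split": {"train": list(split.train), "val": list(split.val), "test": list(split.test)},
        "with_priors": with_priors,
    }
    return CascadeModel(
        lsnet,
        ssnet,
        grouping,
        cg_table,
        fg_table,
        with_priors=with_priors,
        fingerprint=fingerprint,
        history={"lsnet": ls_hist.__dict__, "ssnet": ss_hist.__dict__},
    )


def _config_fingerprint(cfg: TrainConfig) -> dict:
    out = {}
    for k, v in cfg.__dict__.items():
        if isinstance(v, LossConfig) or isinstance(v, AugmentSpec):
            out[k] = dict(v.__dict__)
        else:
            out[k] = list(v) if isinstance(v, tuple) else v
    return out


def fuse_predictions(cg_labels: LabelMap, fg_labels: LabelMap) -> LabelMap:
    """Merge the stage outputs; coarse-stage labels win on conflicts.

    Inputs must carry disjoint registry code sets (a shared nonzero
    code indicates a remapping error and raises).
    """
    if cg_labels.data.shape != fg_labels.data.shape:
        raise ValueError("stage outputs have different shapes")
    cg_codes = set(np.unique(cg_labels.data).tolist()) - {0}
    fg_codes = set(np.unique(fg_labels.data).tolist()) - {0}
    shared = cg_codes & fg_codes
    if shared:
        raise ValueError(
            f"stage outputs share label code(s) {sorted(shared)}; "
            "inputs appear mis-remapped"
        )
    fused = np.where(cg_labels.data > 0, cg_labels.data, fg_labels.data)
    return LabelMap(fused.astype(np.int16), cg_labels.spacing)


def predict_case(model: CascadeModel, vol: Volume, batch_size: int = 12) -> LabelMap:
    """Slice-wise two-stage inference fused into one 10-structure map."""
    img = _normalized(vol).astype(np.float32)
    images = [img[z] for z in range(img.shape[0])]
    n_cg = len(model.grouping.coarse)
    cg_dense = _predict_dense(model.lsnet, images, None, batch_size)
    if model.with_priors:
        priors = [_prior_channels(p, n_cg) for p in cg_dense]
    else:
        priors = None
    fg_dense = _predict_dense(model.ssnet, images, priors, batch_size)
    cg = invert_remap(np.stack(cg_dense), model.cg_table)
    fg = invert_remap(np.stack(fg_dense), model.fg_table)
    return fuse_predictions(
        LabelMap(cg.astype(np.int16), vol.spacing), LabelMap(fg.astype(np.int16), vol.spacing)
    )


def train_single(
    dataset: list[tuple[Volume, LabelMap]],
    cfg: TrainConfig,
    split: Split | None = None,
) -> tuple[UNet2D, dict[int, int]]:
    """Baseline: one network segmenting all ten structures at once."""
    from .registry import CODES

    if split is None:
        split = split_dataset(list(range(len(dataset))), cfg)
    spacing = dataset[0][0].spacing
    inplane = (spacing[1], spacing[2])

    def subset(ids):
        return [dataset[i][0] for i in ids], [dataset[i][1] for i in ids]

    tr_vols, tr_labs = subset(split.train)
    va_vols, va_labs = subset(split.val)
    tr_img, tr_all, table = _case_slices(tr_vols, tr_labs, CODES, cfg.foreground_only)
    va_img, va_all, _ = _case_slices(va_vols, va_labs, CODES)
    va_img = va_img[:: cfg.val_slice_stride]
    va_all = va_all[:: cfg.val_slice_stride]
    net = UNet2D(_netspec(cfg, 1, len(CODES) + 1), seed=derive_seed(cfg.seed, "single-init"))
    train_stage(
        net,
        StageData(tr_img, tr_all, None, inplane),
        StageData(va_img, va_all, None, inplane),
        cfg,
        seed=derive_seed(cfg.seed, "single"),
    )
    return net, table


def predict_single(net: UNet2D, table: dict[int, int], vol: Volume, batch_size: int = 12) -> LabelMap:
    img = _normalized(vol).astype(np.float32)
    images = [img[z] for z in range(img.shape[0])]
    dense = np.stack(_predict_dense(net, images, None, batch_size))
    return LabelMap(invert_remap(dense, table).astype(np.int16), vol.spacing)


# --- experiment harnesses ------------------------------------------------

ARMS = ("baseline", "two_stage", "cascade")


def run_experiment(
    dataset: list[tuple[Volume, LabelMap]],
    cfg: TrainConfig,
    arms: tuple[str, ...] = ARMS,
) -> dict:
    """Train the comparison arms under one split and evaluate on test cases.

    Arms: ``baseline`` (a single network over all ten structures),
    ``two_stage`` (groupwise networks without prior channels) and
    ``cascade`` (the full framework with prior injection).  The
    two-stage and cascade arms share the identically-trained coarse
    network, since their first stages are the same training task.
    Returns per-arm aggregate metric tables plus the raw per-case
    reports.
    """
    split = split_dataset(list(range(len(dataset))), cfg)
    test_cases = [(dataset[i][0], dataset[i][1]) for i in split.test]
    results: dict = {"split": split, "arms": {}}

    cascade_model = None
    shared_lsnet = None
    for arm in arms:
        if arm == "baseline":
            net, table = train_single(dataset, cfg, split)
            preds = [predict_single(net, table, vol) for vol, _ in test_cases]
        elif arm == "two_stage":
            model = train_cascade(dataset, cfg, split, with_priors=False, lsnet=shared_lsnet)
            shared_lsnet = model.lsnet
            preds = [predict_case(model, vol) for vol, _ in test_cases]
        elif arm == "cascade":
            cascade_model = train_cascade(dataset, cfg, split, with_priors=True, lsnet=shared_lsnet)
            shared_lsnet = cascade_model.lsnet
            preds = [predict_case(cascade_model, vol) for vol, _ in test_cases]
        else:
            raise ValueError(f"unknown arm {arm!r}")
        reports = [evaluate_case(lab, pred) for (_, lab), pred in zip(test_cases, preds)]
        results["arms"][arm] = {
            "per_case": reports,
            "aggregate": aggregate_reports(reports),
        }
    results["summary"] = _experiment_summary(results["arms"])
    if cascade_model is not None:
        results["model"] = cascade_model
    return results


def _experiment_summary(arm_results: dict) -> pd.DataFrame:
    frames = []
    for arm, res in arm_results.items():
        agg = res["aggregate"].copy()
        agg.insert(0, "arm", arm)
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)


def small_structure_dsc(results: dict, arm: str) -> float:
    """Mean test DSC over the small structures (PV, IVC, SVC) of one arm."""
    agg = results["arms"][arm]["aggregate"]
    small = agg[agg["size_class"] == "small"]
    return float(small["dsc_mean"].mean())


def grouping_sweep(
    dataset: list[tuple[Volume, LabelMap]],
    cfg: TrainConfig,
    schemes: list[GroupingScheme] | None = None,
) -> pd.DataFrame:
    """Train the plain two-stage pipeline for each grouping scheme and
    tabulate test DSC per structure (one row per scheme)."""
    from .registry import REGISTRY, builtin_groupings

    schemes = schemes if schemes is not None else builtin_groupings()
    split = split_dataset(list(range(len(dataset))), cfg)
    test_cases = [(dataset[i][0], dataset[i][1]) for i in split.test]
    rows = []
    for scheme in schemes:
        cfg_s = replace(cfg, grouping=scheme.name)
        model = train_cascade(dataset, cfg_s, split, with_priors=False)
        reports = [evaluate_case(lab, predict_case(model, vol)) for vol, lab in test_cases]
        agg = aggregate_reports(reports).set_index("structure")
        row = {"grouping": scheme.name}
        for s in REGISTRY:
            row[s.acronym] = float(agg.loc[s.acronym, "dsc_mean"])
        rows.append(row)
    return pd.DataFrame(rows)
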