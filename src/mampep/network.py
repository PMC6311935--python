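"""The binder/non-binder predictor: embedding, stacked 1-D convolutions,
per-level global-average-pooling heads and a fused sigmoid output.

Architecture (defaults). Each residue is embedded into a trainable
15-dimensional vector; two 1-D convolutional levels (16 then 32 filters,
kernel length 7, stride 1, zero "same" padding, leaky-rectifier slope 0.3,
dropout 0.25 after level 1 during training) produce per-site feature maps
F_ijk of the same length L as the peptide. Each level is pooled by a
bias-free global-average head

    c_i = sum_j W_ij * mean_k F_ijk

and the levels are fused by a second bias-free linear map into the binding
probability

    P = sigmoid(sum_i m_i * c_i).

Because the heads are linear in the pooled features, the same weights map
back onto the feature maps as per-site contribution scores (see
:mod:`mampep.mam`); keeping "same" padding is what makes that site alignment
exact for any peptide length, so one trained model scores 8- to 11-mers
without rebuild.

Training minimizes binary cross-entropy plus an L2 penalty (0.01) on
convolution kernels and both linear heads (not the embedding), with Adam,
seeded mini-batch shuffling and early stopping on the monitored loss.
Everything is implemented directly on numpy arrays; gradients are derived
analytically layer by layer.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .alphabet import AA_ALPHABET, encode
from .peptide_io import Dataset, PeptideRecord

__all__ = [
    "ArchSpec", "TrainConfig", "ForwardTrace", "MhcCnn", "Ensemble",
    "build_model", "forward", "train", "train_ensemble", "predict_ensemble",
    "fine_tune", "save_bundle", "load_bundle", "BundleError",
]

BUNDLE_FORMAT_VERSION = 1


class BundleError(RuntimeError):
    """Raised for corrupt or version-mismatched model bundles."""


@dataclass(frozen=True)
class ArchSpec:
    """Architecture hyperparameters of the predictor."""

    embed_dim: int = 15
    conv_filters: tuple[int, ...] = (16, 32)
    kernel_size: int = 7
    leaky_slope: float = 0.3
    dropout_rates: tuple[float, ...] = (0.25, 0.0)  # after level 1 only

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if len(self.conv_filters) < 1 or any(f < 1 for f in self.conv_filters):
            raise ValueError("need >= 1 conv level, each with >= 1 filter")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if len(self.dropout_rates) != len(self.conv_filters):
            object.__setattr__(
                self, "dropout_rates",
                tuple(self.dropout_rates) + (0.0,) * (len(self.conv_filters) - len(self.dropout_rates)),
            )

    @property
    def n_levels(self) -> int:
        return len(self.conv_filters)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        d = dict(d)
        d["conv_filters"] = tuple(d["conv_filters"])
        d["dropout_rates"] = tuple(d["dropout_rates"])
        return cls(**d)


@dataclass
class TrainConfig:
    """Optimization settings.

    ``patience`` counts consecutive epochs without an improvement of more
    than ``min_delta`` in the monitored loss; the best-loss parameter
    snapshot is restored at the end. ``n_models`` is the ensemble size; each
    member is initialized and trained with seed ``seed + member_index``.
    """

    max_epochs: int = 400
    patience: int = 20
    min_delta: float = 1e-4
    batch_size: int = 64
    learning_rate: float = 1e-3
    l2_coeff: float = 0.01
    n_models: int = 10
    seed: int = 0
    monitor: str = "train"        # "train" or "val"
    val_fraction: float = 0.1     # used when monitor == "val"

    def __post_init__(self) -> None:
        if self.max_epochs > 0 and not self.patience < self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.monitor not in ("train", "val"):
            raise ValueError("monitor must be 'train' or 'val'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class ForwardTrace:
    """Intermediate activations of one forward pass.

    ``features[i]`` is the L x J_i post-activation feature map of level i
    (row k = site k); ``level_contribs[i]`` is the pooled scalar c_i;
    ``probability`` is the fused sigmoid output.
    """

    features: list[np.ndarray]
    level_contribs: np.ndarray
    probability: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# Probabilities are clipped into the open interval for reporting and for a
# finite cross-entropy; gradients use the raw sigmoid.
_P_EPS = 1e-12


def _conv1d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """'Same'-padded 1-D convolution.

    x: (B, L, C); w: (F, C, K); b: (F,). Returns z of shape (B, L, F) and the
    (B, L, C*K) window matrix reused by the backward pass.
    """
    B, L, C = x.shape
    F, _, K = w.shape
    pl = (K - 1) // 2
    xp = np.pad(x, ((0, 0), (pl, K - 1 - pl), (0, 0)))
    win = sliding_window_view(xp, K, axis=1)          # (B, L, C, K)
    win2 = np.ascontiguousarray(win).reshape(B * L, C * K)
    z = (win2 @ w.reshape(F, C * K).T).reshape(B, L, F)
    return z + b, win2


def _conv1d_same_backward(dz: np.ndarray, win2: np.ndarray, w: np.ndarray, L: int):
    """Gradients of :func:`_conv1d_same` w.r.t. weights, bias and input."""
    B = dz.shape[0]
    F, C, K = w.shape
    dz2 = dz.reshape(B * L, F)
    dw = (dz2.T @ win2).reshape(F, C, K)
    db = dz2.sum(axis=0)
    dwin = (dz2 @ w.reshape(F, C * K)).reshape(B, L, C, K)
    pl = (K - 1) // 2
    dxp = np.zeros((B, L + K - 1, C))
    for t in range(K):
        dxp[:, t:t + L, :] += dwin[:, :, :, t]
    return dw, db, dxp[:, pl:pl + L, :]


class MhcCnn:
    """Parameter container + forward/backward pass of the predictor.

    Parameters are plain float64 numpy arrays in a fixed order:
    embedding (20 x d), then per level conv kernel (F_i x C_i x K) and bias
    (F_i), then per level GAP head weights (F_i), then fusion weights
    (n_levels,).
    """

    def __init__(self, arch: ArchSpec, embedding, conv_w, conv_b, gap_w, fusion_w):
        self.arch = arch
        self.embedding = embedding
        self.conv_w = list(conv_w)
        self.conv_b = list(conv_b)
        self.gap_w = list(gap_w)
        self.fusion_w = fusion_w

    # -- construction -----------------------------------------------------

    @classmethod
    def build(cls, arch: ArchSpec = ArchSpec(), seed: int = 0) -> "MhcCnn":
        """Seeded random initialization (uniform embedding, Glorot elsewhere)."""
        rng = np.random.default_rng(seed)
        emb = rng.uniform(-0.05, 0.05, size=(len(AA_ALPHABET), arch.embed_dim))
        conv_w, conv_b, gap_w = [], [], []
        c_in = arch.embed_dim
        for f in arch.conv_filters:
            limit = np.sqrt(6.0 / (c_in * arch.kernel_size + f * arch.kernel_size))
            conv_w.append(rng.uniform(-limit, limit, size=(f, c_in, arch.kernel_size)))
            conv_b.append(np.zeros(f))
            c_in = f
        for f in arch.conv_filters:
            limit = np.sqrt(6.0 / (f + 1))
            gap_w.append(rng.uniform(-limit, limit, size=f))
        limit = np.sqrt(6.0 / (arch.n_levels + 1))
        fusion_w = rng.uniform(-limit, limit, size=arch.n_levels)
        return cls(arch, emb, conv_w, conv_b, gap_w, fusion_w)

    def parameters(self) -> list[np.ndarray]:
        return [self.embedding, *self.conv_w, *self.conv_b, *self.gap_w, self.fusion_w]

    def set_parameters(self, params: Sequence[np.ndarray]) -> None:
        n = self.arch.n_levels
        it = list(params)
        self.embedding = it[0]
        self.conv_w = it[1:1 + n]
        self.conv_b = it[1 + n:1 + 2 * n]
        self.gap_w = it[1 + 2 * n:1 + 3 * n]
        self.fusion_w = it[1 + 3 * n]

    def copy(self) -> "MhcCnn":
        return MhcCnn(
            self.arch,
            self.embedding.copy(),
            [w.copy() for w in self.conv_w],
            [b.copy() for b in self.conv_b],
            [g.copy() for g in self.gap_w],
            self.fusion_w.copy(),
        )

    # -- forward ----------------------------------------------------------

    def _activations(self, idx: np.ndarray, training: bool = False,
                     rng: Optional[np.random.Generator] = None):
        """Per-level post-activation feature maps for a (B, L) index batch.

        Returns (acts, cache); cache holds what the backward pass needs and is
        None outside training.
        """
        arch = self.arch
        x = self.embedding[idx]                       # (B, L, d)
        acts, cache = [], {"x": x, "idx": idx, "pre": [], "win": [], "mask": []}
        h = x
        for lvl in range(arch.n_levels):
            z, win2 = _conv1d_same(h, self.conv_w[lvl], self.conv_b[lvl])
            a = np.where(z >= 0, z, arch.leaky_slope * z)
            acts.append(a)
            cache["pre"].append(z)
            cache["win"].append(win2)
            rate = arch.dropout_rates[lvl]
            if training and rate > 0.0:
                mask = (rng.random(a.shape) >= rate) / (1.0 - rate)
                h = a * mask
            else:
                mask = None
                h = a
            cache["mask"].append(mask)
        return acts, (cache if training else None)

    def _logits(self, acts: list[np.ndarray]) -> np.ndarray:
        contribs = [a.mean(axis=1) @ w for a, w in zip(acts, self.gap_w)]
        return np.stack(contribs, axis=1) @ self.fusion_w

    def forward_batch(self, idx: np.ndarray) -> np.ndarray:
        """Inference probabilities for a uniform-length index batch."""
        acts, _ = self._activations(idx)
        return np.clip(_sigmoid(self._logits(acts)), _P_EPS, 1.0 - _P_EPS)

    def forward(self, peptide, training_mode: bool = False,
                rng: Optional[np.random.Generator] = None) -> ForwardTrace:
        """Full forward trace for one peptide (dropout only in training mode)."""
        seq = peptide.sequence if isinstance(peptide, PeptideRecord) else str(peptide)
        idx = encode(seq)[None, :]
        if training_mode and rng is None:
            rng = np.random.default_rng(0)
        acts, _ = self._activations(idx, training=training_mode, rng=rng)
        contribs = np.array([a.mean(axis=1)[0] @ w for a, w in zip(acts, self.gap_w)])
        p = float(np.clip(_sigmoid(contribs @ self.fusion_w), _P_EPS, 1.0 - _P_EPS))
        return ForwardTrace(
            features=[a[0] for a in acts],
            level_contribs=contribs,
            probability=p,
        )

    def predict_proba(self, sequences: Sequence[str]) -> np.ndarray:
        """Probabilities for arbitrary sequences; mixed lengths are grouped."""
        seqs = [s.sequence if isinstance(s, PeptideRecord) else str(s) for s in sequences]
        out = np.empty(len(seqs))
        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(seqs):
            by_len.setdefault(len(s), []).append(i)
        for L, ix in sorted(by_len.items()):
            idx = np.stack([encode(seqs[i]) for i in ix])
            out[np.asarray(ix)] = self.forward_batch(idx)
        return out

    # -- backward ---------------------------------------------------------

    def loss_and_grads(self, idx: np.ndarray, y: np.ndarray, l2: float,
                       rng: np.random.Generator):
        """Mean BCE + L2 penalty and gradients for one uniform-length batch."""
        arch = self.arch
        B, L = idx.shape
        acts, cache = self._activations(idx, training=True, rng=rng)
        # pooled heads operate on pre-dropout activations (the dropout only
        # regularizes the path into the next conv level)
        gaps = [a.mean(axis=1) for a in acts]                 # (B, F_i)
        contribs = np.stack([g @ w for g, w in zip(gaps, self.gap_w)], axis=1)
        logit = contribs @ self.fusion_w
        p = _sigmoid(logit)
        pc = np.clip(p, _P_EPS, 1.0 - _P_EPS)
        loss = -np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))

        dlogit = (p - y) / B                                   # (B,)
        d_fusion = contribs.T @ dlogit
        dc = np.outer(dlogit, self.fusion_w)                   # (B, n_levels)
        d_gap = [g.T @ dc[:, i] for i, g in enumerate(gaps)]
        # gradient flowing into each level's activations
        d_acts = [np.broadcast_to(
                      (dc[:, i, None, None] / L) * self.gap_w[i][None, None, :],
                      acts[i].shape).copy()
                  for i in range(arch.n_levels)]

        d_conv_w = [None] * arch.n_levels
        d_conv_b = [None] * arch.n_levels
        d_next = None                                          # grad w.r.t. level input
        for lvl in range(arch.n_levels - 1, -1, -1):
            da = d_acts[lvl]
            if d_next is not None:
                mask = cache["mask"][lvl]
                da = da + (d_next * mask if mask is not None else d_next)
            dz = da * np.where(cache["pre"][lvl] >= 0, 1.0, arch.leaky_slope)
            dw, db, dx = _conv1d_same_backward(dz, cache["win"][lvl], self.conv_w[lvl], L)
            d_conv_w[lvl], d_conv_b[lvl] = dw, db
            d_next = dx
        d_emb = np.zeros_like(self.embedding)
        np.add.at(d_emb, idx, d_next)

        if l2 > 0.0:
            penal = sum(float(np.sum(w * w)) for w in self.conv_w)
            penal += sum(float(np.sum(g * g)) for g in self.gap_w)
            penal += float(np.sum(self.fusion_w ** 2))
            loss += l2 * penal
            d_conv_w = [dw + 2.0 * l2 * w for dw, w in zip(d_conv_w, self.conv_w)]
            d_gap = [dg + 2.0 * l2 * g for dg, g in zip(d_gap, self.gap_w)]
            d_fusion = d_fusion + 2.0 * l2 * self.fusion_w

        grads = [d_emb, *d_conv_w, *d_conv_b, *d_gap, d_fusion]
        return float(loss), grads

    def dataset_loss(self, idx_groups, y_groups, l2: float) -> float:
        """Inference-mode BCE (+ L2 penalty) over grouped uniform-length data."""
        total, n = 0.0, 0
        for idx, y in zip(idx_groups, y_groups):
            acts, _ = self._activations(idx)
            p = np.clip(_sigmoid(self._logits(acts)), _P_EPS, 1.0 - _P_EPS)
            total += float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
            n += len(y)
        loss = total / n
        if l2 > 0.0:
            loss += l2 * (
                sum(float(np.sum(w * w)) for w in self.conv_w)
                + sum(float(np.sum(g * g)) for g in self.gap_w)
                + float(np.sum(self.fusion_w ** 2))
            )
        return loss


def build_model(arch: ArchSpec = ArchSpec(), seed: int = 0) -> MhcCnn:
    """Seeded construction of an untrained predictor (see :class:`MhcCnn`)."""
    return MhcCnn.build(arch, seed)


def forward(model: MhcCnn, peptide, training_mode: bool = False,
            rng: Optional[np.random.Generator] = None) -> ForwardTrace:
    return model.forward(peptide, training_mode=training_mode, rng=rng)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _group_by_length(seqs: list[str], labels: np.ndarray):
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    groups = []
    for L, ix in sorted(by_len.items()):
        idx = np.stack([encode(seqs[i]) for i in ix])
        groups.append((np.asarray(ix), idx, labels[np.asarray(ix)]))
    return groups


def train(model: MhcCnn, train_data: Dataset, config: TrainConfig,
          learning_rate: Optional[float] = None):
    """Train a model in place copy-wise; returns ``(trained_model, history)``.

    Both classes must be present. Minimizes BCE + L2; stops after
    ``config.patience`` epochs without monitored-loss improvement beyond
    ``config.min_delta`` (or at ``max_epochs``) and restores the best-loss
    snapshot. Fully seeded: initialization is the caller's concern
    (:func:`build_model`), shuffling and dropout derive from ``config.seed``.
    """
    labels = train_data.labels().astype(np.float64)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    model = model.copy()
    history = {"loss": [], "best_epoch": 0, "stopped_epoch": 0, "monitor": config.monitor}
    if config.max_epochs == 0:
        return model, history

    seqs = train_data.sequences()
    rng = np.random.default_rng(config.seed)

    if config.monitor == "val":
        n_val = max(1, int(round(config.val_fraction * len(seqs))))
        perm = rng.permutation(len(seqs))
        val_ix, tr_ix = perm[:n_val], perm[n_val:]
        if len(np.unique(labels[tr_ix])) < 2:
            raise ValueError("validation split left a single-class training set")
        mon_groups = _group_by_length([seqs[i] for i in val_ix], labels[val_ix])
        seqs = [seqs[i] for i in tr_ix]
        labels = labels[tr_ix]
        mon_l2 = 0.0
    else:
        mon_groups = None

    # Pre-encode once, grouped by peptide length.
    all_groups = _group_by_length(seqs, labels)
    pos_of = np.empty(len(seqs), dtype=np.int64)     # (group, row) lookup
    grp_of = np.empty(len(seqs), dtype=np.int64)
    for g, (ix, _, _) in enumerate(all_groups):
        grp_of[ix] = g
        pos_of[ix] = np.arange(len(ix))

    params = model.parameters()
    opt = _Adam(params, learning_rate if learning_rate is not None else config.learning_rate)
    best_loss = np.inf
    best_params = [p.copy() for p in params]
    wait = 0
    n = len(seqs)
    single_group = len(all_groups) == 1
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            if single_group:
                _, idx_g, y_g = all_groups[0]
                rows = pos_of[batch]
                batch_loss, loss_grads = model.loss_and_grads(
                    idx_g[rows], y_g[rows], config.l2_coeff, rng)
            else:
                # uniform-length sub-batches, gradients pooled into one Adam step
                loss_grads, batch_loss = None, 0.0
                for g in np.unique(grp_of[batch]):
                    sel = batch[grp_of[batch] == g]
                    _, idx_g, y_g = all_groups[g]
                    rows = pos_of[sel]
                    loss_g, grads = model.loss_and_grads(
                        idx_g[rows], y_g[rows], config.l2_coeff, rng)
                    w = len(sel) / len(batch)
                    batch_loss += w * loss_g
                    if loss_grads is None:
                        loss_grads = [w * gr for gr in grads]
                    else:
                        for acc, gr in zip(loss_grads, grads):
                            acc += w * gr
            opt.step(params, loss_grads)
            model.set_parameters(params)
            epoch_loss += batch_loss * len(batch)

        if mon_groups is None:
            # epoch-mean minibatch loss as optimized (dropout + L2 included)
            mon = epoch_loss / n
        else:
            mon = model.dataset_loss(
                [g[1] for g in mon_groups], [g[2] for g in mon_groups], mon_l2)
        history["loss"].append(mon)
        if mon < best_loss - config.min_delta:
            best_loss = mon
            best_params = [p.copy() for p in params]
            history["best_epoch"] = epoch
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                history["stopped_epoch"] = epoch
                break
    else:
        history["stopped_epoch"] = config.max_epochs
    model.set_parameters(best_params)
    return model, history


@dataclass
class Ensemble:
    """A bag of identically-architected models merged by arithmetic mean."""

    members: list[MhcCnn]
    arch: ArchSpec = field(default_factory=ArchSpec)
    config: Optional[TrainConfig] = None
    histories: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must be non-empty")

    def __len__(self) -> int:
        return len(self.members)

    def predict_proba(self, sequences) -> np.ndarray:
        if isinstance(sequences, Dataset):
            sequences = sequences.sequences()
        probs = np.stack([m.predict_proba(sequences) for m in self.members])
        return probs.mean(axis=0)

    def copy(self) -> "Ensemble":
        return Ensemble(
            members=[m.copy() for m in self.members],
            arch=self.arch,
            config=copy.deepcopy(self.config),
            histories=copy.deepcopy(self.histories),
        )


def train_ensemble(train_data: Dataset, config: TrainConfig,
                   arch: ArchSpec = ArchSpec()) -> Ensemble:
    """Train ``config.n_models`` members, member i seeded ``config.seed + i``."""
    members, histories = [], []
    for i in range(config.n_models):
        seed_i = config.seed + i
        member = build_model(arch, seed=seed_i)
        cfg_i = dataclasses.replace(config, seed=seed_i)
        trained, hist = train(member, train_data, cfg_i)
        members.append(trained)
        histories.append(hist)
    return Ensemble(members=members, arch=arch, config=config, histories=histories)


def predict_ensemble(ensemble: Ensemble, peptides) -> np.ndarray:
    """Arithmetic-mean probability per peptide across ensemble members."""
    return ensemble.predict_proba(peptides)


def fine_tune(ensemble: Ensemble, new_data: Dataset, lr_multiplier: float = 0.1,
              config: Optional[TrainConfig] = None) -> Ensemble:
    """Continue training every member on ``new_data`` at a reduced learning rate.

    The default multiplier 0.1 gives one tenth of the base rate; the input
    ensemble is left untouched (a copy is adapted). Zero-shot transfer is
    simply not calling this.
    """
    cfg = config if config is not None else ensemble.config
    if cfg is None:
        cfg = TrainConfig()
    adapted = ensemble.copy()
    lr = cfg.learning_rate * lr_multiplier
    histories = []
    for i, member in enumerate(adapted.members):
        cfg_i = dataclasses.replace(cfg, seed=cfg.seed + i)
        trained, hist = train(member, new_data, cfg_i, learning_rate=lr)
        adapted.members[i] = trained
        histories.append(hist)
    adapted.histories = histories
    adapted.config = cfg
    return adapted


def save_bundle(ensemble: Ensemble, path) -> None:
    """Serialize an ensemble to a directory of .npz members + JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "alphabet": AA_ALPHABET,
        "n_models": len(ensemble),
        "arch": ensemble.arch.to_dict(),
        "train_config": ensemble.config.to_dict() if ensemble.config else None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    for i, m in enumerate(ensemble.members):
        arrays = {f"p{j}": p for j, p in enumerate(m.parameters())}
        np.savez(path / f"member_{i}.npz", **arrays)


def load_bundle(path) -> Ensemble:
    """Inverse of :func:`save_bundle`; bit-identical parameters."""
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise BundleError(f"unreadable bundle manifest in {path}: {exc}") from exc
    if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise BundleError(
            f"bundle format {manifest.get('format_version')!r} not supported"
        )
    if manifest.get("alphabet") != AA_ALPHABET:
        raise BundleError("bundle uses a different alphabet ordering")
    arch = ArchSpec.from_dict(manifest["arch"])
    cfg = TrainConfig.from_dict(manifest["train_config"]) if manifest["train_config"] else None
    members = []
    for i in range(manifest["n_models"]):
        f = path / f"member_{i}.npz"
        try:
            with np.load(f) as z:
                params = [z[f"p{j}"] for j in range(len(z.files))]
        except Exception as exc:
            raise BundleError(f"corrupt or missing member file {f}: {exc}") from exc
        m = MhcCnn.build(arch, seed=0)
        if len(params) != len(m.parameters()):
            raise BundleError(f"member file {f} has wrong parameter count")
        m.set_parameters(params)
        members.append(m)
    return Ensemble(members=members, arch=arch, config=cfg)
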