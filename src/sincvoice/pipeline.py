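"""Dataset splitting, cross-validation, chunking, and model training.

Utterances are split 8:2 into train+validation and test pools (stratified
when labels are available), the train+validation pool is partitioned into
5 stratified folds, and each model trains on fixed-length peak-normalized
chunks cut from the waveforms with the utterance's label broadcast to its
chunks.  All randomness (shuffles, init, dropout, batch order) derives
from explicit seeds, so runs are bit-reproducible in single-threaded mode.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nnet
from .networks import NetworkSpec, VoiceNet, build_model
from .vowelsynth import LabeledWaveform

__all__ = [
    "SplitPlan",
    "FoldPlan",
    "TrainState",
    "Hyperparams",
    "split_dataset",
    "make_folds",
    "chunk_waveform",
    "train",
    "train_on_split",
]


@dataclass
class SplitPlan:
    train_val_ids: list
    test_ids: list
    ratio: float
    seed: int


@dataclass
class FoldPlan:
    k: int
    assignments: dict  # utterance id -> fold index


@dataclass
class Hyperparams:
    optimizer: str = "adam"
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    patience: int = 5
    chunk_s: float = 0.2
    shift_s: float = 0.1


@dataclass
class TrainState:
    epoch_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    seed: int = 0
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    best_epoch: int = -1
    best_val_loss: float = float("inf")


def split_dataset(ids: list, ratio: float = 0.8, seed: int = 0,
                  labels: list | None = None) -> SplitPlan:
    """Shuffle and cut: first ``floor(ratio * N)`` ids form train+validation.

    With ``labels`` the split is stratified per class, with the per-class
    remainders trimmed so the train+validation pool size is exactly
    ``floor(ratio * N)``.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate utterance ids")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(ratio * len(ids)))
    if labels is None:
        perm = [ids[i] for i in rng.permutation(len(ids))]
        return SplitPlan(perm[:n_train], perm[n_train:], ratio, seed)

    if len(labels) != len(ids):
        raise ValueError("labels must align with ids")
    by_class: dict = {}
    for uid, lbl in zip(ids, labels):
        by_class.setdefault(lbl, []).append(uid)
    train_val: list = []
    leftovers: list = []  # (fractional part, shuffled remainder candidate)
    for lbl in sorted(by_class):
        members = [by_class[lbl][i] for i in rng.permutation(len(by_class[lbl]))]
        exact = ratio * len(members)
        take = int(np.floor(exact))
        train_val += members[:take]
        leftovers += [(exact - take, m) for m in members[take:]]
    # top up to the exact global count, preferring classes shortest-changed
    deficit = n_train - len(train_val)
    leftovers.sort(key=lambda t: -t[0])
    promote = {m for _f, m in leftovers[:deficit]}
    train_val += [m for _f, m in leftovers if m in promote]
    test = [uid for uid in ids if uid not in set(train_val)]
    return SplitPlan(train_val, test, ratio, seed)


def make_folds(ids: list, labels: list, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold assignment: per-class shuffle then round-robin."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for uid, lbl in zip(ids, labels):
        by_class.setdefault(lbl, []).append(uid)
    assignments: dict = {}
    for lbl in sorted(by_class):
        members = by_class[lbl]
        if len(members) < k:
            raise ValueError(f"class {lbl!r} has {len(members)} < k={k} members")
        order = rng.permutation(len(members))
        for j, idx in enumerate(order):
            assignments[members[idx]] = j % k
    return FoldPlan(k=k, assignments=assignments)


def chunk_waveform(w: LabeledWaveform, chunk_s: float = 0.2,
                   shift_s: float = 0.1) -> np.ndarray:
    """Sliding fixed-length windows, each scaled to unit peak amplitude.

    Returns a (n_chunks, chunk_len) array; an all-zero chunk is passed
    through unscaled.  Chunk count is ``floor((dur - chunk) / shift) + 1``.
    """
    n = len(w.samples)
    chunk_len = int(round(chunk_s * w.sample_rate))
    shift = int(round(shift_s * w.sample_rate))
    if chunk_len > n:
        raise ValueError("chunk longer than utterance")
    starts = np.arange(0, n - chunk_len + 1, shift)
    chunks = np.stack([w.samples[s : s + chunk_len] for s in starts])
    peaks = np.max(np.abs(chunks), axis=1, keepdims=True)
    return chunks / np.where(peaks > 0, peaks, 1.0)


def _chunk_table(utterances: list[LabeledWaveform], class_order: list[str],
                 chunk_s: float, shift_s: float):
    """Stack chunks for a set of utterances; labels broadcast to chunks."""
    xs, ys, owners = [], [], []
    for i, w in enumerate(utterances):
        c = chunk_waveform(w, chunk_s, shift_s)
        xs.append(c)
        ys.append(np.full(len(c), class_order.index(w.label)))
        owners.append(np.full(len(c), i))
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(owners)


def _mean_loss(model: VoiceNet, x: np.ndarray, y: np.ndarray,
               batch_size: int) -> float:
    total, n = 0.0, 0
    for s in range(0, len(x), batch_size):
        xb, yb = x[s : s + batch_size], y[s : s + batch_size]
        loss, _ = nnet.softmax_xent(model.forward_logits(xb, train=False), yb)
        total += loss * len(xb)
        n += len(xb)
    return total / max(n, 1)


def train_on_split(spec: NetworkSpec, train_utts: list[LabeledWaveform],
                   val_utts: list[LabeledWaveform], class_order: list[str],
                   hp: Hyperparams | None = None, seed: int = 0,
                   ) -> tuple[VoiceNet, TrainState]:
    """Train one model on explicit utterance lists.

    Chunk-level cross-entropy with Adam; logs per-epoch mean training loss
    and validation loss, keeps the best-validation checkpoint, and stops
    early after ``patience`` epochs without improvement.
    """
    hp = hp or Hyperparams()
    spec.chunk_s = hp.chunk_s
    model = build_model(spec, seed=seed)
    x_tr, y_tr, _ = _chunk_table(train_utts, class_order, hp.chunk_s, hp.shift_s)
    if len(val_utts):
        x_va, y_va, _ = _chunk_table(val_utts, class_order, hp.chunk_s, hp.shift_s)
    else:
        x_va = y_va = None
    opt = nnet.Adam(model.params(), lr=hp.lr)
    rng = np.random.default_rng(seed + 1)
    state = TrainState(seed=seed, hyperparams=hp)
    best_state = model.get_state()
    stall = 0
    for epoch in range(hp.epochs):
        order = rng.permutation(len(x_tr))
        total, n = 0.0, 0
        for s in range(0, len(order), hp.batch_size):
            idx = order[s : s + hp.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            opt.zero_grad()
            loss, dlogits = nnet.softmax_xent(model.forward_logits(xb, train=True), yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {s // hp.batch_size}"
                )
            model.backward(dlogits)
            opt.step()
            total += loss * len(xb)
            n += len(xb)
        state.epoch_losses.append(total / n)
        if x_va is not None:
            val = _mean_loss(model, x_va, y_va, hp.batch_size)
            state.val_losses.append(val)
            if val < state.best_val_loss - 1e-6:
                state.best_val_loss = val
                state.best_epoch = epoch
                best_state = model.get_state()
                stall = 0
            else:
                stall += 1
                if stall >= hp.patience:
                    break
        else:
            state.best_epoch = epoch
            best_state = model.get_state()
    model.set_state(best_state)
    return model, state


def train(spec: NetworkSpec, folds: FoldPlan, utterances: list[LabeledWaveform],
          class_order: list[str], hp: Hyperparams | None = None, seed: int = 0,
          ) -> list[tuple[VoiceNet, TrainState]]:
    """Cross-validated training: one (model, TrainState) per held-out fold."""
    present = {w.label for w in utterances}
    if not present <= set(class_order):
        raise ValueError(f"labels {present - set(class_order)} not in class order")
    by_id = {w.utterance_id: w for w in utterances}
    results = []
    for fold in range(folds.k):
        tr = [by_id[u] for u, f in folds.assignments.items() if f != fold and u in by_id]
        va = [by_id[u] for u, f in folds.assignments.items() if f == fold and u in by_id]
        if not va or not tr:
            raise ValueError(f"fold {fold} is empty")
        results.append(
            train_on_split(copy.deepcopy(spec), tr, va, class_order, hp,
                           seed=seed + fold)
        )
    return results
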