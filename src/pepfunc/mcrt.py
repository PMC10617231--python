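"""Multi-label classifier retraining (MCRT) and weak-label benchmarks.

After full two-phase training, each function's head is retrained alone as a
binary task on a class-rebalanced bootstrap of the training set, with the
embedding modules and every other head frozen. Class selection uses
square-root sampling: class j of function c is drawn with probability

    p_cj = sqrt(n_cj) / (sqrt(n_cj) + sqrt(N - n_cj)),

a compromise between natural (p ∝ n) and fully balanced (p = 1/2) sampling
that damps the long tail without swamping the retraining set with rare
positives — and, under incomplete annotation, reduces the chance of drawing
mislabelled negatives.

The weak-label constructor simulates incomplete annotation by flipping a
fraction (the WL ratio) of each function's positive entries to negative in
the training and validation splits, never the test split.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .encoding import EncodedDataset
from .training import (TrainingConfig, LogRow, precompute_Z, train_heads_on_Z)
from .network import LabelEmbeddingTransformer


@dataclass(frozen=True)
class SamplingProbabilities:
    p_positive: float
    p_negative: float


@dataclass(frozen=True)
class WeakLabelSpec:
    wl_ratio: float
    seed: int = 0
    scope: tuple[str, ...] = ("train", "validation")

    def __post_init__(self):
        if not (0.0 <= self.wl_ratio <= 1.0):
            raise ValueError(f"wl_ratio must be in [0, 1], got {self.wl_ratio}")


def sampling_probability(n_pos: int, N: int) -> SamplingProbabilities:
    """Square-root class-sampling probabilities for one function.

    ``p_negative`` is returned as ``1 - p_positive`` so the pair sums to 1
    exactly; this equals the direct formula with n_neg = N - n_pos, since
    both shares have the same denominator sqrt(n_pos) + sqrt(n_neg).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 <= n_pos <= N):
        raise ValueError(f"n_pos={n_pos} outside [0, {N}]")
    sp = np.sqrt(n_pos)
    sn = np.sqrt(N - n_pos)
    p_pos = float(sp / (sp + sn))
    return SamplingProbabilities(p_positive=p_pos, p_negative=1.0 - p_pos)


def _bootstrap_indices(y: np.ndarray, size: int, rng: np.random.Generator,
                       name: str) -> np.ndarray:
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError(f"function {name!r} has an empty class "
                         f"(positives={len(pos_idx)}, negatives={len(neg_idx)})")
    probs = sampling_probability(len(pos_idx), len(y))
    pick_pos = rng.random(size) < probs.p_positive
    return np.where(pick_pos,
                    pos_idx[rng.integers(0, len(pos_idx), size=size)],
                    neg_idx[rng.integers(0, len(neg_idx), size=size)])


def bootstrap_balanced(dataset: EncodedDataset, function: int | str,
                       size: int | None = None, seed: int = 0
                       ) -> EncodedDataset:
    """Square-root-rebalanced bootstrap of a dataset for one function.

    Each of ``size`` draws (default: the original dataset size) first picks
    the positive or negative class with the square-root probabilities, then
    a uniform member of that class, with replacement.
    """
    c = dataset.vocab.index(function) if isinstance(function, str) else function
    N = size if size is not None else len(dataset)
    draws = _bootstrap_indices(dataset.Y[:, c], N, np.random.default_rng(seed),
                               list(dataset.vocab)[c])
    return dataset.subset(draws)


def retrain_classifier(model: LabelEmbeddingTransformer, function: int | str,
                       dataset: EncodedDataset, config: TrainingConfig,
                       seed: int = 0) -> list[LogRow]:
    """Retrain one function's head on a (resampled) dataset.

    The embedding modules and all other heads are untouched; the loss is the
    binary cross-entropy restricted to this function's coordinate.
    """
    if not getattr(model, "phase2_done", False):
        raise RuntimeError("retrain_classifier requires a fully trained model")
    c = dataset.vocab.index(function) if isinstance(function, str) else function
    epochs = int(round((config.phase2_epochs if config.phase2_epochs is not None
                        else config.epochs) * config.mcrt_epochs_factor))
    log: list[LogRow] = []
    if epochs <= 0:
        return log
    Z = precompute_Z(model, dataset, config.batch_size * 8)
    rng = np.random.default_rng([seed, 3, c])
    empty_val = np.zeros((0, model.config.C, model.config.d_model))
    train_heads_on_Z(model, Z, dataset.Y, empty_val,
                     np.zeros((0, model.config.C)), config, epochs, rng,
                     f"mcrt:{list(dataset.vocab)[c]}", log, functions=[c])
    return log


def run_mcrt(model: LabelEmbeddingTransformer, train: EncodedDataset,
             config: TrainingConfig, seed: int = 0,
             order: list[int] | None = None) -> list[LogRow]:
    """Retrain every function's head on its own rebalanced bootstrap.

    Each function gets a deterministic sub-seed; because every retraining
    touches only its own head, the processing ``order`` (default 0..C-1,
    also usable to retrain a subset) cannot change any classifier's result.
    """
    if not getattr(model, "phase2_done", False):
        raise RuntimeError("run_mcrt requires a fully trained model")
    log: list[LogRow] = []
    epochs = int(round((config.phase2_epochs if config.phase2_epochs is not None
                        else config.epochs) * config.mcrt_epochs_factor))
    if epochs <= 0:
        return log
    # The backbone is frozen throughout MCRT, so the function representations
    # of the training samples are computed once and bootstraps slice them.
    Z_all = precompute_Z(model, train, config.batch_size * 8)
    C = model.config.C
    empty_val = np.zeros((0, C, model.config.d_model))
    for c in (order if order is not None else range(C)):
        draws = _bootstrap_indices(train.Y[:, c], len(train),
                                   np.random.default_rng([seed, 7, c]),
                                   list(train.vocab)[c])
        rng = np.random.default_rng([seed, 3, c])
        train_heads_on_Z(model, Z_all[draws], train.Y[draws], empty_val,
                         np.zeros((0, C)), config, epochs, rng,
                         f"mcrt:{list(train.vocab)[c]}", log, functions=[c])
    return log


def make_weak_label_dataset(splits: dict[str, EncodedDataset],
                            spec: WeakLabelSpec
                            ) -> tuple[dict[str, EncodedDataset], dict]:
    """Degrade positive annotations to simulate incomplete labelling.

    For every function independently, ``round(wl_ratio * n_pos)`` (half-up)
    of its positive entries in each in-scope split are flipped to 0.
    Samples whose label vectors become all-zero are retained as all-negative.
    The test split is never degraded. Returns the new splits plus a
    provenance record carrying the flip positions and the original labels.
    """
    out: dict[str, EncodedDataset] = {}
    provenance: dict = {"wl_ratio": spec.wl_ratio, "seed": spec.seed,
                        "scope": list(spec.scope), "flipped": {}}
    for split_name, ds in splits.items():
        if split_name not in spec.scope:
            out[split_name] = ds
            continue
        Y = ds.Y.copy()
        flipped: dict[str, list[str]] = {}
        for c, fname in enumerate(ds.vocab):
            pos = np.flatnonzero(Y[:, c] == 1)
            k = int(np.floor(spec.wl_ratio * len(pos) + 0.5))
            if k == 0:
                continue
            rng = np.random.default_rng(
                [spec.seed, zlib.crc32(split_name.encode()) % (2**31), c])
            chosen = rng.choice(pos, size=k, replace=False)
            Y[chosen, c] = 0
            flipped[fname] = [ds.ids[i] for i in np.sort(chosen)]
        out[split_name] = _dc_replace(ds, Y=Y)
        provenance["flipped"][split_name] = flipped
        provenance.setdefault("original_Y", {})[split_name] = ds.Y.copy()
    return out, provenance
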