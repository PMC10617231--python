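"""Loss, optimisation and the two-phase training procedure.

Phase 1 trains the sequence-embedding module, the label-embedding module and
a single shared classifier head, so every function is scored in one common
output space and the decoder can learn inter-function correlations. Phase 2
replaces the shared head with C function-specific heads (initialised from
the shared head) and trains them with the label-embedding module frozen —
and, by default, the sequence-embedding module too, in which case the
function representations Z are fixed and phase 2 reduces to C independent
logistic fits on pre-computed features (exact, and much faster).

Optimisation is AdamW throughout; each phase runs a configured number of
epochs and keeps the final epoch's weights. Hyperparameters are selected by
grid search on the validation loss, and experiments are repeated over a
seed list with arithmetically averaged metrics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .autodiff import AdamW, Parameter, Tensor, no_grad
from .encoding import EncodedDataset
from .network import LabelEmbeddingTransformer, ModelConfig
from . import metrics as _metrics

BCE_EPS = 1e-7


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 32
    warmup_steps: int = 200   # linear LR ramp; post-LN transformers need it
    epochs: int = 30
    phase2_epochs: int | None = None     # defaults to ``epochs``
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    freeze_seq_in_phase2: bool = True
    mcrt_epochs_factor: float = 1.0
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.seeds:
            raise ValueError("seed list must be non-empty")


@dataclass
class LogRow:
    phase: str
    epoch: int
    train_loss: float
    val_loss: float


def write_training_log(rows: list[LogRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("phase\tepoch\ttrain_loss\tval_loss\n")
        for r in rows:
            fh.write(f"{r.phase}\t{r.epoch}\t{r.train_loss:.6f}\t{r.val_loss:.6f}\n")


def bce_loss(y_hat, y):
    """Binary cross-entropy: summed over functions, averaged over samples.

    Probabilities are clipped to [1e-7, 1 - 1e-7] before the logs. Returns a
    graph Tensor when given Tensors, otherwise a float.
    """
    tensor_in = isinstance(y_hat, Tensor)
    p = y_hat if tensor_in else Tensor(np.asarray(y_hat, dtype=float))
    t = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=float))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    p = p.clip(BCE_EPS, 1.0 - BCE_EPS)
    ll = t * p.log() + (1.0 - t) * (1.0 - p).log()
    if p.ndim == 1:
        loss = -ll.sum()
    else:
        loss = -ll.sum(axis=-1).mean()
    return loss if tensor_in else float(loss.data)


def _snapshot(params: dict[str, Parameter]) -> dict[str, np.ndarray]:
    return {k: p.data.copy() for k, p in params.items()}


def _head_fn(model: LabelEmbeddingTransformer, head: str):
    if head == "single":
        return model.classify_single
    if head == "specific":
        return model.classify_specific
    raise ValueError(head)


def _epoch_val_loss(model, head, ds: EncodedDataset, batch_size: int) -> float:
    head_fn = _head_fn(model, head)
    total = 0.0
    with no_grad():
        for lo in range(0, len(ds), batch_size):
            Z, _ = model.forward(ds.Xs[lo:lo + batch_size], ds.mask[lo:lo + batch_size])
            probs = head_fn(Z)
            total += bce_loss(probs, Tensor(ds.Y[lo:lo + batch_size].astype(float))
                              ).data * len(probs.data)
    return float(total / max(len(ds), 1))


def _train_epochs(model, head: str, params: list[Parameter],
                  train: EncodedDataset, val: EncodedDataset,
                  config: TrainingConfig, epochs: int, rng: np.random.Generator,
                  phase: str, log: list[LogRow]) -> None:
    if len(train) == 0:
        raise ValueError("training set is empty")
    head_fn = _head_fn(model, head)
    opt = AdamW(params, lr=config.learning_rate, betas=config.betas,
                weight_decay=config.weight_decay)
    step = 0
    for epoch in range(1, epochs + 1):
        perm = rng.permutation(len(train))
        total = 0.0
        for lo in range(0, len(train), config.batch_size):
            idx = perm[lo:lo + config.batch_size]
            Z, _ = model.forward(train.Xs[idx], train.mask[idx], dropout_rng=rng)
            loss = bce_loss(head_fn(Z), Tensor(train.Y[idx].astype(float)))
            opt.zero_grad()
            loss.backward()
            step += 1
            if config.warmup_steps > 0:
                opt.lr = config.learning_rate * min(1.0, step / config.warmup_steps)
            opt.step()
            total += float(loss.data) * len(idx)
        log.append(LogRow(phase, epoch, total / len(train),
                          _epoch_val_loss(model, head, val, config.batch_size)))


def precompute_Z(model: LabelEmbeddingTransformer, ds: EncodedDataset,
                 batch_size: int = 256) -> np.ndarray:
    """Function representations for a whole dataset with the backbone frozen."""
    out = []
    with no_grad():
        for lo in range(0, len(ds), batch_size):
            Z, _ = model.forward(ds.Xs[lo:lo + batch_size], ds.mask[lo:lo + batch_size])
            out.append(Z.data)
    return np.concatenate(out, axis=0) if out else np.zeros(
        (0, model.config.C, model.config.d_model))


def train_heads_on_Z(model: LabelEmbeddingTransformer, Z: np.ndarray,
                     Y: np.ndarray, Z_val: np.ndarray, Y_val: np.ndarray,
                     config: TrainingConfig, epochs: int,
                     rng: np.random.Generator, phase: str,
                     log: list[LogRow], functions: list[int] | None = None) -> None:
    """Train (a subset of) the function-specific heads on fixed features."""
    if len(Z) == 0:
        raise ValueError("training set is empty")
    funcs = list(functions) if functions is not None else list(range(model.config.C))
    params: list[Parameter] = []
    for c in funcs:
        params += [model.params[f"specific{c}.W"], model.params[f"specific{c}.b"]]
    opt = AdamW(params, lr=config.learning_rate, betas=config.betas,
                weight_decay=config.weight_decay)
    Yf = Y[:, funcs].astype(float)
    Yv = Y_val[:, funcs].astype(float) if len(Y_val) else Y_val
    for epoch in range(1, epochs + 1):
        perm = rng.permutation(len(Z))
        total = 0.0
        for lo in range(0, len(Z), config.batch_size):
            idx = perm[lo:lo + config.batch_size]
            probs = model.classify_specific(Tensor(Z[idx]), functions=funcs)
            loss = bce_loss(probs, Tensor(Yf[idx]))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        if len(Z_val):
            with no_grad():
                vp = model.classify_specific(Tensor(Z_val), functions=funcs)
                vl = float(bce_loss(vp, Tensor(Yv)).data)
        else:
            vl = float("nan")
        log.append(LogRow(phase, epoch, total / len(Z), vl))


def train_phase1(model: LabelEmbeddingTransformer, train: EncodedDataset,
                 val: EncodedDataset, config: TrainingConfig,
                 seed: int = 0) -> list[LogRow]:
    """Phase 1: train E_seq, E_func and the shared single classifier."""
    groups = model.parameter_groups()
    params = groups["E_seq"] + groups["E_func"] + groups["F_single"]
    log: list[LogRow] = []
    rng = np.random.default_rng([seed, 1])
    _train_epochs(model, "single", params, train, val, config,
                  config.epochs, rng, "phase1", log)
    model.phase1_done = True
    return log


def train_phase2(model: LabelEmbeddingTransformer, train: EncodedDataset,
                 val: EncodedDataset, config: TrainingConfig,
                 seed: int = 0) -> list[LogRow]:
    """Phase 2: swap in the function-specific heads and train them with the
    label-embedding module frozen (and, by default, the sequence module too).

    The heads start as copies of the phase-1 shared head, so with zero
    additional updates phase-2 predictions coincide with phase-1 ones.
    """
    if not getattr(model, "phase1_done", False):
        raise RuntimeError("train_phase2 called before train_phase1")
    for c in range(model.config.C):
        model.params[f"specific{c}.W"].data[...] = model.params["single.W"].data
        model.params[f"specific{c}.b"].data[...] = model.params["single.b"].data
    epochs = config.phase2_epochs if config.phase2_epochs is not None else config.epochs
    log: list[LogRow] = []
    rng = np.random.default_rng([seed, 2])
    if config.freeze_seq_in_phase2:
        Z = precompute_Z(model, train, config.batch_size * 8)
        Z_val = precompute_Z(model, val, config.batch_size * 8)
        if epochs > 0:
            train_heads_on_Z(model, Z, train.Y, Z_val, val.Y, config, epochs,
                             rng, "phase2", log)
    else:
        groups = model.parameter_groups()
        params = groups["E_seq"] + groups["F_specific"]
        if epochs > 0:
            _train_epochs(model, "specific", params, train, val, config,
                          epochs, rng, "phase2", log)
    model.phase2_done = True
    return log


def run_two_phase(train: EncodedDataset, val: EncodedDataset,
                  model_config: ModelConfig, config: TrainingConfig,
                  seed: int = 0) -> tuple[LabelEmbeddingTransformer, list[LogRow]]:
    """Fresh model + both training phases under one seed."""
    model = LabelEmbeddingTransformer(model_config, train.vocab, seed=seed)
    log = train_phase1(model, train, val, config, seed=seed)
    log += train_phase2(model, train, val, config, seed=seed)
    return model, log


def grid_search(space: dict[str, list], train: EncodedDataset,
                val: EncodedDataset, config: TrainingConfig,
                model_config: ModelConfig, seed: int = 0
                ) -> tuple[TrainingConfig, list[tuple[dict, float]]]:
    """Exhaustive search over a hyperparameter grid.

    Every combination is trained through both phases and scored by the final
    validation loss; the full (setting, loss) table is returned alongside
    the winning configuration.
    """
    if not space:
        raise ValueError("grid-search space is empty")
    keys = list(space)
    table: list[tuple[dict, float]] = []
    best: tuple[float, TrainingConfig] | None = None
    for values in itertools.product(*(space[k] for k in keys)):
        setting = dict(zip(keys, values))
        cand = replace(config, **setting)
        model, log = run_two_phase(train, val, model_config, cand, seed=seed)
        val_loss = log[-1].val_loss
        table.append((setting, val_loss))
        if best is None or val_loss < best[0]:
            best = (val_loss, cand)
    return best[1], table


def evaluate_model(model: LabelEmbeddingTransformer, ds: EncodedDataset,
                   head: str = "specific",
                   groups: dict[str, str] | None = None) -> "_metrics.MetricsReport":
    probs = model.predict_proba(ds.Xs, ds.mask, head=head)
    return _metrics.compute_report(ds.Y, probs, ds.vocab, groups=groups)


def train_multiseed(train: EncodedDataset, val: EncodedDataset,
                    test: EncodedDataset, config: TrainingConfig,
                    model_config: ModelConfig,
                    groups: dict[str, str] | None = None):
    """One full two-phase run per seed; metrics averaged arithmetically.

    Returns ``(models, per_seed_reports, mean_report_dict)``.
    """
    models, reports = [], []
    for seed in config.seeds:
        model, _ = run_two_phase(train, val, model_config, config, seed=seed)
        models.append(model)
        reports.append(evaluate_model(model, test, groups=groups))
    mean = _metrics.average_reports(reports)
    return models, reports, mean
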