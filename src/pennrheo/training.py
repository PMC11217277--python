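"""Training protocol: minibatch Adam-family optimization in log space.

The loss is the mean squared error between predicted and actual
log10(viscosity).  A seeded 20% of the training partition is held out for
validation; training stops once the validation loss has not improved for
``patience_epochs`` epochs (the best-validation weights are restored), or
at ``max_epochs``.

The high-level entry point is :class:`ViscosityNetwork`, a model object
built from a dataset and an architecture spec whose :meth:`fit` returns a
:class:`TrainingResults` carrying the trained weights, the loss history,
per-partition metrics and (for physics-encoded networks) the recovered
physical constants with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .data import Dataset
from .models import (DenseNetSpec, PeNNCase1, PeNNCase2, PhysicsParams,
                     build_model, extract_physics_params)
from .optimizers import make_optimizer

__all__ = [
    "TrainConfig",
    "History",
    "train",
    "predict",
    "evaluate",
    "mse",
    "r_squared",
    "ViscosityNetwork",
    "TrainingResults",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (defaults follow the benchmark protocol)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    decay: float = 5e-6           # inverse-time: lr_t = lr0 / (1 + decay*t)
    val_fraction: float = 0.20
    patience_epochs: int = 500
    max_epochs: int = 20000
    batch_size: int | str | None = 32   # None -> full batch; "auto" -> ~20 updates/epoch
    restore_best: bool = True
    n_restarts: int = 1
    val_target: float | None = None   # stop restarting once best val mse <= this
    seed: int = 0
    optimizer_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.max_epochs < self.patience_epochs:
            raise ValueError("max_epochs must be >= patience_epochs")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


@dataclass
class History:
    """Per-epoch loss trace of one training run."""

    train_loss: np.ndarray
    val_loss: np.ndarray
    best_epoch: int
    stopped_epoch: int
    hit_epoch_cap: bool = False
    batch_size: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.train_loss)),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
        })


def mse(predicted: np.ndarray, actual: np.ndarray) -> float:
    return float(np.mean((np.asarray(predicted) - np.asarray(actual)) ** 2))


def r_squared(predicted: np.ndarray, actual: np.ndarray) -> float | None:
    """Coefficient of determination about the partition mean.

    Returns ``None`` (not NaN) for zero-variance targets, where R^2 is
    undefined.
    """
    actual = np.asarray(actual, dtype=float)
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0.0:
        return None
    ss_res = float(np.sum((np.asarray(predicted) - actual) ** 2))
    return 1.0 - ss_res / ss_tot


def predict(model, inputs) -> np.ndarray:
    """Deterministic forward pass, vectorized over rows."""
    return model.predict(inputs)


def evaluate(model, dataset: Dataset | tuple) -> dict:
    """``{"mse": ..., "r_squared": ...}`` on one dataset partition."""
    if isinstance(dataset, Dataset):
        X, y = dataset.inputs, dataset.targets
    else:
        X, y = dataset
    if len(X) == 0:
        raise ValueError("cannot evaluate on an empty partition")
    pred = model.predict(X)
    return {"mse": mse(pred, y), "r_squared": r_squared(pred, y)}


def _validation_split(n: int, val_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    return perm[n_val:], perm[:n_val]


def train(model, dataset: Dataset, config: TrainConfig = TrainConfig()):
    """Fit ``model`` to the dataset's training partition.

    Returns ``(model, History)``.  The model is trained in place on the
    rows labelled ``train``; a seeded ``val_fraction`` of those rows is
    reserved for validation and never sees a gradient step.

    With ``config.n_restarts > 1`` the run is repeated from fresh seeded
    initializations and the restart with the lowest best-validation loss
    wins (validation-based model selection; the test/holdout sets play no
    role).  This is the same multi-start principle the flow-curve fitter
    uses: the physics-encoded loss surface is multimodal because the
    surrogate stack and the structural weight can trade roles.  When
    ``config.val_target`` is set, restarting stops early once a restart
    reaches that validation loss — the remaining attempts would be
    redundant.

    Raises
    ------
    FloatingPointError
        If the loss turns non-finite, with the epoch and parameter norm in
        the message.
    """
    if config.n_restarts == 1:
        return _train_single(model, dataset, config)
    restart_seeds = [int(s) for s in np.random.SeedSequence(
        [config.seed, 0xC0FFEE]).generate_state(config.n_restarts) >> 1]
    best = None
    for r, rseed in enumerate(restart_seeds):
        candidate = model if r == 0 else build_model(model.spec, seed=rseed)
        try:
            candidate, hist = _train_single(candidate, dataset,
                                            config.replace(seed=rseed))
        except FloatingPointError:
            if best is None and r == config.n_restarts - 1:
                raise
            continue
        score = hist.val_loss[hist.best_epoch]
        if best is None or score < best[2]:
            best = (candidate.get_weights(), hist, score)
        if config.val_target is not None and score <= config.val_target:
            break
    weights, history, _ = best
    model.set_weights(weights)
    return model, history


def _train_single(model, dataset: Dataset, config: TrainConfig):
    labels = dataset.split_labels
    train_mask = labels == "train"
    if not np.any(train_mask):
        raise ValueError("dataset has no rows labelled 'train'")
    X_all = dataset.inputs[train_mask]
    y_all = dataset.targets[train_mask]
    if X_all.shape[1] != model.spec.input_width:
        raise ValueError(
            f"model expects {model.spec.input_width} input columns, "
            f"dataset has {X_all.shape[1]}"
        )

    # validation seed is decoupled from the train/holdout split seed
    ss = np.random.SeedSequence([config.seed, 0x5EED])
    val_seed, shuffle_seed = [int(s) for s in ss.generate_state(2) >> 1]
    fit_idx, val_idx = _validation_split(len(X_all), config.val_fraction, val_seed)
    X_fit, y_fit = X_all[fit_idx], y_all[fit_idx]
    X_val, y_val = X_all[val_idx], y_all[val_idx]

    if config.batch_size == "auto":
        # ~20 updates per epoch regardless of cell size, clipped to [8, 256]
        batch = int(np.clip(int(np.ceil(len(X_fit) / 20)), 8, 256))
    else:
        batch = config.batch_size or len(X_fit)
    batch = min(batch, len(X_fit))
    opt = make_optimizer(config.optimizer, model.params,
                         learning_rate=config.learning_rate,
                         decay=config.decay, **config.optimizer_kwargs)
    rng = np.random.default_rng(shuffle_seed)

    train_hist, val_hist = [], []
    best_val = np.inf
    best_epoch = 0
    best_weights = model.get_weights()
    n_fit = len(X_fit)

    epoch = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n_fit)
        epoch_sse = 0.0
        for start in range(0, n_fit, batch):
            idx = order[start:start + batch]
            Xb, yb = X_fit[idx], y_fit[idx]
            model.zero_grad()
            pred = model.forward(Xb)
            resid = pred - yb
            epoch_sse += float(np.dot(resid, resid))
            model.backward(2.0 * resid / len(idx))   # d(mse)/d(pred)
            opt.step(model.grads)
        train_loss = epoch_sse / n_fit
        val_loss = mse(model.predict(X_val), y_val)
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            norm = float(np.sqrt(sum(float(np.sum(p * p)) for p in model.params)))
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} "
                f"(train={train_loss}, val={val_loss}, parameter norm={norm:.3g})"
            )
        train_hist.append(train_loss)
        val_hist.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_weights = model.get_weights()
        elif epoch - best_epoch >= config.patience_epochs:
            break

    hit_cap = epoch == config.max_epochs - 1
    if config.restore_best:
        model.set_weights(best_weights)
    history = History(
        train_loss=np.asarray(train_hist),
        val_loss=np.asarray(val_hist),
        best_epoch=best_epoch,
        stopped_epoch=epoch,
        hit_epoch_cap=hit_cap,
        batch_size=batch,
    )
    return model, history


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class ViscosityNetwork:
    """A viscosity regressor (dense or physics-encoded) bound to a dataset.

    Parameters
    ----------
    dataset : Dataset
        Grid dataset with train/holdout labels; training uses the
        ``train`` rows only.
    spec : DenseNetSpec | PeNNSpec | str
        Architecture.  A plain signature string (``"2-32-8-1"``) builds a
        dense baseline; use a :class:`PeNNSpec` for a physics-encoded
        network.
    seed : int
        Seeds weight initialization; :meth:`fit`'s config seed drives the
        validation split and batch shuffling.
    """

    def __init__(self, dataset: Dataset, spec, seed: int = 0):
        if isinstance(spec, str):
            spec = DenseNetSpec.from_signature(spec)
        self.dataset = dataset
        self.spec = spec
        self.seed = seed
        self.model = build_model(spec, seed=seed)

    def fit(self, config: TrainConfig | None = None, **kw) -> "TrainingResults":
        config = (config or TrainConfig(seed=self.seed)).replace(**kw)
        model, history = train(self.model, self.dataset, config)
        metrics = {}
        for label in ("train", "holdout"):
            part = self.dataset.partition(label)
            if len(part):
                metrics[label] = evaluate(model, part)
        return TrainingResults(model=model, spec=self.spec, config=config,
                               history=history, metrics=metrics)


@dataclass
class TrainingResults:
    """Fitted network plus its training history and diagnostics."""

    model: object
    spec: object
    config: TrainConfig
    history: History
    metrics: dict

    def predict(self, inputs) -> np.ndarray:
        return self.model.predict(inputs)

    def evaluate(self, dataset) -> dict:
        return evaluate(self.model, dataset)

    @property
    def physics_params(self) -> PhysicsParams | None:
        if isinstance(self.model, (PeNNCase1, PeNNCase2)):
            return extract_physics_params(self.model)
        return None

    def summary(self) -> str:
        h = self.history
        lines = [
            f"ViscosityNetwork results ({self.spec.signature}, "
            f"{self.model.n_params} trainable parameters)",
            f"  optimizer: {self.config.optimizer}  lr={self.config.learning_rate}"
            f"  decay={self.config.decay}  batch={h.batch_size}",
            f"  epochs: {h.stopped_epoch + 1} (best {h.best_epoch}"
            f"{', hit epoch cap' if h.hit_epoch_cap else ''})",
            f"  best validation mse: {h.val_loss[h.best_epoch]:.4g}",
        ]
        for label, m in self.metrics.items():
            r2 = "undefined" if m["r_squared"] is None else f"{m['r_squared']:.6f}"
            lines.append(f"  {label:8s} mse={m['mse']:.4g}  R^2={r2}")
        pp = self.physics_params
        if pp is not None:
            lines.append("  physical scalars:")
            lines.append(f"    w_S (gamma_dot_c, s) = {pp.w_S:.6g}")
            lines.append(f"    w_C (C)              = {pp.w_C:.6g}")
            lines.append(f"    w_m (1/phi_m)        = {pp.w_m:.6g}")
            lines.append(f"    b_f (log10 eta_f)    = {pp.b_f:.6g}")
        return "\n".join(lines)
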