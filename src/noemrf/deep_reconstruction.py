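"""Neural-network reconstruction of proton exchange parameters.

A fully connected four-layer network (input -> 300 -> 300 -> output, ReLU
hidden activations, sigmoid outputs) is trained on simulated, 2-norm
normalized signal dictionaries to regress two exchange parameters per
trajectory. Targets are min-max scaled to (0, 1) over the dictionary grid
ranges to suit the sigmoid output.

Two deployment modes:

* single network (phantoms): 30-point trajectory -> (concentration/fraction,
  exchange rate);
* sequential two-network (in vivo): network 1 maps the MT-encoding
  trajectory to (f_ss, k_ssw); network 2 receives the rNOE-encoding
  trajectory concatenated with those two (scaled) values and outputs
  (f_s, k_sw).

Training uses Adam (lr 5e-4, step decay every 10 epochs), batch size 256,
mean-squared-error loss, a seeded random validation split, and early
stopping with patience 5. The implementation is plain NumPy with hand-written
backpropagation, which makes seeded runs bit-reproducible on one platform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dictionary import Dictionary, l2_normalize
from .io import ImageStack, QuantMaps

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "ParamScaler",
    "TrainedModel",
    "train",
    "infer",
    "sequential_reconstruct",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture: 4 layers total — input, two hidden (300 units), output."""

    input_dim: int
    hidden: tuple[int, ...] = (300, 300)
    output_dim: int = 2

    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden, self.output_dim]
        return list(zip(dims[:-1], dims[1:]))


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 5e-4
    decay_every_epochs: int = 10
    decay_factor: float = 0.5
    batch_size: int = 256
    max_epochs: int = 100
    early_stopping_patience: int = 5
    validation_fraction: float = 0.2
    seed: int = 0
    #: If > 0, draw fresh Gaussian noise of this s.d. on the (normalized)
    #: inputs every epoch; off by default (train on a single noisy copy).
    augment_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5]")
        for name in ("learning_rate", "batch_size", "max_epochs",
                     "early_stopping_patience", "decay_every_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ParamScaler:
    """Min-max map between physical parameter ranges and the (0,1) box.

    Degenerate axes (min == max) map to 0.5 and invert back to the single
    value, so constant-target training remains well-posed.
    """

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)

    @property
    def ranges(self) -> np.ndarray:
        return self.maxs - self.mins

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        r = self.ranges
        out = np.where(r > 0, (x - self.mins) / np.where(r > 0, r, 1.0), 0.5)
        return out

    def inverse(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        r = self.ranges
        return np.where(r > 0, self.mins + y * r, self.mins)

    @classmethod
    def from_grid(cls, dictionary: Dictionary, names) -> "ParamScaler":
        mins, maxs = [], []
        for n in names:
            vals = dictionary.grid.axis_values(n)
            mins.append(vals.min())
            maxs.append(vals.max())
        return cls(tuple(names), np.array(mins), np.array(maxs))


def _init_weights(spec: NetworkSpec, rng: np.random.Generator):
    weights = []
    dims = spec.layer_dims()
    for li, (fan_in, fan_out) in enumerate(dims):
        last = li == len(dims) - 1
        # He init for ReLU layers, Glorot for the sigmoid output layer
        scale = (
            np.sqrt(2.0 / fan_in) if not last
            else np.sqrt(6.0 / (fan_in + fan_out))
        )
        if last:
            W = rng.uniform(-scale, scale, size=(fan_in, fan_out))
        else:
            W = rng.normal(0.0, scale, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append([W, b])
    return weights


def _forward(weights, X: np.ndarray, keep: bool = False):
    acts = [X]
    h = X
    for i, (W, b) in enumerate(weights):
        z = h @ W + b
        if i < len(weights) - 1:
            h = np.maximum(z, 0.0)
        else:
            h = 1.0 / (1.0 + np.exp(-z))
        acts.append(h)
    return (h, acts) if keep else h


def _backward(weights, acts, dloss_dout):
    """Gradients of the loss w.r.t. each (W, b); dloss_dout is dL/d(sigmoid out)."""
    grads = []
    out = acts[-1]
    delta = dloss_dout * out * (1.0 - out)  # through sigmoid
    for i in range(len(weights) - 1, -1, -1):
        a_prev = acts[i]
        grads.append([a_prev.T @ delta, delta.sum(axis=0)])
        if i > 0:
            delta = (delta @ weights[i][0].T) * (acts[i] > 0)
    grads.reverse()
    return grads


@dataclass
class TrainedModel:
    """Learned parameters with scaling and provenance metadata.

    ``input_mean`` / ``input_std`` standardize each input feature (after the
    2-norm trajectory normalization) using moments of the training
    dictionary; this keeps optimization well-conditioned even though
    informative trajectory differences are small relative to the unit-norm
    signal level.
    """

    spec: NetworkSpec
    weights: list
    out_scaler: ParamScaler
    side_scaler: ParamScaler | None = None
    input_mean: np.ndarray | None = None
    input_std: np.ndarray | None = None
    schedule_id: str | None = None
    training_history: dict = field(default_factory=dict)

    @property
    def n_side_inputs(self) -> int:
        return 0 if self.side_scaler is None else len(self.side_scaler.names)

    def predict(
        self, trajectories: np.ndarray, side_scaled: np.ndarray | None = None
    ) -> np.ndarray:
        """Map normalized trajectories (plus scaled side inputs) to physical
        parameter values, shape (n, output_dim)."""
        X = np.atleast_2d(np.asarray(trajectories, dtype=float))
        X = l2_normalize(X)
        if self.n_side_inputs:
            if side_scaled is None:
                raise ValueError(
                    f"model expects {self.n_side_inputs} side inputs "
                    f"({self.side_scaler.names})"
                )
            X = np.hstack([X, np.atleast_2d(side_scaled)])
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input dim {X.shape[1]} != network input_dim {self.spec.input_dim}"
            )
        if self.input_mean is not None:
            X = (X - self.input_mean) / self.input_std
        return self.out_scaler.inverse(_forward(self.weights, X))


def train(
    dictionary: Dictionary,
    output_axes: tuple[str, str],
    config: TrainingConfig | None = None,
    spec: NetworkSpec | None = None,
    side_input_axes: tuple[str, ...] = (),
) -> TrainedModel:
    """Train a reconstruction network on a simulated dictionary.

    ``output_axes`` designates the two grid axes to regress;
    ``side_input_axes`` (for the second in-vivo network) appends those axes'
    scaled values to the trajectory as extra inputs.
    """
    config = config or TrainingConfig()
    if not dictionary.normalized:
        raise ValueError("dictionary must be 2-norm normalized before training")
    for ax in (*output_axes, *side_input_axes):
        dictionary.grid.axis_values(ax)  # raises KeyError if absent

    values = dictionary.grid.value_matrix()
    names = dictionary.grid.axis_names
    out_scaler = ParamScaler.from_grid(dictionary, output_axes)
    y = out_scaler.forward(values[:, [names.index(a) for a in output_axes]])

    X = dictionary.signals
    side_scaler = None
    if side_input_axes:
        side_scaler = ParamScaler.from_grid(dictionary, side_input_axes)
        side = side_scaler.forward(
            values[:, [names.index(a) for a in side_input_axes]]
        )
        X = np.hstack([X, side])

    if spec is None:
        spec = NetworkSpec(input_dim=X.shape[1], output_dim=len(output_axes))
    if spec.input_dim != X.shape[1]:
        raise ValueError(
            f"spec input_dim {spec.input_dim} != training input width {X.shape[1]}"
        )

    # Standardize inputs with training-set moments (stored on the model);
    # informative trajectory variation is ~1e-3 of the unit-norm signal
    # level, far too small for well-conditioned optimization otherwise.
    input_mean = X.mean(axis=0)
    input_std = X.std(axis=0)
    input_std = np.where(input_std > 0, input_std, 1.0)
    # Epoch augmentation noise acts on the normalized-trajectory scale,
    # i.e. before standardization; side-input columns are left clean.
    aug_scale = np.zeros(X.shape[1])
    aug_scale[: X.shape[1] - len(side_input_axes)] = (
        config.augment_noise_sigma / input_std[: X.shape[1] - len(side_input_axes)]
    )
    X = (X - input_mean) / input_std

    rng = np.random.default_rng(config.seed)
    n = len(X)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("dictionary too small for the validation split")
    X_tr, y_tr = X[tr_idx], y[tr_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    weights = _init_weights(spec, rng)
    m_state = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]
    v_state = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_val = np.inf
    best_weights = [[W.copy(), b.copy()] for W, b in weights]
    patience_left = config.early_stopping_patience
    history = {"train_loss": [], "val_loss": []}

    for epoch in range(config.max_epochs):
        lr = config.learning_rate * config.decay_factor ** (
            epoch // config.decay_every_epochs
        )
        order = rng.permutation(len(X_tr))
        Xe = X_tr[order]
        ye = y_tr[order]
        if config.augment_noise_sigma > 0:
            Xe = Xe + rng.normal(0.0, 1.0, size=Xe.shape) * aug_scale
        epoch_loss = 0.0
        for start in range(0, len(Xe), config.batch_size):
            xb = Xe[start : start + config.batch_size]
            yb = ye[start : start + config.batch_size]
            out, acts = _forward(weights, xb, keep=True)
            diff = out - yb
            epoch_loss += float(np.sum(diff**2))
            dloss = 2.0 * diff / diff.size
            grads = _backward(weights, acts, dloss)
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            for layer, g_layer, m_layer, v_layer in zip(
                weights, grads, m_state, v_state
            ):
                for j in range(2):
                    m_layer[j] = beta1 * m_layer[j] + (1 - beta1) * g_layer[j]
                    v_layer[j] = beta2 * v_layer[j] + (1 - beta2) * g_layer[j] ** 2
                    layer[j] -= lr * (m_layer[j] / bc1) / (
                        np.sqrt(v_layer[j] / bc2) + eps
                    )
        val_out = _forward(weights, X_val)
        val_loss = float(np.mean((val_out - y_val) ** 2))
        history["train_loss"].append(epoch_loss / y_tr.size)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = [[W.copy(), b.copy()] for W, b in weights]
            patience_left = config.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left == 0:
                break

    return TrainedModel(
        spec=spec,
        weights=best_weights,
        out_scaler=out_scaler,
        side_scaler=side_scaler,
        input_mean=input_mean,
        input_std=input_std,
        schedule_id=dictionary.schedule_id,
        training_history=history,
    )


def infer(
    model: TrainedModel,
    stack: ImageStack,
    mask: np.ndarray | None = None,
    side_maps: dict[str, np.ndarray] | None = None,
) -> QuantMaps:
    """Per-pixel forward pass over a stack; NaN outside the mask.

    ``side_maps`` supplies physical-unit maps for each side-input axis (the
    sequential mode passes stage-1 outputs here); they are scaled with the
    model's side scaler before concatenation.
    """
    if mask is None:
        mask = np.ones(stack.spatial_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.spatial_shape:
        raise ValueError("mask shape does not match stack geometry")
    if not mask.any():
        raise ValueError("empty mask")
    if (
        model.schedule_id is not None
        and stack.schedule_hash is not None
        and model.schedule_id != stack.schedule_hash
    ):
        warnings.warn(
            "stack schedule hash does not match the hash the model was "
            "trained on", stacklevel=2,
        )
    traj = stack.trajectories(mask)
    side_scaled = None
    if model.n_side_inputs:
        if side_maps is None:
            raise ValueError(
                f"model requires side inputs {model.side_scaler.names}"
            )
        cols = [np.asarray(side_maps[n])[mask] for n in model.side_scaler.names]
        side_scaled = model.side_scaler.forward(np.stack(cols, axis=1))
    pred = model.predict(traj, side_scaled)
    maps = {}
    for j, name in enumerate(model.out_scaler.names):
        vol = np.full(stack.spatial_shape, np.nan)
        vol[mask] = pred[:, j]
        maps[name] = vol
    return QuantMaps(
        maps=maps, affine=stack.affine, mask=mask,
        provenance={"model_schedule": model.schedule_id},
    )


def sequential_reconstruct(
    model_mt: TrainedModel,
    model_rnoe: TrainedModel,
    stack_mt: ImageStack,
    stack_rnoe: ImageStack,
    mask: np.ndarray | None = None,
) -> QuantMaps:
    """Two-stage in vivo reconstruction: MT network, then rNOE network.

    Stage 1 maps the MT-encoding stack to (f_ss, k_ssw); stage 2 concatenates
    each pixel's normalized rNOE trajectory with the scaled stage-1 estimates
    and outputs (f_s, k_sw). Returns all four maps.
    """
    if stack_mt.spatial_shape != stack_rnoe.spatial_shape:
        raise ValueError(
            f"stacks are not pixel-aligned: {stack_mt.spatial_shape} vs "
            f"{stack_rnoe.spatial_shape}"
        )
    if model_rnoe.n_side_inputs != len(model_mt.out_scaler.names):
        raise ValueError(
            "rNOE model side inputs do not match MT model outputs"
        )
    stage1 = infer(model_mt, stack_mt, mask)
    stage2 = infer(
        model_rnoe, stack_rnoe, mask,
        side_maps={n: stage1[n] for n in model_rnoe.side_scaler.names},
    )
    maps = dict(stage1.maps)
    maps.update(stage2.maps)
    return QuantMaps(
        maps=maps, affine=stack_mt.affine, mask=stage1.mask,
        provenance={
            "mt_model_schedule": model_mt.schedule_id,
            "rnoe_model_schedule": model_rnoe.schedule_id,
        },
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a binary checkpoint (.npz) plus a JSON sidecar next to it."""
    path = Path(path)
    arrays = {}
    for i, (W, b) in enumerate(model.weights):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    if model.input_mean is not None:
        arrays["input_mean"] = model.input_mean
        arrays["input_std"] = model.input_std
    np.savez(path, **arrays)
    sidecar = {
        "spec": {
            "input_dim": model.spec.input_dim,
            "hidden": list(model.spec.hidden),
            "output_dim": model.spec.output_dim,
        },
        "out_scaler": {
            "names": list(model.out_scaler.names),
            "mins": model.out_scaler.mins.tolist(),
            "maxs": model.out_scaler.maxs.tolist(),
        },
        "side_scaler": None
        if model.side_scaler is None
        else {
            "names": list(model.side_scaler.names),
            "mins": model.side_scaler.mins.tolist(),
            "maxs": model.side_scaler.maxs.tolist(),
        },
        "schedule_id": model.schedule_id,
        "n_layers": len(model.weights),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(npz_path)
    weights = [
        [data[f"W{i}"], data[f"b{i}"]] for i in range(meta["n_layers"])
    ]
    spec = NetworkSpec(
        input_dim=meta["spec"]["input_dim"],
        hidden=tuple(meta["spec"]["hidden"]),
        output_dim=meta["spec"]["output_dim"],
    )
    out_scaler = ParamScaler(
        tuple(meta["out_scaler"]["names"]),
        np.array(meta["out_scaler"]["mins"]),
        np.array(meta["out_scaler"]["maxs"]),
    )
    side_scaler = None
    if meta["side_scaler"] is not None:
        side_scaler = ParamScaler(
            tuple(meta["side_scaler"]["names"]),
            np.array(meta["side_scaler"]["mins"]),
            np.array(meta["side_scaler"]["maxs"]),
        )
    return TrainedModel(
        spec=spec, weights=weights, out_scaler=out_scaler,
        side_scaler=side_scaler,
        input_mean=data["input_mean"] if "input_mean" in data else None,
        input_std=data["input_std"] if "input_std" in data else None,
        schedule_id=meta["schedule_id"],
    )
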