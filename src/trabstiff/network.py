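"""Spherical CNN regressing the 6x6 apparent stiffness from spherical maps.

Architecture: three spherical convolution layers (zonal kernels acting
diagonally in spherical-harmonic degree, full cross-channel connections)
with widths 64/128/256, each followed by batch normalization, PReLU, and
area-weighted 2x2 pooling that halves the grid bandwidth (32 -> 16 -> 8 ->
4); an area-weighted global average pool to a 256-vector; dense layers
256 -> 64 (batchnorm + PReLU) and 64 -> 36; the 36 outputs are reshaped to
the 6x6 stiffness matrix in MPa. The output layer has no nonlinearity and
the prediction is not symmetrized. Zonal kernels hold 32/16/8 coefficients
per layer -- each layer's kernel is truncated to its input bandwidth, since
coefficients beyond the Nyquist degree of the pooled grid are undefined;
this yields 420,132 trainable parameters for the 3-channel input (about
0.4 M).

Training minimizes the mean per-sample relative Frobenius error
||C_o - C_p||_F / ||C_o||_F with ADAM under a stepwise learning-rate
schedule. Everything runs on NumPy arrays; gradients are computed layer by
layer in closed form (validated against finite differences in the test
suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from trabstiff.egi import SphericalMap, make_grid
from trabstiff.sphharm import real_transforms
from trabstiff.stiffness import StiffnessMatrix

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SampleRecord",
    "SphCNN",
    "build_model",
    "count_params",
    "frobenius_error",
    "train",
    "evaluate",
    "cross_validate",
    "assign_folds",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    in_channels: int = 3
    conv_widths: tuple = (64, 128, 256)
    kernel_coeffs: tuple = (32, 16, 8)
    dense_widths: tuple = (64, 36)
    input_bandwidth: int = 32
    use_batchnorm: bool = True
    use_dropout: bool = False
    dropout_p: float = 0.5
    #: fixed unit of the regression head: the network natively predicts
    #: stiffness in multiples of the tissue modulus (12 GPa), and the output
    #: is scaled back to MPa. A constant change of units, not a data
    #: normalization; it keeps head parameters O(1) under the ADAM schedule.
    output_scale: float = 12000.0

    def __post_init__(self):
        self.conv_widths = tuple(int(w) for w in self.conv_widths)
        self.kernel_coeffs = tuple(int(k) for k in self.kernel_coeffs)
        self.dense_widths = tuple(int(w) for w in self.dense_widths)
        if len(self.conv_widths) != 3 or len(self.kernel_coeffs) != 3:
            raise ValueError("three convolution layers are expected")
        if self.dense_widths[-1] != 36:
            raise ValueError("the output layer must have 36 units (6x6 stiffness)")
        if self.input_bandwidth % 8 != 0 or self.input_bandwidth < 16:
            raise ValueError(
                "input bandwidth must be a multiple of 8 and >= 16 "
                "(three pooling stages halve it down to >= 2)"
            )
        b = self.input_bandwidth
        for i, kc in enumerate(self.kernel_coeffs):
            if kc > b:
                raise ValueError(
                    f"kernel_coeffs[{i}]={kc} exceeds the layer bandwidth {b}"
                )
            b //= 2


@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 600
    #: tuple of (start_epoch, stop_epoch_exclusive, learning_rate)
    lr_schedule: tuple = ((0, 200, 0.01), (200, 400, 0.001), (400, 600, 0.001))
    seed: int = 0
    folds: int = 5
    augment_azimuthal: bool = False

    def __post_init__(self):
        cover = np.zeros(self.epochs, dtype=bool)
        for start, stop, _ in self.lr_schedule:
            cover[start:stop] = True
        if not cover.all():
            raise ValueError("lr_schedule must cover [0, epochs)")

    def lr_at(self, epoch: int) -> float:
        for start, stop, lr in self.lr_schedule:
            if start <= epoch < stop:
                return lr
        raise ValueError(f"epoch {epoch} outside the schedule")


@dataclass
class SampleRecord:
    """One specimen: spherical input, site label, observed stiffness, fold."""

    sample_id: str
    features: SphericalMap
    site: str
    observed: StiffnessMatrix
    fold: int = -1
    bvtv: float = float("nan")
    volume_path: str = ""
    spacing_mm: float = float("nan")


# ---------------------------------------------------------------------------
# Layers (forward + closed-form backward)
# ---------------------------------------------------------------------------


class _Layer:
    params: dict
    grads: dict

    def param_count(self) -> int:
        return sum(v.size for v in self.params.values())


class SphConv(_Layer):
    """Zonal spherical convolution with full cross-channel connections.

    Pixels -> harmonic coefficients (real basis) -> per-degree scaling by
    2*pi*sqrt(4*pi/(2l+1)) * H[out, in, l] -> pixels, plus an output-channel
    bias. Degrees at or above n_coeff are annihilated.
    """

    def __init__(self, b: int, c_in: int, c_out: int, n_coeff: int, rng):
        if n_coeff > b:
            raise ValueError(f"kernel has {n_coeff} coefficients but bandwidth is {b}")
        self.b, self.c_in, self.c_out, self.n_coeff = b, c_in, c_out, n_coeff
        A, S, l_of_k = real_transforms(b)
        # degrees >= n_coeff are annihilated by the kernel, so analysis and
        # synthesis only carry the first n_coeff^2 packed coefficients
        nc2 = n_coeff * n_coeff
        self.A = A[:nc2]
        self.S = S[:, :nc2]
        ls = np.arange(n_coeff)
        self.deg_scale = 2 * np.pi * np.sqrt(4 * np.pi / (2 * ls + 1))
        self.params = {
            "H": rng.standard_normal((c_out, c_in, n_coeff)) / np.sqrt(c_in * n_coeff),
            "bias": np.zeros(c_out),
        }
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # x: (N, c_in, npix); all matmuls run flattened over (batch x
        # channel) rows, and channel mixing is grouped by degree l, where
        # the zonal kernel is constant, so each group is one matmul
        N, c_in, npix = x.shape
        nc2 = self.A.shape[0]
        self._fh = (x.reshape(N * c_in, npix) @ self.A.T).reshape(N, c_in, nc2)
        H, deg = self.params["H"], self.deg_scale
        yh = np.empty((N, self.c_out, nc2))
        for l in range(self.n_coeff):
            sl = slice(l * l, (l + 1) * (l + 1))
            W = H[:, :, l] * deg[l]  # (c_out, c_in)
            yh[:, :, sl] = np.einsum("oi,nim->nom", W, self._fh[:, :, sl])
        y = (yh.reshape(N * self.c_out, nc2) @ self.S.T).reshape(N, self.c_out, npix)
        return y + self.params["bias"][None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["bias"] = g.sum(axis=(0, 2))
        N, c_out, npix = g.shape
        nc2 = self.A.shape[0]
        gh = (g.reshape(N * c_out, npix) @ self.S).reshape(N, c_out, nc2)
        H, deg = self.params["H"], self.deg_scale
        dH = np.empty_like(H)
        gfh = np.empty_like(self._fh)
        for l in range(self.n_coeff):
            sl = slice(l * l, (l + 1) * (l + 1))
            dH[:, :, l] = deg[l] * np.einsum(
                "nom,nim->oi", gh[:, :, sl], self._fh[:, :, sl]
            )
            gfh[:, :, sl] = np.einsum(
                "oi,nom->nim", H[:, :, l] * deg[l], gh[:, :, sl]
            )
        self.grads["H"] = dH
        c_in = gfh.shape[1]
        return (gfh.reshape(N * c_in, nc2) @ self.A).reshape(N, c_in, npix)


class BatchNorm(_Layer):
    """Per-channel batch normalization over (batch, pixels); affine."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.grads = {}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = [1, -1] + [1] * (x.ndim - 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes, self._training = axes, training
        self._std = np.sqrt(var + self.eps).reshape(shape)
        self._xhat = (x - mean.reshape(shape)) / self._std
        return (
            self.params["gamma"].reshape(shape) * self._xhat
            + self.params["beta"].reshape(shape)
        )

    def backward(self, g: np.ndarray) -> np.ndarray:
        shape = [1, -1] + [1] * (g.ndim - 2)
        axes = self._axes
        self.grads["gamma"] = (g * self._xhat).sum(axis=axes)
        self.grads["beta"] = g.sum(axis=axes)
        gxhat = g * self.params["gamma"].reshape(shape)
        if not self._training:
            return gxhat / self._std
        return (
            gxhat
            - gxhat.mean(axis=axes, keepdims=True)
            - self._xhat * (gxhat * self._xhat).mean(axis=axes, keepdims=True)
        ) / self._std


class PReLU(_Layer):
    """Parametric ReLU with one learned negative slope per channel."""

    def __init__(self, channels: int, init: float = 0.25):
        self.params = {"alpha": np.full(channels, init)}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        shape = [1, -1] + [1] * (x.ndim - 2)
        self._x, self._shape = x, shape
        return np.where(x > 0, x, self.params["alpha"].reshape(shape) * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        axes = (0,) + tuple(range(2, g.ndim))
        neg = self._x <= 0
        self.grads["alpha"] = (g * self._x * neg).sum(axis=axes)
        return g * np.where(neg, self.params["alpha"].reshape(self._shape), 1.0)


class PoolHalf(_Layer):
    """Area-weighted 2x2 mean pooling onto the half-bandwidth grid."""

    def __init__(self, b: int):
        self.b = b
        self._w = make_grid(b).area_weights.reshape(b, 2, b, 2)
        self._wsum = self._w.sum(axis=(1, 3))
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, C = x.shape[:2]
        self._in_shape = x.shape
        v = x.reshape(N, C, self.b, 2, self.b, 2)
        out = (v * self._w).sum(axis=(3, 5)) / self._wsum
        return out.reshape(N, C, -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, C = g.shape[:2]
        gb = (
            g.reshape(N, C, self.b, 1, self.b, 1) / self._wsum[:, None, :, None]
        ) * self._w
        return gb.reshape(self._in_shape)


class GlobalPool(_Layer):
    """Area-weighted global average per channel."""

    def __init__(self, b: int):
        w = make_grid(b).area_weights.ravel()
        self._w = w / w.sum()
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return x @ self._w

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g[:, :, None] * self._w[None, None, :]


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng, zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.standard_normal((n_out, n_in)) * scale,
            "b": np.zeros(n_out),
        }
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["W"] = g.T @ self._x
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"]


class OutputScale(_Layer):
    """Fixed multiplication converting head units to MPa; no parameters."""

    def __init__(self, scale: float):
        self.scale = float(scale)
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return x * self.scale

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self.scale


class Dropout(_Layer):
    """Inverted dropout; no trainable parameters."""

    def __init__(self, p: float, rng):
        self.p = p
        self._rng = rng
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class SphCNN:
    """The full prediction network; see the module docstring."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        b = config.input_bandwidth
        c_prev = config.in_channels
        self.layers: list[_Layer] = []
        for width, kc in zip(config.conv_widths, config.kernel_coeffs):
            self.layers.append(SphConv(b, c_prev, width, kc, rng))
            if config.use_batchnorm:
                self.layers.append(BatchNorm(width))
            self.layers.append(PReLU(width))
            self.layers.append(PoolHalf(b))
            b //= 2
            c_prev = width
        self.layers.append(GlobalPool(b))
        d1, d2 = config.dense_widths
        self.layers.append(Dense(c_prev, d1, rng))
        if config.use_batchnorm:
            self.layers.append(BatchNorm(d1))
        self.layers.append(PReLU(d1))
        if config.use_dropout:
            self.layers.append(Dropout(config.dropout_p, rng))
        # zero-initialized regression head: predictions start at the origin
        self.layers.append(Dense(d1, d2, rng, zero_init=True))
        if config.output_scale != 1.0:
            self.layers.append(OutputScale(config.output_scale))
        self.training_log: list[float] = []

    # ---- plumbing ---------------------------------------------------------
    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name in sorted(layer.params):
                yield f"{i}.{name}", layer, name, layer.params[name]

    def forward_batch(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        h = X
        for layer in self.layers:
            h = layer.forward(h, training)
        return h  # (N, 36)

    def backward_batch(self, grad_out: np.ndarray) -> None:
        g = grad_out
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def forward(self, smap: SphericalMap) -> StiffnessMatrix:
        """Predict the stiffness of a single specimen (eval mode)."""
        cfg = self.config
        if smap.n_channels != cfg.in_channels:
            raise ValueError(
                f"model expects {cfg.in_channels} channels, map has {smap.n_channels}"
            )
        if smap.grid.b != cfg.input_bandwidth:
            raise ValueError(
                f"model expects bandwidth {cfg.input_bandwidth}, map has {smap.grid.b}"
            )
        X = smap.values.reshape(1, cfg.in_channels, -1)
        out = self.forward_batch(X, training=False)
        return StiffnessMatrix(out.reshape(6, 6))

    # ---- persistence ------------------------------------------------------
    def save(self, path) -> None:
        import h5py

        cfg = self.config
        with h5py.File(path, "w") as fh:
            g = fh.create_group("params")
            for key, _, _, arr in self.parameters():
                g.create_dataset(key, data=arr)
            rs = fh.create_group("running_stats")
            for i, layer in enumerate(self.layers):
                if isinstance(layer, BatchNorm):
                    rs.create_dataset(f"{i}.mean", data=layer.running_mean)
                    rs.create_dataset(f"{i}.var", data=layer.running_var)
            fh.attrs["config"] = repr(
                {
                    "in_channels": cfg.in_channels,
                    "conv_widths": cfg.conv_widths,
                    "kernel_coeffs": cfg.kernel_coeffs,
                    "dense_widths": cfg.dense_widths,
                    "input_bandwidth": cfg.input_bandwidth,
                    "use_batchnorm": cfg.use_batchnorm,
                    "use_dropout": cfg.use_dropout,
                }
            )
            fh.create_dataset("training_log", data=np.asarray(self.training_log))

    @classmethod
    def load(cls, path) -> "SphCNN":
        import ast

        import h5py

        with h5py.File(path, "r") as fh:
            cfg = ModelConfig(**ast.literal_eval(fh.attrs["config"]))
            model = cls(cfg, seed=0)
            for key, layer, name, _ in model.parameters():
                layer.params[name] = fh["params"][key][...]
            for i, layer in enumerate(model.layers):
                if isinstance(layer, BatchNorm):
                    layer.running_mean = fh["running_stats"][f"{i}.mean"][...]
                    layer.running_var = fh["running_stats"][f"{i}.var"][...]
            model.training_log = list(fh["training_log"][...])
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0) -> SphCNN:
    """Deterministically initialized network for the given configuration."""
    return SphCNN(config or ModelConfig(), seed=seed)


def count_params(model: SphCNN) -> int:
    """Trainable scalars (batchnorm running statistics excluded)."""
    return sum(layer.param_count() for layer in model.layers)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def frobenius_error(observed, predicted) -> float:
    """Relative Frobenius error ||C_o - C_p||_F / ||C_o||_F on 6x6 matrices."""
    Co = observed.entries if isinstance(observed, StiffnessMatrix) else np.asarray(observed)
    Cp = predicted.entries if isinstance(predicted, StiffnessMatrix) else np.asarray(predicted)
    denom = np.linalg.norm(Co)
    if denom == 0:
        raise ValueError("observed stiffness has zero Frobenius norm")
    return float(np.linalg.norm(Co - Cp) / denom)


def _loss_and_grad(pred: np.ndarray, target: np.ndarray):
    """Mean per-sample relative Frobenius error over a batch of 36-vectors."""
    diff = pred - target
    dn = np.linalg.norm(diff, axis=1)
    tn = np.linalg.norm(target, axis=1)
    if np.any(tn == 0):
        raise ValueError("observed stiffness has zero Frobenius norm")
    loss = float(np.mean(dn / tn))
    safe = np.where(dn > 0, dn, 1.0)
    grad = diff / (safe * tn)[:, None] / pred.shape[0]
    grad[dn == 0] = 0.0
    return loss, grad


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, model: SphCNN, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(a) for k, _, _, a in model.parameters()}
        self.v = {k: np.zeros_like(a) for k, _, _, a in model.parameters()}
        self.t = 0

    def step(self, model: SphCNN, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, name, arr in model.parameters():
            g = layer.grads[name]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            layer.params[name] = arr - lr * mhat / (np.sqrt(vhat) + self.eps)


def _stack_dataset(dataset):
    X = np.stack(
        [r.features.values.reshape(r.features.n_channels, -1) for r in dataset]
    )
    Y = np.stack([r.observed.entries.reshape(36) for r in dataset])
    return X, Y


def train(model: SphCNN, dataset, tc: TrainConfig = TrainConfig()) -> SphCNN:
    """ADAM training with per-epoch reshuffling; deterministic in tc.seed."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    X, Y = _stack_dataset(dataset)
    n = len(dataset)
    rng = np.random.default_rng(tc.seed)
    opt = _Adam(model)
    npix = X.shape[-1]
    nalpha = model.config.input_bandwidth * 2
    for epoch in range(tc.epochs):
        lr = tc.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss, nb = 0.0, 0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb = X[idx]
            if tc.augment_azimuthal:
                shifts = rng.integers(0, nalpha, size=len(idx))
                xb = xb.reshape(len(idx), -1, nalpha, npix // nalpha)
                xb = np.stack([np.roll(s, k, axis=1) for s, k in zip(xb, shifts)])
                xb = xb.reshape(len(idx), -1, npix)
            pred = model.forward_batch(xb, training=True)
            loss, grad = _loss_and_grad(pred, Y[idx])
            model.backward_batch(grad)
            opt.step(model, lr)
            epoch_loss += loss
            nb += 1
        model.training_log.append(epoch_loss / nb)
    _calibrate_batchnorm(model, X)
    return model


def _calibrate_batchnorm(model: SphCNN, X: np.ndarray) -> None:
    """Set batchnorm running statistics to the full-training-set moments.

    Mini-batch running averages are a poor estimate of the activation
    statistics on small datasets; one final full pass in training mode with
    momentum zero pins the inference-time statistics to the actual training
    distribution.
    """
    bns = [l for l in model.layers if isinstance(l, BatchNorm)]
    if not bns:
        return
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 0.0
    model.forward_batch(X, training=True)
    for bn, mom in zip(bns, saved):
        bn.momentum = mom


def evaluate(model: SphCNN, dataset) -> np.ndarray:
    """Per-sample Frobenius errors in dataset order (eval mode)."""
    X, Y = _stack_dataset(dataset)
    pred = model.forward_batch(X, training=False)
    return np.linalg.norm(pred - Y, axis=1) / np.linalg.norm(Y, axis=1)


def assign_folds(dataset, k: int, seed: int) -> None:
    """Stratified-by-site fold labels, in place; deterministic in seed."""
    if k < 2:
        raise ValueError("at least 2 folds are required")
    if k > len(dataset):
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    offset = 0  # rolling across sites keeps the overall fold sizes balanced
    for site in sorted({r.site for r in dataset}):
        idx = [i for i, r in enumerate(dataset) if r.site == site]
        order = rng.permutation(len(idx))
        for pos, j in enumerate(order):
            dataset[idx[j]].fold = (offset + pos) % k
        offset += len(idx)


def cross_validate(
    dataset,
    tc: TrainConfig = TrainConfig(),
    mc: ModelConfig | None = None,
    return_errors: bool = False,
):
    """k-fold cross-validation stratified by site.

    Returns a DataFrame of mean Frobenius errors with one row per fold plus
    a 'mean' row, and columns 'all' plus one per site (the usual fold x site
    comparison-table layout). With return_errors, also a dict sample_id ->
    (fold, site, error) over all validation predictions.
    """
    mc = mc or ModelConfig()
    dataset = list(dataset)
    assign_folds(dataset, tc.folds, tc.seed)
    sites = sorted({r.site for r in dataset})
    rows = {}
    per_sample = {}
    for fold in range(tc.folds):
        train_set = [r for r in dataset if r.fold != fold]
        val_set = [r for r in dataset if r.fold == fold]
        model = build_model(mc, seed=tc.seed + 1000 * fold)
        train(model, train_set, tc)
        errs = evaluate(model, val_set)
        for r, e in zip(val_set, errs):
            per_sample[r.sample_id] = (fold, r.site, float(e))
        row = {"all": float(np.mean(errs))}
        for site in sites:
            se = [e for r, e in zip(val_set, errs) if r.site == site]
            row[site] = float(np.mean(se)) if se else np.nan
        rows[fold] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["mean"] = table.mean()
    table.index.name = "fold"
    if return_errors:
        return table, per_sample
    return table
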