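"""The residual graph-convolutional network for scalar (trait) regression.

Architecture: a pre-convolutional Chebyshev layer at full mesh resolution,
``n_res_blocks`` residual blocks (each two BN -> ReLU -> ChebConv subblocks
with an identity shortcut, a K=1 projection when channel widths change) each
followed by stride-2 max pooling on the coarsening hierarchy, one post
residual block at the coarsest level, then flatten -> dropout -> a single
fully connected output neuron.  Residual shortcuts are added *before* pooling
so both paths live at the same resolution.

Layers are implemented directly on numpy/scipy with hand-written backward
passes (reverse-mode differentiation); the only graph-specific primitive is
the shared Chebyshev recurrence from :mod:`surfgcn.spectral_conv`.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np

from .graph_hierarchy import GraphHierarchy
from .spectral_conv import ChebFilterSpec, ScaledLaplacian, cheb_basis_apply, scale_laplacian

__all__ = ["ModelConfig", "Model", "build_model", "forward", "save_model", "load_model"]


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    ``channels`` lists output widths for the pre-conv layer, each residual
    block, and the post residual block, so ``len(channels) - 2`` residual
    blocks (and that many pooling levels) are built.  The default widths are a
    configuration choice of this package.
    """

    input_features: int = 9
    channels: tuple[int, ...] = (32, 32, 64, 64, 128, 128)
    cheb_order: int = 3
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_features not in (3, 6, 9):
            raise ValueError("input_features must be 3, 6, or 9")
        if len(self.channels) < 3:
            raise ValueError("channels needs >= 3 entries (pre, >=1 residual, post)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.cheb_order < 1:
            raise ValueError("cheb_order must be >= 1")

    @property
    def n_res_blocks(self) -> int:
        return len(self.channels) - 2

    @property
    def pool_levels(self) -> int:
        return self.n_res_blocks


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Layers (forward caches what backward needs; backward accumulates grads)
# ---------------------------------------------------------------------------


class _Layer:
    name: str = ""

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}

    def weight_arrays(self) -> list[np.ndarray]:
        """Arrays subject to l2 regularization (filters and FC weights only)."""
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ChebConv(_Layer):
    """Graph convolution y = sum_k T_k(L~) x theta_k + b.

    Inside the network, activations use the (n, B, F) layout so the Chebyshev
    basis slices reshape to (n*B, F) BLAS operands without copies.
    """

    def __init__(self, scaled: ScaledLaplacian, f_in: int, f_out: int, order: int,
                 rng: np.random.Generator, name: str, dtype=np.float64):
        self.scaled = scaled
        self.name = name
        std = np.sqrt(2.0 / (f_in * order))
        self.theta = rng.normal(0.0, std, size=(f_in, f_out, order)).astype(dtype)
        self.bias = np.zeros(f_out, dtype=dtype)
        self.d_theta = np.zeros_like(self.theta)
        self.d_bias = np.zeros_like(self.bias)
        self._basis: np.ndarray | None = None
        self.last_output: np.ndarray | None = None
        self.grad_output: np.ndarray | None = None

    @property
    def order(self) -> int:
        return self.theta.shape[2]

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.theta": self.theta, f"{self.name}.bias": self.bias}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.theta": self.d_theta, f"{self.name}.bias": self.d_bias}

    def weight_arrays(self) -> list[np.ndarray]:
        return [self.theta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, b, _ = x.shape
        f, g, k = self.theta.shape
        basis = cheb_basis_apply(self.scaled, x.reshape(n, b * f), k)  # (K,n,B*F)
        self._basis = basis
        y = np.zeros((n * b, g), dtype=x.dtype)
        for j in range(k):
            y += basis[j].reshape(n * b, f) @ self.theta[:, :, j].astype(x.dtype)
        y = y.reshape(n, b, g) + self.bias.astype(x.dtype)
        self.last_output = y
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grad_output = grad
        n, b, g = grad.shape
        f, _, k = self.theta.shape
        gflat = grad.reshape(n * b, g)
        for j in range(k):
            self.d_theta[:, :, j] += self._basis[j].reshape(n * b, f).T @ gflat
        self.d_bias += gflat.sum(axis=0)
        # L~ is symmetric: d x = sum_k T_k(L~) (grad theta_k^T)
        gbasis = cheb_basis_apply(self.scaled, grad.reshape(n, b * g), k)
        dx = np.zeros((n * b, f), dtype=grad.dtype)
        for j in range(k):
            dx += gbasis[j].reshape(n * b, g) @ self.theta[:, :, j].T.astype(grad.dtype)
        return dx.reshape(n, b, f)

    def filter_spec(self) -> ChebFilterSpec:
        return ChebFilterSpec(theta=self.theta.copy(), bias=self.bias.copy())


class BatchNorm(_Layer):
    """Per-channel normalization over batch and vertices; momentum-0.9 running stats."""

    EPS = 1e-5

    def __init__(self, channels: int, name: str, momentum: float = 0.9,
                 dtype=np.float64):
        self.name = name
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.d_gamma = np.zeros_like(self.gamma)
        self.d_beta = np.zeros_like(self.beta)
        self._cache: tuple | None = None

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{self.name}.gamma": self.gamma,
            f"{self.name}.beta": self.beta,
            f"{self.name}.running_mean": self.running_mean,
            f"{self.name}.running_var": self.running_var,
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.gamma": self.d_gamma, f"{self.name}.beta": self.d_beta}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, b, f = x.shape
        flat = x.reshape(n * b, f)
        if training:
            m = n * b
            s1 = np.einsum("if->f", flat)
            s2 = np.einsum("if,if->f", flat, flat)
            mean = s1 / m
            var = np.maximum(s2 / m - mean**2, 0.0)
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mean
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.EPS)).astype(x.dtype)
        xhat = (flat - mean.astype(x.dtype)) * inv_std
        self._cache = (xhat, inv_std, training, (n, b, f))
        out = xhat * self.gamma.astype(x.dtype)
        out += self.beta.astype(x.dtype)
        return out.reshape(n, b, f)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, (n, b, f) = self._cache
        gflat = grad.reshape(n * b, f)
        self.d_gamma += np.einsum("if,if->f", gflat, xhat)
        self.d_beta += np.einsum("if->f", gflat)
        if not training:
            return (gflat * (self.gamma * inv_std).astype(grad.dtype)).reshape(n, b, f)
        m = n * b
        gx = gflat * self.gamma.astype(grad.dtype)
        mean_gx = np.einsum("if->f", gx) / m
        mean_gx_xhat = np.einsum("if,if->f", gx, xhat) / m
        out = gx
        out -= mean_gx
        out -= xhat * mean_gx_xhat
        out *= inv_std
        return out.reshape(n, b, f)


class ReLU(_Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool(_Layer):
    """Stride-2 sibling pooling on the hierarchy; fake children never win."""

    def __init__(self, hierarchy: GraphHierarchy, level: int):
        self.level = level
        self.fake = hierarchy.levels[level].fake_mask

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, b, f = x.shape
        work = x.copy()
        work[self.fake] = -np.inf
        paired = work.reshape(n // 2, 2, b, f)
        right_wins = paired[:, 1] > paired[:, 0]
        self._right_wins = right_wins
        out = np.where(right_wins, paired[:, 1], paired[:, 0])
        out[~np.isfinite(out)] = 0.0  # both children fake
        self._shape = (n, b, f)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, b, f = self._shape
        out = np.zeros((n // 2, 2, b, f), dtype=grad.dtype)
        out[:, 1] = np.where(self._right_wins, grad, 0.0)
        out[:, 0] = np.where(self._right_wins, 0.0, grad)
        out = out.reshape(n, b, f)
        out[self.fake] = 0.0
        return out


class Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Dense(_Layer):
    """Fully connected (B, d) -> (B, out).

    Initialized near zero: for a regression head this starts predictions at
    the target mean (targets are quantile-normalized to N(0, 1)), avoiding a
    long recentering transient at small learning rates.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str,
                 dtype=np.float64):
        self.name = name
        self.w = rng.normal(0.0, 0.01 / np.sqrt(d_in), size=(d_in, d_out)).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.d_w = np.zeros_like(self.w)
        self.d_b = np.zeros_like(self.b)

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.w": self.w, f"{self.name}.b": self.b}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.w": self.d_w, f"{self.name}.b": self.d_b}

    def weight_arrays(self) -> list[np.ndarray]:
        return [self.w]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.d_w += self._x.T @ grad
        self.d_b += grad.sum(axis=0)
        return grad @ self.w.T


class ResidualBlock(_Layer):
    """Two (BN -> ReLU -> ChebConv) subblocks plus an identity/projection shortcut."""

    def __init__(self, scaled: ScaledLaplacian, f_in: int, f_out: int, order: int,
                 rng: np.random.Generator, name: str, dtype=np.float64):
        self.name = name
        self.bn1 = BatchNorm(f_in, f"{name}.bn1", dtype=dtype)
        self.relu1 = ReLU()
        self.conv1 = ChebConv(scaled, f_in, f_out, order, rng, f"{name}.conv1",
                              dtype=dtype)
        self.bn2 = BatchNorm(f_out, f"{name}.bn2", dtype=dtype)
        self.relu2 = ReLU()
        self.conv2 = ChebConv(scaled, f_out, f_out, order, rng, f"{name}.conv2",
                              dtype=dtype)
        self.project = (
            ChebConv(scaled, f_in, f_out, 1, rng, f"{name}.project", dtype=dtype)
            if f_in != f_out
            else None
        )

    def _sublayers(self) -> list[_Layer]:
        layers = [self.bn1, self.relu1, self.conv1, self.bn2, self.relu2, self.conv2]
        if self.project is not None:
            layers.append(self.project)
        return layers

    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self._sublayers():
            out.update(layer.parameters())
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self._sublayers():
            out.update(layer.gradients())
        return out

    def weight_arrays(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self._sublayers():
            out.extend(layer.weight_arrays())
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = self.bn1.forward(x, training)
        h = self.relu1.forward(h, training)
        h = self.conv1.forward(h, training)
        h = self.bn2.forward(h, training)
        h = self.relu2.forward(h, training)
        h = self.conv2.forward(h, training)
        shortcut = x if self.project is None else self.project.forward(x, training)
        return h + shortcut

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.conv2.backward(grad)
        g = self.relu2.backward(g)
        g = self.bn2.backward(g)
        g = self.conv1.backward(g)
        g = self.relu1.backward(g)
        g = self.bn1.backward(g)
        if self.project is None:
            return g + grad
        return g + self.project.backward(grad)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


class Model:
    """Residual spectral gCNN mapping (B, n_padded, f) features to B scalars."""

    def __init__(self, config: ModelConfig, hierarchy: GraphHierarchy,
                 template_checksum: int = 0, dtype=np.float32):
        self.dtype = np.dtype(dtype)
        if hierarchy.num_levels < config.pool_levels:
            raise ConfigurationError(
                f"hierarchy has {hierarchy.num_levels} levels, model needs "
                f"{config.pool_levels}"
            )
        self.config = config
        self.hierarchy = hierarchy
        self.template_checksum = template_checksum
        rng = np.random.default_rng(config.seed)

        scaled = []
        for lv in hierarchy.levels:
            sc = scale_laplacian(lv.laplacian)
            sc.matrix = sc.matrix.astype(self.dtype)
            scaled.append(sc)
        ch = config.channels
        k = config.cheb_order
        self.pre_conv = ChebConv(scaled[0], config.input_features, ch[0], k, rng,
                                 "pre_conv", dtype=self.dtype)
        self.res_blocks: list[ResidualBlock] = []
        self.pools: list[MaxPool] = []
        for i in range(config.n_res_blocks):
            self.res_blocks.append(
                ResidualBlock(scaled[i], ch[i], ch[i + 1], k, rng, f"res{i + 1}",
                              dtype=self.dtype)
            )
            self.pools.append(MaxPool(hierarchy, i))
        self.post_block = ResidualBlock(
            scaled[config.pool_levels], ch[-2], ch[-1], k, rng, "post",
            dtype=self.dtype,
        )
        # pre-activation residual networks end with a final BN -> ReLU so the
        # head sees normalized activations
        self.final_bn = BatchNorm(ch[-1], "final_bn", dtype=self.dtype)
        self.final_relu = ReLU()
        n_coarse = hierarchy.levels[config.pool_levels].n_padded
        self.flat_dim = n_coarse * ch[-1]
        self.dropout = Dropout(config.dropout_rate, rng)
        self.fc = Dense(self.flat_dim, 1, rng, "fc", dtype=self.dtype)
        # mean-input subtraction buffer (training-fold mean feature map),
        # analogous to mean-image subtraction in classic CNN pipelines
        self.input_offset = np.zeros(
            (hierarchy.levels[0].n_padded, config.input_features), dtype=self.dtype
        )
        self.training = False

    # -- parameter access ---------------------------------------------------

    def _layers(self) -> list[_Layer]:
        out: list[_Layer] = [self.pre_conv]
        out.extend(self.res_blocks)
        out.append(self.post_block)
        out.append(self.final_bn)
        out.append(self.fc)
        return out

    def parameters(self) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {"input_offset": self.input_offset}
        for layer in self._layers():
            params.update(layer.parameters())
        return params

    def gradients(self) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        for layer in self._layers():
            grads.update(layer.gradients())
        return grads

    def weight_arrays(self) -> list[np.ndarray]:
        """Filter coefficients and FC weights: the l2-regularized set."""
        out: list[np.ndarray] = []
        for layer in self._layers():
            out.extend(layer.weight_arrays())
        return out

    def zero_grad(self) -> None:
        for g in self.gradients().values():
            g[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(params) != set(state):
            raise ValueError("parameter names do not match this model")
        for k, v in params.items():
            v[...] = state[k].astype(v.dtype)

    @property
    def last_conv(self) -> ChebConv:
        """The deepest convolution (saliency attaches here)."""
        return self.post_block.conv2

    def clear_caches(self) -> None:
        """Drop forward/backward activation caches (kept models stay light)."""
        def visit(layer):
            for attr in ("_basis", "last_output", "grad_output", "_cache",
                         "_mask", "_right_wins", "_x"):
                if hasattr(layer, attr):
                    setattr(layer, attr, None)
        for block in [self.pre_conv, *self.res_blocks, self.post_block]:
            if isinstance(block, ResidualBlock):
                for sub in block._sublayers():
                    visit(sub)
            else:
                visit(block)
        for layer in (*self.pools, self.final_bn, self.final_relu, self.dropout,
                      self.fc):
            visit(layer)

    # -- execution ----------------------------------------------------------

    def train_mode(self) -> None:
        self.training = True

    def eval_mode(self) -> None:
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Features (B, n_padded, f) -> predictions (B,)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        n0 = self.hierarchy.levels[0].n_padded
        if x.shape[1] != n0 or x.shape[2] != self.config.input_features:
            raise ValueError(
                f"expected (B, {n0}, {self.config.input_features}) features, "
                f"got {x.shape}"
            )
        # internal layout is (n, B, F): basis products become free-view BLAS
        h = np.ascontiguousarray((x - self.input_offset).transpose(1, 0, 2))
        h = self.pre_conv.forward(h, self.training)
        for block, pool in zip(self.res_blocks, self.pools):
            h = block.forward(h, self.training)
            h = pool.forward(h, self.training)
        h = self.post_block.forward(h, self.training)
        h = self.final_bn.forward(h, self.training)
        h = self.final_relu.forward(h, self.training)
        self._post_shape = h.shape
        h = np.ascontiguousarray(h.transpose(1, 0, 2)).reshape(h.shape[1], -1)
        h = self.dropout.forward(h, self.training)
        y = self.fc.forward(h, self.training)
        return y[:, 0]

    def backward(self, d_pred: np.ndarray) -> None:
        """Backpropagate d(loss)/d(prediction) through the cached forward pass."""
        g = np.asarray(d_pred, dtype=self.dtype)[:, None]
        g = self.fc.backward(g)
        g = self.dropout.backward(g)
        n_c, b, f_c = self._post_shape
        g = np.ascontiguousarray(g.reshape(b, n_c, f_c).transpose(1, 0, 2))
        g = self.final_relu.backward(g)
        g = self.final_bn.backward(g)
        g = self.post_block.backward(g)
        for block, pool in zip(reversed(self.res_blocks), reversed(self.pools)):
            g = pool.backward(g)
            g = block.backward(g)
        self.pre_conv.backward(g)


def build_model(config: ModelConfig, hierarchy: GraphHierarchy,
                template_checksum: int = 0, dtype=np.float32) -> Model:
    """Construct the network with seeded parameter initialization.

    ``dtype`` is the compute precision; single precision roughly halves
    memory traffic and is the training default.
    """
    return Model(config, hierarchy, template_checksum, dtype=dtype)


def forward(model: Model, batch: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`Model.forward`."""
    return model.forward(batch)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_model(model: Model, path) -> None:
    """Serialize parameters + config + template checksum to one archive."""
    state = model.state_dict()
    blob = {
        "config": model.config,
        "template_checksum": model.template_checksum,
        "state": state,
        "dtype": model.dtype,
    }
    with open(path, "wb") as fh:
        pickle.dump(blob, fh)


def load_model(path, hierarchy: GraphHierarchy) -> Model:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    model = Model(blob["config"], hierarchy, blob["template_checksum"],
                  dtype=blob.get("dtype", np.float32))
    model.load_state_dict(blob["state"])
    return model
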