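"""The pre-segmentation network: a UNet++ whose encoder embeds ODE blocks.

The network maps a standardized RGB blood-smear image to a per-pixel white
blood cell probability map.  Its encoder column extracts features with
convolutional blocks followed by continuous-depth (neural ODE) blocks; the
nested decoder re-processes skip features through intermediate nodes (dense
skip pathways), and, with deep supervision on, every top-row node carries a
1x1 convolution + sigmoid head trained with binary cross-entropy.

A residual block ``g + F(g)`` is the one-step Euler discretization of the
ODE block ``dg/dt = F(g, t)`` integrated over a unit time span; both forms
are provided and are exactly interchangeable at a single unit Euler step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import layers as L
from .nn import tensor as T
from .nn.tensor import Tensor
from .ode import SolverConfig, solve_ode

__all__ = [
    "ModelConfig", "ConvDynamics", "ResidualBlock", "OdeBlock",
    "UNetPlusPlus", "build_model", "predict", "sigmoid", "bce_loss",
    "save_checkpoint", "load_checkpoint",
]

BCE_EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of encoder levels (channel count doubles per
    level from ``base_channels``); each encoder level applies
    ``ode_blocks_per_level`` continuous-depth blocks after an entry
    convolution that sets the level's channel count (the ODE dynamics must
    preserve shape, so channel changes happen outside the block).
    """

    depth: int = 4
    base_channels: int = 16
    ode_blocks_per_level: int = 1
    deep_supervision: bool = True
    solver: SolverConfig = field(default_factory=SolverConfig)
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be at least 4")
        if self.ode_blocks_per_level < 1:
            raise ValueError("ode_blocks_per_level must be at least 1")


def sigmoid(u):
    """Logistic function 1 / (1 + e^{-u}); saturates without overflow."""
    if isinstance(u, Tensor):
        return T.sigmoid(u)
    arr = np.asarray(u, dtype=np.float64)
    out = T._sigmoid_np(arr)
    return float(out) if np.isscalar(u) or arr.ndim == 0 else out


def bce_loss(prob_map, mask):
    """Mean binary cross-entropy over all pixels.

    Probabilities are clipped to [eps, 1-eps] before the logs.  Accepts
    numpy arrays (returns a float) or autodiff tensors (returns a scalar
    tensor on the tape).
    """
    if isinstance(prob_map, Tensor):
        if prob_map.shape != np.shape(mask.data if isinstance(mask, Tensor) else mask):
            raise ValueError("probability map and mask shapes differ")
        xi = mask if isinstance(mask, Tensor) else Tensor(np.asarray(mask, dtype=np.float64))
        # the clip bound must stay strictly inside (0, 1) at this precision
        eps = max(BCE_EPS, float(np.finfo(prob_map.data.dtype).eps))
        p = T.clip(prob_map, eps, 1.0 - eps)
        term = xi * T.log(p) + (1.0 - xi) * T.log(1.0 - p)
        return -1.0 * T.mean(term)
    p = np.asarray(prob_map, dtype=np.float64)
    xi = np.asarray(mask, dtype=np.float64)
    if p.shape != xi.shape:
        raise ValueError("probability map and mask shapes differ")
    p = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(xi * np.log(p) + (1.0 - xi) * np.log(1.0 - p)))


class ConvDynamics(L.Module):
    """The parameterized vector field F(g, t): conv -> norm -> ReLU -> conv.

    The closing convolution is zero-initialized so a fresh block starts as
    the identity map (its Euler step leaves the state unchanged), which
    keeps early training stable.  The field is autonomous: t is accepted
    for the solver contract but does not enter the computation.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = L.Conv2d(channels, channels, 3, rng)
        self.norm = L.GroupNorm(channels)
        self.conv2 = L.Conv2d(channels, channels, 3, rng, zero_init=True)

    def forward(self, g: Tensor, t: float = 0.0) -> Tensor:
        out = self.conv2(T.relu(self.norm(self.conv1(g))))
        if out.shape != g.shape:
            raise ValueError("dynamics output shape differs from state shape")
        return out


class ResidualBlock(L.Module):
    """g_{t+1} = g_t + F(g_t): the discrete (one Euler step) form."""

    def __init__(self, dynamics: ConvDynamics):
        self.dynamics = dynamics

    def forward(self, g: Tensor) -> Tensor:
        return g + self.dynamics(g)


class OdeBlock(L.Module):
    """Continuous-depth form: integrate dg/dt = F(g, t) over the span."""

    def __init__(self, dynamics: ConvDynamics, solver: SolverConfig):
        self.dynamics = dynamics
        self.solver = solver

    def forward(self, g: Tensor) -> Tensor:
        return solve_ode(g, self.dynamics.forward, self.solver)


class _EncoderLevel(L.Module):
    def __init__(self, in_ch: int, out_ch: int, n_blocks: int,
                 solver: SolverConfig, rng: np.random.Generator):
        self.entry = L.ConvBlock(in_ch, out_ch, rng)
        self.blocks = [OdeBlock(ConvDynamics(out_ch, rng), solver)
                       for _ in range(n_blocks)]

    def forward(self, x: Tensor) -> Tensor:
        x = self.entry(x)
        for block in self.blocks:
            x = block(x)
        return x


class _Up(L.Module):
    """Bilinear 2x upsampling followed by a 1x1 channel projection."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.proj = L.Conv2d(in_ch, out_ch, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(T.upsample_bilinear2(x))


class UNetPlusPlus(L.Module):
    """Nested encoder-decoder with dense skip pathways and ODE encoder blocks.

    Nodes are indexed X[i][j]: i is the resolution level (0 = full), j the
    nesting depth along the skip pathway.  X[i][0] is the encoder column;
    X[i][j] (j >= 1) receives the concatenation of X[i][0..j-1] with the
    upsampled X[i+1][j-1].  Heads sit on the top-row nodes X[0][1..depth-1].
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.depth
        ch = [config.base_channels * 2 ** i for i in range(d)]

        self.encoders = [
            _EncoderLevel(3 if i == 0 else ch[i - 1], ch[i],
                          config.ode_blocks_per_level, config.solver, rng)
            for i in range(d)
        ]
        # decoder node (i, j) and its upsampling projection, flattened
        self.ups = []
        self.nodes = []
        self._grid: dict[tuple[int, int], tuple[int, int]] = {}
        for j in range(1, d):
            for i in range(d - j):
                self._grid[(i, j)] = (len(self.ups), len(self.nodes))
                self.ups.append(_Up(ch[i + 1], ch[i], rng))
                self.nodes.append(L.ConvBlock((j + 1) * ch[i], ch[i], rng))
        # deep-supervision heads are zero-initialized 1x1 convolutions, so an
        # untrained model predicts probability 0.5 everywhere
        n_heads = d - 1 if config.deep_supervision else 1
        self.heads = [L.Conv2d(ch[0], 1, 1, rng, zero_init=True)
                      for _ in range(n_heads)]

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return the sigmoid output of every supervision head."""
        _validate_input(x, self.config.depth)
        d = self.config.depth
        grid: dict[tuple[int, int], Tensor] = {}
        cur = x
        for i in range(d):
            cur = self.encoders[i](cur if i == 0 else T.max_pool2(grid[(i - 1, 0)]))
            grid[(i, 0)] = cur
        for j in range(1, d):
            for i in range(d - j):
                ui, ni = self._grid[(i, j)]
                up = self.ups[ui](grid[(i + 1, j - 1)])
                cat = T.concat([grid[(i, jj)] for jj in range(j)] + [up], axis=1)
                grid[(i, j)] = self.nodes[ni](cat)
        if self.config.deep_supervision:
            tops = [grid[(0, j)] for j in range(1, d)]
        else:
            tops = [grid[(0, d - 1)]]
        return [T.sigmoid(head(t)) for head, t in zip(self.heads, tops)]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _validate_input(x: Tensor, depth: int) -> None:
    if x.ndim != 4 or x.shape[1] != 3:
        raise ValueError("model input must have shape (N, 3, H, W)")
    h, w = x.shape[2], x.shape[3]
    div = 2 ** (depth - 1)
    if h % div or w % div:
        raise ValueError(
            f"spatial size {h}x{w} must be divisible by {div} at depth {depth}")


def build_model(config: ModelConfig) -> UNetPlusPlus:
    """Construct the network; raises ValueError on an invalid config."""
    return UNetPlusPlus(config)


def normalize_image(pixels: np.ndarray, dtype=np.float64) -> np.ndarray:
    """Map uint8 HxWx3 pixels to a centered float (1, 3, H, W) array."""
    arr = np.asarray(pixels, dtype=dtype)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    return (arr / 255.0 - 0.5).transpose(2, 0, 1)[None]


def predict(model: UNetPlusPlus, image) -> np.ndarray:
    """Forward pass returning the HxW probability map in [0, 1].

    With deep supervision the final map is the mean of all head outputs.
    Accepts a SmearImage-like object with a ``pixels`` attribute or an
    HxWx3 uint8 array.
    """
    pixels = getattr(image, "pixels", image)
    dtype = model.heads[0].weight.data.dtype  # match the model's precision
    x = Tensor(normalize_image(pixels, dtype=dtype))
    with T.no_grad():
        heads = model(x)
        out = np.mean([h.data for h in heads], axis=0)
    return out[0, 0]


def save_checkpoint(model: UNetPlusPlus, path) -> None:
    """Serialize weights + architecture config to a single .npz file."""
    import json

    cfg = model.config
    meta = dict(depth=cfg.depth, base_channels=cfg.base_channels,
                ode_blocks_per_level=cfg.ode_blocks_per_level,
                deep_supervision=cfg.deep_supervision, seed=cfg.seed,
                solver=dict(method=cfg.solver.method, step=cfg.solver.step,
                            tolerance=cfg.solver.tolerance,
                            t_span=list(cfg.solver.t_span)))
    np.savez(path, __config__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path) -> UNetPlusPlus:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    solver = SolverConfig(method=meta["solver"]["method"],
                          step=meta["solver"]["step"],
                          tolerance=meta["solver"]["tolerance"],
                          t_span=tuple(meta["solver"]["t_span"]))
    cfg = ModelConfig(depth=meta["depth"], base_channels=meta["base_channels"],
                      ode_blocks_per_level=meta["ode_blocks_per_level"],
                      deep_supervision=meta["deep_supervision"],
                      solver=solver, seed=meta["seed"])
    model = UNetPlusPlus(cfg)
    model.load_state_dict(state)
    return model
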