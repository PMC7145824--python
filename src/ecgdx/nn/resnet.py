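"""Unidimensional residual network for multi-label ECG classification.

Topology: an initial convolution (kernel 16, 64 filters) followed by
four pre-activation residual blocks with two convolutions each.  Every
block subsamples the temporal axis by 4 (carried by its second
convolution) and the filter count grows by 64 every second block
(64, 64, 128, 128 by default; the schedule is configurable because the
growth rule admits more than one reading).  Skip connections use max
pooling for the temporal reduction and a kernel-1 convolution when the
filter count changes.  The head flattens the final 16 x 128 feature map
into a dense layer with one sigmoid output per class — sigmoids rather
than a softmax because the abnormalities are not mutually exclusive.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from ecgdx.nn.layers import (
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    Layer,
    MaxPool1d,
    Param,
    ReLU,
    sigmoid,
)


class ConfigurationError(ValueError):
    pass


class ShapeError(ValueError):
    pass


@dataclass
class ModelConfig:
    input_len: int = 4096
    n_leads: int = 12
    n_classes: int = 6
    n_residual_blocks: int = 4
    convs_per_block: int = 2
    kernel_len: int = 16
    initial_filters: int = 64
    filter_increment: int = 64
    increment_every: int = 2  # blocks between filter increases
    subsample_per_block: int = 4
    dropout_rate: float = 0.8
    seed: int = 0
    filter_schedule: Optional[tuple[int, ...]] = None  # overrides the rule above

    def __post_init__(self) -> None:
        for name in (
            "input_len", "n_leads", "n_classes", "n_residual_blocks",
            "convs_per_block", "kernel_len", "initial_filters",
            "subsample_per_block",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.input_len % self.subsample_per_block**self.n_residual_blocks:
            raise ConfigurationError(
                f"input_len {self.input_len} not divisible by "
                f"{self.subsample_per_block}^{self.n_residual_blocks}"
            )

    @property
    def filters(self) -> tuple[int, ...]:
        """Per-block filter counts."""
        if self.filter_schedule is not None:
            if len(self.filter_schedule) != self.n_residual_blocks:
                raise ConfigurationError("filter_schedule length != n_residual_blocks")
            return tuple(self.filter_schedule)
        return tuple(
            self.initial_filters + self.filter_increment * (i // self.increment_every)
            for i in range(self.n_residual_blocks)
        )

    @property
    def final_len(self) -> int:
        return self.input_len // self.subsample_per_block**self.n_residual_blocks


class ResidualBlock:
    """Pre-activation block: (BN - ReLU - Dropout - Conv) x 2 plus a
    max-pooled (and, when widths differ, 1x1-convolved) skip path."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        cfg: ModelConfig,
        rng: np.random.Generator,
        drop_rng: np.random.Generator,
        name: str,
    ) -> None:
        k, sub = cfg.kernel_len, cfg.subsample_per_block
        self.main: list[Layer] = []
        c = c_in
        for j in range(cfg.convs_per_block):
            stride = sub if j == cfg.convs_per_block - 1 else 1
            self.main += [
                BatchNorm1d(c, name=f"{name}.bn{j}"),
                ReLU(),
                Dropout(cfg.dropout_rate, drop_rng),
                Conv1d(c, c_out, k, stride=stride, rng=rng, name=f"{name}.conv{j}"),
            ]
            c = c_out
        self.pool = MaxPool1d(sub)
        self.proj = (
            Conv1d(c_in, c_out, 1, rng=rng, name=f"{name}.proj") if c_in != c_out else None
        )
        self.name, self.c_out = name, c_out

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.main:
            out += layer.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x
        for layer in self.main:
            h = layer.forward(h, training)
        s = self.pool.forward(x, training)
        if self.proj is not None:
            s = self.proj.forward(s, training)
        return h + s

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gs = grad
        if self.proj is not None:
            gs = self.proj.backward(gs)
        gs = self.pool.backward(gs)
        gh = grad
        for layer in reversed(self.main):
            gh = layer.backward(gh)
        return gh + gs


class ResNet1d:
    """The assembled network; build via :func:`build_network`."""

    def __init__(self, cfg: ModelConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        # Dropout noise is drawn from a separate stream so that weight
        # initialization is independent of how many batches were seen.
        self.drop_rng = np.random.default_rng((cfg.seed, 0xD0))
        f = cfg.filters
        self.conv0 = Conv1d(cfg.n_leads, cfg.initial_filters, cfg.kernel_len, rng=rng, name="conv0")
        self.bn0 = BatchNorm1d(cfg.initial_filters, name="bn0")
        self.relu0 = ReLU()
        self.blocks: list[ResidualBlock] = []
        c = cfg.initial_filters
        for i in range(cfg.n_residual_blocks):
            self.blocks.append(
                ResidualBlock(c, f[i], cfg, rng, self.drop_rng, name=f"block{i + 1}")
            )
            c = f[i]
        self.head = Dense(cfg.final_len * c, cfg.n_classes, rng=rng, name="head")
        self._flat_shape: tuple[int, ...] | None = None

    # -- parameter plumbing ------------------------------------------------
    def params(self) -> list[Param]:
        out = self.conv0.params() + self.bn0.params()
        for blk in self.blocks:
            out += blk.params()
        return out + self.head.params()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def bn_layers(self) -> list[BatchNorm1d]:
        out = [self.bn0]
        for blk in self.blocks:
            out += [layer for layer in blk.main if isinstance(layer, BatchNorm1d)]
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, bn in enumerate(self.bn_layers()):
            state[f"_running_mean{i}"] = bn.running_mean.copy()
            state[f"_running_var{i}"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for i, bn in enumerate(self.bn_layers()):
            bn.running_mean[...] = state[f"_running_mean{i}"]
            bn.running_var[...] = state[f"_running_var{i}"]

    # -- forward / backward ------------------------------------------------
    def _check_input(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float32)
        expected = (self.cfg.input_len, self.cfg.n_leads)
        if batch.ndim != 3 or batch.shape[1:] != expected:
            raise ShapeError(
                f"expected batch of shape (n, {expected[0]}, {expected[1]}), "
                f"got {batch.shape}"
            )
        return batch  # channels-last (n, samples, leads) end to end

    def forward(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        """Probabilities, one sigmoid output per class."""
        h = self._check_input(batch)
        h = self.relu0.forward(self.bn0.forward(self.conv0.forward(h, training), training), training)
        for blk in self.blocks:
            h = blk.forward(h, training)
        self._flat_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        z = self.head.forward(flat, training)
        return sigmoid(z)

    def backward(self, dz: np.ndarray) -> None:
        """Backpropagate from the pre-sigmoid gradient ``dz``."""
        assert self._flat_shape is not None
        g = self.head.backward(dz.astype(np.float32))
        g = g.reshape(self._flat_shape)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        g = self.conv0.backward(self.bn0.backward(self.relu0.backward(g)))

    # -- introspection -----------------------------------------------------
    def describe(self) -> dict:
        """Layer-by-layer shape/parameter report."""
        cfg = self.cfg
        rows = []
        length = cfg.input_len
        rows.append(
            {
                "layer": "conv0",
                "output_len": length,
                "filters": cfg.initial_filters,
                "n_params": int(sum(p.value.size for p in self.conv0.params() + self.bn0.params())),
            }
        )
        for i, blk in enumerate(self.blocks):
            length //= cfg.subsample_per_block
            rows.append(
                {
                    "layer": f"block{i + 1}",
                    "output_len": length,
                    "filters": blk.c_out,
                    "n_params": int(sum(p.value.size for p in blk.params())),
                }
            )
        rows.append(
            {
                "layer": "dense",
                "output_len": 1,
                "filters": cfg.n_classes,
                "n_params": int(sum(p.value.size for p in self.head.params())),
            }
        )
        return {"layers": rows, "total_params": self.n_parameters()}


def build_network(cfg: ModelConfig) -> ResNet1d:
    """Build (deterministically, from ``cfg.seed``) an untrained network."""
    return ResNet1d(cfg)


def save_checkpoint(path: str, net: ResNet1d) -> None:
    state = net.state_dict()
    state["_config_json"] = np.frombuffer(
        json.dumps(asdict(net.cfg)).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **state)


def load_checkpoint(path: str) -> ResNet1d:
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    cfg_dict = json.loads(bytes(data["_config_json"]).decode())
    if cfg_dict.get("filter_schedule") is not None:
        cfg_dict["filter_schedule"] = tuple(cfg_dict["filter_schedule"])
    cfg = ModelConfig(**cfg_dict)
    net = ResNet1d(cfg)
    net.load_state_dict({k: data[k] for k in data.files if k != "_config_json"})
    return net
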