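"""Convolutional autoencoder for normalized axial DWI slices.

Architecture
------------
Encoder: four blocks, each two 3x3 convolutions -> batch norm -> ELU,
followed by 2x2 average pooling; block widths double from 32
(32, 64, 128, 256). Two further 3x3 convolution layers (512 channels each,
BN + ELU) feed a linear 3x3 projection onto the latent space: a 32-channel
feature map at 1/16 of the input resolution. The decoder mirrors the
encoder — 2x nearest-neighbour upsampling before each block, halving widths
(256, 128, 64, 32) — and ends in a 1x1 convolution with a sigmoid, so
outputs live in (0, 1).

The latent code is a spatial multi-channel array; convex combinations of
two slices' codes, decoded, synthesize the slices in between (see
:mod:`aeslice.superres`).

Training minimizes the reconstruction mean squared error with Adam
(beta1 = 0.5, beta2 = 0.999), batch size 32, learning rate 5e-5 in the
reference configuration; the checkpoint with minimal validation loss is
selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn


@dataclass
class AEConfig:
    """Hyperparameters of the autoencoder.

    The defaults are the reference configuration for 128x128 slices.
    Scaled-down experiments shrink ``input_size`` and the channel widths
    but keep the same topology.
    """

    input_size: Tuple[int, int] = (128, 128)
    block_channels: Tuple[int, ...] = (32, 64, 128, 256)
    tail_channels: Tuple[int, ...] = (512, 512)
    latent_channels: int = 32
    learning_rate: float = 5e-5
    batch_size: int = 32
    epochs: int = 200
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    val_fraction: float = 0.15
    bn_momentum: float = 0.9
    #: epochs at which the learning rate is multiplied by lr_decay_factor;
    #: empty in the reference protocol (constant rate), used by short
    #: scaled-down runs to stabilize late training
    lr_decay_at: Tuple[int, ...] = ()
    lr_decay_factor: float = 0.3
    #: random in-plane flips during training (off in the reference
    #: protocol; small phantom corpora use it to enlarge slice variety)
    augment_flips: bool = False
    seed: int = 0

    def __post_init__(self):
        pool = 2 ** len(self.block_channels)
        if self.input_size[0] % pool or self.input_size[1] % pool:
            raise ValueError(
                f"input size {self.input_size} not divisible by the total "
                f"pooling factor {pool}"
            )

    @property
    def latent_shape(self) -> Tuple[int, int, int]:
        pool = 2 ** len(self.block_channels)
        return (self.latent_channels, self.input_size[0] // pool,
                self.input_size[1] // pool)


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)

    @property
    def selected_epoch(self) -> int:
        return int(np.argmin(self.val_loss))


class ConvAutoencoder:
    """The slice autoencoder; see the module docstring for the topology."""

    def __init__(self, cfg: AEConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        enc: List[nn.Layer] = []
        cin = 1
        for w in cfg.block_channels:
            for c in (w, w):
                enc += [nn.Conv2d(cin, c, 3, rng=rng),
                        nn.BatchNorm2d(c, momentum=cfg.bn_momentum), nn.ELU()]
                cin = c
            enc.append(nn.AvgPool2())
        for t in cfg.tail_channels:
            enc += [nn.Conv2d(cin, t, 3, rng=rng),
                    nn.BatchNorm2d(t, momentum=cfg.bn_momentum), nn.ELU()]
            cin = t
        enc.append(nn.Conv2d(cin, cfg.latent_channels, 3, rng=rng))
        self.encoder = nn.Sequential(enc)

        dec: List[nn.Layer] = []
        cin = cfg.latent_channels
        for w in reversed(cfg.block_channels):
            dec.append(nn.NearestUpsample2())
            for c in (w, w):
                dec += [nn.Conv2d(cin, c, 3, rng=rng),
                        nn.BatchNorm2d(c, momentum=cfg.bn_momentum), nn.ELU()]
                cin = c
        dec += [nn.Conv2d(cin, 1, 1, rng=rng), nn.Sigmoid()]
        self.decoder = nn.Sequential(dec)
        self.set_train(False)

    # ---- parameter accounting -------------------------------------------
    def parameter_count(self) -> dict:
        """Parameter counts: trainable, BN moving statistics, and total.

        ``total`` follows the deep-learning-framework summary convention
        (trainable weights/biases/BN scale-shift plus BN moving statistics).
        """
        trainable = sum(p.size for p in self.params())
        stats = sum(a.size for a in self.encoder.state_arrays()
                    + self.decoder.state_arrays())
        return {"trainable": trainable, "bn_statistics": stats,
                "total": trainable + stats}

    def params(self) -> List[nn.Param]:
        return self.encoder.params() + self.decoder.params()

    def set_train(self, mode: bool):
        self.encoder.set_train(mode)
        self.decoder.set_train(mode)

    # ---- inference -------------------------------------------------------
    def encode(self, sl: np.ndarray) -> np.ndarray:
        """Latent code (C, h, w) of one normalized 2D slice."""
        z = self.encode_batch(sl[None])
        return z[0]

    def encode_batch(self, slices: np.ndarray) -> np.ndarray:
        self._check_input(slices)
        self.set_train(False)
        return self.encoder.forward(
            np.asarray(slices, dtype=np.float32)[:, None])

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode one latent code back to a 2D slice in (0, 1)."""
        return self.decode_batch(z[None])[0]

    def decode_batch(self, zs: np.ndarray) -> np.ndarray:
        want = self.cfg.latent_shape
        if tuple(zs.shape[1:]) != want:
            raise ValueError(f"latent shape {zs.shape[1:]} != expected {want}")
        self.set_train(False)
        return self.decoder.forward(np.asarray(zs, dtype=np.float32))[:, 0]

    def reconstruct_batch(self, slices: np.ndarray) -> np.ndarray:
        return self.decode_batch(self.encode_batch(slices))

    def _check_input(self, slices: np.ndarray):
        if tuple(slices.shape[-2:]) != tuple(self.cfg.input_size):
            raise ValueError(
                f"slice shape {slices.shape[-2:]} != configured input size "
                f"{self.cfg.input_size}"
            )

    # ---- training --------------------------------------------------------
    def _loss_eval(self, slices: np.ndarray, batch: int) -> float:
        self.set_train(False)
        tot, n = 0.0, 0
        for s in range(0, len(slices), batch):
            x = slices[s:s + batch][:, None]
            y = self.decoder.forward(self.encoder.forward(x))
            tot += float(np.sum((y - x) ** 2))
            n += x.size
        return tot / n

    def train(self, slices: np.ndarray,
              val_slices: Optional[np.ndarray] = None,
              verbose: bool = False) -> TrainingHistory:
        """Train on an (n, H, W) slice set; returns the loss history.

        If ``val_slices`` is None, the trailing ``val_fraction`` of the
        (pre-shuffled, seeded) slice set is held out. The parameters of the
        epoch with minimal validation loss are restored before returning.
        """
        cfg = self.cfg
        slices = np.asarray(slices, dtype=np.float32)
        self._check_input(slices)
        if len(slices) < 2:
            raise ValueError("need at least 2 slices to train")
        rng = np.random.default_rng(cfg.seed + 1)
        if val_slices is None:
            perm = rng.permutation(len(slices))
            n_val = max(1, int(round(cfg.val_fraction * len(slices))))
            val_slices = slices[perm[len(slices) - n_val:]]
            slices = slices[perm[: len(slices) - n_val]]
        opt = nn.Adam(self.params(), lr=cfg.learning_rate,
                      beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
        hist = TrainingHistory()
        best = None
        for epoch in range(cfg.epochs):
            if epoch in cfg.lr_decay_at:
                opt.lr *= cfg.lr_decay_factor
            self.set_train(True)
            order = rng.permutation(len(slices))
            tot, nvox = 0.0, 0
            for s in range(0, len(slices), cfg.batch_size):
                x = slices[order[s:s + cfg.batch_size]][:, None]
                if cfg.augment_flips:
                    flips = rng.integers(0, 2, size=3)
                    if flips[0]:
                        x = x[:, :, ::-1, :]
                    if flips[1]:
                        x = x[:, :, :, ::-1]
                    if flips[2] and x.shape[2] == x.shape[3]:
                        x = x.transpose(0, 1, 3, 2)
                    x = np.ascontiguousarray(x)
                z = self.encoder.forward(x)
                y = self.decoder.forward(z)
                loss, dy = nn.mse_loss(y, x)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss}"
                    )
                opt.zero_grad()
                self.encoder.backward(self.decoder.backward(dy))
                opt.step()
                tot += loss * x.size
                nvox += x.size
            hist.train_loss.append(tot / nvox)
            hist.val_loss.append(self._loss_eval(val_slices, cfg.batch_size))
            if best is None or hist.val_loss[-1] < best[0]:
                best = (hist.val_loss[-1], self._snapshot())
            if verbose:
                print(f"epoch {epoch:3d}  train {hist.train_loss[-1]:.3e}  "
                      f"val {hist.val_loss[-1]:.3e}")
        self._restore(best[1])
        return hist

    def _snapshot(self):
        return ([p.data.copy() for p in self.params()],
                [a.copy() for a in self.encoder.state_arrays()
                 + self.decoder.state_arrays()])

    def _restore(self, snap):
        pdata, sdata = snap
        for p, d in zip(self.params(), pdata):
            p.data[...] = d
        for a, d in zip(self.encoder.state_arrays()
                        + self.decoder.state_arrays(), sdata):
            a[...] = d

    # ---- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Save weights as .npz with a JSON sidecar describing the config."""
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        arrays.update({f"s{i}": a for i, a in enumerate(
            self.encoder.state_arrays() + self.decoder.state_arrays())})
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {"config": asdict(self.cfg),
                   "parameter_count": self.parameter_count()}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "ConvAutoencoder":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfgd = sidecar["config"]
        for key in ("input_size", "block_channels", "tail_channels",
                    "lr_decay_at"):
            cfgd[key] = tuple(cfgd[key])
        model = cls(AEConfig(**cfgd))
        with np.load(path.with_suffix(".npz")) as f:
            for i, p in enumerate(model.params()):
                p.data[...] = f[f"p{i}"]
            states = model.encoder.state_arrays() + model.decoder.state_arrays()
            for i, a in enumerate(states):
                a[...] = f[f"s{i}"]
        return model


def build_model(cfg: Optional[AEConfig] = None) -> Tuple[ConvAutoencoder, int]:
    """Build the autoencoder; returns (model, total parameter count)."""
    model = ConvAutoencoder(cfg or AEConfig())
    return model, model.parameter_count()["total"]
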