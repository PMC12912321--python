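"""The multi-channel masked autoencoder (MCMA) network.

A 1-D convolutional encoder-decoder mapping a masked 12 x 1024 frame to a
full 12 x 1024 reconstruction.  The encoder stacks ``depth`` MCBlocks, each
halving the temporal length via a strided convolution; the decoder mirrors
them with MCTBlocks built on transposed convolutions; encoder activations are
fused into the matching decoder level through skip connections.  Each block
has two branches: a convolutional branch (conv -> layer norm -> GELU ->
conv -> instance norm) and a pointwise projection branch, summed and passed
through a final GELU, in the spirit of residual blocks.

Everything here - layers, forward passes and the hand-written backward
passes used by :mod:`mcma.training` - is implemented directly on NumPy.
Convolutions are evaluated as im2col + GEMM with an exact adjoint for the
transposed convolution, so gradients are exact (verified against finite
differences in the test suite).  Internally activations are channels-last
``(batch, length, channels)``; the public surface is channels-first
``(batch, 12, 1024)`` to match the ECG window layout.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import as_strided

CHECKPOINT_FORMAT = "mcma-checkpoint-1"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The kernel size 5 / stride 2 / GELU / LN+IN combination is the published
    recipe; channel widths are configurable because the source architecture
    figure does not enumerate them.
    """

    kernel_size: int = 5
    stride: int = 2
    depth: int = 5
    channel_widths: tuple = (32, 64, 128, 256, 512)
    activation: str = "gelu"
    norms: tuple = (True, True)  # (layer norm, instance norm)
    skips: str = "add"
    seed: int = 0
    in_channels: int = 12
    out_channels: int = 12
    seq_len: int = 1024
    dtype: str = "float32"

    def __post_init__(self):
        self.channel_widths = tuple(int(w) for w in self.channel_widths)
        if self.depth != len(self.channel_widths):
            raise ValueError("depth must equal len(channel_widths)")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.seq_len % (self.stride ** self.depth) != 0:
            raise ValueError(
                f"seq_len {self.seq_len} must be divisible by stride^depth "
                f"= {self.stride ** self.depth}")
        if self.activation != "gelu":
            raise ValueError("only the GELU activation is supported")
        if self.skips not in ("add", "concat"):
            raise ValueError("skips must be 'add' or 'concat'")
        if len(self.norms) != 2:
            raise ValueError("norms must be a (layer_norm, instance_norm) pair")
        self.norms = (bool(self.norms[0]), bool(self.norms[1]))

    def to_dict(self) -> dict:
        return {
            "kernel_size": self.kernel_size, "stride": self.stride,
            "depth": self.depth, "channel_widths": list(self.channel_widths),
            "activation": self.activation, "norms": list(self.norms),
            "skips": self.skips, "seed": self.seed,
            "in_channels": self.in_channels, "out_channels": self.out_channels,
            "seq_len": self.seq_len, "dtype": self.dtype,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["channel_widths"] = tuple(d["channel_widths"])
        d["norms"] = tuple(d["norms"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Layers (channels-last, explicit forward/backward)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Extract sliding windows from padded input ``(B, Lp, C)``.

    Returns ``(B, L_out, k, C)`` as a contiguous array.
    """
    b, lp, c = xp.shape
    l_out = (lp - k) // stride + 1
    s0, s1, s2 = xp.strides
    view = as_strided(xp, (b, l_out, k, c), (s0, stride * s1, s1, s2))
    return np.ascontiguousarray(view)


class Conv1d:
    """1-D convolution, weight layout ``(k * c_in, c_out)``."""

    def __init__(self, c_in, c_out, k, stride, rng, dtype):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = k // 2
        scale = np.sqrt(2.0 / (k * c_in))
        self.W = (rng.standard_normal((k * c_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        b, l, c = x.shape
        if self.pad:
            xp = np.zeros((b, l + 2 * self.pad, c), dtype=x.dtype)
            xp[:, self.pad:self.pad + l] = x
        else:
            xp = x
        if self.stride == 1:
            # tap-loop of batched GEMMs on contiguous slices (no im2col copy)
            lo = l + 2 * self.pad - self.k + 1
            y = np.matmul(xp[:, 0:lo], self.W[0:c])
            for j in range(1, self.k):
                y += np.matmul(xp[:, j:j + lo], self.W[j * c:(j + 1) * c])
            y += self.b
            self._cache = (xp, b, l, lo)
            return y
        cols = _im2col(xp, self.k, self.stride)            # (B, Lo, k, C)
        lo = cols.shape[1]
        cols2 = cols.reshape(b * lo, self.k * c)
        y = cols2 @ self.W + self.b
        self._cache = (cols2, b, l, lo)
        return y.reshape(b, lo, self.c_out)

    def backward(self, dy):
        if self.stride == 1:
            xp, b, l, lo = self._cache
            c = self.c_in
            self.db[...] = dy.sum(axis=(0, 1))
            dW = np.empty_like(self.W)
            lp = l + 2 * self.pad
            dxp = np.zeros((b, lp, c), dtype=dy.dtype)
            for j in range(self.k):
                xv = xp[:, j:j + lo]
                dW[j * c:(j + 1) * c] = np.matmul(
                    xv.transpose(0, 2, 1), dy).sum(axis=0)
                dxp[:, j:j + lo] += np.matmul(dy, self.W[j * c:(j + 1) * c].T)
            self.dW[...] = dW
            return dxp[:, self.pad:self.pad + l] if self.pad else dxp
        cols2, b, l, lo = self._cache
        dy2 = dy.reshape(b * lo, self.c_out)
        self.dW[...] = cols2.T @ dy2
        self.db[...] = dy2.sum(axis=0)
        dcols = (dy2 @ self.W.T).reshape(b, lo, self.k, self.c_in)
        lp = l + 2 * self.pad
        dxp = np.zeros((b, lp, self.c_in), dtype=dy.dtype)
        for j in range(self.k):
            dxp[:, j:j + self.stride * lo:self.stride] += dcols[:, :, j]
        return dxp[:, self.pad:self.pad + l] if self.pad else dxp


class ConvTranspose1d:
    """Transposed 1-D convolution, the exact adjoint of :class:`Conv1d`.

    Weight layout ``(c_in, k * c_out)``; ``output_padding`` extends the tail
    so that stride-2 levels exactly double the temporal length.
    """

    def __init__(self, c_in, c_out, k, stride, rng, dtype, output_padding=None):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = k // 2
        self.outpad = (stride - 1) if output_padding is None else output_padding
        scale = np.sqrt(2.0 / (k * c_in))
        self.W = (rng.standard_normal((c_in, k * c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def out_len(self, l_in):
        return (l_in - 1) * self.stride + self.k - 2 * self.pad + self.outpad

    def forward(self, x):
        b, l, c = x.shape
        x2 = x.reshape(b * l, c)
        cols = (x2 @ self.W).reshape(b, l, self.k, self.c_out)
        lp = (l - 1) * self.stride + self.k
        end = lp - self.pad + self.outpad
        yp = np.zeros((b, max(lp, end), self.c_out), dtype=x.dtype)
        for j in range(self.k):
            yp[:, j:j + self.stride * l:self.stride] += cols[:, :, j]
        y = yp[:, self.pad:end] + self.b
        self._cache = (x2, b, l, lp, end)
        return y

    def backward(self, dy):
        x2, b, l, lp, end = self._cache
        self.db[...] = dy.sum(axis=(0, 1))
        dyp = np.zeros((b, max(lp, end), self.c_out), dtype=dy.dtype)
        dyp[:, self.pad:end] = dy
        dyp = np.ascontiguousarray(dyp[:, :lp])
        s0, s1, s2 = dyp.strides
        dcols = np.ascontiguousarray(as_strided(
            dyp, (b, l, self.k, self.c_out), (s0, self.stride * s1, s1, s2)))
        dcols2 = dcols.reshape(b * l, self.k * self.c_out)
        self.dW[...] = x2.T @ dcols2
        return (dcols2 @ self.W.T).reshape(b, l, self.c_in)


class GELU:
    """GELU in the standard tanh parameterization.

    ``0.5 x (1 + tanh(sqrt(2/pi) (x + 0.044715 x^3)))``; the backward pass is
    the exact derivative of this expression (tanh cached from forward).
    """

    _C = float(np.sqrt(2.0 / np.pi))
    _A = 0.044715

    def __init__(self):
        self._x = None
        self._t = None

    def parameters(self):
        return []

    def forward(self, x):
        t = np.tanh(self._C * (x + self._A * x * x * x))
        self._x = x
        self._t = t
        return 0.5 * x * (1.0 + t)

    def backward(self, dy):
        x = self._x
        t = self._t
        du = self._C * (1.0 + 3.0 * self._A * x * x)
        return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du)


class _TimeNorm:
    """Normalize each channel of each sample over the time axis."""

    eps = 1e-5

    def __init__(self, c, affine, dtype):
        self.affine = affine
        if affine:
            self.g = np.ones(c, dtype=dtype)
            self.beta = np.zeros(c, dtype=dtype)
            self.dg = np.zeros_like(self.g)
            self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def parameters(self):
        return [(self.g, self.dg), (self.beta, self.dbeta)] if self.affine else []

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((x - mu) * inv).astype(x.dtype)
        self._cache = (xhat, inv.astype(x.dtype))
        if self.affine:
            return xhat * self.g + self.beta
        return xhat

    def backward(self, dy):
        xhat, inv = self._cache
        n = xhat.shape[1]
        if self.affine:
            self.dg[...] = (dy * xhat).sum(axis=(0, 1))
            self.dbeta[...] = dy.sum(axis=(0, 1))
            dxhat = dy * self.g
        else:
            dxhat = dy
        t1 = dxhat.sum(axis=1, keepdims=True)
        t2 = (dxhat * xhat).sum(axis=1, keepdims=True)
        return (inv / n) * (n * dxhat - t1 - xhat * t2)


class LayerNormTime(_TimeNorm):
    """Per-channel time-axis normalization with a learned affine transform."""

    def __init__(self, c, dtype):
        super().__init__(c, affine=True, dtype=dtype)


class InstanceNormTime(_TimeNorm):
    """Per-sample, per-channel time-axis normalization (no affine)."""

    def __init__(self, c, dtype):
        super().__init__(c, affine=False, dtype=dtype)


class Identity:
    def parameters(self):
        return []

    def forward(self, x):
        return x

    def backward(self, dy):
        return dy


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

class MCBlock:
    """Downsampling block: strided conv branch + pointwise projection branch."""

    def __init__(self, c_in, c_out, k, stride, norms, rng, dtype):
        self.conv1 = Conv1d(c_in, c_out, k, stride, rng, dtype)
        self.ln = LayerNormTime(c_out, dtype) if norms[0] else Identity()
        self.act1 = GELU()
        self.conv2 = Conv1d(c_out, c_out, k, 1, rng, dtype)
        self.inorm = InstanceNormTime(c_out, dtype) if norms[1] else Identity()
        self.proj = Conv1d(c_in, c_out, 1, stride, rng, dtype)
        self.act2 = GELU()

    def parameters(self):
        mods = (self.conv1, self.ln, self.conv2, self.inorm, self.proj)
        return [p for m in mods for p in m.parameters()]

    def forward(self, x):
        a = self.inorm.forward(self.conv2.forward(
            self.act1.forward(self.ln.forward(self.conv1.forward(x)))))
        b = self.proj.forward(x)
        return self.act2.forward(a + b)

    def backward(self, dy):
        d = self.act2.backward(dy)
        dx = self.proj.backward(d)
        da = self.conv1.backward(self.ln.backward(
            self.act1.backward(self.conv2.backward(self.inorm.backward(d)))))
        return dx + da


class MCTBlock:
    """Upsampling block mirroring :class:`MCBlock` with transposed convs."""

    def __init__(self, c_in, c_out, k, stride, norms, rng, dtype):
        self.tconv1 = ConvTranspose1d(c_in, c_out, k, stride, rng, dtype)
        self.ln = LayerNormTime(c_out, dtype) if norms[0] else Identity()
        self.act1 = GELU()
        self.conv2 = Conv1d(c_out, c_out, k, 1, rng, dtype)
        self.inorm = InstanceNormTime(c_out, dtype) if norms[1] else Identity()
        self.tproj = ConvTranspose1d(c_in, c_out, 1, stride, rng, dtype,
                                     output_padding=stride - 1)
        self.act2 = GELU()

    def parameters(self):
        mods = (self.tconv1, self.ln, self.conv2, self.inorm, self.tproj)
        return [p for m in mods for p in m.parameters()]

    def forward(self, x):
        a = self.inorm.forward(self.conv2.forward(
            self.act1.forward(self.ln.forward(self.tconv1.forward(x)))))
        b = self.tproj.forward(x)
        return self.act2.forward(a + b)

    def backward(self, dy):
        d = self.act2.backward(dy)
        dx = self.tproj.backward(d)
        da = self.tconv1.backward(self.ln.backward(
            self.act1.backward(self.conv2.backward(self.inorm.backward(d)))))
        return dx + da


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class Model:
    """Encoder-decoder autoencoder over 12-channel frames.

    Public ``forward`` accepts ``(12, L)`` or ``(batch, 12, L)`` with any
    ``L`` divisible by ``stride ** depth`` and returns the same shape.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        dtype = np.dtype(config.dtype)
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        k, s, norms = config.kernel_size, config.stride, config.norms
        widths = config.channel_widths
        self.encoder = []
        c_prev = config.in_channels
        for w in widths:
            self.encoder.append(MCBlock(c_prev, w, k, s, norms, rng, dtype))
            c_prev = w
        self.decoder = []
        concat = config.skips == "concat"
        dec_out = list(widths[-2::-1]) + [widths[0]]  # mirror, last level keeps w0
        c_prev = widths[-1]
        for j, w in enumerate(dec_out):
            self.decoder.append(MCTBlock(c_prev, w, k, s, norms, rng, dtype))
            has_skip = j < config.depth - 1
            c_prev = (2 * w) if (concat and has_skip) else w
        self.head = Conv1d(c_prev, config.out_channels, 1, 1, rng, dtype)
        self._skip_concat = concat

    # -- parameters ---------------------------------------------------------

    def parameters(self):
        """List of (value, grad) array pairs, in a deterministic order."""
        out = []
        for blk in self.encoder + self.decoder:
            out.extend(blk.parameters())
        out.extend(self.head.parameters())
        return out

    def num_params(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def get_weights(self):
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights):
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for (p, _), w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x):
        x = np.asarray(x)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (batch, {self.config.in_channels}, L) input, got {x.shape}")
        down = self.config.stride ** self.config.depth
        if x.shape[2] % down != 0:
            raise ValueError(f"sequence length {x.shape[2]} not divisible by {down}")
        return x.astype(self.dtype), single

    def forward(self, x):
        """Map masked frames to reconstructed 12-lead frames (pure function)."""
        xb, single = self._check_input(x)
        h = np.swapaxes(xb, 1, 2)  # channels-last
        skips = []
        for blk in self.encoder:
            h = blk.forward(h)
            skips.append(h)
        self._skips_shapes = [s.shape for s in skips]
        h = skips[-1]
        depth = self.config.depth
        for j, blk in enumerate(self.decoder):
            h = blk.forward(h)
            if j < depth - 1:
                sk = skips[depth - 2 - j]
                h = np.concatenate([h, sk], axis=2) if self._skip_concat else h + sk
        y = self.head.forward(h)
        y = np.swapaxes(y, 1, 2)
        return y[0] if single else y

    def backward(self, dy):
        """Backprop; fills parameter grads. ``dy`` matches forward output shape."""
        dy = np.asarray(dy, dtype=self.dtype)
        if dy.ndim == 2:
            dy = dy[None]
        d = np.swapaxes(dy, 1, 2)
        depth = self.config.depth
        d_enc = [np.zeros(s, dtype=self.dtype) for s in self._skips_shapes]
        dh = self.head.backward(d)
        for j in range(depth - 1, -1, -1):
            if j < depth - 1:
                if self._skip_concat:
                    w = self._skips_shapes[depth - 2 - j][2]
                    d_enc[depth - 2 - j] += dh[:, :, -w:]
                    dh = np.ascontiguousarray(dh[:, :, :-w])
                else:
                    d_enc[depth - 2 - j] += dh
            dh = self.decoder[j].backward(dh)
        d_enc[depth - 1] += dh
        for i in range(depth - 1, -1, -1):
            dx = self.encoder[i].backward(d_enc[i])
            if i > 0:
                d_enc[i - 1] += dx
        return np.swapaxes(dx, 1, 2)


def build_model(config: ModelConfig | None = None) -> Model:
    """Construct an MCMA network; weight init is seeded from ``config.seed``."""
    return Model(config or ModelConfig())


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            m = self.m[i]
            v = self.v[i]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    """A trained model plus its provenance: config, history, recipe hash."""

    config: ModelConfig
    weights: list
    history: list = field(default_factory=list)
    train_config_hash: str = ""

    def build(self) -> Model:
        model = build_model(self.config)
        model.set_weights(self.weights)
        return model


def save_checkpoint(checkpoint_or_model, path, history=None,
                    train_config_hash: str = "") -> Path:
    """Write a checkpoint archive (zip of .npy weight blobs + JSON meta)."""
    if isinstance(checkpoint_or_model, Model):
        ckpt = Checkpoint(checkpoint_or_model.config,
                          checkpoint_or_model.get_weights(),
                          history or [], train_config_hash)
    else:
        ckpt = checkpoint_or_model
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": CHECKPOINT_FORMAT,
        "config": ckpt.config.to_dict(),
        "history": ckpt.history,
        "train_config_hash": ckpt.train_config_hash,
        "n_weights": len(ckpt.weights),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        for i, w in enumerate(ckpt.weights):
            buf = io.BytesIO()
            np.save(buf, w)
            zf.writestr(f"w{i:04d}.npy", buf.getvalue())
    return path


def load_checkpoint(path) -> Checkpoint:
    """Load a checkpoint; raises on a missing file or format mismatch."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(
                f"incompatible checkpoint format {meta.get('format')!r}; "
                f"this build reads {CHECKPOINT_FORMAT!r}")
        weights = [np.load(io.BytesIO(zf.read(f"w{i:04d}.npy")))
                   for i in range(meta["n_weights"])]
    return Checkpoint(ModelConfig.from_dict(meta["config"]), weights,
                      meta["history"], meta["train_config_hash"])
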