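"""Coordinate-and-local attention (CLA) and the plain coordinate-attention
baseline.

CLA recalibrates a feature map X in R^{C×H×W} with three multiplicative
factors:

* a height gate g^h(c, i) and a width gate g^w(c, j), obtained by average-
  pooling X along each spatial axis, passing the concatenated directional
  profiles through a shared 1×1 bottleneck (C -> C/r, BN, Leaky ReLU) and
  re-expanding each direction with its own 1×1 conv + sigmoid — this embeds
  positional information into channel attention;
* a pointwise local-context factor x^l = δ(C2(δ(C1(x)))), two 1×1 convs
  (C -> C/r -> C) with Leaky ReLU δ, capturing local channel interactions.

The output is x'_c(i,j) = x_c(i,j) · g^h_c(i) · g^w_c(j) · x^l_c(i,j).
Coordinate attention (CA) is the same construction without the local factor.

Gates are broadcast: g^h is stored as (N, C, H, 1) and g^w as (N, C, 1, W).
The local factor is not squashed, so it can amplify; pass
``bounded_local=True`` to append a sigmoid if a bounded variant is wanted.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, BatchNorm2d, Conv2d, Module, concat


def _as_tensor4d(x):
    """Accept ndarray/Tensor of rank 3 (C,H,W) or 4 (N,C,H,W); return (t, had_batch)."""
    if isinstance(x, Tensor):
        t = x
    else:
        arr = np.asarray(x)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        t = Tensor(arr)
    if t.ndim == 3:
        return t.reshape((1,) + t.shape), False
    if t.ndim == 4:
        return t, True
    raise ValueError(f"expected rank-3 or rank-4 feature map, got rank {t.ndim}")


def _validate_finite(x: Tensor):
    if not np.isfinite(x.data).all():
        raise ValueError("feature map contains non-finite values")


def directional_pool(x) -> tuple[np.ndarray, np.ndarray]:
    """Average-pool a feature map along each spatial axis.

    Returns ``z_h`` of shape (..., C, H) — the mean over width — and ``z_w``
    of shape (..., C, W) — the mean over height.
    """
    t, had_batch = _as_tensor4d(x)
    _validate_finite(t)
    z_h = t.data.mean(axis=3)
    z_w = t.data.mean(axis=2)
    if not had_batch:
        z_h, z_w = z_h[0], z_w[0]
    return z_h, z_w


class CoordLocalAttention(Module):
    """CLA block (set ``local=False`` for the CA ablation baseline).

    Parameters
    ----------
    channels : int
        C of the incoming feature map; must be divisible by ``reduction``.
    reduction : int
        Bottleneck ratio r; the shared and local 1×1 convs use C/r channels.
    negative_slope : float
        Slope of the Leaky ReLU δ.
    local : bool
        Include the local-context factor (CLA); omit it for plain CA.
    bounded_local : bool
        Squash the local factor through a sigmoid (off by default; the
        published form is unbounded).
    """

    def __init__(self, channels: int, reduction: int = 32, negative_slope: float = 0.1,
                 local: bool = True, bounded_local: bool = False, rng=None):
        super().__init__()
        if channels % reduction != 0 or channels < reduction:
            raise ValueError(
                f"channels ({channels}) must be a multiple of reduction ({reduction})")
        if not 0.0 < negative_slope < 1.0:
            raise ValueError("negative_slope must lie in (0, 1)")
        mid = channels // reduction
        self.channels, self.reduction = channels, reduction
        self.negative_slope = negative_slope
        self.local, self.bounded_local = local, bounded_local
        rng = rng or np.random.default_rng(0)
        self.conv_shared = Conv2d(channels, mid, 1, rng=rng)
        self.bn_shared = BatchNorm2d(mid)
        self.conv_h = Conv2d(mid, channels, 1, rng=rng)
        self.conv_w = Conv2d(mid, channels, 1, rng=rng)
        if local:
            self.conv_l1 = Conv2d(channels, mid, 1, rng=rng)
            self.conv_l2 = Conv2d(mid, channels, 1, rng=rng)
        # test hooks: force the corresponding factor to exactly 1
        self.force_identity_gates = False
        self.force_identity_local = False

    # -- stages ------------------------------------------------------------

    def coordinate_weights(self, z_h, z_w) -> tuple[Tensor, Tensor]:
        """Gates from directional profiles; returns g_h (N,C,H,1), g_w (N,C,1,W)."""
        z_h = z_h if isinstance(z_h, Tensor) else Tensor(np.asarray(z_h, dtype=np.float32))
        z_w = z_w if isinstance(z_w, Tensor) else Tensor(np.asarray(z_w, dtype=np.float32))
        if z_h.ndim == 2:  # (C, H) -> (1, C, H)
            z_h = z_h.reshape((1,) + z_h.shape)
            z_w = z_w.reshape((1,) + z_w.shape)
        n, c, h = z_h.shape
        w = z_w.shape[2]
        if c != self.channels:
            raise ValueError(f"profile channels {c} != configured {self.channels}")
        stacked = concat([z_h.reshape(n, c, h, 1), z_w.reshape(n, c, w, 1)], axis=2)
        f = self.bn_shared(self.conv_shared(stacked)).leaky_relu(self.negative_slope)
        f_h = f[:, :, :h, :]
        f_w = f[:, :, h:, :]
        g_h = self.conv_h(f_h).sigmoid()                      # (N, C, H, 1)
        g_w = self.conv_w(f_w).sigmoid().transpose((0, 1, 3, 2))  # (N, C, 1, W)
        return g_h, g_w

    def local_context(self, x) -> Tensor:
        """x^l = δ(C2(δ(C1(x)))); same shape as the input."""
        t, had_batch = _as_tensor4d(x)
        _validate_finite(t)
        y = self.conv_l1(t).leaky_relu(self.negative_slope)
        y = self.conv_l2(y).leaky_relu(self.negative_slope)
        if self.bounded_local:
            y = y.sigmoid()
        return y if had_batch else y.reshape(y.shape[1:])

    # -- full block --------------------------------------------------------

    def forward(self, x):
        t, had_batch = _as_tensor4d(x)
        _validate_finite(t)
        out = t
        if not self.force_identity_gates:
            z_h = t.mean(axis=3)
            z_w = t.mean(axis=2)
            g_h, g_w = self.coordinate_weights(z_h, z_w)
            out = out * g_h * g_w
        if self.local and not self.force_identity_local:
            n, c, h, w = t.shape
            y = self.conv_l1(t).leaky_relu(self.negative_slope)
            y = self.conv_l2(y).leaky_relu(self.negative_slope)
            if self.bounded_local:
                y = y.sigmoid()
            out = out * y
        return out if had_batch else out.reshape(out.shape[1:])


def CoordAttention(channels: int, reduction: int = 32, negative_slope: float = 0.1,
                   rng=None) -> CoordLocalAttention:
    """Plain coordinate attention: CLA without the local-context factor."""
    return CoordLocalAttention(channels, reduction, negative_slope, local=False, rng=rng)
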