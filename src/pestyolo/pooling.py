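"""Multi-scale max-pooling blocks: SPP, SPPF and the grouped GSPPF.

SPP fuses several receptive fields by pooling the same map with different
kernels in parallel; SPPF obtains the identical result by cascading one
small kernel (three stride-1 k=5 pools reproduce kernels 5, 9 and 13),
which is why the two are interchangeable and tested against each other.

GSPPF splits the deep feature map into four equal channel groups v_1..v_4
after an entry conv and applies SPPF cumulatively:

    y_1 = v_1,  y_2 = SPPF_2(v_2),  y_i = SPPF_i(v_i + y_{i-1})  for i in {3, 4}

then concatenates y_1..y_4 and fuses with an exit conv.  The cascade is
directional: later groups see progressively larger effective receptive
fields, enriching multi-scale structure at finer channel granularity while
keeping the block a drop-in replacement for SPPF.
"""

from __future__ import annotations

import numpy as np

from .nn import ConvBnSiLU, Module, ModuleList, Tensor, concat, maxpool2d_same


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        t = x
    else:
        arr = np.asarray(x)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        t = Tensor(arr)
    if t.ndim == 3:
        return t.reshape((1,) + t.shape), False
    return t, True


class SPPF(Module):
    """Cascaded spatial pyramid pooling (entry conv, 3 pools, exit conv)."""

    def __init__(self, cin: int, cout: int, kernel: int = 5,
                 hidden: int | None = None, rng=None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"pooling kernel must be odd, got {kernel}")
        hidden = hidden if hidden is not None else cin // 2
        self.kernel = kernel
        self.cv1 = ConvBnSiLU(cin, hidden, 1, rng=rng)
        self.cv2 = ConvBnSiLU(hidden * 4, cout, 1, rng=rng)

    def forward(self, x):
        t, had_batch = _as_tensor(x)
        y0 = self.cv1(t)
        y1 = maxpool2d_same(y0, self.kernel)
        y2 = maxpool2d_same(y1, self.kernel)
        y3 = maxpool2d_same(y2, self.kernel)
        out = self.cv2(concat([y0, y1, y2, y3], axis=1))
        return out if had_batch else out.reshape(out.shape[1:])


class SPP(Module):
    """Parallel multi-kernel pooling; the reference SPPF is equivalent to
    ``SPP(kernels=(5, 9, 13))`` with shared conv weights."""

    def __init__(self, cin: int, cout: int, kernels=(5, 9, 13),
                 hidden: int | None = None, rng=None):
        super().__init__()
        for k in kernels:
            if k % 2 == 0:
                raise ValueError(f"pooling kernel must be odd, got {k}")
        hidden = hidden if hidden is not None else cin // 2
        self.kernels = tuple(kernels)
        self.cv1 = ConvBnSiLU(cin, hidden, 1, rng=rng)
        self.cv2 = ConvBnSiLU(hidden * (1 + len(kernels)), cout, 1, rng=rng)

    @classmethod
    def from_sppf(cls, sppf: SPPF) -> "SPP":
        """Weight-sharing SPP twin of an SPPF (for the equivalence check)."""
        k = sppf.kernel
        hidden = sppf.cv1.conv.cout
        spp = cls(sppf.cv1.conv.cin, sppf.cv2.conv.cout,
                  kernels=(k, 2 * k - 1, 3 * k - 2), hidden=hidden)
        spp.load_state_dict(sppf.state_dict())
        return spp

    def forward(self, x):
        t, had_batch = _as_tensor(x)
        y0 = self.cv1(t)
        branches = [y0] + [maxpool2d_same(y0, k) for k in self.kernels]
        out = self.cv2(concat(branches, axis=1))
        return out if had_batch else out.reshape(out.shape[1:])


class GSPPF(Module):
    """Grouped SPPF: cumulative SPPF cascade over four channel groups.

    Channel bookkeeping: the entry conv maps ``cin -> cin``; each group is
    ``cin/groups`` wide; each internal SPPF preserves its group width with a
    half-width hidden layer; the exit conv maps ``cin -> cout``.
    """

    def __init__(self, cin: int, cout: int, kernel: int = 5, groups: int = 4, rng=None):
        super().__init__()
        if cin % groups != 0:
            raise ValueError(
                f"GSPPF needs a channel count divisible by {groups}; got {cin}")
        self.groups = groups
        cg = cin // groups
        self.entry = ConvBnSiLU(cin, cin, 1, rng=rng)
        # group 1 passes through untouched; groups 2..g get their own SPPF
        self.sppfs = ModuleList([SPPF(cg, cg, kernel, hidden=max(cg // 2, 1), rng=rng)
                                 for _ in range(groups - 1)])
        self.exit = ConvBnSiLU(cin, cout, 1, rng=rng)
        self.identity_sppf = False  # test hook: cascade of plain additions

    def forward(self, x):
        t, had_batch = _as_tensor(x)
        v = self.entry(t)
        cg = v.shape[1] // self.groups
        subsets = [v[:, i * cg:(i + 1) * cg] for i in range(self.groups)]
        ys = [subsets[0]]
        for i in range(1, self.groups):
            inner = (lambda z: z) if self.identity_sppf else self.sppfs[i - 1]
            vin = subsets[i] if i == 1 else subsets[i] + ys[-1]
            assert vin.shape == subsets[i].shape
            ys.append(inner(vin))
        out = self.exit(concat(ys, axis=1))
        return out if had_batch else out.reshape(out.shape[1:])
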