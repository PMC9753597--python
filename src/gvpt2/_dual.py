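"""Minimal forward-mode differentiation used for Wilson-tensor derivatives.

A :class:`Dual` carries a value array and its gradient with respect to a
set of seed directions (here: the 3N Cartesian coordinates).  Propagating
closed-form B-matrix rows through this arithmetic yields the B' tensor
analytically, i.e. exact to machine precision with no finite-difference
truncation error.
"""

from __future__ import annotations

import numpy as np


class Dual:
    """Elementwise value/gradient pair; grad has one trailing axis (nd)."""

    __slots__ = ("val", "grad")
    __array_priority__ = 100  # make ndarray ops defer to Dual

    def __init__(self, val, grad):
        self.val = np.asarray(val, dtype=float)
        self.grad = np.asarray(grad, dtype=float)

    @property
    def nd(self) -> int:
        return self.grad.shape[-1]

    @classmethod
    def seed(cls, x: np.ndarray) -> "Dual":
        x = np.asarray(x, dtype=float).reshape(-1)
        return cls(x, np.eye(x.size))

    @classmethod
    def constant(cls, val, nd: int) -> "Dual":
        val = np.asarray(val, dtype=float)
        return cls(val, np.zeros(val.shape + (nd,)))

    def _coerce(self, other) -> "Dual":
        return other if isinstance(other, Dual) else Dual.constant(other, self.nd)

    def _broadcast(self, other):
        other = self._coerce(other)
        vs = np.broadcast_shapes(self.val.shape, other.val.shape)
        gs = vs + (self.nd,)
        return (np.broadcast_to(self.val, vs), np.broadcast_to(self.grad, gs),
                np.broadcast_to(other.val, vs), np.broadcast_to(other.grad, gs))

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        av, ag, bv, bg = self._broadcast(other)
        return Dual(av + bv, ag + bg)

    __radd__ = __add__

    def __neg__(self):
        return Dual(-self.val, -self.grad)

    def __sub__(self, other):
        av, ag, bv, bg = self._broadcast(other)
        return Dual(av - bv, ag - bg)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        av, ag, bv, bg = self._broadcast(other)
        return Dual(av * bv, ag * bv[..., None] + bg * av[..., None])

    __rmul__ = __mul__

    def __truediv__(self, other):
        av, ag, bv, bg = self._broadcast(other)
        val = av / bv
        grad = (ag - bg * val[..., None]) / bv[..., None]
        return Dual(val, grad)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __getitem__(self, idx):
        return Dual(self.val[idx], self.grad[idx])

    # -- functions ----------------------------------------------------------

    def sqrt(self):
        root = np.sqrt(self.val)
        return Dual(root, self.grad * (0.5 / root)[..., None])


def asdual(x, nd: int):
    return x if isinstance(x, Dual) else Dual.constant(x, nd)


def dsqrt(x):
    return x.sqrt() if isinstance(x, Dual) else np.sqrt(x)


def darccos(x):
    if isinstance(x, Dual):
        val = np.arccos(np.clip(x.val, -1.0, 1.0))
        d = -1.0 / np.sqrt(np.clip(1.0 - x.val**2, 1e-300, None))
        return Dual(val, x.grad * d[..., None])
    return np.arccos(np.clip(x, -1.0, 1.0))


def datan2(y, x):
    if isinstance(y, Dual) or isinstance(x, Dual):
        nd = (y if isinstance(y, Dual) else x).nd
        y, x = asdual(y, nd), asdual(x, nd)
        val = np.arctan2(y.val, x.val)
        denom = x.val**2 + y.val**2
        grad = (y.grad * x.val[..., None] - x.grad * y.val[..., None]) / denom[..., None]
        return Dual(val, grad)
    return np.arctan2(y, x)


# -- 3-vector helpers (work on plain ndarrays and Duals alike) --------------

def vdot(a, b):
    if isinstance(a, Dual) or isinstance(b, Dual):
        nd = (a if isinstance(a, Dual) else b).nd
        a, b = asdual(a, nd), asdual(b, nd)
        val = float(np.dot(a.val, b.val))
        grad = (a.grad * b.val[:, None] + b.grad * a.val[:, None]).sum(axis=0)
        return Dual(val, grad)
    return float(np.dot(a, b))


def vcross(a, b):
    if isinstance(a, Dual) or isinstance(b, Dual):
        nd = (a if isinstance(a, Dual) else b).nd
        a, b = asdual(a, nd), asdual(b, nd)
        idx = [(1, 2), (2, 0), (0, 1)]
        comps = [a[i] * b[j] - a[j] * b[i] for i, j in idx]
        val = np.array([c.val for c in comps])
        grad = np.stack([c.grad for c in comps], axis=0)
        return Dual(val, grad)
    return np.cross(a, b)


def vnorm(a):
    return dsqrt(vdot(a, a))
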