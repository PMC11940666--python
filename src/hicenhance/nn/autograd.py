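"""A compact reverse-mode automatic-differentiation engine on NumPy.

Tensors wrap float32 arrays and build a dynamic computation graph; calling
:meth:`Tensor.backward` on a scalar walks the graph in reverse topological
order accumulating gradients.  The operation set is exactly what the
enhancement network needs: broadcasting arithmetic, batched matmul,
reshapes/transposes/concat/slicing, ReLU and sigmoid, softmax, reductions,
im2col 2-D convolution, 2x2 average pooling, bilinear resampling (as a
pair of precomputed interpolation matrices) and layer normalization.

Convolution caches its input and re-unfolds it in the backward pass, which
keeps peak memory proportional to activations rather than im2col buffers.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


_POOL: dict[tuple[int, ...], list[np.ndarray]] = {}
_POOL_MAX_PER_SHAPE = 4


def _scratch(shape: tuple[int, ...]) -> np.ndarray:
    """Take a float32 scratch buffer from the pool (uninitialized)."""
    stack = _POOL.get(shape)
    if stack:
        return stack.pop()
    return np.empty(shape, dtype=np.float32)


def _release(arr: np.ndarray) -> None:
    """Return a scratch buffer to the pool for reuse.

    Reusing large temporaries (conv patch stacks, attention matrices)
    avoids repeated page-fault storms from allocating hundreds of MB of
    fresh memory per training step.
    """
    stack = _POOL.setdefault(arr.shape, [])
    if len(stack) < _POOL_MAX_PER_SHAPE:
        stack.append(arr)


def clear_scratch() -> None:
    _POOL.clear()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._backward is not None:
                # free the graph edge to release intermediate buffers
                node._backward = None
                node._parents = ()

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray, own: bool = True) -> None:
        """Accumulate a gradient contribution.

        ``own=True`` promises ``g`` is a fresh array (or a view into a
        buffer no longer read) that this tensor may keep and mutate;
        callers forwarding the same array to several parents pass
        ``own=False`` so a private copy is made.
        """
        if not self.requires_grad and self._backward is None:
            return
        if self.grad is None:
            if own and g.dtype == np.float32:
                self.grad = g
            else:
                self.grad = g.astype(np.float32)
        else:
            self.grad += g

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(
            p.requires_grad or p._backward is not None for p in parents
        ):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            # the same array may be forwarded verbatim to both parents
            a._accum(_unbroadcast(g, a.shape), own=False)
            b._accum(_unbroadcast(g, b.shape), own=False)

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            # scalar factors get a dot-product fast path (residual scalings)
            if b.data.size == 1:
                a._accum(g * b.data)
                b._accum(np.full(b.shape, (g * a.data).sum(), dtype=np.float32))
            elif a.data.size == 1:
                b._accum(g * a.data)
                a._accum(np.full(a.shape, (g * b.data).sum(), dtype=np.float32))
            else:
                a._accum(_unbroadcast(g * b.data, a.shape))
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), bwd)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.shape))
            b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: a._accum(g.reshape(old))
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: a._accum(g.transpose(inv))
        )

    def __getitem__(self, key):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            full[key] = g
            a._accum(full)

        return Tensor._make(a.data[key], (a,), bwd)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._coerce(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        offs = np.cumsum([0] + sizes)

        def bwd(g):
            for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                # contiguous copy so downstream ops stay on fast paths
                t._accum(np.ascontiguousarray(g[tuple(sl)]))

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
        )

    def pad2d(self, pad: int):
        """Zero-pad the last two axes by ``pad`` on every side."""
        if pad == 0:
            return self
        a = self
        width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]

        def bwd(g):
            sl = (Ellipsis, slice(pad, g.shape[-2] - pad), slice(pad, g.shape[-1] - pad))
            a._accum(g[sl])

        return Tensor._make(np.pad(a.data, width), (a,), bwd)

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(s, (a,), lambda g: a._accum(g * s * (1.0 - s)))

    def silu(self):
        """Swish: x * sigmoid(x) (the gate inside SwiGLU)."""
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        out = a.data * s

        def bwd(g):
            a._accum(g * (s + out * (1.0 - s)))

        return Tensor._make(out, (a,), bwd)

    def clamp01(self):
        a = self
        mask = (a.data > 0) & (a.data < 1)
        return Tensor._make(np.clip(a.data, 0.0, 1.0), (a,), lambda g: a._accum(g * mask))

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return Tensor._make(np.abs(a.data), (a,), lambda g: a._accum(g * sign))

    def softmax(self, axis: int = -1):
        a = self
        s = a.data - a.data.max(axis=axis, keepdims=True)
        np.exp(s, out=s)
        s /= s.sum(axis=axis, keepdims=True)

        def bwd(g):
            # g is consumed here, so the computation may run in place
            dot = np.einsum("...i,...i->...", g, s)[..., None]
            g = np.subtract(g, dot, out=g if g.flags.writeable and g.base is None else None)
            np.multiply(g, s, out=g)
            a._accum(g)

        return Tensor._make(s, (a,), bwd)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- spatial ops ------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None, padding: int = 0):
        """2-D convolution, stride 1, as batched channel matmuls.

        ``self``: (B, Cin, H, W); ``weight``: (Cout, Cin, kh, kw).
        1x1 kernels reduce to a single batched matmul; k x k kernels build
        a shifted-copy stack (cheap strided copies, no im2col gather) and
        contract it against the flattened kernels.  The backward pass uses
        the same machinery: dW is the stack contracted with the output
        gradient, dX the full correlation of the gradient with the
        180-degree-rotated kernels.
        """
        a, w = self, weight
        B, Cin, H, W = a.shape
        Cout, Cin2, kh, kw = w.shape
        if Cin != Cin2:
            raise ValueError(f"channel mismatch: input {Cin} vs weight {Cin2}")
        Ho, Wo = H + 2 * padding - kh + 1, W + 2 * padding - kw + 1
        K = kh * kw
        parents = (a, w) if bias is None else (a, w, bias)

        def stacked(x, c, pad, oh, ow):
            # (B, c, h, w) -> (B, K*c, oh*ow): window offset k varies first.
            # Returns (array, pooled_flag); pooled arrays must be released.
            if K == 1 and pad == 0:
                return x.reshape(B, c, oh * ow), False
            h, wd = x.shape[2], x.shape[3]
            if pad > 0:
                xp = _scratch((B, c, h + 2 * pad, wd + 2 * pad))
                xp.fill(0.0)
                xp[:, :, pad : pad + h, pad : pad + wd] = x
            else:
                xp = x
            st = _scratch((B, K, c, oh, ow))
            k = 0
            for ki in range(kh):
                for kj in range(kw):
                    st[:, k] = xp[:, :, ki : ki + oh, kj : kj + ow]
                    k += 1
            if pad > 0:
                _release(xp)
            return st.reshape(B, K * c, oh * ow), True

        # kernel flattened to (Cout, K*Cin) matching the stack ordering
        wq = np.ascontiguousarray(w.data.transpose(0, 2, 3, 1)).reshape(Cout, K * Cin)
        st, pooled = stacked(a.data, Cin, padding, Ho, Wo)
        out = np.matmul(wq, st)
        if pooled:
            _release(st.reshape(B, K, Cin, Ho, Wo))
        if bias is not None:
            out += bias.data[:, None]
        out = out.reshape(B, Cout, Ho, Wo)

        def bwd(g):
            g2 = np.ascontiguousarray(g).reshape(B, Cout, Ho * Wo)
            st, pooled = stacked(a.data, Cin, padding, Ho, Wo)
            dwq = np.matmul(g2, st.transpose(0, 2, 1)).sum(axis=0)  # (Cout, K*Cin)
            if pooled:
                _release(st.reshape(B, K, Cin, Ho, Wo))
            w._accum(
                np.ascontiguousarray(
                    dwq.reshape(Cout, kh, kw, Cin).transpose(0, 3, 1, 2)
                )
            )
            if bias is not None:
                bias._accum(g2.sum(axis=(0, 2)))
            # full correlation of g with rotated kernels, channels swapped
            wflip = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1].transpose(1, 2, 3, 0)
            ).reshape(Cin, K * Cout)
            gst, gpooled = stacked(
                g2.reshape(B, Cout, Ho, Wo), Cout, kh - 1 - padding, H, W
            )
            a._accum(np.matmul(wflip, gst).reshape(B, Cin, H, W))
            if gpooled:
                _release(gst.reshape(B, K, Cout, H, W))

        return Tensor._make(out, parents, bwd)

    def avg_pool2(self):
        """2x2 average pooling with stride 2 (even spatial dims required)."""
        a = self
        B, C, H, W = a.shape
        if H % 2 or W % 2:
            raise ValueError("avg_pool2 requires even spatial dims; pad first")
        out = a.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

        def bwd(g):
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            a._accum(gx)

        return Tensor._make(out, (a,), bwd)

    def resize_bilinear(self, out_h: int, out_w: int):
        """Bilinear resampling expressed as row/column interpolation matrices."""
        a = self
        B, C, H, W = a.shape
        Ah = _interp_matrix(H, out_h)
        Aw = _interp_matrix(W, out_w)
        out = np.einsum("oi,bcij,pj->bcop", Ah, a.data, Aw, optimize=True)

        def bwd(g):
            a._accum(np.einsum("oi,bcop,pj->bcij", Ah, g, Aw, optimize=True))

        return Tensor._make(out.astype(np.float32), (a,), bwd)

    def pixel_shuffle(self, r: int):
        """Rearrange (B, r^2*C, H, W) into (B, C, r*H, r*W)."""
        if r == 1:
            return self
        a = self
        B, C2, H, W = a.shape
        if C2 % (r * r):
            raise ValueError(f"channels {C2} not divisible by r^2={r * r}")
        C = C2 // (r * r)
        out = (
            a.data.reshape(B, C, r, r, H, W)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(B, C, H * r, W * r)
        )

        def bwd(g):
            gx = (
                g.reshape(B, C, H, r, W, r)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(B, C2, H, W)
            )
            a._accum(gx)

        return Tensor._make(out, (a,), bwd)

    @staticmethod
    def sdpa(q: "Tensor", k: "Tensor", v: "Tensor", scale: float) -> "Tensor":
        """Fused scaled dot-product attention: ``softmax(scale*QK^T) V``.

        Operates on the last two axes, batched over the leading ones.
        Fusing keeps only one attention-sized buffer (the softmax matrix,
        needed for the backward pass) instead of a chain of temporaries.
        """
        att_shape = q.shape[:-1] + (k.shape[-2],)
        att = _scratch(att_shape)
        np.matmul(q.data * np.float32(scale), np.swapaxes(k.data, -1, -2), out=att)
        att -= att.max(axis=-1, keepdims=True)
        np.exp(att, out=att)
        att /= att.sum(axis=-1, keepdims=True)
        out = att @ v.data

        def bwd(g):
            v._accum(np.swapaxes(att, -1, -2) @ g)
            dp = _scratch(att_shape)
            np.matmul(g, np.swapaxes(v.data, -1, -2), out=dp)
            dot = np.einsum("...i,...i->...", dp, att)[..., None]
            dp -= dot
            dp *= att  # dp is now dS (grad wrt pre-softmax scores)
            q._accum(np.float32(scale) * (dp @ k.data))
            k._accum(np.float32(scale) * (np.swapaxes(dp, -1, -2) @ q.data))
            _release(dp)
            _release(att)

        return Tensor._make(out, (q, k, v), bwd)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale and shift."""
        a = self
        mu = a.data.mean(axis=-1, keepdims=True)
        xc = a.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = xhat * gamma.data + beta.data
        n = a.shape[-1]

        def bwd(g):
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
            beta._accum(_unbroadcast(g, beta.shape))
            gx = g * gamma.data
            a._accum(
                inv
                * (
                    gx
                    - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                )
            )

        return Tensor._make(out, (a, gamma, beta), bwd)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Bilinear interpolation weights (half-pixel centres, edges clamped)."""
    if n_in == n_out:
        return np.eye(n_in, dtype=np.float32)
    A = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        x = (o + 0.5) * scale - 0.5
        x = min(max(x, 0.0), n_in - 1.0)
        lo = int(np.floor(x))
        hi = min(lo + 1, n_in - 1)
        t = x - lo
        A[o, lo] += 1.0 - t
        A[o, hi] += t
    return A
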