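"""A minimal reverse-mode automatic-differentiation engine over numpy arrays.

Only the operations the off-target network needs are provided: broadcasting
arithmetic, (batched) matrix multiplication, the usual pointwise
nonlinearities, reductions, reshaping/slicing/concatenation, an embedding
gather, softmax, a fused softmax-cross-entropy loss, and a same-padded 1-D
convolution.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`, which walks the recorded graph in reverse
topological order.  All correctness-critical backward rules are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

DTYPE = np.float32

_grad_enabled = True


class no_grad:
    """Context manager suppressing graph construction (inference/eval paths)."""

    def __enter__(self):
        global _grad_enabled
        self._previous = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._previous
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* over the axes numpy broadcast to reach it from *shape*."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = _grad_enabled and (
            requires_grad or any(p.requires_grad for p in _parents)
        )
        self._parents = (
            tuple(p for p in _parents if p.requires_grad) if self.requires_grad else ()
        )
        self._backward = _backward if self.requires_grad else None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        # `own=True` promises *grad* is a fresh array this tensor may keep
        # and mutate; otherwise it is copied before first use.
        if self.grad is None:
            self.grad = grad if own else grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs from the BLSTM can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # release the graph eagerly: the backward closures close over their
        # output tensors, so without this the cycles linger until gc runs
        for node in topo:
            node._backward = None
            node._parents = ()

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = _ensure(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw():
            if self.requires_grad:
                g = _unbroadcast(out.grad, self.shape)
                self._accum(g, own=g is not out.grad)
            if other.requires_grad:
                g = _unbroadcast(out.grad, other.shape)
                other._accum(g, own=g is not out.grad)

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = _ensure(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape), own=True)

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-_ensure(other))

    def __rsub__(self, other) -> "Tensor":
        return _ensure(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = _ensure(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape),
                    own=True,
                )

        out._backward = bw if out.requires_grad else None
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _parents=(self,))

        def bw():
            self._accum(
                _unbroadcast(out.grad * exponent * self.data ** (exponent - 1), self.shape),
                own=True,
            )

        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = _ensure(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def bw():
            if self.requires_grad:
                ga = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape), own=True)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                other._accum(_unbroadcast(gb, other.shape), own=True)

        out._backward = bw if out.requires_grad else None
        return out

    # -- pointwise nonlinearities ----------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def bw():
            self._accum(out.grad * (self.data > 0), own=True)

        out._backward = bw if out.requires_grad else None
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))

        def bw():
            self._accum(out.grad * s * (1.0 - s), own=True)

        out._backward = bw if out.requires_grad else None
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _parents=(self,))

        def bw():
            self._accum(out.grad * (1.0 - t * t), own=True)

        out._backward = bw if out.requires_grad else None
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))

        def bw():
            self._accum(out.grad * e, own=True)

        out._backward = bw if out.requires_grad else None
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))

        def bw():
            self._accum(out.grad / self.data, own=True)

        out._backward = bw if out.requires_grad else None
        return out

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        out = Tensor(r, _parents=(self,))

        def bw():
            self._accum(out.grad * 0.5 / r, own=True)

        out._backward = bw if out.requires_grad else None
        return out

    # -- reductions / shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy(), own=True)

        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bw():
            self._accum(out.grad.reshape(self.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))

        def bw():
            self._accum(out.grad.transpose(inv))

        out._backward = bw if out.requires_grad else None
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], _parents=(self,))

        def bw():
            g = np.zeros_like(self.data)
            np.add.at(g, key, out.grad)
            self._accum(g, own=True)

        out._backward = bw if out.requires_grad else None
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _parents=(self,))

        def bw():
            g = out.grad
            self._accum((g - (g * s).sum(axis=axis, keepdims=True)) * s, own=True)

        out._backward = bw if out.requires_grad else None
        return out


def _ensure(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along *axis*; gradients are split back at the seams."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    out._backward = bw if out.requires_grad else None
    return out


def embedding_lookup(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of *weight* (V, D) by an integer index array."""
    out = Tensor(weight.data[indices], _parents=(weight,))

    def bw():
        g = np.zeros_like(weight.data)
        np.add.at(g, indices, out.grad)
        weight._accum(g, own=True)

    out._backward = bw if out.requires_grad else None
    return out


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 1-D convolution.

    ``x`` is (batch, length, in_channels); ``weight`` is
    (kernel, in_channels, out_channels); ``bias`` is (out_channels,).  The
    length axis is preserved, which the residual skip-addition and
    position-wise attention both rely on.
    """
    batch, length, c_in = x.shape
    k, c_in_w, c_out = weight.shape
    if c_in_w != c_in:
        raise ValueError(f"channel mismatch: input {c_in}, kernel {c_in_w}")
    pad_l = (k - 1) // 2
    xp = np.zeros((batch, length + k - 1, c_in), dtype=x.data.dtype)
    xp[:, pad_l : pad_l + length, :] = x.data
    # im2col: one contiguous slice copy per kernel offset
    cols = np.empty((batch, length, k * c_in), dtype=x.data.dtype)
    for kk in range(k):
        cols[:, :, kk * c_in : (kk + 1) * c_in] = xp[:, kk : kk + length, :]
    w2 = weight.data.reshape(k * c_in, c_out)
    out = Tensor(cols @ w2 + bias.data, _parents=(x, weight, bias))

    def bw():
        g = out.grad  # (batch, length, c_out)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1)), own=True)
        if weight.requires_grad:
            gw = cols.reshape(-1, k * c_in).T @ g.reshape(-1, c_out)
            weight._accum(gw.reshape(k, c_in, c_out), own=True)
        if x.requires_grad:
            # dx is the correlation of g with the kernel flipped along its
            # length: same im2col trick on padded g, one matmul, no scatter
            gp = np.zeros((batch, length + k - 1, c_out), dtype=g.dtype)
            gp[:, k - 1 - pad_l : k - 1 - pad_l + length, :] = g
            gcols = np.empty((batch, length, k * c_out), dtype=g.dtype)
            for kk in range(k):
                gcols[:, :, kk * c_out : (kk + 1) * c_out] = gp[:, kk : kk + length, :]
            w_flip = weight.data[::-1].transpose(0, 2, 1).reshape(k * c_out, c_in)
            x._accum(gcols @ w_flip, own=True)

    out._backward = bw if out.requires_grad else None
    return out


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of softmax(logits) against one-hot targets."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    n = logits.shape[0]
    loss = -(onehot * log_probs).sum() / n
    out = Tensor(loss, _parents=(logits,))

    def bw():
        probs = np.exp(log_probs)
        logits._accum(out.grad * (probs - onehot) / n, own=True)

    out._backward = bw if out.requires_grad else None
    return out


def unbind_steps(x: Tensor) -> list[Tensor]:
    """Split (batch, length, channels) into `length` views of (batch, channels).

    All children share one lazily allocated gradient buffer that is handed to
    the parent once every child has backpropagated, so the per-step slicing
    inside recurrent layers costs one allocation instead of `length`.  Every
    child must participate in the backward pass (true for recurrent use).
    """
    length = x.shape[1]
    state: dict = {"buf": None, "remaining": length}

    def make(t: int) -> Tensor:
        child = Tensor(x.data[:, t, :], _parents=(x,))

        def bw():
            if state["buf"] is None:
                state["buf"] = np.zeros_like(x.data)
            state["buf"][:, t, :] += child.grad
            state["remaining"] -= 1
            if state["remaining"] == 0:
                x._accum(state["buf"], own=True)

        child._backward = bw if child.requires_grad else None
        return child

    return [make(t) for t in range(length)]


def stack_steps(tensors: Sequence[Tensor]) -> Tensor:
    """Stack `length` tensors of (batch, channels) into (batch, length, channels)."""
    out = Tensor(np.stack([t.data for t in tensors], axis=1), _parents=tuple(tensors))

    def bw():
        for t_i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(out.grad[:, t_i, :])

    out._backward = bw if out.requires_grad else None
    return out


def lstm_recurrence(z_in: Tensor, wh: Tensor, reverse: bool = False) -> Tensor:
    """Full LSTM time loop as a single fused graph node.

    ``z_in`` is the precomputed input contribution to all gates,
    (batch, length, 4*hidden) = x @ Wx + b; ``wh`` is the recurrent weight
    (hidden, 4*hidden).  Gate order along the last axis is input, forget,
    cell, output.  Returns all hidden states (batch, length, hidden).
    Backward is hand-derived backpropagation through time, verified against
    finite differences in the test suite.
    """
    batch, length, four_h = z_in.shape
    hidden = four_h // 4
    steps = range(length - 1, -1, -1) if reverse else range(length)

    zi = z_in.data
    whd = wh.data
    hs = np.empty((batch, length, hidden), dtype=zi.dtype)
    # caches for backward
    gates = np.empty((batch, length, four_h), dtype=zi.dtype)
    cs = np.empty((batch, length, hidden), dtype=zi.dtype)
    tcs = np.empty((batch, length, hidden), dtype=zi.dtype)

    h = np.zeros((batch, hidden), dtype=zi.dtype)
    c = np.zeros((batch, hidden), dtype=zi.dtype)
    for t in steps:
        z = zi[:, t, :] + h @ whd
        i = 1.0 / (1.0 + np.exp(-z[:, :hidden]))
        f = 1.0 / (1.0 + np.exp(-z[:, hidden : 2 * hidden]))
        g = np.tanh(z[:, 2 * hidden : 3 * hidden])
        o = 1.0 / (1.0 + np.exp(-z[:, 3 * hidden :]))
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        gates[:, t, :hidden] = i
        gates[:, t, hidden : 2 * hidden] = f
        gates[:, t, 2 * hidden : 3 * hidden] = g
        gates[:, t, 3 * hidden :] = o
        cs[:, t, :] = c
        tcs[:, t, :] = tc
        hs[:, t, :] = h

    out = Tensor(hs, _parents=(z_in, wh))

    def bw():
        order = list(steps)
        gz_all = np.empty_like(zi)
        gwh = np.zeros_like(whd)
        carry_h = np.zeros((batch, hidden), dtype=zi.dtype)
        carry_c = np.zeros((batch, hidden), dtype=zi.dtype)
        for pos in range(length - 1, -1, -1):
            t = order[pos]
            i = gates[:, t, :hidden]
            f = gates[:, t, hidden : 2 * hidden]
            g = gates[:, t, 2 * hidden : 3 * hidden]
            o = gates[:, t, 3 * hidden :]
            tc = tcs[:, t, :]
            c_prev = cs[:, order[pos - 1], :] if pos > 0 else np.zeros_like(carry_c)
            h_prev = hs[:, order[pos - 1], :] if pos > 0 else np.zeros_like(carry_h)
            gh = out.grad[:, t, :] + carry_h
            gc = carry_c + gh * o * (1.0 - tc * tc)
            gz = np.empty((batch, four_h), dtype=zi.dtype)
            gz[:, :hidden] = gc * g * i * (1.0 - i)
            gz[:, hidden : 2 * hidden] = gc * c_prev * f * (1.0 - f)
            gz[:, 2 * hidden : 3 * hidden] = gc * i * (1.0 - g * g)
            gz[:, 3 * hidden :] = gh * tc * o * (1.0 - o)
            gz_all[:, t, :] = gz
            gwh += h_prev.T @ gz
            carry_h = gz @ whd.T
            carry_c = gc * f
        if z_in.requires_grad:
            z_in._accum(gz_all, own=True)
        if wh.requires_grad:
            wh._accum(gwh, own=True)

    out._backward = bw if out.requires_grad else None
    return out


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mean: np.ndarray,
    var: np.ndarray,
    eps: float,
    batch_stats: bool,
) -> Tensor:
    """Fused batch normalisation over the leading axes of (batch, length, C).

    With ``batch_stats`` the supplied mean/var are the batch moments and the
    backward pass propagates through them; otherwise they are fixed running
    statistics (inference) and the map is a constant affine transform.
    """
    std = np.sqrt(var + eps)
    xhat = (x.data - mean) / std
    out = Tensor(gamma.data * xhat + beta.data, _parents=(x, gamma, beta))
    axes = (0, 1)
    n = x.shape[0] * x.shape[1]

    def bw():
        g = out.grad
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes, keepdims=True), own=True)
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes, keepdims=True), own=True)
        if x.requires_grad:
            if batch_stats:
                gxhat = g * gamma.data
                gx = (
                    gxhat
                    - gxhat.mean(axis=axes, keepdims=True)
                    - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True) / n
                ) / std
            else:
                gx = g * gamma.data / std
            x._accum(gx, own=True)

    out._backward = bw if out.requires_grad else None
    return out
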