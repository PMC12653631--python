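"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Every primitive's backward rule is itself written in terms of the same
primitives, so gradient computation builds a differentiable graph and
higher-order derivatives (needed to train through a Grad-CAM map, which
already contains one gradient) come for free.

Conventions: a configurable global dtype (float32 by default); image batches are NCHW; `grad` is purely
functional (no `.grad` attribute mutation), returning cotangent Tensors.
"""

from __future__ import annotations

import contextlib

import numpy as np

#: global dtype for all graph arrays. float32 keeps the (memory-bound)
#: convolution work fast; numerical oracle tests switch to float64 via
#: `use_dtype` where finite-difference precision matters.
DTYPE = np.float32


@contextlib.contextmanager
def use_dtype(dtype):
    global DTYPE
    prev = DTYPE
    DTYPE = dtype
    try:
        yield
    finally:
        DTYPE = prev


class Tensor:
    """A node in the computation graph.

    Leaves are created directly from arrays; interior nodes carry their
    parents and one vector-Jacobian-product closure per parent.
    """

    __slots__ = ("data", "parents", "vjps")

    def __init__(self, data, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.parents = parents
        self.vjps = vjps

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return mul(self, pow_const(as_tensor(other), -1.0))

    def __pow__(self, c):
        return pow_const(self, c)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, leaf={not self.parents})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / broadcasting primitives
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a cotangent back to `shape` after NumPy broadcasting."""
    if g.shape == tuple(shape):
        return g
    # sum away leading added axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_op(g, axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_op(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, shape)
    return g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(g, b.shape),
        ),
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(mul(g, b), a.shape),
            lambda g: _unbroadcast(mul(g, a), b.shape),
        ),
    )


def pow_const(a, c: float) -> Tensor:
    a = as_tensor(a)
    c = float(c)
    return Tensor(
        a.data ** c,
        parents=(a,),
        vjps=(lambda g: mul(g, mul(c, pow_const(a, c - 1.0))),),
    )


def sqrt(a) -> Tensor:
    return pow_const(a, 0.5)


def exp(a) -> Tensor:
    # vjp recomputes exp(a) rather than closing over the output node:
    # self-referential closures would create cycles that defer freeing
    # the whole step's graph to the cyclic collector
    a = as_tensor(a)
    return Tensor(np.exp(a.data), parents=(a,),
                  vjps=(lambda g: mul(g, exp(a)),))


def log(a) -> Tensor:
    a = as_tensor(a)
    return Tensor(
        np.log(a.data),
        parents=(a,),
        vjps=(lambda g: mul(g, pow_const(a, -1.0)),),
    )


def tanh(a) -> Tensor:
    a = as_tensor(a)

    def _vjp(g):
        t = tanh(a)
        return mul(g, add(1.0, mul(-1.0, mul(t, t))))

    return Tensor(np.tanh(a.data), parents=(a,), vjps=(_vjp,))


def _expit(d: np.ndarray) -> np.ndarray:
    e = np.exp(-np.abs(d))
    return np.where(d >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)

    def _vjp(g):
        s = sigmoid(a)
        return mul(g, mul(s, add(1.0, mul(-1.0, s))))

    return Tensor(_expit(a.data), parents=(a,), vjps=(_vjp,))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = (a.data > 0).astype(DTYPE)  # a.e. derivative, held constant
    return Tensor(
        np.maximum(a.data, 0.0),
        parents=(a,),
        vjps=(lambda g: mul(g, mask),),
    )


def clip_const(a, lo, hi) -> Tensor:
    """Clamp into constant (array) bounds; pass-through gradient inside."""
    a = as_tensor(a)
    lo = np.asarray(lo, dtype=DTYPE)
    hi = np.asarray(hi, dtype=DTYPE)
    inside = ((a.data >= lo) & (a.data <= hi)).astype(DTYPE)
    return Tensor(
        np.clip(a.data, lo, hi),
        parents=(a,),
        vjps=(lambda g: mul(g, inside),),
    )


# ---------------------------------------------------------------------------
# shape / reduction primitives
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    return Tensor(
        a.data.reshape(shape),
        parents=(a,),
        vjps=(lambda g: reshape(g, a.shape),),
    )


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return Tensor(
        a.data.transpose(axes),
        parents=(a,),
        vjps=(lambda g: transpose(g, inv),),
    )


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    return Tensor(
        np.broadcast_to(a.data, shape),
        parents=(a,),
        vjps=(lambda g: _unbroadcast(g, a.shape),),
    )


def sum_op(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        axis_t = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axis_t = (axis % a.ndim,)
    else:
        axis_t = tuple(ax % a.ndim for ax in axis)

    def _vjp(g):
        if not keepdims:
            kshape = tuple(1 if i in axis_t else s for i, s in enumerate(a.shape))
            g = reshape(g, kshape)
        return broadcast_to(g, a.shape)

    return Tensor(a.data.sum(axis=axis_t, keepdims=keepdims), parents=(a,), vjps=(_vjp,))


def mean_op(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    elif isinstance(axis, int):
        n = a.shape[axis % a.ndim]
    else:
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axis]))
    return mul(sum_op(a, axis=axis, keepdims=keepdims), 1.0 / n)


def getitem(a, idx) -> Tensor:
    """Basic (slice/ellipsis) indexing; adjoint scatters into zeros."""
    a = as_tensor(a)
    return Tensor(
        a.data[idx],
        parents=(a,),
        vjps=(lambda g: _unslice(g, idx, a.shape),),
    )


def _unslice(g, idx, shape) -> Tensor:
    g = as_tensor(g)
    out = np.zeros(shape, dtype=DTYPE)
    out[idx] = g.data
    return Tensor(out, parents=(g,), vjps=(lambda h: getitem(h, idx),))


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    axis = axis % tensors[0].ndim
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)
    ndim = tensors[0].ndim

    def _mk_vjp(i):
        sl = tuple(
            slice(offs[i], offs[i + 1]) if ax == axis else slice(None)
            for ax in range(ndim)
        )
        return lambda g: getitem(g, sl)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        vjps=tuple(_mk_vjp(i) for i in range(len(tensors))),
    )


def matmul(a, b) -> Tensor:
    """2-D matrix product."""
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data @ b.data,
        parents=(a, b),
        vjps=(
            lambda g: matmul(g, transpose(b, (1, 0))),
            lambda g: matmul(transpose(a, (1, 0)), g),
        ),
    )


def take_rows(a, idx) -> Tensor:
    """Gather a[i, idx[i]] for a 2-D tensor -> 1-D; constant integer idx."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.int64)
    rows = np.arange(a.shape[0])

    def _vjp(g):
        g = as_tensor(g)
        out = np.zeros(a.shape, dtype=DTYPE)
        out[rows, idx] = g.data
        return Tensor(out, parents=(g,),
                      vjps=(lambda h: take_rows(h, idx),))

    return Tensor(a.data[rows, idx], parents=(a,), vjps=(_vjp,))


# ---------------------------------------------------------------------------
# patch extraction (im2col / col2im) — the workhorses behind convolution
# ---------------------------------------------------------------------------

def im2col(x, k: int, pad: int) -> Tensor:
    """(N,C,H,W) -> (N,C,k,k,OH,OW) sliding 3x3-style patches, stride 1.

    Linear; its adjoint is `col2im` and vice versa, so both directions
    stay differentiable to arbitrary order.
    """
    x = as_tensor(x)
    N, C, H, W = x.shape
    OH, OW = H + 2 * pad - k + 1, W + 2 * pad - k + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.empty((N, C, k, k, OH, OW), dtype=DTYPE)
    for u in range(k):
        for v in range(k):
            out[:, :, u, v] = xp[:, :, u:u + OH, v:v + OW]
    return Tensor(out, parents=(x,),
                  vjps=(lambda g: col2im(g, k, pad, H, W),))


def col2im(cols, k: int, pad: int, H: int, W: int) -> Tensor:
    """Adjoint of `im2col`: overlap-add patches back to (N,C,H,W)."""
    cols = as_tensor(cols)
    N, C = cols.shape[0], cols.shape[1]
    OH, OW = cols.shape[4], cols.shape[5]
    buf = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=DTYPE)
    for u in range(k):
        for v in range(k):
            buf[:, :, u:u + OH, v:v + OW] += cols.data[:, :, u, v]
    out = buf[:, :, pad:pad + H, pad:pad + W]
    return Tensor(out, parents=(cols,),
                  vjps=(lambda g: im2col(g, k, pad),))


# ---------------------------------------------------------------------------
# neural-network composite operations
# ---------------------------------------------------------------------------

def _patch_view(xp: np.ndarray, k: int) -> np.ndarray:
    """(N,C,Hp,Wp) padded array -> zero-copy (N,C,OH,OW,k,k) window view."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return win


def _swap_flip(w: Tensor) -> Tensor:
    """(Cout,Cin,k,k) -> (Cin,Cout,k,k) with both spatial axes reversed;
    the kernel that turns input-gradient backprop into another conv2d."""
    return getitem(transpose(w, (1, 0, 2, 3)),
                   (slice(None), slice(None), slice(None, None, -1),
                    slice(None, None, -1)))


def conv2d(x, w, b=None, pad: int = 1) -> Tensor:
    """Stride-1 cross-correlation. x: (N,C,H,W); w: (Cout,Cin,k,k); b: (Cout,).

    Implemented as a fused primitive (einsum over a zero-copy sliding-
    window view); both vjps are themselves conv-style primitives, keeping
    the operation differentiable to arbitrary order.
    """
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    Cout, Cin, k, _ = w.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_data = np.einsum("nchwuv,dcuv->ndhw", _patch_view(xp, k), w.data,
                         optimize=True)
    out = Tensor(
        out_data,
        parents=(x, w),
        vjps=(
            lambda g: conv2d(g, _swap_flip(w), None, pad=k - 1 - pad),
            lambda g: conv2d_wgrad(x, g, k, pad),
        ),
    )
    if b is not None:
        out = add(out, reshape(b, (1, Cout, 1, 1)))
    return out


def conv2d_wgrad(x, g, k: int, pad: int) -> Tensor:
    """Weight gradient of conv2d: correlate input patches with the output
    cotangent. x: (N,C,H,W); g: (N,D,OH,OW) -> (D,C,k,k)."""
    x, g = as_tensor(x), as_tensor(g)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.einsum("ndhw,nchwuv->dcuv", g.data, _patch_view(xp, k),
                    optimize=True)
    return Tensor(
        out,
        parents=(x, g),
        vjps=(
            lambda h: conv2d(g, _swap_flip(h), None, pad=k - 1 - pad),
            lambda h: conv2d(x, h, None, pad=pad),
        ),
    )


def conv_transpose2x2(x, w, b=None) -> Tensor:
    """Stride-2, kernel-2 transposed convolution (exact 2x upsampling).

    x: (N,Cin,H,W); w: (Cin,Cout,2,2) -> (N,Cout,2H,2W). Windows do not
    overlap, so it reduces to a matmul plus reshuffling.
    """
    x, w = as_tensor(x), as_tensor(w)
    N, Cin, H, W = x.shape
    Cin_w, Cout = w.shape[0], w.shape[1]
    if Cin_w != Cin:
        raise ValueError("conv_transpose2x2 channel mismatch")
    x2 = reshape(transpose(x, (0, 2, 3, 1)), (N * H * W, Cin))
    w2 = reshape(w, (Cin, Cout * 4))
    out2 = matmul(x2, w2)                          # (N*H*W, Cout*4)
    out = reshape(out2, (N, H, W, Cout, 2, 2))
    out = transpose(out, (0, 3, 1, 4, 2, 5))       # (N,Cout,H,2,W,2)
    out = reshape(out, (N, Cout, 2 * H, 2 * W))
    if b is not None:
        out = add(out, reshape(b, (1, Cout, 1, 1)))
    return out


def maxpool2x2(x) -> Tensor:
    """2x2 max pooling, stride 2; ties broken toward the first window slot."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    xw = reshape(x, (N, C, H // 2, 2, W // 2, 2))
    xw = transpose(xw, (0, 1, 2, 4, 3, 5))
    xw = reshape(xw, (N, C, H // 2, W // 2, 4))
    flat = xw.data
    onehot = np.zeros_like(flat)
    idx = flat.argmax(axis=-1)
    np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
    return sum_op(mul(xw, onehot), axis=-1)


def upsample_nearest2x(x) -> Tensor:
    """Nearest-neighbour 2x upsampling (used by heatmap export paths)."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    out = broadcast_to(reshape(x, (N, C, H, 1, W, 1)), (N, C, H, 2, W, 2))
    return reshape(out, (N, C, 2 * H, 2 * W))


def logsumexp(logits, axis=1) -> Tensor:
    logits = as_tensor(logits)
    m = logits.data.max(axis=axis, keepdims=True)  # constant shift; identity holds for any m
    z = add(logits, -m)
    return add(log(sum_op(exp(z), axis=axis)), np.squeeze(m, axis=axis))


def cross_entropy(logits, labels) -> Tensor:
    """Mean cross-entropy between (N,K) logits and integer labels."""
    labels = np.asarray(labels, dtype=np.int64)
    lse = logsumexp(logits, axis=1)
    picked = take_rows(logits, labels)
    return mean_op(add(lse, mul(picked, -1.0)))


def softmax(logits, axis=1):
    logits = as_tensor(logits)
    m = logits.data.max(axis=axis, keepdims=True)
    e = exp(add(logits, -m))
    return mul(e, pow_const(sum_op(e, axis=axis, keepdims=True), -1.0))


# ---------------------------------------------------------------------------
# the gradient engine
# ---------------------------------------------------------------------------

def grad(output: Tensor, inputs, grad_output=None):
    """Cotangents of `output` w.r.t. each tensor in `inputs`.

    Returns a list of Tensors (zeros where an input is unreachable). The
    returned tensors carry their own graphs, so they can be differentiated
    again.
    """
    inputs = list(inputs)
    input_ids = {id(t) for t in inputs}

    # which nodes can reach an input (iterative DFS with memo)
    reach: dict[int, bool] = {}

    def can_reach(root: Tensor) -> bool:
        stack = [(root, False)]
        while stack:
            node, processed = stack.pop()
            nid = id(node)
            if nid in reach:
                continue
            if nid in input_ids:
                reach[nid] = True
                continue
            if processed:
                reach[nid] = any(reach.get(id(p), False) for p in node.parents)
            else:
                stack.append((node, True))
                for p in node.parents:
                    if id(p) not in reach:
                        stack.append((p, False))
        return reach[id(root)]

    if not can_reach(output):
        return [Tensor(np.zeros(t.shape)) for t in inputs]

    # topological order over the reachable subgraph
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        nid = id(node)
        if processed:
            topo.append(node)
            continue
        if nid in seen or not reach.get(nid, False):
            continue
        seen.add(nid)
        stack.append((node, True))
        for p in node.parents:
            if reach.get(id(p), False) and id(p) not in seen:
                stack.append((p, False))

    cot: dict[int, Tensor] = {}
    if grad_output is None:
        cot[id(output)] = Tensor(np.ones(output.shape))
    else:
        cot[id(output)] = as_tensor(grad_output)

    for node in reversed(topo):
        g = cot.get(id(node))
        if g is None:
            continue
        for parent, vjp in zip(node.parents, node.vjps):
            pid = id(parent)
            if not reach.get(pid, False):
                continue
            contrib = vjp(g)
            cot[pid] = contrib if pid not in cot else add(cot[pid], contrib)

    return [cot.get(id(t), Tensor(np.zeros(t.shape))) for t in inputs]


# ---------------------------------------------------------------------------
# modules, initialization, optimizer
# ---------------------------------------------------------------------------

class Module:
    """Bare-bones parameter container with named-state (de)serialization."""

    def named_parameters(self):
        out = []
        for name, val in vars(self).items():
            if isinstance(val, Tensor):
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend((f"{name}.{k}", v) for k, v in val.named_parameters())
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(
                            (f"{name}.{i}.{k}", v) for k, v in item.named_parameters()
                        )
                    elif isinstance(item, Tensor):
                        out.append((f"{name}.{i}", item))
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch for keys: {sorted(missing)}")
        for k, v in state.items():
            arr = np.asarray(v, dtype=DTYPE)
            if arr.shape != params[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            params[k].data = arr.copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape))


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, pad=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = he_normal(rng, (cout, cin, k, k), fan_in=cin * k * k)
        self.b = Tensor(np.zeros(cout))
        self.pad = pad

    def __call__(self, x):
        return conv2d(x, self.w, self.b, pad=self.pad)


class ConvTranspose2x2(Module):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = he_normal(rng, (cin, cout, 2, 2), fan_in=cin * 4)
        self.b = Tensor(np.zeros(cout))

    def __call__(self, x):
        return conv_transpose2x2(x, self.w, self.b)


class Linear(Module):
    def __init__(self, nin, nout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = he_normal(rng, (nin, nout), fan_in=nin)
        self.b = Tensor(np.zeros(nout))

    def __call__(self, x):
        return add(matmul(x, self.w), self.b)


class Adam:
    """Adam with decoupled-from-schedule bias correction and L2 weight decay
    folded into the gradient (the classical formulation)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g_t, m, v in zip(self.params, grads, self.m, self.v):
            g = g_t.data if isinstance(g_t, Tensor) else np.asarray(g_t)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
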