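"""Neural-network layers on top of the autograd core.

Convolution and max-pooling are implemented as single graph nodes using
``sliding_window_view`` + BLAS contractions (im2col style); everything else
is composed from autograd primitives.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, make_node, no_grad


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        out.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = value.astype(np.float32).copy()
            else:
                buffers[name][...] = value

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    """Affine layer ``y = x W^T + b`` with uniform +-1/sqrt(fan_in) init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(out_features, in_features)),
            requires_grad=True,
        )
        self.bias = Tensor(rng.uniform(-bound, bound, size=(out_features,)), requires_grad=True)
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x: Tensor) -> Tensor:
        def backward(out):
            if x.requires_grad:
                x._accumulate(out.grad @ self.weight.data)
            if self.weight.requires_grad:
                self.weight._accumulate(out.grad.T @ x.data)
            if self.bias.requires_grad:
                self.bias._accumulate(out.grad.sum(axis=0))

        return make_node(
            x.data @ self.weight.data.T + self.bias.data,
            (x, self.weight, self.bias),
            backward,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


def _spatial_axes(nd: int) -> tuple[int, ...]:
    return tuple(range(2, 2 + nd))


def _conv_windows(xp: np.ndarray, kernel: tuple[int, ...], stride: int) -> np.ndarray:
    nd = len(kernel)
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=_spatial_axes(nd))
    slicer = (slice(None), slice(None)) + tuple(
        slice(None, None, stride) for _ in range(nd)
    )
    return win[slicer]


class Conv(Module):
    """N-dimensional convolution (cross-correlation), He-normal init, no bias.

    ``x`` is (N, C, *spatial); the weight is (out_channels, in_channels,
    *kernel).  Batch normalization always follows convolutions in this model
    family, so a bias term is omitted.
    """

    def __init__(
        self,
        nd: int,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
    ):
        super().__init__()
        self.nd = nd
        self.stride = stride
        self.padding = padding
        self.kernel = (kernel,) * nd if isinstance(kernel, int) else tuple(kernel)
        fan_in = in_channels * int(np.prod(self.kernel))
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_channels, in_channels) + self.kernel),
            requires_grad=True,
        )
        if any(padding > k - 1 for k in self.kernel):
            raise ValueError("padding larger than kernel-1 is not supported")

    def forward(self, x: Tensor) -> Tensor:
        nd, s, p, k = self.nd, self.stride, self.padding, self.kernel
        if x.ndim != nd + 2:
            raise ValueError(f"expected {nd + 2}-D input, got shape {x.shape}")
        n = x.shape[0]
        in_spatial = x.shape[2:]
        xp = np.pad(x.data, [(0, 0), (0, 0)] + [(p, p)] * nd) if p else x.data
        win = _conv_windows(xp, k, s)
        out_spatial = win.shape[2 : 2 + nd]
        # im2col: rows = (N, *out_spatial), columns = (C, *kernel); the
        # contiguous copy is reused for the weight gradient (pure GEMM)
        perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
        col = np.ascontiguousarray(win.transpose(perm)).reshape(
            n * int(np.prod(out_spatial)), -1
        )
        w_mat = self.weight.data.reshape(self.weight.shape[0], -1)
        out_data = (col @ w_mat.T).reshape((n,) + tuple(out_spatial) + (-1,))
        out_data = np.ascontiguousarray(np.moveaxis(out_data, -1, 1))

        W = self.weight

        def backward(out):
            dout = out.grad
            if W.requires_grad:
                dout_mat = (
                    np.moveaxis(dout, 1, -1).reshape(col.shape[0], -1)
                )
                W._accumulate((dout_mat.T @ col).reshape(W.shape))
            if x.requires_grad:
                x._accumulate(_conv_input_grad(dout, W.data, s, p, in_spatial))

        return make_node(out_data, (x, W), backward)


def _conv_input_grad(dout, weight, stride, padding, in_spatial):
    """Gradient w.r.t. the convolution input: transposed convolution.

    Dilate the output gradient by the stride, pad by (kernel-1-padding) plus
    the stride remainder on the trailing side, and correlate with the
    spatially flipped, channel-transposed kernel.
    """
    nd = len(in_spatial)
    kernel = weight.shape[2:]
    n, o = dout.shape[:2]
    dil_shape = tuple((dout.shape[2 + i] - 1) * stride + 1 for i in range(nd))
    z = np.zeros((n, o) + dil_shape, dtype=np.float32)
    z[(slice(None), slice(None)) + tuple(slice(None, None, stride) for _ in range(nd))] = dout
    pads = [(0, 0), (0, 0)]
    for i in range(nd):
        rem = in_spatial[i] + 2 * padding - kernel[i] - (dout.shape[2 + i] - 1) * stride
        pads.append((kernel[i] - 1 - padding, kernel[i] - 1 - padding + rem))
    zp = np.pad(z, pads)
    win = _conv_windows(zp, kernel, 1)
    wf = np.flip(weight, axis=tuple(range(2, 2 + nd)))
    kernel_axes_win = list(range(2 + nd, 2 + 2 * nd))
    dx = np.tensordot(win, wf, axes=([1] + kernel_axes_win, [0] + list(range(2, 2 + nd))))
    return np.moveaxis(dx, -1, 1)


class MaxPool(Module):
    """N-dimensional max pooling with optional -inf padding."""

    def __init__(self, nd: int, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.nd = nd
        self.kernel = (kernel,) * nd
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        nd, k, s, p = self.nd, self.kernel, self.stride, self.padding
        if (
            p == 0
            and all(ki == s for ki in k)
            and all(x.shape[2 + i] % s == 0 for i in range(nd))
        ):
            return self._forward_nonoverlapping(x)
        xp = (
            np.pad(
                x.data,
                [(0, 0), (0, 0)] + [(p, p)] * nd,
                constant_values=-np.inf,
            )
            if p
            else x.data
        )
        win = _conv_windows(xp, k, s)
        lead = win.shape[: 2 + nd]
        flat = win.reshape(lead + (-1,))
        arg = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def backward(out):
            if not x.requires_grad:
                return
            dxp = np.zeros(xp.shape, dtype=np.float32)
            kk = np.unravel_index(arg, k)
            grids = np.meshgrid(
                *[np.arange(dim) for dim in lead], indexing="ij"
            )
            coords = [grids[0], grids[1]] + [
                grids[2 + i] * s + kk[i] for i in range(nd)
            ]
            flat_idx = np.ravel_multi_index(coords, xp.shape)
            np.add.at(dxp.reshape(-1), flat_idx.reshape(-1), out.grad.reshape(-1))
            if p:
                sl = (slice(None), slice(None)) + tuple(
                    slice(p, p + x.shape[2 + i]) for i in range(nd)
                )
                dxp = dxp[sl]
            x._accumulate(dxp)

        return make_node(np.ascontiguousarray(out_data), (x,), backward)

    def _forward_nonoverlapping(self, x: Tensor) -> Tensor:
        """Fast path for kernel == stride, no padding: one reshape gather."""
        nd, s = self.nd, self.stride
        n, c = x.shape[:2]
        out_spatial = tuple(x.shape[2 + i] // s for i in range(nd))
        split = (n, c) + tuple(d for o in out_spatial for d in (o, s))
        # (N, C, o1, s, o2, s, ...) -> (N, C, o1, o2, ..., s, s, ...)
        perm = (0, 1) + tuple(2 + 2 * i for i in range(nd)) + tuple(
            3 + 2 * i for i in range(nd)
        )
        win = np.ascontiguousarray(x.data.reshape(split).transpose(perm)).reshape(
            (n, c) + out_spatial + (-1,)
        )
        arg = win.argmax(axis=-1)
        out_data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

        def backward(out):
            if not x.requires_grad:
                return
            dwin = np.zeros_like(win)
            np.put_along_axis(dwin, arg[..., None], out.grad[..., None], axis=-1)
            inv_perm = np.argsort(perm)
            dx = (
                dwin.reshape((n, c) + out_spatial + (s,) * nd)
                .transpose(inv_perm)
                .reshape(x.shape)
            )
            x._accumulate(dx)

        return make_node(out_data, (x,), backward)


class AdaptiveAvgPool(Module):
    """Global average pooling over all spatial axes -> (N, C)."""

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(2, x.ndim))
        return x.mean(axis=axes)


class BatchNorm(Module):
    """Batch normalization over the channel axis of (N, C, *spatial) input."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, self.num_features) + (1,) * (x.ndim - 2)
        axes = (0,) + tuple(range(2, x.ndim))
        if not self.training:
            # inference: affine transform with frozen statistics
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            scale = (self.gamma.data * inv).reshape(shape)
            shift = (
                self.beta.data - self.gamma.data * self.running_mean * inv
            ).reshape(shape)
            return make_node(x.data * scale + shift, (x,), lambda out: None)

        # training: single fused node (the composite form costs ~3x in
        # memory traffic, which dominates on CPU)
        d = x.data
        count = d.size // self.num_features
        mu = d.mean(axis=axes)
        xc = d - mu.reshape(shape)
        var = (xc * xc).mean(axis=axes)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv.reshape(shape)
        out_data = xhat * self.gamma.data.reshape(shape) + self.beta.data.reshape(shape)

        m = self.momentum
        self.running_mean *= 1 - m
        self.running_mean += m * mu
        self.running_var *= 1 - m
        self.running_var += m * var * (count / max(count - 1, 1))

        gamma, beta = self.gamma, self.beta

        def backward(out):
            dout = out.grad
            dbeta = dout.sum(axis=axes)
            dgamma = (dout * xhat).sum(axis=axes)
            if beta.requires_grad:
                beta._accumulate(dbeta)
            if gamma.requires_grad:
                gamma._accumulate(dgamma)
            if x.requires_grad:
                dx = (
                    dout
                    - (dbeta / count).reshape(shape)
                    - xhat * (dgamma / count).reshape(shape)
                ) * (gamma.data * inv).reshape(shape)
                x._accumulate(dx)

        return make_node(out_data, (x, gamma, beta), backward)
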