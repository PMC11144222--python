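"""Minimal volumetric neural-network engine (numpy, manual backprop).

Implements exactly the pieces the tooth-segmentation U-Net needs: 3-D
convolution (stride 1 and strided downsampling), batch normalization, ReLU /
LeakyReLU, nearest-neighbour upsampling, sigmoid, a soft-Dice loss and an
Adam optimizer.  Layers operate on ``[N, C, D, H, W]`` float32 arrays and
cache what their backward pass needs; convolution is lowered to a single
BLAS matmul via an im2col view, and its input gradient is scattered back
with one vectorized add per kernel offset.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """k^3 convolution, zero padding, arbitrary stride; He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel**3
        self.weight = Parameter(
            rng.standard_normal((out_ch, in_ch, kernel, kernel, kernel))
            * np.sqrt(2.0 / fan_in)
        )
        self.bias = Parameter(np.zeros(out_ch))
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        # all im2col work happens channels-last so the gather copies move
        # contiguous channel runs instead of single floats
        k, s, p = self.kernel, self.stride, self.pad
        xt = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1))  # [N, D, H, W, C]
        if p:
            xt = np.pad(xt, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        self._in_shape_cl = xt.shape
        win = sliding_window_view(xt, (k, k, k), axis=(1, 2, 3))[:, ::s, ::s, ::s]
        n, d, h, w = win.shape[:4]
        # win axes: [N, D', H', W', C, kd, kh, kw] -> [.., kd, kh, kw, C]
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 7, 4)).reshape(
            n * d * h * w, -1
        )
        self._cols = cols
        self._out_spatial = (d, h, w)
        # weight as [O, kd*kh*kw*C] to match the column order
        wmat = np.ascontiguousarray(
            self.weight.value.transpose(0, 2, 3, 4, 1)
        ).reshape(self.weight.value.shape[0], -1)
        out = cols @ wmat.T + self.bias.value
        return np.ascontiguousarray(
            out.reshape(n, d, h, w, -1).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, grad):
        k, s, p = self.kernel, self.stride, self.pad
        n, oc, d, h, w = grad.shape
        ic = self.weight.value.shape[1]
        gmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 4, 1)).reshape(-1, oc)
        dw = (gmat.T @ self._cols).reshape(oc, k, k, k, ic)
        self.weight.grad += dw.transpose(0, 4, 1, 2, 3)
        self.bias.grad += gmat.sum(axis=0)
        self._cols = None

        # input gradient as a transposed convolution: dilate the output
        # gradient by the stride, zero-pad by k-1, and correlate with the
        # spatially flipped kernel — one im2col + BLAS matmul
        dil = [(e - 1) * s + 1 for e in (d, h, w)]
        z = np.zeros((n, *[e + 2 * (k - 1) for e in dil], oc), dtype=np.float32)
        z[
            :,
            k - 1 : k - 1 + dil[0] : s,
            k - 1 : k - 1 + dil[1] : s,
            k - 1 : k - 1 + dil[2] : s,
        ] = grad.transpose(0, 2, 3, 4, 1)
        win = sliding_window_view(z, (k, k, k), axis=(1, 2, 3))
        u = win.shape[1:4]
        zcols = np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 7, 4)).reshape(
            n * u[0] * u[1] * u[2], -1
        )
        # flipped kernel as [IC, kd*kh*kw*OC] matching the column order
        wf = np.ascontiguousarray(
            self.weight.value[:, :, ::-1, ::-1, ::-1].transpose(1, 2, 3, 4, 0)
        ).reshape(ic, -1)
        dx_part = (zcols @ wf.T).reshape(n, u[0], u[1], u[2], ic)
        dx_cl = np.zeros(self._in_shape_cl, dtype=np.float32)
        dx_cl[:, : u[0], : u[1], : u[2]] = dx_part
        if p:
            dx_cl = dx_cl[:, p:-p, p:-p, p:-p]
        return np.ascontiguousarray(dx_cl.transpose(0, 4, 1, 2, 3))


class BatchNorm3d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).reshape(shape).astype(np.float32)
        self._xhat = (x - mean.reshape(shape)) * self._inv_std
        return self.gamma.value.reshape(shape) * self._xhat + self.beta.value.reshape(shape)

    def backward(self, grad):
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        m = grad.size / grad.shape[1]
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gg = self.gamma.value.reshape(shape)
        dxhat = grad * gg
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes).reshape(shape) / m
        ) * self._inv_std
        self._xhat = None
        return dx.astype(np.float32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.0):
        self.slope = slope

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


def ReLU() -> LeakyReLU:
    return LeakyReLU(0.0)


class NearestUpsample3d(Layer):
    """2x nearest-neighbour upsampling; backward sums each 2^3 block."""

    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, grad):
        n, c, d, h, w = grad.shape
        return (
            grad.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
            .sum(axis=(3, 5, 7))
            .astype(np.float32)
        )


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def soft_dice_loss(probs: np.ndarray, target: np.ndarray, eps: float = 1.0):
    """(loss, dL/dprobs) for the soft-Dice loss over a batch."""
    p = probs.astype(np.float64)
    g = target.astype(np.float64)
    inter = (p * g).sum()
    total = p.sum() + g.sum()
    dice = (2.0 * inter + eps) / (total + eps)
    grad = -(2.0 * g * (total + eps) - (2.0 * inter + eps)) / (total + eps) ** 2
    return 1.0 - dice, grad.astype(np.float32)


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def get_state(layers: list[Layer]) -> list[np.ndarray]:
    """Snapshot of all parameters and batch-norm running statistics."""
    state = []
    for layer in layers:
        for p in layer.parameters():
            state.append(p.value.copy())
        if isinstance(layer, BatchNorm3d):
            state.append(layer.running_mean.copy())
            state.append(layer.running_var.copy())
    return state


def set_state(layers: list[Layer], state: list[np.ndarray]) -> None:
    it = iter(state)
    for layer in layers:
        for p in layer.parameters():
            p.value[...] = next(it)
        if isinstance(layer, BatchNorm3d):
            layer.running_mean[...] = next(it)
            layer.running_var[...] = next(it)
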