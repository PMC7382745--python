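"""Parameterized layers built on the autodiff ops.

Each layer owns named parameter :class:`~mdunet.autodiff.Tensor` objects and a
``__call__`` that builds the forward graph.  Initialization is He fan-in for
convolution weights, unit scale / zero shift for batch norm, drawn from an rng
passed in by the model so a run seed fixes every weight.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (
    Tensor,
    avg_pool2x2,
    conv2d,
    conv_transpose2x2,
    relu,
)

__all__ = ["Conv2d", "ConvTranspose2x2", "BatchNorm2d", "avg_pool2x2", "relu"]


def _he_init(rng, shape, fan_in, dtype):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d:
    """Stride-1 convolution with 'same' zero padding and a bias."""

    def __init__(self, cin, cout, k, rng, dtype=np.float32, name="conv"):
        self.name = name
        self.weight = Tensor(_he_init(rng, (cout, cin, k, k), cin * k * k, dtype),
                             requires_grad=True, name=f"{name}.weight")
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True, name=f"{name}.bias")
        self.out_channels = cout

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias)

    def parameters(self):
        return [self.weight, self.bias]


class ConvTranspose2x2:
    """Kernel-2 stride-2 transposed convolution (2x spatial upsampling)."""

    def __init__(self, cin, cout, rng, dtype=np.float32, name="upconv"):
        self.name = name
        self.weight = Tensor(_he_init(rng, (cin, cout, 2, 2), cin * 4, dtype),
                             requires_grad=True, name=f"{name}.weight")
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True, name=f"{name}.bias")
        self.out_channels = cout

    def __call__(self, x):
        return conv_transpose2x2(x, self.weight, self.bias)

    def parameters(self):
        return [self.weight, self.bias]


class BatchNorm2d:
    """Batch normalization over (N, H, W) per channel with running statistics.

    Training mode normalizes by batch moments and updates the running
    estimates; inference mode uses the running estimates, which makes single
    images and duplicated batch entries produce identical outputs.
    """

    def __init__(self, c, rng=None, momentum=0.1, eps=1e-5, dtype=np.float32, name="bn"):
        self.name = name
        self.gamma = Tensor(np.ones(c, dtype=dtype), requires_grad=True, name=f"{name}.gamma")
        self.beta = Tensor(np.zeros(c, dtype=dtype), requires_grad=True, name=f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, training=False):
        # activations are channels-last: normalize over (N, H, W) per channel
        g, b = self.gamma, self.beta
        if training:
            mean = x.data.mean(axis=(0, 1, 2))
            var = x.data.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(x.data.dtype)
        xhat = (x.data - mean.astype(x.data.dtype)) * invstd
        out_data = xhat * g.data + b.data
        m = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]

        def backward(grad):
            if b.requires_grad:
                b._accumulate(grad.sum(axis=(0, 1, 2)))
            if g.requires_grad:
                g._accumulate((grad * xhat).sum(axis=(0, 1, 2)))
            if x.requires_grad:
                gxhat = grad * g.data
                if training:
                    # full batch-norm backward: mean and var depend on x
                    s1 = gxhat.sum(axis=(0, 1, 2))
                    s2 = (gxhat * xhat).sum(axis=(0, 1, 2))
                    gx = (gxhat - s1 / m - xhat * (s2 / m)) * invstd
                else:
                    gx = gxhat * invstd
                x._accumulate(gx.astype(x.data.dtype, copy=False))

        return Tensor(out_data.astype(x.data.dtype, copy=False), parents=(x, g, b), backward=backward)

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}
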