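"""Layer and optimiser classes on top of the autodiff engine.

Initialisation is explicit: every layer takes a ``numpy.random.Generator``
so a whole network is reproducible from one seed.  He-normal fan-in
initialisation for convolution weights, zeros for biases, ones/zeros for
batch-norm affine parameters.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Tensor


class Module:
    """Minimal container with parameter traversal and train/eval state."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name, array):
        p = Tensor(array, requires_grad=True)
        self._params[name] = p
        object.__setattr__(self, name, p)
        return p

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix=""):
        for n, p in self._params.items():
            yield (f"{prefix}{n}", p)
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mn}.")

    def buffers(self, prefix=""):
        """Non-trainable state (batch-norm running statistics)."""
        for mn, m in self._modules.items():
            yield from m.buffers(prefix=f"{prefix}{mn}.")

    def train(self, mode=True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- checkpoint support -------------------------------------------
    def state_dict(self):
        state = {f"param.{n}": p.data for n, p in self.named_parameters()}
        state.update({f"buffer.{n}": b for n, b in self.buffers()})
        return state

    def load_state_dict(self, state):
        for n, p in self.named_parameters():
            p.data = np.asarray(state[f"param.{n}"], dtype=np.float32)
        for n, b in self.buffers():
            b[...] = np.asarray(state[f"buffer.{n}"], dtype=b.dtype)


def _he_normal(rng, shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, padding=0,
                 dilation=1, bias=True):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_ch * kernel * kernel
        self.register_parameter(
            "weight", _he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = None
        if bias:
            self.register_parameter("bias", np.zeros(out_ch, dtype=np.float32))

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.register_parameter("gamma", np.ones(ch, dtype=np.float32))
        self.register_parameter("beta", np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def buffers(self, prefix=""):
        yield (f"{prefix}running_mean", self.running_mean)
        yield (f"{prefix}running_var", self.running_var)
        yield from super().buffers(prefix)

    def forward(self, x):
        return F.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training,
                              momentum=self.momentum, eps=self.eps)


class ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, padding=None,
                 dilation=1):
        super().__init__()
        if padding is None:
            padding = dilation * (kernel // 2)
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, stride=stride,
                           padding=padding, dilation=dilation, bias=False)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return F.relu(self.bn(self.conv(x)))


class DeformConv2d(Module):
    """Deformable convolution: a plain conv predicts per-tap (dy, dx) offsets,
    then the main kernel samples the input at the displaced positions.

    Offset-predictor weights start at zero, so an untrained layer behaves
    exactly like its non-deformable counterpart.
    """

    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, padding=0,
                 dilation=1, bias=True):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_ch * kernel * kernel
        self.register_parameter(
            "weight", _he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = None
        if bias:
            self.register_parameter("bias", np.zeros(out_ch, dtype=np.float32))
        self.offset_conv = Conv2d(in_ch, 2 * kernel * kernel, kernel, rng,
                                  stride=stride, padding=padding,
                                  dilation=dilation, bias=True)
        self.offset_conv.weight.data[...] = 0.0

    def forward(self, x):
        offset = self.offset_conv(x)
        return F.deform_conv2d(x, offset, self.weight, self.bias,
                               stride=self.stride, padding=self.padding,
                               dilation=self.dilation)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"m{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay folded into
    the gradient (the convention of the reference deep-learning stacks)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
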