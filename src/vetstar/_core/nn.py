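"""Neural-network building blocks on top of the tensor core.

Conv2d uses an im2col/matmul formulation with a direct fast path for
depthwise kernels; BatchNorm2d keeps running statistics for inference.
State is saved/restored as flat ``name -> array`` dictionaries (``.npz``).
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, is_grad_enabled

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "SiLU",
    "ReLU6",
    "Identity",
    "Sequential",
]


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow), oh, ow


def _col2im(cols: np.ndarray, xshape, k: int, stride: int, pad: int):
    n, c, h, w = xshape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int, pad: int, groups: int) -> Tensor:
    """Grouped 2-D convolution; ``weight`` has shape (Cout, Cin/groups, K, K)."""
    n, cin, h, w = x.shape
    cout, cin_g, k, _ = weight.shape
    assert cin == cin_g * groups, "channel/groups mismatch"

    if groups == 1 and k == 1 and stride == 1 and pad == 0:
        # pointwise conv: plain matmul on the flattened map, no im2col copy
        cols = x.data.reshape(n, cin, h * w)
        wmat = weight.data.reshape(cout, cin)
        out_data = np.matmul(wmat[None], cols).reshape(n, cout, h, w)

        def bwd(g):
            gmat = g.reshape(n, cout, h * w)
            if weight.requires_grad:
                gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(0)
                weight._accum(gw.reshape(weight.shape))
            if x.requires_grad:
                x._accum(np.matmul(wmat.T[None], gmat).reshape(x.data.shape))

        parents = (x, weight)
    elif groups == 1:
        cols, oh, ow = _im2col(x.data, k, stride, pad)
        wmat = weight.data.reshape(cout, cin * k * k)
        out_data = np.matmul(wmat[None], cols).reshape(n, cout, oh, ow)

        def bwd(g):
            gmat = g.reshape(n, cout, oh * ow)
            if weight.requires_grad:
                gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(0)
                weight._accum(gw.reshape(weight.shape))
            if x.requires_grad:
                dcols = np.matmul(wmat.T[None], gmat)
                x._accum(_col2im(dcols, x.data.shape, k, stride, pad))

        parents = (x, weight)
    elif groups == cin and cout == cin:
        # depthwise: accumulate shifted slices, no im2col materialisation
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
        oh = (h + 2 * pad - k) // stride + 1
        ow = (w + 2 * pad - k) // stride + 1
        out_data = np.zeros((n, cin, oh, ow), dtype=x.data.dtype)
        for i in range(k):
            for j in range(k):
                out_data += (
                    xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
                    * weight.data[:, 0, i, j][None, :, None, None]
                )

        def bwd(g):
            if weight.requires_grad:
                gw = np.empty_like(weight.data)
                for i in range(k):
                    for j in range(k):
                        gw[:, 0, i, j] = (
                            g * xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
                        ).sum(axis=(0, 2, 3))
                weight._accum(gw)
            if x.requires_grad:
                gx = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        gx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                            g * weight.data[:, 0, i, j][None, :, None, None]
                        )
                x._accum(gx[:, :, pad : pad + h, pad : pad + w] if pad else gx)

        parents = (x, weight)
    else:  # general grouped conv via per-group im2col
        cpg_in, cpg_out = cin // groups, cout // groups
        chunks, saved = [], []
        for gi in range(groups):
            xs = x.data[:, gi * cpg_in : (gi + 1) * cpg_in]
            cols, oh, ow = _im2col(xs, k, stride, pad)
            wmat = weight.data[gi * cpg_out : (gi + 1) * cpg_out].reshape(cpg_out, cpg_in * k * k)
            chunks.append(np.matmul(wmat[None], cols).reshape(n, cpg_out, oh, ow))
            saved.append((cols, wmat))
        out_data = np.concatenate(chunks, axis=1)

        def bwd(g):
            gx_full = np.zeros_like(x.data) if x.requires_grad else None
            for gi in range(groups):
                cols, wmat = saved[gi]
                gmat = g[:, gi * cpg_out : (gi + 1) * cpg_out].reshape(n, cpg_out, oh * ow)
                if weight.requires_grad:
                    gw = np.einsum("ncl,nkl->ck", gmat, cols)
                    weight.grad = weight.grad if weight.grad is not None else np.zeros_like(weight.data)
                    weight.grad[gi * cpg_out : (gi + 1) * cpg_out] += gw.reshape(cpg_out, cpg_in, k, k)
                if gx_full is not None:
                    dcols = np.matmul(wmat.T[None], gmat)
                    gx_full[:, gi * cpg_in : (gi + 1) * cpg_in] += _col2im(
                        dcols, (n, cpg_in, h, w), k, stride, pad
                    )
            if gx_full is not None:
                x._accum(gx_full)

        parents = (x, weight)

    out = Tensor._make(out_data, parents, bwd)
    if bias is not None:
        out = out + bias.reshape(1, cout, 1, 1)
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def named_buffers(self, prefix: str = ""):
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        """Total trainable scalars (conv weights/biases, BN scale and shift)."""
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({k: b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        for k, p in self.named_parameters():
            p.data[...] = state[k]
        for k, b in self.named_buffers():
            b[...] = state[k]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as z:
            self.load_state_dict({k: z[k] for k in z.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=None, groups=1, bias=True, rng=None):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.groups = stride, groups
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin // groups * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound, (cout, cin // groups, k, k)))
        self.bias = Parameter(rng.uniform(-bound, bound, cout)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self._buffers["running_mean"] = np.zeros(c, dtype=np.float32)
        self._buffers["running_var"] = np.ones(c, dtype=np.float32)

    def forward(self, x):
        gamma, beta = self.weight, self.bias
        if self.training and is_grad_enabled():
            ax = (0, 2, 3)
            mu = x.data.mean(axis=ax)
            var = x.data.var(axis=ax)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var
            inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
            out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

            def bwd(g):
                gs = (g * xhat).sum(axis=ax)
                gb = g.sum(axis=ax)
                if gamma.requires_grad:
                    gamma._accum(gs)
                if beta.requires_grad:
                    beta._accum(gb)
                if x.requires_grad:
                    nhw = g.shape[0] * g.shape[2] * g.shape[3]
                    coef = (gamma.data * inv)[None, :, None, None]
                    x._accum(coef * (g - gb[None, :, None, None] / nhw
                                     - xhat * gs[None, :, None, None] / nhw))

            return Tensor._make(out_data, (x, gamma, beta), bwd)
        rm = self._buffers["running_mean"]
        rv = self._buffers["running_var"]
        inv = 1.0 / np.sqrt(rv + self.eps)
        scale = Tensor((gamma.data * inv).reshape(1, self.c, 1, 1))
        shift = Tensor((beta.data - gamma.data * rm * inv).reshape(1, self.c, 1, 1))
        return x * scale + shift


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU6(Module):
    def forward(self, x):
        return x.relu6()


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i):
        return self._seq[i]

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x
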