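"""Generalized-mean (GeM) pooling with a learnable exponent.

GeM reduces each channel's H×W activation map to a single scalar through the
power mean  f_k = ( (1/|X_k|) Σ_i x_i^p )^(1/p).  At p = 1 this is global
average pooling; as p → ∞ it approaches global max pooling.  The exponent is
a trainable parameter (shared across channels by default), so the layer
learns where to sit between "average everything" and "keep only the peak" —
useful when the discriminative evidence (an insect body against clutter) is
spatially concentrated.
"""

from __future__ import annotations

import numpy as np

from .nn import Module, Parameter, Tensor

__all__ = ["GeMPool", "gem_pool"]

P_MIN, P_MAX = 1.0, 100.0  # keeps the mean between the average/max limit cases


def gem_pool(x, p, eps: float = 1e-6) -> Tensor:
    """Generalized-mean pool a feature map to per-channel scalars.

    Parameters
    ----------
    x : Tensor or array, shape [B, C, H, W] or [C, H, W]
        Feature map; entries are clamped to ``>= eps`` before the power, so
        the fractional exponent and its gradient are always defined
        (activations are post-ReLU nonnegative in practice).
    p : Tensor, array or float
        Pooling exponent, scalar or per-channel [C]; clamped to
        [{pmin}, {pmax}].
    Returns
    -------
    Tensor of shape [B, C] (or [C] for unbatched input).
    """
    x = Tensor.as_tensor(x)
    squeeze = x.ndim == 3
    if squeeze:
        x = x.reshape(1, *x.shape)
    if x.ndim != 4:
        raise ValueError(f"expected [B,C,H,W] or [C,H,W], got shape {x.shape}")
    if not np.all(np.isfinite(x.data)):
        raise ValueError("gem_pool requires finite input")
    p = Tensor.as_tensor(p)
    p = p.clip(lo=P_MIN)  # power mean well defined and monotone for p >= 1
    if p.ndim == 1:  # per-channel exponent
        p = p.reshape(1, p.shape[0], 1, 1)
    xc = x.clip(lo=eps)
    # factor out the (constant) per-channel max: gem(x) = m * gem(x/m);
    # keeps x^p in [0, 1] so large exponents cannot overflow
    m = Tensor(xc.data.max(axis=(2, 3), keepdims=True))
    powered = (xc / m) ** p
    mean = powered.mean(axis=(2, 3), keepdims=True)  # [B, C, 1, 1]
    out = m * (mean.log() / p).exp()  # m * mean ** (1/p), grad flows to p
    out = out.reshape(out.shape[0], out.shape[1])
    if squeeze:
        out = out.reshape(out.shape[1])
    return out


gem_pool.__doc__ = gem_pool.__doc__.format(pmin=P_MIN, pmax=P_MAX)


class GeMPool(Module):
    """Trainable GeM pooling layer: [B, C, H, W] -> [B, C].

    Parameters
    ----------
    channels : int, optional
        Needed only when ``shared=False`` (one exponent per channel).
    p_init : float
        Initial exponent (default 3.0, the usual retrieval-literature value).
    shared : bool
        One exponent for all channels (default) or one per channel.
    eps : float
        Lower clamp applied to activations before exponentiation.
    """

    def __init__(self, channels: int | None = None, p_init: float = 3.0,
                 shared: bool = True, eps: float = 1e-6):
        super().__init__()
        if p_init < P_MIN:
            raise ValueError(f"p_init must be >= {P_MIN}")
        if shared:
            self.p = Parameter(np.array(float(p_init)))
        else:
            if channels is None:
                raise ValueError("per-channel GeM needs the channel count")
            self.p = Parameter(np.full(channels, float(p_init)))
        self.eps = eps

    def forward(self, x):
        # the learnable exponent is kept in [1, 100] during optimisation:
        # between the average- and (near-)max-pooling limit cases
        return gem_pool(x, self.p.clip(P_MIN, P_MAX), eps=self.eps)
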