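"""Geometric vector perceptron layers.

A GVP couples rotation-invariant scalar channels ``S_n`` with
rotation-equivariant vector channels ``V_v`` (each a 3-vector). The
forward map is

    V_h = W_h V_v                 (channel mix, no bias)
    S_h = ||V_h||_2               (row-wise norms)
    S_m = W_m [S_h ; S_n] + b     (scalar update, bias allowed)
    V_u = W_u V_h                 (second channel mix, no bias)
    v_u = ||V_u||_2
    V'  = sigma_plus(v_u) . V_u   (row-wise gating)
    S'  = sigma(S_m)

Vector-channel maps mix channels only, never spatial coordinates, and
carry no bias — this is exactly what makes V' transform as R V' under a
global rotation R while S' is unchanged. Norms use an 1e-8 epsilon floor
inside the square root so gradients stay finite at zero vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, index_add, layer_norm

__all__ = ["GvpParams", "gvp_forward", "GvpConvLayer", "gvp_stack_forward"]

_SCALAR_ACTS = {
    "relu": lambda t: t.relu(),
    "identity": lambda t: t,
    "sigmoid": lambda t: t.sigmoid(),
}
_GATE_ACTS = {
    "sigmoid": lambda t: t.sigmoid(),
    "identity": lambda t: t,
}


@dataclass
class GvpParams:
    """Learnable maps of one GVP. Hidden width h = max(v_in, n_in) by default."""

    W_h: Tensor      # (h, v_in)
    W_mu: Tensor     # (v_out, h)
    W_m: Tensor      # (n_out, h + n_in)
    b_m: Tensor      # (n_out,)
    sigma: str = "relu"
    sigma_plus: str = "sigmoid"

    @staticmethod
    def init(
        rng: np.random.Generator,
        n_in: int,
        v_in: int,
        n_out: int,
        v_out: int,
        sigma: str = "relu",
        sigma_plus: str = "sigmoid",
        h: int | None = None,
    ) -> "GvpParams":
        if n_in == 0 and v_in == 0:
            raise ValueError("GVP needs at least one scalar or vector input channel")
        if h is None:
            h = max(v_in, n_in, 1)

        def glorot(fan_out, fan_in):
            s = np.sqrt(2.0 / (fan_in + fan_out))
            return Tensor(rng.normal(0.0, s, size=(fan_out, fan_in)), requires_grad=True)

        return GvpParams(
            W_h=glorot(h, max(v_in, 1)),
            W_mu=glorot(v_out, h),
            W_m=glorot(n_out, h + n_in),
            b_m=Tensor(np.zeros(n_out), requires_grad=True),
            sigma=sigma,
            sigma_plus=sigma_plus,
        )

    def tensors(self) -> list[Tensor]:
        return [self.W_h, self.W_mu, self.W_m, self.b_m]


def gvp_forward(s: Tensor | np.ndarray, v: Tensor | np.ndarray, params: GvpParams) -> tuple[Tensor, Tensor]:
    """One GVP. ``s``: (..., n_in) scalars; ``v``: (..., v_in, 3) vectors.

    Returns ``(S', V')`` with shapes (..., n_out) and (..., v_out, 3).
    """
    s = s if isinstance(s, Tensor) else Tensor(s)
    v = v if isinstance(v, Tensor) else Tensor(v)
    if not np.all(np.isfinite(s.data)) or not np.all(np.isfinite(v.data)):
        raise ValueError("non-finite values in GVP input")
    V_h = params.W_h @ v                      # (..., h, 3)
    S_h = V_h.norm(axis=-1)                   # (..., h)
    S_m = concat([S_h, s], axis=-1) @ params.W_m.T + params.b_m
    V_mu = params.W_mu @ V_h                  # (..., v_out, 3)
    v_mu = V_mu.norm(axis=-1, keepdims=True)  # (..., v_out, 1)
    gate = _GATE_ACTS[params.sigma_plus](v_mu)
    V_prime = gate * V_mu
    S_prime = _SCALAR_ACTS[params.sigma](S_m)
    return S_prime, V_prime


@dataclass
class GvpConvLayer:
    """One graph layer: per-edge message GVP, mean aggregation, residual node GVP.

    Message input for edge (src -> dst): scalars [s_src ; edge_scalars],
    vectors [v_src ; edge_vectors]. Aggregation is the mean over incoming
    edges. Scalar channels get residual + layer norm; vector channels get a
    plain residual (any normalization there would break equivariance).
    """

    message: GvpParams
    update: GvpParams
    ln_gain: Tensor
    ln_bias: Tensor
    ln_gain2: Tensor
    ln_bias2: Tensor

    @staticmethod
    def init(rng: np.random.Generator, ns: int, nv: int, es: int, ev: int) -> "GvpConvLayer":
        return GvpConvLayer(
            message=GvpParams.init(rng, ns + es, nv + ev, ns, nv),
            update=GvpParams.init(rng, ns, nv, ns, nv),
            ln_gain=Tensor(np.ones(ns), requires_grad=True),
            ln_bias=Tensor(np.zeros(ns), requires_grad=True),
            ln_gain2=Tensor(np.ones(ns), requires_grad=True),
            ln_bias2=Tensor(np.zeros(ns), requires_grad=True),
        )

    def tensors(self) -> list[Tensor]:
        return (self.message.tensors() + self.update.tensors()
                + [self.ln_gain, self.ln_bias, self.ln_gain2, self.ln_bias2])

    def forward(
        self,
        s: Tensor,
        v: Tensor,
        edges: np.ndarray,
        edge_s: Tensor,
        edge_v: Tensor,
    ) -> tuple[Tensor, Tensor]:
        L = s.shape[0]
        if len(edges):
            src, dst = edges[:, 0], edges[:, 1]
            ms = concat([s[src], edge_s], axis=-1)
            mv = concat([v[src], edge_v], axis=-2)
            out_s, out_v = gvp_forward(ms, mv, self.message)
            counts = np.bincount(dst, minlength=L).astype(float)
            inv = 1.0 / np.maximum(counts, 1.0)
            agg_s = index_add(L, dst, out_s) * inv[:, None]
            agg_v = index_add(L, dst, out_v) * inv[:, None, None]
            s = layer_norm(s + agg_s, self.ln_gain, self.ln_bias)
            v = v + agg_v
        up_s, up_v = gvp_forward(s, v, self.update)
        s = layer_norm(s + up_s, self.ln_gain2, self.ln_bias2)
        v = v + up_v
        return s, v


def gvp_stack_forward(
    layers: list[GvpConvLayer],
    s: Tensor,
    v: Tensor,
    edges: np.ndarray,
    edge_s: Tensor,
    edge_v: Tensor,
) -> tuple[Tensor, Tensor]:
    """Run the GVP-GNN layers over a protein graph; returns final (s, v)."""
    if not layers:
        raise ValueError("need at least one GVP layer")
    for layer in layers:
        ls, lv = s.shape[-1], v.shape[-2]
        s, v = layer.forward(s, v, edges, edge_s, edge_v)
        if s.shape[-1] != ls or v.shape[-2] != lv:
            raise ValueError("GVP stack layers must preserve channel counts")
    return s, v
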