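"""The Geometry-Complete Perceptron (GCP): a learnable map on (s, V) tuples.

Every entity (node or edge) carries a tuple ``(s, V)`` of t invariant scalar
channels and r equivariant 3-vector channels.  One GCP application:

1. ``z  = V w_dz``             — downscale the vector channels (r -> r/lam),
2. ``Vs = V w_ds``             — three 3-vector probe channels,
3. ``q  = <Vs, (a,b,c)>``      — scalarize the probes against the edge frame
                                 (9 rotation-invariant, reflection-sensitive
                                 numbers; node entities average q over their
                                 out-edges),
4. ``sv = [s, q, ||z||] w_s + b_s`` and ``s' = sigma_s(sv)``,
5. ``V' = (z w_uz) * sigma_g(sigma_+(sv) w_g + b_g)`` — channel-wise vector
   update gated by the new scalars.

All vector-channel maps act on the channel axis only and never mix Cartesian
components, so ``s'`` is rotation-invariant and ``V'`` rotation-equivariant
by construction.  The frame projection q is the only place reflection parity
enters: it is what gives the network chirality sensitivity, and zeroing it
(``use_frames=False``) yields the reflection-blind E(3) ablation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .autodiff import (
    ACTIVATIONS,
    Tensor,
    channel_map,
    concat,
    gather_rows,
    scatter_mean,
    vec_norm,
)

__all__ = ["ScalarVector", "GCPConfig", "GCP", "ResGCP", "scalarize"]


@dataclass
class ScalarVector:
    """A (s, V) feature tuple: s rows x t invariants, V rows x r x 3 vectors.

    Either member may be ``None`` (width zero) — e.g. raw edge features with
    no vector channels, or a scalars-only ablation.
    """

    s: Tensor | None = None
    V: Tensor | None = None

    @property
    def widths(self) -> tuple[int, int]:
        t = 0 if self.s is None else self.s.shape[-1]
        r = 0 if self.V is None else self.V.shape[-2]
        return t, r

    @property
    def n_rows(self) -> int:
        if self.s is not None:
            return self.s.shape[0]
        if self.V is not None:
            return self.V.shape[0]
        raise ValueError("empty ScalarVector")

    def __add__(self, other: "ScalarVector") -> "ScalarVector":
        s = self.s if other.s is None else (other.s if self.s is None else self.s + other.s)
        v = self.V if other.V is None else (other.V if self.V is None else self.V + other.V)
        return ScalarVector(s, v)

    def cat(self, other: "ScalarVector") -> "ScalarVector":
        """Channel-wise concatenation on both members."""
        parts_s = [p for p in (self.s, other.s) if p is not None]
        parts_v = [p for p in (self.V, other.V) if p is not None]
        return ScalarVector(
            concat(parts_s, axis=-1) if parts_s else None,
            concat(parts_v, axis=-2) if parts_v else None,
        )

    def detach(self) -> "ScalarVector":
        return ScalarVector(
            None if self.s is None else self.s.detach(),
            None if self.V is None else self.V.detach(),
        )


@dataclass
class GCPConfig:
    """Hyperparameters shared by every GCP in a network.

    lambda_down : channel downscaling factor (r -> max(1, ceil(r/lambda))).
    omega       : number of stacked GCP applications inside a convolution.
    sigma_s / sigma_plus / sigma_g : names of the scalar, pre-gate and gate
        nonlinearities (keys of ``autodiff.ACTIVATIONS``).
    use_frames / use_scalars / use_vectors / use_residual : ablation switches
        mirroring the "w/o Frames / Scalars / Vectors / ResGCP" variants.
    """

    lambda_down: int = 3
    omega: int = 3
    sigma_s: str = "silu"
    sigma_plus: str = "silu"
    sigma_g: str = "sigmoid"
    use_frames: bool = True
    use_scalars: bool = True
    use_vectors: bool = True
    use_residual: bool = True

    def replace(self, **kw) -> "GCPConfig":
        return replace(self, **kw)


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def _frame_project(v: Tensor, frames_mat: np.ndarray) -> Tensor:
    """Inner products of probe vectors against frame axes.

    ``v`` is (rows, 3, 3) with rows aligned to ``frames_mat`` (rows, 3, 3)
    whose second axis stacks (a, b, c).  Output is (rows, 9), channel-major
    with axis order (a, b, c).  Frames are constants on the tape.
    """
    f = np.asarray(frames_mat, dtype=np.float64)
    out = np.einsum("ecx,eax->eca", v.data, f, optimize=True)
    rows = out.shape[0]

    def grad_fn(g):
        g3 = g.reshape(rows, 3, 3)
        return np.einsum("eca,eax->ecx", g3, f, optimize=True)

    return Tensor(out.reshape(rows, 9), parents=((v, grad_fn),))


def scalarize(
    vs: Tensor,
    frames_mat: np.ndarray,
    edges: np.ndarray,
    entity_kind: str,
    n_nodes: int | None = None,
) -> Tensor:
    """Rotation-invariant frame projections q (Eq. 3/4 style).

    For edge entities, ``vs`` has one row per edge and q is the direct
    projection.  For node entities, each node's probes are projected against
    the frame of every one of its out-edges and averaged; nodes with no
    out-edges get q = 0.
    """
    if entity_kind == "edge":
        return _frame_project(vs, frames_mat)
    if entity_kind == "node":
        if n_nodes is None:
            raise ValueError("node scalarization needs n_nodes")
        src = np.asarray(edges)[:, 0]
        q_edge = _frame_project(gather_rows(vs, src), frames_mat)
        return scatter_mean(q_edge, src, n_nodes)
    raise ValueError(f"unknown entity_kind {entity_kind!r}")


class GCP:
    """One Geometry-Complete Perceptron mapping (t, r) widths to (t', r')."""

    def __init__(
        self,
        rng: np.random.Generator,
        in_dims: tuple[int, int],
        out_dims: tuple[int, int],
        config: GCPConfig | None = None,
    ):
        self.config = config or GCPConfig()
        t, r = in_dims
        t_out, r_out = out_dims
        if t < 1:
            raise ValueError("scalar input width must be >= 1")
        if r == 0 and r_out > 0:
            raise ValueError("cannot create vector channels from none (equivariance)")
        if t_out == 0 and r_out == 0:
            raise ValueError("all-zero output widths")
        self.in_dims = (t, r)
        self.out_dims = (t_out, r_out)
        self.r_down = max(1, math.ceil(r / self.config.lambda_down)) if r > 0 else 0
        self.params: dict[str, Tensor] = {}
        scalar_in = t + (9 + self.r_down if r > 0 else 0)
        if r > 0:
            self.params["w_dz"] = _uniform(rng, (r, self.r_down), r)
            self.params["w_ds"] = _uniform(rng, (r, 3), r)
        self.params["w_s"] = _uniform(rng, (scalar_in, t_out), scalar_in)
        self.params["b_s"] = Tensor(np.zeros(t_out), requires_grad=True)
        if r_out > 0:
            self.params["w_uz"] = _uniform(rng, (self.r_down, r_out), self.r_down)
            self.params["w_g"] = _uniform(rng, (t_out, r_out), t_out)
            self.params["b_g"] = Tensor(np.zeros(r_out), requires_grad=True)

    # -- the five sub-operations -----------------------------------------

    def downscale_z(self, v: Tensor) -> Tensor:
        return channel_map(v, self.params["w_dz"])

    def downscale_vs(self, v: Tensor) -> Tensor:
        return channel_map(v, self.params["w_ds"])

    def update_scalars(self, s: Tensor, q: Tensor | None, z: Tensor | None):
        parts = [s]
        if q is not None:
            parts.append(q)
        if z is not None:
            parts.append(vec_norm(z))
        s_cat = concat(parts, axis=-1) if len(parts) > 1 else s
        sv = s_cat @ self.params["w_s"] + self.params["b_s"]
        return ACTIVATIONS[self.config.sigma_s](sv), sv

    def update_vectors(self, z: Tensor, sv: Tensor) -> Tensor:
        vu = channel_map(z, self.params["w_uz"])
        gate = ACTIVATIONS[self.config.sigma_g](
            ACTIVATIONS[self.config.sigma_plus](sv) @ self.params["w_g"]
            + self.params["b_g"]
        )
        r_out = self.out_dims[1]
        return vu * gate.reshape(gate.shape[0], r_out, 1)

    # -- forward ----------------------------------------------------------

    def forward(
        self,
        sv_in: ScalarVector,
        frames_mat: np.ndarray | None,
        edges: np.ndarray | None,
        entity_kind: str,
        n_nodes: int | None = None,
    ) -> ScalarVector:
        t, r = self.in_dims
        got_t, got_r = sv_in.widths
        if (got_t, got_r) != (t, r):
            raise ValueError(f"width mismatch: expected {(t, r)}, got {(got_t, got_r)}")
        s = sv_in.s
        if not np.all(np.isfinite(s.data)) or (
                r > 0 and not np.all(np.isfinite(sv_in.V.data))):
            raise ValueError("non-finite input features")
        if r > 0:
            z = self.downscale_z(sv_in.V)
            if self.config.use_frames:
                if frames_mat is None:
                    raise ValueError("frames required when use_frames is on")
                vs = self.downscale_vs(sv_in.V)
                q = scalarize(vs, frames_mat, edges, entity_kind, n_nodes)
            else:
                q = Tensor(np.zeros((sv_in.n_rows, 9)))
        else:
            z = q = None
        s_out, sv = self.update_scalars(s, q, z)
        v_out = self.update_vectors(z, sv) if self.out_dims[1] > 0 else None
        return ScalarVector(s_out if self.out_dims[0] > 0 else None, v_out)

    __call__ = forward

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        return {prefix + name: p for name, p in self.params.items()}


class ResGCP:
    """Residual wrapper: gcp(x) + x on both channels (equal in/out widths)."""

    def __init__(self, rng, dims: tuple[int, int], config: GCPConfig | None = None):
        self.gcp = GCP(rng, dims, dims, config)

    def forward(self, sv_in, frames_mat, edges, entity_kind, n_nodes=None):
        out = self.gcp.forward(sv_in, frames_mat, edges, entity_kind, n_nodes)
        return out + sv_in

    __call__ = forward

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        return self.gcp.parameters(prefix)
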