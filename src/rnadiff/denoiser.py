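"""The trainable denoiser network.

Architecture: a coordinate encoder (linear, layer-norm, sigmoid), stacked
two-branch message-passing blocks — a close-contact branch over covalent,
pairing and local edges using radial/angular basis features and a long-range
branch over global edges using distance expansions, fused per node by a
two-way softmax attention with a residual connection — followed by an
unmasked transformer encoder over all atoms and per-atom output heads for
the noise vector and atom/residue type logits.  No pooling anywhere: all
outputs are per node.

The network is intentionally not SE(3)-equivariant; data centering provides
partial invariance, and the noise head sees the current scaled coordinates
through a linear skip alongside the final node state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .graph import N_RADIAL, N_SPHERICAL

#: width of the per-directed-edge close-contact feature rows
CLOSE_EDGE_DIM = N_RADIAL + N_SPHERICAL * N_RADIAL + N_SPHERICAL
GLOBAL_EDGE_DIM = N_RADIAL
NODE_FEATURE_DIM = 3 + 1 + 4 + 256 + 16


@dataclass
class DenoiserConfig:
    n_blocks: int = 6
    hidden: int = 256
    n_transformer_layers: int = 6
    n_heads: int = 8
    n_rbf: int = N_RADIAL
    n_sbf: int = N_SPHERICAL

    def __post_init__(self):
        if min(self.n_blocks, self.hidden, self.n_transformer_layers,
               self.n_heads, self.n_rbf, self.n_sbf) <= 0:
            raise ValueError("all config fields must be positive")
        if self.hidden % self.n_heads:
            raise ValueError("hidden must be divisible by n_heads")

    @classmethod
    def desk_scale(cls) -> "DenoiserConfig":
        """Small configuration for CPU-scale experiments."""
        return cls(n_blocks=2, hidden=64, n_transformer_layers=2, n_heads=4)


@dataclass
class DenoiserOutput:
    eps_hat: nn.Tensor               # (n_atoms, 3)
    atom_type_logits: nn.Tensor      # (n_atoms, 3)
    residue_type_logits: nn.Tensor   # (n_atoms, 4)


@dataclass
class GraphBatch:
    """Constant per-call inputs: node features and directed edge tensors.

    ``alpha_bar`` carries the cumulative signal fraction of the current
    diffusion step; when present, the network predicts the clean
    coordinates internally and converts to a noise estimate analytically.
    """
    node_features: np.ndarray        # (n_atoms, NODE_FEATURE_DIM)
    close_src: np.ndarray
    close_dst: np.ndarray
    close_feats: np.ndarray          # (n_close, CLOSE_EDGE_DIM)
    global_src: np.ndarray
    global_dst: np.ndarray
    global_feats: np.ndarray         # (n_global, GLOBAL_EDGE_DIM)
    alpha_bar: float | None = None


class MessageBlock(nn.Module):
    """Two-branch message passing with learned two-way attention fusion."""

    def __init__(self, hidden: int, rng: np.random.Generator):
        self.local_src = nn.Linear(hidden, hidden, rng, bias=False)
        self.local_edge = nn.Linear(CLOSE_EDGE_DIM, hidden, rng)
        self.local_update = nn.Linear(2 * hidden, hidden, rng)
        self.global_src = nn.Linear(hidden, hidden, rng, bias=False)
        self.global_edge = nn.Linear(GLOBAL_EDGE_DIM, hidden, rng)
        self.global_update = nn.Linear(2 * hidden, hidden, rng)
        self.score_local = nn.Linear(hidden, 1, rng)
        self.score_global = nn.Linear(hidden, 1, rng)

    def _branch(self, h, src, dst, feats, w_src, w_edge, w_update, n):
        if len(src) == 0:
            agg = nn.Tensor(np.zeros((n, h.shape[1])))
        else:
            msg = nn.mul(nn.gather_rows(w_src(h), src),
                         nn.sigmoid(w_edge(nn.Tensor(feats))))
            agg = nn.scatter_sum(msg, dst, n)
        return nn.relu(w_update(nn.concat([h, agg], axis=-1)))

    def __call__(self, h: nn.Tensor, batch: GraphBatch) -> nn.Tensor:
        n = h.shape[0]
        h_loc = self._branch(h, batch.close_src, batch.close_dst,
                             batch.close_feats, self.local_src,
                             self.local_edge, self.local_update, n)
        h_glob = self._branch(h, batch.global_src, batch.global_dst,
                              batch.global_feats, self.global_src,
                              self.global_edge, self.global_update, n)
        att = nn.softmax(nn.concat([self.score_local(h_loc),
                                    self.score_global(h_glob)], axis=-1))
        wl = nn.slice_cols(att, slice(0, 1))
        wg = nn.slice_cols(att, slice(1, 2))
        return h + nn.mul(wl, h_loc) + nn.mul(wg, h_glob)


class TransformerLayer(nn.Module):
    """Pre-norm self-attention encoder layer (no positional encoding)."""

    def __init__(self, hidden: int, n_heads: int, rng: np.random.Generator):
        self.norm1 = nn.LayerNorm(hidden)
        self.attn = nn.MultiheadSelfAttention(hidden, n_heads, rng)
        self.norm2 = nn.LayerNorm(hidden)
        self.ff1 = nn.Linear(hidden, 2 * hidden, rng)
        self.ff2 = nn.Linear(2 * hidden, hidden, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ff2(nn.relu(self.ff1(self.norm2(x))))


class Denoiser(nn.Module):
    def __init__(self, config: DenoiserConfig | None = None, seed: int = 0):
        self.config = config or DenoiserConfig()
        rng = np.random.default_rng(seed)
        h = self.config.hidden
        self.coord_lin = nn.Linear(3, h, rng)
        self.coord_norm = nn.LayerNorm(h)
        self.feat_proj = nn.Linear(NODE_FEATURE_DIM, h, rng)
        self.blocks = [MessageBlock(h, rng) for _ in range(self.config.n_blocks)]
        self.transformer = [TransformerLayer(h, self.config.n_heads, rng)
                            for _ in range(self.config.n_transformer_layers)]
        self.out_norm = nn.LayerNorm(h)
        # the noise head sees the final state, the scaled coordinates (skip)
        # and the raw time embedding; the hidden layer lets it realize the
        # step-dependent gain on x_t that epsilon-regression requires near t=0
        self.head_eps_hidden = nn.Linear(h + 3 + 16, h, rng)
        self.head_eps = nn.Linear(h + 3, 3, rng)
        self.head_atom = nn.Linear(h, 3, rng)
        self.head_residue = nn.Linear(h, 4, rng)

    def encode_coordinates(self, coords_scaled: np.ndarray) -> nn.Tensor:
        """Linear, layer-norm, sigmoid: per-atom vectors in (0, 1)^hidden."""
        coords_scaled = np.asarray(coords_scaled, float)
        if not np.all(np.isfinite(coords_scaled)):
            raise ValueError("non-finite coordinates")
        return nn.sigmoid(self.coord_norm(self.coord_lin(nn.Tensor(coords_scaled))))

    def __call__(self, batch: GraphBatch,
                 coords_scaled: np.ndarray) -> DenoiserOutput:
        return self.predict_noise(batch, coords_scaled)

    def predict_noise(self, batch: GraphBatch,
                      coords_scaled: np.ndarray) -> DenoiserOutput:
        h = self.encode_coordinates(coords_scaled) + \
            self.feat_proj(nn.Tensor(batch.node_features))
        for block in self.blocks:
            h = block(h, batch)
        for layer in self.transformer:
            h = layer(h)
        h = self.out_norm(h)
        coords_t = nn.Tensor(np.asarray(coords_scaled, float))
        t_emb = nn.Tensor(batch.node_features[:, -16:])
        hidden = nn.relu(self.head_eps_hidden(
            nn.concat([h, coords_t, t_emb], axis=-1)))
        head = self.head_eps(nn.concat([hidden, coords_t], axis=-1))
        if batch.alpha_bar is not None:
            # head output is x0-hat; the epsilon estimate follows exactly
            # from x_t = sqrt(abar) x0 + sqrt(1-abar) eps, so the steep
            # step-dependent gain near t=0 is applied analytically rather
            # than learned
            ab = float(batch.alpha_bar)
            eps_hat = (coords_t + head * (-np.sqrt(ab))) * \
                (1.0 / np.sqrt(1.0 - ab))
        else:
            eps_hat = head
        return DenoiserOutput(eps_hat=eps_hat,
                              atom_type_logits=self.head_atom(h),
                              residue_type_logits=self.head_residue(h))
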