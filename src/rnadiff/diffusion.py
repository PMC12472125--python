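"""DDPM over atom coordinates: schedule, corruption, training, sampling.

The forward process corrupts only the coordinates — node features, atom
names and the static connectivity are preserved — with x_t =
sqrt(abar_t) x0 + sqrt(1 - abar_t) eps on a linear beta schedule.  The
denoiser is trained by epsilon-regression; ancestral sampling runs the
learned reverse chain from pure noise, rebuilding dynamic edges from the
current (noisy) coordinates at every step, the same regime at training and
inference time.

Coordinates fed to the network live in the scaled frame (angstroms divided
by 10 after centering); edge geometry is always computed on unscaled
angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import graph as G
from . import embeddings as E
from .denoiser import Denoiser, GraphBatch
from .structure import (Atom, Residue, RnaStructure, SecondaryStructure,
                        COARSE_ATOMS, COORDINATE_SCALE)
from . import nn

#: classic DDPM endpoints at the reference step count, rescaled with T so the
#: total corruption (sum of betas ~ 10) is preserved at any T
_REF_T = 5000
_REF_BETA_START = 2e-5
_REF_BETA_END = 4e-3


@dataclass
class DiffusionConfig:
    T: int = 5000
    beta_start: float | None = None
    beta_end: float | None = None
    seed: int = 0
    predict: str = "epsilon"
    coordinate_scale: float = COORDINATE_SCALE

    def __post_init__(self):
        if self.beta_start is None:
            self.beta_start = _REF_BETA_START * _REF_T / self.T
        if self.beta_end is None:
            # cap keeps the derived schedule valid for very short chains
            self.beta_end = min(_REF_BETA_END * _REF_T / self.T, 0.5)
        if not self.beta_start < self.beta_end:
            raise ValueError("beta_start must be < beta_end")
        if self.predict != "epsilon":
            raise ValueError("only epsilon-prediction is implemented")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "DiffusionConfig":
        return cls(T=200, seed=seed)


@dataclass
class NoiseSchedule:
    T: int
    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray


def make_schedule(cfg: DiffusionConfig) -> NoiseSchedule:
    """Linear beta schedule with derived alpha and cumulative-product tables."""
    if cfg.T < 2:
        raise ValueError("T must be >= 2")
    betas = np.linspace(cfg.beta_start, cfg.beta_end, cfg.T)
    if np.any(betas <= 0) or np.any(betas >= 1):
        raise ValueError("betas must lie in (0, 1)")
    alphas = 1.0 - betas
    return NoiseSchedule(cfg.T, betas, alphas, np.cumprod(alphas))


def time_embedding(t: int, dim: int = 16, T: int = 5000) -> np.ndarray:
    """Sinusoidal step embedding: half sines, half cosines, geometric freqs."""
    if not 0 <= t < T:
        raise ValueError(f"step {t} outside [0, {T})")
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    angles = t * freqs
    return np.concatenate([np.sin(angles), np.cos(angles)])


def forward_sample(x0: np.ndarray, t: int, sched: NoiseSchedule,
                   noise: np.ndarray | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Closed-form corruption x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps."""
    x0 = np.asarray(x0, float)
    if noise is None:
        rng = rng or np.random.default_rng()
        noise = rng.standard_normal(x0.shape)
    ab = sched.alpha_bars[t]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * noise


# ---------------------------------------------------------------------------
# Graph template: everything about an instance except its coordinates
# ---------------------------------------------------------------------------

class GraphTemplate:
    """Static graph and node features of one RNA instance.

    Built once from a coarse structure (or a sequence/secondary-structure
    input); per diffusion step only the dynamic edges and geometric edge
    features are recomputed from the current coordinates.
    """

    def __init__(self, structure: RnaStructure, ss: SecondaryStructure | None,
                 seq_embeddings: np.ndarray | None = None,
                 embed_seed: int = 0, embed_provider: str = "positional",
                 coordinate_scale: float = COORDINATE_SCALE):
        if not structure.coarse_grained:
            raise ValueError("template requires a coarse-grained structure")
        self.structure = structure
        self.ss = ss
        self.scale = coordinate_scale
        self.nodes, _ = G.enumerate_nodes(structure)
        self.static_edges = G.build_static_edges(structure, ss)
        if seq_embeddings is None:
            merged, _ = E.merge_segments(structure.sequences())
            provider = E.get_provider(embed_provider, seed=embed_seed)
            seq_embeddings = provider.embed(merged)
        zeros_t = np.zeros(G.TIME_EMB_DIM)
        self._base_features = G.node_feature_matrix(self.nodes, seq_embeddings,
                                                    zeros_t)

    @property
    def n_atoms(self) -> int:
        return len(self.nodes)

    def batch_for(self, coords_scaled: np.ndarray, t: int,
                  sched: NoiseSchedule) -> GraphBatch:
        """Graph inputs at one diffusion step: dynamic edges are rebuilt from
        the current coordinates; geometry runs on unscaled angstroms."""
        coords_A = np.asarray(coords_scaled, float) * self.scale
        dynamic = G.build_dynamic_edges(coords_A, self.static_edges)
        edges = self.static_edges + dynamic
        csrc, cdst, cfeat = G.close_edge_feature_matrix(edges, coords_A)
        gsrc, gdst, gfeat = G.global_edge_feature_matrix(dynamic, coords_A)
        feats = self._base_features.copy()
        feats[:, -G.TIME_EMB_DIM:] = time_embedding(t, G.TIME_EMB_DIM, sched.T)
        return GraphBatch(node_features=feats, close_src=csrc, close_dst=cdst,
                          close_feats=cfeat, global_src=gsrc, global_dst=gdst,
                          global_feats=gfeat,
                          alpha_bar=float(sched.alpha_bars[t]))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingState:
    """Optimizer hyperparameters and step LR schedule."""
    init_lr: float = 0.003
    lr_decay: float = 0.9
    decay_every: int = 30
    grad_clip: float = 2.0
    batch_size: int = 1
    epoch: int = 0
    history: list[float] = field(default_factory=list)

    def lr(self) -> float:
        return self.init_lr * self.lr_decay ** (self.epoch // self.decay_every)


def training_step(model: Denoiser, items: list[tuple[GraphTemplate, np.ndarray]],
                  sched: NoiseSchedule, state: TrainingState,
                  opt: nn.Adam, rng: np.random.Generator,
                  draws: int = 1, t_sampler=None) -> float:
    """One optimization step of the epsilon-regression objective.

    For every (template, x0) item: draw t uniformly and fresh Gaussian noise
    (``draws`` independent corruptions per item), rebuild dynamic edges on
    the noisy coordinates, and accumulate MSE(eps, eps_hat).  Applies the
    step LR schedule and global-norm gradient clipping before the Adam
    update.  Returns the (finite) scalar loss.  ``t_sampler`` overrides the
    default uniform draw of t (e.g. for stratified sampling).
    """
    if not items:
        raise ValueError("empty batch")
    opt.zero_grad()
    opt.lr = state.lr()
    losses = []
    for template, x0 in items:
        for _ in range(draws):
            t = (int(rng.integers(0, sched.T)) if t_sampler is None
                 else int(t_sampler(rng)))
            noise = rng.standard_normal(x0.shape)
            x_t = forward_sample(x0, t, sched, noise=noise)
            batch = template.batch_for(x_t, t, sched)
            out = model.predict_noise(batch, x_t)
            losses.append(nn.mse(out.eps_hat, noise))
    total = losses[0]
    for item in losses[1:]:
        total = total + item
    total = total * (1.0 / len(losses))
    if not np.isfinite(total.data):
        raise FloatingPointError(
            f"non-finite loss at epoch {state.epoch}: {total.data}")
    total.backward()
    nn.clip_grad_norm(opt.params, state.grad_clip)
    opt.step()
    loss = float(total.data)
    state.history.append(loss)
    return loss


def train(model: Denoiser, items: list[tuple[GraphTemplate, np.ndarray]],
          sched: NoiseSchedule, n_steps: int, seed: int = 0,
          state: TrainingState | None = None, draws: int = 1,
          lr: float | None = None, ema_decay: float = 0.999,
          stratify_t: bool = True) -> TrainingState:
    """Run ``n_steps`` optimization steps; one step counts as one epoch.

    Maintains an exponential moving average of the parameters (standard
    denoising-diffusion practice) and loads it into the model at the end,
    which removes most of the stochastic-gradient jitter from the final
    weights.  Set ``ema_decay=0`` to keep the raw last-step parameters.

    With ``stratify_t`` (default) the diffusion step t is drawn by cycling
    shuffled permutations of 0..T-1 instead of independent uniform draws:
    the marginal distribution is unchanged but every step index is visited
    evenly, a variance-reduction that matters for the few small-t steps
    where the objective is most sensitive.
    """
    state = state or TrainingState()
    if lr is not None:
        state.init_lr = lr
    rng = np.random.default_rng(seed)
    params = model.parameters()
    opt = nn.Adam(params, lr=state.init_lr)
    ema = [p.data.copy() for p in params] if ema_decay else None
    cycle: list[int] = []

    def stratified(r: np.random.Generator) -> int:
        if not cycle:
            cycle.extend(r.permutation(sched.T).tolist())
        return cycle.pop()

    sampler = stratified if stratify_t else None
    for _ in range(n_steps):
        training_step(model, items, sched, state, opt, rng, draws=draws,
                      t_sampler=sampler)
        state.epoch += 1
        if ema is not None:
            for shadow, p in zip(ema, params):
                shadow *= ema_decay
                shadow += (1.0 - ema_decay) * p.data
    if ema is not None:
        model.load_state_arrays(ema)
    return state


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def reverse_step(eps_hat: np.ndarray, x_t: np.ndarray, t: int,
                 sched: NoiseSchedule,
                 rng: np.random.Generator | None = None,
                 noise: np.ndarray | None = None) -> np.ndarray:
    """One ancestral DDPM step x_t -> x_{t-1} from a noise prediction.

    Uses the posterior mean with variance beta-tilde; the final step (t=0)
    is deterministic.  ``noise`` may be supplied explicitly (e.g. zeros for
    a deterministic trajectory).
    """
    beta = sched.betas[t]
    alpha = sched.alphas[t]
    abar = sched.alpha_bars[t]
    mean = (x_t - beta / np.sqrt(1.0 - abar) * eps_hat) / np.sqrt(alpha)
    if t == 0:
        return mean
    abar_prev = sched.alpha_bars[t - 1]
    var = beta * (1.0 - abar_prev) / (1.0 - abar)
    if noise is None:
        rng = rng or np.random.default_rng()
        noise = rng.standard_normal(x_t.shape)
    return mean + np.sqrt(var) * noise


def denoise_trajectory(model: Denoiser, template: GraphTemplate,
                       sched: NoiseSchedule, rng: np.random.Generator,
                       x_start: np.ndarray | None = None,
                       deterministic: bool = False) -> np.ndarray:
    """Run the full reverse chain; returns final scaled coordinates."""
    n = template.n_atoms
    x = (rng.standard_normal((n, 3)) if x_start is None
         else np.asarray(x_start, float))
    for t in range(sched.T - 1, -1, -1):
        batch = template.batch_for(x, t, sched)
        eps_hat = model.predict_noise(batch, x).eps_hat.data
        noise = np.zeros_like(x) if deterministic else None
        x = reverse_step(eps_hat, x, t, sched, rng=rng, noise=noise)
    return x


def structure_from_input(sequences: list[str],
                         name: str = "sampled") -> RnaStructure:
    """Coarse-grained structure template from strand sequences.

    Atoms are the 5-atom set (the first residue of each strand omits P);
    coordinates are zero placeholders to be filled by sampling.
    """
    chains = []
    for ci, seq in enumerate(sequences):
        chain_id = "ABCDEFGHIJ"[ci % 10]
        residues = []
        for i, base in enumerate(seq):
            names = COARSE_ATOMS[base]
            if i == 0:
                names = names[1:]  # no 5' phosphate
            atoms = {n: Atom(n, np.zeros(3)) for n in names}
            residues.append(Residue(chain_id, i, i + 1, base, atoms))
        chains.append(residues)
    return RnaStructure(chains, name=name, coarse_grained=True)


def sample_structure(model: Denoiser, sequences: list[str],
                     ss: SecondaryStructure | None, sched: NoiseSchedule,
                     seed: int = 0, embed_seed: int = 0,
                     coordinate_scale: float = COORDINATE_SCALE
                     ) -> RnaStructure:
    """Generate a coarse structure for a sequence/secondary-structure input.

    Coordinates are initialized as Gaussian noise and refined by the full
    reverse chain; the output is rescaled to angstroms (centered at the
    origin).  Deterministic for a fixed seed.
    """
    template_structure = structure_from_input(sequences)
    template = GraphTemplate(template_structure, ss, embed_seed=embed_seed,
                             coordinate_scale=coordinate_scale)
    rng = np.random.default_rng(seed)
    x = denoise_trajectory(model, template, sched, rng)
    out = template_structure.copy()
    out.set_coords(x * coordinate_scale)
    return out
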