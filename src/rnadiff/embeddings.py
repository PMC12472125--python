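"""Per-residue sequence embeddings.

The generative model consumes one 256-dimensional embedding per nucleotide,
normally produced by an external RNA language model run on the descriptor
segments merged into a single string.  To keep the package download-free,
a deterministic built-in provider maps each base to a fixed random vector
and projects it through the same bias-free 1280-wide ReLU projection head
used for external models.  Swapping providers changes feature values only,
never shapes or graph topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

from .structure import RnaStructure, BASES

logger = logging.getLogger(__name__)

EMBED_DIM = 256
HIDDEN_WIDTH = 1280


class EmbeddingProvider(Protocol):
    """Contract for sequence-embedding providers.

    ``embed`` must return one 256-vector per input position and be
    deterministic for a fixed provider state.
    """
    name: str

    def embed(self, merged_sequence: str) -> np.ndarray: ...


@dataclass
class ProjectionHead:
    """Bias-free linear layer to 1280 units, ReLU, then linear to 256."""
    w1: np.ndarray
    w2: np.ndarray

    @classmethod
    def seeded(cls, input_dim: int, seed: int,
               hidden: int = HIDDEN_WIDTH,
               output: int = EMBED_DIM) -> "ProjectionHead":
        rng = np.random.default_rng(seed)
        w1 = rng.normal(0.0, 1.0 / np.sqrt(input_dim), (input_dim, hidden))
        w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, output))
        return cls(w1, w2)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(x @ self.w1, 0.0) @ self.w2


def merge_segments(sequences: list[str]) -> tuple[str, list[tuple[int, int]]]:
    """Concatenate segment sequences (no separator token) with offsets.

    Returns the merged string and, for each merged position, the
    (segment, position-within-segment) it came from.  Keeping the segments
    in one string preserves sequential context for contextual language
    models; the absence of a separator is a documented limitation.
    """
    if not sequences or any(not s for s in sequences):
        raise ValueError("segments must be non-empty")
    merged = "".join(sequences)
    offsets = [(si, pi) for si, s in enumerate(sequences)
               for pi in range(len(s))]
    return merged, offsets


class FallbackProvider:
    """Deterministic per-nucleotide table embedding.

    Each base maps to a fixed seeded 64-vector pushed through the projection
    head; identical bases always receive identical embeddings (no sequence
    context — the documented gap versus a contextual language model).
    """

    name = "fallback"
    _BASE_DIM = 64

    def __init__(self, seed: int = 0):
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._table = {b: rng.normal(0.0, 1.0, self._BASE_DIM)
                       for b in sorted(BASES)}
        self._head = ProjectionHead.seeded(self._BASE_DIM, seed=seed + 1)

    def embed(self, merged_sequence: str) -> np.ndarray:
        unknown = set(merged_sequence) - BASES
        if unknown:
            raise ValueError(f"unknown symbols: {sorted(unknown)}")
        base_vecs = np.stack([self._table[b] for b in merged_sequence])
        return self._head(base_vecs)


def fallback_embed(merged: str, seed: int = 0) -> np.ndarray:
    """One seeded 256-vector per residue of ``merged``; same base, same vector."""
    return FallbackProvider(seed).embed(merged)


class PositionalProvider:
    """Deterministic position-and-base embedding.

    A contextual language model assigns different vectors to the same base at
    different sequence positions; that position-discriminating property is
    what lets the denoiser tell otherwise feature-identical residues apart.
    This provider emulates it offline: the input to the projection head is
    the base table vector concatenated with a sinusoidal encoding of the
    merged-sequence position.  Deterministic for a fixed seed.
    """

    name = "positional"
    _BASE_DIM = 64
    _POS_DIM = 64

    def __init__(self, seed: int = 0):
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._table = {b: rng.normal(0.0, 1.0, self._BASE_DIM)
                       for b in sorted(BASES)}
        self._head = ProjectionHead.seeded(self._BASE_DIM + self._POS_DIM,
                                           seed=seed + 1)

    def _positional(self, n: int) -> np.ndarray:
        half = self._POS_DIM // 2
        freqs = np.exp(-np.log(10000.0) * np.arange(half) / (half - 1))
        angles = np.outer(np.arange(n), freqs)
        return np.concatenate([np.sin(angles), np.cos(angles)], axis=1)

    def embed(self, merged_sequence: str) -> np.ndarray:
        unknown = set(merged_sequence) - BASES
        if unknown:
            raise ValueError(f"unknown symbols: {sorted(unknown)}")
        base_vecs = np.stack([self._table[b] for b in merged_sequence])
        pos = self._positional(len(merged_sequence))
        return self._head(np.concatenate([base_vecs, pos], axis=1))


_REGISTRY: dict[str, Callable[..., EmbeddingProvider]] = {
    "fallback": FallbackProvider,
    "positional": PositionalProvider,
}


def register_provider(name: str, factory: Callable[..., EmbeddingProvider]) -> None:
    _REGISTRY[name] = factory


def get_provider(name: str, **kwargs) -> EmbeddingProvider:
    """Look up a provider by name; unknown names fall back with a notice."""
    factory = _REGISTRY.get(name)
    if factory is None:
        logger.warning("embedding provider %r not available; "
                       "using the deterministic fallback", name)
        factory = FallbackProvider
    return factory(**kwargs)


def broadcast_to_atoms(per_residue: np.ndarray,
                       structure: RnaStructure) -> np.ndarray:
    """Copy residue r's embedding onto each of residue r's atoms."""
    per_residue = np.asarray(per_residue)
    if len(per_residue) != structure.n_residues:
        raise ValueError("embedding count != residue count")
    rows = []
    for ridx, res in enumerate(structure.residues()):
        rows.extend([per_residue[ridx]] * len(res.atoms))
    return np.stack(rows)
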