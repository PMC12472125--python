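"""Download-free synthetic RNA fixtures with known geometry and pairing.

Structures are built from an idealized base-pair template placed on a helical
screw (A-form-like twist and rise).  They are not crystallographic models:
the point is that every generated structure comes with its exact ground-truth
canonical pair set, passes coarse-graining, carries C5' atoms for descriptor
extraction, and satisfies the geometric windows of the canonical-pair
annotator at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, Residue, RnaStructure, SecondaryStructure, BASE_TRIANGLE

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _default_template() -> dict[str, np.ndarray]:
    # Idealized nucleotide in the base-pair frame, strand placed on the -x
    # side; the pair plane is z=0.  Anchor-anchor distance across the pair is
    # 9.0 A and C2-C2 is 5.8 A, inside the annotator's acceptance windows.
    return {
        "anchor": np.array([-4.50, 0.00, 0.00]),
        "C2": np.array([-2.90, -1.00, 0.00]),
        "third": np.array([-3.20, 1.40, 0.00]),
        "N3": np.array([-2.60, 0.20, 0.00]),
        "C4'": np.array([-6.30, 1.62, 1.50]),
        "C5'": np.array([-6.84, 2.43, 1.20]),
        "P": np.array([-7.47, 0.90, 0.50]),
    }


@dataclass
class HelixParams:
    """Helical screw parameters: twist (deg/bp), rise (A/bp), atom template."""
    twist: float = 32.7
    rise: float = 2.81
    template: dict[str, np.ndarray] = field(default_factory=_default_template)

    def __post_init__(self):
        if not 0 < self.twist < 90:
            raise ValueError("twist must be in (0, 90) degrees")
        if self.rise <= 0:
            raise ValueError("rise must be positive")


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

# strand B template: 180 deg rotation about y flips the partner onto the +x
# side and makes the backbone antiparallel
_FLIP_Y = np.diag([-1.0, 1.0, -1.0])


def _residue_atoms(base: str, frame_rot: np.ndarray, frame_shift: np.ndarray,
                   template: dict[str, np.ndarray],
                   strand_b: bool = False) -> dict[str, Atom]:
    anchor, _c2, third = BASE_TRIANGLE[base]
    atoms = {}
    for key, local in template.items():
        name = {"anchor": anchor, "third": third}.get(key, key)
        local = _FLIP_Y @ local if strand_b else local
        atoms[name] = Atom(name, frame_rot @ local + frame_shift)
    return atoms


def make_helix(seq: str, params: HelixParams | None = None,
               ) -> tuple[RnaStructure, SecondaryStructure]:
    """Ideal duplex of ``seq`` and its reverse complement.

    Returns the two-chain structure and a secondary structure containing
    exactly ``len(seq)`` canonical pairs (global indices: i pairs 2N-1-i).
    """
    if not seq:
        raise ValueError("empty sequence")
    params = params or HelixParams()
    n = len(seq)
    chain_a: list[Residue] = []
    chain_b: list[Residue] = []
    for i, base in enumerate(seq):
        rot = _rot_z(i * params.twist)
        shift = np.array([0.0, 0.0, i * params.rise])
        chain_a.append(Residue("A", i, i + 1, base,
                               _residue_atoms(base, rot, shift, params.template)))
        partner = _COMPLEMENT[base]
        chain_b.append(Residue("B", 0, 0, partner,
                               _residue_atoms(partner, rot, shift,
                                              params.template, strand_b=True)))
    chain_b.reverse()  # 5'->3' order for the antiparallel strand
    for j, res in enumerate(chain_b):
        res.seq_index = j
        res.auth_number = j + 1
    pairs = {(i, 2 * n - 1 - i) for i in range(n)}
    structure = RnaStructure([chain_a, chain_b], name=f"helix{n}")
    return structure, SecondaryStructure(pairs=pairs, strand_breaks=[n])


def make_hairpin(stem_len: int, loop_len: int,
                 params: HelixParams | None = None,
                 ) -> tuple[RnaStructure, SecondaryStructure]:
    """Single-chain hairpin: G/C stem from the helix geometry, A-only loop.

    The loop residues sit on a semicircular arc bridging the stem strands, so
    consecutive C4'-C4' distances stay below 8 A along the whole chain.
    """
    if stem_len < 1:
        raise ValueError("stem_len must be >= 1")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    params = params or HelixParams()
    stem_seq = ("GC" * stem_len)[:stem_len]
    duplex, _ = make_helix(stem_seq, params)
    strand_a, strand_b = duplex.chains

    # arc endpoints: C4' of the last 5' stem residue and its cross-strand mate
    a_end = strand_a[-1].atoms["C4'"].coord
    b_start = strand_b[0].atoms["C4'"].coord
    u = b_start - a_end
    half = np.linalg.norm(u) / 2.0
    u = u / (2.0 * half)
    center = (a_end + b_start) / 2.0
    zhat = np.array([0.0, 0.0, 1.0])

    loop: list[Residue] = []
    top_rot = _rot_z((stem_len - 1) * params.twist)
    for k in range(loop_len):
        t = (k + 1) / (loop_len + 1)
        point = center + half * (-np.cos(np.pi * t) * u + np.sin(np.pi * t) * zhat)
        rot = top_rot @ _rot_z(20.0 * (k + 1))
        atoms = _residue_atoms("A", rot, np.zeros(3), params.template)
        shift = point - atoms["C4'"].coord
        for a in atoms.values():
            a.coord = a.coord + shift
        loop.append(Residue("A", 0, 0, "A", atoms))

    chain = list(strand_a) + loop + list(strand_b)
    for i, res in enumerate(chain):
        res.chain_id, res.seq_index, res.auth_number = "A", i, i + 1
    n = len(chain)
    pairs = {(i, n - 1 - i) for i in range(stem_len)}
    structure = RnaStructure([chain], name=f"hairpin{stem_len}_{loop_len}")
    return structure, SecondaryStructure(pairs=pairs)


def make_multisegment_fixture(n_segments: int, seed: int = 0,
                              params: HelixParams | None = None,
                              ) -> tuple[RnaStructure, SecondaryStructure]:
    """Fixture with ``n_segments`` strands sharing inter-strand pairs.

    n=1 yields a hairpin.  For n>=2, a duplex of length 4*(n-1) is built and
    its complementary strand is cut into (n-1) four-residue strands, each of
    which keeps four canonical contacts with the central strand.
    """
    if not 1 <= n_segments <= 5:
        raise ValueError("n_segments must be in 1..5")
    params = params or HelixParams()
    rng = np.random.default_rng(seed)
    if n_segments == 1:
        return make_hairpin(4, 4, params)
    m = 4 * (n_segments - 1)
    seq = "".join(rng.choice(list("ACGU")) for _ in range(m))
    duplex, ss = make_helix(seq, params)
    strand_a, strand_b = duplex.chains
    chains: list[list[Residue]] = [strand_a]
    chain_ids = "BCDEF"
    for k in range(n_segments - 1):
        piece = [r.copy() for r in strand_b[4 * k:4 * k + 4]]
        for i, res in enumerate(piece):
            res.chain_id, res.seq_index, res.auth_number = chain_ids[k], i, i + 1
        chains.append(piece)
    breaks = [m + 4 * k for k in range(n_segments - 1)]
    structure = RnaStructure(chains, name=f"multiseg{n_segments}_{seed}")
    return structure, SecondaryStructure(pairs=ss.pairs, strand_breaks=breaks)


def perturb(structure: RnaStructure, sigma: float, seed: int = 0) -> RnaStructure:
    """Displace every atom by i.i.d. Gaussian noise of std ``sigma`` (A)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = structure.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    coords = out.coords()
    out.set_coords(coords + rng.normal(0.0, sigma, size=coords.shape))
    return out
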