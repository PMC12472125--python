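"""Local 3D RNA descriptors: extraction and dataset curation.

A descriptor captures the spatial neighborhood of one central residue: every
residue whose C5' atom lies within a distance threshold T of the central C5'
is included, and each included residue is extended by two flanking residues
on both sides (truncated at chain termini).  Overlapping extensions merge
into maximal contiguous segments, so an isolated in-contact residue interior
to its chain always yields a 5-residue segment.

Curation removes unfolded single strands, descriptors with too many
segments, near-identical sequences, and geometric duplicates found by a
partial (Hungarian) structural alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .structure import RnaStructure, Residue
from . import metrics

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_THRESHOLD = 16.0  # A, C5'-C5'
EXTENSION = 2  # flanking residues added on each side


@dataclass(frozen=True)
class Segment:
    """Contiguous run of residues [start, end] (inclusive) in one chain."""
    chain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("segment end < start")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chain_id: str, idx: int) -> bool:
        return chain_id == self.chain_id and self.start <= idx <= self.end


@dataclass
class Descriptor:
    parent_id: str
    central_residue: tuple[str, int]
    segments: tuple[Segment, ...]
    threshold_T: float
    parent: RnaStructure | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        hits = [s for s in self.segments
                if s.contains(*self.central_residue)]
        if len(hits) != 1:
            raise ValueError("central residue must lie in exactly one segment")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def central_segment(self) -> Segment:
        return next(s for s in self.segments if s.contains(*self.central_residue))

    def _chain(self, chain_id: str) -> list[Residue]:
        assert self.parent is not None, "descriptor carries no parent structure"
        for chain in self.parent.chains:
            if chain and chain[0].chain_id == chain_id:
                return chain
        raise KeyError(chain_id)

    def segment_residues(self, seg: Segment) -> list[Residue]:
        return self._chain(seg.chain_id)[seg.start:seg.end + 1]

    def sequence(self) -> str:
        """Concatenated segment sequences, in segment order."""
        return "".join(r.base for s in self.segments
                       for r in self.segment_residues(s))

    def n_residues(self) -> int:
        return sum(len(s) for s in self.segments)

    def segment_trace(self, seg: Segment, atom: str = "C5'") -> np.ndarray:
        return np.array([r.atoms[atom].coord for r in self.segment_residues(seg)])

    def substructure(self) -> RnaStructure:
        """Materialize the descriptor as a standalone structure."""
        chains = []
        for seg in self.segments:
            residues = [r.copy() for r in self.segment_residues(seg)]
            for i, r in enumerate(residues):
                r.seq_index = i
            chains.append(residues)
        return RnaStructure(chains, name=f"{self.parent_id}_desc")


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _merge_ranges(idxs: set[int], lo: int, hi: int) -> list[tuple[int, int]]:
    """Extend every index by EXTENSION, clamp to [lo, hi], merge overlaps."""
    ranges = sorted((max(lo, i - EXTENSION), min(hi, i + EXTENSION))
                    for i in idxs)
    merged: list[tuple[int, int]] = []
    for s, e in ranges:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def extract_descriptors(structure: RnaStructure,
                        threshold: float = DEFAULT_CONTACT_THRESHOLD
                        ) -> list[Descriptor]:
    """One descriptor per central residue, 3rd to (N-2)th of each chain.

    Runs on full-atom input (the contact search needs C5', which the coarse
    model lacks).  Residues without a C5' atom are excluded from the contact
    search with a warning.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    entries: list[tuple[int, str, int]] = []   # (flat, chain_id, idx)
    coords = []
    flat = []
    for chain in structure.chains:
        for res in chain:
            c5 = res.get("C5'")
            if c5 is None:
                logger.warning("residue %s%d lacks C5'; excluded from contacts",
                               res.chain_id, res.auth_number)
                continue
            entries.append((len(coords), res.chain_id, res.seq_index))
            coords.append(c5.coord)
    coords = np.asarray(coords, float)
    if coords.size == 0:
        return []
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)

    descriptors: list[Descriptor] = []
    for chain in structure.chains:
        n = len(chain)
        cid = chain[0].chain_id
        for central in range(2, n - 2):
            rows = [k for k, (_, c, i) in enumerate(entries)
                    if c == cid and i == central]
            if not rows:
                continue
            row = rows[0]
            contact_idx = np.where(dist[row] <= threshold)[0]
            per_chain: dict[str, set[int]] = {}
            for k in contact_idx:
                _, c, i = entries[k]
                per_chain.setdefault(c, set()).add(i)
            per_chain.setdefault(cid, set()).add(central)
            segments: list[Segment] = []
            for ch in structure.chains:
                ccid = ch[0].chain_id
                if ccid not in per_chain:
                    continue
                for s, e in _merge_ranges(per_chain[ccid], 0, len(ch) - 1):
                    segments.append(Segment(ccid, s, e))
            descriptors.append(Descriptor(
                parent_id=structure.name or "structure",
                central_residue=(cid, central),
                segments=tuple(segments),
                threshold_T=threshold,
                parent=structure))
    return descriptors


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical columns under global alignment.

    Scoring: match=1, mismatch=0, gap=-1; identity is the number of
    identical aligned positions over the alignment length (including gap
    columns).  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / length


# ---------------------------------------------------------------------------
# Structural alignment (partial Hungarian matching)
# ---------------------------------------------------------------------------

@dataclass
class CurationConfig:
    max_identity: float = 0.80
    max_segments: int = 3
    rmsd_central_max: float = 2.5
    rmsd_duplex_max: float = 4.0
    rmsd_overall_max: float = 3.5
    min_element_coverage: float = 0.5
    min_residue_coverage: float = 2.0 / 3.0

    def __post_init__(self):
        for name in ("rmsd_central_max", "rmsd_duplex_max", "rmsd_overall_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("max_identity", "min_element_coverage",
                     "min_residue_coverage"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class AlignmentResult:
    matched_segments: set[tuple[int, int]]   # (segment index of a, of b)
    central_rmsd: float
    best_duplex_rmsd: float
    overall_rmsd: float
    element_coverage: float
    residue_coverage: float


def _central_pairs(desc: Descriptor) -> list[tuple[int, np.ndarray]]:
    """C5' coords of the central segment keyed by offset from the central residue."""
    seg = desc.central_segment
    trace = desc.segment_trace(seg)
    _, central_idx = desc.central_residue
    return [(seg.start + k - central_idx, trace[k]) for k in range(len(seg))]


def align_descriptors(a: Descriptor, b: Descriptor,
                      dummy_penalty: float = 4.0) -> AlignmentResult:
    """Partial structural alignment of two descriptors on their C5' traces.

    The central elements are superposed first (residues paired by offset from
    the central residue).  Remaining segments are matched by a minimum-cost
    assignment whose cost is the per-segment RMSD under that superposition;
    dummy rows/columns at ``dummy_penalty`` let segments stay unmatched.
    """
    off_a = dict(_central_pairs(a))
    off_b = dict(_central_pairs(b))
    common = sorted(set(off_a) & set(off_b))
    if len(common) < 3:
        raise ValueError("central elements share fewer than 3 aligned residues")
    pa = np.array([off_a[o] for o in common])
    pb = np.array([off_b[o] for o in common])
    rot, t = metrics.kabsch_superpose(pb, pa)

    def xform(x: np.ndarray) -> np.ndarray:
        return x @ rot.T + t

    central_rmsd = metrics._raw_rmsd(pa, xform(pb))
    central_pairs = [(pa, xform(pb))]

    ia = [i for i, s in enumerate(a.segments) if s != a.central_segment]
    ib = [j for j, s in enumerate(b.segments) if s != b.central_segment]
    na, nb = len(ia), len(ib)
    matched: set[tuple[int, int]] = {
        (a.segments.index(a.central_segment), b.segments.index(b.central_segment))}
    seg_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    if na and nb:
        size = na + nb
        cost = np.full((size, size), float(dummy_penalty))
        cost[na:, nb:] = 0.0
        traces_a = [a.segment_trace(a.segments[i]) for i in ia]
        traces_b = [xform(b.segment_trace(b.segments[j])) for j in ib]
        for r, ta in enumerate(traces_a):
            for c, tb in enumerate(traces_b):
                m = min(len(ta), len(tb))
                cost[r, c] = metrics._raw_rmsd(ta[:m], tb[:m])
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if r < na and c < nb and cost[r, c] < dummy_penalty:
                matched.add((ia[r], ib[c]))
                m = min(len(traces_a[r]), len(traces_b[c]))
                seg_pairs.append((traces_a[r][:m], traces_b[c][:m]))

    # coverage over elements and residues of the larger descriptor
    n_elements = max(a.n_segments, b.n_segments)
    element_coverage = len(matched) / n_elements
    aligned_residues = len(common) + sum(len(x) for x, _ in seg_pairs)
    residue_coverage = aligned_residues / max(a.n_residues(), b.n_residues())

    all_a = np.vstack([p for p, _ in central_pairs + seg_pairs])
    all_b = np.vstack([q for _, q in central_pairs + seg_pairs])
    rot2, t2 = metrics.kabsch_superpose(all_b, all_a)
    overall_rmsd = metrics._raw_rmsd(all_a, all_b @ rot2.T + t2)

    best_duplex = 0.0
    if seg_pairs:
        pb_t = central_pairs[0][1]
        duplex_rmsds = []
        for sa, sb in seg_pairs:
            da = np.vstack([pa, sa])
            db = np.vstack([pb_t, sb])
            r3, t3 = metrics.kabsch_superpose(db, da)
            duplex_rmsds.append(metrics._raw_rmsd(da, db @ r3.T + t3))
        best_duplex = min(duplex_rmsds)

    return AlignmentResult(matched_segments=matched, central_rmsd=central_rmsd,
                           best_duplex_rmsd=best_duplex,
                           overall_rmsd=overall_rmsd,
                           element_coverage=element_coverage,
                           residue_coverage=residue_coverage)


def is_redundant(a: Descriptor, b: Descriptor,
                 cfg: CurationConfig | None = None) -> bool:
    """Two descriptors are redundant when all four criteria hold:

    (i) central-element RMSD <= ``rmsd_central_max``; (ii) the best duplex
    (central element + one matched segment) RMSD <= ``rmsd_duplex_max``
    (vacuously true when either descriptor has a single segment); (iii) the
    match covers more than ``min_element_coverage`` of the elements and more
    than ``min_residue_coverage`` of the residues; (iv) the overall RMSD over
    matched residues <= ``rmsd_overall_max``.
    """
    cfg = cfg or CurationConfig()
    res = align_descriptors(a, b, dummy_penalty=cfg.rmsd_duplex_max)
    if res.central_rmsd > cfg.rmsd_central_max:
        return False
    multi = a.n_segments > 1 and b.n_segments > 1
    duplex_matched = len(res.matched_segments) > 1
    if multi and duplex_matched and res.best_duplex_rmsd > cfg.rmsd_duplex_max:
        return False
    if multi and not duplex_matched:
        return False  # no duplex could be formed although both are multi-segment
    if res.element_coverage <= cfg.min_element_coverage:
        return False
    if res.residue_coverage <= cfg.min_residue_coverage:
        return False
    return res.overall_rmsd <= cfg.rmsd_overall_max


# ---------------------------------------------------------------------------
# Curation pipeline
# ---------------------------------------------------------------------------

def _is_unfolded(desc: Descriptor) -> bool:
    """Single-segment descriptor with no detectable canonical pair."""
    if desc.n_segments > 1:
        return False
    sub = desc.substructure()
    return not metrics.annotate_wcf_pairs(sub)


def curate_dataset(descriptors: list[Descriptor],
                   cfg: CurationConfig | None = None) -> list[Descriptor]:
    """Identity and redundancy filtering, in order:

    1. drop unfolded single-segment descriptors (no canonical pair);
    2. drop descriptors with more than ``max_segments`` segments;
    3. greedy sequence-identity dedup in input order (> ``max_identity``);
    4. greedy structural dedup via :func:`is_redundant`, keeping the first
       representative.  Deterministic; idempotent.
    """
    cfg = cfg or CurationConfig()
    stage = [d for d in descriptors if not _is_unfolded(d)]
    stage = [d for d in stage if d.n_segments <= cfg.max_segments]

    kept: list[Descriptor] = []
    for d in stage:
        if any(sequence_identity(d.sequence(), k.sequence()) > cfg.max_identity
               for k in kept):
            continue
        kept.append(d)

    final: list[Descriptor] = []
    for d in kept:
        if any(_safe_redundant(d, k, cfg) for k in final):
            continue
        final.append(d)
    return final


def _safe_redundant(a: Descriptor, b: Descriptor, cfg: CurationConfig) -> bool:
    try:
        return is_redundant(a, b, cfg)
    except ValueError:
        return False  # central elements not alignable -> not redundant


def partition_by_family(descriptors: list[Descriptor],
                        labels: dict[str, str],
                        train_families: set[str]
                        ) -> tuple[list[Descriptor], list[Descriptor]]:
    """Family-held-out split: train families vs everything else."""
    missing = sorted({d.parent_id for d in descriptors} - set(labels))
    if missing:
        raise KeyError(f"unlabelled parent structures: {missing}")
    train = [d for d in descriptors if labels[d.parent_id] in train_families]
    test = [d for d in descriptors if labels[d.parent_id] not in train_families]
    return train, test


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def write_manifest(descriptors: list[Descriptor], path) -> None:
    """Delimited descriptor table: parent, central residue, segments, sequence."""
    lines = ["parent_id\tcentral_chain\tcentral_index\tsegments\tsequence\n"]
    for d in descriptors:
        segs = ";".join(f"{s.chain_id}:{s.start}-{s.end}" for s in d.segments)
        lines.append(f"{d.parent_id}\t{d.central_residue[0]}\t"
                     f"{d.central_residue[1]}\t{segs}\t{d.sequence()}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
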