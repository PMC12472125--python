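"""Structure comparison metrics for coarse-grained RNA.

Implements superposed RMSD (Kabsch), the base-centric eRMSD distance, the
Interaction Network Fidelity (INF) score over canonical pair sets, and a
geometric Watson-Crick-Franklin pair annotator operating on the coarse
5-atom representation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .structure import RnaStructure, BASE_TRIANGLE


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing |R@mobile+t - target|.

    Proper rotations only (reflections excluded via the sign of det).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - r @ cm
    return r, t


def _raw_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _corresponding_coords(pred: RnaStructure, ref: RnaStructure,
                          atom_names: set[str] | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    rp, rr = pred.residue_list(), ref.residue_list()
    if len(rp) != len(rr):
        raise ValueError("structures have different residue counts")
    if any(a.base != b.base for a, b in zip(rp, rr)):
        raise ValueError("residue sequences differ")
    pa, ra = [], []
    for a, b in zip(rp, rr):
        common = [n for n in a.atoms if n in b.atoms]
        if atom_names is not None:
            common = [n for n in common if n in atom_names]
        for n in common:
            pa.append(a.atoms[n].coord)
            ra.append(b.atoms[n].coord)
    if not pa:
        raise ValueError("no common atoms between structures")
    return np.array(pa), np.array(ra)


def kabsch_rmsd(pred: RnaStructure, ref: RnaStructure, superpose: bool = True,
                atom_names: set[str] | None = None) -> float:
    """RMSD over corresponded atoms, after optimal superposition by default.

    Atoms correspond by (residue position, atom name); ``atom_names``
    restricts the comparison, e.g. ``{"C4'"}`` for a backbone-trace RMSD.
    """
    p, r = _corresponding_coords(pred, ref, atom_names)
    if superpose:
        if len(p) < 3:
            raise ValueError("need >= 3 common atoms to superpose")
        rot, t = kabsch_superpose(p, r)
        p = p @ rot.T + t
    return _raw_rmsd(p, r)


# ---------------------------------------------------------------------------
# eRMSD
# ---------------------------------------------------------------------------

@dataclass
class ErmsdParams:
    """Anisotropic rescaling and smooth-cutoff constants for eRMSD."""
    scale_xy: float = 5.0
    scale_z: float = 3.0
    cutoff: float = 2.4

    @property
    def gamma(self) -> float:
        return math.pi / self.cutoff


def _base_frames(structure: RnaStructure) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue base origin and orthonormal frame from the base triangle."""
    origins, frames = [], []
    for res in structure.residues():
        anchor, c2n, third = BASE_TRIANGLE[res.base]
        try:
            pa = res.atoms[anchor].coord
            pc = res.atoms[c2n].coord
            pt = res.atoms[third].coord
        except KeyError as exc:
            raise ValueError(
                f"residue {res.chain_id}{res.auth_number} lacks base atom "
                f"{exc} needed for the eRMSD frame") from exc
        origin = (pa + pc + pt) / 3.0
        x = pc - origin
        x = x / np.linalg.norm(x)
        z = np.cross(pc - origin, pt - origin)
        z = z / np.linalg.norm(z)
        y = np.cross(z, x)
        origins.append(origin)
        frames.append(np.stack([x, y, z]))
    return np.array(origins), np.array(frames)


def g_vectors(structure: RnaStructure, params: ErmsdParams) -> np.ndarray:
    """G(r~) for every ordered residue pair, shape (N, N, 4).

    r~ is the partner base origin expressed in the local base frame, with x,y
    divided by ``scale_xy`` and z by ``scale_z``.  G maps it smoothly to a
    4-vector that vanishes at and beyond |r~| = cutoff.
    """
    origins, frames = _base_frames(structure)
    n = len(origins)
    rel = origins[None, :, :] - origins[:, None, :]          # i -> j
    local = np.einsum("iab,ijb->ija", frames, rel)           # in frame i
    scaled = local / np.array([params.scale_xy, params.scale_xy, params.scale_z])
    norm = np.linalg.norm(scaled, axis=-1)
    np.fill_diagonal(norm, np.inf)
    gamma = params.gamma
    inside = norm < params.cutoff
    g = np.zeros((n, n, 4))
    safe = np.where(inside, norm, 1.0)
    sin_term = np.where(inside, np.sin(gamma * safe) / (safe * gamma), 0.0)
    g[..., :3] = scaled * sin_term[..., None]
    g[..., 3] = np.where(inside, (1.0 + np.cos(gamma * safe)) / gamma, 0.0)
    return g


def ermsd(pred: RnaStructure, ref: RnaStructure,
          params: ErmsdParams | None = None) -> float:
    """Base-interaction distance over all ordered residue pairs.

    Zero iff every base sees the same (rescaled, cut-off) arrangement of the
    other bases in both structures; symmetric and rigid-motion invariant.
    """
    params = params or ErmsdParams()
    if pred.n_residues != ref.n_residues:
        raise ValueError("structures have different residue counts")
    gp = g_vectors(pred, params)
    gr = g_vectors(ref, params)
    n = pred.n_residues
    return float(np.sqrt(np.sum((gp - gr) ** 2) / n))


# ---------------------------------------------------------------------------
# Canonical pair annotation
# ---------------------------------------------------------------------------

_CANONICAL = {frozenset(p) for p in (("A", "U"), ("G", "C"))}
_WOBBLE = frozenset(("G", "U"))

#: geometric acceptance windows (A / degrees) for a WCF pair in the coarse model
ANCHOR_RANGE = (7.5, 10.5)
C2_RANGE = (4.5, 7.5)
MAX_PLANE_ANGLE_DEG = 35.0
_IDEAL_ANCHOR, _IDEAL_C2 = 9.0, 5.8


def annotate_wcf_pairs(structure: RnaStructure, include_gu: bool = True,
                       anchor_range: tuple[float, float] = ANCHOR_RANGE,
                       c2_range: tuple[float, float] = C2_RANGE,
                       max_plane_angle_deg: float = MAX_PLANE_ANGLE_DEG,
                       ) -> set[tuple[int, int]]:
    """Detect canonical pairs geometrically; each residue in at most one pair.

    Complementary residues qualify when the glycosidic-anchor distance and
    the C2-C2 distance fall inside their windows and the base planes are
    within ``max_plane_angle_deg`` of parallel.  Candidates are accepted
    greedily by closeness to ideal pair geometry.
    """
    residues = structure.residue_list()
    n = len(residues)
    anchors = np.full((n, 3), np.nan)
    c2s = np.full((n, 3), np.nan)
    normals = np.full((n, 3), np.nan)
    for i, res in enumerate(residues):
        an, c2n, third = BASE_TRIANGLE[res.base]
        a, c, t = res.get(an), res.get(c2n), res.get(third)
        if a is None or c is None or t is None:
            continue
        anchors[i], c2s[i] = a.coord, c.coord
        nvec = np.cross(c.coord - a.coord, t.coord - a.coord)
        nn = np.linalg.norm(nvec)
        if nn > 0:
            normals[i] = nvec / nn

    candidates: list[tuple[float, int, int]] = []
    max_cos = math.cos(math.radians(max_plane_angle_deg))
    for i in range(n):
        if np.isnan(anchors[i, 0]):
            continue
        for j in range(i + 1, n):
            if np.isnan(anchors[j, 0]):
                continue
            combo = frozenset((residues[i].base, residues[j].base))
            if combo not in _CANONICAL and not (include_gu and combo == _WOBBLE):
                continue
            da = float(np.linalg.norm(anchors[i] - anchors[j]))
            if not anchor_range[0] <= da <= anchor_range[1]:
                continue
            dc = float(np.linalg.norm(c2s[i] - c2s[j]))
            if not c2_range[0] <= dc <= c2_range[1]:
                continue
            if abs(float(np.dot(normals[i], normals[j]))) < max_cos:
                continue
            score = abs(da - _IDEAL_ANCHOR) + abs(dc - _IDEAL_C2)
            candidates.append((score, i, j))

    pairs: set[tuple[int, int]] = set()
    used: set[int] = set()
    for _score, i, j in sorted(candidates):
        if i in used or j in used:
            continue
        pairs.add((i, j))
        used.update((i, j))
    return pairs


# ---------------------------------------------------------------------------
# INF
# ---------------------------------------------------------------------------

@dataclass
class PairConfusion:
    tp: int = 0
    fp: int = 0
    fn: int = 0


def _normalize(pairs: set[tuple[int, int]]) -> set[tuple[int, int]]:
    return {(min(i, j), max(i, j)) for i, j in pairs}


def inf_score(pred_pairs: set[tuple[int, int]],
              ref_pairs: set[tuple[int, int]]
              ) -> tuple[float, PairConfusion]:
    """Interaction Network Fidelity: geometric mean of precision and recall.

    Conventions for the degenerate cases: both pair sets empty -> 1.0
    (perfect agreement); exactly one empty -> 0.0.
    """
    p, r = _normalize(pred_pairs), _normalize(ref_pairs)
    conf = PairConfusion(tp=len(p & r), fp=len(p - r), fn=len(r - p))
    if not p and not r:
        return 1.0, conf
    if conf.tp == 0:
        return 0.0, conf
    ppv = conf.tp / (conf.tp + conf.fp)
    sty = conf.tp / (conf.tp + conf.fn)
    return float(math.sqrt(ppv * sty)), conf


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    rmsd: float
    ermsd: float
    inf_wcf: float
    confusion_wcf: PairConfusion
    inf_nwc: float | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        d = json.loads(text)
        d["confusion_wcf"] = PairConfusion(**d["confusion_wcf"])
        return cls(**d)


def evaluate(pred: RnaStructure, ref: RnaStructure,
             pred_nwc_pairs: set[tuple[int, int]] | None = None,
             ref_nwc_pairs: set[tuple[int, int]] | None = None,
             ermsd_params: ErmsdParams | None = None,
             include_gu: bool = True) -> MetricReport:
    """Full comparison of a prediction against a reference structure.

    INF(NWC) is computed only when non-canonical pair sets are supplied for
    both structures (annotation of non-canonical geometries is out of scope
    here); otherwise it is left undefined.
    """
    rmsd_val = kabsch_rmsd(pred, ref, superpose=True)
    ermsd_val = ermsd(pred, ref, ermsd_params)
    pred_pairs = annotate_wcf_pairs(pred, include_gu=include_gu)
    ref_pairs = annotate_wcf_pairs(ref, include_gu=include_gu)
    inf_wcf, conf = inf_score(pred_pairs, ref_pairs)
    inf_nwc = None
    if pred_nwc_pairs is not None and ref_nwc_pairs is not None:
        inf_nwc, _ = inf_score(pred_nwc_pairs, ref_nwc_pairs)
    return MetricReport(rmsd=rmsd_val, ermsd=ermsd_val, inf_wcf=inf_wcf,
                        confusion_wcf=conf, inf_nwc=inf_nwc)
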