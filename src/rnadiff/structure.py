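"""RNA structure containers, PDB I/O, dot-bracket parsing, coarse-graining.

The coarse-grained representation keeps five atoms per residue: the two
backbone atoms P and C4' plus a three-atom base triangle (N9-C2-C6 for
purines, N1-C2-C4 for pyrimidines).  A 5'-terminal residue may lack P and
is kept with four atoms.  All internal residue indices are 0-based.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: factor by which coordinates are divided before entering the diffusion model
COORDINATE_SCALE = 10.0

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}
BASES = PURINES | PYRIMIDINES

#: base-triangle atoms per nucleobase class; first entry is the glycosidic anchor
BASE_TRIANGLE = {
    "A": ("N9", "C2", "C6"),
    "G": ("N9", "C2", "C6"),
    "C": ("N1", "C2", "C4"),
    "U": ("N1", "C2", "C4"),
}

#: atoms of the coarse-grained model, in canonical node order
COARSE_ATOMS = {b: ("P", "C4'") + BASE_TRIANGLE[b] for b in BASES}

#: common modified-nucleotide aliases mapped to their parent base
MODIFIED_ALIASES = {
    "PSU": "U", "H2U": "U", "4SU": "U", "OMU": "U", "5MU": "U", "UR3": "U",
    "1MA": "A", "2MA": "A", "A2M": "A", "MA6": "A", "6MZ": "A",
    "5MC": "C", "OMC": "C", "4OC": "C",
    "1MG": "G", "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "G7M": "G",
    "A": "A", "C": "C", "G": "G", "U": "U",
}


def _element_of(name: str) -> str:
    for ch in name:
        if ch in string.ascii_letters:
            e = ch.upper()
            return e if e in {"C", "N", "P", "O"} else "other"
    return "other"


@dataclass
class Atom:
    name: str
    coord: np.ndarray
    element: str = ""

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")
        if not self.element:
            self.element = _element_of(self.name)


@dataclass
class Residue:
    chain_id: str
    seq_index: int
    auth_number: int
    base: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def is_purine(self) -> bool:
        return self.base in PURINES

    @property
    def anchor_name(self) -> str:
        """Glycosidic anchor atom: N9 for purines, N1 for pyrimidines."""
        return BASE_TRIANGLE[self.base][0]

    def get(self, name: str) -> Atom | None:
        return self.atoms.get(name)

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seq_index, self.auth_number, self.base,
                       {n: Atom(a.name, a.coord.copy(), a.element)
                        for n, a in self.atoms.items()})


class RnaStructure:
    """Ordered chains of RNA residues with named, 3D-positioned atoms (A)."""

    def __init__(self, chains: Sequence[Sequence[Residue]], name: str = "",
                 coarse_grained: bool = False, scale_applied: float = 1.0,
                 centroid_offset: np.ndarray | None = None):
        self.chains: list[list[Residue]] = [list(c) for c in chains]
        self.name = name
        self.coarse_grained = coarse_grained
        self.scale_applied = float(scale_applied)
        self.centroid_offset = (np.zeros(3) if centroid_offset is None
                                else np.asarray(centroid_offset, dtype=float))
        if self.n_residues < 1:
            raise ValueError("structure must contain at least one residue")

    # -- iteration & shape ------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def residue_list(self) -> list[Residue]:
        return list(self.residues())

    def sequence(self) -> str:
        return "".join(r.base for r in self.residues())

    def sequences(self) -> list[str]:
        return ["".join(r.base for r in c) for c in self.chains]

    # -- coordinates ------------------------------------------------------
    def coords(self) -> np.ndarray:
        """All atom coordinates, structure order, shape (n_atoms, 3)."""
        return np.array([a.coord for r in self.residues()
                         for a in r.atoms.values()], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        k = 0
        for r in self.residues():
            for a in r.atoms.values():
                a.coord = coords[k].copy()
                k += 1

    def copy(self) -> "RnaStructure":
        return RnaStructure([[r.copy() for r in c] for c in self.chains],
                            name=self.name, coarse_grained=self.coarse_grained,
                            scale_applied=self.scale_applied,
                            centroid_offset=self.centroid_offset.copy())


@dataclass
class SecondaryStructure:
    """Canonical pair constraints over global 0-based residue indices."""
    pairs: set[tuple[int, int]] = field(default_factory=set)
    strand_breaks: list[int] = field(default_factory=list)

    def __post_init__(self):
        norm = set()
        seen: set[int] = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError("a residue cannot pair with itself")
            a, b = (i, j) if i < j else (j, i)
            for k in (a, b):
                if k in seen:
                    raise ValueError(f"residue {k} appears in two pairs")
                seen.add(k)
            norm.add((a, b))
        self.pairs = norm


class PdbParseError(ValueError):
    pass


class EmptyStructureError(PdbParseError):
    pass


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> RnaStructure:
    """Read an RNA structure from PDB (or mmCIF) text, first model only.

    Residues are ordered by chain and author numbering; modified residues
    with a known parent alias are renamed, unknown residue names are skipped
    with a warning.  Raises :class:`EmptyStructureError` when no RNA residue
    with coordinates is found.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise PdbParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on malformed input
        raise PdbParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    chains: list[list[Residue]] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            base = MODIFIED_ALIASES.get(res.name.strip().upper())
            if base is None:
                logger.warning("skipping non-RNA or unknown residue %s %s%s",
                               res.name, chain.name, res.seqid.num)
                continue
            atoms: dict[str, Atom] = {}
            for at in res:
                name = at.name.strip().replace("*", "'")
                if name in atoms:
                    continue  # keep first altloc
                atoms[name] = Atom(name, np.array([at.pos.x, at.pos.y, at.pos.z]),
                                   _element_of(name))
            if atoms:
                residues.append(Residue(chain.name, len(residues),
                                        res.seqid.num, base, atoms))
        if residues:
            chains.append(residues)
    if not chains:
        raise EmptyStructureError(f"{path}: no RNA residues found")
    return RnaStructure(chains, name=path.stem)


_PDB_ATOM = ("ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:>3s} {chain:1s}"
             "{resnum:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
             "{b:6.2f}          {elem:>2s}\n")


def _pdb_atom_name(name: str) -> str:
    # columns 13-16; element right-justified in 13-14 for short names
    return f" {name:<3s}" if len(name) < 4 else name


def write_pdb(structure: RnaStructure, path: str | Path) -> None:
    """Write standard ATOM/TER records.

    Any centering/scaling recorded on the structure is inverted first, so
    the file always holds original-frame angstrom coordinates.
    """
    path = Path(path)
    lines: list[str] = []
    serial = 1
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    for ci, chain in enumerate(structure.chains):
        cid = chain[0].chain_id or chain_ids[ci % len(chain_ids)]
        for res in chain:
            names = (COARSE_ATOMS[res.base] if structure.coarse_grained
                     else list(res.atoms))
            for name in names:
                atom = res.atoms.get(name)
                if atom is None:
                    continue
                xyz = atom.coord * structure.scale_applied + structure.centroid_offset
                elem = atom.element if atom.element in {"C", "N", "P", "O"} else ""
                lines.append(_PDB_ATOM.format(
                    serial=serial, name=_pdb_atom_name(atom.name), alt=" ",
                    res=res.base, chain=cid[:1], resnum=res.auth_number,
                    icode=" ", x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0,
                    elem=elem))
                serial += 1
        lines.append(f"TER   {serial:>5d}      {chain[-1].base:>3s} "
                     f"{cid[:1]}{chain[-1].auth_number:>4d}\n")
        serial += 1
    lines.append("END\n")
    path.write_text("".join(lines))


# ---------------------------------------------------------------------------
# Dot-bracket parsing
# ---------------------------------------------------------------------------

_BRACKET_LAYERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
_SEQ_CHARS = set("ACGU")


def parse_dotbracket(text: str) -> tuple[list[str], SecondaryStructure]:
    """Parse Vienna sequence/structure text into strands and a pair set.

    Accepts either a sequence line and a structure line with strands joined
    by '&', or repeated (sequence, structure) line pairs — one strand each.
    Bracket layers (), [], {}, <> are matched independently, which supports
    pseudoknots.  Indices in the returned pair set are global 0-based over
    the concatenated strands.
    """
    lines = [ln.strip() for ln in text.strip().splitlines()
             if ln.strip() and not ln.startswith((">", "#"))]
    if len(lines) < 2 or len(lines) % 2:
        raise ValueError("expected sequence/structure line pairs")

    seqs: list[str] = []
    structs: list[str] = []
    for seq_line, ss_line in zip(lines[::2], lines[1::2]):
        s_parts = seq_line.upper().split("&")
        d_parts = ss_line.split("&")
        if len(s_parts) != len(d_parts):
            raise ValueError("strand count differs between sequence and structure")
        seqs.extend(s_parts)
        structs.extend(d_parts)

    offsets = []
    total = 0
    for s, d in zip(seqs, structs):
        if len(s) != len(d):
            raise ValueError(f"length mismatch: {s!r} vs {d!r}")
        if not s:
            raise ValueError("empty strand")
        bad = set(s) - _SEQ_CHARS
        if bad:
            raise ValueError(f"illegal sequence characters: {sorted(bad)}")
        offsets.append(total)
        total += len(s)

    structure = "".join(structs)
    legal = {"."} | {c for pair in _BRACKET_LAYERS for c in pair}
    bad = set(structure) - legal
    if bad:
        raise ValueError(f"illegal structure characters: {sorted(bad)}")

    pairs: set[tuple[int, int]] = set()
    for open_ch, close_ch in _BRACKET_LAYERS:
        stack: list[int] = []
        for i, ch in enumerate(structure):
            if ch == open_ch:
                stack.append(i)
            elif ch == close_ch:
                if not stack:
                    raise ValueError(f"unbalanced '{close_ch}' at position {i}")
                pairs.add((stack.pop(), i))
        if stack:
            raise ValueError(f"unbalanced '{open_ch}' ({len(stack)} unclosed)")

    strand_breaks = offsets[1:]
    return seqs, SecondaryStructure(pairs=pairs, strand_breaks=strand_breaks)


# ---------------------------------------------------------------------------
# Coarse-graining and normalization
# ---------------------------------------------------------------------------

class CoarseGrainError(ValueError):
    pass


def coarse_grain(structure: RnaStructure) -> RnaStructure:
    """Reduce each residue to the 5-atom representation.

    A 5'-terminal residue missing P keeps 4 atoms; residues missing any
    base-triangle atom or C4' are dropped with a warning.  Idempotent on
    already-coarse input.  Raises :class:`CoarseGrainError` when more than
    half the residues cannot be converted.
    """
    if structure.coarse_grained:
        return structure.copy()
    dropped = 0
    chains: list[list[Residue]] = []
    for chain in structure.chains:
        new_chain: list[Residue] = []
        for pos, res in enumerate(chain):
            wanted = COARSE_ATOMS[res.base]
            required = wanted[1:]  # P optional at the 5' terminus
            if any(res.get(n) is None for n in required):
                logger.warning("dropping residue %s%d: missing coarse atoms",
                               res.chain_id, res.auth_number)
                dropped += 1
                continue
            atoms = {}
            for n in wanted:
                a = res.get(n)
                if a is None:
                    if n == "P" and pos == 0:
                        continue
                    logger.warning("dropping residue %s%d: missing %s",
                                   res.chain_id, res.auth_number, n)
                    atoms = None
                    break
                atoms[n] = Atom(n, a.coord.copy(), a.element)
            if atoms is None:
                dropped += 1
                continue
            new_chain.append(Residue(res.chain_id, len(new_chain),
                                     res.auth_number, res.base, atoms))
        if new_chain:
            chains.append(new_chain)
    total = structure.n_residues
    if dropped > total / 2:
        raise CoarseGrainError(
            f"{dropped}/{total} residues lack the required atoms")
    if not chains:
        raise CoarseGrainError("no residues survived coarse-graining")
    return RnaStructure(chains, name=structure.name, coarse_grained=True,
                        scale_applied=structure.scale_applied,
                        centroid_offset=structure.centroid_offset.copy())


def center_and_scale(structure: RnaStructure,
                     scale: float = COORDINATE_SCALE) -> RnaStructure:
    """Center coordinates at the origin and divide them by ``scale``.

    The centroid shift and scale factor are recorded on the returned
    structure so the transform is exactly invertible (and is inverted
    automatically by :func:`write_pdb`).
    """
    out = structure.copy()
    coords = out.coords()
    centroid = coords.mean(axis=0)
    out.set_coords((coords - centroid) / scale)
    out.centroid_offset = structure.centroid_offset + centroid * structure.scale_applied
    out.scale_applied = structure.scale_applied * scale
    return out


def unscale(structure: RnaStructure) -> RnaStructure:
    """Invert :func:`center_and_scale`, restoring original-frame angstroms."""
    out = structure.copy()
    out.set_coords(out.coords() * out.scale_applied + out.centroid_offset)
    out.scale_applied = 1.0
    out.centroid_offset = np.zeros(3)
    return out
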