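"""Descriptor extraction, partial structural alignment, and curation."""

import itertools

import numpy as np
import pytest

from rnadiff import descriptors as D
from rnadiff import structure as S
from rnadiff import synthetic as syn

from conftest import random_rotation


def _rigid_copy(structure, rng, shift=(5.0, -3.0, 8.0)):
    out = structure.copy()
    out.set_coords(structure.coords() @ random_rotation(rng).T
                   + np.asarray(shift))
    return out


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def test_chain_of_four_yields_no_descriptors():
    st, _ = syn.make_helix("GCAU")
    chain = S.RnaStructure([st.chains[0]], name="four")
    assert D.extract_descriptors(chain) == []


def test_descriptor_count_is_n_minus_4(strand30):
    descs = D.extract_descriptors(strand30)
    assert len(descs) == 30 - 4


def test_central_residue_range(strand30):
    descs = D.extract_descriptors(strand30)
    centrals = sorted(idx for _, idx in (d.central_residue for d in descs))
    assert centrals == list(range(2, 28))


def test_contacts_match_exhaustive_scan(hairpin):
    """Every residue within T of the central C5' lies inside some segment."""
    st, _ = hairpin
    threshold = 16.0
    for desc in D.extract_descriptors(st, threshold):
        cid, cidx = desc.central_residue
        central_c5 = st.chains[0][cidx].atoms["C5'"].coord
        for res in st.residues():
            d = np.linalg.norm(res.atoms["C5'"].coord - central_c5)
            if d <= threshold:
                assert any(s.contains(res.chain_id, res.seq_index)
                           for s in desc.segments)


def test_isolated_contact_yields_five_residue_segment():
    """A single cross-contact interior to its chain extends to 5 residues."""
    st, _ = syn.make_helix("GCAU" * 5)
    chain_a = [r.copy() for r in st.chains[0]]
    # far-away second chain with exactly one residue pulled within T of the
    # central residue of chain A
    chain_b = [r.copy() for r in st.chains[1]]
    for r in chain_b:
        for a in r.atoms.values():
            a.coord = a.coord + np.array([500.0, 0.0, 0.0])
    target = chain_a[10].atoms["C5'"].coord + np.array([10.0, 0.0, 0.0])
    shift = target - chain_b[10].atoms["C5'"].coord
    for a in chain_b[10].atoms.values():
        a.coord = a.coord + shift
    for i, r in enumerate(chain_b):
        r.chain_id, r.seq_index = "B", i
    two = S.RnaStructure([chain_a, chain_b], name="iso")
    desc = next(d for d in D.extract_descriptors(two)
                if d.central_residue == ("A", 10))
    b_segs = [s for s in desc.segments if s.chain_id == "B"]
    assert len(b_segs) == 1
    assert len(b_segs[0]) == 5
    assert (b_segs[0].start, b_segs[0].end) == (8, 12)


def test_interior_segments_at_least_five_residues(strand30):
    for desc in D.extract_descriptors(strand30):
        for seg in desc.segments:
            chain_len = 30
            interior = seg.start > 0 and seg.end < chain_len - 1
            if interior:
                assert len(seg) >= 5


def test_segments_merge_overlapping_extensions(hairpin):
    st, _ = hairpin
    for desc in D.extract_descriptors(st):
        spans = sorted((s.start, s.end) for s in desc.segments)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 > e1 + 1  # maximal contiguity: no mergeable neighbors


def test_central_residue_inside_exactly_one_segment(strand30):
    for desc in D.extract_descriptors(strand30):
        hits = [s for s in desc.segments if s.contains(*desc.central_residue)]
        assert len(hits) == 1


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ("GAUC", "GAUC", 1.0),
    ("AAAA", "UUUU", 0.0),
    ("GAUC", "GAUU", 0.75),
])
def test_identity_known_values(a, b, expected):
    assert D.sequence_identity(a, b) == pytest.approx(expected)


def test_identity_symmetric():
    assert D.sequence_identity("GGAUC", "GAC") == \
        pytest.approx(D.sequence_identity("GAC", "GGAUC"))


def test_identity_matches_exhaustive_alignment_on_4mers():
    """Global-alignment identity equals a brute-force path enumeration."""
    def oracle(a, b):
        # enumerate all global alignments of two 4-mers via recursion
        best = [-np.inf, 0.0]

        def rec(i, j, score, matches, length):
            if i == len(a) and j == len(b):
                if score > best[0] or (score == best[0]
                                       and matches / length > best[1]):
                    best[0], best[1] = score, matches / length
                return
            if i < len(a) and j < len(b):
                m = 1 if a[i] == b[j] else 0
                rec(i + 1, j + 1, score + m, matches + m, length + 1)
            if i < len(a):
                rec(i + 1, j, score - 1, matches, length + 1)
            if j < len(b):
                rec(i, j + 1, score - 1, matches, length + 1)

        rec(0, 0, 0.0, 0, 0)
        return best[1]

    rng = np.random.default_rng(5)
    for _ in range(10):
        a = "".join(rng.choice(list("ACGU"), 4))
        b = "".join(rng.choice(list("ACGU"), 4))
        assert D.sequence_identity(a, b) == pytest.approx(oracle(a, b))


def test_identity_rejects_empty():
    with pytest.raises(ValueError):
        D.sequence_identity("", "GAUC")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def test_self_alignment_is_perfect(hairpin):
    desc = D.extract_descriptors(hairpin[0])[0]
    res = D.align_descriptors(desc, desc)
    assert res.central_rmsd < 1e-9
    assert res.overall_rmsd < 1e-9
    assert res.element_coverage == 1.0
    assert res.residue_coverage == 1.0


def test_rigid_motion_alignment_is_near_zero(hairpin, rng):
    st, _ = hairpin
    moved = _rigid_copy(st, rng)
    a = D.extract_descriptors(st)[2]
    b = D.extract_descriptors(moved)[2]
    res = D.align_descriptors(a, b)
    assert res.central_rmsd < 1e-6
    assert res.overall_rmsd < 1e-6


def _multiseg_descriptor(seed=0):
    st, _ = syn.make_multisegment_fixture(3, seed=seed)
    descs = D.extract_descriptors(st)
    return next(d for d in descs if d.n_segments == 3)


def test_three_segment_matching_equals_bruteforce(rng):
    """Hungarian matching agrees with enumeration of all partial matchings."""
    a = _multiseg_descriptor()
    st, _ = syn.make_multisegment_fixture(3, seed=0)
    moved = st.copy()
    moved.set_coords(st.coords() @ random_rotation(rng).T + [3.0, 1.0, -2.0])
    # displace one non-central segment far away
    target_chain = moved.chains[2]
    for r in target_chain:
        for at in r.atoms.values():
            at.coord = at.coord + np.array([200.0, 0.0, 0.0])
    b = next(d for d in D.extract_descriptors(moved)
             if d.central_residue == a.central_residue)

    res = D.align_descriptors(a, b)

    # brute-force: enumerate all injective partial matchings of non-central
    # segments, cost = sum of per-segment RMSD (unmatched pays the penalty)
    penalty = 4.0
    off_a = dict(D._central_pairs(a))
    off_b = dict(D._central_pairs(b))
    common = sorted(set(off_a) & set(off_b))
    pa = np.array([off_a[o] for o in common])
    pb = np.array([off_b[o] for o in common])
    from rnadiff import metrics as M
    rot, t = M.kabsch_superpose(pb, pa)
    ia = [i for i, s in enumerate(a.segments) if s != a.central_segment]
    ib = [j for j, s in enumerate(b.segments) if s != b.central_segment]
    best_cost, best_match = np.inf, None
    for perm in itertools.permutations(ib + [None] * len(ia), len(ia)):
        if sum(x is not None for x in perm) != len(set(
                x for x in perm if x is not None)):
            continue
        cost, match = 0.0, set()
        for i_seg, j_seg in zip(ia, perm):
            if j_seg is None:
                cost += penalty
                continue
            ta = a.segment_trace(a.segments[i_seg])
            tb = b.segment_trace(b.segments[j_seg]) @ rot.T + t
            m = min(len(ta), len(tb))
            c = M._raw_rmsd(ta[:m], tb[:m])
            if c < penalty:
                cost += c
                match.add((i_seg, j_seg))
            else:
                cost += penalty
        cost += penalty * (len(ib) - sum(x is not None for x in perm))
        if cost < best_cost - 1e-12:
            best_cost, best_match = cost, match
    central_pair = {(a.segments.index(a.central_segment),
                     b.segments.index(b.central_segment))}
    assert res.matched_segments == central_pair | best_match


# ---------------------------------------------------------------------------
# Redundancy
# ---------------------------------------------------------------------------

def test_self_redundant(hairpin):
    desc = D.extract_descriptors(hairpin[0])[0]
    assert D.is_redundant(desc, desc)


def test_central_rmsd_threshold_rejects(hairpin, rng):
    st, _ = hairpin
    noisy = syn.perturb(st, 3.5, seed=0)  # well past the 2.5 A criterion
    a = D.extract_descriptors(st)[0]
    b = D.extract_descriptors(noisy)
    b = next((d for d in b if d.central_residue == a.central_residue), None)
    if b is not None:
        res = D.align_descriptors(a, b)
        if res.central_rmsd > 2.5:
            assert not D.is_redundant(a, b)


def test_redundancy_symmetric_on_rigid_copies(hairpin, rng):
    st, _ = hairpin
    a = D.extract_descriptors(st)[1]
    b = D.extract_descriptors(_rigid_copy(st, rng))[1]
    assert D.is_redundant(a, b) and D.is_redundant(b, a)


def test_four_criteria_match_hand_evaluation(rng):
    """Rotated copy with one segment deleted: evaluate criteria explicitly."""
    a = _multiseg_descriptor()
    st, _ = syn.make_multisegment_fixture(3, seed=0)
    moved = st.copy()
    moved.set_coords(st.coords() @ random_rotation(rng).T + [1.0, -4.0, 2.0])
    b_full = next(d for d in D.extract_descriptors(moved)
                  if d.central_residue == a.central_residue)
    # drop one non-central segment from b
    keep = tuple(s for s in b_full.segments if s != b_full.central_segment)[:1]
    b = D.Descriptor(b_full.parent_id, b_full.central_residue,
                     (b_full.central_segment,) + keep, b_full.threshold_T,
                     parent=b_full.parent)
    res = D.align_descriptors(a, b, dummy_penalty=4.0)
    cfg = D.CurationConfig()
    expected = (res.central_rmsd <= cfg.rmsd_central_max
                and res.best_duplex_rmsd <= cfg.rmsd_duplex_max
                and len(res.matched_segments) > 1
                and res.element_coverage > cfg.min_element_coverage
                and res.residue_coverage > cfg.min_residue_coverage
                and res.overall_rmsd <= cfg.rmsd_overall_max)
    assert D.is_redundant(a, b, cfg) == expected


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def test_curate_empty_input():
    assert D.curate_dataset([]) == []


def test_curate_drops_four_segment_descriptor(hairpin):
    st, _ = hairpin
    base = D.extract_descriptors(st)[0]
    seg = base.central_segment
    fake_segments = (seg,) + tuple(
        D.Segment("Z", 100 * k, 100 * k + 4) for k in range(1, 4))
    four = D.Descriptor(base.parent_id, base.central_residue, fake_segments,
                        base.threshold_T, parent=base.parent)
    assert four.n_segments == 4
    # bypass geometry stages that would need the fake chains: segment-count
    # filtering happens before any alignment
    kept = D.curate_dataset([four])
    assert kept == []


def test_curate_removes_rigid_motion_duplicate(hairpin, rng):
    st, _ = hairpin
    a = D.extract_descriptors(st)
    b = D.extract_descriptors(_rigid_copy(st, rng))
    kept = D.curate_dataset([a[0], b[0]])
    assert len(kept) == 1
    assert kept[0] is a[0]


def test_curate_removes_high_identity_duplicate(hairpin, rng):
    st, _ = hairpin
    descs = D.extract_descriptors(st)
    # same descriptor twice: identity 1.0 > 0.8 threshold removes the second
    kept = D.curate_dataset([descs[0], descs[0]])
    assert len(kept) == 1


def test_curate_drops_unfolded_single_strand():
    st, _ = syn.make_helix("GCAU" * 4)
    strand = S.RnaStructure([st.chains[0]], name="ss_only")
    descs = D.extract_descriptors(strand)
    # single-strand descriptors of an isolated strand have no WCF pairs
    singles = [d for d in descs if d.n_segments == 1]
    assert singles
    kept = D.curate_dataset(singles)
    assert kept == []


def test_curate_idempotent(hairpin, rng):
    st, _ = hairpin
    pool = (D.extract_descriptors(st)
            + D.extract_descriptors(_rigid_copy(st, rng)))
    once = D.curate_dataset(pool)
    twice = D.curate_dataset(once)
    assert [d.central_residue for d in twice] == \
        [d.central_residue for d in once]


# ---------------------------------------------------------------------------
# Family partition
# ---------------------------------------------------------------------------

def test_partition_all_train(hairpin):
    descs = D.extract_descriptors(hairpin[0])
    labels = {d.parent_id: "tRNA" for d in descs}
    train, test = D.partition_by_family(descs, labels, {"tRNA", "rRNA"})
    assert len(train) == len(descs) and test == []


def test_partition_counts_and_disjoint(hairpin, helix8):
    d1 = D.extract_descriptors(hairpin[0])[:3]
    st2 = helix8[0].copy()
    st2.name = "other"
    d2 = D.extract_descriptors(st2)[:2]
    labels = {d1[0].parent_id: "tRNA", "other": "riboswitch"}
    train, test = D.partition_by_family(d1 + d2, labels, {"tRNA", "rRNA"})
    assert (len(train), len(test)) == (3, 2)
    assert len(train) + len(test) == 5


def test_partition_unlabelled_raises(hairpin):
    descs = D.extract_descriptors(hairpin[0])[:1]
    with pytest.raises(KeyError):
        D.partition_by_family(descs, {}, {"tRNA"})


def test_manifest_roundtrip(tmp_path, hairpin):
    descs = D.extract_descriptors(hairpin[0])[:3]
    path = tmp_path / "manifest.tsv"
    D.write_manifest(descs, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 4
    assert lines[0].startswith("parent_id")
    assert descs[0].sequence() in lines[1]
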