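# Methods

This note documents the models and procedures implemented in `rnadiff`, the
assumptions behind them, the defaults that matter, and what the synthetic
fixtures do and do not establish about real data.

## Problem setting

`rnadiff` generates coarse-grained 3D structures of small RNA fragments
under user-supplied sequence and secondary-structure constraints, and
provides the surrounding machinery: extraction and curation of local 3D
descriptors from experimental structures, atom-level interaction graphs,
and the standard comparison metrics (RMSD, eRMSD, INF).

## Coarse-grained representation

Each nucleotide is reduced to five atoms: the backbone phosphorus P and
sugar C4', plus a three-atom base triangle — N9-C2-C6 for purines and
N1-C2-C4 for pyrimidines.  The triangle fixes the base plane and
orientation, which is what canonical-pair geometry and the eRMSD base
frames need; a 5'-terminal residue may lack P and keeps four atoms.
Before entering the generative model, coordinates are centered at the
origin and divided by 10, putting typical fragment coordinates in roughly
[-5, 5] — matched to the unit-variance Gaussian prior of the diffusion
process.  The shift and scale are recorded on the structure, so the
transform inverts exactly and PDB output is always in original-frame
angstroms.

## Local 3D descriptors

For each chain of N residues, central residues run from the 3rd to the
(N-2)th — N-4 descriptors per chain.  A residue is in contact with the
central residue when their C5' atoms lie within T = 16 angstroms (the
default; exposed as a parameter).  Central and in-contact residues are
extended by two flanking residues on each side, truncated at chain
termini; overlapping extensions merge into maximal contiguous segments, so
an isolated in-contact residue interior to its chain always yields a
5-residue segment.  Extraction requires full-atom input because the coarse
model lacks C5'.

### Curation

Four filters, applied in order, each deterministic:

1. **Unfolded strands** — a single-segment descriptor whose substructure
   contains no detectable canonical pair is dropped.  "Unfolded" is not a
   crisply defined notion; zero canonical pairs is the operationalization
   used here.
2. **Segment count** — descriptors with more than 3 segments are dropped.
3. **Sequence identity** — greedy scan in input order; a descriptor is
   dropped when its concatenated segment sequence exceeds 80% identity to
   an already-kept one.  Identity is computed under global alignment
   (match 1, mismatch 0, gap -1), normalized by alignment length.
4. **Structural redundancy** — greedy scan using a partial alignment: the
   segments containing the central residues are superposed first (C5'
   traces, residues paired by offset from the central residue); the
   remaining segments are matched by a minimum-cost assignment
   (Hungarian), with dummy rows/columns at a fixed penalty equal to the
   duplex threshold so segments may stay unmatched.  Two descriptors are
   redundant when all four of these hold: central RMSD <= 2.5 A; best
   duplex (central element plus one matched segment, re-superposed) RMSD
   <= 4.0 A, vacuous for single-segment descriptors; more than half the
   elements and more than two thirds of the residues covered by the
   match; overall RMSD over matched residues <= 3.5 A.

Coverage denominators use the larger descriptor of the pair, which makes
the redundancy decision symmetric whenever the assignment is unique.

## Interaction graph

Nodes are the coarse atoms in structure order.  Edges come in four
classes:

- **covalent** (static): P-C4', C4'-anchor, the three base-triangle
  bonds, and the backbone link C4'(i)-P(i+1) within a chain;
- **pairing** (static): for each constrained canonical pair, two edges —
  anchor-anchor and C2-C2.  Two edges pin both the separation and the
  relative twist of the pair, which one edge cannot;
- **local** (dynamic): atom pairs without a static edge within 5 A;
- **global** (dynamic): pairs in (5, 16] A.

Dynamic classes are disjoint, avoiding duplicate messages.  Each node
keeps at most 20 dynamic neighbors per class; the cap is enforced as a
mutual k-nearest-neighbor rule (an undirected edge survives only when both
endpoints rank each other within their 20 nearest in that class), the only
symmetric rule that guarantees the cap after deduplication.  Dynamic edges
are rebuilt from the *current* coordinates at every diffusion step — noisy
during training and sampling alike, so the train and inference regimes
match.

Close-contact edges carry the distance, one-hop angles theta (at the edge
source, against every other close neighbor) and two-hop angles phi
(DimeNet-style planar surrogate for torsions).  Distances are expanded in
16 spherical-Bessel radial basis functions under a smooth polynomial
envelope that vanishes at the class cutoff; angles in 7 zonal harmonics
(Legendre polynomials in cos theta).  Because neighbor counts vary, the
per-edge network feature aggregates the harmonics by summation before the
outer product with the radial expansion, giving a fixed 7x16 block; edges
whose source has no other close neighbor fall back to the l=0 harmonic.
Long-range edges carry the radial expansion only.  All geometry is
computed on unscaled angstrom coordinates; the /10 scaling applies only to
the coordinates fed to the denoiser.

## Sequence embeddings

The denoiser consumes one 256-vector per residue, broadcast to the
residue's five atoms.  Multi-segment inputs are merged into a single
string, without a separator token, before embedding — keeping sequential
context at the cost of spurious adjacency across the junction (a known
limitation, kept deliberately).  Providers are pluggable by name:

- **fallback** — a fixed seeded vector per base pushed through the
  projection head.  Positionally blind: two residues of the same base are
  indistinguishable.
- **positional** (default for training and sampling) — base table vector
  concatenated with a sinusoidal position encoding, then projected.  This
  emulates the one property of a contextual RNA language model that the
  generative model actually relies on: residues at different positions
  receive different vectors, so the network can tell otherwise
  feature-identical residues apart.  It carries no evolutionary or
  structural signal, and nothing here should be read as approximating
  real language-model embeddings.

The projection head is a bias-free linear layer to 1280 units, ReLU, then
a linear layer to 256.  An external language-model provider can be
registered under its own name; swapping providers changes feature values
only, never shapes or topology.

## Diffusion model

Standard DDPM over atom coordinates.  Forward corruption
x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps with a linear beta schedule;
T = 5000 steps at paper scale, T = 200 for desk-scale work.  Beta
endpoints are 2e-5 to 4e-3 at T = 5000 and scale as 5000/T so the total
corruption (sum of betas, about 10) is preserved at any T; the terminal
abar is below 1e-3 for every supported T, verified by test.  Only
coordinates are noised; features and the static graph are preserved.

The denoiser is trained by epsilon-regression: per item, t is drawn
uniformly, the coordinates are corrupted, dynamic edges are rebuilt on the
noisy coordinates, and the loss is the MSE between predicted and true
noise.  By default t is drawn by cycling shuffled permutations of 0..T-1
rather than independently — the marginal stays uniform, but every step
index is visited evenly, which matters because the few smallest t carry
the largest objective sensitivity.  Gradient clipping at global norm 2
and a step learning-rate schedule (x0.9 every `decay_every` epochs from
0.003) follow the reference training setup; an exponential moving average
of the parameters (decay 0.999) is maintained and loaded at the end of
training, the standard stabilization for diffusion models.  Sampling is ancestral: coordinates
start as unit Gaussian noise and take T posterior steps with variance
beta-tilde, the last step deterministic.  The primary correctness oracle
is analytic: replacing the network by the true epsilon makes the
deterministic reverse trajectory contract onto x0 (the residual shrinks by
sqrt(alpha_t)(1-abar_{t-1})/(1-abar_t) per step), and the implementation
recovers x0 to better than 1e-4.

## Denoiser network

Coordinates are encoded by a linear layer, layer normalization and a
sigmoid; node features (atom one-hot over {C, P, N}, C4' flag, residue
one-hot, sequence embedding, 16-dim sinusoidal time embedding) are
projected and added.  Message-passing blocks have two branches — a
close-contact branch over covalent/pairing/local edges using the full
radial/angular features, and a long-range branch over global edges using
radial features only — fused per node by a two-way softmax attention with
a residual connection.  Six blocks at paper scale bound the receptive
field at 6 hops, hence 30 A through local edges and 96 A through
long-range edges.  A pre-norm transformer encoder (6 layers, 8 heads at
paper scale) with unmasked self-attention over all atoms follows; with no
positional encoding the whole network is permutation-equivariant.  Per-atom
heads output the noise vector and atom/residue type logits; type logits
are exposed but excluded from the default loss.  There is no pooling
anywhere.

Two deliberate architectural choices.  First, the network is *not*
SE(3)-equivariant (centering provides partial invariance; equivariance is
future work).  Second, the noise estimate is computed through a
clean-coordinate parameterization: a one-hidden-layer MLP head — fed the
final node state, the scaled coordinates and the raw time embedding —
predicts x0-hat, and epsilon-hat follows analytically as
(x_t - sqrt(abar_t) x0-hat)/sqrt(1-abar_t).  The training objective is
unchanged (epsilon MSE), but the steep gain 1/sqrt(1-abar_t), which near
t = 0 amplifies any x0 error by a factor of ~45 at desk scale, is applied
exactly instead of being learned; in practice this cut the optimization
steps needed for a given loss by roughly a factor of four.

Desk-scale configuration: 2 blocks, hidden 64, 2 transformer layers,
4 heads, T = 200 — about 160k parameters, sized for single-CPU training.

## Metrics

- **RMSD** is computed over atoms corresponded by residue position and
  atom name, after optimal (Kabsch, proper-rotation) superposition by
  default; raw mode is exposed.  The printed definition of the metric has
  no superposition, but the reference workflow computes it in a viewer
  that superposes first, so superposition is the default here.
- **eRMSD** builds a base-fixed frame from the three base-triangle atoms
  (origin at their centroid, x toward C2, z along the triangle normal),
  expresses each partner base's origin in that frame, rescales x,y by 5 A
  and z by 3 A, and maps the result through the smooth cutoff function
  G (cutoff 2.4, gamma = pi/2.4) to a 4-vector that vanishes continuously
  at the cutoff.  The score is the root mean square of G-vector
  differences over all ordered pairs, normalized by residue count.  The
  rescaling constants and cutoff follow the published method that
  introduced the metric; the frame differs from the full-atom original in
  using the coarse triangle, so absolute values are comparable only
  between structures in the same representation.  Values below about 0.7
  conventionally indicate native-like arrangements.
- **INF** is the geometric mean of precision and recall over base-pair
  sets; both sets empty scores 1.0, exactly one empty scores 0.0.  G-U
  wobble counts as canonical by default (switchable).  Non-canonical
  annotation is out of scope; INF(NWC) is computed only from externally
  supplied pair sets.
- **Canonical pair annotation** is geometric: complementary bases whose
  anchor-anchor distance lies in [7.5, 10.5] A, C2-C2 distance in
  [4.5, 7.5] A and base-plane angle under 35 degrees, accepted greedily by
  closeness to ideal pair geometry with each residue in at most one pair.
  The windows are calibrated against the synthetic generator (below) and
  exposed as parameters.

## Synthetic fixtures

Fixtures are built from an idealized base-pair template placed on a
helical screw (twist 32.7 degrees/bp, rise 2.81 A/bp, A-form-like).  The
template fixes anchor-anchor (9.0 A) and C2-C2 (5.8 A) separations inside
the annotator windows, includes C5' (for descriptor extraction) and N3
beyond the coarse five, and sets the backbone radius so that cross-strand
C5'-C5' contacts fall inside the 16 A descriptor threshold.  Hairpins
join the stem strands by a semicircular loop arc with consecutive C4'
spacing under 8 A; multi-segment fixtures cut the complementary strand of
a duplex into 4-residue pieces, each keeping four canonical contacts with
the central strand.

What the fixtures establish: exact ground-truth pairing (the annotator
recovers it perfectly at zero noise — a deliberate calibration lock),
known segment topology, determinism per seed.  What they do not
establish: crystallographic realism (bond lengths and backbone geometry
are idealized), sequence-dependent helical parameters, non-canonical
pairs, or thermodynamics.  Passing tests on fixtures therefore
demonstrates algorithmic correctness, not predictive accuracy on
experimental structures.

## Numerical choices and degenerate inputs

- Kabsch uses SVD with a determinant correction; reflections are never
  returned.  Superposition requires at least 3 corresponded atoms.
- Dynamic-edge ties at equal distance break toward the lower node index
  (stable argsort), making graph construction deterministic.
- The radial basis is finite as d -> 0 and exactly zero at and beyond the
  cutoff; basis orthonormality (un-enveloped, r^2 measure) is verified by
  quadrature in the tests.
- Coincident atoms on a close edge raise an error rather than produce
  NaN angles.
- Single-atom structures are allowed through centering/scaling; empty
  structures are rejected at construction.
- All stochastic operations take explicit seeds; the CLI derives named
  sub-seeds (data, init, sampling, embed) from one master seed by
  hashing.

## Problem sizes used in the shipped checks

The self-contained verification runs use desk-scale sizes chosen to keep
the full suite fast on a single CPU: a 12-residue hairpin (60 atoms) for
training and sampling, T = 200 diffusion steps, 7000 optimization steps
per seed for overfit-recovery, 10^4-draw Monte-Carlo checks of forward
marginals, and 100 random 40-atom configurations for the graph
invariants.  Paper-scale settings (T = 5000, 6 blocks, hidden 256, 6
transformer layers) are the package defaults for real use.

## Known limitations

- The autodiff engine and network run on a single CPU in float64; no GPU
  path, no minibatching across many structures beyond a simple list.
- Training at paper scale (800 epochs, batch 128, tens of thousands of
  descriptors) is configured but not exercised by the shipped checks.
- The fallback/positional embedding providers carry no learned sequence
  context; plugging in a real RNA language model is expected to change
  results materially.
- Full-atom reconstruction from the coarse representation is out of
  scope, as are non-canonical pair annotation and lDDT.
- is_redundant symmetry can break on pathological inputs where the
  optimal segment assignment is non-unique.
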