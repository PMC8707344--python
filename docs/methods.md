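# Methods

## The measure

For an ordered chain of reference points p₀ … p_{n−1} (the Cα atoms of one
secondary-structure element, N- to C-terminal), form the difference vectors
vᵢ = pᵢ₊₁ − pᵢ and sum the scalar triple products of consecutive triples:

    chi_total = Σ (vᵢ × vᵢ₊₁) · vᵢ₊₂         over the n − 3 triples.

Each term is the signed volume of the parallelepiped on three consecutive
steps: a pseudoscalar. Under any proper rotation plus translation the value
is unchanged; under any improper transform (mirror) it is negated exactly;
under uniform scaling by s it scales as s³. Chains of fewer than 4 points
have no triple and return exactly 0 rather than an error — the stepwise
table of a growing prefix prints zeros for lengths 1–3, which is the
convention users expect when tracing loops.

A subtlety worth recording: chi_total is *invariant*, not antisymmetric,
under reversal of the point order. Reversal negates all three difference
vectors of each triple ((−1)³) and transposes the triple (one determinant
row swap, −1); the two signs cancel. This is geometrically right — a helix
traversed from either end has the same handedness. The dipole-sequence
variant below, which takes triple products of the sequence vectors
themselves without differencing, picks up only the transposition sign and
therefore *is* antisymmetric under reversal of molecule order. Both
behaviours are asserted in the invariance tests.

## Normalization and the exponent k = 5

The normalized measure divides each triple product by the k-th power of the
mean length of its own three vectors:

    chi_norm = Σ (vᵢ × vᵢ₊₁) · vᵢ₊₂ / Cᵢ ,   Cᵢ = ((|vᵢ|+|vᵢ₊₁|+|vᵢ₊₂|)/3)ᵏ.

The normalization is per-triple, not global, so elements with uneven step
lengths (turns, loops) are treated without assuming a common step; for a
uniform-step helix the two coincide and chi_norm = chi_total / step^k.
Units: coordinates in Å give chi_total in Å³ and chi_norm in Å⁻² at k = 5;
no unit conversion is performed.

k = 5 is fixed by a scaling argument on the ideal helix. One turn of radius
R and height H sampled at N + 1 points A_i = (R cos iφ, R sin iφ, ih),
φ = 2π/N, h = H/N, has all steps of length √(h² + 4R² sin²(φ/2)) and a
per-triple product of exactly 16 h R² sin⁴(φ/2) sin φ, so

    chi_total = 16 · (n_points − 3) · h · R² · sin⁴(φ/2) · sin φ.

As N → ∞ this decays as 32π⁵HR²/N⁵ while the step length decays as
√(H² + 4π²R²)/N: chi ~ step⁵. Only k = 5 makes chi/stepᵏ approach a finite
nonzero constant (32π⁵HR²/(H² + 4π²R²)^{5/2}); k = 4 sends it to zero and
k = 6 to infinity, a factor ~10 per decade of N either way. `scaling_study`
tabulates this. Two numerical notes:

- The closed form is implemented with the per-step rise h = H/N. Writing
  the full turn height in its place does not satisfy the term-by-term
  identity and breaks the 1/N⁵ scaling; the implementation is verified
  against the numeric triple-product sum at 1e−9 relative over a broad
  (R, H, N) sweep.
- The multiplier is the actual number of triples, n_points − 3 = N − 2 for
  a turn of N steps. The raw ratio chi/step⁵ therefore carries an O(1/N)
  boundary factor (N − 2)/N — the first and last steps sit in fewer
  triples than interior steps. The scaling table reports both the raw
  ratio and a boundary-corrected column (multiplied by N/(N − 2)) whose
  residual error is O(1/N²); the corrected column is the one compared at
  the 0.1% level between N = 10³ and 10⁴. At those sizes the computation
  is still fast (< 1 s) and numerically safe: all terms have one sign, so
  no cancellation amplifies rounding.

Handedness classification uses a threshold ε on chi_norm: values above +ε
are positive/D (right-handed), below −ε negative/L, else achiral. ε
defaults to 1e−9 — real structures sit many orders of magnitude away from
zero, so the threshold only absorbs floating-point noise on exactly planar
synthetic inputs; it is exposed for users who want a coarser band.

## Ideal-helix generator

`IdealHelixSpec(R, H, N, handedness)` generates the N + 1 points above;
left handedness negates y (an exact mirror, equivalent to φ → −φ). The
generator accepts the degenerate edges R = 0 (straight line) and H = 0
(planar polygon), both achiral, as long as the step length stays positive.
The sign convention — right-handed generator positive — matches the
protein convention in which right-handed helices plot on the positive side
of a chirality map.

## Structure input

PDB/mmCIF parsing is delegated to gemmi. Elements are selected by author
residue numbering (`A:8-13`), the numbering used in structure citations.
Per residue one Cα is chosen deterministically: blank altloc, else altloc
'A', else highest occupancy. Model 1 is the default for multi-model
entries. A residue missing inside the requested range raises an error
naming the gaps, because silently bridging a gap would produce a ~7.6 Å
pseudo-step and a wrong chirality value; a residue without a Cα raises
likewise. HELIX header records can be used as ready-made selections; the
standard class codes map 1 → alpha, 5 → 3₁₀, 3 → pi. CA-only PDB output
(dummy GLY residues) supports round-tripping generated helices through the
same reader at the format's 3-decimal precision.

## Dipole-sequence (nanotube coil) measure

A coil of a helix-like peptide nanotube is described by the ordered
per-molecule dipole vectors D₁ … Dₙ in Debye. The measure is

    c_total = Σ_{i=1..n−2} (Dᵢ × Dᵢ₊₁) · Dᵢ₊₂ ,   c_norm = c_total / D_av³,

with D_av the arithmetic mean of the magnitudes |Dᵢ|. The i range runs to
n − 2 (not n − 3): the sequence vectors are used directly, with no
differencing, because each molecule contributes one vector. c_norm is
dimensionless and invariant under uniform scaling of all dipoles.

How the dipoles were obtained (quantum-chemical or force-field) is outside
the package: they are inputs, read from delimited tables with columns
(i, Dx, Dy, Dz). Summary rows labelled Dsum, Dcoil or Dav are recognized
and kept as metadata — Dcoil in particular is a whole-coil quantity from a
separate calculation and is never recomputed from the per-molecule rows.
Vector origins (molecular centers of mass) do not enter the formulas and
are not required.

The packaged reference tables hold one 12-molecule coil of an
L-phenylalanine and a D-phenylalanine nanotube with dipoles from an RM1
and an Amber calculation, transcribed at the 3-decimal precision of their
source. Recomputing from rounded components reproduces the published
c_total/c_norm to within 0.5% and the cubed mean magnitudes to within
0.1% (the published footnotes cube the rounded mean); tests use those
tolerances, which are transcription-precision bounds, not method slack.

## Synthetic data and what the tests show

Randomized test chains are built from steps of length 3.6–4.0 Å in uniform
random directions — the Cα–Cα spacing of real proteins with none of their
excluded-volume or dihedral-angle regularity. They exercise the measure's
algebraic properties (invariances, telescoping of the stepwise table,
sign conventions) on realistic length scales; they do not emulate real
secondary-structure geometry, so passing tests validate the measure and
its implementation, not any biological claim about the distribution of
chirality values in the PDB. Ideal helices stand in for regular elements
where an exact oracle exists. One published check that needs real data —
the stepwise chirality of an omega-loop of actinidin (PDB entry 2ACT,
residues 8–13) — runs automatically when a local copy of that entry is
placed at `tests/data/2ACT.pdb`; the structural parts of that test (zero
prefixes, telescoping) run on synthetic chains regardless.

## Known limitations

- No secondary-structure assignment: element boundaries come from the user
  or from HELIX records; turns and loops must be delimited externally.
- No fitting of helix parameters to real coordinates; generation only.
- The chirality map output is records (length, chi_norm, handedness), not
  plots.
- Insertion-code ordering inside a range follows the file's residue order;
  ranges are validated on residue numbers only.
- Coil membership for nanotubes is input slicing: the user supplies which
  molecules form a coil, in order.
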