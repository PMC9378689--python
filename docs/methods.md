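# Methods

This note records the models, conventions and numerical choices behind each
measurement, what the synthetic generators do and do not emulate, and the known
limitations.

## Coordinate model and selections

Structures are read through biotite (fixed-width PDB v3.3 and mmCIF) into a
plain atom container. Author residue numbering with insertion codes is the
coordinate convention throughout, because functional residues of the elongation
complex are cited in author numbering (βE1006, β′D256, β′R77); label_seq is not
used for selections. Altlocs are resolved on read: the highest-occupancy
conformer is kept, ties broken alphabetically, which makes resolution
deterministic and idempotent. Waters are dropped by default (none are modeled
in the relevant cryo-EM depositions; a flag keeps them). Metal ions (Zn²⁺ at
the β′ ZBD, the catalytic Mg²⁺) are retained and flagged.

Domain definitions live in a TOML data file, not in code. The shipped
`ecoli_rnap_domains.toml` curates approximate *E. coli* RNAP boundaries for the
swivel module (clamp, shelf, jaw, SI3, β′ C-terminal region), the core module,
and marker regions (bridge helix, lid, ZBD, βSI2, clamp toe/helices) from the
structural literature on RNAP swiveling. No study prints its exact boundaries,
so these ranges are approximate by design; the swivel-angle tolerance used in
validation (±0.3°) absorbs boundary uncertainty, and users can override the
file per structure.

## Swivel geometry

The swivel angle between a reference and a target EC is a two-stage
measurement:

1. superpose the target onto the reference by least squares over the shared
   core-module Cα atoms (identity pairing on chain/residue/atom name; residues
   modeled in only one structure are dropped symmetrically and counted);
2. superpose the core-aligned target's swivel-module Cα set onto the
   reference's and extract the residual rotation.

The reported scalar is the full residual rotation angle,
θ = arccos((tr **R** − 1)/2) ∈ [0°, 180°], not its projection onto the
bridge-helix axis: swiveling is described as a rotation about an axis roughly
parallel to the bridge helix, so the angle between the residual axis and the
bridge-helix axis (least-squares line through the bridge-helix Cα, oriented
N→C) is reported alongside as a diagnostic rather than folded into the scalar.
The screw decomposition (axis point, translation along the axis) is also
reported. Cα is the default atom subset (domain comparisons in this field are
Cα-based); all-backbone is available. Superposition delegates to
`scipy.spatial.transform.Rotation.align_vectors` (SVD Kabsch, reflections
excluded); degenerate inputs (< 3 atoms, collinear sets) are errors, and
rotations below 10⁻⁶ degrees have no defined axis.

Probe displacements (e.g. the βSI2 tip Cα between swiveled and non-swiveled
complexes) use the same machinery: align on an arbitrary selection, then
measure the Euclidean displacement of a single-atom probe.

## Surface areas and contacts

SASA is Shrake–Rupley sphere sampling with a deterministic golden-spiral
(Fibonacci) point set — no RNG, so results are bit-stable. Defaults: probe
1.4 Å, 960 points per atom; doubling the point count changes a 20-atom
cluster's total by < 0.5 %. Radii are the Bondi (1964) van-der-Waals set,
shipped as data with a name recorded in every result; the radii behind
published PISA-style interface areas are unknown, which is why interface-area
comparisons carry a ±10 % tolerance. Buried surface area follows the PISA
convention BSA = (SASA(A) + SASA(B) − SASA(A∪B))/2; interface residues are
those burying > 0.1 Å² (insensitive to sampling noise while reproducing
"fraction of residues at the interface" statistics).

Deposited cryo-EM models carry no hydrogens, so polar contacts are *potential*
contacts from heavy-atom criteria: hydrogen bonds at donor–acceptor ≤ 3.5 Å
with a ≥ 90° donor–acceptor–antecedent angle where an antecedent exists; salt
bridges at charged-group nitrogen to phosphate/carboxylate oxygen ≤ 4.0 Å
(taking priority over a hydrogen bond for the same atom pair); cation-π at
charged nitrogen to aromatic/base ring centroid ≤ 6.0 Å within 30° of the ring
normal. All cutoffs are arguments.

In-silico base substitution replaces a base's heavy atoms with an idealized
template superposed on the glycosidic anchor triad (purine N9/C4/C8 ↔
pyrimidine N1/C2/C6); sugar and phosphate atoms are untouched. Substituting a
base by itself reproduces the original to numerical precision on idealized
models. Hydrogen-bond recounting against a pocket selection then scores what
each substituted base could donate/accept — the modeling counterpart of a
mutant activity panel.

## Base pairs, hybrids, kinks

Two nucleotides pair when (i) C1′–C1′ ∈ [7.5, 11.5] Å, (ii) the base planes are
coplanar in the strong sense — inter-plane angle ≤ 35° *and* centroid stagger
along the mean normal ≤ 2.0 Å (the stagger test rejects stacked neighbours,
which satisfy the angle test trivially) — and (iii) at least one inter-base
heavy-atom hydrogen bond ≤ 3.5 Å links their edges. Candidates are accepted
greedily by descending hydrogen-bond count then ascending C1′–C1′ distance; a
residue may appear in at most two pairs, the second flagged `is_triplex_extra`
(sufficient for the put minor-groove triple; deeper multiplets are out of
scope). Saenger classification matches the observed hydrogen-bond atom pattern
against a catalog restricted to the classes that matter here: XIX/XX
(canonical; a G:C needs the central N1–N3 bond plus one more), XXVIII (G·U
wobble), VIII (A·G imino) and XI (G·A sheared). Unmatched patterns are
`other`; patterns matching several classes are `unassigned`. Pairs printed in
the literature without Saenger numbers are deliberately not asserted to any
class.

The RNA–DNA hybrid is the contiguous run of inter-chain Watson–Crick pairs
ending at the RNA 3′ terminus. The translocation register is called from the
substrate (i+1) template position — the template residue one step beyond the
3′-end pair in the hybrid's template numbering direction: present and unpaired
→ post-translocated; absent → pre-translocated (the RNA 3′ base still occupies
i+1); RNA 3′ residue at partial occupancy → ambiguous (a mixed roadblocked
population, e.g. +94/+95 stall products). The i+1 residue number can be given
explicitly when the inference convention does not fit a scaffold's numbering.

Kink angles fit a least-squares axis through the C1′-midpoints of each
segment's pairs (≥ 3 pairs per segment) and report the inter-axis angle in
[0°, 90°].

## Assay statistic and conservation

Transcripts are body-labelled via α-³²P CTP, so band intensities scale with
cytosine content; the paused fraction divides each intensity by its
transcript's cytosine count before normalising. Cytosine counts are caller
inputs (whether a study's calibration counted all cytosines or only labelled
positions is not always specified; supplying n_C sidesteps that). Intensities
are assumed background-corrected. The relative anti-pausing activity maps the
paused fraction onto the line anchored by WT (1) and put⁻ (0); it is affine
invariant and not clipped — noise legitimately pushes lanes slightly past the
anchors. Classes: inactivating < 0.2, inert > 0.9, other in between; boundary
values are `other` (the class definitions use strict inequalities). SEM is
sd/√n over replicates; each replicate is quantified against its own gel's
anchor lanes. Conservation is the per-reference-column identity count over the
alignment (gaps never match, T ≡ U, case-insensitive) — the 0–N integer scores
used to colour conservation onto a structure; alignment computation itself is
out of scope, alignments are consumed.

## Masses and deconvolution

RNA masses are sums over an elemental-composition table: internal residue =
nucleoside monophosphate − water, plus one water for the termini, plus the 5′
adjustment (triphosphate +2 HPO₃ — the default, as in-vitro transcripts are
initiated with NTPs; hydroxyl −1 HPO₃). Average masses are the default
(electrospray of ~30 kDa RNA resolves average mass); monoisotopic is
available. Proton mass 1.00728 Da; adducts are not modeled. The deconvolution
is deliberately a consistency search, not a Bayesian algorithm: consecutive
peaks are assumed to carry consecutive charges, every candidate charge for the
highest-m/z peak is tried, and the assignment minimising the spread of implied
neutral masses wins; the consensus is the intensity-weighted mean and the
spread is reported as the residual. It is exact on clean series and recovers
masses within ~2 Da under 0.05 Th m/z jitter, but it is not a peak-picker: it
expects a single species' series.

## Synthetic generators: what they emulate, and what a green test shows

All generators are pure functions of their arguments and a seed.

- **Two-module models**: pseudo-Cα clouds (~100 Å extent) for core and swivel
  modules plus a straight bridge-helix marker line; the swivel group is rotated
  about an axis through that line and i.i.d. Gaussian noise is added. This
  emulates the *geometry* of swiveling — rigid-body rotation about a known axis
  — not protein topology, secondary structure, or correlated model-building
  error. A green recovery test establishes that the two-stage estimator is
  unbiased to < 0.1° under 0.3 Å uncorrelated noise; it cannot establish
  robustness to domain-boundary misassignment on real structures.
- **Duplexes**: full heavy-atom nucleotides from idealized planar base
  templates (constructed in code from idealized bond geometry, hydrogen-bond
  lengths 2.84–2.93 Å, C1′–C1′ 10.4 Å) placed by fiber A-form helical symmetry
  (twist 32.7°, rise 2.81 Å) with zero inclination and the helix axis through
  the pair centres; sugar/phosphate atoms are plausible placeholders, not
  refined geometry. Optional mid-helix bend, RNA/DNA hybrid form with template
  overhangs, and a minor-groove third strand (a purine G donating N2 into a
  purine's N3 — a pyrimidine's glycosidic carbon is geometrically too close to
  its edge to reach the C1′–C1′ window from the minor groove). Green pairing
  tests establish the detector's behaviour on canonical geometry; real
  structures add propeller, inclination, and modeling noise the fixtures do
  not.
- **Gel datasets**: lane intensities inverted from known activities through the
  activity formula with anchors P_WT = 0.05 and P_put⁻ = 0.60 (chosen to match
  a wild type with no visible paused band and a clearly paused put⁻ lane;
  neither fraction is printed in the literature), cytosine counts 24/30 for
  paused/run-off transcripts, and multiplicative log-normal noise at the given
  CV (mean-one parameterisation). Triplicates at 5 % CV mirror a clean
  quantified assay; gel artefacts (smearing, background) are not modeled.
- **Charge series**: exact peak positions (M + z·m_p)/z with optional Gaussian
  m/z jitter in tests.

## Known limitations

- The paper-scale numbers (swivel angles of the deposited complexes, interface
  areas, Mg–Zn distance, 21+5 pair inventory, 11-bp hybrids) require the
  deposited coordinate files; `examples/reproduce_deposited.py` runs them
  against a local download directory, and the corresponding acceptance test
  fails (rather than silently passing) when the files are absent. Chain
  identifiers in that example may need adjusting to the deposition's labels.
- Default domain boundaries are curated approximations (see above).
- The Saenger catalog covers only the classes relevant here; the full 28-class
  taxonomy and the Leontis–Westhof edge taxonomy are out of scope.
- No electrostatics, no interface free energies, no water-mediated contacts,
  no isotope envelopes.
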