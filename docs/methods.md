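# Methods

## Scope and data model

`abdev` screens antibody structures and sequences for developability
liabilities. The structural unit is an `AtomicStructure` — ordered chains of
residues of atoms, carrying coordinates (Å), element, occupancy, altloc,
crystallographic B-factor and an assigned van der Waals radius — parsed
from PDB or mmCIF via gemmi. Residue identity is author numbering
(1-based, insertion codes preserved); antibody semantics (Kabat labels such
as `H97`, CDR/framework regions) are attached from an external
`NumberingMap` CSV rather than computed: scheme assignment is an
external-tool concern, and pinning the map removes ambiguity. Unmapped
residues carry `region="other"`.

Default filters drop waters (HOH/WAT), hetero residues (except aliased
modified residues such as MSE → M) and hydrogens; altloc groups keep the
highest-occupancy copy, ties broken toward altloc `A`. All defaults are
flags on `read_structure`.

### Pinned data tables

* **van der Waals radii** — Bondi values by element, default 1.70 Å for
  unknown elements (name-based inference first). Shipped as package data;
  published SASA implementations differ mainly through this table, which is
  why cross-implementation comparisons below use a ±10% band.
* **Black & Mould hydrophobicity scale** — normalized to [0, 1]
  (F = 1.000, W = 0.878, R = 0.000), transcribed from the 1991 reference.
* **Maximal per-residue SASA** — Tien et al. (2013) theoretical
  Gly-X-Gly values, used as the denominator of relative exposure.
* **Kabat region boundaries** — heavy CDR1 31–35, CDR2 50–65, CDR3 95–102;
  light CDR1 24–34, CDR2 50–56, CDR3 89–97; insertion codes inherit the
  region of the parent number; beyond FR4 is `constant`.

## Solvent-accessible surface area

Shrake–Rupley quadrature, implemented from scratch. Each atom's
solvent-expanded sphere (radius `r_vdw + probe`, probe default 1.4 Å)
carries a deterministic golden-spiral (Fibonacci) point set, default 960
points; a point survives if it lies outside every neighbouring expanded
sphere, and

    area_i = (exposed / total) · 4π (r_i + probe)².

Neighbour candidates come from a spatial grid with cell size
`2·(r_max + probe)` (27-cell stencil); the grid is verified exactly against
the all-pairs path in the tests, and correctness, not speed, is the
contract. Per-residue SASA is the exact sum of the residue's atoms.

Two independent oracles validate the engine: the closed forms for an
isolated sphere (`4πR²`) and for two equal intersecting spheres
(cap area `2πRh`, `h = R − d/2`), and an unbiased Monte-Carlo estimator
(uniform points on each expanded sphere, binomial standard errors) that the
quadrature must match within 3 SE on random packings.

Numerical behaviour worth knowing: translations leave areas exactly
unchanged (the point set rides with each centre), while rotations reshuffle
which boundary points are exposed — the jitter is below 0.1 Å² per atom at
50 000 points and ~0.3 Å² at 2 000. Quadrature error on an isolated sphere
is < 1% at 960 points and decreases with the point count.

## Hydrophobicity profile and hotspots

`score_r = SASA_r × h_aa`, exactly; residues with unknown amino acid are
skipped and logged. Region scores and per-chain totals are exact sums, with
unannotated residues kept in a remainder bucket so that the partition
identity (regions + remainder = chain total) holds to the last bit.

Hotspot classes follow two thresholds in score units: elevated
(score ≥ 100) and moderate (50 ≤ score < 100). The literature reports
classes but no cutoffs; these defaults put a fully exposed Trp
(157 Å² × 0.878 ≈ 138) in the elevated class and mid-exposure
hydrophobics in the moderate band, and are exposed in the configuration.
Profile differencing pairs residues by Kabat label (b − a per label,
unpaired labels reported separately). For crystals with several copies of
the same molecule, `mean_profile_by_label` reports mean ± SD across copies;
single-copy mode is the default for structure-vs-structure comparisons.

## Liability screens

The motif scanner reports **all** occurrences, including overlaps, ordered
by position then kind. Glycosylation is a positional rule object
(N-X-[S/T], X ≠ P), not a literal string. The rule set is deliberately the
four deamidation trimers, DP, and the five isomerization dipeptides —
generic NG/NS dipeptides are not included by default but the rule set is a
plain dataclass and extensible. Oxidation risk is exposure-driven, not
motif-driven: Met and Trp with relative SASA ≥ 0.2 are flagged (threshold
surfaced in config and in each hit's detail string). Rare framework
residues are flagged where the germline frequency of the observed amino
acid at that Kabat position falls below 0.02; CDR positions are never
flagged, and positions missing from the table warn rather than fail.

## Interface analysis

Contacts are exhaustive over residue pairs between two disjoint chain
groups, with a heavy-atom distance cutoff of 4.5 Å by default (kd-tree
implementation, verified against a brute-force all-pairs oracle). Buried
SASA per residue is `SASA(own group alone) − SASA(complex)`; small negative
quadrature differences are clamped to zero and logged. The hydrophobic
fraction of an interface counts unique contact residues with scale value
≥ 0.72 — a cutoff placed so that F, W, Y, L, I, V and M qualify on the
Black–Mould scale and P (0.711) does not. Waters are excluded by default;
no crystallographic symmetry expansion is attempted (only chains present in
the file).

## Structure comparison

Kabsch superposition by SVD of the cross-covariance of centred coordinate
sets, with the reflection branch excluded (determinant correction), so the
rotation is always proper. Pairing policies: Cα-only (default for
whole-domain RMSD), backbone (N, CA, C, O), or all atoms shared by name;
residues pair by Kabat label, and insertion-code residues only through
identical labels. RMSD is symmetric in its arguments and invariant under
rigid pre-transformations of either input, which the tests assert to 1e-9.

B-factor normalization uses the population standard deviation by default
(the convention is switchable); constant or single-value input is refused
rather than returning NaNs. Whether to pool chains or normalize per chain
is the caller's choice: `residue_bfactors` takes a chain filter and pooling
the asymmetric unit is the default.

## Assay analytics

**4PL.** `y = bottom + (top − bottom)/(1 + (EC50/c)^hill)`, least squares
(trust-region reflective) with EC50 fitted in log space. Initialization is
documented because determinism depends on it: bottom/top from the response
extremes, EC50 from the concentration nearest half-maximal response,
hill = ±1 by response direction. The parametrizations
(bottom, top, hill) and (top, bottom, −hill) describe the same curve, so
fits are canonicalized to top > bottom with direction carried by the hill
sign. Flat data and fits pinned to the extrapolation bounds return
`converged=False` instead of a silent answer.

**Relative potency.** `log10(EC50_ref)/log10(EC50_sample) × 100`. The
log-ratio is unit-dependent (logs of sub-unity values flip sign), so the
pinned convention is EC50 in pM with both values > 1 pM, refused otherwise;
base 10 throughout. Under this convention a larger sample EC50 gives a
potency below 100%, matching the reported pM ranges (148–260 pM reference
class vs 518–1609 pM impaired class; the boundary pair gives 79.96%).

**AC-SINS.** Spectra are sampled on a 480–580 nm grid at 2 nm steps; an
ordinary least-squares quadratic is fitted on the inclusive 500–560 nm
window using the actual wavelengths (grid irregularities tolerated), and
the peak is the vertex `λmax = −b/2a`. A non-concave fit (a ≥ 0) is
flagged, not raised. The self-interaction readout is
`Δλmax = λmax(sample) − λmax(control)`, with the control spectrum an
explicit input.

**SEC.** `log10(MW)` regressed on retention volume over ≥ 2 standards
(slope must be negative — larger proteins elute earlier); queries outside
the calibrated range by more than 10% of its width warn about
extrapolation. With exactly two standards the line interpolates them
exactly.

## Synthetic fixtures

All generators are seed-deterministic (byte-identical artifact files under
the same seed) and write a `truth.json` recording every planted parameter,
so tests never recompute truth from the artifact.

* Toy structures: `single_atom` and `two_sphere` carry closed-form SASA
  truth; `cage` surrounds a central atom with an icosahedral shell whose
  complete coverage of the central expanded sphere is verified numerically
  at build time (true area 0); `random_cluster` provides arbitrary packings
  for oracle-agreement tests.
* Liability sequences draw background residues from an alphabet excluding
  N, D, S, E and L — the residues that begin or complete any motif — and
  force the two positions after each plant to alanine, so the planted hits
  are provably the only hits; the generator asserts this against the
  scanner at build time and enforces a two-residue gap between plants.
* Assay fixtures: AC-SINS spectra are exact concave parabolas plus
  additive Gaussian noise (SD in AU); binding curves are 4PL responses at
  12 log-spaced concentrations spanning EC50 × [10⁻², 10²] with
  multiplicative log-normal noise (σ = 0.02 for the standard 2% case);
  SEC standards (670, 158, 44, 17, 1.35 kDa) sit on a true calibration
  line; B-factor sets are Gaussian.

What the fixtures do **not** emulate: real antibody geometry (loop
conformations, packing of a genuine Fv), chemically realistic radii
heterogeneity within a residue, correlated spectral baselines, or
plate-position effects. Passing the synthetic suites therefore demonstrates
algorithmic correctness (geometry, fitting, scanning) — not that the
default thresholds are optimal for any particular antibody. The checks
against the deposited Fab structures (below) are what ties the pipeline to
real data.

## Comparison against deposited structures

The integration checks load down-sampled per-chain fixtures of PDB 6FOE
(imalumab/BaxB01 Fab, two copies per asymmetric unit) and 9FQO (C0083
Fab), produced once by `scripts/fetch_structures.py`: chains trimmed to
the variable domain plus a pad (heavy ≤ 122, light ≤ 112 in author
numbering), coordinates kept to 0.01 Å in a compact CSV. Trimming the
constant domains does not perturb CDR-residue SASA — the probe-based
calculation is local (nothing beyond `2·(r_max + probe) ≈ 7 Å` matters)
and the CDRs sit tens of Å from the truncation — while keeping each file
small and text-only. Single-residue printed values are compared at ±10%
relative tolerance, which absorbs radius-table and quadrature differences
between SASA implementations; per-copy values of the 6FOE duplicates are
averaged. The script verifies sequence anchors (e.g. heavy-97 = Trp in
6FOE, Tyr in 9FQO) before trusting the deposit's Kabat author numbering.

## Problem sizes and numerical choices

Default quadrature is 960 points (error well under 1% on spheres);
oracle-agreement suites use 20 random 3–15-atom packings at 2 000 points
vs 20 000 Monte-Carlo samples; motif-scanner equivalence runs 1 000 random
sequences against the brute-force matcher; 4PL noise recovery uses 20
seeds at 2% noise (median |EC50 error| < 5%), AC-SINS 100 seeds at
0.005 AU (95th-percentile vertex error < 0.2 nm). The rotation-jitter
bound uses 50 000 points on an 8-atom packing. These sizes make the whole
suite run in seconds while leaving every statistical margin comfortable.

## Known limitations

* No Kabat renumbering from sequence; numbering maps are inputs.
* No solvent-excluded (Connolly) surfaces, no MD-ensemble averaging of
  profiles, no aggregation-propensity machine learning, no MHC-II epitope
  prediction (the report schema has a pass-through `immunogenicity` slot
  for externally produced lists).
* Hotspot, exposure, rarity and contact thresholds are field-reasonable
  defaults, not fitted quantities; sensitivity to them should be explored
  per project via the configuration.
* The 4PL fit reports a single least-squares optimum; no profile-likelihood
  confidence intervals on EC50.
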