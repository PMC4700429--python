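# Methods

## The model

`pombe3d` builds population ensembles of 3D genome structures for a small
eukaryotic (fission-yeast-like) nucleus and analyses where epigenomic
features sit within them.

Each chromosome is coarse-grained into **granules** of 3.5 kb of DNA and
30 nm diameter, strung into one polymer chain per chromosome (3583 granules
for the full *S. pombe* genome; the built-in toy genome uses 230).  A
conformation is the set of granule centres, subject to hard constraints that
every returned structure satisfies exactly:

- **confinement** — centres within `R − r_g` of the nuclear centre
  (default nuclear radius `R = 1300` nm, granule radius `r_g = 15` nm);
- **nucleolar exclusion** — centres at least `r_nuc + r_g` from the
  nucleolus centre (a sphere tangent to the envelope opposite the SPB,
  default radius 500 nm);
- **bond window** — consecutive granules within `[0.8, 1.2] × 30` nm;
- **excluded volume** — no non-bonded pair closer than one granule
  diameter (1% tolerance).

Soft terms are annealed by Metropolis Monte Carlo: harmonic bonds
(`k_bond = 0.2 kT/nm²` about 30 nm), a Kratky–Porod bending term
(`κ = 3 kT`, i.e. a persistence length of ~3 granules ≈ 90 nm, an
order-of-magnitude chromatin stiffness), flat-bottomed tether wells
(centromeres → a 300 nm sphere about the SPB at `(0,0,+R)`; telomeres → a
150 nm peripheral shell; rDNA → a band about the nucleolar surface;
`k = 0.01`), and flat-bottomed contact springs (zero inside 45 nm = 1.5
granule diameters).

### Contact restraints

Proximity-ligation contacts are population averages, so each structure is
restrained by its own random subset of granule pairs, drawn without
replacement with probability proportional to detection frequency
(successive renormalised draws).  Never-selected pairs are appended
round-robin across the ensemble so every captured interaction appears in at
least one structure.  The GCC-style convention uses 10% of distinct pairs
per structure; `calibrate_fraction` instead bisects (in log fraction) for
the subset size whose 20-structure ensemble mean radius of gyration,

  Rg = sqrt(mean_g |x_g − x̄|²),

is within 5% of a target — conventionally half the nuclear radius, 650 nm.

Two desk-scale choices depart from naive scaling and deserve emphasis:

1. **Calibration ensembles carry contacts but no tethers.**  With 230
   granules, chromosome arms are only 0.75–1.5 µm of contour; tethering
   centromeres to the SPB caps the whole-genome Rg near ~480 nm no matter
   what the contacts do, so a 650 nm target would be unreachable.  The
   calibration therefore interpolates from the confinement-only (random)
   model, whose mean Rg (~780 nm at these conditions) brackets the target
   from above, down the contact-load axis.  At the full 3583-granule scale
   the arms span the nucleus many times over and this distinction
   disappears.
2. **Calibration skips coverage forcing.**  Forcing every pair into some
   structure adds ~`total/n_structures` springs to each of a 20-structure
   ensemble regardless of the nominal fraction, destroying the
   fraction→compaction map at desk scale.  Production ensembles keep the
   forcing (the coverage guarantee); at the 1000-structure scale of the
   original study the two procedures coincide.

### Monte Carlo schedule and why it is warm

Moves: single-granule Gaussian displacement (8 nm), crankshaft rotation of
≤ 8-granule segments about the chord through their flanks, and a pivot of a
chain tail about a random axis (5% of moves) for large-scale relaxation.
Hard constraints are enforced by rejecting violating moves in *every* phase,
starting from a feasible initial conformation, so structure validity is by
construction rather than by repair.  (A consequence: in the hard regime
excluded volume is a pure hard core and carries no soft energy; a soft-core
quadratic is used when hard constraints are disabled, e.g. the
free-diffusion smoke test.)

The geometric cooling schedule (T: 8 → ~1.2 over 16 levels × 60 sweeps)
deliberately ends near kT = 1 instead of deep-quenching.  The ensemble is
meant to represent a *spectrum* of configurations consistent with the
restraints; annealing to T ≈ 0 collapses any contact-restrained chain onto
its restraint graph (we measured whole-genome Rg ≈ 100 nm for deep quenches
at any spring stiffness), which is an optimization artefact, not a
population.  For the same reason the default contact spring is soft
(`k_contact = 1e−5 kT/nm²`, a few kT over a nuclear diameter): the *number*
of restraints, not the strength of any single one, then controls ensemble
compaction, which is the dial the calibration turns.

Initialization is a self-avoiding persistent walk at fixed 30 nm steps
(direction correlation 0.85, dropped after repeated failures so walks can
turn away from the envelope), with steering that blends step directions
toward an upcoming anchored granule's target region once the remaining
contour approaches the distance to cover; anchored granules therefore start
inside their regions.

## Projection, density maps and contours

Interphase nuclei are treated as rotationally symmetric about the
SPB–nucleolus axis (the z axis, SPB side positive).  Every granule projects
to `(z, r)` with `z = x·ẑ` and `r` the distance from the axis.  Densities
live on a 266 × 266 grid covering `z ∈ [−R, R]`, `r ∈ [0, R]` (pixel sizes
`Δz = 2R/266`, `Δr = R/266`), evaluated at pixel centres:

    D(p) = (1/N_structures) Σ_s Σ_g w_g · exp(−((z_g−z_p)² + (r_g−r_p)²) / 2σ²)

with `σ = 15` nm (the granule radius) and the kernel truncated at 4σ
(< 0.1% mass error).  The kernel is *unnormalised*, so one isolated granule
contributes a peak density of ~1 per structure; the pixel sum times the
pixel area equals `n_granules × 2πσ²` for interior granules.  `w_g` is the
per-granule signal (binary presence or probe counts).

**Relative density** divides an element's density by total chromatin
density plus the regulariser *Dempf* — defined as the density of one
granule at the nuclear periphery — which suppresses discretisation noise
where absolute density is low.  The API default is the conventional 1.33,
appropriate at full genome scale where most of the nucleus sits well above
it.  Dempf is scale-dependent by definition: at the toy scale (230
granules, tens of structures) typical in-nucleus totals are 0.1–0.5 of our
kernel units, so the toy-scale analyses in the test-suite pipeline use
`dempf = 0.1`; with 1.33 the normalisation would be inert and relative maps
would reduce to raw densities (which, in an anchored bouquet, concentrate
at tether sites regardless of compartment).

**Contours** take pixels in descending value until ≥ 15% (configurable) of
the map's total signal is enclosed; ties at the cut enter in stable pixel
order, so the enclosed share overshoots by at most one pixel.  Contours at
nested fractions nest.  **Difference maps** are percentage-point changes
`100 × (a − b)` — antisymmetric and defined where the reference is zero
(the alternative, a true percent ratio, is neither).

**Per-granule impact** profiles answer which granules drive a difference
between two ensembles: pixels within 670 nm of the axis whose *aggregate*
element difference has the chosen sign are fixed once; each granule's
impact is then the mean of its own single-granule relative-density
difference over those pixels, reported against genome position.

**Overlap statistics** report granule counts (linear) or contour-pixel
counts (spatial) with Jaccard and min-normalised overlap, plus the
directional coincidence `|A∩B|/|A|` (the denominator the ">90% coincidence"
style of claim needs; it is not symmetric).

## Synthetic study conditions

The generator stands in for the experimental inputs with planted ground
truth.  Defaults (the conditions all headline numbers are computed under):

- genome: 3 chromosomes of 350/280/175 kb → 100+80+50 = 230 granules at
  3.5 kb; centred 7 kb centromeres, 7 kb telomeres; heterochromatic
  territory = centromere ± 10.5 kb plus 14 kb subtelomeric extensions;
- contacts: 1200 distinct granule pairs; intra-chromosomal weight
  `|i−j|^−1`, inter-chromosomal background 0.1, centromere–centromere
  boost ×20, telomere–telomere boost ×10; frequencies
  `1 + Poisson(Gamma)` with mean ∝ weight (overdispersed, dispersion 1.5),
  so frequently-contacting pairs are both more often sampled and more
  deeply covered;
- ChIP tracks: 1000 records of 300 bp (probe-sized), log-normal signals;
  with probability `bias` (default 0.8) a record is placed in its
  compartment's territory with signal ×8;
- origins: 40 across the six timing×efficiency classes; early/high classes
  biased (0.8) toward euchromatic arms and pericentromeres, late/low toward
  subtelomeres.

What the generator does **not** emulate: restriction-fragment structure or
matrix normalisation of contact maps, peak calling from raw signal,
replication dynamics, or cell-to-cell variation in nuclear geometry.
Passing the planted-recovery tests shows the pipeline recovers
compartmentalisation *it planted*; it does not validate the biological
fidelity of any particular energy constant.

## Problem sizes and numerical choices

Desk-scale runs use 10–50 structures (the original ensembles used 1000);
one structure anneals in ~0.25 s on one core (numba kernels), a 20-structure
calibration completes in ~1 minute.  The uniform-in-sphere radial-law check
uses a genome of *single-granule* chromosomes, for which the `density ∝ r²`
law is exact up to a negligible hard-core correction; whole-chain random
models at 230 granules deviate from it by chain correlation (KS ≈ 0.25) —
a finite-size effect, since 3583-granule chains fill the nucleus and
approach the law.  Weighted sampling is validated against exact enumeration
on ≤ 8 pairs; kernel sums are exactly additive in weights and are checked
granule-by-granule against the all-ones map at 1e−9 relative tolerance.

Degenerate inputs: a zero-radius nucleolus disables the exclusion (and its
anchor region); zero MC sweeps return the input conformation unchanged;
all-zero maps yield empty contours with a warning; an empty selected-pixel
set makes the impact profile zero with a warning.

## Known limitations

- The annealed ensembles are restraint-satisfaction populations, not
  Boltzmann samples; quantities depend on the schedule (documented above)
  as in any optimization-based genome-structure method.
- Rotational projection collapses azimuth: features separated only in
  azimuth appear coincident in (z, r) maps.
- The toy genome's short arms make tether-dominated geometry (the Rabl
  bouquet) more compact relative to the nucleus than the real genome's;
  absolute Rg values under anchors are not comparable between scales.
- Dempf and the contact-spring stiffness are scale-coupled constants; both
  are exposed in the API and must be revisited for genomes of different
  granule counts.
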