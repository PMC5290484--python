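# Methods

This note records the models, conventions, numerical choices and known
limitations behind `phbind`, in the order the pipeline runs them.

## Containers and units

Coordinates and box lengths are nm, times ps, masses Da, energies
kcal/mol. Force constants for umbrella restraints are accepted in
kJ/mol/nm² — the unit they are customarily quoted in — and converted
once through the exact factor 4.184; the Boltzmann constant is
0.0019872041 kcal/(mol K). Only orthorhombic periodic boxes are
supported; triclinic inputs are rejected with an explicit error (the
bilayer systems this package addresses are rectangular). PDB coordinates
(Å) are divided by 10 on read; GRO and XTC are already nm. The GRO
reader is a small fixed-width parser so malformed records can be
reported with their line number; PDB and XTC go through MDAnalysis. The
columnar-TSV trajectory dialect (`time x y z`, one row per particle per
frame block) is this package's own plain-text format and round-trips
bit-exactly.

Particle roles (`protein`, `lipid:POPC`, `lipid:PIP3`, ...) are assigned
from residue names via an editable YAML map
(`phbind/data/residue_roles.yaml`); unknown residues become `other` with
a logged warning. For PIP lipids, head-group phosphate particles are
flagged from a name list (PO4, P1–P5) plus a leading-"P" rule, both
map-driven. Lipids outside the canonical role set keep their own
`lipid:<NAME>` role rather than being silently folded into a neighbour.

## Encounter descriptors

* **d_z** is the absolute z distance between the mass-weighted protein
  COM and the mass-weighted COM of all lipid particles. Each group is
  unwrapped by minimum-imaging about its own first particle before
  averaging, so groups split across the periodic boundary average
  correctly. A signed variant exists behind a flag; the magnitude is the
  default because the analyses treat the two leaflet sides
  symmetrically.
* **R_zz** is element (3,3) of the proper least-squares (Kabsch)
  rotation taking a centred reference backbone onto the centred
  instantaneous backbone (scipy's `Rotation.align_vectors`, with an
  explicit degeneracy check: a near-collinear selection raises rather
  than returning an arbitrary rotation). The reference defaults to the
  first frame of the first trajectory and is always explicit in the
  results — orientation landscapes are only meaningful relative to a
  stated reference geometry.
* **Bound** means d_z strictly below 4.75 nm. The same constant gates
  the orientation bias and lipid clustering in the synthetic generator;
  it lives in one place (`phbind.constants`).
* **Landscapes** are 2-D histograms of (d_z, R_zz) with bin edges
  aligned to multiples of the widths (defaults 0.1 nm × 0.05), half-open
  bins with the final top edge closed so boundary frames are kept, and
  ties in the mode resolved toward smaller d_z (the membrane-proximal
  pose). `mode_contains` uses closed bin intervals, so a preference
  sitting exactly on a bin edge is attributed to whichever neighbouring
  bin wins the count.
* **RMSF** superposes each frame onto the reference (rotation +
  translation), then measures per-particle RMS displacement about the
  particle's time-mean position, averaged to residues and equally over
  repeat trajectories. `align=False` skips the superposition and
  measures raw fluctuations; note that with alignment a single moving
  particle's fluctuation is slightly redistributed onto the others
  through the COM (an oscillation of ±d becomes d(1−1/N) on the mover),
  which is inherent to superposition, not an artefact.

## Contacts, clustering, sites

A PIP lipid is in contact when any of its phosphate particles is within
the cutoff (1 nm, inclusive) of any protein particle, minimum-image. The
neighbour search is a cell list with cell edge ≥ cutoff used purely to
prune candidates; surviving pairs are measured with the same formula as
a brute-force all-pairs search, so the two agree bit-exactly (asserted
in tests). Residue ranking counts one event per frame per contacting
lipid per residue; ties break toward smaller residue id.

Leaflets are assigned by the sign of the phosphate z against the
bilayer midplane (all-lipid COM z); exactly-at-midplane goes to `upper`
(documented tie rule). The clustering statistic counts role-lipids whose
phosphate lies within 1 nm of the protein surface, operationalised as
minimum distance to any protein particle — cheap, monotone, and
commensurate with coarse-grained bead resolution — resolved per leaflet
because protein-induced clustering is local to the bound-side leaflet.
The uniform expectation it is tested against is density × annulus
cross-section area, with the area integrated numerically on a 0.05 nm
lateral grid at the leaflet plane per (subsampled) frame.

Binding-site classification uses contact fractions per loop:
`canonical` when β1/β2 and β3/β4 carry the two largest (nonzero) loop
fractions, `non-canonical` when β1/β2 and β5/β6 do, `none` when loops
capture <10% of contacts, `mixed` otherwise. The β1/β2 default range is
residues 360–372; the other loops are system-specific and must be
configured. Interaction persistence is the fraction of frames a pair's
minimum inter-member distance is within a cutoff (default 0.55 nm for
coarse-grained beads, 0.35 nm for atomistic donor–acceptor pairs), plus
the number of maximal non-contact runs; the fraction is
order-invariant, the break count deliberately is not.

## WHAM

The estimator iterates the standard self-consistency between the
unbiased per-bin probability and the window free-energy constants, in
log space with `logsumexp` for stability, until the constants move less
than 1e-7 kcal/mol (max 1e5 iterations; warm starts from a previous
solution accelerate bootstrap replicates). Default bin width 0.05 nm,
T = 323 K. Two numerical choices matter:

* The bias Boltzmann factor per (window, bin) is the **analytic bin
  average** of exp(−w_i/kT) (a Gaussian integral, computed via the
  normal CDF with a centre-point fallback for underflowing far tails).
  At k_z = 1000 kJ/mol/nm² the restraint's thermal width (~0.05 nm)
  equals the bin width, and evaluating the bias at bin centres is the
  dominant discretisation error; the bin average removes it. Recovery
  tests correspondingly compare against the binned truth
  −kT ln⟨e^(−U/kT)⟩_bin, the exact target of any histogram estimator.
  One consequence worth knowing: a narrow well's binned depth is
  slightly shallower than its point value.
* The histogram support can be **truncated to the planned window span**
  (`z_range`). Samples in the thin tails beyond the outermost windows
  otherwise create a few high-variance edge bins that dominate max-error
  summaries without carrying information.

Adjacent windows (sorted by centre) must share at least one sampled
bin; otherwise a connectivity error names the gap. Unsampled bins carry
NaN, never zero. A single window with k_z = 0 is admitted as a special
case and reduces exactly to Boltzmann inversion of its histogram.

Profiles are shifted so the count-weighted mean over the bulk region —
by default the outermost 10% of the sampled z range, or an explicit
interval — is exactly zero; the shift is idempotent and leaves well
depths and bootstrap errors unchanged. Errors are complete-histogram
bootstrap (resampling within windows, default 200 replicates, each
re-WHAMed and re-shifted; replicates that fail to converge are dropped,
with an error if more than 20% drop). Sequential-interval convergence
splits each window's series into equal blocks, runs WHAM per block, and
reports the first block pair whose maximum profile change falls below a
threshold; data before that point are discarded as equilibration. At
weakly overlapping windows the block metric is dominated by the random
walk of the window constants across the profile, so thresholds should
be set against block-sized bootstrap errors, not pooled ones.

Wells are local minima of the shifted profile (per contiguous sampled
segment) whose prominence exceeds the combined standard error of the
minimum and its enclosing barrier — the prominence is a difference of
two estimated values, so both uncertainties enter. Without bootstrap
errors any positive prominence qualifies, which will surface shot-noise
bumps; attach errors before interpreting well counts.

## Synthetic ground truth

The generator exists to make every analysis testable against a known
answer; it is deliberately a minimal stochastic model, not an MD
surrogate.

* **Protein**: a rigid body of 8 asymmetric pseudo-beads (all flagged
  backbone, residues 360–367, mass 72 Da each) whose COM separation d_z
  evolves by random-walk Metropolis in a prescribed binding potential
  U(d_z) with reflecting walls, and whose orientation evolves by
  Metropolis-accepted small random rotations (uniform axis, Gaussian
  angle) biased by V(R_zz) while bound. Metropolis acceptance makes the
  stationary distribution *exactly* Boltzmann in U and V — the point of
  the generator is closed-form testability, and proposal-noise
  discretisation bias of an uncorrected Euler–Maruyama scheme would
  contaminate the occupancy tests. Reflection at the walls preserves
  proposal symmetry, hence detailed balance.
* **Orientation bias**: harmonic, V = a/2 (R_zz − R_zz*)², defaults
  a = 100 kcal/mol about R_zz* = 0.8. (Under the rotation-group prior
  R_zz is uniform on [−1, 1], so a linear bias −a·R_zz can only prefer
  R_zz = 1; the harmonic form, also available as `linear`, is required
  to impose an interior preferred orientation.)
* **Binding potential**: default is a Gaussian well of depth
  −2.5 kcal/mol and width 0.25 nm at d_z = 4.0 nm, flat in bulk, walls
  at 3.2 and 6.8 nm — a localised contact well with genuine on/off
  exchange (equilibrium bound fraction ≈ 0.90) rather than a confining
  harmonic. For umbrella studies the canonical truth is a double well:
  −3.0 kcal/mol at 1.5 nm and −1.0 kcal/mol at 2.5 nm separation, width
  0.2 nm — a strong contact well followed by a shallower outer well, the
  shape characteristic of a PH-domain/PIP dissociation profile.
* **Membrane**: point lipids at fixed leaflet z (midplane ± 2.5 nm,
  which puts the bound protein's membrane-facing beads within contact
  range of the proximal leaflet), lateral random walk with periodic
  wrapping; composition defaults to 78 POPC : 20 POPS + 4 PIP3 per
  leaflet in an 8 × 8 nm box (~0.63 nm² per lipid). Lipids never change
  leaflet. When the protein is bound and clustering is on, proximal-
  leaflet PIP phosphates feel a Gaussian lateral attraction
  (−ε e^(−r²/2σ²), defaults ε = 2 kcal/mol, σ = 2 nm) toward the
  protein's lateral position, Metropolis-accepted.
* **Kinetic parameters**: frame interval 20 ps (the recording interval
  of the emulated protocol), protein D = 2.5×10⁻³ nm²/ps and lipid
  D = 10⁻⁴ nm²/ps. These are proposal scales for an equilibrium
  sampler, chosen so both protein and lipids decorrelate well within a
  run; they are faster than physical diffusivities and are not
  calibrated to any real system — occupancy statistics are exact
  regardless, but time-correlation quantities from the generator are
  not physical.
* **Umbrella samples** are independent draws from
  exp(−[U(z) + k/2 (z−z₀)²]/kT) by rejection against the analytic
  Gaussian envelope of the bias (acceptance rate monitored; an error
  advises rescaling below 10⁻⁴). Unbiased windows (k = 0) sample by
  inverse-CDF on a fine grid over an explicit range.
* **Saturation curves** are B = B_max C/(K_D + C) plus Gaussian noise.

Everything is bit-reproducible under a fixed seed
(`numpy.random.SeedSequence` spawning per stage/window). What passing
recovery tests show is that the *analysis* is correct and unbiased at
realistic sample sizes; they do not validate force fields, membrane
elasticity, hydrodynamics, or any other physics the generator does not
contain.

## Statistical test design

Trajectory time series are autocorrelated, so tests that assume
independence thin frames well past the mixing time (e.g. the flat-
potential Kolmogorov–Smirnov occupancy check uses every 400th of 50 000
frames), and Monte-Carlo errors are taken between independent seeded
runs (bound fraction: 20 runs) or batch means (annulus occupancy: 10
batches). The encounter recovery study uses 20 runs × 2000 frames; the
umbrella recovery uses 24 windows × 5000 samples with 40–50 bootstrap
replicates — sizes at which every recovery criterion has comfortable
statistical margin on a single CPU in a few minutes.

## Langmuir fitting

Unweighted nonlinear least squares (no weighting is assumed of the
emulated instrument software; 1/B weighting is available behind a flag)
on log(K_D), log(B_max), which enforces positivity without constrained
optimisation. Default initialisation: B_max = 1.1 max(B), K_D = the
concentration whose response is nearest B_max/2. Standard errors are
delta-method transforms of the log-parameter covariance from the
Jacobian at the optimum. Replicates are averaged before fitting, with
their spread reported separately. Non-convergence returns a flagged
result with diagnostics; it is never silently replaced. The fit is
scale-equivariant in B and unit-equivariant in C (both asserted as
properties).

## Pipeline and CLI

`run_demo` chains simulate → encounter → contacts → umbrella/WHAM →
wells → Langmuir at demonstration scale, derives one child seed per
stage from the top-level seed (logged, so stages can be re-run in
isolation), writes TSV outputs plus a JSON summary, and fails loudly
naming the stage. The CLI (`phbind`) is a thin click wrapper; window
files are two-column TSV with a YAML sidecar carrying z₀/k_z.

## Known limitations

* The membrane model has no elasticity, no solvent, no inter-lipid
  interactions, and single-bead lipids; clustering is imposed, not
  emergent.
* 1-D WHAM only; no MBAR, no 2-D reaction coordinates, no
  autocorrelation-aware reweighting beyond block splitting.
* Kinetic (k_on/k_off) sensorgram fitting and mechanistic avidity
  models are out of scope; only equilibrium saturation responses are
  fit.
* PDB support is the common subset (no altloc/insertion-code
  semantics); velocities are not carried; boxes must be orthorhombic.
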