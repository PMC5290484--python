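# phbind

Analysis toolkit for peripheral membrane-protein binding studies:
orientation landscapes and bound-state statistics of protein–bilayer
encounter trajectories, phosphoinositide (PIP) contact and clustering
statistics, umbrella-sampling free-energy profiles via a from-scratch
WHAM estimator with bootstrap errors, and 1:1 Langmuir fitting of
SPR-style binding-saturation curves.

The package is built around the workflow used to characterise how a
pleckstrin homology (PH) domain associates with PIP2/PIP3-containing
bilayers: coarse-grained encounter simulations establish a preferred
membrane-bound orientation and protein-induced PIP clustering, umbrella
sampling quantifies the binding free energy along the membrane normal,
and surface plasmon resonance saturation curves yield dissociation
constants under 1:1 and membrane-mimetic (nanodisc) designs. `phbind`
implements every analysis step of that arc on neutral in-memory
containers, plus synthetic ground-truth generators so the whole pipeline
is testable without running any MD engine or instrument.

## What it computes

**Encounter descriptors.** Per frame: the z distance between protein and
bilayer centres of mass, d_z (minimum-image, mass-weighted); the
orientation descriptor R_zz, the zz element of the Kabsch rotation
superposing a reference backbone onto the instantaneous backbone
(R_zz = 1 same orientation, −1 flipped); and the bound flag,
d_z < 4.75 nm. These feed a normalised 2-D (d_z, R_zz) landscape whose
mode is the preferred binding pose, and per-residue RMSF profiles after
least-squares superposition.

**Contacts and clustering.** A PIP lipid is in contact when any of its
phosphate particles lies within 1 nm of any protein particle
(minimum-image, cell-list search that reproduces the brute-force
all-pairs result exactly). The package ranks residues by contact events,
assigns lipids to leaflets, counts PIP phosphates in a 1 nm annulus of
the protein surface per leaflet (the clustering statistic), classifies
the engaged binding site (canonical = β1/β2 + β3/β4 loops,
non-canonical = β1/β2 + β5/β6), and measures pairwise interaction
persistence (contact fraction and break events).

**Free energies.** Umbrella windows (harmonic restraints, force
constants in kJ/mol/nm²) are combined by the standard WHAM
self-consistency

    P(z_b) = Σ_i h_ib / Σ_i N_i f_i c_ib,   f_i⁻¹ = Σ_b c_ib P(z_b),

with G(z) = −kT ln P(z) in kcal/mol, shifted so the bulk region is 0.
The bias factor c_ib is the analytic bin average of exp(−w_i/kT), which
removes the dominant discretisation error at stiff restraints. Errors
come from a complete-histogram bootstrap; convergence is judged from
sequential-interval profiles; wells are local minima whose prominence
exceeds the combined bootstrap error.

**Affinities.** Equilibrium responses are fit to the 1:1 Langmuir
isotherm B = B_max·C/(K_D + C) by nonlinear least squares in
log-parameters, with standard errors from the curvature at the optimum,
twofold serial-dilution design helpers, and condition comparison via K_D
ratios with propagated errors.

## Worked example

Recover a known double-well binding free energy (−3.0 kcal/mol contact
well at 1.5 nm, −1.0 kcal/mol outer well at 2.5 nm) from Boltzmann
umbrella samples, then fit a noisy saturation curve generated at
K_D = 300 µM:

```python
import numpy as np
from phbind import binding, pmf, synthetic

truth = synthetic.default_double_well()
centers = pmf.plan_umbrella_centers(pmf.UmbrellaPlan(start=1.0))  # 24 windows
windows = synthetic.generate_umbrella_samples(
    truth, [(z, 1000.0) for z in centers], n_samples=5000, seed=42)
span = (float(centers[0]), float(centers[-1]))
profile = pmf.shift_to_bulk(pmf.wham(windows, z_range=span))
profile.errors = pmf.bootstrap_errors(windows, n_boot=50, seed=43, z_range=span)
for z, g in pmf.find_wells(profile).wells:
    print(f"well at {z:.2f} nm: {g:+.2f} kcal/mol")

conc = binding.serial_dilution(2400.0, 8)          # µM, twofold series
curve = synthetic.simulate_saturation(300.0, 100.0, conc, noise_sd=1.0, seed=0)
fit = binding.fit_langmuir(curve)
print(f"KD = {fit.kd:.1f} +/- {fit.kd_se:.1f} uM, Bmax = {fit.bmax:.1f}")
```

Output:

```
well at 1.52 nm: -2.61 kcal/mol
well at 2.48 nm: -0.74 kcal/mol
KD = 294.9 +/- 7.8 uM, Bmax = 99.8
```

Both wells are located within one histogram bin of the truth; the
recovered depths sit within the bootstrap + discretisation envelope
(binning a narrow well shallows its apparent minimum slightly), and the
fitted K_D agrees with the generating value to a few per cent at 1%
response noise. `phbind demo --seed 0 --outdir demo/` runs the whole arc
(simulation → landscape → contacts → WHAM → wells → Langmuir) and writes
TSV outputs plus a pass/fail property report.

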