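# Methods

## Model

`vesibud` implements a coarse-grained dissipative-particle-dynamics (DPD)
model of lipid nanovesicles in a binary aqueous solution.  Four bead
species of common diameter *d* build the system: lipid head (H), lipid
chain (C), water (W) and solute (S).  A lipid is an H3(C6)2 molecule — a
three-bead headgroup and two six-bead hydrocarbon chains — so each lipid
carries 15 beads.  All quantities are in reduced units: *d* = 1,
k_BT = 1, bead mass m = 1, time unit τ = d√(m/k_BT).  For reporting, a
bead diameter maps to about 0.8 nm; this conversion is cosmetic and never
enters the dynamics.

### Pair forces

Beads interact through the standard DPD triplet of short-ranged pairwise
forces with cutoff *d*:

* conservative soft repulsion  F^C = f_ij (1 − r/d) r̂ for r < d,
  with the force-parameter matrix (k_BT/d)

  |     | H  | C  | W    | S    |
  |-----|----|----|------|------|
  | H   | 30 | 50 | 30   | 15   |
  | C   | 50 | 10 | 75   | 75   |
  | W   | 30 | 75 | 25   | f_WS |
  | S   | 15 | 75 | f_WS | 25   |

  Deleting the S row/column recovers the solute-free lipid/water model
  this parameterization extends.  The low f_HS = 15 makes solutes adhere
  to headgroups; f_WS sets the solvent condition.

* dissipative drag  F^D = −γ (1 − r/d)² (r̂·v_ij) r̂ with γ = 4.5, and
* random kicks  F^R = σ (1 − r/d) ξ_ij r̂ / √dt with σ² = 2γ k_BT
  (fluctuation–dissipation), ξ_ij = ξ_ji a unit-variance uniform variate.

Together the drag/noise pair is a momentum-conserving thermostat at
k_BT = 1.  The solvent condition is summarized by the solubility
ζ = √(f_WW f_SS)/f_WS = 25/f_WS: ζ = 25/32 (good solvent, miscible at all
compositions) and ζ = 25/40 (poor solvent, demixes beyond the binodal).

### Bonded terms

The source parameterization defers its bonded constants to an earlier
model description that is not restated here, so the package adopts the
standard values of that DPD membrane family and exposes them as
configuration: harmonic bonds U = (k/2)(r − l₀)² with k = 128 k_BT/d²,
l₀ = 0.5 d between consecutive beads along the headgroup and each chain,
and a chain-stiffness potential U = k_b (1 − cos φ) with k_b = 20 k_BT on
chain triples including the head–chain junction.  These are assumptions,
clearly flagged: any quantitative bonded-sensitive observable (e.g. the
area compressibility) may shift if the original constants differed.

The stiffness potential is evaluated in its distance form
cos φ = (r_ik² − r_ij² − r_jk²)/(2 r_ij r_jk), which provides an exact
central-force decomposition over the three bead pairs.  The decomposition
is used both for dynamics (forces are identical to the angular form) and
for the local-stress analysis, where pairwise central forces are exactly
what the Irving–Kirkwood construction needs.

### Integration

A DPD-adapted velocity-Verlet scheme with velocity prediction parameter
λ = 0.65 and default dt = 0.01 τ advances the dynamics; the dissipative
force at the end of a step uses velocities predicted as v + λ dt f.  At
this timestep the long-run kinetic temperature is within 2% of 1 k_BT
(verified in the suite).  Pair search uses a cell-sorted half-stencil
grid (counting sort, ≥ 3 cells per axis) with an O(N²) all-pairs fallback
for small boxes; the two paths agree to 1e-10 and the fallback doubles as
the test oracle.  NPT runs use a weak-coupling isotropic box rescaling on
the total pressure (coupling time 10 τ, target P = 23.7 k_BT/d³, i.e. the
excess pressure 20.7 plus the kinetic ρ k_BT = 3); the model uses NPT only
to set the density before NVT production, so a rigorous barostat ensemble
is deliberately not attempted.

The pure-water equation of state anchors the implementation: at
ρ = 3/d³ and f_WW = 25 the measured excess (virial-only) pressure is
≈ 20.7 k_BT/d³.  Note that the widely used quadratic fit P_ex ≈ 0.101 f ρ²
would predict 22.7 here; that fit overshoots at ρ = 3, and the directly
measured virial with the fluid's actual pair structure is the correct
reference.

## System assembly

* **Bulk/slab solutions** place round(ρV) beads uniformly at ρ = 3/d³;
  N_S = round(Φ_S N) of them are solute, so that ρ_S = 3Φ_S/d³ in a
  uniform solution.  Slab systems (for coexistence runs) seed all solute
  in a central z-slab of width Φ_S L_z at bulk density.
* **Vesicles** place N_il lipids on an inner and N_ol on an outer
  spherical shell, head shells at radii chosen so each leaflet has
  ≈ 1.25 d² per lipid, heads facing the adjacent water compartment.  The
  interior is filled with exactly N_W^in water beads and no solute; the
  exterior with water and solute at mole fraction Φ_S.  The full-scale
  reference of the study — N_il = 4000, N_ol = 6100 (membrane = 151,500
  beads), N_W^isp = 90,400, 1,440,400 solvent beads in an (80 d)³ box,
  1,591,900 beads in total — is available as `mini_vesicle_spec(scale="full")`
  and its bookkeeping is asserted exactly in the suite; the desk-scale
  default shrinks the same construction to N_il = 50, N_ol = 330 in an
  (18 d)³ box (≈ 19,600 beads, midsurface radius ≈ 4.6 d).
  Solvent filling accounts for the membrane packing denser than water:
  the membrane's effective bead density is 4.75/d³ for vesicles (the
  value implied by the full-scale reference bookkeeping) and a measured
  4.1/d³ for flat bilayers, so the surrounding water reaches its bulk
  density 3/d³ instead of being under-filled.
* **Volume protocol**: the volume parameter ν = N_W^in/N_W^isp is set by
  relocating interior waters to the exterior (deflation) or back
  (inflation).  Relocation rather than deletion keeps the global bead
  totals constant across a ν series, which is how the printed full-scale
  totals remain fixed while ν varies; whether the original study
  relocated or deleted is not stated, so this is the package's documented
  choice.  Compartment membership is decided by radial distance from the
  lipid center of mass relative to the instantaneous midsurface radius.
* **Solute titration** converts exterior W↔S identities in place until
  N_S/(N_S + N_W^ex) is within one bead of the target; the interior stays
  solute-free by construction.
* A short small-timestep pre-run (500 steps at dt = 0.005) relieves
  random-insertion overlaps and relaxes bonds before production.

## Analysis

### Radial profiles and coverage

Profiles ρ_X(r) are shell histograms about the per-frame center of mass
of all lipid beads (circular mean per axis, so box-straddling vesicles
are handled), bin width 0.25 d, averaged over frames.  The midsurface
radius R_mid is the peak of the chain density ρ_C(r), refined by a
quadratic fit through the three bins around the maximum; multimodal
profiles raise an ambiguity error.  Membrane thickness l_me is the FWHM
of the H+C profile (≈ 5 d for this lipid).  The bulk solute density is
the mean over far-field bins — r ≥ 28 d at full scale, otherwise the
outer 20% of the radial range — and the coverage integrates the excess
profile over the exterior volume:

    Γ = (1/A₀) Σ_{r>R_mid} [ρ_S(r) − ρ_S,b] 4π r² Δr,   A₀ = 4π R_mid².

The integration stops at half the smallest box edge minus 1 d to avoid
periodic images.  A contact-counting coverage (S–H contacts within some
l_SH) is deliberately not implemented: the excess-profile route avoids
the arbitrary contact length.

### Spherical stress and elasticity

For a quasi-spherical vesicle the pressure tensor is diagonal in
spherical coordinates, P = P_N e_r⊗e_r + P_T (e_θ⊗e_θ + e_φ⊗e_φ), and
the stress profile is s(r) = P_N − P_T.  Kinetic contributions are binned
at the bead radius; configurational contributions (conservative + bonded
central forces only — drag and noise average to zero and are excluded)
are spread along straight Irving–Kirkwood contours between the two
beads, subdivided into pieces of ≈ bin/4 and projected onto the local
radial/tangential directions per piece.  The binning conserves the total
virial exactly, and the volume integral of (P_N + 2P_T)/3 is verified
against the global virial pressure at 1%.

Derived quantities (bin width 0.2 d, integrals over R_mid ± 5 d — wide
enough for the ≈ 5 d bilayer, narrow enough to keep the geometric weight
from amplifying far-field noise; both configurable):

* bilayer tension  Σ = ∫ dr (r/R_mid)² s(r) — the mechanical route for a
  spherical interface, weight 1 at the midsurface;
* first stress moment  ⟨(r−R_mid) s(r)⟩₀ = ∫ dr (r/R_mid)² (r−R_mid) s(r),
  meaningful at (near-)zero tension; the evaluator refuses when
  |Σ| > 0.1 k_BT/d² unless explicitly overridden;
* spontaneous curvature from  2κ(m − 1/R_mid) = −⟨(r−R_mid) s(r)⟩₀, so a
  vanishing moment gives m = 1/R_mid.  The sign convention is fixed by
  the physics: crowding or adsorption on the outer leaflet produces
  excess lateral pressure outside the midsurface (s < 0 there), a
  negative moment, and hence m > 1/R_mid — consistent with the full-scale
  solute-free value m(0) = 0.089/d > 1/(22.5 d) and with m increasing
  under exterior adsorption.  The exact printed forms of these two
  integrals were not machine-readable in the source; the forms above are
  the standard spherical-interface expressions satisfying every stated
  algebraic constraint, and single-bin spike profiles validate the
  transcription in closed form.
* area compressibility K_A as the least-squares slope of Σ against the
  area dilation (A − A₀)/A₀ near zero, and bending rigidity
  κ = K_A l_me²/48.
* tensionless states: Σ is evaluated at ≥ 3 interior water counts and
  the zero crossing interpolated linearly, returning N_W0^in and
  ν₀ = N_W0^in/N_W^isp.  The search accepts an injected tension
  evaluator, so its logic is tested in closed form and expensive scans
  stay out of the default suite.

### Phase diagram

Coexistence is measured with the slab method: an elongated box
(L_z ≥ 2 L_x), all solute seeded centrally, equilibrated under NVT; the
z-resolved local mole fraction Φ_S(z) (1 d slabs) develops dilute and
dense plateaus whose means are the binodal branches.  Slabs within 3 d of
the two interfaces (boundaries of the above-mid-range region) are
excluded from the averages; on desk-scale boxes whose dense slab is
narrower than twice the exclusion zone, the exclusion shrinks adaptively
with a warning.  A run counts as phase-separated only if the branch
difference exceeds five combined standard errors.  The desk default
(8×8×20 d box, ≈ 3,800 beads, ~10⁵ steps) is far smaller than a
production slab; the measured dilute branch carries a correspondingly
generous (±20%) finite-size tolerance.

At f_WS = 40 this measurement gives a dilute branch of Φ_S ≈ 0.013–0.015
(dense branch ≈ 0.985).  The value was validated three ways during
development: approaching coexistence from below (dilute region seeded
empty) and from above (seeded supersaturated at Φ = 0.05) converges to
the same plateau with no hysteresis; doubling the box cross-section does
not move it; and it agrees with the canonical χ-parameter mapping of
this force law (χ ≈ 0.286 Δf = 4.29 at ρ = 3/d³, whose symmetric
regular-solution binodal puts the dilute branch at ≈ 0.0145 — a mapping
that was itself calibrated against slab-coexistence measurements of the
same fluid class).  Reported binodal values for this parameterization
that sit substantially above this range are therefore more consistent
with a demixing-onset (cloud-point) criterion in a finite box than with
the coexistence dilute branch that the slab method measures; the suite
asserts the model-consistent value and records the discrepancy against
the larger published figure explicitly.

### Morphology

* **Neck diameter** D_ne: principal axis from the gyration tensor of the
  lipid beads; head beads sliced into 1 d axial slabs; per-slab outer
  diameter = 2× the 95th percentile of radial distance from the axis
  (robust to stray beads); D_ne is the slab minimum between the two bud
  centers, located as the occupancy-weighted mean axial position of each
  half (robust for shell-like buds whose per-slab occupancy is flat).
  Near-spherical shapes (relative gyration anisotropy < 0.15) return a
  "no neck" flag.  The neck counts as closed for D_ne < 10 d, open above.
* **Division**: single-linkage clustering of lipid beads at cutoff 1 d
  (periodic KD-tree + connected components); components below 1% of the
  lipids are ignored.
* **Contact area** between adhering membrane segments: outer-leaflet H
  beads with an opposing-segment H bead within 3 d, times the mean area
  per outer-leaflet head bead (spherical estimate A₀/N_H,outer by
  default; synthetic planar geometries supply the per-head area
  directly).  The source study plots this observable without defining its
  estimator, so this construction is the package's own and its full-scale
  plateau value is treated as indicative only.

## Scaled-down study conditions

Full-scale production (1,591,900 beads, multi-μs equivalent trajectories)
is supported by the same code paths but is cluster work.  The shipped
defaults instead use desk-scale systems sized so that the entire suite
runs on one CPU core: a ≈ 19,600-bead vesicle ((18 d)³ box), ≈ 3,800-bead
slabs, and runs of 10⁴–10⁵ steps with frame averaging over the final
half.  Consequences, stated plainly:

* Quantities tied to the full-scale geometry (R_mid ≈ 22.5 d, the
  coverage and curvature coefficients b_Γ = 45.6/124.4 and
  b_m = 1.08/6.04, m(0) = 0.089/d, the 1039 d² contact-area plateau, and
  the recurrent-neck/fission phenomenology) are not reproduced at desk
  scale.  The suite instead asserts their scale-free content: Γ and m
  increase monotonically with Φ_S, and the poor-solvent slopes strictly
  exceed the good-solvent slopes.
* The desk vesicle's small exterior reservoir depletes measurably as
  solute adsorbs, so its bulk plateau sits below 3Φ_S/d³; the coverage is
  always computed against the measured plateau, which keeps the estimate
  internally consistent.
* The desk curvature series inverts the moment relation with a
  series-level nominal K_A = 20 k_BT/d² (κ = K_A l_me²/48 with the
  measured l_me) rather than a per-point K_A measurement; this affects
  only the scale of m, not the monotonicity or slope ordering that the
  tests assert.
* An important desk-scale confounder, measured and documented rather than
  hidden: the first-moment curvature is only meaningful at (near-)zero
  bilayer tension, but the desk vesicle carries a residual tension of
  ≈ +4 k_BT/d² that its volume knob cannot remove (the interior holds
  only ~45 waters — the membrane fills most of the sphere, so the
  tension is packing frustration, not adjustable volume).  The
  adsorption layer modulates that tension and the tension-coupled part
  of the stress moment, and at this scale that contribution outweighs
  the leaflet-asymmetry signal: the raw fixed-volume m *decreases* with
  Φ_S for both solvent conditions (reproduced across seeds), opposite
  to the tensionless-state behavior the moment relation is designed to
  extract.  The corresponding suite check asserts the physically
  expected monotone increase and is therefore expected to fail at desk
  scale; resolving it requires the tensionless-state protocol on a
  vesicle large enough to have a real interior reservoir, which is
  production-scale work.  The coverage response, which does not depend
  on the tensionless state, is clean at desk scale (monotone, with the
  poor-solvent slope several times the good-solvent one).
* Averaging windows ("10 bins of 0.5 μs" at full scale) shrink to the
  final half of each desk run.

## Known limitations

* Bonded constants are adopted, not sourced (above); electrostatics,
  charged lipids, lipid mixtures and explicit proteins are out of scope.
* The weak-coupling barostat does not sample a rigorous NPT ensemble.
* The stress analysis assumes quasi-spherical symmetry; strongly budded
  shapes violate it and are analyzed for morphology only.
* Fission times are stochastic barrier crossings; the package detects
  division but makes no attempt to reproduce specific event times.
* The synthetic fixtures (bead shells, spike profiles) exercise geometry
  and transcription, not thermodynamics; passing them says nothing about
  force-field realism beyond what the EOS/binodal/adsorption runs show.
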