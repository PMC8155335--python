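# vesibud

Coarse-grained simulation and analysis of **solute-driven budding and
fission of lipid nanovesicles**, for membrane biophysicists and
simulators studying how small adsorbing solutes remodel nanoscale
membranes (synaptic-vesicle- and exosome-sized, tens of nm).

Small solutes that adsorb onto the **outer** leaflet of a vesicle
membrane break the bilayer's leaflet symmetry.  The adsorption layer
generates a spontaneous curvature m that grows with the solute
concentration, driving the vesicle from sphere to prolate to a dumbbell
with a narrow membrane neck; close to the binodal of the solute/water
mixture (poor-solvent conditions), solute-mediated adhesion of the two
membrane segments flanking the neck can even cleave it, dividing the
vesicle in two.  `vesibud` implements both halves of this story:

* a **dissipative-particle-dynamics (DPD) engine** for the four-bead
  model (lipid head H, chain C, water W, solute S; H3(C6)2 lipids;
  conservative force F = f_ij(1 − r/d) with the study's force table,
  momentum-conserving thermostat, NVT/NPT, cell-list pair search,
  seeded and deterministic), and
* the **analysis stack**: radial density profiles, solute coverage
  Γ = (1/A₀)∫dr 4πr² Δρ_S(r), spherical Irving–Kirkwood stress profiles
  s(r) = P_N − P_T, bilayer tension Σ = ∫dr (r/R_mid)² s(r), the first
  stress moment and spontaneous curvature via
  2κ(m − 1/R_mid) = −⟨(r−R_mid)s(r)⟩₀, area compressibility K_A and
  bending rigidity κ = K_A l_me²/48, slab-method binodals of the W/S
  mixture, and morphology observables (neck diameter with the 10 d
  open/closed criterion, division detection, contact area).

Everything runs in reduced DPD units (bead diameter d = 1, k_BT = 1);
d maps to ≈ 0.8 nm for reporting.  See `docs/methods.md` for the model,
all defaults, and the desk-scale study conditions.

## Worked example

```bash
python examples/02_vesicle_coverage.py
```

builds a desk-scale vesicle (50 inner + 330 outer lipids in an (18 d)³
box) in a Φ_S = 0.06 solution, runs short dynamics and prints:

```
vesicle: 50+330 lipids (5700 beads), 832 solute beads outside, 19596 beads total
midsurface radius R_mid : 4.59 d   (chain-density peak)
membrane thickness l_me : 4.88 d   (~5 d for this lipid)
far-field solute density: 0.0752/d^3 (mole fraction 0.0245; the small reservoir depletes as solute adsorbs)
coverage Gamma          : 1.485/d^2
```

R_mid locates the bilayer midsurface at the hydrophobic-chain density
peak; the far-field density is the plateau of ρ_S(r) (below 3Φ_S/d³
because the small reservoir depletes as solute adsorbs); and Γ is the
adsorbed excess per unit midsurface area — the quantity whose growth
with Φ_S drives budding.  The other examples cover the
water equation of state (`01`, excess pressure ≈ 20.7 k_BT/d³), the
stress profile and spontaneous curvature (`03`), the poor-solvent
binodal by the slab method (`04`), and neck/division morphology on
synthetic dumbbells (`05`).

A thin CLI wraps the same library for shell use:

```bash
vesibud fixture mini_vesicle -o vesicle.xyz
vesibud analyze profiles vesicle.xyz
vesibud binodal --f-ws 40 --phi 0.1 --phi 0.2 --phi 0.3
```

Trajectories are plain text (extended XYZ or a LAMMPS-dump-compatible
dialect); profiles and summaries are CSV/JSON.

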