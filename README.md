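# beadmodes

Solution-structure analysis for low-resolution bead models: small-angle X-ray
scattering (SAXS) profile analysis, lattice elastic-network dynamics, and
bead-level hydrodynamics.

Studies of flexible extracellular-matrix proteins — tropoelastin, fibrillin
fragments, and their cross-linked complexes — characterise each species by a
1D SAXS curve, an ab initio dummy-atom envelope, an elastic-network picture of
its collective motions, and hydrodynamic observables from analytical
ultracentrifugation and light scattering.  `beadmodes` implements that entire
desk-side chain as a tested Python library with a thin CLI, for structural
biologists who have profiles and envelopes and want reproducible numbers:

* **SAXS profiles** — read `q, I(q), σ` text files; self-consistent **Guinier
  fit** of ln *I* = ln *I₀* − (*Rg*²/3)*q*² on the largest window with
  *q·Rg* ≤ 1; regularised **indirect Fourier transform** to the pair-distance
  distribution *P(r)* with *Dmax* estimation; closed-form scale+background
  **model-vs-data fits** with reduced χ².
* **Bead models** — dummy-atom PDB I/O (DAMMIF/DAMAVER dialect), geometric
  descriptors, **Debye-formula** forward scattering
  *I(q) = f(q)² Σᵢⱼ sin(q·rᵢⱼ)/(q·rᵢⱼ)*, and resampling of envelopes onto a
  regular cubic lattice.
* **Elastic network model** — uniform springs between lattice beads within a
  cutoff (default 1.6 × spacing: nearest + second-nearest neighbours); the
  anisotropic-network Hessian *H* with blocks −(γ/r²)·d⊗d; normal modes from
  *V(u) = ½ uᵀHu*; per-bead RMSF over the six lowest non-zero modes; periodic
  deformation trajectories with amplitude ∝ 1/ω.
* **Mobility analysis** — named-region segmentation of RMSF profiles, pivot
  (bending-node) detection, and component-vs-complex **stabilisation
  reports** with scale-free normalised ratios.
* **Hydrodynamics** — Kirkwood double-sum hydrodynamic radius
  *Rh = N·a / (1 + (a/N) Σᵢ≠ⱼ 1/rᵢⱼ)*, sedimentation coefficient
  *s = M(1 − v̄ρ)/(N_A·6πη·Rh)* and frictional ratio *f/f₀*.
* **Synthetic shapes** — deterministic lattice fills of rods, bent rods and
  rod-plus-lobe solids with seeded noisy profile simulation, so the whole
  chain is testable without instrument data.

## Worked example

Build the L-shaped rod-plus-lobe test particle (a thin 180 × 15 Å rod fused to
a 35 Å lobe — the "larger but similarly elongated" complex analogue), simulate
its noisy SAXS curve, and run the chain:

```python
import beadmodes as bm

model = bm.rod_plus_lobe_fixture()               # 404 beads on a 9 Å lattice
profile = bm.simulate_profile(model, 0.25, 800, bm.NoiseSpec(0.01, seed=3))

bm.guinier_fit(profile).rg                       # 60.6  (Å; true Debye Rg 63.1)
bm.model_geometry(model).dmax                    # 218.5 (Å)

results = bm.ElasticNetworkModel(model).fit()    # cutoff 1.6·a, γ = 1
results.modes.n_zero                             # 6  (rigid-body modes)
prof = results.rmsf()                            # modes 1–6, per-bead RMSF

rh = bm.kirkwood_rh(model)                       # 4.39 nm
bm.hydrodynamic_summary(rh, mass=109.0).s        # 5.92 S
bm.hydrodynamic_summary(rh, mass=109.0).f_over_f0  # 1.39  (elongated)
```

The same chain from the shell:

```bash
beadmodes simulate --kind rod_plus_lobe \
    --dims '{"length":180,"radius":15,"lobe_radius":35}' --spacing 9 \
    --seed 3 -o model.pdb -p profile.dat
beadmodes guinier profile.dat        # {"rg": 60.60, "i0": 1.63e+05, ...}
beadmodes enm model.pdb --rmsf-csv rmsf.csv   # {"n_zero": 6, ...}
beadmodes hydro model.pdb --mass 109 # {"rh_nm": 4.39, "s_svedberg": 5.92, ...}
```

Comparing the free rod against the composite (same lattice, same spring
constant) flags the fused rod end — a global RMSF maximum when free — as
*stabilised* (normalised mobility ratio 0.42), the fixture-level analogue of
cross-linking quenching a component's mobility inside a complex:

```python
rod = bm.rod_fixture()
mapping = bm.match_beads_by_position(rod, model)
free = bm.ElasticNetworkModel(rod).fit().rmsf(region_map=bm.rod_region_map_by_z(rod))
report = bm.compare_mobility(free, prof, mapping)
print(report.summary())
#  region                comp    cplx   ratio  verdict
#  free_end             1.218   1.962   1.611  mobilised
#  middle               0.866   1.221   1.411  mobilised
#  junction_end         1.218   0.516   0.424  stabilised
```

(The free tip's ratio *rises*: fusing the lobe lengthens the beam and softens
its global bending — see `docs/methods.md` for why that is the physically
expected behaviour.)

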