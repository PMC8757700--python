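# stentbench

*In silico* bench testing of bioresorbable polymer vascular scaffolds.

Bioresorbable scaffolds (BVS) are temporary polymer stents — typically
poly-L-lactic acid (PLLA) — that support an artery after angioplasty and
resorb over months.  Qualifying a scaffold design requires a battery of
mechanical bench tests (radial compression onto the delivery catheter,
balloon inflation to the nominal diameter, three-point bending for
flexibility, two-plate crush resistance), and running them physically for
every design iteration is slow and expensive.  `stentbench` reproduces
these tests numerically so that competing designs — e.g. strut-thickness
variants, or patterns with and without drug-pocket slots — can be compared
on stress concentration, stiffness and recoil before anything is
manufactured.

The package provides:

* a **curve-driven elasto-visco-plastic material model**: families of
  measured multilinear true-strain/true-stress curves on a (temperature ×
  strain-rate) grid drive the 3D response directly.  At each Gauss point
  the von Mises equivalent stress
  `σ̄ = √(½[(σ₁₁−σ₂₂)² + (σ₂₂−σ₃₃)² + (σ₃₃−σ₁₁)² + 6(σ₁₂²+σ₂₃²+σ₃₁²)])`
  and the equivalent strain
  `ē = [⅔Σeᵢᵢ² + ⅓Σγᵢⱼ²]^½`
  are computed, the curve family is interpolated at (ē, ė, T), and the
  trial stress is scaled radially so its equivalent measure lands on the
  interpolated curve; loading / unloading / reloading phases track
  hysteresis with anchored unloading branches;
* an **implicit nonlinear FE solver** for 8-node hexahedra
  (updated-Lagrangian, full Gauss quadrature, lumped-mass dynamic
  regularisation per the incremental balance
  `(M/Δt² + K)ΔU = F_ext − F_int − (1/Δt²)M(U⁽ⁱ⁻¹⁾ − Uᵗ)`);
* **penalty-spring contact** with analytic rigid tools (crimping sleeve,
  expansion mandrel, bending rollers, crush plates) and exact
  action–reaction reporting;
* a **parametric scaffold-mesh generator** (zig-zag rings + connectors
  carved from a structured cylindrical hex grid, preset design families,
  pocket-slot variants);
* the **four bench protocols** with residual-stress carry-over
  (crimp → inflate → bend / crush) and design-comparison reports.

See `docs/methods.md` for the model details, assumptions and defaults.

## Worked example

Crimp a miniature scaffold (608 hexahedra, outer radius 1.6 mm, synthetic
PLLA-like curves) down to 60% of its radius and read off the result:

```python
from stentbench import (TestProtocol, make_curve_family, make_mini_stent,
                        run_radial_compression)

family = make_curve_family()          # 3 temperatures x 3 strain rates
mesh = make_mini_stent()              # 2-ring, 4-crown desk-scale scaffold
protocol = TestProtocol("radial_compression", target=0.6 * 1.6, n_steps=24)
result = run_radial_compression(mesh, family, protocol)

print(f"peak effective stress : {result.metrics['peak_effective_stress']:.1f} MPa")
print(f"99th-percentile stress: {result.metrics['p99_effective_stress']:.1f} MPa")
print(f"max plastic strain    : {result.metrics['max_plastic_strain']:.3f}")
print(f"final radial force    : {result.metrics['final_radial_force']:.1f} N")
```

prints

```
peak effective stress : 95.2 MPa
99th-percentile stress: 75.1 MPa
max plastic strain    : 1.118
final radial force    : 984.5 N
```

Peak stress sits at the crown folds, well past the ~62 MPa yield level of
the synthetic material at 37 °C; the worst Gauss point at the sharpest fold
corner accumulates over 100% equivalent plastic strain (the pattern folds
onto itself — there is no self-contact to stop it).  The deeply crimped
state's residual stresses can seed the inflation test
(`run_inflation(mesh, family, protocol, prior=result)`).
`result.history` is a pandas DataFrame of the per-step sleeve radius,
radial force and stress extremes (the load–radius curve).

A command-line interface wraps the same functionality:

```bash
stentbench geometry --preset PLLA_prot_slots --out stent.vtu
stentbench fixtures --out fixtures/
stentbench material-check --curves fixtures/curves/manifest.yaml --rate 0.01 --temp 37 --out trace.csv
stentbench run --test radial_compression --target 0.96 --out results/
stentbench sequence radial_compression inflation crush --out results/
```

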