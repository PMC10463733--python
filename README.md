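# atriastasis

Desk-scale simulation and analysis of **blood stasis in the left atrium
(LA)** — the quantity that links atrial remodeling in atrial fibrillation
to thrombus formation and stroke risk. The package reproduces, in 2D and
on a laptop, the structure of a patient-level computational-hemodynamics
study: phase-resolved chamber geometry stands in for segmented cardiac
CT, a moving-boundary incompressible flow solver computes the
motion-driven velocity field, a residence-time transport equation
quantifies stasis, and a statistics layer compares a control-like and an
AF-like cohort.

## Who it is for

Researchers in cardiovascular computational hemodynamics and biomedical
image analysis who want an end-to-end, fully testable stand-in for a
CT-to-CFD stasis pipeline: every stage (geometry, wall-motion tracking,
flow, scalar transport, statistics) is exercised against analytic or
generator ground truth, at a problem size where the whole pipeline runs
in minutes rather than hundreds of core-hours.

## The model

**Residence time.** Stasis is measured by the blood residence time
`T_res`, a passive scalar with unit source,

```
∂T_res/∂t + ∂/∂x_i (u_i T_res − D ∂T_res/∂x_i) = 1 ,
```

with `D = 1.14e-11 m²/s` (blood self-diffusivity). Fluid everywhere ages
at 1 s/s; pulmonary-vein inflow carries fresh blood (`T_res = 0`), so
regions the flow fails to wash out grow old. `T_res` is reported in
cardiac cycles (CC), volume-averaged over the LA including the appendage
(LAA), the LA without it, and the LAA alone, at end systole.

**Flow.** Incompressible, laminar, Newtonian blood
(μ = 3.5×10⁻³ Pa·s, ρ = 1060 kg/m³) on the deforming LA+LV domain in an
ALE frame, driven purely by wall motion through pressure openings (the
pulmonary veins and the aortic root, 0 Pa gauge by default — only
pressure differences matter); the mitral and aortic valves are binary
(open/closed) and switch with the sign of dV_LV/dt.

**Function descriptors.** Chamber volumes by the divergence theorem,
ejection fractions `EF = (V_max − V_min)/V_max`, BSA-indexed volumes,
peak transvalvular flow rates, and the **LA retention ratio**

```
retention ratio = V_LA,max / SV_LV ,
```

the maximum blood the atrium can hold relative to the blood passing per
beat. Synthetic cohorts draw these parameters from control-group and
AF-group distributions (e.g. indexed LA max volume 41 ± 7 vs
66 ± 15 ml/m², LA EF 53 ± 7 vs 43 ± 9 %).

## Worked example

```python
from atriastasis import (ChamberSpec, SolverConfig, compute_descriptors,
                         generate_chamber_series)
from atriastasis.pipeline import run_subject

spec = ChamberSpec()          # control-group mean subject
series = generate_chamber_series(spec)
d = compute_descriptors(series)
print(f"LA max volume      {d.la_max_vol:6.1f} ml")
print(f"LA EF              {d.la_ef:6.1f} %")
print(f"LV stroke volume   {d.lv_sv:6.1f} ml")
print(f"LA retention ratio {d.la_retention_ratio:6.2f}")

result = run_subject(spec, config=SolverConfig.desk_2d("coarse"),
                     n_init_cycles=1, n_scalar_cycles=2)
s = result.stasis
print(f"RT LA with LAA     {s.rt_la_with_laa:6.2f} CC")
print(f"RT LA without LAA  {s.rt_la_without_laa:6.2f} CC")
print(f"RT LAA             {s.rt_laa:6.2f} CC")
```

prints (about half a minute on one core):

```
LA max volume        87.0 ml
LA EF                53.0 %
LV stroke volume     98.0 ml
LA retention ratio   0.89
RT LA with LAA       0.52 CC
RT LA without LAA    0.48 CC
RT LAA               1.11 CC
```

The descriptors round-trip the prescribed subject parameters (87 ml LA,
EF 53 %, SV 98 ml → retention ratio 0.89), and after two residence-time
cycles the appendage already retains blood about twice as long as the
atrial body — the signature stasis pattern. Cohort-level runs
(`atriastasis.pipeline.simulate_cohort`) feed the statistics layer:
group summaries with two-sample t-tests, univariate regressions of
residence time on each descriptor with R²/p/95 % CI, and a leave-one-out
leverage report.

A thin CLI mirrors the pipeline stages:
`atriastasis generate|track|simulate|stats --help`.

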