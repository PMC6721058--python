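# plankle — planar multibody statics of the human ankle

`plankle` models the true ankle joint (talocrural joint) as a planar
multibody system: the tibia and fibula are rigidly joined into a fixed basis
(TFS), the talus and calcaneus into a moving body (TCS) located by three
generalized coordinates — a sagittal rotation θ and the position
**p** = (pₓ, p_y) of the moving frame origin.  The two bodies are connected
by six nonlinear cables standing in for the ATT, TC, PTT, ATF, CF and PTF
ligaments and by two frontal-plane-symmetric Hertzian sphere–sphere contact
pairs standing in for the tibiotalar cartilage.  It is aimed at
biomechanics researchers and educators who want ankle load states and
moment–rotation behaviour from a model with a handful of parameters rather
than a finite-element mesh.

## The mechanics

Each ligament cable *i* with basis attachment **a**ᵢ and moving attachment
**b**ᵢ^TCS carries tension only:

    bᵢ = R(θ) bᵢ^TCS + p,      lᵢ = |bᵢ − aᵢ|,      εᵢ = (lᵢ − l_slack,i)/l_slack,i
    Fᵢ = Aᵢ exp(Bᵢ εᵢ − 1)   for εᵢ > 0, else 0          (force law "exp_shifted")

with slack lengths computed at the neutral pose.  The law above is the
default; the classical continuous variant Fᵢ = Aᵢ(exp(Bᵢεᵢ) − 1)
(`exp_minus_one`) is available behind a switch, because the shifted form
jumps by A/e at activation — see `docs/methods.md` for the consequences.
Each contact pair (female radius r_a, male radius r_b < r_a, shared E, ν)
follows the Hertz law

    K = 2E / (3(1 − ν²)) · √(r_a r_b / (r_a − r_b)),      F_c = K δ^{3/2}

with penetration δ = |O_b − O_a| + r_b − r_a.  Statics solves

    ΣFᵢ + ΣF_c,j + F_ext = 0,      ΣMᵢ + ΣM_c,j + M_ext = 0

for (θ, pₓ, p_y) with Levenberg–Marquardt, accepting a solution when the
sum of absolute residual components (N, N, N·m) is below 1·10⁻¹⁰.

Because real ankle ligaments are spatial, a sagittal projection distorts
their strains badly (a nearly frontal ligament like the ATF has almost no
in-plane slack length).  The `finetune` module therefore refits the planar
coefficients (A, B): the segments are translated ±4 mm along x and y, the
3-D ligament force is projected onto the sagittal plane, and nonlinear
least squares matches the planar cable force to those four projected
targets.  Geometry is never altered — only material coefficients.

## Worked example

```python
import numpy as np
from plankle import default_ankle_fixture, LoadCase, solve_equilibrium

model = default_ankle_fixture()           # deterministic synthetic geometry
res = solve_equilibrium(model, LoadCase.pure_moment(1.0))   # 1 N*m plantarflexion
print(np.degrees(res.state.theta), res.residual_norm)
for lig, load in zip(model.ligaments, res.ligament_loads):
    print(lig.name, 100 * load.strain, load.force_value)
```

prints (abridged):

```
theta      = 22.74 deg          residual = 3.6e-13  (sum |Fx|,|Fy|,|M|)
ATT:  strain +15.90 %   force  83.93 N
TC:   strain  -2.37 %   force   0.00 N
PTT:  strain -17.21 %   force   0.00 N
contact force (both pairs)     83.85 N
```

A positive external moment of 1 N·m plantarflexes the joint by 22.7°; the
anterior tibiotalar ligament is the only substantially loaded cable and its
pull is balanced by the cartilage contact — the expected division of labour
for this motion.  The residual confirms the 10⁻¹⁰ acceptance rule is met
with ten orders of magnitude to spare.

The same through the CLI:

```sh
plankle fixture --out ankle.json
plankle solve --model ankle.json --moment 1.0
plankle simulate sim2 --model ankle.json --out-dir out/   # ±5 N*m, 51 steps
plankle fit-ligaments --ligaments ligs3d.json --out fits.csv
```

`simulate` writes a sweep table CSV (moment, Δθ, per-ligament strain % and
force N, contact force, convergence flag) and a JSON summary with the
dorsiflexion/plantarflexion ranges and per-ligament peak/mean strains.

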