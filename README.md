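# ecmdfl

Predicting multi-cell compaction of a 3-D extracellular-matrix (ECM) fiber
gel by **superposing single-cell reduced-order models**, built with
**dual-faceted (DF) linearization** and PCA model reduction.

## The problem

Contractile cells embedded in a collagen-like gel pull on the fiber
network through focal adhesions, compacting it; groups of cells produce
collective compaction that single cells do not.  Simulating the coupled
nonlinear mechanics — fiber stretch and bending, membrane cortical
tension, stochastic adhesion kinetics, stiffness-directed polarity and
lamellipodial protrusion — scales poorly with cell number.  `ecmdfl`
implements both the full nonlinear simulator (ground truth) and a
computationally cheap surrogate: the nonlinear forces are *promoted to
auxiliary state variables*, making the dynamics linear in an augmented
space,

    ζ_c = (x_c; F_cort-elas; F_FA) ∈ R^{9Nc},   ζ_e = (x_e; F_elas) ∈ R^{6Ne},

PCA compresses the augmented states to latent coordinates
`z = Vᵀ(ζ − μ)`, and least squares identifies the latent dynamics

    dz_c/dt = A z_c + B u + C z_e,        (one copy per cell)
    dz_e/dt = G z_e + Σ_k D^k z_c^k,      (shared ECM)

where `u` is the lamellipodial input and the couplings
`D^k = V_x^eᵀ (1/D_e) P_map^k V_FFA^c` are assembled analytically from
the adhesion mapping matrices — never regressed.  Because cells enter the
ECM equation only through the sum, a model trained on *single-cell* runs
predicts *multi-cell* behaviour by superposition, and is compared against
first-order Taylor and trajectory-piecewise-linear (TPWL) baselines.

Intended users: researchers in computational mechanobiology and
model-order reduction who want a small, fully scripted testbed for
lifting-linearization methods on a mechanistically honest cell–ECM model.

## Worked example

```python
import numpy as np
from ecmdfl.pipeline import training_configs, run_training, fit_reduction, two_cell_compare

# ten single-cell nonlinear runs (T = 3600 s) on one shared fiber network
cfgs = training_configs(10, seed=0)
trajs = run_training(cfgs)

# dual-faceted augmentation -> PCA (m_c = m_e = 30) -> least squares
# (fit_stable_reduction selects the order by a dissipativity diagnostic)
res = fit_reduction(trajs, 30, 30, ridge=1e-6)
print(res.summary())

# two cells 30 um apart: latent superposition vs full nonlinear, t = 50 min
out = two_cell_compare(seed=0, t_end=3000.0, spacing=30.0,
                       results=res, base_cfg=cfgs[0])
print(f"gel shrinkage: nonlinear {100*out['shrink_full']:.2f}%, "
      f"latent {100*out['shrink_latent']:.2f}%")
```

Output from this exact script (seed 0):

```
Latent cell-ECM dynamics (dual-faceted linearization + PCA reduction)
======================================================================
latent dimensions        m_c = 30, m_e = 30  (total 60)
retained variance        cell 0.999938, ECM 0.999150
training samples         cell eq 36000, ECM eq 36000
ridge parameter          1.000e-06
residual RMS (cell eq)   4.140349e-03  (data RMS 1.124765e-02)
residual RMS (ECM eq)    1.207186e-03  (data RMS 1.977559e-02)
spectral abscissa        A: -0.000009 1/s, G: -0.000066 1/s
======================================================================
gel shrinkage: nonlinear 4.10%, latent 5.29%
```

Reading it: the identified dynamics are dissipative (negative spectral
abscissas), the ECM equation is fitted to ~6% residual, and the reduced
two-cell prediction reproduces the nonlinear gel shrinkage while
over-predicting it — the linear surrogate extrapolates the
compaction–tension feedback that the nonlinear gel saturates.  On the
single-cell benchmark (fresh realization, 30-minute horizon) the
membrane-node RMSE ordering is

```
DF latent (4.6 um)  <  TPWL, kappa=100 (12.9 um)  <  Taylor (diverged)
```

A command-line interface mirrors the library
(`ecmdfl fixture | simulate-full | train | simulate-latent |
simulate-baseline | metrics | report`); see `ecmdfl --help`.

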