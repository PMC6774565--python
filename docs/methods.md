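# Methods

## The model

`ecmdfl` simulates the mechanics of contractile cells embedded in a 3-D
cross-linked fiber network (the extracellular matrix, ECM) and predicts the
collective gel compaction produced by several cells from models identified
on *single-cell* simulations only.

### Full nonlinear system

Every node — membrane node $x_i^{c,k}$ of cell $k$ or fiber node $x_j^e$ —
is overdamped: inertia is negligible and the forces on a node balance a
viscous drag,

$$ F^{c,k}_{\text{cort-elas},i} + F^{c,k}_{\text{FA},i} + F^{c,k}_{L,i}
   = D_c\,\dot x_i^{c,k}, \qquad
   F^e_{\text{elas},j} + F^e_{\text{FA},j} = D_e\,\dot x_j^e . $$

* **ECM**: straight fibers subdivided into Hookean segments
  ($k_\text{axial}$), harmonic-cosine angular springs at interior fiber
  nodes ($k_\text{bend}$, energy $k_b(1-\cos\theta)$ about the straight
  rest shape), and crosslink springs joining nodes of distinct fibers
  within a crosslink radius.  The generated geometry is the stress-free
  reference.  Nodes near the two flat ends of the cylindrical domain (or
  the bottom face of the box domain) are fixed.
* **Cell membrane**: a closed icosphere mesh with edge springs
  ($k_\text{edge}$) plus an isotropic cortical tension $\gamma$ whose
  force is $-\gamma\,\nabla(\text{membrane area})$ — the contractile
  engine of compaction.
* **Focal adhesions**: a membrane node within $d_\text{bind}$ of a free
  ECM node attaches with probability $p_\text{on}$ per kinetic step; the
  bond is a tension-only spring of stiffness $k_\text{FA} n_\text{int}$
  whose rest length is the separation at formation, so it transmits zero
  force at attachment and loads smoothly as the membrane contracts.  Bonds
  stretched beyond $d_\text{break}$ detach.  Forces are exactly paired:
  the ECM partner receives the negation of the membrane force, so the
  global adhesion force sum vanishes to machine precision.  With rest
  length zero the law reduces to the plain linear spring
  $k_\text{FA} n_\text{int}(x^e_j - x^{c}_i)$.  We chose the unloaded-at-
  formation variant as a deterministic stand-in for gradual integrin
  recruitment: an instantly loaded spring injects $O(10\,\mathrm{nN})$
  force discontinuities that act as impulsive noise on the identification
  stage (see below).
* **Polarity and lamellipodia**: each cell carries a unit polarity vector
  rotating toward the local maximum-stiffness direction,
  $\dot d = \kappa\, d \times (d_\text{ms} \times d)$, where
  $d_\text{ms}$ is the leading eigenvector of the local fiber-tension
  tensor $\sum_s |T_s|\, \hat u_s \hat u_s^{\mathsf T}$ over springs within
  a sensing radius (an interchangeable estimator; the interface only
  requires a unit vector).  Membrane nodes inside the cone of half-angle
  $\alpha_L$ about the polarity receive an outward lamellipodial force
  $f_L$; these forces form the control input $u^k$.

The integrator is explicit Euler with substep `dt` (default 0.25 s);
adhesion and polarity updates run once per recorded sample (default every
1 s), which is the model's kinetic time step — the substeps are purely
numerical.

### Dual-faceted linearization and reduction

The nonlinear forces are promoted to *auxiliary state variables*: per cell
$\zeta^{c,k} = (x^{c,k};\,F^{c,k}_\text{cort-elas};\,F^{c,k}_\text{FA})
\in \mathbb R^{9N_c}$ and for the ECM $\zeta^e = (x^e;\,F^e_\text{elas})
\in \mathbb R^{6N_e}$ ($u^k$ stays outside as an input; the ECM-side
adhesion forces are determined by the cells through the mapping matrices
and are excluded).  In this augmented space the coordinate equations are
linear by construction, and the force-derivative equations are
approximated by linear regressions — two complementary linear "facets" of
the same nonlinear system.

PCA of the pooled, mean-centred training samples gives orthonormal bases
$V^c$ (9$N_c$ × $m_c$) and $V^e$ (6$N_e$ × $m_e$); latent states are
$z = V^{\mathsf T}(\zeta - \mu)$.  The reduced dynamics are

$$ \dot z^{c,k} = A z^{c,k} + B u^k + C z^e + a_0, \qquad
   \dot z^{e} = G z^e + g_0 + \textstyle\sum_k \big( D^k z^{c,k} + b^k \big), $$

with $A, B, C, G$ identified by ridge least squares and the couplings
assembled **analytically**, never regressed:
$D^k = V_x^{e\,\mathsf T} (1/D_e) P^k_\text{map} V^c_{F_\text{FA}}$, where
$P^k_\text{map}$ is the sparse $\{0,-1\}$ matrix routing each cell's
adhesion forces to their ECM partner nodes.  $D^k$ is refreshed whenever
bonds change (each bond is a rank-≤3 update).  Adding a cell never
requires re-identification — only the $D^k$ set and the sum change; cells
interact exclusively through the shared ECM latent state.

Implementation choices that matter:

* **Intercepts** $a_0, g_0$ (and the known offsets $b^k =
  V_x^{e\,\mathsf T}(1/D_e) P^k_\text{map}\,\mu_{F_\text{FA}}$) carry the
  centring means: because the latent coordinates are centred, the true
  augmented dynamics are affine in $z$, and omitting the constant terms
  leaves a systematic bias that measurably degrades the fit.  The
  intercept column is not penalised by the ridge.
* **Derivative estimation** uses forward differences at the sampling
  interval and the latent rollout uses explicit Euler at the same
  interval.  This makes the identified model the *exact one-step map*
  whenever the underlying dynamics are linear, which is what the
  linear-consistency test exercises; a central-difference scheme leaves an
  $O(h^2)$ inconsistency between fit and rollout.
* **Training-time coupling subtraction** uses the recorded adhesion
  forces through $P^k_\text{map}$ (known matrices × known data), not
  their basis reconstruction, to keep truncation error out of the ECM
  regression target.  At prediction time the reconstruction is used,
  because no recorded truth exists.
* **During the reduced rollout** the geometry is reconstructed from the
  latent states every step to (i) recompute $u^k$ through the
  polarity/stiffness-sensing loop, (ii) run the stochastic adhesion update
  and refresh $D^k$.  Fixed boundary nodes are pinned to their reference
  positions regardless of reconstruction noise.

### Baselines

* **Taylor**: one global first-order expansion of the complete smooth
  vector field about the initial state, with the bond topology and
  lamellipodial input frozen there — a single LTI model, exact at $t=0$.
* **TPWL** (trajectory piecewise-linear): about 100 such local affine
  models at points selected greedily (equal arc-length increments) along a
  training trajectory, each carrying that frame's bond topology and
  input; the simulated field is their normalised-Gaussian-kernel-weighted
  combination.  With a single point it degenerates to Taylor.

Freezing the discrete structures in the baselines is deliberate: a global
(or piecewise) algebraic linearization has no mechanism to re-run adhesion
kinetics, whereas the reduced latent model keeps that loop online — the
comparison isolates exactly this structural difference.

## Default parameters

Units: µm, s, nN throughout.

| parameter | default | meaning |
|---|---|---|
| `k_axial`, `k_cross` | 2.0 nN/µm | fiber segment / crosslink stiffness |
| `k_bend` | 0.1 nN·µm | fiber angular stiffness |
| `D_e`, `D_c` | 10 nN·s/µm | nodal damping |
| `k_edge` | 1.0 nN/µm | membrane edge stiffness |
| `gamma` | 0.2 nN/µm² | cortical tension |
| `k_fa`, `n_int` | 0.5 nN/µm, 10 | adhesion stiffness per integrin, integrins per bond |
| `d_bind`, `d_break`, `p_on` | 4, 10 µm, 0.5 | adhesion kinetics |
| `f_L`, `alpha_L`, `kappa` | 1 nN, π/3, 0.002 s⁻¹ | lamellipodial force, cone half-angle, polarity rate |
| `sensing_radius` | 15 µm | stiffness-sensing neighbourhood |
| `cell_radius` | 6 µm | icosphere rest radius (42 nodes) |
| `dt`, sampling | 0.25 s, 1 s | integrator substep, kinetic/recording step |

The binding range and crosslink radius are commensurate with the mesh
resolution: at ~290 ECM nodes in the 40 × 100 µm cylinder the internode
spacing is ≈ 7.5 µm, so µm-scale binding ranges would produce no adhesion
at all.  The stiffness/damping scale sets relaxation times of seconds,
so explicit Euler at 0.25 s is comfortably inside the stability bound.
The cortical tension is chosen so a single cell contracts by roughly 5–10%
of its radius over minutes and visibly deforms the gel — a compaction
regime in which the single-cell identification is also well conditioned
(see *Stability* below).

## Study designs

All studies run at desk scale: $N_e \approx 290$ fiber nodes,
$N_c = 42$ membrane nodes per cell, ten single-cell training runs of
3600 s sampled at 1 s, on one fixed network shared between training and
prediction.  (The method is mesh-agnostic; these sizes keep the complete
pipeline within minutes on one core.)

* **Training**: run 0 places the cell at the cylinder centre; the others
  sample positions uniformly inside the domain with a margin.  Each run
  has its own polarity initialisation and adhesion-kinetics seed.
* **Reduction**: the model order is selected with a dissipativity
  diagnostic (`fit_stable_reduction`): among a fixed candidate list
  (30+30 down to 10+10) the richest order whose identified spectral
  abscissas stay below 5·10⁻⁴ s⁻¹ is kept — that tolerance bounds the
  linear amplification over the 50-minute study horizon to about e^1.5.
  Which order qualifies depends on the training realization: least-squares
  identification of near-neutral modes can land slightly in the right
  half-plane, and larger ECM dimensions admit noisy modes whose fitted
  dynamics are expansive.  The selection touches only the model *order*;
  the least-squares solutions themselves are never constrained.  The
  variance retained at 30+30 exceeds 0.999.
* **Single-cell benchmark**: all models predict a *fresh realization* —
  same placement as training run 0, new seed (hence new initial polarity
  and adhesion history) — starting from its 60 s state (after adhesions
  have formed) over a 30-minute horizon.  Reported error is membrane-node
  RMSE against the nonlinear truth.
* **Two-cell study**: cells 30 µm apart on the cylinder axis; the full
  nonlinear simulation and the superposition of single-cell-trained
  latent models run to 50 min.  Compaction is quantified by material
  slices (nodes assigned to 10 µm axial slabs by their *initial*
  coordinate; per-slice convex-hull volume normalised by its $t=0$ value)
  and by the total gel volume (convex hull of all ECM nodes — the
  slice-sum is avoided for totals because deformed material slabs overlap
  and double-count).
* **Spacing study**: two-cell runs at 30/50/100 µm spacing; the force
  transmitted to the gel midpoint is the mean ECM elastic-force magnitude
  over nodes initially in the central 16 µm slab.

## What the synthetic data does and does not emulate

The generator reproduces the *structure* of the biological system —
discrete fiber elasticity with bending, paired adhesions, contractile
membranes, stiffness-directed polarity — with parameters set for a
desk-scale gel, not calibrated to a specific collagen concentration or
cell line.  Fibers neither rupture nor degrade (no proteolysis), adhesion
has no catch/slip force dependence, membranes carry no volume constraint
or nucleus, and the mesh is two orders of magnitude coarser than
experimental gels.  Passing tests therefore demonstrate the *method* —
augmentation, reduction, identification, superposition — under honest
nonlinear, stochastic conditions, not quantitative agreement with any
particular experiment.

## Numerical choices and degenerate inputs

* PCA eigenvectors carry a deterministic sign (largest-magnitude entry
  positive); in the thin-data regime ($n < d$) the basis comes from an
  SVD of the centred data matrix, and retained columns are re-orthonormalised
  by QR.  Requests beyond the numerical data rank raise.
* The ridge parameter is trace-scaled (`ridge * tr(XᵀX)/p`, default
  1e-6 in the pipeline); with `ridge=0` a rank-deficient regressor raises
  instead of silently min-norming.  An identically zero input channel
  warns (B is indeterminate).
* Collapsed springs/edges, degenerate triangles, non-finite states, empty
  sensing neighbourhoods and over-stretched configurations raise with
  specific messages; the latent rollout has a divergence detector.
* Anti-parallel polarity/stiffness vectors are a valid unstable
  equilibrium and are returned unchanged.

## Stability of the identified dynamics, and known limitations

Least-squares identification of a near-neutral mode (a cell's absolute
position is only softly anchored through the gel) can place its eigenvalue
slightly in the right half-plane, and the compaction→tension positive
feedback is genuinely expansive when linearized; both effects grow with
traction strength and with the retained ECM dimension.  The package
*flags* non-dissipative identifications (warning + summary line) rather
than constraining the regression.  Consequences at desk scale:

* the reduced model tracks a fresh single-cell realization to ~0.5 µm
  over the first minutes and a few µm over 30 min — far better than the
  frozen-topology baselines at that horizon, but not at the sub-µm level
  over long horizons;
* the latent superposition model *over-predicts* two-cell gel shrinkage
  at 50 min (the linear model extrapolates the tension feedback that the
  nonlinear system saturates), by roughly a quarter to a third in
  relative terms at this mesh scale;
* prediction error on held-out realizations is floored by the intrinsic
  sensitivity of the stochastic adhesion/polarity loop, which no reduced
  model can undercut.

These are properties of the method at small mesh scale, documented here
so that the acceptance numbers can be read for what they are.
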