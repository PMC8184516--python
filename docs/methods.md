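# Methods

This note documents the models implemented in `neuraltube`, the numerical
choices behind them, and what the bundled synthetic data and geometry do
and do not establish.

## The in-vitro rostrocaudal network

Five nodes: the brain-region fate reporters FB (forebrain), MB (midbrain),
HB (hindbrain), the kinase activity GSK3, and the external input CT, the
concentration of a GSK3 inhibitor (µM). CT emulates WNT signalling:
high CT means low GSK3 activity means strong effective WNT.

Dynamics follow the Hill formalism. Each node's production is a saturating
fraction in which every activator contributes `c_i * x^n_i` to numerator
and denominator and every repressor contributes to the denominator only,
minus first-order degradation. For the consensus (data-selected) topology:

    d[FB]/dt   = c1*G^n1 / (1 + c1*G^n1 + c2*MB^n2 + c3*HB^n3)            - δ1*FB
    d[MB]/dt   = c4*MB^n4 / (1 + c4*MB^n4 + c5*FB^n5 + c6*HB^n6 + c7*G^n7) - δ2*MB
    d[HB]/dt   = c8*HB^n8 / (1 + c8*HB^n8 + c9*FB^n9 + c10*MB^n10 + c11*G^n11) - δ3*HB
    d[GSK3]/dt = c12*G^n12 / (1 + c12*G^n12 + c13*CT^n13)                 - δ4*GSK3
    d[CT]/dt   = 0

FB, MB and HB are mutually repressive (a tristable switch); MB, HB and
GSK3 self-activate; GSK3 activates FB and represses MB and HB, with the
repression of HB (c11) much stronger than that of MB (c7). The circuit's
dose response is *transient-selected*: every steady state is computed from
the fixed initial condition FB = MB = HB = GSK3 = 1, and which attractor
wins depends on CT through the GSK3 trajectory. GSK3's steady level falls
steeply with CT and collapses to zero near 0.28 µM, which sets the
forebrain/midbrain transition; the MB–HB competition at low GSK3 sets the
midbrain/hindbrain transition.

### Default parameter values

`neuraltube/data/published_defaults.yaml` is the single source of truth. The
in-vitro constants (c1..c13, n1..n13, δ1..δ4) are the published optimum of
the topology-selection fit. The printed source table is typographically
ambiguous in places (run-together digits in the plain-text rendering we
worked from); where more than one reading of a rate-constant row was
possible, the shipped reading was selected as the unique candidate that
reproduces the published mechanistic statements simultaneously: the
wildtype FB→MB→HB progression with rising CT, strong-MB onset at 0.2 µM
under HB knockdown, the >5-fold MB-window expansion under HB knockdown,
the suppression of FB under MB overexpression, the relative repression
strengths HB⊣MB ≫ MB⊣HB and GSK3⊣HB > GSK3⊣MB, and a WNT-buffer node (see
below) with a stable off state. Two published thresholds are not exactly
met by any admissible reading: the FB-knockdown strong-MB offset computes
to 0.25 µM (published 0.3) and the FB+MB-double-knockdown HB onset to
0.30 µM (published 0.2). These residuals are reported as-is; they are not
adjusted for.

### Integration

Fixed-step classical Runge–Kutta (RK4), step h = 2 time units, run until
the largest componentwise |d/dt| drops below `tol` (default 1e-8) or
`max_time` (default 10,000) is reached, whichever is first. States are
clipped at zero after each stage evaluation and step: Hill terms are
meaningless for negative levels and only discretisation overshoot can
produce them. Near the GSK3 collapse concentration the dynamics slow
critically; a handful of grid points in a fine dose–response may report
`converged=False` at the default cap without visibly moving. Dose-response
output is max-scaled per channel over the CT grid, which is also the scale
on which knockdown (clamp at 0) and overexpression (clamp at 1) levels are
defined. Clamping fixes the node's derivative at zero so the initial value
persists for the entire trajectory.

## Topology selection

All 2^12 = 4096 assignments of activation/repression to the twelve free
interactions are enumerated in documented binary-counting order (the two
fixed interactions, CT⊣GSK3 and GSK3→GSK3, are immutable). Each topology
is fit to a three-channel dose–response dataset by bounded quasi-Newton
(L-BFGS-B) minimisation of the squared-deviation cost

    Ed(p) = Σ_CT Σ_{i ∈ {FB,MB,HB}} (d_i − r_i(p))²

with seeded multistart. Free parameters per topology: one (c, n) pair per
present edge plus δ1..δ4; rate constants are optimised in log10 space over
[1e-4, 1e4], Hill coefficients over [1, 6], degradation rates over
[1e-3, 10]. These bounds span the magnitudes of the default set; the
source does not state the ones originally used. Both sides of the cost are
on the max-normalised scale: the data by construction, the model by
per-channel max-scaling of its steady response. (A raw-model comparison is
untenable: the default optimum's raw FB level is ≈5.4, so it could not be
an optimum against data capped at 1.)

Winners are all results within a relative cost tolerance (default 1e-2) of
the sweep minimum. In the best result, any self-interaction whose fitted
rate constant falls below `prune_eps` (default 0.05) times the median of
the other edges' rate constants is declared absent — this is the rule that
removes the forebrain self-interaction (published fitted value 5e-4
against peers of order 0.1–1000). Topology similarity is the fraction of
identically assigned interactions over the 14-position universe (twelve
variable plus two fixed), counting "absent" as an assignment.

Full 4096-topology sweeps at publication scale are supported but slow on
one core; the test suite exercises the machinery on reduced edge
subspaces (2–3 free edges, 1–2 restarts), which is sufficient for
ground-truth recovery on noiseless model-generated data.

## Expression data

Z-scoring is per gene across CT levels with the population (divide-by-n)
standard deviation. Gene clustering is hierarchical agglomerative with
single linkage (nearest-point rule) on Euclidean distances between
z-scored profiles; flat clusters are obtained by cutting to k clusters
(k = 3 for the three brain regions). Genes are pre-sorted lexicographically
by id before linkage so equal-distance merges resolve deterministically and
the result is order-independent. The correlation map is Pearson, ordered by
the linkage leaf order.

The synthetic qPCR generator emulates the three-region structure:
forebrain-like genes follow a falling logistic in CT (midpoint 0.3 µM),
hindbrain-like genes a rising logistic (onset 0.5 µM), midbrain-like genes
a Gaussian bump (centre 0.4 µM, width 0.12 µM), each with additive
Gaussian noise truncated at zero (qPCR levels are non-negative). Because
of the truncation, profile expectations match the templates only away
from the zero floor. The generator reproduces the clustering structure of
real data (three positively correlated blocks) but not its technical
replicate structure, amplification-efficiency artefacts, or any
gene-specific dynamic range, so passing clustering/selection tests show
correctness of the machinery, not performance on noisy real qPCR.

## Sensitivity analysis

For each parameter and relative change Δ, the parameter is scaled by
(1 + Δ), the steady dose response recomputed, and the cost reported as a
fold-change of the reference cost; a global mode scales all parameters
jointly. When the reference cost is exactly zero (model-generated data), an
unchanged zero cost reports fold-change 1 and any worse cost reports
infinity. Deltas that would make a parameter non-positive are skipped.

## Morphogen biophysics

The radius of gyration of a folded protein is estimated as
RG = 3·N^(2/5) Å from chain length N (≈32 Å for WNT at N = 370, ≈35 Å for
SHH at N = 462). The He–Niemeyer-style diffusivity correlation
D = 6.85e-15 · T/(η · M^(1/3) · RG) is provided as a pure function under
its stated mixed units (T in K, η in cP, M in kg/kmol, RG in Å, D in
m²/s). Evaluated literally with the WNT/SHH inputs it does *not* come out
at the published 150.7 and 133.4 µm²/s (the literal value is several
orders of magnitude smaller), and no natural re-reading of the units we
tried reproduces them; the correlation's prefactor presumably absorbs a
convention we cannot recover. The simulation therefore takes its
diffusivities from the parameter file, which ships the published values,
and the estimator remains a documented utility.

## The in-vivo 3D model

### Intracellular system

Each lattice cell runs a nine-species ODE system. The rostrocaudal branch
is the in-vitro circuit with GSK3 driven not by CT but by a WNT-responsive
buffer node U (c14 WNT-activation with exponent n14 = 2.5, c15
self-activation, c16 self-repression, δ5 decay); U represses GSK3 through
c13. The buffer's off state is absorbing without WNT and stable against
small WNT, which is structurally required: were U to switch on at any
trace of WNT, GSK3 would collapse tube-wide and no forebrain domain could
exist. The dorsoventral branch is the established minimal
Gli/Pax6/Olig2/Nkx2.2 circuit: Pax6 (dorsal, D) produced constitutively
and repressed by Nkx2.2 and Olig2; Olig2 (lateral, L) and Nkx2.2
(ventral, V) gated by Gli activity G/(1+G) with mutual repression; Gli
driven by SHH/(1+SHH) and repressed by WNT.

Of the dorsoventral constants, the Gli production scale (5.0), its decay
(k4 = 0.15), the WNT-repression constants (WcritG = 1, h6 = 1) and the
initial conditions are published values; the remaining constants are not
printed in our source and are package choices, fixed once to reproduce the
canonical behaviour of this circuit under a ventral SHH source and dorsal
WNT source: V ventrally, a lateral L stripe, D dorsally; V expanding and D
shrinking under SHH overexpression; D-only under SHH knockdown. Two
choices matter and are deliberate: Olig2 turns over more slowly than its
neighbours (k2 = 0.3 vs k1 = k3 = 1), which lets it accumulate through the
residual Nkx2.2 repression at intermediate Gli, and Nkx2.2's repression
by Olig2 is weak (OcritN = 3) while its repression of Olig2 is strong
(NcritO = 1, h3 = 6), so Nkx2.2 wins the high-Gli race ventrally. Without
the slow-Olig2 choice the lateral domain does not form at all in this
equation structure, because Gli is initialised high (G = 3) and Nkx2.2
wins the initial transient everywhere it can sustain itself.

### Geometry

The tissue is a parametric hollow bent tube voxelised at 10 µm (one cell
per voxel; x rostro→caudal, y ventral→dorsal, z left–right): a straight
caudal segment plus a circular-arc flexure (default 90°) whose outer side
is dorsal. Morphogen sources are painted as voxel roles: floor plate (fp,
ventral stripe, SHH) along the tube; zona limitans (zli, SHH) as a
transverse ring in the forebrain; roof plate (rp, dorsal stripe, WNT)
starting caudal of the forebrain territory; isthmic organiser (io, WNT)
as a transverse ring at the midbrain–hindbrain boundary; and a ventral
midbrain WNT patch (v). The full-size preset is 1000 µm long with outer
radius 120 µm and 30 µm wall (~20k cells). This is a schematic stand-in
for the anatomical voxel asset used in the original study, which is not
recoverable from the publication; all quantitative 3D outputs are
geometry-dependent and are validated as qualitative properties, never as
printed numbers.

### Transport and time stepping

Morphogens obey the discrete Fick law on the 6-connected lattice of
occupied voxels, d[X_i]/dt = D Σ_j ([X_j] − [X_i]) − δ[X], with zero-flux
boundaries (missing neighbours contribute nothing). Source voxels are
clamped to their production level (WNT_prod = 2, SHH_prod = 1) after every
update; morphogen overexpression multiplies the clamped level ten-fold,
knockdown sets it to zero. Updates are explicit Euler; each step first
updates the morphogen fields, then every cell's network. The admissible
step is dt ≤ 1/(12·D_lattice) — half the formal 3D stability limit, for
margin — which is ≈0.055 s at D = 150.7 µm²/s on a 10 µm lattice; the
default dt is 0.05 and exceeding the bound is an error. Convergence is
declared when the largest per-step change of any field falls below `tol`
(default 1e-6, checked every 25 steps). Cells whose GSK3 sits near the
collapse threshold converge only algebraically; production runs therefore
cap at a step budget and the fate pattern is read from the capped state
(domain counts move by only a few percent between 20k and 120k steps on
the default preset). Swapping the within-step update order (network before
morphogens) changes trajectories but leaves converged fields identical to
numerical precision; only the slowly decaying residual channels differ, at
the 1e-4 level.

### Quantification

Slice expression is the percentage of occupied slice voxels with a level
strictly above threshold: T = 1 for the dorsoventral channels and T = 0 —
implemented as > 1e-6 — for the rostrocaudal ones. Because losing
rostrocaudal channels can carry slowly decaying residuals at a capped
step budget, `quantify` additionally reports dominance-based fate shares
(the fraction of slice voxels whose maximal channel is each fate), which
partition the slice; domain comparisons between conditions use these
where residuals would saturate the thresholded percentage. Fate maps
assign per branch the maximal channel above the branch threshold, with
ties broken in the fixed orders FB > MB > HB and D > L > V. Slice
coordinates snap to the nearest voxel layer.

### Test-scale simulations

The test suite runs the 3D battery on a reduced preset (800 µm tube,
outer radius 90 µm, ~11.5k cells, 24,000 Euler steps ≈ 1200 s simulated)
and property checks on a 300 µm straight tube. These sizes are the
package's chosen CI scale; the full-size preset shows the same qualitative
pattern. One caveat is recorded honestly: on these thin geometries a
ten-fold WNT overexpression perturbs the dorsoventral percentages
substantially (the dorsal domain grows several-fold at the reference
slice), whereas the original study reports only a small dorsoventral
response on its larger anatomical geometry; the corresponding acceptance
property therefore asserts preservation of the dorsoventral organisation
(all domains present, ventral dominance at the reference slice), not a
magnitude bound.

## Known limitations

- No growth, cell movement, or dynamic induction of secretion sites; the
  morphogen sources are static, so phenomena that depend on boundary
  self-organisation (e.g. isthmic-organiser/MB-HB boundary colocalisation)
  are out of reach.
- The in-vitro dose response is transient-selected from a fixed initial
  state; it is not a bifurcation analysis, and basin boundaries are probed
  only by simulation.
- Deterministic ODEs only: no stochastic (Langevin/Gillespie) variants,
  no delays.
- Two published knockdown threshold concentrations are reproduced only to
  within one 0.05 µM grid cell or not at all (see the defaults section);
  the residual traces back to irreducible ambiguity in the printed
  parameter table.
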