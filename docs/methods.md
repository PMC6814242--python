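# Methods

This note documents the models, numerical choices, calibrations and known
limitations of the package, in the package's own terms.

## Activator–inhibitor model and Turing analysis

The generic two-species model uses Gierer–Meinhardt kinetics: a slowly
diffusing activator promotes its own (optionally saturating) production and
the production of a fast-diffusing inhibitor that limits it,

    dA/dt = D_A ∇²A + s_A A² / (k_I I (1 + κ_A A²)) + k_A − kd_A A
    dI/dt = D_I ∇²I + s_I A² − kd_I I.

Space is measured in lattice pixels and time in simulation steps; the two
canonical parameterizations (`RDParams.spots_inside_turing()` with
D_A = 0.0025 and `spots_outside_turing()` with D_A = 0.014, both with
s_A = s_I = 0.01, k_I = 1, k_A = 0, kd_A = 0.001, kd_I = 0.008, D_I = 0.4)
share the positive fixed point (A*, I*) = (8, 80) and differ only in
whether unequal diffusion destabilizes it. A stripe-forming set with
activator saturation κ_A = 0.25 is also provided; its critical wavelength
(≈2.5 px in the printed units) is marginally resolved on the unit lattice,
so stripe simulations are run at doubled spatial resolution (diffusivities
×4), which is a pure unit choice.

On a colony mask, production acts only on foreground pixels; degradation
uses the inside rates within the colony and a common `kd_out` outside;
diffusion covers the whole periodic lattice. Integration is forward Euler
with the 5-point periodic Laplacian and default step 0.8·dx²/(4·max D); a
spectral variant multiplies by the exact Fourier eigenvalues of the same
stencil and therefore matches the real-space step to machine precision.
Negative concentrations are clamped to zero after each step. Because the
activator production divides by I, the `edge_high` initial condition places
a small positive inhibitor level on the rim together with the activator
(an activator rim with I = 0 is singular); the subsequent dynamics are
insensitive to that level over two orders of magnitude.

Regime classification computes the steady state by bisection along the
inhibitor nullcline (cross-checked against long-time well-mixed
integration), an analytic Jacobian (cross-checked against central
differences), and the standard two-component conditions. When the
instability's wavelength exceeds a supplied colony diameter the report
flags `wavelength_exceeds_colony`, since an instability longer than the
colony cannot shape its fate pattern. Simulations that test the
classification run on a truly unmasked periodic lattice (`mask=None`): a
masked lattice necessarily carries a production-free frame that acts as a
boundary forcing and produces finite-amplitude patterns even in the
linearly stable regime.

## BMP→WNT→NODAL cascade

The cascade simulates WNT activity u and NODAL activity v on a colony in
physical units (µm, hours), driven by an imposed BMP input b(x, t) that is
uniform until t_restrict = 12 h and afterwards restricted to an exponential
edge profile (width 140 µm):

    du/dt = D_u ∇²u + [β_u + α_b b + α_u u²/(K_u²+u²)] − γ_u u
    dv/dt = D_v ∇²v + [β_v e(x) + α_w u + α_v H(v−v_th) v²/(K_v²+v²)] − γ_v v

with production (bracketed terms) confined to the colony and degradation
everywhere. e(x) is a 25 µm edge-localized profile representing TGF-β in
the medium activating NODAL at the colony edge; its amplitude is chosen so
it cannot ignite NODAL autoactivation on its own. The Laplacian is the
9-point isotropic stencil, and for canonical shapes the distance fields
feeding b, e and all fate measurements are computed analytically against
the ideal shape boundary: the lattice distance transform carries an
orientation-dependent bias of up to one pixel that otherwise contaminates
corner-versus-side comparisons on non-circular shapes.

The default parameters were calibrated in one pass against the qualitative
behaviors the model must reproduce, and then frozen:

* **WNT is a slow integrator** (γ_u = 0.005 h⁻¹, D_u = 60 µm²h⁻¹,
  α_b = 0.05): the colony-wide uniform BMP phase loads only a fraction of
  the final amplitude, and after edge restriction the edge-produced pool
  keeps accumulating and spreading inward. The inner edge of the
  above-half-maximum domain then sweeps toward the center at ~10 µm/h with
  a highly linear trajectory (R² ≈ 0.98). Because this front motion is the
  spreading of already-produced WNT rather than a regenerative wave,
  switching off WNT autoactivation at 15 h (the secretion-inhibition
  experiment) lowers the final peak but leaves the front speed and the
  peak's radial position essentially unchanged. A regenerative (bistable)
  WNT wave was explicitly rejected during design: it cannot reproduce the
  secretion-independence of the front.
* **WNT autoactivation is ring-confined** (α_u = 0.015, K_u = 1.6): the
  half-saturation sits above the interior operating level, so
  autoactivation mainly boosts the peak ring, giving the observed
  peak-level reduction under secretion inhibition without altering the
  wave geometry.
* **NODAL is an excitable unit** (γ_v = 0.3 h⁻¹, D_v = 800 µm²h⁻¹,
  α_w = 0.15, α_v = 0.6, K_v = 0.5, v_th = 0.4): WNT drive pushes v across
  v_th near the WNT ring at ≈24 h (within the experimentally bracketed
  20–30 h initiation window), after which autoactivation propagates a
  fast (~50 µm/h) wave to the colony center regardless of upstream input.
  This threshold produces the binary response to WNT blockade: blocking
  before initiation leaves NODAL as an edge rim (half-maximum extent
  ≤100 µm from the boundary, clearly edge-restricted on a 700 µm colony);
  blocking after initiation does not prevent the wave from completing.

The model deliberately omits feedback of WNT/NODAL on BMP and the
repression of WNT by BMP at the very edge; consequently the simulated
BMP-inhibition runs reduce WNT levels but do not move the WNT peak toward
the edge, a known limitation shared with the modeling the package
reproduces.

Grid convergence: halving the pixel size changes the steady-state radial
profiles by ≈1% (u) and ≈1.3% (v).

## Fate rules and geometry transfer

Fates are assigned per pixel from cumulative above-threshold exposure
times, reflecting the finding that signal *durations*, not instantaneous
levels, control differentiation:

* **EXE** (extra-embryonic/CDX2): ≥20 h of BMP above a level threshold.
  The 20 h requirement is the experimental minimum; the level is
  calibrated so the EXE/MESO boundary sits at 70 µm from the edge on the
  700 µm control circle.
* **MESO** (mesoderm/BRA): WNT exposure and NODAL exposure both above
  duration thresholds, and not EXE. WNT is the permissive initiator (its
  duration threshold is calibrated at a deep 220 µm reach) while NODAL is
  the spatially binding up-regulator (calibrated so the MESO/CENTER
  boundary sits at 160 µm), mirroring the initiates/up-regulates division
  of labor. The WNT level is the half-maximum active-signaling definition;
  the NODAL level is v_th.
* **CENTER** (pluripotent/SOX2): every remaining colony pixel that saw any
  signal; NONE is reserved for identically zero histories. Precedence is
  EXE > MESO > CENTER.

Calibration runs once on the 700 µm circle; the same rules then transfer
to other geometries. Predicted consequences: circles of ≤250 µm diameter
lose the CENTER fate entirely (the signaling waves cover them too quickly);
at 200 µm the NODAL criterion is within ~2 h of its threshold, i.e. the
center-loss boundary sits near 250 µm in this calibration. On triangles
and pacman shapes the mesoderm territory expands inward at corners: corner
sectors exceed the midpoints of the straight edges by ~25% (triangle) and
~21% (pacman). The mechanism is an earlier NODAL ignition near corners,
where a WNT-producing boundary wraps around the interior. The
corner-expansion metric compares angular sectors (±12°) around the
geometric corner directions with sectors at the straight-edge midpoints
(triangle sides, pacman wedge cuts); shapes are simulated at 1100 µm
nominal diameter and 7 µm/pixel so the fate boundary lies in the interior
rather than saturating the shapes' inradius.

## Quantification recipes

Radial profiles are functions of edge distance (Euclidean distance
transform, shifted one pixel so boundary pixels read zero), binned at
10 µm by default. The nuclear recipe extracts nuclear pixels, averages
marker and DAPI over nuclear pixels within a 120 µm disc, divides the two
local means, bins the ratio, and averages within and then across colonies
(mean ± SEM). Empty bins are reported as NaN, never zero. The non-membrane
recipe subtracts the membrane mask from the colony mask and profiles the
remaining pixels. Wave tracking thresholds at half the spatiotemporal
maximum of the binned means (a fixed threshold can be supplied to compare
perturbed conditions under a common definition); the active region at each
time is the contiguous above-threshold run containing the profile maximum,
its outer edge is the back and inner edge the front, and the front is fit
by ordinary least squares over the advancing phase — the maximal inward
stretch of the front trace, which reduces to the whole trace for monotone
experimental-style tracks. Cell-track statistics report total, signed
radial, and arc displacements per root cell, exclude single-point tracks
into a QC count, and encode progeny as 0/2/3/4 (no division / one
division / one / both daughters divide). The similarity index counts cells
whose neighborhood within 62 µm is >60% same-label, over cells with at
least one neighbor.

## Gene-set procedures

Differential-expression significance is pluggable: precomputed flags from
a count-based test are accepted as input, and a Welch t-test on log2
values with Benjamini–Hochberg correction is built in for synthetic data
only. Fold changes are ratios of condition-mean FPKM with pseudocount
0.01. The retention filter is inclusive (FC ≥ 2 via |log2 FC| ≥ 1,
abundance ≥ 1 in at least one compared condition); ranking ties break
lexicographically by gene id. The union set takes the top 100 up- and
down-regulated genes per treatment; the lineage-specificity filter
requires between-lineage DE, no within-lineage DE across days, and
RPKM ≥ 10 on at least 2 of 3 days.

## Synthetic data

Generators are deterministic given a seed (a top-level seed fans out to
per-component streams). The wave generator plants a logistic-shouldered
plateau whose inner front follows 13.57 µm + 6.02 µm/h × t, the measured
WNT-front trajectory, sampled hourly from 24 h with configurable Gaussian
noise. Colony images place non-overlapping nuclear discs (0.03 nuclei/px²,
a confluent density) with uniform DAPI, marker channels evaluated from
radial recipes at each pixel's edge distance, a bright one-pixel membrane
ring around each nucleus, and additive Gaussian noise; the exact nuclear
and membrane masks are returned so recipes can be tested bit-exactly.
Track generation applies a radial drift with per-frame jitter and
mid-movie divisions. The expression generator plants 100 up- and 100
down-regulated genes (8-fold, log-normal noise sd 0.2) per treatment on
adequately expressed baselines, with a 77-gene up / 54-gene down core
shared by all three treatments and 9 extra genes per pair in each
direction — an overlap structure solved once from inclusion–exclusion so
the top-100 union is exactly 284 genes.

What the generators do *not* emulate: optical blur and shading, nuclear
segmentation errors (masks are exact), cell movement during imaging,
count-level RNA-seq noise and library-size effects. Passing round trips
therefore demonstrate the correctness of the recipes and set procedures,
not robustness to segmentation or sequencing artifacts.

## Numerical and degenerate-input conventions

Explicit steps abort with a diagnostic on non-finite fields. Masks must
contain exactly one connected component with a one-pixel background margin
(periodic boundaries must not wrap the colony onto itself). Profiles with
no bin above threshold yield an empty track with undefined fit; a
time-constant profile yields slope 0 with R² = 0 by convention. The
similarity index is NaN when every cell is isolated. Fate assignment on
identically zero histories returns NONE everywhere.
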