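# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic benchmarks do and do
not demonstrate.

## Thermodynamic layer

The activation level E of a target gene is the probability that the
basal transcriptional machinery (BTM) is bound, computed over all
binding configurations of the predicted sites in the gene's regulatory
region. A configuration is a non-overlapping subset of bound sites
plus an effective/neutral flag for every bound repressor. Weights:

* site strength `q(S) = K(S_max) * v_TF * exp[LLR(S) - LLR(S_max)]`;
  K is the affinity of the TF's strongest possible site, v the nuclear
  protein concentration, LLR the PWM log-odds score;
* `W(sigma)` is the product of bound-site strengths, times the
  homotypic cooperativity bonus ω for *adjacent* bound same-TF pairs
  with edge-to-edge distance ≤ `coop_range` (default 50 bp), times
  β = |T| for every effective repressor;
* `Q(sigma) = q_btm * prod T^ab` over bound activators (repressors,
  neutral or effective, contribute nothing to Q);
* `E = sum W*Q / (sum W*Q + sum W)`.

**Short-range repression.** An effective repressor excludes all other
binding within `d_R` of its site midpoint (midpoint distance ≤ d_R is
forbidden, strictly greater is allowed). β scales W in numerator and
denominator, so a repressor with no neighbors inside d_R cancels from
the occupancy ratio exactly: repression acts only through local
quenching, and E can never be pushed *below* the basal level
`q_btm/(1+q_btm)`. One per-gene d_R is broadcast to all repressors of
that gene, matching the four-range parameterisation of the free
vector.

**Signed T with role by sign.** T > 0: activator weight α; T < 0:
repressor strength β = |T|; T = 0: the TF binds neutrally (occupies
sequence but neither contacts the BTM nor quenches).

**Evaluators.** `activation_brute_force` enumerates every
configuration (refused above 15 sites) and is the oracle.
`activation_dp` is an exact O(n²) dynamic program over sites sorted by
start: because non-overlapping sites have ordered midpoints,
compatibility (overlap, quenching exclusion, adjacent-pair
cooperativity) with the most recent bound site implies compatibility
with all earlier ones. The two agree to 1e-10 relative error on
hundreds of randomised instances with overlaps, mixed roles and
cooperativity on/off; the integrator's jitted kernel re-implements the
same DP and is tested against the pure-Python version.

**Monotonicity caveat.** E is provably non-decreasing in any
activator's T. It is *not* globally non-increasing in a repressor's
|T|: one effective repressor can exclude another repressor's binding,
freeing the activators that the second repressor was quenching, so E
can rise. This is genuine model behaviour (enumeration and DP agree),
not an artefact; the repressor-direction monotonicity check therefore
uses instances whose single repressor has mutually independent sites.

## Dynamical layer

Per gene and nucleus, mRNA u and protein v follow delay
reaction–diffusion equations with no-flux boundaries (missing-neighbor
term dropped). The simulated period spans cleavage cycle 13 (default
16 min, 29 nuclei at full scale) and cycle 14A (8 classes × 6.5 min;
nuclei double at the boundary, daughters inheriting the mother's
concentrations instantaneously; an optional synthesis blackout after
mitosis is off by default). Output snapshots are taken at the midpoint
of cycle 13 and of every 14A class. E is recomputed at every
integration step from the current protein fields (gap feedback) and
the external TF profiles, which are piecewise-linearly interpolated in
time between class midpoints with constant extrapolation at the ends;
for the cycle-13 phase, external profiles given on the cycle-14 grid
are mapped to mothers by daughter-pair averaging.

**Integration scheme.** Fixed-step exponential-Euler: the decay term
is integrated exactly (`u <- u*exp(-λ dt) + (synthesis+diffusion) *
(1-exp(-λ dt))/λ`), which reduces to explicit Euler as λ·dt → 0,
conserves mass exactly in pure-diffusion runs, and is exact for the
constant-forcing closed form used in the tests. Default dt = 0.0625
min (≈ 0.01 class durations, and a divisor of all output times so
snapshots land on steps). The delayed mRNA u(t−τ) is read from a
per-step history buffer with linear interpolation between steps —
without interpolation the solution is piecewise-constant in τ and the
sensitivity of the model to the delay parameter is identically zero.
Before t₀ the history is clamped to the initial state; across the
division the daughter looks up its mother's history. Delays rule out
the stock stiff ODE solvers, which is why the integrator is bespoke.

## Objective

`Error = RSS + 5e4 * wPGP + 1e-3 * Σ(T^ab)²` with configurable
weights. RSS runs over exactly the observed (gene, nucleus, time
class) triples. wPGP (weighted Pattern Generating Potential; 0 is a
perfect fit) is computed per (gene, time class) spatial pattern and
averaged over patterns; all-zero reference patterns are skipped. The
penalty denominator is implemented exactly as the printed formula,
`[Σ(r_max - r_i)]²`; because the slack appears squared, the score is
not bounded by 1 when observations crowd r_max. A config switch
(`normalization="rmax"`) selects the alternative `Σ(r_max - r_i) *
r_max` scaling, under which wPGP ∈ [0, 1] whenever predictions stay
within [0, r_max]; neither variant is chosen silently.

The variance-stabilising square root is applied (exactly once) to both
model and data before the identifiability analysis, because the
measurement error of quantitative expression data grows approximately
linearly with the mean.

## Fitting

The free vector has 68 entries at full scale (32 T, 4 q_btm, 8 K, 8 ω,
4 d_R, 4 τ, 8 λ); synthesis rates and diffusion coefficients are fixed
configuration. Default bounds: T ∈ [−10⁴, 10⁴], K ∈ [10⁻⁵, 0.1],
ω ∈ [1, 5], d_R ∈ [50, 250] bp, τ ∈ [0, 10] min, λ from half-lives of
1–100 min, q_btm ∈ [10⁻³, 10].

The optimiser is scipy's differential evolution (rand/1/bin, dithered
mutation (0.5, 1), crossover 0.9, immediate updating, Sobol
initialisation), followed by a bounded L-BFGS-B polish of the best
member with a hard evaluation cap. The search runs in a transformed
space — log10 for the strictly positive scale blocks (K, q_btm, λ) and
a sign-preserving symlog for T — because uniform sampling of the
natural ranges places essentially all trial points in the saturated
regime of the occupancy function; the model always sees natural units,
and fits are deterministic given the seed. Fits in which any TF's
affinity drops below K = 10⁻⁴ are flagged as degenerate (the regulator
is effectively switched off).

Cross-validation partitions the observations randomly into k
near-equal subsets (default k = 4), fitting on k−1 and scoring rms on
the held-out subset. The negative control swaps the target patterns of
gene pairs with respect to their regulatory regions (hb↔kni and Kr↔gt
at full scale; the two genes in the toy) and refits.

## Identifiability

The sensitivity matrix J (N residuals × m parameters) is the central
finite difference (relative step 10⁻⁴) of the square-root-transformed
residual vector. Per-parameter confidence intervals are the axis
projections of the joint ellipsoid `d^T J^T J d ≤ m/(N−m) · S(θ̂) ·
F_{α,m,N−m}`; a parameter whose sign matters counts as identifiable
when its interval excludes zero. Columns are normalised before the
inversion (an exact rescaling) because parameter scales span many
orders of magnitude; structurally zero columns yield infinite
intervals and a non-identifiable flag. The axis projection is exact
(equal to the t-interval) only for m = 1 and conservative for m > 1,
so the Monte-Carlo calibration checks two things: per-parameter
coverage on an m = 1 linear-Gaussian toy (≈ 95%), and the joint
ellipsoid itself at m = 3, whose coverage is exactly 1−α in the
linear-Gaussian model.

The collinearity index of a parameter subset is
γ = 1/√λ_min of the column-normalised J^T J submatrix (γ = 1 for
orthogonal columns; for two columns with correlation r,
γ = 1/√(1−r)); subsets of size 2–3 with γ above the threshold 4 are
reported by exhaustive enumeration, sorted descending.

## In-silico experiments

The regulatory weight of a site, `w_r = (RSS_ref − RSS_mut)/RSS_ref`,
is computed with the site excluded and all parameters frozen (a refit
per site would be prohibitive, and frozen-parameter weights are the
quantity the ranked-removal analysis needs); by this sign convention a
site the model output relies on gets w_r < 0, so ranking and the
high-impact threshold (default |w_r| > 0.005) use the magnitude.
Ranked removal deletes sites cumulatively in order of increasing
|w_r| and reports RSS relative to the reference. Null mutants zero the
mutated gene's synthesis rates and optionally substitute mutant TF
profiles. Reporter constructs restrict the activation input to the
sites of one named CRE and take *all* regulator concentrations from a
supplied dataset (no feedback of the reporter product); reporter
output is meant to be compared in spatial shape, not absolute level.
Topology is summarised by counting positive and negative fitted T
entries per (gene, TF) pair across a collection of fits; zeros count
in neither category.

## Synthetic fixtures and what they show

The generator produces PWMs with controllable information content,
background sequence with consensus words planted at known positions
(redrawn deterministically until scanning recovers exactly the truth
set), analytic A-P gradients (exponential / sigmoid / Gaussian bump)
with multiplicative Gaussian noise of configurable CV — emulating the
approximately concentration-proportional error of quantitative imaging
data — clipped to [0, r_max] = [0, 255].

The standard toy study is two gap-like genes and three regulators over
20 cycle-14 nuclei and 5 time classes (c13 + T1–T4), 5% noise CV,
seed 0: an anterior exponential input (M1) activates gA and quenches
gB; a posterior sigmoid input (M2) activates gB and quenches gA; gA
autoactivates and quenches gB. Each 600-bp region carries 7 planted
sites (≤ 12, within reach of the enumeration oracle), with repressor
sites interleaved among activator sites — short-range quenching acts
only within d_R — and one same-TF pair inside the cooperativity range
so ω is exercised. Affinities put q = K·v_max at order 1, the
competition regime implied by published affinity estimates for this
system. Synthesis and diffusion constants are fixed at values giving
protein levels within the fluorescence range; decay half-lives are 5
min (mRNA) and 12 min (protein), delays 2–3 min.

Two diverse input shapes keep the sensitivity columns of the
regulatory parameters linearly separable; with a single gradient every
column shares one axis shape and the T entries are unidentifiable in
principle. A strong K↔T ridge remains even so — halving K while
doubling the corresponding T entries moves the RSS by ≈ 1% — which is
the weak-to-moderate-binding degeneracy where mainly the product K·T
is constrained, and the T-penalty term selects the small-|T| end of
that ridge. Consequently T *magnitudes* are not expected to return
from a fit, and per-entry certification (a 95% interval excluding
zero) is out of reach at this data size: across the generating truth
and every fitted optimum we examined, the certified T set is empty,
with intervals one to two orders of magnitude wider than the
estimates. What the recovery benchmark can demonstrate at toy scale
is that the full pipeline (site prediction → occupancy → dynamics →
DE fit) recovers the *point-estimate sign structure* of the network
(5–6 of 6 entries across seeds) at the noise floor; the
certified-subset sign check it also performs is an honest statement
of what the data size supports — certification would need the larger
N, the site-strength diversity and the weaker relative T-penalty of a
full-scale study. None of this shows that fitted magnitudes are
meaningful under collinearity, nor anything about real embryo data,
imaging artefacts, or the full 68-parameter landscape, whose
exploration needs cluster-scale budgets.

Benchmark problem sizes (desk scale, one CPU): recovery uses the best
of three multi-start fits of ≈ 9 × 10³ DE evaluations plus a capped
polish; the negative control fits true and shuffled data at a smaller
budget over three seeds. Monte-Carlo calibration uses 1000 replicates;
oracle equivalence uses 200 random instances.

## Known limitations

* One spatial dimension, instantaneous mitosis, no nonspecific
  binding, no heterotypic cooperativity, distance-independent ω within
  its range.
* The delay enters through a history buffer; events between grid
  points are linearly interpolated.
* Frozen-parameter regulatory weights may differ from refit-based
  weights when sites back each other up.
* The printed-formula wPGP penalty is scale-sensitive near r_max (see
  above).
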