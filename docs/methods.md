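# Methods

## The model

`thermoexpr` predicts the transcriptional output of a locus in a syncytial
embryo nucleus from (i) the DNA sequence and its chromatin accessibility,
(ii) one position weight matrix (PWM) per transcription factor (TF), and
(iii) the local TF concentrations. Prediction composes five layers, in a
fixed order, per nucleus ν on the anterior–posterior (%EL) grid:

**Site map.** Each PWM is slid along both strands; windows with normalized
log-odds score ≥ a per-TF threshold and not overlapping closed chromatin
become binding sites. Scores are log2(p/background) with min–max rescaling
per PWM to [0, 1], so thresholds are comparable across TFs. This layer is
identical for every nucleus; spatial information enters only through
concentrations.

**Occupancy f.** Thermodynamic equilibrium over binding configurations.
A site's statistical weight is `w_i = K_tf · norm_score_i · [TF]_ν`.
Configurations are subsets of mutually non-overlapping sites (steric
exclusion); homotypic cooperativity (Bcd only in the eve configuration)
multiplies the weight by ω for every consecutively bound pair of
cooperative-TF sites whose edge-to-edge gap is within the cooperativity
range. The partition function and per-site marginals are computed exactly
by a forward–backward dynamic program over sites sorted by end coordinate;
its correctness is pinned by an exhaustive 2^n enumeration oracle in the
test suite (agreement to 1e-9 on random overlapping instances), not by
construction.

**Coactivation and quenching F.** Bound-TF occupancies are split into an
activator channel A and a quencher channel q. True activators put all of f
into A. A coactivation target (Hb, with incoming edges from Bcd and Cad)
splits: with in-range source sites, the probability that at least one bound
source coactivates is `1 − Π_c (1 − E_co(c)·f_c)`; that fraction of bound
Hb moves to the activator channel, the rest keeps quenching. Each bound
quencher within its action range then reduces nearby sites' activator
channel multiplicatively: `F_i = A_i · Π_q (1 − E_q(tf_q)·q_q)`.
Overlapping pairs (which cannot be co-bound) are excluded from both
interactions. Interactions act on marginal occupancies (mean-field), the
standard treatment in this model family.

**Activation efficiency FEaA.** `FEaA_i = F_i · E_a(tf_i)`; a coactivated
target uses its own distinct efficacy by default (`Ea_Hb_coact`); a variant
that reuses the quenching efficiency is available via
`ModelConfig.coactivation_variant = "convert_eq"`.

**Window competition R×T.** The locus is tiled with windows of length α
(anchored at the 5′ end; an overlapping sliding variant exists behind
`ModelConfig.window_mode`). A window with total activating content
`T = Σ FEaA` realizes `T/(1 + T/κ)` of it, so each member site keeps the
fraction `R = 1/(1 + T/κ)` — crowded windows give diminishing returns per
site as they compete for the promoter's limited interaction capacity κ
(`ModelConfig.competition_capacity`, default 1.0 in barrier-reduction
units). This saturating form was chosen over a normalized share
`T_w / Σ T_w` deliberately: the share form is not monotone — weakening an
already-weak window *raises* total output — which violates the model-level
guarantee that increasing a quencher concentration can never increase
expression. The saturating form preserves all required behaviour: with one
window all sites keep a common factor, identical windows realize identical
totals, Σ R×T ≤ Σ FEaA, and monotonicity holds site-wise.

**Promoter activity M.** A diffusion-limited Arrhenius law: the summed
barrier reduction Σ R×T lowers the activation energy barrier,

    M = basal + M_max · exp(−scale · max(θ − ΣRT, 0)).

M is non-decreasing in ΣRT, equals `basal + M_max` exactly once ΣRT ≥ θ,
and is within `M_max·e^(−scale·θ)` of the basal level at zero activation
(θ·scale is large in all presets, so the floor is effectively basal).

### Free parameters (eve configuration: exactly 32)

| group | parameters | count |
|---|---|---|
| binding scale | `K_tf`, all 8 TFs | 8 |
| activator efficacy | `Ea_Bcd`, `Ea_Cad`, `Ea_Dst`, `Ea_Hb_coact` | 4 |
| quenching efficiency | `Eq_Hb`, `Eq_Gt`, `Eq_Kr`, `Eq_Kni`, `Eq_Tll` | 5 |
| coactivation efficiency | `Eco_Bcd_Hb`, `Eco_Cad_Hb` | 2 |
| Bcd–Bcd cooperativity | strength ω, range (bp) | 2 |
| quenching range (bp) | one per quencher | 5 |
| coactivation range (bp) | one per edge | 2 |
| promoter | `M_max`, `theta`, `scale`, `basal` | 4 |

Efficacies and efficiencies are dimensionless in [0, 1]; ranges are in bp
(defaults near 150 bp, the short-range-repression scale); K relates
normalized score × concentration (relative fluorescence units) to a
dimensionless site weight. The window length α is *not* optimized: it is
held fixed per run and swept externally (300/500/800/1000 bp in the
`alpha_sweep` analysis). κ is likewise a run-level constant, not a free
parameter, keeping the optimizer dimension at 32.

Monotonicity caveats: with coactivation enabled, raising Hb concentration
can raise expression (that is the point of coactivation), so the
quencher-monotonicity guarantee is stated with coactivation edges disabled,
and holds for the non-coactivated quenchers regardless. The guarantee also
presumes activator sites of different TFs do not sterically overlap, which
holds in the synthetic presets.

## Fitting

`rms_cost` is the root-mean-square difference between observed and
predicted profiles over the analysis window 35.5–92.5 %EL (58 nuclei,
1 %EL steps). The name-giving root and mean are applied; the raw
sum-of-squares variant is available via `raw_sum=True` for strict
cross-checks against conventions that omit them. Thresholds (default 12)
are on the expression scale (relative fluorescence, ~0–100).

Simulated annealing uses geometric cooling (T ← 0.9·T by default) with
single-parameter Gaussian moves clipped to the search box and a move scale
that adapts toward ~40% acceptance. Classic SA schedules are a free
implementation choice here; the schedule details are exposed in
`AnnealingConfig` and every fit is fully reproducible from its seed. An
optional polish stage alternates bounded Powell and L-BFGS-B passes from
the best-seen point; the combination escapes the axis-aligned stalls
either method reaches alone and is what makes near-exact noise-free
recovery (RMS < 1% of scale in 32 dimensions) attainable at desk scale.

Ensembles are n independent seeded fits (`seed_base .. seed_base+n−1`),
deterministic in content and order regardless of scheduling.

## Compatibility filters

Filter 1: `rms ≤ threshold` (inclusive boundary). Filter 2, evaluated only
on filter-1 passers: at the reference nucleus (stripe-2 peak, 40.5 %EL),
rank sites by their share of Σ R×T (post-competition activity; an
FEaA-based variant is configurable), take the shortest prefix reaching the
active fraction (default 80%, ties broken 5′-first), and pass iff at least
one of these *major activators* intersects the reference enhancer region
(S2E analogue, −1600..−800 bp). Coactivated Hb sites live in the activator
channel and therefore count as activators here.

## Search-space refinement

From the compatible fits of round 1, per parameter: compute Q1, Q3 by
linear interpolation (NumPy's default; Tukey hinges differ and the
convention is therefore fixed and documented), IQ = Q3 − Q1, and the band
[Q1 − 1.5·IQ, Q3 + 1.5·IQ]. Parameters with any value outside the band
(category a) get the old bounds clipped to the band; parameters without
outliers (category b) get the observed min/max. Degenerate bounds are
ε-widened. When a round yields fewer than 4 compatible fits, the pipeline
refines from the 10 best-RMS fits instead of aborting — a deliberate
small-ensemble fallback, logged when taken; at campaign scale it never
triggers.

## Ensemble analysis

The weighted site frequency of site s is
`(Σ_fits contribution(s)) · count(s) / max_s' count(s')`, rescaled so the
top site scores 1; contribution is the site's R×T share within the fit's
major set. Sums use exactly-rounded accumulation so the result is invariant
to fit order.

A functional cluster is one major-set activator (center) plus the quencher
sites with nonzero repression efficiency and the coactivator sites with
nonzero occupancy that act on it within interaction range; by default each
member TF's own fitted action range is used (one source of truth with the
model layers), with a fixed override available. Clusters are ranked by the
summed activator-channel contribution of center plus coactivator members
(a cluster-sum reading; ranking by center alone is the other defensible
choice), ties 5′-first.

## Clustering of fits

Parameter matrices are z-scored column-wise with the sample (n−1) standard
deviation; constant columns are dropped with a warning. The number of
clusters is chosen by majority vote over five internal validity indices —
silhouette, Calinski–Harabasz, Davies–Bouldin (negated), a gap statistic
with 10 uniform reference draws, and Dunn — for k = 2..10, ties to the
smaller k; when no k gets more than one vote the data is flagged
low-confidence and the smallest candidate is reported. This fixed
five-index subset stands in for larger index collections; majority-vote
semantics are preserved. k-means uses ≥10 seeded restarts and labels are
canonicalized by cluster size (descending). PCA is a covariance
eigendecomposition with components ordered by explained variance and signs
fixed so each component's largest-magnitude loading is positive; the first
three components are exported for visualization. Smaller clusters are
reported alongside the dominant one — an alternative-logic cluster is a
candidate hypothesis, not noise.

## Synthetic data

The generator emulates the statistical structure of the blastoderm stripe
system, not any measured dataset:

- **Sequence**: i.i.d. random background with consensus motifs planted at
  fixed positions, then *scrubbed* — background bases are mutated until a
  scan at the scenario threshold recovers exactly the planted sites.
  Planted sites never overlap.
- **PWMs**: sharp synthetic matrices (count 12 on the consensus base,
  pseudocount 1), with deliberately non-palindromic consensi so reverse
  strands score low.
- **Gradients** (relative fluorescence units, scale ~100): Bcd-like
  exponential anterior decay, Cad-like logistic posterior rise, a flat
  Dst-like profile, and Gaussian/logistic gap-gene-like domains for
  Hb/Gt/Kr/Kni/Tll, on the 35.5–92.5 %EL grid.
- **`eve_like`**: a planted enhancer at −1600..−800 bp (3 Bcd, 2 Hb,
  1 Dst site with Gt/Kr/Kni border sites) drives a stripe peaked exactly at
  40.5 %EL under the ground-truth parameters (peak ≈ 83, posterior
  baseline ≈ 50 from a second posterior module — multi-stripe structure is
  a feature of the template system); a decoy upstream region is silenced by
  Hb/Kr quenching; one closed-chromatin interval is masked.
- **`minimal`**: one activator + one quencher, ≤ 12 sites, small enough
  for exhaustive enumeration.
- **`two_logic`**: two planted enhancer regions, each sufficient for the
  stripe under its own parameter regime (Bcd/coactivated-Hb logic vs
  Dst logic with disjoint activator TFs), used to test that fit clustering
  separates regulatory logics.
- **Noise**: additive Gaussian (sd 3, a few percent of scale) clipped at
  zero — a simple stand-in for reporter-quantification error; it is not a
  calibrated noise model.
- Search boxes: a wide a-priori box (`prior_range`) standing in for
  biological prior knowledge, and a ±40% truth-centred box (`true_range`)
  for recovery tests.

What passing tests on this generator do **not** show: performance on real
loci with correlated background sequence, PWM cross-talk between related
motifs, unknown accessibility, concentration measurement error, or
model-misspecified regulatory grammar. The generator shares the forward
model with the fitter by design (the tests target the inference machinery,
not model adequacy).

## Problem sizes and numerics

Desk-scale campaigns use 50 fits/round with ~1200 SA evaluations plus a
600-evaluation polish per fit; the two-round enrichment property is
measured over 5 scenario seeds. These sizes were chosen so the full suite
and the acceptance script each complete in minutes on one core while
leaving the enrichment effect far from marginal (round-1 compatible
fractions around 40–70%, round-2 near 95–100%). Campaign-scale runs
(2 × 2000 fits) are supported through the same pipeline (`RunConfig.n_fits`)
and are a pipeline mode, not a test requirement. The occupancy DP is
JIT-compiled with numba when available, with an identical pure-Python
fallback; a forward profile evaluation is ~0.3 ms compiled. Partition
functions are computed in plain float64 — with the default parameter
bounds the largest configuration weights are far below overflow.

## Known limitations

- Pioneer factors, freely diffusing hubs, dorsal–ventral coupling and
  chromatin dynamics are out of scope by design.
- Cooperativity is nearest-bound-neighbour; arbitrary pair interactions
  would require a different DP state.
- The sliding-window competition variant is not monotonicity-preserving
  (the tiled default is) and is provided for comparison only.
- Filter 2 assumes an activation-driven phenotype and a known reference
  enhancer; transfer to a system without prior enhancer knowledge means
  running filter 1 alone.
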