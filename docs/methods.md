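# Methods

This note records the models behind each stage, the defaults and why they were
chosen, the numerical conventions, and what the synthetic-data generators do —
and do not — emulate.

## Factorial differential expression

### Model and test

Each gene's normalized log2 signal is modelled as a balanced two-way factorial,
Y_ijk = μ + G_i + N_j + GN_ij + E_ijk, with genotype i ∈ {WT, MUT}, nitrate
j ∈ {HN, LN}, r replicates per cell and Gaussian errors. The balanced-design
decomposition is computed in closed form:

* SS_G = 2r · Σ_i (ȳ_i·· − ȳ···)², SS_N analogously over nitrate margins,
* SS_GxN = r · Σ_ij (ȳ_ij· − ȳ_i·· − ȳ_·j· + ȳ···)²,
* SS_E = Σ_ijk (y_ijk − ȳ_ij·)², df_E = 4(r − 1).

With r = 3 the per-gene error estimate is too weak to carry a test, so a
single error variance is pooled across genes and treated as known. Under the
null each contrast's SS is σ²·χ²(1), so T_c = SS_c/σ̂² is referred to χ²(1)
(`reference="f"` switches to F(1, pooled df); at thousands of pooled degrees
of freedom the two are indistinguishable to ~1%). Genes with zero total
variance get T = 0 and p = 1 on every contrast automatically.

Unbalanced designs are rejected rather than approximated: with unequal cell
counts the SS decomposition is no longer orthogonal (Type I/II/III ambiguity)
and the closed forms above are invalid. The experimental designs this targets
are balanced.

### Pooled ("global") variance and trimming

Genes with extreme per-gene residual variance are removed before pooling:
two-sided quantile trim, defaults (0.025, 0.975), linear-interpolation
quantile convention, strict inequalities (a gene sitting exactly on a quantile
is retained). σ̂² is the mean of the retained s² — equivalent to pooled
SS_E / pooled df_E because df_E is constant across genes.

Because s² ~ σ²·χ²(df)/df is right-skewed, symmetric-in-probability trimming
removes more mass from the upper tail than the lower one and the raw trimmed
mean underestimates σ² (by ≈ 2% at df = 8 with the default trim). That bias
is small but consequential: it inflates every T statistic by the same factor
and pushes the family-wise error rate of the Bonferroni pipeline measurably
above its nominal level (≈ 0.06 instead of 0.05 per contrast in Monte-Carlo
runs). `estimate_global_variance` therefore divides the trimmed mean by its
expected value under the Gaussian null,

    c(df, q_lo, q_hi) = [F_{df+2}(b) − F_{df+2}(a)] / (q_hi − q_lo),
    a = F_df⁻¹(q_lo),  b = F_df⁻¹(q_hi),

the standard consistency correction for a trimmed scale estimator (the same
idea as the normal-consistency constant of a winsorized SD). With the
correction the pooled estimate is unbiased and the measured per-contrast FWER
sits at its nominal 0.05. `bias_correction=False` gives the raw trimmed mean.
The correction assumes a common σ² across the genes that survive the trim; on
real data, where trimming exists precisely because some genes have outlying
variances, it remains an approximation — a reasonable one, since the factor
is within 2–3% of 1 for any plausible trim.

### Multiplicity

Bonferroni per contrast: p_adj = min(1, m·p_raw) with m defaulting to the
number of genes actually tested (those passing the expressed filter);
`m_policy="all"` in the CLI adjusts over the pre-filter probe count instead.
Declaration uses strict inequality p_adj < α (α = 0.05). Note what is and is
not controlled: each contrast family's FWER is ≤ α, but the union over the
three (mutually independent, by orthogonality of the SS decomposition)
families is ≈ 1 − (1 − α)³ ≈ 0.14 by construction. The calibration module
measures and reports the per-contrast rates, which is the guarantee the
procedure makes.

### Expressed filter

A probe is kept when its maximum log2 signal across all samples is strictly
greater than 4. Filtering precedes all testing, and the default multiplicity
universe is the filtered set. The matrix is assumed already normalized
(log2 scale); no normalization is performed here.

## Ecophysiology

Derived per plant: LRL = (TRL − PRL)/LRN; TDW = SDW + RDW; TotN =
SDW·%ShootN/100 + RDW·%RootN/100 (grams of N); RDW/TDW. Degenerate cases:
LRN = 0 with TRL = PRL gives LRL = 0 (no laterals); LRN = 0 with TRL > PRL is
an inconsistent record and raises. All zero dry mass raises (ratio undefined).

Efficiency metrics are computed on group (genotype × nitrate) means per
sampling day, because plants are destructively sampled — there is no
within-plant time series. For each consecutive interval [t1, t2]:

* NUR = (TotN̄(t2) − TotN̄(t1)) / ∫ area dt, the integral being the trapezoid
  between the two sampled mean areas (equivalently: the mean area profile is
  taken linear in time between sampling days, the only assumption the data can
  support). An RDW-based denominator is available (`basis="rdw"`). Units:
  g N cm⁻² day⁻¹ (or g N g⁻¹ day⁻¹ for the RDW basis).
* NLA = (LeafĀ(t2) − LeafĀ(t1)) / (TotN̄(t2) − TotN̄(t1)), cm² per g N;
  flagged NaN (not an error) when ΔTotN = 0.

`interval_efficiencies(..., n_grid=k)` refines the internal integration grid;
for the linear-in-time area this provably leaves NUR unchanged, which is
tested.

### LSD letter display

At each sampling day the four genotype × nitrate groups are compared by
Fisher's LSD: one-way ANOVA pooled MSE, LSD_ij = t(1 − α/2, df_E) ·
√(MSE·(1/n_i + 1/n_j)), α = 0.05 by default. Letters come from
insert-and-absorb on means sorted descending: each group's maximal run of
mutually non-significant neighbours becomes a candidate interval, intervals
contained in others are absorbed, and surviving intervals are lettered in
order. When every group is internally constant, MSE = 0 is floored at machine
epsilon × (grand mean)² so letters stay well-defined. The experimental unit
is whatever one input row represents — per-plant values or per-replicate
means; the latter matches designs where tanks of pooled plants constitute the
biological replicate.

## qPCR relative quantification

Per-gene standard curve: least squares of CT on log10(quantity) over ≥ 3
distinct dilution points; efficiency E = 10^(−1/slope); non-negative slopes
are rejected. Unknowns: technical replicates are averaged on the CT scale
(CT is the near-Gaussian measurement scale; averaging quantities would be
biased), then quantity = 10^((CT − intercept)/slope). Each (sample,
biological replicate) unit is normalized by the geometric mean of its
reference-gene quantities — geometric rather than arithmetic because
reference levels are multiplicative quantities and the geometric mean is
scale-equivariant in each gene; `combine="mean"` is available. Fold changes
between conditions are ratios of geometric means over biological replicates.

## Synthetic-data generators

All three generators are deterministic given their seed (one `Generator` per
call; all draws flow from it in a fixed order).

### Expression

Balanced 2 × 2 × r design (defaults r = 3, 2000 genes). Per-gene baselines
uniform on 2–14 log2 units — the realistic dynamic range of normalized array
signal. Effects are planted on independently drawn gene subsets (overlap
allowed, mirroring genes responsive to several effects): a main effect e is
coded ±e/2 across the margin so the marginal-mean difference equals e; an
interaction i is coded (+i/4, −i/4, −i/4, +i/4) so the classical 2×2
interaction contrast equals i. I.i.d. Gaussian noise, default sd 0.5 log2 —
a typical residual scale for replicated arrays. Ground truth records flags,
signed effects and baselines.

What it does not emulate: probe-level effects, normalization artefacts,
correlated genes, heteroscedasticity across the intensity range. Passing
recovery tests therefore demonstrates the statistics are implemented
correctly, not that real arrays meet the model's assumptions.

### Growth

State variables at sampling days {7, 10, 14, 21, 28} (days after transfer).
Deterministic core per genotype × nitrate scenario: TDW(t) = TDW₀·e^(rgr·t);
RDW = allocation · TDW; root area = specific root area · RDW; LeafA =
leaf-area coefficient · SDW; whole-plant N accumulates as u · ∫ area dt with
the area taken **linear in time between sampling days** and the integral
evaluated by trapezoid on a fine internal grid (64 sub-steps — exact for the
piecewise-linear area, so refining the grid changes nothing). The
piecewise-linear convention is deliberate: plants are only observed at
sampling days, so the estimator downstream can only ever integrate the
linearly interpolated mean area; building the generator on the same latent
trajectory makes "estimate equals truth at zero noise" an identity rather
than an O((rgr·Δt)²) approximation, and keeps the closed loop a test of the
code instead of a test of an unknowable between-sampling trajectory.

Default scenario parameters (per day; chosen once as field-realistic for
young *Medicago* seedlings in hydroponics, with the mutant depressed in
growth and uptake and over-allocating to its highly branched,
short-lateralled roots): rgr 0.09–0.13 d⁻¹, root allocation 0.30–0.42,
specific uptake rate u 2.5–6.0 × 10⁻⁵ g N cm⁻² d⁻¹, specific root area
250 cm² g⁻¹, leaf area 180–220 cm² per g shoot, TDW₀ 5 mg, TotN₀ 0.2 mg.
These give tissue N concentrations of ~3–4% of dry mass throughout.

Noise: two multiplicative lognormal components, both mean-one —
`cv_between_plants` (default 0.10) as a per-plant size factor shared by all
of that plant's measures, and `cv_measurement` (default 0.02) independent per
variable. Both are exposed because pooled-tank designs leave open whether
per-plant or per-replicate variability dominates. Lateral-root counts are
rounded to integers under noise (left exact in the zero-noise limit so the
closed-loop identities hold). %ShootN/%RootN are back-computed from the
simulated N pools (a fixed root share, default 0.25), so TotN recomputed
downstream reproduces the generator's pool exactly.

### qPCR

CT = intercept + slope·log10(q) with slope = −1/log10(E); default intercept
35 cycles at q = 1. Per gene: a 5-point 10-fold serial dilution (quantities
100 … 0.01) and 3 technical × 3 biological replicates per condition
(control q = 1, treated q = fold change). Reference genes (EF1, UBQ) carry
fold change 1 and E = 2. Technical noise is Gaussian on the CT scale
(default sd 0.1 cycles, a typical plate-level repeatability). No biological
variance component is simulated beyond the planted condition difference.

## Monte-Carlo calibration (`calibration.py`)

`fwer_simulation` runs the full testing chain (SS decomposition → trimmed,
bias-corrected pooled variance → χ²(1) contrast tests → per-contrast
Bonferroni) on independent null datasets and reports, per contrast family,
the fraction of datasets with ≥ 1 declared gene (defaults: 1,000 datasets,
2,000 genes, r = 3, noise sd 0.5 — ~10 s on one CPU). `null_uniformity`
reports per-contrast p-value means and KS distances plus the KS distance of
the pooled 6,000 p-values; pooling the three independent families estimates
the same KS distance with a ~√3 smaller noise floor (0.011 vs 0.019 at
n = 2000), so a bound of 0.03 discriminates real miscalibration from KS
sampling noise instead of flagging ~10% of perfectly calibrated runs.

## Problem sizes and known limitations

* The acceptance script and test suite run the FWER study at 1,000 × 2,000
  genes and the IO round trip at 61,278 × 12 — the full chip width — in
  seconds to a few minutes on one CPU; all other checks are sub-second.
* The χ²(1) reference treats σ̂² as exactly known; with ~15,000 pooled df its
  relative error is ~1%, which inflates extreme tails by well under 1% — far
  below Monte-Carlo resolution, but not exactly zero.
* Direction calls for the interaction contrast are deliberately not provided
  (a 2×2 interaction has no single direction); inspect the four cell means.
* Ties in marginal means are reported as the "down" direction with an
  explicit tie flag, keeping output deterministic.
* External gene lists are matched as exact identifier sets; no cross-platform
  identifier translation is attempted.
* The pipeline consumes already-normalized matrices; probe-level processing
  and normalization are out of scope.
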