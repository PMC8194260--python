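# Methods

## Effect sizes

Each study contributes, per gene, a log2 fold-change θ_i = mean(log2 case) −
mean(log2 control) with sampling variance v_i = s²_case/n_case +
s²_control/n_control (unbiased sample variances). This Welch-style variance
of a difference in means is the natural companion to inverse-variance
weighting; an equal-weight alternative (v_i ≡ 1) can be emulated by passing
a constant-variance effect table to `MegaAnalysis.from_effects`. Missing
values are ignored within a group; a gene needs at least two non-missing
values per group in a study to contribute there, because otherwise the
variance is not estimable. Groups that are exactly constant produce a
variance of 0; such effects are flagged degenerate and dropped before
combination, since a zero variance would receive infinite weight. Genes
measurable in fewer than two studies are excluded from combination — Q needs
df ≥ 1 to be meaningful.

Matrices whose maximum exceeds 30 are assumed to be linear-scale intensities
and are log2(x+1)-transformed on read; log2 data pass through untouched.
This is a heuristic — genuinely log-scale data never approach 30, and
linear microarray or count data always do — and it can be pre-empted by
supplying already-logged matrices.

Probe-level arrays are collapsed to genes either by keeping the probe with
the highest mean expression (`max_mean`, ties broken lexicographically by
probe id so the result is deterministic) or by per-sample averaging across
a gene's probes.

## Combination and model selection

The fixed-effect estimate is the inverse-variance weighted mean; Cochran's
Q = Σ w_i (θ_i − θ̂)² with df = k − 1 measures excess dispersion. The
heterogeneity percentage is ISq = 100·(Q − df)/Q, floored at 0 whenever
Q ≤ df. Model selection is deliberately the hard switch on Q vs df: Q ≤ df
selects the fixed-effect model (τ² = 0), anything larger selects
DerSimonian–Laird random effects with τ² = max(0, (Q − df)/C),
C = Σ w_i − Σ w_i²/Σ w_i, and weights 1/(v_i + τ²). With τ² = 0 the random
model reduces bitwise to the fixed one, which the tests assert. Q-p is the
upper-tail χ²_df probability of Q.

The combined effect's p-value is the two-sided normal tail of effect/se —
the standard choice for inverse-variance combination. P-values below double
precision underflow to exactly 0 and are flagged (`p_underflow`) rather than
clamped. The per-gene significance cutoff defaults to p < 0.05 and is
configurable, including Bonferroni and BH variants via
`MegaAnalysisResults.significant`. The panel table is sorted by p ascending
with gene id as a deterministic tie-break. REML or other τ² estimators are
not implemented; DerSimonian–Laird is the canonical moment estimator for
this design and an R `metafor` cross-check in the test suite confirms the
numbers.

## Covariate regression

Per-study effects are regressed on three study-level covariates: total
sample size, country of origin (categorical) and study age in years. The
default mode is univariate — one simple regression per covariate, the
country covariate tested by the overall F statistic across its contrasts —
because with few contributing studies a joint three-predictor fit has no
residual degrees of freedom; a joint mode exists and refuses to run without
at least one residual df. Covariates constant across the contributing
studies are reported as not-estimable (NaN) rather than given a meaningless
p-value. Fits are ordinary least squares (statsmodels).

## Enrichment and the gene–gene network

Over-representation of a query list in a gene set uses the one-sided Fisher
exact test: p = P(X ≥ k) for X hypergeometric(N, K, n), where N is the
background size, K the set size within the background, n the query size and
k the overlap. The background defaults to the union of all collection
members plus the query — the least presumptuous universe when none is given
— and is configurable. BH step-up q-values are computed across the
collection. The gene–gene interaction network connects two query genes when
they co-occur in the overlap of at least one set passing the threshold
(default p < 0.001, applicable to q instead via config); the edge weight
counts such shared sets. Edges are emitted in canonical sorted order, so the
network is independent of input permutation. GO-DAG ancestry propagation is
out of scope; sets are taken as flat member lists.

## Relation-network assembly

Relation tables carry directed, signed regulation edges with reference
counts. Unsigned relations are discarded first. Two signed maps are built —
entities the upstream disease regulates, and entities regulating the
downstream disease — with entities matched case-insensitively after
whitespace normalisation, since curated tables mix naming conventions.
Conflicting signs for one entity are an error by default; a
majority-by-reference-count resolution is available behind a flag, with
exact ties still erroring. The intersection of the two maps yields one
verdict per shared entity: it favors the downstream disease exactly when
the sign product is +1 (activating an activator, or deactivating an
inhibitor), otherwise it opposes it. The same sign-product rule classifies
expression evidence, using the sign of a gene's combined LFC as the
upstream sign; a zero LFC has no direction and raises.

## Synthetic data

The generator mirrors the combination model's assumptions: study-level
effects θ_gi = LFC_g + δ_gi with δ_gi ~ N(0, τ²), and per-sample log2
expression N(baseline + group·θ_gi, σ²). Defaults: the nine-study design of
the published case/control catalog (its sample sizes 5/12 … 5/24, countries,
study ages and platform labels), a 203-gene panel, baseline 8.0 and
per-sample noise SD σ = 1.0 — a realistic magnitude for log2 microarray
intensities. When more studies are requested than the catalog holds,
countries cycle through a fixed four-country list and sample sizes default
to 10+10. Study-level covariates can shift θ_gi linearly to plant
covariate signal. Relation and gene-set generators plant a known regulator
overlap (default 18 entities, 15 favoring) and known enriched sets, and
return the truth for verification.

What the generator does **not** emulate: probe-level artifacts, platform
batch effects, non-normal heavy-tailed noise (available behind no flag —
out of scope), correlated genes, or compositional effects. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under its own assumptions, not robustness to real microarray
pathologies; preprocessing quality remains the caller's responsibility.

## Numerical and design choices

- Problem sizes: calibration and recovery checks run on 1000-gene panels
  with nine studies of 10+10 samples; model-selection curves use 400-gene
  panels per τ². These sizes put Monte-Carlo error comfortably inside the
  asserted bands while keeping runs to seconds.
- Under the stated conditions the DerSimonian–Laird 95% CI covers at ~0.93:
  slight undercoverage with k = 9 and estimated v_i is a known property of
  the normal-quantile DL interval, and sits inside the asserted
  [0.92, 0.97] band.
- With τ² = 0 the Q > df event has probability just under one half, so the
  random model is selected for roughly half the null genes; the switch is a
  selection rule, not a test at a conventional level.
- Hypergeometric p-values are computed via the survival function at k − 1;
  they are exactly 1 for k = 0 and are clipped into [0, 1] against rounding.
- Tie-breaks everywhere are lexicographic (probe ids, gene ids, set ids,
  edge order) so every table and network is deterministic under input
  permutation and re-runs are byte-identical.
- The pipeline writes a manifest (package version, full config, stage
  outputs) next to its tables; rerunning the same config reproduces the
  tables exactly.

## Known limitations

- The combination is two-stage (per-study effects, then weighting); a
  one-stage pooled mixed model over all samples is out of scope.
- No moderated/shrunken variance estimation; with very small groups the
  per-study variances are noisy and the DL interval undercovers slightly.
- The catalog inclusion filter matches canonical metadata strings; it does
  not query any external repository.
- Enrichment treats gene sets as flat lists and the relation network treats
  entities as opaque identifiers; no ontology semantics are applied.
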