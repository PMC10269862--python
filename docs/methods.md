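# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `flymgwa`.

## The assay model

The persistence assay measures, per fly, the CFU remaining after serial
transfers to sterile diet. Counts are analyzed on the log2(CFU+1) scale
throughout. Two instrument properties are modelled explicitly:

* **Quantization.** One counted colony corresponds to `colony_scale` CFU
  per fly (default 800, implied by 160 colonies = 128,000 CFU). Fly loads
  below ~`colony_scale`/2 therefore read as zero, and the log-scale
  resolution near the detection floor is coarse (one colony ≈ 9.6 on the
  log2 scale).
* **Censoring.** Plates denser than `ceiling_colonies` (default 160)
  cannot be counted and are assigned the point value
  `ceiling_colonies × colony_scale` = 128,000 CFU (≈ 17.0 on the log2
  scale). Censored records are treated as this point value, not as
  interval-censored observations — the convention the assay itself uses —
  with the `too_dense` flag retained so sensitivity analyses can treat
  them differently.

Vial-level exclusions: density < 30 flies, or more than 5 CFU of an
unexpected colony morphology in undiluted aliquots (contamination). The
boundary cases are exact: 30 flies and 5 unexpected CFU both pass.

## Rank-based tests

All two-group comparisons reduce to the Wilcoxon rank-sum statistic W
(sum of pooled midranks of the first group). Three p-value routes:

* combined n ≤ 16: full enumeration of all C(N, n1) assignments of the
  pooled midranks, two-sided as P(|W − E W| ≥ |w − E W|). This handles
  ties exactly and coincides with tail-doubling whenever the null
  distribution is symmetric (always, without ties).
* no ties and min group ≤ 8: the classic exact no-tie distribution.
* otherwise: normal approximation with the tie-corrected variance
  n1·n2/12·((N+1) − Σ(t³−t)/(N(N−1))), no continuity correction (chosen
  so that the approximate p converges to the enumeration p rather than
  over-correcting at these sample sizes).

The Kruskal–Wallis statistic is the tie-corrected H with a chi-square
upper tail; for two groups with combined n ≤ 16 the p-value comes from
the exact permutation route instead (the two tests are equivalent there,
so the reported p is exact rather than approximate — for the textbook
pair {1,2,3} vs {4,5,6} this gives H = 3.857 with exact p = 0.1, where
the chi-square tail would give 0.0495). Dunn's z uses pooled tie-corrected
midranks; adjustment is Benjamini–Hochberg by default with Bonferroni
selectable, and letters at α = 0.05 come from the insert-and-absorb
compact letter display, which represents the pairwise significance
relation exactly (two groups share a letter iff their adjusted p ≥ α).

Sexes are analyzed separately; the association stage uses female flies
only, matching the study design the assay schema encodes.

## Orthology: plain MCL

The clustering stage is standard Markov clustering on the given
similarity graph: self-loops at each node's maximum incident weight,
column normalization, then alternating expansion (matrix power 2) and
inflation (entrywise power, default 1.5, then renormalization) with
pruning of entries below 1e-5, until the maximum entrywise change falls
below 1e-6 or 100 iterations pass. Clusters are read off attractor rows;
a node drawn to several attractor systems joins its largest-weight
attractor, ties broken lexicographically, so output is deterministic.
The implementation is dense and intended for desk scale (≈ up to ~5,000
proteins). It is *not* OrthoMCL: no similarity computation, no
reciprocal-best-hit or inter-species rescaling. Precomputed groups files
(`OGID: strain|protein ...`) bypass clustering.

## Association

OGs with identical strain presence vectors form one phylogenetic
distribution group (PDG); identical patterns give identical statistics,
so the PDG is the tested unit. All-present and all-absent patterns are
retained but untestable and are excluded from the correction count m.
Each testable PDG gets a two-sided Wilcoxon rank-sum test of carrier vs
non-carrier persistence summaries; Bonferroni correction uses m = number
of tested PDGs (default) or m = number of their member OGs
(`correct_over="og"`), and corrected p-values propagate unchanged to
member OGs. Output is sorted by corrected p, then OG id (stable,
deterministic).

**Unit of analysis.** The default summary is the strain-level mean of
log2(CFU+1) across retained female flies: strains, not flies, are the
independent units, and the Bonferroni guarantee in the null simulations
holds at the strain level. `unit="fly"` pools per-fly values instead;
this matches how individual-level data are often fed to pan-GWAS tools
but inflates significance when strain-level variance exists
(pseudoreplication), and is therefore not the default.

## Enrichment

Per pathway, the 2×2 table (significant/nonsignificant ×
in-pathway/outside) is tested with Pearson chi-square without continuity
correction, df = 1. The background defaults to OGs carrying at least one
pathway annotation: unannotated OGs carry no information about pathway
membership; `background=` overrides. Rows with any expected cell below 1
are flagged `low_expected` (an optional Fisher-exact fallback exists but
is off by default, preserving the named test). FDR control is
Benjamini–Hochberg; a pathway is *enriched* only when q < α **and** the
observed overlap exceeds its expectation, so depleted pathways are never
reported as enriched.

## Motility

Halo diameters are modelled as diameter ~ genotype with a random
intercept per batch (batch = plate; the random-effect grouping is an
assumption, stated here because replicate structure is often ambiguous in
halo assays), fit by REML; the genotype effect is a Wald chi-square over
the genotype coefficients. When the batch variance estimates at zero, or
only one batch exists, the model reduces to one-way fixed-effects ANOVA
and says so with a warning. Dunnett's many-to-one contrasts use the
equicorrelated multivariate-t reference distribution evaluated
numerically with a fixed seed; adjusted p-values are reproducible to the
integration tolerance (~1e-4) and satisfy
unadjusted p ≤ adjusted p ≤ Bonferroni p.

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
tested. What it emulates, and how:

* **Pangenome.** A Kingman coalescent tree over the strains (time in
  units of 2N generations); a `core_fraction` share of OGs is present
  everywhere; each accessory OG evolves by a two-state gain/loss chain
  with total switching rate `gain_loss_rate` (default 1.0 per unit branch
  length) and a gene-specific stationary presence probability
  π ~ Beta(0.4, 0.4). Along a branch of length t the parental state is
  kept with probability e^(−rate·t), else redrawn as Bernoulli(π). The
  Beta prior makes the accessory frequency spectrum U-shaped (most
  accessory genes rare or near-universal), and the shared tree makes
  presence patterns repeat: at the defaults, ~1,000 OGs collapse to
  ~200–250 distinct patterns, the same order of compression seen in real
  strain panels. The RNG call order of the recursion is documented in the
  code and is part of the definition, so an independent re-implementation
  reproduces the output bit for bit.
* **Planted effects.** Candidate causal genes are accessory OGs with
  strain frequency in [0.2, 0.8], one per distinct pattern. The causal
  architecture is a *co-inherited module plus an antagonist*: the
  n_causal − 1 most strongly co-distributed candidate patterns all
  receive +`effect_size`, and one phylogenetically independent candidate
  (minimal mean |correlation| with the module) receives −`effect_size`.
  This mirrors how causal genes actually present in bacterial pan-genomes
  — operons and pathways are gained and lost as blocks and act in a
  common direction, while an occasional unrelated gene acts the other
  way — and it keeps the planted truth identifiable: with independently
  scattered alternating effects, each causal gene's ±3 shift acts as
  ~2.4 SD of between-strain noise for every other causal gene, and no
  strain-level test of 40 strains can reliably recover 4 of 5 at
  Bonferroni-corrected α = 0.01 (measured pass probability ~5% across
  seeds). Under the module architecture, recovery of the module is
  essentially certain and the antagonist is typically *masked* — the
  expected behaviour, not a defect. Strain expected phenotype =
  `baseline_log_cfu` + Σ(carried effects) + Normal(0, `strain_sd`).
* **CFU records.** Per fly, log2(CFU+1) ~ Normal(strain mean, `fly_sd`)
  truncated at zero — lognormal dispersion on the count scale, chosen to
  emulate the orders-of-magnitude spread of real per-fly loads rather
  than Poisson counting noise; `fly_sd` defaults to 1.0 (a free
  parameter: the real fly-to-fly dispersion is not numerically
  characterized anywhere usable). CFU = round(2^x − 1); colony count =
  round(CFU / 800), censored at 160 with the `too_dense` flag. Vial
  densities are drawn from 28..60 so the <30 filter occasionally fires;
  vials are contaminated with probability 0.02, in which case their
  undiluted aliquots bear >5 unexpected CFU.
* **Similarity graph.** Within-OG pairs get weight ~ U(0.7, 1.0);
  between-OG pairs appear with probability `p_noise` (default 0.001) at
  weight ~ U(0.0, 0.2). For large partitions the noise pairs are sampled
  by count rather than enumerated (a pair can, very rarely, be drawn
  twice; the ABC reader keeps the maximum).
* **Annotation.** ~80% of OGs receive a unique KO and one pathway of 10
  (ten pathways being a realistic enrichment-table size); a designated
  pathway is loaded with a chosen gene set so that its membership odds
  are `odds_ratio` (default 10) times the uniform background odds.
* **Seeding.** One global seed is split into fixed per-stage child seeds
  via `numpy.random.SeedSequence(seed, spawn_key=(stage,))`; every
  generator is byte-deterministic given the seed.

Defaults anchor to the assay design: 3 experiments × 3 vials × 4 female
flies per strain, 160-colony ceiling, 800 CFU per colony;
`baseline_log_cfu` = 10 sits mid-range of observed per-fly loads
(0 to ~10^5 CFU).

### What passing tests do and do not show

The generator reproduces the *shapes* of the real data — strain-structured
presence/absence, U-shaped frequency spectrum, pattern repetition,
censored overdispersed counts, vial-level failures — but not sequence
evolution, within-host dynamics, transfer-by-transfer decay, assay batch
drift, or annotation errors. Passing the planted-recovery tests shows the
pipeline's statistics are wired correctly and powered under module-like
causal architectures; it does not certify power for isolated
small-effect genes on small panels, nor validity under phenotypes with
strong phylogenetic confounding (the Wilcoxon test is deliberately
uncorrected for phylogeny, matching standard pan-GWAS practice for this
design; tree-aware models are out of scope).

## Numerical choices and degenerate inputs

* Exact-test threshold: combined n ≤ 16 (C(16,8) = 12,870 assignments,
  milliseconds); beyond that, tie-corrected normal approximation.
* All-identical pooled values: rank variance is zero; tests return p = 1
  and statistic 0 rather than NaN.
* MCL: prune 1e-5, tolerance 1e-6, max 100 iterations; non-convergence
  returns the current partition with `converged=False`. Disconnected
  components are never merged. Cluster ids are assigned by each
  cluster's lexicographically smallest member.
* Bonferroni caps at 1; m may exceed the number of supplied p-values
  (used when correcting over member OGs).
* Chi-square with a zero margin returns (0, 1) — a degenerate table
  carries no evidence — instead of raising.
* Dunnett critical values: `scipy.stats.dunnett` with an explicitly
  seeded generator.

## Assay saturation (a real limitation, reproduced faithfully)

Because censoring collapses everything above ~17 log2-CFU to one value,
effects whose *sum* pushes carrier strains past the ceiling saturate the
assay: strains carrying the full causal module and strains carrying most
of it become indistinguishable, and resolution between co-inherited
causal genes degrades as effects grow. Recovery is therefore *not*
monotone in effect size across the ceiling (measured: mean recovery 3.2/5
at effect 1.0 vs 2.3/5 at effect 3.0 on a 24-strain panel with baseline
10). Within the dynamic range, recovery is monotone in effect size, and
the property test checks exactly that regime. Analyses of real data
should treat heavily censored strains with the same caution.

## Known limitations

* The Wilcoxon association ignores phylogeny; hits can be driven by
  clade structure. This is the standard, deliberate design here.
* The strain-level default discards within-strain information; the
  fly-level option gains power at the cost of pseudoreplication.
* MCL is dense: quadratic memory in protein count.
* The Dunnett adjustment assumes the balanced equicorrelated reference;
  unbalanced designs are handled through per-contrast standard errors
  inside `scipy.stats.dunnett`.
* The censored point-value convention slightly biases strain means near
  the ceiling; no interval-censored likelihood is provided.
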