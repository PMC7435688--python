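# Methods

This note documents the models, numerical choices, and limitations behind
`sterolscreen`, in the spirit of a statistical-software methods appendix.

## Sequence identity and clustering

Pairwise identity is defined in the CD-HIT convention: the number of
identical aligned residues divided by the length of the **shorter**
sequence, on a global alignment with match +1, mismatch 0, and affine gaps
(open 10, extend 1; end gaps penalized). A tiny match bonus (1 + 1e-6)
breaks score ties toward the alignment with the most identities, which makes
the reported identity well defined among co-optimal alignments and lets an
independent DP oracle (lexicographic maximization of score, then matches)
reproduce it exactly. Coverage of the shorter sequence is the fraction of
its residues aligned opposite residues rather than gaps.

Greedy clustering mirrors CD-HIT semantics: sequences sorted longest-first
(ties broken lexicographically by id, so the order is deterministic), each
sequence joining the **first** representative it matches rather than the
best-scoring one, otherwise founding a new cluster. Thresholds are inclusive
(`>=`) for the nucleotide catalog stage (95% identity / 90% coverage) and
strict (`>`) for the protein stage, matching the ">50% aa identity" wording
of the protein-cluster definition. The protein stage also requires 50%
coverage of the shorter sequence; no coverage is prescribed for that stage
in the source description, so the nucleotide convention is mirrored and the
value is configurable.

Instead of a k-mer prefilter, hopeless pairs are skipped using a provably
safe bound: a second alignment pass with near-zero gap penalties (ε = 0.01)
upper-bounds the achievable match count for *any* gap placement
(M\* ≤ score_ε + ε·(len a + len b)), because no k-mer criterion can
guarantee never to skip a passing pair at a 50% identity threshold (a
passing pair whose matches alternate with mismatches shares no k-mer for
k ≥ 2). Pairs whose bound falls below the threshold cannot pass and are
skipped; all others get the full affine-gap alignment.

Query mapping (`screen.map_queries`) instead uses **local**
(Smith–Waterman, BLOSUM62, gap open 11 / extend 1) alignment, mimicking the
ublast-style search used for isolate-proteome and enzyme queries: identity
is measured over alignment columns and coverage as the aligned span of the
query over its length. As in any heuristic homology search, alignments below
a minimal raw score (default 75) are not reported; hits at the laxest
cutoffs used here (25% identity over at least half a query) score several
times higher, while unrelated protein pairs stay well below.

## TPM, detection, and screening

TPM divides each gene's count by its length, then scales each sample to one
million; an all-zero sample yields an all-zero column rather than a division
error, and TPM = 0 exactly when the count is 0. A cluster is detected in a
sample when any member gene has TPM > 0. Screening computes per-cluster
confusion counts against the binary metabolite call on the paired-sample
intersection only (samples missing either data type are excluded); ratios
with zero denominators are reported as missing, never as 0. Clusters below
1% detection prevalence are dropped before scoring output, and the candidate
filter applies *strict* inequalities (>0.3 sensitivity, >0.9 specificity), so
a cluster at exactly 0.3 is rejected. Prioritization tiers are purely
definitional — tier 1 requires both an isolate-proteome hit and an enzyme
hit, tier 2 exactly one, tier 3 neither — because the original selection
logic is not fully explicit about which combination was required; the tier
system exposes all combinations instead of guessing.

## Association statistics

The Woolf odds-ratio interval is exp(log OR ± z·√(1/a+1/b+1/c+1/d)); any
zero cell triggers the Haldane–Anscombe +0.5 correction to all four cells
(flagged in the result). Because the estimator behind published
odds-ratio intervals of this kind is often unstated and printed intervals
can be asymmetric, a conditional Fisher-exact interval is exposed as an
alternative method, with the method name carried in the result. A 2×2 with
an empty margin has no defined odds ratio and raises.

Metabolite abundances are transformed as z-scores of log₁₀ values with a
1e-5 pseudo-count substituted for zeros, using the sample (n−1) standard
deviation, computed within cohort. Linear models are OLS; logistic models
are maximum likelihood with complete separation reported as an error.
Repeated-measures cohorts use a random-intercept linear model fitted by
maximum likelihood (not REML, so the τ² = 0 boundary reduces exactly to
OLS; the implementation checks the OLS likelihood explicitly and returns
the boundary solution when it is at least as high). Fixed-effect tests are
normal-approximation Wald tests throughout — a deliberate simplification of
Satterthwaite degrees of freedom, acceptable at the group counts involved. A
logistic mixed model is not implemented; for dichotomous outcomes with
repeated measures the options are subject-level aggregation or the plain
logistic model, a documented limitation. Categorical covariates are
dummy-coded with the alphabetically first level as reference.

## Meta-analysis and lipid derivations

Random-effects pooling is DerSimonian–Laird: fixed inverse-variance weights
give Cochran's Q; τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)); random weights
1/(se²+τ²) give the pooled estimate and its normal CI;
I² = max(0, (Q−(k−1))/Q)·100. The DL moment estimator is the historic
default of the standard meta-analysis packages this mirrors; a REML variant
is intentionally not the default. With k = 1 the pooled result reduces to
the single study. LDL is derived by Friedewald (divisor 2.2 in mmol/L,
divisor 5 available for mg/dL), invalid above TG = 4.5 mmol/L (error) and
flagged, not clipped, when negative. GWAS effects in SD units are converted
to mmol/L by multiplying with the cohort lipid SD and reporting three
decimals, the convention for per-allele lipid effects.

## The synthetic-study generator

The generator exists to give every pipeline stage a planted ground truth
with the statistical structure the analysis assumes. Defaults are the study
conditions used throughout the tests and the acceptance experiments:

| parameter | default | rationale |
|---|---|---|
| samples | 200 | order of a single paired cohort |
| species / encoder clade | 30 / 4 | small community, minority clade |
| genes per species | 6 | enough for catalog structure at tractable all-pairs alignment cost |
| planted identity range | 0.55–0.90 to the root | the documented family spans ~50–95% pairwise identity |
| encoder per-species prevalence | 0.14 | clade prevalence ≈ 45%, inside the 37–92% span observed across cohorts |
| background species prevalence | 0.6 | common commensals |
| abundances | log-normal(0, 1), clade scaled to 1.4% mean share | reported clade mean relative abundance |
| depth | 2×10⁵ counts/sample | detection of present clade members near-certain, as with stringent read mapping |
| δ (coprostanol call | encoder present) | 0.95 | strong but imperfect coupling |
| ε (background positive rate) | 0.02 | coprostanol-positive samples without detected encoders exist; ε models this agnostic of mechanism (detection limits vs unknown distant homologs) |
| cholesterol reduction / cholestenone fold in encoder samples | 0.25–0.45× / 3.3–5.4× | the reported 75%/55% reductions and 5.4/3.3-fold increases |
| TC effect | −0.15 mmol/L, noise SD 0.9 | the pooled serum effect and a realistic TC dispersion |
| covariates | age ~ N(50, 12), sex Bern(0.5), antibiotics Bern(0.1), statin Bern(0.15), statin effect −1.2 mmol/L | documented, configurable defaults |

The planted family diverges along a **shared path**: one random site-order
permutation and one replacement residue per site are drawn for the family,
and a variant with target identity t mutates the first round((1−t)·L) sites
in that order. Two variants then differ only at sites mutated in exactly one
of them, so every within-family identity is at least 1−(hi−lo) ≈ 0.65 and
the family provably forms a single cluster at the >50% threshold — a
deliberate idealization (descent along a single lineage) rather than
independent divergence, under which distant variants could fall below the
threshold and split the cluster. A small fraction (2%) of divergence events
are rendered as single-residue indels rather than substitutions; tying
indels to the divergence budget (instead of a flat per-site rate) keeps a
target identity of 1.0 an exact copy. Realized identities track targets
within ±0.03 under the alignment oracle.

Counts are Poisson with expectation depth × species share × gene-length
fraction (no overdispersion by default). The encoder clade's abundance scale
factor is calibrated in first order — solving p = f·E_enc/(f·E_enc + E_bg)
for f with prevalence-weighted expected present-species counts — which lands
the empirical mean share within roughly ±0.15 percentage points of the 1.4%
target at n = 1000 (the Jensen-type bias of the ratio is second order). One stool sample per participant is the default; a
repeated-measures mode assigns k consecutive samples per participant for the
mixed-model stage. A single RNG stream per study makes bundles byte-identical
given config + seed.

What the generator does **not** emulate: read-level sequencing artifacts,
assembly fragmentation, phylogenetically realistic substitution processes,
strain-level variation, compositional correlations between species, or
covariate–microbiome confounding. Passing tests therefore demonstrate that
the statistical machinery recovers planted truth under the assumed
generative structure — not that the pipeline is robust to real-data
pathologies upstream of it.

## Scale of the verification experiments

The replicated experiments run 20 discovery studies (planted-family
recovery), 100 odds-ratio replicates at n = 300 with a true OR of 40, and
100 three-cohort meta-analysis replicates at n = 623/292/384 — sizes chosen
so the full suite and the acceptance script each complete in minutes on a
single CPU while leaving the Monte-Carlo acceptance margins wide (observed:
20/20 recovery, ≈95% interval coverage, pooled estimate within 0.01 of the
planted −0.15 mmol/L, median I² = 0).

## Known limitations

- The headline cohort-scale numbers (the 0.92/0.68 cluster, the 42.73 and
  28.94 odds ratios, the pooled −0.15 [−0.27, −0.03]) require the original
  cohort data and supplementary per-study tables, which are not distributed
  here; the package verifies the *machinery* by planted-truth recovery at
  matched designs instead.
- Greedy first-fit clustering is order-dependent by design (CD-HIT
  semantics); a best-fit mode would change borderline assignments.
- The local-search score floor (75) is a heuristic gate: vanishingly weak
  homologies below it are not reported, consistent with heuristic search
  tools but not with exhaustive Smith–Waterman.
- No forest-plot rendering, E-value statistics, HMM search, or species-level
  abundance binning; those are out of scope.
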