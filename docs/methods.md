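# Methods

## Statistical model and conventions

All methylation–response, methylation–expression and copy-number
associations are Spearman rank correlations; expression–response
associations are Pearson correlations on log₂ expression versus log₁₀
IC50.  Both use the same two-sided p-value:

    t = r * sqrt((n - 2) / (1 - r^2)),   p = 2 * P(T_{n-2} > |t|),

with average ranks for ties.  This t approximation is the single supported
p-value method: it reproduces the published (ρ, n = 66) → p operating
points to the precision their rounded inputs allow, and it makes every
reported record self-consistent — re-evaluating the convention on a
record's (coefficient, n_used) returns its p_O exactly.  Perfect
correlations are floored at the smallest representable positive double
rather than 0, keeping −log₁₀(p) finite.  Missing data are handled by
pairwise-complete deletion; `n_used` is recorded on every result, and
results on fewer than 3 complete pairs or with a constant rank vector are
*undefined*: they are logged and excluded from FDR families, never coerced
to a number.

Known bias: the t approximation is anti-conservative in its deep tail.  At
n = 66 the exact permutation null puts ≈1.4× more mass below p ≈ 10⁻⁴ than
the approximation claims (measured by Monte-Carlo over rank permutations;
at p ≈ 10⁻³ the factor is ≈1.08).  Consequences are quantified under
*Calibration* below.

### Multiple-testing families

Three regimes, mirroring how array-scale pharmaco-epigenomic screens report
results:

1. **Epigenome-wide probes** — fixed thresholds only: strict
   p < 9.42×10⁻⁸ (genome-wide significance for a single EPIC probe) and
   liberal p < 5×10⁻⁷.  No probe-level FDR.  At n = 66 these correspond to
   |ρ| > 0.6012 and |ρ| > 0.5729 (`critical_rho`, bisection to 10⁻⁶).
2. **Epigenome-wide regions** — one BH family over *all* region × agent
   tests, with tier flags at p_FDR < 0.05 / 0.10 / 0.15.
3. **Candidate analysis** — two further BH families (candidate probes ×
   candidate agents, candidate regions × candidate agents), adjusted
   separately from each other and from the epigenome-wide family.

BH adjustment is the standard step-up estimator (delegated to statsmodels,
verified elementwise against a brute-force implementation of the
definition).  Undefined tests are removed before adjustment, so family
sizes count only defined tests.

### Region aggregation

Each probe may carry several (gene, region-class) annotations, parsed
positionally from the manifest's paired semicolon lists.  A region value is
the unweighted arithmetic mean of non-missing member-probe betas, computed
after QC (masked cells and dropped probes never contribute); the six region
classes are never pooled with each other.  There is no minimum probe count
per region — single-probe regions are legitimate and reproduce their
probe's correlation exactly — but `probes_per_region` is reported so users
can filter.  Regions whose probes were all removed by QC are omitted and
logged.

### Quality control

Two filters with boundary-inclusive thresholds (exclusion at equality):
cells with detection p ≥ 10⁻³ are masked to missing; probes with median
detection p ≥ 10⁻⁶ across all samples, or carrying the SNP-overlap mask
flag, are dropped.  The median uses all detection p-values (detection p is
never missing), which makes the two steps commute and the whole chain
idempotent.  The QC report reconciles exactly: retained + dropped = input
probes.

### Drug response

Replicate IC50s (molar) are log₁₀-transformed, then the median is taken per
(agent, cell line).  Agents with fewer than 2 distinct non-missing values
(configurable) are excluded as non-variable, with a reason logged per
agent.  Spearman results are invariant to the log base; the Pearson
expression–response coefficient is too (scale change only).

### Integration and lineage

For each association record, the best-matching transcript is the one (among
transcripts sharing the gene symbol) with the smallest methylation–
expression Spearman p over the qualifying probes; ties break on |ρ|, then
lexicographic id, making outputs deterministic.  The regulatory-pattern
classifier labels a (meth–drug, meth–expr, expr–drug) triple
`canonical_repression` when methylation significantly represses expression
and expression associates with response opposite in sign to methylation;
`expression_coupled_positive` when methylation and expression couple
positively with same-sign response associations; `undetermined` when any
leg has p ≥ 0.05 or |coefficient| < 0.3 (both configurable; defaults chosen
so textbook repression magnitudes, e.g. meth–expr ρ ≈ −0.84 with
expr–drug r ≈ +0.5, classify correctly); anything else is `inconsistent`.
The copy-number screen flags a gene `cn_unexplained` when copy number
correlates with none of methylation, expression or response beyond
|ρ| = 0.2.

Lineage structure is UPGMA (average-linkage) clustering of samples on
Euclidean distances over log₂ expression of the six lineage markers ASCL1,
ASCL2, NEUROD1, INSM1, YAP1, POU2F3 (scipy's linkage; heights verified
against a hand-computed four-point dendrogram).  When a marker gene has
several transcripts the highest-variance one is used.  The cluster count at
cut time is a user parameter, default k = 2.

## Synthetic data

The generator emulates the structure of a 66-line SCLC pharmaco-epigenomic
screen so that every stage is testable at desk scale without any external
download.  Defaults: 66 samples, 200 genes × 18 probes over the six region
classes + 150 intergenic probes (≈3,750 probes), 30 agents × 3 IC50
replicates, 2 constant (non-variable) agents, detection-failure rate 0.002,
SNP-flag rate 0.02, 15 whole-probe failures, 5% of null-gene probes
multi-assigned to a second gene/region.

Beta-values are logit-normal: each (gene, region) has a per-sample latent
on the logit scale (baseline spread sd 1.2 across regions, unit per-sample
variance); member probes add a probe offset (sd 0.4) and measurement noise
(sd 0.15) before the logistic map, which keeps support in [0, 1] with
realistic intermediate methylation and needs no clipping.

Planted archetypes (12 canonical-repressive, 6 positive-coupled, 6
copy-number-driven, 6 lineage-linked, rest null):

* **canonical_repressive** — the TSS200 latent represses the gene's primary
  transcript (Gaussian coupling equivalent to Spearman ρ ≈ −0.9), and the
  transcript drives the target agent's log(IC50) such that the *net*
  methylation→response coupling hits the target Spearman |ρ| = 0.75
  (couplings convert via r = 2·sin(πρ/6)).  The causal chain
  methylation → expression → response is therefore recoverable end to end.
* **positive_coupled** — gene-body latent and expression share a factor
  (ρ ≈ +0.8); response couples to the latent directly at the target
  strength, same sign as methylation.
* **cn_driven** — a binary copy-number gain (30% of samples) enters the
  body-methylation latent and expression jointly (weight 0.7); the
  copy-number table reports 0.8·gain + noise for a 33-sample subset.
* **lineage_linked** — two sample clusters (60/40) separated by 3 log₂
  units in the six marker expressions, with promoter-methylation offsets
  (1.5 logit units) on the silenced side.

Each planted gene targets a distinct variable agent.  Replicate IC50s add
log₁₀ noise (sd 0.1); constant agents are exactly constant so the
variability filter's truth is crisp.  QC truth is deterministic by
construction: planted cell failures draw detection p in [10⁻³, 1) (always
masked), planted bad probes draw all cells in [10⁻⁴, 10⁻³·¹] (always
dropped by the median rule, never cell-masked), all other probes stay below
10⁻⁸ (never touched).  Bad/SNP probes and multi-assigned probes are drawn
from null genes only, so planted (region, agent) truth labels are
unambiguous.  One seeded generator drives everything; identical
configuration gives byte-identical bundles.

What the generator does *not* emulate: Illumina type-I/II probe chemistry,
chromosomal autocorrelation of methylation, correlated drug-response
profiles across mechanistically related agents, batch structure.  Passing
recovery tests therefore demonstrates the pipeline's statistical
correctness under clean planted signal, not performance on real arrays.

## Calibration and recovery

Measured on the default bundle (sizes above; region family ≈ 1,200 regions
× 28 variable agents ≈ 33,500 tests/seed, pooled over 20 seeds):

* planted region effects at target |ρ| = 0.75 are recovered with TPR = 1.0
  at p_FDR < 0.1 (the realized feature-level correlation, after probe
  noise, region averaging and replicate noise, is ≈0.73 — far above the BH
  operating point of |ρ| ≈ 0.47);
* the empirical false-discovery proportion among those calls is ≈0.12–0.16
  depending on the seed batch, i.e. above the nominal q = 0.1.  This excess
  is exactly the t-approximation's deep-tail anti-conservatism: the null
  false-positive rate of a rank test is distribution-free, so the ≈1.4×
  tail inflation at the BH threshold (p ≈ 10⁻⁴) multiplies the nominal
  FDR regardless of any generator setting.  Expected FDP ≈ 0.145; batches
  of 20 seeds fluctuate around that value (observed 0.121–0.156 across
  four independent batches).  Users needing tighter FDR control at these
  depths should lower q rather than trust the nominal level;
* all-null bundles (no planted effects) average < 1 region call per run at
  p_FDR < 0.05;
* constant agents, masked cells and dropped probes match planted truth
  exactly.

Problem sizes were chosen so the full suite and the acceptance script each
run in minutes on a single CPU; the statistical conclusions above are
insensitive to the exact counts (the FDP analysis in particular is
scale-free).

## Numerical choices and edge cases

* p-values floored at the smallest positive double; coefficients within
  10⁻¹² of ±1 snapped to ±1 (rank vectors that are exactly monotone must
  give exactly ±1 despite floating-point dot products).
* `critical_rho` bisects the strictly monotone p(ρ) map to 10⁻⁶.
* Vectorised association passes rank complete feature rows once per
  response-missingness pattern and fall back to pairwise-complete scalar
  computation for rows with missing cells; both paths share the identical
  p-value code.
* Deterministic tie-breaks everywhere results are ordered: records sort by
  (p_O, feature id, agent); best-probe/transcript selection by
  (p, −|coefficient|, id).
* Manifest entries with unpaired gene/region lists, blank region classes,
  or out-of-vocabulary region classes are rejected with the probe named —
  never guessed.
* The pipeline exits 2 on validation errors and 3 when every test in a
  required stage is undefined; outputs embed threshold provenance as `#`
  header lines and the run manifest records SHA-256 hashes of every file.

## Limitations

Raw-IDAT normalisation, batch correction, dose-response curve fitting and
plate-level QC are upstream of this package's inputs.  Probe-level FDR for
the epigenome-wide pass is intentionally absent (fixed thresholds mirror
the published two-tier convention).  The t-approximation's tail bias is
documented rather than corrected; an exact or Edgeworth-corrected p-value
would change the published operating points and is out of scope.
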