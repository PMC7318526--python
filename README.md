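# methylpharm

Epigenome-wide association of DNA methylation with drug response in cancer
cell-line panels.

Small cell lung cancer (SCLC) cell lines — and cancer cell-line screens in
general — pair genome-wide Illumina EPIC methylation-array profiles
(beta-values β ∈ [0, 1] per CpG probe) with in-vitro drug-response measures
(IC50 across hundreds of agents).  `methylpharm` implements the analysis
that connects the two: probe-level quality control, gene-region averaging
over the six EPIC region classes (TSS1500, TSS200, 5′UTR, first exon, gene
body, 3′UTR), Spearman correlation of methylation with log(IC50) under
three distinct multiple-testing regimes, and downstream integration with
transcript expression, copy number and SCLC lineage-marker clustering.  It
is written for computational biologists running pharmaco-epigenomic screens
who need the statistical conventions of the published analyses to be exact
and testable.

## The statistics at the core

Every association is a correlation with a two-sided p-value from the
t approximation

&nbsp;&nbsp;&nbsp;&nbsp;*t* = ρ·√((n−2)/(1−ρ²)),&nbsp;&nbsp; df = n−2,

with average ranks for ties and pairwise-complete deletion of missing
values.  Probe-level epigenome-wide results are judged against fixed
thresholds (strict p < 9.42×10⁻⁸ for a single EPIC probe; liberal
p < 5×10⁻⁷), while region-level results receive Benjamini–Hochberg FDR
adjustment over the single family of all region × agent tests.  A focused
candidate-gene analysis runs two further, fully independent BH families
(candidate probes × candidate agents; candidate regions × candidate
agents).  Drug response enters as the median of log₁₀ IC50 over replicates,
restricted to agents whose response varies across lines.  Positive ρ means
higher methylation accompanies higher log(IC50), i.e. resistance.

A synthetic-data generator produces complete input bundles (beta +
detection-p matrices, EPIC-style manifest, replicate IC50 table, expression
matrix with transcript→gene map, copy-number matrix) with planted gene
archetypes — promoter-repressed drivers of sensitivity, positively
expression-coupled genes, copy-number-driven genes, lineage-linked markers —
so the whole pipeline is validated end to end against known truth.

## Worked example

```python
from methylpharm import (SimulationConfig, simulate_dataset, run_probe_qc,
                         build_region_index, average_region_betas,
                         median_log_ic50, filter_variable_agents,
                         epigenome_wide_analysis, evaluate_recovery,
                         spearman_p_from_rho, critical_rho)

ds = simulate_dataset(SimulationConfig(seed=7))
b = ds.bundle
beta, qc = run_probe_qc(b.beta, b.detection_p, b.manifest)
index = build_region_index(b.manifest, beta.index)
regions, n_probes = average_region_betas(beta, index)
response = median_log_ic50(b.drug_replicates)
variable, _ = filter_variable_agents(response)
probe_rec, region_rec = epigenome_wide_analysis(beta, regions,
                                                response.loc[variable])
```

printing the QC report, the top region associations and the recovery of the
planted effects gives:

```
QC: masked 510 cells; dropped 15 unreliable + 68 SNP probes; 3667 retained
aggregated 3667 probes into 1197 gene regions
28 of 30 agents show variable response
     feature_id  agent  coefficient      p_value        p_fdr
GENE0009|TSS200 AGT009    -0.832961 4.214449e-18 1.412515e-13
  GENE0022|Body AGT022     0.813047 1.117574e-16 1.872830e-12
  GENE0015|Body AGT015     0.800772 6.980787e-16 7.798936e-12
recovery at p_FDR<0.1: TPR=1.00, FDP=0.111 (27 calls, 24 planted)
```

The top hit is a planted promoter-methylation effect: TSS200 methylation of
GENE0009 anticorrelates (ρ = −0.83) with log(IC50) of its target agent —
higher promoter methylation, more sensitive line.  The convention checks
reproduce published operating points at n = 66 samples:

```python
spearman_p_from_rho(0.6927, 66)   # 1.16e-10
critical_rho(66, 9.42e-8)         # 0.6012  (strict hits all have |rho| > 0.6)
```

A command-line interface wraps the same stages
(`methylpharm simulate | qc | aggregate | run-all | report`); `run-all`
executes the full pipeline from a YAML path config and writes an artifact
manifest with SHA-256 hashes — two runs on identical inputs are
byte-identical.

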