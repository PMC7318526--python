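"""Synthetic methylation / expression / drug-response bundles with known truth.

The generator emulates the shape and statistical structure of a 66-cell-line
pharmaco-epigenomic screen: a probe x sample beta matrix on [0, 1] with a
paired detection-p matrix, an EPIC-style manifest with six region classes
per gene, a replicate IC50 table, a log2 transcript-expression matrix with a
transcript -> gene map, and a gene-level copy-number matrix for a sample
subset.

Beta-values arise from logit-normal latents: each (gene, region) has a
per-sample latent on the logit scale; member probes add a probe offset and
probe noise before the logistic map, which keeps support in [0, 1] with
realistic intermediate methylation.  Planted gene archetypes:

* ``canonical_repressive`` — promoter (TSS200) latent represses the primary
  transcript, and the transcript drives the target agent's log(IC50), so the
  methylation -> expression -> response chain is recoverable end to end;
* ``positive_coupled`` — gene-body latent and expression share a factor
  positively; response couples to the latent in the same direction;
* ``cn_driven`` — a copy-number gain in a sample subset raises gene-body
  methylation measure and expression jointly;
* ``lineage_linked`` — two sample clusters differ in the six lineage-marker
  expressions and in planted promoter-methylation offsets;
* ``null`` — no couplings.

Effect sizes are stated as target Spearman correlations and converted to the
Pearson couplings of the underlying Gaussian factors via
r = 2 sin(pi * rho / 6).  QC failures (cell-level detection failures,
whole-probe failures, SNP-mask flags) and non-variable agents are planted
with exact, deterministic truth labels.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    REGION_CLASSES,
    DatasetBundle,
    ProbeAnnotation,
    write_drug_replicates,
    write_manifest,
    write_matrix,
)
from .integration import LINEAGE_MARKERS
from .regions import RegionKey

__all__ = ["SimulationConfig", "SyntheticTruth", "SyntheticDataset",
           "simulate_manifest", "simulate_dataset", "evaluate_recovery",
           "write_bundle", "spearman_to_pearson"]

#: Driver region class per planted archetype (promoter for repression,
#: gene body for positive / copy-number coupling).
DRIVER_REGION = {"canonical_repressive": "TSS200",
                 "positive_coupled": "Body",
                 "cn_driven": "Body"}


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson coupling of a bivariate Gaussian with target Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic screen.

    Defaults mirror the scale of the emulated study: 66 cell lines,
    3 IC50 replicates per agent/line, ~4,000 probes over ~200 genes with
    the six region classes, 30 agents of which 2 are non-variable.
    """

    n_samples: int = 66
    n_genes: int = 200
    probes_per_region: dict = field(default_factory=lambda: {
        "TSS1500": 4, "TSS200": 3, "5UTR": 2, "1stExon": 2, "Body": 6, "3UTR": 1})
    n_intergenic: int = 150
    n_agents: int = 30
    n_replicates: int = 3
    n_constant_agents: int = 2
    n_canonical: int = 12
    n_positive_coupled: int = 6
    n_cn_driven: int = 6
    n_lineage_linked: int = 6
    target_spearman: float = 0.75       # net planted |rho|, methylation vs log(IC50)
    meth_expr_spearman: float = 0.9     # canonical promoter-expression coupling
    positive_meth_expr_rho: float = 0.8
    cn_coupling: float = 0.7
    probe_offset_sd: float = 0.4        # logit units, probe-to-probe baseline shift
    probe_noise_sd: float = 0.15        # logit units, per-cell measurement noise
    latent_mu_sd: float = 1.2           # spread of region baseline methylation
    replicate_sd: float = 0.1           # log10 units between IC50 replicates
    detection_failure_rate: float = 0.002
    n_bad_probes: int = 15
    snp_rate: float = 0.02
    multi_assign_fraction: float = 0.05
    cn_sample_fraction: float = 0.5
    cn_gain_fraction: float = 0.3
    lineage_fraction: float = 0.6       # fraction of samples in the NE-like cluster
    marker_shift: float = 3.0           # log2 units between lineage clusters
    lineage_meth_offset: float = 1.5    # logit units of planted lineage methylation
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_agents, self.n_replicates) < 1:
            raise ValueError("counts must be positive")
        planted = (self.n_canonical + self.n_positive_coupled + self.n_cn_driven
                   + self.n_lineage_linked)
        if planted > self.n_genes:
            raise ValueError("archetype counts exceed n_genes")
        if self.n_lineage_linked > len(LINEAGE_MARKERS):
            raise ValueError(f"at most {len(LINEAGE_MARKERS)} lineage-linked genes")
        n_targeted = self.n_canonical + self.n_positive_coupled + self.n_cn_driven
        if n_targeted > self.n_agents - self.n_constant_agents:
            raise ValueError("not enough variable agents for the planted effects")
        for arch, region in DRIVER_REGION.items():
            count = getattr(self, {"canonical_repressive": "n_canonical",
                                   "positive_coupled": "n_positive_coupled",
                                   "cn_driven": "n_cn_driven"}[arch])
            if count > 0 and self.probes_per_region.get(region, 0) < 1:
                raise ValueError(f"planted {arch} effects need probes in {region}")
        if not (0 <= self.detection_failure_rate <= 1 and 0 <= self.snp_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for every planted structure in one bundle."""

    archetypes: dict[str, str]
    target_agent: dict[str, str]
    driver_region: dict[str, str]
    planted_region_pairs: set[tuple[str, str]]
    planted_probe_pairs: set[tuple[str, str]]
    planted_transcript: dict[str, str]
    failed_cells: set[tuple[str, str]]
    bad_probes: set[str]
    snp_probes: set[str]
    constant_agents: list[str]
    lineage_labels: dict[str, str]
    cn_genes: list[str]
    bundle_id: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "archetypes": self.archetypes,
            "target_agent": self.target_agent,
            "driver_region": self.driver_region,
            "planted_region_pairs": sorted(map(list, self.planted_region_pairs)),
            "planted_probe_pairs": sorted(map(list, self.planted_probe_pairs)),
            "planted_transcript": self.planted_transcript,
            "failed_cells": sorted(map(list, self.failed_cells)),
            "bad_probes": sorted(self.bad_probes),
            "snp_probes": sorted(self.snp_probes),
            "constant_agents": self.constant_agents,
            "lineage_labels": self.lineage_labels,
            "cn_genes": self.cn_genes,
            "bundle_id": self.bundle_id,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class SyntheticDataset:
    bundle: DatasetBundle
    truth: SyntheticTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# gene / archetype bookkeeping


def _gene_table(config: SimulationConfig) -> list[tuple[str, str]]:
    """Ordered (gene, archetype) pairs: markers first, then planted, then null."""
    genes: list[tuple[str, str]] = []
    for marker in LINEAGE_MARKERS[: config.n_lineage_linked]:
        genes.append((marker, "lineage_linked"))
    idx = 1
    for arch, count in (("canonical_repressive", config.n_canonical),
                        ("positive_coupled", config.n_positive_coupled),
                        ("cn_driven", config.n_cn_driven)):
        for _ in range(count):
            genes.append((f"GENE{idx:04d}", arch))
            idx += 1
    while len(genes) < config.n_genes:
        genes.append((f"GENE{idx:04d}", "null"))
        idx += 1
    return genes


def simulate_manifest(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    genes: list[tuple[str, str]] | None = None,
) -> dict[str, ProbeAnnotation]:
    """EPIC-style manifest: per gene, probes in the six region classes.

    Positions increase along a pseudo-chromosome in region order
    (TSS1500 upstream first, 3'UTR last).  A configured fraction of
    null-gene probes carries a second (gene, region) assignment, and SNP
    flags are planted at ``snp_rate`` among null-gene and intergenic probes
    so every planted effect keeps its full probe complement.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if genes is None:
        genes = _gene_table(config)
    null_genes = [g for g, a in genes if a == "null"]
    manifest: dict[str, ProbeAnnotation] = {}
    probe_no = 1
    eligible: list[str] = []  # probes eligible for SNP flags / multi-assignment
    for gi, (gene, arch) in enumerate(genes):
        chrom = f"chr{(gi % 22) + 1}"
        base = 1_000_000 * (gi + 1)
        cytoband = f"{(gi % 22) + 1}q{(gi % 40) + 1}.{(gi % 3) + 1}"
        offset = 0
        for region in REGION_CLASSES:
            for _ in range(config.probes_per_region.get(region, 0)):
                pid = f"cg{probe_no:08d}"
                probe_no += 1
                offset += 137
                manifest[pid] = ProbeAnnotation(
                    probe_id=pid, chromosome=chrom, position=base + offset,
                    cytoband=cytoband, gene_assignments=((gene, region),),
                    snp_masked=False,
                )
                if arch == "null":
                    eligible.append(pid)
    for k in range(config.n_intergenic):
        pid = f"cg{probe_no:08d}"
        probe_no += 1
        chrom = f"chr{(k % 22) + 1}"
        manifest[pid] = ProbeAnnotation(
            probe_id=pid, chromosome=chrom,
            position=500_000 + 97 * k, cytoband=f"{(k % 22) + 1}p1.1",
            gene_assignments=(), snp_masked=False,
        )
        eligible.append(pid)

    # second assignments among null genes only, so planted truth stays crisp
    null_probes = [p for p in eligible if manifest[p].gene_assignments]
    n_multi = int(round(config.multi_assign_fraction * len(null_probes)))
    if n_multi and len(null_genes) > 1:
        chosen = rng.choice(len(null_probes), size=n_multi, replace=False)
        for i in sorted(chosen):
            pid = null_probes[i]
            ann = manifest[pid]
            own = ann.gene_assignments[0][0]
            others = [g for g in null_genes if g != own]
            gene2 = others[int(rng.integers(len(others)))]
            region2 = REGION_CLASSES[int(rng.integers(len(REGION_CLASSES)))]
            manifest[pid] = dataclasses.replace(
                ann, gene_assignments=ann.gene_assignments + ((gene2, region2),)
            )

    snp_mask = rng.random(len(eligible)) < config.snp_rate
    for pid, flag in zip(eligible, snp_mask):
        if flag:
            manifest[pid] = dataclasses.replace(manifest[pid], snp_masked=True)
    return manifest


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete input bundle plus its ground truth.

    Identical config (including seed) yields a byte-identical bundle.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config)
    manifest = simulate_manifest(config, rng, genes)
    samples = [f"CL{i + 1:03d}" for i in range(config.n_samples)]
    n = config.n_samples

    lineage = np.where(rng.random(n) < config.lineage_fraction, "NE", "P")
    lineage_labels = dict(zip(samples, lineage.tolist()))
    ne_mask = lineage == "NE"

    # agent panel: planted genes get distinct variable agents
    agent_ids = [f"AGT{i + 1:03d}" for i in range(config.n_agents)]
    constant_agents = agent_ids[config.n_agents - config.n_constant_agents:]
    variable_agents = agent_ids[: config.n_agents - config.n_constant_agents]
    planted_genes = [(g, a) for g, a in genes
                     if a in ("canonical_repressive", "positive_coupled", "cn_driven")]
    target_agent = {g: variable_agents[i] for i, (g, _) in enumerate(planted_genes)}

    target_r = spearman_to_pearson(config.target_spearman)
    meth_expr_r = spearman_to_pearson(config.meth_expr_spearman)
    expr_resp_r = target_r / meth_expr_r
    if abs(expr_resp_r) >= 1:
        raise ValueError("target correlation exceeds the expression coupling")

    # --- latents and couplings -------------------------------------------
    region_latent: dict[RegionKey, np.ndarray] = {}
    driver_z: dict[str, np.ndarray] = {}   # unit-variance random part per planted gene
    cn_gain: dict[str, np.ndarray] = {}
    for gene, arch in genes:
        for region in REGION_CLASSES:
            if config.probes_per_region.get(region, 0) < 1:
                continue
            mu = rng.normal(0.0, config.latent_mu_sd)
            z = rng.standard_normal(n)
            if arch in DRIVER_REGION and region == DRIVER_REGION[arch]:
                if arch == "cn_driven":
                    gain = (rng.random(n) < config.cn_gain_fraction).astype(float)
                    sd = gain.std()
                    cz = (gain - gain.mean()) / sd if sd > 0 else np.zeros(n)
                    w = config.cn_coupling
                    u = math.sqrt(1 - w * w) * z + w * cz
                    cn_gain[gene] = gain
                    region_latent[RegionKey(gene, region)] = mu + u
                    driver_z[gene] = u
                else:
                    region_latent[RegionKey(gene, region)] = mu + z
                    driver_z[gene] = z
            elif arch == "lineage_linked" and region == "TSS200":
                # promoter methylation higher in the cluster where the marker is low
                high_in_ne = gene in ("ASCL1", "ASCL2", "INSM1", "NEUROD1")
                offs = np.where(ne_mask, 0.0, config.lineage_meth_offset)
                if not high_in_ne:
                    offs = np.where(ne_mask, config.lineage_meth_offset, 0.0)
                region_latent[RegionKey(gene, region)] = mu + z * 0.5 + offs
            else:
                region_latent[RegionKey(gene, region)] = mu + z

    # --- beta matrix ------------------------------------------------------
    probe_ids = list(manifest)
    beta_rows = np.empty((len(probe_ids), n))
    for i, pid in enumerate(probe_ids):
        ann = manifest[pid]
        if ann.gene_assignments:
            key = RegionKey(*ann.gene_assignments[0])
            latent = region_latent.get(key)
            if latent is None:  # region class with zero configured probes
                latent = rng.normal(0.0, config.latent_mu_sd) + rng.standard_normal(n)
        else:
            latent = rng.normal(0.0, config.latent_mu_sd) + rng.standard_normal(n)
        logit = (latent + rng.normal(0.0, config.probe_offset_sd)
                 + rng.normal(0.0, config.probe_noise_sd, size=n))
        beta_rows[i] = 1.0 / (1.0 + np.exp(-logit))
    beta = pd.DataFrame(beta_rows, index=probe_ids, columns=samples)

    # --- expression -------------------------------------------------------
    tx_rows, tx_ids, tx_genes = [], [], []
    planted_transcript: dict[str, str] = {}

    def add_tx(gene: str, k: int, values: np.ndarray) -> str:
        tx = f"TX_{gene}_{k:02d}"
        tx_ids.append(tx)
        tx_genes.append(gene)
        tx_rows.append(values)
        return tx

    for gene, arch in genes:
        base = rng.normal(7.0, 1.0)
        if arch == "canonical_repressive":
            z = driver_z[gene]
            sig = -meth_expr_r * z + math.sqrt(1 - meth_expr_r ** 2) * rng.standard_normal(n)
            planted_transcript[gene] = add_tx(gene, 1, base + sig)
            add_tx(gene, 2, base + rng.standard_normal(n))  # decoy
        elif arch == "positive_coupled":
            z = driver_z[gene]
            r = config.positive_meth_expr_rho
            sig = r * z + math.sqrt(1 - r * r) * rng.standard_normal(n)
            planted_transcript[gene] = add_tx(gene, 1, base + sig)
            add_tx(gene, 2, base + rng.standard_normal(n))
        elif arch == "cn_driven":
            u = driver_z[gene]
            w = config.cn_coupling
            sig = w * u + math.sqrt(1 - w * w) * rng.standard_normal(n)
            planted_transcript[gene] = add_tx(gene, 1, base + sig)
        elif arch == "lineage_linked":
            high_in_ne = gene in ("ASCL1", "ASCL2", "INSM1", "NEUROD1")
            shift = np.where(ne_mask == high_in_ne, config.marker_shift, 0.0)
            add_tx(gene, 1, base + shift + rng.standard_normal(n))
        else:
            add_tx(gene, 1, base + rng.standard_normal(n))
    expression = pd.DataFrame(np.asarray(tx_rows), index=tx_ids, columns=samples)
    tx_map = pd.Series(tx_genes, index=pd.Index(tx_ids, name="transcript_id"),
                       name="gene")

    # --- drug response ----------------------------------------------------
    agent_means: dict[str, np.ndarray] = {}
    gene_of_agent = {a: g for g, a in target_agent.items()}
    for agent in agent_ids:
        mu_a = rng.normal(-6.0, 0.5)
        if agent in constant_agents:
            agent_means[agent] = np.full(n, -5.0)
            continue
        gene = gene_of_agent.get(agent)
        if gene is None:
            agent_means[agent] = mu_a + rng.standard_normal(n)
            continue
        arch = dict(genes)[gene]
        if arch == "canonical_repressive":
            # couple through the planted transcript's signal component
            tx_sig = (expression.loc[planted_transcript[gene]].to_numpy()
                      - expression.loc[planted_transcript[gene]].mean())
            x = tx_sig / tx_sig.std()
            r2 = expr_resp_r
            resp = r2 * x + math.sqrt(max(0.0, 1 - r2 * r2)) * rng.standard_normal(n)
        else:  # positive_coupled and cn_driven couple to the driver latent
            u = driver_z[gene]
            resp = target_r * u + math.sqrt(1 - target_r ** 2) * rng.standard_normal(n)
        agent_means[agent] = mu_a + resp

    rep_rows = []
    for agent in agent_ids:
        means = agent_means[agent]
        for rep in range(1, config.n_replicates + 1):
            noise = (np.zeros(n) if agent in constant_agents
                     else rng.normal(0.0, config.replicate_sd, size=n))
            for s, m, e in zip(samples, means, noise):
                rep_rows.append((agent, s, rep, 10.0 ** (m + e)))
    replicates = pd.DataFrame(rep_rows, columns=["agent", "cell_line",
                                                 "replicate", "ic50"])

    # --- copy number ------------------------------------------------------
    n_cn_samples = max(3, int(round(config.cn_sample_fraction * n)))
    cn_samples = sorted(rng.choice(samples, size=min(n_cn_samples, n), replace=False))
    cn_rows, cn_index = [], []
    for gene, arch in genes:
        if arch != "cn_driven":
            continue
        gain = cn_gain[gene]
        vals = 0.8 * gain + rng.normal(0.0, 0.1, size=n)
        cn_index.append(gene)
        cn_rows.append(pd.Series(vals, index=samples)[cn_samples].to_numpy())
    copy_number = (pd.DataFrame(np.asarray(cn_rows), index=cn_index, columns=cn_samples)
                   if cn_rows else None)

    # --- detection p with planted failures --------------------------------
    bad_eligible = [p for p in probe_ids
                    if not manifest[p].snp_masked
                    and (not manifest[p].gene_assignments
                         or dict(genes)[manifest[p].gene_assignments[0][0]] == "null")]
    n_bad = min(config.n_bad_probes, len(bad_eligible))
    bad_probes = set(rng.choice(bad_eligible, size=n_bad, replace=False).tolist()) \
        if n_bad else set()

    detp = 10.0 ** rng.uniform(-12.0, -8.0, size=(len(probe_ids), n))
    failed_cells: set[tuple[str, str]] = set()
    fail_mask = rng.random((len(probe_ids), n)) < config.detection_failure_rate
    for i, pid in enumerate(probe_ids):
        if pid in bad_probes:
            # whole-probe failure: median >= 1e-4, every cell below the 1e-3
            # masking cutoff so cell masking and probe dropping stay disjoint
            detp[i] = 10.0 ** rng.uniform(-4.0, -3.1, size=n)
            continue
        for j in np.where(fail_mask[i])[0]:
            detp[i, j] = 10.0 ** rng.uniform(-3.0, 0.0)
            failed_cells.add((pid, samples[j]))
    detection_p = pd.DataFrame(detp, index=probe_ids, columns=samples)

    # --- assemble ---------------------------------------------------------
    archetypes = dict(genes)
    snp_probes = {p for p in probe_ids if manifest[p].snp_masked}
    planted_region_pairs = {
        (str(RegionKey(g, DRIVER_REGION[archetypes[g]])), a)
        for g, a in target_agent.items()
    }
    planted_probe_pairs = set()
    for g, a in target_agent.items():
        region = DRIVER_REGION[archetypes[g]]
        for pid in probe_ids:
            if (g, region) in manifest[pid].gene_assignments:
                planted_probe_pairs.add((pid, a))

    candidate_genes = frozenset(g for g, _ in planted_genes) | frozenset(
        g for g, arch in genes if arch == "null")  # candidates include decoys
    bundle = DatasetBundle(
        beta=beta, detection_p=detection_p, manifest=manifest,
        drug_replicates=replicates, expression=expression,
        transcript_gene_map=tx_map, copy_number=copy_number,
        candidate_genes=frozenset(sorted(candidate_genes)[:60]),
        candidate_agents=frozenset(target_agent.values()),
    )
    truth = SyntheticTruth(
        archetypes=archetypes,
        target_agent=target_agent,
        driver_region={g: DRIVER_REGION[archetypes[g]] for g in target_agent},
        planted_region_pairs=planted_region_pairs,
        planted_probe_pairs=planted_probe_pairs,
        planted_transcript=planted_transcript,
        failed_cells=failed_cells,
        bad_probes=bad_probes,
        snp_probes=snp_probes,
        constant_agents=list(constant_agents),
        lineage_labels=lineage_labels,
        cn_genes=sorted(cn_gain),
        bundle_id=f"synthetic-seed{config.seed}",
    )
    return SyntheticDataset(bundle=bundle, truth=truth, config=config)


# ---------------------------------------------------------------------------
# recovery metrics


def evaluate_recovery(
    records: pd.DataFrame,
    truth: SyntheticTruth,
    tier,
    level: str = "region",
) -> dict:
    """TPR / FDP of planted effects at a significance tier.

    ``tier`` is a float (p_FDR cutoff) or one of ``"strict"`` /
    ``"liberal"`` (fixed probe thresholds).  ``level`` selects the truth
    set: planted (region, agent) or (probe, agent) pairs.
    """
    if level == "region":
        truth_pairs = set(truth.planted_region_pairs)
    elif level == "probe":
        truth_pairs = set(truth.planted_probe_pairs)
    else:
        raise ValueError(f"unknown level {level!r}")

    if isinstance(tier, str):
        col = {"strict": "passes_strict", "liberal": "passes_liberal"}[tier]
        called = records.loc[records[col].fillna(False).astype(bool)]
    else:
        called = records.loc[records["p_fdr"] < tier]
    calls = set(zip(called["feature_id"], called["agent"]))

    tp = calls & truth_pairs
    tpr = len(tp) / len(truth_pairs) if truth_pairs else float("nan")
    fdp = (len(calls) - len(tp)) / len(calls) if calls else 0.0
    by_arch: dict[str, dict] = {}
    for pair in truth_pairs:
        gene = pair[0].split("|")[0] if level == "region" else None
        if gene is not None:
            arch = truth.archetypes.get(gene, "unknown")
            d = by_arch.setdefault(arch, {"planted": 0, "recovered": 0})
            d["planted"] += 1
            d["recovered"] += int(pair in tp)
    return {"tpr": tpr, "fdp": fdp, "n_calls": len(calls),
            "n_planted": len(truth_pairs), "by_archetype": by_arch}


# ---------------------------------------------------------------------------
# writing


def write_bundle(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every bundle table plus truth JSON; returns a path config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    b = dataset.bundle
    paths = {
        "beta": str(outdir / "beta.tsv"),
        "detection_p": str(outdir / "detection_p.tsv"),
        "manifest": str(outdir / "manifest.csv"),
        "drug_replicates": str(outdir / "drug_replicates.csv"),
        "expression": str(outdir / "expression.tsv"),
        "transcript_gene_map": str(outdir / "transcript_gene_map.tsv"),
    }
    write_matrix(b.beta, paths["beta"])
    write_matrix(b.detection_p, paths["detection_p"])
    write_manifest(b.manifest, paths["manifest"])
    write_drug_replicates(b.drug_replicates, paths["drug_replicates"])
    write_matrix(b.expression, paths["expression"])
    b.transcript_gene_map.rename_axis("transcript_id").reset_index().to_csv(
        paths["transcript_gene_map"], sep="\t", index=False)
    if b.copy_number is not None:
        paths["copy_number"] = str(outdir / "copy_number.tsv")
        write_matrix(b.copy_number, paths["copy_number"])
    if b.candidate_genes:
        paths["candidate_genes"] = str(outdir / "candidate_genes.txt")
        Path(paths["candidate_genes"]).write_text(
            "\n".join(sorted(b.candidate_genes)) + "\n")
    if b.candidate_agents:
        paths["candidate_agents"] = str(outdir / "candidate_agents.txt")
        Path(paths["candidate_agents"]).write_text(
            "\n".join(sorted(b.candidate_agents)) + "\n")
    dataset.truth.to_json(outdir / "truth.json")
    return paths
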