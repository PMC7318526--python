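"""Methylation-drug-response association analyses.

The engine prepares the response matrix (median log10 IC50 over replicates,
restriction to agents with variable response), runs the epigenome-wide
probe and region passes, the candidate-gene passes with their own FDR
families, and builds per-gene summary rows.

Multiple-testing regimes mirror the three-family design:

* epigenome-wide probes — fixed thresholds only (strict 9.42e-8, liberal
  5e-7 for a single EPIC probe); no probe-level FDR;
* epigenome-wide regions — one BH family over all region x agent tests;
* candidate probes and candidate regions — two further BH families,
  adjusted separately and never mixed with the epigenome-wide results.

Record collections are DataFrames with the column schema of
:data:`methylpharm.data_io.RESULT_COLUMNS`; a row is one feature-agent test.
The sign convention is positive rho = higher methylation with higher
log(IC50), i.e. resistance; negative rho marks sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import SMALLEST_P, bh_adjust, pearson, spearman
from .data_io import DataValidationError, ProbeAnnotation
from .regions import region_key_from_string

logger = logging.getLogger(__name__)

__all__ = [
    "STRICT_PROBE_THRESHOLD",
    "LIBERAL_PROBE_THRESHOLD",
    "FDR_TIERS",
    "CandidateSpec",
    "CandidateResults",
    "median_log_ic50",
    "filter_variable_agents",
    "correlate_features_with_response",
    "epigenome_wide_analysis",
    "candidate_analysis",
    "gene_level_summary",
    "probe_metadata",
]

#: Fixed significance threshold for a single EPIC methylation probe.
STRICT_PROBE_THRESHOLD = 9.42e-8
#: More liberal probe threshold used for the broader gene-level summaries.
LIBERAL_PROBE_THRESHOLD = 5e-7
#: FDR tiers narrated for region-level results (reported as flags).
FDR_TIERS = (0.05, 0.10, 0.15)


@dataclass(frozen=True)
class CandidateSpec:
    """Candidate gene and agent sets for the focused analysis."""

    genes: frozenset[str]
    agents: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes or not self.agents:
            raise DataValidationError("candidate gene and agent sets must be non-empty")


@dataclass
class CandidateResults:
    """Candidate-analysis output: two records tables with their family sizes."""

    probe_records: pd.DataFrame
    region_records: pd.DataFrame
    probe_family_size: int
    region_family_size: int


# ---------------------------------------------------------------------------
# response preparation


def median_log_ic50(replicates: pd.DataFrame) -> pd.DataFrame:
    """Median of per-replicate log10(IC50) per (agent, cell line).

    IC50 is in molar units, so 1 uM maps to -6.  Cells with no replicate
    measurements are missing.
    """
    if (replicates["ic50"] <= 0).any():
        bad = replicates.loc[replicates["ic50"] <= 0].iloc[0]
        raise DataValidationError(
            f"non-positive IC50 for agent {bad['agent']!r}, cell line {bad['cell_line']!r}"
        )
    logs = replicates.assign(log_ic50=np.log10(replicates["ic50"].to_numpy()))
    response = logs.pivot_table(index="agent", columns="cell_line",
                                values="log_ic50", aggfunc="median")
    response.index.name = "agent"
    response.columns.name = "cell_line"
    return response


def filter_variable_agents(
    response: pd.DataFrame,
    min_distinct: int = 2,
    min_range: float = 0.0,
) -> tuple[list[str], pd.DataFrame]:
    """Agents whose response varies across cell lines, plus an exclusion log.

    Variability is operationalised as >= ``min_distinct`` distinct
    non-missing values and a value range > ``min_range`` log units.
    """
    retained, excluded = [], []
    for agent, row in response.iterrows():
        vals = row.dropna().to_numpy()
        n_distinct = len(np.unique(vals))
        if n_distinct < min_distinct:
            excluded.append((agent, f"fewer than {min_distinct} distinct values"))
        elif vals.size and float(np.ptp(vals)) <= min_range:
            excluded.append((agent, f"range <= {min_range} log units"))
        else:
            retained.append(agent)
    log = pd.DataFrame(excluded, columns=["agent", "reason"])
    if len(log):
        logger.info("excluded %d non-variable agents", len(log))
    return retained, log


# ---------------------------------------------------------------------------
# correlation engine


def _p_from_rho_vector(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorised two-sided t-approximation p; identical to core_stats."""
    rho = np.abs(rho)
    p = np.empty_like(rho)
    exact = rho >= 1.0
    p[exact] = SMALLEST_P
    ok = ~exact
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho[ok] * np.sqrt((n[ok] - 2) / (1.0 - rho[ok] ** 2))
    p[ok] = 2.0 * stats.t.sf(t, n[ok] - 2)
    return np.clip(p, SMALLEST_P, 1.0)


def _spearman_block(features: np.ndarray, y: np.ndarray,
                    feature_ranks: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho of each complete feature row against complete vector y.

    ``features`` has no missing entries here; constant rows return NaN.
    ``feature_ranks`` lets callers reuse row ranks across agents that share
    the same sample mask.
    """
    n = y.size
    ry = stats.rankdata(y)
    rf = stats.rankdata(features, axis=1) if feature_ranks is None else feature_ranks
    ry_c = ry - ry.mean()
    rf_c = rf - rf.mean(axis=1, keepdims=True)
    denom = np.sqrt((rf_c ** 2).sum(axis=1) * (ry_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rf_c @ ry_c) / denom
    rho[denom == 0] = np.nan
    return np.clip(rho, -1.0, 1.0), np.full(features.shape[0], n)


def probe_metadata(manifest: dict[str, ProbeAnnotation]) -> pd.DataFrame:
    """Per-probe gene / region-class metadata (semicolon-joined lists)."""
    rows = {
        pid: (";".join(dict.fromkeys(g for g, _ in ann.gene_assignments)),
              ";".join(r for _, r in ann.gene_assignments))
        for pid, ann in manifest.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["gene", "region_class"])


def correlate_features_with_response(
    features: pd.DataFrame,
    response: pd.DataFrame,
    family: str,
    feature_kind: str = "probe",
    feature_meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman-correlate every feature row with every agent's response.

    Feature rows with no missing values are ranked once per agent and
    correlated in a single vectorised pass; rows with missing entries fall
    back to pairwise-complete :func:`methylpharm.core_stats.spearman`.
    Undefined tests (constant vectors, < 3 complete pairs) are logged and
    excluded, never emitted as records.
    """
    shared = [s for s in features.columns if s in set(response.columns)]
    if not shared:
        raise DataValidationError("no shared samples between features and response")
    feats = features[shared]
    resp = response[shared]
    vals = feats.to_numpy()
    row_complete = np.isfinite(vals).all(axis=1)

    frames, exclusions = [], []
    rank_cache: dict[bytes, np.ndarray] = {}
    for agent, yrow in resp.iterrows():
        y = yrow.to_numpy()
        y_ok = np.isfinite(y)
        if y_ok.sum() < 3 or np.ptp(y[y_ok]) == 0:
            exclusions.append(("*", agent, "undefined response vector"))
            continue
        sub = vals[:, y_ok]
        ysub = y[y_ok]
        complete = np.isfinite(sub).all(axis=1)
        rho = np.full(vals.shape[0], np.nan)
        n_used = np.zeros(vals.shape[0], dtype=int)
        if complete.any():
            key = y_ok.tobytes()
            if key not in rank_cache:
                rank_cache[key] = stats.rankdata(sub[complete], axis=1)
            r, n = _spearman_block(sub[complete], ysub,
                                   feature_ranks=rank_cache[key])
            rho[complete] = r
            n_used[complete] = n
        for i in np.where(~complete)[0]:
            res = spearman(sub[i], ysub)
            if res is None:
                continue
            rho[i] = res.coefficient
            n_used[i] = res.n_used
        defined = np.isfinite(rho)
        for fid in feats.index[~defined]:
            exclusions.append((fid, agent, "undefined correlation"))
        if not defined.any():
            continue
        p = _p_from_rho_vector(rho[defined], n_used[defined].astype(float))
        frames.append(pd.DataFrame({
            "feature_id": feats.index[defined],
            "agent": agent,
            "coefficient": rho[defined],
            "p_value": p,
            "n_used": n_used[defined],
        }))

    exclusion_log = pd.DataFrame(exclusions, columns=["feature_id", "agent", "reason"])
    if not frames:
        records = pd.DataFrame(columns=["feature_id", "agent", "coefficient",
                                        "p_value", "n_used"])
    else:
        records = pd.concat(frames, ignore_index=True)
    records["feature_kind"] = feature_kind
    records["family"] = family
    if feature_meta is not None:
        records = records.join(feature_meta, on="feature_id")
    else:
        records["gene"] = ""
        records["region_class"] = ""
    return records, exclusion_log


def _region_meta(region_ids) -> pd.DataFrame:
    keys = [region_key_from_string(r) for r in region_ids]
    return pd.DataFrame(
        {"gene": [k.gene for k in keys], "region_class": [k.region_class for k in keys]},
        index=pd.Index(region_ids),
    )


def _attach_probe_flags(records: pd.DataFrame, strict: float, liberal: float) -> pd.DataFrame:
    records = records.copy()
    records["passes_strict"] = records["p_value"] < strict
    records["passes_liberal"] = records["p_value"] < liberal
    records["p_fdr"] = np.nan
    return records


def _attach_fdr(records: pd.DataFrame) -> pd.DataFrame:
    records = records.copy()
    if len(records):
        records["p_fdr"] = bh_adjust(records["p_value"].to_numpy()).adjusted
    else:
        records["p_fdr"] = np.array([], dtype=float)
    for tier in FDR_TIERS:
        records[f"fdr_lt_{int(tier * 100):02d}"] = records["p_fdr"] < tier
    return records


def epigenome_wide_analysis(
    beta: pd.DataFrame,
    regions: pd.DataFrame,
    response: pd.DataFrame,
    strict: float = STRICT_PROBE_THRESHOLD,
    liberal: float = LIBERAL_PROBE_THRESHOLD,
    probe_meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The epigenome-wide probe and region passes.

    Probe records carry the fixed-threshold flags only; region records carry
    BH-adjusted p-values from the single family spanning all region x agent
    tests, flagged at the 0.05 / 0.10 / 0.15 tiers.  ``response`` must
    already be restricted to agents with variable response.
    """
    probe_records, probe_excl = correlate_features_with_response(
        beta, response, family="epigenome_probe", feature_kind="probe",
        feature_meta=probe_meta,
    )
    probe_records = _attach_probe_flags(probe_records, strict, liberal)

    region_records, region_excl = correlate_features_with_response(
        regions, response, family="epigenome_region", feature_kind="region",
        feature_meta=_region_meta(regions.index),
    )
    region_records = _attach_fdr(region_records)
    region_records["passes_strict"] = region_records["p_value"] < strict
    region_records["passes_liberal"] = region_records["p_value"] < liberal
    if len(probe_excl) or len(region_excl):
        logger.info("epigenome-wide pass: %d probe and %d region tests undefined",
                    len(probe_excl), len(region_excl))
    return probe_records, region_records


def candidate_analysis(
    beta: pd.DataFrame,
    regions: pd.DataFrame,
    response: pd.DataFrame,
    spec: CandidateSpec,
    manifest: dict[str, ProbeAnnotation],
) -> CandidateResults:
    """The focused candidate-gene passes with their own two BH families.

    Probes in or near candidate genes and regions of candidate genes are
    tested against the candidate agents only; each of the two families is
    adjusted separately and independently of the epigenome-wide analysis.
    """
    cand_probes = [
        pid for pid in beta.index
        if pid in manifest
        and any(g in spec.genes for g, _ in manifest[pid].gene_assignments)
    ]
    cand_regions = [
        rid for rid in regions.index
        if region_key_from_string(rid).gene in spec.genes
    ]
    cand_agents = [a for a in response.index if a in spec.agents]
    if not cand_probes or not cand_agents:
        raise DataValidationError(
            "empty candidate intersection: no candidate probes or agents present"
        )
    sub_response = response.loc[cand_agents]
    probe_records, _ = correlate_features_with_response(
        beta.loc[cand_probes], sub_response, family="candidate_probe",
        feature_kind="probe", feature_meta=probe_metadata(manifest),
    )
    probe_records = _attach_fdr(probe_records)
    region_records, _ = correlate_features_with_response(
        regions.loc[cand_regions], sub_response, family="candidate_region",
        feature_kind="region", feature_meta=_region_meta(cand_regions),
    )
    region_records = _attach_fdr(region_records)
    return CandidateResults(
        probe_records=probe_records,
        region_records=region_records,
        probe_family_size=len(probe_records),
        region_family_size=len(region_records),
    )


# ---------------------------------------------------------------------------
# gene-level summary


def _best_row(group: pd.DataFrame) -> pd.Series:
    """Deterministic best record: smallest p, then largest |rho|, then id."""
    ordered = group.assign(_abs=-group["coefficient"].abs()).sort_values(
        ["p_value", "_abs", "feature_id"], kind="mergesort"
    )
    return ordered.iloc[0]


def gene_level_summary(
    probe_records: pd.DataFrame,
    beta: pd.DataFrame,
    expression: pd.DataFrame | None,
    transcript_gene_map: pd.Series | None,
    response: pd.DataFrame,
    liberal: float = LIBERAL_PROBE_THRESHOLD,
) -> pd.DataFrame:
    """Per (gene, agent) summary over probes passing the liberal threshold.

    For each (gene, agent) with >= 1 qualifying probe the best probe's rho
    and p are reported.  Among transcripts whose gene symbol matches, the
    transcript with the smallest Spearman p between its expression and the
    methylation of any qualifying probe is selected, and its Pearson
    correlation with log(IC50) is reported.  Probes assigned to several
    genes contribute a combined multi-gene row (gene field joined with
    ';'); genes with no matching transcript leave the expression columns
    empty.
    """
    qualifying = probe_records.loc[probe_records["p_value"] < liberal]
    rows = []
    gene_to_tx: dict[str, list[str]] = {}
    me_samples: list[str] = []
    er_samples: list[str] = []
    if expression is not None and transcript_gene_map is not None:
        me_samples = [s for s in beta.columns if s in set(expression.columns)]
        er_samples = [s for s in response.columns if s in set(expression.columns)]
        for tx, gene in transcript_gene_map.items():
            if tx in expression.index:
                gene_to_tx.setdefault(gene, []).append(tx)

    for (gene_field, agent), group in qualifying.groupby(["gene", "agent"], sort=True):
        best = _best_row(group)
        row = {
            "gene": gene_field,
            "agent": agent,
            "n_qualifying_probes": len(group),
            "best_probe": best["feature_id"],
            "best_probe_rho": best["coefficient"],
            "best_probe_p": best["p_value"],
            "best_transcript": "",
            "meth_expr_rho": np.nan,
            "meth_expr_p": np.nan,
            "expr_response_r": np.nan,
            "expr_response_p": np.nan,
        }
        genes = [g for g in str(gene_field).split(";") if g]
        candidates = []
        for g in genes:
            for tx in gene_to_tx.get(g, []):
                for probe in group["feature_id"]:
                    res = spearman(expression.loc[tx, me_samples],
                                   beta.loc[probe, me_samples])
                    if res is not None:
                        candidates.append((res.p_value, -abs(res.coefficient), tx, res))
        if candidates:
            candidates.sort(key=lambda c: (c[0], c[1], c[2]))
            p_me, _, tx_best, res_me = candidates[0]
            row["best_transcript"] = tx_best
            row["meth_expr_rho"] = res_me.coefficient
            row["meth_expr_p"] = p_me
            if agent in response.index:
                pr = pearson(expression.loc[tx_best, er_samples],
                             response.loc[agent, er_samples])
                if pr is not None:
                    row["expr_response_r"] = pr.coefficient
                    row["expr_response_p"] = pr.p_value
        rows.append(row)
    return pd.DataFrame(rows)
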