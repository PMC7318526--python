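"""Linking methylation hits to expression, drug response, copy number and
lineage structure.

The canonical signature of direct epigenetic regulation of chemosensitivity
is: methylation negatively correlated with the gene's transcript expression,
with expression correlated with log(IC50) in the opposite direction from
methylation (promoter methylation silences the gene; the gene's product
drives sensitivity or resistance).  A positive methylation-expression
correlation instead points at confounders such as copy-number events, which
the copy-number screen checks explicitly.

Lineage structure is summarised by UPGMA (average-linkage) clustering of
samples over six lineage marker genes (ASCL1, ASCL2, NEUROD1, INSM1, YAP1,
POU2F3) on Euclidean distances of their log2 expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .core_stats import CorrelationResult, pearson, spearman
from .data_io import DataValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "LINEAGE_MARKERS",
    "PATTERN_TAGS",
    "LineageClusteringResult",
    "methylation_expression_correlations",
    "expression_response_correlations",
    "classify_regulatory_pattern",
    "copy_number_screen",
    "lineage_clustering",
    "marker_expression",
    "marker_correlations",
    "build_linked_reports",
]

#: The six SCLC lineage marker genes.
LINEAGE_MARKERS: tuple[str, ...] = ("ASCL1", "ASCL2", "NEUROD1", "INSM1", "YAP1", "POU2F3")

PATTERN_TAGS = ("canonical_repression", "expression_coupled_positive",
                "inconsistent", "undetermined")


def _shared(a: pd.DataFrame, b: pd.DataFrame) -> list[str]:
    bs = set(b.columns)
    return [s for s in a.columns if s in bs]


def methylation_expression_correlations(
    features: pd.DataFrame,
    feature_genes: pd.Series,
    expression: pd.DataFrame,
    transcript_gene_map: pd.Series,
) -> pd.DataFrame:
    """Spearman correlation of each feature with its gene's transcripts.

    ``feature_genes`` maps feature id -> gene symbol (or ';'-joined
    symbols).  Features whose gene has no matching transcript are logged
    and yield no rows.
    """
    shared = _shared(features, expression)
    gene_to_tx: dict[str, list[str]] = {}
    for tx, gene in transcript_gene_map.items():
        if tx in expression.index:
            gene_to_tx.setdefault(gene, []).append(tx)
    rows, unmatched = [], 0
    for fid in features.index:
        genes = [g for g in str(feature_genes.get(fid, "")).split(";") if g]
        txs = [tx for g in genes for tx in gene_to_tx.get(g, [])]
        if not txs:
            unmatched += 1
            continue
        for tx in txs:
            res = spearman(features.loc[fid, shared], expression.loc[tx, shared])
            if res is None:
                continue
            rows.append({"feature_id": fid, "transcript": tx,
                         "gene": transcript_gene_map[tx],
                         "coefficient": res.coefficient, "p_value": res.p_value,
                         "n_used": res.n_used, "method": "spearman"})
    if unmatched:
        logger.info("%d features had no matching transcript", unmatched)
    return pd.DataFrame(rows, columns=["feature_id", "transcript", "gene",
                                       "coefficient", "p_value", "n_used", "method"])


def expression_response_correlations(
    expression: pd.DataFrame,
    response: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of each transcript with each agent's log(IC50)."""
    shared = _shared(expression, response)
    if len(shared) < 3:
        raise DataValidationError("fewer than 3 shared samples")
    rows = []
    for tx in expression.index:
        for agent in response.index:
            res = pearson(expression.loc[tx, shared], response.loc[agent, shared])
            if res is None:
                logger.debug("undefined expression-response test: %s / %s", tx, agent)
                continue
            rows.append({"transcript": tx, "agent": agent,
                         "coefficient": res.coefficient, "p_value": res.p_value,
                         "n_used": res.n_used, "method": "pearson"})
    return pd.DataFrame(rows, columns=["transcript", "agent", "coefficient",
                                       "p_value", "n_used", "method"])


def classify_regulatory_pattern(
    meth_drug: CorrelationResult,
    meth_expr: CorrelationResult,
    expr_drug: CorrelationResult,
    sig_alpha: float = 0.05,
    min_abs: float = 0.3,
) -> str:
    """Classify one (gene, feature, agent) triple of correlations.

    ``canonical_repression``: methylation significantly represses
    expression (negative meth-expr) and expression associates with response
    in the opposite direction from methylation.
    ``expression_coupled_positive``: methylation and expression positively
    coupled, with same-direction response associations (copy-number or
    other non-repressive coupling).  ``undetermined``: any leg insignificant
    or below ``min_abs``.  Anything else is ``inconsistent``.
    """
    legs = (meth_drug, meth_expr, expr_drug)
    if any(l is None or l.p_value >= sig_alpha or abs(l.coefficient) < min_abs
           for l in legs):
        return "undetermined"
    if meth_expr.coefficient < 0 and np.sign(expr_drug.coefficient) == -np.sign(meth_drug.coefficient):
        return "canonical_repression"
    if meth_expr.coefficient > 0 and np.sign(expr_drug.coefficient) == np.sign(meth_drug.coefficient):
        return "expression_coupled_positive"
    return "inconsistent"


def build_linked_reports(
    records: pd.DataFrame,
    features: pd.DataFrame,
    expression: pd.DataFrame,
    transcript_gene_map: pd.Series,
    response: pd.DataFrame,
    sig_alpha: float = 0.05,
    min_abs: float = 0.3,
) -> pd.DataFrame:
    """One linked report row per association record, with pattern tags.

    For each (feature, agent) record the best-matching transcript (smallest
    methylation-expression p) provides the meth-expr and expr-response legs.
    """
    shared_me = _shared(features, expression)
    shared_er = _shared(expression, response)
    shared_md = _shared(features, response)
    gene_to_tx: dict[str, list[str]] = {}
    for tx, gene in transcript_gene_map.items():
        if tx in expression.index:
            gene_to_tx.setdefault(gene, []).append(tx)
    rows = []
    for rec in records.itertuples(index=False):
        md = spearman(features.loc[rec.feature_id, shared_md],
                      response.loc[rec.agent, shared_md])
        genes = [g for g in str(rec.gene).split(";") if g]
        best = None
        for g in genes:
            for tx in gene_to_tx.get(g, []):
                me = spearman(features.loc[rec.feature_id, shared_me],
                              expression.loc[tx, shared_me])
                if me is not None and (best is None or me.p_value < best[1].p_value):
                    best = (tx, me)
        row = {"gene": rec.gene, "feature_id": rec.feature_id, "agent": rec.agent,
               "meth_drug_rho": md.coefficient if md else np.nan,
               "meth_drug_p": md.p_value if md else np.nan,
               "transcript": "", "meth_expr_rho": np.nan, "meth_expr_p": np.nan,
               "expr_drug_r": np.nan, "expr_drug_p": np.nan,
               "pattern": "undetermined"}
        if best is not None:
            tx, me = best
            ed = pearson(expression.loc[tx, shared_er], response.loc[rec.agent, shared_er])
            row.update(transcript=tx, meth_expr_rho=me.coefficient, meth_expr_p=me.p_value)
            if ed is not None:
                row.update(expr_drug_r=ed.coefficient, expr_drug_p=ed.p_value)
            row["pattern"] = classify_regulatory_pattern(md, me, ed, sig_alpha, min_abs)
        rows.append(row)
    return pd.DataFrame(rows)


def copy_number_screen(
    copy_number: pd.DataFrame,
    features: pd.DataFrame,
    expression: pd.DataFrame,
    response: pd.DataFrame,
    targets: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman screen of copy number against methylation, expression, response.

    ``targets`` rows name (gene, feature_id, transcript, agent) triples to
    screen; genes absent from the copy-number matrix are skipped with a log
    message.  ``cn_unexplained`` is flagged when all three |coefficients|
    are < 0.2 — a positive methylation-expression coupling that copy number
    does not account for.
    """
    rows = []
    for t in targets.itertuples(index=False):
        if t.gene not in copy_number.index:
            logger.info("gene %s absent from copy-number matrix; skipped", t.gene)
            continue
        cn = copy_number.loc[t.gene]
        out = {"gene": t.gene, "feature_id": t.feature_id,
               "transcript": t.transcript, "agent": t.agent}
        for label, table, row_id in (
            ("cn_meth_rho", features, t.feature_id),
            ("cn_expr_rho", expression, t.transcript),
            ("cn_response_rho", response, t.agent),
        ):
            res = None
            if table is not None and row_id in table.index:
                shared = [s for s in copy_number.columns if s in set(table.columns)]
                res = spearman(cn[shared], table.loc[row_id, shared])
            out[label] = res.coefficient if res else np.nan
            out[label.replace("_rho", "_p")] = res.p_value if res else np.nan
        coefs = [out["cn_meth_rho"], out["cn_expr_rho"], out["cn_response_rho"]]
        out["cn_unexplained"] = bool(np.all(np.abs(np.nan_to_num(coefs)) < 0.2))
        rows.append(out)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lineage clustering


@dataclass
class LineageClusteringResult:
    """UPGMA dendrogram over samples plus the marker matrix used."""

    linkage: np.ndarray          # scipy linkage matrix (merge heights non-decreasing)
    sample_ids: list[str]
    marker_matrix: pd.DataFrame  # markers x samples

    def cut(self, k: int = 2) -> pd.Series:
        """Cluster assignments (1..k) at a k-cluster cut."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def newick(self) -> str:
        """Dendrogram as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def marker_expression(
    expression: pd.DataFrame,
    transcript_gene_map: pd.Series | None = None,
    markers=LINEAGE_MARKERS,
) -> pd.DataFrame:
    """Marker x sample expression matrix.

    Marker rows are taken directly when the expression index carries gene
    symbols; otherwise the transcript -> gene map is consulted, picking the
    highest-variance transcript per marker gene.  Missing markers raise a
    single error listing all of them.
    """
    rows, missing = {}, []
    for marker in markers:
        if marker in expression.index:
            rows[marker] = expression.loc[marker]
            continue
        txs = []
        if transcript_gene_map is not None:
            txs = [tx for tx, g in transcript_gene_map.items()
                   if g == marker and tx in expression.index]
        if not txs:
            missing.append(marker)
            continue
        best = max(txs, key=lambda tx: (float(np.nanvar(expression.loc[tx])), tx))
        rows[marker] = expression.loc[best]
    if missing:
        raise DataValidationError(f"lineage markers missing from expression: {missing}")
    return pd.DataFrame(rows).T


def lineage_clustering(
    expression: pd.DataFrame,
    transcript_gene_map: pd.Series | None = None,
    markers=LINEAGE_MARKERS,
) -> LineageClusteringResult:
    """Average-linkage (UPGMA) clustering of samples on marker expression.

    Distances are Euclidean over the log2 expression of the marker genes.
    The merge order is deterministic for a given sample order (equal
    distances resolve to the lowest-index pair).
    """
    marker_mat = marker_expression(expression, transcript_gene_map, markers)
    if marker_mat.shape[1] < 2:
        raise DataValidationError("clustering requires at least 2 samples")
    data = marker_mat.T.to_numpy()
    if not np.isfinite(data).all():
        raise DataValidationError("marker expression contains missing values")
    linkage = hierarchy.linkage(data, method="average", metric="euclidean")
    return LineageClusteringResult(
        linkage=linkage,
        sample_ids=list(marker_mat.columns),
        marker_matrix=marker_mat,
    )


def marker_correlations(
    feature: pd.Series,
    marker_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman and Pearson correlation of one feature with each marker."""
    shared = [s for s in marker_matrix.columns if s in set(feature.index)]
    rows = []
    for marker in marker_matrix.index:
        sp = spearman(feature[shared], marker_matrix.loc[marker, shared])
        pe = pearson(feature[shared], marker_matrix.loc[marker, shared])
        rows.append({
            "marker": marker,
            "spearman_rho": sp.coefficient if sp else np.nan,
            "spearman_p": sp.p_value if sp else np.nan,
            "pearson_r": pe.coefficient if pe else np.nan,
            "pearson_p": pe.p_value if pe else np.nan,
            "n_used": sp.n_used if sp else 0,
        })
    return pd.DataFrame(rows)
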