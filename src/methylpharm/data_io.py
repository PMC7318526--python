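"""Reading, writing and cross-validating the pipeline's tabular inputs.

All matrices travel as TSV with feature ids in the first column and sample
ids as remaining columns; missing values are the literal ``NA``.  The probe
manifest is a CSV whose gene and region columns are semicolon lists paired
positionally, following the EPIC manifest's UCSC_RefGene_Name /
UCSC_RefGene_Group convention.  Drug replicates arrive as a long CSV with
header ``agent,cell_line,replicate,ic50`` (IC50 in molar units).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "REGION_CLASSES",
    "DataValidationError",
    "ManifestParseError",
    "ProbeAnnotation",
    "DatasetBundle",
    "RESULT_COLUMNS",
    "load_matrix",
    "write_matrix",
    "load_beta_matrix",
    "load_detection_p_matrix",
    "load_manifest",
    "write_manifest",
    "load_drug_replicates",
    "write_drug_replicates",
    "load_expression",
    "load_transcript_gene_map",
    "load_copy_number",
    "load_gene_list",
    "load_dataset",
    "write_results",
    "read_results",
]

#: The six gene-region classes of the EPIC manifest annotation.
REGION_CLASSES: tuple[str, ...] = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")


class DataValidationError(ValueError):
    """A table violated an invariant (range, axis alignment, positivity)."""


class ManifestParseError(ValueError):
    """The probe manifest could not be parsed (e.g. unpaired gene/region lists)."""


@dataclass(frozen=True)
class ProbeAnnotation:
    """Annotation of one methylation probe.

    ``gene_assignments`` is an ordered tuple of (gene symbol, region class)
    pairs; it is empty for intergenic probes.  ``position`` is 1-based.
    """

    probe_id: str
    chromosome: str
    position: int
    cytoband: str
    gene_assignments: tuple[tuple[str, str], ...]
    snp_masked: bool

    def __post_init__(self) -> None:
        for gene, region in self.gene_assignments:
            if region not in REGION_CLASSES:
                raise ManifestParseError(
                    f"probe {self.probe_id}: unknown region class {region!r}"
                )
            if not gene:
                raise ManifestParseError(f"probe {self.probe_id}: empty gene symbol")


@dataclass
class DatasetBundle:
    """The full set of tables one analysis run consumes."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    manifest: dict[str, ProbeAnnotation]
    drug_replicates: pd.DataFrame
    expression: pd.DataFrame | None = None
    transcript_gene_map: pd.Series | None = None
    copy_number: pd.DataFrame | None = None
    candidate_genes: frozenset[str] = field(default_factory=frozenset)
    candidate_agents: frozenset[str] = field(default_factory=frozenset)

    @property
    def shared_samples(self) -> list[str]:
        """Sample ids present in every required table (sorted)."""
        shared = set(self.beta.columns) & set(self.drug_replicates["cell_line"])
        if self.expression is not None:
            shared &= set(self.expression.columns)
        return sorted(shared)


# ---------------------------------------------------------------------------
# matrices


def load_matrix(path, na_values: str = "NA") -> pd.DataFrame:
    """Load a TSV matrix (first column = row id, remaining columns = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[na_values],
                     keep_default_na=False, comment="#")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataValidationError(f"{path}: duplicate row id {dup!r}")
    if df.columns.has_duplicates:
        raise DataValidationError(f"{path}: duplicate sample ids")
    bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        where = f"row {row[0]!r}, column {col!r}" if len(row) else f"column {col!r}"
        raise DataValidationError(f"{path}: non-numeric cell at {where}")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path, na_rep: str = "NA") -> None:
    df.to_csv(path, sep="\t", na_rep=na_rep, index_label="id")


def _check_unit_interval(df: pd.DataFrame, path, what: str) -> None:
    vals = df.to_numpy()
    bad = (vals < 0) | (vals > 1)
    bad &= np.isfinite(vals)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise DataValidationError(
            f"{path}: {what} {vals[i, j]!r} outside [0, 1] at "
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
        )


def load_beta_matrix(path) -> pd.DataFrame:
    """Load a probe x sample beta-value matrix; values must lie in [0, 1]."""
    df = load_matrix(path)
    _check_unit_interval(df, path, "beta-value")
    return df


def load_detection_p_matrix(path) -> pd.DataFrame:
    """Load a probe x sample detection-p matrix; values must lie in [0, 1]."""
    df = load_matrix(path)
    if df.isna().any().any():
        raise DataValidationError(f"{path}: detection p-values may not be missing")
    _check_unit_interval(df, path, "detection p")
    return df


# ---------------------------------------------------------------------------
# manifest


def _parse_assignments(probe_id: str, genes: str, regions: str):
    gene_list = [g for g in str(genes).split(";") if g] if genes else []
    region_list = [r for r in str(regions).split(";") if r] if regions else []
    if len(gene_list) != len(region_list):
        raise ManifestParseError(
            f"probe {probe_id}: gene list ({len(gene_list)}) and region list "
            f"({len(region_list)}) have different lengths"
        )
    seen, pairs = set(), []
    for pair in zip(gene_list, region_list):
        if pair not in seen:  # transcript-level duplicates collapse
            seen.add(pair)
            pairs.append(pair)
    return tuple(pairs)


def load_manifest(path) -> dict[str, ProbeAnnotation]:
    """Load the probe annotation CSV into an ordered probe -> annotation map."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"probe_id", "chromosome", "position", "cytoband", "genes",
                "regions", "snp_masked"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestParseError(f"{path}: missing columns {sorted(missing)}")
    manifest: dict[str, ProbeAnnotation] = {}
    for row in df.itertuples(index=False):
        if row.probe_id in manifest:
            raise ManifestParseError(f"{path}: duplicate probe id {row.probe_id!r}")
        manifest[row.probe_id] = ProbeAnnotation(
            probe_id=row.probe_id,
            chromosome=row.chromosome,
            position=int(row.position),
            cytoband=row.cytoband,
            gene_assignments=_parse_assignments(row.probe_id, row.genes, row.regions),
            snp_masked=row.snp_masked in ("1", "True", "true", "TRUE"),
        )
    return manifest


def write_manifest(manifest: dict[str, ProbeAnnotation], path) -> None:
    rows = []
    for ann in manifest.values():
        rows.append({
            "probe_id": ann.probe_id,
            "chromosome": ann.chromosome,
            "position": ann.position,
            "cytoband": ann.cytoband,
            "genes": ";".join(g for g, _ in ann.gene_assignments),
            "regions": ";".join(r for _, r in ann.gene_assignments),
            "snp_masked": int(ann.snp_masked),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# drug response, expression, copy number, candidate lists


def load_drug_replicates(path) -> pd.DataFrame:
    """Load the replicate IC50 table (agent, cell_line, replicate, ic50 in M)."""
    df = pd.read_csv(path)
    required = {"agent", "cell_line", "replicate", "ic50"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    df["ic50"] = pd.to_numeric(df["ic50"], errors="raise")
    if (df["ic50"] <= 0).any() or df["ic50"].isna().any():
        bad = df.loc[(df["ic50"] <= 0) | df["ic50"].isna()].iloc[0]
        raise DataValidationError(
            f"{path}: non-positive IC50 for agent {bad['agent']!r}, "
            f"cell line {bad['cell_line']!r}"
        )
    return df


def write_drug_replicates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_expression(path) -> pd.DataFrame:
    """Load the transcript x sample log2 expression matrix."""
    return load_matrix(path)


def load_transcript_gene_map(path) -> pd.Series:
    """Load the transcript -> gene-symbol map (TSV: transcript_id, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"transcript_id", "gene"} <= set(df.columns):
        raise DataValidationError(f"{path}: expected columns transcript_id, gene")
    if df["transcript_id"].duplicated().any():
        raise DataValidationError(f"{path}: duplicate transcript ids")
    return df.set_index("transcript_id")["gene"]


def load_copy_number(path) -> pd.DataFrame:
    """Load the gene x sample log2 copy-number ratio matrix (finite values)."""
    df = load_matrix(path)
    if df.isna().any().any():
        raise DataValidationError(f"{path}: copy-number values must be finite")
    return df


def load_gene_list(path) -> frozenset[str]:
    """Load a plain-text list (one symbol per line, '#' comments allowed)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return frozenset(out)


# ---------------------------------------------------------------------------
# bundle


def load_dataset(config) -> DatasetBundle:
    """Load every table named in a path config (dict or YAML file path).

    Recognised keys: beta, detection_p, manifest, drug_replicates,
    expression, transcript_gene_map, copy_number, candidate_genes,
    candidate_agents.  The beta and detection-p matrices must share axes
    exactly; the shared-sample intersection across tables is logged.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    for key in ("beta", "detection_p", "manifest", "drug_replicates"):
        if key not in config:
            raise DataValidationError(f"path config is missing required key {key!r}")
        if not Path(config[key]).exists():
            raise DataValidationError(f"{key} file not found: {config[key]}")

    beta = load_beta_matrix(config["beta"])
    detp = load_detection_p_matrix(config["detection_p"])
    if not beta.index.equals(detp.index) or not beta.columns.equals(detp.columns):
        raise DataValidationError(
            "beta and detection-p matrices have mismatched axes"
        )
    manifest = load_manifest(config["manifest"])
    replicates = load_drug_replicates(config["drug_replicates"])

    bundle = DatasetBundle(beta=beta, detection_p=detp, manifest=manifest,
                           drug_replicates=replicates)
    if config.get("expression"):
        bundle.expression = load_expression(config["expression"])
    if config.get("transcript_gene_map"):
        bundle.transcript_gene_map = load_transcript_gene_map(config["transcript_gene_map"])
    if config.get("copy_number"):
        bundle.copy_number = load_copy_number(config["copy_number"])
    if config.get("candidate_genes"):
        bundle.candidate_genes = load_gene_list(config["candidate_genes"])
    if config.get("candidate_agents"):
        bundle.candidate_agents = load_gene_list(config["candidate_agents"])

    shared = bundle.shared_samples
    logger.info(
        "loaded dataset: %d probes, %d samples in beta; %d samples shared "
        "across required tables", beta.shape[0], beta.shape[1], len(shared)
    )
    return bundle


# ---------------------------------------------------------------------------
# association-record TSV

#: Stable column order of every association-record table.
RESULT_COLUMNS: tuple[str, ...] = (
    "feature_id", "feature_kind", "gene", "region_class", "agent",
    "coefficient", "p_value", "p_fdr", "passes_strict", "passes_liberal",
    "n_used", "family",
)


def write_results(records: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    """Write association records as TSV with a stable column and row order.

    Rows are sorted by (p_value, feature_id, agent); ``header_comments``
    become '#'-prefixed provenance lines at the top of the file.
    """
    out = records.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[list(RESULT_COLUMNS)]
    if len(out):
        out = out.sort_values(["p_value", "feature_id", "agent"], kind="mergesort")
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    """Read an association-record TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                     keep_default_na=False)
    for col in ("passes_strict", "passes_liberal"):
        if col in df.columns and df[col].notna().any():
            df[col] = df[col].astype("boolean").astype(object)
    return df
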