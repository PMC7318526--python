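"""Gene-region averaging of probe-level methylation.

Each probe may be annotated to several (gene, region-class) pairs; the six
region classes (TSS1500, TSS200, 5'UTR, first exon, gene body, 3'UTR) are
kept strictly separate.  A region's value in a sample is the unweighted
arithmetic mean of the non-missing member-probe betas; it is missing only
when every member probe is missing in that sample.  Aggregation runs on the
QC-filtered matrix, so averages never include masked cells or dropped probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import sparse

from .data_io import REGION_CLASSES, ProbeAnnotation

logger = logging.getLogger(__name__)

__all__ = ["RegionKey", "RegionIndex", "build_region_index", "average_region_betas",
           "region_key_from_string"]


class RegionKey(NamedTuple):
    """Identity of one aggregated region: (gene symbol, region class)."""

    gene: str
    region_class: str

    def __str__(self) -> str:
        return f"{self.gene}|{self.region_class}"


def region_key_from_string(s: str) -> RegionKey:
    gene, _, region = s.rpartition("|")
    return RegionKey(gene, region)


@dataclass
class RegionIndex:
    """Mutually consistent region -> probes and probe -> regions maps."""

    probes_by_region: dict[RegionKey, tuple[str, ...]] = field(default_factory=dict)
    regions_by_probe: dict[str, frozenset[RegionKey]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probes_by_region)


def build_region_index(
    manifest: dict[str, ProbeAnnotation],
    retained_probes,
) -> RegionIndex:
    """Index QC-retained probes under every (gene, region) they annotate.

    Multi-gene / multi-region probes appear under each of their keys;
    intergenic probes appear under none.
    """
    retained = set(retained_probes)
    unknown = retained - set(manifest)
    if unknown:
        raise ValueError(f"retained probes missing from manifest: {sorted(unknown)[:5]}")
    forward: dict[RegionKey, list[str]] = {}
    reverse: dict[str, set[RegionKey]] = {}
    for probe_id, ann in manifest.items():
        if probe_id not in retained:
            continue
        for gene, region in ann.gene_assignments:
            key = RegionKey(gene, region)
            forward.setdefault(key, []).append(probe_id)
            reverse.setdefault(probe_id, set()).add(key)
    return RegionIndex(
        probes_by_region={k: tuple(v) for k, v in forward.items()},
        regions_by_probe={p: frozenset(k) for p, k in reverse.items()},
    )


def average_region_betas(
    beta: pd.DataFrame,
    index: RegionIndex,
) -> tuple[pd.DataFrame, pd.Series]:
    """Average member-probe betas per region and sample.

    Returns the region x sample matrix (row ids ``GENE|REGIONCLASS``) and a
    probe count per region.  Regions whose member probes are all absent from
    ``beta`` (e.g. dropped by QC) are omitted and logged.
    """
    keys, rows, cols = [], [], []
    probe_pos = {p: i for i, p in enumerate(beta.index)}
    dropped = 0
    for key in sorted(index.probes_by_region):
        probes = [p for p in index.probes_by_region[key] if p in probe_pos]
        if not probes:
            dropped += 1
            continue
        r = len(keys)
        keys.append(key)
        rows.extend([r] * len(probes))
        cols.extend(probe_pos[p] for p in probes)
    if dropped:
        logger.info("omitted %d regions with no retained probes", dropped)

    membership = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(keys), beta.shape[0])
    )
    vals = beta.to_numpy()
    present = np.isfinite(vals)
    sums = membership @ np.where(present, vals, 0.0)
    counts = membership @ present.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)

    region_ids = [str(k) for k in keys]
    region_df = pd.DataFrame(means, index=region_ids, columns=beta.columns)
    probes_per_region = pd.Series(
        np.asarray(membership.sum(axis=1)).ravel().astype(int),
        index=region_ids, name="n_probes"
    )
    return region_df, probes_per_region
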