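"""Probe-level quality control for methylation beta matrices.

Two filters produce the analysis-ready matrix:

* cell masking — any beta whose detection p is >= 1e-3 (boundary inclusive)
  is set to missing;
* probe removal — probes whose median detection p across all samples is
  >= 1e-6, and probes carrying the SNP-overlap mask flag, are dropped.

Both steps are local (per cell / per probe) so their order does not change
the retained probe set, and re-running QC on its own output is a no-op.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .data_io import DataValidationError, ProbeAnnotation

__all__ = ["QcReport", "mask_low_quality_values", "drop_unreliable_probes", "run_probe_qc"]

DETECTION_P_VALUE_THRESHOLD = 1e-3
DETECTION_P_MEDIAN_THRESHOLD = 1e-6


@dataclass
class QcReport:
    """Accounting of what QC removed; retained + dropped = input probes."""

    n_values_masked: int = 0
    n_probes_dropped_detp: int = 0
    n_probes_dropped_snp: int = 0
    n_probes_retained: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _check_axes(beta: pd.DataFrame, detp: pd.DataFrame) -> None:
    if not beta.index.equals(detp.index) or not beta.columns.equals(detp.columns):
        raise DataValidationError("beta and detection-p matrices have mismatched axes")


def mask_low_quality_values(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    value_threshold: float = DETECTION_P_VALUE_THRESHOLD,
) -> tuple[pd.DataFrame, QcReport]:
    """Set to missing every beta cell whose detection p >= ``value_threshold``.

    ``n_values_masked`` counts only cells that were non-missing before.
    """
    _check_axes(beta, detp)
    unreliable = detp.to_numpy() >= value_threshold
    newly = unreliable & np.isfinite(beta.to_numpy())
    masked = beta.mask(pd.DataFrame(unreliable, index=beta.index, columns=beta.columns))
    return masked, QcReport(n_values_masked=int(newly.sum()),
                            n_probes_retained=beta.shape[0])


def drop_unreliable_probes(
    detp: pd.DataFrame,
    manifest: dict[str, ProbeAnnotation],
    median_threshold: float = DETECTION_P_MEDIAN_THRESHOLD,
) -> tuple[pd.Index, QcReport]:
    """Probes to retain after the median-detection-p and SNP-mask filters.

    A probe failing both filters is counted once, under the detection-p
    reason, so the report's counts always reconcile with the matrix diff.
    """
    medians = detp.median(axis=1)
    bad_detp = medians >= median_threshold
    snp = pd.Series(
        [manifest[p].snp_masked if p in manifest else False for p in detp.index],
        index=detp.index,
    )
    snp_only = snp & ~bad_detp
    retained = detp.index[~bad_detp & ~snp]
    report = QcReport(
        n_probes_dropped_detp=int(bad_detp.sum()),
        n_probes_dropped_snp=int(snp_only.sum()),
        n_probes_retained=int(len(retained)),
    )
    return retained, report


def run_probe_qc(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    manifest: dict[str, ProbeAnnotation],
    value_threshold: float = DETECTION_P_VALUE_THRESHOLD,
    median_threshold: float = DETECTION_P_MEDIAN_THRESHOLD,
) -> tuple[pd.DataFrame, QcReport]:
    """Mask low-quality cells, then drop unreliable / SNP-masked probes.

    The probe median uses all detection p-values (masked cells included),
    so the two steps commute on the retained probe set.
    """
    masked, mask_report = mask_low_quality_values(beta, detp, value_threshold)
    retained, drop_report = drop_unreliable_probes(detp, manifest, median_threshold)
    filtered = masked.loc[retained]
    report = QcReport(
        n_values_masked=mask_report.n_values_masked,
        n_probes_dropped_detp=drop_report.n_probes_dropped_detp,
        n_probes_dropped_snp=drop_report.n_probes_dropped_snp,
        n_probes_retained=drop_report.n_probes_retained,
    )
    return filtered, report
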