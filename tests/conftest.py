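"""Shared fixtures: small synthetic bundles and their derived artifacts."""

import pytest

from methylpharm import associations as assoc
from methylpharm.qc import run_probe_qc
from methylpharm.regions import average_region_betas, build_region_index
from methylpharm.simulate import SimulationConfig, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """A desk-scale screen: 24 genes, 66 samples, 12 agents."""
    base = dict(
        n_samples=66,
        n_genes=24,
        probes_per_region={"TSS1500": 2, "TSS200": 2, "5UTR": 1,
                           "1stExon": 1, "Body": 3, "3UTR": 1},
        n_intergenic=10,
        n_agents=12,
        n_constant_agents=2,
        n_canonical=3,
        n_positive_coupled=2,
        n_cn_driven=2,
        n_lineage_linked=6,
        n_bad_probes=3,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """QC-filtered beta, region matrix, variable-agent response for the bundle."""
    b = small_dataset.bundle
    filtered, qc_report = run_probe_qc(b.beta, b.detection_p, b.manifest)
    index = build_region_index(b.manifest, filtered.index)
    regions, probes_per_region = average_region_betas(filtered, index)
    response = assoc.median_log_ic50(b.drug_replicates)
    variable, exclusions = assoc.filter_variable_agents(response)
    return {
        "filtered_beta": filtered,
        "qc_report": qc_report,
        "region_index": index,
        "regions": regions,
        "probes_per_region": probes_per_region,
        "response": response.loc[variable],
        "full_response": response,
        "agent_exclusions": exclusions,
    }


@pytest.fixture(scope="session")
def small_records(small_dataset, small_pipeline):
    probe_records, region_records = assoc.epigenome_wide_analysis(
        small_pipeline["filtered_beta"],
        small_pipeline["regions"],
        small_pipeline["response"],
        probe_meta=assoc.probe_metadata(small_dataset.bundle.manifest),
    )
    return probe_records, region_records
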