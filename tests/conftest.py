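import numpy as np
import pandas as pd
import pytest

import ampliconvar as av
from ampliconvar.containers import FeatureTable, make_metadata


@pytest.fixture(scope="session")
def full_study():
    """Full 19-run synthetic study (218 mock + 29 stool + 222 negatives)."""
    return av.simulate_study(seed=11)


@pytest.fixture(scope="session")
def qc_result(full_study):
    return av.qc_pipeline(full_study.counts, full_study.metadata,
                          rarefaction_seed=3)


def dilution_run_design(seed):
    """The prospective dilution run plus its negative controls."""
    return av.StudyDesign(runs=(av.RunDesign("run18", n_negative=24),),
                          dilution_levels=av.simulate.DILUTION_FACTORS,
                          replicates_per_level=10, seed=seed)


@pytest.fixture(scope="session")
def dilution_qc():
    """QC-filtered dilution series of a 12-strain staggered mock community."""
    spec = av.mock_community(n_taxa=12, proportions="staggered")
    study = av.simulate_study(spec, dilution_run_design(seed=5))
    qc = av.qc_pipeline(study.counts, study.metadata, rarefaction_seed=5)
    return study, qc


@pytest.fixture
def tiny_table():
    """Hand-built 4 SV x 4 sample table with 2 negative controls."""
    counts = pd.DataFrame(
        {
            "s1": [5, 10, 0, 4],
            "s2": [40, 10, 0, 6],
            "n1": [3, 0, 7, 0],
            "n2": [2, 0, 3, 0],
        },
        index=["sv1", "sv2", "sv3", "sv4"],
    )
    taxonomy = pd.Series(
        {
            "sv1": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Enterococcaceae; g__Enterococcus; s__faecalis",
            "sv2": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Enterococcaceae; g__Enterococcus; s__faecium",
            "sv3": "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Pseudomonadales; f__Pseudomonadaceae; g__Pseudomonas; s__",
            "sv4": "k__Bacteria; p__Firmicutes; c__Bacilli; o__; f__; g__; s__",
        }
    )
    table = FeatureTable(counts, taxonomy)
    metadata = make_metadata(pd.DataFrame({
        "sample_id": ["s1", "s2", "n1", "n2"],
        "run_id": ["run01", "run02", "run01", "run02"],
        "sample_type": ["mock", "mock", "negative", "negative"],
    }))
    return table, metadata
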