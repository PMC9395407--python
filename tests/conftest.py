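import numpy as np
import pytest

import ovinecnv as oc


@pytest.fixture(scope="session")
def tiny_config() -> oc.SimConfig:
    """A minutes-free miniature cohort: 2 breeds x 4, 2 chromosomes x 300."""
    return oc.SimConfig(
        n_breeds=2,
        n_per_breed=4,
        n_chromosomes=2,
        snps_per_chromosome=300,
        chrom_length_bp=15_000_000,
        cnvs_per_individual_mean=1.0,
        cnv_length_range_bp=(100_000, 2_000_000),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config) -> oc.Cohort:
    return oc.simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def desk_cohort() -> oc.Cohort:
    """The reduced reference-scale cohort: 2 breeds x 15, 5,000 SNPs, seed 7."""
    return oc.simulate_cohort(oc.pipeline.desk_scale_config(seed=7).sim)


@pytest.fixture(scope="session")
def desk_calls(desk_cohort):
    """CNV calls over every sample of the desk-scale cohort (no sample QC)."""
    import pandas as pd

    coh = desk_cohort
    theta = oc.signal.compute_theta(coh.x, coh.y)
    clusters = oc.signal.estimate_clusters(theta, coh.x + coh.y, coh.dosage)
    sigs = [
        oc.signal.transform_sample(row.sample_id, row.breed, coh.x[i], coh.y[i], clusters)
        for i, row in coh.samples.iterrows()
    ]
    pfb, _ = oc.signal.compile_pfb(np.vstack([s.baf for s in sigs]))
    chrom = coh.marker_map["chrom"].to_numpy()
    pos = coh.marker_map["pos"].to_numpy()
    calls = []
    for s in sigs:
        for c in pd.unique(chrom):
            sel = (chrom == c) & clusters.usable
            got, _ = oc.hmm.call_chromosome(
                pos[sel], s.lrr[sel], s.baf[sel], pfb[sel], oc.hmm.DEFAULT_PARAMS, s.sample_id, str(c)
            )
            calls.extend(got)
    return calls
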