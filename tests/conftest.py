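import numpy as np
import pytest

import sweepmix as sm


@pytest.fixture(scope="session")
def toy():
    """One toy genome shared across the suite (generation ~1 s)."""
    return sm.simulate_toy_genome(seed=3)


@pytest.fixture(scope="session")
def toy_pipeline_features(toy):
    """Feature table produced by running the pipeline on the toy genome."""
    snps = sm.filter_maf(toy.snps)
    snps, _ = sm.standardize_ihs(snps)
    result = sm.assemble_feature_table(
        toy.genes, toy.window_size, toy.gmap, toy.density_tracks, toy.gaps,
        toy.sequences, snps, chrom_lengths=toy.chrom_lengths)
    return result


@pytest.fixture()
def small_params():
    return sm.MDRParameters(intercept=-0.85, slopes=np.array([0.5, -0.5]),
                            mu0=-0.39, sigma0=0.85, mu1=0.9, sigma1=0.95)
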