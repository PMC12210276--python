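import numpy as np
import pandas as pd
import pytest

import chromcal as cc


@pytest.fixture(scope="session")
def atac_sim():
    """Mid-sized paired cohort with planted differential regions and one
    informative plus one pure-noise covariate."""
    spec = cc.AtacSimSpec(
        n_subjects=20,
        n_regions=500,
        frac_differential=0.1,
        effect_lfc=2.0,
        covariates=[("frip_dev", 1.0, 0.2), ("noise_cov", 0.0, 0.0)],
        seed=11,
    )
    matrix, sheet, truth = cc.simulate_atac_counts(spec)
    return matrix, sheet, truth


@pytest.fixture(scope="session")
def normalized_atac(atac_sim):
    matrix, sheet, truth = atac_sim
    filtered, _ = cc.filter_low_signal(matrix)
    normalized, factors = cc.normalize_pipeline(filtered, sheet)
    return normalized, sheet, truth, factors


def toy_count_matrix(counts: np.ndarray, library_sizes=None) -> cc.RegionCountMatrix:
    """Wrap a plain array as a RegionCountMatrix with dummy coordinates."""
    counts = np.asarray(counts)
    n_reg, n_samp = counts.shape
    regions = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_reg) * 100,
            "end": np.arange(n_reg) * 100 + 50,
        },
        index=[f"r{i}" for i in range(n_reg)],
    )
    cdf = pd.DataFrame(
        counts, index=regions.index, columns=[f"s{j}" for j in range(n_samp)]
    )
    libs = (
        None
        if library_sizes is None
        else pd.Series(library_sizes, index=cdf.columns)
    )
    return cc.RegionCountMatrix(regions=regions, counts=cdf, library_sizes=libs)
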