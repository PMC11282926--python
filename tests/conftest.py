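import numpy as np
import pandas as pd
import pytest

from prs_interplay.containers import GenotypeMatrix
from prs_interplay.simulate import ArtifactConfig, SimConfig, simulate_cohort


def make_geno(dosages, chrom=None, pos=None, ref="A", alt="G", info=1.0,
              ids=None):
    """Toy GenotypeMatrix from a dense dosage array."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    variants = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
        "id": ids if ids is not None else [f"v{j + 1}" for j in range(m)],
        "ref": [ref] * m if isinstance(ref, str) else ref,
        "alt": [alt] * m if isinstance(alt, str) else alt,
        "info": [info] * m if np.isscalar(info) else info,
    })
    samples = np.array([f"S{i + 1:04d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(d, samples, variants)


@pytest.fixture(scope="session")
def small_cohort():
    """A small clean simulated cohort shared across read-only tests."""
    cfg = SimConfig(n_cases=200, n_controls=1000, n_variants=2000, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def artifact_cohort():
    """Small cohort with injected duplicates/relatives/bad variants."""
    cfg = SimConfig(n_cases=60, n_controls=120, n_variants=3000, seed=5,
                    missing_rate=0.01)
    art = ArtifactConfig(n_duplicates=2, n_relatives=2, n_hwe_violations=3,
                         n_low_info=3)
    return simulate_cohort(cfg, art)
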