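import numpy as np
import pandas as pd
import pytest

from hapgwas.genotypes import PhasedGenotypes
from hapgwas.sim import SimConfig, default_qtl_panel, simulate_study


def make_geno(hap, chrom="1", pos=None, samples=None):
    """Small helper: wrap a (2n, m) 0/1 array as PhasedGenotypes."""
    hap = np.asarray(hap, dtype=np.int8)
    n2, m = hap.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if samples is None:
        samples = [f"s{i}" for i in range(n2 // 2)]
    variants = pd.DataFrame({
        "chrom": chrom, "pos": pos, "id": [f"m{j}" for j in range(m)],
        "ref": "A", "alt": "G",
    })
    return PhasedGenotypes(samples, variants, hap)


@pytest.fixture(scope="session")
def small_study():
    """One frozen simulated study with planted QTL (session-cached)."""
    cfg = SimConfig(seed=11, qtls=default_qtl_panel())
    geno, phen, truth = simulate_study(cfg)
    return cfg, geno, phen, truth
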