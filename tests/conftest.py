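import numpy as np
import pandas as pd
import pytest

from pennyscan.io_formats import GenotypeMatrix
from pennyscan.synthetic_data import SimConfig, ToyGeneSpec, make_toy_gene, simulate_neutral_cohort


def matrix_from_haplotypes(hap, positions=None, chrom="Chr1", pops=None, groups=None, anc=True):
    """Build a GenotypeMatrix from a (sites x haplotypes) 0/1 array.

    Haplotype columns pair into diploids; default labels put the first half
    of samples into H1/HG and the second into L1/LG.
    """
    hap = np.asarray(hap, dtype=np.int8)
    n_sites, n_hap = hap.shape
    assert n_hap % 2 == 0
    n_samples = n_hap // 2
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    if pops is None:
        half = n_samples // 2 or n_samples
        pops = ["H1"] * half + ["L1"] * (n_samples - half)
    if groups is None:
        groups = ["HG" if p.startswith("H") else "LG" for p in pops]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "ref": "A",
            "alt": "T",
        }
    )
    if anc:
        sites["anc"] = "A"
    return GenotypeMatrix(
        sites=sites,
        samples=[f"s{i}" for i in range(n_samples)],
        populations=np.array(pops, dtype=object),
        groups=np.array(groups, dtype=object),
        dosage=(hap[:, 0::2] + hap[:, 1::2]).astype(np.int8),
        haplotypes=hap,
    )


@pytest.fixture(scope="session")
def neutral_cohort():
    """One deterministic 1-Mb neutral cohort under the default study design."""
    return simulate_neutral_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def toy_gene_plus():
    return make_toy_gene(ToyGeneSpec(strand="+"))


@pytest.fixture(scope="session")
def toy_gene_minus():
    return make_toy_gene(ToyGeneSpec(strand="-"))
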