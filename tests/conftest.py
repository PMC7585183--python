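import numpy as np
import pytest

from sweepscan.genotype_io import PopulationManifest, VariantMatrix
from sweepscan.synthetic_data import SimulationConfig, simulate_genotypes


def make_matrix(sites, sample_ids, ploidy=2):
    """Build a VariantMatrix from [(chrom, pos, ref, alt, genotype rows), ...]."""
    chroms, poss, refs, alts, classes, gts = [], [], [], [], [], []
    for chrom, pos, ref, alt, rows in sites:
        chroms.append(chrom)
        poss.append(pos)
        refs.append(ref)
        alts.append(alt)
        classes.append("SNP" if len(ref) == len(alt) == 1 else "indel")
        gts.append(np.array(rows, dtype=np.int8))
    genotypes = (
        np.stack(gts) if gts else np.zeros((0, len(sample_ids), ploidy), dtype=np.int8)
    )
    return VariantMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        vclass=np.array(classes, dtype=object),
        genotypes=genotypes,
        sample_ids=list(sample_ids),
    )


@pytest.fixture
def two_pop_manifest():
    return PopulationManifest(
        {
            "W1": "wild", "W2": "wild", "W3": "wild",
            "L1": "local", "L2": "local", "L3": "local",
            "I1": "improved", "I2": "improved",
        }
    )


@pytest.fixture(scope="session")
def default_panel():
    """One deterministic draw of the default synthetic three-population panel."""
    cfg = SimulationConfig(seed=1)
    vm, manifest, regions, truth = simulate_genotypes(cfg)
    return cfg, vm, manifest, regions, truth
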