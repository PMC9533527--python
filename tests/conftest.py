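import numpy as np
import pandas as pd
import pytest

import corrscan as cs


@pytest.fixture(scope="session")
def tiny_map() -> cs.SnpMap:
    """3 SNPs on one chromosome."""
    return cs.SnpMap(
        chromosome=np.array(["1", "1", "1"], dtype=object),
        position=np.array([100, 200, 300], dtype=np.int64),
        snp_id=np.array(["s1", "s2", "s3"], dtype=object),
    )


@pytest.fixture(scope="session")
def desk_map() -> cs.SnpMap:
    """The desk-scale study map: 10 chromosomes x 1500 SNPs -> 110 windows."""
    return cs.default_fixture_map()


@pytest.fixture(scope="session")
def small_geno() -> cs.GenotypeMatrix:
    """200 individuals x 3 chromosomes x 400 SNPs with short-range LD."""
    return cs.simulate_genotypes(200, cs.uniform_map(3, 400), ld_rho=0.3, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_pheno(ids, y, groups=None, trait="t"):
    df = pd.DataFrame({"id": ids, trait: y})
    if groups is not None:
        df["group"] = groups
    return cs.PhenotypeTable.from_frame(df, trait, fixed=["group"] if groups is not None else [])
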