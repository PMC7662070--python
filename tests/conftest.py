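import numpy as np
import pytest

from plsgp.bayes import correct_phenotypes
from plsgp.genio import GenotypeMatrix, make_pedigree
from plsgp.relmat import filter_markers
from plsgp.simulate import SimConfig, simulate_study


@pytest.fixture
def toy_genotypes():
    """One-marker two-individual toy: dosages (0, 2), p = 0.5."""
    return GenotypeMatrix(["a", "b"], ["m1"], np.array([[0.0], [2.0]]))


@pytest.fixture
def fullsib_pedigree():
    """Two founders and a full-sib pair."""
    return make_pedigree([("s", "0", "0"), ("d", "0", "0"),
                          ("c1", "s", "d"), ("c2", "s", "d")])


@pytest.fixture(scope="session")
def small_study():
    """A modest simulated study shared by sampler/CV tests.

    200 genotypes in 20 full-sib families, 500 markers, 2 traits with
    h2 = (0.3, 0.5) and r_G = 0.6.
    """
    R = np.array([[1.0, 0.6], [0.6, 1.0]])
    cfg = SimConfig(n_founders=20, n_families=20, n_per_family=9,
                    n_markers=500, n_qtl=100, target_h2=(0.3, 0.5),
                    target_rG=R, n_replicates=2, n_blocks_per_replicate=4,
                    seed=11)
    geno, ped, pheno, truth = simulate_study(cfg)
    geno = filter_markers(geno, 0.05, 0.0)
    corrected = correct_phenotypes(pheno, ["block"])
    corrected = corrected.loc[geno.individual_ids]
    return {"config": cfg, "genotypes": geno, "pedigree": ped,
            "phenotypes": pheno, "truth": truth, "corrected": corrected}
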