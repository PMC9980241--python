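import numpy as np
import pytest

from prsmix.pgs_io import VariantKey
from prsmix.scoring import GenotypeMatrix, build_panel
from prsmix.simulate import make_demo_study


@pytest.fixture(scope="session")
def demo_study():
    """Small end-to-end study: genotypes, 6 harmonized scorings, outcome, covariates."""
    return make_demo_study(n_samples=1200, m=60, n_gwas=2500, h2=0.5, seed=7)


@pytest.fixture(scope="session")
def demo_panel(demo_study):
    genotypes, scorings, _, _ = demo_study
    panel = build_panel(genotypes, scorings)
    panel.trait_labels = {s.score_id: s.trait_label for s in scorings}
    return panel


@pytest.fixture
def small_genotypes():
    """Deterministic 4-sample, 3-variant dosage matrix without missingness."""
    variants = [
        VariantKey("1", 100, "A", "G"),
        VariantKey("1", 200, "C", "T"),
        VariantKey("2", 300, "G", "C"),
    ]
    dosages = np.array([
        [0.0, 1.0, 2.0],
        [2.0, 0.0, 1.0],
        [1.0, 2.0, 0.0],
        [1.0, 1.0, 1.0],
    ])
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], variants, dosages)
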