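import numpy as np
import pytest

from ceus_radiomics.features import extract_study
from ceus_radiomics.phantom import (ROIMask, default_roi, generate_study,
                                    generate_vessel_tree, phenotype_config,
                                    render_sequence)


def noiseless_config(phenotype="P2", **overrides):
    """A deterministic, noise-free phantom configuration."""
    return phenotype_config(phenotype, speckle_scale=0.0, bubble_flicker=0.0,
                            temporal_noise=0.0, background_level=0.0, **overrides)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-noise phantom scan with its ground truth and true ROI."""
    cfg = phenotype_config("P2", rng_seed=0)
    roi = default_roi(cfg)
    tree = generate_vessel_tree(cfg, roi)
    seq, truth = render_sequence(tree, cfg, roi)
    return cfg, ROIMask(roi), seq, truth


@pytest.fixture(scope="session")
def small_study():
    """A reduced study (1 animal per class, 64x64 frames) for fast end-to-end tests."""
    configs = {p: phenotype_config(p, image_size=(64, 64), n_frames=40,
                                   destruction_frame=14)
               for p in ("P1", "P2", "P3")}
    return generate_study(n_per_class=(1, 1, 1), configs=configs, seed=11)


@pytest.fixture(scope="session")
def default_study():
    """The default 28-scan-per-dataset test/retest study."""
    return generate_study(seed=1)


@pytest.fixture(scope="session")
def default_study_features(default_study):
    """Feature table of the default study (168 rows x 235 features)."""
    return extract_study(default_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
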