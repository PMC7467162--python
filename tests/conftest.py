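import numpy as np
import pytest

from waxshelix import boosted_models as bm
from waxshelix import dataset_builder as db
from waxshelix import helix_forge as hf


@pytest.fixture(scope="session")
def canonical_model():
    return hf.canonical_aform()


@pytest.fixture(scope="session")
def tiny_ensemble():
    """A dozen jittered conformations for geometry/scattering checks."""
    return hf.sample_ensemble(12, seed=42)


@pytest.fixture(scope="session")
def zero_jitter_params():
    """Fifty random parameter sets with no bead jitter (round-trip oracles)."""
    rng = np.random.default_rng(7)
    ranges = hf.ParameterRanges(jitter_scale=0.0)
    return [hf.sample_parameter_set(rng, f"zj{i:03d}", ranges) for i in range(50)]


@pytest.fixture(scope="session")
def small_dataset():
    """40 conformations x 9 conditions, split with the default fractions."""
    models = hf.sample_ensemble(40, seed=5)
    ds = db.assemble(models)
    return db.split_by_conformation(ds, seed=3)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced tree counts so unit tests stay fast; hyperparameters default."""
    return bm.TrainingConfig(
        n_trees_cv=25, n_trees_final=60, early_stopping_patience=15
    )
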