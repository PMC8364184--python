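import numpy as np
import pytest

from mscausal import network, training


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_arch():
    """A miniature architecture for fast structural and gradient tests."""
    return network.Architecture(
        image_size=16,
        kernel_size=6,
        n_kernels=4,
        mt_units=8,
        pivc_units=4,
        mstd_units=10,
        vest_units=8,
    )


@pytest.fixture(scope="session")
def desk_study():
    """One desk-preset training run shared by the slower analyses.

    Training a desk-scale network takes a few minutes; the emergent-property
    and behavioral tests all interrogate this single shared network (the
    acceptance script averages over a replicate ensemble instead).
    """
    cfg = training.desk_config(seed=202)
    dataset = training.generate_dataset(cfg.n_examples, cfg.seed, cfg.arch)
    params, history = training.train(cfg, dataset)
    thresholds = training.compute_causal_thresholds(dataset.vis_v, dataset.vest_v)
    return {
        "config": cfg,
        "dataset": dataset,
        "params": params,
        "history": history,
        "thresholds": thresholds,
    }


@pytest.fixture(scope="session")
def desk_characterization(desk_study):
    """Unit-characterization battery on the shared trained network."""
    from mscausal import characterization as chz
    from mscausal.experiments import characterize_network

    rng = np.random.default_rng(77)
    cfg = chz.CharacterizationConfig(n_trials_roc=64, n_trials_tuning=32, map_trials=4)
    return characterize_network(desk_study["params"], rng, cfg)
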