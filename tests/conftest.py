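import numpy as np
import pytest

from sacseg import pipeline, synthetic_data


@pytest.fixture(scope="session")
def small_scene():
    """One 96x96 scene with 10 nuclei, shared read-only across tests."""
    return synthetic_data.generate_scene(96, 96, 10, seed=3)


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory):
    """Eight 64x64 scenes with pseudo-labels on disk."""
    root = tmp_path_factory.mktemp("dataset64")
    scenes = synthetic_data.generate_dataset(8, 64, 64, (3, 7), seed=11)
    synthetic_data.write_dataset(scenes, root)
    pipeline.make_pseudo_labels(root, root / "labels")
    return root


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """One full desk-scale two-stage run (16 synthetic 96x96 images, tiny
    networks, 5+5 epochs), shared by the end-to-end assertions."""
    out = tmp_path_factory.mktemp("desk_run")
    cfg = pipeline.desk_scale_config(seed=0)
    cfg["baseline"] = {"enabled": True, "epochs": 5, "base_width": 8}
    result = pipeline.run_full(cfg, out)
    return out, cfg, result


def rng(seed=0):
    return np.random.default_rng(seed)
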