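import numpy as np
import pytest

from herdsense.accel_io import LabelCodec
from herdsense.pipeline import PipelineConfig, run_pipeline
from herdsense.windowing import WindowDataset


def make_window_dataset(counts: dict[str, int], T: int = 10, seed: int = 0,
                        dtype=np.float64) -> WindowDataset:
    """Random-feature window dataset with the given per-class counts."""
    codec = LabelCodec.from_labels(counts)
    rng = np.random.default_rng(seed)
    n = sum(counts.values())
    X = rng.normal(size=(n, T, 3)).astype(dtype)
    y = np.concatenate(
        [np.full(c, codec.code_of(name), dtype=np.int64) for name, c in counts.items()]
    )
    return WindowDataset(X=X, y=y, codec=codec)


@pytest.fixture(scope="session")
def e2e_results():
    """Full pipeline on the simulator preset, three seeds, with and without
    SMOTE balancing.  Computed once; several tests read different aspects."""
    out = {"smote": [], "ablation": []}
    for seed in (1, 2, 3):
        for key, use_smote in (("smote", True), ("ablation", False)):
            cfg = PipelineConfig(seed=seed, use_smote=use_smote)
            out[key].append(run_pipeline(cfg))
    return out
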