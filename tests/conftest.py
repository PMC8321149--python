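import numpy as np
import pytest
from hypothesis import settings

from mcslbp import (
    ColorImage,
    SyntheticConfig,
    extract_features,
    generate_arrays,
    run_strategy,
    evaluate_holdout,
)
from mcslbp.scores import sparse_similarity

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def naive_lbp_code_image(center_plane, neighbor_plane, R=1):
    """Independent per-pixel double-loop LBP reference (E, then CCW; s(0)=1)."""
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    c = np.asarray(center_plane, dtype=int)
    n = np.asarray(neighbor_plane, dtype=int)
    H, W = c.shape
    out = np.zeros((H - 2 * R, W - 2 * R), dtype=int)
    for i in range(R, H - R):
        for j in range(R, W - R):
            code = 0
            for p, (dy, dx) in enumerate(offsets):
                if n[i + dy * R, j + dx * R] >= c[i, j]:
                    code += 1 << p
            out[i - R, j - R] = code
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rgb_image(rng, h=8, w=8):
    return ColorImage(rng.integers(0, 256, size=(h, w, 3)).astype(np.uint8), "RGB")


@pytest.fixture
def random_image(rng):
    return random_rgb_image(rng)


def _run_one_seed(seed):
    """Full pipeline under the study conditions for one seed.

    4 classes, 5 images/class in each of train and test, 64x64, signal
    confined to the R channel, sigma = 8; the test subset doubles as the
    validation subset (benchmark-style protocol).
    """
    config = SyntheticConfig(seed=seed)
    images, labels, subsets, ids = generate_arrays(config, subsets=("train", "test"))
    fm = extract_features(images, labels, sample_ids=ids)
    train = fm.subset_rows(subsets == "train")
    test = fm.subset_rows(subsets == "test")
    S = sparse_similarity(train.values, train.labels)
    none_res = run_strategy("none", train, test, similarity=S)
    mcshs_res = run_strategy("MCSHS", train, test, similarity=S)
    mcshbs_res = run_strategy("MCSHBS", train, test, similarity=S)
    return {
        "seed": seed,
        "histogram_order": mcshs_res.ranking_order,
        "none_test_accuracy": evaluate_holdout(train, test, none_res).accuracy,
        "mcshs_test_accuracy": evaluate_holdout(train, test, mcshs_res).accuracy,
        "mcshbs_test_accuracy": evaluate_holdout(train, test, mcshbs_res).accuracy,
        "mcshbs_val_accuracy": mcshbs_res.best_validation_accuracy,
        "none_val_accuracy": none_res.best_validation_accuracy,
        "mcshbs_dimension": mcshbs_res.selected_dimension,
    }


@pytest.fixture(scope="session")
def study_results():
    """Twenty seeded end-to-end runs under the study conditions."""
    return [_run_one_seed(seed) for seed in range(20)]
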