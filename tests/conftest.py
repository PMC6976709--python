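"""Shared fixtures: small synthetic scenes, classifier tables and transect
scenarios used across the suite.  Everything is generated at test time from
fixed seeds."""

import numpy as np
import pytest

from planktransect.classify import ClassMap
from planktransect.synth import (
    ConfusionSpec,
    SceneSpec,
    TransectSpec,
    gen_classified_vignettes,
    gen_frames,
    gen_transect,
)


def diagonal_confusion(k: int, accuracy: float) -> np.ndarray:
    """Row-stochastic confusion with `accuracy` on the diagonal and the
    remaining mass spread uniformly over the off-diagonal classes."""
    off = (1.0 - accuracy) / (k - 1)
    conf = np.full((k, k), off) + np.eye(k) * (accuracy - off)
    return conf / conf.sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def scene():
    """Planted-blob frames with good contrast and low noise, plus blanks for
    the background profile."""
    spec = SceneSpec(n_frames=8, blob_count_per_frame=5, noise_sd=0.03, seed=5)
    frames, truth = gen_frames(spec)
    blanks, _ = gen_frames(
        SceneSpec(n_frames=8, blob_count_per_frame=0, noise_sd=0.03, seed=99)
    )
    return spec, frames, truth, blanks


@pytest.fixture(scope="session")
def confusion_setup():
    """8 fine classes -> 4 groups, 70% fine-class accuracy, informative
    confidence (correct predictions stochastically more confident)."""
    k, g = 8, 4
    mapping = tuple(i % g for i in range(k))
    spec = ConfusionSpec(
        n_fine_classes=k,
        n_groups=g,
        mapping=mapping,
        confusion=diagonal_confusion(k, 0.7),
        class_abundances=np.full(k, 12500.0),
        seed=7,
    )
    class_map = ClassMap({i: f"g{mapping[i]}" for i in range(k)})
    fine_to_group = {i: f"g{mapping[i]}" for i in range(k)}
    train = gen_classified_vignettes(spec, seed=11)
    test = gen_classified_vignettes(spec, seed=12)
    return spec, class_map, fine_to_group, train, test


@pytest.fixture(scope="session")
def transect():
    return gen_transect(TransectSpec(seed=0))
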