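"""Shared fixtures.

Expensive artefacts (phantom banks, trained networks) are session-scoped
so that module tests and the acceptance suite share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from mammojig.jigsaw import PermutationSet, generate_permutation_set
from mammojig.models import EncoderSpec, build_cfn
from mammojig.study import make_study_data
from mammojig.synthetic import SyntheticConfig
from mammojig.training import TrainConfig, train_jigsaw


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_patients=12, seed=7)


@pytest.fixture(scope="session")
def phantom_bank():
    """~100 synthetic crops with metadata, exclusions applied."""
    return make_study_data(patients=70, seed=3)


@pytest.fixture(scope="session")
def phantom_images(phantom_bank) -> list[np.ndarray]:
    return [phantom_bank.images[i] for i in phantom_bank.table.image_id]


@pytest.fixture(scope="session")
def permset31() -> PermutationSet:
    return generate_permutation_set(n_extra=30, pool_size=2000, seed=0)


@pytest.fixture(scope="session")
def two_perm_set() -> PermutationSet:
    return PermutationSet(
        permutations=[tuple(range(9)), (1, 2, 0, 4, 5, 3, 7, 8, 6)]
    )


@pytest.fixture(scope="session")
def encoder_spec() -> EncoderSpec:
    return EncoderSpec(name="small_cnn", input_pool=8)


@pytest.fixture(scope="session")
def trained_cfn_two_perm(phantom_images, two_perm_set, encoder_spec):
    """CFN trained on the 2-permutation pretext task (shared smoke model)."""
    model = build_cfn(encoder_spec, n_classes=2, seed=0)
    cfg = TrainConfig.jigsaw(epochs=30, batch_size=16, seed=0)
    model, history = train_jigsaw(model, phantom_images, two_perm_set, cfg)
    return model, history


@pytest.fixture(scope="session")
def mass_classifier(encoder_spec):
    """Classifier trained on spiculated-mass vs normal phantoms, with a
    held-back set of lesion images + masks for attention analysis."""
    from mammojig.synthetic import generate_record, total_images
    from mammojig.training import train_classifier

    from mammojig.models import build_classifier

    cfg = SyntheticConfig(
        n_patients=90, seed=41, exclusion_rates={},
        finding_mix={"mass": 0.5, "calcification": 0.0,
                     "distortion": 0.0, "normal": 0.5},
        cancer_rate_per_finding={"mass": 1.0},
        density_mix=0.3,
    )
    images, labels, lesion_items = [], [], []
    for i in range(total_images(cfg)):
        img, mask, rec = generate_record(cfg, i)
        if rec.finding == "mass" and len(lesion_items) < 20:
            lesion_items.append((img, mask))  # held back for CAM analysis
        else:
            images.append(img)
            labels.append(rec.cancer)
    model = build_classifier(encoder_spec, seed=0)
    model, history = train_classifier(
        model, images, np.asarray(labels),
        TrainConfig.finetune(epochs=15, batch_size=16, seed=0))
    return model, history, images, np.asarray(labels), lesion_items


@pytest.fixture(scope="session")
def directional_study(permset31, encoder_spec):
    """Scaled-down arm comparison: Scratch-Jig vs Scratch over seeded
    synthetic datasets (~300 crops each), 20 pretext + 20 fine-tune
    epochs, one patient-grouped validation fold per seed."""
    from mammojig.evaluation import grouped_kfold, roc_auc
    from mammojig.study import make_study_data
    from mammojig.training import run_arm, standard_arms

    results: dict[str, list[float]] = {"Scratch-Jig": [], "Scratch": []}
    for seed in range(3):
        data = make_study_data(patients=200, seed=100 + seed)
        splits = grouped_kfold(data.table.patient_id, k=5, trials=1, seed=seed)
        for arm in standard_arms():
            table = run_arm(
                arm, data, permset31,
                TrainConfig.jigsaw(epochs=20, batch_size=32, seed=seed),
                TrainConfig.finetune(epochs=20, batch_size=32, seed=seed),
                splits, spec=encoder_spec, folds=[0])
            _, auc = roc_auc(table.score, table.label)
            results[arm.name].append(auc)
    return results
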