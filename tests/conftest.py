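from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shgtex import default_study_classes, generate_study
from shgtex.pipeline import PipelineConfig, extract_features
from shgtex.synthetic import StudyClass, TextureClassSpec


@pytest.fixture(scope="session")
def study_features() -> pd.DataFrame:
    """Per-angle feature table of the default four-class study at native
    512x512 resolution (seed 1); shared across the discrimination tests."""
    dataset = generate_study(default_study_classes(), seed=1)
    return extract_features(dataset.images, PipelineConfig())


@pytest.fixture(scope="session")
def balanced_features() -> pd.DataFrame:
    """A balanced two-class dataset (50 + 50 images, 512x512, seed 7) whose
    4-angle extraction yields 400 SHG datapoints; used for null tests."""
    base = TextureClassSpec(
        name="base", orientation_coherence=0.5, fiber_density=10.0,
        intensity_contrast=1.0, noise_sd=9.0,
    )
    classes = {
        "a": StudyClass("group1", "primary_SCC", 50, base, base, ("PA",)),
        "b": StudyClass("group1", "metachronous_HGD", 50, base, base, ("PB",)),
    }
    dataset = generate_study(classes, seed=7)
    feats = extract_features(dataset.images, PipelineConfig())
    return feats[feats["channel"] == "SHG"].reset_index(drop=True)


def make_feature_frame(rng: np.random.Generator, n: int, **labels) -> pd.DataFrame:
    """Random but well-behaved feature records for table-level tests."""
    from shgtex.texture import FEATURE_NAMES

    base = {
        "contrast": rng.normal(10, 1, n),
        "dissimilarity": rng.normal(2, 0.2, n),
        "homogeneity": rng.uniform(0.4, 0.6, n),
        "energy": rng.uniform(0.2, 0.3, n),
        "asm": rng.uniform(0.04, 0.09, n),
        "correlation": rng.uniform(0.5, 0.9, n),
    }
    df = pd.DataFrame({k: base[k] for k in FEATURE_NAMES})
    df["channel"] = labels.get("channel", "SHG")
    df["group"] = labels.get("group", "group1")
    df["diagnosis"] = labels.get("diagnosis", "primary_SCC")
    df["patient_id"] = labels.get("patient_id", "P01")
    df["field_id"] = [f"f{i}" for i in range(n)]
    df["angle_deg"] = 0
    return df
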