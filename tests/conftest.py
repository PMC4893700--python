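"""Shared fixtures: the default synthetic benchmark and small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from dilimet.preprocess import preprocess_pipeline
from dilimet.synth import (
    NoiseParams,
    SignatureSpec,
    build_default_design,
    build_feature_catalog,
    default_signatures,
    simulate,
)

BENCHMARK_SEED = 7


@pytest.fixture(scope="session")
def design():
    return build_default_design()


@pytest.fixture(scope="session")
def catalog():
    return build_feature_catalog()


@pytest.fixture(scope="session")
def signatures(catalog):
    return default_signatures(catalog)


@pytest.fixture(scope="session")
def benchmark(design, catalog, signatures):
    """Default synthetic benchmark: raw block tables + truth."""
    return simulate(design, catalog, signatures, seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def entity_matrix(benchmark):
    tables, _ = benchmark
    return preprocess_pipeline(tables)


@pytest.fixture(scope="session")
def trained_pipeline(entity_matrix):
    """Split + default variable selection on the benchmark development set."""
    from dilimet.pipeline import select_variables, split_dev_validation

    split = split_dev_validation(entity_matrix, seed=0)
    dev = entity_matrix.subset(split.development)
    val = entity_matrix.subset(split.validation)
    trace, model = select_variables(dev, n_repeats=3, seed=0)
    return split, dev, val, trace, model


def small_catalog(n_features: int, n_background: int = 0, seed: int = 0):
    """Anonymous catalog without the mandatory marker set, split evenly."""
    base = n_features // 4
    sizes = [base] * 4
    sizes[-1] += n_features - 4 * base
    return build_feature_catalog(n_features, tuple(sizes), markers=[],
                                 n_background=n_background, seed=seed)


def simulate_matrix(signatures, n_features: int, seed: int,
                    n_background: int = 0, noise: NoiseParams | None = None,
                    design=None):
    """Simulate and fully preprocess a small study into an entity matrix."""
    cat = small_catalog(n_features, n_background=n_background)
    des = design or build_default_design()
    tables, truth = simulate(des, cat, signatures, noise=noise, seed=seed)
    ratio = 3.0 if n_background else None
    return preprocess_pipeline(tables, blank_min_ratio=ratio), cat, truth


def null_matrix(n_features: int, seed: int):
    """Entity matrix with no planted effects (pure noise)."""
    mat, _, _ = simulate_matrix([], n_features, seed)
    return mat


def planted_signature(feature_id: str, effects: dict, dose_dependent=False):
    return SignatureSpec(feature_id, effects, dose_dependent=dose_dependent)
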