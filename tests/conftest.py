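"""Shared fixtures: synthetic frames and tables, generated at session scope."""

from __future__ import annotations

import numpy as np
import pytest

from cappheno.synthetic_caps import (
    SyntheticCapSpec,
    WeightTableSpec,
    gen_cap_image,
    gen_cap_suite,
    gen_weight_table,
    _scales,
)


@pytest.fixture(scope="session")
def clean_cap():
    """Noise-free, crack-free cap on a green background (256 px frame)."""
    return gen_cap_image(
        SyntheticCapSpec(
            image_height=256,
            image_width=256,
            center=(128.0, 128.0),
            semi_long=60.0,
            semi_short=45.0,
            orientation=35.0,
            n_cracks=0,
            noise_sd=0.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def noisy_cap():
    """Cracked, noisy cap — the hard study condition."""
    return gen_cap_image(
        SyntheticCapSpec(
            image_height=256,
            image_width=256,
            center=(128.0, 128.0),
            semi_long=60.0,
            semi_short=45.0,
            orientation=35.0,
            n_cracks=12,
            noise_sd=8.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def edge_suite():
    """20-frame benchmark suite at the hard condition (noise 8, 12 cracks)."""
    return gen_cap_suite(20, base_seed=0, noise_sd=8.0, n_cracks=12, size=256)


def recovery_table_spec(seed: int) -> WeightTableSpec:
    """Weight table with a known linear model on the M3 traits.

    Weight is 0.5*Area + 0.5*Perimeter (unit-variance coefficients) plus
    noise equal to 3% of the weight span — the parameter-recovery condition.
    """
    base = WeightTableSpec(n_samples=500, seed=seed)
    s = _scales(base.feature_ranges)
    return WeightTableSpec(
        n_samples=500,
        seed=seed,
        beta={"Area": 0.5 / s["Area"], "Perimeter": 0.5 / s["Perimeter"]},
        noise_sd=0.03 * 150.0,
    )


@pytest.fixture(scope="session")
def recovery_table():
    return gen_weight_table(recovery_table_spec(1))


@pytest.fixture(scope="session")
def default_weight_table():
    """686-sample table under the default (published-ranking) conditions."""
    return gen_weight_table(WeightTableSpec(n_samples=686, seed=1))
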