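"""Shared fixtures: small cells, toy models, and cached scenario bundles."""

from __future__ import annotations

import functools

import numpy as np
import pytest

import phaseloop as pl


@pytest.fixture
def cubic_cell() -> pl.UnitCell:
    return pl.UnitCell(10.0, 10.0, 10.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def ten_atom_model(rng) -> pl.AtomModel:
    return pl.AtomModel(
        element=["C", "N", "O", "S"] + ["C"] * 6,
        xyz=rng.uniform(2.0, 8.0, size=(10, 3)),
        B=np.full(10, 20.0),
        occ=np.ones(10),
    )


@functools.lru_cache(maxsize=4)
def scenario(seed: int) -> pl.ScenarioBundle:
    """Cached full-size standard scenario (generation costs ~10 s)."""
    return pl.standard_scenario(seed=seed)


@functools.lru_cache(maxsize=4)
def small_scenario(seed: int) -> pl.ScenarioBundle:
    """Compact variant for unit-level pipeline tests."""
    return pl.standard_scenario(
        seed=seed,
        n_residues=30,
        cell=pl.UnitCell(46.0, 48.0, 50.0),
        d_min=2.8,
        em_resolution=5.5,
        n_extension_steps=3,
        n_cycles=3,
    )


@pytest.fixture
def scenario1() -> pl.ScenarioBundle:
    return scenario(1)


@pytest.fixture
def small_scenario1() -> pl.ScenarioBundle:
    return small_scenario(1)
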