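import numpy as np
import pytest

from landsim import (
    CROP,
    NATURAL,
    CapitalGrid,
    build_config,
    get_preset,
    run_ensemble,
)

# Reduced-scale study conditions shared by the ensemble-level checks:
# 20x20 arena, 500 search iterations (experiment 7 keeps its defining 100),
# 25 timesteps, 10 realisations.
REDUCED = dict(width=20, height=20)
REDUCED_ITERATIONS = 500
REDUCED_REPS = 10
ENSEMBLE_SEED = 7


@pytest.fixture
def toy_world_2x2():
    """Hand-set 2x2 capitals with a strict per-cell best type."""
    crop = np.array([[0.9, 0.2], [0.6, 0.1]])
    natural = np.array([[0.1, 0.8], [0.3, 0.95]])
    return CapitalGrid(width=2, height=2, capitals={CROP: crop, NATURAL: natural})


@pytest.fixture
def baseline_afts():
    return (get_preset("high_intensity_farmer"), get_preset("conservationist"))


class _EnsembleCache:
    """Compute each reduced-scale experiment ensemble once per session."""

    def __init__(self):
        self._cache = {}

    def __call__(self, code: str):
        if code not in self._cache:
            overrides = dict(REDUCED)
            if not code.startswith("7"):
                overrides["search_iterations"] = REDUCED_ITERATIONS
            cfg = build_config(code, **overrides)
            self._cache[code] = run_ensemble(
                cfg.to_engine_config(), n_reps=REDUCED_REPS, base_seed=ENSEMBLE_SEED
            )
        return self._cache[code]


@pytest.fixture(scope="session")
def ensembles():
    return _EnsembleCache()
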