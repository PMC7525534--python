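import math

import numpy as np
import pytest

import drfsim as d


@pytest.fixture(scope="session")
def spec():
    return d.EGO_SPEC


@pytest.fixture(scope="session")
def drf():
    return d.DRF_DEFAULT


@pytest.fixture(scope="session")
def normal():
    return d.get_preset("normal")


@pytest.fixture(scope="session")
def sport():
    return d.get_preset("sport")


class RunCache:
    """Session-wide cache of closed-loop runs keyed by scenario + preset."""

    def __init__(self):
        self._cache = {}

    def __call__(self, scenario_name, preset="normal", overrides=None, **cfg_kw):
        key = (scenario_name, preset, tuple(sorted((overrides or {}).items())),
               tuple(sorted(cfg_kw.items())))
        if key not in self._cache:
            sc = d.build_scenario(scenario_name, overrides or {})
            log = d.run(sc, d.DRF_DEFAULT, d.get_preset(preset),
                        d.SimConfig(**cfg_kw), d.EGO_SPEC)
            self._cache[key] = (sc, log)
        return self._cache[key]


@pytest.fixture(scope="session")
def sim():
    """Cached simulator runs shared across trend tests."""
    return RunCache()


def straight_grid(x0=-2.0, x1=90.0, y0=-15.0, y1=15.0, delta=0.25):
    nx = int(round((x1 - x0) / delta))
    ny = int(round((y1 - y0) / delta))
    return d.FieldGrid((x0, y0), delta, nx, ny)
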