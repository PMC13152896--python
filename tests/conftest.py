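import numpy as np
import pandas as pd
import pytest

from uvmorph import CohortConfig, SpectrumSet, Spectrum, VisualSystem, WavelengthGrid, simulate_cohort


GRID = WavelengthGrid()
WL = GRID.wavelengths()


def make_set(reflectances, ids=None, patches=None, **meta):
    """Build a SpectrumSet on the canonical grid from raw reflectance rows."""
    refl = np.atleast_2d(np.asarray(reflectances, dtype=float))
    n = refl.shape[0]
    ids = ids or [f"s{i}" for i in range(n)]
    patches = patches or ["throat"] * n
    md = pd.DataFrame(
        {
            "id": ids,
            "patch": patches,
            "sex": meta.get("sex", ["male"] * n),
            "locality": meta.get("locality", ["locA"] * n),
            "human_morph": meta.get("human_morph", ["white"] * n),
        }
    )
    return SpectrumSet(GRID, refl, md)


def make_spectrum(reflectance, sid="s0", patch="throat"):
    return Spectrum(sid, patch, WL, np.asarray(reflectance, dtype=float))


@pytest.fixture(scope="session")
def grid():
    return GRID


@pytest.fixture(scope="session")
def vs():
    return VisualSystem()


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort: 400 specimens, 50:50 white classes, seed 0."""
    cfg = CohortConfig(seed=0)
    sset, truth = simulate_cohort(cfg)
    return cfg, sset, truth
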