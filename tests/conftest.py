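import numpy as np
import pytest

from sleepfc import synthetic_data as sd
from sleepfc.containers import BoldRun


GRID = (12, 12, 12)


def toy_run(data2d: np.ndarray, mask: np.ndarray | None = None, tr: float = 2.16,
            **kwargs) -> BoldRun:
    """Wrap a (n_voxels, T) array into a degenerate 1 x 1 x n_voxels grid run."""
    data2d = np.asarray(data2d, dtype=float)
    n_vox, T = data2d.shape
    vol = data2d.reshape(1, 1, n_vox, T)
    m = np.ones((1, 1, n_vox), dtype=bool) if mask is None else mask
    return BoldRun(data=vol, tr=tr, mask=m, **kwargs)


@pytest.fixture
def pattern_pair():
    return sd.make_pattern_pair(GRID, overlap_fraction=0.5, seed=7)


@pytest.fixture
def small_run(pattern_pair):
    """150-volume run with a constant-envelope consolidated coupling."""
    la, co = pattern_pair
    T = 150
    spec = sd.SimSpec(
        grid_shape=GRID,
        n_volumes=T,
        patterns=[la, co],
        coupling=[sd.CouplingSchedule("consolidated", np.full(T, 0.8))],
        seed=11,
    )
    return sd.simulate_run(spec)


def make_run(coupling_envs: dict, seed: int, T: int = 150, grid=GRID,
             noise_sd: float = 1.0, stochastic: bool = True,
             nuisance: sd.NuisanceSpec | None = None, patterns=None):
    """Convenience run factory used across the suite."""
    if patterns is None:
        patterns = sd.make_pattern_pair(grid, overlap_fraction=0.5, seed=7)
    la, co = patterns
    byid = {p.pattern_id: p for p in (la, co)}
    coupling = [
        sd.CouplingSchedule(pid, np.broadcast_to(env, (T,)).astype(float),
                            stochastic=stochastic)
        for pid, env in coupling_envs.items()
    ]
    spec = sd.SimSpec(
        grid_shape=grid, n_volumes=T, patterns=list(byid.values()),
        coupling=coupling, noise_sd=noise_sd,
        nuisance=nuisance or sd.NuisanceSpec(), seed=seed,
    )
    return sd.simulate_run(spec)
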