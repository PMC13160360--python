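import numpy as np
import pytest

import frontscan as fs


@pytest.fixture(scope="session")
def default_scene():
    """The default synthetic survey scene: raw grids, truth, cleaned grids."""
    cfg = fs.SimulationConfig(seed=7)
    grids, truth = fs.simulate_echograms(cfg)
    clean = fs.clean_echograms(grids, fs.PipelineConfig(seed=7))
    return cfg, grids, truth, clean


@pytest.fixture(scope="session")
def classified_scene(default_scene):
    """Statistics-grid MVBS and ΔMVBS classification of the default scene."""
    cfg, _, truth, clean = default_scene
    m38 = fs.compute_mvbs(clean[38.0], 3.0, 0.25)
    m120 = fs.compute_mvbs(clean[120.0], 3.0, 0.25)
    classified = fs.classify_cells(m38, m120)
    truth_grid = fs.truth_on_grid(truth, m38.dist_edges, m38.depth_edges, cfg)
    return cfg, m38, m120, classified, truth_grid


def flat_grid(sv_db=-70.0, n_pings=30, n_bins=40, freq=38.0, bin_m=1.0,
              alpha=0.0):
    """A uniform-Sv echogram for unit tests."""
    return fs.EchogramGrid(
        freq_khz=freq,
        time_s=np.arange(n_pings, dtype=float),
        lat=np.linspace(76.0, 76.1, n_pings),
        lon=np.full(n_pings, 30.0),
        distance_nmi=0.01 * np.arange(n_pings),
        depth_edges=bin_m * np.arange(n_bins + 1, dtype=float),
        sv=np.full((n_pings, n_bins), sv_db, dtype=float),
        alpha_db_per_m=alpha,
    )
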