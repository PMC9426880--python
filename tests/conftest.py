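import numpy as np
import pandas as pd
import pytest

from dsurf.abundance import ht_segments
from dsurf.detection import DetectionModel, fit_detection
from dsurf.survey_data import effort_area_km2, truncate_observations
from dsurf.synthetic import SimulationScenario, simulate


def small_scenario(seed: int = 0, **overrides) -> SimulationScenario:
    """Desk-scale survey: 90 candidate units over 2,700 km^2, 24 surveyed."""
    params = dict(
        seed=seed,
        nx_km=60,
        ny_km=45,
        n_surveyed=24,
        expected_n=3000.0,
        corr_length_km=6.0,
        density_coefs={"elevation": -0.5},
        detection_key="half_normal",
        sigma_by_canopy={"hardwood": 150.0, "mixed": 150.0, "open": 150.0},
    )
    params.update(overrides)
    return SimulationScenario(**params)


@pytest.fixture(scope="session")
def sim_small():
    """One simulated small survey shared across tests."""
    return simulate(small_scenario(seed=42))


@pytest.fixture(scope="session")
def sim_mcds():
    """A survey with canopy-dependent hazard-rate detection (exercises MCDS)."""
    sc = small_scenario(
        seed=7,
        expected_n=6000.0,
        detection_key="hazard_rate",
        sigma_by_canopy={"hardwood": 150.0, "mixed": 165.0, "open": 205.0},
    )
    sc.detection_b = 2.5
    return sc, simulate(sc)


@pytest.fixture(scope="session")
def fitted_small(sim_small):
    """Detection fit + HT segment table + PC1 column for the small survey."""
    obs = truncate_observations(sim_small["obs"], 350)
    det = fit_detection(obs, DetectionModel(key="half_normal", covariates=(), truncation=350))
    seg = ht_segments(obs, sim_small["segments"], det.p_for(obs))
    seg["effort_area"] = effort_area_km2(sim_small["segments"], 350).to_numpy()
    m = sim_small["segments"]["elevation"].mean()
    s = sim_small["segments"]["elevation"].std(ddof=1)
    seg["PC1"] = (sim_small["segments"]["elevation"] - m) / s
    grid = sim_small["grid"].copy()
    grid["PC1"] = (grid["elevation"] - m) / s
    return {"obs": obs, "det": det, "segments": seg, "grid": grid}


def rtweedie(mu, phi, p, rng):
    """Compound Poisson-gamma sampler for Tweedie responses (1 < p < 2)."""
    mu = np.asarray(mu, float)
    lam = mu ** (2 - p) / (phi * (2 - p))
    alpha = (2 - p) / (p - 1)
    gam = phi * (p - 1) * mu ** (p - 1)
    n = rng.poisson(lam)
    out = np.zeros_like(mu)
    pos = n > 0
    out[pos] = rng.gamma(n[pos] * alpha, gam[pos])
    return out
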