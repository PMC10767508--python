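import numpy as np
import pytest

from soilfate import kinetics


@pytest.fixture
def canonical_days() -> np.ndarray:
    return np.array(kinetics.CANONICAL_DAYS)


def make_series(model: str, params: dict, days=None, soil_id="S01",
                compound="SDZ", noise_sigma: float = 0.0,
                rng: np.random.Generator | None = None) -> kinetics.DecaySeries:
    """Decay series from a known truth; noiseless unless sigma > 0."""
    days = np.array(kinetics.CANONICAL_DAYS if days is None else days,
                    dtype=float)
    values = kinetics.predict_concentration(model, params, days)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        values = values * np.exp(rng.normal(0.0, noise_sigma, days.size))
    return kinetics.DecaySeries(soil_id=soil_id, compound=compound,
                                times=days, values=values)
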