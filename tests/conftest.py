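import numpy as np
import pytest

from devtempo import synthdata
from devtempo.synthdata import (
    PRIMARY_PROPORTIONS,
    RenderConfig,
    ThermalParams,
    render_movie,
    schedule_from_proportions,
)


@pytest.fixture(scope="session")
def mel_params() -> ThermalParams:
    """Thermal law pinned to 33 h at 17.5 C and 16 h at 27.5 C."""
    return ThermalParams.from_endpoints(17.5, 33.0, 27.5, 16.0,
                                        noise_cv=0.05)


@pytest.fixture(scope="session")
def small_movie():
    """One rendered 300-frame movie of the eight primary events."""
    cfg = RenderConfig(n_frames=300, n_planes=3, noise_sigma=0.01)
    rng = np.random.default_rng(7)
    schedule = schedule_from_proportions(
        PRIMARY_PROPORTIONS, anchor_lo=60, anchor_hi=270, n_frames=300,
        jitter_frames=3, rng=rng)
    return render_movie(schedule, cfg, seed=7), schedule


@pytest.fixture(scope="session")
def primary_bank():
    """Reference bank of the stage templates for the primary events."""
    from devtempo.staging import ReferenceBank

    events = PRIMARY_PROPORTIONS.ordered_events()
    return ReferenceBank(
        composites={e: synthdata.stage_template(e) for e in events},
        provenance={e: 1 for e in events})
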