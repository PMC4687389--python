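import numpy as np
import pytest

from dicequant import SolverConfig, profiles_at_scan_days, reference_domain
from dicequant.domain import SECONDS_PER_DAY


@pytest.fixture(scope="session")
def ref_domain():
    return reference_domain()


@pytest.fixture(scope="session")
def coarse_config():
    """Fitting-grade discretisation: fast enough to run many forward solves."""
    return SolverConfig(n_cells=320, time_step=900.0)


@pytest.fixture(scope="session")
def day_field(ref_domain):
    """Forward solution at effective days 0/5/15/30 on the default grid."""
    return profiles_at_scan_days(ref_domain, [0, 5, 15, 30])


@pytest.fixture(scope="session")
def noiseless_observations(ref_domain, coarse_config):
    """Synthetic concentration profiles at days 5/15/30 from the calibrated
    parameter set, sampled every 0.1 mm over the 15 mm transect."""
    from dicequant.profiles import LineProfile

    field = profiles_at_scan_days(ref_domain, [5, 15, 30], coarse_config)
    positions = np.linspace(0.0, 0.015, 151)
    profiles = []
    for day, sid in [(5.0, "A"), (15.0, "C"), (30.0, "D")]:
        conc = field.interp_total(day * SECONDS_PER_DAY, positions)
        profiles.append(
            LineProfile(sid, day, day, positions, np.zeros_like(positions), conc=conc)
        )
    return profiles
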