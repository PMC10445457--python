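import pytest

from dropletlab.resource_model import HardwareConfig, ReactionJob


@pytest.fixture
def uniform_cfg() -> HardwareConfig:
    """All bottleneck stages 60 s; convenient for hand arithmetic."""
    return HardwareConfig(
        n_reactors=2,
        t_prep=60.0,
        t_transit_in=60.0,
        t_rinse_a=60.0,
        t_transit_out=60.0,
        t_rinse_b=60.0,
        t_hplc=60.0,
        time_unit=1.0,
    )


@pytest.fixture
def default_cfg() -> HardwareConfig:
    return HardwareConfig()


@pytest.fixture
def bookend_cfg() -> HardwareConfig:
    """Preparation long relative to the transit/rinse bottlenecks, as on the
    physical platform; back-to-back prep is then collision-free whenever the
    reactions are long."""
    return HardwareConfig(
        n_reactors=2,
        t_prep=180.0,
        t_transit_in=30.0,
        t_rinse_a=30.0,
        t_transit_out=30.0,
        t_rinse_b=60.0,
        t_hplc=120.0,
        time_unit=1.0,
    )


def make_jobs(residences, temperature=70.0, prefix="j"):
    return [
        ReactionJob(job_id=f"{prefix}{i}", temperature=temperature,
                    residence_time=float(r))
        for i, r in enumerate(residences)
    ]
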