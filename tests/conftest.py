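import pytest

from clinicflow import analysis, des, synthetic_emr as emr


@pytest.fixture(scope="session")
def covid_cohort():
    """A pandemic-era synthetic cohort with intact timestamps (n=400, seed 7)."""
    cfg = emr.era_preset("covid", n_encounters=400, seed=7, missingness_rate=0.0)
    return emr.generate_cohort(cfg)


@pytest.fixture()
def deterministic_params():
    """All-sd-zero parameters so event traces can be computed by hand."""
    return analysis.SimParams(
        waiting_room_time=(4.0, 0.0),
        tech_time=(19.0, 0.0),
        exam_time=(8.0, 0.0),
        p_dilation=0.0,
        p_imaging=0.0,
        cleaning_delay=(4.0, 4.0),
        guest_probability=0.0,
    )


@pytest.fixture()
def single_slot_config():
    def make(volume: int, rooms: int = 4, techs: int = 2) -> des.ClinicConfig:
        return des.ClinicConfig(
            n_providers=1,
            n_techs=techs,
            rooms_per_provider=rooms,
            volume_per_provider=volume,
            max_urgent=0,
        )

    return make
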