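import dataclasses

import pytest

import chemoresist as cr


@pytest.fixture(scope="session")
def scenario_results():
    """All four bundled treatment scenarios, run once per session."""
    return {name: cr.run_scenario(cr.preset(name)) for name in cr.PRESET_NAMES}


def make_single_population_spec(
    *,
    r: float = 0.25,
    K: float = 1e6,
    T0: float = 1e4,
    C0: float = 0.0,
    kill_T: float = 0.15,
    t_start: float = 50.0,
    horizon: float = 500.0,
) -> cr.ScenarioSpec:
    """A wild-tumor-only intrinsic run: no mutation, no coupling, no normal cells."""
    return cr.ScenarioSpec(
        name="single",
        model="intrinsic",
        params=cr.ModelParams(r_T=r, K_T=K, r_N=0.0, kappa=0.0, tau=0.0),
        drug1=cr.DrugSchedule(C0=C0, t_start=t_start, M=1.0, kill_T=kill_T),
        initial_state=cr.PopulationState(N=0.0, T=T0),
        horizon=horizon,
    )


def replace_spec(spec, **kw):
    return dataclasses.replace(spec, **kw)
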