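import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def behavior_series():
    """One completed go/no-go reversal session from the forgetting agent."""
    from mesolimbic import synthetic as syn

    table, latents = syn.simulate_task_session(
        syn.TaskConfig(), syn.AgentSpec("qph_f", (0.4, 0.1, 0.3, 5.0)),
        n_trials_max=400, seed=11,
    )
    d = table.df
    return {
        "table": table,
        "latents": latents,
        "s": d["state"].to_numpy(),
        "a": d["action_code"].to_numpy(),
        "r": d["reward"].to_numpy(),
    }


@pytest.fixture(scope="session")
def coupled_pair():
    """A 20-minute source/target recording with 0.2-s-lag coupling."""
    from mesolimbic import synthetic as syn

    src = syn.UnitSpec(role="SPN", baseline_hz=2.0)
    tgt = syn.UnitSpec(role="DAN", baseline_hz=4.0)
    coup = syn.AssemblyCouplingSpec(lag_s=0.2, precision_s=0.05, efficacy=0.5)
    a, b = syn.simulate_assembly_pair(src, tgt, coup, span_s=1200.0, seed=5)
    return a, b


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
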