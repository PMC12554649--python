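import pytest

from ruralcoord.coupling import ccd_table
from ruralcoord.critic_index import score_panel
from ruralcoord.sbm_dea import efficiency_panel
from ruralcoord.synthetic_data import SyntheticTruth, generate_panel


@pytest.fixture(scope="session")
def default_run():
    """The default synthetic panel pushed through U1 -> U2 -> D once."""
    gen = generate_panel(SyntheticTruth(seed=7))
    weights, u1 = score_panel(gen.panel)
    eff = efficiency_panel(gen.panel)
    u2 = eff.set_index(["unit", "year"])["TE"]
    table = ccd_table(u1, u2)
    return {"gen": gen, "weights": weights, "u1": u1, "eff": eff, "ccd": table}


@pytest.fixture()
def small_gen():
    """A 6-unit x 4-year panel, cheap enough for per-test regeneration."""
    truth = SyntheticTruth(
        seed=3,
        n_units=6,
        n_years=4,
        region_sizes={"East": 2, "Central": 2, "West": 2},
    )
    return generate_panel(truth)
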