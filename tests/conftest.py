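import pytest

from nidleflux import (
    build_problem,
    classify_reactions,
    fixtures,
    split_reversible,
)


def make_problem(model, profile, **kwargs):
    irr = split_reversible(model)
    activity = classify_reactions(irr, profile)
    return irr, activity, build_problem(irr, profile, activity, **kwargs)


@pytest.fixture(scope="session")
def t1_case():
    model, profile, manifest = fixtures.t1()
    irr, activity, problem = make_problem(model, profile)
    return {
        "model": model,
        "profile": profile,
        "manifest": manifest,
        "irr": irr,
        "activity": activity,
        "problem": problem,
    }


@pytest.fixture(scope="session")
def canonical_cases():
    out = {}
    for name, builder in fixtures.CANONICAL.items():
        model, profile, manifest = builder()
        irr, activity, problem = make_problem(model, profile)
        out[name] = {
            "model": model,
            "profile": profile,
            "manifest": manifest,
            "irr": irr,
            "activity": activity,
            "problem": problem,
        }
    return out


@pytest.fixture(scope="session")
def single_path_case():
    """Linear chain where every feasible flux distribution is unique."""
    model, profile, manifest = fixtures.plant_kcat_scenario(v_star=3.0, e_star=1e-3)
    irr, activity, problem = make_problem(model, profile)
    return {
        "model": model,
        "profile": profile,
        "manifest": manifest,
        "irr": irr,
        "activity": activity,
        "problem": problem,
    }
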