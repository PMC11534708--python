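import math

import pytest

from discost import (
    SimConfig,
    WashingtonGroupClassifier,
    assign_quintiles,
    generate_population,
    normalize_expenditure,
)


def prepare_households(survey):
    """Classified, indexed, quintiled household table ready for SOL fitting."""
    hh = survey.households.merge(
        WashingtonGroupClassifier().household_flags(survey.members), on="household_id"
    )
    hh["y"] = normalize_expenditure(hh["exp_pc"], hh["poverty_line"])
    hh["quintile"] = assign_quintiles(hh["y"].to_numpy())
    if "asset_index" in hh.columns:
        hh["sol_index"] = hh["asset_index"]
    else:
        from discost import index_from_frame

        hh["sol_index"] = index_from_frame(hh)
    return hh


@pytest.fixture(scope="session")
def midsize_survey():
    """Default study conditions at a moderate size: noisy linear index, embedded costs."""
    return generate_population(SimConfig(n_households=20_000, seed=42))


@pytest.fixture(scope="session")
def midsize_households(midsize_survey):
    return prepare_households(midsize_survey)


def noiseless_config(n_households=20_000, seed=5):
    """Diagnostic configuration: exact linear index, no noise, no control effects.

    The expenditure spread and index slope are set so the latent index
    stays strictly inside [0, 100] (no clamping), making the SOL estimand
    identified exactly.
    """
    return SimConfig(
        n_households=n_households,
        seed=seed,
        noise_sd=0.0,
        gamma_true={},
        asset_mode="linear_index",
        expenditure_lognormal=(math.log(850_000), 0.4),
        alpha_true=5.0,
        k_true=10.0,
    )


@pytest.fixture(scope="session")
def noiseless_survey():
    return generate_population(noiseless_config())


@pytest.fixture(scope="session")
def noiseless_households(noiseless_survey):
    return prepare_households(noiseless_survey)
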