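"""Shared builders for test parameterizations."""

from phenocycle.synthetic import GrowthParams


def logistic_params(onset: float, rate: float = 0.25) -> GrowthParams:
    """Minimal growth parameter set with a given senescence midpoint."""
    return GrowthParams(
        eb_asymptote=2e6, eb_rate=0.18, eb_inflection=45.0,
        ripening_start=55.0, ripening_decline=0.03,
        ph_asymptote=500.0, heading_das=47.0,
        senescence_onset=onset, senescence_rate=rate,
    )
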