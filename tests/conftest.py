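import math

import pytest

from garsmeta import EffectEstimate


def make_est(log_or: float, se: float, label: str | None = None) -> EffectEstimate:
    """Build a consistent EffectEstimate from a log-OR and its SE."""
    z = 1.959963984540054
    return EffectEstimate(
        log_or=log_or, se=se, or_value=math.exp(log_or),
        ci_low=math.exp(log_or - z * se), ci_high=math.exp(log_or + z * se),
        label=label,
    )


@pytest.fixture
def est_factory():
    return make_est
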