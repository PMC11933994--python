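"""Small toy-model builders shared across test modules."""

import numpy as np

from kidneywait.parameters import (
    PARAM_NAMES,
    AgeStratum,
    CohortSpec,
    HealthState,
    MonthlyTransitionSet,
)


def toy_spec(horizon=12, **state_totals):
    """CohortSpec putting all mass of each named state in the middle stratum."""
    total = float(sum(state_totals.values()))
    split = {
        (AgeStratum.Y45_64, HealthState[name.upper()]): v / total
        for name, v in state_totals.items()
    }
    return CohortSpec(total_count=total, state_split=split, horizon=horizon)


def params_with(**overrides):
    """All-zero transition set with the named monthly probabilities set."""
    values = {name: np.zeros(3) for name in PARAM_NAMES}
    values.update(
        {
            k: np.full(3, v) if np.ndim(v) == 0 else np.asarray(v, float)
            for k, v in overrides.items()
        }
    )
    return MonthlyTransitionSet(values)
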