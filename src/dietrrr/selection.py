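"""Backwards-elimination screening of food groups against single responses.

Food groups with low predictability for the chosen risk-factor profile are
removed before pattern extraction: each response is regressed on all food
groups, the least significant food is dropped while its coefficient p-value
exceeds alpha, and a food is finally retained for the pattern model when it
survives for at least ``min_responses`` responses in at least one wave
(configurable to require both waves).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class EliminationStep:
    """One drop in the backwards path."""

    step: int
    dropped: str
    p_value: float
    remaining: list[str]


@dataclass
class EliminationResult:
    retained: list[str]
    steps: list[EliminationStep]
    final_p_values: pd.Series


@dataclass
class SelectionResult:
    """Cross-wave retention decision.

    ``indicator`` is a foods x (wave, response) boolean frame marking final
    per-response retained sets; ``counts`` the per-wave number of responses
    for which each food survived; ``retained_foods`` the final list passed to
    the pattern model, in the original food order.
    """

    retained_foods: list[str]
    indicator: pd.DataFrame
    counts: pd.DataFrame
    min_responses: int
    wave_rule: str
    audit: dict = field(default_factory=dict)


def backward_eliminate(
    X: pd.DataFrame, y: pd.Series, alpha: float = 0.05
) -> EliminationResult:
    """Backwards elimination of one response on standardized foods.

    Iteratively fits OLS (with intercept) of ``y`` on the current food set
    and drops the food with the largest coefficient p-value while it exceeds
    ``alpha``. Ties are broken deterministically by dropping the later
    column. Stops when every remaining p-value is <= alpha or the set is
    empty.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(
            f"n={n} rows cannot support OLS on p={p} foods plus intercept"
        )
    cols = list(X.columns)
    yv = np.asarray(y, dtype=float)
    steps: list[EliminationStep] = []
    final_p = pd.Series(dtype=float)
    step = 0
    while cols:
        fit = sm.OLS(yv, sm.add_constant(X[cols].to_numpy(), has_constant="add")).fit()
        pvals = pd.Series(fit.pvalues[1:], index=cols)
        final_p = pvals
        worst = pvals.max()
        if worst <= alpha:
            break
        # later column wins ties
        tied = [c for c in cols if pvals[c] == worst]
        drop = tied[-1]
        step += 1
        cols = [c for c in cols if c != drop]
        steps.append(
            EliminationStep(step=step, dropped=drop, p_value=float(worst), remaining=list(cols))
        )
    if not cols:
        final_p = pd.Series(dtype=float)
    return EliminationResult(retained=cols, steps=steps, final_p_values=final_p)


def replay_elimination(foods: list[str], steps: list[EliminationStep]) -> list[str]:
    """Reconstruct the final retained set from the audit log."""
    cols = list(foods)
    for s in sorted(steps, key=lambda s: s.step):
        cols.remove(s.dropped)
    return cols


def select_food_groups(
    wave_maps: dict[str, dict[str, list[str]]],
    food_universe: list[str],
    min_responses: int = 3,
    wave_rule: str = "either",
) -> SelectionResult:
    """Apply the cross-wave retention rule to per-response retained sets.

    A food is retained when it appears in the final backwards-selected sets
    of at least ``min_responses`` responses in at least one wave
    (``wave_rule="either"``) or in every wave (``"both"``).
    """
    if wave_rule not in ("either", "both"):
        raise ValueError("wave_rule must be 'either' or 'both'")
    if min_responses < 1:
        raise ValueError("min_responses must be >= 1")
    universe = set(food_universe)
    for wave, per_response in wave_maps.items():
        for response, foods in per_response.items():
            extra = set(foods) - universe
            if extra:
                raise ValueError(
                    f"foods outside the shared universe in {wave}/{response}: {sorted(extra)}"
                )
    cols = pd.MultiIndex.from_tuples(
        [
            (wave, response)
            for wave, per_response in wave_maps.items()
            for response in per_response
        ],
        names=["wave", "response"],
    )
    indicator = pd.DataFrame(False, index=list(food_universe), columns=cols)
    for wave, per_response in wave_maps.items():
        for response, foods in per_response.items():
            indicator.loc[list(foods), (wave, response)] = True
    counts = indicator.T.groupby(level="wave").sum().T
    meets = counts >= min_responses
    keep = meets.any(axis=1) if wave_rule == "either" else meets.all(axis=1)
    retained = [f for f in food_universe if keep[f]]
    return SelectionResult(
        retained_foods=retained,
        indicator=indicator,
        counts=counts,
        min_responses=min_responses,
        wave_rule=wave_rule,
    )
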