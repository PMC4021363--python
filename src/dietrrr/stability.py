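"""Exploratory-vs-confirmatory cross-wave stability of dietary patterns.

Exploratory scores come from fitting the pattern model within a wave;
confirmatory scores fix the food-group weights of one wave (the loading
wave, L) and apply them to the standardized intakes of the other (the diet
wave, D). Comparing the two separates diet change from weight change.
Because factor signs are arbitrary, the second wave's model is sign-aligned
to the first before any correlation is reported. Pearson correlations carry
Fisher-z confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import cross_wave_descriptives, standardize
from .rrr import RRRModel, label_patterns
from .tables import IntakeTable


@dataclass
class ConfirmatoryScore:
    """Fixed-weight pattern scores: diet wave D scored with wave-L weights."""

    scores: pd.DataFrame  # participants x k, mean 0 / SD 1 per factor
    diet_wave: str
    loading_wave: str
    standardization: str  # "diet" or "loading"


@dataclass
class StabilityReport:
    correlations: pd.DataFrame
    p_values: pd.DataFrame
    ci_lower: pd.DataFrame
    ci_upper: pd.DataFrame
    sign_vector: np.ndarray
    structure: pd.DataFrame
    food_spearman: pd.DataFrame | None
    labels: dict[str, list[dict]]
    n: int


def confirmatory_score(
    model: RRRModel, intake: IntakeTable, standardization: str = "diet"
) -> ConfirmatoryScore:
    """Score one wave's diet with another wave's fixed pattern weights.

    The diet-wave intakes are standardized by their own means/SDs by default
    (``standardization="loading"`` reuses the loading wave's parameters),
    multiplied by the fixed weights, and each factor rescaled to sample SD 1
    so correlations are comparable across blocks.
    """
    missing = [f for f in model.food_names if f not in intake.foods.columns]
    if missing:
        raise ValueError(f"diet-wave intake lacks model foods: {missing}")
    sub = intake.foods[model.food_names]
    if standardization == "diet":
        Z = standardize(sub).values
    elif standardization == "loading":
        Z = (sub - model.x_means) / model.x_sds
    else:
        raise ValueError("standardization must be 'diet' or 'loading'")
    t = Z.to_numpy() @ model.weights.to_numpy()
    t = t - t.mean(axis=0)
    sd = t.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    scores = pd.DataFrame(t / sd, index=intake.participants, columns=model.factor_names)
    return ConfirmatoryScore(
        scores=scores,
        diet_wave=intake.wave,
        loading_wave=model.wave or "loading",
        standardization=standardization,
    )


def align_signs(model_a: RRRModel, model_b: RRRModel) -> np.ndarray:
    """Sign vector for wave-B factors, matched to wave A by index.

    A factor is flipped when the dot product of its weight vector with the
    same-index wave-A weights is negative; a zero dot product keeps +1.
    """
    if model_a.food_names != model_b.food_names:
        raise ValueError("models must share the same food universe, in order")
    if model_a.k != model_b.k:
        raise ValueError("models must have the same number of factors")
    dots = (model_a.weights.to_numpy() * model_b.weights.to_numpy()).sum(axis=0)
    return np.where(dots < 0, -1.0, 1.0)


def apply_signs(model: RRRModel, signs: np.ndarray) -> RRRModel:
    """Return a copy of ``model`` with factor signs flipped per ``signs``."""
    s = np.asarray(signs, dtype=float)
    return dc_replace(
        model,
        weights=model.weights * s,
        response_loadings=model.response_loadings * s,
        scores=model.scores * s,
        food_loadings=model.food_loadings * s,
    )


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n <= 3:
        raise ValueError("Fisher CI requires n > 3")
    if abs(r) >= 1:
        raise ValueError("Fisher CI undefined at |r| = 1")
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def _corr_blocks(scores: pd.DataFrame, level: float = 0.95):
    n = len(scores)
    cols = scores.columns
    r = scores.corr()
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    lo = pd.DataFrame(np.nan, index=cols, columns=cols)
    hi = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j < i:
                continue
            rij = float(r.loc[a, b])
            if i == j:
                p.loc[a, b] = 0.0
                lo.loc[a, b] = hi.loc[a, b] = 1.0
                continue
            pij = float(stats.pearsonr(scores[a], scores[b]).pvalue)
            p.loc[a, b] = p.loc[b, a] = pij
            if abs(rij) >= 1 - 1e-12:
                lo.loc[a, b] = lo.loc[b, a] = rij
                hi.loc[a, b] = hi.loc[b, a] = rij
            else:
                lo_ij, hi_ij = fisher_ci(rij, n, level)
                lo.loc[a, b] = lo.loc[b, a] = lo_ij
                hi.loc[a, b] = hi.loc[b, a] = hi_ij
    return r, p, lo, hi


def stability_report(
    model_w1: RRRModel,
    model_w2: RRRModel,
    conf_d2_l1: ConfirmatoryScore,
    conf_d1_l2: ConfirmatoryScore,
    intake_w1: IntakeTable | None = None,
    intake_w2: IntakeTable | None = None,
    highlight_threshold: float = 0.10,
    level: float = 0.95,
) -> StabilityReport:
    """Full cross-wave correlation matrix plus structural comparison.

    The matrix covers four blocks: exploratory wave-1 and wave-2 factors and
    both confirmatory directions. Wave-2 factors are sign-aligned to wave 1
    first, so the report is invariant under arbitrary sign flips of either
    model. Structural rows give, per factor, the high-weight foods shared
    across waves and their weight-sign agreement.
    """
    signs = align_signs(model_w1, model_w2)
    model_w2 = apply_signs(model_w2, signs)
    conf_d2_l1_scores = conf_d2_l1.scores
    conf_d1_l2_scores = conf_d1_l2.scores * signs  # wave-2 loadings flipped too

    e1 = model_w1.scores
    e2 = model_w2.scores
    if not (
        e1.index.equals(e2.index)
        and e1.index.equals(conf_d2_l1_scores.index)
        and e1.index.equals(conf_d1_l2_scores.index)
    ):
        raise ValueError("score sets must be aligned on the same participants")

    blocks = {
        "expl_w1": e1,
        "expl_w2": e2,
        "conf_d2_l1": conf_d2_l1_scores,
        "conf_d1_l2": conf_d1_l2_scores,
    }
    combined = pd.concat(
        {name: df for name, df in blocks.items()}, axis=1
    )
    combined.columns = [f"{blk}:{fac}" for blk, fac in combined.columns]
    r, p, lo, hi = _corr_blocks(combined, level)

    rows = []
    for factor in model_w1.factor_names:
        w1 = model_w1.weights[factor]
        w2 = model_w2.weights[factor]
        high1 = set(w1.index[w1.abs() > highlight_threshold])
        high2 = set(w2.index[w2.abs() > highlight_threshold])
        shared = sorted(high1 & high2)
        agree = (
            float(np.mean([np.sign(w1[f]) == np.sign(w2[f]) for f in shared]))
            if shared
            else np.nan
        )
        cos = float(
            w1 @ w2 / (np.linalg.norm(w1) * np.linalg.norm(w2))
        )
        rows.append(
            {
                "factor": factor,
                "high_weight_w1": ",".join(sorted(high1)),
                "high_weight_w2": ",".join(sorted(high2)),
                "shared_high_weight": ",".join(shared),
                "n_shared": len(shared),
                "sign_agreement": agree,
                "weight_cosine": cos,
            }
        )
    structure = pd.DataFrame(rows).set_index("factor")

    food_spearman = None
    if intake_w1 is not None and intake_w2 is not None:
        food_spearman = cross_wave_descriptives(intake_w1, intake_w2)

    labels = {
        "wave1": label_patterns(model_w1, highlight_threshold),
        "wave2": label_patterns(model_w2, highlight_threshold),
    }
    return StabilityReport(
        correlations=r,
        p_values=p,
        ci_lower=lo,
        ci_upper=hi,
        sign_vector=signs,
        structure=structure,
        food_spearman=food_spearman,
        labels=labels,
        n=len(combined),
    )
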