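"""End-to-end two-wave pipeline and report writers.

Stage order: optional energy-residual adjustment -> standardization ->
backwards screening of food groups against each single response in each
wave -> cross-wave retention rule -> pattern-count selection by
cross-validated PRESS with the Van der Voet test (on the baseline wave) ->
exploratory pattern extraction per wave -> sign alignment -> confirmatory
scoring in both directions -> stability report. The pipeline is a pure
function of (tables, config, seed); every stage is logged.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossval, preprocess, rrr, selection, stability
from .tables import IntakeTable, ResponsePanel, align_waves

logger = logging.getLogger("dietrrr")


class PipelineError(RuntimeError):
    """Raised when the pipeline cannot proceed (e.g. screening retains < 2 foods)."""


@dataclass
class PipelineConfig:
    """Thresholds and Monte-Carlo settings for the full analysis."""

    alpha_backwards: float = 0.05
    min_responses_retained: int = 3
    retention_wave_rule: str = "either"  # "either" or "both"
    cv_n_splits: int = 1000
    cv_test_fraction: float = 0.1
    cv_k_max: int | None = None  # default: min(#retained foods, #responses)
    vandervoet_alpha: float = 0.10
    n_randomizations: int = 2000
    weight_highlight_threshold: float = 0.10
    energy_adjust: bool = False
    confirmatory_standardization: str = "diet"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_backwards", "cv_test_fraction", "vandervoet_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("min_responses_retained", "cv_n_splits", "n_randomizations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self)))
        return Path(path)


@dataclass
class PipelineResult:
    config: PipelineConfig
    selection: selection.SelectionResult
    press: crossval.PressCurve
    chosen_k: int
    models: dict[str, rrr.RRRModel] = field(default_factory=dict)
    explained: dict[str, pd.DataFrame] = field(default_factory=dict)
    confirmatory: dict[str, stability.ConfirmatoryScore] = field(default_factory=dict)
    stability: stability.StabilityReport | None = None
    descriptives: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)

    @property
    def has_patterns(self) -> bool:
        return self.chosen_k > 0


def run_pipeline(
    config: PipelineConfig,
    intake_w1: IntakeTable,
    responses_w1: ResponsePanel,
    intake_w2: IntakeTable,
    responses_w2: ResponsePanel,
) -> PipelineResult:
    """Run the full stability analysis on two aligned measurement waves."""
    log: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log.append(msg)

    intake_w1, responses_w1 = align_waves(intake_w1, responses_w1)
    intake_w2, responses_w2 = align_waves(intake_w2, responses_w2)
    if not intake_w1.participants.equals(intake_w2.participants):
        if set(intake_w1.participants) != set(intake_w2.participants):
            raise PipelineError("the two waves must cover the same participants")
        intake_w2 = IntakeTable(
            foods=intake_w2.foods.reindex(intake_w1.participants),
            wave=intake_w2.wave,
            energy=None
            if intake_w2.energy is None
            else intake_w2.energy.reindex(intake_w1.participants),
        )
        intake_w2, responses_w2 = align_waves(intake_w2, responses_w2)
    if intake_w1.food_names != intake_w2.food_names:
        raise PipelineError("the two waves must share the same food columns")

    descriptives = preprocess.cross_wave_descriptives(intake_w1, intake_w2)

    if config.energy_adjust:
        note("energy-adjusting food intakes by the residual method")
        intake_w1 = preprocess.energy_adjust_table(intake_w1)
        intake_w2 = preprocess.energy_adjust_table(intake_w2)

    X1 = preprocess.standardize(intake_w1.foods, wave=intake_w1.wave)
    X2 = preprocess.standardize(intake_w2.foods, wave=intake_w2.wave)
    Y1 = preprocess.standardize(responses_w1.values, wave=responses_w1.wave)
    Y2 = preprocess.standardize(responses_w2.values, wave=responses_w2.wave)

    # backwards screening per wave and response
    wave_maps: dict[str, dict[str, list[str]]] = {}
    audit: dict = {}
    for wave, X, Y in ((intake_w1.wave, X1, Y1), (intake_w2.wave, X2, Y2)):
        per_response = {}
        for response in Y.columns:
            res = selection.backward_eliminate(
                X.values, Y.values[response], alpha=config.alpha_backwards
            )
            per_response[response] = res.retained
            audit[(wave, response)] = res
        wave_maps[wave] = per_response
    sel = selection.select_food_groups(
        wave_maps,
        food_universe=intake_w1.food_names,
        min_responses=config.min_responses_retained,
        wave_rule=config.retention_wave_rule,
    )
    sel.audit = audit
    note(
        f"backwards screening retained {len(sel.retained_foods)}/{len(intake_w1.food_names)} "
        f"food groups: {', '.join(sel.retained_foods)}"
    )
    if len(sel.retained_foods) < 2:
        raise PipelineError(
            f"screening retained {len(sel.retained_foods)} food group(s); "
            "at least 2 are required for pattern extraction"
        )

    foods1 = intake_w1.foods[sel.retained_foods]
    foods2 = intake_w2.foods[sel.retained_foods]
    q = len(responses_w1.response_names)
    k_max = min(
        config.cv_k_max if config.cv_k_max is not None else q,
        len(sel.retained_foods),
        q,
    )
    curve = crossval.press_curve(
        foods1,
        responses_w1.values,
        k_max=k_max,
        n_splits=config.cv_n_splits,
        test_fraction=config.cv_test_fraction,
        seed=config.seed,
        n_randomizations=config.n_randomizations,
    )
    chosen_k = crossval.choose_n_patterns(curve, alpha=config.vandervoet_alpha)
    note(
        f"PRESS minimized at k={curve.ref_k}; chosen number of patterns k={chosen_k} "
        f"(alpha={config.vandervoet_alpha})"
    )

    result = PipelineResult(
        config=config,
        selection=sel,
        press=curve,
        chosen_k=chosen_k,
        descriptives=descriptives,
        log=log,
    )
    if chosen_k == 0:
        note("no dietary pattern predicts the responses better than the null model")
        return result

    X1r = preprocess.standardize(foods1, wave=intake_w1.wave)
    X2r = preprocess.standardize(foods2, wave=intake_w2.wave)
    m1 = rrr.fit_rrr(X1r, Y1, chosen_k)
    m2 = rrr.fit_rrr(X2r, Y2, chosen_k)
    signs = stability.align_signs(m1, m2)
    m2 = stability.apply_signs(m2, signs)
    result.models = {intake_w1.wave: m1, intake_w2.wave: m2}
    result.explained = {
        intake_w1.wave: rrr.explained_variation(m1, X1r, Y1),
        intake_w2.wave: rrr.explained_variation(m2, X2r, Y2),
    }

    sub1 = IntakeTable.__new__(IntakeTable)
    sub1.foods, sub1.wave, sub1.energy = foods1, intake_w1.wave, None
    sub2 = IntakeTable.__new__(IntakeTable)
    sub2.foods, sub2.wave, sub2.energy = foods2, intake_w2.wave, None
    conf_d2_l1 = stability.confirmatory_score(
        m1, sub2, standardization=config.confirmatory_standardization
    )
    conf_d1_l2 = stability.confirmatory_score(
        m2, sub1, standardization=config.confirmatory_standardization
    )
    result.confirmatory = {"d2_l1": conf_d2_l1, "d1_l2": conf_d1_l2}
    result.stability = stability.stability_report(
        m1,
        m2,
        conf_d2_l1,
        conf_d1_l2,
        intake_w1=intake_w1,
        intake_w2=intake_w2,
        highlight_threshold=config.weight_highlight_threshold,
    )
    note("stability report computed")
    return result


def _fmt(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    return df.round(decimals)


def write_pattern_report(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Emit the human-readable report files for a pipeline run.

    Weights are printed to 2 decimals with high-weight flags, explained
    variation to 1 decimal with all-responses/all-foods summary rows, plus
    the PRESS/selection tables and the cross-wave correlation matrix. With
    k = 0 only the selection and PRESS tables are written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path)
        written.append(path)

    ind = result.selection.indicator.copy()
    ind.columns = [f"{w}:{r}" for w, r in ind.columns]
    emit(ind.astype(int), "selection_indicator.csv")
    emit(result.selection.counts, "selection_counts.csv")
    if result.selection.audit:
        lines = []
        for (wave, response), elim in result.selection.audit.items():
            lines.append(f"[{wave} / {response}] retained: {', '.join(elim.retained) or '(none)'}")
            for step in elim.steps:
                lines.append(
                    f"  step {step.step}: dropped {step.dropped} (p={step.p_value:.4f})"
                )
        audit_path = outdir / "selection_audit.txt"
        audit_path.write_text("\n".join(lines) + "\n")
        written.append(audit_path)
    emit(result.press.to_frame(), "press_curve.csv")
    if result.descriptives is not None:
        emit(_fmt(result.descriptives, 2), "food_descriptives.csv")

    summary = [
        f"retained food groups ({len(result.selection.retained_foods)}): "
        + ", ".join(result.selection.retained_foods),
        f"PRESS minimized at k={result.press.ref_k}; chosen k={result.chosen_k}",
    ]
    if not result.has_patterns:
        summary.append(
            "no dietary pattern predicts the response set better than the null model"
        )
    else:
        thr = result.config.weight_highlight_threshold
        for wave, model in result.models.items():
            flag = model.weights.abs() > thr
            wdf = model.weights.map(lambda v: f"{v:.2f}") + flag.map(
                lambda f: "*" if f else ""
            )
            emit(wdf, f"weights_{wave}.csv")
            emit(_fmt(result.explained[wave], 1), f"explained_variation_{wave}.csv")
            for lab in stability_labels(result, wave):
                summary.append(f"{wave} {lab['factor']}: {lab['label']}")
            model.to_json(outdir / f"model_{wave}.json")
            written.append(outdir / f"model_{wave}.json")
        rep = result.stability
        emit(_fmt(rep.correlations, 2), "stability_correlations.csv")
        emit(rep.p_values, "stability_p_values.csv")
        emit(_fmt(rep.ci_lower, 3), "stability_ci_lower.csv")
        emit(_fmt(rep.ci_upper, 3), "stability_ci_upper.csv")
        emit(rep.structure, "pattern_structure.csv")
        waves = list(result.models)
        for i, factor in enumerate(result.models[waves[0]].factor_names):
            r = rep.correlations.loc[f"expl_w1:{factor}", f"expl_w2:{factor}"]
            summary.append(f"cross-wave exploratory correlation, {factor}: {r:.2f}")
    summary.extend(result.log)
    path = outdir / "summary.txt"
    path.write_text("\n".join(summary) + "\n")
    written.append(path)
    return written


def stability_labels(result: PipelineResult, wave: str) -> list[dict]:
    return rrr.label_patterns(
        result.models[wave], result.config.weight_highlight_threshold
    )
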