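"""Greedy sequential ablation harness over the model configuration.

Ten studies each vary one knob of :class:`~paperecg.inres.ModelConfig`
(residual scaling, filter size, filter count, pooling type, activation,
batch size, head type, loss, optimizer, learning rate) while carrying every
previously adopted value forward. After each study the harness adopts the
accuracy-maximizing candidate — except that a candidate with strictly lower
computational complexity is preferred when its accuracy is within a
tolerance ``delta`` (default 0.5 accuracy points) of the maximum, the rule
that trades a sliver of accuracy for a much cheaper model.

Each candidate row is labelled against the running best accuracy (the value
adopted after the previous study): ``improved`` above it, ``identical``
equal to two decimals, ``dropped`` below (the starting configuration's own
row is therefore ``identical`` by construction).

The evaluator is injected: tests and replays feed recorded accuracies
(:data:`REFERENCE_STUDY_LOG` ships the reference training log), while live
runs can train reduced models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import pandas as pd

from .errors import ConfigurationError
from .inres import ActivationSpec, ModelConfig


@dataclass(frozen=True)
class Study:
    name: str
    knob: str
    candidates: tuple           # values assigned to the knob
    labels: tuple[str, ...]     # display names, parallel to candidates

    def apply(self, cfg: ModelConfig, value) -> ModelConfig:
        return replace(cfg, **{self.knob: value})


@dataclass(frozen=True)
class EvalOutcome:
    accuracy: float             # percent
    complexity_m: float         # millions of multiply-accumulates
    epoch_seconds: float = 0.0


@dataclass
class AblationReport:
    rows: list[dict] = field(default_factory=list)
    final_config: ModelConfig | None = None
    base_accuracy: float = float("nan")

    def chosen(self, study_name: str):
        for row in self.rows:
            if row["study"] == study_name and row["chosen"]:
                return row
        return None


def default_study_plan() -> tuple[Study, ...]:
    """The ten studies with their candidate values, in protocol order."""
    return (
        Study("rsf", "rsf_enabled", (True, False), ("with", "without")),
        Study("filter_size", "filter_size", (3, 2, 5), ("3x3", "2x2", "5x5")),
        Study("n_filters", "n_filters", (16, 32, 64), ("16", "32", "64")),
        Study("pool_type", "pool_type", ("max", "average"), ("max", "average")),
        Study("activation", "activation",
              tuple(ActivationSpec(k) for k in
                    ("prelu", "relu", "leakyrelu", "tanh", "elu")),
              ("PReLU", "ReLU", "LeakyReLU", "Tanh", "ELU")),
        Study("batch_size", "batch_size", (16, 32, 64, 128),
              ("16", "32", "64", "128")),
        Study("head_type", "head_type",
              ("flatten", "global-max-pool", "global-average-pool"),
              ("flatten", "global-max", "global-average")),
        Study("loss", "loss",
              ("binary_crossentropy", "categorical_crossentropy",
               "mean_squared_error", "mean_absolute_error",
               "mean_squared_logarithmic_error", "kullback_leibler_divergence"),
              ("binary-cross-entropy", "categorical-cross-entropy",
               "mean-squared-error", "mean-absolute-error",
               "mean-squared-log-error", "kl-divergence")),
        Study("optimizer", "optimizer",
              ("adam", "nadam", "sgd", "adamax", "rmsprop"),
              ("Adam", "Nadam", "SGD", "Adamax", "RMSprop")),
        Study("learning_rate", "learning_rate",
              (0.01, 0.007, 0.001, 0.0007, 0.0001),
              ("0.01", "0.007", "0.001", "0.0007", "0.0001")),
    )


def default_base_config() -> ModelConfig:
    """Starting configuration: unscaled residuals, 32 filters, ReLU,
    global-average head, Adam at 0.001."""
    return ModelConfig(
        filter_size=3, n_filters=32, pool_type="max",
        activation=ActivationSpec("relu"), head_type="global-average-pool",
        loss="categorical_crossentropy", optimizer="adam",
        learning_rate=0.001, batch_size=32, rsf_enabled=False,
    )


#: Recorded (accuracy %, complexity in millions, seconds/epoch) of the
#: reference training runs for every candidate, keyed by (study, label).
REFERENCE_STUDY_LOG: dict[tuple[str, str], EvalOutcome] = {
    ("__base__", "__base__"): EvalOutcome(95.01, 657.3, 84),
    ("rsf", "with"): EvalOutcome(95.59, 434.5, 77),
    ("rsf", "without"): EvalOutcome(95.01, 657.3, 84),
    ("filter_size", "3x3"): EvalOutcome(95.59, 434.5, 77),
    ("filter_size", "2x2"): EvalOutcome(95.04, 327.4, 71),
    ("filter_size", "5x5"): EvalOutcome(95.894, 717.4, 85),
    ("n_filters", "16"): EvalOutcome(95.23, 286.24, 74),
    ("n_filters", "32"): EvalOutcome(95.59, 290.4, 77),
    ("n_filters", "64"): EvalOutcome(96.29, 294.4, 78),
    ("pool_type", "max"): EvalOutcome(96.29, 294.4, 77),
    ("pool_type", "average"): EvalOutcome(96.29, 294.4, 77),
    ("activation", "PReLU"): EvalOutcome(97.28, 294.4, 77),
    ("activation", "ReLU"): EvalOutcome(96.29, 294.4, 77),
    ("activation", "LeakyReLU"): EvalOutcome(95.55, 294.4, 77),
    ("activation", "Tanh"): EvalOutcome(96.11, 294.4, 77),
    ("activation", "ELU"): EvalOutcome(96.29, 294.4, 77),
    ("batch_size", "16"): EvalOutcome(97.53, 294.4, 77),
    ("batch_size", "32"): EvalOutcome(97.78, 294.4, 77),
    ("batch_size", "64"): EvalOutcome(97.28, 294.4, 78),
    ("batch_size", "128"): EvalOutcome(96.78, 294.4, 78),
    ("head_type", "flatten"): EvalOutcome(97.89, 294.4, 77),
    ("head_type", "global-max"): EvalOutcome(97.02, 294.4, 78),
    ("head_type", "global-average"): EvalOutcome(97.35, 294.4, 77),
    ("loss", "binary-cross-entropy"): EvalOutcome(96.37, 294.4, 78),
    ("loss", "categorical-cross-entropy"): EvalOutcome(97.89, 294.4, 77),
    ("loss", "mean-squared-error"): EvalOutcome(96.73, 294.4, 77),
    ("loss", "mean-absolute-error"): EvalOutcome(97.37, 294.4, 78),
    ("loss", "mean-squared-log-error"): EvalOutcome(96.81, 294.4, 78),
    ("loss", "kl-divergence"): EvalOutcome(97.78, 294.4, 78),
    ("optimizer", "Adam"): EvalOutcome(98.03, 294.4, 77),
    ("optimizer", "Nadam"): EvalOutcome(96.94, 294.4, 77),
    ("optimizer", "SGD"): EvalOutcome(96.58, 297.5, 78),
    ("optimizer", "Adamax"): EvalOutcome(97.89, 294.4, 77),
    ("optimizer", "RMSprop"): EvalOutcome(96.08, 294.4, 79),
    ("learning_rate", "0.01"): EvalOutcome(96.67, 294.4, 77),
    ("learning_rate", "0.007"): EvalOutcome(97.46, 294.4, 77),
    ("learning_rate", "0.001"): EvalOutcome(98.03, 294.4, 77),
    ("learning_rate", "0.0007"): EvalOutcome(98.34, 294.4, 78),
    ("learning_rate", "0.0001"): EvalOutcome(97.83, 294.4, 78),
}


def make_reference_evaluator() -> Callable:
    """Evaluator replaying :data:`REFERENCE_STUDY_LOG`."""

    def evaluator(cfg: ModelConfig, study: str | None = None,
                  candidate: str | None = None) -> EvalOutcome:
        key = (study or "__base__", candidate or "__base__")
        try:
            return REFERENCE_STUDY_LOG[key]
        except KeyError:
            raise ConfigurationError(f"no recorded outcome for {key}") from None

    return evaluator


def _finding(accuracy: float, running_best: float, tol: float = 0.005) -> str:
    if accuracy > running_best + tol:
        return "improved"
    if abs(accuracy - running_best) <= tol:
        return "identical"
    return "dropped"


def run_ablation(plan: Sequence[Study], base_cfg: ModelConfig,
                 evaluator: Callable, delta: float = 0.5) -> AblationReport:
    """Execute the greedy protocol and return the per-candidate report.

    ``evaluator(cfg, study=name, candidate=label)`` returns an
    :class:`EvalOutcome` (or an ``(accuracy, complexity, seconds)`` tuple).
    A failing candidate is recorded and skipped. With ``delta=0`` selection
    degenerates to pure accuracy argmax (lower complexity only breaks exact
    ties).
    """
    report = AblationReport()
    base_out = _coerce(evaluator(base_cfg, study=None, candidate=None))
    report.base_accuracy = base_out.accuracy
    running_best = base_out.accuracy
    cfg = base_cfg

    for study in plan:
        if not study.candidates:
            raise ConfigurationError(f"study {study.name!r} has no candidates")
        evaluated = []
        for value, label in zip(study.candidates, study.labels):
            cand_cfg = study.apply(cfg, value)
            try:
                out = _coerce(evaluator(cand_cfg, study=study.name,
                                        candidate=label))
            except Exception as exc:  # noqa: BLE001 - candidate isolation
                report.rows.append({
                    "study": study.name, "candidate": label,
                    "accuracy": float("nan"), "complexity_m": float("nan"),
                    "epoch_seconds": float("nan"),
                    "finding": f"failed: {exc}", "chosen": False,
                })
                continue
            row = {
                "study": study.name, "candidate": label,
                "accuracy": out.accuracy, "complexity_m": out.complexity_m,
                "epoch_seconds": out.epoch_seconds,
                "finding": _finding(out.accuracy, running_best),
                "chosen": False,
            }
            report.rows.append(row)
            evaluated.append((row, value, out))
        if not evaluated:
            continue
        best_acc = max(out.accuracy for _, _, out in evaluated)
        eligible = [e for e in evaluated if e[2].accuracy >= best_acc - delta]
        min_cx = min(out.complexity_m for _, _, out in eligible)
        finalists = [e for e in eligible if out_cx(e) == min_cx]
        chosen = max(finalists, key=lambda e: e[2].accuracy)
        chosen[0]["chosen"] = True
        cfg = study.apply(cfg, chosen[1])
        running_best = chosen[2].accuracy

    report.final_config = cfg
    return report


def out_cx(entry) -> float:
    return entry[2].complexity_m


def _coerce(out) -> EvalOutcome:
    if isinstance(out, EvalOutcome):
        return out
    return EvalOutcome(*out)


def format_report(report: AblationReport) -> pd.DataFrame:
    """Tabular view of a completed report (CSV round-trips losslessly)."""
    return pd.DataFrame(
        report.rows,
        columns=["study", "candidate", "accuracy", "complexity_m",
                 "epoch_seconds", "finding", "chosen"],
    )
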