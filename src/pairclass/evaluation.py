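"""Common evaluation harness for all predictor families.

Accuracy, per-class recall, confusion matrices, tie counting, score-margin
summaries and purity-sensitivity curves.  A tied prediction counts as
correct only if the reference class is the reported (lexicographically
first) winner — a conservative convention, stated in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .results import PredictionResult


@dataclass
class EvalReport:
    accuracy: float
    per_class_recall: pd.Series
    confusion: pd.DataFrame  # reference × predicted
    tie_count: int
    mean_margin: float
    per_platform_accuracy: pd.Series | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "per_class_recall": self.per_class_recall.to_dict(),
            "confusion": {str(k): v for k, v in self.confusion.to_dict(orient="index").items()},
            "tie_count": self.tie_count,
            "mean_margin": self.mean_margin,
        }
        if self.per_platform_accuracy is not None:
            out["per_platform_accuracy"] = self.per_platform_accuracy.to_dict()
        return out

    def __str__(self) -> str:
        lines = [
            f"accuracy:    {self.accuracy:.4f}",
            f"tie count:   {self.tie_count}",
            f"mean margin: {self.mean_margin:.4f}",
            "per-class recall:",
        ]
        for cls, r in self.per_class_recall.items():
            lines.append(f"  {cls}: {r:.4f}")
        if self.per_platform_accuracy is not None:
            lines.append("per-platform accuracy:")
            for p, a in self.per_platform_accuracy.items():
                lines.append(f"  {p}: {a:.4f}")
        lines.append("confusion matrix (reference x predicted):")
        lines.append(self.confusion.to_string())
        return "\n".join(lines)


def evaluate(
    predictions: PredictionResult,
    reference: pd.Series,
    *,
    platforms: pd.Series | None = None,
) -> EvalReport:
    """Score predictions against reference labels."""
    reference = pd.Series(reference)
    pred_ids = pd.Index(predictions.sample_ids)
    if set(pred_ids) != set(reference.index):
        offending = sorted(set(pred_ids).symmetric_difference(reference.index))[:5]
        raise ValueError(f"sample sets differ between predictions and reference: {offending}")
    reference = reference.loc[pred_ids]
    classes = sorted(set(predictions.classes) | set(reference.unique()))
    correct = predictions.predicted == reference
    confusion = pd.crosstab(reference, predictions.predicted).reindex(
        index=classes, columns=classes, fill_value=0
    )
    confusion.index.name = "reference"
    confusion.columns.name = "predicted"
    recall = pd.Series(
        {
            cls: float(correct[reference == cls].mean()) if (reference == cls).any() else np.nan
            for cls in classes
        },
        name="recall",
    )
    per_platform = None
    if platforms is not None:
        platforms = pd.Series(platforms).loc[pred_ids]
        per_platform = correct.groupby(platforms).mean().astype(float)
    return EvalReport(
        accuracy=float(correct.mean()),
        per_class_recall=recall,
        confusion=confusion,
        tie_count=int(predictions.tie.sum()),
        mean_margin=float(predictions.margin.mean()),
        per_platform_accuracy=per_platform,
    )


def margin_profile(predictions: PredictionResult) -> pd.DataFrame:
    """Mean/median margin overall and per predicted class."""
    df = pd.DataFrame({"predicted": predictions.predicted, "margin": predictions.margin})
    per_class = df.groupby("predicted")["margin"].agg(["mean", "median", "count"])
    overall = pd.DataFrame(
        {"mean": [df["margin"].mean()], "median": [df["margin"].median()], "count": [len(df)]},
        index=["overall"],
    )
    return pd.concat([overall, per_class])


def purity_sensitivity(
    train_and_predict,
    config,
    purity_grid,
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy and mean margin of a predictor across fixed purity levels.

    ``train_and_predict(train_cohort, test_cohort) -> PredictionResult`` is
    trained once on a cohort generated at the configured purity and then
    applied to test cohorts regenerated at each purity level in the grid
    (same seed offsets, so the curve is reproducible).
    """
    from dataclasses import replace

    from .synthetic import simulate_cohort

    train_cohort, _ = simulate_cohort(replace(config, seed=seed))
    rows = []
    for purity in purity_grid:
        # fresh samples from the same gene-level ground truth
        test_cfg = replace(
            config, purity_fixed=float(purity), seed=seed, sample_seed_offset=1_000_000
        )
        test_cohort, _ = simulate_cohort(test_cfg)
        pred = train_and_predict(train_cohort, test_cohort)
        correct = pred.predicted == test_cohort.labels.loc[pred.sample_ids]
        rows.append(
            {
                "purity": float(purity),
                "accuracy": float(correct.mean()),
                "mean_margin": float(pred.margin.mean()),
                "tie_rate": float(pred.tie.mean()),
            }
        )
    return pd.DataFrame(rows)
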