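"""Common prediction-result container shared by all predictor families."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PredictionResult:
    """Per-sample per-class scores with the derived class call.

    ``scores`` is a samples × classes DataFrame.  The predicted class attains
    the maximum score; when two or more classes tie exactly for the top score
    the tie flag is set and the lexicographically first tied class is
    reported (a deterministic, auditable convention).  ``margin`` is the top
    score minus the second-highest score (0 under a tie).
    """

    scores: pd.DataFrame
    predicted: pd.Series
    margin: pd.Series
    tie: pd.Series

    @classmethod
    def from_scores(cls, scores: pd.DataFrame) -> "PredictionResult":
        scores = scores.reindex(sorted(scores.columns), axis=1)
        arr = scores.to_numpy(dtype=float)
        if arr.shape[1] < 2:
            raise ValueError("need at least two classes to form a prediction")
        top = arr.max(axis=1)
        is_top = arr == top[:, None]
        # lexicographically first class attaining the maximum (columns sorted)
        win_idx = is_top.argmax(axis=1)
        tie = is_top.sum(axis=1) >= 2
        part = np.partition(arr, -2, axis=1)
        margin = top - part[:, -2]
        classes = scores.columns.to_numpy()
        idx = scores.index
        return cls(
            scores=scores,
            predicted=pd.Series(classes[win_idx], index=idx, name="predicted"),
            margin=pd.Series(margin, index=idx, name="margin"),
            tie=pd.Series(tie, index=idx, name="tie"),
        )

    @property
    def sample_ids(self) -> list:
        return self.scores.index.tolist()

    @property
    def classes(self) -> list:
        return self.scores.columns.tolist()

    def to_frame(self) -> pd.DataFrame:
        """Flat table: sample_id, predicted_class, tie_flag, margin, one score column per class."""
        out = pd.DataFrame(
            {
                "predicted_class": self.predicted,
                "tie_flag": self.tie.astype(int),
                "margin": self.margin,
            }
        )
        for c in self.scores.columns:
            out[f"score_{c}"] = self.scores[c]
        out.index.name = "sample_id"
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PredictionResult":
        score_cols = [c for c in df.columns if c.startswith("score_")]
        scores = df[score_cols].rename(columns=lambda c: c[len("score_"):])
        return cls.from_scores(scores)
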