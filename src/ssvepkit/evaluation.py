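"""Sliding-window experiments, window-length sweeps, ANOVA and Tukey.

The phase-effect experiment slides a fixed-length window through every
trial in one-sample steps, classifying each position with each detector
and recording per-position accuracy and ITR.  Comparing the run that
includes the transient onset against one that trims the first 50 samples
(~200 ms at 256 Hz) isolates the cost of the transient visual response;
the per-approach coefficient of variation over positions measures
robustness to phase shift.  A one-way ANOVA over approaches followed by
Tukey's honestly-significant-difference test settles whether the
approaches genuinely differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import EpochArray, StimulusGrid, ValidationError
from .metrics import DEFAULT_GAZE_SECONDS, ITRParams, itr
from .preprocessing import WindowSpec, extract_windows

__all__ = [
    "EvaluationTable",
    "classify_epochs",
    "sliding_window_experiment",
    "window_length_sweep",
    "summarize",
    "one_way_anova",
    "anova_from_sums",
    "tukey_critical_difference",
    "tukey_hsd",
]


@dataclass(frozen=True)
class EvaluationTable:
    """Long-format evaluation records.

    ``records`` has one row per (approach, condition) with columns
    ``approach``, ``condition`` (window start sample or window length in
    seconds), ``accuracy`` (percent) and ``itr`` (bits/min).
    """

    records: pd.DataFrame

    def for_approach(self, name: str) -> pd.DataFrame:
        return self.records[self.records["approach"] == name]


def classify_epochs(epochs: EpochArray, detector) -> pd.DataFrame:
    """Classify every trial (full length); one row per trial.

    Columns: trial, true label, decided label, and the per-stimulus
    scores — the delimited batch-result layout shared by all detectors.
    """
    rows = []
    for i in range(epochs.n_trials):
        result = detector.classify(epochs.data[i])
        row = {
            "trial": i,
            "true_label": int(epochs.labels[i]),
            "decided": result.decided,
        }
        row.update({f"score_{k + 1}": s for k, s in enumerate(result.scores)})
        rows.append(row)
    return pd.DataFrame(rows)


def _accuracy_percent(epochs: EpochArray, detector, windows) -> float:
    correct = sum(
        int(detector.classify(w.data[i]).decided == w.labels[i])
        for w in windows
        for i in range(w.n_trials)
    )
    total = sum(w.n_trials for w in windows)
    return 100.0 * correct / total


def sliding_window_experiment(
    epochs: EpochArray,
    detectors: Sequence,
    window: WindowSpec,
    grid: StimulusGrid | None = None,
    *,
    gaze_seconds: float = DEFAULT_GAZE_SECONDS,
) -> EvaluationTable:
    """Accuracy and ITR at every sliding-window position per approach.

    The window spec's ``trim_samples`` selects the experiment mode: 0
    keeps the transient onset in play, 50 (~200 ms at 256 Hz) starts in
    the steady state.  ITR uses the window length plus the gaze-shift
    overhead as the decision period; below-chance accuracies contribute
    zero bits.
    """
    grid = grid or epochs.grid
    window_seconds = window.length_samples / epochs.sample_rate
    rows = []
    for detector in detectors:
        for start, windowed in extract_windows(epochs, window, mode="sliding"):
            correct = sum(
                int(detector.classify(windowed.data[i]).decided == windowed.labels[i])
                for i in range(windowed.n_trials)
            )
            acc = correct / windowed.n_trials
            rate = (
                itr(
                    ITRParams(grid.k, acc, window_seconds, gaze_seconds),
                    clip_below_chance=True,
                )
                if acc > 0
                else 0.0
            )
            rows.append(
                {
                    "approach": detector.name,
                    "condition": start,
                    "accuracy": 100.0 * acc,
                    "itr": rate,
                }
            )
    return EvaluationTable(records=pd.DataFrame(rows))


def window_length_sweep(
    epochs: EpochArray,
    detectors: Sequence,
    lengths_seconds: Sequence[float],
    grid: StimulusGrid | None = None,
    *,
    start_sample: int = 0,
    gaze_seconds: float = DEFAULT_GAZE_SECONDS,
) -> tuple[EvaluationTable, pd.DataFrame]:
    """Accuracy/ITR per window length, plus the maximum-ITR summary.

    Returns the long-format table (condition = window length in seconds)
    and one row per detector with the length attaining its maximum ITR
    and the accuracy there — the per-user "best operating point" logic.
    """
    grid = grid or epochs.grid
    rows = []
    for seconds in lengths_seconds:
        length = round(seconds * epochs.sample_rate)
        if start_sample + length > epochs.n_samples:
            raise ValidationError(
                f"window of {seconds} s does not fit in {epochs.duration} s trials"
            )
        spec = WindowSpec(length_samples=length, start_sample=start_sample)
        for detector in detectors:
            _, windowed = next(iter(extract_windows(epochs, spec, mode="fixed")))
            correct = sum(
                int(detector.classify(windowed.data[i]).decided == windowed.labels[i])
                for i in range(windowed.n_trials)
            )
            acc = correct / windowed.n_trials
            rate = (
                itr(
                    ITRParams(grid.k, acc, seconds, gaze_seconds),
                    clip_below_chance=True,
                )
                if acc > 0
                else 0.0
            )
            rows.append(
                {
                    "approach": detector.name,
                    "condition": seconds,
                    "accuracy": 100.0 * acc,
                    "itr": rate,
                }
            )
    table = pd.DataFrame(rows)
    best_rows = []
    for name, group in table.groupby("approach", sort=False):
        best = group.loc[group["itr"].idxmax()]
        best_rows.append(
            {
                "approach": name,
                "best_window_seconds": best["condition"],
                "accuracy": best["accuracy"],
                "itr": best["itr"],
            }
        )
    return EvaluationTable(records=table), pd.DataFrame(best_rows)


def summarize(table: EvaluationTable, response: str = "accuracy") -> pd.DataFrame:
    """Per-approach mean, sample std and coefficient of variation (%)."""
    rows = []
    for name, group in table.records.groupby("approach", sort=False):
        values = group[response].to_numpy()
        mean = values.mean()
        std = values.std(ddof=1)
        rows.append(
            {
                "approach": name,
                "mean": mean,
                "std": std,
                "cv": 100.0 * std / mean if mean != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def one_way_anova(table: EvaluationTable, response: str = "accuracy") -> pd.DataFrame:
    """One-way ANOVA over approaches: SS, df, MS and F per source.

    Rows ``Treatments``, ``Error``, ``Total``; the sums of squares are
    additive and ``F = MS_treatments / MS_error``.
    """
    groups = [
        group[response].to_numpy()
        for _, group in table.records.groupby("approach", sort=False)
    ]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 observations each")
    all_values = np.concatenate(groups)
    grand_mean = all_values.mean()
    ss_total = float(np.sum((all_values - grand_mean) ** 2))
    ss_treat = float(
        sum(g.size * (g.mean() - grand_mean) ** 2 for g in groups)
    )
    ss_err = ss_total - ss_treat
    df_treat = len(groups) - 1
    df_err = all_values.size - len(groups)
    return anova_from_sums(ss_treat, df_treat, ss_err, df_err)


def anova_from_sums(
    ss_treat: float, df_treat: int, ss_err: float, df_err: int
) -> pd.DataFrame:
    """ANOVA decomposition from already-computed sums of squares."""
    if min(df_treat, df_err) < 1:
        raise ValidationError("degrees of freedom must be positive")
    ms_treat = ss_treat / df_treat
    ms_err = ss_err / df_err
    f = ms_treat / ms_err if ms_err > 0 else np.inf
    return pd.DataFrame(
        [
            {"source": "Treatments", "df": df_treat, "ss": ss_treat,
             "ms": ms_treat, "f": f},
            {"source": "Error", "df": df_err, "ss": ss_err,
             "ms": ms_err, "f": np.nan},
            {"source": "Total", "df": df_treat + df_err,
             "ss": ss_treat + ss_err, "ms": np.nan, "f": np.nan},
        ]
    )


def tukey_critical_difference(q: float, mse: float, n_per_group: int) -> float:
    """Tukey HSD critical value ``q * sqrt(MSE / n)``.

    Pairwise group-mean differences exceeding it are significant.
    """
    if q <= 0 or mse < 0 or n_per_group <= 0:
        raise ValidationError("q and n must be positive, mse non-negative")
    return float(q * np.sqrt(mse / n_per_group))


def tukey_hsd(
    table: EvaluationTable,
    response: str = "accuracy",
    *,
    q: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Tukey comparisons between approaches.

    ``q`` defaults to the studentized-range quantile for (number of
    groups, error df) at level ``alpha``.  Requires balanced groups.
    One row per unordered pair: the absolute mean difference, the
    critical difference and the significance verdict.
    """
    grouped = {
        name: group[response].to_numpy()
        for name, group in table.records.groupby("approach", sort=False)
    }
    names = list(grouped)
    sizes = {len(v) for v in grouped.values()}
    if len(sizes) != 1:
        raise ValidationError("Tukey HSD here requires balanced groups")
    n = sizes.pop()
    anova = one_way_anova(table, response)
    mse = float(anova.loc[anova["source"] == "Error", "ms"].iloc[0])
    df_err = int(anova.loc[anova["source"] == "Error", "df"].iloc[0])
    if q is None:
        q = float(stats.studentized_range.ppf(1 - alpha, len(names), df_err))
    dvs = tukey_critical_difference(q, mse, n)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = abs(grouped[a].mean() - grouped[b].mean())
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_difference": diff,
                    "q": q,
                    "critical_difference": dvs,
                    "significant": diff > dvs,
                }
            )
    return pd.DataFrame(rows)
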