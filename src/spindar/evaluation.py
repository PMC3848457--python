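"""Time-based comparison of two labelled interval sets.

Every instant of the compared span falls into exactly one of four states:
Agreement (both labelings mark an event), Null Agreement (neither does),
False Negative (only the reference/truth does) and False Positive (only
the detector does).  An optional fuzzy window forgives FP/FN mass lying
within ``fuzzy_s`` of an Agreement region — small boundary timing errors
between two labelers are treated as agreements.

All interval arithmetic is carried out on the discrete sample grid at
``fs`` so the four state durations sum exactly to the compared duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventList

__all__ = ["ComparisonSummary", "compare_labels", "f_beta", "roc_curve"]


@dataclass
class ComparisonSummary:
    """Durations of the four comparison states and the derived metrics."""

    t_agree: float
    t_null: float
    t_fp: float
    t_fn: float
    n_truth: int
    n_hit: int
    fs: float

    @property
    def total(self) -> float:
        return self.t_agree + self.t_null + self.t_fp + self.t_fn

    @property
    def precision(self) -> float:
        d = self.t_agree + self.t_fp
        return self.t_agree / d if d > 0 else 0.0

    @property
    def recall(self) -> float:
        d = self.t_agree + self.t_fn
        return self.t_agree / d if d > 0 else 0.0

    sensitivity = recall

    @property
    def specificity(self) -> float:
        d = self.t_null + self.t_fp
        return self.t_null / d if d > 0 else 0.0

    @property
    def hit_rate(self) -> float:
        return self.n_hit / self.n_truth if self.n_truth else 0.0

    @property
    def ste_s(self) -> float:
        """Temporal error: total FN time per reference event."""
        return self.t_fn / self.n_truth if self.n_truth else 0.0

    def to_dict(self) -> dict:
        return {
            "t_agree_s": self.t_agree,
            "t_null_s": self.t_null,
            "t_fp_s": self.t_fp,
            "t_fn_s": self.t_fn,
            "n_truth": self.n_truth,
            "n_hit": self.n_hit,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "hit_rate": self.hit_rate,
            "ste_s": self.ste_s,
        }

    def summary(self) -> str:
        rows = [
            ("Sensitivity/Recall", f"{self.recall:.3f}"),
            ("Specificity", f"{self.specificity:.3f}"),
            ("Precision", f"{self.precision:.3f}"),
            ("Hit Rate", f"{100 * self.hit_rate:.2f}% ({self.n_hit}/{self.n_truth})"),
            ("Temporal Error", f"~{1e3 * self.ste_s:.0f} ms"),
            ("Agreement", f"{self.t_agree:.3f} s"),
            ("Null Agreement", f"{self.t_null:.3f} s"),
            ("False Negative", f"{self.t_fn:.3f} s"),
            ("False Positive", f"{self.t_fp:.3f} s"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def compare_labels(
    truth: EventList,
    detected: EventList,
    fuzzy_s: float = 0.0,
    total_dur_s: float | None = None,
    fs: float = 128.0,
) -> ComparisonSummary:
    """Classify every instant into the four comparison states.

    FP/FN samples within ``fuzzy_s`` of an Agreement region (the region
    dilated by ``fuzzy_s`` on each side) are reassigned to Agreement.
    ``n_hit`` counts truth events overlapping at least one sample of any
    detected event.
    """
    if total_dur_s is None:
        ends = [e.intervals[-1, 1] for e in (truth, detected) if len(e)]
        total_dur_s = max(ends) if ends else 0.0
    n = int(round(total_dur_s * fs))
    t_mask = truth.to_mask(fs, n)
    d_mask = detected.to_mask(fs, n)

    agree = t_mask & d_mask
    fn = t_mask & ~d_mask
    fp = ~t_mask & d_mask

    if fuzzy_s > 0 and agree.any():
        w = int(round(fuzzy_s * fs))
        if w > 0:
            kernel = np.ones(2 * w + 1)
            near_agree = np.convolve(agree, kernel, mode="same") > 0
            forgiven = (fn | fp) & near_agree
            agree |= forgiven
            fn &= ~forgiven
            fp &= ~forgiven

    n_hit = sum(
        bool(d_mask[int(round(a * fs)): int(round(b * fs))].any())
        for a, b in truth.intervals
    )
    dt = 1.0 / fs
    return ComparisonSummary(
        t_agree=agree.sum() * dt,
        t_null=(n - agree.sum() - fn.sum() - fp.sum()) * dt,
        t_fp=fp.sum() * dt,
        t_fn=fn.sum() * dt,
        n_truth=len(truth),
        n_hit=n_hit,
        fs=fs,
    )


def f_beta(precision: float, recall: float, beta: float = 1.0) -> float:
    """Weighted F-measure; beta > 1 weighs recall above precision.

    Defined as 0 when precision and recall are both 0.
    """
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


def roc_curve(
    traces,
    truth: EventList,
    fuzzy_s: float = 0.0,
    grid: np.ndarray | None = None,
    vote_fraction: float = 1.0 / 3.0,
    merge_gap_s: float = 0.250,
    min_dur_s: float = 0.250,
    total_dur_s: float | None = None,
) -> np.ndarray:
    """Time-based ROC points over a threshold grid.

    Returns rows ``(fpr, tpr, tau)`` sorted by tau; TPR is the time-based
    recall and FPR is one minus the specificity.
    """
    from .detect import default_threshold_grid, detect_events

    if len(truth) == 0:
        raise ValueError("truth must contain at least one event")
    if grid is None:
        grid = default_threshold_grid(traces)
    grid = np.sort(np.asarray(grid, dtype=float))
    fs = traces[0].fs
    if total_dur_s is None:
        total_dur_s = traces[0].psi.size / fs
    rows = []
    for tau in grid:
        detected = detect_events(traces, tau, vote_fraction, merge_gap_s, min_dur_s)
        s = compare_labels(truth, detected, fuzzy_s, total_dur_s, fs=fs)
        rows.append((1.0 - s.specificity, s.recall, tau))
    return np.asarray(rows)
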