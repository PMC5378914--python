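"""M17 muscle electrophysiology: baseline-normalized spike rates.

The M17 muscle drives the proboscis extension response; its spike rate
during an odor is an electrophysiological readout of conditioned
responding.  Each trial provides a 5 s pre-stimulus baseline window and a
4 s odor window; the response measure is the odor-window rate normalized by
the baseline rate.  Normalization is subtractive by default — baseline
rates near zero (mineral oil ~1 Hz) make ratios unstable and the reported
values are on an absolute Hz scale — with a divisive mode available.
"""

from __future__ import annotations

import logging
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import M17Record, STIMULI

__all__ = ["normalized_rate", "memory_scores", "DEFAULT_EPHYS_COMPARISONS"]

logger = logging.getLogger(__name__)


def normalized_rate(rec: M17Record, mode: str = "subtract") -> float:
    """Odor-window spike rate normalized by the trial's baseline rate.

    ``subtract`` (default): odor_count/odor_dur - baseline_count/base_dur,
    in Hz; negative values indicate suppression.  ``divide``: the rate
    ratio, requiring a nonzero baseline count.
    """
    b0, b1 = rec.baseline_window
    o0, o1 = rec.odor_window
    base_rate = rec.count_in((b0, b1)) / (b1 - b0)
    odor_rate = rec.count_in((o0, o1)) / (o1 - o0)
    if mode == "subtract":
        return odor_rate - base_rate
    if mode == "divide":
        if base_rate == 0:
            raise ValueError(
                "divisive normalization undefined with a silent baseline"
            )
        return odor_rate / base_rate
    raise ValueError(f"unknown mode {mode!r}; use 'subtract' or 'divide'")


#: Comparisons the M17 analysis emits for the statistics stage:
#: (name, kind).  "within" = CS+ vs mineral oil per cell (paired design,
#: one-tailed: trained bees respond more to the CS+); "between" = treatment
#: contrast on a stimulus within a group.
DEFAULT_EPHYS_COMPARISONS: Tuple[Tuple[str, str], ...] = (
    ("cs_vs_oil", "within"),
    ("new_by_treatment", "between"),
    ("ext6_by_treatment", "between"),
)


def memory_scores(
    cohort: Sequence[M17Record],
    mode: str = "subtract",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize a cohort of M17 records.

    Returns ``(summary, per_bee)``:

    * ``per_bee`` — one row per (bee, stimulus) with the normalized rate
      and cohort labels, the input to the statistics stage;
    * ``summary`` — mean, SEM and n per (group, treatment, stimulus).

    Bees missing a stimulus simply contribute no row for it; comparisons
    consuming the table drop such bees and the event is logged.  n = 1
    cells report SEM = NaN (flagged, not an error).
    """
    rows = []
    for rec in cohort:
        rows.append({
            "bee": f"{rec.group}_{rec.treatment}_{rec.bee_id:02d}",
            "group": rec.group,
            "treatment": rec.treatment,
            "stimulus": rec.stimulus_label,
            "rate": normalized_rate(rec, mode=mode),
        })
    per_bee = pd.DataFrame(
        rows, columns=["bee", "group", "treatment", "stimulus", "rate"])
    # canonical row order: summaries independent of input ordering
    per_bee = per_bee.sort_values(
        ["group", "treatment", "stimulus", "bee"]).reset_index(drop=True)

    expected = set(STIMULI)
    for bee, sub in per_bee.groupby("bee"):
        missing = expected - set(sub["stimulus"])
        if missing:
            logger.warning(
                "bee %s lacks stimuli %s; excluded from those comparisons",
                bee, sorted(missing),
            )

    if per_bee.empty:
        summary = pd.DataFrame(
            columns=["group", "treatment", "stimulus", "mean", "sem", "n"])
    else:
        grouped = per_bee.groupby(["group", "treatment", "stimulus"])["rate"]
        summary = grouped.agg(
            mean="mean",
            sem=lambda v: (v.std(ddof=1) / np.sqrt(len(v))
                           if len(v) > 1 else np.nan),
            n="count",
        ).reset_index()
        for _, row in summary[summary["n"] == 1].iterrows():
            logger.warning(
                "cell (%s, %s, %s) has a single bee: SEM undefined",
                row["group"], row["treatment"], row["stimulus"],
            )
    return summary, per_bee
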