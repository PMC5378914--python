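"""Cohort-level statistical report over the metrics and ephys tables.

A *comparison manifest* enumerates the contrasts to run; each entry names a
metric slice of the per-bee metrics table (or the per-bee M17 rate table),
the design, and the tails.  Every entry is executed through the gated
test-selection workflow of :mod:`beelobe.stats` and the report records the
full decision trail: test chosen, normality and variance diagnostics, p,
Cohen's d and its category.  No multiple-testing correction is applied;
the report states the number of comparisons so users can apply their own.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import EXTINCTION_STIMULI, GROUPS, TREATMENTS
from .stats import ComparisonSpec, CohortResult, select_and_run

__all__ = ["default_manifest", "run_report", "report_to_markdown"]

METRICS_COLUMNS = ("bee", "group", "treatment", "metric", "stimulus", "value")
EPHYS_COLUMNS = ("bee", "group", "treatment", "stimulus", "rate")


def default_manifest() -> List[dict]:
    """The study's comparison set.

    Treatment contrasts (solvent vs inhibitor) within each training group on
    the imaging metrics, per-trial extinction contrasts, and the M17
    contrasts (CS+ vs mineral oil within bee, one-tailed; treatment
    contrasts on the new odor and the last extinction trial).
    """
    manifest: List[dict] = []
    for group in GROUPS:
        manifest += [
            dict(name=f"early_separation[{group}]", source="metrics",
                 metric="early_separation", stimulus="cs_vs_new",
                 group=group, contrast="treatment", tails="two"),
            dict(name=f"odor_period_separation[{group}]", source="metrics",
                 metric="odor_period_separation", stimulus="cs_vs_new",
                 group=group, contrast="treatment", tails="two"),
            dict(name=f"distinct_pattern[{group}]", source="metrics",
                 metric="distinct_pattern", stimulus="cs_vs_new",
                 group=group, contrast="treatment", tails="one",
                 direction="greater"),
            dict(name=f"pct_responders_new[{group}]", source="metrics",
                 metric="pct_responders", stimulus="new",
                 group=group, contrast="treatment", tails="two"),
            dict(name=f"dominant_peak_new[{group}]", source="metrics",
                 metric="dominant_peak_new_ref", stimulus="new",
                 group=group, contrast="treatment", tails="two"),
            dict(name=f"pct_responders_ext5[{group}]", source="metrics",
                 metric="pct_responders", stimulus="ext5",
                 group=group, contrast="treatment", tails="two"),
        ]
        for stim in EXTINCTION_STIMULI[1:]:
            manifest += [
                dict(name=f"extinction_distance_{stim}[{group}]",
                     source="metrics", metric="extinction_distance",
                     stimulus=stim, group=group, contrast="treatment",
                     tails="two"),
                dict(name=f"extinction_dominant_{stim}[{group}]",
                     source="metrics", metric="extinction_dominant_peak",
                     stimulus=stim, group=group, contrast="treatment",
                     tails="two"),
            ]
        for treatment in TREATMENTS:
            manifest.append(
                dict(name=f"m17_cs_vs_oil[{group},{treatment}]",
                     source="ephys", contrast="stimulus",
                     stimuli=["cs_plus", "mineral_oil"],
                     group=group, treatment=treatment,
                     tails="one", direction="greater"))
        manifest += [
            dict(name=f"m17_new[{group}]", source="ephys",
                 contrast="treatment", stimulus="new", group=group,
                 tails="two"),
            dict(name=f"m17_ext6[{group}]", source="ephys",
                 contrast="treatment", stimulus="ext6", group=group,
                 tails="two"),
        ]
    return manifest


def _treatment_samples(df: pd.DataFrame,
                       value_col: str) -> Tuple[np.ndarray, np.ndarray]:
    df = df.sort_values("bee")
    x = df.loc[df["treatment"] == "solvent", value_col].to_numpy(float)
    y = df.loc[df["treatment"] == "inhibitor", value_col].to_numpy(float)
    return x, y


def _spec_for(entry: dict) -> ComparisonSpec:
    design = "paired" if entry.get("contrast") == "stimulus" else "independent"
    return ComparisonSpec(
        metric=entry.get("metric", entry.get("stimulus", "")),
        design=design,
        tails=entry.get("tails", "two"),
        direction=entry.get("direction"),
        alpha=float(entry.get("alpha", 0.05)),
    )


def _gather(entry: dict, metrics: Optional[pd.DataFrame],
            ephys: Optional[pd.DataFrame]) -> Tuple[np.ndarray, np.ndarray]:
    source = entry.get("source", "metrics")
    if source == "metrics":
        if metrics is None:
            raise KeyError("metrics table not provided")
        sub = metrics[
            (metrics["metric"] == entry["metric"])
            & (metrics["stimulus"] == entry["stimulus"])
            & (metrics["group"] == entry["group"])
        ]
        if sub.empty:
            raise KeyError(
                f"metric {entry['metric']}/{entry['stimulus']} absent for "
                f"group {entry['group']}"
            )
        return _treatment_samples(sub, "value")
    if source != "ephys":
        raise KeyError(f"unknown source {source!r}")
    if ephys is None:
        raise KeyError("ephys table not provided")
    if entry.get("contrast") == "stimulus":
        sub = ephys[(ephys["group"] == entry["group"])
                    & (ephys["treatment"] == entry["treatment"])]
        a, b = entry["stimuli"]
        wide = sub.pivot_table(index="bee", columns="stimulus",
                               values="rate", aggfunc="first")
        if a not in wide.columns or b not in wide.columns:
            raise KeyError(f"stimuli {a}/{b} absent in ephys table")
        wide = wide[[a, b]].dropna().sort_index()
        if wide.empty:
            raise KeyError(f"no bee has both {a} and {b}")
        return wide[a].to_numpy(float), wide[b].to_numpy(float)
    sub = ephys[(ephys["group"] == entry["group"])
                & (ephys["stimulus"] == entry["stimulus"])]
    if sub.empty:
        raise KeyError(
            f"ephys stimulus {entry['stimulus']} absent for group "
            f"{entry['group']}"
        )
    return _treatment_samples(sub, "rate")


def _result_record(entry: dict, spec: ComparisonSpec,
                   res: CohortResult) -> dict:
    return {
        "name": entry["name"],
        "source": entry.get("source", "metrics"),
        "design": spec.design,
        "tails": spec.tails,
        "direction": spec.direction,
        "alpha": spec.alpha,
        "test_used": res.test_used,
        "p_value": res.p_value,
        "significant": res.significant,
        "effect_size_d": res.effect_size_d,
        "effect_category": res.effect_category,
        "n_x": res.n_x,
        "n_y": res.n_y,
        "diagnostics": {
            "shapiro_p_x": res.shapiro_p_x,
            "shapiro_p_y": res.shapiro_p_y,
            "f_test_p": res.f_test_p,
        },
        "notes": list(res.notes),
    }


def run_report(
    metrics_table: Optional[pd.DataFrame],
    ephys_table: Optional[pd.DataFrame],
    manifest: Optional[Sequence[dict]] = None,
) -> dict:
    """Execute a comparison manifest and return the JSON-ready report.

    An empty manifest yields an empty report; a manifest referencing data
    absent from the tables raises with the full list of gaps.
    """
    if manifest is None:
        manifest = default_manifest()
    if metrics_table is not None:
        missing = set(METRICS_COLUMNS) - set(metrics_table.columns)
        if missing:
            raise ValueError(f"metrics table lacks columns {sorted(missing)}")
    if ephys_table is not None:
        missing = set(EPHYS_COLUMNS) - set(ephys_table.columns)
        if missing:
            raise ValueError(f"ephys table lacks columns {sorted(missing)}")

    gaps: List[str] = []
    gathered = []
    for entry in manifest:
        try:
            x, y = _gather(entry, metrics_table, ephys_table)
        except KeyError as err:
            gaps.append(f"{entry.get('name', '?')}: {err.args[0]}")
            continue
        gathered.append((entry, x, y))
    if gaps:
        raise ValueError(
            "manifest references unavailable data:\n  " + "\n  ".join(gaps)
        )

    comparisons = []
    for entry, x, y in gathered:
        spec = _spec_for(entry)
        res = select_and_run(x, y, spec)
        comparisons.append(_result_record(entry, spec, res))
    return {
        "n_comparisons": len(comparisons),
        "multiple_testing_correction": "none",
        "comparisons": comparisons,
    }


def report_to_markdown(report: dict) -> str:
    """Human-readable summary table of a report dict."""
    lines = [
        "# Cohort statistics",
        "",
        f"{report['n_comparisons']} comparisons; no multiple-testing "
        "correction applied.",
        "",
        "| comparison | test | tails | p | sig. | d | category | n |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for c in report["comparisons"]:
        d = ("-" if c["effect_size_d"] is None
             else f"{c['effect_size_d']:.3f}")
        cat = c["effect_category"] or "-"
        lines.append(
            f"| {c['name']} | {c['test_used']} | {c['tails']} | "
            f"{c['p_value']:.4g} | {'*' if c['significant'] else ''} | "
            f"{d} | {cat} | {c['n_x']}/{c['n_y']} |"
        )
    return "\n".join(lines) + "\n"
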