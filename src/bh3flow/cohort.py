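"""Cohort-level statistics, the loss heatmap, and the chained pipeline.

Group comparisons use the unpaired two-tailed Student t test
(pooled-variance) by default, with Welch's correction behind a flag;
summaries are reported as mean ± SEM.  The heatmap is a pure reshaping of
profile losses (reagents × samples) with display values clamped to
[0, 100] and a green-to-red scale from lowest to highest loss.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .events import Manifest, TubeRecord, ValidationError
from .gating import GatingConfig, GatingResult, run_gating
from .priming import (DependencyPanel, PrimingProfile, build_profile,
                      call_dependencies, dependency_metrics)

__all__ = [
    "GroupComparison", "CohortSummary", "compare_groups", "assemble_heatmap",
    "plot_heatmap", "run_pipeline", "significance_stars",
]


@dataclass
class GroupComparison:
    """Two-sample test result with per-group descriptive statistics."""

    t: float
    df: float
    p: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int
    variant: str


def _sem(x: np.ndarray) -> float:
    # SEM = SD / sqrt(n), with the sample (ddof=1) standard deviation
    return float(np.std(x, ddof=1) / math.sqrt(len(x)))


def compare_groups(a: Sequence[float], b: Sequence[float],
                   variant: str = "student") -> GroupComparison:
    """Unpaired two-tailed t test between two groups of values.

    ``variant="student"`` pools the variances (the convention matched
    here); ``"welch"`` uses the unequal-variance correction.  Two groups
    with zero variance and equal means return t = 0, p = 1 by convention.
    """
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("group values must be finite")

    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            t_stat, p_val = 0.0, 1.0
            dof = len(a) + len(b) - 2 if variant == "student" else float("nan")
            return GroupComparison(t_stat, dof, p_val, float(a.mean()), 0.0,
                                   float(b.mean()), 0.0, len(a), len(b), variant)

    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    if variant == "student":
        dof = float(len(a) + len(b) - 2)
    else:
        dof = float(res.df)
    return GroupComparison(
        t=float(res.statistic), df=dof, p=float(res.pvalue),
        mean_a=float(a.mean()), sem_a=_sem(a),
        mean_b=float(b.mean()), sem_b=_sem(b),
        n_a=len(a), n_b=len(b), variant=variant,
    )


def significance_stars(p: float) -> str:
    """Conventional star rendering at 0.05 / 0.01 / 0.001 / 0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def assemble_heatmap(
    profiles: Sequence[PrimingProfile],
    reagent_order: Optional[Sequence[Tuple[str, float]]] = None,
    clamp: bool = True,
) -> pd.DataFrame:
    """Reagents × samples matrix of % cyt c loss for heatmap display.

    Display values are clamped to [0, 100]; a condition missing from a
    profile renders as NaN (absent), never as zero.  No aggregation — every
    cell equals the profile's value for that condition.
    """
    if not profiles:
        raise ValidationError("no profiles supplied")
    if reagent_order is None:
        seen: List[Tuple[str, float]] = []
        for prof in profiles:
            for cond in prof.losses:
                if cond not in seen:
                    seen.append(cond)
        reagent_order = seen
    rows = [f"{reagent}@{conc:g}uM" for reagent, conc in reagent_order]
    matrix = pd.DataFrame(
        np.nan, index=rows, columns=[p.sample_id for p in profiles], dtype=float,
    )
    for prof in profiles:
        for (reagent, conc), value in prof.losses.items():
            key = f"{reagent}@{conc:g}uM"
            if key in matrix.index:
                v = float(np.clip(value, 0.0, 100.0)) if clamp else float(value)
                matrix.loc[key, prof.sample_id] = v
    return matrix


def plot_heatmap(matrix: pd.DataFrame, path, title: str = "% cyt c loss"):
    """Render the loss matrix (green = lowest, red = highest) to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.5 * matrix.shape[1] + 2), max(3.0, 0.5 * matrix.shape[0] + 1)),
    )
    im = ax.imshow(matrix.to_numpy(), cmap="RdYlGn_r", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="% cyt c loss")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


@dataclass
class CohortSummary:
    """Everything the chained pipeline computes for a cohort."""

    groups: Dict[str, List[str]]                       # group -> sample ids
    group_stats: pd.DataFrame                          # per-condition means/SEM/test
    loss_matrix: pd.DataFrame                          # reagents x samples
    profiles: Dict[str, PrimingProfile]
    panels: Dict[str, DependencyPanel]
    calls: Dict[str, Dict[str, object]]
    qc: Dict[str, Dict[str, List[str]]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "groups": self.groups,
            "group_stats": json.loads(self.group_stats.to_json(orient="records")),
            "loss_matrix": {
                "index": list(self.loss_matrix.index),
                "columns": list(self.loss_matrix.columns),
                "values": [
                    [None if pd.isna(v) else round(float(v), 6) for v in row]
                    for row in self.loss_matrix.to_numpy()
                ],
            },
            "losses": {
                sid: {f"{r}@{c:g}uM": round(v, 6) for (r, c), v in sorted(p.losses.items())}
                for sid, p in sorted(self.profiles.items())
            },
            "dependency_calls": {
                sid: calls for sid, calls in sorted(self.calls.items())
            },
            "qc": self.qc,
        }


def _default_group(sample_id: str) -> str:
    # simulate_cohort names samples "<preset>_<idx>"
    return sample_id.rsplit("_", 1)[0]


def run_pipeline(
    manifest: Manifest,
    gating_config: Optional[GatingConfig] = None,
    out_dir=None,
    groups: Optional[Mapping[str, str]] = None,
    panel_concentration_uM: float = 10.0,
    dependency_threshold: float = 20.0,
    test_variant: str = "student",
) -> CohortSummary:
    """Gate every tube, build profiles, derive dependencies, compare groups.

    Parameters
    ----------
    manifest
        Tube manifest (validated: controls present per sample).
    gating_config
        Gating boundaries; defaults match the synthetic generator.
    out_dir
        When given, per-stage artifacts are written there: gating report
        TSV, loss-matrix TSV, dependency-call TSV, heatmap PNG and a
        machine-readable ``summary.json``.
    groups
        Optional sample_id -> group label mapping; defaults to the sample
        id prefix.  Statistics are computed between the first two groups
        present when exactly two exist.
    """
    cfg = gating_config or GatingConfig()
    gating_rows = []
    per_sample: Dict[str, List[Tuple[TubeRecord, GatingResult]]] = {}
    for rec in manifest:
        try:
            result = run_gating(rec, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"gating failed for tube {rec.path!r} "
                f"(sample {rec.sample_id}, {rec.reagent}@{rec.concentration_uM:g}uM)"
            ) from exc
        per_sample.setdefault(rec.sample_id, []).append((rec, result))
        gating_rows.append({
            "file": rec.path, "sample_id": rec.sample_id, "reagent": rec.reagent,
            "concentration_uM": rec.concentration_uM, "replicate": rec.replicate,
            "control_role": rec.control_role,
            **{f"n_{k}": v for k, v in result.counts.items()},
            "mfi": result.mfi if result.mfi is not None else "",
            "flags": ";".join(result.qc_flags),
        })
    gating_report = pd.DataFrame(gating_rows)

    profiles: Dict[str, PrimingProfile] = {}
    panels: Dict[str, DependencyPanel] = {}
    calls: Dict[str, Dict[str, object]] = {}
    qc: Dict[str, Dict[str, List[str]]] = {}
    for sample_id, tubes in per_sample.items():
        prof = build_profile(tubes)
        profiles[sample_id] = prof
        panels[sample_id] = dependency_metrics(prof, panel_concentration_uM)
        calls[sample_id] = call_dependencies(panels[sample_id], dependency_threshold)
        if prof.qc:
            qc[sample_id] = prof.qc

    group_of = dict(groups) if groups else {s: _default_group(s) for s in profiles}
    group_members: Dict[str, List[str]] = {}
    for sid in profiles:
        group_members.setdefault(group_of.get(sid, "all"), []).append(sid)

    conditions = sorted({c for p in profiles.values() for c in p.losses})
    stat_rows = []
    group_names = list(group_members)
    for reagent, conc in conditions:
        row = {"reagent": reagent, "concentration_uM": conc}
        values = {
            g: [profiles[s].losses[(reagent, conc)] for s in members
                if (reagent, conc) in profiles[s].losses]
            for g, members in group_members.items()
        }
        for g, vals in values.items():
            row[f"mean_{g}"] = float(np.mean(vals)) if vals else np.nan
            row[f"sem_{g}"] = _sem(np.asarray(vals)) if len(vals) >= 2 else np.nan
        if len(group_names) == 2:
            va, vb = values[group_names[0]], values[group_names[1]]
            if len(va) >= 2 and len(vb) >= 2:
                cmp_res = compare_groups(va, vb, variant=test_variant)
                row.update(t=cmp_res.t, df=cmp_res.df, p=cmp_res.p,
                           stars=significance_stars(cmp_res.p))
        stat_rows.append(row)
    group_stats = pd.DataFrame(stat_rows)

    loss_matrix = assemble_heatmap(list(profiles.values()))
    summary = CohortSummary(
        groups=group_members, group_stats=group_stats, loss_matrix=loss_matrix,
        profiles=profiles, panels=panels, calls=calls, qc=qc,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gating_report.to_csv(out_dir / "gating_report.tsv", sep="\t", index=False)
        loss_matrix.to_csv(out_dir / "loss_matrix.tsv", sep="\t")
        group_stats.to_csv(out_dir / "group_stats.tsv", sep="\t", index=False)
        dep_rows = []
        for sid in sorted(panels):
            panel = panels[sid]
            dep_rows.append({
                "sample_id": sid,
                "bcl2_dep": panel.bcl2_dep, "mcl1_dep": panel.mcl1_dep,
                "bclxl_dep": panel.bclxl_dep, "bfl1_dep": panel.bfl1_dep,
                "venetoclax_response": panel.venetoclax_response,
                "calls": ";".join(
                    k for k, v in calls[sid].items() if v is True and k != "no_clear_dependency"
                ) or ("no_clear_dependency" if calls[sid]["no_clear_dependency"] else ""),
                "flags": ";".join(panel.flags),
            })
        pd.DataFrame(dep_rows).to_csv(out_dir / "dependency_calls.tsv", sep="\t", index=False)
        plot_heatmap(loss_matrix, out_dir / "heatmap.png")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary.to_json_dict(), fh, indent=2, sort_keys=True)
    return summary
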