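"""Desk-scale study designs: depth sweep, multi-target pairs, method race.

These reproduce the structure of three computational experiments on the
package's spherical fixtures:

* depth sweep — a 50-node target is moved to progressively deeper anchor
  points (depth index 1 shallow .. 5 deep) and each optimizer is scored at
  every depth; the headline question is how the peak ratio degrades with
  depth for single-frequency (tACS) versus interference (tTIS) montages.
* multi-target — two well-separated deep regions are stimulated at once and
  each is scored separately inside its own half of the node set (split by an
  explicit hemisphere plane).
* method comparison — all requested optimizers attack one target; the report
  carries metrics, loss-vs-iteration curves, per-node modulation vectors and
  evaluation-call counts (a gradient run calls the loss once per epoch, a GA
  population times generations).

Replication over seeds stands in for replication over head models; trend
claims are majority-of-seeds statements, not point values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .leadfield import (
    DEFAULT_TARGET_SIZE,
    LeadField,
    TargetSpec,
    nearest_node_target,
    select_depth_target,
)
from .optimizers import (
    GaConfig,
    OptimizationResult,
    UsnnConfig,
    ga_optimize,
    lse_optimize,
    usnn_optimize,
)
from .stimulation import compute_field, evaluate, modulation

__all__ = [
    "StudyDesign",
    "METHODS",
    "MULTI_TARGET_ANCHORS",
    "run_method",
    "run_depth_study",
    "run_multitarget_study",
    "compare_methods",
]

METHODS = ("lse_tacs", "usnn_tacs", "usnn_ttis", "ga_2pair", "ga_hd")

#: Anchor directions (unit-ish vectors) and fractional depths for the four
#: multi-target positions: 1/3 stand in for left/right prefrontal folds,
#: 2/4 for right/left parieto-temporo-occipital folds.
MULTI_TARGET_ANCHORS = {
    1: (np.array([0.80, 0.45, 0.40]), 0.75),
    2: (np.array([-0.75, -0.50, 0.45]), 0.70),
    3: (np.array([0.80, -0.45, 0.40]), 0.75),
    4: (np.array([-0.75, 0.50, 0.45]), 0.70),
}

#: Hemisphere-split axis per target pair ("y": left/right, "x":
#: anterior/posterior).  Explicit because the choice is a study parameter.
DEFAULT_PARTITION_AXES = {(1, 2): "y", (1, 3): "y", (1, 4): "x"}


@dataclass(frozen=True)
class StudyDesign:
    """What to run: which methods, seeds, depths or target pairs."""

    kind: str
    methods: tuple[str, ...]
    seeds: tuple[int, ...]
    depth_indices: tuple[int, ...] = (1, 2, 3, 4, 5)
    target_pairs: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (1, 4))
    partition_axes: dict = field(default_factory=lambda: dict(DEFAULT_PARTITION_AXES))
    target_size: int = DEFAULT_TARGET_SIZE
    usnn_epochs: int = 1000
    usnn_hidden: tuple[int, ...] = (64, 64, 64)
    ga_population: int = 50
    ga_generations: int = 20
    slope: float = 1.0

    def __post_init__(self):
        if self.kind not in ("depth_sweep", "multi_target", "method_comparison"):
            raise ValueError(f"unknown study kind '{self.kind}'")
        if not self.methods:
            raise ValueError("at least one method is required")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @property
    def replicates(self) -> int:
        return len(self.seeds)


def run_method(method: str, leadfield: LeadField, targetspec: TargetSpec,
               seed: int, design: StudyDesign) -> OptimizationResult:
    """Run one optimizer and wrap the outcome uniformly."""
    if method == "lse_tacs":
        pattern = lse_optimize(leadfield, targetspec)
        metrics = evaluate(leadfield, pattern, targetspec, slope=design.slope)
        return OptimizationResult(pattern=pattern,
                                  loss_history=np.empty(0),
                                  final_metrics=metrics, seed=seed,
                                  eval_calls=1, wall_info="lse")
    if method in ("usnn_tacs", "usnn_ttis"):
        cfg = UsnnConfig(mode="tACS" if method == "usnn_tacs" else "tTIS",
                         epochs=design.usnn_epochs,
                         hidden_widths=design.usnn_hidden,
                         slope=design.slope, seed=seed)
        return usnn_optimize(leadfield, targetspec, cfg)
    if method in ("ga_2pair", "ga_hd"):
        cfg = GaConfig(chromosome_kind="two_pair" if method == "ga_2pair"
                       else "hd",
                       population=design.ga_population,
                       generations=design.ga_generations,
                       elite_count=max(1, design.ga_population // 20),
                       slope=design.slope, seed=seed)
        return ga_optimize(leadfield, targetspec, cfg)
    raise ValueError(f"unknown method '{method}'")


def _envelope(leadfield: LeadField, result: OptimizationResult) -> np.ndarray:
    e1 = compute_field(leadfield, result.pattern.f1_currents)
    e2 = compute_field(leadfield, result.pattern.f2_currents)
    return modulation(e1, e2, form="envelope_min")


def _base_row(method: str, seed: int, result: OptimizationResult,
              target_peak: float) -> dict:
    m = result.final_metrics
    return {"method": method, "seed": seed, "PR": m.PR, "CR": m.CR,
            "MR_exact": m.MR_exact, "MR_smooth": m.MR_smooth,
            "loss": m.loss, "target_peak_modulation": target_peak,
            "eval_calls": result.eval_calls, "error": ""}


def run_depth_study(leadfield: LeadField, design: StudyDesign
                    ) -> tuple[pd.DataFrame, dict]:
    """Depth sweep; returns the tidy table and per-method PR-vs-depth slopes.

    Optimizer failures are recorded in the row's ``error`` column rather than
    aborting the sweep.
    """
    if design.kind != "depth_sweep":
        raise ValueError("design.kind must be 'depth_sweep'")
    rows = []
    for depth in design.depth_indices:
        target = select_depth_target(leadfield, depth, k=design.target_size)
        for method in design.methods:
            for seed in design.seeds:
                try:
                    res = run_method(method, leadfield, target, seed, design)
                    peak = float(_envelope(leadfield, res)[
                        target.all_indices].max())
                    row = _base_row(method, seed, res, peak)
                except Exception as exc:  # recorded per-cell, not fatal
                    row = {"method": method, "seed": seed, "PR": np.nan,
                           "CR": np.nan, "MR_exact": np.nan,
                           "MR_smooth": np.nan, "loss": np.nan,
                           "target_peak_modulation": np.nan,
                           "eval_calls": 0, "error": repr(exc)}
                row["depth_index"] = depth
                rows.append(row)
    table = pd.DataFrame(rows)
    slopes = {}
    for method in design.methods:
        sub = table[(table.method == method) & table.PR.notna()]
        if sub.depth_index.nunique() >= 2:
            slopes[method] = float(np.polyfit(sub.depth_index, sub.PR, 1)[0])
        else:
            slopes[method] = np.nan
    return table, slopes


def hemisphere_partitions(leadfield: LeadField, targetspec: TargetSpec,
                          axis: str) -> list[np.ndarray]:
    """Split all nodes into two halves by a centre plane, one per region.

    ``axis`` is the coordinate normal to the splitting plane ("x" gives an
    anterior/posterior split, "y" left/right).  Each partition is assigned to
    the region whose centroid lies on its side.
    """
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    coords = leadfield.node_coords
    side = coords[:, ax] >= 0.0
    first = np.flatnonzero(side)
    second = np.flatnonzero(~side)
    parts = []
    for region in targetspec.regions:
        centroid = coords[np.asarray(region, int)].mean(axis=0)
        parts.append(first if centroid[ax] >= 0 else second)
    if parts[0] is parts[1]:
        raise ValueError("both regions fall on the same side of the "
                         f"{axis}=0 plane; choose another partition axis")
    return parts


def multi_target_spec(leadfield: LeadField, pair: tuple[int, int],
                      k: int = DEFAULT_TARGET_SIZE) -> TargetSpec:
    """Union target of two anchor regions (k nearest nodes each)."""
    r_c = float(np.max(np.linalg.norm(leadfield.node_coords, axis=1)))
    regions = []
    for pos_index in pair:
        direction, frac = MULTI_TARGET_ANCHORS[pos_index]
        anchor = direction / np.linalg.norm(direction) * frac * r_c
        regions.append(nearest_node_target(leadfield, anchor, k).regions[0])
    return TargetSpec(regions=tuple(regions), n_nodes=leadfield.n_nodes)


def run_multitarget_study(leadfield: LeadField, design: StudyDesign
                          ) -> pd.DataFrame:
    """Multi-target study with per-region partitioned evaluation."""
    if design.kind != "multi_target":
        raise ValueError("design.kind must be 'multi_target'")
    rows = []
    for pair in design.target_pairs:
        target = multi_target_spec(leadfield, pair, k=design.target_size)
        axis = design.partition_axes.get(tuple(pair), "y")
        parts = hemisphere_partitions(leadfield, target, axis)
        for method in design.methods:
            for seed in design.seeds:
                try:
                    res = run_method(method, leadfield, target, seed, design)
                    metrics = evaluate(leadfield, res.pattern, target,
                                       partitions=parts, slope=design.slope)
                    peak = float(_envelope(leadfield, res)[
                        target.all_indices].max())
                    row = _base_row(method, seed, res, peak)
                    row.update({"loss": metrics.loss})
                    for r_i, reg in enumerate(metrics.per_region, start=1):
                        for key, val in reg.items():
                            row[f"region{r_i}_{key}"] = val
                except Exception as exc:
                    row = {"method": method, "seed": seed, "error": repr(exc)}
                row["pair"] = f"{pair[0]}-{pair[1]}"
                rows.append(row)
    return pd.DataFrame(rows)


def compare_methods(leadfield: LeadField, targetspec: TargetSpec,
                    design: StudyDesign) -> dict:
    """Side-by-side comparison of methods on one target.

    Returns a dict with a tidy metrics table, per-method loss histories,
    per-node modulation vectors, and evaluation-call counts.
    """
    if len(design.methods) < 2:
        raise ValueError("method comparison needs at least two methods")
    rows, histories, modulations = [], {}, {}
    for method in design.methods:
        for seed in design.seeds:
            res = run_method(method, leadfield, targetspec, seed, design)
            peak = float(_envelope(leadfield, res)[
                targetspec.all_indices].max())
            rows.append(_base_row(method, seed, res, peak))
            if res.loss_history.size:
                histories[(method, seed)] = res.loss_history
            modulations[(method, seed)] = _envelope(leadfield, res)
    return {"table": pd.DataFrame(rows), "loss_histories": histories,
            "modulations": modulations}
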