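"""Fields, beat modulation, focality metrics, loss and safety normalization.

The temporal-interference envelope at a node with per-frequency normal fields
``a`` and ``b`` is ``2 min(|a|, |b|)``: the slow beat rides on the smaller of
the two carrier amplitudes.  Along a fixed direction this equals
``|a + b| - |a - b|`` whenever the two fields share a sign; with opposite
signs the signed form goes negative, so the non-negative ``envelope_min`` form
is the canonical one for reporting while the signed form (which the gradient
optimizer trains against) is kept as an option.

Montage quality is scored by three ratios:

* PR (peak ratio): peak modulation inside the target over peak outside.
* CR (concentration ratio): target modulation density over whole-surface
  density, areas approximated by node counts.
* MR (mis-stimulation ratio): number of non-target nodes whose modulation
  exceeds the target-mean modulation, over the target node count.  For
  gradient descent the count is smoothed by a logistic centred on the target
  mean.

The training loss is ``MR / (PR * CR)`` (smaller is better), with exponents
on each ratio configurable.

Safety normalization maps a raw pattern ``I0`` to ``I1 = 2 * I0 / max|I0|``
(per-electrode limit 2 mA) and then rescales to ``sum|I| = 8`` mA if the
absolute sum exceeds 8 mA (total anodal current at most 4 mA).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .leadfield import LeadField, TargetSpec

__all__ = [
    "CurrentPattern",
    "ModulationField",
    "StimMetrics",
    "DegenerateMontageError",
    "compute_field",
    "modulation",
    "tacs_modulation",
    "peak_ratio",
    "concentration_ratio",
    "mis_stimulation_ratio_exact",
    "mis_area_smooth",
    "loss",
    "normalize_currents",
    "evaluate",
    "MAX_ELECTRODE_CURRENT_MA",
    "MAX_TOTAL_CURRENT_MA",
]

#: Per-electrode current limit (mA).
MAX_ELECTRODE_CURRENT_MA = 2.0
#: Limit on the sum of absolute electrode currents (mA); equals twice the
#: maximum total anodal current of 4 mA.
MAX_TOTAL_CURRENT_MA = 8.0

_ZERO_SUM_TOL = 1e-9


class DegenerateMontageError(ValueError):
    """An all-zero current pattern cannot be normalized or evaluated."""


@dataclass(frozen=True)
class CurrentPattern:
    """Per-frequency electrode current vectors (length M, zero net current).

    ``stage`` tracks normalization: "I0" raw, "I1" after the per-electrode
    max-normalization, "I" fully safety-normalized.
    """

    f1_currents: np.ndarray
    f2_currents: np.ndarray
    stage: str = "I0"
    nominal_frequencies: tuple[float, float] = (2000.0, 2010.0)

    def __post_init__(self):
        f1 = np.asarray(self.f1_currents, dtype=float)
        f2 = np.asarray(self.f2_currents, dtype=float)
        if f1.shape != f2.shape or f1.ndim != 1:
            raise ValueError("current vectors must be 1-D and equal length")
        if self.stage not in ("I0", "I1", "I"):
            raise ValueError("stage must be one of I0, I1, I")
        for v in (f1, f2):
            if abs(v.sum()) > _ZERO_SUM_TOL * max(1.0, np.abs(v).max(initial=0.0)):
                raise ValueError("currents must sum to zero (Kirchhoff)")
        if self.stage == "I":
            for v in (f1, f2):
                if np.abs(v).max() > MAX_ELECTRODE_CURRENT_MA + 1e-9:
                    raise ValueError("stage-I pattern violates the 2 mA limit")
                if np.abs(v).sum() > MAX_TOTAL_CURRENT_MA + 1e-9:
                    raise ValueError("stage-I pattern violates the 8 mA limit")
        object.__setattr__(self, "f1_currents", f1)
        object.__setattr__(self, "f2_currents", f2)

    @property
    def n_electrodes(self) -> int:
        return self.f1_currents.shape[0]

    def to_json(self, labels=None) -> str:
        data = {"stage": self.stage,
                "f1_mA": list(self.f1_currents),
                "f2_mA": list(self.f2_currents)}
        if labels is not None:
            data["labels"] = list(labels)
        return json.dumps(data)

    @classmethod
    def from_json(cls, text: str) -> "CurrentPattern":
        d = json.loads(text)
        return cls(f1_currents=np.asarray(d["f1_mA"], float),
                   f2_currents=np.asarray(d["f2_mA"], float),
                   stage=d.get("stage", "I"))


@dataclass(frozen=True)
class ModulationField:
    """Per-node signed fields of the two carriers and their beat envelope."""

    field_f1: np.ndarray
    field_f2: np.ndarray
    modulation: np.ndarray

    def __post_init__(self):
        if not (self.field_f1.shape == self.field_f2.shape
                == self.modulation.shape):
            raise ValueError("field and modulation lengths must agree")


@dataclass(frozen=True)
class StimMetrics:
    """Focality scores of one evaluated montage."""

    PR: float
    CR: float
    MR_exact: float
    MR_smooth: float
    loss: float
    per_region: tuple[dict, ...] = ()

    def to_dict(self) -> dict:
        d = {"PR": self.PR, "CR": self.CR, "MR_exact": self.MR_exact,
             "MR_smooth": self.MR_smooth, "loss": self.loss}
        if self.per_region:
            d["per_region"] = list(self.per_region)
        return d


# ---------------------------------------------------------------------------
# Fields and modulation
# ---------------------------------------------------------------------------

def _check_zero_sum(currents: np.ndarray) -> np.ndarray:
    currents = np.asarray(currents, dtype=float)
    scale = max(1.0, np.abs(currents).max(initial=0.0))
    if abs(currents.sum()) > _ZERO_SUM_TOL * scale:
        raise ValueError("currents must sum to zero")
    return currents


def compute_field(leadfield: LeadField, currents: np.ndarray) -> np.ndarray:
    """Normal field (V/m) at every node for a full-length current vector (mA).

    The reference electrode's current is implied by the zero-sum constraint
    and is not multiplied into the reduced lead-field product.
    """
    currents = _check_zero_sum(currents)
    if currents.shape[0] != leadfield.n_electrodes:
        raise ValueError("need one current per electrode")
    ref = leadfield.layout.reference_index
    reduced = np.delete(currents, ref)
    return leadfield.matrix @ reduced


def modulation(field_f1: np.ndarray, field_f2: np.ndarray,
               form: str = "signed_difference") -> np.ndarray:
    """Beat-envelope modulation of two per-frequency normal fields.

    ``signed_difference`` returns ``|a+b| - |a-b|`` (may be negative when the
    fields have opposite signs); ``envelope_min`` returns the canonical
    non-negative ``2 min(|a|, |b|)``.  The two agree exactly wherever
    ``a * b >= 0``.
    """
    a = np.asarray(field_f1, dtype=float)
    b = np.asarray(field_f2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("field vectors must have equal length")
    if form == "signed_difference":
        return np.abs(a + b) - np.abs(a - b)
    if form == "envelope_min":
        return 2.0 * np.minimum(np.abs(a), np.abs(b))
    raise ValueError(f"unknown modulation form '{form}'")


def tacs_modulation(field: np.ndarray) -> np.ndarray:
    """Single-frequency modulation: peak-to-peak field, i.e. ``2 |E|``."""
    return 2.0 * np.abs(np.asarray(field, dtype=float))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _target_mask(n: int, target: np.ndarray) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    mask[np.asarray(target, dtype=int)] = True
    return mask


def peak_ratio(mod: np.ndarray, target: np.ndarray) -> float:
    """Peak modulation inside the target over peak outside."""
    mod = np.asarray(mod, dtype=float)
    mask = _target_mask(mod.shape[0], target)
    if not mask.any() or mask.all():
        raise ValueError("target must be a non-empty strict subset of nodes")
    t_peak = mod[mask].max()
    nt_peak = mod[~mask].max()
    if nt_peak == 0.0:
        if t_peak > 0.0:
            return float("inf")
        warnings.warn("peak ratio 0/0: modulation is identically zero")
        return 0.0
    return float(t_peak / nt_peak)


def concentration_ratio(mod: np.ndarray, target: np.ndarray) -> float:
    """Target modulation density over whole-surface modulation density."""
    mod = np.asarray(mod, dtype=float)
    mask = _target_mask(mod.shape[0], target)
    if not mask.any():
        raise ValueError("target must be non-empty")
    total = mod.sum()
    if total == 0.0:
        return 0.0
    target_density = mod[mask].sum() / mask.sum()
    total_density = total / mod.shape[0]
    return float(target_density / total_density)


def mis_stimulation_ratio_exact(mod: np.ndarray, target: np.ndarray) -> float:
    """Non-target nodes strictly above the target-mean modulation, over
    the target node count.  Ties at exactly the mean do not count."""
    mod = np.asarray(mod, dtype=float)
    mask = _target_mask(mod.shape[0], target)
    if not mask.any():
        raise ValueError("target must be non-empty")
    mean_t = mod[mask].mean()
    count = int(np.sum(mod[~mask] > mean_t))
    return float(count) / int(mask.sum())


def mis_area_smooth(mod: np.ndarray, target: np.ndarray,
                    slope: float = 1.0) -> float:
    """Differentiable mis-stimulated area: logistic count of non-target nodes
    above the target-mean modulation."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    mod = np.asarray(mod, dtype=float)
    mask = _target_mask(mod.shape[0], target)
    if not mask.any():
        raise ValueError("target must be non-empty")
    mean_t = mod[mask].mean()
    z = slope * (mod[~mask] - mean_t)
    # stable logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return float(out.sum())


def loss(mod: np.ndarray, target: np.ndarray, slope: float = 1.0,
         exponents: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Combined montage loss ``MR_smooth^a / (PR^b * CR^c)``; default a=b=c=1."""
    mask = _target_mask(np.asarray(mod).shape[0], target)
    pr = peak_ratio(mod, target)
    cr = concentration_ratio(mod, target)
    mr = mis_area_smooth(mod, target, slope) / int(mask.sum())
    a, b, c = exponents
    denom = pr ** b * cr ** c
    if denom == 0.0:
        warnings.warn("degenerate montage: PR*CR is zero")
        return float("inf")
    if np.isinf(denom):  # perfectly focal montage
        return 0.0
    return float(mr ** a / denom)


# ---------------------------------------------------------------------------
# Safety normalization
# ---------------------------------------------------------------------------

def _normalize_channel(raw: np.ndarray) -> np.ndarray:
    peak = np.abs(raw).max()
    if peak == 0.0:
        raise DegenerateMontageError("all-zero current pattern")
    i1 = raw / peak * MAX_ELECTRODE_CURRENT_MA
    total = np.abs(i1).sum()
    if total > MAX_TOTAL_CURRENT_MA:
        i1 = i1 / total * MAX_TOTAL_CURRENT_MA
    return i1


def normalize_currents(pattern: CurrentPattern,
                       mode: str = "per_frequency") -> CurrentPattern:
    """Safety-normalize a raw pattern to stage I.

    ``per_frequency`` (default) applies the 2 mA / 8 mA limits to each
    frequency channel independently, matching two independent stimulators;
    ``joint`` applies them to the concatenation of both channels.
    """
    f1 = np.asarray(pattern.f1_currents, dtype=float)
    f2 = np.asarray(pattern.f2_currents, dtype=float)
    if mode == "per_frequency":
        f1n = _normalize_channel(f1)
        f2n = _normalize_channel(f2)
    elif mode == "joint":
        both = _normalize_channel(np.concatenate([f1, f2]))
        f1n, f2n = both[:f1.size], both[f1.size:]
    else:
        raise ValueError("mode must be 'per_frequency' or 'joint'")
    return replace(pattern, f1_currents=f1n, f2_currents=f2n, stage="I")


# ---------------------------------------------------------------------------
# End-to-end evaluation
# ---------------------------------------------------------------------------

def _region_metrics(mod: np.ndarray, node_subset: np.ndarray,
                    region: np.ndarray, slope: float) -> dict:
    """PR/CR/MR of one region evaluated over a subset of nodes only."""
    sub = np.asarray(node_subset, dtype=int)
    local = mod[sub]
    pos = {int(g): i for i, g in enumerate(sub)}
    local_target = np.asarray([pos[int(i)] for i in region], dtype=int)
    return {
        "PR": peak_ratio(local, local_target),
        "CR": concentration_ratio(local, local_target),
        "MR_exact": mis_stimulation_ratio_exact(local, local_target),
    }


def evaluate(leadfield: LeadField, pattern: CurrentPattern,
             targetspec: TargetSpec, partitions=None,
             slope: float = 1.0) -> StimMetrics:
    """Full evaluation of a stage-I montage.

    Computes both carrier fields, the canonical (envelope) modulation, and the
    global PR/CR/MR metrics.  ``partitions``, when given, is a sequence of
    node-index arrays covering all nodes, one per target region, and per-region
    metrics are computed restricting the node set to each partition.
    """
    if pattern.stage != "I":
        raise ValueError("evaluate() requires a fully normalized (stage I) "
                         "pattern; call normalize_currents first")
    if np.abs(pattern.f1_currents).max() == 0 or \
            np.abs(pattern.f2_currents).max() == 0:
        raise DegenerateMontageError("all-zero current pattern")
    e1 = compute_field(leadfield, pattern.f1_currents)
    e2 = compute_field(leadfield, pattern.f2_currents)
    mod = modulation(e1, e2, form="envelope_min")
    target = targetspec.all_indices
    mask = _target_mask(leadfield.n_nodes, target)
    metrics = StimMetrics(
        PR=peak_ratio(mod, target),
        CR=concentration_ratio(mod, target),
        MR_exact=mis_stimulation_ratio_exact(mod, target),
        MR_smooth=mis_area_smooth(mod, target, slope) / int(mask.sum()),
        loss=loss(mod, target, slope),
    )
    if partitions is not None:
        if len(partitions) != len(targetspec.regions):
            raise ValueError("one partition per target region required")
        covered = np.concatenate([np.asarray(p, dtype=int) for p in partitions])
        if np.unique(covered).size != leadfield.n_nodes:
            raise ValueError("partitions must cover all nodes exactly once")
        per = []
        for part, region in zip(partitions, targetspec.regions):
            part = np.asarray(part, dtype=int)
            if not np.isin(np.asarray(region, int), part).all():
                raise ValueError("each region must lie inside its partition")
            per.append(_region_metrics(mod, part, np.asarray(region, int),
                                       slope))
        metrics = replace(metrics, per_region=tuple(per))
    return metrics
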