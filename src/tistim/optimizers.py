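"""Montage optimizers: least-squares, unsupervised generator network, GA.

Three routes to a current pattern:

* :func:`lse_optimize` — the classical single-frequency (tACS) solution: the
  minimum-norm least-squares fit of the lead field to an ideal binary field
  vector, then safety-normalized.  Linear, instant, but blind to focality.
* :func:`usnn_optimize` — an unsupervised generator network.  A constant unit
  input feeds a small fully connected network (linear + ReLU + layer
  normalization per hidden layer) whose output layer emits one raw current per
  non-reference electrode per frequency channel.  The physics downstream of
  the generator — zero-sum completion, safety normalization, lead-field
  superposition, beat modulation, ratio loss — is part of the computation
  graph with fixed (non-trainable) weights, so the ratio loss backpropagates
  into the generator.  Trained with Adam; the best-loss iterate is returned.
* :func:`ga_optimize` — a generation-based genetic algorithm over either
  two-pair chromosomes (one anode/cathode pair per frequency, the
  conventional interference montage) or high-definition chromosomes (all
  electrode currents for both frequencies), minimizing the same loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autograd import Adam, Tensor, concat
from .leadfield import LeadField, TargetSpec
from .stimulation import (
    MAX_ELECTRODE_CURRENT_MA,
    MAX_TOTAL_CURRENT_MA,
    CurrentPattern,
    DegenerateMontageError,
    StimMetrics,
    evaluate,
    normalize_currents,
)

__all__ = [
    "UsnnConfig",
    "GaConfig",
    "OptimizationResult",
    "lse_optimize",
    "lse_solution",
    "usnn_optimize",
    "ga_optimize",
]


@dataclass(frozen=True)
class UsnnConfig:
    """Generator-network training configuration.

    ``mode`` selects single-frequency ("tACS", one output channel, modulation
    ``2|E|``) or interference ("tTIS", two channels, beat modulation).
    ``training_form`` picks the modulation expression the loss is built on:
    the non-negative envelope ``2 min(|a|,|b|)`` (default; keeps the ratio
    loss bounded below by zero) or the signed difference ``|a+b|-|a-b|``
    (negative where the carrier fields disagree in sign, which makes the
    ratio loss unbounded below — usable only for short exploratory runs).
    """

    hidden_widths: tuple[int, ...] = (64, 64, 64)
    epochs: int = 1000
    learning_rate: float = 1e-3
    seed: int = 0
    mode: str = "tTIS"
    slope: float = 1.0
    normalization_mode: str = "per_frequency"
    training_form: str = "envelope_min"
    exponents: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.mode not in ("tACS", "tTIS"):
            raise ValueError("mode must be 'tACS' or 'tTIS'")


@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm configuration (two-pair or HD chromosomes)."""

    population: int = 1000
    generations: int = 100
    chromosome_kind: str = "hd"
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_scale: float = 0.4
    elite_count: int = 10
    seed: int = 0
    slope: float = 1.0
    normalization_mode: str = "per_frequency"
    training_form: str = "envelope_min"
    use_exact_mr: bool = False

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.population < 2 * self.elite_count:
            raise ValueError("population must be >= 2 * elite_count")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.chromosome_kind not in ("two_pair", "hd"):
            raise ValueError("chromosome_kind must be 'two_pair' or 'hd'")


@dataclass(frozen=True)
class OptimizationResult:
    """A finished optimization run."""

    pattern: CurrentPattern
    loss_history: np.ndarray
    final_metrics: StimMetrics
    seed: int
    eval_calls: int
    wall_info: str = ""


# ---------------------------------------------------------------------------
# LSE (tACS baseline)
# ---------------------------------------------------------------------------

def lse_solution(leadfield: LeadField, targetspec: TargetSpec) -> np.ndarray:
    """Raw minimum-norm least-squares reduced currents (mA, un-normalized).

    Solves ``E I = E_target`` via the pseudo-inverse; defined even for
    rank-deficient ``E`` (warns on large condition numbers).
    """
    E = leadfield.matrix
    target_field = targetspec.binary_field()
    cond = np.linalg.cond(E)
    if cond > 1e10:
        warnings.warn(f"lead-field matrix is ill-conditioned "
                      f"(cond ~ {cond:.2e}); LSE solution may be unstable")
    reduced, *_ = np.linalg.lstsq(E, target_field, rcond=None)
    return reduced


def lse_optimize(leadfield: LeadField, targetspec: TargetSpec,
                 normalization_mode: str = "per_frequency") -> CurrentPattern:
    """Least-squares current pattern for single-frequency stimulation.

    The raw :func:`lse_solution` currents are expanded to a zero-sum full
    vector and safety-normalized; both frequency channels are set equal
    (a single-frequency montage).
    """
    reduced = lse_solution(leadfield, targetspec)
    full = _expand_zero_sum(reduced, leadfield.layout.reference_index)
    raw = CurrentPattern(f1_currents=full, f2_currents=full.copy(),
                         stage="I0")
    return normalize_currents(raw, mode=normalization_mode)


def _expand_zero_sum(reduced: np.ndarray, ref: int) -> np.ndarray:
    """Insert the reference electrode's balancing current."""
    return np.insert(reduced, ref, -reduced.sum())


# ---------------------------------------------------------------------------
# USNN
# ---------------------------------------------------------------------------

class _Generator:
    """Constant-input MLP emitting raw electrode currents."""

    _LN_EPS = 1e-5

    def __init__(self, hidden_widths, n_out, rng: np.random.Generator):
        self.params: list[Tensor] = []
        self.layers = []
        fan_in = 1
        for w in hidden_widths:
            W = Tensor(rng.normal(scale=np.sqrt(2.0 / fan_in), size=(w, fan_in)),
                       requires_grad=True)
            b = Tensor(np.zeros(w), requires_grad=True)
            gamma = Tensor(np.ones(w), requires_grad=True)
            beta = Tensor(np.zeros(w), requires_grad=True)
            self.layers.append(("hidden", W, b, gamma, beta))
            self.params += [W, b, gamma, beta]
            fan_in = w
        W = Tensor(rng.normal(scale=np.sqrt(1.0 / fan_in), size=(n_out, fan_in)),
                   requires_grad=True)
        b = Tensor(np.zeros(n_out), requires_grad=True)
        self.layers.append(("out", W, b))
        self.params += [W, b]

    def forward(self) -> Tensor:
        h = Tensor(np.ones(1))
        for layer in self.layers:
            if layer[0] == "hidden":
                _, W, b, gamma, beta = layer
                h = (W @ h + b).relu()
                mu = h.mean()
                centred = h - mu
                var = (centred * centred).mean()
                h = centred / (var + self._LN_EPS).sqrt() * gamma + beta
            else:
                _, W, b = layer
                h = W @ h + b
        return h


def _normalize_channel_graph(raw: Tensor) -> Tensor:
    """Differentiable safety normalization of one full current vector."""
    peak = raw.abs().max()
    i1 = raw / peak * MAX_ELECTRODE_CURRENT_MA
    total = i1.abs().sum()
    if total.item() > MAX_TOTAL_CURRENT_MA:
        i1 = i1 / total * MAX_TOTAL_CURRENT_MA
    return i1


def _full_currents_graph(reduced: Tensor, ref: int) -> Tensor:
    """Append the reference electrode's balancing current at index ``ref``."""
    balance = (-reduced.sum()).reshape((1,))
    parts = []
    if ref > 0:
        parts.append(reduced[np.arange(ref)])
    parts.append(balance)
    n = reduced.value.shape[0]
    if ref < n:
        parts.append(reduced[np.arange(ref, n)])
    return concat(parts)


def _training_loss_graph(mod: Tensor, t_idx: np.ndarray, nt_idx: np.ndarray,
                         slope: float, exponents) -> tuple[Tensor, dict]:
    n = mod.value.shape[0]
    mod_t = mod[t_idx]
    mod_nt = mod[nt_idx]
    pr = mod_t.max() / mod_nt.max()
    cr = (mod_t.sum() / len(t_idx)) / (mod.sum() / n)
    mr = ((mod_nt - mod_t.mean()) * slope).sigmoid().sum() / len(t_idx)
    a, b, c = exponents
    if a == 1.0 and b == 1.0 and c == 1.0:
        total = mr / (pr * cr)
    else:
        # general exponents via the log-domain (values must be positive)
        total = ((mr.log() * a) - (pr.log() * b) - (cr.log() * c)).exp()
    parts = {"PR": pr.item(), "CR": cr.item(), "MR_smooth": mr.item()}
    return total, parts


def usnn_optimize(leadfield: LeadField, targetspec: TargetSpec,
                  config: UsnnConfig) -> OptimizationResult:
    """Train the unsupervised generator network and return the best montage."""
    ref = leadfield.layout.reference_index
    m_free = leadfield.n_electrodes - 1
    n_channels = 2 if config.mode == "tTIS" else 1
    t_idx = targetspec.all_indices
    nt_idx = np.setdiff1d(np.arange(leadfield.n_nodes), t_idx)
    lf = Tensor(leadfield.matrix)
    non_ref = np.asarray([m for m in range(leadfield.n_electrodes) if m != ref])

    for attempt in range(2):
        seed = config.seed + attempt
        rng = np.random.default_rng(seed)
        gen = _Generator(config.hidden_widths, n_channels * m_free, rng)
        out0 = gen.forward()
        if np.abs(out0.value).max() == 0.0:
            continue  # re-initialize once with seed+1
        break
    else:
        raise DegenerateMontageError("generator emitted all-zero currents "
                                     "after re-initialization")

    opt = Adam(gen.params, lr=config.learning_rate)
    history = np.empty(config.epochs)
    best = {"loss": np.inf, "f1": None, "f2": None}

    for epoch in range(config.epochs):
        out = gen.forward()
        channels_full = []
        for ch in range(n_channels):
            reduced = out[np.arange(ch * m_free, (ch + 1) * m_free)]
            channels_full.append(_full_currents_graph(reduced, ref))
        if config.normalization_mode == "joint":
            both = _normalize_channel_graph(concat(channels_full))
            M = leadfield.n_electrodes
            norm_full = [both[np.arange(ch * M, (ch + 1) * M)]
                         for ch in range(n_channels)]
        else:
            norm_full = [_normalize_channel_graph(c) for c in channels_full]
        fields = [lf @ c[non_ref] for c in norm_full]
        if config.mode == "tTIS":
            a, b = fields
            if config.training_form == "signed_difference":
                mod = (a + b).abs() - (a - b).abs()
            else:
                half = ((a + b).abs() - (a - b).abs()) * 0.5
                # 2*min(|a|,|b|) = ||a|+|b|| - ||a|-|b|| ; use abs composition
                mod = (a.abs() + b.abs()) - (a.abs() - b.abs()).abs()
        else:
            mod = fields[0].abs() * 2.0
        loss_t, _ = _training_loss_graph(mod, t_idx, nt_idx, config.slope,
                                         config.exponents)
        loss_val = loss_t.item()
        if not np.isfinite(loss_val):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch} "
                f"(lr={config.learning_rate}, slope={config.slope}); "
                "reduce the learning rate or the sigmoid slope")
        history[epoch] = loss_val
        if loss_val < best["loss"]:
            best["loss"] = loss_val
            best["f1"] = norm_full[0].value.copy()
            best["f2"] = (norm_full[1].value.copy() if n_channels == 2
                          else norm_full[0].value.copy())
        loss_t.backward()
        opt.step()

    pattern = CurrentPattern(f1_currents=best["f1"], f2_currents=best["f2"],
                             stage="I")
    metrics = evaluate(leadfield, pattern, targetspec, slope=config.slope)
    return OptimizationResult(pattern=pattern, loss_history=history,
                              final_metrics=metrics, seed=config.seed,
                              eval_calls=config.epochs,
                              wall_info=f"usnn mode={config.mode}")


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def _pattern_from_hd(genes: np.ndarray, ref: int) -> tuple[np.ndarray, np.ndarray]:
    m_free = genes.size // 2
    f1 = _expand_zero_sum(genes[:m_free], ref)
    f2 = _expand_zero_sum(genes[m_free:], ref)
    return f1, f2


def _pattern_from_two_pair(genes: np.ndarray, n_elec: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    a1, c1, m1, a2, c2, m2 = genes
    f1 = np.zeros(n_elec)
    f2 = np.zeros(n_elec)
    f1[int(a1)] += m1
    f1[int(c1)] -= m1
    f2[int(a2)] += m2
    f2[int(c2)] -= m2
    return f1, f2


def _ga_loss(leadfield: LeadField, f1: np.ndarray, f2: np.ndarray,
             t_idx: np.ndarray, nt_idx: np.ndarray,
             config: GaConfig) -> float:
    from . import stimulation as st

    try:
        pat = normalize_currents(
            CurrentPattern(f1_currents=f1, f2_currents=f2, stage="I0"),
            mode=config.normalization_mode)
    except DegenerateMontageError:
        return np.inf
    e1 = st.compute_field(leadfield, pat.f1_currents)
    e2 = st.compute_field(leadfield, pat.f2_currents)
    mod = st.modulation(e1, e2, form=config.training_form)
    n = mod.shape[0]
    nt_max = mod[nt_idx].max()
    total = mod.sum()
    if nt_max == 0.0 or total == 0.0:
        return np.inf
    pr = mod[t_idx].max() / nt_max
    cr = (mod[t_idx].sum() / t_idx.size) / (total / n)
    if config.use_exact_mr:
        mr = np.sum(mod[nt_idx] > mod[t_idx].mean()) / t_idx.size
    else:
        z = config.slope * (mod[nt_idx] - mod[t_idx].mean())
        mr = np.sum(np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                             np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
                    ) / t_idx.size
    denom = pr * cr
    if denom <= 0 or not np.isfinite(denom):
        return np.inf
    return float(mr / denom)


def ga_optimize(leadfield: LeadField, targetspec: TargetSpec,
                config: GaConfig) -> OptimizationResult:
    """Evolve a population of montages minimizing the montage loss.

    Tournament selection (size 2), uniform crossover, Gaussian mutation on
    current genes (random reassignment on electrode-index genes), and elite
    conservation; the per-generation best loss is non-increasing.
    """
    n_elec = leadfield.n_electrodes
    if config.chromosome_kind == "two_pair" and n_elec < 2:
        raise ValueError("two-pair chromosomes need at least 2 electrodes")
    ref = leadfield.layout.reference_index
    rng = np.random.default_rng(config.seed)
    t_idx = targetspec.all_indices
    nt_idx = np.setdiff1d(np.arange(leadfield.n_nodes), t_idx)
    m_free = n_elec - 1

    if config.chromosome_kind == "hd":
        pop = rng.normal(size=(config.population, 2 * m_free))
        n_genes = 2 * m_free
    else:
        pop = np.empty((config.population, 6))
        for i in range(config.population):
            pop[i] = _random_two_pair(rng, n_elec)
        n_genes = 6

    def decode(genes):
        if config.chromosome_kind == "hd":
            return _pattern_from_hd(genes, ref)
        return _pattern_from_two_pair(genes, n_elec)

    def fitness(genes):
        f1, f2 = decode(genes)
        return _ga_loss(leadfield, f1, f2, t_idx, nt_idx, config)

    losses = np.array([fitness(g) for g in pop])
    history = np.empty(config.generations)
    for gen_i in range(config.generations):
        order = np.argsort(losses, kind="stable")
        pop, losses = pop[order], losses[order]
        history[gen_i] = losses[0]
        new_pop = [pop[i].copy() for i in range(config.elite_count)]
        new_losses = [losses[i] for i in range(config.elite_count)]
        while len(new_pop) < config.population:
            p1 = _tournament(rng, losses)
            child = pop[p1].copy()
            if rng.random() < config.crossover_rate:
                p2 = _tournament(rng, losses)
                mask = rng.random(n_genes) < 0.5
                child[mask] = pop[p2][mask]
            _mutate(rng, child, config, n_elec)
            new_pop.append(child)
            new_losses.append(fitness(child))
        pop = np.asarray(new_pop)
        losses = np.asarray(new_losses)

    best_i = int(np.argmin(losses))
    f1, f2 = decode(pop[best_i])
    pattern = normalize_currents(
        CurrentPattern(f1_currents=f1, f2_currents=f2, stage="I0"),
        mode=config.normalization_mode)
    metrics = evaluate(leadfield, pattern, targetspec, slope=config.slope)
    return OptimizationResult(
        pattern=pattern, loss_history=history, final_metrics=metrics,
        seed=config.seed,
        eval_calls=config.population * config.generations,
        wall_info=f"ga kind={config.chromosome_kind}")


def _random_two_pair(rng: np.random.Generator, n_elec: int) -> np.ndarray:
    a1, c1 = rng.choice(n_elec, size=2, replace=False)
    a2, c2 = rng.choice(n_elec, size=2, replace=False)
    m1, m2 = rng.uniform(0.1, MAX_ELECTRODE_CURRENT_MA, size=2)
    return np.array([a1, c1, m1, a2, c2, m2])


def _tournament(rng: np.random.Generator, losses: np.ndarray, size: int = 2
                ) -> int:
    idx = rng.integers(0, losses.size, size=size)
    return int(idx[np.argmin(losses[idx])])


def _mutate(rng: np.random.Generator, genes: np.ndarray, config: GaConfig,
            n_elec: int) -> None:
    if config.chromosome_kind == "hd":
        mask = rng.random(genes.size) < config.mutation_rate
        genes[mask] += rng.normal(scale=config.mutation_scale,
                                  size=int(mask.sum()))
        return
    # two_pair layout: (a1, c1, m1, a2, c2, m2)
    for pos in (0, 1, 3, 4):
        if rng.random() < config.mutation_rate:
            genes[pos] = rng.integers(0, n_elec)
    for pos in (2, 5):
        if rng.random() < config.mutation_rate:
            genes[pos] = abs(genes[pos] + rng.normal(
                scale=config.mutation_scale))
    # repair anode == cathode collisions
    for a, c in ((0, 1), (3, 4)):
        if int(genes[a]) == int(genes[c]):
            genes[c] = (int(genes[c]) + 1) % n_elec
    for pos in (2, 5):
        genes[pos] = min(max(genes[pos], 1e-3), MAX_ELECTRODE_CURRENT_MA)
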