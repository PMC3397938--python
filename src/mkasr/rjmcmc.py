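"""Reversible-jump MCMC over Mk rate models, rates, κ, and tree index.

For one binary character the model space holds exactly four rate models:
both rates free (M_free), rates constrained equal (M_eq), and the two
one-way models in which the backward or forward rate is fixed to zero
(M_q01only, M_q10only).  The sampler draws from the joint posterior of
(model, rates, κ, hyperprior mean m, tree index) given the character and a
posterior sample of trees:

  * rates carry an Exponential(mean m) prior, with m itself uniform on
    (0, 10) (a hierarchical hyperprior sampled within the chain);
  * κ is uniform on (0, 5);
  * the model prior is uniform over the model space;
  * each tree in the posterior sample is a priori equally likely.

Moves are Metropolis–Hastings: normal perturbations (reflected into the
support) for rates, κ and m; an independence jump between models that
redraws the target model's free rates from the Exponential(m) prior, whose
proposal density cancels the prior so the acceptance ratio reduces to the
likelihood ratio; and a uniform re-draw of the tree index.  During burn-in
the rate-proposal deviation is auto-tuned toward a 20–40% acceptance band
and frozen afterwards to preserve detailed balance.

Three-state characters use a single all-rates-free model (no trans-model
jumps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .characters import CharacterColumn, to_partials
from .mk_likelihood import PruningEngine, RateParameters, RootPrior
from .trees import TreeSample

__all__ = [
    "Model",
    "ModelSpace",
    "PriorSpec",
    "RunConfig",
    "FULL_SCALE_PROFILE",
    "MCMCState",
    "Chain",
    "enumerate_models",
    "tune_rate_deviation",
    "propose",
    "run_chain",
    "run_replicates",
    "MCMCError",
]


class MCMCError(RuntimeError):
    """Raised when the chain encounters an invalid configuration or a
    non-finite posterior."""


# ---------------------------------------------------------------------------
# model space


@dataclass(frozen=True)
class Model:
    """One rate-model configuration.

    ``free_names`` are the sampled parameters; ``expand`` maps them to the
    full off-diagonal rate vector.
    """

    name: str
    k: int
    free_names: tuple[str, ...]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def expand(self, free: Sequence[float]) -> tuple[float, ...]:
        if self.k == 2:
            if self.name == "free":
                return (free[0], free[1])
            if self.name == "equal":
                return (free[0], free[0])
            if self.name == "q01_only":
                return (free[0], 0.0)
            if self.name == "q10_only":
                return (0.0, free[0])
        return tuple(free)  # k=3: all six rates free


@dataclass(frozen=True)
class ModelSpace:
    k: int
    models: tuple[Model, ...]

    def __len__(self) -> int:
        return len(self.models)

    def index(self, name: str) -> int:
        for i, m in enumerate(self.models):
            if m.name == name:
                return i
        raise MCMCError(f"no model named {name!r}")


def enumerate_models(k: int) -> ModelSpace:
    """The rate-model space: four models for a binary character, a single
    all-rates-free model for three states."""
    if k == 2:
        return ModelSpace(
            k=2,
            models=(
                Model("free", 2, ("q01", "q10")),
                Model("equal", 2, ("rate",)),
                Model("q01_only", 2, ("q01",)),
                Model("q10_only", 2, ("q10",)),
            ),
        )
    if k == 3:
        names = tuple(f"q{i}{j}" for i in range(3) for j in range(3) if i != j)
        return ModelSpace(k=3, models=(Model("free", 3, names),))
    raise MCMCError(f"unsupported number of states k={k}")


# ---------------------------------------------------------------------------
# priors and run configuration


@dataclass(frozen=True)
class PriorSpec:
    """Hierarchical priors: rates ~ Exponential(mean m), m ~ U(0, m_max),
    κ ~ U(0, kappa_max), models uniform."""

    m_range: tuple[float, float] = (0.0, 10.0)
    kappa_range: tuple[float, float] = (0.0, 5.0)

    def log_rate_prior(self, free: Sequence[float], m: float) -> float:
        if m <= 0:
            return -math.inf
        lp = 0.0
        for q in free:
            if q < 0:
                return -math.inf
            lp += -math.log(m) - q / m
        return lp


@dataclass
class RunConfig:
    """Chain-length and proposal settings.

    Desk-scale defaults (2e6 generations, thin 1000) stand in for the
    full-scale protocol preserved in :data:`FULL_SCALE_PROFILE` (220e6
    generations, 20e6 burn-in).
    """

    generations: int = 2_000_000
    burn_in: int | None = None  # default: generations // 10
    thinning: int = 1000
    target_acceptance: tuple[float, float] = (0.20, 0.40)
    rate_deviation: float = 1.0
    tuning_interval: int = 1000
    kappa_deviation: float = 1.0
    m_deviation: float = 2.0
    seed: int = 0
    root_prior: str = "uniform"  # or "stationary"
    n_replicates: int = 3
    move_weights: dict = field(
        default_factory=lambda: {
            "rates": 0.4, "kappa": 0.2, "m": 0.1, "model": 0.15, "tree": 0.15
        }
    )
    fix_kappa: float | None = None
    fix_m: float | None = None

    def __post_init__(self) -> None:
        burn = self.generations // 10 if self.burn_in is None else self.burn_in
        if not (0 <= burn < self.generations):
            raise MCMCError("burn-in must be < generations")
        self.burn_in = burn
        if self.thinning < 1:
            raise MCMCError("thinning must be >= 1")
        lo, hi = self.target_acceptance
        if not (0 < lo < hi < 1):
            raise MCMCError("acceptance band must lie inside (0, 1)")


#: The full-scale protocol: 220e6 generations, first 20e6 discarded,
#: sampled every 1000th, three replicate runs.
FULL_SCALE_PROFILE = RunConfig(
    generations=220_000_000, burn_in=20_000_000, thinning=1000, n_replicates=3
)


@dataclass
class MCMCState:
    """Current position of the chain."""

    model_index: int
    free: tuple[float, ...]
    kappa: float
    m: float
    tree_index: int
    loglik: float
    log_rate_prior: float

    def rates(self, space: ModelSpace) -> tuple[float, ...]:
        return space.models[self.model_index].expand(self.free)


# ---------------------------------------------------------------------------
# chain container


@dataclass
class Chain:
    """Saved post-burn-in, thinned samples plus run metadata."""

    samples: pd.DataFrame
    model_space: ModelSpace
    config: RunConfig
    seed: int
    k: int
    acceptance: dict
    tuning_trace: list
    final_rate_deviation: float
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def rate_columns(self) -> list[str]:
        if self.k == 2:
            return ["q01", "q10"]
        return [f"q{i}{j}" for i in range(self.k) for j in range(self.k) if i != j]

    def acceptance_rate(self, move: str) -> float:
        prop, acc = self.acceptance.get(move, (0, 0))
        return acc / prop if prop else math.nan

    def model_posterior(self) -> dict[str, float]:
        counts = self.samples["model"].value_counts()
        return {
            m.name: float(counts.get(m.name, 0)) / len(self.samples)
            for m in self.model_space.models
        }

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# mkasr trace\n# seed\t{self.seed}\n# k\t{self.k}\n")
            fh.write(f"# root_prior\t{self.config.root_prior}\n")
            fh.write(f"# generations\t{self.config.generations}\n")
            fh.write(f"# burn_in\t{self.config.burn_in}\n")
            fh.write(f"# thinning\t{self.config.thinning}\n")
            fh.write(f"# final_rate_deviation\t{self.final_rate_deviation!r}\n")
            for move, (prop, acc) in sorted(self.acceptance.items()):
                fh.write(f"# acceptance_{move}\t{acc}/{prop}\n")
            self.samples.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read_tsv(cls, path) -> "Chain":
        """Reload a trace written by :meth:`write_tsv` (samples + the
        metadata needed for summaries)."""
        meta: dict[str, str] = {}
        with open(path, "r", encoding="utf-8") as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    meta[parts[0]] = parts[1]
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            samples = pd.read_csv(fh, sep="\t")
        k = int(meta.get("k", 2))
        config = RunConfig(
            generations=int(meta.get("generations", 0) or 2),
            burn_in=int(meta.get("burn_in", 0)),
            thinning=int(meta.get("thinning", 1)),
            seed=int(meta.get("seed", 0)),
            root_prior=meta.get("root_prior", "uniform"),
        )
        acceptance = {}
        for key, val in meta.items():
            if key.startswith("acceptance_"):
                acc, prop = val.split("/")
                acceptance[key[len("acceptance_"):]] = (int(prop), int(acc))
        return cls(
            samples=samples,
            model_space=enumerate_models(k),
            config=config,
            seed=int(meta.get("seed", 0)),
            k=k,
            acceptance=acceptance,
            tuning_trace=[],
            final_rate_deviation=float(meta.get("final_rate_deviation", "nan")),
            provenance=str(path),
        )


# ---------------------------------------------------------------------------
# proposals


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a real number into [lo, hi] by reflection at both boundaries
    (a symmetric proposal on the interval)."""
    width = hi - lo
    y = math.fmod(x - lo, 2.0 * width)
    if y < 0:
        y += 2.0 * width
    if y > width:
        y = 2.0 * width - y
    return lo + y


def tune_rate_deviation(acceptance_rate: float, current_deviation: float) -> float:
    """Multiplicative adjustment of the rate-proposal deviation toward the
    20–40% acceptance band; clamped to [1e-6, 1e3]."""
    if not (0.0 <= acceptance_rate <= 1.0):
        raise MCMCError(f"acceptance rate must be in [0, 1], got {acceptance_rate}")
    new = current_deviation
    if acceptance_rate < 0.20:
        new = current_deviation * 0.8
    elif acceptance_rate > 0.40:
        new = current_deviation * 1.25
    return min(max(new, 1e-6), 1e3)


def propose(
    state: MCMCState,
    move: str,
    model_space: ModelSpace,
    priors: PriorSpec,
    rng: np.random.Generator,
    rate_deviation: float,
    kappa_deviation: float = 1.0,
    m_deviation: float = 2.0,
    n_trees: int = 1,
) -> tuple[MCMCState, float]:
    """Build a candidate state for one move type.

    Returns (candidate, log proposal-ratio correction).  The correction is
    log q(reverse)/q(forward); reflected normal kernels are symmetric
    (correction 0), and the prior-draw model jump's correction is the log
    prior-density ratio of the dropped vs. drawn free rates (which cancels
    the rate-prior ratio in the posterior, leaving the likelihood ratio).
    The candidate's ``loglik`` is not evaluated here.
    """
    model = model_space.models[state.model_index]
    if move == "rates":
        new_free = tuple(
            abs(q + rng.normal(0.0, rate_deviation)) for q in state.free
        )
        cand = replace(
            state,
            free=new_free,
            log_rate_prior=priors.log_rate_prior(new_free, state.m),
        )
        return cand, 0.0
    if move == "kappa":
        lo, hi = priors.kappa_range
        new_kappa = _reflect(state.kappa + rng.normal(0.0, kappa_deviation), lo, hi)
        return replace(state, kappa=new_kappa), 0.0
    if move == "m":
        lo, hi = priors.m_range
        new_m = _reflect(state.m + rng.normal(0.0, m_deviation), lo, hi)
        cand = replace(
            state, m=new_m, log_rate_prior=priors.log_rate_prior(state.free, new_m)
        )
        return cand, 0.0
    if move == "model":
        others = [i for i in range(len(model_space)) if i != state.model_index]
        new_index = others[int(rng.integers(len(others)))]
        new_model = model_space.models[new_index]
        new_free = tuple(rng.exponential(state.m) for _ in range(new_model.n_free))
        old_lp = state.log_rate_prior
        new_lp = priors.log_rate_prior(new_free, state.m)
        cand = replace(
            state, model_index=new_index, free=new_free, log_rate_prior=new_lp
        )
        return cand, old_lp - new_lp
    if move == "tree":
        new_tree = int(rng.integers(n_trees))
        return replace(state, tree_index=new_tree), 0.0
    raise MCMCError(f"unknown move {move!r}")


# ---------------------------------------------------------------------------
# the sampler


class _Likelihood:
    """Per-tree pruning engines with a flat-likelihood shortcut when every
    tip is missing (posterior = prior)."""

    def __init__(self, tree_sample: TreeSample, column: CharacterColumn, k: int,
                 root_prior: str):
        self.k = k
        self.root_prior = root_prior
        partials = to_partials(column, sorted(tree_sample.taxon_set))
        self.flat = all(vec.all() for vec in partials.values())
        self.engines = (
            []
            if self.flat
            else [PruningEngine(t, partials, k) for t in tree_sample]
        )

    def __call__(self, rates: tuple[float, ...], kappa: float, tree_index: int) -> float:
        if self.flat:
            return 0.0
        engine = self.engines[tree_index]
        if self.k == 2:
            q01, q10 = rates
            if self.root_prior == "stationary":
                s = q01 + q10
                pi0, pi1 = (q10 / s, q01 / s) if s > 0 else (0.5, 0.5)
            else:
                pi0 = pi1 = 0.5
            return engine.loglik_binary(q01, q10, kappa, pi0, pi1)
        rp = RateParameters(self.k, rates)
        prior = (
            RootPrior.stationary(rp)
            if self.root_prior == "stationary"
            else RootPrior.uniform(self.k)
        )
        return engine.loglik(rp, kappa, prior)


def run_chain(
    config: RunConfig,
    tree_sample: TreeSample,
    column: CharacterColumn,
    priors: PriorSpec | None = None,
    model_space: ModelSpace | None = None,
    rng: np.random.Generator | None = None,
) -> Chain:
    """Metropolis–Hastings with the reversible-jump move mixture.

    Burn-in samples are discarded, the remainder thinned at the configured
    interval; the rate-proposal deviation is tuned only during burn-in.
    """
    priors = priors or PriorSpec()
    k = column.k
    model_space = model_space or enumerate_models(k)
    if model_space.k != k:
        raise MCMCError("model space does not match the character's state count")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    lik = _Likelihood(tree_sample, column, k, config.root_prior)
    n_trees = len(tree_sample)

    weights = dict(config.move_weights)
    if config.fix_kappa is not None:
        weights["kappa"] = 0.0
    if config.fix_m is not None:
        weights["m"] = 0.0
    if len(model_space) == 1:
        weights["model"] = 0.0
    if n_trees == 1:
        weights["tree"] = 0.0
    total = sum(weights.values())
    if total <= 0:
        raise MCMCError("no active moves")
    move_names = [m for m in ("rates", "kappa", "m", "model", "tree") if weights.get(m, 0) > 0]
    cum = np.cumsum([weights[m] / total for m in move_names])

    # initial state drawn from the prior; redraw if the likelihood
    # underflows (states of zero posterior mass cannot start the chain)
    state = None
    for _ in range(1000):
        m0 = config.fix_m if config.fix_m is not None else float(rng.uniform(*priors.m_range))
        kappa0 = (
            config.fix_kappa
            if config.fix_kappa is not None
            else float(rng.uniform(*priors.kappa_range))
        )
        model_index = int(rng.integers(len(model_space)))
        free0 = tuple(
            rng.exponential(m0) for _ in range(model_space.models[model_index].n_free)
        )
        cand0 = MCMCState(
            model_index=model_index,
            free=free0,
            kappa=kappa0,
            m=m0,
            tree_index=int(rng.integers(n_trees)),
            loglik=0.0,
            log_rate_prior=priors.log_rate_prior(free0, m0),
        )
        cand0.loglik = lik(cand0.rates(model_space), cand0.kappa, cand0.tree_index)
        if math.isfinite(cand0.loglik):
            state = cand0
            break
    if state is None:
        raise MCMCError(
            "could not find an initial state of finite likelihood; "
            "check the character data against the trees"
        )

    rate_dev = config.rate_deviation
    tuning_trace: list[tuple[int, float, float]] = []
    window = {"prop": 0, "acc": 0}
    acceptance = {mv: [0, 0] for mv in move_names}  # post-burn-in [prop, acc]

    rate_cols = (
        ["q01", "q10"]
        if k == 2
        else [f"q{i}{j}" for i in range(k) for j in range(k) if i != j]
    )
    records: dict[str, list] = {
        name: []
        for name in (
            ["generation", "model"] + rate_cols + ["kappa", "m", "tree_index", "loglik", "logprior"]
        )
    }

    burn_in = config.burn_in
    thin = config.thinning
    uniform = rng.random
    normal = rng.normal

    for gen in range(1, config.generations + 1):
        u = uniform()
        mi = int(np.searchsorted(cum, u, side="right"))
        if mi >= len(move_names):
            mi = len(move_names) - 1
        move = move_names[mi]
        in_burn = gen <= burn_in

        cand, _ = propose(
            state,
            move,
            model_space,
            priors,
            rng,
            rate_dev,
            config.kappa_deviation,
            config.m_deviation,
            n_trees,
        )
        if move == "m":
            delta = cand.log_rate_prior - state.log_rate_prior
            cand.loglik = state.loglik
        else:
            cand.loglik = lik(cand.rates(model_space), cand.kappa, cand.tree_index)
            delta = cand.loglik - state.loglik
            if move == "rates":
                delta += cand.log_rate_prior - state.log_rate_prior
            # model and tree moves: prior/proposal terms cancel exactly
        if math.isnan(delta):
            raise MCMCError(f"non-finite posterior at generation {gen} ({move} move)")

        accepted = delta >= 0 or uniform() < math.exp(delta)
        if accepted:
            state = cand

        if move == "rates":
            window["prop"] += 1
            window["acc"] += int(accepted)
        if not in_burn:
            acceptance[move][0] += 1
            acceptance[move][1] += int(accepted)

        if in_burn and gen % config.tuning_interval == 0 and window["prop"] > 0:
            rate_acc = window["acc"] / window["prop"]
            new_dev = tune_rate_deviation(rate_acc, rate_dev)
            tuning_trace.append((gen, rate_dev, rate_acc))
            rate_dev = new_dev
            window = {"prop": 0, "acc": 0}

        if not in_burn and (gen - burn_in) % thin == 0:
            rates = state.rates(model_space)
            records["generation"].append(gen)
            records["model"].append(model_space.models[state.model_index].name)
            for name, val in zip(rate_cols, rates):
                records[name].append(val)
            records["kappa"].append(state.kappa)
            records["m"].append(state.m)
            records["tree_index"].append(state.tree_index)
            records["loglik"].append(state.loglik)
            records["logprior"].append(state.log_rate_prior)

    samples = pd.DataFrame(records)
    return Chain(
        samples=samples,
        model_space=model_space,
        config=config,
        seed=config.seed,
        k=k,
        acceptance={mv: tuple(v) for mv, v in acceptance.items()},
        tuning_trace=tuning_trace,
        final_rate_deviation=rate_dev,
        provenance=f"character {column.name!r}",
    )


def run_replicates(
    config: RunConfig,
    tree_sample: TreeSample,
    column: CharacterColumn,
    priors: PriorSpec | None = None,
    model_space: ModelSpace | None = None,
) -> list[Chain]:
    """The replicate-run protocol: n_replicates independent chains with
    seeds spawned deterministically from the configured seed."""
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_replicates)
    chains = []
    for s in seeds:
        rep_config = replace(config, seed=int(s) % (2**31 - 1))
        rep_config.burn_in = config.burn_in
        chains.append(
            run_chain(rep_config, tree_sample, column, priors, model_space)
        )
    return chains
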