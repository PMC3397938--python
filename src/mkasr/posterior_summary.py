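"""Posterior summaries: rate ratios, κ HPD intervals, marginal node-state
probabilities, model posteriors and convergence diagnostics.

The reporting quantities mirror the standard tabular output of a Bayesian
ancestral-state analysis: for each character the ratio of the posterior
average forward rate to the posterior average backward rate (a ratio of
averages, not an average of ratios; samples where a rate is fixed at zero
by the current model count toward the averages), the posterior mean of κ
with its 95% highest-posterior-density interval, the marginal probability
of state 0 at each MRCA-defined query node averaged over the posterior
sample, the model posterior frequencies, and effective sample sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .characters import CharacterColumn, to_partials
from .mk_likelihood import PruningEngine, RateParameters, RootPrior
from .rjmcmc import Chain, PriorSpec
from .trees import NodeQuery, TreeSample, mrca

__all__ = [
    "CredibleInterval",
    "SummaryTable",
    "hpd",
    "rate_ratio",
    "ess",
    "node_probabilities",
    "summarize",
    "replicate_agreement",
    "SummaryError",
]


class SummaryError(ValueError):
    pass


@dataclass(frozen=True)
class CredibleInterval:
    """Shortest interval containing the stated posterior mass."""

    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise SummaryError("lower bound exceeds upper bound")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    def __str__(self) -> str:
        return f"({self.lower:.3f}–{self.upper:.3f})"


def hpd(samples, level: float = 0.95) -> CredibleInterval:
    """Highest-posterior-density interval: the shortest contiguous
    order-statistic window covering ceil(level * n) samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise SummaryError(f"need at least 20 samples for an HPD, got {n}")
    if not (0.0 < level < 1.0):
        raise SummaryError("level must be in (0, 1)")
    w = int(math.ceil(level * n))
    if w >= n:
        return CredibleInterval(float(x[0]), float(x[-1]), level)
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))
    return CredibleInterval(float(x[i]), float(x[i + w - 1]), level)


def rate_ratio(chain: Chain) -> float:
    """mean(q01) / mean(q10) over the model-averaged posterior (zero-rate
    model samples included)."""
    if chain.k != 2:
        raise SummaryError("rate ratio is defined for binary characters")
    q01 = chain.samples["q01"].to_numpy()
    q10 = chain.samples["q10"].to_numpy()
    mean10 = q10.mean()
    if mean10 == 0.0:
        warnings.warn("average backward rate is zero; ratio reported as +inf")
        return math.inf
    return float(q01.mean() / mean10)


def ess(samples) -> float:
    """Effective sample size: n / (1 + 2 * sum of autocorrelations), with
    Geyer's initial-positive-sequence truncation."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 50:
        raise SummaryError(f"need at least 50 samples for an ESS, got {n}")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0.0:
        return 1.0  # constant series: one effective draw
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs while they stay positive
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(n, n / tau))


def node_probabilities(
    chain: Chain,
    tree_sample: TreeSample,
    column: CharacterColumn,
    queries: list[NodeQuery],
    root_prior: str | None = None,
) -> dict[str, np.ndarray]:
    """Posterior marginal state probabilities at each query node.

    For every saved sample the query MRCAs are resolved on that sample's
    tree and the marginal reconstruction is computed under that sample's
    model, rates and κ; the resulting vectors are averaged with equal
    weight across samples (they are already posterior-weighted).
    """
    for q in queries:
        missing = q.taxon_set - tree_sample.taxon_set
        if missing:
            raise SummaryError(
                f"query {q.name!r} names taxa absent from the tree sample: "
                f"{', '.join(sorted(missing))}"
            )
    if len(chain) == 0:
        raise SummaryError("empty chain")
    k = chain.k
    root_prior = root_prior or chain.config.root_prior
    partials = to_partials(column, sorted(tree_sample.taxon_set))
    engines: dict[int, PruningEngine] = {}
    node_idx: dict[tuple[int, str], int] = {}

    rate_cols = chain.rate_columns
    rates_arr = chain.samples[rate_cols].to_numpy()
    kappas = chain.samples["kappa"].to_numpy()
    tree_idxs = chain.samples["tree_index"].to_numpy().astype(int)

    totals = {q.name: np.zeros(k) for q in queries}
    for rates_row, kappa, ti in zip(rates_arr, kappas, tree_idxs):
        engine = engines.get(ti)
        if engine is None:
            engine = PruningEngine(tree_sample[ti], partials, k)
            engines[ti] = engine
            for q in queries:
                node = mrca(tree_sample[ti], q.taxon_set)
                node_idx[(ti, q.name)] = engine.node_index(node)
        rp = RateParameters(k, tuple(rates_row))
        prior = (
            RootPrior.stationary(rp)
            if root_prior == "stationary"
            else RootPrior.uniform(k)
        )
        marg = engine.node_marginals(rp, float(kappa), prior)
        for q in queries:
            totals[q.name] += marg[node_idx[(ti, q.name)]]
    n = len(chain)
    return {name: vec / n for name, vec in totals.items()}


@dataclass
class SummaryTable:
    """Per-character posterior report shaped like the study's result
    tables: coded states, q01/q10, κ with 95% HPD, node state-0
    probabilities (full simplex for k=3), model posterior and ESS."""

    character: str
    k: int
    root_prior: str
    q_ratio: float | None
    kappa_mean: float
    kappa_hpd: CredibleInterval
    node_probs: dict[str, np.ndarray]
    model_posterior: dict[str, float]
    ess_per_parameter: dict[str, float]
    n_samples: int
    rate_means: dict[str, float] = field(default_factory=dict)
    state_space: tuple[int, ...] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows: list[tuple[str, str]] = []
        if self.state_space is not None:
            rows.append(
                ("coded states", " / ".join(str(s) for s in self.state_space))
            )
        if self.q_ratio is not None:
            rows.append(("q01/q10", f"{self.q_ratio:.3f}"))
        rows.append(
            ("kappa", f"{self.kappa_mean:.3f} {self.kappa_hpd}")
        )
        for name in sorted(self.node_probs):
            vec = self.node_probs[name]
            if self.k == 2:
                rows.append((f"Node {name}", f"{vec[0]:.3f}"))
            else:
                rows.append(
                    (f"Node {name}", ", ".join(f"{p:.3f}" for p in vec))
                )
        for mname, freq in self.model_posterior.items():
            rows.append((f"P(model {mname})", f"{freq:.3f}"))
        return pd.DataFrame(rows, columns=["quantity", self.character])

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# character\t{self.character}\n")
            fh.write(f"# root_prior\t{self.root_prior}\n")
            fh.write(f"# n_samples\t{self.n_samples}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _pool(chains: list[Chain]) -> Chain:
    if len(chains) == 1:
        return chains[0]
    pooled = pd.concat([c.samples for c in chains], ignore_index=True)
    first = chains[0]
    acceptance = {}
    for mv in first.acceptance:
        props = sum(c.acceptance.get(mv, (0, 0))[0] for c in chains)
        accs = sum(c.acceptance.get(mv, (0, 0))[1] for c in chains)
        acceptance[mv] = (props, accs)
    return Chain(
        samples=pooled,
        model_space=first.model_space,
        config=first.config,
        seed=first.seed,
        k=first.k,
        acceptance=acceptance,
        tuning_trace=[],
        final_rate_deviation=first.final_rate_deviation,
        provenance=f"pooled from {len(chains)} replicate chains",
    )


def summarize(
    chains: Chain | list[Chain],
    tree_sample: TreeSample | None = None,
    column: CharacterColumn | None = None,
    queries: list[NodeQuery] | None = None,
    level: float = 0.95,
) -> SummaryTable:
    """Summarize one chain or a pooled set of replicate chains."""
    chain_list = [chains] if isinstance(chains, Chain) else list(chains)
    chain = _pool(chain_list)
    if len(chain) == 0:
        raise SummaryError("no saved samples to summarize")
    kappa = chain.samples["kappa"].to_numpy()
    scalar_cols = chain.rate_columns + ["kappa", "m"]
    ess_map = {}
    for colname in scalar_cols:
        vals = chain.samples[colname].to_numpy()
        ess_map[colname] = ess(vals) if len(vals) >= 50 else math.nan
    node_probs = {}
    if tree_sample is not None and column is not None and queries:
        node_probs = node_probabilities(chain, tree_sample, column, queries)
    return SummaryTable(
        character=column.name if column is not None else chain.provenance,
        k=chain.k,
        root_prior=chain.config.root_prior,
        q_ratio=rate_ratio(chain) if chain.k == 2 else None,
        kappa_mean=float(kappa.mean()),
        kappa_hpd=hpd(kappa, level),
        node_probs=node_probs,
        model_posterior=chain.model_posterior(),
        ess_per_parameter=ess_map,
        n_samples=len(chain),
        rate_means={
            colname: float(chain.samples[colname].mean())
            for colname in chain.rate_columns
        },
        state_space=column.state_space if column is not None else None,
    )


def replicate_agreement(chains: list[Chain], parameter: str = "kappa") -> pd.DataFrame:
    """Check that replicate runs agree: each run's posterior mean of the
    parameter must lie within 2 Monte-Carlo standard errors (SE from the
    run's ESS) of the grand mean across runs."""
    if len(chains) < 2:
        raise SummaryError("need at least two chains to compare")
    rows = []
    means = []
    ses = []
    for c in chains:
        vals = c.samples[parameter].to_numpy()
        mu = float(vals.mean())
        e = ess(vals)
        se = float(vals.std(ddof=1)) / math.sqrt(max(e, 1.0))
        means.append(mu)
        ses.append(se)
    grand = float(np.mean(means))
    for i, (mu, se) in enumerate(zip(means, ses)):
        combined = math.sqrt(se**2 + float(np.mean(ses)) ** 2 / len(chains))
        rows.append(
            {
                "run": i,
                "mean": mu,
                "mc_se": se,
                "grand_mean": grand,
                "agrees": abs(mu - grand) <= 2.0 * combined,
            }
        )
    return pd.DataFrame(rows)
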