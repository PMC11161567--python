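"""Equal-rates Mk model for substrate preference: likelihood, Bayesian MCMC
over the transition rate, marginal ancestral-state posteriors, and
transition calling at speciation nodes.

The model has k states (default the three substrates: ultramafic, schistose,
limestone) and a single overall leaving rate ``mu``; the rate matrix is
Q_ij = mu/(k-1) for i != j and Q_ii = -mu, giving the closed-form transition
probability P_ii(t) = 1/k + (1 - 1/k) exp(-mu t k/(k-1)). Tips may be
polymorphic (observed in several substrates) or missing (encoded as the full
state set); both use ambiguity coding, i.e. a tip partial of 1 on each
observed state.

The Bayesian machinery is a Metropolis-Hastings random walk on log(mu) with
an exponential prior (mean 10 by default), two independent runs of 25 000
generations with the first 25 % discarded as burn-in; per-sample marginal
ancestral-state probabilities from the pruning up-down pass are averaged
over the retained (thinned) samples and over runs after a convergence check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .trees import EventNodeSet, Phylogeny, TreeError

__all__ = [
    "MkModel",
    "parse_tip_states",
    "mk_loglik",
    "mk_marginals",
    "mk_mcmc",
    "MkPosterior",
    "call_substrate_transitions",
]

SUBSTRATES = ("ultramafic", "schistose", "limestone")


@dataclass
class MkModel:
    """Equal-rates k-state Markov model with overall leaving rate ``mu``."""
    states: tuple[str, ...] = SUBSTRATES
    mu: float = 1.0
    root_prior: np.ndarray | None = None  # uniform when None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.root_prior is not None:
            self.root_prior = np.asarray(self.root_prior, dtype=float)
            if abs(self.root_prior.sum() - 1) > 1e-9:
                raise ValueError("root prior must sum to 1")

    @property
    def k(self) -> int:
        return len(self.states)

    def prior(self) -> np.ndarray:
        if self.root_prior is None:
            return np.full(self.k, 1.0 / self.k)
        return self.root_prior

    def rate_matrix(self) -> np.ndarray:
        k = self.k
        q = np.full((k, k), self.mu / (k - 1))
        np.fill_diagonal(q, -self.mu)
        return q

    def transition_matrix(self, t: float) -> np.ndarray:
        """exp(Q t) in closed form for the equal-rates chain."""
        k = self.k
        decay = np.exp(-self.mu * t * k / (k - 1))
        off = (1.0 - decay) / k
        p = np.full((k, k), off)
        np.fill_diagonal(p, 1.0 / k + (1.0 - 1.0 / k) * decay)
        return p


def parse_tip_states(
    obs: Mapping[str, Iterable[str] | str],
    states: tuple[str, ...] = SUBSTRATES,
) -> dict[str, frozenset[str]]:
    """Normalize tip observations: a string like ``"ultramafic|schistose"``,
    ``"?"`` (missing, i.e. all states) or an iterable of state names."""
    out: dict[str, frozenset[str]] = {}
    for sp, raw in obs.items():
        if isinstance(raw, str):
            raw = states if raw.strip() == "?" else raw.split("|")
        s = frozenset(x.strip() for x in raw)
        unknown = s - set(states)
        if unknown:
            raise ValueError(f"unknown states for {sp}: {sorted(unknown)}")
        if not s:
            raise ValueError(f"empty state set for {sp}")
        out[sp.strip().replace(" ", "_")] = s
    return out


def _tip_partial(state_set: frozenset[str], states: tuple[str, ...]) -> np.ndarray:
    return np.array([1.0 if s in state_set else 0.0 for s in states])


def _upward(tree: Phylogeny, obs: dict[str, frozenset[str]], model: MkModel):
    """Pruning pass. Returns (up partials per node, branch messages per node,
    total log scaling, log-likelihood)."""
    prior = model.prior()
    up: dict[int, np.ndarray] = {}
    msg: dict[int, np.ndarray] = {}  # child id -> message at top of its branch
    logscale = 0.0
    for n in tree.postorder():
        if n.is_leaf:
            if n.label not in obs:
                raise TreeError(f"tip {n.label!r} absent from observations")
            part = _tip_partial(obs[n.label], model.states)
        else:
            part = np.ones(model.k)
            for c in n.children:
                part = part * msg[id(c)]
            s = part.max()
            if s <= 0:
                return up, msg, -np.inf, -np.inf
            part = part / s
            logscale += np.log(s)
        up[id(n)] = part
        if n.parent is not None:
            if n.length is None:
                raise TreeError(f"missing branch length above node {n.id}")
            msg[id(n)] = model.transition_matrix(n.length) @ part
    lik = float(prior @ up[id(tree.root)])
    loglik = -np.inf if lik <= 0 else np.log(lik) + logscale
    return up, msg, logscale, loglik


def mk_loglik(tree: Phylogeny, obs: Mapping[str, Iterable[str] | str],
              model: MkModel) -> float:
    """Felsenstein-pruning log-likelihood of the tip data under ``model``."""
    tips = parse_tip_states(obs, model.states)
    return _upward(tree, tips, model)[3]


def mk_marginals(tree: Phylogeny, obs: Mapping[str, Iterable[str] | str],
                 model: MkModel) -> dict[str, np.ndarray]:
    """Marginal ancestral-state probabilities at every internal node for a
    fixed rate, via the up-down pass."""
    tips = parse_tip_states(obs, model.states)
    up, msg, _, loglik = _upward(tree, tips, model)
    if not np.isfinite(loglik):
        raise ValueError("data have zero likelihood under this model")
    down: dict[int, np.ndarray] = {id(tree.root): model.prior()}
    out: dict[str, np.ndarray] = {}
    for n in tree.preorder():
        if not n.is_leaf:
            m = up[id(n)] * down[id(n)]
            out[n.id] = m / m.sum()
        for c in n.children:
            contrib = down[id(n)].copy()
            for s in n.children:
                if s is not c:
                    contrib = contrib * msg[id(s)]
            d = model.transition_matrix(c.length).T @ contrib
            tot = d.sum()
            down[id(c)] = d / tot if tot > 0 else d
    return out


# ---------------------------------------------------------------------------
# MCMC over the transition rate
# ---------------------------------------------------------------------------

def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return float(n / (1 + 2 * s))


@dataclass
class MkPosterior:
    """Combined posterior over the rate and marginal node-state posteriors."""
    states: tuple[str, ...]
    node_probs: dict[str, np.ndarray]
    mu_samples: list[np.ndarray]  # per run, post burn-in
    ess: float
    accept_rates: list[float]
    converged: bool
    per_run_node_probs: list[dict[str, np.ndarray]] = field(repr=False, default_factory=list)
    traces: list[pd.DataFrame] = field(repr=False, default_factory=list)

    @property
    def mu_combined(self) -> np.ndarray:
        return np.concatenate(self.mu_samples)

    def map_state(self, node_id: str) -> tuple[str, float, bool]:
        """(state, probability, tied) for the maximum-a-posteriori state."""
        p = self.node_probs[node_id]
        order = np.argsort(p)[::-1]
        tied = bool(np.isclose(p[order[0]], p[order[1]]))
        return self.states[order[0]], float(p[order[0]]), tied

    def to_frame(self) -> pd.DataFrame:
        rows = [(nid, s, float(p))
                for nid, probs in sorted(self.node_probs.items())
                for s, p in zip(self.states, probs)]
        return pd.DataFrame(rows, columns=["node", "state", "probability"])


def mk_mcmc(
    tree: Phylogeny,
    obs: Mapping[str, Iterable[str] | str],
    prior_mean: float = 10.0,
    generations: int = 25_000,
    runs: int = 2,
    burnin_fraction: float = 0.25,
    seed: int | None = None,
    thin_marginals: int = 25,
    ess_floor: float = 100.0,
) -> MkPosterior:
    """Metropolis-Hastings sampler for the equal-rates transition rate.

    The proposal is a log-scale random walk (multiplicative scaling) whose
    step is tuned during burn-in towards a 20-50 % acceptance rate; the prior
    on ``mu`` is exponential with mean ``prior_mean``. Marginal node-state
    probabilities are computed by the up-down pass at every
    ``thin_marginals``-th retained sample and averaged. Runs are combined
    after a convergence check (posterior means within half a pooled SD);
    failure to converge or an ESS below ``ess_floor`` warns, never fails.
    """
    tips = parse_tip_states(obs)
    states = SUBSTRATES
    internal_ids = [n.id for n in tree.internal_nodes()]
    rng_master = np.random.default_rng(seed)
    run_seeds = rng_master.integers(0, 2**31 - 1, size=runs)

    burnin = int(generations * burnin_fraction)
    all_mu: list[np.ndarray] = []
    accept_rates: list[float] = []
    per_run_probs: list[dict[str, np.ndarray]] = []
    traces: list[pd.DataFrame] = []

    for r in range(runs):
        rng = np.random.default_rng(run_seeds[r])
        mu = float(rng.exponential(prior_mean))
        model = MkModel(states, mu)
        ll = _upward(tree, tips, model)[3]
        lp = -mu / prior_mean
        step = 0.5
        accepted = 0
        recent = []
        mus = np.empty(generations)
        lls = np.empty(generations)
        lps = np.empty(generations)
        prob_sum = {nid: np.zeros(len(states)) for nid in internal_ids}
        n_prob = 0
        for g in range(generations):
            prop = mu * np.exp(step * rng.normal())
            ll_p = _upward(tree, tips, MkModel(states, prop))[3]
            lp_p = -prop / prior_mean
            # log Hastings correction for the multiplicative proposal
            log_alpha = (ll_p + lp_p) - (ll + lp) + np.log(prop / mu)
            if np.log(rng.uniform()) < log_alpha:
                mu, ll, lp = prop, ll_p, lp_p
                accepted += 1
                recent.append(1)
            else:
                recent.append(0)
            mus[g] = mu
            lls[g] = ll
            lps[g] = lp
            if g < burnin and (g + 1) % 100 == 0:  # tune during burn-in only
                rate = np.mean(recent[-100:])
                if rate < 0.2:
                    step *= 0.7
                elif rate > 0.5:
                    step *= 1.4
            if g >= burnin and (g - burnin) % thin_marginals == 0:
                marg = mk_marginals(tree, tips, MkModel(states, mu))
                for nid in internal_ids:
                    prob_sum[nid] += marg[nid]
                n_prob += 1
        all_mu.append(mus[burnin:])
        accept_rates.append(accepted / generations)
        per_run_probs.append({nid: prob_sum[nid] / n_prob for nid in internal_ids})
        traces.append(pd.DataFrame({"generation": np.arange(generations),
                                    "mu": mus, "loglik": lls,
                                    "logprior": lps}))

    ess = sum(_ess(m) for m in all_mu)
    if ess < ess_floor:
        warnings.warn(f"rate ESS {ess:.0f} below floor {ess_floor:.0f}",
                      stacklevel=2)
    converged = True
    if runs > 1:
        means = [m.mean() for m in all_mu]
        pooled_sd = float(np.concatenate(all_mu).std())
        converged = (pooled_sd == 0
                     or max(means) - min(means) < 0.5 * pooled_sd)
        if not converged:
            warnings.warn("run posterior means differ by more than half a "
                          "posterior SD; inspect traces", stacklevel=2)
    node_probs = {
        nid: np.mean([p[nid] for p in per_run_probs], axis=0)
        for nid in internal_ids
    }
    return MkPosterior(states, node_probs, all_mu, ess, accept_rates,
                       converged, per_run_probs, traces)


# ---------------------------------------------------------------------------
# Transition calling
# ---------------------------------------------------------------------------

def call_substrate_transitions(
    posterior: MkPosterior,
    tips: Mapping[str, Iterable[str] | str],
    nodes: EventNodeSet,
    tree: Phylogeny,
    map_threshold: float = 0.5,
) -> dict[str, str]:
    """Per-node substrate-transition verdicts.

    At an assessable node the two daughter sides' extant substrate sets are
    compared directly: any set difference (including one species on two
    substrates whose sister holds only one) is a transition. At a deeper
    (substrate-only) node the maximum-a-posteriori state is compared with
    each daughter lineage's representative (daughter-node MAP, or the tip's
    observed set); MAP ties or probabilities below ``map_threshold`` yield
    ``"uncertain"`` and are not counted as transitions.
    """
    obs = parse_tip_states(tips, posterior.states)

    def side_set(node) -> frozenset[str]:
        out: set[str] = set()
        for leaf in tree.leaves(node):
            if leaf.label in obs:
                out |= obs[leaf.label]
        return frozenset(out)

    verdicts: dict[str, str] = {}
    for nid in nodes.assessable:
        n = tree.node(nid)
        if len(n.children) != 2:
            verdicts[nid] = "uncertain"
            continue
        a, b = (side_set(c) for c in n.children)
        verdicts[nid] = "transition" if a != b else "none"

    for nid in nodes.substrate_only:
        n = tree.node(nid)
        state, p, tied = posterior.map_state(nid)
        if tied or p < map_threshold:
            verdicts[nid] = "uncertain"
            continue
        verdict = "none"
        uncertain = False
        for c in n.children:
            if c.is_leaf:
                if state not in obs.get(c.label, frozenset()):
                    verdict = "transition"
            else:
                cstate, cp, ctied = posterior.map_state(c.id)
                if ctied or cp < map_threshold:
                    uncertain = True
                elif cstate != state:
                    verdict = "transition"
        if verdict == "none" and uncertain:
            verdict = "uncertain"
        verdicts[nid] = verdict
    return verdicts
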