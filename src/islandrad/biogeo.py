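"""Parametric ancestral-range inference for discrete areas.

A geographic range is a subset of the area system, capped at ``max_areas``
(default 3) areas at a time; the state space contains the null range (the
extirpation sink) and every subset up to the cap. Anagenetic evolution along
branches is dispersal (range expansion into area b at rate
``d * sum_{a in R} m_ab``, with m the distance multipliers) and extirpation
(area loss at rate ``e``); cladogenetic change at nodes follows the family's
event table:

* DEC        - sympatry/subset sympatry, vicariance with one singleton
               daughter, optional founder-event jumps;
* DIVALIKE   - sympatry for singletons, vicariance into any two nonempty
               halves, optional jumps; no subset sympatry;
* BAYAREALIKE- both daughters inherit the parent range unchanged, optional
               jumps.

Per parent range each eligible outcome carries its event-class weight
(sympatry/subset y, vicariance v, jump j; y = v = (3-j)/3 for DEC,
(2-j)/2 for DIVALIKE, y = 1-j for BAYAREALIKE) and the outcome weights are
normalized to sum to one. Distance-scaled dispersal uses the one-parameter
power law m_ab = (dist_ab / dbar)^x with dbar the mean off-diagonal
distance, so x = 0 recovers the distance-free model and the normalization
point dist = dbar is parameter-independent.

Model fitting maximizes the pruning likelihood over the free parameters
(d, e always; j and x when enabled) by multi-start Nelder-Mead on
transformed coordinates, and candidate models are compared by AICc with
n = number of tips.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import Phylogeny, TreeError

__all__ = [
    "AreaSystem",
    "BiogeoModel",
    "BiogeoFit",
    "build_state_space",
    "dispersal_multipliers",
    "anagenetic_Q",
    "cladogenesis_table",
    "biogeo_loglik",
    "fit_biogeo",
    "aicc",
    "aicc_compare",
    "ancestral_range_marginals",
]

FAMILIES = ("DEC", "DIVALIKE", "BAYAREALIKE")
_J_MAX = {"DEC": 3.0, "DIVALIKE": 2.0, "BAYAREALIKE": 1.0}


@dataclass
class AreaSystem:
    """Ordered area labels with a symmetric pairwise distance matrix (km)."""
    labels: tuple[str, ...]
    distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.labels) > 26:
            raise ValueError("at most 26 areas supported")
        if self.distances is not None:
            d = np.asarray(self.distances, dtype=float)
            if d.shape != (len(self.labels),) * 2:
                raise ValueError("distance matrix shape mismatch")
            if not np.allclose(d, d.T):
                raise ValueError("distance matrix must be symmetric")
            if np.any(np.diag(d) != 0):
                raise ValueError("distance diagonal must be zero")
            if np.any(d[~np.eye(len(self.labels), dtype=bool)] <= 0):
                raise ValueError("off-diagonal distances must be > 0")
            self.distances = d

    @property
    def n(self) -> int:
        return len(self.labels)

    def range_from_labels(self, labels) -> tuple[int, ...]:
        idx = {l: i for i, l in enumerate(self.labels)}
        try:
            return tuple(sorted(idx[l] for l in labels))
        except KeyError as exc:
            raise ValueError(f"unknown area label: {exc}") from None

    def range_string(self, state: tuple[int, ...]) -> str:
        return "".join(self.labels[i] for i in state) or "-"


@dataclass
class BiogeoModel:
    """A model family with its anagenetic and cladogenetic parameters."""
    family: str
    d: float = 0.01   # per-area dispersal rate, events/Myr
    e: float = 0.01   # per-area extirpation rate
    j: float = 0.0    # founder-event weight (0 = +J off)
    x: float = 0.0    # distance exponent (0 = distance off)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.d < 0 or self.e < 0:
            raise ValueError("d and e must be >= 0")
        if not 0 <= self.j < _J_MAX[self.family] + 1e-12:
            raise ValueError(f"j must be in [0, {_J_MAX[self.family]})")


def build_state_space(n_areas: int, max_areas: int = 3) -> list[tuple[int, ...]]:
    """All ranges up to ``max_areas`` areas: the null range first, then
    subsets grouped by cardinality, lexicographic within a group."""
    if not 1 <= max_areas <= n_areas:
        raise ValueError("need 1 <= max_areas <= n_areas")
    states: list[tuple[int, ...]] = [()]
    for c in range(1, max_areas + 1):
        states.extend(itertools.combinations(range(n_areas), c))
    return states


def dispersal_multipliers(areas: AreaSystem, x: float) -> np.ndarray:
    """Power-law multipliers m_ab = (dist_ab / mean off-diagonal dist)^x;
    all ones when x = 0 or no distances are supplied."""
    n = areas.n
    if x == 0 or areas.distances is None:
        return np.ones((n, n))
    off = ~np.eye(n, dtype=bool)
    dbar = areas.distances[off].mean()
    m = np.ones((n, n))
    m[off] = (areas.distances[off] / dbar) ** x
    return m


def anagenetic_Q(states: Sequence[tuple[int, ...]], d: float, e: float,
                 multipliers: np.ndarray, max_areas: int = 3) -> np.ndarray:
    """Dense anagenetic rate matrix over the range state space.

    Range R gains area b (|R u {b}| <= max_areas) at rate
    d * sum_{a in R} m_ab; R loses each of its areas at rate e (singletons
    decay to the null range, which is absorbing). Rows sum to zero.
    """
    index = {s: i for i, s in enumerate(states)}
    S = len(states)
    q = np.zeros((S, S))
    for i, state in enumerate(states):
        if not state:
            continue  # null range absorbing
        sset = set(state)
        if len(state) < max_areas:
            for b in range(multipliers.shape[0]):
                if b in sset:
                    continue
                target = tuple(sorted(state + (b,)))
                rate = d * sum(multipliers[a, b] for a in state)
                q[i, index[target]] += rate
        for a in state:
            target = tuple(x for x in state if x != a)
            q[i, index[target]] += e
        q[i, i] = -q[i].sum()
    return q


# ---------------------------------------------------------------------------
# Cladogenesis
# ---------------------------------------------------------------------------

_CLS_SYM, _CLS_VIC, _CLS_JUMP = 0, 1, 2


@dataclass
class CladoEvents:
    """Flat ordered-outcome enumeration for one family over a state space;
    outcome weights for a given j are filled in by :meth:`weights`."""
    family: str
    parent: np.ndarray  # parent state index per outcome
    left: np.ndarray
    right: np.ndarray
    cls: np.ndarray     # event class per outcome
    n_states: int

    def weights(self, j: float) -> np.ndarray:
        if self.family == "DEC":
            y = v = (3.0 - j) / 3.0
        elif self.family == "DIVALIKE":
            y = v = (2.0 - j) / 2.0
        else:
            y, v = 1.0 - j, 0.0
        w = np.choose(self.cls, [y, v, j]).astype(float)
        totals = np.bincount(self.parent, weights=w, minlength=self.n_states)
        w = w / totals[self.parent]
        return w


def enumerate_clado_events(states: Sequence[tuple[int, ...]], family: str,
                           n_areas: int) -> CladoEvents:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    index = {s: i for i, s in enumerate(states)}
    P: list[int] = []
    L: list[int] = []
    R: list[int] = []
    C: list[int] = []

    for pi, parent in enumerate(states):
        if not parent:
            continue
        pset = set(parent)
        outcomes: set[tuple[tuple[int, ...], tuple[int, ...], int]] = set()
        if len(parent) == 1 or family == "BAYAREALIKE":
            outcomes.add((parent, parent, _CLS_SYM))
        if len(parent) > 1 and family == "DEC":
            for a in parent:
                single = (a,)
                rest = tuple(x for x in parent if x != a)
                outcomes.add((parent, single, _CLS_SYM))   # subset sympatry
                outcomes.add((single, parent, _CLS_SYM))
                outcomes.add((single, rest, _CLS_VIC))     # vicariance
                outcomes.add((rest, single, _CLS_VIC))
        if len(parent) > 1 and family == "DIVALIKE":
            for r in range(1, len(parent)):
                for half in itertools.combinations(parent, r):
                    rest = tuple(x for x in parent if x not in half)
                    outcomes.add((half, rest, _CLS_VIC))
                    outcomes.add((rest, half, _CLS_VIC))
        for b in range(n_areas):  # founder-event jumps
            if b in pset:
                continue
            outcomes.add((parent, (b,), _CLS_JUMP))
            outcomes.add(((b,), parent, _CLS_JUMP))
        for l, r, c in sorted(outcomes):
            P.append(pi)
            L.append(index[l])
            R.append(index[r])
            C.append(c)
    return CladoEvents(family, np.array(P), np.array(L), np.array(R),
                       np.array(C), len(states))


def cladogenesis_table(
    states: Sequence[tuple[int, ...]], family: str, j: float, n_areas: int,
) -> dict[int, list[tuple[int, int, float]]]:
    """Per-parent weighted daughter-pair outcomes (ordered pairs); weights
    sum to 1 for every nonnull parent."""
    ev = enumerate_clado_events(states, family, n_areas)
    w = ev.weights(j)
    table: dict[int, list[tuple[int, int, float]]] = {}
    for p, l, r, wi in zip(ev.parent, ev.left, ev.right, w):
        if wi > 0:
            table.setdefault(int(p), []).append((int(l), int(r), float(wi)))
    return table


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _propagators(q: np.ndarray, lengths: Sequence[float]) -> dict[float, np.ndarray]:
    """exp(Q t) per unique branch length; eigendecomposition with an expm
    fallback when the decomposition is ill-conditioned."""
    uniq = sorted(set(float(t) for t in lengths))
    out: dict[float, np.ndarray] = {}
    try:
        w, v = np.linalg.eig(q)
        vi = np.linalg.inv(v)
        tmax = uniq[-1] if uniq else 1.0
        probe = np.real((v * np.exp(w * tmax)) @ vi)
        if not np.allclose(probe.sum(axis=1), 1.0, atol=1e-8):
            raise np.linalg.LinAlgError("row sums off")
        ok = True
    except np.linalg.LinAlgError:
        ok = False
    for t in uniq:
        if ok:
            p = np.real((v * np.exp(w * t)) @ vi)
        else:
            p = expm(q * t)
        np.clip(p, 0.0, None, out=p)
        out[t] = p
    return out


class _Engine:
    """Shared state-space machinery for one (tree, data, family) problem."""

    def __init__(self, tree: Phylogeny, tip_ranges: Mapping[str, tuple[int, ...]],
                 areas: AreaSystem, family: str, max_areas: int = 3):
        self.tree = tree
        self.areas = areas
        self.max_areas = max_areas
        self.states = build_state_space(areas.n, max_areas)
        self.index = {s: i for i, s in enumerate(self.states)}
        self.events = enumerate_clado_events(self.states, family, areas.n)
        self.family = family
        self.tip_partial: dict[str, np.ndarray] = {}
        for tip in tree.tip_labels:
            if tip not in tip_ranges:
                raise TreeError(f"tip {tip!r} has no observed range")
            state = tuple(sorted(tip_ranges[tip]))
            if not state:
                raise ValueError(f"tip {tip!r} has a null observed range")
            if len(state) > max_areas:
                raise ValueError(
                    f"tip {tip!r} range exceeds max_areas={max_areas}")
            part = np.zeros(len(self.states))
            part[self.index[state]] = 1.0
            self.tip_partial[tip] = part
        for n in tree.internal_nodes():
            if len(n.children) != 2:
                raise TreeError("range inference requires a binary tree")
        self.lengths = [n.length for n in tree.preorder() if n.parent is not None]
        if any(t is None for t in self.lengths):
            raise TreeError("branch lengths required")
        # root prior: uniform over nonnull states
        self.prior = np.ones(len(self.states))
        self.prior[0] = 0.0
        self.prior /= self.prior.sum()

    def _passes(self, model: BiogeoModel, need_down: bool = False):
        m = dispersal_multipliers(self.areas, model.x)
        q = anagenetic_Q(self.states, model.d, model.e, m, self.max_areas)
        props = _propagators(q, self.lengths)
        w = self.events.weights(model.j)
        ev = self.events
        S = len(self.states)

        up: dict[int, np.ndarray] = {}
        bmsg: dict[int, np.ndarray] = {}  # child -> message at its top (post-clado state)
        logscale = 0.0
        for n in self.tree.postorder():
            if n.is_leaf:
                part = self.tip_partial[n.label]
            else:
                bl = bmsg[id(n.children[0])]
                br = bmsg[id(n.children[1])]
                part = np.bincount(ev.parent, weights=w * bl[ev.left] * br[ev.right],
                                   minlength=S)
                s = part.max()
                if s <= 0:
                    return None, None, -np.inf
                part /= s
                logscale += math.log(s)
            up[id(n)] = part
            if n.parent is not None:
                bmsg[id(n)] = props[float(n.length)] @ part
        lik = float(self.prior @ up[id(self.tree.root)])
        loglik = -np.inf if lik <= 0 else math.log(lik) + logscale
        if not need_down or not np.isfinite(loglik):
            return up, None, loglik

        down: dict[int, np.ndarray] = {id(self.tree.root): self.prior.copy()}
        for n in self.tree.preorder():
            if n.is_leaf:
                continue
            dn = down[id(n)]
            bl = bmsg[id(n.children[0])]
            br = bmsg[id(n.children[1])]
            contrib = dn[ev.parent] * w
            g_left = np.bincount(ev.left, weights=contrib * br[ev.right], minlength=S)
            g_right = np.bincount(ev.right, weights=contrib * bl[ev.left], minlength=S)
            for child, g in ((n.children[0], g_left), (n.children[1], g_right)):
                dmsg = props[float(child.length)].T @ g
                tot = dmsg.sum()
                down[id(child)] = dmsg / tot if tot > 0 else dmsg
        return up, down, loglik

    def loglik(self, model: BiogeoModel, condition_on_survival: bool = False) -> float:
        ll = self._passes(model)[2]
        if not condition_on_survival or not np.isfinite(ll):
            return ll
        # P(every tip non-null): same pruning with every tip ambiguous over
        # all non-null ranges; subtracting its log conditions the likelihood
        # on the event the simulator/regeneration scheme conditions on.
        saved = self.tip_partial
        amb = np.ones(len(self.states))
        amb[0] = 0.0
        try:
            self.tip_partial = {tip: amb for tip in saved}
            log_surv = self._passes(model)[2]
        finally:
            self.tip_partial = saved
        return ll - log_surv

    def marginals(self, model: BiogeoModel) -> dict[str, np.ndarray]:
        up, down, loglik = self._passes(model, need_down=True)
        if not np.isfinite(loglik):
            raise ValueError("zero-likelihood model; no marginals")
        out: dict[str, np.ndarray] = {}
        for n in self.tree.internal_nodes():
            m = up[id(n)] * down[id(n)]
            m[0] = 0.0  # null range excluded from reports
            out[n.id] = m / m.sum()
        return out


def biogeo_loglik(tree: Phylogeny, tip_ranges: Mapping, model: BiogeoModel,
                  areas: AreaSystem, max_areas: int = 3,
                  condition_on_survival: bool = False) -> float:
    """Pruning log-likelihood of observed tip ranges under ``model``.

    ``tip_ranges`` maps species to a collection of area labels (or area
    index tuples). The root state is integrated against a uniform prior over
    nonnull ranges. ``condition_on_survival`` divides by the probability
    that every tip range is non-null, matching data generated (or sampled)
    conditional on all lineages retaining a range; the default matches the
    convention of standard range-inference packages.
    """
    ranges = _coerce_ranges(tip_ranges, areas)
    return _Engine(tree, ranges, areas, model.family, max_areas).loglik(
        model, condition_on_survival)


def read_range_table(path, areas: AreaSystem) -> dict[str, tuple[str, ...]]:
    """Read a species x area presence/absence CSV (first column species,
    remaining columns area labels, entries 0/1) into label ranges."""
    df = pd.read_csv(path)
    area_cols = [c for c in df.columns[1:] if c in areas.labels]
    missing = set(df.columns[1:]) - set(area_cols)
    if missing:
        raise ValueError(f"columns not in the area system: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row.iloc[0])] = tuple(c for c in area_cols if row[c])
    return out


def _coerce_ranges(tip_ranges: Mapping, areas: AreaSystem) -> dict[str, tuple[int, ...]]:
    out = {}
    for sp, r in tip_ranges.items():
        if r and all(isinstance(x, str) for x in r):
            out[sp] = areas.range_from_labels(r)
        else:
            out[sp] = tuple(sorted(int(x) for x in r))
    return out


# ---------------------------------------------------------------------------
# Fitting and model comparison
# ---------------------------------------------------------------------------

def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass
class BiogeoFit:
    model: BiogeoModel
    use_j: bool
    use_distance: bool
    loglik: float
    k: int
    n_tips: int
    aicc: float
    start_reports: list[dict] = field(default_factory=list, repr=False)

    @property
    def name(self) -> str:
        tags = "+J" if self.use_j else ""
        tags += "+x" if self.use_distance else ""
        return self.model.family + tags


def fit_biogeo(
    tree: Phylogeny,
    tip_ranges: Mapping,
    areas: AreaSystem,
    family: str,
    use_j: bool = False,
    use_distance: bool = False,
    max_areas: int = 3,
    starts: int = 5,
    seed: int | None = None,
    maxiter: int | None = None,
    condition_on_survival: bool = False,
) -> BiogeoFit:
    """Maximum-likelihood fit of one model family.

    Free parameters are log-transformed (d, e) or squashed into their boxes
    (j into [0, j_max), x into [-5, 0]); ``starts`` jittered Nelder-Mead
    starts guard against the multimodal surfaces +J models produce. The
    best start is retained; per-start diagnostics are kept on the fit.
    """
    if use_distance and areas.distances is None:
        raise ValueError("distance-constrained fit requires a distance matrix")
    ranges = _coerce_ranges(tip_ranges, areas)
    engine = _Engine(tree, ranges, areas, family, max_areas)
    jmax = _J_MAX[family]
    rng = np.random.default_rng(seed)
    depth = max(tree.depths().values()) or 1.0
    base = [math.log(1.0 / depth), math.log(0.5 / depth)]
    if use_j:
        base.append(_logit(0.1 / jmax))
    if use_distance:
        base.append(_logit(0.2))  # x near -1

    def unpack(theta) -> BiogeoModel:
        d, e = math.exp(theta[0]), math.exp(theta[1])
        i = 2
        j = 0.0
        x = 0.0
        if use_j:
            j = jmax * _sigmoid(theta[i]) * (1 - 1e-9)
            i += 1
        if use_distance:
            x = -5.0 * _sigmoid(theta[i])
        return BiogeoModel(family, d, e, j, x)

    def neg(theta):
        if np.any(np.abs(theta[:2]) > 25):
            return 1e10
        ll = engine.loglik(unpack(theta), condition_on_survival)
        return 1e10 if not np.isfinite(ll) else -ll

    npar = len(base)
    best = None
    reports = []
    for s in range(starts):
        theta0 = np.array(base) + (rng.normal(size=npar) if s else 0.0)
        res = minimize(neg, theta0, method="Nelder-Mead",
                       options={"maxiter": maxiter or 300 * npar,
                                "fatol": 1e-6, "xatol": 1e-5})
        reports.append({"start": s, "fun": float(res.fun),
                        "converged": bool(res.success),
                        "nit": int(res.nit)})
        if res.fun < 1e9 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"all starts failed: {reports}")
    model = unpack(best.x)
    lnl = -float(best.fun)
    n = len(tree)
    k = npar
    return BiogeoFit(model, use_j, use_distance, lnl, k, n,
                     aicc(lnl, k, n), reports)


def aicc(loglik: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion,
    AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n - k - 1 <= 0")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_compare(fits: Sequence[BiogeoFit], n: int | None = None,
                 none_threshold: float = 10.0) -> pd.DataFrame:
    """Rank fits by AICc; delta is relative to the best model.

    Support labels follow the conventional bands: delta <= 2 "substantial",
    4 <= delta <= 7 "considerably less", delta > ``none_threshold``
    "essentially none", with gaps labelled "intermediate".
    """
    rows = []
    for f in fits:
        nn = n if n is not None else f.n_tips
        rows.append((f.name, f.model.family, f.use_j, f.use_distance,
                     f.loglik, f.k, aicc(f.loglik, f.k, nn)))
    df = pd.DataFrame(rows, columns=["model", "family", "use_j",
                                     "use_distance", "loglik", "k", "aicc"])
    df = df.sort_values("aicc", kind="stable").reset_index(drop=True)
    df["delta"] = df["aicc"] - df["aicc"].iloc[0]

    def label(d: float) -> str:
        if d <= 2:
            return "substantial"
        if d > none_threshold:
            return "essentially none"
        if 4 <= d <= 7:
            return "considerably less"
        return "intermediate"

    df["support"] = df["delta"].map(label)
    return df


def ancestral_range_marginals(
    tree: Phylogeny, tip_ranges: Mapping, model: BiogeoModel,
    areas: AreaSystem, max_areas: int = 3,
) -> pd.DataFrame:
    """Marginal probability of each range at each internal node under
    ``model`` (typically the MLE), reported for the node state immediately
    before cladogenesis; the null range is excluded and rows renormalized.
    """
    ranges = _coerce_ranges(tip_ranges, areas)
    engine = _Engine(tree, ranges, areas, model.family, max_areas)
    marg = engine.marginals(model)
    rows = [
        (nid, areas.range_string(engine.states[i]), float(p))
        for nid, probs in marg.items()
        for i, p in enumerate(probs) if p > 0
    ]
    return pd.DataFrame(rows, columns=["node", "range", "probability"])
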