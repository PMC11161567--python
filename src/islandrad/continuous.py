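"""Continuous ecological preferences: two-sample tests and Brownian-motion
ancestral reconstruction.

``student_t_test`` is the classical pooled-variance unpaired Student's
t-test on occurrence-level value vectors (a Welch option exists for
robustness checks). ``bm_ancestral`` estimates ancestral trait values on a
rooted tree under Brownian motion by maximum likelihood, using a linear-time
up-down message-passing scheme; the estimates coincide with the
generalized-least-squares solution given the tip covariance implied by
shared path lengths, which serves as the independent oracle in the tests.
Tip values enter the reconstruction as one value per species (species means
of occurrence-level values, by convention); the t-tests, in contrast, use
the full occurrence-level vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trees import Node, Phylogeny, TreeError

__all__ = ["TTestResult", "student_t_test", "BMReconstruction", "bm_ancestral"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int
    significant: bool
    alpha: float = 0.05


def student_t_test(x, y, alpha: float = 0.05, welch: bool = False) -> TTestResult:
    """Unpaired two-sample t-test, two-sided.

    Pooled-variance (Student) form by default with df = n1 + n2 - 2;
    ``welch=True`` switches to the unequal-variance form with
    Welch-Satterthwaite df. Degenerate inputs: zero pooled variance with
    equal means gives t = 0, p = 1; with unequal means it is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    nx, ny = x.size, y.size
    mx, my = float(x.mean()), float(y.mean())
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    if welch:
        se2 = vx / nx + vy / ny
        if se2 == 0:
            if mx == my:
                return TTestResult(0.0, nx + ny - 2, 1.0, mx, my, nx, ny, False, alpha)
            raise ValueError("degenerate variance with unequal means")
        t = (mx - my) / math.sqrt(se2)
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        df = nx + ny - 2
        if sp2 == 0:
            if mx == my:
                return TTestResult(0.0, df, 1.0, mx, my, nx, ny, False, alpha)
            raise ValueError("degenerate variance with unequal means")
        t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = float(2 * stats.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, mx, my, nx, ny, p < alpha, alpha)


# ---------------------------------------------------------------------------
# Brownian-motion ancestral states
# ---------------------------------------------------------------------------

@dataclass
class BMReconstruction:
    """ML ancestral states under Brownian motion.

    ``estimates`` maps node id -> trait value (tips equal their observed
    values); ``variances`` maps node id -> estimation variance (sigma2-scaled
    conditional variance; 0 at tips); ``sigma2`` is the ML rate in
    trait^2 per unit branch length; ``root`` is the root estimate.
    """
    estimates: dict[str, float]
    variances: dict[str, float]
    sigma2: float
    root: float


def _combine(messages: list[tuple[float, float]]) -> tuple[float, float, float]:
    """Precision-weighted combination of Gaussian messages (mean, var);
    returns (mean, var, sum of squared standardized contrasts)."""
    m, v = messages[0]
    ss = 0.0
    for m2, v2 in messages[1:]:
        ss += (m - m2) ** 2 / (v + v2)
        prec = 1 / v + 1 / v2
        m = (m / v + m2 / v2) / prec
        v = 1 / prec
    return m, v, ss


def bm_ancestral(tree: Phylogeny, tip_values: dict[str, float]) -> BMReconstruction:
    """Maximum-likelihood Brownian-motion ancestral state reconstruction.

    One value per tip is required. The upward pass computes, for each node,
    the conditional Gaussian summary of its subtree (yielding the ML rate
    from the standardized contrasts, sigma2 = SS/n); the downward pass adds
    the complement of each subtree, so every internal estimate uses all tips.
    """
    tips = set(tree.tip_labels)
    vals = {k.strip().replace(" ", "_"): float(v) for k, v in tip_values.items()}
    missing = tips - set(vals)
    if missing:
        raise TreeError(f"missing tip values for: {sorted(missing)[:5]}")

    up: dict[int, tuple[float, float]] = {}  # node -> (mean, var at node)
    ss_total = 0.0
    for n in tree.postorder():
        if n.is_leaf:
            up[id(n)] = (vals[n.label], 0.0)
            continue
        msgs = []
        for c in n.children:
            if c.length is None:
                raise TreeError(f"missing branch length above node {c.id}")
            m, v = up[id(c)]
            msgs.append((m, v + c.length))
        try:
            m, v, ss = _combine(msgs)
        except ZeroDivisionError:
            raise TreeError(
                "zero-length sister branches with fixed tip values: "
                "ancestral state not identifiable") from None
        ss_total += ss
        up[id(n)] = (m, v)

    n_tips = len(tips)
    sigma2 = ss_total / n_tips  # ML convention (divide by n)

    # downward pass: message summarizing everything outside each node's subtree
    down: dict[int, tuple[float, float] | None] = {id(tree.root): None}
    estimates: dict[str, float] = {}
    variances: dict[str, float] = {}
    for n in tree.preorder():
        d = down[id(n)]
        if n.is_leaf:
            estimates[n.id] = vals[n.label]
            variances[n.id] = 0.0
        else:
            msgs = [(up[id(c)][0], up[id(c)][1] + c.length) for c in n.children]
            if d is not None:
                msgs.append(d)
            m, v, _ = _combine(msgs)
            estimates[n.id] = m
            variances[n.id] = sigma2 * v
        for c in n.children:
            others = [(up[id(s)][0], up[id(s)][1] + s.length)
                      for s in n.children if s is not c]
            if d is not None:
                others.append(d)
            m, v, _ = _combine(others)
            down[id(c)] = (m, v + c.length)

    return BMReconstruction(estimates, variances, sigma2, estimates[tree.root.id])
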