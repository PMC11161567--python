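"""Per-speciation-event transition assessment and the survey tally.

Each assessable speciation event — a sister-species pair, or a pair plus its
single closest relative — is scored for four transition flags:

* range: yes when the two sides' occupied-cell ranges classify as
  parapatric or allopatric (a sympatric pair shows no range difference; a
  fully disjoint pair a fortiori does);
* precipitation / elevation: yes when the unpaired Student's t-test between
  the two sides' pooled occurrence-level values is significant at alpha;
* substrate: yes when the union substrate sets of the two sides differ
  (one species on two substrates whose sister holds one substrate counts).

For pair-vs-relative events the pair's occurrences, cells and substrates
are pooled into one side. Missing data make the affected flag
"not-assessable" while the others are still computed. The tally
cross-classifies the reports the way the survey is normally summarized
(events with/without a range transition, each broken down by the ecological
transition combination), counting a transition shared by a pair node and
its enclosing pair-plus-relative node once, at the deeper node (the minimum
number of transitions needed to explain the data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .continuous import student_t_test
from .discrete import parse_tip_states
from .occurrences import TraitTable
from .overlap import OccupancyRange, classify_overlap, pooled_range
from .trees import Phylogeny, sister_pairs

__all__ = [
    "SpeciationEvent",
    "TransitionReport",
    "SurveyTally",
    "events_from_tree",
    "assess_event",
    "tally_survey",
]

YES, NO, NA = "yes", "no", "not-assessable"


@dataclass(frozen=True)
class SpeciationEvent:
    """An assessable node: a sister pair, or a pair vs its single closest
    relative (``parent_node_id`` links the latter to its pair node so the
    minimum-transition rule can deduplicate)."""
    node_id: str
    scope: str  # "pair" | "pair_vs_relative"
    side_a: tuple[str, ...]
    side_b: tuple[str, ...]
    pair_node_id: str | None = None  # for pair_vs_relative: the nested pair


def events_from_tree(tree: Phylogeny,
                     focal_clades: Sequence[Iterable[str]]) -> list[SpeciationEvent]:
    """Build the assessable event list: one event per focal sister pair and
    one per pair whose closest relative is a single tip."""
    events: list[SpeciationEvent] = []
    for clade in focal_clades:
        tips = set(clade)
        if len(tips) < 2:
            continue
        mrca = tree.mrca(tips)
        clade_nodes = {n.id for n in tree.internal_nodes(mrca)}
        for pair in sister_pairs(tree, tips):
            if pair.node_id not in clade_nodes:
                continue
            events.append(SpeciationEvent(pair.node_id, "pair",
                                          (pair.tip_a,), (pair.tip_b,)))
            if pair.relative_is_single:
                parent = tree.node(pair.node_id).parent
                if parent is not None and parent.id in clade_nodes:
                    events.append(SpeciationEvent(
                        parent.id, "pair_vs_relative",
                        (pair.tip_a, pair.tip_b), pair.relative_tips,
                        pair_node_id=pair.node_id))
    return events


@dataclass
class TransitionReport:
    event: SpeciationEvent
    flags: dict[str, str]  # range/precipitation/elevation/substrate -> yes|no|not-assessable
    overlap_class: str | None = None
    overlap_fractions: tuple[float, float] | None = None
    tests: dict[str, tuple[float, float, float]] = field(default_factory=dict)  # var -> (t, df, p)
    substrate_sets: tuple[frozenset[str], frozenset[str]] | None = None


def assess_event(
    event: SpeciationEvent,
    ranges: Mapping[str, OccupancyRange],
    traits: TraitTable,
    substrates: Mapping[str, Iterable[str] | str],
    alpha: float = 0.05,
    variables: tuple[str, ...] = ("precipitation", "elevation"),
) -> TransitionReport:
    """Score one event; each flag degrades independently to not-assessable
    when a member species lacks the required data."""
    import numpy as np

    report = TransitionReport(event, {})
    sides = (event.side_a, event.side_b)

    # range flag
    try:
        pooled = [pooled_range([ranges[sp] for sp in side], name="|".join(side))
                  for side in sides]
        ov = classify_overlap(pooled[0], pooled[1])
        report.overlap_class = ov.klass
        report.overlap_fractions = (ov.f_a, ov.f_b)
        report.flags["range"] = YES if ov.klass in ("parapatric", "allopatric") else NO
    except (KeyError, ValueError):
        report.flags["range"] = NA

    # continuous flags
    for var in variables:
        x = np.concatenate([traits.values(sp, var) for sp in event.side_a]) \
            if event.side_a else np.array([])
        y = np.concatenate([traits.values(sp, var) for sp in event.side_b]) \
            if event.side_b else np.array([])
        if x.size < 2 or y.size < 2:
            report.flags[var] = NA
            continue
        try:
            res = student_t_test(x, y, alpha=alpha)
        except ValueError:
            report.flags[var] = NA
            continue
        report.tests[var] = (res.t, res.df, res.p)
        report.flags[var] = YES if res.significant else NO

    # substrate flag
    try:
        obs = parse_tip_states({sp: substrates[sp]
                                for side in sides for sp in side})
        set_a = frozenset().union(*(obs[sp] for sp in event.side_a))
        set_b = frozenset().union(*(obs[sp] for sp in event.side_b))
        report.substrate_sets = (set_a, set_b)
        report.flags["substrate"] = YES if set_a != set_b else NO
    except (KeyError, ValueError):
        report.flags["substrate"] = NA

    return report


_ECO_CATEGORIES = [
    "none", "precipitation only", "elevation only", "substrate only",
    "precipitation+elevation", "all three", "other",
]


def _eco_category(flags: Mapping[str, str],
                  variables: tuple[str, ...] = ("precipitation", "elevation")) -> str:
    p = flags.get(variables[0]) == YES
    e = flags.get(variables[1]) == YES
    s = flags.get("substrate") == YES
    if not (p or e or s):
        return "none"
    if p and e and s:
        return "all three"
    if p and not e and not s:
        return "precipitation only"
    if e and not p and not s:
        return "elevation only"
    if s and not p and not e:
        return "substrate only"
    if p and e and not s:
        return "precipitation+elevation"
    return "other"


@dataclass
class SurveyTally:
    """Cross-classification of the transition reports.

    ``with_range`` / ``without_range`` map ecological-transition categories
    to counts within events that did / did not show a range transition;
    deep-node substrate calls are tallied separately.
    """
    n_assessed: int
    n_range: int
    n_no_range: int
    with_range: dict[str, int]
    without_range: dict[str, int]
    n_deep: int = 0
    n_deep_substrate: int = 0
    n_deep_uncertain: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("assessed", "", self.n_assessed),
                ("range transition", "", self.n_range)]
        rows += [("range transition", c, self.with_range.get(c, 0))
                 for c in _ECO_CATEGORIES]
        rows += [("no range transition", "", self.n_no_range)]
        rows += [("no range transition", c, self.without_range.get(c, 0))
                 for c in _ECO_CATEGORIES]
        rows += [("deep nodes", "", self.n_deep),
                 ("deep nodes", "substrate transition", self.n_deep_substrate),
                 ("deep nodes", "uncertain", self.n_deep_uncertain)]
        return pd.DataFrame(rows, columns=["group", "category", "count"])


def tally_survey(reports: Sequence[TransitionReport],
                 deep_calls: Mapping[str, str] | None = None) -> SurveyTally:
    """Tally the event reports (order-invariant pure function).

    Before counting, a transition flagged at both a pair node and its
    enclosing pair-plus-relative node is attributed to the deeper node only.
    """
    by_node = {r.event.node_id: r for r in reports}
    effective: dict[str, dict[str, str]] = {
        r.event.node_id: dict(r.flags) for r in reports
    }
    for r in reports:
        if r.event.scope != "pair_vs_relative" or r.event.pair_node_id is None:
            continue
        inner = by_node.get(r.event.pair_node_id)
        if inner is None:
            continue
        for var, val in r.flags.items():
            if val == YES and effective[inner.event.node_id].get(var) == YES:
                effective[inner.event.node_id][var] = NO

    with_range: dict[str, int] = {}
    without_range: dict[str, int] = {}
    n_range = n_no_range = 0
    for r in sorted(reports, key=lambda r: r.event.node_id):
        flags = effective[r.event.node_id]
        cat = _eco_category(flags)
        if flags.get("range") == YES:
            n_range += 1
            with_range[cat] = with_range.get(cat, 0) + 1
        else:
            n_no_range += 1
            without_range[cat] = without_range.get(cat, 0) + 1

    tally = SurveyTally(len(reports), n_range, n_no_range,
                        with_range, without_range)
    if deep_calls:
        tally.n_deep = len(deep_calls)
        tally.n_deep_substrate = sum(1 for v in deep_calls.values()
                                     if v == "transition")
        tally.n_deep_uncertain = sum(1 for v in deep_calls.values()
                                     if v == "uncertain")
    return tally
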