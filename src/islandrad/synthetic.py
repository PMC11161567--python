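"""Ground-truth generators: trees, traits, character histories, range
histories, occurrence clouds and rasters, plus planted-defect records and a
fully specified planted survey scenario.

Every generator is a pure function of its parameters and a seed; a single
scenario seed derives per-component seeds by fixed offsets so regenerating
one layer never perturbs another. The generators exist so that every
inference stage of the package can be tested against a recorded truth:
simulated histories are retained (node states, per-branch events, defect
ledgers), and small-fixture simulators are cross-validated against the
corresponding likelihood modules in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biogeo import (AreaSystem, BiogeoModel, anagenetic_Q, build_state_space,
                     cladogenesis_table, dispersal_multipliers)
from .discrete import MkModel
from .occurrences import RasterGrid
from .trees import Node, Phylogeny, prune_to_taxa, read_tree

__all__ = [
    "sim_tree",
    "yule_tip_count",
    "sim_bm",
    "sim_mk",
    "MkSimulation",
    "sim_ranges",
    "RangeSimulation",
    "sim_occurrences",
    "gradient_raster",
    "planted_survey_scenario",
    "PlantedSurveyScenario",
]


# ---------------------------------------------------------------------------
# Birth-death trees
# ---------------------------------------------------------------------------

def sim_tree(n_tips: int, birth_rate: float, death_rate: float = 0.0,
             seed: int | None = None, max_tries: int = 1000) -> Phylogeny:
    """Forward (Gillespie) birth-death simulation from a crown split,
    conditioned on ``n_tips`` surviving lineages by rejection.

    The simulation stops when the ``n_tips``-th extant lineage appears and
    the present is placed at the moment the next event would have happened,
    so terminal branches have strictly positive length and the tree is
    ultrametric. Raises after ``max_tries`` failed attempts (all lineages
    extinct), which indicates death close to or above birth.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = np.random.default_rng(seed)
    total_rate = birth_rate + death_rate

    for _ in range(max_tries):
        root = Node()
        a, b = Node(), Node()
        root.add_child(a)
        root.add_child(b)
        birth_time = {id(a): 0.0, id(b): 0.0}
        active = [a, b]
        t = 0.0
        failed = False
        while len(active) < n_tips:
            if not active:
                failed = True
                break
            t += rng.exponential(1.0 / (len(active) * total_rate))
            i = rng.integers(len(active))
            lineage = active.pop(i)
            lineage.length = t - birth_time[id(lineage)]
            if rng.uniform() < birth_rate / total_rate:
                for _ in range(2):
                    c = lineage.add_child(Node())
                    birth_time[id(c)] = t
                    active.append(c)
            # else extinction: lineage simply leaves the active set
        if failed or len(active) < 2:
            continue
        # present = moment the next event would have occurred
        present = t + rng.exponential(1.0 / (len(active) * total_rate))
        for n in active:
            n.length = present - birth_time[id(n)]
        survivors = []
        counter = {"live": 0, "dead": 0}

        def label_leaves(node: Node) -> None:
            if not node.children:
                if node in active_set:
                    counter["live"] += 1
                    node.label = f"t{counter['live']}"
                    survivors.append(node.label)
                else:
                    counter["dead"] += 1
                    node.label = f"x{counter['dead']}"
                return
            for c in node.children:
                label_leaves(c)

        active_set = set(active)
        label_leaves(root)
        full = Phylogeny(root)
        return prune_to_taxa(full, survivors)
    raise RuntimeError(
        f"no surviving tree in {max_tries} tries; lower the death rate")


def yule_tip_count(birth_rate: float, t_stop: float,
                   seed: int | None = None) -> int:
    """Number of lineages of a pure-birth process (starting from one
    lineage) at time ``t_stop``; E[N] = exp(birth_rate * t)."""
    rng = np.random.default_rng(seed)
    n, t = 1, 0.0
    while True:
        t += rng.exponential(1.0 / (n * birth_rate))
        if t > t_stop:
            return n
        n += 1


# ---------------------------------------------------------------------------
# Continuous and discrete character evolution
# ---------------------------------------------------------------------------

def sim_bm(tree: Phylogeny, root_value: float, sigma2: float,
           seed: int | None = None) -> dict[str, float]:
    """Brownian evolution: Gaussian increments with variance
    sigma2 x branch length; returns values for every node id (tips and
    internal), the internal ones being the retained truth."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    for n in tree.preorder():
        if n.parent is None:
            values[n.id] = root_value
        else:
            sd = np.sqrt(sigma2 * n.length)
            values[n.id] = values[n.parent.id] + sd * rng.normal()
    return values


@dataclass
class MkSimulation:
    tip_states: dict[str, str]
    node_states: dict[str, str]
    branch_events: dict[str, list[tuple[float, str, str]]]  # node id -> events above it

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.branch_events.values())


def sim_mk(tree: Phylogeny, model: MkModel, seed: int | None = None) -> MkSimulation:
    """Gillespie simulation of the equal-rates chain along every branch:
    Exp(mu) waiting times, uniform jumps to one of the other states; the
    full per-branch history is recorded."""
    rng = np.random.default_rng(seed)
    states = model.states
    node_states: dict[str, str] = {}
    events: dict[str, list[tuple[float, str, str]]] = {}
    for n in tree.preorder():
        if n.parent is None:
            node_states[n.id] = states[rng.integers(len(states))] \
                if model.root_prior is None else \
                rng.choice(states, p=model.root_prior)
            continue
        state = node_states[n.parent.id]
        t, evs = 0.0, []
        while True:
            t += rng.exponential(1.0 / model.mu)
            if t >= n.length:
                break
            new = [s for s in states if s != state][rng.integers(len(states) - 1)]
            evs.append((t, state, new))
            state = new
        node_states[n.id] = state
        events[n.id] = evs
    tips = {n.label: node_states[n.id] for n in tree.leaves()}
    return MkSimulation(tips, node_states, events)


@dataclass
class RangeSimulation:
    tip_ranges: dict[str, tuple[int, ...]]
    node_ranges: dict[str, tuple[int, ...]]
    event_log: list[tuple[str, str, str, str]]  # (node id, kind, from, to)


def sim_ranges(tree: Phylogeny, model: BiogeoModel, areas: AreaSystem,
               root_range: Sequence[str] | Sequence[int],
               seed: int | None = None, max_areas: int = 3,
               max_tries: int = 50) -> RangeSimulation:
    """Simulate range evolution: Gillespie anagenesis along branches under
    the model's dispersal/extirpation rates, cladogenetic draws from the
    family's event table at nodes. A lineage reaching the null range is
    extinct in place; scenarios where any tip ends null are degenerate and
    regenerated up to ``max_tries`` times."""
    states = build_state_space(areas.n, max_areas)
    index = {s: i for i, s in enumerate(states)}
    mult = dispersal_multipliers(areas, model.x)
    q = anagenetic_Q(states, model.d, model.e, mult, max_areas)
    table = cladogenesis_table(states, model.family, model.j, areas.n)
    if root_range and all(isinstance(x, str) for x in root_range):
        root_state = areas.range_from_labels(root_range)
    else:
        root_state = tuple(sorted(int(x) for x in root_range))
    rng_master = np.random.default_rng(seed)

    for _ in range(max_tries):
        rng = np.random.default_rng(rng_master.integers(2**31 - 1))
        node_ranges: dict[str, tuple[int, ...]] = {}
        log: list[tuple[str, str, str, str]] = []

        def along_branch(start: int, length: float, node_id: str) -> int:
            i, t = start, 0.0
            while True:
                rate = -q[i, i]
                if rate <= 0:
                    return i  # null range or frozen dynamics
                t += rng.exponential(1.0 / rate)
                if t >= length:
                    return i
                rates = q[i].copy()
                rates[i] = 0.0
                j = rng.choice(len(states), p=rates / rates.sum())
                log.append((node_id, "anagenetic",
                            areas.range_string(states[i]),
                            areas.range_string(states[j])))
                i = j

        stack = [(tree.root, index[root_state])]
        while stack:
            node, state_i = stack.pop()
            node_ranges[node.id] = states[state_i]
            if node.is_leaf:
                continue
            if states[state_i]:
                outcomes = table[state_i]
                w = np.array([o[2] for o in outcomes])
                li, ri, _ = outcomes[rng.choice(len(outcomes), p=w / w.sum())]
            else:
                li = ri = state_i  # extinct lineage stays null
            for child, ci in zip(node.children, (li, ri)):
                if ci != state_i:
                    log.append((child.id, "cladogenetic",
                                areas.range_string(states[state_i]),
                                areas.range_string(states[ci])))
                end = along_branch(ci, child.length, child.id)
                stack.append((child, end))

        tips = {n.label: node_ranges[n.id] for n in tree.leaves()}
        if all(tips.values()):
            return RangeSimulation(tips, node_ranges, log)
    raise RuntimeError("degenerate range scenario (null-range tips) in every try; "
                       "lower the extirpation rate")


# ---------------------------------------------------------------------------
# Rasters and occurrence clouds
# ---------------------------------------------------------------------------

def gradient_raster(ncols: int, nrows: int, origin=(0.0, 0.0),
                    cell: float = 0.01, base: float = 0.0,
                    col_slope: float = 0.0, row_slope: float = 0.0,
                    noise_sd: float = 0.0, seed: int | None = None) -> RasterGrid:
    """Smooth planar gradient (value = base + col_slope*col + row_slope*row)
    with optional seeded Gaussian noise: per-cell values are analytically
    known, which makes extraction exactly checkable."""
    cols, rows = np.meshgrid(np.arange(ncols), np.arange(nrows))
    values = base + col_slope * cols + row_slope * rows
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0, noise_sd, values.shape)
    return RasterGrid(origin, cell, values)


DEFECT_CLASSES = ("zero-coordinate", "pre-1945", "uncertainty", "duplicate")


def sim_occurrences(
    blobs: Mapping[str, tuple[float, float, float]],
    n_per_species: int = 50,
    defect_counts: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Occurrence clouds from per-species Gaussian blobs (lon centre, lat
    centre, sd in degrees), with defective records planted at stated counts.

    Clean records carry year 2000-2019 and uncertainty 10-50 m. Planted
    defects are appended copies of clean records with one defect each: a
    zero coordinate, a pre-1945 collection year, a coordinate uncertainty
    just above 100 km, or an exact coordinate duplicate. The returned ledger
    holds the exact planted count per class for filter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sp, (cx, cy, sd) in sorted(blobs.items()):
        lon = cx + sd * rng.normal(size=n_per_species)
        lat = cy + sd * rng.normal(size=n_per_species)
        for x, y in zip(lon, lat):
            rows.append((sp, x, y, 2000 + int(rng.integers(20)),
                         10 + 40 * rng.uniform(), "synthetic-clean"))
    df = pd.DataFrame(rows, columns=["species", "lon", "lat", "year",
                                     "uncertainty_m", "source"])
    ledger = {c: 0 for c in DEFECT_CLASSES}
    if defect_counts:
        bad_rows = []
        for cls, count in defect_counts.items():
            if cls not in DEFECT_CLASSES:
                raise ValueError(f"unknown defect class {cls!r}")
            ledger[cls] = int(count)
            for _ in range(int(count)):
                base = df.iloc[int(rng.integers(len(df)))].copy()
                base["source"] = f"synthetic-{cls}"
                if cls == "zero-coordinate":
                    base["lon" if rng.uniform() < 0.5 else "lat"] = 0.0
                    # give the zeroed record fresh other coordinate so it is
                    # not also an exact duplicate
                    base["year"] = 2001
                elif cls == "pre-1945":
                    base["year"] = int(1900 + rng.integers(45))
                    base["lon"] = base["lon"] + 1e-6 * (1 + rng.integers(100))
                elif cls == "uncertainty":
                    base["uncertainty_m"] = 100_001.0 + float(rng.integers(10_000))
                    base["lon"] = base["lon"] + 1e-6 * (1 + rng.integers(100))
                # duplicate: an exact copy, nothing changed
                bad_rows.append(base)
        df = pd.concat([df, pd.DataFrame(bad_rows)], ignore_index=True)
    return df, ledger


# ---------------------------------------------------------------------------
# The planted survey scenario
# ---------------------------------------------------------------------------

@dataclass
class PlantedSurveyScenario:
    """A deterministic end-to-end fixture with hand-planted transitions.

    Ten species in two focal clades occupy rectangular cell blocks on two
    orthogonal-gradient rasters (precipitation varies west-east only,
    elevation north-south only), so range overlap, both t-tests and the
    substrate comparison have exactly known outcomes for every event. The
    ``expected_flags`` holds the hand-derived raw transition table per
    event; ``expected_tally`` additionally applies the minimum-transition
    deduplication rule, as the tally does.
    """
    tree: Phylogeny
    focal_clades: list[tuple[str, ...]]
    records: pd.DataFrame
    rasters: dict[str, RasterGrid]
    substrates: dict[str, str]
    cell_size: float
    expected_flags: dict[frozenset, dict[str, str]]
    expected_tally: dict = field(default_factory=dict)


def _block_records(species: str, cols: range, rows: range,
                   cell: float) -> list[tuple]:
    out = []
    for c in cols:
        for r in rows:
            lon = (c + 0.5) * cell
            lat = -(r + 0.5) * cell
            out.append((species, lon, lat, 2005, 25.0, "synthetic-planted"))
    return out


def planted_survey_scenario(seed: int = 0) -> PlantedSurveyScenario:
    """Build the planted fixture (deterministic; seed kept for interface
    symmetry with the other generators)."""
    cell = 0.01
    newick = ("((((s1:1,s2:1):1,s3:2):1,((s4:1,s5:1):1,s6:2):1):2,"
              "((s7:2,s8:2):2,(s9:2,s10:2):2):2);")
    tree = read_tree(newick)
    clade1 = ("s1", "s2", "s3", "s4", "s5", "s6")
    clade2 = ("s7", "s8", "s9", "s10")

    blocks = {
        "s1": (range(0, 10), range(0, 10)),
        "s2": (range(0, 10), range(0, 10)),      # identical to s1
        "s3": (range(60, 70), range(0, 10)),     # far east: precip shift
        "s4": (range(0, 10), range(20, 30)),
        "s5": (range(0, 10), range(60, 70)),     # far south: elevation shift
        "s6": (range(0, 10), range(20, 30)),     # inside s4+s5 union
        "s7": (range(30, 40), range(0, 10)),
        "s8": (range(30, 45), range(0, 10)),     # contains s7: sympatric
        "s9": (range(80, 90), range(50, 60)),
        "s10": (range(80, 90), range(50, 60)),   # identical to s9
    }
    rows: list[tuple] = []
    for sp, (cols, rws) in blocks.items():
        rows.extend(_block_records(sp, cols, rws, cell))
    records = pd.DataFrame(rows, columns=["species", "lon", "lat", "year",
                                          "uncertainty_m", "source"])

    rasters = {
        # mm/yr, west-east gradient only
        "precipitation": gradient_raster(100, 80, cell=cell, base=800.0,
                                         col_slope=20.0),
        # metres, north-south gradient only
        "elevation": gradient_raster(100, 80, cell=cell, base=100.0,
                                     row_slope=10.0),
    }
    substrates = {
        "s1": "ultramafic", "s2": "ultramafic", "s3": "ultramafic",
        "s4": "ultramafic", "s5": "ultramafic",
        "s6": "ultramafic|schistose",
        "s7": "schistose", "s8": "schistose",
        "s9": "limestone", "s10": "ultramafic",
    }

    # hand-derived planted outcomes per event (after deduplication)
    expected_flags = {
        frozenset({("s1",), ("s2",)}): dict(range="no", precipitation="no",
                                            elevation="no", substrate="no"),
        frozenset({("s1", "s2"), ("s3",)}): dict(range="yes",
                                                 precipitation="yes",
                                                 elevation="no",
                                                 substrate="no"),
        # raw flags: the s4/s5 elevation difference is real but is
        # attributed to the deeper (pair + relative) node in the tally by
        # the minimum-transition rule
        frozenset({("s4",), ("s5",)}): dict(range="yes", precipitation="no",
                                            elevation="yes", substrate="no"),
        frozenset({("s4", "s5"), ("s6",)}): dict(range="no",
                                                 precipitation="no",
                                                 elevation="yes",
                                                 substrate="yes"),
        frozenset({("s7",), ("s8",)}): dict(range="no", precipitation="yes",
                                            elevation="no", substrate="no"),
        frozenset({("s9",), ("s10",)}): dict(range="no", precipitation="no",
                                             elevation="no", substrate="yes"),
    }
    expected_tally = {
        "n_assessed": 6,
        "n_range": 2,
        "with_range": {"precipitation only": 1, "none": 1},
        "without_range": {"none": 1, "other": 1, "precipitation only": 1,
                          "substrate only": 1},
        "n_deep": 2,
    }
    return PlantedSurveyScenario(tree, [clade1, clade2], records, rasters,
                                 substrates, cell, expected_flags,
                                 expected_tally)
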