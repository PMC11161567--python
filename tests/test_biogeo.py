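"""Range state space, rate matrices, cladogenesis tables, likelihood,
fitting and AICc comparison."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from islandrad import (
    AreaSystem,
    BiogeoModel,
    aicc,
    aicc_compare,
    anagenetic_Q,
    ancestral_range_marginals,
    biogeo_loglik,
    build_state_space,
    cladogenesis_table,
    dispersal_multipliers,
    fit_biogeo,
    read_tree,
)
from islandrad.biogeo import BiogeoFit
from islandrad.synthetic import sim_ranges


class TestStateSpace:
    def test_two_areas(self):
        assert build_state_space(2, 2) == [(), (0,), (1,), (0, 1)]

    def test_eleven_areas_max_three(self):
        states = build_state_space(11, 3)
        assert len(states) == 232  # 1 + 11 + 55 + 165

    def test_three_areas_max_one(self):
        assert len(build_state_space(3, 1)) == 4

    def test_ordering_null_first_then_cardinality(self):
        states = build_state_space(3, 3)
        sizes = [len(s) for s in states]
        assert sizes == sorted(sizes)
        assert states[0] == ()


class TestDispersalMultipliers:
    def test_x_zero_gives_ones(self, five_area_system):
        assert np.all(dispersal_multipliers(five_area_system, 0.0) == 1.0)

    def test_mean_distance_is_normalization_point(self):
        areas = AreaSystem(("A", "B", "C"),
                           np.array([[0, 250, 250], [250, 0, 250],
                                     [250, 250, 0]], float))
        m = dispersal_multipliers(areas, -2.3)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(m[off], 1.0)

    def test_direct_evaluation(self):
        areas = AreaSystem(("A", "B", "C"),
                           np.array([[0, 100, 400], [100, 0, 250],
                                     [400, 250, 0]], float))
        m = dispersal_multipliers(areas, -1.0)
        assert m[0, 1] == pytest.approx(2.5)    # (100/250)^-1
        assert m[0, 2] == pytest.approx(0.625)  # (400/250)^-1
        assert np.allclose(m, m.T)


class TestAnageneticQ:
    def test_rows_sum_to_zero_on_random_draws(self, rng):
        states = build_state_space(4, 3)
        for _ in range(5):
            m = np.exp(rng.normal(size=(4, 4)))
            m = (m + m.T) / 2
            q = anagenetic_Q(states, rng.uniform(0, 1), rng.uniform(0, 1), m, 3)
            assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_two_area_rates_by_construction(self):
        states = build_state_space(2, 2)
        q = anagenetic_Q(states, d=0.7, e=0.2, multipliers=np.ones((2, 2)),
                         max_areas=2)
        i = {s: k for k, s in enumerate(states)}
        assert q[i[(0,)], i[(0, 1)]] == pytest.approx(0.7)
        assert q[i[(0, 1)], i[(0,)]] == pytest.approx(0.2)
        assert q[i[(0,)], i[()]] == pytest.approx(0.2)  # singleton decay
        assert np.all(q[i[()]] == 0.0)  # null absorbing

    def test_three_area_hand_assembled_oracle(self):
        # unequal multipliers: every nonzero entry checked against a
        # hand-built table
        states = build_state_space(3, 2)
        m = np.array([[0, 2.0, 0.5], [2.0, 0, 1.0], [0.5, 1.0, 0]])
        d, e = 0.3, 0.1
        q = anagenetic_Q(states, d, e, m, 2)
        i = {s: k for k, s in enumerate(states)}
        expected = {
            ((0,), (0, 1)): d * 2.0, ((0,), (0, 2)): d * 0.5,
            ((1,), (0, 1)): d * 2.0, ((1,), (1, 2)): d * 1.0,
            ((2,), (0, 2)): d * 0.5, ((2,), (1, 2)): d * 1.0,
            ((0,), ()): e, ((1,), ()): e, ((2,), ()): e,
            ((0, 1), (0,)): e, ((0, 1), (1,)): e,
            ((0, 2), (0,)): e, ((0, 2), (2,)): e,
            ((1, 2), (1,)): e, ((1, 2), (2,)): e,
        }
        for a in states:
            for b in states:
                if a == b:
                    continue
                assert q[i[a], i[b]] == pytest.approx(expected.get((a, b), 0.0))

    def test_propagator_rows_sum_to_one(self, rng):
        states = build_state_space(4, 3)
        m = np.ones((4, 4))
        q = anagenetic_Q(states, 0.4, 0.1, m, 3)
        for t in rng.uniform(0.1, 5.0, size=3):
            p = expm(q * t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)


class TestCladogenesis:
    def test_singleton_dec_identical_inheritance(self):
        states = build_state_space(2, 2)
        table = cladogenesis_table(states, "DEC", 0.0, 2)
        i = {s: k for k, s in enumerate(states)}
        outcomes = table[i[(0,)]]
        assert outcomes == [(i[(0,)], i[(0,)], 1.0)]

    def test_bayarealike_widespread_no_change(self):
        states = build_state_space(2, 2)
        table = cladogenesis_table(states, "BAYAREALIKE", 0.0, 2)
        i = {s: k for k, s in enumerate(states)}
        assert table[i[(0, 1)]] == [(i[(0, 1)], i[(0, 1)], 1.0)]

    def test_dec_widespread_six_outcomes_each_sixth(self):
        states = build_state_space(2, 2)
        table = cladogenesis_table(states, "DEC", 0.0, 2)
        i = {s: k for k, s in enumerate(states)}
        outcomes = table[i[(0, 1)]]
        assert len(outcomes) == 6
        assert all(w == pytest.approx(1 / 6) for _, _, w in outcomes)
        got = {(l, r) for l, r, _ in outcomes}
        A, B, AB = i[(0,)], i[(1,)], i[(0, 1)]
        assert got == {(AB, A), (AB, B), (A, AB), (B, AB), (A, B), (B, A)}

    def test_weights_sum_to_one_per_parent(self):
        states = build_state_space(4, 3)
        for family in ("DEC", "DIVALIKE", "BAYAREALIKE"):
            for j in (0.0, 0.3):
                table = cladogenesis_table(states, family, j, 4)
                for parent, outcomes in table.items():
                    assert sum(w for _, _, w in outcomes) == pytest.approx(1.0)

    def test_divalike_allows_widespread_vicariance_but_no_subset(self):
        states = build_state_space(4, 3)
        table = cladogenesis_table(states, "DIVALIKE", 0.0, 4)
        i = {s: k for k, s in enumerate(states)}
        parent = i[(0, 1, 2)]
        pairs = {(states[l], states[r]) for l, r, _ in table[parent]}
        assert ((0,), (1, 2)) in pairs          # vicariance
        assert ((0, 1), (2,)) in pairs
        assert ((0,), (0, 1, 2)) not in pairs   # no subset sympatry
        assert ((0, 1, 2), (0, 1, 2)) not in pairs


class TestLoglik:
    def test_frozen_dynamics_equal_root_prior(self, two_area_system, random_tree):
        t = random_tree(5, seed=51)
        model = BiogeoModel("DEC", d=0.0, e=0.0, j=0.0)
        tips = {l: ("A",) for l in t.tip_labels}
        ll = biogeo_loglik(t, tips, model, two_area_system, max_areas=2)
        assert ll == pytest.approx(math.log(1 / 3), abs=1e-10)

    def test_matches_runge_kutta_ode_oracle(self, two_area_system):
        # independent oracle: integrate the branch ODE m' = Q m by RK4 and
        # assemble the 2-tip likelihood by hand
        tree = read_tree("(A:0.8,B:1.3);")
        model = BiogeoModel("DEC", d=0.23, e=0.11)
        states = build_state_space(2, 2)
        q = anagenetic_Q(states, model.d, model.e, np.ones((2, 2)), 2)

        def rk4(vec, length, h=1e-4):
            n = int(round(length / h))
            for _ in range(n):
                k1 = q @ vec
                k2 = q @ (vec + h / 2 * k1)
                k3 = q @ (vec + h / 2 * k2)
                k4 = q @ (vec + h * k3)
                vec = vec + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            return vec

        i = {s: k for k, s in enumerate(states)}
        part_a = np.zeros(4); part_a[i[(0,)]] = 1.0   # tip A observed {A}
        part_b = np.zeros(4); part_b[i[(1,)]] = 1.0   # tip B observed {B}
        ma = rk4(part_a, 0.8)
        mb = rk4(part_b, 1.3)
        # root cladogenesis by hand: singletons copy; {AB} splits 6 ways
        A, B, AB = i[(0,)], i[(1,)], i[(0, 1)]
        up = np.zeros(4)
        up[A] = ma[A] * mb[A]
        up[B] = ma[B] * mb[B]
        up[AB] = sum(ma[l] * mb[r] / 6
                     for l, r in [(AB, A), (AB, B), (A, AB), (B, AB),
                                  (A, B), (B, A)])
        expected = math.log((up[A] + up[B] + up[AB]) / 3)
        ll = biogeo_loglik(tree, {"A": ("A",), "B": ("B",)}, model,
                           two_area_system, max_areas=2)
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_invariant_under_area_relabelling(self, random_tree):
        t = random_tree(6, seed=55)
        dist = np.array([[0, 200, 700], [200, 0, 450], [700, 450, 0]], float)
        areas = AreaSystem(("A", "B", "C"), dist)
        model = BiogeoModel("DEC", d=0.2, e=0.05, x=-1.0)
        sim = sim_ranges(t, model, areas, ("A",), seed=56, max_areas=2)
        ll = biogeo_loglik(t, sim.tip_ranges, model, areas, max_areas=2)
        perm = [2, 0, 1]
        areas2 = AreaSystem(("C", "A", "B"), dist[np.ix_(perm, perm)])
        relabel = {0: 1, 1: 2, 2: 0}  # old index -> new index
        tips2 = {sp: tuple(sorted(relabel[a] for a in r))
                 for sp, r in sim.tip_ranges.items()}
        ll2 = biogeo_loglik(t, tips2, model, areas2, max_areas=2)
        assert ll == pytest.approx(ll2, abs=1e-9)

    def test_plus_j_converges_to_no_j(self, two_area_system, random_tree):
        t = random_tree(6, seed=57)
        tips = {l: ("A",) if i % 2 else ("B",)
                for i, l in enumerate(t.tip_labels)}
        base = BiogeoModel("DEC", d=0.15, e=0.02, j=0.0)
        tiny = BiogeoModel("DEC", d=0.15, e=0.02, j=1e-10)
        ll0 = biogeo_loglik(t, tips, base, two_area_system, max_areas=2)
        ll1 = biogeo_loglik(t, tips, tiny, two_area_system, max_areas=2)
        assert abs(ll1 - ll0) < 1e-6

    def test_unreachable_tip_state_cannot_raise_likelihood(self, two_area_system):
        t = read_tree("((A:1,B:1):1,C:2);")
        model = BiogeoModel("DEC", d=0.0, e=0.0)
        match = biogeo_loglik(t, {"A": ("A",), "B": ("A",), "C": ("A",)},
                              model, two_area_system, max_areas=2)
        mismatch = biogeo_loglik(t, {"A": ("A",), "B": ("B",), "C": ("A",)},
                                 model, two_area_system, max_areas=2)
        assert mismatch == -np.inf or mismatch < match


class TestFitAndCompare:
    def test_same_seed_identical_fit(self, two_area_system, random_tree):
        t = random_tree(8, seed=61)
        model = BiogeoModel("DEC", d=0.3, e=0.05)
        sim = sim_ranges(t, model, two_area_system, ("A",), seed=62, max_areas=2)
        f1 = fit_biogeo(t, sim.tip_ranges, two_area_system, "DEC", starts=2,
                        seed=7, max_areas=2)
        f2 = fit_biogeo(t, sim.tip_ranges, two_area_system, "DEC", starts=2,
                        seed=7, max_areas=2)
        assert f1.model == f2.model and f1.loglik == f2.loglik

    def test_generating_family_fits_vicariant_data_better(self, five_area_system):
        # data with strong vicariant signal: BAYAREALIKE cannot split ranges
        # at nodes, so DIVALIKE should reach at least its likelihood
        from islandrad.synthetic import sim_tree
        diffs = []
        for rep in range(4):
            t = sim_tree(25, 0.3, 0.0, seed=800 + rep)
            truth = BiogeoModel("DIVALIKE", d=0.05, e=0.005)
            sim = sim_ranges(t, truth, five_area_system, ("A", "B", "C"),
                             seed=900 + rep, max_areas=3)
            fd = fit_biogeo(t, sim.tip_ranges, five_area_system, "DIVALIKE",
                            starts=2, seed=rep, max_areas=3)
            fb = fit_biogeo(t, sim.tip_ranges, five_area_system, "BAYAREALIKE",
                            starts=2, seed=rep, max_areas=3)
            diffs.append(fd.loglik - fb.loglik)
        assert np.mean(diffs) >= 0

    def test_aicc_closed_form(self):
        assert aicc(-100.0, 3, 20) == pytest.approx(207.5)

    def test_aicc_undefined_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(-10.0, 5, 6)

    def test_aicc_increases_with_k_at_fixed_loglik(self):
        values = [aicc(-50.0, k, 30) for k in range(1, 6)]
        assert values == sorted(values)

    def test_compare_equal_fits_share_zero_delta(self):
        m = BiogeoModel("DEC", 0.1, 0.1)
        f1 = BiogeoFit(m, False, False, -80.0, 2, 30, aicc(-80.0, 2, 30))
        f2 = BiogeoFit(m, False, False, -80.0, 2, 30, aicc(-80.0, 2, 30))
        df = aicc_compare([f1, f2], n=30)
        assert list(df["delta"]) == [0.0, 0.0]
        assert set(df["support"]) == {"substantial"}


class TestMarginals:
    def test_frozen_dynamics_certain_state(self, two_area_system, random_tree):
        t = random_tree(5, seed=71)
        model = BiogeoModel("DEC", d=0.0, e=0.0)
        tips = {l: ("A",) for l in t.tip_labels}
        df = ancestral_range_marginals(t, tips, model, two_area_system, 2)
        top = df[df["probability"] > 0.999]
        assert set(top["range"]) == {"A"}
        assert len(top) == len(t.internal_nodes())

    def test_rows_sum_to_one(self, five_area_system, random_tree):
        t = random_tree(8, seed=73)
        model = BiogeoModel("DEC", d=0.2, e=0.05)
        sim = sim_ranges(t, model, five_area_system, ("A",), seed=74)
        df = ancestral_range_marginals(t, sim.tip_ranges, model,
                                       five_area_system)
        sums = df.groupby("node")["probability"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_matches_enumeration_oracle_three_tips(self, two_area_system):
        tree = read_tree("((A:0.5,B:0.7):0.4,C:0.9);")
        model = BiogeoModel("DEC", d=0.3, e=0.08)
        states = build_state_space(2, 2)
        q = anagenetic_Q(states, model.d, model.e, np.ones((2, 2)), 2)
        table = cladogenesis_table(states, "DEC", 0.0, 2)
        obs = {"A": (0,), "B": (1,), "C": (0,)}
        i = {s: k for k, s in enumerate(states)}
        pm = {t: expm(q * t) for t in (0.5, 0.7, 0.4, 0.9)}
        prior = np.array([0, 1 / 3, 1 / 3, 1 / 3])
        # enumerate (root state, root outcome, inner-node state, inner outcome)
        root_m = np.zeros(4)
        inner_m = np.zeros(4)
        for s_root in range(4):
            for l, r, w in table.get(s_root, []):
                for s_in in range(4):  # inner node state after branch 0.4
                    p_branch = pm[0.4][l, s_in]
                    p_c = pm[0.9][r, i[obs["C"]]]
                    for l2, r2, w2 in table.get(s_in, []):
                        p_ab = (pm[0.5][l2, i[obs["A"]]]
                                * pm[0.7][r2, i[obs["B"]]])
                        contrib = prior[s_root] * w * p_branch * p_c * w2 * p_ab
                        root_m[s_root] += contrib
                        inner_m[s_in] += contrib
        root_m /= root_m.sum()
        inner_m /= inner_m.sum()
        df = ancestral_range_marginals(tree, {"A": ("A",), "B": ("B",),
                                              "C": ("A",)},
                                       model, two_area_system, 2)
        inner_id = tree.mrca(["A", "B"]).id
        root_id = tree.root.id
        for nid, oracle in ((root_id, root_m), (inner_id, inner_m)):
            got = dict(zip(df[df["node"] == nid]["range"],
                           df[df["node"] == nid]["probability"]))
            labels = {1: "A", 2: "B", 3: "AB"}
            for k, lab in labels.items():
                assert got.get(lab, 0.0) == pytest.approx(oracle[k], abs=1e-9)


class TestTwelveModelGrid:
    def test_grid_runs_end_to_end_within_budget(self, five_area_system,
                                                random_tree):
        # 3 families x (+/-)J x (+/-)distance on a simulated 40-tip,
        # 5-area dataset, compared by AICc
        import time
        from islandrad import fit_biogeo, aicc_compare
        from islandrad.synthetic import sim_ranges, sim_tree

        t0 = time.time()
        tree = sim_tree(40, 0.3, 0.0, seed=777)
        truth = BiogeoModel("DEC", d=0.08, e=0.01)
        sim = sim_ranges(tree, truth, five_area_system, ("A",), seed=778)
        fits = []
        for family in ("DEC", "DIVALIKE", "BAYAREALIKE"):
            for use_j in (False, True):
                for use_x in (False, True):
                    fits.append(fit_biogeo(
                        tree, sim.tip_ranges, five_area_system, family,
                        use_j=use_j, use_distance=use_x, starts=2,
                        seed=len(fits), maxiter=150))
        table = aicc_compare(fits, n=40)
        assert len(table) == 12
        assert table["delta"].iloc[0] == 0.0
        assert table["aicc"].is_monotonic_increasing
        assert time.time() - t0 < 600  # well inside the runtime budget


class TestRangeTableIO:
    def test_presence_absence_roundtrip(self, tmp_path, five_area_system):
        import pandas as pd
        from islandrad.biogeo import read_range_table
        path = tmp_path / "ranges.csv"
        pd.DataFrame([["sp1", 1, 0, 1, 0, 0], ["sp2", 0, 0, 0, 0, 1]],
                     columns=["species", *five_area_system.labels]).to_csv(
            path, index=False)
        ranges = read_range_table(path, five_area_system)
        assert ranges == {"sp1": ("A", "C"), "sp2": ("E",)}
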