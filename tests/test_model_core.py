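"""Structure of the 22-state scheme, generator matrices, propagation and
steady states."""

import numpy as np
import pytest
import scipy.integrate

from blockstate import (CurrentParams, KineticScheme, LigandContext, RateSet,
                        build_scheme, current, p_open, propagate, rate_matrix,
                        steady_state)
from blockstate.model_core import Edge, StateLabel

GLU_SAT = LigandContext(glu_uM=1000.0)


class TestSchemeTopology:
    def test_state_count_and_conducting_set(self, scheme):
        assert scheme.n_states == 22
        cond = [scheme.states[i] for i in scheme.conducting_indices]
        assert len(cond) == 2
        assert {(s.plane, s.arm, s.core) for s in cond} == {
            ("Ca-free", "unblocked", "RA2open"),
            ("Ca-bound", "unblocked", "RA2open")}

    def test_plane_arm_partition(self, scheme):
        counts = {}
        for s in scheme.states:
            counts[(s.plane, s.arm)] = counts.get((s.plane, s.arm), 0) + 1
        assert counts == {("Ca-free", "unblocked"): 5, ("Ca-free", "blocked"): 5,
                          ("Ca-bound", "unblocked"): 6, ("Ca-bound", "blocked"): 6}

    def test_cdd_states_only_in_ca_bound_plane(self, scheme):
        for s in scheme.states:
            if s.core == "cddRA2":
                assert s.plane == "Ca-bound"
        with pytest.raises(ValueError):
            StateLabel("Ca-free", "unblocked", "cddRA2")

    def test_blocker_binds_open_states_only(self, scheme):
        """Trapping contract: the only arm-crossing edges connect the
        conducting states to their blocked counterparts."""
        for e in scheme.edges:
            a, b = scheme.states[e.src], scheme.states[e.dst]
            if a.arm != b.arm:
                assert a.core == "RA2open" and b.core == "RA2open"
                assert e.rate_name in ("k_M_plus", "k_M_minus")
        # no memantine edge touches a desensitized state
        for e in scheme.edges:
            if e.rate_name in ("k_M_plus", "k_M_minus"):
                assert scheme.states[e.src].core == "RA2open"

    def test_every_ca_free_state_has_one_ca_edge(self, scheme):
        ca_edges = [e for e in scheme.edges if e.rate_name == "k_Ca_plus"]
        srcs = [e.src for e in ca_edges]
        upper = [i for i, s in enumerate(scheme.states) if s.plane == "Ca-free"]
        assert sorted(srcs) == sorted(upper)
        assert all(e.ligand == "ca_i" for e in ca_edges)

    def test_cdd_connects_only_to_closed_fully_bound_state(self, scheme):
        for e in scheme.edges:
            a, b = scheme.states[e.src], scheme.states[e.dst]
            if b.core == "cddRA2":
                assert a.core == "RA2" and a.plane == "Ca-bound" and a.arm == b.arm

    def test_plane_crossing_squares_satisfy_detailed_balance(self, table_rates):
        """Independent oracle: enumerate every 4-cycle through a Ca-binding
        pair and compare clockwise vs counterclockwise rate products.  With
        plane-symmetric in-plane rates every such cycle must balance."""
        scheme = build_scheme(table_rates)
        lig = LigandContext(glu_uM=137.0, mem_uM=3.0, ca_i_uM=2.5)
        rd = table_rates.as_dict()

        def edge_rate(e):
            mult = {"none": 1.0, "glu": lig.glu_uM, "mem": lig.mem_uM,
                    "ca_i": lig.ca_i_uM}[e.ligand]
            return rd[e.rate_name] * mult * e.stat_factor

        emap = {}
        for e in scheme.edges:
            emap[(e.src, e.dst)] = edge_rate(e)
        ca_pairs = [(e.src, e.dst) for e in scheme.edges
                    if e.rate_name == "k_Ca_plus"]
        n_squares = 0
        for (u1, l1) in ca_pairs:
            for (u2, l2) in ca_pairs:
                if u1 >= u2 or (u1, u2) not in emap:
                    continue
                # square u1 -> u2 -> l2 -> l1 -> u1
                assert (l1, l2) in emap, "in-plane edge missing its mirror"
                cw = emap[(u1, u2)] * emap[(u2, l2)] * emap[(l2, l1)] * emap[(l1, u1)]
                ccw = emap[(u1, l1)] * emap[(l1, l2)] * emap[(l2, u2)] * emap[(u2, u1)]
                assert cw == pytest.approx(ccw, rel=1e-12)
                n_squares += 1
        assert n_squares > 0

    def test_statistical_factors_switch(self, table_rates):
        with_f = build_scheme(table_rates, statistical_factors=True)
        without = build_scheme(table_rates, statistical_factors=False)
        f_with = {e.stat_factor for e in with_f.edges}
        assert f_with == {1.0, 2.0}
        assert {e.stat_factor for e in without.edges} == {1.0}


class TestRateMatrix:
    @pytest.mark.parametrize("lig", [
        LigandContext(), GLU_SAT, LigandContext(1000, 10, 50),
        LigandContext(1, 0.1, 0.001)])
    def test_rows_sum_to_zero(self, scheme, table_rates, lig):
        Q = rate_matrix(scheme, table_rates, lig)
        scale = max(np.abs(Q).max(), 1.0)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12 * scale

    def test_no_entry_into_blocked_arm_without_blocker(self, scheme, table_rates):
        Q = rate_matrix(scheme, table_rates, LigandContext(1000, 0, 10))
        blocked = [i for i, s in enumerate(scheme.states) if s.arm == "blocked"]
        unblocked = [i for i in range(22) if i not in blocked]
        assert np.all(Q[np.ix_(unblocked, blocked)] == 0)

    def test_no_entry_into_ca_plane_without_ca(self, scheme, table_rates):
        Q = rate_matrix(scheme, table_rates, LigandContext(1000, 10, 0))
        lower = [i for i, s in enumerate(scheme.states) if s.plane == "Ca-bound"]
        upper = [i for i in range(22) if i not in lower]
        assert np.all(Q[np.ix_(upper, lower)] == 0)

    def test_unknown_rate_name_raises(self, table_rates):
        bad = KineticScheme(
            states=[StateLabel("Ca-free", "unblocked", "R"),
                    StateLabel("Ca-free", "unblocked", "RA")],
            edges=[Edge(0, 1, "k_bogus")])
        with pytest.raises(KeyError):
            rate_matrix(bad, table_rates, LigandContext())


class TestPropagation:
    def test_conservation_and_positivity(self, scheme, table_rates):
        p0 = steady_state(scheme, table_rates, LigandContext(ca_i_uM=10))
        _, occ = propagate(scheme, table_rates, LigandContext(1000, 3, 10),
                           p0, duration_s=5.0, dt_s=1e-3)
        assert np.abs(occ.sum(axis=1) - 1).max() < 1e-9
        assert occ.min() >= 0

    def test_steady_state_is_fixed_point(self, scheme, table_rates):
        lig = LigandContext(1000, 1, 10)
        ss = steady_state(scheme, table_rates, lig)
        _, occ = propagate(scheme, table_rates, lig, ss, 2.0, 1e-2)
        assert np.abs(occ - ss).max() < 1e-8

    def test_matches_stiff_ode_oracle(self, scheme, table_rates):
        """Independent oracle: Radau integration of dp/dt = p Q at tight
        tolerance."""
        lig = LigandContext(1000, 1, 10)
        Q = rate_matrix(scheme, table_rates, lig)
        p0 = steady_state(scheme, table_rates, LigandContext(ca_i_uM=10))
        t, occ = propagate(scheme, table_rates, lig, p0, 0.5, 1e-3)
        sol = scipy.integrate.solve_ivp(
            lambda _, p: p @ Q, (0, 0.5), p0, method="Radau",
            t_eval=t, rtol=1e-10, atol=1e-12)
        assert np.abs(occ - sol.y.T).max() < 1e-6

    def test_plane_confinement_without_ca(self, scheme, table_rates):
        lig = LigandContext(1000, 3, 0)
        p0 = np.zeros(22)
        p0[0] = 1.0  # resting Ca-free receptor
        _, occ = propagate(scheme, table_rates, lig, p0, 10.0, 1e-2)
        lower = [i for i, s in enumerate(scheme.states) if s.plane == "Ca-bound"]
        assert np.abs(occ[:, lower]).max() == 0.0

    def test_blocked_arm_confinement_without_blocker(self, scheme, table_rates):
        lig = LigandContext(1000, 0, 10)
        p0 = steady_state(scheme, table_rates, LigandContext(ca_i_uM=10))
        _, occ = propagate(scheme, table_rates, lig, p0, 10.0, 1e-2)
        blocked = [i for i, s in enumerate(scheme.states) if s.arm == "blocked"]
        assert np.abs(occ[:, blocked]).max() == 0.0

    def test_invalid_inputs(self, scheme, table_rates):
        p0 = np.zeros(22)
        p0[0] = 1.0
        with pytest.raises(ValueError):
            propagate(scheme, table_rates, GLU_SAT, p0, -1.0, 1e-3)
        with pytest.raises(ValueError):
            propagate(scheme, table_rates, GLU_SAT, np.ones(22), 1.0, 1e-3)


class TestSteadyState:
    def test_two_state_closed_form(self, table_rates):
        toy = KineticScheme(
            states=[StateLabel("Ca-free", "unblocked", "RA2"),
                    StateLabel("Ca-free", "unblocked", "RA2open")],
            edges=[Edge(0, 1, "k_g_plus"), Edge(1, 0, "k_g_minus")])
        p = steady_state(toy, table_rates, LigandContext())
        f, r = table_rates.k_g_plus, table_rates.k_g_minus
        assert p[1] == pytest.approx(f / (f + r), rel=1e-12)

    def test_agrees_with_long_time_integration(self, scheme, table_rates):
        lig = LigandContext(1000, 0, 0)
        ss = steady_state(scheme, table_rates, lig)
        p0 = np.zeros(22)
        p0[0] = 1.0
        _, occ = propagate(scheme, table_rates, lig, p0, 60.0, 10.0)
        assert np.abs(occ[-1] - ss) .max() < 1e-6

    def test_oracle_equivalence_random_draws(self, scheme, rng):
        """Steady state equals long-time propagation for random rate sets and
        ligand contexts (matrix-exponential step is exact, so a handful of
        long steps reaches equilibrium)."""
        base = RateSet().as_dict()
        for _ in range(20):
            jitter = {k: v * np.exp(rng.uniform(-np.log(3), np.log(3)))
                      for k, v in base.items()}
            rates = RateSet(**jitter)
            lig = LigandContext(glu_uM=10 ** rng.uniform(1, 3.3),
                                mem_uM=10 ** rng.uniform(-1, 1.7),
                                ca_i_uM=10 ** rng.uniform(-2, 1.7))
            ss = steady_state(scheme, rates, lig)
            p0 = np.zeros(22)
            p0[0] = 1.0
            _, occ = propagate(scheme, rates, lig, p0, 2000.0, 500.0)
            assert np.abs(occ[-1] - ss).max() < 1e-6

    def test_high_ca_lowers_open_probability(self, scheme, table_rates):
        po0 = p_open(steady_state(scheme, table_rates, LigandContext(1000, 0, 0)), scheme)
        po10 = p_open(steady_state(scheme, table_rates, LigandContext(1000, 0, 10)), scheme)
        assert po10 < po0

    def test_block_monotone_in_ca(self, scheme, table_rates):
        """With K_cddM > K_cdd, steady-state fractional block at fixed
        blocker concentration does not decrease with [Ca2+]i."""
        def fractional_block(ca):
            po_free = p_open(steady_state(scheme, table_rates,
                                          LigandContext(1000, 0, ca)), scheme)
            po_mem = p_open(steady_state(scheme, table_rates,
                                         LigandContext(1000, 1, ca)), scheme)
            return 1.0 - po_mem / po_free
        blocks = [fractional_block(ca) for ca in (0, 0.05, 0.2, 1, 5, 10, 50)]
        assert np.all(np.diff(blocks) >= -1e-12)

    def test_block_ca_independent_when_cdd_symmetrized(self, scheme, table_rates):
        """Setting the blocked-arm desensitization rates equal to the
        unblocked ones removes all [Ca2+]i dependence of block (the model's
        analogue of blockers that show no Ca-dependent inhibition)."""
        sym = table_rates.updated(k_cddM_plus=table_rates.k_cdd_plus,
                                  k_cddM_minus=table_rates.k_cdd_minus,
                                  k_dM_plus=table_rates.k_d_plus)
        def frac(ca):
            po_free = p_open(steady_state(scheme, sym,
                                          LigandContext(1000, 0, ca)), scheme)
            po_mem = p_open(steady_state(scheme, sym,
                                         LigandContext(1000, 3, ca)), scheme)
            return po_mem / po_free
        assert frac(0.0) == pytest.approx(frac(10.0), abs=1e-6)


class TestCurrent:
    @pytest.mark.parametrize("po,N,expected", [
        (1.0, 1.0, -3.25), (0.0, 1.0, 0.0), (0.13, 100.0, -42.25)])
    def test_current_arithmetic(self, scheme, po, N, expected):
        occ = np.zeros(22)
        occ[scheme.conducting_indices[0]] = po
        occ[0] = 1 - po
        params = CurrentParams(N=N, gamma_pS=50, Vm_mV=-65, Vrev_mV=0)
        assert current(occ, scheme, params) == pytest.approx(expected)

    def test_sign_is_inward_below_reversal(self, scheme, table_rates):
        ss = steady_state(scheme, table_rates, LigandContext(1000, 0, 0))
        assert current(ss, scheme, CurrentParams(N=100)) < 0


class TestSerialization:
    def test_rate_set_json_round_trip(self, table_rates):
        d = table_rates.to_json_dict(statistical_factors=False)
        back, options = RateSet.from_json_dict(d)
        assert back.as_dict() == table_rates.as_dict()
        assert options["statistical_factors"] is False

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateSet(k_d_plus=-1.0)
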