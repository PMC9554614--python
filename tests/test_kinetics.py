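import numpy as np
import pytest
from scipy.linalg import expm

import nanosyn as ns
from nanosyn.kinetics import (RATES, STATE_INDEX, STATES, KineticScheme,
                              Transition, attempt_binding, default_scheme,
                              equivalent_concentration, lateral_move_probability,
                              step_markov)
from nanosyn.molecules import BOUND, FREE, init_release


class TestSchemeInvariants:
    def test_default_scheme_valid(self):
        sch = default_scheme()
        assert sum(t.kind == "binding" for t in sch.transitions) == 3
        assert sum(t.to == "O2" for t in sch.transitions if t.kind != "binding") >= 1
        sch.check_dt(50e-9)

    def test_c0_absorbing_without_ligand(self):
        # matrix-exponential oracle: from any state, the ligand-free chain
        # relaxes to C0
        sch = default_scheme()
        P = expm(sch.generator_matrix(0.0) * 0.5)  # half a second
        assert np.all(P[:, STATE_INDEX["C0"]] > 0.99)

    def test_broken_schemes_rejected(self):
        edges = default_scheme().transitions
        with pytest.raises(ValueError, match="binding"):
            KineticScheme(edges + [Transition("C2", "D2a", 1.0, "binding")])
        with pytest.raises(ValueError, match="glutamate count"):
            KineticScheme([Transition("C0", "C2", 1.0, "binding")] + edges[1:])
        with pytest.raises(ValueError, match="C0"):
            KineticScheme(edges + [Transition("C0", "D2a", 1.0, "conformational")])

    def test_dt_guard(self):
        with pytest.raises(ValueError, match="time step"):
            default_scheme().check_dt(2e-6)

    def test_affinity_scale_touches_only_K1_K2(self):
        base = {t.name: t.rate for t in default_scheme().transitions}
        scaled = {t.name: t.rate for t in default_scheme(2.0).transitions}
        for name, rate in scaled.items():
            if name in ("K1", "K2"):
                assert rate == pytest.approx(2 * base[name])
            else:
                assert rate == base[name]

    def test_csv_round_trip(self, tmp_path):
        sch = default_scheme(1.5)
        path = tmp_path / "scheme.csv"
        sch.to_csv(path)
        back = KineticScheme.from_csv(path)
        assert back.transitions == sch.transitions


class TestEquivalentConcentration:
    def test_reference_value(self):
        # half-sphere of radius 5 nm: 261.8 nm^3 -> ~6.34 mM
        assert equivalent_concentration(5.0) == pytest.approx(6.34e-3, rel=1e-3)

    def test_cubic_scaling(self):
        assert equivalent_concentration(10.0) == pytest.approx(
            equivalent_concentration(5.0) / 8)

    def test_vanishes_for_large_radius(self):
        assert equivalent_concentration(1e6) < 1e-18


class TestBinding:
    def test_per_pair_probability(self, numerics):
        p = RATES["K1"] * equivalent_concentration(5.0) * numerics.dt_s
        assert p == pytest.approx(5.8e-3, rel=0.01)

    def _one_molecule(self, params, numerics, x, y, z):
        ens = init_release(params.replace(nnt=1), numerics, np.random.default_rng(0))
        ens.x[0], ens.y[0], ens.z[0] = x, y, z
        return ens

    def test_out_of_radius_never_binds(self, params, numerics):
        sch = default_scheme()
        rec = (np.array([0.0]), np.array([0.0]))
        for _ in range(200):
            ens = self._one_molecule(params, numerics, 5.1, 0.0, params.H_c - 0.5)
            st = np.zeros(1, dtype=np.int8)
            assert attempt_binding(ens, *rec, st, sch, params, numerics,
                                   np.random.default_rng(1)) == []

    def test_open_state_has_no_binding_edge(self, params, numerics):
        sch = default_scheme()
        ens = self._one_molecule(params, numerics, 0.0, 0.0, params.H_c - 0.5)
        st = np.full(1, STATE_INDEX["O2"], dtype=np.int8)
        rng = np.random.default_rng(2)
        for _ in range(500):
            assert attempt_binding(ens, np.zeros(1), np.zeros(1), st, sch,
                                   params, numerics, rng) == []

    def test_empirical_binding_rate(self, params, numerics):
        sch = default_scheme()
        p_expect = RATES["K1"] * equivalent_concentration(5.0) * numerics.dt_s
        rng = np.random.default_rng(3)
        n, hits = 20_000, 0
        for _ in range(n):
            ens = self._one_molecule(params, numerics, 1.0, 0.0, params.H_c - 1.0)
            st = np.zeros(1, dtype=np.int8)
            if attempt_binding(ens, np.zeros(1), np.zeros(1), st, sch,
                               params, numerics, rng):
                hits += 1
                assert ens.status[0] == BOUND and st[0] == STATE_INDEX["C1"]
        se = np.sqrt(p_expect * (1 - p_expect) / n)
        assert hits / n == pytest.approx(p_expect, abs=4 * se)


class TestMarkov:
    def test_c2_opening_probability(self):
        # beta * dt ~ 2.58e-3 per 50 ns step
        sch = default_scheme()
        rng = np.random.default_rng(4)
        st = np.full(200_000, STATE_INDEX["C2"], dtype=np.int8)
        new, _ = step_markov(st, sch, 50e-9, rng)
        p = np.mean(new == STATE_INDEX["O2"])
        expect = RATES["beta"] * 50e-9
        assert p == pytest.approx(expect, abs=4 * np.sqrt(expect / len(st)))

    def test_matches_matrix_exponential_under_fixed_concentration(self):
        """Sampled occupancies at 0.5 ms equal the expm oracle within MC error."""
        sch = default_scheme()
        C, dt, T, n = 1e-3, 1e-6, 5e-4, 30_000
        cum, target, unbind = sch.step_tables(dt)
        kon = sch.binding_rate_by_state()
        btgt = sch.binding_target_by_state()
        p_bind = kon * C * dt
        rng = np.random.default_rng(5)
        st = np.zeros(n, dtype=np.int64)
        for _ in range(int(T / dt)):
            bind = rng.random(n) < p_bind[st]
            st[bind] = btgt[st[bind]]
            u = rng.random(n)
            k = (u[:, None] >= cum[st]).sum(axis=1)
            st = target[st, k].astype(np.int64)
        emp = np.bincount(st, minlength=9) / n
        exact = expm(sch.generator_matrix(C) * T)[0]
        se = np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(emp - exact) < 3 * se + 2e-3)

    def test_unbinding_edges_flagged(self):
        sch = default_scheme()
        rng = np.random.default_rng(6)
        st = np.full(300_000, STATE_INDEX["C1"], dtype=np.int8)
        new, released = step_markov(st, sch, 50e-9, rng)
        went_c0 = new == STATE_INDEX["C0"]
        assert np.array_equal(released, went_c0)
        assert went_c0.sum() > 0


def test_lateral_move_probability():
    # 4 D dt / h^2 with D_r = 0.1 um^2/s, h = 10 nm, dt = 50 ns
    assert lateral_move_probability(0.1, 50.0, 10.0) == pytest.approx(2e-4)
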