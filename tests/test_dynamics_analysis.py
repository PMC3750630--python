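"""Fixed points, Jacobians, eigen-structures and gain-sweep transitions.

Published reference magnitudes for a=5, b=1, c=5, delta_omega0=1: decoupled
roots 0.11 (attracting) and 2.53 (repelling) with 1D Jacobians -8.87 and
2.75; situated |eta| = 2.28 at the attractor and 0.43 at the repeller.
Transition gains frozen from an independent bisection oracle over the same
equations: 2.2260 (repeller pair reassignment), 5.1994 (attractor pair
vanishes), 10.4494 (attractor pair re-appears).
"""

import numpy as np
import pytest

from situated_hkb import HKBParams
from situated_hkb.dynamics_analysis import (
    FixedPoint,
    detect_transitions,
    eigen_at,
    find_decoupled_fixed_points,
    find_situated_fixed_points,
    jacobian_decoupled,
    jacobian_passive,
    jacobian_situated,
    sweep_eigenvalues,
)
from situated_hkb.model_core import situated_rates

S_GRID = np.arange(0.0, 15.0001, 0.05)


class TestDecoupledFixedPoints:
    def test_canonical_roots(self, decoupled_roots):
        phis = sorted(f.phi for f in decoupled_roots)
        assert phis[0] == pytest.approx(0.11, abs=0.005)
        assert phis[1] == pytest.approx(2.53, abs=0.005)
        kinds = {round(f.phi, 2): f.kind for f in decoupled_roots}
        assert kinds[0.11] == "attractor"
        assert kinds[2.53] == "repeller"

    def test_zero_drift_roots(self):
        fps = find_decoupled_fixed_points(HKBParams(delta_omega0=0.0))
        phis = sorted(f.phi for f in fps)
        assert phis == pytest.approx([0.0, np.pi], abs=1e-9)

    def test_metastable_has_no_roots(self):
        assert find_decoupled_fixed_points(HKBParams(delta_omega0=10.0)) == []

    def test_residual_rate_below_tolerance(self, params, decoupled_roots):
        from situated_hkb import decoupled_rate

        for f in decoupled_roots:
            assert abs(decoupled_rate(f.phi, 1.0, params)) < 1e-10


class TestDecoupledJacobian:
    def test_published_values(self, params, decoupled_roots):
        att = next(f for f in decoupled_roots if f.kind == "attractor")
        rep = next(f for f in decoupled_roots if f.kind == "repeller")
        assert jacobian_decoupled(att.phi, params) == pytest.approx(-8.87, abs=0.03)
        assert jacobian_decoupled(rep.phi, params) == pytest.approx(2.75, abs=0.03)

    def test_vanishes_without_coupling(self):
        p = HKBParams(a=0.0, b=0.0)
        assert jacobian_decoupled(1.7, p) == 0.0


class TestSituatedFixedPoints:
    def test_published_eta_magnitudes(self, attractor, repeller):
        assert abs(attractor.eta) == pytest.approx(2.28, abs=0.02)
        assert abs(repeller.eta) == pytest.approx(0.43, abs=0.02)

    def test_phi_equals_decoupled_roots(self, situated_fps, decoupled_roots):
        dec = sorted(f.phi for f in decoupled_roots)
        for fp in situated_fps:
            assert min(abs(fp.phi - r) for r in dec) < 1e-9

    def test_alpha_is_quarter_turn(self, situated_fps):
        for fp in situated_fps:
            assert abs(fp.alpha) == pytest.approx(np.pi / 2, abs=1e-12)

    def test_mirror_partners_are_saddles(self, situated_fps):
        kinds = sorted(f.kind for f in situated_fps)
        assert kinds == ["attractor", "repeller", "saddle", "saddle"]

    def test_rates_vanish(self, params, situated_fps):
        for fp in situated_fps:
            assert np.max(np.abs(situated_rates(fp.location, params))) < 1e-9

    def test_locations_independent_of_gain(self, params):
        ref = find_situated_fixed_points(params.replace(s=0.0))
        for s in (5.0, 15.0):
            fps = find_situated_fixed_points(params.replace(s=s))
            drift = max(
                np.max(np.abs(a.location - b.location)) for a, b in zip(ref, fps)
            )
            assert drift < 1e-10


class TestSituatedJacobian:
    def test_matches_central_finite_differences(self, params, rng):
        h = 1e-6
        for _ in range(100):
            x = np.array(
                [rng.uniform(0, 2 * np.pi), rng.uniform(0.5, 3), rng.uniform(-3, 3)]
            )
            if rng.random() < 0.5:
                x[1] = -x[1]
            J = jacobian_situated(x, params)
            fd = np.empty((3, 3))
            for j in range(3):
                e = np.zeros(3)
                e[j] = h
                fd[:, j] = (
                    situated_rates(x + e, params) - situated_rates(x - e, params)
                ) / (2 * h)
            assert np.max(np.abs(J - fd)) < 1e-6

    def test_zero_gain_first_row(self):
        p = HKBParams(s=0.0)
        x = [0.9, 1.4, -0.7]
        J = jacobian_situated(x, p)
        assert J[0, 0] == pytest.approx(jacobian_decoupled(0.9, p), abs=1e-14)
        assert J[0, 1] == 0.0
        assert J[0, 2] == 0.0

    def test_trace_equals_eigenvalue_sum(self, params, attractor):
        J = jacobian_situated(attractor.location, params)
        eig = eigen_at(attractor, params)
        assert np.trace(J) == pytest.approx(eig.trace, abs=1e-8)


class TestPassiveJacobian:
    def _fp4(self, attractor):
        loc = np.append(attractor.location, attractor.phi)
        return FixedPoint(loc, attractor.kind, "passive")

    def test_copy_column_is_exactly_zero(self, params, attractor):
        J = jacobian_passive(self._fp4(attractor).location, params)
        assert np.all(J[:3, 3] == 0.0)

    def test_corner_entry_is_decoupled_jacobian(self, params, attractor):
        J = jacobian_passive(self._fp4(attractor).location, params)
        assert J[3, 3] == pytest.approx(jacobian_decoupled(attractor.phi, params))

    def test_block_triangular_spectrum(self, params, attractor):
        """4D eigenvalues = 3D spectrum union the decoupled Jacobian."""
        fp4 = self._fp4(attractor)
        w4 = np.sort_complex(eigen_at(fp4, params).eigenvalues)
        w3 = eigen_at(attractor, params).eigenvalues
        lam4 = jacobian_decoupled(attractor.phi, params)
        expected = np.sort_complex(np.append(w3, lam4))
        assert np.max(np.abs(w4 - expected)) < 1e-8

    def test_eigenvector_structure(self, params, attractor):
        """v4 lies on the phi_star axis; other modes have v_i,phi* = v_i,phi."""
        fp4 = self._fp4(attractor)
        eig = eigen_at(fp4, params)
        lam4 = jacobian_decoupled(attractor.phi, params)
        i4 = int(np.argmin(np.abs(eig.eigenvalues - lam4)))
        v4 = eig.eigenvectors[:, i4]
        v4 = v4 / v4[np.argmax(np.abs(v4))]
        assert np.allclose(v4, [0, 0, 0, 1], atol=1e-8)
        for i in range(4):
            if i == i4:
                continue
            v = eig.eigenvectors[:, i]
            assert abs(v[0] - v[3]) < 1e-6


class TestEigenAt:
    def test_decoupled_attractor_single_eigenvalue(self, params, decoupled_roots):
        att = next(f for f in decoupled_roots if f.kind == "attractor")
        eig = eigen_at(att, params)
        assert len(eig.eigenvalues) == 1
        assert eig.eigenvalues[0].real == pytest.approx(-8.87, abs=0.03)
        assert eig.complex_pair is None

    def test_sorted_by_descending_real_part(self, params, repeller):
        w = eigen_at(repeller, params).eigenvalues
        assert np.all(np.diff(w.real) <= 1e-12)

    def test_conjugate_pair_flagged_inside_spiral_window(self, params, attractor):
        for s in (2.5, 3.0, 5.0):
            eig = eigen_at(attractor, params.replace(s=s))
            assert eig.complex_pair is not None
            lam = eig.eigenvalues[list(eig.complex_pair)]
            assert lam[0] == pytest.approx(np.conj(lam[1]), abs=1e-9)
        assert eigen_at(attractor, params.replace(s=7.0)).complex_pair is None

    def test_against_characteristic_polynomial_oracle(self, rng):
        """Spectra at situated fixed points match hand-built charpoly roots."""
        checked = 0
        while checked < 100:
            p = HKBParams(
                a=rng.uniform(1, 6),
                b=rng.uniform(0.1, 2),
                c=rng.uniform(0.5, 6),
                s=rng.uniform(0, 15),
            )
            try:
                fps = find_situated_fixed_points(p, cross_validate=False)
            except Exception:
                continue
            if not fps:
                continue
            fp = fps[checked % len(fps)]
            J = jacobian_situated(fp.location, p)
            tr = np.trace(J)
            m = (
                J[0, 0] * J[1, 1]
                - J[0, 1] * J[1, 0]
                + J[0, 0] * J[2, 2]
                - J[0, 2] * J[2, 0]
                + J[1, 1] * J[2, 2]
                - J[1, 2] * J[2, 1]
            )
            det = np.linalg.det(J)
            oracle = np.sort_complex(np.roots([1.0, -tr, m, -det]))
            w = np.sort_complex(eigen_at(fp, p).eigenvalues)
            assert np.max(np.abs(w - oracle)) < 1e-6 * max(1.0, np.max(np.abs(w)))
            checked += 1


@pytest.fixture(scope="module")
def sweep():
    return sweep_eigenvalues(HKBParams(), S_GRID)


class TestSweepAndTransitions:

    def test_sweep_is_finite(self, sweep):
        for site in ("attractor", "repeller"):
            for eig in sweep.site_eigs(site):
                assert np.all(np.isfinite(eig.eigenvalues))

    def test_attractor_stays_attracting(self, sweep):
        """Strictly attracting for s > 0; marginal (center in the eta-alpha
        plane) at exactly s = 0 where the sensorimotor feedback vanishes."""
        for s, eig in zip(sweep.s_values, sweep.site_eigs("attractor")):
            if s == 0.0:
                assert np.all(eig.eigenvalues.real < 1e-12)
            else:
                assert np.all(eig.eigenvalues.real < 0)

    def test_repeller_keeps_positive_real_part(self, sweep):
        for eig in sweep.site_eigs("repeller"):
            assert np.max(eig.eigenvalues.real) > 0

    def test_transitions_match_frozen_oracle(self, sweep):
        events = detect_transitions(sweep)
        table = {(e.site, e.kind): e.s_value for e in events}
        assert len(events) == 3
        assert table[("repeller", "plane_switch")] == pytest.approx(2.2260, abs=2e-3)
        assert table[("attractor", "pair_vanishes")] == pytest.approx(5.1994, abs=2e-3)
        assert table[("attractor", "pair_appears")] == pytest.approx(10.4494, abs=2e-3)

    def test_sweep_frame_shape(self, sweep):
        df = sweep.to_frame()
        assert len(df) == 2 * len(S_GRID)
        assert {"s", "site", "re_lambda1", "im_lambda3", "pair_plane"} <= set(df.columns)

    def test_rejects_unsorted_grid(self, params):
        with pytest.raises(ValueError):
            sweep_eigenvalues(params, [1.0, 0.5])
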