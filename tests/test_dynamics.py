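"""Force terms, rotation operators and the synchronous population step."""

import dataclasses

import numpy as np
import pytest

from angiosim.dynamics import (
    CellState,
    ModelParams,
    Population,
    advance,
    alignment_rotation,
    attractive_force,
    contact_rotation,
    contact_rotation_axes,
    driving_force,
    repulsive_force,
    step,
    velocity_update,
)
from angiosim.geometry import (
    SamplingGrid,
    cells_in_contact,
    is_orthonormal_frame,
    shape_from_oblateness,
)
from angiosim.simulation import complete_frame

from conftest import random_frame


def make_cell(r, v=(0, 0, 0), e_x=(1, 0, 0)):
    return CellState(np.asarray(r, float), np.asarray(v, float),
                     complete_frame(np.asarray(e_x, float)))


class TestPairForces:
    def test_repulsion_zero_without_contact(self, params):
        ci, cj = make_cell([0, 0, 0]), make_cell([1, 0, 0])
        assert np.allclose(repulsive_force(ci, cj, params, in_contact=False), 0.0)

    def test_repulsion_baseline_magnitude_and_direction(self, params):
        ci, cj = make_cell([0, 0, 0]), make_cell([1, 0, 0])
        F = repulsive_force(ci, cj, params, in_contact=True)
        assert np.allclose(F, [-0.02, 0, 0])  # points from j toward i

    def test_pair_force_antisymmetry(self, params, rng):
        for _ in range(10):
            ri, rj = rng.uniform(-2, 2, (2, 3))
            ci, cj = make_cell(ri), make_cell(rj)
            assert np.allclose(
                repulsive_force(ci, cj, params, True),
                -repulsive_force(cj, ci, params, True),
            )
            assert np.allclose(
                attractive_force(ci, cj, params, R_a=10.0),
                -attractive_force(cj, ci, params, R_a=10.0),
            )

    def test_attraction_boundary_inclusive(self, params):
        ci, cj = make_cell([0, 0, 0]), make_cell([0, 2, 0])
        assert np.allclose(attractive_force(ci, cj, params, R_a=2.0), [0, 0.001, 0])
        assert np.allclose(attractive_force(ci, cj, params, R_a=2.0 - 1e-9), 0.0)

    def test_driving_force_branches(self, params):
        resting = make_cell([0, 0, 0], v=[0, 0, 0])
        moving = make_cell([0, 0, 0], v=[0.003, 0, 0])
        assert np.allclose(driving_force(resting, True, params), 0.0)
        assert np.allclose(driving_force(moving, False, params), 0.0)
        assert np.allclose(driving_force(moving, True, params), [0.002, 0, 0])

    def test_coincident_centres_use_major_axis_tie_break(self, params):
        ci = make_cell([0, 0, 0], e_x=[0, 1, 0])
        cj = make_cell([0, 0, 0], e_x=[1, 0, 0])
        F = repulsive_force(ci, cj, params, in_contact=True)
        assert np.allclose(F, [0, -0.02, 0])  # along -e_x of the first cell


class TestVelocityUpdate:
    def test_friction_factor(self, params):
        c = make_cell([0, 0, 0], v=[1, 0, 0])
        v1 = velocity_update(c, np.zeros(3), np.zeros(3), params)
        assert np.allclose(v1, [0.9, 0, 0])

    def test_free_decay_closed_form(self, params):
        v = np.array([0.7, -0.2, 0.1])
        c = make_cell([0, 0, 0], v=v)
        for n in range(1, 30):
            c.v = velocity_update(c, np.zeros(3), np.zeros(3), params)
        assert np.linalg.norm(c.v) == pytest.approx(
            0.9**29 * np.linalg.norm(v), abs=1e-12
        )


class TestAlignmentRotation:
    def test_zero_velocity_gives_identity(self, params):
        c = make_cell([0, 0, 0])
        assert np.allclose(alignment_rotation(c, np.zeros(3), params), np.eye(3))

    def test_quarter_angle_rotation_magnitude(self, params):
        # xi = pi/4 between e_x = x and v along (1,1,0): angle = gamma2*sin(pi/2)
        c = make_cell([0, 0, 0], e_x=[1, 0, 0])
        v_next = np.array([1.0, 1.0, 0.0])
        Q = alignment_rotation(c, v_next, params)
        e_x_new = Q @ c.e_x
        angle = np.arccos(np.clip(e_x_new @ c.e_x, -1, 1))
        assert angle == pytest.approx(0.01, rel=1e-9)
        # rotates toward the velocity, not away
        assert e_x_new @ (v_next / np.linalg.norm(v_next)) > c.e_x @ (
            v_next / np.linalg.norm(v_next)
        )

    @pytest.mark.parametrize("v_dir", [[1, 0, 0], [-1, 0, 0]])
    def test_parallel_and_antiparallel_are_fixed_points(self, params, v_dir):
        c = make_cell([0, 0, 0], e_x=[1, 0, 0])
        assert np.allclose(alignment_rotation(c, np.array(v_dir, float), params), np.eye(3))

    def test_perpendicular_equilibrium(self, params):
        # xi = pi/2: sin(2 xi) = 0 -> identity (head-tail symmetric alignment)
        c = make_cell([0, 0, 0], e_x=[1, 0, 0])
        assert np.allclose(
            alignment_rotation(c, np.array([0.0, 2.0, 0.0]), params), np.eye(3),
            atol=1e-12,
        )


class TestContactRotation:
    def test_no_penetration_identity(self, params):
        c = make_cell([0, 0, 0])
        assert np.allclose(contact_rotation(c, np.empty((0, 2)), params), np.eye(3))

    def test_single_point_rotation_angle(self, params):
        # phi_k = pi/4 at k = K/4; rotation angle is f_p * sin(2 phi_k) = f_p
        c = make_cell([0, 0, 0], e_x=[0, 0, 1.0])
        k = params.K // 4  # K=10 -> k=2, phi=pi/5; use explicit k with phi=pi/4 via K=8
        p8 = dataclasses.replace(params, K=8)
        P = contact_rotation(c, np.array([[2, 3]]), p8)  # k=2 -> phi = pi/4
        angle = np.arccos(np.clip((np.trace(P) - 1) / 2, -1, 1))
        assert angle == pytest.approx(p8.f_p, rel=1e-9)
        axis_expected = contact_rotation_axes(c, p8.L)[3]
        # rotation axis is n_l up to sign (sign carries the -f_p)
        w = np.array([P[2, 1] - P[1, 2], P[0, 2] - P[2, 0], P[1, 0] - P[0, 1]])
        assert np.allclose(np.cross(w, axis_expected), 0.0, atol=1e-12)

    def test_pole_contacts_contribute_nothing(self, params):
        c = make_cell([0, 0, 0])
        kl = np.array([[0, l] for l in range(params.L)] + [[params.K, l] for l in range(params.L)])
        assert np.allclose(contact_rotation(c, kl, params), np.eye(3), atol=1e-15)

    def test_axes_are_minor_axis_rotated_about_major(self, params, rng):
        c = CellState(np.zeros(3), np.zeros(3), random_frame(rng))
        axes = contact_rotation_axes(c, params.L)
        assert np.allclose(axes[0], c.e_z, atol=1e-12)
        # quarter turn about e_x maps e_z -> -e_y
        assert np.allclose(axes[params.L // 4], -c.e_y, atol=1e-12)


class TestStep:
    def test_isolated_resting_cell_is_fixed_point(self, shape07, grid, params):
        c = make_cell([1.0, 2.0, 3.0])
        out = step([c], shape07, grid, params)
        assert np.allclose(out[0].r, c.r) and np.allclose(out[0].v, 0.0)
        assert np.allclose(out[0].frame, c.frame)

    def test_attracting_resting_pair_approaches(self, shape07, grid, params):
        # separated beyond contact but within R_a: distance strictly decreases
        d0 = 2.6
        cells = [make_cell([0, 0, 0], e_x=[0, 0, 1]), make_cell([d0, 0, 0], e_x=[0, 0, 1])]
        for _ in range(5):
            cells = step(cells, shape07, grid, params)
        d = np.linalg.norm(cells[1].r - cells[0].r)
        assert d < d0

    def test_overlapping_resting_pair_repels_with_net_force(self, shape07, grid, params):
        cells = [make_cell([0, 0, 0], e_x=[0, 0, 1]), make_cell([0.5, 0, 0], e_x=[0, 0, 1])]
        out = step(cells, shape07, grid, params)
        # net radial force f_r - f_a = 0.019 on each, directed apart
        assert out[0].v[0] == pytest.approx(-0.019, abs=1e-12)
        assert out[1].v[0] == pytest.approx(+0.019, abs=1e-12)

    def test_momentum_conserved_without_friction_and_driving(self, shape07, grid):
        p = ModelParams(gamma1=0.0, d=0.0)
        rng = np.random.default_rng(3)
        cells = [
            CellState(rng.uniform(-1, 1, 3), rng.uniform(-0.05, 0.05, 3), random_frame(rng))
            for _ in range(4)
        ]
        total0 = sum(c.v for c in cells)
        out = step(cells, shape07, grid, p)
        total1 = sum(c.v for c in out)
        assert np.allclose(total0, total1, atol=1e-15)

    def test_head_on_collision_preserves_mirror_symmetry(self, shape07, grid, params):
        cells = [
            make_cell([-1.0, 0, 0], v=[0.05, 0, 0], e_x=[0, 0, 1]),
            make_cell([+1.0, 0, 0], v=[-0.05, 0, 0], e_x=[0, 0, 1]),
        ]
        for _ in range(50):
            cells = step(cells, shape07, grid, params)
            assert np.allclose(cells[0].r, -cells[1].r, atol=1e-12)
            assert np.allclose(cells[0].v, -cells[1].v, atol=1e-12)

    def test_frames_stay_orthonormal_over_long_run(self, shape07, grid, params):
        rng = np.random.default_rng(5)
        pop = Population(
            ids=np.arange(3),
            r=np.array([[0.0, 0, 0], [1.5, 0, 0], [0.7, 1.2, 0]]),
            v=rng.uniform(-0.02, 0.02, (3, 3)),
            frames=np.stack([random_frame(rng) for _ in range(3)]),
        )
        for t in range(100_000):
            pop, _ = advance(pop, shape07, grid, params)
        for f in pop.frames:
            assert is_orthonormal_frame(f, tol=1e-9)

    def test_rotation_generator_norm_bound(self, shape07, grid, params, rng):
        # per-step frame rotation angle <= gamma2 + (K+1) L f_p
        bound = params.gamma2 + (params.K + 1) * params.L * params.f_p
        pop = Population(
            ids=np.arange(2),
            r=np.array([[0.0, 0, 0], [0.8, 0.3, 0.1]]),
            v=rng.uniform(-0.1, 0.1, (2, 3)),
            frames=np.stack([random_frame(rng) for _ in range(2)]),
        )
        for _ in range(50):
            new, _ = advance(pop, shape07, grid, params)
            for old_f, new_f in zip(pop.frames, new.frames):
                R = new_f @ old_f.T
                angle = np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1))
                assert angle <= bound + 1e-9
            pop = new


class TestEngineAgainstReferenceOps:
    """The vectorised engine must reproduce the per-pair reference operations."""

    def reference_step(self, cells, shape, grid, params):
        n = len(cells)
        R_a = params.attraction_radius(shape)
        contact = {}
        pen = {i: [] for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                res = cells_in_contact(
                    (shape, cells[i].r, cells[i].frame),
                    (shape, cells[j].r, cells[j].frame),
                    grid,
                    symmetric=params.symmetric_contact,
                )
                contact[(i, j)] = res.in_contact
                if res.in_contact:
                    pen[i].extend(res.penetrating_i.tolist())
                    pen[j].extend(res.penetrating_j.tolist())
        out = []
        for i in range(n):
            F = np.zeros(3)
            has_nb = False
            for j in range(n):
                if j == i:
                    continue
                inc = contact[(min(i, j), max(i, j))]
                lo, hi = (i, j) if i < j else (j, i)
                ci, cj = cells[lo], cells[hi]
                Fr = repulsive_force(ci, cj, params, inc)
                Fa = attractive_force(ci, cj, params, R_a)
                sgn = 1.0 if i == lo else -1.0
                F += sgn * (Fr + Fa)
                if np.linalg.norm(cells[j].r - cells[i].r) <= R_a:
                    has_nb = True
            D = driving_force(cells[i], has_nb, params)
            v_new = velocity_update(cells[i], F, D, params)
            r_new = cells[i].r + cells[i].v
            Q = alignment_rotation(cells[i], v_new, params)
            P = contact_rotation(cells[i], np.array(pen[i]).reshape(-1, 2), params)
            from angiosim.geometry import nearest_rotation

            frame_new = nearest_rotation(Q @ P @ cells[i].frame)
            out.append(CellState(r_new, v_new, frame_new))
        return out

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_engine_matches_reference_composition(self, shape07, grid, params, seed):
        rng = np.random.default_rng(seed)
        cells = [
            CellState(rng.uniform(-2, 2, 3), rng.uniform(-0.05, 0.05, 3), random_frame(rng))
            for _ in range(6)
        ]
        got = step(cells, shape07, grid, params)
        want = self.reference_step(cells, shape07, grid, params)
        for g, w in zip(got, want):
            assert np.allclose(g.r, w.r, atol=1e-14)
            assert np.allclose(g.v, w.v, atol=1e-14)
            assert np.allclose(g.frame, w.frame, atol=1e-12)

    def test_neighbor_search_matches_all_pairs(self, shape07, grid, params):
        """Pruned pair search must change nothing vs. brute force (here: a config
        spread widely so the KD-tree cutoff actually prunes)."""
        rng = np.random.default_rng(11)
        cells = [
            CellState(rng.uniform(-12, 12, 3), rng.uniform(-0.05, 0.05, 3), random_frame(rng))
            for _ in range(25)
        ]
        got = step(cells, shape07, grid, params)
        want = self.reference_step(cells, shape07, grid, params)
        for g, w in zip(got, want):
            assert np.allclose(g.v, w.v, atol=1e-14)
            assert np.allclose(g.frame, w.frame, atol=1e-12)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ModelParams(gamma1=1.0)
    with pytest.raises(ValueError):
        ModelParams(f_r=0.001, f_a=0.02)
    with pytest.raises(ValueError):
        ModelParams(d=-0.1)
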