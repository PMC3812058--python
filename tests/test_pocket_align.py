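"""PS-score machinery: superposition, solvers, seeds, three-phase alignment."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketspace import pocket_align as pa
from pocketspace import synthetic_data as sd
from pocketspace.errors import AlignmentError, SuperpositionError
from pocketspace.structure_io import Pocket, Residue
from conftest import brute_force_assignment, quaternion_rmsd, random_rotation


class TestKabsch:
    def test_identical_sets(self):
        A = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = pa.kabsch_superpose(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-8)

    def test_exact_rigid_copy(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(25, 3))
        R0 = random_rotation(rng)
        B = A @ R0.T + np.array([4.0, -2.0, 9.0])
        _, _, rmsd = pa.kabsch_superpose(A, B)
        assert rmsd <= 1e-8

    def test_quaternion_oracle_100_seeds(self):
        """SVD-based Kabsch RMSD matches Horn's quaternion method."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 40))
            A = rng.normal(size=(n, 3)) * 5
            B = rng.normal(size=(n, 3)) * 5
            _, _, rmsd = pa.kabsch_superpose(A, B)
            assert rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-6)

    def test_proper_rotation_even_for_mirrored_input(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(12, 3))
        B = A.copy()
        B[:, 0] *= -1  # mirror image
        R, _, _ = pa.kabsch_superpose(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [np.zeros((2, 3)),
                                     np.outer(np.arange(6), [1.0, 0, 0])])
    def test_degenerate_inputs(self, bad):
        with pytest.raises(SuperpositionError):
            pa.kabsch_superpose(bad, bad)


class TestChemGroups:
    @pytest.mark.parametrize(
        "a, b, same",
        [("L", "V", True), ("L", "A", False), ("H", "H", True),
         ("E", "Q", True), ("K", "R", True), ("S", "P", False)],
    )
    def test_group_pairs(self, a, b, same):
        assert (pa.chem_group(a) == pa.chem_group(b)) is same

    def test_nonstandard_matches_nothing(self):
        assert pa.chem_group("X") is None
        assert pa.CHEM_GROUPS.get("X", -1) == -1


class TestVectorTerm:
    @staticmethod
    def _res(aa, ca, cb):
        return Residue(aa, "A", 1, np.asarray(ca, float),
                       None if cb is None else np.asarray(cb, float))

    def test_gly_conventions(self):
        g = self._res("G", [0, 0, 0], None)
        a = self._res("A", [0, 0, 0], [1.5, 0, 0])
        assert pa.vector_term(g, g) == 1.0
        assert pa.vector_term(g, a) == pytest.approx(0.77)
        assert pa.vector_term(a, g) == pytest.approx(0.77)

    def test_parallel_vectors_maximal(self):
        a = self._res("A", [0, 0, 0], [1.5, 0, 0])
        b = self._res("L", [5, 5, 5], [6.5, 5, 5])
        assert pa.vector_term(a, b, (np.eye(3), np.zeros(3))) == pytest.approx(1.0)

    def test_monotone_in_angle(self):
        a = self._res("A", [0, 0, 0], [1.5, 0, 0])
        values = []
        for theta in np.linspace(0, np.pi, 7):
            b = self._res("A", [0, 0, 0],
                          [1.5 * np.cos(theta), 1.5 * np.sin(theta), 0])
            values.append(pa.vector_term(a, b, (np.eye(3), np.zeros(3))))
        assert all(x >= y - 1e-12 for x, y in zip(values, values[1:]))
        assert values[0] == pytest.approx(1.0)


def _toy_pocket(spec):
    """spec: list of (aa, ca, cb_dir or None)."""
    residues = []
    for i, (aa, ca, cbd) in enumerate(spec):
        ca = np.asarray(ca, float)
        cb = None if cbd is None else ca + 1.53 * np.asarray(cbd, float)
        residues.append(Residue(aa, "A", i + 1, ca, cb))
    return Pocket(residues=residues, entry_id="TOY")


class TestPsScore:
    def test_identical_copy_is_one(self):
        p = sd.make_pocket(L=20, seed=4)
        pairs = [(i, i) for i in range(p.L)]
        assert pa.ps_score(pairs, p, p, (np.eye(3), np.zeros(3))) == pytest.approx(1.0)

    def test_hand_oracle_three_residues(self):
        """Spreadsheet-style evaluation of the printed formula on a toy pair."""
        tmpl = _toy_pocket([
            ("L", [0, 0, 0], [1, 0, 0]),
            ("A", [3.8, 0, 0], [0, 1, 0]),
            ("H", [7.6, 0, 0], [0, 0, 1]),
        ])
        qry = _toy_pocket([
            ("V", [1.0, 0, 0], [np.cos(np.pi / 3), np.sin(np.pi / 3), 0]),
            ("G", [3.8, 0.5, 0], None),
            ("H", [7.6, 0, 2.0], [0, 0, 1]),
        ])
        params = pa.DEFAULT_PARAMS
        # independent arithmetic over the documented formula
        d0 = max(
            (params.d0_a * 1.0 + params.d0_b) * (3 / params.length_ref) ** params.length_scale_alpha,
            params.d0_min,
        )
        d = [1.0, 0.5, 2.0]
        p_term = [0.5 * (1 + np.cos(np.pi / 3)), 0.77, 1.0]
        r_term = [1.0, 1.0, 1.0]  # L~V (I), A~G (II), H~H (VIII)
        c = params.chem_weight
        expected = sum(
            1.0 / (1.0 + (di / d0) ** 2) * (pi_ + c * ri) / (1 + c)
            for di, pi_, ri in zip(d, p_term, r_term)
        ) / 3.0
        got = pa.ps_score([(0, 0), (1, 1), (2, 2)], tmpl, qry, (np.eye(3), np.zeros(3)))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_distance_limit_kills_score(self):
        tmpl = _toy_pocket([("A", [0, 0, 0], [1, 0, 0]),
                            ("A", [3.8, 0, 0], [1, 0, 0]),
                            ("A", [7.6, 0, 0], [1, 0, 0])])
        far = _toy_pocket([("A", [1e6, 0, 0], [1, 0, 0]),
                           ("A", [1e6 + 3.8, 0, 0], [1, 0, 0]),
                           ("A", [1e6 + 7.6, 0, 0], [1, 0, 0])])
        score = pa.ps_score([(0, 0), (1, 1), (2, 2)], tmpl, far,
                            (np.eye(3), np.zeros(3)))
        assert score < 1e-9

    def test_empty_alignment_sentinel(self):
        p = sd.make_pocket(L=12, seed=1)
        assert pa.ps_score([], p, p, (np.eye(3), np.zeros(3))) == 0.0


class TestLsapSolver:
    def test_diagonal_identity(self):
        cost = 1.0 - np.eye(3)
        assert list(pa.solve_lsap(cost)) == [0, 1, 2]

    def test_brute_force_oracle_100_seeds(self):
        """Shortest-augmenting-path solution equals the exhaustive minimum."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 9))
            cost = rng.normal(size=(n, n))
            cols = pa.solve_lsap(cost)
            assert sorted(cols) == list(range(n))
            got = cost[np.arange(n), cols].sum()
            assert got == pytest.approx(brute_force_assignment(cost), abs=1e-9)

    def test_rectangular_both_orientations(self):
        rng = np.random.default_rng(7)
        cost = rng.normal(size=(4, 7))
        cols = pa.solve_lsap(cost)
        assert len(cols) == 4 and len(set(cols)) == 4
        rows = pa.solve_lsap(cost.T)
        assigned = [r for r in rows if r >= 0]
        assert len(rows) == 7 and len(assigned) == 4 and len(set(assigned)) == 4

    def test_scipy_cross_check(self):
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(12)
        for _ in range(10):
            cost = rng.normal(size=(30, 30))
            cols = pa.solve_lsap(cost)
            ri, ci = linear_sum_assignment(cost)
            assert cost[np.arange(30), cols].sum() == pytest.approx(
                cost[ri, ci].sum(), abs=1e-9
            )


class TestSeeds:
    def test_zero_shift_seed_present_for_identical(self):
        p = sd.make_pocket(L=15, seed=2)
        seeds = pa.seed_alignments(p, p)
        full = (tuple(range(15)), tuple(range(15)))
        assert any((tuple(ti), tuple(qi)) == full for ti, qi in seeds)

    def test_truncation_offset_recovered(self):
        p = sd.make_pocket(L=30, seed=3)
        q = replace(p, residues=p.residues[5:])
        seeds = pa.seed_alignments(p, q)
        # a gapless seed mapping template residue 5 -> query residue 0
        assert any(ti[0] - qi[0] == 5 for ti, qi in seeds)

    def test_unrelated_pockets_still_get_seeds(self):
        a = sd.make_pocket(L=14, seed=4)
        b = sd.make_pocket(L=19, seed=5)
        assert len(pa.seed_alignments(a, b)) >= 1


class TestThreePhaseAlignment(object):
    def test_self_alignment_perfect(self, warm_aligner):
        p = sd.make_pocket(L=25, seed=6)
        aln = pa.align_pockets(p, p)
        assert aln.ps_score == pytest.approx(1.0, abs=1e-9)
        assert aln.n_aligned == 25
        assert aln.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_recovers_identity(self, warm_aligner):
        p = sd.make_pocket(L=30, seed=7)
        R = random_rotation(np.random.default_rng(8))
        q = p.transformed(R, np.array([3.0, -14.0, 6.0]))
        aln = pa.align_pockets(p, q)
        assert aln.ps_score == pytest.approx(1.0, abs=1e-6)
        assert aln.pairs == [(i, i) for i in range(30)]

    def test_noisy_copy_full_coverage(self, warm_aligner):
        p = sd.make_pocket(L=50, seed=9)
        rmsds = []
        for s in range(5):
            q = sd.perturb_pocket(p, 0.5, seed=s)
            aln = pa.align_pockets(p, q)
            assert aln.n_aligned >= 48
            rmsds.append(aln.rmsd)
        # expected Ca displacement ~ sigma*sqrt(3); superposition shrinks it a bit
        assert 0.4 < np.mean(rmsds) < 1.2

    def test_permuted_residue_order_recovered(self, warm_aligner):
        p = sd.make_pocket(L=24, seed=10)
        perm = np.random.default_rng(11).permutation(24)
        q = replace(p, residues=[p.residues[i] for i in perm])
        aln = pa.align_pockets(p, q)
        assert aln.ps_score >= 1.0 - 1e-6
        assert not aln.sequential

    def test_deterministic(self, warm_aligner):
        a = sd.make_pocket(L=28, seed=12)
        b = sd.make_pocket(L=31, seed=13)
        r1 = pa.align_pockets(a, b)
        r2 = pa.align_pockets(a, b)
        assert r1.ps_score == r2.ps_score
        assert r1.pairs == r2.pairs

    def test_too_small_pocket(self):
        small = _toy_pocket([("A", [0, 0, 0], [1, 0, 0]), ("A", [3.8, 0, 0], [1, 0, 0])])
        p = sd.make_pocket(L=12, seed=1)
        with pytest.raises(AlignmentError):
            pa.align_pockets(small, p)

    def test_null_pairs_rarely_significant(self, warm_aligner, null_model_40):
        """Unrelated random pockets mostly land in the null bulk (P > 0.05)."""
        model, _ = null_model_40
        rng = np.random.default_rng(14)
        n_trials, n_sig = 100, 0
        for _ in range(n_trials):
            a = sd.make_pocket(L=40, seed=int(rng.integers(0, 2**31 - 1)))
            b = sd.make_pocket(L=40, seed=int(rng.integers(0, 2**31 - 1)))
            aln = pa.align_pockets(a, b, model=model)
            if aln.p_value < 0.05:
                n_sig += 1
        assert n_sig <= 10


class TestGumbelModel:
    def test_parameter_recovery(self):
        from scipy.stats import gumbel_r

        rng = np.random.default_rng(15)
        samples = gumbel_r.rvs(loc=0.25, scale=0.03, size=5000, random_state=rng)
        model = pa.calibrate_gumbel([(s, 50) for s in samples], [40, 60])
        assert model.mu[0] == pytest.approx(0.25, abs=0.005)
        assert model.beta[0] == pytest.approx(0.03, abs=0.005)

    def test_p_at_mu_closed_form(self):
        model = pa.GumbelModel(np.array([40.0, 60.0]), np.array([0.25]),
                               np.array([0.03]), np.array([5000]))
        assert model.p_value(0.25, 50) == pytest.approx(1 - np.exp(-1), abs=1e-9)

    def test_survival_strictly_decreasing(self):
        model = pa.GumbelModel(np.array([40.0, 60.0]), np.array([0.25]),
                               np.array([0.03]), np.array([5000]))
        grid = np.linspace(0.18, 0.60, 85)  # where the survival is fp-resolvable
        pv = [model.p_value(s, 50) for s in grid]
        assert all(a > b for a, b in zip(pv, pv[1:]))

    def test_self_consistent_false_positive_rate(self):
        """On true Gumbel null scores the fitted model reproduces its nominal rate."""
        from scipy.stats import gumbel_r

        rng = np.random.default_rng(16)
        samples = gumbel_r.rvs(loc=0.28, scale=0.02, size=2000, random_state=rng)
        model = pa.calibrate_gumbel([(s, 50) for s in samples], [40, 60])
        frac = np.mean([model.p_value(s, 50) < 0.05 for s in samples])
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_underfilled_bin_widens_with_warning(self):
        rng = np.random.default_rng(17)
        samples = [(float(s), 45) for s in rng.normal(0.3, 0.02, size=300)]
        samples += [(float(s), 75) for s in rng.normal(0.3, 0.02, size=5)]
        with pytest.warns(UserWarning, match="widened"):
            model = pa.calibrate_gumbel(samples, [40, 60, 90])
        assert np.isfinite(model.mu).all()

    def test_missing_model_error(self):
        with pytest.raises(pa.CalibrationError):
            pa.p_value(0.5, 50, None)

    def test_tail_p_near_zero(self):
        model = pa.GumbelModel(np.array([40.0, 60.0]), np.array([0.28]),
                               np.array([0.02]), np.array([2000]))
        assert model.p_value(0.99, 50) < 1e-10


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_kabsch_rigid_property(seed):
    """Any rigid copy superposes back to (near) zero RMSD."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 20))
    A = rng.normal(size=(n, 3)) * 4
    if np.linalg.svd(A - A.mean(0), compute_uv=False)[1] < 1e-6:
        return  # skip degenerate draws
    B = A @ random_rotation(rng).T + rng.normal(size=3) * 10
    _, _, rmsd = pa.kabsch_superpose(A, B)
    assert rmsd < 1e-7
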