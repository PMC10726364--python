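"""Grid-search charge enumeration, dipole filtering, and probe-energy scoring."""

import itertools
import math

import numpy as np
import pytest

from ringdyn.charge_fit import (
    COULOMB_K,
    EA_TO_DEBYE,
    ChargeFitProblem,
    ChargeSet,
    FitAtom,
    WaterProbe,
    compute_dipole,
    dipole_filter,
    enumerate_charge_sets,
    interaction_energy,
    rank_candidates,
    run_grid_search,
    score_interactions,
)
from ringdyn.errors import DegenerateGeometryError, EnumerationCapError, UsageError


def brute_force_count(problem: ChargeFitProblem) -> int:
    """Independent exhaustive oracle over the integer charge lattice."""
    order, members = problem.free_groups()
    g = problem.grid
    ranges = []
    for gid in order:
        idx = members[gid]
        lo = math.ceil(max(problem.atoms[i].bounds[0] for i in idx) / g - 1e-9)
        hi = math.floor(min(problem.atoms[i].bounds[1] for i in idx) / g + 1e-9)
        ranges.append(range(lo, hi + 1))
    mult = [len(members[gid]) for gid in order]
    frozen = sum(a.frozen_charge or 0.0 for a in problem.atoms if a.frozen_charge is not None)
    target = round((problem.total_charge - frozen) / g)
    return sum(
        1
        for combo in itertools.product(*ranges)
        if sum(m * v for m, v in zip(mult, combo)) == target
    )


def atoms_line(n, spacing=1.0, **kw):
    return [FitAtom(f"A{i}", (i * spacing, 0.0, 0.0), **kw) for i in range(n)]


class TestEnumeration:
    def test_single_atom_forced_by_sum(self):
        problem = ChargeFitProblem(atoms=atoms_line(1), total_charge=-0.15)
        sets = list(enumerate_charge_sets(problem))
        assert len(sets) == 1
        assert sets[0].charges == (-0.15,)

    def test_two_atom_lattice(self):
        atoms = [
            FitAtom("A", (0, 0, 0), bounds=(-0.05, 0.05)),
            FitAtom("B", (1, 0, 0), bounds=(-0.05, 0.05)),
        ]
        problem = ChargeFitProblem(atoms=atoms, total_charge=0.0)
        sets = [cs.charges for cs in enumerate_charge_sets(problem)]
        assert sets == [(-0.05, 0.05), (0.0, 0.0), (0.05, -0.05)]

    def test_symmetry_group_ties_atoms(self):
        atoms = [
            FitAtom("H1", (0, 0, 0), group="H", bounds=(-0.10, 0.10)),
            FitAtom("H2", (1, 0, 0), group="H", bounds=(-0.10, 0.10)),
            FitAtom("C", (2, 0, 0), bounds=(-0.10, 0.10)),
        ]
        problem = ChargeFitProblem(atoms=atoms, total_charge=0.0)
        sets = list(enumerate_charge_sets(problem))
        assert len(sets) == brute_force_count(problem)
        for cs in sets:
            assert cs.charges[0] == cs.charges[1]  # symmetry-consistent
            assert sum(cs.charges) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_groups", [1, 2, 3, 4, 5])
    def test_count_matches_brute_force_oracle(self, n_groups):
        """Enumeration equals an independent itertools oracle up to 5 free groups."""
        rng = np.random.default_rng(n_groups)
        atoms = []
        for g in range(n_groups):
            mult = int(rng.integers(1, 3))
            lo = float(rng.choice([-0.2, -0.15, -0.1]))
            hi = float(rng.choice([0.1, 0.15, 0.2]))
            for j in range(mult):
                atoms.append(
                    FitAtom(f"G{g}_{j}", (g + 0.1 * j, 0, 0), group=f"g{g}", bounds=(lo, hi))
                )
        problem = ChargeFitProblem(atoms=atoms, total_charge=0.05)
        assert len(list(enumerate_charge_sets(problem))) == brute_force_count(problem)

    def test_every_set_grid_aligned_and_summing(self):
        atoms = atoms_line(3, bounds=(-0.2, 0.2))
        problem = ChargeFitProblem(atoms=atoms, total_charge=0.1)
        for cs in enumerate_charge_sets(problem):
            assert sum(cs.charges) == pytest.approx(0.1, abs=1e-9)
            for q in cs.charges:
                assert q / problem.grid == pytest.approx(round(q / problem.grid), abs=1e-9)

    def test_infeasible_sum_warns_and_yields_nothing(self):
        problem = ChargeFitProblem(atoms=atoms_line(1), total_charge=-0.17)
        with pytest.warns(UserWarning, match="integer multiple"):
            assert list(enumerate_charge_sets(problem)) == []

    def test_cap_refusal_reports_projected_bound(self):
        atoms = atoms_line(6, bounds=(-1.0, 1.0))
        problem = ChargeFitProblem(atoms=atoms, total_charge=0.0, enumeration_cap=1000)
        with pytest.raises(EnumerationCapError) as err:
            list(enumerate_charge_sets(problem))
        assert err.value.projected == 41**6

    def test_frozen_backbone_charges_pass_through(self):
        atoms = [
            FitAtom("N", (0, 0, 0), frozen_charge=-0.3),
            FitAtom("X", (1, 0, 0), bounds=(-0.5, 0.5)),
        ]
        problem = ChargeFitProblem(atoms=atoms, total_charge=0.0)
        sets = list(enumerate_charge_sets(problem))
        assert len(sets) == 1
        assert sets[0].charges == (-0.3, 0.3)


class TestDipole:
    def test_all_zero_charges(self):
        assert compute_dipole([0.0, 0.0], [[0, 0, 0], [1, 0, 0]]) == 0.0

    def test_unit_conversion_constant(self):
        """+0.5/-0.5 e at 1 A -> 0.5 e*A = 2.40160 D."""
        mu = compute_dipole([0.5, -0.5], [[0, 0, 0], [1, 0, 0]])
        assert mu == pytest.approx(0.5 * EA_TO_DEBYE, abs=1e-9)
        assert mu == pytest.approx(2.40160, abs=1e-5)

    def test_neutral_set_origin_independent(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-3, 3, size=(5, 3))
        q = rng.uniform(-0.5, 0.5, size=5)
        q[-1] = -q[:-1].sum()
        for _ in range(20):
            shift = rng.uniform(-100, 100, size=3)
            assert compute_dipole(q, pos + shift) == pytest.approx(
                compute_dipole(q, pos), abs=1e-9
            )

    def test_filter_band_inclusive(self):
        """Ratios 1.2 and 1.5 retain; 1.0 and 1.55 reject."""
        pos = [[0, 0, 0], [1, 0, 0]]
        ref = 1.0 * EA_TO_DEBYE  # reference: 1 e*A

        def charge_set(ratio):
            return ChargeSet(charges=(ratio, -ratio))

        problem = ChargeFitProblem(
            atoms=[FitAtom("A", (0, 0, 0)), FitAtom("B", (1, 0, 0))],
            reference_dipole=ref,
        )
        candidates = [charge_set(r) for r in (1.0, 1.2, 1.35, 1.5, 1.55)]
        kept = list(dipole_filter(candidates, problem))
        ratios = [compute_dipole(cs, np.asarray(pos)) / ref for cs in kept]
        assert ratios == pytest.approx([1.2, 1.35, 1.5])

    def test_filter_requires_positive_reference(self):
        problem = ChargeFitProblem(atoms=atoms_line(1), reference_dipole=None)
        with pytest.raises(UsageError):
            list(dipole_filter([ChargeSet((0.0,))], problem))


class TestInteractions:
    def test_coulomb_constant_check(self):
        """Unit opposite charges at K/100 A give exactly -100 kcal/mol."""
        probe = WaterProbe(
            positions=[[COULOMB_K / 100.0, 0, 0], [50, 50, 50], [60, 60, 60]],
            reference_energy=0.0,
            charges=(-1.0, 0.0, 0.0),
            lj=(None, None, None),
        )
        e = interaction_energy([1.0], [[0.0, 0.0, 0.0]], [None], probe)
        assert e == pytest.approx(-100.0, abs=1e-9)

    def test_zero_charges_no_lj_gives_zero(self):
        probe = WaterProbe(
            positions=[[3, 0, 0], [3.8, 0.6, 0], [3.8, -0.6, 0]],
            reference_energy=0.0,
            lj=(None, None, None),
        )
        assert interaction_energy([0.0, 0.0], [[0, 0, 0], [1, 0, 0]], [None, None], probe) == 0.0

    def test_coincident_atoms_raise(self):
        probe = WaterProbe(
            positions=[[0, 0, 0], [1, 1, 1], [2, 2, 2]],
            reference_energy=0.0,
            lj=(None, None, None),
        )
        with pytest.raises(DegenerateGeometryError):
            interaction_energy([1.0], [[0, 0, 0]], [None], probe)

    def _self_consistent_problem(self):
        """Probes whose reference energies the module itself computed for a known set."""
        atoms = [
            FitAtom("C", (0.0, 0.0, 0.0), bounds=(-0.2, 0.2)),
            FitAtom("O", (1.2, 0.0, 0.0), bounds=(-0.2, 0.2)),
        ]
        lj = {"C": (0.07, 1.99), "O": (0.12, 1.70)}
        known = ChargeSet(charges=(0.15, -0.15))
        probes = []
        for dist in (3.2, 3.6, 4.5):
            probe = WaterProbe(
                positions=[[dist, 0, 0], [dist + 0.76, 0.59, 0], [dist + 0.76, -0.59, 0]],
                reference_energy=0.0,
            )
            e = interaction_energy(
                known.charges, [a.position for a in atoms], [lj[a.name] for a in atoms], probe
            )
            probes.append(
                WaterProbe(positions=probe.positions, reference_energy=e)
            )
        return (
            ChargeFitProblem(atoms=atoms, total_charge=0.0, lj_params=lj, probes=probes),
            known,
        )

    def test_self_consistent_reference_passes_with_zero_deviation(self):
        problem, known = self._self_consistent_problem()
        result = score_interactions(known, problem)
        np.testing.assert_allclose(result.deviations, 0.0, atol=1e-10)
        assert result.passed

    def test_tolerance_pass_fail_boundary(self):
        """A 0.25 e set deviates beyond +/-0.2 kcal/mol on these probes; fails."""
        problem, known = self._self_consistent_problem()
        wrong = ChargeSet(charges=(0.25, -0.25))
        result = score_interactions(wrong, problem)
        assert result.max_abs > problem.tolerance
        assert not result.passed

    def test_grid_search_recovers_self_consistent_charges(self):
        problem, known = self._self_consistent_problem()
        ranked = run_grid_search(problem, apply_dipole_filter=False)
        assert ranked[0][0].charges == known.charges
        assert ranked[0][1].rms == pytest.approx(0.0, abs=1e-10)

    def test_filter_then_score_order_independent(self):
        """Same passing set whether the dipole filter runs before or after scoring."""
        problem, known = self._self_consistent_problem()
        problem.reference_dipole = compute_dipole(known, problem.positions) / 1.35
        filtered_then_scored = {
            cs.charges
            for cs in dipole_filter(enumerate_charge_sets(problem), problem)
            if score_interactions(cs, problem).passed
        }
        passing = [
            cs for cs in enumerate_charge_sets(problem)
            if score_interactions(cs, problem).passed
        ]
        scored_then_filtered = {cs.charges for cs in dipole_filter(passing, problem)}
        assert filtered_then_scored == scored_then_filtered
        assert known.charges in filtered_then_scored


class TestRanking:
    def test_orders_by_rms_then_ties(self):
        def fake(rms, max_abs, charges):
            from ringdyn.charge_fit import ScoreResult

            return (
                ChargeSet(charges),
                ScoreResult(np.array([rms]), rms, max_abs, True, 0.2),
            )

        worse, better = fake(0.10, 0.1, (0.1,)), fake(0.05, 0.05, (0.2,))
        assert rank_candidates([worse, better])[0][0].charges == (0.2,)
        # tie on rms broken by max_abs, then lexicographic charges
        a, b = fake(0.05, 0.09, (0.3,)), fake(0.05, 0.04, (0.4,))
        assert rank_candidates([a, b])[0][0].charges == (0.4,)

    def test_agrees_with_sort_oracle_on_random_fixtures(self):
        from ringdyn.charge_fit import ScoreResult

        rng = np.random.default_rng(42)
        items = []
        for i in range(100):
            rms = float(rng.choice([0.05, 0.1, 0.2]))
            mx = float(rng.choice([0.1, 0.3]))
            items.append(
                (ChargeSet((float(rng.integers(-5, 5)) * 0.05,)),
                 ScoreResult(np.array([]), rms, mx, True, 0.2))
            )
        expected = sorted(items, key=lambda t: (t[1].rms, t[1].max_abs, t[0].charges))
        assert [t[0].charges for t in rank_candidates(items)] == [
            t[0].charges for t in expected
        ]
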