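import math

import numpy as np
import pytest

from rotamerbh.torsion import KB_KCAL_MOL_K, normalize_angle
from rotamerbh.library import equilibrium_populations
from rotamerbh.bh import (
    BHScheme,
    MinimumRecord,
    Potential,
    cartesian_displacement_move,
    group_rotation_move,
    harmonic_free_energy,
    local_minimize,
    markov_diagnostics,
    metropolis_accept,
    rotamer_move,
    run_basin_hopping,
    scheme_presets,
    set_dihedral,
    superposition_rmsd,
    rotate_dihedral,
)


class QuadraticBowl(Potential):
    """V = 0.5 * sum(k_i x_i^2) with known normal-mode frequencies."""

    def __init__(self, ks):
        self.ks = np.asarray(ks, dtype=float)

    def energy(self, x):
        return 0.5 * float(np.sum(self.ks * np.ravel(x) ** 2))

    def gradient(self, x):
        return (self.ks * np.ravel(x)).reshape(np.shape(x))

    def hessian(self, x):
        return np.diag(self.ks)


class DoubleWell1D(Potential):
    """V = x^4 - 2 x^2 (+ tilt*x): minima near +-1."""

    def __init__(self, tilt=0.0):
        self.tilt = tilt

    def energy(self, x):
        x = float(np.ravel(x)[0])
        return x**4 - 2 * x**2 + self.tilt * x

    def gradient(self, x):
        xv = float(np.ravel(x)[0])
        return np.reshape([4 * xv**3 - 4 * xv + self.tilt], np.shape(x))


class TestLocalMinimize:
    def test_isotropic_bowl(self):
        pot = QuadraticBowl([2.0, 2.0, 2.0])
        rec = local_minimize(pot, np.ones(3))
        assert rec.converged
        assert rec.potential_energy == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rec.coordinates, 0.0, atol=1e-6)

    def test_start_at_minimum_is_cheap(self):
        pot = QuadraticBowl([1.0, 3.0])
        rec = local_minimize(pot, np.zeros(2))
        assert rec.converged
        assert rec.minimizer_iterations <= 1
        assert rec.function_evaluations <= 3

    def test_double_well_falls_to_positive_minimum(self):
        rec = local_minimize(DoubleWell1D(), np.array([0.1]))
        assert rec.coordinates[0] == pytest.approx(1.0, abs=1e-5)
        assert rec.potential_energy == pytest.approx(-1.0, abs=1e-9)

    def test_nonconvergence_flagged_not_raised(self):
        pot = QuadraticBowl([1.0])
        rec = local_minimize(pot, np.array([100.0]), rms_force_tol=1e-12, max_iter=1)
        assert not rec.converged


class TestHarmonicFreeEnergy:
    def test_anisotropic_closed_form(self):
        ks = np.array([1.0, 4.0])  # omegas 1 and 2
        pot = QuadraticBowl(ks)
        rec = local_minimize(pot, np.array([0.3, -0.2]))
        T = 298.0
        F = harmonic_free_energy(pot, rec, temperature=T)
        expected = rec.potential_energy + KB_KCAL_MOL_K * T * sum(
            math.log(math.sqrt(k)) for k in ks
        )
        assert F == pytest.approx(expected, abs=1e-6)

    def test_frequency_ratio_two_gives_population_ratio_two(self):
        # equal-depth wells, omega2 = 2*omega1 -> p1/p2 = 2
        pot1, pot2 = QuadraticBowl([1.0]), QuadraticBowl([4.0])
        r1 = local_minimize(pot1, np.zeros(1))
        r2 = local_minimize(pot2, np.zeros(1))
        F1 = harmonic_free_energy(pot1, r1)
        F2 = harmonic_free_energy(pot2, r2)
        p = equilibrium_populations([F1, F2])
        assert p[0] / p[1] == pytest.approx(2.0, rel=1e-9)

    def test_identical_wells_zero_difference(self):
        pot = QuadraticBowl([2.0, 5.0])
        r = local_minimize(pot, np.array([0.1, 0.1]))
        assert harmonic_free_energy(pot, r) == pytest.approx(
            harmonic_free_energy(pot, r)
        )

    def test_saddle_rejected(self):
        pot = QuadraticBowl([1.0, -1.0])
        rec = MinimumRecord(0, np.zeros(2), 0.0)
        with pytest.raises(ValueError, match="not a minimum"):
            harmonic_free_energy(pot, rec)


class TestMetropolis:
    def test_downhill_and_tie_always_accepted(self):
        rng = np.random.default_rng(0)
        assert metropolis_accept(-1.0, 1.3, rng)
        assert metropolis_accept(0.0, 1.3, rng)

    def test_acceptance_frequency_at_ln2(self):
        T = 1.3
        rng = np.random.default_rng(123)
        delta = T * math.log(2)
        n = 10_000
        acc = sum(metropolis_accept(delta, T, rng) for _ in range(n)) / n
        assert acc == pytest.approx(0.5, abs=0.02)


def bonded_geometry(pot, coords):
    x = coords.reshape(-1, 3)
    bonds = np.array(
        [np.linalg.norm(x[j] - x[i]) for i, j in pot.topology.bonds]
    )
    return bonds


class TestMoves:
    def test_full_turn_is_identity(self, chain2):
        x = chain2.start_coordinates()
        q = chain2.topology.residues[0].chi_quads[0]
        x2 = rotate_dihedral(x, chain2.topology, q, 360.0)
        assert np.allclose(x2, x, atol=1e-9)

    def test_rotation_inverse(self, chain2):
        x = chain2.start_coordinates()
        q = chain2.topology.backbone_quads[0]
        x2 = rotate_dihedral(
            rotate_dihedral(x, chain2.topology, q, 77.0), chain2.topology, q, -77.0
        )
        assert np.allclose(x2, x, atol=1e-9)

    def test_zero_selection_probability_identity(self, chain2):
        rng = np.random.default_rng(0)
        x = chain2.start_coordinates()
        x2 = group_rotation_move(x, chain2.topology, rng, dihedral_selection_prob=0.0)
        assert np.array_equal(x2, x)

    def test_moves_preserve_bond_geometry(self, chain2):
        rng = np.random.default_rng(1)
        x = chain2.start_coordinates()
        before = bonded_geometry(chain2, x)
        x2 = group_rotation_move(
            x, chain2.topology, rng, dihedral_selection_prob=1.0
        )
        assert np.allclose(bonded_geometry(chain2, x2), before, atol=1e-9)

    def test_cartesian_move_bound_and_determinism(self):
        x = np.zeros((5, 3))
        a = cartesian_displacement_move(x, np.random.default_rng(9), 1.0)
        b = cartesian_displacement_move(x, np.random.default_rng(9), 1.0)
        assert np.array_equal(a, b)
        assert np.all(np.linalg.norm(a, axis=1) <= math.sqrt(3.0) + 1e-12)
        assert np.array_equal(
            cartesian_displacement_move(x, np.random.default_rng(0), 0.0), x
        )

    def test_rotamer_move_forces_chi_mean(self, chain2, chain2_library):
        rng = np.random.default_rng(4)
        x = chain2.start_coordinates()
        x2 = rotamer_move(x, chain2.topology, chain2_library, 2, rng)
        chi = chain2.measure_chi(x2)
        for i, res in enumerate(chain2.topology.residues):
            ctx = chain2.topology.context(res)
            dists = [
                abs(normalize_angle(chi[i] - r.chi_mean[0]))
                for r in chain2_library.get(ctx)
            ]
            assert min(dists) < 1e-6

    def test_rotamer_move_leaves_backbone(self, chain2, chain2_library):
        rng = np.random.default_rng(4)
        x = chain2.start_coordinates()
        bb_before = chain2.measure_backbone(x)
        x2 = rotamer_move(x, chain2.topology, chain2_library, 2, rng)
        assert np.allclose(chain2.measure_backbone(x2), bb_before, atol=1e-9)

    def test_rotamer_draw_frequencies_follow_probabilities(self, chain2, chain2_library):
        res = chain2.topology.residues[0]
        ctx = chain2.topology.context(res)
        rots = chain2_library.get(ctx)
        probs = np.array([r.probability for r in rots])
        probs = probs / probs.sum()
        rng = np.random.default_rng(77)
        x = chain2.start_coordinates()
        counts = np.zeros(len(rots))
        n = 10_000
        for _ in range(n):
            x2 = rotamer_move(x, chain2.topology, chain2_library, 2, rng)
            chi0 = chain2.measure_chi(x2)[0]
            k = int(
                np.argmin(
                    [abs(normalize_angle(chi0 - r.chi_mean[0])) for r in rots]
                )
            )
            counts[k] += 1
        assert np.all(np.abs(counts / n - probs) < 0.02)

    def test_rotamer_move_missing_context_named(self, chain2, chain2_library):
        lib = type(chain2_library)(
            entries={}, temperature=298.0, cutoff=40.0, prune=0.005
        )
        with pytest.raises(KeyError, match="RS1"):
            rotamer_move(
                chain2.start_coordinates(), chain2.topology, lib, 1,
                np.random.default_rng(0),
            )


class TestRunBasinHopping:
    def scheme(self, **kw):
        base = dict(
            name="t", side_move="group_rotation", n_SC=1, f_SC=1, n_BB=1, f_BB=1,
            temperature=1.3,
        )
        base.update(kw)
        return BHScheme(**base)

    def test_zero_steps_returns_minimized_start(self, chain2):
        traj = run_basin_hopping(
            chain2, chain2.start_coordinates(), self.scheme(), 0, 0
        )
        assert len(traj.records) == 1
        assert traj.records[0].converged

    def test_infinite_temperature_accepts_everything(self, chain2):
        traj = run_basin_hopping(
            chain2, chain2.start_coordinates(),
            self.scheme(temperature=1e12), 25, 1,
        )
        assert all(r.accepted for r in traj.records)

    def test_records_satisfy_force_tolerance(self, chain2):
        traj = run_basin_hopping(
            chain2, chain2.start_coordinates(), self.scheme(), 25, 2
        )
        for r in traj.records:
            assert r.rms_gradient <= 1e-6
            re_min = local_minimize(chain2, r.coordinates)
            assert abs(re_min.potential_energy - r.potential_energy) < 1e-9

    def test_move_cadence(self, chain2, chain2_library):
        sch = self.scheme(side_move="rotamer", n_SC=1, f_SC=2, n_BB=1, f_BB=3)
        traj = run_basin_hopping(
            chain2, chain2.start_coordinates(), sch, 12, 3, library=chain2_library
        )
        for r in traj.records[1:]:
            assert ("SC" in r.move_type) == (r.step % 2 == 0)
            assert ("BB" in r.move_type) == (r.step % 3 == 0)

    def test_rotamer_scheme_finds_toy_global_minimum(self, chain4, chain4_library):
        sch = scheme_presets()["rotamer 2"]
        for seed in (0, 1, 2):
            traj = run_basin_hopping(
                chain4, chain4.start_coordinates(), sch, 2000, seed,
                library=chain4_library,
                reference_energy=chain4.global_minimum_energy,
                stop_at_success=True,
            )
            assert traj.success_step is not None
            assert traj.best_energy <= chain4.global_minimum_energy + 1.0

    def test_detailed_balance_on_double_well(self):
        # tilted 1-D double well explored with Cartesian displacements: the
        # Markov chain should occupy the two basins with Boltzmann weights.
        # The displacement is chosen much wider than the basin spacing so the
        # inter-basin proposal density is symmetric (a narrow kernel would
        # bias the chain by basin geometry, not by energies).
        pot = DoubleWell1D(tilt=0.3)
        mins = sorted(
            local_minimize(pot, np.array([s])).potential_energy for s in (-1.0, 1.0)
        )
        dV = mins[1] - mins[0]
        T = 1.0
        sch = self.scheme(n_SC=0, n_BB=0, displacement_amplitude=20.0, temperature=T)
        traj = run_basin_hopping(pot, np.array([1.0]), sch, 4000, 5)
        side = []
        current = traj.records[0]
        for r in traj.records[1:]:
            if r.accepted:
                current = r
            side.append(current.coordinates[0] > 0)
        frac_high = np.mean(side)  # x>0 is the shallower (higher) basin
        expected = math.exp(-dV / T) / (1 + math.exp(-dV / T))
        blocks = np.array_split(np.asarray(side, dtype=float), 20)
        se = np.std([b.mean() for b in blocks], ddof=1) / math.sqrt(len(blocks))
        assert abs(frac_high - expected) < 3 * max(se, 0.01)

    def test_febh_acceptance_uses_free_energy(self):
        pot = QuadraticBowl([1.0, 1.0])
        sch = self.scheme(n_SC=0, n_BB=0, displacement_amplitude=0.5,
                          use_free_energy=True)
        traj = run_basin_hopping(pot, np.array([0.5, 0.5]), sch, 3, 0)
        assert all(r.free_energy is not None for r in traj.records)


class TestDiagnostics:
    def test_identical_minima_zero_series(self, chain2):
        rec = local_minimize(chain2, chain2.start_coordinates())
        traj_records = []
        for s in range(3):
            r = MinimumRecord(s, rec.coordinates.copy(), rec.potential_energy,
                              accepted=True)
            traj_records.append(r)
        from rotamerbh.bh import BHTrajectory

        traj = BHTrajectory(records=traj_records)
        diag = markov_diagnostics(traj)
        assert np.allclose(diag["delta_e"], 0.0)
        assert np.allclose(diag["delta_d"], 0.0, atol=1e-9)

    def test_rigid_rotation_gives_zero_distance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 3))
        b = Rotation.random(random_state=np.random.RandomState(1)).apply(a) + 3.0
        assert superposition_rmsd(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_hand_built_energy_series(self):
        from rotamerbh.bh import BHTrajectory

        coords = np.zeros((2, 3))
        records = [
            MinimumRecord(0, coords, 0.0, accepted=True),
            MinimumRecord(1, coords, 2.0, accepted=True),
            MinimumRecord(2, coords, 1.0, accepted=True),
        ]
        diag = markov_diagnostics(BHTrajectory(records=records))
        assert list(diag["delta_e"]) == [2.0, -1.0]


class TestSchemePresets:
    def test_benchmark_rows_verbatim(self):
        presets = scheme_presets()
        assert (
            presets["rotamer 2"].n_SC,
            presets["rotamer 2"].f_SC,
            presets["rotamer 2"].n_BB,
            presets["rotamer 2"].f_BB,
        ) == (2, 1, 2, 2)
        assert (
            presets["group rotation 4"].n_SC,
            presets["group rotation 4"].f_SC,
            presets["group rotation 4"].n_BB,
            presets["group rotation 4"].f_BB,
        ) == (6, 1, 2, 1)

    def test_all_presets_benchmark_conditions(self):
        presets = scheme_presets()
        assert len(presets) == 12
        assert sum(s.side_move == "rotamer" for s in presets.values()) == 8
        assert sum(s.side_move == "group_rotation" for s in presets.values()) == 4
        for s in presets.values():
            assert s.temperature == 1.3
            assert s.displacement_amplitude == 0.0
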