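import numpy as np
import pytest

from phbind import model_io, pmf, synthetic
from phbind.constants import kt_kcal
from phbind.pmf import (
    ConnectivityError,
    PMFProfile,
    UmbrellaPlan,
    UmbrellaWindow,
    bootstrap_errors,
    convergence_profiles,
    extract_windows,
    find_wells,
    plan_umbrella_centers,
    read_window_file,
    shift_to_bulk,
    wham,
    write_window_file,
)
from phbind.potentials import flat

from conftest import build_topology, frame


class TestWindowPlanning:
    def test_default_protocol_gives_24_centers(self):
        centers = plan_umbrella_centers(UmbrellaPlan(start=1.0))
        assert len(centers) == 24
        fine = centers[centers <= 3.0 + 1e-9]
        coarse = centers[centers > 3.0 + 1e-9]
        assert len(fine) == 21 and len(coarse) == 3
        assert np.allclose(np.diff(fine), 0.1)
        assert np.allclose(np.diff(coarse), 0.2)

    def test_total_equal_fine_range_has_no_coarse_segment(self):
        centers = plan_umbrella_centers(UmbrellaPlan(start=0.5, total=2.0))
        assert len(centers) == 21

    def test_coarse_step_never_overshoots(self):
        centers = plan_umbrella_centers(UmbrellaPlan(start=0.5, total=2.05))
        assert len(centers) == 21

    def test_total_shorter_than_fine_range_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaPlan(start=0.5, total=1.0)


class TestExtractWindows:
    def _pull_trajectory(self, rate=0.001, dt=20.0, t_end=2800.0, start=1.0):
        topo = build_topology(["protein", "lipid:PIP3"])
        frames = []
        t = 0.0
        while t <= t_end:
            sep = start + rate * t
            frames.append(frame([[5, 5, 5 + sep], [5, 5, 5.0]], box=(10, 10, 20), time=t))
            t += dt
        return model_io.Trajectory(topology=topo, frames=frames)

    @staticmethod
    def _rc(fr):
        return fr.coords[0, 2] - fr.coords[1, 2]

    def test_pull_at_stated_rate_hits_every_center(self):
        traj = self._pull_trajectory()
        plan = UmbrellaPlan(start=1.0)
        out = extract_windows(traj, plan, self._rc)
        assert len(out) == 24
        for fr, z0 in out:
            assert abs(self._rc(fr) - z0) <= 0.01

    def test_short_trajectory_reports_missing_centers(self):
        traj = self._pull_trajectory(t_end=1000.0)
        with pytest.raises(ValueError, match="centres"):
            extract_windows(traj, UmbrellaPlan(start=1.0), self._rc)

    def test_ties_resolve_to_earliest_frame(self):
        topo = build_topology(["protein", "lipid:PIP3"])
        frames = [
            frame([[5, 5, 5 + s], [5, 5, 5.0]], box=(10, 10, 20), time=t)
            for t, s in [(0.0, 1.0), (20.0, 1.0), (40.0, 1.1), (60.0, 1.1)]
        ]
        traj = model_io.Trajectory(topology=topo, frames=frames)
        plan = UmbrellaPlan(start=1.0, total=0.1, fine_range=0.1)
        out = extract_windows(traj, plan, self._rc)
        assert out[0][0].time == 0.0
        assert out[1][0].time == 40.0


class TestWham:
    def test_unbiased_window_is_boltzmann_inversion(self):
        """With a single zero-bias window WHAM must reduce exactly to
        -kT ln(histogram) up to an additive constant."""
        truth = synthetic.default_double_well()
        wins = synthetic.generate_umbrella_samples(
            truth, [(2.0, 0.0)], 5000, seed=3, z_range=(1.0, 3.6)
        )
        prof = wham(wins)
        kt = kt_kcal(prof.temperature)
        edges = prof.z[0] - prof.bin_width / 2 + prof.bin_width * np.arange(len(prof.z) + 1)
        h = np.histogram(wins[0].samples, bins=edges)[0].astype(float)
        direct = -kt * np.log(np.where(h > 0, h, np.nan) / h.sum())
        dev = prof.free_energy - direct
        dev = dev[np.isfinite(dev)]
        assert np.max(np.abs(dev - dev.mean())) <= 1e-10

    def test_invariant_under_window_reordering(self):
        truth = synthetic.default_double_well()
        centers = plan_umbrella_centers(UmbrellaPlan(start=1.0))
        wins = synthetic.generate_umbrella_samples(
            truth, [(z, 1000.0) for z in centers], 1000, seed=5
        )
        a = shift_to_bulk(wham(wins, z_range=(1.0, 3.6)))
        rng = np.random.default_rng(0)
        b = shift_to_bulk(
            wham([wins[i] for i in rng.permutation(len(wins))], z_range=(1.0, 3.6))
        )
        mask = a.sampled & b.sampled
        assert np.max(np.abs(a.free_energy[mask] - b.free_energy[mask])) < 1e-8

    def test_single_biased_window_on_flat_truth_is_flat(self):
        wins = synthetic.generate_umbrella_samples(flat(), [(2.0, 1000.0)], 10_000, seed=6)
        prof = shift_to_bulk(wham(wins))
        g = prof.free_energy[prof.sampled]
        # central, well-sampled bins only (tails are shot-noise dominated)
        core = prof.counts[prof.sampled] > 100
        assert np.max(np.abs(g[core] - g[core].mean())) < 0.1

    def test_unit_discipline_recovers_truth_in_kcal(self):
        """A bias quoted in kJ/mol/nm^2 against a truth quoted in
        kcal/mol must cancel through the single 4.184 conversion: WHAM on
        a harmonic truth reproduces the kcal/mol profile. A conversion
        error anywhere would distort the recovered well by several
        kcal/mol."""
        from phbind.potentials import harmonic

        truth = harmonic(2.0, 20.0)  # kcal/mol/nm^2
        centers = np.arange(1.6, 2.45, 0.1)
        wins = synthetic.generate_umbrella_samples(
            truth, [(z, 1000.0) for z in centers], 10_000, seed=8
        )
        prof = wham(wins, z_range=(1.6, 2.4))
        kt = kt_kcal(prof.temperature)
        edges = (
            prof.z[0] - prof.bin_width / 2
            + prof.bin_width * np.arange(len(prof.z) + 1)
        )
        target = np.array(
            [
                -kt * np.log(np.mean(np.exp(-truth(np.linspace(a, b, 51)) / kt)))
                for a, b in zip(edges[:-1], edges[1:])
            ]
        )
        mask = prof.sampled & (prof.counts > 200)
        dev = prof.free_energy[mask] - target[mask]
        assert np.max(np.abs(dev - dev.mean())) < 0.15

    def test_disconnected_windows_raise_connectivity_error(self):
        w1 = UmbrellaWindow(1.0, 1000.0, np.full(100, 1.0) + np.linspace(0, 0.02, 100))
        w2 = UmbrellaWindow(3.0, 1000.0, np.full(100, 3.0) + np.linspace(0, 0.02, 100))
        with pytest.raises(ConnectivityError):
            wham([w1, w2])

    def test_unsampled_bins_are_nan_not_zero(self):
        wins = synthetic.generate_umbrella_samples(flat(), [(2.0, 1000.0)], 500, seed=9)
        prof = wham(wins, z_range=(1.0, 3.0))
        assert np.isnan(prof.free_energy[0])
        assert np.isnan(prof.free_energy[-1])


class TestShiftToBulk:
    def _profile(self, g, counts=None):
        g = np.asarray(g, dtype=float)
        return PMFProfile(
            z=np.arange(len(g)) * 0.05 + 1.0,
            free_energy=g,
            counts=np.ones(len(g)) if counts is None else np.asarray(counts),
            temperature=323.0,
            bin_width=0.05,
        )

    def test_constant_profile_shifts_to_zero(self):
        prof = shift_to_bulk(self._profile(np.full(20, 5.0)))
        assert np.allclose(prof.free_energy, 0.0, atol=1e-12)

    def test_idempotent(self):
        prof = self._profile(np.linspace(3, 0, 20))
        once = shift_to_bulk(prof)
        twice = shift_to_bulk(once)
        assert np.allclose(once.free_energy, twice.free_energy, atol=1e-12)

    def test_well_depth_gauge_invariant(self):
        g = -np.exp(-((np.arange(30) - 10.0) ** 2) / 8.0) * 3.0
        a = shift_to_bulk(self._profile(g))
        b = shift_to_bulk(self._profile(g + 7.3))
        assert np.allclose(a.free_energy, b.free_energy, atol=1e-12)

    def test_empty_bulk_region_rejected(self):
        prof = self._profile(np.zeros(10))
        with pytest.raises(ValueError):
            shift_to_bulk(prof, bulk=(99.0, 100.0))


class TestBootstrap:
    def test_degenerate_samples_give_zero_errors(self):
        wins = [
            UmbrellaWindow(z0, 10.0, np.full(50, 2.0)) for z0 in (1.9, 2.0, 2.1)
        ]
        errs = bootstrap_errors(wins, n_boot=10, seed=0)
        assert np.nanmax(errs) == 0.0

    def test_seeded_run_reproducible(self):
        wins = synthetic.generate_umbrella_samples(
            synthetic.default_double_well(),
            [(z, 1000.0) for z in plan_umbrella_centers(UmbrellaPlan(start=1.0))],
            500,
            seed=4,
        )
        e1 = bootstrap_errors(wins, n_boot=15, seed=11, z_range=(1.0, 3.6))
        e2 = bootstrap_errors(wins, n_boot=15, seed=11, z_range=(1.0, 3.6))
        assert np.array_equal(e1, e2, equal_nan=True)

    def test_errors_shrink_with_sample_size(self):
        """Quadrupling per-window samples should roughly halve the
        bootstrap errors (Monte-Carlo 1/sqrt(n) scaling)."""
        truth = synthetic.default_double_well()
        centers = plan_umbrella_centers(UmbrellaPlan(start=1.0))
        biases = [(z, 1000.0) for z in centers]
        small = synthetic.generate_umbrella_samples(truth, biases, 1000, seed=5)
        large = synthetic.generate_umbrella_samples(truth, biases, 4000, seed=5)
        e_small = bootstrap_errors(small, n_boot=40, seed=8, z_range=(1.0, 3.6))
        e_large = bootstrap_errors(large, n_boot=40, seed=8, z_range=(1.0, 3.6))
        ratio = np.nanmedian(e_large) / np.nanmedian(e_small)
        assert 0.4 < ratio < 0.6


class TestConvergence:
    def test_stationary_windows_converge_immediately(self):
        truth = synthetic.default_double_well()
        centers = plan_umbrella_centers(UmbrellaPlan(start=1.0))
        wins = synthetic.generate_umbrella_samples(
            truth, [(z, 1000.0) for z in centers], 10_000, seed=6
        )
        report = convergence_profiles(wins, n_blocks=2, threshold=0.5, z_range=(1.0, 3.6))
        assert report.equilibration_end_block == 0
        assert report.metrics[1] < 0.5

    def test_drifted_first_block_detected(self):
        """Windows whose first third is systematically displaced should
        flag equilibration ending only after the drifted block."""
        truth = synthetic.default_double_well()
        centers = plan_umbrella_centers(UmbrellaPlan(start=1.0))
        wins = synthetic.generate_umbrella_samples(
            truth, [(z, 1000.0) for z in centers], 9000, seed=7
        )
        shifted = []
        for w in wins:
            s = w.samples.copy()
            third = len(s) // 3
            s[:third] = s[:third] + 0.30  # drifted early segment
            shifted.append(UmbrellaWindow(w.z0, w.k_z, s))
        report = convergence_profiles(
            shifted, n_blocks=3, threshold=0.5, z_range=(1.0, 3.9)
        )
        assert report.equilibration_end_block == 1
        assert report.metrics[1] > report.metrics[2]

    def test_final_profile_uses_post_equilibration_blocks(self):
        truth = synthetic.default_double_well()
        centers = plan_umbrella_centers(UmbrellaPlan(start=1.0))
        wins = synthetic.generate_umbrella_samples(
            truth, [(z, 1000.0) for z in centers], 10_000, seed=9
        )
        report = convergence_profiles(wins, n_blocks=2, threshold=0.5, z_range=(1.0, 3.6))
        pooled = wham(wins, z_range=(1.0, 3.6))
        # equilibration ended at block 0 -> final profile uses all samples
        assert report.final_profile.counts.sum() == pooled.counts.sum()

    def test_fewer_than_two_blocks_rejected(self):
        with pytest.raises(ValueError):
            convergence_profiles([], n_blocks=1)


class TestFindWells:
    def _shifted(self, g, errors=None):
        prof = PMFProfile(
            z=np.arange(len(g)) * 0.05 + 1.0,
            free_energy=np.asarray(g, dtype=float),
            counts=np.ones(len(g)),
            temperature=323.0,
            bin_width=0.05,
            errors=None if errors is None else np.asarray(errors, dtype=float),
            bulk_shifted=True,
        )
        return prof

    def test_single_parabola_gives_one_well(self):
        z = np.arange(30)
        g = 0.02 * (z - 12) ** 2 - 2.0
        report = find_wells(self._shifted(g))
        assert len(report.wells) == 1
        assert report.wells[0][0] == pytest.approx(1.0 + 12 * 0.05)

    def test_flat_profile_has_no_wells(self):
        report = find_wells(self._shifted(np.zeros(20)))
        assert report.wells == []

    def test_monotone_profile_has_no_wells(self):
        report = find_wells(self._shifted(np.linspace(-3, 0, 25)))
        assert report.wells == []

    def test_insignificant_bump_filtered_by_errors(self):
        g = np.zeros(20)
        g[10] = -0.05  # dip well inside the error bars
        report = find_wells(self._shifted(g, errors=np.full(20, 0.2)))
        assert report.wells == []

    def test_unshifted_profile_rejected(self):
        prof = PMFProfile(
            z=np.arange(5) * 0.05,
            free_energy=np.zeros(5),
            counts=np.ones(5),
            temperature=323.0,
            bin_width=0.05,
        )
        with pytest.raises(ValueError, match="bulk"):
            find_wells(prof)

    def test_global_minimum_is_deepest(self):
        g = np.zeros(40)
        g[8:13] = [-1, -2.5, -3.0, -2.5, -1]
        g[25:28] = [-0.5, -1.0, -0.5]
        report = find_wells(self._shifted(g))
        assert len(report.wells) == 2
        assert report.global_minimum[1] == pytest.approx(-3.0)
        assert report.barriers[0] == pytest.approx(0.0)


class TestWindowFiles:
    def test_round_trip(self, tmp_path):
        w = UmbrellaWindow(1.5, 1000.0, np.linspace(1.4, 1.6, 10), k_xy=100.0)
        path = tmp_path / "window_00.tsv"
        write_window_file(w, path)
        back = read_window_file(path)
        assert back.z0 == w.z0
        assert back.k_z == w.k_z
        assert back.k_xy == w.k_xy
        assert np.allclose(back.samples, w.samples)
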