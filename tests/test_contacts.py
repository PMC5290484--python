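import numpy as np
import pytest

from phbind import contacts, model_io, synthetic
from phbind.contacts import (
    annulus_count,
    classify_binding_site,
    contact_count_series,
    interaction_persistence,
    leaflet_assign,
    pip_contacts,
    proximal_leaflet,
    residue_contact_ranking,
)
from phbind.encounter import AnalysisConfig, OrientationSeries
from phbind.neighbor import min_image_distance, pairs_within_cutoff

from conftest import build_topology, frame


def brute_force_contacts(fr, topo, cutoff, role):
    """Independent O(N^2) minimum-image oracle."""
    prot = np.flatnonzero(topo.protein_mask())
    phos = np.flatnonzero((topo.roles == role) & topo.is_phosphate)
    out = set()
    for i in phos:
        for j in prot:
            delta = fr.coords[i] - fr.coords[j]
            delta -= fr.box * np.round(delta / fr.box)
            if np.sqrt(np.sum(delta**2)) <= cutoff:
                out.add(int(topo.molecule_ids[i]))
    return out


class TestPipContacts:
    def _pair_topology(self):
        return build_topology(["protein", "lipid:PIP3"])

    def test_phosphate_just_inside_cutoff(self):
        topo = self._pair_topology()
        fr = frame([[5, 5, 5], [5, 5, 5.99]])
        assert pip_contacts(fr, topo) == {int(topo.molecule_ids[1])}

    def test_phosphate_just_outside_cutoff(self):
        topo = self._pair_topology()
        fr = frame([[5, 5, 5], [5, 5, 6.01]])
        assert pip_contacts(fr, topo) == set()

    def test_cutoff_is_inclusive(self):
        topo = self._pair_topology()
        fr = frame([[5, 5, 5], [5, 5, 6.0]])
        assert len(pip_contacts(fr, topo)) == 1

    def test_contact_across_periodic_boundary(self):
        topo = self._pair_topology()
        fr = frame([[0.2, 5, 5], [9.9, 5, 5]])
        assert len(pip_contacts(fr, topo)) == 1

    def test_absent_role_warns_and_returns_empty(self, caplog):
        topo = build_topology(["protein"])
        with caplog.at_level("WARNING"):
            out = pip_contacts(frame([[5, 5, 5]]), topo, role="lipid:PIP2")
        assert out == set()
        assert "lipid:PIP2" in caplog.text

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        topo = build_topology(["protein"] * 8 + ["lipid:PIP3"] * 50)
        fr = frame(rng.uniform(0, [8, 8, 14], size=(58, 3)), box=(8, 8, 14))
        got = pip_contacts(fr, topo)
        expected = brute_force_contacts(fr, topo, 1.0, "lipid:PIP3")
        assert got == expected


class TestCellList:
    @pytest.mark.parametrize("seed", range(3))
    def test_pairs_equal_all_pairs_search(self, seed):
        rng = np.random.default_rng(100 + seed)
        box = np.array([9.0, 7.0, 11.0])
        a = rng.uniform(0, box, size=(20, 3))
        b = rng.uniform(0, box, size=(200, 3))
        got = set(map(tuple, pairs_within_cutoff(a, b, box, 1.3)))
        d = min_image_distance(a, b, box)
        expected = set(zip(*np.nonzero(d <= 1.3)))
        assert got == expected

    def test_cutoff_beyond_half_box_rejected(self):
        with pytest.raises(ValueError):
            pairs_within_cutoff(np.zeros((1, 3)), np.zeros((1, 3)), [2, 2, 2], 1.5)


def _mini_trajectory(z_protein):
    """Protein bead + one PIP3 whose contact state tracks z_protein."""
    topo = build_topology(["protein", "lipid:PIP3", "lipid:POPC", "lipid:POPC"])
    frames = []
    for k, zp in enumerate(z_protein):
        frames.append(
            frame(
                [[5, 5, zp], [5, 5, 2.5], [1, 1, 2.5], [2, 2, 7.5]],
                time=20.0 * k,
            )
        )
    return model_io.Trajectory(topology=topo, frames=frames)


class TestContactSeries:
    def test_bound_filter_keeps_expected_frames(self):
        traj = _mini_trajectory([3.0, 9.9, 3.2])
        d = np.array([abs(zp - 4.375) for zp in [3.0, 9.9, 3.2]])  # not used
        series = OrientationSeries(
            traj.times, [3.0, 6.0, 3.0], [0.8] * 3, [True, False, True]
        )
        out = contact_count_series(traj, series, bound_only=True)
        assert len(out) == 2

    def test_no_bound_frames_gives_empty_series(self):
        traj = _mini_trajectory([9.0, 9.0])
        series = OrientationSeries(traj.times, [6.0, 6.0], [0.0, 0.0], [False, False])
        out = contact_count_series(traj, series, bound_only=True)
        assert len(out) == 0

    def test_all_frames_superset_of_bound_frames(self):
        traj = _mini_trajectory([3.0, 9.9, 3.2])
        series = OrientationSeries(
            traj.times, [3.0, 6.0, 3.0], [0.8] * 3, [True, False, True]
        )
        all_f = contact_count_series(traj, series, bound_only=False)
        bound = contact_count_series(traj, series, bound_only=True)
        assert all_f.counts.sum() >= bound.counts.sum()

    def test_length_mismatch_rejected(self):
        traj = _mini_trajectory([3.0, 3.0])
        series = OrientationSeries([0.0], [3.0], [0.8], [True])
        with pytest.raises(ValueError, match="length"):
            contact_count_series(traj, series)


class TestResidueRanking:
    def test_nearest_residue_ranks_first(self):
        topo = build_topology(
            ["protein", "protein", "lipid:PIP3"], residue_ids=[360, 361, 400]
        )
        frames = [
            frame([[5, 5, 5.0], [5, 5, 7.5], [5, 5, 5.5]], time=20.0 * k)
            for k in range(4)
        ]
        traj = model_io.Trajectory(topology=topo, frames=frames)
        ranking = residue_contact_ranking(traj)
        assert ranking[0] == (360, 4)
        assert ranking[1] == (361, 0)

    def test_no_contacts_orders_by_residue_id(self):
        topo = build_topology(
            ["protein", "protein", "lipid:PIP3"], residue_ids=[361, 360, 400]
        )
        traj = model_io.Trajectory(
            topology=topo, frames=[frame([[1, 1, 1], [1, 1, 2], [5, 5, 8]])]
        )
        ranking = residue_contact_ranking(traj)
        assert [r for r, _ in ranking] == [360, 361]
        assert all(c == 0 for _, c in ranking)

    def test_residue_sum_bounds_lipid_events(self):
        """A lipid touching several residues is counted once per residue,
        so the residue-count sum is >= the per-frame contact-set total."""
        cfg = synthetic.SyntheticConfig(seed=13, n_frames=200)
        traj, _ = synthetic.generate_encounter_trajectory(cfg)
        ranking = residue_contact_ranking(traj)
        series = OrientationSeries(
            traj.times,
            [3.0] * len(traj),
            [0.8] * len(traj),
            [True] * len(traj),
        )
        cs = contact_count_series(traj, series, bound_only=False)
        assert sum(c for _, c in ranking) >= cs.counts.sum()


class TestLeaflets:
    def test_assignment_by_midplane_sign(self):
        topo = build_topology(["protein", "lipid:POPC", "lipid:POPC"])
        fr = frame([[5, 5, 9], [5, 5, 3.0], [5, 5, 7.0]])
        assign = leaflet_assign(fr, topo)
        mols = topo.molecule_ids
        assert assign[int(mols[1])] == "lower"
        assert assign[int(mols[2])] == "upper"

    def test_exactly_at_midplane_assigns_upper(self):
        topo = build_topology(["protein", "lipid:POPC", "lipid:POPC", "lipid:POPC"])
        fr = frame([[5, 5, 9], [5, 5, 3.0], [5, 5, 7.0], [5, 5, 5.0]])
        assign = leaflet_assign(fr, topo)
        assert assign[int(topo.molecule_ids[3])] == "upper"

    def test_generator_leaflet_labels_recovered_exactly(self):
        cfg = synthetic.SyntheticConfig(seed=2, n_frames=2)
        traj, truth = synthetic.generate_encounter_trajectory(cfg)
        assign = leaflet_assign(traj.frames[0], traj.topology)
        assert assign == truth.leaflet_labels

    def test_proximal_leaflet_is_protein_side(self):
        cfg = synthetic.SyntheticConfig(seed=2, n_frames=2)
        traj, _ = synthetic.generate_encounter_trajectory(cfg)
        assert proximal_leaflet(traj.frames[0], traj.topology) == "upper"


class TestAnnulus:
    def test_no_lipids_gives_zero(self):
        topo = build_topology(["protein"])
        assert annulus_count(frame([[5, 5, 5]]), topo, leaflet="both") == 0

    def test_hand_built_distances(self):
        roles = ["protein"] + ["lipid:PIP3"] * 7
        topo = build_topology(roles)
        coords = [[5, 5, 5]]
        for k in range(4):
            coords.append([5 + 0.5, 5, 5 + 0.02 * k])  # 4 at ~0.5 nm
        for k in range(3):
            coords.append([5 + 2.5, 5, 5 + 0.02 * k])  # 3 at ~2.5 nm
        fr = frame(coords)
        assert annulus_count(fr, topo, leaflet="both") == 4

    def test_both_equals_proximal_plus_distal(self):
        cfg = synthetic.SyntheticConfig(seed=17, n_frames=50)
        traj, _ = synthetic.generate_encounter_trajectory(cfg)
        for fr in traj.frames[::10]:
            total = annulus_count(fr, traj.topology, leaflet="both")
            prox = annulus_count(fr, traj.topology, leaflet="proximal")
            dist = annulus_count(fr, traj.topology, leaflet="distal")
            assert total == prox + dist


class TestSiteClassification:
    LOOPS = {"b1b2": (360, 372), "b3b4": (390, 400), "b5b6": (420, 430)}

    def test_canonical_site(self):
        counts = {365: 10, 395: 8, 450: 1}
        assert classify_binding_site(counts, self.LOOPS).label == "canonical"

    def test_non_canonical_site(self):
        counts = {365: 10, 425: 8, 450: 1}
        assert classify_binding_site(counts, self.LOOPS).label == "non-canonical"

    def test_zero_contacts_is_none(self):
        assert classify_binding_site({}, self.LOOPS).label == "none"

    def test_mostly_non_loop_contacts_is_none(self):
        counts = {365: 1, 500: 99}
        assert classify_binding_site(counts, self.LOOPS).label == "none"

    def test_b3b4_with_b5b6_is_mixed(self):
        counts = {395: 10, 425: 8}
        assert classify_binding_site(counts, self.LOOPS).label == "mixed"

    def test_overlapping_ranges_rejected(self):
        loops = {"b1b2": (360, 372), "b3b4": (370, 380), "b5b6": None}
        with pytest.raises(ValueError, match="overlap"):
            classify_binding_site({365: 1}, loops)

    def test_fractions_sum_at_most_one(self):
        counts = {365: 5, 395: 3, 500: 2}
        call = classify_binding_site(counts, self.LOOPS)
        assert sum(call.loop_fractions.values()) <= 1.0


class TestPersistence:
    def _traj(self, distances):
        topo = build_topology(["protein", "protein"], residue_ids=[360, 396])
        frames = [
            frame([[5, 5, 5], [5, 5, 5 + d]], time=20.0 * k)
            for k, d in enumerate(distances)
        ]
        return model_io.Trajectory(topology=topo, frames=frames)

    def test_always_formed(self):
        traj = self._traj([0.3] * 10)
        assert interaction_persistence(traj, (360, 396), cutoff=0.35) == (1.0, 0)

    def test_alternating_breaks(self):
        traj = self._traj([0.3, 0.6] * 5)
        frac, breaks = interaction_persistence(traj, (360, 396), cutoff=0.35)
        assert frac == 0.5
        assert breaks == 5

    def test_never_formed(self):
        traj = self._traj([0.8] * 6)
        assert interaction_persistence(traj, (360, 396), cutoff=0.35) == (0.0, 1)

    def test_fraction_invariant_to_frame_order(self):
        distances = [0.3, 0.6, 0.6, 0.3, 0.3, 0.6]
        f1, _ = interaction_persistence(self._traj(distances), (360, 396), cutoff=0.35)
        f2, _ = interaction_persistence(
            self._traj(distances[::-1]), (360, 396), cutoff=0.35
        )
        assert f1 == f2

    def test_identical_members_rejected(self):
        traj = self._traj([0.3])
        with pytest.raises(ValueError, match="differ"):
            interaction_persistence(traj, (360, 360))
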