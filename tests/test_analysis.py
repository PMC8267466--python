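"""Trajectory statistics against brute-force and generator oracles."""

import math
import warnings

import numpy as np
import pytest

from sheetmem.analysis import (
    AnalysisSeries,
    ContactCriterion,
    batch_summary,
    chain_order,
    com_distance_z,
    count_bound_waters,
    count_contacts,
    insertion_time,
    interaction_energy,
    local_lipid_selection,
    membrane_thickness,
    split_head_tail_contacts,
)
from sheetmem.membrane import (
    DEFAULT_BEAD_SPECIES,
    SimOptions,
    make_system,
    pair_energy,
    scripted_scenario,
    simulate,
)
from sheetmem.nanosheet import fresh_params
from sheetmem.trajectory import Frame, Topology, Trajectory

from conftest import brute_min_dist, random_frame


def two_atom_frame(r, box=(10.0, 10.0, 10.0)):
    top = Topology(
        kinds=np.array(["S", "tail"]),
        lipid_id=np.array([-1, 0]),
        leaflet=np.array(["", "upper"]),
        chain_pos=np.array([-1, 0]),
        masses=np.array([32.06, 100.0]),
    )
    pos = np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0 + r]])
    return Frame(pos, np.asarray(box), top)


class TestContacts:
    def test_five_angstrom_boundary_is_strict(self):
        assert count_contacts(two_atom_frame(0.49), [0], [1]) == 1
        assert count_contacts(two_atom_frame(0.51), [0], [1]) == 0

    def test_minimum_image_across_xy_boundary(self):
        frame = two_atom_frame(0.0)
        frame.positions[1] = [9.9, 5.0, 5.0]
        frame.positions[0] = [0.2, 5.0, 5.0]  # 0.3 nm through the boundary
        assert count_contacts(frame, [0], [1]) == 1

    def test_empty_or_overlapping_groups_rejected(self):
        frame = two_atom_frame(0.3)
        with pytest.raises(ValueError):
            count_contacts(frame, [], [1])
        with pytest.raises(ValueError):
            count_contacts(frame, [0, 1], [1])

    def test_matches_brute_force_on_randomized_frames(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            frame = random_frame(rng)
            a = np.arange(12)
            b = np.arange(12, 42)
            d = brute_min_dist(frame, a, b)
            expected = int(np.sum(d < 0.5))
            assert count_contacts(frame, a, b) == expected

    def test_scripted_scenario_matches_generator_truth(self):
        traj, truth = scripted_scenario("preorganize_insert", seed=11, n_frames=60)
        top = traj.topology
        counted = [
            count_contacts(f, top.sheet_indices, top.lipid_indices) for f in traj
        ]
        assert np.array_equal(counted, truth["contacts"])


class TestHeadTailSplit:
    def test_partition_additivity_random_frames(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            frame = random_frame(rng)
            a = np.arange(12)
            b = np.arange(12, 42)
            head, tail = split_head_tail_contacts(frame, a, b)
            assert head + tail == count_contacts(frame, a, b)
            # brute-force recomputation of each half
            kinds = frame.topology.kinds[b]
            d = brute_min_dist(frame, a, b)
            assert head == int(np.sum((d < 0.5) & (kinds == "head")))
            assert tail == int(np.sum((d < 0.5) & (kinds == "tail")))

    def test_sheet_among_tail_beads_only(self):
        rng = np.random.default_rng(1)
        frame = random_frame(rng)
        tails = np.flatnonzero(frame.topology.kinds == "tail")
        # co-locate the sheet with a tail bead, far from any head bead
        heads = np.flatnonzero(frame.topology.kinds == "head")
        frame.positions[heads, 2] = 50.0
        frame.positions[0] = frame.positions[tails[0]] + 0.1
        head, tail = split_head_tail_contacts(frame, [0], np.arange(12, 42))
        assert head == 0 and tail >= 1

    def test_unlabeled_beads_rejected(self):
        frame = two_atom_frame(0.3)
        frame.topology.kinds[1] = "blob"
        with pytest.raises(ValueError, match="head/tail"):
            split_head_tail_contacts(frame, [0], [1])


class TestBoundWaters:
    def test_no_waters_is_zero(self):
        frame = two_atom_frame(0.3)
        assert count_bound_waters(frame, [0], []) == 0

    def test_three_and_a_half_angstrom_boundary_inclusive(self):
        assert count_bound_waters(two_atom_frame(0.34), [0], [1]) == 1
        assert count_bound_waters(two_atom_frame(0.36), [0], [1]) == 0

    def test_scripted_dehydration_matches_truth(self):
        traj, truth = scripted_scenario("direct_insert", seed=8, n_frames=60)
        top = traj.topology
        counted = [
            count_bound_waters(f, top.sheet_indices, top.water_indices) for f in traj
        ]
        assert np.array_equal(counted, truth["bound_waters"])


class TestComDistance:
    def test_zero_at_midplane(self):
        frame = two_atom_frame(0.0)
        assert com_distance_z(frame, [0], [1]) == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        frame = random_frame(rng)
        a, b = np.arange(12), np.arange(12, 42)
        ref = com_distance_z(frame, a, b)
        frame.positions += np.array([1.3, -0.7, 2.1])
        assert com_distance_z(frame, a, b) == pytest.approx(ref, abs=1e-12)

    def test_reference_system_starts_near_4p2(self):
        system = make_system(side_length=1.6, n_lipids_per_leaflet=16)
        traj = simulate(system, 1, 1, seed=0)
        frame = traj.frame(0)
        top = traj.topology
        d = com_distance_z(frame, top.sheet_indices, top.lipid_indices)
        assert d == pytest.approx(4.2, abs=0.1)


class TestInteractionEnergy:
    species = {**fresh_params().species, **DEFAULT_BEAD_SPECIES}

    def test_separated_groups_zero(self):
        frame = two_atom_frame(5.0)
        assert interaction_energy(frame, [0], [1], self.species) == (0.0, 0.0)

    def test_missing_parameters_named(self):
        frame = two_atom_frame(0.5)
        with pytest.raises(KeyError, match="tail"):
            interaction_energy(frame, [0], [1], {"S": self.species["S"]})

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(99)
        charges_all = None
        for _ in range(100):
            frame = random_frame(rng, n_a=10, n_b=40)
            a, b = np.arange(10), np.arange(10, 50)
            vdw, coul = interaction_energy(frame, a, b, self.species, charges=None, cutoff=1.2)
            # brute force with independently combined parameters
            ref_v = ref_c = 0.0
            box = frame.box
            for i in a:
                for j in b:
                    d = frame.positions[j] - frame.positions[i]
                    dx = d[0] - box[0] * round(d[0] / box[0])
                    dy = d[1] - box[1] * round(d[1] / box[1])
                    r = math.sqrt(dx * dx + dy * dy + d[2] * d[2])
                    if r >= 1.2:
                        continue
                    sa = self.species[frame.topology.kinds[i]]
                    sb = self.species[frame.topology.kinds[j]]
                    v, c = pair_energy(r, sa, sb, 1.2)
                    ref_v += v
                    ref_c += c
            assert vdw == pytest.approx(ref_v, rel=1e-10, abs=1e-10)
            assert coul == pytest.approx(ref_c, rel=1e-10, abs=1e-10)


class TestChainOrder:
    def _frame(self, vectors):
        n = len(vectors) * 2
        kinds = np.array(["tail"] * n)
        lipid = np.repeat(np.arange(len(vectors)), 2)
        chain = np.tile([0, 1], len(vectors))
        pos = np.zeros((n, 3))
        for i, v in enumerate(vectors):
            pos[2 * i + 1] = v
        top = Topology(
            kinds=kinds, lipid_id=lipid, leaflet=np.array(["upper"] * n),
            chain_pos=chain, masses=np.ones(n),
        )
        return Frame(pos, np.array([50.0, 50.0, 50.0]), top)

    def test_aligned_chains_give_one(self):
        frame = self._frame([(0, 0, 1.0)] * 5 + [(0, 0, -1.0)] * 5)
        assert chain_order(frame).s_chain == 1.0

    def test_perpendicular_chains_give_minus_half(self):
        frame = self._frame([(1.0, 0, 0), (0, 1.0, 0), (-1.0, 0, 0)])
        assert chain_order(frame).s_chain == -0.5

    def test_uniform_random_orientations_average_to_zero(self):
        rng = np.random.default_rng(17)
        n = 100_000
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        frame = self._frame(list(v))
        s = chain_order(frame).s_chain
        # Var[0.5(3cos^2-1)] = 1/5 for uniform orientations
        se = math.sqrt(0.2 / n)
        assert abs(s) < 3 * se

    def test_range_invariant(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            v = rng.standard_normal((8, 3))
            s = chain_order(self._frame(list(v))).s_chain
            assert -0.5 - 1e-12 <= s <= 1.0 + 1e-12

    def test_zero_length_chain_warned_and_skipped(self):
        frame = self._frame([(0, 0, 0.0), (0, 0, 1.0)])
        with pytest.warns(UserWarning, match="zero-length"):
            res = chain_order(frame)
        assert res.s_chain == 1.0


class TestLocalSelection:
    def test_far_sheet_selects_nothing(self):
        rng = np.random.default_rng(2)
        frame = random_frame(rng)
        frame.positions[:12, 2] = 100.0
        assert len(local_lipid_selection(frame, np.arange(12), 1.0)) == 0

    def test_infinite_radius_selects_all(self):
        rng = np.random.default_rng(2)
        frame = random_frame(rng)
        sel = local_lipid_selection(frame, np.arange(12), 1e6)
        assert np.array_equal(sel, np.unique(frame.topology.lipid_id[12:]))

    def test_matches_per_lipid_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            frame = random_frame(rng)
            a = np.arange(12)
            d = brute_min_dist(frame, a, np.arange(12, 42))
            lip = frame.topology.lipid_id[12:]
            expected = np.unique(lip[d <= 1.0])
            got = local_lipid_selection(frame, a, 1.0)
            assert np.array_equal(got, expected)


class TestThickness:
    def _bilayer_frame(self, dz=2.0):
        n = 8
        kinds = np.array(["head"] * n)
        leaf = np.array(["upper"] * 4 + ["lower"] * 4)
        pos = np.zeros((n, 3))
        pos[:4, 2] = 5.0 + dz
        pos[4:, 2] = 5.0 - dz
        top = Topology(
            kinds=kinds, lipid_id=np.arange(n), leaflet=leaf,
            chain_pos=np.full(n, -1), masses=np.ones(n),
        )
        return Frame(pos, np.array([10.0, 10.0, 10.0]), top)

    def test_constructed_leaflet_planes(self):
        assert membrane_thickness(self._bilayer_frame(2.0)) == 4.0

    def test_z_translation_invariance(self):
        frame = self._bilayer_frame(1.5)
        ref = membrane_thickness(frame)
        frame.positions[:, 2] += 3.7
        assert membrane_thickness(frame) == pytest.approx(ref, abs=1e-12)

    def test_missing_leaflet_rejected(self):
        frame = self._bilayer_frame()
        frame.topology.leaflet[:] = "upper"
        with pytest.raises(ValueError, match="lower"):
            membrane_thickness(frame)

    def test_inserted_repulsive_sheet_thickens_membrane_locally(self):
        """A rigid repulsive inclusion spanning the bilayer pushes the
        nearby head beads outward: local thickness exceeds the
        unperturbed control (seed-paired sign test, 5 pairs)."""
        wins = 0
        for seed in range(5):
            vals = {}
            for perturbed in (True, False):
                opts = SimOptions(repulsive_beads=True, sheet_mobile=False)
                system = make_system(
                    side_length=4.0, aging="fresh", n_lipids_per_leaflet=36,
                    start_distance=0.0 if perturbed else 6.0,
                    vertex="up", options=opts, tail_well_depth=0.0,
                )
                traj = simulate(system, 1500, 150, seed=200 + seed)
                top = traj.topology
                frames = [traj.frame(i) for i in range(traj.n_frames // 2, traj.n_frames)]
                if perturbed:
                    t = [
                        membrane_thickness(f, lipid_subset=local_lipid_selection(f, top.sheet_indices, 1.0))
                        for f in frames
                    ]
                else:
                    t = [membrane_thickness(f) for f in frames]
                vals[perturbed] = np.mean(t)
            wins += vals[True] > vals[False]
        assert wins >= 4


class TestInsertionTime:
    def test_no_insert_returns_none(self):
        traj, _ = scripted_scenario("no_insert", seed=5, n_frames=60)
        assert insertion_time(traj) is None

    def test_direct_insert_matches_truth_within_one_frame(self):
        traj, truth = scripted_scenario("direct_insert", seed=6)
        t = insertion_time(traj)
        dt = traj.times[1] - traj.times[0]
        assert abs(t - truth["insertion_time"]) <= dt

    def test_transient_dip_not_counted(self):
        # synthetic CoM path: brief dip below the head plane, then out
        mem_kinds = ["head"] * 4
        kinds = np.array(["Mo"] + mem_kinds)
        top = Topology(
            kinds=kinds,
            lipid_id=np.array([-1, 0, 1, 2, 3]),
            leaflet=np.array(["", "upper", "upper", "upper", "upper"]),
            chain_pos=np.full(5, -1),
            masses=np.ones(5),
        )
        n_frames = 40
        pos = np.zeros((n_frames, 5, 3))
        pos[:, 1:, 2] = 8.0  # static head plane
        z = np.full(n_frames, 9.0)
        z[10:12] = 7.5  # two-frame dip, shorter than the sustain window
        pos[:, 0, 2] = z
        traj = Trajectory(top, np.arange(n_frames, dtype=float), pos, np.array([5.0, 5.0, 12.0]))
        assert insertion_time(traj, sustain_window=5.0) is None


class TestOrderings:
    """Matched fresh/aged coarse runs reproduce the study's orderings."""

    @staticmethod
    def _tail_frames(traj):
        return [traj.frame(i) for i in range(int(0.6 * traj.n_frames), traj.n_frames)]

    def test_fresh_inserts_at_least_as_deep(self, ordering_runs):
        wins = 0
        for pair in ordering_runs:
            depth = {}
            for aging, traj in pair.items():
                top = traj.topology
                depth[aging] = np.mean(
                    [
                        com_distance_z(f, top.sheet_indices, top.lipid_indices)
                        for f in self._tail_frames(traj)
                    ]
                )
            wins += depth["fresh"] <= depth["aged"] + 1e-9
        assert wins >= 4

    def test_fresh_makes_more_tail_contacts(self, ordering_runs):
        wins = 0
        for pair in ordering_runs:
            tails = {}
            for aging, traj in pair.items():
                top = traj.topology
                tails[aging] = np.mean(
                    [
                        split_head_tail_contacts(f, top.sheet_indices, top.lipid_indices)[1]
                        for f in self._tail_frames(traj)
                    ]
                )
            wins += tails["fresh"] >= tails["aged"] - 1e-9
        assert wins >= 4

    def test_fresh_disorders_local_chains_more(self, ordering_runs):
        wins = 0
        for pair in ordering_runs:
            s = {}
            for aging, traj in pair.items():
                top = traj.topology
                vals = []
                for f in self._tail_frames(traj):
                    sel = local_lipid_selection(f, top.sheet_indices, 1.0)
                    if len(sel):
                        vals.append(chain_order(f, lipid_subset=sel).s_chain)
                s[aging] = np.mean(vals) if vals else np.nan
            if np.isnan(s["fresh"]) or np.isnan(s["aged"]):
                continue
            wins += s["fresh"] <= s["aged"] + 1e-9
        assert wins >= 4


class TestRotationInvariance:
    def test_quarter_turn_about_normal_preserves_statistics(self):
        rng = np.random.default_rng(41)
        frame = random_frame(rng, box=(4.0, 4.0, 8.0))
        a, b = np.arange(12), np.arange(12, 42)
        ref_contacts = count_contacts(frame, a, b)
        ref_sel = local_lipid_selection(frame, a, 1.0)
        # rotate 90 deg about the box centre, re-wrap into [0, L)
        c = np.array([2.0, 2.0])
        xy = frame.positions[:, :2] - c
        frame.positions[:, 0] = -xy[:, 1] + c[0]
        frame.positions[:, 1] = xy[:, 0] + c[1]
        frame.positions[:, :2] %= 4.0
        assert count_contacts(frame, a, b) == ref_contacts
        assert np.array_equal(local_lipid_selection(frame, a, 1.0), ref_sel)


class TestBatchSummary:
    def _series(self, values, label="x"):
        return AnalysisSeries(np.arange(len(values), dtype=float), np.asarray(values, float), label)

    def test_constant_series(self):
        df = batch_summary([{"c": self._series([7.0] * 10)}], averaging_window=4.0)
        assert df["tail_mean"].iloc[0] == 7.0
        assert np.isnan(df["se"].iloc[0]) or df["se"].iloc[0] == 0.0

    def test_full_window_equals_plain_mean(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        df = batch_summary([{"c": self._series(vals)}], averaging_window=3.0)
        assert df["tail_mean"].iloc[0] == np.mean(vals)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            batch_summary([{"c": self._series([1.0, 2.0])}], averaging_window=10.0)

    def test_se_shrinks_with_replicates(self):
        rng = np.random.default_rng(55)
        seriess = [
            {"c": self._series(rng.normal(0, 1, 400))} for _ in range(5)
        ]
        df = batch_summary(seriess, averaging_window=399.0)
        se = df["se"].iloc[0]
        single_spread = np.std([d["c"].values.mean() for d in seriess], ddof=1)
        assert se == pytest.approx(single_spread / math.sqrt(5), rel=1e-9)
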