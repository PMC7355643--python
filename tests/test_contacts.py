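"""Contact maps, interaction typing, nonlocal contact numbers, segments."""

import numpy as np
import pytest

import idrdyn.synthetic as syn
from idrdyn.contacts import (
    ContactMap,
    cation_pi_events,
    contact_frequency_map,
    correlated_segments,
    nonlocal_contact_number,
    saltbridge_hbond_events,
)
from tests.conftest import build_ensemble


def _two_sidechain_ensemble(distance, n_frames=4):
    spec = [
        (1, "ALA", "CA", "C", "backbone"), (1, "ALA", "CB", "C", "sidechain"),
        (2, "ALA", "CA", "C", "backbone"),
        (3, "ALA", "CA", "C", "backbone"), (3, "ALA", "CB", "C", "sidechain"),
    ]
    frames = np.zeros((n_frames, 5, 3))
    frames[:, 0] = [0, -3, 0]
    frames[:, 2] = [20, -3, 0]
    frames[:, 3] = [40, -3, 0]
    frames[:, 4] = [distance, 0, 0]
    return build_ensemble(spec, frames)


class TestContactFrequencyMap:
    def test_cutoff_rule_inside_and_outside(self):
        inside = contact_frequency_map(_two_sidechain_ensemble(3.4), "sc-sc")
        outside = contact_frequency_map(_two_sidechain_ensemble(3.6), "sc-sc")
        assert inside.frequency(1, 3) == 1.0
        assert outside.frequency(1, 3) == 0.0

    def test_symmetry_and_frame_reordering_invariance(self):
        ens, _ = syn.planted_contact_ensemble(8, [(2, 6, 0.4)], n_frames=200, seed=3)
        cmap = contact_frequency_map(ens, "sc-sc")
        assert np.allclose(cmap.frequencies, cmap.frequencies.T)
        shuffled = syn.planted_contact_ensemble(8, [(2, 6, 0.4)], n_frames=200, seed=3)[0]
        rng = np.random.default_rng(1)
        shuffled.coordinates = shuffled.coordinates[rng.permutation(200)]
        cmap2 = contact_frequency_map(shuffled, "sc-sc")
        assert np.allclose(cmap.frequencies, cmap2.frequencies)

    @pytest.mark.parametrize("mode", ["sc-sc", "sc-bb"])
    def test_matches_brute_force_distance_scan(self, mode):
        ens, _ = syn.planted_contact_ensemble(
            6, [(1, 4, 0.5), (3, 6, 0.2)], n_frames=40, seed=8
        )
        rng = np.random.default_rng(0)
        ens.coordinates += rng.normal(scale=1.5, size=ens.coordinates.shape)
        got = contact_frequency_map(ens, mode)
        top = ens.topology
        pos = {r: k for k, r in enumerate(got.residue_ids)}
        expected = np.zeros_like(got.frequencies)
        role_j = "sidechain" if mode == "sc-sc" else "backbone"
        for ri in got.residue_ids:
            ai = [k for k, a in enumerate(top.atoms)
                  if a.residue_index == ri and a.role == "sidechain" and a.element != "H"]
            for rj in got.residue_ids:
                if ri == rj:
                    continue
                aj = [k for k, a in enumerate(top.atoms)
                      if a.residue_index == rj and a.role == role_j and a.element != "H"]
                best = 0.0
                for x in ai:
                    for y in aj:
                        hits = 0
                        for f in range(ens.n_frames):
                            d = np.linalg.norm(ens.coordinates[f, x] - ens.coordinates[f, y])
                            hits += d < 3.5
                        best = max(best, hits / ens.n_frames)
                expected[pos[ri], pos[rj]] = best
        if mode == "sc-sc":
            expected = np.maximum(expected, expected.T)
        assert np.array_equal(got.frequencies, expected)

    def test_no_sidechains_warns_and_returns_empty(self):
        ens = syn.ideal_chain([-70.0] * 4, [150.0] * 4)  # backbone-only
        with pytest.warns(UserWarning):
            cmap = contact_frequency_map(ens, "sc-sc")
        assert np.all(cmap.frequencies == 0.0)


def _toy_map(n, entries):
    freqs = np.zeros((n, n))
    for i, j, f in entries:
        freqs[i - 1, j - 1] = freqs[j - 1, i - 1] = f
    return ContactMap(mode="sc-sc", residue_ids=list(range(1, n + 1)),
                      frequencies=freqs, n_frames=1)


class TestNonlocalContactNumber:
    def test_all_zero_map(self):
        assert np.all(nonlocal_contact_number(_toy_map(10, [])) == 0.0)

    def test_hand_counted_single_pair(self):
        # residue 1 on a 10-residue chain has 6 eligible partners (5..10)
        values = nonlocal_contact_number(_toy_map(10, [(1, 6, 0.5)]))
        assert values[0] == pytest.approx(0.5 / 6.0)
        # residue 6 has eligible partners 1, 2 and 10 -> 0.5 / 3
        assert values[5] == pytest.approx(0.5 / 3.0)

    def test_linearity_under_halving(self):
        a = nonlocal_contact_number(_toy_map(12, [(2, 7, 0.4), (3, 11, 0.2)]))
        b = nonlocal_contact_number(_toy_map(12, [(2, 7, 0.2), (3, 11, 0.1)]))
        assert np.allclose(a, 2.0 * b)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            nonlocal_contact_number(_toy_map(7, []))

    def test_half_range_means(self):
        _, halves = nonlocal_contact_number(
            _toy_map(10, [(1, 6, 0.6)]), ranges=[(1, 5), (6, 10)]
        )
        assert len(halves) == 2 and halves[0] > 0


class TestCationPi:
    def test_axial_geometry_is_event(self, tyr_arg_builder):
        ens = tyr_arg_builder((0.0, 0.0, 3.5))
        events = cation_pi_events(ens)
        assert len(events) == 1 and events[0].frequency == 1.0
        assert (events[0].residue_i, events[0].residue_j) == (1, 3)

    def test_equatorial_geometry_rejected_by_angle(self, tyr_arg_builder):
        ens = tyr_arg_builder((4.0, 0.0, 0.0))  # in the ring plane: angle 90 deg
        assert cation_pi_events(ens)[0].frequency == 0.0

    def test_distance_rule_rejects_beyond_5A(self, tyr_arg_builder):
        # 10 degrees off axis at 5.2 A
        r = 5.2
        ens = tyr_arg_builder((r * np.sin(np.radians(10)), 0.0, r * np.cos(np.radians(10))))
        assert cation_pi_events(ens)[0].frequency == 0.0
        near = tyr_arg_builder((4.8 * np.sin(np.radians(10)), 0.0, 4.8 * np.cos(np.radians(10))))
        assert cation_pi_events(near)[0].frequency == 1.0


class TestSaltBridgesAndHBonds:
    def _arg_glu(self, n_dist):
        spec = [
            (1, "ARG", "NH1", "N", "sidechain"),
            (2, "ALA", "CA", "C", "backbone"),
            (3, "GLU", "OE1", "O", "sidechain"),
        ]
        frames = np.zeros((2, 3, 3))
        frames[:, 1] = [50.0, 0.0, 0.0]
        frames[:, 2, 0] = n_dist
        return build_ensemble(spec, frames)

    def test_canonical_salt_bridge(self):
        events = saltbridge_hbond_events(self._arg_glu(2.9))
        sb = [e for e in events if e.kind == "salt_bridge"]
        assert len(sb) == 1 and sb[0].frequency == 1.0

    def test_distant_pair_is_not_salt_bridge(self):
        events = saltbridge_hbond_events(self._arg_glu(4.2))
        assert all(e.frequency == 0.0 for e in events if e.kind == "salt_bridge")

    def _donor_acceptor(self, dha_angle_deg):
        # sidechain N-H donor (residue 1) and backbone O acceptor (residue 3)
        spec = [
            (1, "LYS", "NZ", "N", "sidechain"),
            (1, "LYS", "HZ1", "H", "sidechain"),
            (2, "ALA", "CA", "C", "backbone"),
            (3, "ALA", "O", "O", "backbone"),
        ]
        frames = np.zeros((1, 4, 3))
        frames[0, 1] = [1.0, 0.0, 0.0]  # H along +x from N
        frames[0, 2] = [-50.0, 0.0, 0.0]
        # acceptor placed so that the D-H...A angle has the requested value
        t = np.radians(180.0 - dha_angle_deg)
        frames[0, 3] = frames[0, 1] + 2.4 * np.array([np.cos(t), np.sin(t), 0.0])
        return build_ensemble(spec, frames)

    def test_hbond_angle_criterion(self):
        linear = saltbridge_hbond_events(self._donor_acceptor(180.0))
        bent = saltbridge_hbond_events(self._donor_acceptor(100.0))
        hb = [e for e in linear if e.kind == "scbb_hbond"]
        assert len(hb) == 1 and hb[0].frequency == 1.0
        assert all(e.frequency == 0.0 for e in bent if e.kind == "scbb_hbond")


class TestCorrelatedSegments:
    def test_overlapping_edges_merge(self):
        segs = correlated_segments(_toy_map(10, [(2, 6, 0.5), (5, 9, 0.5)]))
        assert [(s.start, s.end) for s in segs] == [(2, 9)]

    def test_empty_map_has_no_segments(self):
        assert correlated_segments(_toy_map(10, [])) == []

    def test_two_disjoint_blocks_give_two_segments(self):
        ens, _ = syn.planted_contact_ensemble(
            30, [(5, 10, 0.8), (20, 26, 0.8)], n_frames=300, seed=2
        )
        cmap = contact_frequency_map(ens, "sc-sc")
        segs = correlated_segments(cmap)
        assert [(s.start, s.end) for s in segs] == [(5, 10), (20, 26)]

    def test_threshold_monotonicity(self):
        cmap = _toy_map(20, [(2, 6, 0.02), (8, 14, 0.005), (15, 19, 0.6)])
        spans = []
        for thr in (0.001, 0.01, 0.1, 0.7):
            spans.append(sum(s.span for s in correlated_segments(cmap, freq_threshold=thr)))
        assert all(a >= b for a, b in zip(spans, spans[1:]))

    def test_min_span_filter(self):
        segs = correlated_segments(_toy_map(10, [(3, 5, 0.5)]), min_span=4)
        assert segs == []
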