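"""Contact detection, strength series, retention filter, map comparison."""

import numpy as np
import pytest

from dnamech import (ContactCutoffs, SystemLabel, TrajectoryHandle,
                     build_coordinates, compare_maps, default_system_spec,
                     detect_contacts, filter_and_map, generate_helical_ensemble,
                     strength_series)
from dnamech.contact_dynamics import (CLASS_HBOND, CLASS_HYDROPHOBIC,
                                      CLASS_NONSPECIFIC, ContactRecord,
                                      contact_map)


def _pair_handle(protein_positions, protein_atom="NH1", protein_res="ARG",
                 dna_atom="O6", dna_res="DG", with_h=True):
    """One DNA bp (G:C) plus one protein atom at scripted positions.

    ``protein_positions``: (n_frames, 3) positions of the protein atom; the
    DNA acceptor sits at the origin.
    """
    protein_positions = np.asarray(protein_positions, dtype=float)
    n = len(protein_positions)
    names = [dna_atom, "N1", "N1", protein_atom]
    resnames = [dna_res, dna_res, "DC", protein_res]
    resids = [1, 1, 1, 167]
    chains = ["A", "A", "B", "D"]
    coords = np.zeros((n, 4, 3))
    coords[:, 1] = [1.4, 0, 0]       # second DNA atom, arbitrary
    coords[:, 2] = [0, 30, 0]        # complementary strand far away
    coords[:, 3] = protein_positions
    if with_h:
        names.append("HH1")
        resnames.append(protein_res)
        resids.append(167)
        chains.append("D")
        h = np.zeros((n, 1, 3))
        # H on the donor-acceptor line, 1 A from the donor
        u = -protein_positions / np.linalg.norm(
            protein_positions, axis=1, keepdims=True)
        h[:, 0, :] = protein_positions + u
        coords = np.concatenate([coords, h], axis=1)
    return TrajectoryHandle.from_arrays(
        coords, names, resnames, resids, chains,
        {"A": "dna_watson", "B": "dna_crick", "D": "protein:D"},
        timestep=1.0)


class TestDetection:
    def test_ideal_hbond_in_every_frame(self):
        pos = np.tile([2.9, 0.0, 0.0], (5, 1))
        traj = _pair_handle(pos)
        recs = strength_series(detect_contacts(traj), traj)
        rec = next(r for r in recs
                   if r.class_strength.get(CLASS_HBOND) is not None)
        assert rec.occupancy == 1.0
        assert rec.class_occupancy(CLASS_HBOND) == 1.0

    def test_pair_beyond_cutoffs_is_silent(self):
        pos = np.tile([5.5, 0.0, 0.0], (5, 1))
        traj = _pair_handle(pos)
        events = detect_contacts(traj)
        assert len(events.frame) == 0

    def test_bent_hbond_rejected_by_angle(self):
        # donor at 3.0 A but H pointing away -> angle ~ 0 deg at the H
        n = 3
        names = ["O6", "N1", "N1", "NH1", "HH1"]
        resnames = ["DG", "DG", "DC", "ARG", "ARG"]
        resids = [1, 1, 1, 167, 167]
        chains = ["A", "A", "B", "D", "D"]
        coords = np.zeros((n, 5, 3))
        coords[:, 1] = [1.4, 0, 0]
        coords[:, 2] = [0, 30, 0]
        coords[:, 3] = [3.0, 0, 0]
        coords[:, 4] = [4.0, 0, 0]       # H on the far side of the donor
        traj = TrajectoryHandle.from_arrays(
            coords, names, resnames, resids, chains,
            {"A": "dna_watson", "B": "dna_crick", "D": "protein:D"},
            timestep=1.0)
        events = detect_contacts(traj)
        assert CLASS_HBOND not in [
            ("specific_hbond", "specific_hydrophobic", "nonspecific")[c]
            for c in events.contact_class]

    def test_backbone_participation_makes_nonspecific(self):
        pos = np.tile([3.0, 0.0, 0.0], (4, 1))
        traj = _pair_handle(pos, dna_atom="P")
        events = detect_contacts(traj)
        assert len(events.frame) > 0
        assert all(c == 2 for c in events.contact_class)

    def test_hydrophobic_methyl_contact(self):
        pos = np.tile([3.9, 0.0, 0.0], (4, 1))
        traj = _pair_handle(pos, protein_atom="CB", protein_res="ALA",
                            dna_atom="C7", dna_res="DT", with_h=False)
        recs = strength_series(detect_contacts(traj), traj)
        assert any(r.class_occupancy(CLASS_HYDROPHOBIC) == 1.0 for r in recs)

    def test_scripted_occupancy_vs_brute_force_recount(self, small_system):
        spec, ens, traj = small_system
        events = detect_contacts(traj)
        recs = strength_series(events, traj)
        # brute force: recount every frame for the scripted Arg167 pair
        names = np.asarray(traj.universe.atoms.names)
        chains = np.asarray(traj.universe.atoms.chainIDs)
        resids = np.asarray(traj.universe.atoms.resids)
        rec = next(r for r in recs if r.protein == ("D", "ARG", 167)
                   and r.dna[:2] == ("C", 11))
        counts = np.zeros(traj.n_frames, dtype=int)
        heavy = np.array([not n.startswith("H") for n in names])
        pa = np.flatnonzero((chains == "D") & (resids == 167) & heavy)
        o6 = traj.atom_index[(11, "C", "O6")]
        for f in range(traj.n_frames):
            xyz = traj.coordinates(f)
            for i in pa:
                if np.linalg.norm(xyz[i] - xyz[o6]) <= 3.5:
                    counts[f] += 1
        np.testing.assert_array_equal(rec.strength, counts)
        assert rec.occupancy == np.mean(counts >= 1)


class TestStrengthAndFilter:
    def _record(self, strengths, protein=("D", "ARG", 167), dna=("C", 11, "DG")):
        return ContactRecord(protein=protein, dna=dna,
                             strength=np.asarray(strengths, dtype=int))

    def test_always_in_contact_single_pair(self):
        rec = self._record([1] * 10)
        assert rec.occupancy == 1.0
        assert rec.mean_strength == 1.0

    def test_two_pairs_always_in_contact_additivity(self):
        rec = self._record([2] * 10)
        assert rec.mean_strength == 2.0

    def test_alternating_contact_occupancy(self):
        rec = self._record([1, 0] * 50)
        assert rec.occupancy == 0.5

    def test_retention_is_strictly_greater_than_threshold(self):
        n = 1000
        drop = self._record([1] * 50 + [0] * 950)          # 0.05
        boundary = self._record([1] * 100 + [0] * 900)     # exactly 0.10
        keep = self._record([1] * 101 + [0] * 899)         # 0.101
        cmap = filter_and_map([drop, boundary, keep], threshold=0.10)
        assert [r.occupancy for r in cmap.records] == [0.101]

    def test_planted_counts_through_filter(self):
        rng = np.random.default_rng(0)
        occupancies = [0.02, 0.05, 0.08, 0.2, 0.4, 0.6, 0.9]
        records = []
        for k, occ in enumerate(occupancies):
            s = (rng.random(500) < occ).astype(int)
            records.append(ContactRecord(
                protein=("D", "ARG", 100 + k), dna=("W", k + 1, "DT"),
                strength=s))
        cmap = filter_and_map(records, threshold=0.10)
        expected = sum(1 for r in records if r.occupancy > 0.10)
        assert len(cmap.records) == expected

    def test_raising_threshold_never_adds_records(self):
        rng = np.random.default_rng(1)
        records = [ContactRecord(("D", "ARG", 100 + k), ("W", k + 1, "DT"),
                                 (rng.random(200) < rng.random()).astype(int))
                   for k in range(20)]
        sizes = [len(filter_and_map(records, threshold=t).records)
                 for t in (0.0, 0.1, 0.3, 0.5, 0.9)]
        assert sizes == sorted(sizes, reverse=True)


class TestComparison:
    def test_map_vs_itself_is_identity(self, small_system):
        _, _, traj = small_system
        cmap = contact_map(traj)
        comp = compare_maps(cmap, cmap)
        assert comp.gained == [] and comp.lost == []
        assert np.allclose(comp.deltas["delta_mean_strength"], 0.0)

    def test_planted_gain_reported(self):
        a = filter_and_map([ContactRecord(("D", "ARG", 167), ("C", 11, "DG"),
                                          np.ones(10, dtype=int))], 0.1)
        extra = ContactRecord(("D", "LYS", 163), ("W", 13, "DC"),
                              np.ones(10, dtype=int))
        b = filter_and_map(a.records + [extra], 0.1)
        comp = compare_maps(a, b)
        assert comp.gained == [("D", 163, "W", 13)]
        assert comp.lost == []

    def test_methylation_turns_hbond_into_hydrophobic_contact(self):
        # DP1 Arg167-type readout: H-bonds to the Crick guanines on WT DNA,
        # hydrophobic packing against the 5-methyl group on ME DNA
        def dominant(meth):
            spec = default_system_spec(SystemLabel(meth, "E2F1DP1"),
                                       n_frames=80, seed=3)
            ens = generate_helical_ensemble(spec)
            traj = build_coordinates(ens, spec)
            cmap = contact_map(traj)
            recs = [r for r in cmap.records if r.protein == ("D", "ARG", 167)]
            assert recs
            best = max(recs, key=lambda r: r.class_mean_strength(CLASS_HBOND)
                       + r.class_mean_strength(CLASS_HYDROPHOBIC))
            return best.dominant_class
        assert dominant("WT") == CLASS_HBOND
        assert dominant("ME") == CLASS_HYDROPHOBIC
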