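"""Per-frame protein-DNA contact detection and dynamic contact maps.

Contacts are classified per atom pair:

* ``specific_hbond`` — protein side-chain donor/acceptor with DNA base
  acceptor/donor, heavy-atom distance <= 3.5 A and donor-H...acceptor angle
  >= 135 deg (the angle test is waived when the donor carries no hydrogen
  in the topology);
* ``specific_hydrophobic`` — apolar carbon pairs (including the thymine
  methyl and the 5-methyl carbon of methylcytosine) within 4.5 A;
* ``nonspecific`` — any heavy-atom pair within the hydrophobic cutoff in
  which a DNA-backbone or protein-backbone atom participates.

The contact strength of a residue pair in a frame is the integer number of
qualifying atom-pair events between them; occupancy is the fraction of
frames with strength >= 1.  The dynamic contact map retains residue pairs
present for longer than 10% of the trajectory (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import ConfigurationError, TrajectoryHandle

CLASS_HBOND = "specific_hbond"
CLASS_HYDROPHOBIC = "specific_hydrophobic"
CLASS_NONSPECIFIC = "nonspecific"
CONTACT_CLASSES = (CLASS_HBOND, CLASS_HYDROPHOBIC, CLASS_NONSPECIFIC)


@dataclass(frozen=True)
class ContactCutoffs:
    d_hbond: float = 3.5       # heavy-atom donor-acceptor distance, A
    theta_hbond: float = 135.0  # donor-H...acceptor angle, deg
    d_hydrophobic: float = 4.5  # C-C distance, A


DNA_BACKBONE_ATOMS = {"P", "OP1", "OP2", "O1P", "O2P", "O5'", "C5'", "C4'",
                      "O4'", "C3'", "O3'", "C2'", "C1'"}
PROTEIN_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA"}

DNA_BASE_DONORS = {
    "DA": {"N6"}, "DC": {"N4"}, "5MC": {"N4"}, "DG": {"N1", "N2"},
    "DT": {"N3"},
}
DNA_BASE_ACCEPTORS = {
    "DA": {"N1", "N3", "N7"}, "DC": {"O2", "N3"}, "5MC": {"O2", "N3"},
    "DG": {"O6", "N7", "N3"}, "DT": {"O2", "O4"},
}
PROTEIN_SC_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "TRP": {"NE1"}, "CYS": {"SG"},
}
PROTEIN_SC_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"},
}
#: aliphatic/aromatic carbons with no attached O/N
APOLAR_CARBONS = {
    "ALA": {"CB"}, "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"}, "ILE": {"CB", "CG1", "CG2", "CD1"},
    "PRO": {"CB", "CG"}, "MET": {"CB", "CG"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "TRP": {"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "ARG": {"CB", "CG"}, "LYS": {"CB", "CG", "CD"}, "THR": {"CG2"},
    "GLN": {"CB"}, "GLU": {"CB"}, "ASN": {"CB"}, "ASP": {"CB"},
    "HIS": {"CB"}, "SER": {"CB"}, "CYS": {"CB"},
    "DT": {"C7", "C2'"}, "5MC": {"C5M", "C2'"},
    "DA": {"C2'"}, "DC": {"C2'"}, "DG": {"C2'"},
}


@dataclass
class ContactEvents:
    """Raw per-frame atom-pair contact events."""

    frame: np.ndarray           # (n_events,)
    protein_atom: np.ndarray    # universe atom indices
    dna_atom: np.ndarray
    contact_class: np.ndarray   # index into CONTACT_CLASSES
    n_frames: int
    cutoffs: ContactCutoffs


@dataclass
class ContactRecord:
    """Aggregated contact between one protein and one DNA residue."""

    protein: tuple[str, str, int]      # (chain, resname, resid)
    dna: tuple[str, int, str]          # (strand W/C, bp number, resname)
    strength: np.ndarray               # (n_frames,) total event count
    class_strength: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.strength >= 1))

    @property
    def mean_strength(self) -> float:
        return float(self.strength.mean())

    def class_occupancy(self, cls: str) -> float:
        arr = self.class_strength.get(cls)
        return float(np.mean(arr >= 1)) if arr is not None else 0.0

    def class_mean_strength(self, cls: str) -> float:
        arr = self.class_strength.get(cls)
        return float(arr.mean()) if arr is not None else 0.0

    @property
    def dominant_class(self) -> str:
        """Prevailing character of the contact.

        Specific classes take precedence: a residue pair that forms any
        specific contact is characterised by its stronger specific class
        (H-bonding vs hydrophobic); only contacts with no specific
        component are nonspecific.
        """
        means = {c: self.class_mean_strength(c) for c in CONTACT_CLASSES}
        if means[CLASS_HBOND] > 0 or means[CLASS_HYDROPHOBIC] > 0:
            return (CLASS_HBOND if means[CLASS_HBOND]
                    >= means[CLASS_HYDROPHOBIC] else CLASS_HYDROPHOBIC)
        return CLASS_NONSPECIFIC

    @property
    def key(self) -> tuple:
        return (self.protein[0], self.protein[2], self.dna[0], self.dna[1])


@dataclass
class ContactMap:
    records: list[ContactRecord]
    threshold: float
    n_frames: int

    def to_table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "protein_chain": r.protein[0], "protein_resname": r.protein[1],
                "protein_resid": r.protein[2], "dna_strand": r.dna[0],
                "dna_bp": r.dna[1], "dna_resname": r.dna[2],
                "occupancy": r.occupancy, "mean_strength": r.mean_strength,
                "dominant_class": r.dominant_class,
                **{f"mean_{c}": r.class_mean_strength(c) for c in CONTACT_CLASSES},
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _atom_metadata(traj: TrajectoryHandle):
    u = traj.universe
    names = np.asarray(u.atoms.names)
    resnames = np.asarray(u.atoms.resnames)
    resids = np.asarray(u.atoms.resids)
    chains = (np.asarray(u.atoms.chainIDs) if hasattr(u.atoms, "chainIDs")
              else np.asarray(u.atoms.segids))
    return names, resnames, resids, chains


def detect_contacts(traj: TrajectoryHandle,
                    cutoffs: ContactCutoffs = ContactCutoffs()) -> ContactEvents:
    """Detect per-frame H-bond, hydrophobic and nonspecific contact events
    between protein and DNA heavy atoms."""
    prot = traj.atoms_with_role("protein")
    if len(prot) == 0:
        raise ConfigurationError("no chain has a protein role")
    dna = traj.atoms_with_role("dna_watson") + traj.atoms_with_role("dna_crick")
    if len(dna) == 0:
        raise ConfigurationError("no chain has a DNA role")

    names, resnames, resids, chains = _atom_metadata(traj)
    p_idx = prot.indices
    d_idx = dna.indices

    def is_h(i):
        return names[i].startswith("H")

    p_heavy = np.array([i for i in p_idx if not is_h(i)])
    d_heavy = np.array([i for i in d_idx if not is_h(i)])

    # per-atom classification
    def classify(idx, backbone_set, donors, acceptors):
        bb = np.array([names[i] in backbone_set for i in idx])
        don = np.array([names[i] in donors.get(resnames[i], ()) for i in idx])
        acc = np.array([names[i] in acceptors.get(resnames[i], ()) for i in idx])
        apo = np.array([names[i] in APOLAR_CARBONS.get(resnames[i], ())
                        for i in idx])
        return bb, don, acc, apo

    p_bb, p_don, p_acc, p_apo = classify(
        p_heavy, PROTEIN_BACKBONE_ATOMS, PROTEIN_SC_DONORS, PROTEIN_SC_ACCEPTORS)
    d_bb, d_don, d_acc, d_apo = classify(
        d_heavy, DNA_BACKBONE_ATOMS, DNA_BASE_DONORS, DNA_BASE_ACCEPTORS)

    # hydrogens attached to each donor (same residue, name-matched by
    # proximity in the first frame within 1.3 A)
    coords0 = traj.coordinates(0)
    donor_h: dict[int, list[int]] = {}
    h_atoms = [i for i in np.concatenate([p_idx, d_idx]) if is_h(i)]
    if h_atoms:
        heavy_donors = ([i for i, d in zip(p_heavy, p_don) if d]
                        + [i for i, d in zip(d_heavy, d_don) if d])
        for hd in heavy_donors:
            near = [h for h in h_atoms
                    if resids[h] == resids[hd] and chains[h] == chains[hd]
                    and np.linalg.norm(coords0[h] - coords0[hd]) < 1.3]
            if near:
                donor_h[hd] = near

    r_max = max(cutoffs.d_hbond, cutoffs.d_hydrophobic)
    ev_frame, ev_p, ev_d, ev_c = [], [], [], []

    for f in range(traj.n_frames):
        xyz = traj.coordinates(f)
        tree = cKDTree(xyz[p_heavy])
        hits = tree.query_ball_point(xyz[d_heavy], r=r_max)
        for dj, plist in enumerate(hits):
            for pj in plist:
                pa, da = p_heavy[pj], d_heavy[dj]
                r = np.linalg.norm(xyz[pa] - xyz[da])
                backbone = p_bb[pj] or d_bb[dj]
                if backbone:
                    if r <= cutoffs.d_hydrophobic:
                        ev_frame.append(f); ev_p.append(pa); ev_d.append(da)
                        ev_c.append(2)
                    continue
                # side chain vs base from here on
                hbond = False
                if r <= cutoffs.d_hbond:
                    for donor, acceptor in ((pa, da), (da, pa)):
                        d_ok = (p_don[pj] if donor == pa else d_don[dj])
                        a_ok = (d_acc[dj] if acceptor == da else p_acc[pj])
                        if not (d_ok and a_ok):
                            continue
                        hs = donor_h.get(donor)
                        if not hs:
                            hbond = True
                            break
                        for h in hs:
                            v1 = xyz[donor] - xyz[h]
                            v2 = xyz[acceptor] - xyz[h]
                            cosv = np.dot(v1, v2) / (np.linalg.norm(v1)
                                                     * np.linalg.norm(v2))
                            ang = np.degrees(np.arccos(np.clip(cosv, -1, 1)))
                            if ang >= cutoffs.theta_hbond:
                                hbond = True
                                break
                        if hbond:
                            break
                if hbond:
                    ev_frame.append(f); ev_p.append(pa); ev_d.append(da)
                    ev_c.append(0)
                elif (r <= cutoffs.d_hydrophobic and p_apo[pj] and d_apo[dj]):
                    ev_frame.append(f); ev_p.append(pa); ev_d.append(da)
                    ev_c.append(1)

    return ContactEvents(
        frame=np.array(ev_frame, dtype=int),
        protein_atom=np.array(ev_p, dtype=int),
        dna_atom=np.array(ev_d, dtype=int),
        contact_class=np.array(ev_c, dtype=int),
        n_frames=traj.n_frames, cutoffs=cutoffs)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def strength_series(events: ContactEvents,
                    traj: TrajectoryHandle) -> list[ContactRecord]:
    """Aggregate atom-pair events into per-residue-pair strength series."""
    names, resnames, resids, chains = _atom_metadata(traj)
    strand_of: dict[str, str] = {}
    for cid, role in traj.roles.items():
        if role == "dna_watson":
            strand_of[cid] = "W"
        elif role == "dna_crick":
            strand_of[cid] = "C"

    records: dict[tuple, ContactRecord] = {}
    for f, pa, da, c in zip(events.frame, events.protein_atom,
                            events.dna_atom, events.contact_class):
        pkey = (str(chains[pa]), str(resnames[pa]), int(resids[pa]))
        dkey = (strand_of.get(str(chains[da]), "?"), int(resids[da]),
                str(resnames[da]))
        key = (pkey, dkey)
        rec = records.get(key)
        if rec is None:
            rec = ContactRecord(
                protein=pkey, dna=dkey,
                strength=np.zeros(events.n_frames, dtype=int))
            records[key] = rec
        rec.strength[f] += 1
        cls = CONTACT_CLASSES[c]
        if cls not in rec.class_strength:
            rec.class_strength[cls] = np.zeros(events.n_frames, dtype=int)
        rec.class_strength[cls][f] += 1
    return sorted(records.values(),
                  key=lambda r: (r.dna[1], r.dna[0], r.protein[0], r.protein[2]))


def filter_and_map(records: Iterable[ContactRecord],
                   threshold: float = 0.10,
                   n_frames: int | None = None) -> ContactMap:
    """Retain residue pairs present for longer than ``threshold`` of the
    trajectory (strict inequality), sorted by DNA bp then protein residue."""
    kept = [r for r in records if r.occupancy > threshold]
    kept.sort(key=lambda r: (r.dna[1], r.dna[0], r.protein[0], r.protein[2]))
    nf = n_frames if n_frames is not None else (
        len(kept[0].strength) if kept else 0)
    return ContactMap(records=kept, threshold=threshold, n_frames=nf)


def contact_map(traj: TrajectoryHandle,
                cutoffs: ContactCutoffs = ContactCutoffs(),
                threshold: float = 0.10) -> ContactMap:
    """Convenience pipeline: detect -> aggregate -> filter."""
    events = detect_contacts(traj, cutoffs)
    return filter_and_map(strength_series(events, traj), threshold,
                          n_frames=traj.n_frames)


# ---------------------------------------------------------------------------
# Map comparison
# ---------------------------------------------------------------------------

@dataclass
class MapComparison:
    deltas: pd.DataFrame                  # aligned pairs, delta mean strength
    gained: list[tuple]                   # keys only in map_b
    lost: list[tuple]                     # keys only in map_a
    class_shifts: list[dict]              # dominant-class changes


def compare_maps(map_a: ContactMap, map_b: ContactMap) -> MapComparison:
    """Align two contact maps by (protein residue, DNA residue).

    ``gained`` lists contacts present only in ``map_b``, ``lost`` those
    only in ``map_a``; ``class_shifts`` reports pairs whose dominant
    contact class changed (e.g. H-bond-dominated to hydrophobic-dominated).
    """
    a = {r.key: r for r in map_a.records}
    b = {r.key: r for r in map_b.records}
    rows, shifts = [], []
    for key in sorted(set(a) | set(b)):
        ra, rb = a.get(key), b.get(key)
        rows.append({
            "protein_chain": key[0], "protein_resid": key[1],
            "dna_strand": key[2], "dna_bp": key[3],
            "mean_strength_a": ra.mean_strength if ra else 0.0,
            "mean_strength_b": rb.mean_strength if rb else 0.0,
            "delta_mean_strength": (rb.mean_strength if rb else 0.0)
                                   - (ra.mean_strength if ra else 0.0),
        })
        if ra and rb and ra.dominant_class != rb.dominant_class:
            shifts.append({"key": key, "from": ra.dominant_class,
                           "to": rb.dominant_class})
    return MapComparison(
        deltas=pd.DataFrame(rows),
        gained=sorted(set(b) - set(a)),
        lost=sorted(set(a) - set(b)),
        class_shifts=shifts)
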