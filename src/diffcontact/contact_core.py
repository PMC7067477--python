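"""Contact maps, difference contact maps, and DSR identification.

Two residues are in contact when the minimum distance between their
side-chain heavy atoms is strictly below the contact threshold (default
5 A); for glycine the CA atom stands in for the absent side chain, and a
residue with no side-chain heavy atoms forms no contacts. Subtracting
the contact maps of two conformations gives the difference contact map:
the contacts present in exactly one conformation. Entries whose
inter-residue distance changes by no more than the delta threshold
(default 5 A; "<= is removed") are filtered out as local fluctuations,
and the residues of the surviving entries are the differentially
stabilizing residues (DSRs).

All distances are compared in double precision with no rounding: PDB
coordinates carry three decimals, and rounding would create artifacts at
the thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from diffcontact.pdb_io import BACKBONE_ATOMS, Atom, Residue, StructureModel
from diffcontact.alignment import ResidueMap

logger = logging.getLogger(__name__)

Side = Literal["A_only", "B_only"]


@dataclass(frozen=True)
class DCMParameters:
    """Thresholds of the difference-contact-map method.

    contact_threshold
        Contact if min side-chain heavy-atom distance < this (A).
    delta_threshold
        Difference entries with inter-residue distance change <= this (A)
        are filtered out.
    mismatch_tolerance
        Maximum tolerated fraction of differing paired residues.
    min_seq_separation
        Minimum mapped-index separation |i - j| for a pair to be eligible
        as a contact; 1 means sequence neighbours are included.
    """

    contact_threshold: float = 5.0
    delta_threshold: float = 5.0
    mismatch_tolerance: float = 0.05
    min_seq_separation: int = 1

    def __post_init__(self):
        if self.contact_threshold <= 0 or self.delta_threshold <= 0 or self.mismatch_tolerance <= 0:
            raise ValueError("all thresholds must be positive")
        if self.min_seq_separation < 1:
            raise ValueError("min_seq_separation must be >= 1")


@dataclass
class ContactMap:
    """Contacts of one conformation over the mapped positions.

    ``contacts`` maps unordered mapped-position pairs (i, j), i < j, to
    the minimum side-chain heavy-atom distance in Angstrom.
    """

    size: int
    contacts: dict[tuple[int, int], float]
    side: Side = "A_only"

    def __contains__(self, pair) -> bool:
        return tuple(sorted(pair)) in self.contacts

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass
class DiffEntry:
    """One conformation-exclusive contact.

    ``i`` and ``j`` are mapped positions (i < j); ``side`` says which
    conformation has the contact; ``dist_a``/``dist_b`` are the minimum
    side-chain distances in each model (None when a side chain is
    unresolved); ``delta`` is |dist_a - dist_b| when both are defined.
    """

    i: int
    j: int
    side: Side
    dist_a: Optional[float]
    dist_b: Optional[float]
    delta: Optional[float]
    filtered: bool = False


@dataclass
class DifferenceContactMap:
    """Signed symmetric difference of two conformations' contact maps."""

    entries: list[DiffEntry]
    size: int

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def filtered_entries(self) -> list[DiffEntry]:
        return [e for e in self.entries if e.filtered]


@dataclass
class DSRSet:
    """Differentially stabilizing residues with per-residue contact counts.

    ``records`` maps each mapped position to a dict with both models'
    author numbering and residue names plus the number of filtered
    difference contacts the residue takes part in.
    """

    records: dict[int, dict]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> set[int]:
        return set(self.records)


def sidechain_heavy_atoms(res: Residue) -> list[Atom]:
    """Side-chain heavy atoms of a residue; for glycine, the CA atom.

    Backbone atoms (N, CA, C, O, OXT) and hydrogens are excluded. A
    residue with none of the relevant atoms resolved returns an empty
    list and therefore forms no contacts.
    """
    if res.name == "GLY":
        ca = res.atom("CA")
        return [ca] if ca is not None else []
    return [a for a in res.atoms if a.name not in BACKBONE_ATOMS and a.element not in ("H", "D")]


def min_sidechain_distance(res_a: Residue, res_b: Residue) -> Optional[float]:
    """Minimum distance between the residues' side-chain heavy atoms (A).

    None when either residue has no side-chain heavy atoms.
    """
    atoms_a = sidechain_heavy_atoms(res_a)
    atoms_b = sidechain_heavy_atoms(res_b)
    if not atoms_a or not atoms_b:
        return None
    xa = np.array([a.coords for a in atoms_a])
    xb = np.array([b.coords for b in atoms_b])
    return float(cdist(xa, xb).min())


def _mapped_residues(model: StructureModel, rmap: ResidueMap, side: Side) -> list[Residue]:
    col = 0 if side == "A_only" else 1
    return [model.residues[p[col]] for p in rmap.pairs]


def compute_contact_map(
    model: StructureModel, rmap: ResidueMap, side: Side, params: DCMParameters = DCMParameters()
) -> ContactMap:
    """Contact map of one model over the mapped positions.

    A pair (i, j), j - i >= ``min_seq_separation``, is a contact iff its
    minimum side-chain heavy-atom distance is strictly below
    ``contact_threshold``. A k-d tree over side-chain atoms finds every
    atom pair within the threshold; the per-residue-pair minimum over
    those atom pairs equals the true minimum for any pair below it.
    """
    residues = _mapped_residues(model, rmap, side)
    coords, owner = [], []
    for pos, res in enumerate(residues):
        for atom in sidechain_heavy_atoms(res):
            coords.append(atom.coords)
            owner.append(pos)
    contacts: dict[tuple[int, int], float] = {}
    if coords:
        coords = np.asarray(coords)
        owner = np.asarray(owner)
        tree = cKDTree(coords)
        pairs = tree.query_pairs(r=params.contact_threshold, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
            oi, oj = owner[pairs[:, 0]], owner[pairs[:, 1]]
            lo, hi = np.minimum(oi, oj), np.maximum(oi, oj)
            keep = (hi - lo >= params.min_seq_separation) & (d < params.contact_threshold)
            for i, j, dist in zip(lo[keep], hi[keep], d[keep]):
                key = (int(i), int(j))
                if key not in contacts or dist < contacts[key]:
                    contacts[key] = float(dist)
    return ContactMap(size=rmap.n_pairs, contacts=contacts, side=side)


def difference_map(
    cm_a: ContactMap,
    cm_b: ContactMap,
    model_a: StructureModel,
    model_b: StructureModel,
    rmap: ResidueMap,
    params: DCMParameters = DCMParameters(),
) -> DifferenceContactMap:
    """Subtract two contact maps computed over the same residue pairing.

    The entries are the symmetric difference of the contact sets, each
    labelled with the conformation it belongs to and annotated with the
    inter-residue distance in both models.
    """
    if cm_a.size != cm_b.size or cm_a.size != rmap.n_pairs:
        raise ValueError("contact maps were not computed over the same residue map")
    res_a = _mapped_residues(model_a, rmap, "A_only")
    res_b = _mapped_residues(model_b, rmap, "B_only")
    entries: list[DiffEntry] = []
    for i, j in sorted(set(cm_a.contacts) ^ set(cm_b.contacts)):
        side: Side = "A_only" if (i, j) in cm_a.contacts else "B_only"
        dist_a = cm_a.contacts.get((i, j))
        if dist_a is None:
            dist_a = min_sidechain_distance(res_a[i], res_a[j])
        dist_b = cm_b.contacts.get((i, j))
        if dist_b is None:
            dist_b = min_sidechain_distance(res_b[i], res_b[j])
        delta = abs(dist_a - dist_b) if dist_a is not None and dist_b is not None else None
        entries.append(DiffEntry(i=i, j=j, side=side, dist_a=dist_a, dist_b=dist_b, delta=delta))
    return DifferenceContactMap(entries=entries, size=rmap.n_pairs)


def filter_difference_map(
    dcm: DifferenceContactMap, params: DCMParameters = DCMParameters()
) -> DifferenceContactMap:
    """Mark entries whose distance change exceeds the delta threshold.

    An entry survives iff its delta is defined and strictly greater than
    ``delta_threshold`` (changes of exactly the threshold are removed).
    Entries with undefined delta — one conformation lacks resolved
    side-chain atoms — cannot be evaluated and are dropped with a logged
    warning rather than given an invented distance.
    """
    out = []
    for e in dcm.entries:
        if e.delta is None:
            logger.warning(
                "difference entry (%d, %d) has no measurable distance change "
                "(unresolved side chain on one side); excluded from the filtered map",
                e.i,
                e.j,
            )
            out.append(replace(e, filtered=False))
        else:
            out.append(replace(e, filtered=e.delta > params.delta_threshold))
    return DifferenceContactMap(entries=out, size=dcm.size)


def identify_dsrs(
    dcm: DifferenceContactMap,
    model_a: StructureModel,
    model_b: StructureModel,
    rmap: ResidueMap,
) -> DSRSet:
    """Residues taking part in at least one filtered difference contact.

    Each DSR is reported with both models' author numbering and residue
    names (they may differ) and the number of filtered contacts it forms.
    """
    res_a = _mapped_residues(model_a, rmap, "A_only")
    res_b = _mapped_residues(model_b, rmap, "B_only")
    records: dict[int, dict] = {}
    for e in dcm.filtered_entries:
        for pos in (e.i, e.j):
            rec = records.setdefault(
                pos,
                {
                    "seq_id_a": res_a[pos].seq_id,
                    "name_a": res_a[pos].name,
                    "seq_id_b": res_b[pos].seq_id,
                    "name_b": res_b[pos].name,
                    "n_filtered_contacts": 0,
                },
            )
            rec["n_filtered_contacts"] += 1
    return DSRSet(records=records)
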