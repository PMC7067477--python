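"""Summary metrics for a conformational pair.

Covers the global and per-pair numbers reported alongside a difference
contact map: the CA superposition RMSD between the two models, the
fraction of contacts that changed between the conformations, and the
classification of filtered difference contacts by domain pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from diffcontact.pdb_io import StructureModel
from diffcontact.alignment import ResidueMap
from diffcontact.contact_core import ContactMap, DifferenceContactMap

DenominatorMode = Literal["union", "mean", "min"]


@dataclass
class DomainAnnotation:
    """A named domain as inclusive author-numbering residue intervals."""

    name: str
    ranges: list[tuple[int, int]]

    def __post_init__(self):
        ivs = sorted(self.ranges)
        for (a1, b1), (a2, _) in zip(ivs, ivs[1:]):
            if a2 <= b1:
                raise ValueError(f"domain {self.name!r}: overlapping intervals")
        for a, b in ivs:
            if b < a:
                raise ValueError(f"domain {self.name!r}: interval ({a}, {b}) is inverted")

    def __contains__(self, seq_id: int) -> bool:
        return any(a <= seq_id <= b for a, b in self.ranges)


@dataclass
class PairSummary:
    """Headline numbers for one conformational pair."""

    rmsd: float
    n_pairs: int
    mismatch_fraction: float
    n_contacts_a: int
    n_contacts_b: int
    n_diff: int
    n_filtered: int
    n_a_only_filtered: int
    n_b_only_filtered: int
    changed_fraction: float
    n_dsrs: int


def superposition_rmsd(model_a: StructureModel, model_b: StructureModel, rmap: ResidueMap) -> float:
    """CA RMSD after least-squares optimal (Kabsch) superposition.

    Uses the CA atoms of the mapped residue pairs where both sides have
    one; requires at least three such pairs. Symmetric in its arguments
    and invariant under rigid motion of either model.
    """
    pa, pb = [], []
    for ia, ib in rmap.pairs:
        ca_a = model_a.residues[ia].atom("CA")
        ca_b = model_b.residues[ib].atom("CA")
        if ca_a is not None and ca_b is not None:
            pa.append(ca_a.coords)
            pb.append(ca_b.coords)
    if len(pa) < 3:
        raise ValueError(f"need >=3 mapped CA pairs for superposition, got {len(pa)}")
    pa = np.asarray(pa)
    pb = np.asarray(pb)
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(len(pa)))


def changed_contact_fraction(
    cm_a: ContactMap,
    cm_b: ContactMap,
    dcm_filtered: DifferenceContactMap,
    mode: DenominatorMode = "union",
) -> float:
    """Fraction of contacts that changed between the two conformations.

    The numerator is the number of filtered difference entries. The
    denominator is the total number of contacts; "total" is taken as the
    size of the union of the two contact sets by default (symmetric and
    bounded, so the fraction lies in [0, 1]), with per-conformation mean
    or minimum as alternatives. Returns 0 when the denominator is empty.
    """
    n_changed = len(dcm_filtered.filtered_entries)
    if mode == "union":
        denom = len(set(cm_a.contacts) | set(cm_b.contacts))
    elif mode == "mean":
        denom = (len(cm_a) + len(cm_b)) / 2
    elif mode == "min":
        denom = min(len(cm_a), len(cm_b))
    else:
        raise ValueError(f"unknown denominator mode {mode!r}")
    return n_changed / denom if denom else 0.0


def classify_interdomain(
    dcm_filtered: DifferenceContactMap,
    domains: list[DomainAnnotation],
    model: StructureModel,
    rmap: ResidueMap,
    side: Literal["A_only", "B_only"] = "A_only",
) -> dict[tuple[str, str], int]:
    """Count filtered difference contacts per unordered domain pair.

    Domains are given in the author numbering of ``model`` (side A by
    default). Residues outside every domain are labelled ``"other"``.
    Distinct domains must not overlap. The returned counts sum to the
    number of filtered entries; keys are sorted label pairs, so
    intra-domain contacts appear as ``(name, name)``.
    """
    for k, d1 in enumerate(domains):
        for d2 in domains[k + 1 :]:
            for a, b in d1.ranges:
                if any(not (b < a2 or b2 < a) for a2, b2 in d2.ranges):
                    raise ValueError(f"domains {d1.name!r} and {d2.name!r} overlap")
    col = 0 if side == "A_only" else 1
    seq_ids = [model.residues[p[col]].seq_id for p in rmap.pairs]

    def label(pos: int) -> str:
        for d in domains:
            if seq_ids[pos] in d:
                return d.name
        return "other"

    counts: dict[tuple[str, str], int] = {}
    for e in dcm_filtered.filtered_entries:
        key = tuple(sorted((label(e.i), label(e.j))))
        counts[key] = counts.get(key, 0) + 1
    return counts
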