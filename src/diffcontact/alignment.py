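"""Sequence alignment and residue correspondence between two models.

The two chains' deposited (SEQRES) sequences are globally aligned, the
alignment is corrected by dropping columns where either side is a gap or
has no observed coordinates, and the surviving columns become a strictly
monotone one-to-one residue pairing (:class:`ResidueMap`). A pair of
models is considered comparable only if the paired residues are (almost)
identical: more than 5% differing residue names disqualifies the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from diffcontact.pdb_io import StructureModel

#: Global-alignment scoring; at >=95% sequence identity the matching is
#: insensitive to these, but they are fixed for reproducibility.
ALIGNMENT_PARAMS = {"matrix": "BLOSUM62", "open_gap_score": -10.0, "extend_gap_score": -0.5}


@dataclass
class ResidueMap:
    """Order-preserving one-to-one pairing of residues between two models.

    ``pairs`` holds indices into ``model_a.residues`` / ``model_b.residues``;
    both coordinates are strictly increasing (no crossings, no repeats).
    """

    pairs: list[tuple[int, int]]
    n_name_mismatches: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self) -> None:
        prev_a, prev_b = -1, -1
        for ia, ib in self.pairs:
            if ia <= prev_a or ib <= prev_b:
                raise ValueError("residue map is not strictly increasing in both models")
            prev_a, prev_b = ia, ib


@dataclass
class CompatibilityVerdict:
    """Outcome of the pre-comparison skip rule."""

    compatible: bool
    reason: str
    mismatch_fraction: float


class AlignmentError(ValueError):
    """Raised for empty sequences or alignment/model inconsistencies."""


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(ALIGNMENT_PARAMS["matrix"])
    aligner.open_gap_score = ALIGNMENT_PARAMS["open_gap_score"]
    aligner.extend_gap_score = ALIGNMENT_PARAMS["extend_gap_score"]
    return aligner


def align_sequences(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global pairwise alignment of two one-letter sequences.

    Returns two equal-length gapped strings; removing the gaps recovers
    the inputs exactly. Needleman-Wunsch with BLOSUM62, gap open 10,
    gap extend 0.5 (see :data:`ALIGNMENT_PARAMS`).
    """
    if not seq_a or not seq_b:
        raise AlignmentError("cannot align an empty sequence")
    aln = _aligner().align(seq_a, seq_b)[0]
    gapped_a, gapped_b = str(aln[0]), str(aln[1])
    assert gapped_a.replace("-", "") == seq_a and gapped_b.replace("-", "") == seq_b
    return gapped_a, gapped_b


def build_residue_map(
    aln: tuple[str, str], model_a: StructureModel, model_b: StructureModel
) -> ResidueMap:
    """Corrected residue pairing from a SEQRES-level alignment.

    Alignment columns are dropped when either side is a gap, or when
    either side's SEQRES position has no observed residue with
    coordinates in its model; the survivors are returned in order.
    """
    gapped_a, gapped_b = aln
    if gapped_a.replace("-", "") != model_a.seqres or gapped_b.replace("-", "") != model_b.seqres:
        raise AlignmentError("degapped alignment does not match the models' SEQRES sequences")
    # SEQRES position (1-based) -> residue index, for residues with coordinates
    obs_a = {r.label_seq: i for i, r in enumerate(model_a.residues) if r.label_seq is not None and r.atoms}
    obs_b = {r.label_seq: i for i, r in enumerate(model_b.residues) if r.label_seq is not None and r.atoms}
    pairs: list[tuple[int, int]] = []
    mismatches = 0
    pos_a = pos_b = 0
    for ca, cb in zip(gapped_a, gapped_b):
        if ca != "-":
            pos_a += 1
        if cb != "-":
            pos_b += 1
        if ca == "-" or cb == "-":
            continue
        ia, ib = obs_a.get(pos_a), obs_b.get(pos_b)
        if ia is None or ib is None:
            continue
        pairs.append((ia, ib))
        if model_a.residues[ia].name != model_b.residues[ib].name:
            mismatches += 1
    rmap = ResidueMap(pairs=pairs, n_name_mismatches=mismatches)
    rmap.validate()
    return rmap


def check_compatibility(
    rmap: ResidueMap,
    model_a: StructureModel,
    model_b: StructureModel,
    mismatch_tolerance: float = 0.05,
) -> CompatibilityVerdict:
    """Apply the skip rule: fail if more than 5% of paired residues differ.

    The threshold is strict: a mismatch fraction exactly at the tolerance
    still passes. The map is one-to-one by construction, so the extracted
    residue counts on the two sides are equal.
    """
    if rmap.n_pairs == 0:
        return CompatibilityVerdict(False, "no aligned residues", 1.0)
    fraction = rmap.n_name_mismatches / rmap.n_pairs
    if fraction > mismatch_tolerance:
        return CompatibilityVerdict(
            False,
            f"{rmap.n_name_mismatches}/{rmap.n_pairs} paired residues differ "
            f"({fraction:.1%} > {mismatch_tolerance:.0%})",
            fraction,
        )
    return CompatibilityVerdict(
        True,
        f"{rmap.n_pairs} extracted residue pairs, {rmap.n_name_mismatches} name mismatches",
        fraction,
    )
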