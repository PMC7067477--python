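"""PDB input/output with residue-eligibility filtering.

Structures are read into a minimal :class:`StructureModel`: one chain's
eligible residues (empty insertion code, not HETATM) with their heavy
atoms, plus the chain's SEQRES sequence. Hydrogens are dropped, and for
alternate locations only the highest-occupancy conformer of each atom is
kept (ties broken by altloc identifier, ascending). Multi-model (NMR)
files are reduced to a single model, MODEL 1 by default.

Parsing and serialization are delegated to gemmi; this module only applies
the eligibility rules and converts to/from the package's own containers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Backbone heavy-atom names excluded from side chains (OXT = terminal carboxyl O).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be parsed or lacks required content."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom: name, element symbol, coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name!r}: coords must be 3 finite numbers")
        if not self.name.strip():
            raise ValueError("atom name is empty")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "name", self.name.strip())


@dataclass
class Residue:
    """One residue: 3-letter code, author number, and its heavy atoms.

    ``label_seq`` is the 1-based position in the chain's SEQRES sequence,
    or ``None`` if the residue could not be matched to SEQRES.
    """

    name: str
    seq_id: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)
    het_flag: bool = False
    label_seq: Optional[int] = None

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """One chain of one structure: eligible residues plus SEQRES.

    ``seqres`` is the one-letter deposited sequence (``X`` for residues
    without a standard one-letter code); ``residues`` hold only residues
    with empty insertion code and no hetero flag, in chain order.
    """

    pdb_id: str
    chain_id: str
    residues: list[Residue]
    seqres: str

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at_seqres(self, label_seq: int) -> Optional[Residue]:
        """Observed residue at a 1-based SEQRES position, or None."""
        for r in self.residues:
            if r.label_seq == label_seq:
                return r
        return None


def _one_letter(three: Sequence[str]) -> str:
    """One-letter sequence from 3-letter codes; unknown/nonstandard -> X."""
    out = []
    for name in three:
        info = gemmi.find_tabulated_residue(name)
        code = info.one_letter_code.upper() if info else " "
        out.append(code if code.strip() and code.isalpha() else "X")
    return "".join(out)


def _select_altlocs(res: gemmi.Residue) -> list[Atom]:
    """Heavy atoms of a gemmi residue, one conformer per atom name.

    Highest occupancy wins; ties go to the lexicographically smallest
    altloc identifier (blank altloc sorts first).
    """
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        if a.is_hydrogen():
            continue
        by_name.setdefault(a.name, []).append(a)
    atoms = []
    for name, group in by_name.items():
        best = min(group, key=lambda a: (-round(a.occ, 4), a.altloc if a.altloc != "\x00" else " "))
        atoms.append(
            Atom(
                name=name,
                element=best.element.name,
                coords=np.array([best.pos.x, best.pos.y, best.pos.z]),
                altloc="" if best.altloc == "\x00" else best.altloc,
                occupancy=float(best.occ),
            )
        )
    return atoms


def parse_structure(pdb_text: str, chain_id: str, pdb_id: str = "", model_index: int = 0) -> StructureModel:
    """Parse one chain of a PDB file into a :class:`StructureModel`.

    Applies the eligibility rules: only ATOM residues (no HETATM) with an
    empty insertion code are kept; hydrogens are dropped; one altloc per
    atom name is retained. ``model_index`` selects among MODEL records of
    a multi-model file (default: first model).

    Raises :class:`PDBFormatError` if the chain is missing, has no
    eligible residues, or the text cannot be parsed.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"malformed PDB text: {exc}") from exc
    if len(st) == 0:
        raise PDBFormatError("no models in PDB text")
    if model_index >= len(st):
        raise PDBFormatError(f"model index {model_index} out of range ({len(st)} models)")
    st.setup_entities()
    st.assign_label_seq_id()
    model = st[model_index]
    chain = model.find_chain(chain_id)
    if chain is None:
        avail = ", ".join(ch.name for ch in model) or "(none)"
        raise PDBFormatError(f"chain {chain_id!r} not found; available chains: {avail}")

    chain_subchains = {gres.subchain for gres in chain}
    seqres_three: list[str] = []
    for ent in st.entities:
        if ent.full_sequence and chain_subchains.intersection(ent.subchains):
            seqres_three = [gemmi.Entity.first_mon(m) for m in ent.full_sequence]
            break

    residues: list[Residue] = []
    for gres in chain:
        if gres.het_flag != "A":
            continue
        if gres.seqid.icode.strip():
            continue
        atoms = _select_altlocs(gres)
        label_seq = int(gres.label_seq) if gres.label_seq is not None else None
        residues.append(
            Residue(
                name=gres.name,
                seq_id=int(gres.seqid.num),
                insertion_code="",
                atoms=atoms,
                het_flag=False,
                label_seq=label_seq,
            )
        )
    if not residues:
        raise PDBFormatError(f"chain {chain_id!r} has no eligible residues (non-HETATM, empty insertion code)")

    if seqres_three:
        seqres = _one_letter(seqres_three)
    else:
        logger.warning(
            "chain %s: no SEQRES records; reconstructing sequence from observed residues "
            "(deposited-sequence alignment will be approximate)",
            chain_id,
        )
        seqres = _one_letter([r.name for r in residues])
        for i, r in enumerate(residues):
            r.label_seq = i + 1

    # residues gemmi could not place in SEQRES stay flagged unmatched
    return StructureModel(pdb_id=pdb_id or (st.name or "").strip().lower(), chain_id=chain_id, residues=residues, seqres=seqres)


def write_structure(model: StructureModel) -> str:
    """Serialize a :class:`StructureModel` to PDB text (SEQRES + ATOM).

    Round-trips through :func:`parse_structure`: residue names, author
    numbers, atom names and coordinates (to the PDB's 3-decimal precision)
    are preserved. Raises ``ValueError`` on an empty model or a residue
    without atoms.
    """
    if not model.residues:
        raise ValueError("cannot write a model with no residues")
    st = gemmi.Structure()
    st.name = model.pdb_id or "SYNT"
    gmodel = gemmi.Model("1")
    chain = gemmi.Chain(model.chain_id)
    for res in model.residues:
        if not res.atoms:
            raise ValueError(f"residue {res.name} {res.seq_id} has no atoms")
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seq_id, " ")
        gres.het_flag = "A"
        for atom in res.atoms:
            if not np.all(np.isfinite(atom.coords)):
                raise ValueError(f"non-finite coords on {res.name} {res.seq_id} {atom.name}")
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coords)
            ga.occ = atom.occupancy
            ga.b_iso = 0.0
            gres.add_atom(ga)
        chain.add_residue(gres)
    gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    if model.seqres and st.entities:
        # emit the model's own SEQRES (may exceed the observed residues)
        st.entities[0].full_sequence = [_three_letter(c, model) for c in range(len(model.seqres))]
    opts = gemmi.PdbWriteOptions(seqres_records=True, end_record=True)
    return st.make_pdb_string(opts)


def _three_letter(pos: int, model: StructureModel) -> str:
    """3-letter code for SEQRES position ``pos`` (0-based) of the model."""
    res = model.residue_at_seqres(pos + 1)
    if res is not None:
        return res.name
    one = model.seqres[pos]
    info = gemmi.expand_one_letter(one, gemmi.ResidueKind.AA)
    return info if info else "UNK"


def fetch_pdb(pdb_id: str, cache_dir, timeout: float = 15.0) -> str:
    """Download a PDB entry from the RCSB archive, caching to ``cache_dir``.

    Network access is a convenience only; all tests that can run offline
    use synthetic fixtures instead.
    """
    import pathlib
    import urllib.request

    cache_dir = pathlib.Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{pdb_id.lower()}.pdb"
    if path.exists():
        return path.read_text()
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    path.write_text(text)
    return text
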