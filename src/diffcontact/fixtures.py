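"""Synthetic two-conformation structure pairs with known ground truth.

The generator emits a pair of single-chain PDB files representing the
same artificial protein in two conformations, plus the ground truth a
correct difference-contact-map pipeline must recover: the two contact
sets, the conformation-exclusive contacts, and the subset surviving the
distance-change filter.

Geometry is deliberately minimal rather than physically realistic: the
chain is a poly-alanine "hairpin" whose two arms face each other with a
contact interface, sprinkled with glycines (to exercise the CA-for-Gly
rule), and conformation B is conformation A with a rigid, hinge or shear
motion applied to the residues past the hinge. Designated probe residues
carry a single side-chain pseudo-atom placed to realize planted
inter-residue distances exactly, including values sitting exactly on the
contact and filter thresholds.

Ground truth is never trusted from construction: it is re-measured from
the emitted PDB texts by an independent brute-force pass (a minimal
column-sliced ATOM reader and an all-pairs distance scan) so that a bug
in the structure writer cannot silently propagate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Optional

import numpy as np

from diffcontact.pdb_io import Atom, Residue, StructureModel, write_structure
from diffcontact.contact_core import DCMParameters

Motion = Literal["hinge", "shear", "rigid", "none"]

_SPACING = 3.8  # CA-CA spacing along an arm, A
_ARM_GAP = 5.2  # vertical offset between the two arms, A
_CB_RISE = 1.5  # CB offset from CA towards the facing arm, A
_RIGID_AXIS = np.array([1.0, 2.0, 3.0]) / np.linalg.norm([1.0, 2.0, 3.0])
_RIGID_SHIFT = np.array([7.0, -4.0, 11.0])


class PlantedContact(NamedTuple):
    """A requested inter-residue distance in each conformation.

    ``j`` becomes a probe residue whose single side-chain pseudo-atom is
    placed at exactly ``dist_a`` (conformation A) and ``dist_b``
    (conformation B) from residue ``i``'s side-chain atom.
    """

    i: int
    j: int
    dist_a: float
    dist_b: float


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic conformational pair.

    ``hinge_position``: last residue index that does not move (default:
    the midpoint). ``hinge_angle`` is in degrees; ``shear_shift`` is the
    translation in A used when ``motion == "shear"``. ``jitter`` adds a
    uniform perturbation to backbone positions so fixtures differ across
    seeds.
    """

    n_residues: int = 30
    motion: Motion = "hinge"
    hinge_position: Optional[int] = None
    hinge_angle: float = 60.0
    shear_shift: float = 3.0
    planted_contacts: tuple[PlantedContact, ...] = ()
    jitter: float = 0.3
    seed: int = 0

    @property
    def hinge(self) -> int:
        return self.hinge_position if self.hinge_position is not None else self.n_residues // 2


@dataclass
class GroundTruth:
    """What the pipeline must recover, re-measured from the emitted files.

    Pairs are 0-based residue indices (i, j), i < j; sides are
    ``"A_only"``/``"B_only"``.
    """

    contacts_a: set[tuple[int, int]]
    contacts_b: set[tuple[int, int]]
    expected_diff: set[tuple[tuple[int, int], str]]
    expected_filtered: set[tuple[tuple[int, int], str]]
    deltas: dict[tuple[int, int], Optional[float]] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for (i, j), side in sorted(self.expected_diff):
            rows.append(
                {
                    "i": i,
                    "j": j,
                    "side": side,
                    "delta": self.deltas.get((i, j)),
                    "filtered": ((i, j), side) in self.expected_filtered,
                }
            )
        return rows


class FixtureError(ValueError):
    """Raised when a requested fixture cannot be realized."""


def _gly_positions(n: int) -> set[int]:
    # deterministic sprinkling of glycines along the chain
    return {k for k in range(n) if k % 7 == 3}


def _backbone(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """CA positions and CB directions (unit z sign) for conformation A."""
    rng = np.random.default_rng(spec.seed)
    n, h = spec.n_residues, spec.hinge
    ca = np.zeros((n, 3))
    cb_sign = np.ones(n)
    for k in range(n):
        if k <= h:
            ca[k] = (_SPACING * k, 0.0, 0.0)
            cb_sign[k] = 1.0
        else:
            # second arm folds back above the first, side chains pointing down
            ca[k] = (_SPACING * (2 * h + 1 - k), 0.0, _ARM_GAP)
            cb_sign[k] = -1.0
    if spec.jitter > 0:
        ca += rng.uniform(-spec.jitter, spec.jitter, size=ca.shape)
    return ca, cb_sign


def _build_model(
    spec: FixtureSpec, ca: np.ndarray, cb_sign: np.ndarray, label: str, names: list[str]
) -> StructureModel:
    residues = []
    for k in range(spec.n_residues):
        name = names[k]
        atoms = [
            Atom("N", "N", ca[k] + (-1.2, 0.9, 0.0)),
            Atom("CA", "C", ca[k]),
            Atom("C", "C", ca[k] + (1.2, 0.9, 0.0)),
            Atom("O", "O", ca[k] + (1.4, 2.0, 0.0)),
        ]
        if name != "GLY":
            atoms.append(Atom("CB", "C", ca[k] + (0.0, 0.0, _CB_RISE * cb_sign[k])))
        residues.append(Residue(name=name, seq_id=k + 1, atoms=atoms, label_seq=k + 1))
    seqres = "".join({"ALA": "A", "GLY": "G", "VAL": "V", "SER": "S"}.get(n, "X") for n in names)
    return StructureModel(pdb_id=label, chain_id="A", residues=residues, seqres=seqres)


def _apply_motion(spec: FixtureSpec, ca: np.ndarray) -> np.ndarray:
    """Conformation B backbone: the motion applied to residues past the hinge."""
    n, h = spec.n_residues, spec.hinge
    out = ca.copy()
    moving = np.arange(n) > h
    if spec.motion == "none":
        return out
    if spec.motion == "rigid":
        rot = _rotation_matrix(_RIGID_AXIS, math.radians(spec.hinge_angle))
        center = ca.mean(axis=0)
        return (ca - center) @ rot.T + center + _RIGID_SHIFT
    if spec.motion == "hinge":
        pivot = ca[min(h + 1, n - 1)]
        rot = _rotation_matrix(np.array([0.0, 1.0, 0.0]), math.radians(spec.hinge_angle))
        out[moving] = (ca[moving] - pivot) @ rot.T + pivot
        return out
    if spec.motion == "shear":
        out[moving] += np.array([0.0, spec.shear_shift, 0.0])
        return out
    raise FixtureError(f"unknown motion {spec.motion!r}")


def _rotation_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    ux, uy, uz = axis
    c, s = math.cos(theta), math.sin(theta)
    return np.array(
        [
            [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
        ]
    )


def _contact_atom(res: Residue) -> Atom:
    return res.atom("CA") if res.name == "GLY" else res.atom("CB")


def _set_contact_atom(res: Residue, coords: np.ndarray) -> None:
    name = "CA" if res.name == "GLY" else "CB"
    res.atoms = [a for a in res.atoms if a.name != name] + [Atom(name, "C", coords)]


def _plant(model: StructureModel, contacts: tuple[PlantedContact, ...], which: str) -> None:
    """Realize planted distances by anchoring i on integer coordinates and
    placing j's probe atom axis-aligned below it (the -y halfspace is empty
    in the base geometry, so planted distances are not confounded by the
    lattice). Integer anchors make distances exactly equal to the planted
    value after the file's 3-decimal rounding, which keeps contacts planted
    exactly on a threshold on the intended side of a strict comparison.
    """
    probes = [c.j for c in contacts]
    if len(set(probes)) != len(probes):
        raise FixtureError("each probe residue j may appear in only one planted contact")
    for c in contacts:
        d = c.dist_a if which == "A" else c.dist_b
        if d <= 0:
            raise FixtureError(f"planted contact ({c.i}, {c.j}): distance must be positive")
        res_i, res_j = model.residues[c.i], model.residues[c.j]
        anchor = np.round(_contact_atom(res_i).coords).astype(float)
        _set_contact_atom(res_i, anchor)
        _set_contact_atom(res_j, anchor + np.array([0.0, -d, 0.0]))


def make_pair(spec: FixtureSpec, params: DCMParameters = DCMParameters()) -> tuple[str, str, GroundTruth]:
    """Generate a conformational pair and its re-measured ground truth.

    Returns ``(pdb_text_a, pdb_text_b, truth)``. Generation is
    deterministic given ``spec.seed``: the same spec yields byte-identical
    PDB texts. Raises :class:`FixtureError` when a planted contact cannot
    be realized (verified post hoc on the emitted coordinates).
    """
    if spec.n_residues < 4:
        raise FixtureError("need at least 4 residues")
    for c in spec.planted_contacts:
        for idx in (c.i, c.j):
            if not 0 <= idx < spec.n_residues:
                raise FixtureError(f"planted contact index {idx} out of range")
        if c.i == c.j:
            raise FixtureError("planted contact needs two distinct residues")

    gly = _gly_positions(spec.n_residues)
    probe_idx = {c.j for c in spec.planted_contacts} | {c.i for c in spec.planted_contacts}
    names = ["GLY" if (k in gly and k not in probe_idx) else "ALA" for k in range(spec.n_residues)]

    ca_a, cb_sign = _backbone(spec)
    model_a = _build_model(spec, ca_a, cb_sign, "synA", names)
    if spec.motion == "rigid":
        # every atom undergoes the same rotation + translation
        rot = _rotation_matrix(_RIGID_AXIS, math.radians(spec.hinge_angle))
        center = ca_a.mean(axis=0)
        model_b = _build_model(spec, ca_a, cb_sign, "synB", names)
        for res in model_b.residues:
            res.atoms = [
                Atom(a.name, a.element, _rigid_point(a.coords, rot, center)) for a in res.atoms
            ]
    else:
        ca_b = _apply_motion(spec, ca_a)
        model_b = _build_model(spec, ca_b, cb_sign, "synB", names)
    _plant(model_a, spec.planted_contacts, "A")
    _plant(model_b, spec.planted_contacts, "B")

    text_a = write_structure(model_a)
    text_b = write_structure(model_b)
    truth = measure_ground_truth(text_a, text_b, params)
    _verify_planted(text_a, spec, "A")
    _verify_planted(text_b, spec, "B")
    return text_a, text_b, truth


def _rigid_point(p: np.ndarray, rot: np.ndarray, center: np.ndarray) -> np.ndarray:
    return (p - center) @ rot.T + center + _RIGID_SHIFT


def make_mutation_pair(
    spec: FixtureSpec, mutated_positions: list[int], params: DCMParameters = DCMParameters()
) -> tuple[str, str, GroundTruth]:
    """A pair with identical coordinates but mutated residue identities.

    Model B carries alanine-to-valine substitutions (coordinates and the
    single CB side-chain atom unchanged) at ``mutated_positions``; this
    exercises the mismatch-fraction skip rule without moving any atom.
    """
    for p in mutated_positions:
        if not 0 <= p < spec.n_residues:
            raise FixtureError(f"mutated position {p} out of range")
    base = replace(spec, motion="none")
    gly = _gly_positions(base.n_residues)
    probe_idx = {c.j for c in base.planted_contacts} | {c.i for c in base.planted_contacts}
    names = ["GLY" if (k in gly and k not in probe_idx) else "ALA" for k in range(base.n_residues)]
    for p in mutated_positions:
        if names[p] == "GLY":
            raise FixtureError(f"position {p} is glycine in the base fixture; mutate a non-glycine position")
    ca_a, cb_sign = _backbone(base)
    model_a = _build_model(base, ca_a, cb_sign, "synA", names)
    names_b = list(names)
    for p in mutated_positions:
        names_b[p] = "VAL"
    model_b = _build_model(base, ca_a, cb_sign, "synB", names_b)
    _plant(model_a, base.planted_contacts, "A")
    _plant(model_b, base.planted_contacts, "B")
    text_a = write_structure(model_a)
    text_b = write_structure(model_b)
    truth = measure_ground_truth(text_a, text_b, params)
    return text_a, text_b, truth


def _verify_planted(text: str, spec: FixtureSpec, which: str) -> None:
    residues = _brute_parse(text)
    for c in spec.planted_contacts:
        want = c.dist_a if which == "A" else c.dist_b
        got = _brute_min_dist(residues[c.i], residues[c.j])
        if got is None or abs(got - want) > 2e-3:
            raise FixtureError(
                f"planted contact ({c.i}, {c.j}) not realized in conformation {which}: "
                f"requested {want} A, measured {got} A"
            )


# --- independent brute-force measurement (kept free of the package's own
# --- parser and contact code so it can serve as an oracle)

_BB = {"N", "CA", "C", "O", "OXT"}


def _brute_parse(pdb_text: str) -> list[dict]:
    """Column-sliced ATOM reader: list of {name, atoms: {aname: xyz}}."""
    residues: list[dict] = []
    seen: dict[tuple, int] = {}
    for line in pdb_text.splitlines():
        if not line.startswith("ATOM"):
            continue
        key = (line[21], int(line[22:26]), line[26])
        if key not in seen:
            seen[key] = len(residues)
            residues.append({"name": line[17:20].strip(), "atoms": {}})
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        residues[seen[key]]["atoms"][line[12:16].strip()] = xyz
    return residues


def _brute_sidechain(res: dict) -> list[tuple]:
    if res["name"] == "GLY":
        return [res["atoms"]["CA"]] if "CA" in res["atoms"] else []
    return [xyz for name, xyz in res["atoms"].items() if name not in _BB]


def _brute_min_dist(res_a: dict, res_b: dict) -> Optional[float]:
    sa, sb = _brute_sidechain(res_a), _brute_sidechain(res_b)
    if not sa or not sb:
        return None
    best = None
    for xa in sa:
        for xb in sb:
            d = math.dist(xa, xb)
            if best is None or d < best:
                best = d
    return best


def measure_ground_truth(
    pdb_text_a: str, pdb_text_b: str, params: DCMParameters = DCMParameters()
) -> GroundTruth:
    """All-pairs brute-force ground truth from two emitted PDB texts.

    Assumes the identity residue mapping (fixture pairs always have the
    same residue count); contact, difference and filter semantics follow
    the method's strict/non-strict boundary rules.
    """
    ra = _brute_parse(pdb_text_a)
    rb = _brute_parse(pdb_text_b)
    if len(ra) != len(rb):
        raise FixtureError("fixture pair has unequal residue counts")
    n = len(ra)
    contacts_a: set = set()
    contacts_b: set = set()
    dists_a: dict = {}
    dists_b: dict = {}
    for i in range(n):
        for j in range(i + params.min_seq_separation, n):
            da = _brute_min_dist(ra[i], ra[j])
            db = _brute_min_dist(rb[i], rb[j])
            dists_a[(i, j)], dists_b[(i, j)] = da, db
            if da is not None and da < params.contact_threshold:
                contacts_a.add((i, j))
            if db is not None and db < params.contact_threshold:
                contacts_b.add((i, j))
    expected_diff = set()
    expected_filtered = set()
    deltas: dict = {}
    for pair in contacts_a ^ contacts_b:
        side = "A_only" if pair in contacts_a else "B_only"
        expected_diff.add((pair, side))
        da, db = dists_a[pair], dists_b[pair]
        delta = abs(da - db) if da is not None and db is not None else None
        deltas[pair] = delta
        if delta is not None and delta > params.delta_threshold:
            expected_filtered.add((pair, side))
    return GroundTruth(
        contacts_a=contacts_a,
        contacts_b=contacts_b,
        expected_diff=expected_diff,
        expected_filtered=expected_filtered,
        deltas=deltas,
    )
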