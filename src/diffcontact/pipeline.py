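"""End-to-end pipeline and report writing.

``run_pipeline`` chains the full method — parse, SEQRES alignment,
compatibility check, per-conformation contact maps, difference map,
distance-change filter, DSR identification, summary metrics — and writes
diff-able CSV reports plus an optional difference-map plot. Row order and
column schema are fixed so outputs are byte-stable across reruns.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from diffcontact._version import __version__ as _pkg_version
from diffcontact.pdb_io import StructureModel, parse_structure
from diffcontact.alignment import align_sequences, build_residue_map, check_compatibility, ResidueMap, CompatibilityVerdict
from diffcontact.contact_core import (
    DCMParameters,
    DifferenceContactMap,
    DSRSet,
    compute_contact_map,
    difference_map,
    filter_difference_map,
    identify_dsrs,
)
from diffcontact.metrics import (
    DomainAnnotation,
    PairSummary,
    changed_contact_fraction,
    classify_interdomain,
    superposition_rmsd,
)

logger = logging.getLogger(__name__)

#: process exit codes used by the CLI
EXIT_OK, EXIT_ERROR, EXIT_INCOMPATIBLE = 0, 1, 3


class IncompatiblePairError(RuntimeError):
    """The two models fail the residue-identity skip rule."""

    def __init__(self, verdict: CompatibilityVerdict):
        super().__init__(f"models are not comparable: {verdict.reason}")
        self.verdict = verdict


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    path_a: Path
    chain_a: str
    path_b: Path
    chain_b: str
    params: DCMParameters = field(default_factory=DCMParameters)
    denominator: str = "union"
    domains_path: Optional[Path] = None
    out_dir: Optional[Path] = None
    model_index: int = 0
    plot: bool = True
    plot_style: str = "overlay"
    label_a: str = ""
    label_b: str = ""


@dataclass
class PipelineResult:
    model_a: StructureModel
    model_b: StructureModel
    rmap: ResidueMap
    verdict: CompatibilityVerdict
    dcm: DifferenceContactMap
    dsrs: DSRSet
    summary: PairSummary
    domain_counts: Optional[dict] = None
    contacts_frame: Optional[pd.DataFrame] = None


def load_domains(path) -> list[DomainAnnotation]:
    """Read domain annotations from a small YAML file.

    Expected shape::

        domains:
          NMP: [[30, 59]]
          LID: [[122, 159], [170, 175]]

    Ranges are inclusive author-numbering intervals.
    """
    data = yaml.safe_load(Path(path).read_text())
    domains = []
    for name, ranges in (data.get("domains") or {}).items():
        domains.append(DomainAnnotation(name=str(name), ranges=[tuple(r) for r in ranges]))
    return domains


def _metadata_lines(config: RunConfig) -> list[str]:
    p = config.params
    return [
        f"# diffcontact {_pkg_version}",
        f"# contact_threshold={p.contact_threshold} delta_threshold={p.delta_threshold} "
        f"mismatch_tolerance={p.mismatch_tolerance} min_seq_separation={p.min_seq_separation} "
        f"denominator={config.denominator}",
    ]


def contacts_table(result: PipelineResult) -> pd.DataFrame:
    """One row per difference entry, sorted by mapped index pair."""
    res_a = [result.model_a.residues[ia] for ia, _ in result.rmap.pairs]
    res_b = [result.model_b.residues[ib] for _, ib in result.rmap.pairs]
    rows = []
    for e in sorted(result.dcm.entries, key=lambda e: (e.i, e.j)):
        rows.append(
            {
                "i": e.i,
                "j": e.j,
                "resid_a_i": res_a[e.i].seq_id,
                "resname_a_i": res_a[e.i].name,
                "resid_b_i": res_b[e.i].seq_id,
                "resname_b_i": res_b[e.i].name,
                "resid_a_j": res_a[e.j].seq_id,
                "resname_a_j": res_a[e.j].name,
                "resid_b_j": res_b[e.j].seq_id,
                "resname_b_j": res_b[e.j].name,
                "side": e.side,
                "dist_a": e.dist_a,
                "dist_b": e.dist_b,
                "delta": e.delta,
                "filtered": e.filtered,
            }
        )
    columns = [
        "i", "j",
        "resid_a_i", "resname_a_i", "resid_b_i", "resname_b_i",
        "resid_a_j", "resname_a_j", "resid_b_j", "resname_b_j",
        "side", "dist_a", "dist_b", "delta", "filtered",
    ]
    return pd.DataFrame(rows, columns=columns)


def summary_table(config: RunConfig, result: PipelineResult) -> pd.DataFrame:
    s = result.summary
    row = {
        "label_a": config.label_a or result.model_a.pdb_id,
        "chain_a": config.chain_a,
        "label_b": config.label_b or result.model_b.pdb_id,
        "chain_b": config.chain_b,
        "compatible": result.verdict.compatible,
        **dataclasses.asdict(s),
        "denominator": config.denominator,
        **{f"param_{k}": v for k, v in dataclasses.asdict(config.params).items()},
        "version": _pkg_version,
    }
    return pd.DataFrame([row])


def _write_csv(frame: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(header_lines) + "\n")
        frame.to_csv(fh, index=False, float_format="%.4f")


def plot_difference_map(result: PipelineResult, path: Path, style: str = "overlay") -> None:
    """Two-color scatter of the filtered difference map.

    ``overlay``: both sides mirrored across the diagonal, colored by the
    conformation the contact belongs to. ``split``: side A in the upper
    triangle, side B in the lower.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    colors = {"A_only": "tab:red", "B_only": "tab:blue"}
    for side in ("A_only", "B_only"):
        pts = [(e.i, e.j) for e in result.dcm.filtered_entries if e.side == side]
        if style == "overlay":
            xy = [(i, j) for i, j in pts] + [(j, i) for i, j in pts]
        elif side == "A_only":
            xy = [(i, j) for i, j in pts]
        else:
            xy = [(j, i) for i, j in pts]
        if xy:
            ax.scatter(*zip(*xy), s=12, c=colors[side], label=side.replace("_only", ""))
    n = result.dcm.size
    ax.plot([0, n], [0, n], lw=0.5, c="0.7")
    ax.set_xlim(0, n)
    ax.set_ylim(0, n)
    ax.set_xlabel("mapped residue index")
    ax.set_ylabel("mapped residue index")
    ax.set_title("Filtered difference contact map")
    ax.legend(loc="upper left")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full difference-contact-map pipeline for one pair.

    Raises :class:`IncompatiblePairError` when the pair fails the
    mismatch skip rule. When ``config.out_dir`` is set, writes
    ``contacts.csv`` (one row per difference entry), ``summary.csv``
    (per-pair metadata), ``dsrs.csv``, an optional plot and a run log.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        logging.getLogger("diffcontact").addHandler(handler)
    try:
        return _run(config, out_dir)
    finally:
        if out_dir:
            logging.getLogger("diffcontact").removeHandler(handler)
            handler.close()


def _run(config: RunConfig, out_dir: Optional[Path]) -> PipelineResult:
    params = config.params
    model_a = parse_structure(
        Path(config.path_a).read_text(), config.chain_a,
        pdb_id=config.label_a or Path(config.path_a).stem, model_index=config.model_index,
    )
    model_b = parse_structure(
        Path(config.path_b).read_text(), config.chain_b,
        pdb_id=config.label_b or Path(config.path_b).stem, model_index=config.model_index,
    )
    logger.info("parsed %s:%s (%d residues) and %s:%s (%d residues)",
                model_a.pdb_id, config.chain_a, len(model_a), model_b.pdb_id, config.chain_b, len(model_b))
    aln = align_sequences(model_a.seqres, model_b.seqres)
    rmap = build_residue_map(aln, model_a, model_b)
    verdict = check_compatibility(rmap, model_a, model_b, params.mismatch_tolerance)
    logger.info("residue map: %d pairs, mismatch fraction %.4f", rmap.n_pairs, verdict.mismatch_fraction)
    if not verdict.compatible:
        if out_dir:
            logger.error("pair skipped: %s", verdict.reason)
        raise IncompatiblePairError(verdict)

    cm_a = compute_contact_map(model_a, rmap, "A_only", params)
    cm_b = compute_contact_map(model_b, rmap, "B_only", params)
    dcm = filter_difference_map(difference_map(cm_a, cm_b, model_a, model_b, rmap, params), params)
    dsrs = identify_dsrs(dcm, model_a, model_b, rmap)
    rmsd = superposition_rmsd(model_a, model_b, rmap)
    changed = changed_contact_fraction(cm_a, cm_b, dcm, mode=config.denominator)
    filtered = dcm.filtered_entries
    summary = PairSummary(
        rmsd=rmsd,
        n_pairs=rmap.n_pairs,
        mismatch_fraction=verdict.mismatch_fraction,
        n_contacts_a=len(cm_a),
        n_contacts_b=len(cm_b),
        n_diff=len(dcm),
        n_filtered=len(filtered),
        n_a_only_filtered=sum(1 for e in filtered if e.side == "A_only"),
        n_b_only_filtered=sum(1 for e in filtered if e.side == "B_only"),
        changed_fraction=changed,
        n_dsrs=len(dsrs),
    )
    result = PipelineResult(
        model_a=model_a, model_b=model_b, rmap=rmap, verdict=verdict,
        dcm=dcm, dsrs=dsrs, summary=summary,
    )
    result.contacts_frame = contacts_table(result)
    if config.domains_path:
        domains = load_domains(config.domains_path)
        result.domain_counts = classify_interdomain(dcm, domains, model_a, rmap)
        logger.info("domain-pair counts: %s", result.domain_counts)
    logger.info(
        "contacts: A=%d B=%d, diff=%d, filtered=%d (A-only %d / B-only %d), "
        "changed fraction %.4f, RMSD %.2f A, DSRs %d",
        summary.n_contacts_a, summary.n_contacts_b, summary.n_diff, summary.n_filtered,
        summary.n_a_only_filtered, summary.n_b_only_filtered, changed, rmsd, len(dsrs),
    )

    if out_dir:
        header = _metadata_lines(config)
        _write_csv(result.contacts_frame, out_dir / "contacts.csv", header)
        _write_csv(summary_table(config, result), out_dir / "summary.csv", header)
        dsr_rows = [
            {"position": pos, **rec} for pos, rec in sorted(result.dsrs.records.items())
        ]
        _write_csv(
            pd.DataFrame(dsr_rows, columns=["position", "seq_id_a", "name_a", "seq_id_b", "name_b", "n_filtered_contacts"]),
            out_dir / "dsrs.csv",
            header,
        )
        if result.domain_counts is not None:
            dom_rows = [
                {"domain_1": k[0], "domain_2": k[1], "n_filtered_contacts": v}
                for k, v in sorted(result.domain_counts.items())
            ]
            _write_csv(pd.DataFrame(dom_rows, columns=["domain_1", "domain_2", "n_filtered_contacts"]),
                       out_dir / "domain_counts.csv", header)
        if config.plot:
            plot_difference_map(result, out_dir / "difference_map.png", style=config.plot_style)
    return result
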