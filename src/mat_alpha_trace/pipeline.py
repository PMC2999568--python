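"""End-to-end orchestration of the domain-family analysis.

Stages: per-class alignment -> core filtering -> profiles and consensus
sequences -> all-pairs consensus comparison -> joint ML phylogeny with
LR-ELW edge supports -> monophyly verdicts and KH/SH topology tests ->
per-class ancestral reconstruction and comparison -> downstream motif
scan -> machine-readable report. Every stochastic step derives from the
single seed recorded in the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .ancestral import reconstruct_class_ancestor
from .compare import all_pairs_comparison, compare_consensus, comparison_table
from .ml_phylo import (
    _nni_neighbors_by_index,
    distance_matrix,
    elw_edge_support,
    kh_sh_test,
    neighbor_joining,
    nni_search,
    optimize_branch_lengths_and_model,
)
from .models import lg_model
from .motif_scan import ALPHA1_DOWNSTREAM_CORE, downstream_window, scan
from .msa import progressive_align
from .profiles import (
    Alignment,
    column_frequencies,
    consensus,
    coverage_filter,
    extract_core,
    remove_gappy_columns,
)
from .sequences import DomainClass, DomainSequence, read_fasta, read_table
from .trees import PhyloTree

logger = logging.getLogger(__name__)

ALPHA1_CLASSES = (DomainClass.ALPHA1_A, DomainClass.ALPHA1_B)


@dataclass
class RunConfig:
    """Reproducible run description (round-trips through JSON)."""

    seed: int = 0
    class_files: dict[str, str] = field(default_factory=dict)
    table_file: str | None = None
    aligned: bool = False
    anchor: tuple[str, int, int] | None = None  # (row id, 1-based start, end)
    coverage_threshold: float = 0.8
    gap_column_threshold: float = 0.5
    model: str = "LG+G"
    gamma_categories: int = 4
    n_replicates: int = 1000
    protein_file: str | None = None
    domain_end: dict[str, int] = field(default_factory=dict)
    motif_pattern: str = ALPHA1_DOWNSTREAM_CORE
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_threshold <= 1.0):
            raise ValueError("coverage_threshold must be in (0, 1]")
        if not (0.0 <= self.gap_column_threshold < 1.0):
            raise ValueError("gap_column_threshold must be in [0, 1)")
        if self.model not in ("LG", "LG+G", "LG+I+G"):
            raise ValueError(f"unsupported model {self.model!r}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if d["anchor"] is not None:
            d["anchor"] = list(d["anchor"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if d.get("anchor") is not None:
            d["anchor"] = tuple(d["anchor"])
        return cls(**d)


def _build_model(config: RunConfig):
    if config.model == "LG":
        return lg_model()
    if config.model == "LG+G":
        return lg_model(alpha=1.0, n_categories=config.gamma_categories)
    return lg_model(alpha=1.0, n_categories=config.gamma_categories, p_invariant=0.05)


def load_inputs(config: RunConfig) -> dict[DomainClass, list[DomainSequence]]:
    by_class: dict[DomainClass, list[DomainSequence]] = {}
    if config.table_file:
        for s in read_table(config.table_file):
            by_class.setdefault(s.domain_class, []).append(s)
    for label, path in config.class_files.items():
        cls = DomainClass.from_label(label)
        by_class.setdefault(cls, []).extend(read_fasta(path, domain_class=cls))
    if not by_class:
        raise FileNotFoundError("no input sequences configured")
    for cls, seqs in by_class.items():
        if not seqs:
            raise ValueError(f"class {cls.value} has no sequences")
    return by_class


@dataclass
class AnalysisReport:
    """All pipeline results, regenerable from config + inputs + seed."""

    config: dict[str, Any]
    per_class: dict[str, dict[str, Any]]
    joint_alignment: dict[str, Any]
    comparisons: list[dict[str, Any]]
    tree_newick: str
    log_likelihood: float
    model: dict[str, Any]
    edge_supports: list[dict[str, Any]]
    monophyly: dict[str, Any]
    kh_sh: list[dict[str, Any]]
    ancestor_comparison: dict[str, Any] | None
    motif_hits: list[dict[str, Any]]
    provenance: dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))


def _prepare_class_alignment(
    seqs: list[DomainSequence], config: RunConfig
) -> tuple[Alignment, list[str]]:
    if config.aligned:
        aln = Alignment([s.id for s in seqs], [s.residues for s in seqs])
    else:
        aln = progressive_align(seqs)
    if config.anchor is not None and config.anchor[0] in aln.ids:
        row, start, end = config.anchor
        aln = extract_core(aln, row, start, end)
    aln, removed = coverage_filter(aln, config.coverage_threshold)
    aln = remove_gappy_columns(aln, config.gap_column_threshold)
    return aln, removed


def run_pipeline(
    config: RunConfig,
    sequences: Mapping[DomainClass, list[DomainSequence]] | None = None,
) -> AnalysisReport:
    """Execute every stage; optional stages degrade gracefully."""
    t0 = time.time()
    rng_seed = int(config.seed)
    by_class = dict(sequences) if sequences is not None else load_inputs(config)
    model = _build_model(config)

    # --- per-class profiling ---------------------------------------------
    per_class: dict[str, dict[str, Any]] = {}
    consensuses = []
    class_alignments: dict[DomainClass, Alignment] = {}
    for cls, seqs in sorted(by_class.items(), key=lambda kv: kv[0].value):
        aln, removed = _prepare_class_alignment(seqs, config)
        profile = column_frequencies(aln)
        cons = consensus(profile, source_class=cls.value)
        consensuses.append(cons)
        class_alignments[cls] = aln
        per_class[cls.value] = {
            "n_input": len(seqs),
            "n_kept": aln.n_rows,
            "removed_ids": removed,
            "n_columns": aln.n_columns,
            "consensus": cons.residues,
            "mean_information_bits": float(profile.information_bits.mean()),
        }
        logger.info(
            "class %s: %d/%d rows kept, %d columns",
            cls.value, aln.n_rows, len(seqs), aln.n_columns,
        )

    comparisons = (
        comparison_table(all_pairs_comparison(consensuses)).to_dict("records")
        if len(consensuses) >= 2
        else []
    )

    # --- joint phylogeny ---------------------------------------------------
    all_seqs = [s for cls in sorted(by_class, key=lambda c: c.value) for s in by_class[cls]]
    class_of = {s.id: s.domain_class for s in all_seqs}
    joint = progressive_align(all_seqs) if not config.aligned else Alignment(
        [s.id for s in all_seqs], [s.residues for s in all_seqs]
    )
    joint, joint_removed = coverage_filter(joint, config.coverage_threshold)
    joint = remove_gappy_columns(joint, config.gap_column_threshold)
    if joint_removed:
        logger.info("joint alignment: removed %s", joint_removed)

    dmat, ids = distance_matrix(joint, model)
    start_tree = neighbor_joining(dmat, ids)
    best_tree, best_lnl = nni_search(start_tree, joint, model)
    best_tree, model, best_lnl = optimize_branch_lengths_and_model(best_tree, joint, model)
    support_report = elw_edge_support(
        best_tree, joint, model, n_replicates=config.n_replicates, seed=rng_seed
    )
    annotated = support_report.tree or best_tree

    alpha1_ids = [i for i in ids if class_of[i] in ALPHA1_CLASSES]
    mata_ids = [i for i in ids if class_of[i] is DomainClass.MATA_HMG]
    monophyly: dict[str, Any] = {}
    for label, taxa in [
        ("alpha1", alpha1_ids),
        ("alpha1+MATA_HMG", alpha1_ids + mata_ids),
    ]:
        if not taxa:
            continue
        mono = annotated.is_monophyletic(taxa)
        support = _support_of(support_report, frozenset(taxa), set(ids))
        monophyly[label] = {"monophyletic": mono, "elw_support": support, "n_taxa": len(taxa)}

    # --- topology tests ----------------------------------------------------
    kh_sh: list[dict[str, Any]] = []
    try:
        alternatives = _alternative_topologies(annotated, support_report)
        if alternatives:
            tests = kh_sh_test(
                [annotated, *alternatives], joint, model,
                n_replicates=config.n_replicates, seed=rng_seed,
            )
            kh_sh = [dataclasses.asdict(r) for r in tests]
    except Exception as exc:  # noqa: BLE001 - optional stage
        logger.warning("KH/SH stage skipped: %s", exc)

    # --- ancestors ----------------------------------------------------------
    ancestor_comparison = None
    try:
        a1_rows = [i for i in joint.ids if class_of[i] in ALPHA1_CLASSES]
        mata_rows = [i for i in joint.ids if class_of[i] is DomainClass.MATA_HMG]
        if len(a1_rows) >= 3 and len(mata_rows) >= 3:
            anc_a = reconstruct_class_ancestor(joint.select_rows(a1_rows), model, "alpha1")
            anc_b = reconstruct_class_ancestor(joint.select_rows(mata_rows), model, "MATA_HMG")
            cmp_res = compare_consensus(
                anc_a.map_residues, anc_b.map_residues,
                query_id="alpha1_ancestor", subject_id="MATA_HMG_ancestor",
            )
            ancestor_comparison = {
                "alpha1_ancestor": anc_a.map_residues,
                "mata_ancestor": anc_b.map_residues,
                "identity_pct": cmp_res.identity_pct,
                "positives_pct": cmp_res.positives_pct,
                "e_value": cmp_res.e_value,
            }
    except Exception as exc:  # noqa: BLE001 - optional stage
        logger.warning("ancestral stage skipped: %s", exc)

    # --- motif scan ---------------------------------------------------------
    motif_hits: list[dict[str, Any]] = []
    proteins = read_fasta(config.protein_file) if config.protein_file else []
    for prot in proteins:
        dom_end = config.domain_end.get(prot.id)
        target, _n = (prot, len(prot)) if dom_end is None else downstream_window(prot, dom_end)
        if target is None:
            motif_hits.append({"id": prot.id, "start": None, "match": None, "note": "empty downstream window"})
            continue
        offset = dom_end if dom_end is not None else 0
        for hit in scan(target, config.motif_pattern):
            motif_hits.append(
                {"id": prot.id, "start": hit.start + offset, "match": hit.matched, "note": ""}
            )

    report = AnalysisReport(
        config=json.loads(config.to_json()),
        per_class=per_class,
        joint_alignment={
            "n_rows": joint.n_rows,
            "n_columns": joint.n_columns,
            "removed_ids": joint_removed,
        },
        comparisons=comparisons,
        tree_newick=annotated.to_newick(include_supports=True),
        log_likelihood=best_lnl,
        model={
            "name": model.name,
            "alpha": model.alpha,
            "p_invariant": model.p_invariant,
            "gamma_categories": model.n_categories,
        },
        edge_supports=[
            {"bipartition": sorted(s.bipartition), "support": s.support}
            for s in support_report.supports
        ],
        monophyly=monophyly,
        kh_sh=kh_sh,
        ancestor_comparison=ancestor_comparison,
        motif_hits=motif_hits,
        provenance={
            "package": "mat-alpha-trace",
            "version": __version__,
            "seed": rng_seed,
            "n_replicates": config.n_replicates,
            "runtime_s": round(time.time() - t0, 2),
        },
    )
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.txt").write_text(report_render(report)[0])
        (outdir / "best_tree.nwk").write_text(report.tree_newick + "\n")
    return report


def _support_of(support_report, taxa: frozenset, all_ids: set) -> float | None:
    complement = frozenset(all_ids) - taxa
    for s in support_report.supports:
        if s.bipartition == taxa or s.bipartition == complement:
            return s.support
    return None


def _alternative_topologies(tree: PhyloTree, support_report) -> list[PhyloTree]:
    """NNI rearrangements around the weakest internal edge, as alternative
    hypotheses for the topology tests."""
    if not support_report.supports:
        return []
    weakest = min(support_report.supports, key=lambda s: s.support)
    return _nni_neighbors_by_index(support_report.tree, weakest.edge_index)


def report_render(report: AnalysisReport) -> tuple[str, str]:
    """(human-readable text, machine JSON)."""
    lines = []
    lines.append(f"mat-alpha-trace analysis (seed {report.provenance['seed']})")
    lines.append(f"model: {report.model['name']}, alpha={report.model['alpha']}")
    lines.append(f"best tree lnL: {report.log_likelihood:.4f}")
    lines.append("")
    lines.append("per-class profiles:")
    for cls, info in report.per_class.items():
        lines.append(
            f"  {cls}: {info['n_kept']}/{info['n_input']} kept, "
            f"{info['n_columns']} columns, consensus {info['consensus']}"
        )
    lines.append("")
    lines.append("consensus comparisons:")
    for row in report.comparisons:
        lines.append(
            f"  {row['qid']} vs {row['sid']}: identity {row['pident']:.1f}%, "
            f"positives {row['ppos']:.1f}%, E={row['evalue']:.2g}"
        )
    lines.append("")
    for label, verdict in report.monophyly.items():
        sup = verdict["elw_support"]
        sup_txt = f"{sup:.1f}" if sup is not None else "n/a"
        lines.append(
            f"clade {label} ({verdict['n_taxa']} taxa): "
            f"monophyletic={verdict['monophyletic']} (LR-ELW support {sup_txt})"
        )
    if report.kh_sh:
        lines.append("")
        lines.append("topology tests (vs best):")
        for row in report.kh_sh:
            lines.append(
                f"  topology {row['index']}: dlnL={row['delta_lnl']:.3f} "
                f"KH p={row['kh_p']:.3f} SH p={row['sh_p']:.3f}"
            )
    if report.ancestor_comparison:
        ac = report.ancestor_comparison
        lines.append("")
        lines.append(
            "ancestor comparison (alpha1 vs MATA_HMG): "
            f"identity {ac['identity_pct']:.1f}%, positives {ac['positives_pct']:.1f}%, "
            f"E={ac['e_value']:.2g}"
        )
    lines.append("")
    if report.motif_hits:
        lines.append("motif hits:")
        for hit in report.motif_hits:
            if hit["start"] is None:
                lines.append(f"  {hit['id']}: {hit['note']}")
            else:
                lines.append(f"  {hit['id']}: {hit['match']} at position {hit['start']}")
    else:
        lines.append("motif hits: no matches")
    return "\n".join(lines) + "\n", report.to_json()
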