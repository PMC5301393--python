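"""End-to-end orchestration: genomes -> families -> groups -> typing report.

``run_classify`` drives proteome comparison, Markov clustering, phage
grouping, adhesion-module typing and PCR typing, persisting every
intermediate artifact as TSV/JSON so that each report field can be
reproduced by calling the underlying module operations directly.
``run_survey`` batch-types genomes with a primer panel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import adhesion_typer as at
from . import insilico_pcr as pcr
from . import mcl_clustering as mcl_mod
from . import proteome_similarity as sim
from .genome_io import AnnotatedPhage

logger = logging.getLogger("p335")


@dataclass
class RunConfig:
    thresholds: sim.SimilarityThresholds = field(
        default_factory=sim.SimilarityThresholds)
    mcl_params: mcl_mod.MclParams = field(default_factory=mcl_mod.MclParams)
    link_threshold: float = 0.5
    match_params: pcr.MatchParams = field(default_factory=pcr.MatchParams)
    dependent_log_threshold: float = 4.0
    use_bbh_graph: bool = True
    seed: int = 0
    output_dir: Path | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, phage_id: str | None, cause: Exception):
        detail = f" (phage {phage_id})" if phage_id else ""
        super().__init__(f"stage {stage!r} failed{detail}: {cause}")
        self.stage = stage
        self.phage_id = phage_id


@dataclass
class ClassifyReport:
    rows: list[dict[str, object]]
    grouping: mcl_mod.PhageGrouping | None
    families: list[mcl_mod.ProteinFamily]
    assignments: dict[str, at.SubGroupAssignment]
    warnings: list[str] = field(default_factory=list)


def run_classify(
    phages: Sequence[AnnotatedPhage],
    config: RunConfig | None = None,
    panel: at.ReferencePanel | None = None,
    primer_panel: Sequence[pcr.PrimerPair] | None = None,
) -> ClassifyReport:
    """Classify a cohort of annotated phages.

    Produces one report row per phage with its proteome group,
    architecture call, RBP sub-group, concordance flag and PCR typing
    labels.  With fewer than two phages the grouping stages are skipped
    with a warning and per-phage typing still runs.
    """
    config = config or RunConfig()
    panel = panel or at.default_panel()
    primer_panel = primer_panel if primer_panel is not None \
        else pcr.default_p335_panel()
    report_warnings: list[str] = []

    proteomes = {p.id: p.proteins() for p in phages}
    protein_to_phage = {
        pid: phage_id for phage_id, prots in proteomes.items() for pid in prots
    }

    grouping: mcl_mod.PhageGrouping | None = None
    families: list[mcl_mod.ProteinFamily] = []
    if len(phages) >= 2:
        try:
            hits = sim.all_vs_all(proteomes, config.thresholds)
        except Exception as exc:  # noqa: BLE001
            raise StageError("all_vs_all", None, exc) from exc
        logger.info("retained %d hits across %d proteomes", len(hits),
                    len(proteomes))
        try:
            kept = hits
            if config.use_bbh_graph:
                bbh = sim.bidirectional_best_hits(hits, protein_to_phage)
                kept = [
                    h for h in hits
                    if frozenset((h.query_id, h.subject_id)) in bbh
                ]
            graph = mcl_mod.graph_from_hits(kept, list(protein_to_phage))
            families = mcl_mod.mcl(graph, config.mcl_params)
        except Exception as exc:  # noqa: BLE001
            raise StageError("mcl", None, exc) from exc
        logger.info("%d protein families", len(families))
        try:
            profiles = mcl_mod.phage_profiles(families, proteomes)
            grouping = mcl_mod.group_phages(profiles, config.link_threshold)
        except Exception as exc:  # noqa: BLE001
            raise StageError("group_phages", None, exc) from exc
        logger.info("%d proteome groups", len(grouping.groups))
    else:
        report_warnings.append("grouping_skipped:fewer_than_two_phages")

    architectures: dict[str, at.ArchitectureCall] = {}
    rbp_subgroups: dict[str, str] = {}
    for phage in phages:
        try:
            module = at.locate_module(phage, panel)
            module = at.assign_roles(module, panel)
            architectures[phage.id] = at.classify_architecture(
                module, panel.bands)
            rbp_seq = at.rbp_query_sequence(module)
            rbp_subgroups[phage.id] = (
                at.assign_rbp_subgroup(rbp_seq, panel)
                if rbp_seq else "novel"
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("adhesion_typing", phage.id, exc) from exc

    group_labels: dict[str, str | None] = {}
    if grouping is not None:
        members = {gid: sorted(m) for gid, m in grouping.group_labels().items()}
        group_labels = at.majority_subgroup_labels(members, rbp_subgroups)

    assignments: dict[str, at.SubGroupAssignment] = {}
    typing: dict[str, pcr.TypingResult] = {}
    rows: list[dict[str, object]] = []
    for phage in phages:
        gid = grouping.group_of(phage.id) if grouping is not None else None
        label = group_labels.get(gid) if gid is not None else None
        assignment = at.assemble_assignment(
            phage.id, gid, label, architectures[phage.id],
            rbp_subgroups[phage.id],
        )
        assignments[phage.id] = assignment
        try:
            typing[phage.id] = pcr.simulate_multiplex(
                phage.genome, primer_panel, config.match_params)
        except Exception as exc:  # noqa: BLE001
            raise StageError("pcr_typing", phage.id, exc) from exc
        arch = architectures[phage.id]
        rows.append(
            {
                "phage_id": phage.id,
                "proteome_group": gid or "",
                "proteome_subgroup": label or "",
                "rbp_subgroup": assignment.rbp_subgroup,
                "concordant": "" if assignment.concordant is None
                else str(assignment.concordant),
                "dit_class": arch.dit_class,
                "tal_class": arch.tal_class,
                "bppu_class": arch.bppu_class,
                "bppa_present": str(arch.bppa_present),
                "rbp_size_aa": arch.rbp_size_aa,
                "pcr_labels": ",".join(sorted(typing[phage.id].called_labels))
                or "untyped",
                "warnings": ";".join(arch.warnings),
            }
        )

    report = ClassifyReport(
        rows=rows, grouping=grouping, families=families,
        assignments=assignments, warnings=report_warnings,
    )
    if config.output_dir is not None:
        _persist(report, config)
    return report


def _persist(report: ClassifyReport, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report_tsv(report.rows, outdir / "classification.tsv")
    if report.families:
        mcl_mod.write_families(report.families, outdir / "families.tsv")
    if report.grouping is not None:
        mcl_mod.write_grouping(report.grouping, outdir / "groups.tsv")
    payload = {
        pid: {
            "proteome_group": a.proteome_group,
            "proteome_subgroup": a.proteome_subgroup,
            "rbp_subgroup": a.rbp_subgroup,
            "concordant": a.concordant,
        }
        for pid, a in report.assignments.items()
    }
    (outdir / "assignments.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True))


def write_report_tsv(rows: list[dict[str, object]], path: str | Path) -> None:
    if not rows:
        Path(path).write_text("")
        return
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


@dataclass
class SurveyResult:
    results: dict[str, pcr.TypingResult]
    label_counts: dict[str, int]
    n_failed: int = 0


def run_survey(
    genomes: Sequence,
    panel: Sequence[pcr.PrimerPair] | None = None,
    params: pcr.MatchParams | None = None,
) -> SurveyResult:
    """Type each genome with the panel; unreadable entries are skipped."""
    panel = panel if panel is not None else pcr.default_p335_panel()
    params = params or pcr.MatchParams()
    results: dict[str, pcr.TypingResult] = {}
    n_failed = 0
    for genome in genomes:
        try:
            results[genome.id] = pcr.simulate_multiplex(genome, panel, params)
        except Exception as exc:  # noqa: BLE001
            logger.warning("survey: skipping %s: %s",
                           getattr(genome, "id", "?"), exc)
            n_failed += 1
    counts: dict[str, int] = {}
    for r in results.values():
        for label in sorted(r.called_labels | r.unvalidated_labels):
            counts[label] = counts.get(label, 0) + 1
    return SurveyResult(results=results, label_counts=counts, n_failed=n_failed)
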