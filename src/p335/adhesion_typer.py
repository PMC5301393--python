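"""Adhesion-module location, role assignment and sub-group typing.

The adhesion module is the gene span from the tail tape measure protein
(TMP) through to, but not including, the lysis cassette (holin + lysin).
Components are identified by homology to a labelled reference panel and
classified into architecture classes by size bands; the receptor-binding
protein (RBP, or the C-terminal half of a fused Tal-RBP) is typed into
sub-groups I-IV against the panel's RBP representatives, and a phage is
flagged discordant when its proteome-level group and its RBP sub-group
disagree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .genome_io import AnnotatedPhage, OrfRecord
from .proteome_similarity import AlignmentHit, align_pair

SUBGROUP_ORDER = ("I", "II", "III", "IV")

SINGLETON_ROLES = ("TMP", "Dit", "Tal")
PERIPHERAL_ROLES = ("BppU", "BppA", "BppL", "RBP", "TalRBP")
LYSIS_ROLES = ("holin", "lysin")


@dataclass(frozen=True)
class SizeBands:
    """Architecture size bands (aa), midpoints between published clusters."""

    dit_classical_max: int = 270
    dit_classical_p2_max: int = 350
    dit_evolved_min: int = 450
    tal_short_max: int = 450
    tal_long_min: int = 850
    bppu_extended_min: int = 401
    tmp_fallback_min: int = 700


@dataclass(frozen=True)
class PanelEntry:
    ref_id: str
    role: str
    subgroup: str | None
    protein: str


@dataclass
class ReferencePanel:
    """Labelled reference proteins plus homology thresholds and bands."""

    entries: list[PanelEntry]
    min_identity: float = 0.3
    min_coverage: float = 0.5
    bands: SizeBands = field(default_factory=SizeBands)

    def __post_init__(self) -> None:
        ids = [e.ref_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference ids in panel")
        roles = {e.role for e in self.entries}
        for needed in ("TMP", "holin", "lysin", "RBP"):
            if needed not in roles:
                raise ValueError(f"panel is missing {needed!r} references")

    def by_role(self, role: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.role == role]

    def best_hit(self, protein: str, roles: Sequence[str]) -> tuple[
            PanelEntry, AlignmentHit] | None:
        """Best panel match among roles, or None below thresholds.

        Homology requires identity above ``min_identity`` with the
        reference covered over at least ``min_coverage`` of its length;
        a cheap length prefilter skips references that could never reach
        that coverage.
        """
        best: tuple[float, float, PanelEntry, AlignmentHit] | None = None
        for role in roles:
            for entry in self.by_role(role):
                if len(protein) < self.min_coverage * len(entry.protein):
                    continue
                hit = align_pair(protein, entry.protein,
                                 query_id="query", subject_id=entry.ref_id)
                if hit.identity <= self.min_identity:
                    continue
                if hit.subject_coverage < self.min_coverage:
                    continue
                # ties keep the first entry in (roles, panel) order
                if best is None or (hit.score, hit.identity) > best[:2]:
                    best = (hit.score, hit.identity, entry, hit)
        if best is None:
            return None
        return best[2], best[3]


@dataclass
class AdhesionModule:
    phage_id: str
    components: list[tuple[str | None, OrfRecord]]
    arity: str = "unassigned"
    warnings: list[str] = field(default_factory=list)

    def role_orf(self, role: str) -> OrfRecord | None:
        for r, orf in self.components:
            if r == role:
                return orf
        return None


@dataclass(frozen=True)
class ArchitectureCall:
    dit_class: str
    tal_class: str
    bppu_class: str
    bppa_present: bool
    rbp_size_aa: int
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class SubGroupAssignment:
    phage_id: str
    proteome_group: str | None
    proteome_subgroup: str | None
    rbp_subgroup: str
    architecture: ArchitectureCall | None
    concordant: bool | None


class ModuleNotFound(ValueError):
    pass


class AmbiguousRole(ValueError):
    pass


def locate_module(phage: AnnotatedPhage, panel: ReferencePanel) -> AdhesionModule:
    """Locate the TMP -> pre-lysis gene span of a phage.

    The TMP is the best panel-TMP homolog, falling back to the longest
    ORF of at least ``tmp_fallback_min`` aa.  The module ends before the
    first holin/lysin homolog downstream of the TMP; with no lysis
    cassette the module runs to the genome end with a warning.
    """
    orfs = phage.orfs
    if not orfs:
        raise ModuleNotFound(f"{phage.id}: no ORFs annotated")
    module_warnings: list[str] = []
    tmp_best: tuple[float, int] | None = None
    for i, orf in enumerate(orfs):
        hit = panel.best_hit(orf.protein, ["TMP"])
        if hit is not None and (tmp_best is None or hit[1].score > tmp_best[0]):
            tmp_best = (hit[1].score, i)
    if tmp_best is not None:
        tmp_index = tmp_best[1]
    else:
        candidates = [(o.length_aa, i) for i, o in enumerate(orfs)
                      if o.length_aa >= panel.bands.tmp_fallback_min]
        if not candidates:
            raise ModuleNotFound(
                f"{phage.id}: no TMP homolog and no ORF >= "
                f"{panel.bands.tmp_fallback_min} aa"
            )
        tmp_index = max(candidates)[1]
        module_warnings.append("tmp_by_length_fallback")
    lysis_index: int | None = None
    for i in range(tmp_index + 1, len(orfs)):
        if panel.best_hit(orfs[i].protein, list(LYSIS_ROLES)) is not None:
            lysis_index = i
            break
    if lysis_index is None:
        lysis_index = len(orfs)
        module_warnings.append("no_lysis_cassette:module_extends_to_end")
    components: list[tuple[str | None, OrfRecord]] = [("TMP", orfs[tmp_index])]
    components += [(None, orfs[i]) for i in range(tmp_index + 1, lysis_index)]
    return AdhesionModule(phage_id=phage.id, components=components,
                          warnings=module_warnings)


def assign_roles(module: AdhesionModule, panel: ReferencePanel) -> AdhesionModule:
    """Assign panel roles to the module ORFs, respecting gene order.

    Expected order is TMP, Dit, Tal (or a fused Tal-RBP), then the
    peripheral components.  An ORF matching a fused Tal-RBP reference,
    or matching Tal on its N-terminal half and an RBP on its C-terminal
    half, is labelled ``TalRBP``.  Two claims on a singleton role raise
    :class:`AmbiguousRole`.
    """
    assigned: list[tuple[str | None, OrfRecord]] = []
    claimed: Counter[str] = Counter()
    candidate_roles = ["Dit", "Tal", "TalRBP", "BppU", "BppA", "BppL", "RBP"]
    for role, orf in module.components:
        if role == "TMP":
            assigned.append((role, orf))
            claimed["TMP"] += 1
            continue
        call: str | None = None
        best = panel.best_hit(orf.protein, candidate_roles)
        if best is not None:
            call = best[0].role
        elif orf.length_aa >= 800:
            half = len(orf.protein) // 2
            n_hit = panel.best_hit(orf.protein[:half], ["Tal"])
            c_hit = panel.best_hit(orf.protein[half:], ["RBP", "BppL"])
            if n_hit is not None and c_hit is not None:
                call = "TalRBP"
            elif n_hit is not None:
                call = "Tal"
        if call in ("BppL",):
            call = "BppL"
        assigned.append((call, orf))
        if call is not None:
            claimed[call] += 1
    for single in SINGLETON_ROLES + ("TalRBP",):
        if claimed[single] > 1:
            ids = [o.orf_id for r, o in assigned if r == single]
            raise AmbiguousRole(
                f"{module.phage_id}: role {single!r} claimed by {ids}"
            )
    if claimed["TalRBP"]:
        arity = "fused_tal_rbp"
    elif claimed["BppU"] or claimed["BppA"] or claimed["BppL"]:
        arity = "multi_component_baseplate"
    elif claimed["RBP"]:
        arity = "single_component_RBP"
    else:
        arity = "unassigned"
    if not (claimed["Dit"] and (claimed["Tal"] or claimed["TalRBP"])):
        raise AmbiguousRole(
            f"{module.phage_id}: module lacks Dit and/or Tal assignments"
        )
    order = [r for r, _ in assigned if r in ("TMP", "Dit", "Tal", "TalRBP")]
    expected = [r for r in ("TMP", "Dit", "Tal", "TalRBP") if r in order]
    if order != expected:
        raise AmbiguousRole(
            f"{module.phage_id}: core gene order violated: {order}"
        )
    return AdhesionModule(
        phage_id=module.phage_id, components=assigned, arity=arity,
        warnings=list(module.warnings),
    )


def _band_call(value: int, bands: SizeBands,
               warn: list[str]) -> str:
    if value <= bands.dit_classical_max:
        return "classical"
    if value <= bands.dit_classical_p2_max:
        return "classical_p2"
    if value >= bands.dit_evolved_min:
        return "evolved"
    # band gap: nearest boundary wins
    warn.append(f"dit_size_in_band_gap:{value}")
    to_p2 = value - bands.dit_classical_p2_max
    to_evolved = bands.dit_evolved_min - value
    return "classical_p2" if to_p2 <= to_evolved else "evolved"


def classify_architecture(module: AdhesionModule,
                          bands: SizeBands | None = None) -> ArchitectureCall:
    """Architecture classes from component sizes (see :class:`SizeBands`)."""
    bands = bands or SizeBands()
    warn: list[str] = list(module.warnings)
    dit = module.role_orf("Dit")
    tal = module.role_orf("Tal")
    fused = module.role_orf("TalRBP")
    if dit is None or (tal is None and fused is None):
        raise ValueError(f"{module.phage_id}: missing Dit or Tal")
    dit_class = _band_call(dit.length_aa, bands, warn)
    if fused is not None:
        tal_class = "fused_with_RBP"
    elif tal.length_aa >= bands.tal_long_min:
        tal_class = "long_PGNase"
    elif tal.length_aa <= bands.tal_short_max:
        tal_class = "short_p2like"
    else:
        warn.append(f"tal_size_in_band_gap:{tal.length_aa}")
        mid = (bands.tal_short_max + bands.tal_long_min) / 2
        tal_class = "short_p2like" if tal.length_aa < mid else "long_PGNase"
    bppu = module.role_orf("BppU")
    if bppu is None:
        bppu_class = "absent"
    elif bppu.length_aa >= bands.bppu_extended_min:
        bppu_class = "extended"
    else:
        bppu_class = "classical"
    rbp = module.role_orf("RBP") or module.role_orf("BppL")
    return ArchitectureCall(
        dit_class=dit_class,
        tal_class=tal_class,
        bppu_class=bppu_class,
        bppa_present=module.role_orf("BppA") is not None,
        rbp_size_aa=rbp.length_aa if rbp is not None else 0,
        warnings=tuple(warn),
    )


def rbp_query_sequence(module: AdhesionModule) -> str | None:
    """The receptor-binding sequence of a module.

    Single-component modules contribute the RBP/BppL protein; fused
    Tal-RBP modules contribute the C-terminal half only.
    """
    rbp = module.role_orf("RBP") or module.role_orf("BppL")
    if rbp is not None:
        return rbp.protein
    fused = module.role_orf("TalRBP")
    if fused is not None:
        return fused.protein[len(fused.protein) // 2:]
    return None


def assign_rbp_subgroup(rbp_protein: str, panel: ReferencePanel) -> str:
    """Type an RBP sequence into I-IV against the panel, else ``novel``.

    The winner is the best-scoring panel RBP with identity above the
    panel threshold over sufficient reference coverage; ties break by
    higher identity, then panel sub-group order I < II < III < IV.
    """
    if not rbp_protein:
        raise ValueError("empty RBP sequence")
    best: tuple[float, float, int, str] | None = None
    for entry in panel.by_role("RBP"):
        if entry.subgroup is None:
            continue
        if len(rbp_protein) < panel.min_coverage * len(entry.protein):
            continue
        hit = align_pair(rbp_protein, entry.protein,
                         query_id="rbp", subject_id=entry.ref_id)
        if hit.identity <= panel.min_identity:
            continue
        if hit.subject_coverage < panel.min_coverage:
            continue
        rank = SUBGROUP_ORDER.index(entry.subgroup)
        key = (hit.score, hit.identity, -rank, entry.subgroup)
        if best is None or key[:3] > best[:3]:
            best = key
    return best[3] if best is not None else "novel"


def assemble_assignment(
    phage_id: str,
    proteome_group: str | None,
    proteome_subgroup: str | None,
    architecture: ArchitectureCall | None,
    rbp_subgroup: str,
) -> SubGroupAssignment:
    """Combine proteome grouping and RBP typing; flag discordance."""
    concordant: bool | None = None
    if proteome_subgroup is not None and rbp_subgroup != "novel":
        concordant = proteome_subgroup == rbp_subgroup
    return SubGroupAssignment(
        phage_id=phage_id,
        proteome_group=proteome_group,
        proteome_subgroup=proteome_subgroup,
        rbp_subgroup=rbp_subgroup,
        architecture=architecture,
        concordant=concordant,
    )


def majority_subgroup_labels(
    group_members: Mapping[str, Iterable[str]],
    rbp_subgroups: Mapping[str, str],
) -> dict[str, str | None]:
    """Per-group sub-group label = majority RBP sub-group of the members.

    Ties break by sub-group order; groups whose members are all novel
    get no label.
    """
    labels: dict[str, str | None] = {}
    for gid, members in group_members.items():
        votes = Counter(
            rbp_subgroups[m] for m in members
            if rbp_subgroups.get(m) not in (None, "novel")
        )
        if not votes:
            labels[gid] = None
            continue
        top = max(votes.values())
        tied = [sg for sg, v in votes.items() if v == top]
        labels[gid] = min(tied, key=SUBGROUP_ORDER.index)
    return labels


def default_panel() -> ReferencePanel:
    """The built-in panel of synthetic reference stand-ins.

    References are the deterministic seed proteins that also back the
    synthetic-genome generator, sized after the published exemplars
    (BK5-T for I, TP901-1 for II, LC3 for III, BM13 for IV).  Real
    reference proteins can be supplied instead via ``read_panel``.
    """
    from . import synthetic_data as syn

    entries: list[PanelEntry] = []
    for sg in SUBGROUP_ORDER:
        sizes = syn.DEFAULT_COMPONENT_SIZES[sg]
        entries.append(PanelEntry(f"TMP_{sg}", "TMP", sg,
                                  syn.adhesion_seed(sg, "TMP")))
        entries.append(PanelEntry(f"Dit_{sg}", "Dit", sg,
                                  syn.adhesion_seed(sg, "Dit")))
        if "TalRBP" in sizes:
            entries.append(PanelEntry(f"TalRBP_{sg}", "TalRBP", sg,
                                      syn.adhesion_seed(sg, "TalRBP")))
        else:
            entries.append(PanelEntry(f"Tal_{sg}", "Tal", sg,
                                      syn.adhesion_seed(sg, "Tal")))
        entries.append(PanelEntry(f"RBP_{sg}", "RBP", sg, syn.rbp_seed(sg)))
    entries.append(PanelEntry("BppU_II", "BppU", "II",
                              syn.adhesion_seed("II", "BppU")))
    entries.append(PanelEntry("BppL_II", "BppL", "II",
                              syn.adhesion_seed("II", "BppL")))
    entries.append(PanelEntry("holin", "holin", None, syn.holin_seed()))
    entries.append(PanelEntry("lysin", "lysin", None, syn.lysin_seed()))
    return ReferencePanel(entries=entries)


def write_panel(panel: ReferencePanel, fasta_path: str | Path,
                yaml_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for e in panel.entries:
            sg = e.subgroup or "-"
            fh.write(f">{e.ref_id} role={e.role} subgroup={sg}\n")
            for i in range(0, len(e.protein), 70):
                fh.write(e.protein[i : i + 70] + "\n")
    config = {
        "min_identity": panel.min_identity,
        "min_coverage": panel.min_coverage,
        "bands": {k: getattr(panel.bands, k)
                  for k in SizeBands.__dataclass_fields__},
    }
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def read_panel(fasta_path: str | Path,
               yaml_path: str | Path | None = None) -> ReferencePanel:
    entries: list[PanelEntry] = []
    ref_id = role = subgroup = None
    seq: list[str] = []

    def flush() -> None:
        if ref_id is not None:
            entries.append(PanelEntry(ref_id, role, subgroup, "".join(seq)))

    with open(fasta_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                ref_id = fields[0]
                meta = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
                role = meta.get("role", "unknown")
                subgroup = meta.get("subgroup")
                if subgroup == "-":
                    subgroup = None
                seq = []
            else:
                seq.append(line.strip())
    flush()
    kwargs: dict = {}
    if yaml_path is not None:
        with open(yaml_path) as fh:
            config = yaml.safe_load(fh) or {}
        if "min_identity" in config:
            kwargs["min_identity"] = float(config["min_identity"])
        if "min_coverage" in config:
            kwargs["min_coverage"] = float(config["min_coverage"])
        if "bands" in config:
            kwargs["bands"] = SizeBands(**config["bands"])
    return ReferencePanel(entries=entries, **kwargs)
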