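"""Synthetic phage genomes with planted, fully recorded ground truth.

Generates fixture phages whose adhesion modules follow the four
sub-group architectures (component sizes taken from the published
exemplars), protein families diverged to controlled percent identity,
planted primer binding sites at exact spacings, Poisson plaque counts
around true titres, and Bernoulli host-range matrices.  Every planted
feature is recorded in a :class:`TruthSet` so downstream stages can be
scored against known truth.

All generators are pure functions of their integer seed.  Reference
"seed" proteins are derived deterministically from their name, so the
same sequences back both the generator and the default reference panel
used for adhesion typing.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .genome_io import AnnotatedPhage, GenomeRecord, OrfRecord, reverse_complement
from .insilico_pcr import PrimerPair
from .phenotype_stats import CWPS_TYPES, HostRangeMatrix, PlaqueAssay

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_SEED_BASE = 0x5E_335  # namespace for all deterministic generators

SUBGROUPS = ("I", "II", "III", "IV")

# Component sizes (aa) per sub-group, following the published exemplar
# architectures: I = BK5-T (evolved Dit + fused Tal-RBP), II = TP901-1,
# III = LC3, IV = BM13.  TMP sizes are plausible inventions (>= 700 aa).
DEFAULT_COMPONENT_SIZES: dict[str, dict[str, int]] = {
    "I": {"TMP": 940, "Dit": 548, "TalRBP": 1904},
    "II": {"TMP": 950, "Dit": 253, "Tal": 918, "BppU": 299, "BppL": 163},
    "III": {"TMP": 930, "Dit": 298, "Tal": 385, "RBP": 343},
    "IV": {"TMP": 920, "Dit": 290, "Tal": 371, "RBP": 342},
}
RBP_HEAD_LEN = 604  # C-terminal RBP head of the sub-group I fused Tal-RBP
HOLIN_LEN = 88
LYSIN_LEN = 255

ROLE_ORDER = ("TMP", "Dit", "Tal", "TalRBP", "BppU", "BppA", "BppL", "RBP")


def _name_rng(name: str) -> np.random.Generator:
    return np.random.default_rng([_SEED_BASE, zlib.crc32(name.encode())])


def reference_protein(name: str, length: int) -> str:
    """Deterministic pseudo-random protein for a named reference seed."""
    if length < 2:
        raise ValueError("reference protein must be >= 2 aa")
    rng = _name_rng(name)
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
    return "M" + body


def adhesion_seed(subgroup: str, role: str, length: int | None = None) -> str:
    """The reference seed protein for a (sub-group, role) component."""
    sizes = DEFAULT_COMPONENT_SIZES[subgroup]
    if role == "TalRBP":
        total = length or sizes["TalRBP"]
        tal_part = reference_protein("ref|I|TalCore", total - RBP_HEAD_LEN)
        return tal_part + rbp_head_seed()
    return reference_protein(f"ref|{subgroup}|{role}", length or sizes[role])


def rbp_head_seed() -> str:
    """RBP head domain shared by the fused sub-group I Tal-RBP."""
    # generated headless (no M start constraint needed inside a fusion)
    rng = _name_rng("ref|I|RBPhead")
    return "".join(rng.choice(list(AMINO_ACIDS), size=RBP_HEAD_LEN))


def holin_seed() -> str:
    return reference_protein("ref|shared|holin", HOLIN_LEN)


def lysin_seed() -> str:
    return reference_protein("ref|shared|lysin", LYSIN_LEN)


def rbp_seed(subgroup: str) -> str:
    """The receptor-binding reference protein of a sub-group.

    For sub-group I this is the RBP head domain of the fused Tal-RBP;
    for II the BppL; for III/IV the single-component RBP.
    """
    if subgroup == "I":
        return rbp_head_seed()
    if subgroup == "II":
        return adhesion_seed("II", "BppL")
    return adhesion_seed(subgroup, "RBP")


def background_seed(subgroup: str, index: int) -> str:
    name = f"bg|{subgroup}|{index:02d}"
    length = int(_name_rng(name + "|len").integers(120, 351))
    return reference_protein(name, length)


@dataclass(frozen=True)
class PhageTemplate:
    subgroup: str
    component_sizes: Mapping[str, int] | None = None
    n_background_orfs: int = 40
    target_gc: float = 0.36

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown sub-group {self.subgroup!r}")
        if not 0 < self.target_gc < 1:
            raise ValueError("target_gc must be in (0,1)")
        sizes = self.sizes()
        if any(v <= 0 for v in sizes.values()):
            raise ValueError("component sizes must be positive")

    def sizes(self) -> dict[str, int]:
        sizes = dict(DEFAULT_COMPONENT_SIZES[self.subgroup])
        if self.component_sizes:
            sizes.update(self.component_sizes)
        return sizes

    def roles(self) -> list[str]:
        return [r for r in ROLE_ORDER if r in self.sizes()]


@dataclass
class PlantedAmplicon:
    genome_id: str
    pair_name: str
    start: int
    length_bp: int


@dataclass
class PhageTruth:
    phage_id: str
    subgroup: str
    rbp_subgroup: str
    module_orf_ids: list[str]
    roles: dict[str, str]                # orf_id -> planted role
    protein_families: dict[str, str]     # protein_id -> seed family name
    lysis_orf_ids: list[str]


@dataclass
class TruthSet:
    phages: dict[str, PhageTruth] = field(default_factory=dict)
    amplicons: list[PlantedAmplicon] = field(default_factory=list)
    true_titres: dict[str, float] = field(default_factory=dict)
    true_eops: dict[str, float] = field(default_factory=dict)
    host_range: dict[str, dict[str, bool]] = field(default_factory=dict)

    def add_phage(self, truth: PhageTruth) -> None:
        if truth.phage_id in self.phages:
            raise ValueError(f"duplicate phage in truth: {truth.phage_id!r}")
        self.phages[truth.phage_id] = truth

    def to_json(self, path: str | Path) -> None:
        payload = {
            "phages": {k: asdict(v) for k, v in self.phages.items()},
            "amplicons": [asdict(a) for a in self.amplicons],
            "true_titres": self.true_titres,
            "true_eops": self.true_eops,
            "host_range": self.host_range,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


_CODON_FOR: dict[str, str] | None = None


def _codon_for() -> dict[str, str]:
    """Lexicographically first codon per residue, bacterial code."""
    global _CODON_FOR
    if _CODON_FOR is None:
        table = CodonTable.unambiguous_dna_by_id[11].forward_table
        mapping: dict[str, str] = {}
        for codon in sorted(table):
            aa = table[codon]
            mapping.setdefault(aa, codon)
        mapping["M"] = "ATG"
        _CODON_FOR = mapping
    return _CODON_FOR


def back_translate(protein: str) -> str:
    """Deterministic back-translation (first codon per residue) + TAA stop."""
    codons = _codon_for()
    return "".join(codons[aa] for aa in protein) + "TAA"


def mutate_protein(protein: str,
                   target_identity: float,
                   seed: int | np.random.Generator) -> str:
    """Substitution-only mutant at an expected identity level.

    Each position is independently substituted with probability
    ``1 - target_identity`` to a uniformly chosen different residue.
    """
    if not protein:
        raise ValueError("protein is empty")
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng([_SEED_BASE, int(seed)])
    p_sub = 1.0 - target_identity
    out = list(protein)
    hits = np.nonzero(rng.random(len(out)) < p_sub)[0]
    for i in hits:
        choices = [aa for aa in AMINO_ACIDS if aa != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _filler(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = rng.choice(
        list("GCAT"), size=length, p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    )
    return "".join(bases)


def make_phage(
    template: PhageTemplate,
    divergence: float,
    seed: int,
    phage_id: str | None = None,
    rbp_override: str | None = None,
) -> tuple[AnnotatedPhage, PhageTruth]:
    """Generate one annotated phage genome plus its truth record.

    The genome carries (in order) upstream background ORFs, the adhesion
    module at template sizes, a holin/lysin pair immediately after the
    adhesion genes, and downstream background ORFs, with GC-steered
    intergenic filler.  All planted proteins are the reference seeds
    mutated at ``divergence``.  ``rbp_override`` swaps in another
    sub-group's receptor-binding seed to build a chimera.
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    if rbp_override is not None and rbp_override not in SUBGROUPS:
        raise ValueError(f"unknown rbp_override {rbp_override!r}")
    rng = np.random.default_rng([_SEED_BASE, int(seed)])
    identity = 1.0 - divergence
    sg = template.subgroup
    phage_id = phage_id or f"syn{sg}_{seed}"
    sizes = template.sizes()

    def derive(seq: str) -> str:
        if divergence == 0:
            return seq
        mutant = mutate_protein(seq, identity, rng)
        return "M" + mutant[1:]

    # (role-or-None, protein) in genome order
    genes: list[tuple[str | None, str]] = []
    n_bg = template.n_background_orfs
    n_up = (n_bg + 1) // 2
    for k in range(n_up):
        genes.append((None, derive(background_seed(sg, k))))
    module_roles = template.roles()
    overridden_roles: set[str] = set()
    for role in module_roles:
        protein = adhesion_seed(sg, role, sizes[role])
        if rbp_override is not None and role in ("BppL", "RBP", "TalRBP"):
            override_seq = rbp_seed(rbp_override)
            if role == "TalRBP":
                protein = protein[: len(protein) - RBP_HEAD_LEN] + override_seq
            else:
                protein = "M" + override_seq[1:]
            overridden_roles.add(role)
        genes.append((role, derive(protein)))
    genes.append(("holin", derive(holin_seed())))
    genes.append(("lysin", derive(lysin_seed())))
    for k in range(n_up, n_bg):
        genes.append((None, derive(background_seed(sg, k))))

    chunks: list[str] = []
    orfs: list[OrfRecord] = []
    roles: dict[str, str] = {}
    families: dict[str, str] = {}
    pos = 0
    lead = int(rng.integers(60, 120))
    chunks.append(_filler(rng, lead, template.target_gc))
    pos += lead
    bg_index = 0
    for i, (role, protein) in enumerate(genes, 1):
        orf_id = f"orf{i:02d}"
        dna = back_translate(protein)
        strand = "+"
        if role is None and bg_index == 1:  # one background gene on minus strand
            dna = reverse_complement(dna)
            strand = "-"
        chunks.append(dna)
        orfs.append(OrfRecord(orf_id, pos, pos + len(dna), strand, protein,
                              label=role))
        if role is not None:
            roles[orf_id] = role
            if role in ("holin", "lysin"):
                family = f"shared|{role}"
            elif role in overridden_roles:
                family = f"{rbp_override}|rbp_seed"
            else:
                family = f"{sg}|{role}"
        else:
            family = f"bg|{sg}|{bg_index:02d}"
            bg_index += 1
        families[f"{phage_id}|{orf_id}"] = family
        pos += len(dna)
        gap = int(rng.integers(20, 80))
        chunks.append(_filler(rng, gap, template.target_gc))
        pos += gap

    sequence = "".join(chunks)
    genome = GenomeRecord(id=phage_id, sequence=sequence)
    phage = AnnotatedPhage(genome=genome, orfs=orfs)
    module_ids = [o.orf_id for o in orfs if roles.get(o.orf_id) in module_roles]
    lysis_ids = [o.orf_id for o in orfs if roles.get(o.orf_id) in ("holin", "lysin")]
    truth = PhageTruth(
        phage_id=phage_id,
        subgroup=sg,
        rbp_subgroup=rbp_override or sg,
        module_orf_ids=module_ids,
        roles=roles,
        protein_families=families,
        lysis_orf_ids=lysis_ids,
    )
    return phage, truth


def plant_primer_sites(
    genome: GenomeRecord,
    pair: PrimerPair,
    spacing_bp: int,
    position: int,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[GenomeRecord, PlantedAmplicon]:
    """Write a primer pair's binding sites into a genome at exact spacing.

    The forward primer is written at ``position`` on the plus strand and
    the reverse complement of the reverse primer ends exactly
    ``spacing_bp`` bases downstream of the forward start, so in-silico
    PCR recovers one product of ``spacing_bp`` bp.
    """
    fwd, rev = pair.forward, pair.reverse
    if spacing_bp < len(fwd) + len(rev):
        raise ValueError("spacing smaller than combined primer lengths")
    if position < 0 or position + spacing_bp > len(genome):
        raise ValueError("primer sites do not fit in the genome")
    span = (position, position + spacing_bp)
    if occupied is not None:
        for s, e in occupied:
            if span[0] < e and s < span[1]:
                raise ValueError(
                    f"planted site {span} overlaps existing feature ({s}, {e})"
                )
        occupied.append(span)
    seq = list(genome.sequence)
    seq[position : position + len(fwd)] = fwd
    rc = reverse_complement(rev)
    rev_start = position + spacing_bp - len(rev)
    seq[rev_start : rev_start + len(rev)] = rc
    mutated = GenomeRecord(
        id=genome.id, sequence="".join(seq),
        topology=genome.topology, description=genome.description,
    )
    return mutated, PlantedAmplicon(genome.id, pair.name, position, spacing_bp)


def make_plaque_data(
    true_titre: float,
    true_eop: float,
    volume_plated_ml: float,
    n_replicates: int,
    seed: int,
    *,
    phage_id: str = "phage",
    condition: str = "EDTA_0.1mM",
) -> list[PlaqueAssay]:
    """Poisson plaque counts around ``true_titre * true_eop * volume``."""
    if true_titre <= 0:
        raise ValueError("true_titre must be > 0")
    if not 0 <= true_eop <= 1:
        raise ValueError("true_eop must be in [0, 1]")
    rng = np.random.default_rng([_SEED_BASE, int(seed)])
    mean = true_titre * true_eop * volume_plated_ml
    return [
        PlaqueAssay(
            phage_id=phage_id, condition=condition,
            plaque_count=int(rng.poisson(mean)),
            volume_plated_ml=volume_plated_ml, replicate=r + 1,
        )
        for r in range(n_replicates)
    ]


def make_host_range(
    n_phages: int,
    strains_with_cwps: Mapping[str, str],
    infect_prob_by_type: Mapping[str, float],
    seed: int,
) -> HostRangeMatrix:
    """Bernoulli host-range matrix with type-specific infection odds."""
    for strain, cwps in strains_with_cwps.items():
        if cwps not in CWPS_TYPES:
            raise ValueError(f"strain {strain!r}: unknown CWPS label {cwps!r}")
    for cwps, p in infect_prob_by_type.items():
        if not 0 <= p <= 1:
            raise ValueError(f"probability for type {cwps!r} outside [0,1]")
    rng = np.random.default_rng([_SEED_BASE, int(seed)])
    phages = [f"phage{i + 1:02d}" for i in range(n_phages)]
    strains = sorted(strains_with_cwps)
    matrix = np.zeros((n_phages, len(strains)), dtype=bool)
    for i in range(n_phages):
        for j, strain in enumerate(strains):
            p = infect_prob_by_type.get(strains_with_cwps[strain], 0.0)
            matrix[i, j] = rng.random() < p
    return HostRangeMatrix(
        phages=phages, strains=strains, matrix=matrix,
        strain_types=dict(strains_with_cwps),
    )


def make_cohort(
    seeds_per_subgroup: Mapping[str, Sequence[int]],
    divergence: float,
    *,
    n_background_orfs: int = 40,
    chimeras: Mapping[str, tuple[str, str, int]] | None = None,
) -> tuple[list[AnnotatedPhage], TruthSet]:
    """Generate a cohort of phages across sub-group templates.

    ``chimeras`` maps phage_id -> (backbone subgroup, rbp subgroup, seed).
    """
    phages: list[AnnotatedPhage] = []
    truth = TruthSet()
    for sg in SUBGROUPS:
        for seed in seeds_per_subgroup.get(sg, ()):
            template = PhageTemplate(sg, n_background_orfs=n_background_orfs)
            phage, pt = make_phage(template, divergence, seed,
                                   phage_id=f"syn{sg}_{seed}")
            phages.append(phage)
            truth.add_phage(pt)
    for phage_id, (backbone, rbp_sg, seed) in (chimeras or {}).items():
        template = PhageTemplate(backbone, n_background_orfs=n_background_orfs)
        phage, pt = make_phage(template, divergence, seed, phage_id=phage_id,
                               rbp_override=rbp_sg)
        phages.append(phage)
        truth.add_phage(pt)
    return phages, truth
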