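"""In-silico single-pair and multiplex PCR against phage/strain genomes.

Primer sites are located on both strands with a configurable mismatch
budget and an exact 3'-anchor requirement; amplicons span from the first
base of the forward primer site to the last base of the reverse site
(product sizes count both primers, the standard convention).  Multiplex
typing evaluates each pair independently -- primer competition, which
defeated the wet multiplex assay, is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .genome_io import GenomeRecord, reverse_complement

PRIMER_ALPHABET = frozenset("ACGT")
MIN_PRIMER_LEN = 15


@dataclass(frozen=True)
class PrimerPair:
    """A primer pair written 5'->3' with an optional expected product size."""

    name: str
    forward: str
    reverse: str
    expected_size_bp: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        for which, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if len(seq) < MIN_PRIMER_LEN:
                raise ValueError(f"{self.name}: {which} primer shorter than "
                                 f"{MIN_PRIMER_LEN} nt")
            bad = set(seq.upper()) - PRIMER_ALPHABET
            if bad:
                raise ValueError(f"{self.name}: {which} primer has non-ACGT "
                                 f"characters {sorted(bad)}")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class MatchParams:
    max_mismatches: int = 0
    three_prime_exact_nt: int = 5
    max_product_bp: int = 5000
    size_tolerance_bp: int = 20

    def __post_init__(self) -> None:
        for name in ("max_mismatches", "three_prime_exact_nt",
                     "max_product_bp", "size_tolerance_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PrimerSite:
    position: int  # 0-based start of the match on the forward strand
    strand: str    # "+": primer as written; "-": its reverse complement
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    pair_name: str
    start: int
    end: int
    orientation: str  # strand carrying the forward primer

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def _count_mismatches(window: str, primer: str, anchor_3prime: int,
                      anchored_at_end: bool) -> int | None:
    """Mismatches of primer vs window, or None if the 3' anchor fails.

    ``anchored_at_end`` marks whether the primer's 3' end maps to the end
    of the window (plus-strand orientation) or its start (minus strand).
    N in the genome counts as a mismatch.
    """
    mismatches = 0
    n = len(primer)
    for i in range(n):
        if window[i] != primer[i]:
            in_anchor = (i >= n - anchor_3prime) if anchored_at_end \
                else (i < anchor_3prime)
            if in_anchor:
                return None
            mismatches += 1
    return mismatches


def find_primer_sites(genome: GenomeRecord, primer: str,
                      params: MatchParams | None = None) -> list[PrimerSite]:
    """All match positions of the primer on either strand.

    Plus-strand sites match the primer as written; minus-strand sites
    match its reverse complement on the forward sequence (so the primer
    anneals to the plus strand).  Circular genomes are scanned across
    the origin; wrapped positions are reported modulo genome length.
    """
    params = params or MatchParams()
    primer = primer.upper()
    rc = reverse_complement(primer)
    n = len(primer)
    glen = len(genome)
    seq = genome.sequence
    limit = glen - n + 1
    if genome.topology == "circular":
        seq = seq + seq[: n - 1]
        limit = glen
    sites: list[PrimerSite] = []
    for pos in range(max(limit, 0)):
        window = seq[pos : pos + n]
        mm = _count_mismatches(window, primer, params.three_prime_exact_nt, True)
        if mm is not None and mm <= params.max_mismatches:
            sites.append(PrimerSite(pos % glen, "+", mm))
        mm = _count_mismatches(window, rc, params.three_prime_exact_nt, False)
        if mm is not None and mm <= params.max_mismatches:
            sites.append(PrimerSite(pos % glen, "-", mm))
    return sites


def predict_amplicons(genome: GenomeRecord, pair: PrimerPair,
                      params: MatchParams | None = None) -> list[Amplicon]:
    """All products the pair can amplify within ``max_product_bp``.

    A product forms when a forward-primer site and a reverse-primer site
    face each other (3' ends pointing inward) on opposite strands.  Both
    genome orientations are considered.  Linear genomes do not wrap;
    circular ones do (wrapped products are reported with end > genome
    length).
    """
    params = params or MatchParams()
    f_sites = find_primer_sites(genome, pair.forward, params)
    r_sites = find_primer_sites(genome, pair.reverse, params)
    glen = len(genome)
    len_f, len_r = len(pair.forward), len(pair.reverse)
    amplicons: list[Amplicon] = []

    def pair_up(starts: list[int], ends: list[tuple[int, int]],
                orientation: str) -> None:
        # starts: 5'-most coordinate of the outward site; ends: (site
        # position, site length) of the inward-facing partner site.
        for s in starts:
            for epos, elen in ends:
                end = epos + elen
                candidates = [end]
                if genome.topology == "circular" and end <= s:
                    candidates = [end + glen]
                for e in candidates:
                    length = e - s
                    if length < len_f + len_r:
                        continue
                    if length > params.max_product_bp:
                        continue
                    amplicons.append(Amplicon(pair.name, s, e, orientation))

    pair_up(
        [s.position for s in f_sites if s.strand == "+"],
        [(s.position, len_r) for s in r_sites if s.strand == "-"],
        "+",
    )
    pair_up(
        [s.position for s in r_sites if s.strand == "+"],
        [(s.position, len_f) for s in f_sites if s.strand == "-"],
        "-",
    )
    return sorted(amplicons, key=lambda a: (a.start, a.end, a.orientation))


@dataclass
class TypingResult:
    genome_id: str
    amplicons: dict[str, list[Amplicon]] = field(default_factory=dict)
    called_labels: set[str] = field(default_factory=set)
    unvalidated_labels: set[str] = field(default_factory=set)
    flags: list[str] = field(default_factory=list)

    @property
    def typed(self) -> bool:
        return bool(self.called_labels or self.unvalidated_labels)


def simulate_multiplex(genome: GenomeRecord, panel: Sequence[PrimerPair],
                       params: MatchParams | None = None) -> TypingResult:
    """Type a genome with a panel, each pair evaluated independently.

    A pair's label is called when a product lies within
    ``size_tolerance_bp`` of the expected size; pairs without a printed
    expected size call their label via any product, flagged unvalidated.
    Multiple called labels are reported with a conflict flag, never
    resolved.
    """
    params = params or MatchParams()
    if not panel:
        raise ValueError("panel is empty")
    names = [p.name for p in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate pair names in panel")
    result = TypingResult(genome_id=genome.id)
    for pair in panel:
        amps = predict_amplicons(genome, pair, params)
        if not amps:
            continue
        result.amplicons[pair.name] = amps
        label = pair.label or pair.name
        if pair.expected_size_bp is None:
            result.unvalidated_labels.add(label)
            result.flags.append(f"{pair.name}:unvalidated")
            continue
        matching = [
            a for a in amps
            if abs(a.length_bp - pair.expected_size_bp) <= params.size_tolerance_bp
        ]
        if matching:
            result.called_labels.add(label)
        else:
            result.flags.append(f"{pair.name}:size_mismatch")
    if len(result.called_labels) > 1:
        result.flags.append("multiple_labels")
    return result


CWPS_EXPECTED = {"A": 442, "B": 183, "C": 686}
CWPS_CONTROL_SIZE = 891


def cwps_type(strain_genome: GenomeRecord, cwps_panel: Sequence[PrimerPair],
              params: MatchParams | None = None) -> tuple[str, bool]:
    """CWPS genotype (A/B/C/unknown) plus control validity.

    The panel must contain a pair labelled ``control`` (the rmlB product,
    891 bp) and pairs labelled A, B and C.  Returns ``("invalid", False)``
    when the control fails to amplify.
    """
    params = params or MatchParams()
    by_label = {p.label: p for p in cwps_panel}
    if "control" not in by_label:
        raise ValueError("CWPS panel is missing the rmlB control pair")
    control = by_label["control"]
    expected_control = control.expected_size_bp or CWPS_CONTROL_SIZE
    control_amps = [
        a for a in predict_amplicons(strain_genome, control, params)
        if abs(a.length_bp - expected_control) <= params.size_tolerance_bp
    ]
    control_ok = bool(control_amps)
    if not control_ok:
        return "invalid", False
    for cwps in ("A", "B", "C"):
        pair = by_label.get(cwps)
        if pair is None:
            continue
        expected = pair.expected_size_bp or CWPS_EXPECTED[cwps]
        amps = [
            a for a in predict_amplicons(strain_genome, pair, params)
            if abs(a.length_bp - expected) <= params.size_tolerance_bp
        ]
        if amps:
            return cwps, True
    return "unknown", True


def load_panel(path: str | Path) -> list[PrimerPair]:
    """Load a primer panel from YAML (list of pair mappings) or TSV."""
    path = Path(path)
    pairs: list[PrimerPair] = []
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            entries = yaml.safe_load(fh)
        for e in entries:
            pairs.append(
                PrimerPair(
                    name=e["name"], forward=e["forward"], reverse=e["reverse"],
                    expected_size_bp=e.get("expected_size_bp"),
                    label=e.get("label"),
                )
            )
    else:
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("name\t"):
                    continue
                f = line.split("\t")
                pairs.append(
                    PrimerPair(
                        name=f[0], forward=f[1], reverse=f[2],
                        expected_size_bp=int(f[3]) if len(f) > 3 and f[3] else None,
                        label=f[4] if len(f) > 4 and f[4] else None,
                    )
                )
    return pairs


def default_p335_panel() -> list[PrimerPair]:
    """The seven-pair P335 typing panel with published product sizes."""
    return [
        PrimerPair("38502", "gatagtgaatctccgggagcg", "atcactgattgttactgtgtcccc",
                   1002, "I/38502"),
        PrimerPair("Tuc2009U", "catgcggatgtcaatagtcaagcc",
                   "gtatcaaatccattcgcttcggttc", None, "II/Tuc2009U"),
        PrimerPair("53801", "caaagatgggaagatagagagta", "cctcgtggtgcgccggt",
                   554, "II/53801"),
        PrimerPair("98101", "gacagaacattttataacactatccac",
                   "caaactgtaacgcattatcactggc", 268, "II/98101"),
        PrimerPair("98204", "gcctttggagctttttcggttgat", "gcgccgttaggtatattatcc",
                   412, "II/98204"),
        PrimerPair("LC3", "cgttgaagtaaatggaagcttaac", "gaggatatttccccaccaattg",
                   128, "III/LC3"),
        PrimerPair("62503", "gaccgtgaatatagttctgatgaat",
                   "gtagtaattccgatttcccattctc", 784, "IV/62503"),
    ]


def write_panel(panel: Iterable[PrimerPair], path: str | Path) -> None:
    entries = [
        {
            "name": p.name, "forward": p.forward, "reverse": p.reverse,
            "expected_size_bp": p.expected_size_bp, "label": p.label,
        }
        for p in panel
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def typing_summary(results: Mapping[str, TypingResult]) -> list[dict[str, object]]:
    rows = []
    for gid in sorted(results):
        r = results[gid]
        rows.append(
            {
                "genome_id": gid,
                "labels": ",".join(sorted(r.called_labels)) or "untyped",
                "unvalidated": ",".join(sorted(r.unvalidated_labels)),
                "n_amplicons": sum(len(v) for v in r.amplicons.values()),
                "flags": ";".join(r.flags),
            }
        )
    return rows
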