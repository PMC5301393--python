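"""All-against-all protein comparison and bidirectional best hits.

Pairwise comparison is Smith-Waterman local alignment with BLOSUM62 and
affine gaps (first gap residue -11, each further residue -1), with
E-values from the Karlin-Altschul formula using fixed gapped BLOSUM62
constants.  The aligner is a deterministic stand-in for BLASTP behind
the same acceptance semantics: a hit is retained when E <= 1e-4,
identity is strictly greater than 50% and both sequences are covered
over at least 50% of their length.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

# Gapped BLOSUM62 statistics (BLAST defaults for open 11 / extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

GAP_OPEN = -11.0
GAP_EXTEND = -1.0


@dataclass(frozen=True)
class ScoringConfig:
    matrix: str = "BLOSUM62"
    gap_open: float = GAP_OPEN
    gap_extend: float = GAP_EXTEND


@dataclass(frozen=True)
class SimilarityThresholds:
    """Retention cut-offs: E <= max_evalue, identity > min_identity
    (strict), and coverage of BOTH sequences >= min_coverage."""

    max_evalue: float = 1e-4
    min_identity: float = 0.5
    min_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    identity: float
    aln_length: int
    query_coverage: float
    subject_coverage: float
    score: float
    evalue: float
    n_identical: int = 0
    n_gap_opens: int = 0

    def passes(self, thresholds: SimilarityThresholds) -> bool:
        return (
            self.evalue <= thresholds.max_evalue
            and self.identity > thresholds.min_identity
            and min(self.query_coverage, self.subject_coverage)
            >= thresholds.min_coverage
        )


def _make_aligner(config: ScoringConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(config.matrix)
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    return aligner


def _validate_protein(name: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"protein {name!r} is empty")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"protein {name!r}: invalid residues {sorted(bad)}")


def evalue(score: float, query_len: int, db_residues: int) -> float:
    """Karlin-Altschul expect value for a raw score in a fixed search space."""
    return KA_K * query_len * db_residues * math.exp(-KA_LAMBDA * score)


def bitscore(score: float) -> float:
    return (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)


def align_pair(
    protein_a: str,
    protein_b: str,
    scoring_config: ScoringConfig | None = None,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    db_residues: int | None = None,
) -> AlignmentHit:
    """Best local alignment of two proteins as an :class:`AlignmentHit`.

    Identity uses the BLAST convention: identical columns divided by the
    total number of alignment columns, gap columns included.  Coverage is
    the aligned span of each sequence divided by its full length.  The
    E-value search space is ``len(query) * db_residues``; by default the
    subject alone is the database.
    """
    config = scoring_config or ScoringConfig()
    _validate_protein(query_id, protein_a)
    _validate_protein(subject_id, protein_b)
    aligner = _make_aligner(config)
    if db_residues is None:
        db_residues = len(protein_b)
    alignments = aligner.align(protein_a, protein_b)
    try:
        aln = alignments[0]
    except IndexError:
        # no positive-scoring local alignment exists
        return AlignmentHit(
            query_id=query_id, subject_id=subject_id, identity=0.0,
            aln_length=0, query_coverage=0.0, subject_coverage=0.0,
            score=0.0, evalue=evalue(0.0, len(protein_a), db_residues),
        )
    q_blocks, s_blocks = aln.aligned
    n_both = 0
    n_identical = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        n_both += qe - qs
        n_identical += sum(
            1 for i, j in zip(range(qs, qe), range(ss, se))
            if protein_a[i] == protein_b[j]
        )
    q_span = int(q_blocks[-1][1] - q_blocks[0][0]) if len(q_blocks) else 0
    s_span = int(s_blocks[-1][1] - s_blocks[0][0]) if len(s_blocks) else 0
    aln_length = q_span + s_span - n_both
    n_gap_opens = sum(
        1
        for k in range(1, len(q_blocks))
        if q_blocks[k][0] > q_blocks[k - 1][1] or s_blocks[k][0] > s_blocks[k - 1][1]
    )
    score = float(aln.score)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=n_identical / aln_length if aln_length else 0.0,
        aln_length=aln_length,
        query_coverage=q_span / len(protein_a),
        subject_coverage=s_span / len(protein_b),
        score=score,
        evalue=evalue(score, len(protein_a), db_residues),
        n_identical=n_identical,
        n_gap_opens=n_gap_opens,
    )


def _swap(hit: AlignmentHit) -> AlignmentHit:
    return AlignmentHit(
        query_id=hit.subject_id,
        subject_id=hit.query_id,
        identity=hit.identity,
        aln_length=hit.aln_length,
        query_coverage=hit.subject_coverage,
        subject_coverage=hit.query_coverage,
        score=hit.score,
        evalue=hit.evalue,
        n_identical=hit.n_identical,
        n_gap_opens=hit.n_gap_opens,
    )


def all_vs_all(
    proteomes: Mapping[str, Mapping[str, str]],
    thresholds: SimilarityThresholds | None = None,
    scoring_config: ScoringConfig | None = None,
) -> list[AlignmentHit]:
    """Cross-proteome all-against-all comparison with threshold filtering.

    ``proteomes`` maps phage id to {protein id: sequence}; protein ids
    must be globally unique.  Self-hits and within-proteome pairs are
    excluded.  Both hit orientations (a->b and b->a) are emitted; the
    Smith-Waterman score and identity are symmetric, so each unordered
    pair is aligned once.
    """
    thresholds = thresholds or SimilarityThresholds()
    if not proteomes:
        raise ValueError("at least one proteome required")
    seen: set[str] = set()
    for phage, prots in proteomes.items():
        for pid, seq in prots.items():
            if pid in seen:
                raise ValueError(f"duplicate protein id across proteomes: {pid!r}")
            seen.add(pid)
            _validate_protein(pid, seq)
    db_residues = sum(
        len(s) for prots in proteomes.values() for s in prots.values()
    )
    hits: list[AlignmentHit] = []
    phage_ids = sorted(proteomes)
    for pa, pb in itertools.combinations(phage_ids, 2):
        for qid, qseq in sorted(proteomes[pa].items()):
            for sid, sseq in sorted(proteomes[pb].items()):
                # both-sequence coverage >= min_coverage is impossible when
                # lengths differ by more than the coverage factor
                if min(len(qseq), len(sseq)) < thresholds.min_coverage * max(
                    len(qseq), len(sseq)
                ):
                    continue
                hit = align_pair(
                    qseq,
                    sseq,
                    scoring_config,
                    query_id=qid,
                    subject_id=sid,
                    db_residues=db_residues,
                )
                if hit.passes(thresholds):
                    hits.append(hit)
                back = _swap(hit)
                back = AlignmentHit(
                    **{
                        **back.__dict__,
                        "evalue": evalue(hit.score, len(sseq), db_residues),
                    }
                )
                if back.passes(thresholds):
                    hits.append(back)
    return hits


def bidirectional_best_hits(
    hits: Iterable[AlignmentHit],
    protein_to_phage: Mapping[str, str],
) -> set[frozenset[str]]:
    """Reciprocal best-scoring partners per ordered phage pair.

    For each query the best subject in each other phage is chosen by
    (score, identity, lexicographically smallest subject id); a pair is
    a BBH when the choice is reciprocal.
    """
    best: dict[tuple[str, str], AlignmentHit] = {}
    for hit in hits:
        key = (hit.query_id, protein_to_phage[hit.subject_id])
        cur = best.get(key)
        if cur is None or _better(hit, cur):
            best[key] = hit
    pairs: set[frozenset[str]] = set()
    for (qid, _), hit in best.items():
        sid = hit.subject_id
        back = best.get((sid, protein_to_phage[qid]))
        if back is not None and back.subject_id == qid:
            pairs.add(frozenset((qid, sid)))
    return pairs


def _better(a: AlignmentHit, b: AlignmentHit) -> bool:
    ka = (a.score, a.identity, _neg_lex(a.subject_id))
    kb = (b.score, b.identity, _neg_lex(b.subject_id))
    return ka > kb


class _neg_lex(str):
    """Orders lexicographically ascending under a max comparison."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qcovs", "scovs", "evalue", "bitscore",
]


def write_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """BLAST outfmt-6-style TSV (coverage columns replace coordinates)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(OUTFMT6_COLUMNS) + "\n")
        for h in hits:
            mismatch = h.aln_length - h.n_identical
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{100 * h.identity:.2f}\t"
                f"{h.aln_length}\t{mismatch}\t{h.n_gap_opens}\t"
                f"{100 * h.query_coverage:.2f}\t{100 * h.subject_coverage:.2f}\t"
                f"{h.evalue:.3g}\t{bitscore(h.score):.1f}\n"
            )


def read_hits(path: str | Path) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            pident = float(f[2]) / 100.0
            length = int(f[3])
            n_identical = round(pident * length)
            bits = float(f[9])
            raw = (bits * math.log(2.0) + math.log(KA_K)) / KA_LAMBDA
            hits.append(
                AlignmentHit(
                    query_id=f[0],
                    subject_id=f[1],
                    identity=pident,
                    aln_length=length,
                    query_coverage=float(f[6]) / 100.0,
                    subject_coverage=float(f[7]) / 100.0,
                    score=raw,
                    evalue=float(f[8]),
                    n_identical=n_identical,
                    n_gap_opens=int(f[5]),
                )
            )
    return hits
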