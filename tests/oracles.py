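"""Independent brute-force oracles used to validate the package.

These deliberately re-derive results with the simplest possible
algorithms (plain dynamic programming, sliding windows, exhaustive
loops) and share no code with the implementations they check.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def sw_score(a: str, b: str, gap_open: float = 11.0,
             gap_extend: float = 1.0) -> float:
    """Smith-Waterman affine-gap best local score via three-matrix DP.

    A gap of length k costs gap_open + (k - 1) * gap_extend, matching
    the package's aligner convention.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            sub = _BLOSUM62[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def six_frame_orfs(sequence: str, min_codons: int,
                   starts=("ATG", "GTG", "TTG")) -> set[tuple[int, int, str]]:
    """All longest-per-stop ORFs as (fwd_start, fwd_end, strand) triples."""
    stops = {"TAA", "TAG", "TGA"}
    out: set[tuple[int, int, str]] = set()
    glen = len(sequence)
    for strand, seq in (("+", sequence),
                        ("-", str(Seq(sequence).reverse_complement()))):
        for frame in range(3):
            codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
            open_start = None
            for k, codon in enumerate(codons):
                pos = frame + 3 * k
                if codon in stops:
                    if open_start is not None:
                        end = pos + 3
                        if (end - open_start) // 3 >= min_codons:
                            if strand == "+":
                                out.add((open_start, end, "+"))
                            else:
                                out.add((glen - end, glen - open_start, "-"))
                        open_start = None
                elif open_start is None and codon in starts:
                    open_start = pos
    return out


def primer_sites(sequence: str, primer: str, max_mismatches: int,
                 anchor: int) -> set[tuple[int, str, int]]:
    """Sliding-window primer scan with a 3'-exact anchor, both strands."""
    rc = str(Seq(primer).reverse_complement())
    n = len(primer)
    found: set[tuple[int, str, int]] = set()
    for pos in range(len(sequence) - n + 1):
        window = sequence[pos:pos + n]
        # plus strand: primer 3' end is the window's last base
        mm = sum(1 for x, y in zip(window, primer) if x != y)
        anchor_ok = window[n - anchor:] == primer[n - anchor:]
        if anchor_ok and mm <= max_mismatches:
            found.add((pos, "+", mm))
        # minus strand: primer anneals reverse-complemented; its 3' end
        # corresponds to the window's first base
        mm = sum(1 for x, y in zip(window, rc) if x != y)
        anchor_ok = window[:anchor] == rc[:anchor]
        if anchor_ok and mm <= max_mismatches:
            found.add((pos, "-", mm))
    return found


def amplicon_spans(f_plus: list[int], r_minus: list[tuple[int, int]],
                   r_plus: list[int], f_minus: list[tuple[int, int]],
                   len_f: int, len_r: int,
                   max_product: int) -> set[tuple[int, int, str]]:
    """Exhaustive facing-site pairing (linear genomes)."""
    out: set[tuple[int, int, str]] = set()
    for s in f_plus:
        for epos, elen in r_minus:
            length = epos + elen - s
            if len_f + len_r <= length <= max_product:
                out.add((s, epos + elen, "+"))
    for s in r_plus:
        for epos, elen in f_minus:
            length = epos + elen - s
            if len_f + len_r <= length <= max_product:
                out.add((s, epos + elen, "-"))
    return out


def connected_components(nodes: list[str],
                         edges: list[tuple[str, str]]) -> set[frozenset[str]]:
    index = {n: i for i, n in enumerate(nodes)}
    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(index[a])] = find(index[b])
    comps: dict[int, set[str]] = {}
    for n, i in index.items():
        comps.setdefault(find(i), set()).add(n)
    return {frozenset(c) for c in comps.values()}


def crosstab_loops(matrix, strains, phages, strain_types):
    """Double-loop host-range cross-tabulation."""
    strains_by_type = {t: 0 for t in "ABCU"}
    phages_by_type = {t: 0 for t in "ABCU"}
    for j, strain in enumerate(strains):
        if any(matrix[i][j] for i in range(len(phages))):
            strains_by_type[strain_types[strain]] += 1
    for t in "ABCU":
        cols = [j for j, s in enumerate(strains) if strain_types[s] == t]
        count = 0
        for i in range(len(phages)):
            if any(matrix[i][j] for j in cols):
                count += 1
        phages_by_type[t] = count
    return strains_by_type, phages_by_type


def mcl_iterate(adjacency: np.ndarray, inflation: float = 2.0,
                max_iter: int = 200, eps: float = 1e-8,
                prune: float = 1e-5) -> np.ndarray:
    """Reference MCL iteration on a small dense matrix (self-loops = max
    incident weight), returning the idempotent limit matrix."""
    adj = adjacency.astype(float).copy()
    loops = adj.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(adj, loops)
    mat = adj / adj.sum(axis=0)
    for _ in range(max_iter):
        prev = mat
        mat = mat @ mat
        mat = np.power(mat, inflation)
        mat = mat / mat.sum(axis=0)
        mat[mat < prune] = 0.0
        mat = mat / mat.sum(axis=0)
        if np.abs(mat - prev).max() < eps:
            return mat
    raise RuntimeError("reference MCL did not converge")
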