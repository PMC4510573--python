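"""Shared fixtures and independent reference oracles.

The oracle implementations here deliberately use different algorithms and
code paths from the package: exhaustive six-frame ORF enumeration, a
hand-rolled dynamic-programming local aligner, sliding-window motif checks
and all-pairs rank statistics. They exist to cross-check the package, never
to stand in for it.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from reannot.genome import START_CODONS, STOP_CODONS, reverse_complement

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------- ORF oracle
def orf_oracle(dna: str, min_len_nt: int = 60) -> set[tuple[int, int, str]]:
    """Exhaustive six-frame enumeration of maximal start..stop ORFs."""

    def one_strand(seq: str) -> set[tuple[int, int]]:
        found = set()
        n = len(seq)
        for frame in range(3):
            codon_pos = list(range(frame, n - 2, 3))
            stops = [p for p in codon_pos if seq[p : p + 3] in STOP_CODONS]
            starts = [p for p in codon_pos if seq[p : p + 3] in START_CODONS]
            for stop in stops:
                prev_stops = [s for s in stops if s < stop]
                lo = max(prev_stops) + 3 if prev_stops else frame
                cand = [s for s in starts if lo <= s < stop]
                if not cand:
                    continue
                start = min(cand)  # maximal ORF in this stop-free interval
                if stop + 3 - start > min_len_nt and "N" not in seq[start : stop + 3]:
                    found.add((start + 1, stop + 3))
        return found

    L = len(dna)
    out = {(s, e, "+") for s, e in one_strand(dna)}
    for s, e in one_strand(reverse_complement(dna)):
        out.add((L - e + 1, L - s + 1, "-"))
    return out


# ------------------------------------------------------- local-align oracles
def sw_dp_oracle(a: str, b: str, gap: float = -8.0) -> float:
    """Hand-rolled Smith–Waterman score matrix (independent of Biopython)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = BLOSUM62[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, H[i - 1, j] + gap, H[i, j - 1] + gap)
            best = max(best, H[i, j])
    return best


def nw_global_score(a: str, b: str, gap: float = -8.0) -> float:
    """Global alignment score; both sequences consumed entirely."""
    n, m = len(a), len(b)
    D = np.full((n + 1, m + 1), -np.inf)
    D[0, 0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i and j:
                D[i, j] = max(D[i, j], D[i - 1, j - 1] + BLOSUM62[a[i - 1], b[j - 1]])
            if i:
                D[i, j] = max(D[i, j], D[i - 1, j] + gap)
            if j:
                D[i, j] = max(D[i, j], D[i, j - 1] + gap)
    return float(D[n, m])


def exhaustive_local_score(a: str, b: str, gap: float = -8.0) -> float:
    """Best local score as max over all substring pairs of their global score."""
    best = 0.0
    for i in range(len(a)):
        for k in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for l in range(j + 1, len(b) + 1):
                    best = max(best, nw_global_score(a[i:k], b[j:l], gap))
    return best


# ------------------------------------------------------------ PROSITE oracle
def window_match_oracle(seq: str, elements: list[tuple[str, set[str]]]) -> set[tuple[int, int]]:
    """Sliding-window check for fixed-length patterns.

    Each element is (kind, residues) with kind in {fixed, set, exclude, any}.
    """
    k = len(elements)
    out = set()
    for s in range(len(seq) - k + 1):
        ok = True
        for off, (kind, residues) in enumerate(elements):
            aa = seq[s + off]
            if kind == "any":
                continue
            if kind == "exclude":
                if aa in residues:
                    ok = False
                    break
            elif aa not in residues:
                ok = False
                break
        if ok:
            out.add((s + 1, s + k))
    return out


# ---------------------------------------------------------------- AUC oracle
def mann_whitney_auc(pos: list[int], neg: list[int]) -> float:
    """(#concordant + 0.5 * #tied) / (n1 * n0) by all-pairs counting."""
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20151015)
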