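"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: Viterbi scores are
recomputed by exhaustive enumeration over every legal state path of the
search profile, and ORFs by a literal codon walk over all six frames.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from burpmine.profilehmm import AA_INDEX, NEG_INF, ProfileHMM
from burpmine.seqformats import CODON_TABLE

LOG_HALF = -1.0


def _core_paths(hmm: ProfileHMM, residues: list[int]):
    """Scores of every core path consuming exactly ``residues``.

    A core path enters at B->Mk (cost log2(1/M)), moves through M/I/D
    states via the node transitions, and exits to E from a match state at
    no cost.  Yields total log2-odds scores (emissions + transitions).
    """
    M = hmm.length
    with np.errstate(divide="ignore"):
        msc = np.log2(hmm.match_emissions) - np.log2(hmm.background)
        isc = np.log2(hmm.insert_emissions) - np.log2(hmm.background)
        t = np.log2(hmm.transitions)
    entry = -math.log2(M)
    r = residues
    n = len(r)
    out: list[float] = []

    def emit_m(k, i):
        return msc[k - 1, r[i]] if r[i] >= 0 else 0.0

    def emit_i(k, i):
        return isc[k - 1, r[i]] if r[i] >= 0 else 0.0

    def walk(state, k, i, score):
        # state in {M, I, D}; k = current node (1-based); i = residues used
        if state == "M":
            if i == n:
                out.append(score)      # exit to E (free) after last residue
            if k == M:
                return
            if i < n:
                walk("M", k + 1, i + 1, score + t[k, 0] + emit_m(k + 1, i))
                if k < M:
                    walk("I", k, i + 1, score + t[k, 1] + emit_i(k, i))
            walk("D", k + 1, i, score + t[k, 2])
        elif state == "I":
            if i < n:
                walk("M", k + 1, i + 1, score + t[k, 3] + emit_m(k + 1, i))
                walk("I", k, i + 1, score + t[k, 4] + emit_i(k, i))
        else:  # D
            if k == M:
                return
            if i < n:
                walk("M", k + 1, i + 1, score + t[k, 5] + emit_m(k + 1, i))
            walk("D", k + 1, i, score + t[k, 6])

    for k0 in range(1, M + 1):
        if n >= 1:
            walk("M", k0, 1, entry + emit_m(k0, 0))
    return out


def _best_core(hmm, residues):
    scores = _core_paths(hmm, residues)
    return max(scores) if scores else NEG_INF


def enumerate_viterbi(hmm: ProfileHMM, protein: str,
                      mode: str = "multihit_local") -> float:
    """Best total bit score over all complete state paths (exhaustive).

    Paths decompose into ordered disjoint hit intervals separated by
    N/J/C flanking loops; every interval's core alignments are enumerated
    explicitly, so this is an independent check of the Viterbi recursion.
    """
    multihit = mode == "multihit_local"
    x = [AA_INDEX.get(a, -1) for a in protein.upper()]
    L = len(x)
    if L == 0:
        return NEG_INF
    tEC = LOG_HALF if multihit else 0.0
    q = L / (L + 3.0) if multihit else L / (L + 2.0)
    loop = math.log2(q)
    move = math.log2(1.0 - q)
    max_hits = L if multihit else 1
    best = NEG_INF
    # choose h disjoint, ordered, non-empty intervals
    for h in range(1, max_hits + 1):
        # interval boundaries: 0 <= s1 < e1 <= s2 < e2 <= ... <= L
        for bounds in itertools.combinations_with_replacement(range(L + 1),
                                                             2 * h):
            ivals = [(bounds[2 * j], bounds[2 * j + 1]) for j in range(h)]
            if any(s >= e for s, e in ivals):
                continue
            score = 0.0
            # N: loop per residue before the first interval, then N->B
            score += ivals[0][0] * loop + move
            ok = True
            for j, (s, e) in enumerate(ivals):
                seg = _best_core(hmm, x[s:e])
                if seg == NEG_INF:
                    ok = False
                    break
                score += seg
                if j < h - 1:
                    gap = ivals[j + 1][0] - e
                    # E->J, J loops over gap residues, J->B
                    score += LOG_HALF + gap * loop + move
            if not ok:
                continue
            # E->C, C loops over trailing residues, C->T
            score += tEC + (L - ivals[-1][1]) * loop + move
            best = max(best, score)
    if best == NEG_INF:
        return best
    # subtract the geometric-length null: q^L (1-q) prod bg(x_i)
    return best - (L * loop + move)


def six_frame_orfs(seq: str, min_aa: int):
    """Literal codon-walk ORF oracle: (strand, frame, protein) tuples."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    out = []
    for strand in "+-":
        s = seq if strand == "+" else "".join(comp[c] for c in reversed(seq))
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
            prot = "".join("X" if "N" in c else CODON_TABLE[c]
                           for c in codons)
            for stretch in prot.split("*"):
                if len(stretch) >= min_aa:
                    out.append((strand, frame, stretch))
    return out
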