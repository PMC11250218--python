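"""Profile hidden Markov models for precursor-peptide mining.

A profile HMM summarises an alignment of known split-burpitide precursor
(recognition) sequences: one match state per well-occupied column, with
insert and delete states absorbing indels.  Candidate proteins are scored
by local Viterbi alignment in log-odds bits against a fixed background
composition, and significance is reported as a Gumbel-tail E-value, with
hits accepted at the mining threshold E <= 0.1.

The search profile is Plan7-shaped (N/B/M/I/D/E/C/J states):

* flanking states N, C and the multihit loop J emit background residues
  (zero log-odds) with a length-conditioned self-loop probability
  q = L/(L+3) (multihit) or L/(L+2) (unihit) and move probability 1-q,
  so flanking a long target is essentially free, as in HMMER's length
  model;
* local entry B->Mk is uniform (1/M) over match states;
* local exit Mk->E is free (log-odds 0) from any match state;
* multihit mode splits E between C and J (1/2 each); unihit sends E->C
  with probability 1;
* the null model emits the background with the same geometric length
  distribution, P(x|null) = q^L (1-q) prod bg(x_i), so flanking residues
  are score-neutral and the bit score measures the aligned segments
  (local-alignment semantics).

This parameterisation is deliberately simple and fully explicit so that a
brute-force enumeration over all state paths reproduces the scores on
small models; it is not intended to be bit-compatible with HMMER.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqformats import SeqRecord

__all__ = [
    "AMINO_ORDER", "BACKGROUND", "ProfileHMM", "HmmHit",
    "build_profile", "viterbi_score", "evalue", "calibrate", "search",
    "parse_hmmer3", "write_hmmer3",
]

#: Alphabetical amino-acid order (matches HMMER3 amino files).
AMINO_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ORDER)}

#: Robinson & Robinson amino-acid background frequencies (Swiss-Prot-style
#: composition), renormalised; fixed for determinism.
_RR = {
    "A": 0.078047, "R": 0.051269, "N": 0.044873, "D": 0.053640,
    "C": 0.019246, "Q": 0.042644, "E": 0.062949, "G": 0.073772,
    "H": 0.021992, "I": 0.051420, "L": 0.090191, "K": 0.057438,
    "M": 0.022425, "F": 0.038556, "P": 0.052028, "S": 0.071198,
    "T": 0.058413, "W": 0.013298, "Y": 0.032165, "V": 0.064409,
}
BACKGROUND = np.array([_RR[aa] for aa in AMINO_ORDER])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

LOG2_HALF = -1.0     # log2 of every flanking/loop transition probability
TRANS_ORDER = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
NEG_INF = float("-inf")
LN2 = math.log(2.0)


@dataclass
class ProfileHMM:
    """Match/insert emissions, node transitions and Gumbel calibration.

    ``transitions`` has M+1 rows in ``TRANS_ORDER``: row 0 holds the
    begin-node transitions of a HMMER file (kept for round-tripping; the
    local search profile uses uniform entry instead) and row k the
    7-tuple out of node k.  Row M's MM slot is the M->E probability.
    ``viterbi_lambda`` is per bit.
    """

    name: str
    match_emissions: np.ndarray          # (M, 20)
    insert_emissions: np.ndarray         # (M, 20)
    transitions: np.ndarray              # (M+1, 7)
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    viterbi_mu: float | None = None
    viterbi_lambda: float | None = None
    calibration_source: str | None = None

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def __post_init__(self):
        M = self.length
        if M < 1:
            raise ValueError("model must have at least one node")
        for nm, arr in (("match", self.match_emissions),
                        ("insert", self.insert_emissions)):
            if arr.shape != (M, 20):
                raise ValueError(f"{nm} emissions must be (M, 20)")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"{nm} emission rows must sum to 1")
        if self.transitions.shape != (M + 1, 7):
            raise ValueError("transitions must be (M+1, 7)")
        self._tables = None

    def log_odds(self):
        """(match, insert, transition) log2 tables; cached."""
        if self._tables is None:
            with np.errstate(divide="ignore"):
                msc = np.log2(self.match_emissions) - np.log2(self.background)
                isc = np.log2(self.insert_emissions) - np.log2(self.background)
                t = np.log2(self.transitions)
            self._tables = (msc, isc, t)
        return self._tables


@dataclass
class HmmHit:
    """One scored target with its best local alignment segment."""

    target_id: str
    bit_score: float
    e_value: float
    ali_start: int     # 0-based half-open on the target protein
    ali_end: int
    model_start: int   # 0-based half-open over model nodes
    model_end: int

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("negative E-value")
        if not self.ali_start < self.ali_end:
            raise ValueError("empty alignment span")


# ---------------------------------------------------------------------------
# Model construction from an alignment
# ---------------------------------------------------------------------------

_GAPS = set("-.")
_PAIR_IDX = {"MM": 0, "MI": 1, "MD": 2, "IM": 3, "II": 4, "DM": 5, "DD": 6}


def build_profile(alignment: Sequence[str], gap_fraction_threshold: float = 0.5,
                  pseudocount: float = 1.0, name: str = "profile") -> ProfileHMM:
    """Estimate a profile HMM from a gapped alignment.

    Columns whose gap fraction is below the threshold become match
    states.  Emissions are smoothed towards the background and
    transition groups towards a uniform prior, each with total weight
    ``pseudocount``; the estimate is fully deterministic.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 aligned sequences")
    width = len(alignment[0])
    if any(len(s) != width for s in alignment):
        raise ValueError("ragged alignment rows")
    rows = [s.upper() for s in alignment]
    valid = set(AMINO_ORDER) | _GAPS | {"X"}
    for s in rows:
        bad = set(s) - valid
        if bad:
            raise ValueError(f"invalid alignment characters {sorted(bad)}")
    n = len(rows)
    gap_frac = [sum(1 for s in rows if s[c] in _GAPS) / n for c in range(width)]
    match_cols = [c for c in range(width)
                  if gap_frac[c] < gap_fraction_threshold]
    M = len(match_cols)
    if M == 0:
        raise ValueError("alignment has zero match columns")
    col_node = {c: k + 1 for k, c in enumerate(match_cols)}

    m_counts = np.zeros((M, 20))
    i_counts = np.zeros((M, 20))
    t_counts = np.zeros((M + 1, 7))

    for s in rows:
        prev = ("M", 0)   # virtual begin node
        for c in range(width):
            ch = s[c]
            if c in col_node:
                k = col_node[c]
                if ch in _GAPS:
                    state = ("D", k)
                else:
                    state = ("M", k)
                    if ch in AA_INDEX:
                        m_counts[k - 1, AA_INDEX[ch]] += 1
            else:
                if ch in _GAPS:
                    continue
                state = ("I", prev[1])
                if state[1] >= 1 and ch in AA_INDEX:
                    i_counts[state[1] - 1, AA_INDEX[ch]] += 1
            idx = _PAIR_IDX.get(prev[0] + state[0])
            if idx is not None:       # D->I and I->D are not modelled
                t_counts[prev[1], idx] += 1
            prev = state
        idx = {"M": 0, "I": 3, "D": 5}[prev[0]]   # exit to virtual end
        t_counts[prev[1], idx] += 1

    bg = BACKGROUND
    m_em = (m_counts + pseudocount * bg) / (
        m_counts.sum(axis=1, keepdims=True) + pseudocount)
    i_em = (i_counts + pseudocount * bg) / (
        i_counts.sum(axis=1, keepdims=True) + pseudocount)

    trans = np.zeros((M + 1, 7))
    groups = ((0, 3, np.full(3, 1 / 3)),    # M -> M/I/D
              (3, 5, np.full(2, 1 / 2)),    # I -> M/I
              (5, 7, np.full(2, 1 / 2)))    # D -> M/D
    for k in range(M + 1):
        for lo, hi, prior in groups:
            c = t_counts[k, lo:hi]
            trans[k, lo:hi] = (c + pseudocount * prior) / (c.sum() + pseudocount)
    trans[M] = [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]   # M->E forced
    return ProfileHMM(name=name, match_emissions=m_em, insert_emissions=i_em,
                      transitions=trans)


# ---------------------------------------------------------------------------
# Viterbi scoring
# ---------------------------------------------------------------------------

def _encode(protein: str) -> np.ndarray:
    """Residue indices; X/ambiguity codes map to -1 (background emission)."""
    return np.array([AA_INDEX.get(aa, -1) for aa in protein.upper()],
                    dtype=int)


def _score_only(hmm: ProfileHMM, x: np.ndarray, multihit: bool) -> float:
    """Vectorised Viterbi bit score (no traceback)."""
    M = hmm.length
    msc, isc, t = hmm.log_odds()
    L = len(x)
    entry = -math.log2(M)
    tEC = LOG2_HALF if multihit else 0.0
    q = L / (L + 3.0) if multihit else L / (L + 2.0)
    loop = math.log2(q)          # N/C/J self-loop (emits background)
    move = math.log2(1.0 - q)    # N->B, J->B, C->T

    tMM = t[1:M, 0]
    tMI = t[1:M + 1, 1]
    tMD = t[1:M, 2]
    tIM = t[1:M, 3]
    tII = t[1:M + 1, 4]
    tDM = t[1:M, 5]
    tDD = t[1:M, 6]
    # cumulative D->D chain: S[c] = sum of tDD[0:c]
    S = np.concatenate(([0.0], np.cumsum(tDD))) if M > 1 else np.zeros(1)

    pm = np.full(M, NEG_INF)
    pi = np.full(M, NEG_INF)
    pd = np.full(M, NEG_INF)
    vn = 0.0
    vb = move
    vj = NEG_INF
    vc = NEG_INF
    zeros = np.zeros(M)
    with np.errstate(invalid="ignore"):
        for i in range(1, L + 1):
            r = x[i - 1]
            cand = np.full(M, vb + entry)
            if M > 1:
                np.maximum(cand[1:], pm[:-1] + tMM, out=cand[1:])
                np.maximum(cand[1:], pi[:-1] + tIM, out=cand[1:])
                np.maximum(cand[1:], pd[:-1] + tDM, out=cand[1:])
            vm = (msc[:, r] if r >= 0 else zeros) + cand
            vi = (isc[:, r] if r >= 0 else zeros) + np.maximum(pm + tMI,
                                                               pi + tII)
            vi[M - 1] = NEG_INF
            vd = np.full(M, NEG_INF)
            if M > 1:
                a = vm[:-1] + tMD
                run = np.maximum.accumulate(a - S[1:])
                vd[1:] = S[1:] + run
            ve = vm.max()
            if multihit:
                vj = max(vj + loop, ve + LOG2_HALF)
            vc = max(vc + loop, ve + tEC)
            vn = vn + loop
            vb = vn + move
            if multihit:
                vb = max(vb, vj + move)
            pm, pi, pd = vm, vi, vd
    # C->T move, then subtract the geometric-length null (q^L (1-q))
    return float(vc + move - (L * loop + move))


def _full_trace(hmm: ProfileHMM, x: np.ndarray, multihit: bool):
    """Plain Viterbi with explicit backpointers; returns (score, segments).

    Each segment is (ali_start, ali_end, model_start, model_end,
    segment_bits) with half-open coordinates.  Tie-breaks: Match over
    Insert over Delete over B-entry, then smaller model index.
    """
    M = hmm.length
    msc, isc, t = hmm.log_odds()
    L = len(x)
    entry = -math.log2(M)
    tEC = LOG2_HALF if multihit else 0.0
    q = L / (L + 3.0) if multihit else L / (L + 2.0)
    loop = math.log2(q)
    move = math.log2(1.0 - q)

    Vm = np.full((L + 1, M), NEG_INF)
    Vi = np.full((L + 1, M), NEG_INF)
    Vd = np.full((L + 1, M), NEG_INF)
    Vn = np.full(L + 1, NEG_INF)
    Vb = np.full(L + 1, NEG_INF)
    Ve = np.full(L + 1, NEG_INF)
    Vj = np.full(L + 1, NEG_INF)
    Vc = np.full(L + 1, NEG_INF)
    # backpointers: for M states 0=B,1=M,2=I,3=D; for I 0=M,1=I; D 0=M,1=D
    Bm = np.zeros((L + 1, M), dtype=np.int8)
    Bi = np.zeros((L + 1, M), dtype=np.int8)
    Bd = np.zeros((L + 1, M), dtype=np.int8)
    Be = np.zeros(L + 1, dtype=int)       # exit node
    Bj = np.zeros(L + 1, dtype=np.int8)   # 0 = from E, 1 = loop
    Bc = np.zeros(L + 1, dtype=np.int8)   # 0 = from E, 1 = loop
    Bb = np.zeros(L + 1, dtype=np.int8)   # 0 = from N, 1 = from J
    Vn[0] = 0.0
    Vb[0] = move

    for i in range(1, L + 1):
        r = x[i - 1]
        for k in range(M):
            best = Vb[i - 1] + entry
            ptr = 0
            if k > 0:
                v = Vm[i - 1, k - 1] + t[k, 0]
                if v > best:
                    best, ptr = v, 1
                v = Vi[i - 1, k - 1] + t[k, 3]
                if v > best:
                    best, ptr = v, 2
                v = Vd[i - 1, k - 1] + t[k, 5]
                if v > best:
                    best, ptr = v, 3
            em = msc[k, r] if r >= 0 else 0.0
            Vm[i, k] = em + best
            Bm[i, k] = ptr
            if k < M - 1:
                a = Vm[i - 1, k] + t[k + 1, 1]
                b = Vi[i - 1, k] + t[k + 1, 4]
                iem = isc[k, r] if r >= 0 else 0.0
                if a >= b:
                    Vi[i, k] = iem + a
                    Bi[i, k] = 0
                else:
                    Vi[i, k] = iem + b
                    Bi[i, k] = 1
        for k in range(1, M):
            a = Vm[i, k - 1] + t[k, 2]
            b = Vd[i, k - 1] + t[k, 6]
            if a >= b:
                Vd[i, k] = a
                Bd[i, k] = 0
            else:
                Vd[i, k] = b
                Bd[i, k] = 1
        ke = int(np.argmax(Vm[i]))    # first max -> smallest node
        Ve[i] = Vm[i, ke]
        Be[i] = ke
        if multihit:
            a = Ve[i] + LOG2_HALF
            b = Vj[i - 1] + loop
            Vj[i], Bj[i] = (a, 0) if a >= b else (b, 1)
        a = Ve[i] + tEC
        b = Vc[i - 1] + loop
        Vc[i], Bc[i] = (a, 0) if a >= b else (b, 1)
        Vn[i] = Vn[i - 1] + loop
        Vb[i] = Vn[i] + move
        Bb[i] = 0
        if multihit and Vj[i] + move > Vb[i]:
            Vb[i] = Vj[i] + move
            Bb[i] = 1

    score = float(Vc[L] + move - (L * loop + move))  # minus length null
    if not np.isfinite(score):
        return NEG_INF, []

    segments = []
    i = L
    while i > 0 and Bc[i] == 1:
        i -= 1
    # i is now the row where C was entered from E
    while i > 0:
        # E at row i: walk one hit segment backwards
        k = int(Be[i])
        end_i, end_k = i, k
        state = "M"
        while True:
            if state == "M":
                ptr = Bm[i, k]
                i -= 1
                if ptr == 0:
                    start_i, start_k = i, k
                    break
                k -= 1
                if ptr == 1:
                    state = "M"
                elif ptr == 2:
                    state = "I"
                else:
                    state = "D"
            elif state == "I":
                state = "M" if Bi[i, k] == 0 else "I"
                i -= 1
            else:   # D (within-row, no residue consumed)
                state = "M" if Bd[i, k] == 0 else "D"
                k -= 1
        seg_bits = float(Ve[end_i] - Vb[start_i])
        segments.append((start_i, end_i, start_k, end_k + 1, seg_bits))
        # continue through B at row start_i
        if Bb[start_i] == 0:
            break
        i = start_i
        while i > 0 and Bj[i] == 1:
            i -= 1
        if i == 0:
            break
    segments.reverse()
    return score, segments


def viterbi_score(hmm: ProfileHMM, protein: str, mode: str = "multihit_local"):
    """Local Viterbi bit score and best alignment segment.

    Returns ``(bit_score, HmmHit | None)``; an empty or unalignable
    protein yields ``(-inf, None)``.
    """
    if mode not in ("multihit_local", "unihit_local"):
        raise ValueError(f"unknown mode {mode!r}")
    if not protein:
        return NEG_INF, None
    x = _encode(protein)
    score, segments = _full_trace(hmm, x, mode == "multihit_local")
    if not segments:
        return NEG_INF, None
    best = max(segments, key=lambda s: s[4])
    a0, a1, k0, k1, _ = best
    hit = HmmHit(target_id="", bit_score=score, e_value=0.0,
                 ali_start=a0, ali_end=a1, model_start=k0, model_end=k1)
    return score, hit


def viterbi_bits(hmm: ProfileHMM, protein: str,
                 mode: str = "multihit_local") -> float:
    """Bit score only (fast path, no alignment)."""
    if not protein:
        return NEG_INF
    return _score_only(hmm, _encode(protein), mode == "multihit_local")


# ---------------------------------------------------------------------------
# E-values and calibration
# ---------------------------------------------------------------------------

def evalue(hmm: ProfileHMM, bit_score: float, database_size: int) -> float:
    """Gumbel-tail E-value for a Viterbi bit score.

    P(S >= s) = 1 - exp(-exp(-lambda (s - mu))); E = database_size * P.
    """
    if database_size < 1:
        raise ValueError("database_size must be >= 1")
    if hmm.viterbi_lambda is None or hmm.viterbi_mu is None:
        raise ValueError("model is not calibrated; run calibrate() first")
    lam, mu = hmm.viterbi_lambda, hmm.viterbi_mu
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if bit_score == NEG_INF:
        return float(database_size)
    p = -math.expm1(-math.exp(-lam * (bit_score - mu)))
    return database_size * p


def calibrate(hmm: ProfileHMM, sequences: Sequence[str] | None = None,
              n_samples: int = 200, length: int = 100,
              seed: int = 0, mode: str = "multihit_local") -> ProfileHMM:
    """Estimate the Gumbel location from seeded shuffled decoys.

    When target ``sequences`` are given, decoys are residue shuffles of a
    seeded sample of them, preserving the searched set's composition and
    length distribution; otherwise decoys are drawn i.i.d. from the
    model's background at the given length.  lambda is fixed at ln 2
    (the theoretical slope for log-odds bit scores) and mu is its
    maximum-likelihood location, mu = -(1/lambda) ln(mean exp(-lambda
    s_i)).  Modifies the model in place and flags it as
    shuffle-calibrated.
    """
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ORDER))
    scores = np.empty(n_samples)
    for j in range(n_samples):
        if sequences:
            src = sequences[int(rng.integers(len(sequences)))]
            arr = np.array(list(src))
            rng.shuffle(arr)
            seq = "".join(arr)
        else:
            seq = "".join(rng.choice(aas, size=length, p=hmm.background))
        scores[j] = viterbi_bits(hmm, seq, mode=mode)
    lam = LN2
    mu = -(1.0 / lam) * math.log(float(np.mean(np.exp(-lam * scores))))
    hmm.viterbi_mu = float(mu)
    hmm.viterbi_lambda = lam
    hmm.calibration_source = "shuffle"
    return hmm


def search(hmm: ProfileHMM, proteins: Sequence[SeqRecord],
           e_threshold: float = 0.1, mode: str = "multihit_local",
           seed: int = 0) -> list[HmmHit]:
    """Score every protein and keep hits with E <= threshold.

    database_size is the number of proteins searched (per-assembly
    semantics).  Uncalibrated models are first calibrated from seeded
    background decoys and flagged as such.
    """
    if not proteins:
        raise ValueError("empty protein set")
    if hmm.viterbi_lambda is None or hmm.viterbi_mu is None:
        calibrate(hmm, sequences=[r.sequence for r in proteins],
                  seed=seed, mode=mode)
    N = len(proteins)
    hits = []
    for rec in proteins:
        s = viterbi_bits(hmm, rec.sequence, mode=mode)
        e = evalue(hmm, s, N)
        if e <= e_threshold:
            _, hit = viterbi_score(hmm, rec.sequence, mode=mode)
            if hit is None:
                continue
            hit.target_id = rec.id
            hit.e_value = e
            hits.append(hit)
    hits.sort(key=lambda h: (h.e_value, h.target_id))
    return hits


# ---------------------------------------------------------------------------
# HMMER3 ASCII I/O
# ---------------------------------------------------------------------------

def _prob_to_field(p: float) -> str:
    return "*" if p <= 0 else f"{-math.log(p):.10f}"


def _field_to_prob(tok: str) -> float:
    return 0.0 if tok == "*" else math.exp(-float(tok))


def write_hmmer3(hmm: ProfileHMM, path: str | Path) -> None:
    """Write the model as HMMER3/f ASCII (negative-natural-log fields).

    Fields carry 10 decimals so that parse(write(m)) round-trips every
    probability to better than 1e-9.
    """
    M = hmm.length
    trans_names = "m->m     m->i     m->d     i->m     i->i     d->m     d->d"
    with open(path, "w") as fh:
        fh.write("HMMER3/f [burpmine]\n")
        fh.write(f"NAME  {hmm.name}\n")
        fh.write(f"LENG  {M}\n")
        fh.write("ALPH  amino\n")
        if hmm.viterbi_mu is not None and hmm.viterbi_lambda is not None:
            fh.write(f"STATS LOCAL VITERBI  {hmm.viterbi_mu:.5f}  "
                     f"{hmm.viterbi_lambda:.5f}\n")
        fh.write("HMM          " + "        ".join(AMINO_ORDER) + "\n")
        fh.write("            " + trans_names + "\n")
        fh.write("  COMPO   " +
                 " ".join(_prob_to_field(p) for p in hmm.background) + "\n")
        fh.write("          " +
                 " ".join(_prob_to_field(p) for p in hmm.background) + "\n")
        fh.write("          " +
                 " ".join(_prob_to_field(p) for p in hmm.transitions[0]) + "\n")
        for k in range(1, M + 1):
            fh.write(f"{k:7d}   " + " ".join(
                _prob_to_field(p) for p in hmm.match_emissions[k - 1]) + "\n")
            fh.write("          " + " ".join(
                _prob_to_field(p) for p in hmm.insert_emissions[k - 1]) + "\n")
            fh.write("          " + " ".join(
                _prob_to_field(p) for p in hmm.transitions[k]) + "\n")
        fh.write("//\n")


def parse_hmmer3(path: str | Path) -> ProfileHMM:
    """Parse a HMMER3 ASCII profile (amino alphabet) into probabilities.

    Handles files written by HMMER's hmmbuild as well as our own writer;
    emission fields are negative natural logs, '*' meaning probability 0.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("HMMER3"):
        raise ValueError("not a HMMER3 ASCII file (missing format line)")
    name = "unnamed"
    leng = None
    mu = lam = None
    i = 1
    while i < len(lines):
        line = lines[i]
        if line.startswith("HMM "):
            break
        key = line.split(None, 1)[0] if line.strip() else ""
        if key == "NAME":
            name = line.split(None, 1)[1].strip()
        elif key == "LENG":
            leng = int(line.split()[1])
        elif key == "ALPH":
            alph = line.split()[1].lower()
            if alph != "amino":
                raise ValueError(f"unsupported alphabet {alph!r}")
        elif key == "STATS":
            parts = line.split()
            if parts[1] == "LOCAL" and parts[2] == "VITERBI":
                mu, lam = float(parts[3]), float(parts[4])
        i += 1
    if leng is None:
        raise ValueError("missing LENG header")
    if i >= len(lines):
        raise ValueError("missing HMM section")
    order = lines[i].split()[1:]
    if order and "".join(order) != AMINO_ORDER:
        raise ValueError("unexpected residue column order")
    i += 2   # skip the transition-name line
    background = BACKGROUND.copy()
    if i < len(lines) and lines[i].split() and lines[i].split()[0] == "COMPO":
        background = np.array([_field_to_prob(t)
                               for t in lines[i].split()[1:21]])
        i += 1
    i += 1   # node-0 insert emissions (background-like; not used)
    trans0 = [_field_to_prob(t) for t in lines[i].split()[:7]]
    i += 1
    m_em = np.zeros((leng, 20))
    i_em = np.zeros((leng, 20))
    trans = np.zeros((leng + 1, 7))
    trans[0] = trans0
    for k in range(1, leng + 1):
        if i + 2 >= len(lines):
            raise ValueError(f"truncated node block at node {k}")
        toks = lines[i].split()
        if not toks or toks[0] != str(k) or len(toks) < 21:
            raise ValueError(f"truncated or misnumbered node block at node {k}")
        m_em[k - 1] = [_field_to_prob(t) for t in toks[1:21]]
        i_em[k - 1] = [_field_to_prob(t) for t in lines[i + 1].split()[:20]]
        trans[k] = [_field_to_prob(t) for t in lines[i + 2].split()[:7]]
        i += 3
    # absorb representation rounding so invariants hold exactly
    m_em /= m_em.sum(axis=1, keepdims=True)
    i_sum = i_em.sum(axis=1, keepdims=True)
    i_em = np.where(i_sum > 0, i_em / np.where(i_sum == 0, 1.0, i_sum),
                    BACKGROUND)
    background = background / background.sum()
    return ProfileHMM(name=name, match_emissions=m_em, insert_emissions=i_em,
                      transitions=trans, background=background,
                      viterbi_mu=mu, viterbi_lambda=lam,
                      calibration_source="file" if mu is not None else None)
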