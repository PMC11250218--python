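"""Split/fused classification, core-peptide extraction and summarisation.

A transcript whose translated ORF matches the precursor profile can be
either a stand-alone (split) precursor peptide or a fused burpitide
cyclase that carries its own core.  Fused cyclases are recognised by the
BURP-domain active-site motif CHX10CHX25-27CHX25-26CH and removed; the
survivors are counted per assembly (unique at the translated-protein
level) and averaged per species, and their core peptides — short windows
ending in the cyclisation anchor residue downstream of the recognition
sequence — are summarised as a position frequency matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .profilehmm import HmmHit, ProfileHMM, search as _hmm_search
from .seqformats import Orf, SeqRecord

__all__ = [
    "BURP_MOTIF", "CoreRuleset", "CORE_RULESETS",
    "PrecursorCandidate", "CoreAnnotation", "Pfm",
    "detect_burp", "classify_split", "extract_cores",
    "count_unique", "core_pfm", "annotate_tree",
]

#: BURP-domain active-site motif; x is any residue (including X).
BURP_MOTIF = re.compile(r"CH.{10}CH.{25,27}CH.{25,26}CH")


@dataclass
class CoreAnnotation:
    """A candidate core peptide within a precursor protein."""

    core: str
    start: int          # 0-based half-open on the protein
    end: int
    anchor: str         # final residue: Y (ether), W or H (moroidin-type)
    family_ruleset: str

    def __post_init__(self):
        if not 3 <= len(self.core) <= 8:
            raise ValueError("core length must be 3-8 residues")
        if self.core[-1] != self.anchor:
            raise ValueError("anchor must equal the final core residue")


@dataclass
class PrecursorCandidate:
    """A translated ORF with its profile hit and classification."""

    assembly_id: str
    species: str
    orf: Orf
    hit: HmmHit
    is_fused: bool = False
    cores: list[CoreAnnotation] = field(default_factory=list)


@dataclass
class Pfm:
    """Position frequency matrix over aligned core peptides.

    Cores are right-aligned on the anchor; positions shorter cores do not
    reach are tallied under '-' so every column sums to ``n_sequences``.
    """

    columns: list[dict[str, int]]
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.columns).fillna(0).astype(int)
        df.index.name = "position"
        return df


# ---------------------------------------------------------------------------
# BURP detection and split/fused classification
# ---------------------------------------------------------------------------

def detect_burp(protein: str, burp_hmm: ProfileHMM | None = None,
                e_threshold: float = 0.1) -> tuple[int, int] | None:
    """Leftmost BURP-domain span in a protein, or None.

    By default the conserved CHX10CHX25-27CHX25-26CH active-site motif is
    used; if a BURP profile HMM (a PF03181 stand-in) is supplied, a
    profile search at the same 0.1 E-value inclusion threshold is used
    instead and the hit's alignment span is returned.
    """
    if burp_hmm is not None:
        rec = SeqRecord(id="q", sequence=protein, alphabet="aa")
        hits = _hmm_search(burp_hmm, [rec], e_threshold=e_threshold)
        if not hits:
            return None
        return hits[0].ali_start, hits[0].ali_end
    m = BURP_MOTIF.search(protein)
    return m.span() if m else None


def classify_split(candidates: Sequence[PrecursorCandidate]
                   ) -> list[PrecursorCandidate]:
    """Keep only non-fused candidates (order preserved, idempotent)."""
    return [c for c in candidates if not c.is_fused]


# ---------------------------------------------------------------------------
# Core extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreRuleset:
    """Window lengths, anchor residues and search region for cores."""

    name: str
    min_len: int = 4
    max_len: int = 6
    anchors: frozenset = frozenset({"Y", "W"})
    #: residue that must occur somewhere inside the window (e.g. W for
    #: moroidin-type cores ending in His)
    require_residue: str | None = None
    #: search region: residues downstream of the profile-hit end
    region: int = 20


CORE_RULESETS: dict[str, CoreRuleset] = {
    "default": CoreRuleset("default"),
    # moroidin-type: 8-mer ending in His with the crosslinking Trp inside
    "moroidin": CoreRuleset("moroidin", min_len=8, max_len=8,
                            anchors=frozenset({"H"}), require_residue="W"),
}


def extract_cores(protein: str, hit: HmmHit,
                  ruleset: CoreRuleset | str = "default"
                  ) -> list[CoreAnnotation]:
    """Candidate cores downstream of the profile-hit end.

    Every window within the search region whose length is in range and
    whose final residue is an allowed anchor is reported (overlaps
    included), in deterministic left-to-right order; an empty list means
    no anchored window was found.
    """
    if isinstance(ruleset, str):
        ruleset = CORE_RULESETS[ruleset]
    lo = hit.ali_end
    hi = min(len(protein), lo + ruleset.region)
    out: list[CoreAnnotation] = []
    for start in range(lo, hi):
        for length in range(ruleset.min_len, ruleset.max_len + 1):
            end = start + length
            if end > len(protein):
                continue
            window = protein[start:end]
            if window[-1] not in ruleset.anchors:
                continue
            if ruleset.require_residue and \
                    ruleset.require_residue not in window[:-1]:
                continue
            if "X" in window or "*" in window:
                continue
            out.append(CoreAnnotation(core=window, start=start, end=end,
                                      anchor=window[-1],
                                      family_ruleset=ruleset.name))
    return out


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_unique(candidates: Sequence[PrecursorCandidate],
                 group_by: str = "species") -> pd.DataFrame:
    """Unique-precursor counts per assembly or species means.

    Uniqueness is exact translated-protein identity within an assembly
    (assemblies emit redundant isoforms; nucleotide-level dedup would
    overcount).  ``group_by='assembly'`` returns per-assembly counts;
    ``'species'`` returns the arithmetic mean of per-assembly counts,
    sorted by species name.
    """
    if group_by not in ("assembly", "species"):
        raise ValueError("group_by must be 'assembly' or 'species'")
    per_assembly: dict[tuple[str, str], set[str]] = {}
    for c in candidates:
        per_assembly.setdefault((c.species, c.assembly_id),
                                set()).add(c.orf.protein)
    rows = [{"species": sp, "assembly_id": asm, "n_unique": len(prots)}
            for (sp, asm), prots in sorted(per_assembly.items())]
    asm_df = pd.DataFrame(rows, columns=["species", "assembly_id", "n_unique"])
    if group_by == "assembly":
        return asm_df.reset_index(drop=True)
    sp = (asm_df.groupby("species")["n_unique"].mean()
          .reset_index(name="mean_count").sort_values("species")
          .reset_index(drop=True))
    return sp


# ---------------------------------------------------------------------------
# Core position frequency matrix
# ---------------------------------------------------------------------------

def core_pfm(candidates: Sequence[PrecursorCandidate],
             max_per_assembly: int = 3, align_on: str = "anchor") -> Pfm:
    """PFM of core peptides, up to ``max_per_assembly`` unique cores each.

    Per assembly, unique cores are ranked by ascending parent-hit E-value
    (ties by lexicographic core) and the top ``max_per_assembly`` enter
    the matrix, right-aligned on the anchor residue.
    """
    if align_on != "anchor":
        raise ValueError("only anchor alignment is supported")
    chosen: list[str] = []
    by_assembly: dict[str, dict[str, float]] = {}
    for c in candidates:
        for core in c.cores:
            d = by_assembly.setdefault(c.assembly_id, {})
            e = c.hit.e_value
            if core.core not in d or e < d[core.core]:
                d[core.core] = e
    for asm in sorted(by_assembly):
        ranked = sorted(by_assembly[asm].items(), key=lambda kv: (kv[1], kv[0]))
        chosen.extend(core for core, _ in ranked[:max_per_assembly])
    if not chosen:
        raise ValueError("no cores to summarise")
    width = max(len(c) for c in chosen)
    padded = [c.rjust(width, "-") for c in chosen]
    columns: list[dict[str, int]] = []
    for pos in range(width):
        col: dict[str, int] = {}
        for p in padded:
            col[p[pos]] = col.get(p[pos], 0) + 1
        columns.append(col)
    return Pfm(columns=columns, n_sequences=len(chosen))


# ---------------------------------------------------------------------------
# Cladogram annotation
# ---------------------------------------------------------------------------

_VAR_SUFFIX = re.compile(r"\s+var\.\s+.*$")


def _norm_species(name: str) -> str:
    s = name.replace("_", " ").strip().lower()
    s = _VAR_SUFFIX.sub("", s)
    return re.sub(r"\s+", " ", s)


def annotate_tree(newick_path: str | Path, species_counts: pd.DataFrame
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach per-species mean counts to the leaves of a Newick tree.

    Species names and leaf labels are matched case-insensitively with
    underscore/space normalisation and "var." suffixes stripped.  Returns
    (leaf table, unmatched count rows); leaves without a count carry NA.
    """
    import dendropy
    try:
        tree = dendropy.Tree.get(path=str(newick_path), schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick in {newick_path}: {exc}") from exc
    counts = {_norm_species(r["species"]): (r["species"], float(r["mean_count"]))
              for _, r in species_counts.iterrows()}
    rows = []
    used = set()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else str(leaf)
        key = _norm_species(label)
        if key in counts:
            sp, cnt = counts[key]
            used.add(key)
            rows.append({"leaf": label, "species": sp, "mean_count": cnt})
        else:
            rows.append({"leaf": label, "species": None,
                         "mean_count": float("nan")})
    leaf_df = pd.DataFrame(rows, columns=["leaf", "species", "mean_count"])
    unmatched = species_counts[
        ~species_counts["species"].map(_norm_species).isin(used)
    ].reset_index(drop=True)
    return leaf_df, unmatched
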