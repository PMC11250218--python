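"""Sequence/spectrum record types, FASTA and MGF I/O, six-frame ORF calling.

The ORF caller replaces a full gene predictor for assembled transcripts:
burpitide precursors are short (sometimes < 60 aa) and frequently sit on
fragmented contigs without an annotated start, so ORFs are defined
stop-to-stop in all six frames with a configurable minimum length.
Coordinates are always 0-based half-open on the forward strand of the
parent transcript.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord", "Orf", "Spectrum", "MsFeature",
    "read_fasta", "write_fasta", "extract_orfs",
    "read_spectra", "write_mgf", "read_feature_table", "write_feature_table",
]

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

#: standard genetic code (NCBI table 1), codon -> amino acid ('*' = stop)
CODON_TABLE: dict[str, str] = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _c in enumerate(
        (a + b + c for a in _BASES for b in _BASES for c in _BASES)):
    CODON_TABLE[_c] = _AA[_i]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SeqRecord:
    """A named sequence with a declared alphabet ("nt" or "aa")."""

    id: str
    sequence: str
    description: str = ""
    alphabet: str = "nt"

    def __post_init__(self):
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid record id {self.id!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        allowed = NUCLEOTIDES if self.alphabet == "nt" else AMINO_ACIDS
        bad = set(self.sequence.upper()) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} not in "
                f"{self.alphabet} alphabet")
        self.sequence = self.sequence.upper()


@dataclass
class Orf:
    """An open reading frame; nt coordinates on the forward strand."""

    parent_id: str
    strand: str            # '+' or '-'
    frame: int             # 0, 1, 2 (offset on the reading strand)
    nt_start: int          # 0-based half-open, forward strand
    nt_end: int
    protein: str

    def __post_init__(self):
        if (self.nt_end - self.nt_start) % 3 != 0:
            raise ValueError("ORF span not a multiple of 3")
        if "*" in self.protein:
            raise ValueError("internal stop in ORF protein")


@dataclass
class Spectrum:
    """Centroided MS/MS peak list with its precursor."""

    spectrum_id: str
    precursor_mz: float
    charge: int = 1
    peaks: list[tuple[float, float]] = field(default_factory=list)
    tissue_label: str | None = None

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")
        self.peaks = sorted(self.peaks)


@dataclass
class MsFeature:
    """One LC-MS feature row (m/z, retention time, intensity)."""

    feature_id: str
    mz: float
    rt: float
    intensity: float
    tissue_label: str | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("feature m/z must be positive")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "nt") -> list[SeqRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(SeqRecord(id=rec.id, sequence=str(rec.seq),
                             description=rec.description[len(rec.id):].strip(),
                             alphabet=alphabet))
    return out


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
           for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Translation and ORF extraction
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string codon-by-codon (table 1).

    Trailing partial codons are dropped; any codon containing N yields X.
    """
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        aas.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(aas)


def extract_orfs(transcript: SeqRecord, min_aa: int = 50,
                 require_start: bool = False) -> list[Orf]:
    """All stop-to-stop ORFs in all six frames of a transcript.

    Returns ORFs whose protein is at least ``min_aa`` residues, ordered by
    (strand, frame, nt_start).  With ``require_start`` each protein is
    trimmed to begin at its first Met (ORFs without one are dropped).
    """
    if transcript.alphabet != "nt":
        raise ValueError("extract_orfs requires a nucleotide record")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = transcript.sequence
    L = len(seq)
    orfs: list[Orf] = []
    for strand in "+-":
        read = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            prot = translate(read[frame:])
            # split into stop-free stretches; track codon offsets
            start = 0
            for m in re.finditer(r"\*", prot + "*"):
                stretch = prot[start:m.start()]
                aa_off = start
                has_stop = m.start() < len(prot)
                if require_start and stretch:
                    met = stretch.find("M")
                    if met < 0:
                        stretch = ""
                    else:
                        stretch = stretch[met:]
                        aa_off += met
                if len(stretch) >= min_aa:
                    # codon span on the reading strand (include the stop
                    # codon in the nt span when present)
                    r_start = frame + 3 * aa_off
                    r_end = frame + 3 * m.start() + (3 if has_stop else 0)
                    if strand == "+":
                        nt_start, nt_end = r_start, r_end
                    else:
                        nt_start, nt_end = L - r_end, L - r_start
                    orfs.append(Orf(parent_id=transcript.id, strand=strand,
                                    frame=frame, nt_start=nt_start,
                                    nt_end=nt_end, protein=stretch))
                start = m.start() + 1
    orfs.sort(key=lambda o: (o.strand, o.frame, o.nt_start))
    return orfs


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_spectra(path: str | Path, dialect: str = "mgf") -> list[Spectrum]:
    """Read an MGF file (BEGIN IONS blocks); peaks are sorted on read."""
    if dialect != "mgf":
        raise ValueError(f"unsupported dialect {dialect!r}")
    spectra: list[Spectrum] = []
    block: dict | None = None
    n_block = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                n_block += 1
                block = {"peaks": [], "params": {}}
                continue
            if line == "END IONS":
                if block is None:
                    raise ValueError("END IONS without BEGIN IONS")
                params = block["params"]
                if "PEPMASS" not in params:
                    raise ValueError(f"block {n_block} missing PEPMASS")
                charge = 1
                if "CHARGE" in params:
                    charge = int(params["CHARGE"].rstrip("+"))
                spectra.append(Spectrum(
                    spectrum_id=params.get("TITLE", f"spectrum_{n_block}"),
                    precursor_mz=float(params["PEPMASS"].split()[0]),
                    charge=charge, peaks=block["peaks"],
                    tissue_label=params.get("TISSUE")))
                block = None
                continue
            if block is None:
                continue
            if "=" in line and not line[0].isdigit():
                key, val = line.split("=", 1)
                block["params"][key.upper()] = val
            else:
                mz, inten = line.split()[:2]
                block["peaks"].append((float(mz), float(inten)))
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.spectrum_id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={sp.charge}+\n")
            if sp.tissue_label:
                fh.write(f"TISSUE={sp.tissue_label}\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# Feature tables (CSV: feature_id, mz, rt, intensity, tissue)
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> list[MsFeature]:
    import pandas as pd
    df = pd.read_csv(path)
    out = []
    for i, row in df.iterrows():
        out.append(MsFeature(
            feature_id=str(row.get("feature_id", f"F{i}")),
            mz=float(row["mz"]), rt=float(row["rt"]),
            intensity=float(row["intensity"]),
            tissue_label=(str(row["tissue"])
                          if "tissue" in df.columns else None)))
    return out


def write_feature_table(features: Iterable[MsFeature], path: str | Path) -> None:
    import pandas as pd
    rows = [{"feature_id": f.feature_id, "mz": f.mz, "rt": f.rt,
             "intensity": f.intensity, "tissue": f.tissue_label or ""}
            for f in features]
    pd.DataFrame(rows).to_csv(path, index=False)
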