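"""Deterministic synthetic fixtures: transcriptomes, truth tables, spectra.

The generator emulates the inputs the mining pipeline consumes in the
wild — assembled plant transcriptomes containing stand-alone (split)
precursor genes, fused BURP-domain cyclase genes, and unrelated decoy
transcripts — plus simulated MS/MS spectra of the predicted modified
cyclic peptides.  Everything is driven by a single integer seed and
regenerates byte-identically, so end-to-end tests need no downloads.

A split precursor gene is a random N-terminal context, a lightly mutated
copy of a fixed fixture recognition sequence, a core peptide drawn from a
configurable pool, and a short tail; fused genes additionally embed a
BURP active-site motif instance upstream.  The fixture recognition
sequence is an invented constant (it is NOT a natural burpitide
recognition sequence); substitute real sequences via ``recognition``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import burpchem
from .profilehmm import BACKGROUND, AMINO_ORDER, ProfileHMM, build_profile
from .seqformats import MsFeature, SeqRecord, Spectrum, reverse_complement, \
    write_fasta, write_mgf, write_feature_table

__all__ = [
    "FIXTURE_RECOGNITION", "DEFAULT_CORE_POOL", "FixtureBundle",
    "make_recognition_alignment", "make_fixture_hmm",
    "make_transcriptome", "make_spectra_bundle",
]

#: Invented constant recognition sequence used by all fixtures (25 aa;
#: deliberately free of C, W and Y so it cannot mimic a BURP motif or an
#: anchored core).
FIXTURE_RECOGNITION = "ASLDKETFNPMVRGQHIESTLAGDK"

#: Default planted core peptides: ether-type 4-mers with terminal Tyr,
#: plus the moroidin-type 8-mer.
DEFAULT_CORE_POOL = ("FFFY", "FPLY", "GFLY", "FLVY", "QLLVWRGH")

_AA = np.array(list(AMINO_ORDER))

#: Codons per amino acid for uniform synonymous reverse translation.
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
from .seqformats import CODON_TABLE as _CT  # noqa: E402
for _codon, _aa in _CT.items():
    _CODONS.setdefault(_aa, []).append(_codon)


@dataclass
class FixtureBundle:
    """Synthetic transcriptome + truth table (+ optional spectra)."""

    transcripts: list[SeqRecord]
    truth: pd.DataFrame
    spectra: list[Spectrum] = field(default_factory=list)
    feature_table: list[MsFeature] = field(default_factory=list)
    seed: int = 0

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.transcripts, outdir / "transcripts.fasta")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if self.spectra:
            write_mgf(self.spectra, outdir / "spectra.mgf")
        if self.feature_table:
            write_feature_table(self.feature_table, outdir / "features.csv")

    def assembly_fastas(self, outdir: str | Path) -> list[Path]:
        """One FASTA per assembly (the per-assembly pipeline input)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        by_asm: dict[str, list[SeqRecord]] = {}
        id2asm = dict(zip(self.truth["transcript_id"],
                          self.truth["assembly_id"]))
        for rec in self.transcripts:
            by_asm.setdefault(id2asm[rec.id], []).append(rec)
        paths = []
        for asm in sorted(by_asm):
            p = outdir / f"{asm}.fasta"
            write_fasta(by_asm[asm], p)
            paths.append(p)
        return paths


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_AA, size=n, p=BACKGROUND))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for aa in seq:
        if rng.random() < rate:
            out.append(str(rng.choice(_AA)))
        else:
            out.append(aa)
    return "".join(out)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(str(rng.choice(_CODONS[aa])) for aa in protein)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=n))


def _burp_motif_instance(rng: np.random.Generator) -> str:
    """A protein segment matching CHX10CHX25-27CHX25-26CH."""
    aa_no_ch = np.array([a for a in AMINO_ORDER if a not in "CH"])
    def block(n):
        return "".join(rng.choice(aa_no_ch, size=n))
    return ("CH" + block(10) + "CH" + block(int(rng.integers(25, 28)))
            + "CH" + block(int(rng.integers(25, 27))) + "CH")


def make_recognition_alignment(n: int = 12, sub_rate: float = 0.10,
                               seed: int = 0,
                               recognition: str = FIXTURE_RECOGNITION
                               ) -> list[str]:
    """Ungapped alignment of mutated recognition-sequence copies."""
    rng = np.random.default_rng(seed)
    return [_mutate(rng, recognition, sub_rate) for _ in range(n)]


def make_fixture_hmm(seed: int = 0, n: int = 12,
                     recognition: str = FIXTURE_RECOGNITION) -> ProfileHMM:
    """Profile HMM trained on the fixture recognition alignment."""
    aln = make_recognition_alignment(n=n, seed=seed, recognition=recognition)
    return build_profile(aln, name="fixture-precursor")


def make_transcriptome(n_split: int, n_fused: int, n_decoys: int,
                       species_plan: Sequence[tuple[str, int]],
                       seed: int = 0,
                       core_pool: Sequence[str] = DEFAULT_CORE_POOL,
                       recognition: str = FIXTURE_RECOGNITION
                       ) -> FixtureBundle:
    """Plant split precursors, fused cyclases and decoys per assembly.

    Each assembly in ``species_plan`` (a list of (species, n_assemblies)
    pairs) receives ``n_split`` split precursor genes, ``n_fused`` fused
    BURP genes and ``n_decoys`` random decoy transcripts.  Roughly half
    the transcripts are emitted reverse-complemented.  The truth table
    has one row per transcript: transcript_id, assembly_id, species,
    kind (split_precursor / fused / decoy), planted_core, protein.
    """
    if n_split < 0 or n_fused < 0 or n_decoys < 0:
        raise ValueError("counts must be non-negative")
    if n_split + n_fused + n_decoys == 0:
        raise ValueError("zero total transcripts requested")
    rng = np.random.default_rng(seed)
    transcripts: list[SeqRecord] = []
    rows: list[dict] = []
    for species, n_assemblies in species_plan:
        slug = species.replace(" ", "_")
        for a in range(n_assemblies):
            asm = f"{slug}_a{a}"
            idx = 0
            plan = (["split_precursor"] * n_split + ["fused"] * n_fused
                    + ["decoy"] * n_decoys)
            for kind in plan:
                tid = f"{asm}_t{idx:04d}"
                idx += 1
                core = ""
                protein = ""
                if kind == "split_precursor":
                    core = core_pool[
                        (idx - 1) % len(core_pool)] if core_pool else "FFFY"
                    protein = (_random_protein(rng, int(rng.integers(20, 31)))
                               + _mutate(rng, recognition, 0.05)
                               + core
                               + _random_protein(rng, 3))
                    # in-frame stop before the gene so the stop-to-stop ORF
                    # is exactly the planted protein
                    nt = (_random_nt(rng, int(rng.integers(30, 61))) + "TAA"
                          + _reverse_translate(rng, protein) + "TAA"
                          + _random_nt(rng, int(rng.integers(20, 41))))
                elif kind == "fused":
                    core = core_pool[
                        (idx - 1) % len(core_pool)] if core_pool else "FFFY"
                    protein = (_random_protein(rng, int(rng.integers(5, 11)))
                               + _burp_motif_instance(rng)
                               + _random_protein(rng, 5)
                               + _mutate(rng, recognition, 0.05)
                               + core
                               + _random_protein(rng, 3))
                    # in-frame stop before the gene so the stop-to-stop ORF
                    # is exactly the planted protein
                    nt = (_random_nt(rng, int(rng.integers(30, 61))) + "TAA"
                          + _reverse_translate(rng, protein) + "TAA"
                          + _random_nt(rng, int(rng.integers(20, 41))))
                else:
                    nt = _random_nt(rng, int(rng.integers(300, 601)))
                if rng.random() < 0.5:
                    nt = reverse_complement(nt)
                transcripts.append(SeqRecord(id=tid, sequence=nt,
                                             description=kind))
                rows.append({"transcript_id": tid, "assembly_id": asm,
                             "species": species, "kind": kind,
                             "planted_core": core, "protein": protein})
    truth = pd.DataFrame(rows, columns=["transcript_id", "assembly_id",
                                        "species", "kind", "planted_core",
                                        "protein"])
    return FixtureBundle(transcripts=transcripts, truth=truth, seed=seed)


def make_spectra_bundle(predictions: Sequence[burpchem.CompoundPrediction],
                        noise_peaks: int = 5, mz_jitter_sd: float = 0.0,
                        seed: int = 0, replicates: int = 1
                        ) -> tuple[list[Spectrum], list[MsFeature]]:
    """Simulated MS/MS spectra and an LC-MS feature table.

    Each prediction yields ``replicates`` spectra whose precursor is its
    [M+H]+ with Gaussian jitter of ``mz_jitter_sd`` ppm; fragment peaks
    come from the predicted b/y/immonium ions (same jitter) plus
    ``noise_peaks`` uniform low-intensity noise peaks.  Feature rows
    carry the jittered precursors and tissue labels drawn from
    {leaf, stem, root}.
    """
    if not predictions:
        raise ValueError("need at least one prediction")
    if mz_jitter_sd < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    tissues = np.array(["leaf", "stem", "root"])
    spectra: list[Spectrum] = []
    features: list[MsFeature] = []
    fid = 0
    for p_i, pred in enumerate(predictions):
        mh = pred.adduct_mz["M+H"]
        frags = burpchem.fragment_ions(pred)
        for r in range(replicates):
            jit = 1.0 + rng.normal(0.0, mz_jitter_sd) * 1e-6
            prec = mh * jit
            peaks = []
            for _, mz in frags:
                fj = 1.0 + rng.normal(0.0, mz_jitter_sd) * 1e-6
                peaks.append((mz * fj, float(rng.uniform(0.3, 1.0))))
            for _ in range(noise_peaks):
                peaks.append((float(rng.uniform(100.0, prec)),
                              float(rng.uniform(0.01, 0.1))))
            tissue = str(rng.choice(tissues))
            sid = f"P{p_i}_r{r}"
            spectra.append(Spectrum(spectrum_id=sid, precursor_mz=prec,
                                    charge=1, peaks=peaks,
                                    tissue_label=tissue))
            features.append(MsFeature(feature_id=f"F{fid}", mz=prec,
                                      rt=float(rng.uniform(0.5, 12.5)),
                                      intensity=float(rng.lognormal(12, 1)),
                                      tissue_label=tissue))
            fid += 1
    return spectra, features
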