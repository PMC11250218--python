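"""BURP filtering, core extraction, counting, PFM, tree annotation."""

import numpy as np
import pandas as pd
import pytest

from burpmine import precursors as pc
from burpmine.profilehmm import HmmHit
from burpmine.seqformats import Orf


def _hit(ali_end, e=1e-6):
    return HmmHit(target_id="t", bit_score=50.0, e_value=e,
                  ali_start=max(0, ali_end - 10), ali_end=ali_end,
                  model_start=0, model_end=10)


def _candidate(assembly, protein, e=1e-6, species="Sp x", fused=False,
               cores=()):
    orf = Orf(parent_id="p", strand="+", frame=0, nt_start=0,
              nt_end=3 * len(protein), protein=protein)
    c = pc.PrecursorCandidate(assembly_id=assembly, species=species,
                              orf=orf, hit=_hit(10, e), is_fused=fused)
    c.cores = list(cores)
    return c


# ---------------------------------------------------------------------------
# BURP detection
# ---------------------------------------------------------------------------

def test_burp_motif_found_in_constructed_domain():
    motif = "CH" + "A" * 10 + "CH" + "A" * 26 + "CH" + "A" * 25 + "CH"
    protein = "A" * 50 + motif + "A" * 50
    span = pc.detect_burp(protein)
    assert span == (50, 50 + len(motif))


def test_burp_absent_in_polyalanine_and_out_of_range_spacer():
    assert pc.detect_burp("A" * 400) is None
    bad = "CH" + "A" * 10 + "CH" + "A" * 28 + "CH" + "A" * 25 + "CH"
    assert pc.detect_burp("A" * 10 + bad + "A" * 10) is None


def test_classify_split_filters_and_is_idempotent():
    cands = [_candidate("a", "MKLV" * 15, fused=f)
             for f in (False, True, False, True, False)]
    split = pc.classify_split(cands)
    assert [c.is_fused for c in split] == [False] * 3
    assert split == pc.classify_split(split)
    assert pc.classify_split([c for c in cands if c.is_fused] ) == []


def test_fused_gene_with_precursor_signal_is_excluded(fixture_hmm,
                                                      mining_bundle):
    """A fused gene hit by the precursor profile still gets filtered."""
    truth = mining_bundle.truth
    fused = truth[truth.kind == "fused"].iloc[0]
    assert pc.detect_burp(fused.protein) is not None
    split = truth[truth.kind == "split_precursor"].iloc[0]
    assert pc.detect_burp(split.protein) is None


# ---------------------------------------------------------------------------
# Core extraction
# ---------------------------------------------------------------------------

def test_extract_cores_finds_fffy_downstream_of_hit():
    protein = "M" * 20 + "AGDFFFYAE"
    hit = _hit(ali_end=22)
    cores = [c.core for c in pc.extract_cores(protein, hit)]
    assert "FFFY" in cores
    starts = [c.start for c in pc.extract_cores(protein, hit)]
    assert starts == sorted(starts)


def test_extract_cores_moroidin_ruleset():
    protein = "M" * 10 + "QLLVWRGH" + "AAA"
    hit = _hit(ali_end=10)
    cores = pc.extract_cores(protein, hit, ruleset="moroidin")
    assert [c.core for c in cores] == ["QLLVWRGH"]
    assert cores[0].anchor == "H"


def test_extract_cores_empty_without_anchor():
    protein = "M" * 10 + "AGDEALLKAG"
    assert pc.extract_cores(protein, _hit(10)) == []


def test_core_annotation_invariants():
    cores = pc.extract_cores("M" * 10 + "FAYLWGDY", _hit(10))
    assert cores
    for c in cores:
        assert c.core[-1] == c.anchor
        assert 3 <= len(c.core) <= 8
        assert c.anchor in {"Y", "W"}


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def test_count_unique_dedups_identical_proteins():
    prot = "MKLV" * 15
    cands = [_candidate("a1", prot), _candidate("a1", prot)]
    df = pc.count_unique(cands, group_by="assembly")
    assert df.n_unique.tolist() == [1]


def test_species_average_is_arithmetic_mean():
    cands = [_candidate("a1", f"P{i}" + "MKLV" * 14) for i in range(20)]
    cands += [_candidate("a2", f"Q{i}" + "MKLV" * 14) for i in range(40)]
    sp = pc.count_unique(cands, group_by="species")
    assert sp.mean_count.tolist() == [30.0]


def test_counting_is_permutation_invariant():
    rng = np.random.default_rng(0)
    cands = [_candidate(f"a{i % 3}", f"P{i}" + "MKLV" * 14,
                        species=f"S{i % 2}") for i in range(12)]
    base = pc.count_unique(cands)
    for _ in range(3):
        perm = list(cands)
        rng.shuffle(perm)
        assert pc.count_unique(perm).equals(base)


# ---------------------------------------------------------------------------
# PFM
# ---------------------------------------------------------------------------

def test_pfm_identical_cores_have_unit_modal_frequency():
    ann = pc.CoreAnnotation("FFFY", 0, 4, "Y", "default")
    cands = [_candidate(f"a{i}", f"P{i}" + "MKLV" * 14, cores=[ann])
             for i in range(3)]
    pfm = pc.core_pfm(cands)
    assert pfm.n_sequences == 3
    for col in pfm.columns:
        assert max(col.values()) == 3


def test_pfm_caps_cores_per_assembly_at_three():
    cores = [pc.CoreAnnotation(c, 0, 4, "Y", "default")
             for c in ("FFFY", "FLLY", "AGDY", "WPLY", "GGGY")]
    cands = [_candidate("a1", "MKLV" * 15, e=1e-7, cores=cores)]
    pfm = pc.core_pfm(cands)
    assert pfm.n_sequences == 3
    for col in pfm.columns:
        assert sum(col.values()) == pfm.n_sequences


def test_pfm_column_sums_equal_n_sequences_with_mixed_lengths():
    anns = [pc.CoreAnnotation(c, 0, len(c), c[-1], "default")
            for c in ("FFFY", "AGDLY", "QLW")]
    cands = [_candidate(f"a{i}", f"P{i}" + "MKLV" * 14, cores=[a])
             for i, a in enumerate(anns)]
    pfm = pc.core_pfm(cands)
    assert all(sum(col.values()) == pfm.n_sequences for col in pfm.columns)


# ---------------------------------------------------------------------------
# Tree annotation
# ---------------------------------------------------------------------------

def test_annotate_tree_matching_and_na(tmp_path):
    nwk = tmp_path / "t.nwk"
    nwk.write_text("((Coffea_arabica,Ceanothus_americanus),Zea_mays);\n")
    counts = pd.DataFrame({"species": ["Coffea arabica",
                                       "Ceanothus americanus",
                                       "Celosia argentea var. cristata"],
                           "mean_count": [50.0, 22.0, 10.0]})
    leaves, unmatched = pc.annotate_tree(nwk, counts)
    assert len(leaves) == 3
    coffea = leaves[leaves.leaf.str.contains("arabica")].iloc[0]
    assert coffea.species == "Coffea arabica" and coffea.mean_count == 50.0
    zea = leaves[leaves.leaf.str.contains("mays")].iloc[0]
    assert pd.isna(zea.mean_count)
    assert unmatched.species.tolist() == ["Celosia argentea var. cristata"]
    # permuting count rows changes nothing
    leaves2, _ = pc.annotate_tree(nwk, counts.iloc[::-1])
    assert leaves2.equals(leaves)


def test_annotate_tree_malformed_newick(tmp_path):
    nwk = tmp_path / "bad.nwk"
    nwk.write_text("((A,B),C\n")
    with pytest.raises(ValueError, match="[Nn]ewick"):
        pc.annotate_tree(nwk, pd.DataFrame({"species": ["A"],
                                            "mean_count": [1.0]}))
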