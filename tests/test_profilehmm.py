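"""Profile construction, Viterbi scoring, E-values, HMMER3 I/O."""

import math

import numpy as np
import pytest

from burpmine import profilehmm as ph
from burpmine.seqformats import SeqRecord
from conftest import conserved_profile, random_profile
from _oracles import enumerate_viterbi


# ---------------------------------------------------------------------------
# build_profile
# ---------------------------------------------------------------------------

def test_build_profile_degenerate_alignment():
    hmm = ph.build_profile(["MKLVY"] * 3)
    assert hmm.length == 5
    for k, aa in enumerate("MKLVY"):
        row = hmm.match_emissions[k]
        assert np.argmax(row) == ph.AA_INDEX[aa]
        assert row[ph.AA_INDEX[aa]] > max(np.delete(row, ph.AA_INDEX[aa]))
    assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0)
    for k in range(hmm.length + 1):
        assert np.isclose(hmm.transitions[k, 0:3].sum(), 1.0)
        assert np.isclose(hmm.transitions[k, 3:5].sum(), 1.0)
        assert np.isclose(hmm.transitions[k, 5:7].sum(), 1.0)


def test_gap_fraction_threshold_excludes_gappy_column():
    # middle column 60% gaps -> insert column at threshold 0.5
    aln = ["MAY", "MAY", "M-Y", "M-Y", "M-Y"]
    hmm = ph.build_profile(aln)
    assert hmm.length == 2


def test_build_profile_input_validation():
    with pytest.raises(ValueError, match="ragged"):
        ph.build_profile(["MKY", "MK"])
    with pytest.raises(ValueError, match="at least 2"):
        ph.build_profile(["MKY"])
    with pytest.raises(ValueError, match="zero match columns"):
        ph.build_profile(["--", "--", "AA"])


def test_build_profile_recovers_simulated_model():
    """Sequences simulated from a known 8-node profile rebuild its modal
    residues (parameter recovery at n=10)."""
    # conservation 0.8: at n=10 the modal count ~ Bin(10, 0.8) exceeds any
    # competitor except with probability ~1e-4 per column, so modal
    # identity is well-posed at this sample size
    rng = np.random.default_rng(5)
    gen = conserved_profile(rng, 8, conservation=0.8)
    seqs = []
    for _ in range(10):
        seqs.append("".join(
            ph.AMINO_ORDER[rng.choice(20, p=gen.match_emissions[k])]
            for k in range(8)))
    built = ph.build_profile(seqs)
    assert built.length == 8
    modal_gen = gen.match_emissions.argmax(axis=1)
    modal_built = built.match_emissions.argmax(axis=1)
    assert (modal_gen == modal_built).all()


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

def test_single_node_model_matches_path_enumeration():
    """1-node model emitting Y: score equals exhaustive enumeration."""
    me = np.full((1, 20), 1e-12)
    me[0, ph.AA_INDEX["Y"]] = 1 - 19e-12
    ie = ph.BACKGROUND.reshape(1, 20).copy()
    tr = np.array([[1, 0, 0, 1, 0, 1, 0]] * 2, float)
    hmm = ph.ProfileHMM("one", me, ie, tr)
    s, hit = ph.viterbi_score(hmm, "Y")
    assert s == pytest.approx(enumerate_viterbi(hmm, "Y"), abs=1e-9)
    assert (hit.ali_start, hit.ali_end) == (0, 1)
    assert (hit.model_start, hit.model_end) == (0, 1)


@pytest.mark.parametrize("mode", ["multihit_local", "unihit_local"])
@pytest.mark.parametrize("seed", range(15))
def test_viterbi_equals_enumeration_random_models(seed, mode):
    rng = np.random.default_rng(seed)
    M = int(rng.integers(1, 4))
    L = int(rng.integers(1, 7))
    hmm = random_profile(rng, M)
    prot = "".join(rng.choice(list(ph.AMINO_ORDER), size=L))
    expected = enumerate_viterbi(hmm, prot, mode=mode)
    assert ph.viterbi_bits(hmm, prot, mode=mode) == \
        pytest.approx(expected, abs=1e-9)
    s, _ = ph.viterbi_score(hmm, prot, mode=mode)
    assert s == pytest.approx(expected, abs=1e-9)


def test_impossible_emissions_give_sentinel():
    me = np.zeros((1, 20))
    me[0, ph.AA_INDEX["Y"]] = 1.0
    ie = ph.BACKGROUND.reshape(1, 20).copy()
    tr = np.array([[1, 0, 0, 1, 0, 1, 0]] * 2, float)
    hmm = ph.ProfileHMM("one", me, ie, tr)
    s, hit = ph.viterbi_score(hmm, "AAA")
    assert s == ph.NEG_INF and hit is None
    assert ph.viterbi_score(hmm, "")[0] == ph.NEG_INF


def test_multihit_beats_unihit_on_duplicated_segment():
    rng = np.random.default_rng(7)
    hmm = random_profile(rng, 3, concentration=0.1)
    motif = "".join(ph.AMINO_ORDER[i]
                    for i in hmm.match_emissions.argmax(axis=1))
    target = motif + "A" + motif
    multi = ph.viterbi_bits(hmm, target, mode="multihit_local")
    uni = ph.viterbi_bits(hmm, target, mode="unihit_local")
    assert multi >= uni


def test_x_residues_emit_background():
    rng = np.random.default_rng(8)
    hmm = random_profile(rng, 2)
    assert np.isfinite(ph.viterbi_bits(hmm, "XXXX"))


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------

def _calibrated(mu=10.0, lam=ph.LN2):
    rng = np.random.default_rng(0)
    hmm = random_profile(rng, 2)
    hmm.viterbi_mu, hmm.viterbi_lambda = mu, lam
    return hmm


def test_evalue_at_gumbel_location():
    hmm = _calibrated(mu=5.0)
    p = ph.evalue(hmm, 5.0, 1)
    assert p == pytest.approx(1 - math.exp(-1), abs=1e-12)
    assert ph.evalue(hmm, 5.0, 1000) == pytest.approx(1000 * p)


def test_evalue_closed_form_ten_bits_above_mu():
    hmm = _calibrated(mu=3.0, lam=0.693)
    e = ph.evalue(hmm, 13.0, 1000)
    closed_form = 1000 * (1 - math.exp(-math.exp(-0.693 * 10)))
    assert e == pytest.approx(closed_form, rel=1e-12)
    assert e == pytest.approx(0.975, abs=0.005)  # the usual quoted rounding


def test_evalue_monotone_in_score_linear_in_database_size():
    hmm = _calibrated(mu=2.0)
    scores = np.linspace(2.0, 40, 30)    # above mu: tail is unsaturated
    es = [ph.evalue(hmm, s, 100) for s in scores]
    assert all(a > b for a, b in zip(es, es[1:]))
    for s in (1.0, 7.5, 20.0):
        e1 = ph.evalue(hmm, s, 100)
        e2 = ph.evalue(hmm, s, 200)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)
    with pytest.raises(ValueError):
        ph.evalue(hmm, 5.0, 0)


def test_search_thresholds_and_database_scaling(fixture_hmm, mining_bundle):
    from burpmine import seqformats as sf
    truth = mining_bundle.truth
    tids = set(truth[truth.assembly_id == "Fixturea_synthetica_a0"]
               .transcript_id)
    prots = []
    for tr in [t for t in mining_bundle.transcripts if t.id in tids]:
        for o in sf.extract_orfs(tr, min_aa=50):
            prots.append(SeqRecord(id=f"{o.parent_id}|{o.strand}{o.frame}"
                                   f"|{o.nt_start}", sequence=o.protein,
                                   alphabet="aa"))
    hits = ph.search(fixture_hmm, prots, e_threshold=0.1, seed=0)
    assert hits == sorted(hits, key=lambda h: (h.e_value, h.target_id))
    assert ph.search(fixture_hmm, prots, e_threshold=0.0) == []
    # doubling the database doubles E; same hits at doubled threshold
    doubled = prots + [SeqRecord(id=p.id + "_dup", sequence=p.sequence,
                                 alphabet="aa") for p in prots]
    hits2 = ph.search(fixture_hmm, doubled, e_threshold=0.2)
    by_id = {h.target_id: h for h in hits2}
    for h in hits:
        assert by_id[h.target_id].e_value == pytest.approx(2 * h.e_value,
                                                           rel=1e-9)
    assert len(hits2) == 2 * len(hits)


def test_search_finds_planted_precursors_among_decoys(fixture_hmm,
                                                      mining_bundle):
    """All 7 planted genes (5 split + 2 fused) hit; no decoys at E<=0.1."""
    from burpmine import seqformats as sf
    truth = mining_bundle.truth
    kind = dict(zip(truth.transcript_id, truth.kind))
    tids = set(truth[truth.assembly_id == "Fixturea_synthetica_a1"]
               .transcript_id)
    prots = []
    for tr in [t for t in mining_bundle.transcripts if t.id in tids]:
        for o in sf.extract_orfs(tr, min_aa=50):
            prots.append(SeqRecord(id=f"{o.parent_id}|{o.strand}{o.frame}"
                                   f"|{o.nt_start}", sequence=o.protein,
                                   alphabet="aa"))
    hits = ph.search(fixture_hmm, prots, e_threshold=0.1, seed=0)
    hit_parents = {h.target_id.split("|")[0] for h in hits}
    planted = set(truth[(truth.assembly_id == "Fixturea_synthetica_a1")
                        & (truth.kind != "decoy")].transcript_id)
    assert planted <= hit_parents
    # at E<=0.1 the expected decoy survivors per search is 0.1 by the
    # E-value definition; anything beyond one would mean miscalibration
    decoys = [p for p in hit_parents if kind[p] == "decoy"]
    assert len(decoys) <= 1


# ---------------------------------------------------------------------------
# HMMER3 I/O
# ---------------------------------------------------------------------------

def test_hmmer3_round_trip_probabilities_and_scores(tmp_path, fixture_hmm):
    p = tmp_path / "m.hmm"
    ph.write_hmmer3(fixture_hmm, p)
    back = ph.parse_hmmer3(p)
    assert back.length == fixture_hmm.length
    assert np.abs(back.match_emissions
                  - fixture_hmm.match_emissions).max() < 1e-9
    assert np.abs(back.insert_emissions
                  - fixture_hmm.insert_emissions).max() < 1e-9
    assert np.abs(back.transitions[1:-1]
                  - fixture_hmm.transitions[1:-1]).max() < 1e-9
    rng = np.random.default_rng(11)
    for _ in range(5):
        prot = "".join(rng.choice(list(ph.AMINO_ORDER), size=40))
        assert ph.viterbi_bits(back, prot) == pytest.approx(
            ph.viterbi_bits(fixture_hmm, prot), abs=1e-6)


def test_parse_real_hmmbuild_output(tmp_path):
    """A model built by HMMER itself parses; LENG and row sums check out."""
    pyhmmer = pytest.importorskip("pyhmmer")
    seqs = [b"MKLVAYQW", b"MKLVAYEW", b"MKIVAYQW", b"MKLVSYQW"]
    alphabet = pyhmmer.easel.Alphabet.amino()
    msa = pyhmmer.easel.TextMSA(
        name=b"toy",
        sequences=[pyhmmer.easel.TextSequence(name=f"s{i}".encode(),
                                              sequence=s.decode())
                   for i, s in enumerate(seqs)])
    builder = pyhmmer.plan7.Builder(alphabet)
    hmm, _, _ = builder.build_msa(msa.digitize(alphabet),
                                  pyhmmer.plan7.Background(alphabet))
    p = tmp_path / "real.hmm"
    with open(p, "wb") as fh:
        hmm.write(fh)
    parsed = ph.parse_hmmer3(p)
    assert parsed.length == hmm.M
    assert np.allclose(parsed.match_emissions.sum(axis=1), 1.0, atol=1e-6)
    assert parsed.viterbi_mu is not None   # hmmbuild ships STATS lines


def test_parse_errors(tmp_path):
    bad = tmp_path / "bad.hmm"
    bad.write_text("not a model\n")
    with pytest.raises(ValueError, match="HMMER3"):
        ph.parse_hmmer3(bad)
    # truncated node block names the node
    good = tmp_path / "good.hmm"
    ph.write_hmmer3(ph.build_profile(["MKY", "MKY"]), good)
    lines = good.read_text().splitlines()
    truncated = tmp_path / "trunc.hmm"
    truncated.write_text("\n".join(lines[:-5]) + "\n")
    with pytest.raises(ValueError, match=r"node \d"):
        ph.parse_hmmer3(truncated)
    dna = tmp_path / "dna.hmm"
    dna.write_text("HMMER3/f [x]\nNAME  n\nLENG  2\nALPH  dna\nHMM\n")
    with pytest.raises(ValueError, match="alphabet"):
        ph.parse_hmmer3(dna)
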