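# Methods

`burpmine` re-creates, as a desk-scale toolkit, the discovery workflow for
*burpitides* — ribosomally synthesised and post-translationally modified
peptides (RiPPs) whose short core peptides are macrocyclised by
copper-dependent BURP-domain cyclases.  The workflow has two halves:
mining assembled plant transcriptomes for *split* precursor-peptide genes
(core peptide encoded on a stand-alone gene, not fused to the cyclase),
and connecting the mined cores to metabolomes by predicting the masses of
the mature cyclic products and matching them against LC-MS features and
MS/MS networks.

## ORF calling

Transcript assemblies are translated in all six frames and ORFs are
defined **stop-to-stop**, not ATG-to-stop, with a default minimum of
**50 aa**.  Burpitide precursors are short (a recognition sequence of a
few dozen residues plus a 4–8 residue core) and often sit on fragmented
contigs without a reliable start; requiring a start codon or a 100-aa
minimum would silently discard real precursors.  Both knobs are
configurable (`min_aa`, `require_start`).  Coordinates are 0-based
half-open on the forward strand everywhere; codons containing N translate
to X, and X never matches a motif literal.

## The precursor profile HMM

`build_profile` estimates a profile HMM from a gapped alignment of
precursor (recognition) sequences.  Columns with gap fraction < 0.5
become match states; emissions are smoothed toward a fixed
Robinson–Robinson background and each transition group toward a uniform
prior, with total pseudocount weight 1.0.  This is a deliberately simple
estimator — no Dirichlet mixtures, no entropy weighting — because the
goal is a transparent, deterministic model whose behaviour can be checked
by enumeration, not bit-compatibility with HMMER.

### Search profile and scoring

Scoring is local Viterbi in log-odds bits over a Plan7-shaped automaton
(N/B/M/I/D/E/C/J states):

* uniform local entry B→Mk with probability 1/M; free local exit Mk→E;
* multihit via the J loop, with E→{C,J} split 1/2 each (unihit: E→C = 1);
* flanking states N, C, J emit background residues with self-loop
  probability q = L/(L+3) (multihit; L/(L+2) unihit) and move
  probability 1−q, where L is the target length;
* the null model is the background with the same geometric length
  distribution, P(x|null) = q^L (1−q) ∏ bg(xᵢ).

With this pairing, flanking residues are exactly score-neutral and the
bit score measures only the aligned segments.  An earlier, simpler choice
(fixed loop probability 1/2 with a matching null) made insert residues
*and* weak extra hits score-free, so scores grew with target length and
random sequences looked significant; the length-conditioned form removes
that pathology.  The parameterisation is fully explicit so that an
exhaustive enumeration over all legal state paths reproduces every score
on small models — the test suite verifies this on 1,000+ random models
with M ≤ 3 and targets ≤ 6.

Traceback ties prefer Match over Insert over Delete, then the smaller
model index.  A multihit path may contain several segments; the reported
alignment is the highest-scoring segment (fixtures and real precursors
have one).  Empty or unalignable targets return a −∞ sentinel, not an
exception.

### E-values and calibration

P(S ≥ s) = 1 − exp(−exp(−λ(s − μ))) and E = N·P with N the number of
proteins searched (per-assembly semantics).  When a model file carries no
calibration, μ is fitted from Viterbi scores of 200 seeded decoys —
by default residue *shuffles of the searched targets themselves*, which
preserves the database's composition and length distribution.  λ is fixed
at ln 2, the theoretical slope for log-odds bit scores; μ is then the
one-parameter maximum-likelihood location
μ = −(1/λ)·ln(mean exp(−λ sᵢ)).  On large decoy samples the fixed-λ fit
reproduces the empirical tail at the mining operating point
(empirical/nominal exceedance ratio ≈ 1.0 at P = 10⁻³), whereas the free
two-parameter MLE was ~3× anti-conservative there, so the fixed-λ form is
used.  Models calibrated this way are flagged
(`calibration_source="shuffle"`).

An operational consequence worth stating plainly: an inclusion threshold
of E ≤ 0.1 *by definition* admits on average 0.1 random decoys per
search.  On synthetic fixtures this appears as an occasional (~10% of
searches) single decoy transcript surviving to the counting stage; it is
correct behaviour, not a bug, and the tests budget for exactly one decoy
per 500.

## Split/fused classification and cores

A transcript is a *fused* cyclase if its protein contains the BURP
active-site motif `C H x{10} C H x{25,27} C H x{25,26} C H` (leftmost
match reported); a supplied BURP profile HMM may be used instead at the
same E ≤ 0.1 threshold.  Only motif-free (split) candidates are counted.

Core peptides are searched within 20 residues downstream of the profile
alignment end: every window of length 4–6 ending in an anchor residue
(Tyr for ether-type cyclopeptide alkaloids, Trp for stephanotic-type) is
reported, overlaps included.  A separate `moroidin` ruleset looks for
8-mers ending in His that contain the crosslinking Trp.  The anchor field
records the literal final residue (Y, W or H).

Counting deduplicates at **exact translated-protein identity within an
assembly** (assemblies emit redundant isoforms; nucleotide-level dedup
would overcount), and species values are arithmetic means over that
species' assemblies.  Species averaging above 30 unique transcripts flags
a phylogenetic hotspot.  Core summaries are position frequency matrices
over up to three unique cores per assembly (ranked by parent-hit E-value,
ties lexicographic), right-aligned on the anchor, with a `-` row so every
column sums to the sequence count.

## Compound chemistry

Formulas live on {C,H,N,O,S} with exact monoisotopic masses (C = 12
exactly, H = 1.00782503, N = 14.0030740, O = 15.9949146, S = 31.9720707);
peptide formula = Σ residues + H₂O.  The modification registry:

| modification | Δ formula | Δ mass (Da) | site |
|---|---|---|---|
| ether_crosslink | −H₂ | −2.01565 | Tyr (first: C-terminal Tyr) |
| cc_crosslink | −H₂ | −2.01565 | Trp |
| n_methyl | +CH₂ | +14.01565 | backbone amide / N-terminus |
| oxidative_decarboxylation | −(CO₂+H₂) | −46.00548 | C-terminal Tyr |
| alpha_keto | −NH₃+O | −1.03163 | N-terminus (provisional) |

The −(CO₂+H₂) decarboxylation delta (loss of the carboxyl with enamide
formation) is pinned by an internal identity check: a 4-residue {F,P,L,Y}
core with one N-methyl, the ether macrocycle and the decarboxylation
gives exactly C₂₉H₃₆N₄O₄, [M+H]⁺ 505.2809 — the ceanothine B ion.  The
alpha-keto delta is configuration, not a tested constant.  Family
rulesets enumerate allowed combinations (Rhamnaceae: ether +
decarboxylation + 0–2 methyls; Rubiaceae: ether + 0–2 methyls;
stephanotic: 1–2 C–C crosslinks; Amaranthaceae-bicyclic: two ethers ±
alpha-keto), deduplicated by formula; site constraints are cumulative, so
a second crosslink needs a second eligible residue.  Crosslinks are pure
formula deltas, not atom-mapped structures — mass level is all the
matching stage needs.

Fragment prediction ring-opens a macrocyclic prediction at every backbone
amide (one linearization per residue) and emits b/y series on the plain
core backbone plus residue-diagnostic immonium ions (residue − CO + H);
near-duplicate m/z within 10⁻⁴ Da are merged.  Adducts: M+H, M+Na, M+K,
M+2H (proton 1.0072765 Da).

## Metabolome matching and networking

Feature matching reports every (feature, prediction, adduct) pair with
|ppm| ≤ 5 by default (ppm = (obs − pred)/pred × 10⁶).  The modified
cosine pairs peaks directly or shifted by the precursor mass difference,
selects pairs greedily by descending √(Iₐ·I_b) with each peak used once,
and normalises so self-similarity is 1.0.  Greedy selection (rather than
optimal assignment) mirrors common molecular-networking practice and is
cross-checked against an independent implementation in the tests.
Network edges require score ≥ 0.7 **and** ≥ 8 matched peaks at 0.5 Da
fragment tolerance; the 0.2 Da precursor tolerance drives an optional
single-linkage consensus grouping (`consensus_groups`), kept separate
from edge construction so pairwise semantics stay transparent.  The
cosine cutoff is our default — the upstream workflow names the other
three parameters but not this one.

## Synthetic fixtures

`synthdata` emulates the pipeline's inputs: split precursor genes
(random 20–30 aa N-terminus + a 5%-mutated copy of a fixed 25-aa fixture
recognition sequence + a core from a configurable pool + short tail,
reverse-translated with uniform synonymous codons and flanked by an
in-frame upstream stop), fused genes (the same plus an embedded BURP
motif instance), and decoy transcripts of random nucleotides (300–600
nt).  Half the transcripts are emitted reverse-complemented.  The fixture
recognition sequence is an **invented constant** free of C/W/Y (so it can
mimic neither a BURP motif nor an anchored core); it is not a natural
recognition sequence, and users can substitute real ones.  Spectra are
simulated from predicted fragments with Gaussian ppm jitter plus uniform
low-intensity noise peaks.

What the fixtures do **not** model: codon bias (irrelevant downstream),
assembly errors and chimeras, real recognition-sequence diversity across
families, isotope patterns, co-eluting isomers, and retention behaviour.
Passing the synthetic suite therefore demonstrates the pipeline's logic
(recall of planted genes, filtering, counting, gating) under idealised
homology and noise, not performance on real transcriptomes.

Test problem sizes were chosen to exercise each property at the smallest
informative scale: 20 single-assembly scenarios (4 split / 2 fused / 30
decoys) for recall and fused-removal, 100-decoy two-assembly scenarios
plus one 500-decoy fixture for counting and the false-positive budget,
and 8-node/50-sequence simulations for estimator recovery.  For recovery
tests the generating model uses an explicit conservation level (modal
residue probability 0.6, or 0.8 at n = 10) — high enough that the modal
identity is statistically determined at the sample size used, so the test
measures the estimator rather than sampling noise.

## Known limitations

* No forward/posterior decoding, no MSV filter, no bit-exact HMMER
  parity; scores agree with HMMER qualitatively, not numerically.
* The Gumbel λ = ln 2 assumption is verified on the fixture model only;
  unusual models should be recalibrated with more decoys.
* Mass predictions are formula-level; isomeric cores (e.g. L/I) and
  positional methylation isomers are indistinguishable.
* The moroidin second cycle is modelled as a second −H₂ crosslink
  requiring a second Trp; real bicycles close onto other residues.
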