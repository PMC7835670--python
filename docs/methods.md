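# Methods

`splicescreen` implements an alternative-splicing-derived immunotherapy-target
discovery pipeline and exercises it end-to-end on synthetic cohorts with
planted ground truth. This note documents the models, the numerical choices,
what the synthetic data does and does not emulate, and the design decisions
that were genuinely open.

## PSI model

The unit of quantification is the local splice variation (LSV): a reference
exon together with k ≥ 2 competing junctions sharing its donor (source LSV)
or acceptor (target LSV). For one sample, given per-junction read counts
r = (r₁ … r_k), the posterior over the junction-selection frequencies
Ψ = (Ψ₁ … Ψ_k) is

    Ψ | r ~ Dirichlet(α + r),   α_j = 1/k (symmetric, uninformative)

Per-junction summaries come from the Beta marginal
Beta(α_j + r_j, Σ_{i≠j}(α_i + r_i)): the expectation E(Ψ_j), the equal-tail
95% credible interval (2.5/97.5 Beta percentiles), and a binned mass over
B = 40 equal bins on [0, 1] (exact Beta integrals per bin). Position-level
read evidence, GC correction, and bootstrap resampling over read positions
(features of alignment-level tooling) are deliberately collapsed to total
junction counts: the inputs here are count tables, and the statistical
contract — a posterior over Ψ with credible intervals — is preserved.
The recorded quantifiability thresholds are: an LSV is quantifiable in a
sample when its reads exceed 10; unannotated (de novo) junctions need more
than 5 reads summed over the cohort to enter the splice graph; a group
posterior is quantifiable when more than half its samples are.

**Group pooling.** A group posterior is the arithmetic mean of the
quantifiable samples' binned masses, renormalized — a mixture, so it
reflects between-sample heterogeneity, not the standard error of a mean.
Group E(Ψ) is the bin-center mean, renormalized across junctions so the
vector sums to exactly 1 (bin-center means alone are off by O(B⁻²) each).

**Differential PSI.** For two groups, the distribution of
dΨ = Ψ_a − Ψ_b is formed per junction by discrete cross-correlation of the
two binned masses under independence. A junction is differentially spliced
when |E(dΨ)| > 0.1 and P(|dΨ| > 0.1) ≥ 0.95.

Numerics of P(|dΨ| > 0.1): naive bin-center counting misplaces mass when a
posterior concentrates within one or two bins at the decision boundary —
exactly the regime of near-zero or near-fixed junctions. Two refinements are
applied, neither of which changes what the bins assert: (i) each marginal's
bin masses are preserved exactly but distributed *within* each bin following
a Beta profile moment-matched to the distribution (iterated on the refined
grid; near-exact for single-sample posteriors, whose marginals are Beta, and
a smooth interpolant for mixtures); (ii) the threshold cell is split by the
triangular within-cell correction. Against a 10⁶-draw Monte-Carlo sampler of
the underlying Dirichlet posteriors, the worst-case discrepancy over random
posterior pairs is below 0.005 on both E(dΨ) and P(|dΨ| > 0.1); the test
suite enforces 0.01.

## Tumor-specific neojunction filter

A junction is called tumor-specific when both hold:

1. **Zero normal evidence.** Zero supporting reads in every normal sample.
   "PSI = 0 in normals" is interpreted as this observable event — the only
   one consistent with certainty of absence; any single normal read vetoes.
2. **Tumor expression.** The pooled tumor-group posterior puts ≥ 95% of its
   mass above a PSI floor of 10% (fractional boundary-bin handling).

The pooled-group reading of the tumor-side criterion is the default; a
per-sample mode can be composed from the same primitives. Calls report both
evidence quantities regardless of pass/fail.

## Junction → protein projection

GFF3 (1-based inclusive) is converted to 0-based half-open at parse time;
transcript offsets count spliced bases 5'→3' in transcript orientation.
A junction's protein locus is the residue whose codon contains the first
coding base on its acceptor (3') side — the position from which the junction
alters the protein — looked up in a topological-domain partition of the
protein (extracellular / transmembrane / cytoplasmic, 1-based inclusive
residue ranges). Junctions upstream of the CDS map to UTR5, downstream to
UTR3, CDS-less transcripts to noncoding. When a junction is compatible with
several transcripts, all loci are reported and CAR nomination requires at
least one extracellular label. The representative transcript for region
classification is the longest-CDS isoform. Exonic bases of CDS-less
transcripts are reported as untranslated (binned with UTR3), since the
five-class per-base scheme has no separate noncoding-exon class.

## Junction products and confirmation

Windows are symmetric in spliced coordinates — `flank` bases each side of
the junction in coding orientation (48 nt total for peptide derivation,
50 nt for neoantigen windows, 600 nt for single-cell references), truncated
at transcript ends with the truncation recorded. A genomic window would
include intron; junction-spanning products must cross the splice. Each
window is translated in three frames, split at stop codons, and only
fragments whose codon span straddles the junction midpoint are kept.

Confirmation against a peptide database replaces a spectrum search with
exact matching (equality or substring) while keeping the decision rule:
reversed-sequence decoys (seeded shuffle for palindromes) estimate the FDR
as decoy hits / target hits, and matches are accepted only while that
estimate is ≤ 0.05. Tryptic-digest modeling and PTMs are out of scope, as is
spectrum scoring.

## Single-cell screen

Junction references are 600 nt spliced windows. A read supports a junction
iff it matches the reference exactly (either orientation) with ≥ 10 nt on
both sides of the junction midpoint; each read counts for at most one
junction (largest two-sided overhang, ties by junction id). Exact substring
matching replaces an aligner because the synthetic reads are error-free;
the evidence contract (junction-spanning support) is the same, and the
matcher sits behind a small interface that an aligner adapter could
implement. Specificity is zero-tolerance: a junction is neoplastic-specific
iff ≥ 1 neoplastic cell (stem + differentiated) expresses it and zero glia,
immune or endothelial cells do. The stem-enrichment ratio is the stem
expressing-fraction over the differentiated one (∞ when only stem cells
express; undefined when neither does).

## Neoantigen filter

Candidates are all stop-free 8–11-mers from the three-frame translation of
a 50 nt window whose codon span crosses the junction. Binding goes through
a two-argument predictor interface (peptide, allele) → score, lower =
stronger. The default predictor is a deterministic mock: per (allele,
length), a position × amino-acid weight matrix drawn from a generator
seeded by a stable hash of the allele name; the score is the negated mean
positional weight. It makes no biological claim — it exists so the filter
chain (percent rank, thresholding, per-patient serotypes) is exactly
reproducible; an external affinity tool plugs in through the same
interface. Percent rank is 100 × (fraction of a seeded random
natural-frequency peptide background with better-or-equal score); strong
binders have rank < 0.5. The background defaults to 10,000 peptides per
(allele, length) in the library (2,000 in the pipeline default, for speed);
rank is distributional, so background size trades resolution near 0 for
runtime — at 2,000, the smallest nonzero rank is 0.05, an order of
magnitude below the 0.5 threshold.

## Motif scanning

Motifs are position weight matrices scored as log-odds in bits against a
uniform background; ambiguous bases contribute 0 bits. The default
acceptance threshold is 80% of each motif's maximum achievable score
(database-specific thresholds are not reproducible here). The scanning
universe for differentially spliced genes is the spliced transcript plus
250 nt intron flanks — intronic binding sites are reported, full pre-mRNA
scanning is available by composing the same primitives. Hits are classified
by gene region (longest-CDS transcript) and summarized as a region
distribution and a per-motif ranking (genes hit, then total hits, then id).
A small toy PWM set ships with the package; real motif collections load
from JASPAR-like count/probability text.

## Synthetic cohorts

The generator builds one gene per contig, each with a single planted
alternative-splicing event: a cassette exon (default), an alternative 3'
acceptor (+9 nt), or an alternative 5' donor (−9 nt). The canonical
junction is annotated; the alternative junction is absent from the GFF3 and
must be discovered de novo. Genes alternate strands; CDSs start with ATG,
end with a stop, contain no internal stops, and are multiples of 3 by
construction. Surface genes get a three-part topology partition covering
every residue exactly once, positioned so the planted junction's residue
falls in the requested domain.

Cohort model: per sample and LSV, PSI ~ Dirichlet(concentration × group
truth) with exact zeros preserved (so tumor-only plants have exactly zero
normal reads — the filter's hard guarantee is testable), depth ~
Poisson(mean coverage), counts ~ Multinomial. Defaults: 30 genes, 10 tumor
(alternating primary/recurrent) + 10 normal samples, 100 reads/LSV,
concentration 50 (sample-to-sample PSI s.d. ≈ 0.06 at Ψ = 0.5 — visible
overdispersion without swamping the group signal), 60 cells in each of five
types, 60 nt reads. Planted tumor PSI for tumor-only events is drawn from
U(0.3, 0.6): comfortably above the 10% floor, below fixation. The two
recurrent-enriched background events use shifts of ≈ 0.5 PSI so the
primary-vs-recurrent contrast is detectable at the 5 + 5 sample scale — a
mixture-pooled group posterior needs large effects at small n.

Single-cell reads are exact substrings of spliced isoform sequences, with
junction-spanning reads emitted only from permitted cell types; a planted
stem bias b scales the stem-cell expression rate (b = 2 emulates the
two-fold stem enrichment the screen should detect). Background reads from
annotated transcripts exercise the matcher's rejection path. The peptide
database contains the junction peptides of in-database plants plus seeded
noise peptides guaranteed not to contain any candidate junction peptide.

What the synthetic data does **not** emulate: sequencing error and base
qualities, alignment artifacts, UMI/platform structure, intron-retention
evidence from coverage, isoform diversity beyond one event per gene,
realistic inter-gene homology, and mass-spectrometry detectability biases
(trypsin cleavage). Green tests therefore certify the statistical and
combinatorial machinery — posterior calibration, filter logic, coordinate
arithmetic, matcher equivalence, determinism — not performance on real
reads, where alignment error and annotation incompleteness dominate.

## Degenerate inputs and tie-breaks

Zero-count LSVs return the prior (uniform) posterior, flagged
unquantifiable. Groups with no quantifiable sample average all samples but
are unquantifiable. Empty cell types yield missing frequencies; a zero
differentiated fraction with positive stem fraction reports ∞. Read-to-
junction ties break by longest overhang, then lexicographic junction id;
motif rank ties by total hits, then motif id. A palindromic peptide's decoy
is a seeded shuffle; a fully degenerate (single-residue) peptide keeps its
reversal. Junction keys are `contig:donor-acceptor:strand` with 0-based
half-open coordinates and donor < acceptor on the contig.

## Pipeline scale

The default end-to-end run (30 genes, 20 samples, 300 cells) completes in a
few seconds; the statistical verification experiments (1000-LSV CI
calibration, Monte-Carlo ΔPSI comparison, 100-gene recovery cohort) were
sized to make sampling noise negligible relative to their tolerances while
keeping a full run under a minute.
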