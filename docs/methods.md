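# Methods

`mitocomp` implements the comparative characterization of annotated
insect mitochondrial genomes: composition and strand asymmetry, codon
usage under the invertebrate mitochondrial code, structural metrics of
the circular molecule, alignment-based divergence statistics, and
distance-based phylogenetic checks. This note documents the models,
conventions, numerical choices, and what the synthetic study can and
cannot show.

## Data model and coordinate conventions

All coordinates are 0-based half-open on the deposited forward (J)
strand; GenBank's 1-based inclusive locations and the TSV feature
table's 1-based coordinates are converted at the I/O boundary. A
feature on the minority (N) strand stores its interval on the deposited
strand; its sense sequence is the reverse complement of the slice. A
feature may wrap the replication origin of the circular molecule
(`start > end` plus a flag); its sequence concatenates tail + head
before orientation. Gene names are normalized to a canonical 37-symbol
set through a shipped synonym table (COX1 → COI, rrnL → rRNA-16S, …);
unknown names are kept with a warning so partially annotated records
stay usable. The serine and leucine tRNA paralogs are disambiguated by
anticodon class when one is annotated (Ser1 = GCU class reading AGN,
Ser2 = UGA class reading UCN; Leu1 = UAG class, Leu2 = UAA class).

## Composition and skew

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed from
raw counts (identical to the percentage form; the scale cancels).
Ambiguity code N never enters a numerator or denominator; an empty or
all-N category yields NaN rather than zero. Per-gene and per-class
statistics use SENSE-strand sequences concatenated in genome order:
this is the convention under which protein-coding genes show their
characteristic negative AT-skews while positive GC-skews appear only in
minority-strand genes. Whole-genome statistics are computed on the
deposited strand and are rotation-invariant. Codon-position statistics
drop incomplete terminal codons (with a warning) from the
codon-position tally only.

## Codon usage

Everything runs under NCBI translation table 5 (AGA/AGG = Ser giving an
8-codon serine family, ATA = Met, TGA = Trp, stops = {TAA, TAG}, 62
sense codons). RSCU(c) = count(c) × |family| / family_total; family
values sum to the family size whenever the family is observed, and an
unobserved family reports 0 for all members. Two codon tallies are
kept: all complete codons (concatenated PCG length / 3) and the
stop-excluded count; the former is the headline "codons in use" figure,
the latter is what RSCU and amino-acid frequencies are built on. The
average RSCU across genomes is the unweighted mean of per-genome RSCU
values; pooled-count RSCU is available by summing tables first. RSCU
tables display codons in the RNA alphabet (UUA, not TTA); storage is
DNA. Start codons are classified ATN / TTG / GTG / other; stops as
complete TAA / complete TAG / incomplete T/TA (a CDS length ≢ 0 mod 3
ending in T or TA is taken as a polyadenylation-completed stop).

## Structural metrics

Consecutive features in circular start order define gaps
g = next.start − prev.end (mod genome length): g > 0 is an intergenic
spacer, g < 0 an overlap kept in a separate list, so "non-coding
nucleotides" sums positive gaps only. The circular conservation
identity Σ features + Σ spacers − Σ overlaps = genome length holds
exactly. Gene-order strings are rotation-normalized (anchored at
tRNA-Ile) with +/− strand signs.

tRNA secondary structures are input, not predicted: a 2-line-per-tRNA
text format (name, sequence, dot-bracket). Base pairs are classified
{AU, UA, GC, CG} Watson–Crick, {GU, UG} wobble, anything else a
mismatch with its identity recorded; T is read as U. Cloverleaf arms
are identified positionally from pairing topology alone: the outermost
stem is the acceptor; stems nested directly inside it are, 5′→3′, the
DHU, anticodon and TΨC arms. Exactly two internal stems is reported as
"DHU arm replaced by a loop" — the pattern of mitochondrial tRNA-Ser1.
No thermodynamic folding is performed.

## Divergence statistics

Nucleotide diversity π is the mean over row pairs of
(differences / sites compared), a site being compared only when both
rows carry an unambiguous base (pairwise deletion). The sliding window
uses 200-column windows at a 25-column step, window coordinates
1-based;
the trailing partial window is included and flagged rather than
dropped, and an alignment shorter than one window yields a single
whole-alignment window.

Distances: p, Jukes–Cantor (d = −3/4 ln(1 − 4p/3)), and Tamura–Nei
(TN93) with purine/pyrimidine transition classes separated and base
frequencies averaged over the two rows of each pair (this per-pair
convention is cross-checked in the tests against `ape::dist.dna` run on
isolated pairs; `ape` on a full matrix pools frequencies across all
rows and differs in the 4th decimal). Log-domain violations yield NaN
with a warning, never a clamped value. TN93 stands in for composite-
likelihood distances, which require joint estimation across all pairs.

Nei–Gojobori (1986) counting: per codon, each position contributes the
fraction of its three single-base changes that are synonymous (changes
creating a stop count as nonsynonymous sites); site counts are averaged
over the two sequences. Differences between codons differing at k
positions average the synonymous/nonsynonymous steps over all k!
minimal pathways, excluding pathways through stop codons and
renormalizing (all pathways are used if every one is blocked). Codons
containing gaps, N, or a stop in either row are excluded pairwise.
pN = Nd/N and pS = Sd/S are Jukes–Cantor corrected; ω = dN/dS is NaN
when dS = 0 or a correction is out of domain. A consequence worth
knowing: under purely synonymous evolution, ω is exactly 0 only while
every codon carries at most one hit — two synonymous hits in one codon
can force pathway intermediates through nonsynonymous states, giving a
small positive Nd. The tests assert the exact-zero property under its
single-hit precondition.

## Phylogenetics

Neighbor joining is the classical Saitou–Nei algorithm on the Q
criterion with deterministic lowest-index tie-breaking, so identical
inputs give bit-identical trees; negative branch lengths are clamped to
0 with a warning. On additive matrices NJ recovers the generating
topology and branch lengths exactly (to numerical precision), which the
tests verify on random 4–8-taxon trees. Midpoint rooting places the
root halfway along the longest leaf-to-leaf path (diameter ties broken
by sorted leaf names); monophyly of a taxon set means some clade equals
it exactly. Newick serialization uses 17 significant digits so
write→read round-trips are exact.

The 13-PCG supermatrix concatenates sense-strand genes in the fixed
order ND2, COI, COII, ATP8, ATP6, COIII, ND3, ND5, ND4, ND4L, ND6,
CytB, ND1 with exact partition bounds; equal-length orthologs give an
identity alignment, unequal lengths give unaligned export material for
an external aligner (MAFFT or similar). Bayesian and maximum-likelihood
inference are deliberately out of scope: the module exports NEXUS with
an MrBayes block (nst=6 rates=gamma, 2 runs × 4 chains, 5,000,000
generations, sample frequency 1000, 25% burn-in), relaxed PHYLIP, and
RAxML-style `DNA, gene = start-end` partition lines. Support values are
the external tools' business.

## Synthetic data: what it emulates, and what it does not

`simulate_mitogenome` generates a circular ~15 kb molecule with the
typical insect arrangement of 13 PCGs / 22 tRNAs / 2 rRNAs on both
strands, anchored at tRNA-Ile. Default targets are the study
conditions: whole-genome AT 0.79, AT-skew +0.011, GC-skew −0.166,
third-codon-position AT 0.95, 24 intergenic spacers of 1–47 nt
(geometric-ish, mean ≈ 9 nt). Base probabilities are derived from the
AT/skew targets; PCG third positions are sampled from an AT-boosted
version preserving both skews, with the non-third-position AT solved so
the whole genome hits its target in expectation; minority-strand genes
are sampled from the complemented distribution on their sense strand so
the deposited strand keeps the target composition. PCGs start with ATN
(TTG for ATP6), end with TAA, and are internally stop-free. tRNAs are
built on a cloverleaf template (acceptor 7 bp, DHU 4 bp, anticodon and
TΨC 5 bp stems; lengths 64–74 nt) with per-pair wobble (0.04) and
mismatch (0.004) rates; tRNA-Ser1 uses the DHU-less template.

Because the codon constraints (stop avoidance, fixed terminal codons,
stem complementarity, wobble pairs) shift realized composition by up to
~0.01 in the skews, generation is two-pass: a pilot genome is measured
and the input probabilities corrected by the residual before the final
draw. The remaining deviation is sampling noise: for a single 15 kb
genome the GC-skew standard deviation is ≈ 0.019 (≈ 3.1 kb of G+C), so
targets are verified as means across seeds (10 seeds give a standard
error ≈ 0.006). A single genome's AT content (sd ≈ 0.004) is checked
directly at ±0.02.

What the generator does not emulate: real codon preference beyond the
third-position AT bias (so synthetic RSCU peaks near 3, not the
UUA ≈ 5.4 of real mosquito mitogenomes), amino-acid composition of real
proteins, the control region, gene overlaps, and indels. Passing tests
demonstrate correct statistics and estimator behavior, not that real
genomes look like the simulations.

`evolve_cds` evolves codon sequences by proposal/acceptance: Poisson
(branch length × sites) single-base proposals (transition bias κ,
default 1), accepted with probability 1 if synonymous, ω if
nonsynonymous, 0 if stop-creating. This approximates an MG94-style
process transparently but is not identical to it; with κ > 1 the
Nei–Gojobori estimator shows its known transition-bias underestimation,
which is why κ = 1 is the default study condition. Recovery bands used
in the tests: ω̂ ∈ [0.05, 0.2] at ω = 0.1 and [0.8, 1.25] at ω = 1.0
for 5,000 codons at divergence 0.2 (10 seeds).

`mutate_alignment` derives rows i.i.d. from an ancestor with per-site
substitution probability p (uniform among the three other bases);
the expected pairwise difference 2p(1−p) + ⅔p² and its standard error
are logged, and estimates are verified within 3 SE of the logged value.

`evolve_genome_family` evolves one ancestral genome along a known
Newick tree (default: a five-taxon ingroup — a cherry, two successive
earlier-diverging lineages — plus a distant outgroup, branch lengths
0.015–0.25). PCGs evolve under the codon process with per-gene ω
defaults ordered like the purifying-selection strength seen in mosquito
mitogenomes (COI 0.012 … ATP8 0.1); first and last codons are frozen so
start/stop classification survives; everything else evolves neutrally.
Substitution-only evolution keeps coordinates identical across taxa, so
orthologs identity-align — real orthologs of unequal length require an
external aligner by design.

## Reproducibility

One integer seed drives every stochastic component through
`numpy.random.default_rng`; derived sub-seeds are fixed offsets of it.
Identical seeds give byte-identical genomes, truth logs, pipeline
outputs and trees. All rounding is presentational; internal values are
kept at full precision. Stochastic test tolerances are computed from
logged truth (closed forms and standard errors), not tuned constants,
except the two documented ω recovery bands above.

## Known limitations

- The ungapped codon aligner only accepts equal-length orthologs;
  real-data dN/dS and supermatrix stages need externally aligned input
  when lengths differ.
- TN93 per-pair frequency estimation differs from pooled-frequency
  implementations in the 3rd–4th decimal on short alignments.
- The reported-value checks against the deposited *Haemagogus* records
  require downloading those GenBank files
  (`python scripts/fetch_accessions.py`); they are not redistributed
  with the package.
- NG86 with pathway averaging is a counting method; it underestimates ω
  under strong transition bias and is not a substitute for
  likelihood-based codon models.
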