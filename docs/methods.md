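# Methods

## Segment model and mining

K- and Y-segments are modelled as ungapped position frequency matrices
(PFMs).  `build_pfm` tallies equal-length seed strings column by column and
adds a flat pseudocount (default 0.5) to every symbol of every column, so a
column sums to `n_seeds + 20 × 0.5`.  A window is scored by the log-odds sum
`S(w) = Σ_j log2(p_j(w_j) / b(w_j))` in bits, where `p_j` is the smoothed
column frequency and `b` the background composition.

**Scanning background.**  Segment scanning scores against a *uniform*
residue background (1/20 per amino acid).  Against a skewed composition the
per-column log-odds argmax is dominated by rare residues (W, C): the
"maximum achievable score" then belongs to a window of rare residues rather
than the consensus, which both breaks the identity "the count-argmax word
scores 1" and pushes genuine segment instances far below any fixed relative
threshold.  With a uniform background the log-odds argmax equals the count
argmax and the consensus word is the best-scoring window.  The skewed
(globular-average) composition is still used where composition is the
question: the synthetic background proteins and the biochemical contrast.

**Relative score.**  A hit's relative score is min–max scaled:
`(S − S_min) / (S_max − S_min)` over the best and worst achievable window
scores, in [0, 1] — the standard relative score of PWM scanning toolkits.
Plain division by the maximum makes the scale depend on how negative the
unobserved-residue penalty happens to be, so the same fixed threshold tags
very different divergence levels as the seed pool grows; min–max scaling
keeps a 0.7 threshold meaning "about 70% of the way from the worst to the
best window" throughout the iteration.  The consensus word still scores
exactly 1.  The default threshold is 0.7 for both K- and Y-segment mining
(recall-oriented; both are exposed in the pipeline config).  At a 10%
per-position substitution rate this recovers K-segments with up to ~5 of 15
positions substituted and Y-segments with up to ~2 of 7.

**Iterative expansion.**  Each round rebuilds the PFM from the deduplicated
seed pool (exact-string, global deduplication), rescans every protein, and
adds hit substrings not yet in the pool; the loop stops when a round adds
nothing new (or after `max_rounds`, default 10).  The pool is a set of
fixed-length strings over a finite alphabet and only grows, so termination
is guaranteed.  The threshold is held fixed across rounds to prevent
profile drift.  On the synthetic proteomes the search converges in two
rounds.

S-segments are maximal runs of ≥ 3 serines (regular expression), scored by
run length.

## Classification

Overlapping hits are resolved greedily: descending score (S hits scored by
run length), ties broken by leftmost start, then K > Y > S.  The surviving
ordered kind string is classified by the grammar `K+ → K_n`, `K+S+ → KS`,
`S+K+ → SK_n`, `Y+K+ → Y_nK_n`, `Y+S+K+ → Y_nSK_n`; everything else —
including any architecture without a K-segment, a Y after a K, or an S
interleaved between K's — is `unclassified` rather than forced into a
class.  Formulas print multiplicities (`Y2SK3`); multiple S runs are not
encoded in the name (a bare `S`), matching how the class names are written.

Alignment validation uses a self-contained Gotoh global aligner (BLOSUM62,
gap open 10, gap extend 0.5; a gap of length L costs `10 + 0.5(L−1)`; end
gaps are penalised like internal ones, i.e. a true global alignment).
Traceback tie-break: diagonal, then gap in the reference, then gap in the
candidate.  Identity is identical aligned pairs over alignment columns;
similarity counts pairs with a positive substitution score.  Scores are
verified exactly against Biopython's `PairwiseAligner` in the tests.

## Promoter extraction

Internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted once at the parsing boundary.  The anchor is the
5' end of the mRNA feature when present, else the gene feature, else the
CDS start.  For a + strand gene the promoter is `[max(0, tss−L), tss)`;
for a − strand gene `[tss+1, min(contig_end, tss+1+L))`
reverse-complemented, so the sequence always reads 5'→3' toward the gene.
`L` defaults to 1000 bp; promoters clipped by a contig edge are flagged
truncated.  N bases are kept verbatim; promoters over 50% N are excluded
from discovery.  Promoters are *not* truncated at upstream neighbouring
genes.

## Biochemical profile

GRAVY is the mean Kyte–Doolittle hydropathy over standard residues
(ambiguous residues B/Z/X/U are dropped from numerator and denominator
with a logged count).  The disorder scorer is deliberately *not* IUPred
(whose pairwise energy-estimation matrices are out of scope): over a
centred 21-residue window (clipped at the ends) it computes the scaled
mean hydropathy `<H> = (mean KD + 4.5)/9` and the mean net charge
magnitude `|<R>|` (K, R = +1; D, E = −1), forms the fold index
`I = 2.785·<H> − |<R>| − 1.151` (the charge–hydropathy boundary line), and
maps it to `score = clamp(0.5 − I, 0, 1)`, so score > 0.5 ⇔ predicted
disorder, preserving the usual decision rule.  The scorer is pluggable
(`disorder_proportion(scorer=...)`).  Consequently the absolute disorder
percentages of IUPred-based analyses are not comparable — only the
direction and significance of the dehydrin-vs-background contrast are
meaningful here, and that is what the tests assert.

The group contrast uses Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom (Student's pooled test is available
as an option).  Two identical degenerate groups return t = 0, p = 1.

## Motif discovery

Words and their reverse complements are canonicalised to the
lexicographically smaller form before counting, so a promoter counts once
regardless of strand.  For each k in 6..10, every canonical k-mer present
in ≥ 2 foreground promoters is tested: with `b` of `B` background
promoters containing the word, the null presence rate is
`p0 = max((b+1)/(B+2), p_chance)`, where `p_chance` is the probability
that a promoter of the background's mean length contains the word under a
zero-order model of the background base composition (Poisson
approximation, both strands).  The floor is essential: candidate words are
selected on the same foreground counts being tested, and for long words
absent from the background the Laplace estimate alone is unrealistically
small, so chance words present in a handful of foreground promoters leak
through as discoveries (measured: 4 of 20 complete-null replicates
produced a false discovery without the floor, 0 of 20 with it).  The
zero-order floor plays the role of the background sequence model in de
novo discovery tools.  The p-value is the binomial upper tail
`P(X ≥ n_with)`, `X ~ Bin(n_fg, p0)`; presence/absence per promoter (not
occurrence counts) matches n/N occurrence reporting.  Benjamini–Hochberg
runs once, jointly over all tested words of all k (the batch-size wording
was open; one joint batch is the more conservative reading), gate
q ≤ 0.01, ranking by q then observed/expected ratio.

Redundant words (substring/superstring or shift-by-≤2 overlap with ≥ 5
identical shared bases, either strand) collapse onto the better-ranked
seed.  Each surviving word is expanded into an occurrence PFM from all its
foreground occurrences ± 2 bp of flank (minus-strand matches
reverse-complemented; promoter-edge occurrences padded with N, excluded
column-wise, and flank columns with no observations at all dropped).  The
IUPAC consensus includes, per column, every base at frequency ≥ 0.25.

## Annotation

PFM–PFM alignment is ungapped: the score of an offset/orientation is the
mean per-column Pearson correlation of the frequency 4-vectors over the
overlap (≥ 5 columns), maximised over all offsets and both orientations;
ties prefer the smaller |offset|, then forward.  A zero-variance
(uninformative) column correlates 0 with everything, 1 with an identical
uninformative column.

Match significance is empirical.  A null replica of the query shuffles the
column order *and* permutes the base identities within every column —
preserving each column's information content while destroying both
arrangement and composition, i.e. an unrelated motif of equal complexity.
(A plain column-order shuffle keeps the exact columns, so any replica that
happens to contain a perfect five-column run scores exactly as well as the
true match; the empirical p-value then has a floor far above the
significance gate and no true match can ever pass.  Measured tie rates
under plain shuffling were 0.1–1.2% per replica for the short
repeated-base elements in the library.)  With n_null = 1000 replicas,
`p = (1 + #null ≥ observed)/(1 + n_null)` and `E = p × |library|`
(27 elements); matches at E ≤ 0.05 are reported.  Note the attainable
E-value floor is `|library|/(n_null+1)` ≈ 0.027, so n_null below ~540
would make the gate unreachable.

The bundled element library is a PLACE-style stand-in (27 named elements
with their IUPAC consensi and function notes), not a PLACE redistribution.
Clustering uses UPGMA on `1 − clip(best alignment score, 0, 1)` with a
0.25 cut; the representative minimises summed within-cluster distance,
ties broken by q-value.

## Synthetic data

The proteome generator assembles each dehydrin as linkers interleaved with
mutated segment instances in the class's canonical order (multiplicity
1–3 for `_n` parts; S runs of 5–8 serines; linkers 15–40 residues).
Linkers are drawn from the globular-average composition with
disorder-promoting residues (G, S, E, K, P, Q, T, H) weighted 2× and
renormalised; background proteins (80–300 residues) use the plain
globular average (Swiss-Prot mean composition, shipped as a fixture).
Substitutions are i.i.d. per position with no indels, keeping truth
coordinates exact.  Two guards keep the planted truth *true*: linkers are
rejection-sampled so they contain no serine triple and contribute no
serine adjacent to an S-segment (either would silently create or extend
an S-run), and a mutated S-segment must retain a run of ≥ 3 serines — an
S-segment that lost its defining run would no longer be an S-segment and
its truth label would be false.  K/Y segments are *not* protected:
heavily mutated instances that fall below threshold are legitimate
detection failures.

The genome generator places one gene per random 6 kb contig, on either
strand, with a chosen fraction of genes given 50–999 bp of upstream
sequence (the near-edge, truncated-promoter case).  The promoter generator
plants at most one copy of a word per promoter, at a uniform position on a
uniform strand, in otherwise i.i.d. uniform A/C/G/T sequence.

What the generators do not emulate: realistic genome composition
(isochores, repeats, GC skew), splice structure, orthology between
species, positional bias of real promoter elements, and the correlated
residue structure of real proteins.  Passing tests therefore demonstrate
the correctness and statistical calibration of the machinery under known
truth, not performance on real genomes.

## Pipeline and problem sizes

The pipeline replays the study at desk scale with one seed: 200 background
proteins + 50 planted dehydrins (10 per class, substitution rate 0.1),
a 50-gene genome, per-class promoter pools of 40 (the real class sets hold
21–123 promoters) with class-specific planted words realising element
cores (LTRE `ACCGACA`, I-box `GATAAGR`, CRT `RCCGACC`, G-box/ABRE cores),
and a 1000-promoter background pool.  Identical config + seed reproduces
every output byte for byte; each run writes its resolved config, per-stage
timings and a log.  A q-gate of 0 yields empty motif tables and a clean
exit.

## Known limitations

* The discovery statistic tests presence/absence, so it cannot separate
  one occurrence per promoter from many, and words shorter than `k_min`
  are only visible through their flank extensions — a planted word shorter
  than 6 bp dilutes across eight 1-bp extensions and is effectively
  undetectable against a 1000 bp uniform background (see the ledgered
  analysis of the headline planted-word condition).
* The empirical E-value cannot go below `|library|/(n_null+1)`.
* The disorder percentages are not IUPred-comparable (direction only).
* Global alignment percentages depend on the traceback tie-break among
  co-optimal alignments; scores do not.
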