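# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinates and genome model

Internally all features are 0-based, half-open on the reference (heavy)
strand; every file format read or written is 1-based inclusive (the GenBank
dialect). Origin-spanning features carry a `wrapped` flag with `end <
start`; their sequence is the concatenation of the two arcs. Layout gaps are
computed on reference coordinates regardless of coding strand — published
overlap counts mix strands (e.g. adjacent tRNAs on opposite strands) — and
the circular junction between the last and first feature is included, since
the molecule has no natural end. A gap of 0 counts as neither overlap nor
spacer. The two Leu and two Ser tRNA isoacceptors are disambiguated
positionally when a source annotation gives only the bare amino acid: in the
conserved vertebrate arrangement Leu(UUR) precedes Leu(CUN) and Ser(UCN)
precedes Ser(AGY) on the reference strand.

## Composition and skew

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C). A zero denominator yields a
missing value, never an exception. N and other ambiguity codes count toward
sequence totals but are excluded from skew denominators and from the A/C/G/T
percentage numerators. Protein-coding genes are profiled on the coding
strand by default, so the one light-strand gene (ND6) is reported in its own
reading sense; a switch reports reference-strand values instead (the choice
matters only for the sign of ND6's skews). Cohort dispersion uses the
population SD (divisor n): the cohort is treated as the complete set of
genomes under study, not a sample from a larger one, and the bundled
published summary values reproduce exactly under this convention. Tables
round to 2 decimals to match the usual published granularity; internal
values keep full precision.

## Codon usage

The genetic code is Biopython's vertebrate mitochondrial table (AGA/AGG
stop, TGA = Trp, ATA = Met; starts {ATG, GTG, ATT, ATC, ATA}). A gene whose
coding length is 1 or 2 beyond a codon multiple and ends in `T`/`TA` is
classified as carrying an incomplete stop (`T--`/`TA-`), completed to TAA by
post-transcriptional polyadenylation; summary tallies pool both truncated
forms into one `T-` class. Single-nucleotide frameshift insertions listed on
a feature (the avian ND3 extra C at gene position 174) are excised before
framing, treating the insertion as untranslated. Genes whose annotated frame
yields an internal stop are flagged and excluded from usage tallies with a
logged warning rather than silently reframed.

## Site variation and distances

A column is constant (one state), parsimony-informative (≥ 2 states each in
≥ 2 sequences), or a singleton (variable but not informative); percentages
are reported against analyzed columns. The default deletion policy is
complete deletion — any column containing a gap or N is excluded — matching
the usual practice of computing these statistics after removing stop codons
and indels; pairwise deletion is available. p-distance is mismatches over
compared sites. Neighbor joining uses the standard Q-criterion with branch
lengths from the usual formulas, negative branch lengths clamped to zero,
and ties broken deterministically by the lexicographic order of the pair's
smallest member labels, so reruns are byte-identical. NJ is included as
plumbing for qualitative topology checks (e.g. suborder monophyly), not as
a substitute for likelihood or Bayesian inference.

## Selection (NG86)

Potential synonymous sites per codon are per-position fractions of
single-nucleotide changes that preserve the amino acid, computed over the
changes that do not create a stop (each position still contributes exactly
one site, so S + N = 3). Observed differences at multi-hit codons are
averaged over all orderings of the single changes with equal weights;
pathways through stop codons are excluded, and a codon pair whose pathways
all cross a stop is skipped entirely. Proportions are corrected with
Jukes–Cantor, undefined at p ≥ 3/4. The gene-level ω is the ratio of means
(mean pairwise dN over mean pairwise dS), not the mean of ratios: with many
near-zero pairwise dS values the mean-of-ratios is unstable, while the
ratio of means behaves like a counting estimator pooled over pairs. All
pairwise estimates come from a precomputed 64×64 codon-pair table, so
gene-level runs are linear in alignment size.

Two estimator properties worth knowing: (1) with ω = 0 the true
nonsynonymous substitution count is zero, yet pathway averaging attributes a
small nonsynonymous fraction to purely synonymous double hits (CTC→TTA via
the TTC intermediate), so estimated Ka is near but not exactly zero; (2)
classic NG86 uses no transition/transversion weighting, so under transition
bias ω is mildly underestimated (about 15–20 % at κ = 2 in the recovery
experiments below).

## Tandem repeats

Only exact repeats are detected: a reported span satisfies
`seq[i] == seq[i − period]` throughout, so every call is verifiable by
direct string comparison and the detector has an unambiguous brute-force
oracle. This diverges from the mismatch-tolerant alignment scoring of the
classic repeat-finder programs; degraded copies truncate a run here instead
of being absorbed, so repeat inventories on real control regions can differ
from published tool output in count, though prevalence orderings of the
dominant motifs are robust. Defaults: period 2–200 (period 1 excluded, so
homopolymers surface as period-2 calls), ≥ 2.0 copies with fractional final
copies allowed, span ≥ 8. Overlapping candidate runs are resolved greedily:
longest span, then smallest period, then leftmost start. Motifs are
canonicalized to their least rotation so phase-shifted tallies merge.

## tRNA folding

The cloverleaf model: 7-bp acceptor stem, D-arm (3–4 bp stem, 4–12 nt
loop) or a 4–12 nt replacement loop in the D-armless model, 5-bp anticodon
stem with a 7-nt loop (anticodon at loop positions 3–5), 3–23 nt variable
region, T-arm (4–5 bp stem, 5–9 nt loop), and one unpaired discriminator at
the 3′ end (the CCA tail is not mitochondrially encoded). Scoring is integer
(G·C = 3, A·T = 2, G·U = 1); each stem tolerates at most one mismatch,
scored 0. The search enumerates every admissible arm partition — a few
hundred per sequence — and is therefore already exhaustive; integer scores
keep the optimum exactly reproducible. The D-armless model competes only
when allowed and wins only on a strictly higher score; remaining ties
prefer the canonical model, then the smaller D-loop, then the smaller
variable region. Thermodynamic (nearest-neighbour energy) folding and tRNA
gene discovery are out of scope by design.

## Synthetic data

The generator emulates the statistical structure the analyses assume, with
defaults chosen as study-style conditions: the conserved avian gene order
(37 genes + CR; ND6 and eight tRNAs on the light strand), typical shorebird
PCG lengths (ATP8 168 bp … ND5 1818 bp; COIII and ND4 ending on `T--`),
planted starts/stops (GTG for COI and ND5, ATT for ND3, ATG elsewhere; the
observed mix of TAA/TAG/AGA/AGG stops), the ND3 extra C, overlaps
ATP8/ATP6 −10 and ATP6/COIII −1, control-region arrays AAACAAC×8 and
AAAC×6, and a D-armless tRNA-Ser(AGY).

Composition control is by exact-count sampling: a shuffled base multiset
matching the per-region targets, so regions of a few hundred bp land within
fractions of a percentage point of target (the contract is ±1.5 points for
regions ≥ 300 bp). In-frame stop codons are repaired by swapping a base with
another position rather than overwriting, preserving counts; control-region
unique blocks draw from a pool whose counts compensate for the A/C-rich
planted arrays, and the assembled region is verified to contain exactly the
planted repeats (redrawn otherwise). Overlaps are realized as shared
sequence with downstream precedence: the downstream head is drawn so it
spells no stop in the upstream frame, and the upstream tail is forced equal
to it, so planted codons survive assembly exactly.

The codon evolver is an exact per-site Gillespie simulation under thinned
rates: transitions weighted 3κ/(κ+2) and transversions 3/(κ+2) (mean
nucleotide rate 1), nonsynonymous changes further multiplied by ω, changes
into stops rejected outright. A branch of length b therefore yields about b
substitutions per codon site at ω = 1. The default κ = 2 is a conventional
modest transition bias; vertebrate mitochondria often show stronger bias,
under which NG86's unweighted pathway counting would be more biased (a
documented estimator limitation, not a generator artifact). Cohorts evolve
each gene along one shared random tree (default branch lengths uniform in
0.02–0.08, giving pairwise distances broadly like a within-order cohort)
with per-gene ω defaults that mirror the purifying-selection gradient seen
in shorebird mitogenomes (COI 0.01 … ATP8 0.16). First/last and
junction-overlapping codons are frozen during evolution; tRNAs are
redesigned per taxon (D-loop lengths vary, structural class does not),
rRNAs accumulate light point substitution, and control regions vary in
unique-block length, which is what varies cohort genome sizes.

Deliberately not modelled: indels, rearrangement, among-site rate
heterogeneity, dinucleotide composition structure, and realistic repeat
degradation. Passing recovery tests on this generator therefore demonstrates
correctness of the estimators under the stated model, not robustness to
alignment error or heterotachy in real data.

## Problem sizes and verification

The test suite checks every bespoke algorithm against an independent
brute-force oracle written from the definitions: NG86 against recursive
pathway enumeration (200 random 30-codon pairs), site classification
against per-column counting (200 random 6×30 alignments), repeat detection
against a naive per-(start, period) enumerator (100 strings of 300 bp),
folding against nested-loop partition enumeration (50 sequences ≤ 75 nt),
and NJ against 50 random additive trees (Robinson–Foulds distance 0
required). Parameter recovery runs the evolver at ω ∈ {0.05, 0.2, 1.0}, 20
taxa × 500 codons × 20 seeds, requiring medians within ±30 % and rank-order
recovery in ≥ 19/20 seed sets; planted codons, repeats and fold classes
must be recovered exactly on a 20-genome cohort. Two further checks
recompute published per-accession quantities and the three-suborder NJ
topology from the 20 GenBank records; since the package redistributes no
third-party sequence data, those two require fetching the records first
(`scripts/fetch_accessions.py`) and fail with an explanatory message when
the records are absent.
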