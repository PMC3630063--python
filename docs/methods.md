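# Methods

This note documents the models, parameter choices and numerical decisions
behind plantmir, and what the synthetic studies do and do not establish
about real data.

## Study design being modeled

Two small-RNA libraries (control and drought-stressed leaf tissue), each a
single sequencing run of pooled RNA, plus two degradome (PARE) libraries
mapped against a transcriptome. There are no biological replicates — the
statistics are the single-library exact test and empirical shuffle
controls, exactly the regime the pipeline's original tools (SOAP, MFOLD,
psRNATarget-style scanning, CleaveLand) were built for.

## Read preprocessing

The 3′ adapter is removed at the leftmost exact occurrence of its first
8 nt; shorter suffix overlaps are left untrimmed, which keeps trimming
deterministic and unambiguous. Reads are kept when the insert is 18–30 nt
with mean Phred ≥ 20 (configurable; the quality threshold is a convention,
not a published value). Identical inserts collapse into unique tags with
per-library counts; T is mapped to U at the boundary and all analysis is in
RNA space. Mapping is exact-match on both strands via an 18-mer index with
verification; tags with more than 20 loci (configurable) are set aside as
repeat-derived. Annotation precedence is structural RNA (GFF3 locus
overlap, optionally sequence identity) > known miRNA (exact or ≤2-nt
end-shifted match to a catalog mature, the usual isomiR allowance) >
candidate. siRNA-like duplexes are reported for 22–24 nt tag pairs on
opposite strands whose 3′ ends each overhang the partner's paired region by
exactly 2 nt.

## Folding model

A deliberately simple, fully specified stacking model replaces a Turner
thermodynamic folder: nested structures only, pairs G:C/A:U/G:U, hairpin
loops ≥ 3, and energy only from stacked pair neighbours (G:C −3.0, A:U
−2.0, G:U −1.0 kcal/mol; a stack of two unlike pairs contributes the mean
of their values). Isolated pairs carry no energy, which suppresses the
scattered pairing a plain base-pair-maximization recursion would produce.
The optimum is computed by an O(n³) dynamic programme (integer arithmetic
in half-kcal units, so ties are exact; ties break toward the pairing with
the smallest 5′ index). The suite proves optimality against exhaustive
enumeration of all nested structures for sequences up to 15 nt. Published
MFOLD energies in the packaged catalog are fixture data and are not
reproduced by this model; the −30 kcal/mol stability threshold applies to
whichever folding backend is configured.

## Hairpin excision and the plant miRNA criteria

Candidate tags are extended into windows of 60–280 nt (step 20) with the
tag on either arm, covering the 80–272 nt precursor-length range of the
published catalog. A window is a hairpin candidate when ≥16 tag nucleotides
pair to one side of the tag in a single helix — operationally: consecutive
paired tag positions and their partners interrupted by ≤3 nt, with at most
4 bulged bases per strand across the helix footprint. This tight
definition matters: in random sequence, windows containing a fortuitous
16-pair one-sided helix for a given 21-mer occur at a rate of roughly one
per ten loci under a wobble-permissive pairing alphabet, so the stem test
alone cannot separate precursors from background; the downstream criteria
do. The best window per arm is kept (lowest MFE, ties to the shorter
window).

The miRNA* is derived from the structure under the canonical duplex
geometry: the star pairs mature positions 1..L−2 and both strands carry
2-nt 3′ overhangs; unpaired duplex ends are bridged by extrapolating the
helix register. Acceptance requires (in order) a definable star, star reads
observed (count ≥ 1 across libraries), ≤4 mismatched duplex positions with
no bulge >2 nt, and precursor MFE ≤ −30 kcal/mol. Because a sequenced star
passes the same symmetric criteria, acceptances whose precursor loci
overlap are merged and the more abundant tag is reported as the mature.
Families group identical mature sequences, with lettered variants per
locus.

## Exact differential-expression test

The test treats p(y|x) as a negative binomial in y (parameters x+1 and
N₂/(N₁+N₂)) and takes the smaller of the two tails. Numerics: terms are
evaluated as exp of log-gamma expressions and accumulated with `math.fsum`
(exact compensated summation); the upper tail uses the 1−Σ complement only
while that is well conditioned (≥10⁻²) and is otherwise re-summed forward
from k = y, which is cheap because the distribution mode then lies below y.
Agreement with direct long-double summation of the printed formula is
~10⁻¹¹ relative across the full range down to float64 underflow. The
two-tail minimum, taken literally from the formula, is *not* symmetric
under (x,N₁)↔(y,N₂) exchange — only the pmf itself is symmetric at N₁=N₂ —
and p is non-increasing away from x only up to an exact tie at the first
step.

Calls: tags below 1 RPM in *both* libraries are discarded (keeping on/off
tags, which single-library designs do report); a call needs |log₂ RPM
ratio| ≥ 1 and p ≤ 0.01. A Benjamini–Hochberg q column is emitted for
reference but does not gate calls, matching the no-correction practice of
the single-library lineage. A tag expressed in only one library is treated
as an infinite fold change with direction from the expressed side.

**Known limitation — overdispersion.** The exact test assumes sampling
noise only. Under negative-binomial extra-variance φ (var = μ + φμ²) it is
anticonservative at high counts: at φ = 0.05 the measured fraction of null
tags with p ≤ 0.01 is ~2% at mean 5, ~8% at mean 20 and ~20% at mean 50,
growing with the mean. Type-I behaviour is therefore only meaningful in
the low-count regime (φμ ≲ 1), and the suite's type-I check uses
star-like null abundances (means 1–10 per library) at φ = 0.05. The
counts-level recovery simulation models two single pooled libraries with
technical-scale dispersion φ = 0.01, DE miRNA means of 50–500 (the design
floor for qPCR-verifiable candidates) and null means of 5–50 (the
low-abundance band typical of novel-miRNA catalogs). With biological
replicates and gene-wise dispersion estimation this test should be
replaced wholesale — that is outside this package's design.

## Target prediction

Alignment is anti-parallel, positions counted from the miRNA 5′ end, with
at most one single-nucleotide bulge on either strand (window length L±1);
the bulge is placed to minimize the penalty, ties to the largest position
index. Penalty weights (mismatch 1, G:U 0.5, gap 2, positions 2–13
doubled) follow the established plant target-prediction lineage and are
configurable; the score cutoffs are < 2.5 for de novo prediction and < 4.0
for degradome-supported confirmation — published confirmation tables carry
scores up to 4, so the stricter threshold applies only to de novo scans.
Rules i–v are evaluated on the state vector (gaps count as
mismatch-equivalents of 1 in rules i/v and as mismatch-like in adjacency
rules; G:U is tolerated at positions 10–11); rule vi compares duplex
stacking energy against the miRNA's perfect complement (≥74%). Scanning is
vectorized (per-register penalty matrices + prefix sums over all window
starts) but provably equal to brute-force evaluation of every window; the
suite checks that equality on a 100-kb transcriptome.

## Degradome analysis

Reads (already 5′-adapter-trimmed) anchor by their first 20 nt at every
exact transcript match, one count per matching transcript. The cleavage
site of an alignment is the transcript position paired to miRNA nucleotide
10; support requires an exact 5′ end there (PARE is nucleotide-resolved; a
window option exists for noisy data). Category maximum/median statistics
are computed over positions with ≥1 read by default — a zero-inflated
median over all positions would make nearly every event category II — with
a switch for the all-positions variant. The shuffle control permutes the
miRNA (composition-preserving, seeded), rescans the transcriptome in
degradome mode, and succeeds when any supported event is at least as good
(penalty ≤ observed, reads ≥ observed); p = (1+s)/(1+n) with the +1
pseudocount avoiding p = 0 at finite n.

## Synthetic data: what it emulates, and what it does not

The generator plants hairpin precursors (perfect inverted-repeat stems of
36–60 bp with three G:U wobbles opposite the mature, loop 8 nt, LP 80–280)
on both strands of a 2×60-kb genome; wobbles keep the duplex paired while
breaking the palindrome, so mature and star map uniquely to one strand, as
real imperfect hairpins do. Mature/star duplexes obey the 2-nt 3′ overhang
geometry by construction. Libraries draw negative-binomial counts
(dispersion 0.05) around means scaled to 30 000 reads per library, append
the 3′ adapter, add 10% structural-RNA contaminant reads from annotated
rRNA/tRNA loci, planted 22–24 nt siRNA duplex pairs, and ~3% junk (short
inserts, low-quality reads). Drought means are control means times the
planted fold changes, *without* renormalizing library size — so planted
induction genuinely shifts the library total, and the exact test's calls
on the end-to-end run include composition-driven proportion shifts, as
they would in a real pair of libraries. Transcripts (20 × ~1 kb) carry one
exact-complement target site per miRNA; degradome reads start exactly at
the true cleavage position with probability `degradome_signal_fraction`
(default 0.7) and uniformly otherwise.

Not modeled: sequencing errors, quality-score realism, isomiR end
heterogeneity, multi-mapping repeat families beyond the contaminant
tracks, spliced transcripts, and partial (translational-repression-only)
target interactions. Passing the recovery suites therefore demonstrates
correctness of the algorithms under the stated generative model, not
performance on real libraries with those additional artefacts.

Simulated problem sizes (2×60-kb genome, 20 hairpins, 30 000 reads per
library, 10 000 degradome reads, 3 seeds) were chosen so a full recovery
study folds hundreds of windows and scans thousands of shuffles while the
whole suite stays comfortably interactive on a laptop.

## Reproducibility

Every stochastic component takes a seed; identical config + seed gives
byte-identical FASTA/FASTQ/JSON outputs and byte-stable pipeline TSVs. The
pipeline manifest records versions, parameters and input digests. The
display length range of library reports follows the simulator's 18–30 nt
output; narrower published display ranges are a reporting choice, not a
filter.
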