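# Methods

## Model and counting conventions

All coordinates are 0-based and half-open internally; the A of an AUG is
position 0 of its codon. Conversion to 1-based coordinates happens only
at format boundaries (wiggle output, SAM input). Footprints are assigned
a P-site at `five_prime_pos + offset` with a single offset (default
12 nt) for all read lengths of 25–34 nt: the dominant 5′-end position of
start-codon-engaged 48S complexes sits 12 nt upstream of the AUG across
lengths, and a per-length offset table can be supplied by users who
calibrate otherwise.

Window counts (mRPF `[−3,+6]`, iRPF `[+9, stop]`, cdsRPF `[0, stop]`,
uRPF `[5′ end, −5]`, all relative to the main AUG, endpoints inclusive)
are independent interval-membership counts: a read contributes to every
window containing its P-site. Note that the mRPF window straddles the
CDS start, so `cdsRPF ≥ mRPF` is not an identity — reads at −3..−1 are
mRPFs but not cdsRPFs; the exact partition is
`cdsRPF = (reads in [0,+6]) + (reads at +7,+8) + iRPF`. Transcripts with
a 5′UTR shorter than 5 nt have an empty uRPF window and count 0 rather
than being excluded, so translatome-level ratios are defined over the
same transcript universe in every sample. Internal AUGs are collected in
any reading frame (footprint counting is positional, not ORF-aware); an
`in_frame_only` flag restricts to in-frame AUGs for ORF semantics.

Mapping is exact-match by default, seeded by leading 12-mers, with
multimappers discarded; a one-mismatch mode re-seeds from the second
k-mer block. Real-data users can instead import transcriptome-space SAM
from any aligner (primary, forward-strand alignments only). Reads are
conserved exactly: assigned + no_linker + unknown_barcode +
out_of_length + unmapped + multimapped + off_end = total input.

## Spike-in normalization

Size factors are computed from the spike-in transcripts only: for each
sample, the geometric mean of 25–34 nt read counts over every spike-in
AUG site (the main AUG plus each internal AUG, each counted in its own
`[−3,+6]` window). Sites with zero reads in a sample are excluded from
that sample's geometric mean rather than pseudocounted (log 0 is
undefined); a sample with no spike-in reads at all is a hard error. All
samples are multiplied **up** to the sample with the highest geometric
mean — factors ≥ 1, reference factor exactly 1 — rather than
median-ratio-centered, preserving the absolute (constant spike-in
amount) interpretation of between-sample changes. The per-site (rather
than per-transcript-total) reading of the geometric mean is a documented
choice. For differential testing the factors are converted to
divisor-sense size factors `1/factor`, rescaled to geometric mean 1.

## Differential testing

The NB test is a deliberately self-contained member of the DESeq2
family: method-of-moments gene-wise dispersion on size-factor-scaled
counts (per condition, then averaged; floored at 1e-8), a mean–dispersion
trend `a0 + a1/μ` fitted by least squares with one outlier-trimming pass,
and gene-wise dispersions blended with the trend with weight
`w = min(1, 1/(n_min − 1))` (0.5 at three replicates per condition, fully
trended at two). The log2 fold change adds a 0.5-count stabilizer to each
condition's normalized mean; the same stabilized means are used in the
delta-method standard error `SE² = (1/μ_A + α)/n_A + (1/μ_B + α)/n_B`
(an unstabilized ratio is undefined whenever one condition is all
zeros). Omitted relative to DESeq2: Cox–Reid adjusted dispersion MLE,
LFC shrinkage, Cook's outlier filtering — so significant-gene counts
against a DESeq2 run agree approximately, not exactly (the test suite
cross-checks fold-change estimates against pyDESeq2 on planted effects).

The Wald statistic is referred to a t distribution with Satterthwaite
effective degrees of freedom `d_g/(1−w)²`, where `d_g = n_A + n_B − 2`:
the blended dispersion has `(1−w)²` times the sampling variance of the
gene-wise estimator, and a plain normal reference is measurably
anticonservative at three replicates (~6% type-I at nominal 5% in
repeated null simulations, vs ~4.5% for the moderated reference). At
`w = 1` (two replicates) the dispersion is fully trended and the
reference reduces to the normal.

BH correction is the standard step-up (via statsmodels); significance
classes require FDR < 0.05 **and** fold change > 2 (up) or < 0.5 (down).
Depth filtering by total raw reads across samples supports both strict
(`>`) and inclusive (`≥`) rules, as different experiment designs state
different cutoffs. RE and RRO changes — ratios of ratios the count model
does not cover — are tested by a paired bootstrap of per-replicate log2
ratios (10⁴ resamples, seeded); with three replicates this is a coarse
screen, floored at p = 1/resamples, and is reported separately from the
NB results.

Leaky-scanning calls require mRPF class `down`, iRPF class `up`, and
`ΔiRPF ≥ 0.5·|ΔmRPF|` on mean normalized counts ("at least 50%"
reciprocity, so the boundary case passes); the mirrored 5′UTR rule flags
uRPF-down/mRPF-up transcripts with `|ΔuRPF| ≥ 0.5·ΔmRPF`. Overlap
significance between gene sets is the exact hypergeometric upper tail
with a representation factor `observed/expected`.

## Feature analysis

PARS interval scores: `total` sums the 5′UTR; `max30` is the maximum
30 nt window sum over start positions `0..utr5_len−30`, falling back to
`total` for 5′UTRs under 30 nt; `start30` sums `[−15, +14]` around the
main AUG (defined for 5′UTRs ≥ 15 nt; the −15..+14 split of "the 30 nt
surrounding the start codon" is a documented choice); `plus15/30/45`
anchor at the A of the main AUG. The context score is the geometric mean
over the nine flanking positions −6..−1 and +4..+6 (1-based, start codon
at +1..+3; the invariant AUG itself is excluded since it only adds a
constant factor) of `f(b,i)/max_b′ f(b′,i)` from a position-frequency
matrix, which ships as a required TSV input — the matrix of highly
translated mRNAs is not reproduced from external data, and the synthetic
module emits a toy matrix. Equal-count binning sorts ascending (ties
broken by transcript id), splits into contiguous bins differing in size
by at most one with larger bins first, and absent metrics are excluded
listwise, never imputed.

## Synthetic data: what it emulates and what it does not

The generator's defaults define the standard desk-scale study: 200
transcripts (5′UTRs 15–150 nt, CDSs 300–900 nt, 50 nt 3′UTRs), two
conditions × three replicates, ~2×10⁵ footprint reads per unit-scale
library, per-sample library scales uniform in [0.6, 1.4], two spike-ins
at a ~1:10 ratio carrying 12 planted internal AUGs each (~10⁴ reads per
unit library, enough that geometric-mean factors recover planted scales
within 5%), NB count noise with per-transcript dispersion
Gamma-distributed around 0.05 (three-replicate shot-plus-overdispersion
structure), 10% planted leaky transcripts (main-AUG rate ×0.25 in the
helicase condition with 80% of the loss moved to a chosen internal AUG),
and 30% helicase-responsive transcripts whose control-condition
recruitment is suppressed by 2^(−0.3·burden) for a 5′UTR "structure
burden" uniform on [0, 10]; the synthetic PARS track sums to that burden
over the 5′UTR, concentrated in one 30 nt window so Max30 recovers it.
Footprint 5′ ends get jitter {0: 0.8, −1: 0.1, +1: 0.1} by default,
emulating the minority of shorter/longer protections seen in real
libraries; baseline internal initiation is 10% and upstream initiation
0.25% of the main-AUG rate, the latter matching the order of magnitude
of translatome-wide uRPF/mRPF ratios (~0.002). Footprint read lengths
are uniform on 25–34 nt — a placeholder, since the real length
distribution within that window is not modeled.

Not emulated: sequencing errors, PCR duplication, non-coding RNA
contamination, multi-isoform transcripts, genome-space alignment and
splicing, cap-proximal biases. Passing recovery tests therefore shows
the pipeline's arithmetic and statistics are correct under a faithful
noise model, not that real libraries are free of these additional
artifacts; real-data users should pre-filter ncRNA and may import
external alignments.

## Numerical and degenerate-input conventions

RE is absent (NaN), never zero, when mRNA density is zero; RRO is absent
when cdsRPF is zero; constant vectors have no Spearman coefficient;
all-zero genes in both conditions get no p-value (NaN propagates through
BH untouched). The GCN4-style exclusion list applies to the uRPF/mRPF
ratio only and removes the transcript from numerator and denominator.
Wiggle output emits one variableStep block per transcript, 1-based.
All randomness flows from a single seed through `numpy` spawned
generators; rerunning any stage with the same inputs and seed is
byte-identical, and the pipeline manifest records the config digest and
the SHA-256 of every output.

## Problem sizes used in the checks

The acceptance script and end-to-end tests run the standard study above
(~1.2×10⁶ footprint reads across six libraries, ~5×10⁴ input RNA reads
per sample), a 2 000-gene null simulation for test calibration, and a
60-transcript jitter-free study for the metagene geometry check; the
unit suite uses a 40-transcript study. These sizes were chosen so the
entire suite completes in well under a minute while leaving the
stochastic recovery margins wide (RE rank correlation ≈ 0.99 against a
>0.9 requirement; leaky recall 90–100% against ≥80%).
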