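# Methods

This note documents the models and procedures `snppanel` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Coordinates and containers

All positions are 1-based inclusive (VCF convention); BED export is the
only 0-based, half-open surface. Genotypes are alternate-allele dosages
in {0, 1, 2} with an explicit MISSING sentinel (−1), never conflated
with homozygous reference — call-rate and missingness statistics depend
on the distinction. Half-missing diploid VCF calls (`./0`) map to
MISSING; non-diploid records are rejected rather than coerced.

## Candidate screening

**Minor-allele frequency and ΔF.** MAF folds an alternate-allele
frequency to `min(f, 1 − f)`. ΔF is the *signed* MAF difference, breed
minus control, thresholded as ΔF ≥ threshold. The wording the thresholds
come from ("the MAFs of X minus the MAFs of Y") describes a signed
difference, so that is the default; an absolute-value mode is available
behind `DesignConfig.delta_f_absolute` for screens where either
direction of divergence is wanted. Default thresholds: 0.609 (local
breeds vs the commercial control) and 0.731 (commercial lines vs the
local control); the MAF floor is 0.05 in the focal breed. A locus
passing in several breeds is emitted once with the largest ΔF as its
score. Chromosome-W loci are excluded: pooled mixed-sex libraries make W
frequencies unreliable, and the panel targets autosomes plus Z.

**Association top fraction.** Per trait, the `ceil(fraction × n)`
smallest p-values are taken before the union over traits; `ceil` is used
so that small trait tables still contribute at least one marker. Ties in
p are broken by genomic position for determinism.

**Gene-based selection.** Markers within ±5 kb of a gene interval are
ranked by consequence class — missense/splice-region first, then
splicing, start/stop changes, UTRs, synonymous, up/downstream (1 kb),
intron, everything else — and at most 5 per gene are kept, ties broken by
ascending position. The full rank order beyond "coding, splicing and UTR
first" is this package's convention, chosen to follow standard
severity orderings of consequence annotations. A locus inside two genes'
(flanked) intervals may be nominated by both and is deduplicated at
emission, so a shared flank region can carry up to twice the per-gene
cap.

**Feed-efficiency (RFI) screen.** The Fst cut is the 0.95 empirical
quantile of the input table's own Fst column — "the top 5% kept" is the
only reading of the published filter consistent with the reduction it
reports — followed by a mean-ΔF floor of 0.35. A degenerate
(all-identical) Fst column makes the quantile uninformative; the screen
then warns and applies the ΔF floor alone.

**Fst estimator.** `wc_fst` is the two-population Weir–Cockerham (1984)
variance-components estimator in its allele-count form: with
per-population allele sample sizes n_i and frequencies p_i,
MSP = Σ n_i (p_i − p̄)², MSG = Σ n_i p_i (1 − p_i) / Σ (n_i − 1), and
θ = (MSP − MSG) / (MSP + (n_c − 1) MSG). The raw estimate (which can be
negative, or undefined when both populations are fixed for the same
allele) is returned alongside a [0, 1]-clamped value for reporting.
`wc_fst_multilocus` combines loci as the ratio of summed numerator and
denominator components — the standard combination; averaging per-locus
ratios is biased downward at modest sample sizes (visible at 96 alleles
per pool).

**Assembly.** Deduplication at a shared (chrom, pos) follows priority
(P1 > P2 > BACKGROUND), then a fixed group order (gwas, candidate gene,
RFI, resequencing, snpdb) for determinism. Losing sources are recorded
on the winning record (`other_groups`); conflicting alleles at one
position raise a warning and the higher-precedence record wins.

## Panel design

The genome is walked per chromosome in windows of `window_length`
(default 22,000 bp). The placement criterion for a crowded window is the
positional variance SD² of the point set {window start, window end,
chosen positions}, divisor equal to the point-set size (4 for a pair, 3
for a single). Minimising this printed formula prefers candidates near
the window midpoint rather than an evenly spread pair; the
implementation follows the formula as printed, and an exhaustive
brute-force search over all pairs serves as the oracle in tests.

Window advancement: after a window that selected markers, the next
window starts at the rightmost selected position ("the backward window
starts from the probe position"); after an empty window, at the window
end. Consequently consecutive windows may overlap, and a candidate
rejected by the pair rule can be reconsidered — and selected — in the
following window; this keeps inter-marker spacing bounded, which is the
stated goal of the procedure. Ledger window starts are strictly
increasing; in the degenerate case where the only selection sits exactly
on the window start, the next window starts at the window end instead.
The terminal partial window of a chromosome is treated like any other.

Pass rules: priority-1 windows keep 1–2 markers (exhaustive SD²
minimisation at ≥3 candidates, ties broken by the lexicographically
smallest pair); whitelisted special-interest indels are force-selected
even beyond the pair limit and count toward occupancy. The priority-2
pass fills only windows that reserved nothing (a window whose priority-1
candidates were all rejected still counts as filled only if it kept at
least one — rejection leaves it empty and fillable only when no marker
was reserved, which cannot happen under the a/b/c rules). The background
pass fills remaining empty windows with one database marker, preferring
assay-validated markers, then proximity to the window midpoint, then the
lower position. Every selection is deterministic for fixed inputs; the
manifest writer is byte-stable.

A terminal chromosome-end sliver shorter than the window length may
contain no background marker at all and then legitimately stays empty;
coverage properties are therefore stated over full-length windows.

## Panel reporting

Mean adjacent distance per chromosome is the mean of successive position
differences divided by 1,000 (the plausible alternative —
chromosome length over count — is noted but not used). Percentages and
kilobase distances are rounded half-up at two decimals, integer percents
for overlaps, matching the printed-table conventions the summaries are
checked against. Overlap between panels is exact (chrom, pos) key
matching with all Venn regions reported; the pairwise percent is
relative to the first panel of the ordered pair.

The `published` module carries the released 55K array's per-chromosome
counts, source-group composition, annotation-class counts and
cross-array overlap counts, plus a *synthetic reconstruction* of a panel
with exactly those summary properties (positions are evenly spaced
stand-ins, as the released coordinates are not bundled). The
reconstruction exists so the report arithmetic can be exercised against
the published totals; nothing else consumes it.

## Genotype evaluation

QC removes samples with missing rate above 10% and markers failing call
rate (< 95%), MAF (< 0.05; a marker at exactly 0.05 is kept) or the
exact Hardy–Weinberg test (p < 0.001), in that order of reasons, each
removal carrying exactly one primary reason. Because removing markers
can raise a sample's missing rate and vice versa, the sample and marker
passes iterate to a fixpoint, which makes the filter idempotent by
construction. Marker HWE is computed within populations when labels
exist (pooled HWE conflates structure with typing error) and the
minimum per-population p is compared to the threshold; with no labels
the pooled counts are used.

The HWE test is the exact conditional test on the observed allele
counts: the p-value sums the probabilities of all heterozygote counts
whose conditional probability does not exceed the observed one (no
mid-p). The distribution is evaluated by the standard two-sided
recurrence anchored near its mode, so unnormalised terms neither
overflow nor lose the mass that matters; a 1 + 1e−12 relative guard on
the "≤ observed" comparison absorbs float noise in ties. Monomorphic
markers return p = 1.

Polymorphism summaries report, per population: the mean per-marker call
rate (the published table does not say whether its call rates average
over samples or markers; per-marker is used and documented), the count
of loci with within-population MAF strictly above 0.05, and the mean MAF
over *all* loci (all-missing loci contribute 0).

## Population structure and LD

IBS distance between two samples is one minus the mean allele-sharing
fraction 1 − |g_i − g_j|/2 over mutually called loci; a pair sharing no
called locus is an error rather than a silent 0. MDS is classical
Torgerson scaling (double-centre −½D², eigendecompose, scale
eigenvectors by √eigenvalue); negative eigenvalues — possible because
IBS distances need not be Euclidean — are truncated to zero with a
warning. Coordinates are defined up to sign and rotation.

r² is the squared Pearson correlation of dosage vectors over mutually
called samples (the composite estimator standard in array QC for
unphased data; EM haplotype-based r² is out of scope). Pairs where
either column is constant are undefined and excluded from bin means
rather than zero-filled. LD decay bins all intra-chromosome pairs within
40 kb into 5 kb bins by default.

## Synthetic data

The generator emulates the study conditions the toolkit was built
around: eight pooled breeds (five local, three commercial) of 48
diploids each, pooled-frequency estimates with binomial noise at 2 × 48
allele draws, breed differentiation from the Balding–Nichols model
(Beta(p(1−F)/F, (1−p)(1−F)/F) around a uniform [0.05, 0.95] ancestral
frequency) with target Fst 0.15 — a typical local-vs-commercial chicken
contrast — validation cohorts of 18 samples per population (the real
cohorts held 15–21), 2.5% missingness (real call rates ranged 97.0–98.7%),
and strong short-range LD via first-order haplotype copying (rate 0.9 at
2 kb spacing). Balding–Nichols was chosen for its analytic Fst control,
which the parameter-recovery tests exploit; copying was chosen as the
cheapest LD model with monotone distance decay.

The design fixture is a desk-scale genome (three chromosomes totalling
4.5 Mb, ≈ 205 design windows) with candidate densities mirroring the
real design's per-window proportions: ≈ 0.5 priority-1 and ≈ 2.6
priority-2 candidates per 22 kb window and a dense background database,
with 5 whitelisted indels standing in for the 25 special-interest ones.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: linked selection and real
LD-block structure (copying gives geometric decay only), clustering of
differential SNPs into divergent regions (candidates are uniform, so the
background pass fills fewer windows than in the real design),
genotyping-batch and probe-chemistry artefacts, allele-frequency
spectra of real populations, and assembly/liftover error. Note also that
the copying model does not preserve per-locus marginal frequencies (each
allele copies its left neighbour with the copy rate), so
frequency-recovery tests use the no-LD configuration.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep the full
suite fast while leaving every statistical check well-powered: 10,000
loci for Fst recovery, 10,000 replicates at n = 500 for exact-test
calibration, 2,000 loci × 60 samples for population recovery, 200
random windows (≤ 50 candidates) for the placement oracle, and the
4.5 Mb fixture genome for end-to-end design runs.
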