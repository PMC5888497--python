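# Methods

`guidemeth` analyses whole-genome bisulfite sequencing (WGBS) of cells
transfected with RNA-guided dCas9 methyltransferases — catalytically dead
Cas9 fused to the DNMT3A or DNMT3B catalytic domain — to characterise where
the enzymes deposit CpG methylation on target and off target.  Because the
full experiment (nine transfection groups, >30x human WGBS) is not
reproducible at desk scale, the package ships a first-class synthetic-data
generator that emulates the study design with known injected effects, and
every analysis stage is validated against that ground truth.

## Methylation levels

A CpG site is addressed by the position of the C on the forward strand
(0-based), with reads from both strands pooled.  The methylation level of a
site in a sample is M/N (methylated / total reads); only sites with depth
N >= 4 enter any calculation, applied per sample and per site, and a
failing site is *missing*, never zero.  Replicates within a transfection
group are pooled by summing M and N before taking the ratio, which keeps
region means depth-weighted; an unweighted (mean-of-ratios) weighting is
exposed for region and genome summaries where each site should count
equally.  Bisulfite conversion is estimated from an unmethylated lambda
phage spike-in (48,502 bp reference) as 100 x (1 - sum M / sum N) over all
cytosines, all contexts, with no depth filter.

## DMR calling

DMRs are called between two conditions with the parameter set
delta >= 0.1, per-CpG P <= 0.01, >= 3 CpGs, length >= 10 bp, 100 bp
smoothing window.  The per-CpG statistic is this package's own simplified
stand-in for a shrinkage-based beta-binomial test: levels are smoothed with
a depth-weighted moving window (+-50 bp, same chromosome), and each site is
scored with the Wald statistic

    z = (p1s - p2s) / sqrt( pbar (1 - pbar) (1/n1 + 1/n2) + phi0 )

where n1 and n2 are the summed passing depths inside the smoothing window,
pbar the pooled smoothed level with one methylated and one unmethylated
pseudo-read, and phi0 an additive prior variance for extra-binomial noise.
phi0 defaults to 0.001; with >= 2 replicates per condition it is replaced
by a method-of-moments estimate of the between-replicate variance excess.
P-values come from the standard normal and are deliberately not adjusted
for multiplicity — the region-forming step, not a per-site FDR, controls
false calls.

Qualifying sites (p <= 0.01 and |delta| >= 0.1) seed regions; runs of
same-direction seeds with inter-seed gaps <= 100 bp (the smoothing window,
chosen as the merge gap) form candidates, which must span >= 10 bp and
>= 3 CpGs with |mean delta| >= 0.1.  A region ends 2 bp after its last
member CpG so the final dinucleotide is covered; this boundary convention
matters for the 10 bp length rule and is fixed here.  Candidate regions are
disjoint by construction.

Calibration caveat: the additive phi0 cannot track how overdispersion
scales with the number of sites sharing a smoothing window.  On a fully
null comparison the per-site test is calibrated (fraction p <= 0.01 about
0.01–0.02 at depth 30), but window-level fluctuations produce occasional
clusters of correlated false seeds, so a small number of null DMRs
(roughly 10–20% of a strong injected-scenario count on the default
synthetic genome) survive the region rules.  This is precisely the class
of stochastic DMR the monotonicity filter below exists to remove; the
filter, not the caller, is the final line of defence, as in the original
experimental design.

## The stochastic-DMR monotonicity filter

Authentic dCas9-methyltransferase DMRs must respond monotonically to
enzyme dose and gRNA presence across the nine transfection groups.  For
the uPA comparison a hypermethylated DMR must satisfy the ordered chains

    level(9: pUC19) <= level(5: 3A only) <= level(7: 3A 50 ng + uPA 50 ng)
                    <= level(1: 3A 500 ng + uPA 500 ng)
    level(2: 3B + uPA) <= level(1)
    level(6: 3B only)  <= level(2)

with all inequalities mirrored (>=) for hypomethylated DMRs, and the
TGFBR3 comparison substituting groups 8, 3 and 4.  Inequalities are
non-strict and evaluated with zero slack by default (a configurable
epsilon exists because sampling noise makes exact ordering brittle, but
the default matches the published criteria).  Group levels are computed
over the DMR interval only, depth-weighted, from raw (unsmoothed) counts;
a DMR with a missing level in any chained group is reported as
unresolvable, distinct from failing.  Chains are configuration data, so
other designs need no code changes.

## Enrichment, DHS profiles, seed density, peak overlap

Region sets are characterised against matched background windows: random
intervals equal in number, with lengths resampled from the input length
multiset and placement uniform over the genome (feature overlap is
allowed, matching a genome-wide null).  A region "falls into" a feature
class when it overlaps >= 1 bp of any class interval and may count in
several classes; each class is tested with a two-sided Fisher exact test
on the 2x2 in/out x region/background table.  DHS metaplots length-scale
each DHS body into 20 bins with 1 kb flanks in 10 fixed bins each,
averaging passing per-site levels, and compare groups with a Wilcoxon
matched-pairs signed-rank test over per-DHS body means.  Seed–PAM density
counts occurrences of a guide's PAM-proximal 5-nt (or 11-nt) seed followed
by NGG on either strand, overlapping occurrences included, normalised per
kb; DMRs are expanded by 100 bp first because methylation flanks the
binding site.  Set comparisons report both a Fisher exact test on pooled
counts and a Welch t-test on per-window densities — the two conventions in
circulation for this analysis — without privileging either.  DMR–ChIP-peak
overlap expands DMRs by 100 bp, counts members overlapping >= 1 peak
(once, however many peaks they touch), and tests enrichment against
matched background windows.

## The synthetic-data generator

The generator emulates the WGBS count structure of the nine-group design;
it does not simulate reads, alignment, PCR bias or copy-number variation.

*Genome.*  Default 5 Mb over 2 chromosomes, 41% GC.  Forward-strand gene
models (2 kb promoter, 5'UTR, CDS exons split by introns, 3'UTR) are laid
down with random spacing; CpG islands (1.2 kb) cover gene TSSs and receive
planted CG dinucleotides (probability 0.10 per dinucleotide position),
while CpGs elsewhere are thinned (survival 0.22, or 0.5 inside Alu/LINE
repeats, which are CpG-rich in real genomes), reproducing the
island-vs-background observed/expected CpG contrast.  DHSs (150–500 bp)
sit preferentially (70%) at TSSs.  Feature fractions default to roughly
human-like genome shares at this scale.

*Effects.*  Counts are N ~ Poisson(30) and M ~ beta-binomial with
overdispersion phi = 0.01 around an expected level p = clamp(baseline +
effects, 0, 1), plus apparent methylation from incomplete bisulfite
conversion (rate 0.995).  Baselines per feature class follow the canonical
mammalian landscape: unmethylated islands (0.08), intermediate shores
(0.35) and promoters (0.20), highly methylated gene bodies and repeats
(0.70–0.80).  Injected effects:

- on-target: +0.5 at CpGs 10–50 bp outside a protospacer of the sample's
  gRNA set, half weight at 1–9 bp, zero strictly inside any protospacer
  (the bound dCas9 footprint blocks the methyltransferase);
- off-target hyper: +0.45 at DHS windows carrying a 5-nt-seed–NGG match of
  the set's guides (40 planted per set by default, 75% at TSS-proximal
  DHSs), excluding the on-target locus itself;
- off-target hypo: -0.40 at 40 random Alu/LINE1 repeats per set.

Effects scale multiplicatively with construct activity (DNMT3A 1.0,
DNMT3B 0.6, catalytic-dead E752A/E697A mutants 0) and transfected dose
(500 ng -> 1.0, 50 ng -> 0.55).  On-target and gRNA-dependent off-target
terms scale with the product of enzyme-dose and gRNA-dose factors; groups
without the matching gRNA set retain a small enzyme-alone open-chromatin
off-target component (factor 0.15), reflecting untargeted activity of the
overexpressed enzyme.  These factors were chosen once so that every
inequality of the monotonicity chains holds in expectation with a strict
margin at 30x depth; the off-target delta magnitudes are generator choices
within the plausible range implied by a 0.1 calling threshold, not
measured values.  Truth tables record every injected interval as BED with
the signed full-scale delta in the score column.

*ChIP peaks.*  Synthetic dCas9 binding peaks (200 bp) are emitted at a
configurable fraction of genome-wide seed–PAM matches, preferentially
inside DHSs, with centres jittered <= 20 bp from the match, plus a peak at
each on-target site.

What passing on this generator shows — and does not.  The generator
reproduces the count structure, depth, overdispersion, conversion noise,
feature co-location (promoter/CGI/DHS) and the dose/construct/gRNA effect
logic of the design, so it exercises every decision the pipeline makes.
It does not reproduce read-level artefacts, mapping bias, real CpG spatial
autocorrelation of methylation states, or real off-target site selection,
so recovery rates here bound software correctness, not expected
performance on real libraries.

## Problem sizes and numerical choices

Default analyses run on the 5 Mb genome (~60,000 CpGs, nine samples),
the scale at which all distributed results and tests are computed; a 1 Mb
configuration backs the unit-test fixtures.  Degenerate inputs are handled
explicitly: windows with no passing coverage are missing and skipped with
a log line, empty feature classes report p = 1, equal counts give z = 0
and p = 1 exactly, and exact ties pass the chain inequalities.  The region
boundary (+2 bp), the merge gap (100 bp) and per-member Venn-style overlap
counting (>= 1 bp) are fixed conventions documented above because the
downstream counts depend on them.

## Known limitations

- The DMR statistic is a deliberate simplification; it does not reproduce
  shrinkage-based callers numerically, and its additive dispersion prior
  under-covers window-level overdispersion (see the calibration caveat).
- The chain filter with zero slack is brittle near ties; real analyses may
  want a small epsilon, at the cost of deviating from the literal criteria.
- Background sampling matches number and length only, not GC or CpG
  composition; enrichment against composition-matched nulls would be more
  conservative.
- Multi-class feature counting means percentages across classes need not
  sum to 100.
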