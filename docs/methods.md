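# Methods

This note records the models, defaults, and numerical choices behind
`magqc`, and what the synthetic benchmarks do and do not demonstrate.

## Replichore model and ori/ter prediction

The skew engine computes (G − C)/(G + C) per window (default window
1000 bp, step 10 bp, both configurable), with N excluded from both
numerator and denominator and windows wrapping on circular replicons;
GC-free windows get skew 0 and are flagged.  The cumulative skew is the
running sum over windows.  Under bidirectional replication with a
G-rich leading strand, the cumulative curve falls to a global minimum
at the origin and rises to a maximum at the terminus; `predict_ori_ter`
reports those extrema.  Because only the terminus is typically marked
in published skew plots, the orientation convention is explicit and
switchable (`ori_at = min | max`).

Classification as *bidirectional* requires (i) cumulative amplitude at
or above `amplitude_min` and (ii) arm balance — the ori→ter arc as a
fraction of the replicon — within [0.3, 0.7].  `amplitude_min` is not a
fixed number: `null_amplitude_threshold` shuffles the sequence
(preserving length and composition) 200 times by default and returns
the 99th percentile of the null amplitude, making the call length- and
GC-aware.  By construction ~1 % of truly unbiased replicons will still
exceed the threshold; the arm-balance condition removes part of that
remainder.

Two caveats are inherent to cumulative-skew extrema.  First, the
extremum location jitters by roughly a window around the true position,
so recovery is meaningful at window resolution: with non-overlapping
1 kb windows, synthetic replicons with skew strength ≥ 0.5 recover ori
and ter within one window step; with the fine default step of 10 bp the
same jitter spans a few steps.  Second, when the two arms are strongly
unbalanced, the linearization point biases the extrema — one reason the
classifier refuses the bidirectional label outside [0.3, 0.7] balance.

## Read support, unsupported regions, SNP tiers

Support counts, at each position, alignments with identity
1 − NM/aligned-length ≥ 0.95 (inclusive — a cutoff keeps the boundary
read) that belong to properly paired fragments (singletons are weaker
evidence; the requirement is switchable).  Unsupported regions are
maximal runs below `min_depth` (default 1, i.e. "uninterrupted support"
means no zero-coverage position); on circular replicons a run touching
both ends is reported as one wrap-around interval with start > end,
normalized in serialized reports.

`snp_scan` builds a substitution-only pileup from retained alignments
(identity ≥ 0.97, mirroring mapping at up-to-3 %-SNP stringency; indels
are out of scope).  The most frequent non-reference base defines the
alternate allele.  Tiering: alternate fraction in (strict, relaxed] →
`relaxed-only` (strain variation); above relaxed → `fail` (candidate
assembly error); defaults strict = 0.0, relaxed = 0.03, both inclusive
on the right.  Positions under `min_depth` (default 5) are skipped and
counted.  At strict = 0 every sequencing error above the depth floor
produces a call, so on error-containing libraries the relaxed tier is
the informative one; the verdict only blocks on `fail`-tier positions.

## Chimera evidence and the GC-shift null

GC content is computed in non-overlapping windows (default 1 kb) and
adjacent windows are compared.  The score is z = |ΔGC| / σ_LOO where
σ_LOO is the root-mean-square of all adjacent-window differences on the
replicon *excluding the tested one*.  Two details matter.  RMS (not the
standard deviation of folded absolute differences) is the right scale
estimate because differences of a stationary profile have zero mean.
Leave-one-out matters because a genuine jump otherwise dominates its
own scale estimate and the score saturates near √n_windows, making any
fixed threshold length-dependent.

The default `z_min = 5.0` was calibrated on simulation: over 800
homogeneous-composition replicons of 20–100 kb the per-replicon maximum
z never exceeded 4.7, while a donor junction aligned with a window
boundary scores ≥ 5.6 at a GC shift of 0.2 and ≥ 13 at 0.4.  A junction
landing mid-window splits its shift across two differences, and weak
shifts can then drop below threshold — such junctions are still caught
by the read-support stream, which is why `flag_chimeras` unions both
evidence classes (intervals within `join_dist`, default 1 kb, merge).
On linear contigs the first and last insert-length of sequence
inherently lack spanning pairs; `exclude_end_dist` drops those trivial
end gaps from chimera evidence.

Terminal redundancy scans overlap lengths from half the contig down to
`min_overlap` (default 100 bp) and returns the longest prefix/suffix
pair whose Hamming mismatch fraction is ≤ `max_mismatch_frac` (default
0.01) — evidence of circularizability, not an editing operation.

The completeness verdict is *complete* iff there are no unsupported
regions at depth ≥ 1, no fail-tier SNPs, and the replication signature
is bidirectional; an explicit waiver downgrades a non-bidirectional
signature to a warning (several archaeal lineages do not show the
pattern, so its absence is not by itself an assembly defect).

## Quantification

Alignments are retained at MAPQ ≥ 10 and identity ≥ 0.97, both
inclusive (a MAPQ-10, 3-mismatch/100 bp read is kept).  Secondary and
supplementary records are ignored on ingest — MAPQ filtering
presupposes primary placements — and records lacking the NM tag are a
hard error naming the record, since identity cannot be computed.

Counting is per fragment: alignment segments sharing a read id (pair
mates, split segments) collapse into one fragment whose span runs from
the leftmost to the rightmost aligned base.  A fragment is assigned to
the gene containing its span midpoint — deterministic and free of
double counting; ties among overlapping genes break by gene start then
id, and an `overlap` counting mode is provided for comparison only.
Fragments hitting no gene are tallied as intergenic, so gene-assigned +
intergenic = retained fragments, per sample.

RPKM_g = count_g / ((length_g/10³) × (total_mapped/10⁶)) with
total_mapped = retained fragments after filtering (the internally
consistent denominator; a pre-filter denominator is exposed as a
switch at the CLI level by passing the unfiltered total).  When every
fragment is gene-assigned, Σ_g RPKM_g · length_g(kb) = 10⁶ exactly.

Relative abundance applies a 95 % identity cutoff per fragment, assigns
each passing fragment to its genome (ties across genomes resolved
uniformly at random with a fixed seed — ambiguous = random), and
reports percentages over assigned + unmapped, summing to 100.

## Feature summaries

The tRNA parser reads the scanner's tabular dialect: 1-based inclusive
coordinates with begin > end on the minus strand (normalized on
ingest), comma-separated multi-intron columns, and "0/0" as the
no-intron sentinel.  The standard table carries no anticodon
coordinates; an extended 11/12-column variant (written by
`write_trna_table`) adds anticodon begin/end, and records without them
classify intron positions as `unknown`.  An intron is *canonical*
(between tRNA positions 37 and 38) when its 5′ boundary lies within
±1 nt of the position immediately 3′ of the anticodon — the tolerance
absorbs one-off coordinate conventions and the basis of each call is
recorded.  Exact standard numbering would require secondary-structure
alignment and is out of scope.

The homology-hit filter keeps a hit iff |subject length − query length|
< 0.75 × query length, strictly (the boundary case is rejected), read
on full sequence lengths — the rule names sequences, not alignments —
with an aligned-length variant behind a flag.  Dereplication keeps the
best hit per query: highest bitscore, then lowest e-value, then input
order.

## Synthetic data: what it emulates, what it does not

The generator imposes skew by biasing the G↔C choice per replichore
arc (A/T unbiased), yielding expected windowed skew ±s — the minimal
model producing the two-arm cumulative "V".  DNA libraries are
synthesized directly as alignment records (optionally serialized to
SAM with NM set): fragment count = round(coverage·L/(2·read length)),
uniform placement, uniform substitution errors at the configured rate,
planted variants carried per covering read at the minor-allele
fraction, MAPQ 60 for unique placements and 0 for draws from the
optional ambiguous fraction.  Reads crossing a circular origin are
emitted as two segments sharing a read id, so support is seamless at
the origin.  Masked intervals drop overlapping reads; the observed
zero-coverage run therefore covers the mask and can extend up to one
read length beyond it on either side (discrete placement).  Chimeras
concatenate a donor prefix and suffix; donor-only libraries place
fragments entirely on one side of the junction, so the junction has no
spanning support.  RNA libraries plant exact per-gene fragment counts
with midpoints inside the gene and draw identity and MAPQ from
discrete spectra, so expected post-filter counts factorize as
abundance × P(identity ≥ cutoff) × P(MAPQ ≥ cutoff).

Not emulated: indels, quality-score variation, coverage bias,
chimeric-pair artifacts, reference bias from a real aligner, or any
error profile of a particular instrument.  Passing benchmarks therefore
demonstrate correctness of the detectors' logic and calibration under
a clean substitution-only model, not performance on real libraries —
on real data the identity filters absorb indel-containing alignments
differently and σ_null reflects genuine compositional heterogeneity.

## Benchmark scales and determinism

The built-in benchmarks run on one CPU in minutes: 50–100 random
sequences of 10–100 kb for the exact skew invariants, 20 replicons of
50–100 kb for ori/ter recovery, 20 planted chimeras and 20 clean
replicons of 40 kb at 20× for the detector recall/precision figures,
30-gene expression sets for the quantification identities.  Every
stochastic step takes an explicit seed; identical seeds reproduce
byte-identical sequences, alignment lists, and serialized tables (the
pipeline manifest records parameters and input checksums to make
re-runs auditable).
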