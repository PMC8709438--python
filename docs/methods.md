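# Methods

## Scope and data model

`rlmeth` operates downstream of modified-base calling: its inputs are a
multi-replicon assembly (FASTA), gene annotation with COG letters
(GFF3), per-condition per-site call tables (bedMethyl or a simple TSV
with columns replicon, position, strand, base, mod_type, coverage,
modified), and per-condition depth (bedGraph or per-replicon means).
Internal coordinates are 0-based half-open on the forward strand; GFF3
(1-based inclusive) is converted on read, BED/bedGraph output is
written 0-based. Replicons are circular by default, which matters in
two places: motif matches may span the origin (found by scanning the
sequence extended with its first *L*−1 bases), and promoter windows
wrap around the origin instead of clipping.

## Motif scanning

Motifs are degenerate IUPAC patterns with a designated 1-based modified
position and modification type (6mA, 4mC or 5mC); the pattern character
at the modified position must be compatible with the modified base.
Scanning uses a regex with a look-ahead so *overlapping matches are all
reported*; genome positions holding N or any ambiguity code never
match. For a palindromic pattern (equal to its IUPAC reverse
complement — true of GANTC, GATC and GGCGCC) each genomic locus is one
occurrence, reported on "+" and carrying the modified-base coordinate
on both strands: for a match at [s, s+L) with modified position *m*,
the "+" site is s+m−1 and the "−" site is s+L−m. Non-palindromic
patterns are scanned separately on each strand and counted per strand.
Per-replicon count tables therefore use *site-level* counting for
palindromes. Promoter intersection counts an occurrence as inside a
region iff its full match interval overlaps the region by ≥ 1 base
(half-open semantics); the per-replicon table counts distinct
occurrences touching ≥ 1 promoter, while a separate gene × motif
boolean table (any motif in that gene's promoter) feeds enrichment.

## Promoters

A promoter is the `upstream_len` (default 100) bases immediately
upstream of the start codon: [s−100, s) for a + strand gene [s, e),
[e, e+100) for a − strand gene. Windows are not trimmed when they
overlap an upstream gene body, and genes whose window crosses the
origin of a circular replicon keep the full 100 bp by wrapping. These
two choices are deliberate simplifications; both are exposed through
the region objects if a stricter convention is needed.

## Methylation aggregation

The site methylation level is 100·modified/coverage, defined only for
coverage ≥ `min_coverage` (default 5 reads — low enough to keep most
sites at 20–50× depth, high enough that a single read cannot swing a
site by more than 20 points). All summaries are unweighted means of
per-site levels: the quantity being averaged is "percent of methylated
reads at a position", so deep sites do not dominate. A palindromic
motif locus contributes its two strand calls as two observations; this
convention is recorded in output metadata because pooling strands as
one observation would halve n without materially moving the means.
Sliding windows default to width 5000 bp / step 1000 bp; windows tile
each replicon from 0 in steps of `step`, are clipped at the replicon
end, and empty windows are emitted with n_sites = 0 and undefined
percent. Genome-wide base averages include motif sites (motif loci are
≈1% of callable sites at these motif densities, shifting background
averages by well under half a percentage point).

Condition comparison reports side-by-side per-motif means, their
difference, and a pooled-read effect size (difference of pooled
modified/total fractions) as a depth-weighted complement to the
unweighted means; no headline p-value is attached because biological
replication, not read sampling, is the relevant error source.

## Copy number

Relative abundance of replicon *r* in condition *c* is mean depth of
*r* divided by mean depth of the chromosome, with absent positions
counting as depth 0. Plain means are used — no GC correction, no
origin/terminus detrending — because the estimand is a genome-scale
ratio and systematic biases largely cancel between numerator and
denominator; a symmetric trimmed-mean option (`trim_fraction`) exists
for tracks with localized artifacts. Ratios are reported to 2 decimals.

## Enrichment

The test universe is all genes with ≥ 1 COG letter; genes with several
letters count once in each category. For category with K background and
k foreground members, the p-value is the upper tail P(X ≥ k) of
Hypergeometric(N, K, n) (scipy), BH-adjusted across the categories
tested (K ≥ 1). Over-representation is the default; depletion is
available behind a flag. Note that BH step-up adjustment is not
idempotent — re-adjusting adjusted values can raise them further — so
adjusted values are reported once and never re-entered into the
procedure.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not sequencing physics. Genomes are i.i.d. base draws at a target GC;
genes are non-overlapping stranded intervals with COG letters drawn
from a fixed frequency table (default ≈ 25% unannotated, L at 4%).
Calls: each genomic position yields exactly one A or C call (on the
strand where the base is A or C); coverage ~ Poisson(mean_depth ×
copy_ratio), modified ~ Binomial(coverage, p) with p the motif
probability at scanned modified sites (longest motif wins if sites
coincide) and the base background otherwise. Depth tracks are
independent per-position Poisson draws. All generators are
bit-reproducible from (seed, parameters); compound studies derive all
child seeds from one seed via `numpy` SeedSequence spawning.

What is *not* modelled, and therefore what passing recovery tests do
not establish for real data: phase variation (per-read methylation
heterogeneity), the Ori→Ter replication gradient that produces the
bow-shaped chromosome profiles in dividing cells (a `position_effect`
hook on `simulate_calls` accepts a position-dependent probability
modifier), mappability/GC coverage bias, read-length structure, and
basecaller error correlation. Recovery tests demonstrate that the
aggregation pipeline is an unbiased, correctly-plumbed estimator of
per-site probabilities, not that the caller upstream is accurate.

### Emulation profiles

Two packaged condition profiles encode the free-living vs. bacteroid
parameter set the package is organized around, on a 500-kb five-replicon
genome (Chromosome 300 kb, pRL10 40 kb, pRL11 40 kb, pRL12 50 kb, pSym
70 kb; per-replicon GC 61.09/60.61/60.89/60.40/58.12) at 50× depth:

| parameter | bacteroid | cell_culture |
|---|---|---|
| GANTC | 0.98 | 0.55 |
| GGCGCC | 0.98 | 0.98 |
| GATC | 0.50 chromosome / 0.40 plasmids | 0.25 |
| background A | 0.75 | 0.40 |
| background C | 0.46 | 0.38 |
| copy ratios (pRL10/11/12, pSym) | 0.91 / 0.94 / 0.97 / 0.59 | 0.58 / 0.50 / 0.48 / 0.60 |

Three cell-culture values are inventions constrained only by ordering:
GANTC 0.55 (no single published level exists for dividing cells, where
methylation tracks the replication cycle), GATC 0.25 (below the C
background, the observed ordering), background A 0.40 (well below the
bacteroid level). The rest are the published study's values. The 500-kb
scale keeps a two-condition simulation plus full analysis under ~15 s
on one CPU while leaving ≥ 400 loci for the rarest motif (GGCGCC), so
binomial standard errors on recovered means stay below 0.1 percentage
points.

## Testing strategy and problem sizes

Scanners are checked against an exhaustive per-offset, per-strand
oracle on twenty seeded 10-kb sequences; interval intersection against
a quadratic all-pairs oracle; window means against direct
re-aggregation; the hypergeometric tail against exact
binomial-coefficient enumeration for every urn with N ≤ 12; BH against
hand-computed step-up vectors. Parameter recovery runs the packaged
emulation at 500 kb/50× (tolerance 2 percentage points, ≫ the ~0.1-pt
standard errors) and copy-ratio recovery at 20× (tolerance 0.02).
The enrichment power check plants COG L on a 100-gene foreground at 3×
the 0.15 background rate within a 200-gene universe and requires
detection (L top-ranked, p_adj < 0.05) in ≥ 95 of 100 seeded draws;
type-I control requires ≤ 7% of raw p < 0.05 over 1000 uniform
foregrounds (the hypergeometric test is conservative on discrete
counts, so the realized rate is below nominal).

## Known limitations

- Aggregated per-site calls only; no per-read analysis, so phase
  variation is invisible by construction.
- Promoter definition is positional (100 bp upstream), not TSS-based;
  operon structure is ignored, so internal genes carry "promoters"
  inside upstream coding sequence.
- Copy-number estimation assumes native DNA libraries; amplified
  libraries void the depth ∝ copy-number premise.
- The motif count tables use the site-level convention for palindromes;
  strand-level counts are exactly 2× for palindromic motifs, and both
  conventions can be derived from the occurrence lists if comparison
  with strand-level published counts is needed.
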