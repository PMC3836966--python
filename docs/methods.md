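# Methods

This note records the models, parameter choices and numerical conventions
behind `physmap`, and what the synthetic tests do and do not demonstrate.

## Fingerprint model and overlap scoring

A clone's HICF fingerprint is modelled as the restriction fragments of its
genomic interval. Recognition sites follow a renewal process with geometric
spacing (mean 2,500 bp, `DigestParams.mean_spacing`); fragments are
observable within `band_range` (default 500–10,000 bp), which leaves ~35
bands on a 111 kb clone. Each band is perturbed by multiplicative sizing
noise (`NoiseParams.band_sigma`, default 1e-4 — sub-base-pair accuracy for
typical fragment sizes, matching capillary sizing) and rounded to integer
units. Sites are generated lazily in fixed 1 Mb blocks keyed by the arm's
seed, so overlapping clones always see identical fragments.

Band matching is a greedy two-pointer sweep over the sorted band lists with
tolerance `band_tolerance` (default 3 units); for this interval-compatible
structure the sweep is a maximum matching (verified against exhaustive
bipartite matching in the tests). The Sulston score is the binomial tail
P(X ≥ shared) with per-band chance probability `1 − (1 − p_match)^n_max`.
The generic default `p_match = 0.03` suits band values on a narrow gel-unit
scale; the pipeline instead derives `p_match` from the digest model as the
probability that two unrelated observable fragments agree within tolerance
(`chance_match_probability`, ≈ 1.5e-3 for the defaults). With ~35-band
prints this makes a 1e-15 cutoff correspond to roughly half the bands
shared, i.e. ~56 % clone overlap (`detectable_overlap_fraction`).

## Assembly

**LTC-style.** Connected components of the 1e-15 graph are screened for
linear topology. Exact proper-interval recognition uses 3-sweep
lexicographic BFS with the umbrella (consecutive closed neighbourhood)
check; `is_linear` also returns a greedily chosen offending set. Exact
recognition is deliberately *not* the quality-control trigger on noisy
data: a single sub-threshold overlap breaks the umbrella property, so
resolution instead targets

- *bridge clones*: a clone whose neighbourhood splits into groups that
  cannot reach each other within four hops without it. This covers both
  contaminated fingerprints gluing two distant regions and single-clone
  coverage pinches; in either case the contig is cut at the bridge and the
  clone keeps its edges to the side sharing more bands (so a chimera stays
  with its genuine locus);
- *heavy offenders*: clones with at least `q_violation_min` (default 8)
  umbrella conflicts after the cuts, removed to singletons. A clone gluing
  two regions scores on the order of the glued component's size, whereas
  band-sampling noise leaves only one or two conflicts; the threshold
  separates those regimes with a wide margin.

Contigs below `min_contig_clones` (default 6) are dissolved to singletons.

**FPC-style.** Components form at the strictest cutoff of the ladder
(1e-75), then the cutoff relaxes step-wise to 1e-45 with singleton
clustering (incremental building), single-to-end attachment, end-to-end
merging over the `end_window` (2) terminal clones, and a DQer rule that
re-splits any contig whose questionable-clone fraction exceeds
`q_fraction` (10 %) at the previous, stricter cutoff. With ~35-band
synthetic prints the strict end of the ladder is unreachable (even
identical prints score ~1e-45), so in practice contigs form near the loose
end — the mode is systematically more conservative than LTC, which is the
behaviour being compared.

**Offsets and lengths.** A clone's offset is the median over all edges to
already-placed clones of `offset(u) + (1 − shared/(retention·n_u))·insert`,
where `n_u` is the left clone's band count, `retention` (0.95) is the
chance a shared band survives sizing noise within tolerance, and `insert`
is the 111 kb library mean. Using the left clone's band count (not the
pair minimum) keeps the step unbiased when the next clone is short or
nested; pooling the per-edge estimates by median suppresses band-count
noise. Contig length is the offset span plus the last clone's length;
median error on synthetic contigs is ~6 %. MTP selection is a greedy
left-to-right interval cover with minimum pairwise overlap 10 kb, ties to
the lexicographically smaller clone id (equals the exhaustive minimum cover
on gap-free contigs up to 10 clones in the tests).

## Genome zipper

`build_zipper` runs TE-filter → three-genome intersection → syntenic
interval extraction → zip-in → inversion correction → numbering (telomere
= 1). A displaced gene is inserted at the midpoint of the interval-index
slots implied by its flanking homologs in the two other genomes; an
integer midpoint (a tie) inserts before that gene, i.e. toward the lower
index, and genes whose two genomes disagree on the flanks are excluded and
logged. Edge insertions (before the first or after the last interval gene)
are allowed and carry the `zipped_in` flag like any other.

## 3D-pool deconvolution

Pool positives per dimension are found by top-k peeling: the k highest
pools are accepted at the largest k (≤ 4) for which every candidate stands
out against the remaining pools, either by mean + x·SD (multipliers 2.4 /
2.7 / 2.8 for plates / rows / columns) or by a one-sample t-test in
prediction-interval form, `t = (v − mean)/(s·sqrt(1 + 1/n))`, at p < 0.01.
Peeling is what lets two carriers in a small dimension both be called —
either alone would be masked by the other inflating the background. A
dimension needs at least four pools (three background values); genes on
more than four clones per dimension are not fully deconvolvable. Zero
background variance counts any strictly higher value as positive, so
noise-free signals deconvolve exactly. A clone address is called iff its
plate, row and column pools are all positive; probes with several
consistent addresses are flagged ambiguous and reported, and the pipeline
anchors with unique addresses only. The pipeline defaults to the t-test
detector because the m+xSD multipliers need ≥ 8 pools per dimension to see
a single carrier — true at full library scale (dozens of plates), not for
the handful of plate pools in a desk-scale run.

## Level 2/3 anchoring conventions

Contigs anchor at the *minimum* zipper position among their syntenic
genes; the centromere segment (contigs with Cereba-type retrotransposon
BES only) is ordered by contig id, documented as arbitrary. Duplicated
zipper evidence across contigs is allowed and flagged. Consensus marker
positions are the exact (fsum) mean of available per-map centimorgan
values rounded half-away-from-zero — this reproduces every fully
tabulated published consensus position. A genetics-vs-synteny conflict is
a marker whose consensus-cM rank and contig zipper rank differ by more
than `rank_window` (2). Bin boundaries on the zipper are midpoints between
adjacent bins' extreme positions after discarding positions lying beyond
at least `k_outlier` (5) opposing points; a hit-free bin is bounded by its
neighbour's last position. Gene densities are truncated (not rounded) to
two decimals — truncation reproduces all four published per-bin values,
rounding half-up would miss two. The recombination profile uses the
zipper index as the physical proxy, so its distal fraction is measured on
the gene axis; because genes concentrate distally, the same map looks less
concentrated on the gene axis than on the base-pair axis.

## Sequence model

Records sort by (contig rank, clone offset, hit position); each source
sequence appears at most once. Definition lines use 1-based inclusive
coordinates ("282–1376" style) and integer-kb contig ranges; the parser
accepts both en-dash and hyphen. BES composition assigns each base by
precedence known TE > novel TE > gene > rDNA > organellar > unclassified
(the standard Triticeae annotation convention), base-pair weighted.

## What the generator emulates — and what it does not

The synthetic arm reproduces the statistical structure the analysis
relies on: a 275 Mb arm (desk runs use a proportionally scaled 20 Mb arm
with 2,000 clones, chosen so the full five-seed pipeline runs in under a
minute), a distal-to-proximal gene-density gradient over three deletion-bin
regions, ~82 % TE content from a family catalogue with Fatima most
abundant and Cereba confined to the proximal 5 %, uniform clone starts
with truncated-normal 111 kb inserts at 94 % purity (contaminants are
intervals of a second, unrelated synthetic arm), well-to-well fingerprint
contamination (3 % of wells receive ≥ 30 % of a same-plate clone's bands),
3D pools with Gaussian background and a cross-hybridisation rate, paired
~703 bp BES, lognormal ~1 kb shotgun contigs, eight genetic maps jittered
around a shared truth with exponentially distally concentrated
recombination (half the map in the distal ~14 % of the physical length),
and deletion-bin ESTs assigned by true gene position. True contig
membership chains clones whose overlap reaches the digest model's
detectable fraction, so "adjacency recovery" measures the assembler
against what fingerprinting can in principle see.

Not emulated: nucleotide-level evolution (sequences are i.i.d. random and
generated only where alignment inputs are needed, so homology hits among
synthetic sequences are exact-copy alignments, not diverged ones);
gene islands and segmental duplication; fingerprint failure (every clone
yields a print, vs ~83 % in real projects); restriction-site sequence
bias; population-specific marker ordering errors beyond Gaussian jitter.
Passing tests therefore show the algorithms are correct under the stated
statistical model, not that the thresholds are optimal for any particular
real library.

## Known limitations

- The bridge-cut rule cannot distinguish a chimeric join from a genuine
  single-clone pinch; both are cut, which trades a small amount of
  fragmentation for robustness against contamination.
- The Sulston binomial-tail approximation saturates for dense digests
  (many small fragments), where the per-band chance probability grows
  toward 1 and stringency cutoffs below ~1e-50 become unreachable for
  realistic band counts.
- Level 2 anchoring inherits the published convention of the minimum
  zipper position, which can misplace contigs whose lowest-numbered gene
  evidence is a paralog.
- Marker integration averages centimorgan positions across populations;
  the consensus is a pragmatic summary, not a joint map estimate.
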