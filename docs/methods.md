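# Methods

## The problem

Nascent run-on assays (PRO-seq, GRO-seq) map engaged RNA polymerase at base
resolution, strand-specifically. The unit of transcription they measure is
the *primary transcript*: initiation at a TSS, elongation through the gene
body, and termination well past the polyadenylation/cleavage site. Curated
mRNA annotations describe neither end well — they enumerate alternative
first exons without saying which start dominates in a given cell state, and
their 3' ends stop at the cleavage site even though polymerase reads
through for kilobases. Quantifying run-on data inside mRNA boundaries
therefore mixes silent promoter sequence into pause windows and discards
termination-zone signal. This package infers data-driven TSS and TTS
coordinates per gene, uses them to assign gene identifiers to de novo
transcription-unit (TU) calls, and quantifies genes (counts, pause indices)
under the refined coordinates.

## TSS inference

Model: active initiation produces promoter-proximally paused polymerase,
i.e. a sharp coverage peak a few tens of bases downstream of the true
start. Among a gene's annotated first-exon 5' ends (candidates, one per
distinct 5' end), the dominant TSS is the candidate with the maximal read
count in the window of ``W`` bases transcribed immediately downstream.

* ``W`` — evaluation window, default 500 bases (also the radius used when
  scoring a start by its distance to the nearest read peak). With ``W``
  fixed, ranking windows by count and by density is the same argmax, so raw
  counts are used.
* Ties break toward the most 5' candidate (conservative: longer
  transcript); genes whose candidates all score zero return the most 5'
  candidate flagged ``zero_signal``.
* Window length is deliberately independent of first-exon length; a short
  first exon does not shrink its window.
* Novel (unannotated) starts are out of scope by design: the method selects
  among annotated candidates. Discovering new starts is the job of 5'-end
  assays (PRO-cap, Start-seq, 5' GRO-seq).

A start coordinate is scored post hoc by ``distance_to_peak``: the signed,
strand-aware distance to the nearest base that is positive and a local
maximum within ±500 bases (ties: smaller absolute distance, then
downstream).

## TTS inference

Model: elongation density is roughly uniform across the body; termination
is slow, so density *rises* near the gene end and then decays to background
past the cleavage site. The procedure per gene:

1. **Search region** — from the 3'-most ``gene_fraction`` of the gene
   (default 0.2) to ``downstream_extension`` bases (default 10,000) past the
   most distal annotated end. The defaults suit mammalian termination
   zones, which commonly extend 1–10 kb past the poly(A) site.
2. **Binning** — whole bins of ``bin_width`` B (default 200 bases) tiled
   from the region's 5' end; a trailing partial bin is dropped. Under 4
   whole bins the gene is reported unprocessable.
3. **Smoothing** — a penalized cubic smoothing spline
   (`scipy.interpolate.make_smoothing_spline`) through the bin counts,
   fitted in bin-index coordinates so the penalty does not depend on B. The
   penalty λ (``smoothness``) defaults to generalized cross-validation,
   the same default family as R's `smooth.spline`; λ→0 recovers the
   counts exactly, and constant or linear profiles are reproduced for any
   λ because the penalty is on curvature. Regions of 4 bins (below the
   smoother's minimum support of 5 points) use the zero-penalty limit,
   whose fitted values at the bins are the counts themselves.
4. **Peak** — the global maximum of the fitted curve, provided it exceeds a
   background floor of max(1 read, half the mean of the three 5'-most
   bins); the floor prevents peak calls in silent regions while accepting
   termination signal that only modestly exceeds the body level. Ties go to
   the most 5' bin.
5. **Decay** — the first bin 3' of the peak whose fitted value falls to
   ``tau`` × the peak value (default tau=0.1). A relative threshold is used
   because noisy counts never reach exactly zero; it is also scale-free
   across expression levels. The TTS is the *5' edge* of the decay bin —
   the conservative choice inside the bin's ±B ambiguity. Decreasing tau
   can only move the TTS 3'-ward on a fixed curve.

Fallbacks keep every gene in the report: no credible peak → TTS at the
annotated end (``no_peak_gene_end``); peak without decay before the region
end → TTS at the region end (``no_decay_region_end``). Only ``decay_found``
genes enter the refined BED unless fallbacks are explicitly kept.

The search region is not truncated at the next same-strand gene by
default; closely spaced active neighbours can therefore contaminate the 3'
signal. This is a known, deliberate simplification.

## TU annotation

TU callers (e.g. groHMM) segment coverage into contiguous transcribed
intervals with no names. Each TU is compared against the inferred gene set
on its chromosome and strand; a gene *qualifies* when the TU covers at
least ``min_frac`` (default 0.5) of the *gene's* length. The threshold is
on fraction-of-gene, not fraction-of-TU, so a long TU engulfing a short
gene still inherits its name. A TU with one qualifying gene keeps its
interval and takes the name; with k ≥ 2 it is split at the midpoints
between adjacent genes' facing boundaries into k segments that exactly
tile the parent; with none it is ``UNANNOTATED``. Odd midpoints round
toward the TU's 5' side, which makes splitting exactly mirror-symmetric
between strands. If the inferred genes themselves overlap (they normally
do not), contested bases go to the longer gene, ties to the more 5' one,
so the gene set behind the split is always disjoint. When one gene ends up
covered by several records, each record keeps the plain ``gene_id`` and
its display label gains a 5'→3' ordinal (``geneA_1``, ``geneA_2``).

An optional snap of TU boundaries onto inferred gene boundaries was
considered and not implemented; annotated TUs keep the caller's (or the
split's) coordinates.

## Quantification

``count_matrix`` sums reads per gene interval per sample — a plain TSV a
differential-expression tool (DESeq2, edgeR) consumes directly; no
normalization or testing is done here. The pause index is

    PI = (pause_count / pause_len) / (body_count / body_len)

with the pause window the first ``pause_len`` (default 50) transcribed
bases from the TSS and the body from ``pause_len + body_gap`` (default gap
0) to the TTS. Zero body density leaves PI undefined (flagged), never
infinite; genes shorter than ``pause_len + body_gap + 1`` are flagged and
excluded from distributions. The directional claim the tests check: when
an annotation's start sits upstream of the true initiation site, its pause
window covers silent sequence, so coordinates anchored at the true TSS
yield a strictly larger PI.

## Synthetic data

The generator writes the exact formats the pipeline consumes (bedGraph ×2
strands, isoform table, TU BED, truth TSV) and a truth table. Per gene it
places: a pause peak (``pause_reads``, default 300, multinomially spread
over a 50-base window starting 20–60 bases downstream of the true TSS);
per-base Poisson body counts (mean ``body_rate``, default 0.5 reads/base —
a typical expressed-gene density in mammalian PRO-seq at moderate depth);
readthrough at body density for ``readthrough_len`` (default 2,000) bases
past the annotated end; a termination peak of ``termination_peak_reads``
(default 600) whose per-base rate decays linearly to zero over
``termination_decay_len`` (default 600) bases — the true TTS is the decay
end; and optional genome-wide Poisson background. The standard layout
(``default_study``) places alternating-strand genes of 8–15 kb with 26 kb
between footprints (same-strand neighbours 52 kb apart, so search regions
never touch a neighbour), 2–4 candidate first exons per gene with decoys
0.6–3 kb upstream of the true start — mimicking the common situation in
which the curated envelope starts upstream of the active promoter.

What the generator does not emulate: mappability and GC artifacts,
enhancer bidirectional transcription near 3' ends, overlapping or nested
genes, and neighbour readthrough into downstream promoters. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated signal model, not performance on adversarial real loci.

Test and verification scales — 100-gene studies for recovery rates
(noiseless and with background at 1% of body rate), 50 seeds × 6 genes for
the TU partition property, 500–600 randomized queries against a dense
per-base oracle for the counting primitives — run in seconds while giving
binomial resolution comfortably below the asserted margins.

## Numerical choices and edge cases

* Coordinates are uniformly 0-based half-open (BED); 5' and 3' ends of
  minus-strand features are handled by two helpers, never inline
  arithmetic. Minus-strand signal files may carry negative values;
  magnitudes are stored.
* Region queries run on run-length steps with a precomputed cumulative
  mass, so a count is two binary searches; bin counting is one vectorized
  query per region.
* Queries on chromosomes absent from the track return 0 with a warning
  (annotation builds routinely include scaffolds the tracks lack).
* Genes whose isoforms disagree on chromosome or strand are dropped with a
  warning, not repaired.
* Expression filter defaults (min 25 reads and 1 read/kb over the largest
  interval) are deliberate knobs, not claims about any reference pipeline.

## Known limitations

* GCV smoothing treats a *single* outlying bin — a lone sharp spike over
  near-silence — as noise and smears it; profiles like that want a small
  explicit ``smoothness`` (e.g. 0.1). With a realistic termination
  structure spanning ≥2–3 bins, GCV tracks the peak well.
* TTS resolution is ±1 bin by construction; B trades resolution against
  count stability.
* Multi-modal termination (plural peaks) is resolved by the global
  maximum; selecting among multiple peaks is a possible extension.
* The pause-index window definitions vary across the literature; both
  windows are parameters and comparisons should fix them explicitly.
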