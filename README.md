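# pta — primary transcript annotation for nascent run-on sequencing

Nascent run-on assays (PRO-seq / GRO-seq) map engaged RNA polymerase at
base resolution, strand-specifically. The transcribed unit they measure —
the **primary transcript** — does not match mRNA annotations: initiation
concentrates at one of several annotated alternative starts, and
polymerase reads through kilobases past the polyadenylation/cleavage site
before terminating. `pta` infers data-driven primary-transcript
coordinates from the coverage itself and puts them to work:

* **TSS inference** — among a gene's annotated first-exon 5' ends, pick
  the candidate whose downstream window of `W` bases (default 500)
  carries the maximal read count; promoter-proximally paused polymerase
  makes the active start the clear winner.
* **TTS inference** — over a 3' search region (the 3'-most fraction of
  the gene plus a fixed extension past its annotated end), bin the
  coverage (bin width `B`), fit a penalized cubic smoothing spline to the
  bin counts, take the fitted curve's global maximum as the termination
  peak, and call the TTS at the first downstream bin whose fitted value
  decays to `tau`·peak (default `tau` = 0.1).
* **TU annotation** — de novo transcription units (e.g. groHMM calls)
  inherit gene identifiers by overlap with the inferred genes; TUs
  spanning several genes are split at midpoints between adjacent gene
  boundaries into segments that exactly tile the TU; TUs covering no gene
  are marked `UNANNOTATED`.
* **Quantification** — per-gene count matrices under any coordinate set
  (export for DESeq2/edgeR and the like), and promoter-proximal pause
  indices PI = (pause reads / pause length) / (body reads / body length).

Inputs are strand-specific bedGraph (or bigWig) coverage, isoform
annotations (BED12 or a 6+2-column isoform table), and optionally BED6 TU
calls. All outputs are BED6/TSV. A seeded synthetic-data generator
(`pta synth` / `pta.synth`) emulates PRO-seq signal — pause peak, uniform
body, termination peak with decay, readthrough, Poisson background — with
a ground-truth table, so the whole stack is testable without downloads.

## Worked example

Generate a small synthetic dataset (6 genes, 0.5 reads/base body density,
background at 1 % of the body rate) and run the full pipeline:

```bash
pta synth --n-genes 6 --seed 11 --noise-rate 0.005 --outdir fixtures/
pta pipeline \
    --isoforms fixtures/isoforms.bed \
    --plus fixtures/coverage_plus.bedgraph \
    --minus fixtures/coverage_minus.bedgraph \
    --tus fixtures/tus.bed \
    --outdir out/
```

`out/inferred_genes.bed` holds the refined primary-transcript
coordinates:

```
chrS	18200	29646	gene001	0	+
chrS	38688	53330	gene002	0	-
chrS	70200	81862	gene003	0	+
```

For `gene001` the truth table says the planted TSS is 18,200 and the
planted termination-decay end is 29,736, while the *annotated* envelope
runs 15,687–27,136: the inferred start skipped the decoy upstream first
exon exactly, and the inferred end lands 90 bases short of the true TTS
(within one 200-base bin), capturing the ~2.5 kb of readthrough the
annotation misses. `out/tss_report.tsv` shows why the call is confident:

```
gene_id	chrom	strand	tss	window_count	n_candidates	tie_broken	zero_signal
gene001	chrS	+	18200	558	2	False	False
gene002	chrS	-	53330	564	3	False	False
```

558 reads sit in the 500-base window downstream of the winning candidate
(pause peak plus body), versus background-level counts at the decoys.
`out/pause_index.tsv` quantifies pausing under the refined coordinates —
e.g. `gene003` has pause density 3.7 reads/base against body density 0.54,
pause index 6.8. Had the pause window been anchored at the annotated
start 2.8 kb upstream, it would cover silent DNA and dilute the index
toward zero; that directional improvement is asserted package-wide in the
test suite.

Every stage is equally usable as a library:

```python
from pta import collect_first_exons, infer_tss, infer_tts, read_bed, read_coverage

track = read_coverage("fixtures/coverage_plus.bedgraph",
                      "fixtures/coverage_minus.bedgraph")
genes = collect_first_exons(read_bed("fixtures/isoforms.bed", "isoform_table"))
call = infer_tss(genes["gene001"], track)        # TSSCall(tss=18200, ...)
tts = infer_tts(genes["gene001"].largest_iv, track)  # TTSCall(tts=29646, ...)
```

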