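# regulocus

Locus-scale regulatory genomics toolkit for analysing how a distal
super-enhancer contacts the promoters of a clustered gene family. The
package implements four analysis stages plus a synthetic-locus generator
that produces every input with known ground truth, so the whole pipeline
runs with no external data:

- **fragmap** — in-silico restriction digestion of a genome into an
  ordered fragment map (cleavage at the motif's 5' start, e.g. `^GATC`),
  blind-fragment annotation from a secondary cutter (`CATG`), and
  assignment of count records and viewpoints to fragments.
- **tracks** — viewpoint contact profiles: viewpoint exclusion (±2 kb by
  default), normalization to a reference region (single multiplicative
  factor, reference sum = 1e6), an 11-fragment running mean, and
  between-condition log2 ratio tracks.
- **difftest** — differential-contact significance: per-fragment
  increased/decreased signs on unsmoothed normalized signal, a 2×2
  region-by-direction contingency table (enhancer region vs the remainder
  of its domain), and a G-test of independence (df = 1, optional Williams
  correction).
- **se_rank** — super-enhancer calling: stitch peaks within 12.5 kb, rank
  by summed signal, and apply the hockey-stick cutoff (first slope > 1 on
  the unit-scaled rank curve).
- **nucleus** — single-nucleus ATAC QC (six strict thresholds:
  peak-region fragments in (3000, 100000), % reads in peaks > 15,
  blacklist ratio < 0.025, nucleosome signal < 10, TSS enrichment > 2)
  and fiber-type classification by promoter-accessibility dominance.
- **simulate** — synthetic genome/locus with planted cut sites, 4C counts
  with power-law distance decay, negative-binomial noise and a plantable
  loop enrichment, a peak landscape with one heavy 7-peak cluster, and a
  nucleus×promoter matrix from a labelled class mixture.

## Command line

Everything is reachable through one entry point (`regulocus`, or
`python -m regulocus.cli`). A complete synthetic run:

```sh
regulocus simulate --seed 1 --out run/
regulocus digest   --fasta run/genome.fa --out run/fragments.bed
regulocus track    --counts run/counts_A.tsv --fragments run/fragments.bed \
                   --viewpoint chrS:562000-562001 --coords zero-half-open \
                   --reference run/tads.bed --condition A --out-prefix run/trackA
regulocus track    --counts run/counts_B.tsv --fragments run/fragments.bed \
                   --viewpoint chrS:562000-562001 --coords zero-half-open \
                   --reference run/tads.bed --condition B --out-prefix run/trackB
regulocus difftest --track-a run/trackA.normalized.bedgraph \
                   --track-b run/trackB.normalized.bedgraph \
                   --fragments run/fragments.bed \
                   --viewpoint chrS:562000-562001 \
                   --se chrS:500000-542000 --tad chrS:450000-700000 \
                   --coords zero-half-open --out run/difftest.tsv
regulocus se-call  --peaks run/peaks.bed --signal-col 5 --out-prefix run/se
regulocus classify --metrics run/nuclei.tsv --out run/labels.tsv
```

Region strings on the command line default to 1-based inclusive
(genome-browser style, commas and en dashes accepted, e.g.
`chr11: 67,103,534–67,145,377`); pass `--coords zero-half-open` for BED
convention. All internal computation is 0-based half-open. Every
subcommand writes a `manifest.json` with its parameters, seed, and input
SHA-256 hashes.

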