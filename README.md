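# cutscope

Analysis toolkit for CRISPR/Cas9 start-codon-disruption experiments:

- **digenome** — a gap-tolerant cut-site caller for in-vitro Cas9 digestion
  sequencing: strand-specific read-start/coverage profiles from sorted
  SAM/BAM, a ≥5-read-start filter, a ≥25%-of-coverage filter, plus/minus
  joining with blunt / 1 bp gap / 1 bp overhang geometry, and a
  combined-strand score (candidates reported at score > 60).
- **offtarget** — classification of candidate sites by homology to the
  guide+PAM sequence: windowed single-gap-tolerant scanning on both strands,
  percent identity over the full guide+PAM length, degenerate PAM matching,
  and genomic-context annotation (coding / intron / antisense / intergenic)
  from BED or GFF3.
- **amplicon** — indel quantification from amplicon deep sequencing:
  median-quality filtering, global affine-gap alignment to the expected
  amplicon, no-change/insertion/deletion classification in a window around
  the start codon, indel-size spectra, inserted-base composition of 1-bp
  insertions inside the codon, and cryptic-ATG / Kozak −3 assessment.
- **quantify** — cell-number inference from gDNA mass, normalization of
  indel rates by inferred/expected cell populations, mean ± SD summaries,
  and an in-silico CviAII/Hin1II (C^ATG) restriction-digest screen with
  merged-band prediction.
- **synthdata** — deterministic generators for toy genomes, Cas9-digestion
  read sets with known cut-site truth, and amplicon read sets with a
  configurable indel spectrum, so the whole pipeline is testable offline.
- **pipeline** — end-to-end orchestration with TSV reports and JSON
  manifests that reconcile read counts across stages.

## CLI

```sh
# synthetic inputs
cutscope simulate genome --length 10000 --seed 1 --out genome.fa
cutscope simulate digenome --genome genome.fa --cut chr1:5000:blunt:1.0 \
    --depth 30 --seed 1 --out reads.sam
cutscope simulate amplicon --reads 10000 --event ins:83:1:A:0.2 \
    --seed 1 --out reads.fastq

# cut-site calling and homology classification
cutscope digenome call --bam reads.sam --min-starts 5 --min-frac 0.25 \
    --score 60 --out candidates.tsv
cutscope offtarget classify --treated reads.sam --genome genome.fa \
    --guide GATTACAGATTACAGATTATGG --identity 70 --outdir out/

# amplicon quantification and normalization
cutscope amplicon quantify --fastq reads.fastq --outdir out/
cutscope quantify normalize --rate 18.5 --gdna 192
cutscope quantify digest --fasta amplicon.fa --enzyme CviAII

# full runs from a YAML config (mode: digenome | amplicon)
cutscope run --config run.yaml --seed 1
```

Coordinates are 0-based half-open internally; TSV reports use 1-based
starts. All simulators are byte-deterministic for a fixed seed.

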