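# cycmotif

Toolkit for finding candidate nucleotide-cyclase catalytic centres in
protein sequences with PROSITE-style bracket patterns, plus the supporting
machinery to interpret and validate such searches:

- **motif model** — parse/serialize bracket patterns (`[RKS]`, `X`, `X{9}`,
  `X{1,3}`) into position-annotated motif objects, with derivation
  operators (substitute a residue class, pin a wildcard position, prepend
  an upstream anchor) and a catalogue of built-in cyclase-centre presets
  (`gc_core`, `ac_core`, `ac_anchored`, `ac_fv5`, `ac_kr15`,
  `functional_core`).
- **scanner** — exhaustive variable-gap matching over protein FASTA files,
  reporting every distinct match span (including overlaps and alternative
  gap lengths), with per-record and per-locus (isoform-collapsed) hit
  counts, TSV and GFF3 output.
- **background stats** — union-bound probability that a motif matches at a
  fixed position under an i.i.d. residue composition, and expected
  site/record hit counts for a proteome.
- **co-expression** — Pearson-correlation gene ranking against a query gene
  (ECG lists) and log2 fold-change tables between labelled conditions.
- **simulator** — synthetic proteomes with planted motif instances (exact
  ground truth) and expression matrices with designed correlation and
  induction structure; used throughout the test suite as an oracle.

## CLI

```sh
cycmotif presets                       # list built-in motifs (--yaml-out to export)
cycmotif scan --motif ac_core --motif "[R]X{2}[DE]" \
    --fasta proteome.fasta --counting locus \
    --summary-tsv summary.tsv --hits-tsv hits.tsv --gff3 hits.gff3 \
    --background uniform               # adds expected-hit columns
cycmotif simulate --n-records 500 --mean-length 300 --motif ac_core \
    --n-insertions 100 --seed 7 --out-fasta sim.fasta --out-truth truth.tsv
cycmotif coexpr --matrix expr.tsv --groups groups.tsv --query AT1G68110 \
    --k 200 --out-ecg ecg.tsv --treatment infected --control mock \
    --out-lfc lfc.tsv
```

Every subcommand also accepts `--config cfg.yaml`; explicit flags override
config values.  Exit codes: 0 ok, 1 usage error, 2 data error.

## File formats

- Proteins: plain FASTA (uppercased at load, one trailing `*` stripped,
  ambiguity codes never satisfy a named class).
- Hits: TSV (`record_id, motif, start, end, matched, gap_choices`) and
  optional GFF3 (`polypeptide_motif`, 1-based inclusive protein coords).
- Expression: TSV with gene ids in the first column and sample ids as the
  header; optional two-column `sample<TAB>condition` group file.
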