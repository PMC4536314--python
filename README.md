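# eventpsi

Event-centric alternative-splicing analysis from transcript quantification.

`eventpsi` enumerates binary alternative-splicing events from a transcript
annotation (GTF) and computes their per-sample inclusion levels (PSI, Ψ)
directly from transcript abundances, skipping read mapping entirely. Any
quantifier that emits a transcript × sample TPM table (Salmon, kallisto,
Sailfish, RSEM, ...) can drive it, which makes genome-wide splicing
profiling fast enough for large sample collections on a laptop.

It is aimed at transcriptomics researchers who want event-level splicing
estimates (the representation used by RT-PCR validation and most splicing-
regulation analyses) without the cost of junction-read counting tools.

## The model

An alternative-splicing **event** is a local, binary variation of the
exon–intron structure within one gene. Seven types are enumerated:

| code | event | reported (Ψ) form |
|------|-------|--------------------|
| SE | skipping (cassette) exon | includes the middle exon |
| A5 | alternative 5′ (donor) site | minimizes the intron length |
| A3 | alternative 3′ (acceptor) site | minimizes the intron length |
| MX | mutually exclusive exons | contains the genomically left-most alternative exon (regardless of strand) |
| RI | retained intron | retains the intron |
| AF | alternative first exon | maximizes the intron length |
| AL | alternative last exon | maximizes the intron length |

Each event partitions the gene's supporting isoforms into two disjoint
sets: F₁ (the reported form) and F₂ (the alternative form). Given
transcript abundances TPMₖ, the inclusion level of the event in a sample
is

```
Ψ = Σ_{k ∈ F1} TPM_k / Σ_{j ∈ F1 ∪ F2} TPM_j
```

Ψ is reported as `NA` when the denominator is zero or when the gene's
total TPM does not exceed the expression filter (`--total-filter`, e.g. 1).
Events are keyed by splice-junction coordinates, so isoforms that differ
only in outer exon boundaries pool into the same event. Event identifiers
follow `<gene_id>;<type>:<seqname>:<coordinates>:<strand>`.

## Worked example

The `makeFixtures` subcommand writes a synthetic annotation plus a TPM
table whose ground-truth Ψ is known exactly (each gene has two isoforms
differing by a single event, so Ψ equals the inclusion isoform's relative
abundance):

```console
$ eventpsi makeFixtures -o fx --events-per-type 1 --samples 2 --seed 5
$ eventpsi generateEvents -i fx.gtf -o events
INFO eventpsi: annotation: 7 genes, 14 transcripts
INFO eventpsi: SE: 1 events -> events_SE.ioe
...
$ cat events_SE.ioe
seqname gene_id event_id        alternative_transcripts total_transcripts
chrS    G_SE_0  G_SE_0;SE:chrS:2282-2679:3012-3767:+    G_SE_0.t1       G_SE_0.t1,G_SE_0.t2
```

The ioe row says: the skipping-exon event in gene `G_SE_0` spans the two
inclusion junctions 2282–2679 and 3012–3767; isoform `t1` realizes the
inclusion form, and `t1`+`t2` together carry the whole event. Computing Ψ
from the TPM table:

```console
$ eventpsi psiPerEvent --ioe-file events_SE.ioe --expression-file fx.tpm -o se
$ cat se.psi
event_id        sample1 sample2
G_SE_0;SE:chrS:2282-2679:3012-3767:+    0.053930702381656426    0.38336888078551823
```

i.e. 5.4% of the gene's output includes the exon in sample 1 and 38.3% in
sample 2 — exactly the relative abundances planted in `fx.tpm` (compare
`fx_truth.psi`). `evaluate` quantifies agreement between two PSI files
(Pearson r and the cumulative |ΔΨ| curve):

```console
$ eventpsi evaluate --estimated se_big.psi --reference truth_big.psi
sample  sample1
n_events        5
pearson_r       1.000000
cdf@0.05        1.000000
...
```

The same functionality is available as a library
(`eventpsi.parse_gtf`, `eventpsi.detect_events`, `eventpsi.psi_per_event`,
...); see the module docstrings and `docs/methods.md`.

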