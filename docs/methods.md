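# Methods

## Event model

A splicing event is a binary local variation of exon–intron structure
within a single gene; transcripts from different genes never co-define an
event, even when they overlap genomically, because the event identifier
binds one `gene_id`. Coordinates are handled exactly as in GTF — 1-based,
inclusive at both ends — throughout the package, so every number in an
event identifier can be matched against the annotation without off-by-one
conversions. A junction is written as the pair (donor-side exon end,
acceptor-side exon start) in genomic order.

Detection conditions per type (all evidence must come from transcripts of
the same gene):

* **SE** — some transcript carries the junction pair (e1,s2),(e2,s3) with
  the exon (s2,e2) between them, and another carries the skipping
  junction (e1,s3).
* **A5/A3** — two junctions share one anchor coordinate and differ at the
  other, and the exons flanking the variable boundary overlap (otherwise
  the variation is a different exon, not an alternative boundary of the
  same exon). The type label is strand-aware: a variation at the genomic
  left coordinate is a donor (A5) variation on `+` and an acceptor (A3)
  variation on `-`.
* **MX** — two internal exons share both outer junction anchors, do not
  overlap, and never co-occur in one isoform.
* **RI** — one form splices the junction (e1,s2); the other contains a
  single exon spanning the whole region.
* **AF/AL** — two distinct, non-overlapping terminal exons splice to a
  shared anchor junction. First/last is assigned per strand (the first
  exon of a minus-strand transcript is its genomically right-most one).

### Form conventions (which side Ψ reports)

F1 is: the inclusion form (SE); the form minimizing intron length
(A5/A3); the form whose alternative exon has the smallest start
coordinate, regardless of strand (MX); the form retaining the intron
(RI); the form maximizing intron length (AF/AL).

### Junction keying and outer boundaries

Events are keyed by their junction coordinates, so isoforms that differ
only in outer exon boundaries pool into the same event; this maximizes
the transcript sets entering the Ψ ratio. Where the identifier includes
non-junction boundaries (RI outer exon start/end, AF/AL terminal exon
boundaries), the package uses the *widest* boundaries among supporting
transcripts (minimum start / maximum end). Consequences worth knowing:
the RI retaining form must span those widest boundaries, and an AF/AL
event is only emitted when the terminal exons of *all* supporters of the
two forms are mutually non-overlapping. These are deliberate,
conservative choices; any fixed convention here is defensible, and this
one makes pooling deterministic and output byte-stable.

Form membership is intentionally simple: a transcript supports a form iff
its intron chain contains the form's defining junction(s), plus the
defining exon for SE-inclusion and MX, the spanning exon for
RI-retention, and the matching terminal exon for AF/AL. Membership never
depends on which transcript pair first revealed the event, so re-running
detection, or duplicating transcript entries, reproduces the identical
catalog.

### Mirror symmetry

Reflecting all coordinates through a constant and flipping the strand is
the reverse complement of the locus and preserves every event type;
reflecting without the strand flip exchanges A5↔A3 and AF↔AL and
preserves SE/MX/RI. Ψ values carry over unchanged under both transforms
for every type except MX: the left-most rule is strand-agnostic by
definition, so the reported MX form swaps under any reflection and Ψ maps
to 1−Ψ. The test suite pins both behaviours.

## Ψ computation

Ψ = ΣF1 TPM / Σ(F1∪F2) TPM per event and sample. Degenerate inputs never
raise: a zero denominator gives NA; an event none of whose transcripts
appear in the quantification gives NA (and an all-NA catalog raises,
since that indicates mismatched annotation and quantification);
transcripts listed in an event but absent from the table contribute zero
TPM with a one-time warning. NA causes are counted and attached to the
result (`DataFrame.attrs["na_causes"]`).

The expression filter drops Ψ values (to NA) in samples where the gene's
total TPM is not strictly greater than the threshold; a threshold of 1 is
the conventional choice for noisy low-expression genes. The filter is
applied per sample. By default no filter is active. Gene totals are the
sum of the gene's transcript TPMs — all annotated transcripts when an
annotation is available, otherwise the union of the gene's event
transcripts recorded in the ioe file (the only information the ioe
carries). Bias-corrected and uncorrected TPMs are accepted identically;
no correction is applied internally.

## Synthetic data

`make_two_isoform_gene` builds a gene whose two isoforms differ by
exactly one event of a requested type, on a toy chromosome of ~10^4 bp
(structure is all that matters; no sequence is generated). For such genes
Ψ is identical to the inclusion isoform's relative abundance, so
`make_quantification` inverts the pipeline exactly: inclusion TPM =
ψ·T, alternative TPM = (1−ψ)·T for a chosen gene total T. This is the
ground-truth construction the recovery tests rely on, and it is exact —
recovery is asserted to 1e-9, not approximately.

`make_noisy_quantification` multiplies each TPM by an i.i.d. log-normal
factor with unit mean and a chosen coefficient of variation. This mimics
the magnitude structure of quantification error (positive, roughly
multiplicative) but none of its real correlates: no read-sampling
shot noise at low expression, no length or GC bias, no correlated errors
between isoforms sharing sequence. Passing the noise tests therefore
shows the pipeline degrades gracefully and monotonically with abundance
error, not that any particular real-data accuracy is achieved.

`make_random_gene` draws 2–5 transcripts over a shared grid of 2–6 exon
slots with optional alternative boundaries, producing the tangled
multi-event genes used to cross-check the detectors against the
brute-force oracle in `tests/oracle.py` (pairwise template matching by
direct case analysis — an independent implementation, not a wrapper).

## Numerical and formatting choices

* Ψ uses plain double-precision division; with exact two-isoform input
  the only rounding is in the final divide, hence the 1e-9 recovery bound
  (observed error is typically 0 to a few ulp).
* All outputs are byte-stable: events sort by (seqname, first signature
  coordinate, event id); transcript lists in ioe files are comma-joined
  sorted; the PSI matrix follows catalog order. Missing Ψ is rendered
  `NA`.
* The GTF parser accepts Ensembl and UCSC attribute spacing, deduplicates
  repeated exon lines, merges book-ended exons (zero-length introns break
  junction logic) with a warning, and drops transcripts whose strand
  disagrees with their gene's first-seen strand (the form conventions are
  undefined across mixed strands). The default chromosome filter keeps
  autosomes and X/Y in both `1` and `chr1` naming; `--keep-scaffolds`
  disables it.
* Correlation is `scipy.stats.pearsonr`; the |ΔΨ| CDF is an exact
  empirical CDF evaluated on a user grid. Pairs with NA on either side
  are dropped before metrics (comparisons are restricted to events
  quantified by both sources).

## Problem sizes in the checks

The acceptance script uses 500 planted two-isoform genes (all seven
types), 1000 random multi-transcript genes for oracle agreement, 300
events for the noise benchmark at CV 0.2, and 100 events for the
complementarity bound — sizes at which every quantity is stable to well
within the reported precision while the whole script runs in seconds.

## Known limitations

* Only binary events; complex variations with three or more
  conformations are better described at the transcript-isoform level.
* Accuracy on real data is bounded by the quantifier and the annotation's
  completeness; uncertainty in transcript quantification is not
  propagated into Ψ (no confidence intervals).
* No GFF3 input, no CDS/UTR modelling, and no differential-splicing
  (ΔΨ significance) testing — estimation only.
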