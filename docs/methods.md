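# Methods

## Model and procedure

`techimera` calls a transcript TE-initiated when its 5' end arises inside
an annotated transposable element and the surrounding read evidence is
consistent with transcription emanating from the element. The unit of
evidence is the *fragment*: a proper read pair collapsed to its two
aligned mates (split around skipped introns) plus the outer span between
them. Two discovery routes are used:

* **tss_in_te** — the assembled transcript's TSS base (start of the first
  exon on `+`, `end − 1` of the genomically last exon on `−`) lies inside
  a TE interval. Fragmented element rows sharing an identity key are first
  merged to their envelope, so an LTR interrupted by later Alu insertions
  counts as one promoter.
* **upstream_extension** — the assembly lacks the TE-initiated 5' end, but
  at least one fragment has one mate inside a TE upstream of the
  transcript's first exon (within a linking distance, default 10 kb) and
  the other mate inside that exon.

When the assembly already contains a TE-initiated isoform of a gene in a
given element, the extension route is suppressed for that (element, gene):
otherwise every assembled TE isoform would also spawn a redundant
extension call on the gene's native transcript and double-count the locus.

### Filter metrics

All exon-level counting uses mate blocks, not outer spans: the outer span
of a junction-spanning fragment covers the whole intron it straddles and
would credit native spliced fragments to a TE-resident exon. Per-base
*coverage*, by contrast, deliberately counts outer spans (fragment-level
coverage), which is what the upstream-coverage filter and the promoter
peak analysis consume.

* **Supporting fragments** — fragments with a mate on the TE-resident
  first exon (TSS route) or bridging fragments (extension route); the
  cutoff is max(base, ⌈N/divisor⌉) for a library of N mapped fragments
  (base 3, divisor 2·10⁷ relaxed; base 6, divisor 10⁷ stringent). The
  divisor rule is interpreted in fragments (read pairs), the same unit as
  the count it gates.
* **Directional bias** — sense/antisense ratio of oriented fragments
  overlapping the TE, sense meaning the candidate transcript's direction.
  Orientation comes from the spliced-aligner `XS` strand tag; fragments
  without one are excluded. No antisense evidence gives +∞ (passes); no
  oriented evidence at all is undefined (fails).
* **First-exon RPKM** — fragments per kb of first exon per million mapped
  fragments.
* **Contribution** — the TE first exon's fragment share over the union of
  the gene's distinct first exons; first exons with >50 % reciprocal
  overlap are pooled as one promoter. An all-zero denominator is
  undefined (fails).
* **Upstream coverage ratio** — mean fragment coverage in the TE over the
  adjacent upstream window (transcription direction), window length
  min(TE length, 1 kb), truncated at the chromosome edge; a zero-length
  window passes with a flag, zero upstream coverage with nonzero TE
  coverage gives +∞.
* **Upstream exon ratio** — mean RPKM of gene exons entirely upstream of
  the TE first exon relative to that exon's RPKM; passes strictly below
  the cutoff, vacuously when no upstream exons exist.

Threshold semantics follow the wording of each rule: "at least"/"-fold
higher" filters pass at ≥ the cutoff, the upstream-exon filter at strict <.
Candidates are ordered by (chromosome, TE start, transcript id), making
call tables byte-deterministic for fixed input.

### Cohort statistics

* Class-normalized counts: mean accepted calls per library per class,
  divided by the class's genomic coverage (union length), scaled by the
  all-class density over normal samples, which is the cohort-pooled
  expectation and maps to 1.0.
* Paired counts: accepted calls of one class (default LTR), scaled to
  calls per 10⁷ mapped fragments. The scale cancels in the sign test.
* Sign test: exact binomial at p₀ = 0.5 over informative pairs (ties
  excluded); two-sided p = 2·min(tails), capped at 1 — identical to the
  minimum-likelihood two-sided p under the symmetric null.
* Recurrence: per (gene, TE element) locus, presence/absence per library
  forms a 2×2 table tested with Fisher's exact test (two-sided),
  Benjamini–Hochberg adjusted across loci; loci never called in a normal
  library are additionally flagged cancer-only. Fisher + BH is a choice —
  the enrichment test is isolated behind one function so a binomial or
  mid-p variant could be swapped in.
* Promoter contribution: peak (per-base maximum) fragment coverage over
  the TE and native promoter intervals; `te_share = peak_te /
  (peak_te + peak_native)`, and the summed promoter peak relative to the
  peak over downstream common exons as a total-expression check.
* Activity/expression correlation: Spearman rank correlation (midranks
  for ties) between per-patient TE-exon RPKM and the within-pair change
  in mean common-exon RPKM; the p-value is an exact two-sided permutation
  p for n ≤ 8 and the large-sample approximation otherwise.

### Truncated ORF prediction

For a chimera that lost the exon carrying the native ATG, translation is
assumed to start at the first ATG in the native reading frame (scanning
model). The frame is anchored by the cDNA offset of a stated native codon;
all in-frame ATGs within the native CDS span are reported, the first one
selected, and `n_lost_residues` is its codon index minus one. ATGs in the
TE-derived leader are outside the native frame region and not considered;
absence of any in-frame ATG flags the transcript non-coding.

## Synthetic data

The simulator lays out a toy diploid-agnostic genome (default: two 1-Mb
chromosomes) whose first half holds gene loci and whose second half holds
background TE annotations of every class, including a deliberately
fragmented two-row element. Default genes (5 exons × 500 bp, 3-kb introns)
cover three promoter archetypes — a solo LTR in intron 1 driving an
alternative first exon, an antisense LTR upstream splicing into exon 1,
and a TE over the annotated first exon — plus a TE-free negative control,
an antisense read-through decoy and a sub-threshold decoy, across the
ERV1/ERVL/MaLR LTR subclasses and a SINE-promoted gene that LTR-specific
de-repression leaves untouched.

Fragments are sampled per isoform: a uniform 150–350 bp insert placed
uniformly along the mature transcript, 100-bp mates projected to genomic
blocks through the exon chain, written as coordinate-sorted SAM with `XS`
strand tags (flipped with the orientation-noise probability, default
0.01). Each library's total fragment count is fixed at its sequenced depth
(default 4 000 fragments, ±20 % jitter) and allocated multinomially over
isoform weights — RNA-seq is compositional, so de-repression shifts
composition rather than adding reads; modeling it additively would make
cancer libraries systematically deeper and invert library-size-corrected
comparisons. Cancer members multiply TE-isoform weights by a per-class
de-repression factor (default LTR ×10), and every library additionally
draws a lognormal TE-activity factor (σ = 0.4, unit mean), reproducing the
between-patient heterogeneity that the activity/expression correlation
analysis requires; drawing it in both conditions keeps the
no-de-repression null exchangeable. One percent of fragments are uniform
intergenic noise.

Ground truth is tabulated per planted chimera from the realized fragments:
junction-evidence counts, first-exon counts, sense/antisense counts,
contribution and RPKM are simple overlap counts recomputable by the filter
formulas; the two coverage-ratio metrics are evaluated on the generated
fragments with the caller's own coverage functions (their values depend on
the whole fragment cloud, not on planted counts alone), so the end-to-end
recovery test exercises SAM round-trip, discovery, pairing and the count
filters independently, while coverage filters are checked for consistency.

What the simulator does not model: sequence content (reads carry no
bases), alignment and assembly errors, multi-mapping, PCR duplicates,
overlapping genes, and expression-level covariates. Passing tests
therefore demonstrate the correctness of the calling and statistics
machinery under clean alignments, not robustness to mapping artifacts.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale cohorts — 20 matched pairs
(50 for the null-balance check) at 4 000 fragments per library — chosen so
every planted effect sits several σ from its threshold while the whole
suite completes in about a minute. Degenerate inputs follow explicit
conventions stated per metric (∞ passes, NaN/undefined fails, vacuous
cases pass); the exact permutation cutoff for Spearman is n ≤ 8; BH
adjustment and Fisher tests use the standard library routines; coordinate
handling is 0-based half-open internally with GTF read/written 1-based
inclusive and RepeatMasker `.out` converted on input.

## Known limitations

* BED inputs without a class column fall back to a repeat-name prefix
  table covering common human nomenclature; unknown names become class
  `Other`.
* The envelope merge of fragmented elements counts interruption bases as
  element coverage, so class coverage is not invariant under merging for
  gapped elements (inherent to the envelope definition).
* Single-end libraries are unsupported; orientation inference requires
  `XS` tags (no splice-motif fallback, since reads carry no sequence in
  the simulator and real spliced aligners emit the tag).
* The contribution denominator uses first exons only; genes whose
  isoforms share a first exon but differ downstream are treated as one
  promoter.
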