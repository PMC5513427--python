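"""Detection of TE-initiated (chimeric) transcripts from aligned fragments.

Candidates are (TE, transcript) pairs discovered either because the
transcript's TSS lies inside an annotated TE (``tss_in_te``) or because
read-pair clusters bridge an upstream TE into the transcript's first exon
(``upstream_extension``).  Each candidate is then scored with the six filter
metrics — supporting fragments, directional bias, first-exon RPKM,
contribution to the gene's promoter-level output, TE-versus-upstream
coverage and upstream-exon expression — and accepted when every metric
clears the active :class:`ThresholdSet` (relaxed or stringent).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotations_io import (
    GenomicInterval,
    TEAnnotation,
    TranscriptModel,
    first_exon,
    transcript_tss,
)

__all__ = [
    "FragmentAlignment",
    "Library",
    "ThresholdSet",
    "ChimeraCandidate",
    "CallSet",
    "CoverageSummary",
    "load_fragments",
    "min_supporting_fragments",
    "per_base_coverage",
    "discover_candidates",
    "compute_directional_bias",
    "compute_exon_rpkm",
    "compute_contribution",
    "compute_upstream_coverage_ratio",
    "compute_upstream_exon_ratio",
    "apply_thresholds",
    "call_library",
    "write_calls",
    "read_calls",
    "CALL_COLUMNS",
]

FILTER_NAMES = ("fragments", "bias", "rpkm", "contribution", "upcov", "upexon")

DEFAULT_LINKING_DISTANCE = 10_000
DEFAULT_UPSTREAM_WINDOW_CAP = 1_000


class DetectionError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentAlignment:
    """One paired-end fragment collapsed from its two mates.

    ``outer`` spans the 5'-most to 3'-most aligned base of the pair;
    ``mate_blocks`` keeps each mate's aligned blocks (split around skipped
    introns), used for exon-level assignment — an outer span crosses any
    intron the fragment straddles, so exon counting must not use it.
    ``orientation`` is the inferred transcriptional direction of the
    fragment.
    """

    outer: GenomicInterval
    orientation: str = "."  # +, -, or . for unknown
    spliced: bool = False
    library_id: str = ""
    mate_blocks: (
        tuple[tuple[GenomicInterval, ...], tuple[GenomicInterval, ...]] | None
    ) = None

    def blocks(self) -> tuple[GenomicInterval, ...]:
        if self.mate_blocks is None:
            return (self.outer,)
        return self.mate_blocks[0] + self.mate_blocks[1]

    def mate_overlaps(self, interval: GenomicInterval) -> bool:
        return any(b.overlaps(interval) for b in self.blocks())


@dataclass(frozen=True)
class Library:
    library_id: str
    patient_id: str = ""
    condition: str = "cancer"  # cancer | normal
    total_fragments: int = 1

    def __post_init__(self) -> None:
        if self.condition not in ("cancer", "normal"):
            raise DetectionError(f"invalid condition {self.condition!r}")
        if self.total_fragments <= 0:
            raise DetectionError("total_fragments must be positive")


@dataclass(frozen=True)
class ThresholdSet:
    """Filter cutoffs for calling a TE-initiated transcript.

    ``relaxed`` maximizes sensitivity, ``stringent`` specificity; the
    supporting-fragment requirement additionally scales with library size
    via ``spCOE_divisor`` (one fragment per that many mapped fragments).
    """

    mode: str
    scREADS: int
    scTHREAD: float
    scRPKM: float
    scCONTR: float
    scUPCOV: float
    scUPEXON: float
    spCOE_divisor: float

    @classmethod
    def relaxed(cls) -> "ThresholdSet":
        return cls("relaxed", 3, 5.0, 1.0, 0.1, 2.0, 1.5, 20e6)

    @classmethod
    def stringent(cls) -> "ThresholdSet":
        return cls("stringent", 6, 10.0, 1.0, 0.5, 3.0, 1.5, 10e6)

    @classmethod
    def from_mode(cls, mode: str) -> "ThresholdSet":
        if mode == "relaxed":
            return cls.relaxed()
        if mode == "stringent":
            return cls.stringent()
        raise DetectionError(f"unknown threshold mode {mode!r}")


@dataclass
class ChimeraCandidate:
    """A (TE, transcript) pair with filter metrics and verdicts.

    Ratio metrics may be ``inf`` (always passing) or ``nan`` (undefined,
    always failing); ``upstream_exon_ratio`` is ``None`` when the gene has
    no exons upstream of the TE-resident first exon (vacuous pass).
    """

    te: TEAnnotation
    transcript: TranscriptModel
    route: str  # tss_in_te | upstream_extension
    n_supporting_fragments: int | None = None
    directional_bias: float | None = None
    exon_rpkm: float | None = None
    contribution: float | None = None
    upstream_cov_ratio: float | None = None
    upstream_exon_ratio: float | None = None
    upstream_exon_applicable: bool = False
    verdicts: dict[str, bool] = field(default_factory=dict)
    accepted: bool = False
    flags: tuple[str, ...] = ()


@dataclass
class CallSet:
    library: Library
    thresholds: ThresholdSet
    candidates: list[ChimeraCandidate]

    @property
    def library_id(self) -> str:
        return self.library.library_id

    @property
    def calls(self) -> list[ChimeraCandidate]:
        return [c for c in self.candidates if c.accepted]


@dataclass(frozen=True)
class CoverageSummary:
    depth: np.ndarray
    mean: float
    peak: float


# --------------------------------------------------------------------------
# Fragment loading
# --------------------------------------------------------------------------

def load_fragments(
    path: str | os.PathLike, library: Library
) -> list[FragmentAlignment]:
    """Collapse primary proper pairs of a SAM/BAM file into fragments.

    Secondary, supplementary, duplicate and unmapped records are skipped.
    Transcriptional orientation is taken from the ``XS`` strand tag
    (spliced-aligner convention) when present, else unknown.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    try:
        af = pysam.AlignmentFile(str(path), mode)
    except (ValueError, OSError) as exc:
        raise DetectionError(f"{path}: cannot open alignments: {exc}") from exc
    with af:
        if not af.header.references:
            raise DetectionError(f"{path}: missing or empty SAM header")
        pending: dict[str, pysam.AlignedSegment] = {}
        fragments: list[FragmentAlignment] = []
        n_records = 0
        for rec in af:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
            ):
                continue
            n_records += 1
            if not rec.is_paired:
                raise DetectionError(
                    f"{path}: unpaired record {rec.query_name!r}; "
                    "single-end libraries are not supported"
                )
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            fragments.append(_pair_to_fragment(mate, rec, library.library_id))
        if n_records and not fragments:
            raise DetectionError(
                f"{path}: no complete pairs found; single-end or truncated input"
            )
    return fragments


def _pair_to_fragment(
    a: pysam.AlignedSegment, b: pysam.AlignedSegment, library_id: str
) -> FragmentAlignment:
    chrom = a.reference_name
    blocks_a = tuple(
        GenomicInterval(chrom, s, e) for s, e in a.get_blocks()
    )
    blocks_b = tuple(
        GenomicInterval(b.reference_name, s, e) for s, e in b.get_blocks()
    )
    all_blocks = blocks_a + blocks_b
    outer = GenomicInterval(
        chrom,
        min(iv.start for iv in all_blocks),
        max(iv.end for iv in all_blocks),
    )
    orientation = "."
    for rec in (a, b):
        if rec.has_tag("XS"):
            orientation = rec.get_tag("XS")
            break
    spliced = any("N" in (rec.cigarstring or "") for rec in (a, b))
    return FragmentAlignment(
        outer=outer,
        orientation=orientation if orientation in "+-" else ".",
        spliced=spliced,
        library_id=library_id,
        mate_blocks=(blocks_a, blocks_b),
    )


# --------------------------------------------------------------------------
# Filter metrics
# --------------------------------------------------------------------------

def min_supporting_fragments(total_fragments: int, thresholds: ThresholdSet) -> int:
    """Library-size-scaled fragment threshold: the greater of the base
    requirement and one fragment per ``spCOE_divisor`` mapped fragments."""
    if total_fragments <= 0:
        raise DetectionError("total_fragments must be positive")
    return max(thresholds.scREADS, math.ceil(total_fragments / thresholds.spCOE_divisor))


def per_base_coverage(
    fragments: list[FragmentAlignment], interval: GenomicInterval
) -> CoverageSummary:
    """Depth of fragment outer spans over each base of ``interval``."""
    n = len(interval)
    diff = np.zeros(n + 1, dtype=np.int64)
    for frag in fragments:
        ov_start = max(frag.outer.start, interval.start)
        ov_end = min(frag.outer.end, interval.end)
        if frag.outer.chrom == interval.chrom and ov_start < ov_end:
            diff[ov_start - interval.start] += 1
            diff[ov_end - interval.start] -= 1
    depth = np.cumsum(diff[:-1])
    return CoverageSummary(
        depth=depth, mean=float(depth.mean()), peak=float(depth.max(initial=0))
    )


def _count_mate_overlaps(
    fragments: list[FragmentAlignment], interval: GenomicInterval
) -> int:
    """Fragments with at least one aligned mate block overlapping the
    interval."""
    return sum(1 for frag in fragments if frag.mate_overlaps(interval))


def compute_exon_rpkm(
    exon: GenomicInterval, fragments: list[FragmentAlignment], library: Library
) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    n = _count_mate_overlaps(fragments, exon)
    return n / ((len(exon) / 1e3) * (library.total_fragments / 1e6))


def compute_directional_bias(
    candidate: ChimeraCandidate, fragments: list[FragmentAlignment]
) -> float:
    """Sense/antisense ratio of oriented fragments over the TE interval,
    sense meaning the candidate transcript's direction of transcription.
    ``inf`` when no antisense fragment exists; ``nan`` (undefined, fails)
    when no oriented fragment overlaps the TE."""
    te_iv = candidate.te.interval
    sense = antisense = 0
    for frag in fragments:
        if frag.orientation not in "+-" or not frag.outer.overlaps(te_iv):
            continue
        if frag.orientation == candidate.transcript.strand:
            sense += 1
        else:
            antisense += 1
    if sense + antisense == 0:
        return math.nan
    if antisense == 0:
        return math.inf
    return sense / antisense


def _pool_first_exons(
    gene_transcripts: list[TranscriptModel],
) -> list[list[GenomicInterval]]:
    """Group the distinct first exons of a gene's transcripts, pooling
    exons with >50% reciprocal overlap (alternative TSS resolution)."""
    exons: list[GenomicInterval] = []
    for tx in gene_transcripts:
        fe = first_exon(tx)
        if fe not in exons:
            exons.append(fe)
    parent = list(range(len(exons)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(exons)):
        for j in range(i + 1, len(exons)):
            ov = exons[i].overlap_length(exons[j])
            if ov > 0.5 * len(exons[i]) and ov > 0.5 * len(exons[j]):
                parent[find(i)] = find(j)
    groups: dict[int, list[GenomicInterval]] = {}
    for i, exon in enumerate(exons):
        groups.setdefault(find(i), []).append(exon)
    return list(groups.values())


def compute_contribution(
    candidate: ChimeraCandidate,
    gene_transcripts: list[TranscriptModel],
    fragments: list[FragmentAlignment],
) -> float:
    """Fraction of the gene's promoter-level output from the TE first exon.

    The denominator is the fragment total over the union of distinct first
    exons of the gene's transcripts; first exons with >50% reciprocal
    overlap are pooled as one promoter.  ``nan`` when no first exon has any
    fragment (undefined, fails).
    """
    te_fe = first_exon(candidate.transcript)
    groups = _pool_first_exons(gene_transcripts)
    te_count = 0
    total = 0
    for group in groups:
        count = sum(
            1
            for frag in fragments
            if any(frag.mate_overlaps(exon) for exon in group)
        )
        total += count
        if any(exon == te_fe for exon in group):
            te_count = count
    if total == 0:
        return math.nan
    return min(1.0, max(0.0, te_count / total))


def compute_upstream_coverage_ratio(
    candidate: ChimeraCandidate,
    fragments: list[FragmentAlignment],
    window_cap: int = DEFAULT_UPSTREAM_WINDOW_CAP,
) -> tuple[float, tuple[str, ...]]:
    """Mean coverage inside the TE over mean coverage in the adjacent
    upstream window (transcription direction); window length is
    ``min(TE length, window_cap)``, truncated at the chromosome edge."""
    te_iv = candidate.te.interval
    strand = candidate.transcript.strand
    wlen = min(len(te_iv), window_cap)
    if strand == "+":
        w_start, w_end = te_iv.start - wlen, te_iv.start
        if w_start < 0:
            w_start = 0
    else:
        w_start, w_end = te_iv.end, te_iv.end + wlen
    flags: tuple[str, ...] = ()
    if w_start >= w_end:
        return math.inf, ("no_upstream_window",)
    te_mean = per_base_coverage(fragments, te_iv).mean
    window = GenomicInterval(te_iv.chrom, w_start, w_end)
    up_mean = per_base_coverage(fragments, window).mean
    if up_mean == 0:
        return (math.inf if te_mean > 0 else math.nan), flags
    return te_mean / up_mean, flags


def compute_upstream_exon_ratio(
    candidate: ChimeraCandidate,
    gene_transcripts: list[TranscriptModel],
    fragments: list[FragmentAlignment],
    library: Library,
) -> float | None:
    """Mean RPKM of gene exons upstream (transcription direction) of the
    TE-resident first exon, relative to that exon's RPKM.

    ``None`` when the gene has no upstream exons (the filter then passes
    vacuously); ``inf`` when the TE exon itself has zero RPKM.
    """
    te_fe = first_exon(candidate.transcript)
    strand = candidate.transcript.strand
    upstream: list[GenomicInterval] = []
    seen = set()
    for tx in gene_transcripts:
        for exon in tx.exons:
            if exon == te_fe or exon in seen:
                continue
            if strand == "+" and exon.end <= te_fe.start:
                upstream.append(exon)
                seen.add(exon)
            elif strand == "-" and exon.start >= te_fe.end:
                upstream.append(exon)
                seen.add(exon)
    if not upstream:
        return None
    te_rpkm = compute_exon_rpkm(te_fe, fragments, library)
    up_rpkm = float(
        np.mean([compute_exon_rpkm(e, fragments, library) for e in upstream])
    )
    if te_rpkm == 0:
        return math.inf
    return up_rpkm / te_rpkm


# --------------------------------------------------------------------------
# Candidate discovery
# --------------------------------------------------------------------------

def discover_candidates(
    transcripts: list[TranscriptModel],
    fragments: list[FragmentAlignment],
    tes: list[TEAnnotation],
    linking_distance: int = DEFAULT_LINKING_DISTANCE,
) -> list[ChimeraCandidate]:
    """Find (TE, transcript) candidate pairs.

    Route ``tss_in_te``: the transcript's TSS base falls inside a TE
    interval.  Route ``upstream_extension``: at least one fragment bridges
    an upstream TE (one mate inside the TE, the other inside the
    transcript's first exon), the TE's near edge lying within
    ``linking_distance`` of the first exon.  Duplicate pairs keep the
    ``tss_in_te`` route.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, te in enumerate(tes):
        iv = te.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)

    frag_by_chrom: dict[str, list[FragmentAlignment]] = {}
    for frag in fragments:
        frag_by_chrom.setdefault(frag.outer.chrom, []).append(frag)

    found: dict[tuple[str, str], ChimeraCandidate] = {}
    tss_genes: set[tuple[str, str]] = set()
    for tx in transcripts:
        tree = trees.get(tx.chrom)
        if tree is None:
            continue
        tss = transcript_tss(tx)
        for hit in tree.at(tss):
            te = tes[hit.data]
            te_key = te.element_id or repr(te.interval)
            found[(te_key, tx.transcript_id)] = ChimeraCandidate(
                te=te, transcript=tx, route="tss_in_te"
            )
            tss_genes.add((te_key, tx.gene_id))
    # upstream-extension route: TEs upstream of a transcript's first exon
    # whose near edge is within linking_distance, supported by at least one
    # bridging fragment.  Skipped when the assembly already contains a
    # TE-initiated isoform of the same gene in the same element — the
    # extension evidence is then redundant with the assembled contig.
    for tx in transcripts:
        tree = trees.get(tx.chrom)
        if tree is None:
            continue
        fe = first_exon(tx)
        if tx.strand == "+":
            region = (max(0, fe.start - linking_distance), fe.start)
        else:
            region = (fe.end, fe.end + linking_distance)
        for hit in tree.overlap(*region):
            te = tes[hit.data]
            te_key = te.element_id or repr(te.interval)
            if (te_key, tx.transcript_id) in found or (
                te_key,
                tx.gene_id,
            ) in tss_genes:
                continue
            if _has_bridging_fragment(
                frag_by_chrom.get(tx.chrom, []), te.interval, fe
            ):
                found[(te_key, tx.transcript_id)] = ChimeraCandidate(
                    te=te, transcript=tx, route="upstream_extension"
                )
    ordered = sorted(
        found.values(),
        key=lambda c: (
            c.te.interval.chrom,
            c.te.interval.start,
            c.transcript.transcript_id,
        ),
    )
    return ordered


def _bridging_fragments(
    fragments: list[FragmentAlignment],
    te_iv: GenomicInterval,
    fe: GenomicInterval,
) -> list[FragmentAlignment]:
    out = []
    for frag in fragments:
        if frag.mate_blocks is None:
            continue
        m1, m2 = frag.mate_blocks
        hit1_te = any(b.overlaps(te_iv) for b in m1)
        hit2_te = any(b.overlaps(te_iv) for b in m2)
        hit1_fe = any(b.overlaps(fe) for b in m1)
        hit2_fe = any(b.overlaps(fe) for b in m2)
        if (hit1_te and hit2_fe) or (hit2_te and hit1_fe):
            out.append(frag)
    return out


def _has_bridging_fragment(
    fragments: list[FragmentAlignment],
    te_iv: GenomicInterval,
    fe: GenomicInterval,
) -> bool:
    return bool(_bridging_fragments(fragments, te_iv, fe))


def _count_supporting_fragments(
    candidate: ChimeraCandidate, fragments: list[FragmentAlignment]
) -> int:
    """Chimeric-junction evidence: fragments on the TE-resident first exon
    for the TSS route, bridging fragments for the extension route."""
    if candidate.route == "tss_in_te":
        return _count_mate_overlaps(fragments, first_exon(candidate.transcript))
    return len(
        _bridging_fragments(
            fragments, candidate.te.interval, first_exon(candidate.transcript)
        )
    )


# --------------------------------------------------------------------------
# Threshold application and library-level calling
# --------------------------------------------------------------------------

def apply_thresholds(
    candidate: ChimeraCandidate, thresholds: ThresholdSet, library: Library
) -> ChimeraCandidate:
    """Fill per-filter verdicts and the accept decision.

    Every "minimum"/"-fold higher" filter passes at >= its cutoff; the
    upstream-exon filter passes at strictly < its cutoff ("less than
    1.5-fold").  ``nan`` metrics fail, ``inf`` ratios pass, a ``None``
    upstream-exon ratio passes vacuously.
    """
    required = {
        "n_supporting_fragments": candidate.n_supporting_fragments,
        "directional_bias": candidate.directional_bias,
        "exon_rpkm": candidate.exon_rpkm,
        "contribution": candidate.contribution,
        "upstream_cov_ratio": candidate.upstream_cov_ratio,
    }
    for name, value in required.items():
        if value is None:
            raise DetectionError(f"metric {name} missing on candidate")

    def ge(value: float, cutoff: float) -> bool:
        return not math.isnan(value) and value >= cutoff

    n_min = min_supporting_fragments(library.total_fragments, thresholds)
    verdicts = {
        "fragments": candidate.n_supporting_fragments >= n_min,
        "bias": ge(candidate.directional_bias, thresholds.scTHREAD),
        "rpkm": ge(candidate.exon_rpkm, thresholds.scRPKM),
        "contribution": ge(candidate.contribution, thresholds.scCONTR),
        "upcov": ge(candidate.upstream_cov_ratio, thresholds.scUPCOV),
        "upexon": (
            candidate.upstream_exon_ratio is None
            or (
                not math.isnan(candidate.upstream_exon_ratio)
                and candidate.upstream_exon_ratio < thresholds.scUPEXON
            )
        ),
    }
    candidate.verdicts = verdicts
    candidate.accepted = all(verdicts.values())
    return candidate


def compute_candidate_metrics(
    candidate: ChimeraCandidate,
    gene_transcripts: list[TranscriptModel],
    fragments: list[FragmentAlignment],
    library: Library,
    upstream_window_cap: int = DEFAULT_UPSTREAM_WINDOW_CAP,
) -> ChimeraCandidate:
    """Fill all six filter metrics on a discovered candidate in place."""
    candidate.n_supporting_fragments = _count_supporting_fragments(
        candidate, fragments
    )
    candidate.directional_bias = compute_directional_bias(candidate, fragments)
    candidate.exon_rpkm = compute_exon_rpkm(
        first_exon(candidate.transcript), fragments, library
    )
    candidate.contribution = compute_contribution(
        candidate, gene_transcripts, fragments
    )
    ratio, flags = compute_upstream_coverage_ratio(
        candidate, fragments, upstream_window_cap
    )
    candidate.upstream_cov_ratio = ratio
    candidate.flags = candidate.flags + flags
    candidate.upstream_exon_ratio = compute_upstream_exon_ratio(
        candidate, gene_transcripts, fragments, library
    )
    candidate.upstream_exon_applicable = candidate.upstream_exon_ratio is not None
    return candidate


def call_library(
    transcripts: list[TranscriptModel],
    fragments: list[FragmentAlignment],
    tes: list[TEAnnotation],
    library: Library,
    thresholds: ThresholdSet,
    linking_distance: int = DEFAULT_LINKING_DISTANCE,
    upstream_window_cap: int = DEFAULT_UPSTREAM_WINDOW_CAP,
) -> CallSet:
    """Run discovery, metric computation and thresholding for one library."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    candidates = discover_candidates(transcripts, fragments, tes, linking_distance)
    frag_by_chrom: dict[str, list[FragmentAlignment]] = {}
    for frag in fragments:
        frag_by_chrom.setdefault(frag.outer.chrom, []).append(frag)
    for cand in candidates:
        local = frag_by_chrom.get(cand.transcript.chrom, [])
        compute_candidate_metrics(
            cand,
            by_gene[cand.transcript.gene_id],
            local,
            library,
            upstream_window_cap,
        )
        apply_thresholds(cand, thresholds, library)
    return CallSet(library=library, thresholds=thresholds, candidates=candidates)


# --------------------------------------------------------------------------
# Call TSV I/O (master-list shape)
# --------------------------------------------------------------------------

CALL_COLUMNS = [
    "library_id",
    "chrom",
    "te_start",
    "te_end",
    "te_name",
    "te_family",
    "te_class",
    "ltr_subclass",
    "element_id",
    "gene_id",
    "transcript_id",
    "route",
    "n_fragments",
    "bias",
    "rpkm",
    "contribution",
    "upcov_ratio",
    "upexon_ratio",
    "pass_fragments",
    "pass_bias",
    "pass_rpkm",
    "pass_contribution",
    "pass_upcov",
    "pass_upexon",
    "accepted",
]


def _fmt_ratio(value: float | None) -> str:
    if value is None:
        return "NA"
    if math.isinf(value):
        return "inf"
    if math.isnan(value):
        return "nan"
    return f"{value:.6g}"


def write_calls(callset: CallSet, path: str | os.PathLike) -> None:
    rows = []
    for c in callset.candidates:
        rows.append(
            {
                "library_id": callset.library_id,
                "chrom": c.te.interval.chrom,
                "te_start": c.te.interval.start,
                "te_end": c.te.interval.end,
                "te_name": c.te.repeat_name,
                "te_family": c.te.repeat_family,
                "te_class": c.te.te_class,
                "ltr_subclass": c.te.ltr_subclass,
                "element_id": c.te.element_id,
                "gene_id": c.transcript.gene_id,
                "transcript_id": c.transcript.transcript_id,
                "route": c.route,
                "n_fragments": c.n_supporting_fragments,
                "bias": _fmt_ratio(c.directional_bias),
                "rpkm": _fmt_ratio(c.exon_rpkm),
                "contribution": _fmt_ratio(c.contribution),
                "upcov_ratio": _fmt_ratio(c.upstream_cov_ratio),
                "upexon_ratio": _fmt_ratio(c.upstream_exon_ratio),
                **{f"pass_{k}": int(c.verdicts.get(k, False)) for k in FILTER_NAMES},
                "accepted": int(c.accepted),
            }
        )
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_calls(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"library_id": str, "chrom": str, "element_id": str}
    )
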