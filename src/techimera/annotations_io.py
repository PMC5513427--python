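"""Annotation I/O: transposable-element intervals, transcript models, genomes.

Coordinate conventions used throughout the package:

* internal intervals are 0-based, half-open ``[start, end)``;
* GTF is read and written as 1-based inclusive;
* BED is 0-based half-open.

The module parses RepeatMasker ``.out`` tables and BED TE annotations into
:class:`TEAnnotation` records, Cufflinks-style GTF into
:class:`TranscriptModel` records, merges fragmented element copies, computes
per-class genomic coverage, and predicts the truncated open reading frame of
a chimeric transcript that lost its native start codon.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, replace

import gffutils

__all__ = [
    "GenomicInterval",
    "TEAnnotation",
    "TranscriptModel",
    "TruncationReport",
    "parse_repeatmasker",
    "merge_fragmented_elements",
    "parse_transcript_models",
    "write_transcript_models",
    "write_te_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "class_genomic_coverage",
    "first_exon",
    "transcript_tss",
    "predict_truncated_orf",
    "classify_repeat",
]

STRANDS = ("+", "-", ".")
TE_CLASSES = ("LTR", "LINE", "SINE", "DNA", "Other")
LTR_SUBCLASSES = ("ERV1", "ERVL", "MaLR", "none")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("interval chromosome must be non-empty")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class TEAnnotation:
    """One annotated transposable-element interval.

    ``element_id`` links rows belonging to one biological element whose
    genomic copy was fragmented, e.g. an LTR interrupted by later Alu
    insertions; :func:`merge_fragmented_elements` joins such rows.
    """

    interval: GenomicInterval
    repeat_name: str
    repeat_family: str = ""
    te_class: str = "Other"
    ltr_subclass: str = "none"
    element_id: str = ""
    unknown_chrom: bool = False

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise AnnotationError(f"invalid te_class {self.te_class!r}")
        if self.ltr_subclass not in LTR_SUBCLASSES:
            raise AnnotationError(f"invalid ltr_subclass {self.ltr_subclass!r}")
        if self.ltr_subclass != "none" and self.te_class != "LTR":
            raise AnnotationError(
                "ltr_subclass is only meaningful for te_class LTR"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """Assembled multi-exon transcript; exons ordered 5'->3' in transcription
    direction (genomically descending for minus-strand transcripts)."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        if not self.exons:
            raise AnnotationError(
                f"transcript {self.transcript_id}: at least one exon required"
            )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in itertools.pairwise(genomic):
            if a.end > b.start:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        expected = tuple(genomic) if self.strand == "+" else tuple(genomic[::-1])
        if tuple(self.exons) != expected:
            object.__setattr__(self, "exons", expected)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    def cdna_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class TruncationReport:
    """Predicted translational consequence of a chimeric 5' replacement.

    Codon indices are 1-based positions in the native coding frame; the
    first in-frame ATG downstream of the chimeric junction defines the
    putative new start, losing ``n_lost_residues`` native N-terminal
    residues.
    """

    junction_offset: int
    first_inframe_atg_codon: int | None
    n_lost_residues: int | None
    candidate_atgs: tuple[int, ...]
    non_coding: bool = False


# --------------------------------------------------------------------------
# RepeatMasker class string -> (te_class, ltr_subclass)
# --------------------------------------------------------------------------

_LTR_SUBCLASS_MAP = {
    "ERV1": "ERV1",
    "ERVL": "ERVL",
    "ERVL-MALR": "MaLR",
    "MALR": "MaLR",
}

# Subfamily-name fallbacks for BED files that carry no class column.  These
# cover the common human repeat nomenclature prefixes (MST*/MLT*/THE* are
# MaLR LTRs; LTR*/MER4*/HERV* are ERV1-dominated; Alu/MIR are SINEs; L1/L2
# are LINEs).
_NAME_CLASS_RULES: tuple[tuple[str, tuple[str, str]], ...] = (
    ("MST", ("LTR", "MaLR")),
    ("MLT", ("LTR", "MaLR")),
    ("THE", ("LTR", "MaLR")),
    ("HERV", ("LTR", "ERV1")),
    ("MER4", ("LTR", "ERV1")),
    ("LTR", ("LTR", "ERV1")),
    ("ERVL", ("LTR", "ERVL")),
    ("ALU", ("SINE", "none")),
    ("MIR", ("SINE", "none")),
    ("L1", ("LINE", "none")),
    ("L2", ("LINE", "none")),
    ("L3", ("LINE", "none")),
    ("SVA", ("Other", "none")),
    ("MARNA", ("DNA", "none")),
    ("TIGGER", ("DNA", "none")),
    ("CHARLIE", ("DNA", "none")),
    ("MER1", ("DNA", "none")),
)


def classify_repeat(class_family: str = "", repeat_name: str = "") -> tuple[str, str]:
    """Map a RepeatMasker ``class/family`` string (or, failing that, a
    subfamily name) to ``(te_class, ltr_subclass)``."""
    cf = class_family.strip()
    if cf:
        top, _, fam = cf.partition("/")
        top_u = top.upper()
        if top_u == "LTR":
            sub = _LTR_SUBCLASS_MAP.get(fam.upper(), "none")
            return "LTR", sub
        if top_u.startswith("LINE"):
            return "LINE", "none"
        if top_u.startswith("SINE"):
            return "SINE", "none"
        if top_u.startswith("DNA"):
            return "DNA", "none"
        return "Other", "none"
    name_u = repeat_name.upper()
    for prefix, result in _NAME_CLASS_RULES:
        if name_u.startswith(prefix):
            return result
    return "Other", "none"


# --------------------------------------------------------------------------
# RepeatMasker .out / BED parsing
# --------------------------------------------------------------------------

def _looks_like_rm_out(first_lines: list[str]) -> bool:
    for line in first_lines:
        if line.lstrip().lower().startswith(("sw", "score")):
            return True
        fields = line.split()
        # data row of a headerless .out: score, div, del, ins are numeric
        if len(fields) >= 14:
            try:
                int(fields[0])
                float(fields[1])
                float(fields[2])
                float(fields[3])
                return True
            except ValueError:
                pass
    return False


def _parse_rm_out_line(fields: list[str], lineno: int) -> TEAnnotation:
    try:
        chrom = fields[4]
        start = int(fields[5]) - 1  # .out is 1-based inclusive
        end = int(fields[6])
        strand = "+" if fields[8] == "+" else "-"
        repeat_name = fields[9]
        class_family = fields[10]
        element_id = fields[14] if len(fields) > 14 else ""
    except (IndexError, ValueError) as exc:
        raise AnnotationError(f"malformed RepeatMasker line {lineno}: {exc}") from exc
    te_class, ltr_subclass = classify_repeat(class_family, repeat_name)
    try:
        interval = GenomicInterval(chrom, start, end, strand)
    except AnnotationError as exc:
        raise AnnotationError(f"malformed RepeatMasker line {lineno}: {exc}") from exc
    return TEAnnotation(
        interval=interval,
        repeat_name=repeat_name,
        repeat_family=class_family,
        te_class=te_class,
        ltr_subclass=ltr_subclass,
        element_id=element_id,
    )


def _parse_bed_line(fields: list[str], lineno: int) -> TEAnnotation:
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
        name = fields[3] if len(fields) > 3 else f"TE_{lineno}"
        strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
        family = fields[6] if len(fields) > 6 else ""
        class_str = fields[7] if len(fields) > 7 else ""
        element_id = fields[8] if len(fields) > 8 else ""
    except (IndexError, ValueError) as exc:
        raise AnnotationError(f"malformed BED line {lineno}: {exc}") from exc
    if class_str:
        te_class, ltr_subclass = classify_repeat(f"{class_str}/{family}", name)
    elif family:
        te_class, ltr_subclass = classify_repeat(family, name)
    else:
        te_class, ltr_subclass = classify_repeat("", name)
    try:
        interval = GenomicInterval(chrom, start, end, strand)
    except AnnotationError as exc:
        raise AnnotationError(f"malformed BED line {lineno}: {exc}") from exc
    return TEAnnotation(
        interval=interval,
        repeat_name=name,
        repeat_family=family or class_str,
        te_class=te_class,
        ltr_subclass=ltr_subclass,
        element_id=element_id,
    )


def parse_repeatmasker(
    path: str | os.PathLike,
    chrom_sizes: dict[str, int] | None = None,
) -> list[TEAnnotation]:
    """Parse a TE annotation file (RepeatMasker ``.out`` or BED dialect).

    The dialect is auto-detected.  Records on chromosomes absent from
    ``chrom_sizes`` (when given) are retained but flagged via
    ``unknown_chrom``.  Rows lacking an explicit element identifier get a
    synthetic one (``repeat_name.ordinal``) so each row is its own element.
    """
    with open(path) as fh:
        lines = fh.readlines()
    content = [
        (i + 1, ln.rstrip("\n"))
        for i, ln in enumerate(lines)
        if ln.strip() and not ln.startswith(("#", "track", "browser"))
    ]
    if not content:
        raise AnnotationError(f"{path}: empty annotation file")
    is_out = _looks_like_rm_out([ln for _, ln in content[:4]])
    records: list[TEAnnotation] = []
    for lineno, line in content:
        stripped = line.lstrip()
        if is_out and (
            stripped.lower().startswith(("sw", "score"))
            or set(stripped) <= set("= -")
        ):
            continue  # header lines of the .out format
        fields = stripped.split()
        if is_out:
            records.append(_parse_rm_out_line(fields, lineno))
        else:
            records.append(_parse_bed_line(fields, lineno))
    # assign synthetic element ids to rows lacking one
    counter = itertools.count()
    records = [
        rec
        if rec.element_id
        else replace(rec, element_id=f"{rec.repeat_name}.{next(counter)}")
        for rec in records
    ]
    if chrom_sizes is not None:
        records = [
            replace(rec, unknown_chrom=rec.interval.chrom not in chrom_sizes)
            for rec in records
        ]
    return records


def merge_fragmented_elements(annotations: list[TEAnnotation]) -> list[TEAnnotation]:
    """Join rows sharing an ``element_id`` into one envelope interval.

    A biological element split by later insertions (for example an LTR
    interrupted by antisense Alu copies) appears as several annotation rows;
    for promoter analysis it is one element, so rows with the same
    ``element_id`` are merged into ``[min start, max end)``.
    """
    by_id: dict[str, list[TEAnnotation]] = {}
    order: list[str] = []
    for rec in annotations:
        if rec.element_id not in by_id:
            order.append(rec.element_id)
        by_id.setdefault(rec.element_id, []).append(rec)
    merged: list[TEAnnotation] = []
    for eid in order:
        group = by_id[eid]
        if len(group) == 1:
            merged.append(group[0])
            continue
        chroms = {r.interval.chrom for r in group}
        if len(chroms) > 1:
            raise AnnotationError(
                f"element_id {eid!r} spans multiple chromosomes: {sorted(chroms)}"
            )
        head = group[0]
        envelope = GenomicInterval(
            head.interval.chrom,
            min(r.interval.start for r in group),
            max(r.interval.end for r in group),
            head.interval.strand,
        )
        merged.append(replace(head, interval=envelope))
    return sorted(merged, key=lambda r: (r.interval.chrom, r.interval.start))


# --------------------------------------------------------------------------
# GTF transcript models
# --------------------------------------------------------------------------

def parse_transcript_models(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse assembled transcript models from a GTF file.

    Only ``exon`` features are used; each must carry ``gene_id`` and
    ``transcript_id`` attributes (Cufflinks/StringTie convention).  Exons are
    grouped per transcript and ordered 5'->3' along the transcript strand.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationError(f"{path}: cannot parse GTF: {exc}") from exc

    groups: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.all_features(featuretype="exon", order_by=("seqid", "start")):
        tids = feat.attributes.get("transcript_id")
        gids = feat.attributes.get("gene_id")
        if not tids:
            raise AnnotationError(
                f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks a transcript_id attribute"
            )
        tid = tids[0]
        gid = gids[0] if gids else tid
        entry = groups.get(tid)
        if entry is None:
            groups[tid] = entry = {"gene_id": gid, "strand": feat.strand, "exons": []}
            order.append(tid)
        if feat.strand != entry["strand"]:
            raise AnnotationError(
                f"{path}: transcript {tid} has exons on inconsistent strands"
            )
        entry["exons"].append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    transcripts = []
    for tid in order:
        entry = groups[tid]
        if entry["strand"] not in ("+", "-"):
            raise AnnotationError(
                f"{path}: transcript {tid} has no usable strand"
            )
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=entry["gene_id"],
                strand=entry["strand"],
                exons=tuple(entry["exons"]),
            )
        )
    return transcripts


def write_transcript_models(
    transcripts: list[TranscriptModel], path: str | os.PathLike
) -> None:
    """Write transcript models as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            for exon in sorted(tx.exons, key=lambda e: e.start):
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            "techimera",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def write_te_bed(annotations: list[TEAnnotation], path: str | os.PathLike) -> None:
    """Write TE annotations as BED6+3 (family, class, element_id extras)."""
    with open(path, "w") as fh:
        for rec in annotations:
            iv = rec.interval
            class_str = rec.te_class
            if rec.te_class == "LTR" and rec.ltr_subclass != "none":
                fam = {"MaLR": "ERVL-MaLR"}.get(rec.ltr_subclass, rec.ltr_subclass)
            else:
                fam = rec.repeat_family
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        rec.repeat_name,
                        "0",
                        iv.strand if iv.strand in "+-" else ".",
                        fam,
                        class_str,
                        rec.element_id,
                    ]
                )
                + "\n"
            )


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise AnnotationError(f"{path}: malformed line {lineno}")
            sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise AnnotationError(f"{path}: empty chrom sizes file")
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# --------------------------------------------------------------------------
# Coverage and 5'-end utilities
# --------------------------------------------------------------------------

def _union_length(intervals: list[GenomicInterval]) -> int:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_start, cur_end = spans[0]
        for s, e in spans[1:]:
            if s > cur_end:
                total += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        total += cur_end - cur_start
    return total


def class_genomic_coverage(annotations: list[TEAnnotation]) -> dict[str, int]:
    """Genomic base pairs covered by each TE class (overlap-merged union).

    Returns coverage for every top-level class plus, for LTRs, the
    ``LTR:<subclass>`` resolution used by the ERV-class breakdown.
    """
    buckets: dict[str, list[GenomicInterval]] = {}
    for rec in annotations:
        buckets.setdefault(rec.te_class, []).append(rec.interval)
        if rec.te_class == "LTR":
            buckets.setdefault(f"LTR:{rec.ltr_subclass}", []).append(rec.interval)
    coverage = {cls: 0 for cls in TE_CLASSES}
    for key, ivs in buckets.items():
        coverage[key] = _union_length(ivs)
    return coverage


def first_exon(transcript: TranscriptModel) -> GenomicInterval:
    """The 5'-most exon in transcription direction (genomically last for
    minus-strand transcripts)."""
    return transcript.exons[0]


def transcript_tss(transcript: TranscriptModel) -> int:
    """TSS base of the transcript: ``start`` of the first exon on the plus
    strand, ``end - 1`` on the minus strand."""
    exon = first_exon(transcript)
    return exon.start if transcript.strand == "+" else exon.end - 1


# --------------------------------------------------------------------------
# Truncated ORF prediction
# --------------------------------------------------------------------------

def predict_truncated_orf(
    cdna: str,
    native_cds_codons: int,
    anchor_cdna_offset: int,
    anchor_codon: int = 1,
    junction_offset: int = 0,
) -> TruncationReport:
    """Predict the start codon and lost residues of a chimeric transcript.

    A TE-promoted isoform replaces the native 5' end; when the native ATG
    lies in a lost exon, translation is assumed to begin at the first
    in-frame ATG of the retained coding sequence (scanning-model reading).

    Parameters
    ----------
    cdna:
        Chimeric transcript sequence (TE-derived leader plus the retained
        native region).
    native_cds_codons:
        Length of the native coding sequence in codons.
    anchor_cdna_offset:
        0-based cDNA position of the first base of native codon
        ``anchor_codon`` — the frame anchor tying the chimera to the native
        reading frame.
    anchor_codon:
        1-based native codon index at the anchor position.
    junction_offset:
        cDNA position of the TE/native junction, recorded in the report.
    """
    seq = cdna.upper().replace("U", "T")
    frame_start = anchor_cdna_offset - 3 * (anchor_codon - 1)
    candidates: list[int] = []
    # scan only where the native frame exists (codon index >= 1)
    p = frame_start if frame_start >= 0 else frame_start + 3 * (
        (-frame_start + 2) // 3
    )
    for pos in range(p, len(seq) - 2, 3):
        codon_index = (pos - frame_start) // 3 + 1
        if codon_index > native_cds_codons:
            break
        if seq[pos : pos + 3] == "ATG":
            candidates.append(codon_index)
    if not candidates:
        return TruncationReport(
            junction_offset=junction_offset,
            first_inframe_atg_codon=None,
            n_lost_residues=None,
            candidate_atgs=(),
            non_coding=True,
        )
    first = candidates[0]
    return TruncationReport(
        junction_offset=junction_offset,
        first_inframe_atg_codon=first,
        n_lost_residues=first - 1,
        candidate_atgs=tuple(candidates),
        non_coding=False,
    )
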