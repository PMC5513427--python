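"""Self-contained simulator for matched cancer/normal RNA-seq fixtures.

The generator builds a toy genome carrying the three promoter archetypes a
TE-exaptation screen must handle — a solitary LTR inside an intron driving
an alternative first exon, an antisense LTR upstream of the gene splicing
into it, and a TE overlapping the annotated first exon — plus background
TE annotations of every class and negative-control genes.  Paired-end
fragments are sampled per isoform along the mature transcript and projected
to the genome through the exon structure, written as standard SAM, GTF,
BED and pairing-sheet files, together with a ground-truth table of planted
counts and the verdict each threshold mode is expected to reach.

Cancer members of a pair express TE-initiated isoforms at a per-class
de-repression multiple of the matched normal baseline, emulating the
epigenetic release of LTR promoters in tumors.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from .annotations_io import (
    GenomicInterval,
    TEAnnotation,
    TranscriptModel,
    classify_repeat,
    first_exon,
    merge_fragmented_elements,
    write_chrom_sizes,
    write_te_bed,
    write_transcript_models,
)
from .detection import (
    ChimeraCandidate,
    FragmentAlignment,
    Library,
    ThresholdSet,
    compute_upstream_coverage_ratio,
    compute_upstream_exon_ratio,
    min_supporting_fragments,
)

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "TruthRecord",
    "Fixture",
    "GeneFixture",
    "LibraryResult",
    "CohortBundle",
    "default_gene_specs",
    "build_fixture_genome",
    "simulate_library",
    "simulate_cohort",
]

ARCHETYPES = ("intronic_ltr", "upstream_antisense_ltr", "te_first_exon", "none")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSpec:
    """Declarative description of one simulated gene.

    ``te_fraction`` is the normal-condition share of the gene's expression
    budget spent on the TE-initiated isoform (the cancer member multiplies
    it by the class's de-repression factor); ``weight`` is the gene's share
    of library depth.  ``te_sense_fraction`` below 1 plants antisense
    read-through over the TE (a decoy the directional-bias filter must
    reject), and ``assembly_truncated`` omits the TE isoform from the GTF
    so the caller must recover it from bridging read pairs.
    """

    name: str
    archetype: str
    te_name: str = "MSTD"
    te_class: str = "LTR"
    ltr_subclass: str = "MaLR"
    te_fraction: float = 0.0
    weight: float = 0.08
    te_sense_fraction: float = 1.0
    assembly_truncated: bool = False

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise SimulationError(f"unknown archetype {self.archetype!r}")
        if not 0 <= self.te_fraction:
            raise SimulationError("te_fraction must be >= 0")
        if not 0 <= self.te_sense_fraction <= 1:
            raise SimulationError("te_sense_fraction must be in [0, 1]")


def default_gene_specs() -> tuple[GeneSpec, ...]:
    """The default simulated gene roster.

    Covers every archetype, LTR subclasses ERV1/ERVL/MaLR, a SINE-promoted
    gene that de-repression leaves untouched, a TE-free negative control,
    and two decoys (antisense read-through; sub-threshold support).
    """
    return (
        GeneSpec("geneA", "intronic_ltr", "MSTD", "LTR", "MaLR", 0.35),
        GeneSpec("geneB", "intronic_ltr", "LTR7", "LTR", "ERV1", 0.30),
        GeneSpec("geneC", "upstream_antisense_ltr", "LTR7B", "LTR", "ERV1", 0.20),
        GeneSpec("geneD", "te_first_exon", "MLT1C", "LTR", "MaLR", 0.25),
        GeneSpec("geneE", "intronic_ltr", "MSTA", "LTR", "MaLR", 0.01),
        GeneSpec("geneF", "te_first_exon", "AluY", "SINE", "none", 0.20),
        GeneSpec("geneG", "te_first_exon", "LTR33", "LTR", "ERVL", 0.15),
        GeneSpec("geneH", "none", te_fraction=0.0),
        GeneSpec(
            "geneI", "intronic_ltr", "LTR12C", "LTR", "ERV1", 0.20,
            te_sense_fraction=0.0,
        ),
        GeneSpec("geneJ", "intronic_ltr", "THE1B", "LTR", "MaLR", 0.005),
        GeneSpec(
            "geneK", "upstream_antisense_ltr", "LTR7Y", "LTR", "ERV1", 0.20,
            assembly_truncated=True,
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_pairs: int = 20
    depth: int = 4000
    depth_jitter: float = 0.2
    orientation_noise: float = 0.01
    noise_fraction: float = 0.01
    derepression: dict[str, float] = field(
        default_factory=lambda: {"LTR": 10.0}
    )
    # per-library lognormal scatter (sigma) of TE-promoter activity, drawn
    # independently for every library: matched cohorts are heterogeneous in
    # how strongly TE promoters fire, and the activity/expression
    # correlation analysis needs that between-patient variation
    derepression_sigma: float = 0.4
    fragment_length: tuple[int, int] = (150, 350)
    read_length: int = 100
    exon_length: int = 500
    intron_length: int = 3000
    n_exons: int = 5
    background_te_per_class: dict[str, int] = field(
        default_factory=lambda: {"LTR": 12, "LINE": 15, "SINE": 20, "DNA": 8}
    )
    genes: tuple[GeneSpec, ...] = field(default_factory=default_gene_specs)

    def __post_init__(self) -> None:
        for prob in (self.orientation_noise, self.noise_fraction):
            if not 0 <= prob <= 1:
                raise SimulationError("probabilities must be in [0, 1]")
        if self.depth <= 0 or self.n_pairs < 1:
            raise SimulationError("depth must be > 0 and n_pairs >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one (library, TE-gene) planted chimera."""

    library_id: str
    condition: str
    gene_id: str
    transcript_id: str
    element_id: str
    te_class: str
    ltr_subclass: str
    route: str
    n_te_fragments: int          # planted junction evidence (route-specific)
    n_te_exon_fragments: int     # fragments on the TE-resident first exon
    n_native_first_exon_fragments: int
    n_sense: int
    n_antisense: int
    contribution: float
    te_exon_rpkm: float
    upstream_cov_ratio: float
    upstream_exon_ratio: float | None
    expected_accept_relaxed: bool
    expected_accept_stringent: bool

    def expected_accept(self, mode: str) -> bool:
        return (
            self.expected_accept_relaxed
            if mode == "relaxed"
            else self.expected_accept_stringent
        )


@dataclass
class GeneFixture:
    spec: GeneSpec
    strand: str
    chrom: str
    native_tx: TranscriptModel | None
    te_tx: TranscriptModel | None
    te_rows: tuple[TEAnnotation, ...]
    te_merged: TEAnnotation | None


@dataclass
class Fixture:
    config: SimulationConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneFixture]
    background_tes: list[TEAnnotation]

    def te_annotations(self) -> list[TEAnnotation]:
        rows: list[TEAnnotation] = []
        for gene in self.genes:
            rows.extend(gene.te_rows)
        rows.extend(self.background_tes)
        return sorted(rows, key=lambda r: (r.interval.chrom, r.interval.start))

    def gtf_transcripts(self) -> list[TranscriptModel]:
        """Transcript models as the per-library assembly would report them
        (TE isoforms of assembly-truncated genes are absent)."""
        out: list[TranscriptModel] = []
        for gene in self.genes:
            if gene.native_tx is not None:
                out.append(gene.native_tx)
            if (
                gene.te_tx is not None
                and gene.te_tx is not gene.native_tx
                and not gene.spec.assembly_truncated
            ):
                out.append(gene.te_tx)
        return out


@dataclass
class LibraryResult:
    library: Library
    fragments: list[FragmentAlignment]
    truth: list[TruthRecord]
    sam_path: Path | None = None


@dataclass
class CohortBundle:
    fixture: Fixture
    outdir: Path
    gtf_path: Path
    te_bed_path: Path
    chrom_sizes_path: Path
    pairing_path: Path
    truth_path: Path
    libraries: list[LibraryResult]

    def pairing(self) -> dict[str, tuple[str, str]]:
        pairs: dict[str, tuple[str, str]] = {}
        for res in self.libraries:
            lib = res.library
            cancer, normal = pairs.get(lib.patient_id, ("", ""))
            if lib.condition == "cancer":
                cancer = lib.library_id
            else:
                normal = lib.library_id
            pairs[lib.patient_id] = (cancer, normal)
        return pairs


# --------------------------------------------------------------------------
# Genome construction
# --------------------------------------------------------------------------

def _map_local(
    local_start: int, local_end: int, anchor: int, strand: str, chrom: str,
    iv_strand: str | None = None,
) -> GenomicInterval:
    """Map a local (transcription-frame) interval to genome coordinates.

    For a plus-strand gene local position p maps to ``anchor + p``; for a
    minus-strand gene it maps mirrored so the TSS (local 0) is the highest
    base of the first exon.
    """
    if strand == "+":
        g = GenomicInterval(chrom, anchor + local_start, anchor + local_end)
    else:
        g = GenomicInterval(chrom, anchor - local_end, anchor - local_start)
    return replace(g, strand=iv_strand if iv_strand else strand)


def _build_gene(
    spec: GeneSpec,
    chrom: str,
    anchor: int,
    strand: str,
    config: SimulationConfig,
    element_ordinal: int,
) -> GeneFixture:
    E, I, K = config.exon_length, config.intron_length, config.n_exons
    exon_local = [(k * (E + I), k * (E + I) + E) for k in range(K)]

    def mk(local, iv_strand=None):
        return _map_local(local[0], local[1], anchor, strand, chrom, iv_strand)

    native_exons = tuple(mk(l) for l in exon_local)
    native_tx = TranscriptModel(
        transcript_id=f"{spec.name}.native",
        gene_id=spec.name,
        strand=strand,
        exons=native_exons,
    )
    eid = f"{spec.te_name}.{element_ordinal}"
    family = (
        f"{'ERVL-MaLR' if spec.ltr_subclass == 'MaLR' else spec.ltr_subclass}"
        if spec.te_class == "LTR"
        else ""
    )

    def te_ann(local, te_strand):
        return TEAnnotation(
            interval=mk(local, te_strand),
            repeat_name=spec.te_name,
            repeat_family=f"{spec.te_class}/{family}" if family else spec.te_class,
            te_class=spec.te_class,
            ltr_subclass=spec.ltr_subclass,
            element_id=eid,
        )

    if spec.archetype == "none":
        return GeneFixture(spec, strand, chrom, native_tx, None, (), None)

    if spec.archetype == "intronic_ltr":
        # solo LTR inside intron 1; TE isoform = TE exon spliced to exons 2..K
        ltr_local = (E + 1200, E + 2100)
        te_exon_local = (E + 1250, E + 2050)
        te_exons = (mk(te_exon_local),) + native_exons[1:]
        te_tx = TranscriptModel(
            transcript_id=f"{spec.name}.te",
            gene_id=spec.name,
            strand=strand,
            exons=te_exons,
        )
        rows = (te_ann(ltr_local, strand),)
    elif spec.archetype == "upstream_antisense_ltr":
        # antisense LTR upstream of the gene; TE isoform splices into exon 1
        anti = "-" if strand == "+" else "+"
        ltr_local = (-2500, -1900)
        te_exon_local = (-2450, -1950)
        te_exons = (mk(te_exon_local),) + native_exons
        te_tx = TranscriptModel(
            transcript_id=f"{spec.name}.te",
            gene_id=spec.name,
            strand=strand,
            exons=te_exons,
        )
        rows = (te_ann(ltr_local, anti),)
    else:  # te_first_exon: the annotated first exon sits inside the TE
        ltr_local = (-100, 300)
        te_tx = native_tx
        native_tx = None
        rows = (te_ann(ltr_local, strand),)

    merged = merge_fragmented_elements(list(rows))[0]
    return GeneFixture(spec, strand, chrom, native_tx, te_tx, rows, merged)


_BACKGROUND_NAMES = {
    "LTR": ("MLT1B", "LTR/ERVL-MaLR"),
    "LINE": ("L1PA14", "LINE/L1"),
    "SINE": ("AluSx", "SINE/Alu"),
    "DNA": ("MER1A", "DNA/hAT-Charlie"),
}
_BACKGROUND_LEN = {
    "LTR": (300, 900),
    "LINE": (500, 3000),
    "SINE": (100, 400),
    "DNA": (200, 800),
}


def build_fixture_genome(config: SimulationConfig) -> Fixture:
    """Lay out the toy genome: gene loci with their TE archetypes in the
    first half of each chromosome, background TE annotations (including one
    deliberately fragmented element per chromosome) in the second half."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sizes = {c: config.chromosome_length for c in chroms}
    slot = 60_000
    genes_per_chrom = math.ceil(len(config.genes) / config.n_chromosomes)
    needed = 20_000 + genes_per_chrom * slot
    gene_zone_end = int(config.chromosome_length * 0.55)
    if needed > gene_zone_end:
        raise SimulationError(
            f"cannot fit {len(config.genes)} genes on {config.n_chromosomes} "
            f"chromosomes of {config.chromosome_length} bp; need chromosome_length "
            f">= {int(needed / 0.55) + 1}"
        )
    genes: list[GeneFixture] = []
    for i, spec in enumerate(config.genes):
        chrom = chroms[i % config.n_chromosomes]
        slot_index = i // config.n_chromosomes
        base = 20_000 + slot_index * slot
        strand = "+" if i % 2 == 0 else "-"
        gene_span = (
            config.n_exons * config.exon_length
            + (config.n_exons - 1) * config.intron_length
        )
        anchor = base + 6_000 if strand == "+" else base + 6_000 + gene_span
        genes.append(_build_gene(spec, chrom, anchor, strand, config, i))

    background: list[TEAnnotation] = []
    ordinal = 1000
    for chrom in chroms:
        zone_start = int(config.chromosome_length * 0.60)
        zone_end = int(config.chromosome_length * 0.95)
        for te_class, count in sorted(config.background_te_per_class.items()):
            name, family = _BACKGROUND_NAMES[te_class]
            lo, hi = _BACKGROUND_LEN[te_class]
            for _ in range(count):
                length = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(zone_start, zone_end - length))
                strand = "+" if rng.random() < 0.5 else "-"
                te_cls, sub = classify_repeat(family, name)
                background.append(
                    TEAnnotation(
                        interval=GenomicInterval(chrom, start, start + length, strand),
                        repeat_name=name,
                        repeat_family=family,
                        te_class=te_cls,
                        ltr_subclass=sub,
                        element_id=f"{name}.{ordinal}",
                    )
                )
                ordinal += 1
        # one fragmented LTR element: two rows sharing an element id
        frag_start = zone_end + 1_000
        eid = f"MLT1B.{ordinal}"
        ordinal += 1
        for s, e in ((frag_start, frag_start + 250), (frag_start + 450, frag_start + 700)):
            background.append(
                TEAnnotation(
                    interval=GenomicInterval(chrom, s, e, "+"),
                    repeat_name="MLT1B",
                    repeat_family="LTR/ERVL-MaLR",
                    te_class="LTR",
                    ltr_subclass="MaLR",
                    element_id=eid,
                )
            )
    return Fixture(
        config=config, chrom_sizes=sizes, genes=genes, background_tes=background
    )


# --------------------------------------------------------------------------
# Fragment sampling
# --------------------------------------------------------------------------

def _cdna_to_blocks(
    tx: TranscriptModel, cstart: int, cend: int
) -> tuple[GenomicInterval, ...]:
    """Project a cDNA interval onto genomic blocks through the exon chain."""
    blocks: list[GenomicInterval] = []
    offset = 0
    for exon in tx.exons:
        elen = len(exon)
        lo = max(cstart, offset)
        hi = min(cend, offset + elen)
        if lo < hi:
            if tx.strand == "+":
                blocks.append(
                    GenomicInterval(
                        exon.chrom, exon.start + (lo - offset), exon.start + (hi - offset)
                    )
                )
            else:
                blocks.append(
                    GenomicInterval(
                        exon.chrom, exon.end - (hi - offset), exon.end - (lo - offset)
                    )
                )
        offset += elen
    return tuple(sorted(blocks, key=lambda b: b.start))


@dataclass
class _RawFragment:
    qname: str
    chrom: str
    mate1: tuple[GenomicInterval, ...]  # transcript-5' mate
    mate2: tuple[GenomicInterval, ...]
    strand: str           # transcriptional strand of the source (or ".")
    xs: str               # recorded orientation tag ("+", "-", or "")
    source_tx: str


def _sample_tx_fragments(
    tx: TranscriptModel,
    count: int,
    sense_prob: float,
    rng: np.random.Generator,
    config: SimulationConfig,
    prefix: str,
) -> list[_RawFragment]:
    L = tx.cdna_length()
    rl = config.read_length
    flo, fhi = config.fragment_length
    out = []
    for i in range(count):
        flen = int(rng.integers(flo, fhi + 1))
        flen = min(flen, L)
        s = int(rng.integers(0, L - flen + 1))
        m1 = _cdna_to_blocks(tx, s, s + min(rl, flen))
        m2 = _cdna_to_blocks(tx, s + flen - min(rl, flen), s + flen)
        sense = rng.random() < sense_prob
        xs = tx.strand if sense else ("-" if tx.strand == "+" else "+")
        out.append(
            _RawFragment(
                qname=f"{prefix}.{i}",
                chrom=tx.chrom,
                mate1=m1,
                mate2=m2,
                strand=tx.strand,
                xs=xs,
                source_tx=tx.transcript_id,
            )
        )
    return out


def _sample_noise_fragments(
    count: int,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
    config: SimulationConfig,
    prefix: str,
) -> list[_RawFragment]:
    chroms = sorted(chrom_sizes)
    rl = config.read_length
    flo, fhi = config.fragment_length
    out = []
    for i in range(count):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        flen = int(rng.integers(flo, fhi + 1))
        start = int(rng.integers(0, chrom_sizes[chrom] - flen))
        m1 = (GenomicInterval(chrom, start, start + rl),)
        m2 = (GenomicInterval(chrom, start + flen - rl, start + flen),)
        out.append(
            _RawFragment(
                qname=f"{prefix}.{i}",
                chrom=chrom,
                mate1=m1,
                mate2=m2,
                strand="+",
                xs="",
                source_tx="",
            )
        )
    return out


def _raw_to_alignment(raw: _RawFragment, library_id: str) -> FragmentAlignment:
    all_blocks = raw.mate1 + raw.mate2
    outer = GenomicInterval(
        raw.chrom,
        min(b.start for b in all_blocks),
        max(b.end for b in all_blocks),
    )
    spliced = len(raw.mate1) > 1 or len(raw.mate2) > 1
    return FragmentAlignment(
        outer=outer,
        orientation=raw.xs if raw.xs in "+-" else ".",
        spliced=spliced,
        library_id=library_id,
        mate_blocks=(raw.mate1, raw.mate2),
    )


# --------------------------------------------------------------------------
# SAM output
# --------------------------------------------------------------------------

def write_sam(
    raws: list[_RawFragment],
    chrom_sizes: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Write raw fragments as a coordinate-sorted SAM file."""
    chroms = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_sizes[c]} for c in chroms],
    }
    ref_id = {c: i for i, c in enumerate(chroms)}
    records = []
    for raw in raws:
        records.extend(_make_pair(raw, ref_id))
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.is_read2))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            out.write(rec)


def _blocks_to_cigar(blocks: tuple[GenomicInterval, ...]) -> list[tuple[int, int]]:
    cigar: list[tuple[int, int]] = []
    prev_end = None
    for b in blocks:
        if prev_end is not None and b.start > prev_end:
            cigar.append((3, b.start - prev_end))  # N
        cigar.append((0, len(b)))  # M
        prev_end = b.end
    return cigar


def _make_pair(raw: _RawFragment, ref_id: dict[str, int]) -> list[pysam.AlignedSegment]:
    out = []
    outer_start = min(b.start for b in raw.mate1 + raw.mate2)
    outer_end = max(b.end for b in raw.mate1 + raw.mate2)
    tlen = outer_end - outer_start
    for idx, (blocks, other) in enumerate(
        ((raw.mate1, raw.mate2), (raw.mate2, raw.mate1))
    ):
        rec = pysam.AlignedSegment()
        rec.query_name = raw.qname
        rec.reference_id = ref_id[raw.chrom]
        rec.reference_start = blocks[0].start
        rec.cigartuples = _blocks_to_cigar(blocks)
        rec.mapping_quality = 60
        rec.next_reference_id = ref_id[raw.chrom]
        rec.next_reference_start = other[0].start
        rec.is_paired = True
        rec.is_proper_pair = True
        rec.is_read1 = idx == 0
        rec.is_read2 = idx == 1
        # the transcript-5' mate is on the reverse reference strand for
        # minus-strand sources
        mate_is_reverse = (raw.strand == "-") == (idx == 0)
        rec.is_reverse = mate_is_reverse
        rec.mate_is_reverse = not mate_is_reverse
        rec.template_length = tlen if rec.reference_start <= other[0].start else -tlen
        if raw.xs:
            rec.set_tag("XS", raw.xs)
        out.append(rec)
    return out


# --------------------------------------------------------------------------
# Library simulation and truth bookkeeping
# --------------------------------------------------------------------------

def _expected_counts(
    gene: GeneFixture,
    gene_depth: float,
    condition: str,
    config: SimulationConfig,
    activity: float = 1.0,
) -> tuple[float, float]:
    """(native, TE) expected fragment counts for one gene in one library."""
    spec = gene.spec
    mult = (
        config.derepression.get(spec.te_class, 1.0) if condition == "cancer" else 1.0
    )
    mult *= activity
    te_mean = gene_depth * spec.te_fraction * mult if gene.te_tx is not None else 0.0
    native_mean = gene_depth * (1 - spec.te_fraction) if gene.native_tx is not None else 0.0
    if gene.spec.archetype == "te_first_exon":
        native_mean = 0.0
    return native_mean, te_mean


def simulate_library(
    fixture: Fixture,
    library_id: str,
    patient_id: str,
    condition: str,
    seed_seq: np.random.SeedSequence,
    outdir: str | os.PathLike | None = None,
) -> LibraryResult:
    """Sample one library's fragments, write its SAM (when ``outdir`` is
    given) and derive the truth table from the realized fragments."""
    config = fixture.config
    rng = np.random.default_rng(seed_seq)
    depth = int(
        round(
            config.depth
            * rng.uniform(1 - config.depth_jitter, 1 + config.depth_jitter)
        )
    )
    # expression weights per isoform; the library's total fragment count is
    # fixed at the sequenced depth, so de-repression shifts composition
    # rather than adding reads (RNA-seq is compositional)
    sigma = config.derepression_sigma
    activity = float(np.exp(rng.normal(0.0, sigma) - sigma**2 / 2)) if sigma else 1.0
    sources: list[tuple] = []  # (tx | None, weight, sense_prob, prefix)
    for gene in fixture.genes:
        gene_weight = gene.spec.weight
        native_mean, te_mean = _expected_counts(
            gene, gene_weight, condition, config, activity
        )
        if gene.native_tx is not None and native_mean > 0:
            sources.append(
                (
                    gene.native_tx,
                    native_mean,
                    1 - config.orientation_noise,
                    f"{library_id}.{gene.spec.name}.n",
                )
            )
        if gene.te_tx is not None and te_mean > 0:
            s = gene.spec.te_sense_fraction
            sense_prob = s * (1 - config.orientation_noise) + (
                1 - s
            ) * config.orientation_noise
            sources.append(
                (
                    gene.te_tx,
                    te_mean,
                    sense_prob,
                    f"{library_id}.{gene.spec.name}.t",
                )
            )
    sources.append((None, config.noise_fraction, 0.0, f"{library_id}.noise"))
    weights = np.array([w for _, w, _, _ in sources], dtype=float)
    counts = rng.multinomial(depth, weights / weights.sum())
    raws: list[_RawFragment] = []
    for (tx, _, sense_prob, prefix), n in zip(sources, counts):
        if n == 0:
            continue
        if tx is None:
            raws.extend(
                _sample_noise_fragments(
                    int(n), fixture.chrom_sizes, rng, config, prefix
                )
            )
        else:
            raws.extend(
                _sample_tx_fragments(tx, int(n), sense_prob, rng, config, prefix)
            )
    library = Library(
        library_id=library_id,
        patient_id=patient_id,
        condition=condition,
        total_fragments=max(1, len(raws)),
    )
    fragments = [_raw_to_alignment(r, library_id) for r in raws]
    truth = _truth_records(fixture, library, fragments)
    sam_path = None
    if outdir is not None:
        sam_path = Path(outdir) / f"{library_id}.sam"
        write_sam(raws, fixture.chrom_sizes, sam_path)
    return LibraryResult(
        library=library, fragments=fragments, truth=truth, sam_path=sam_path
    )


def _truth_records(
    fixture: Fixture, library: Library, fragments: list[FragmentAlignment]
) -> list[TruthRecord]:
    records = []
    by_chrom: dict[str, list[FragmentAlignment]] = {}
    for frag in fragments:
        by_chrom.setdefault(frag.outer.chrom, []).append(frag)
    for gene in fixture.genes:
        if gene.te_tx is None or gene.te_merged is None:
            continue
        local = by_chrom.get(gene.chrom, [])
        te_iv = gene.te_merged.interval
        te_fe = first_exon(gene.te_tx)
        route = "tss_in_te"
        candidate_tx = gene.te_tx
        if gene.spec.assembly_truncated and gene.native_tx is not None:
            route = "upstream_extension"
            candidate_tx = gene.native_tx
        cand_fe = first_exon(candidate_tx)
        n_te_exon = sum(1 for f in local if f.mate_overlaps(te_fe))
        if route == "tss_in_te":
            n_support = sum(1 for f in local if f.mate_overlaps(cand_fe))
        else:
            n_support = sum(
                1
                for f in local
                if f.mate_blocks is not None
                and (
                    (
                        any(b.overlaps(te_iv) for b in f.mate_blocks[0])
                        and any(b.overlaps(cand_fe) for b in f.mate_blocks[1])
                    )
                    or (
                        any(b.overlaps(te_iv) for b in f.mate_blocks[1])
                        and any(b.overlaps(cand_fe) for b in f.mate_blocks[0])
                    )
                )
            )
        if gene.native_tx is not None and gene.native_tx is not gene.te_tx:
            native_fe = first_exon(gene.native_tx)
            n_native_fe = sum(1 for f in local if f.mate_overlaps(native_fe))
        else:
            n_native_fe = 0
        n_cand_fe = sum(1 for f in local if f.mate_overlaps(cand_fe))
        # contribution over the distinct first exons the caller will see
        if route == "upstream_extension" or gene.native_tx is None:
            contribution = 1.0 if n_cand_fe > 0 else math.nan
            denom = n_cand_fe
        else:
            denom = n_te_exon + n_native_fe
            contribution = n_te_exon / denom if denom > 0 else math.nan
        n_sense = n_anti = 0
        for f in local:
            if f.orientation not in "+-" or not f.outer.overlaps(te_iv):
                continue
            if f.orientation == candidate_tx.strand:
                n_sense += 1
            else:
                n_anti += 1
        rpkm = n_cand_fe / ((len(cand_fe) / 1e3) * (library.total_fragments / 1e6))
        probe = ChimeraCandidate(te=gene.te_merged, transcript=candidate_tx, route=route)
        upcov, _ = compute_upstream_coverage_ratio(probe, local)
        # transcript set visible to the caller for this gene
        visible = []
        if gene.native_tx is not None:
            visible.append(gene.native_tx)
        if gene.te_tx is not None and gene.te_tx is not gene.native_tx and not gene.spec.assembly_truncated:
            visible.append(gene.te_tx)
        upexon = compute_upstream_exon_ratio(probe, visible, local, library)
        if n_sense + n_anti == 0:
            bias = math.nan
        elif n_anti == 0:
            bias = math.inf
        else:
            bias = n_sense / n_anti
        expected = {}
        for mode in ("relaxed", "stringent"):
            th = ThresholdSet.from_mode(mode)
            n_min = min_supporting_fragments(library.total_fragments, th)
            ok = (
                n_support >= n_min
                and (not math.isnan(bias) and bias >= th.scTHREAD)
                and rpkm >= th.scRPKM
                and (not math.isnan(contribution) and contribution >= th.scCONTR)
                and (not math.isnan(upcov) and upcov >= th.scUPCOV)
                and (upexon is None or (not math.isnan(upexon) and upexon < th.scUPEXON))
            )
            expected[mode] = bool(ok)
        records.append(
            TruthRecord(
                library_id=library.library_id,
                condition=library.condition,
                gene_id=gene.spec.name,
                transcript_id=candidate_tx.transcript_id,
                element_id=gene.te_merged.element_id,
                te_class=gene.spec.te_class,
                ltr_subclass=gene.spec.ltr_subclass,
                route=route,
                n_te_fragments=n_support,
                n_te_exon_fragments=n_te_exon,
                n_native_first_exon_fragments=n_native_fe,
                n_sense=n_sense,
                n_antisense=n_anti,
                contribution=contribution,
                te_exon_rpkm=rpkm,
                upstream_cov_ratio=upcov,
                upstream_exon_ratio=upexon,
                expected_accept_relaxed=expected["relaxed"],
                expected_accept_stringent=expected["stringent"],
            )
        )
    return records


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig,
    outdir: str | os.PathLike | None = None,
    fixture: Fixture | None = None,
) -> CohortBundle:
    """Simulate matched cancer/normal pairs sharing one fixture genome.

    Per-library seeds are derived deterministically from ``config.seed``;
    the same configuration therefore yields byte-identical output files.
    When ``outdir`` is None everything stays in memory and no files are
    written (paths in the returned bundle are unset).
    """
    if fixture is None:
        fixture = build_fixture_genome(config)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence([config.seed, 202])
    children = master.spawn(2 * config.n_pairs)
    libraries: list[LibraryResult] = []
    for p in range(config.n_pairs):
        patient = f"patient{p + 1:03d}"
        for j, condition in enumerate(("cancer", "normal")):
            library_id = f"{patient}.{condition}"
            libraries.append(
                simulate_library(
                    fixture,
                    library_id,
                    patient,
                    condition,
                    children[2 * p + j],
                    outdir=out,
                )
            )
    gtf_path = te_bed_path = sizes_path = pairing_path = truth_path = None
    if out is not None:
        gtf_path = out / "transcripts.gtf"
        write_transcript_models(fixture.gtf_transcripts(), gtf_path)
        te_bed_path = out / "te_annotation.bed"
        write_te_bed(fixture.te_annotations(), te_bed_path)
        sizes_path = out / "chrom.sizes"
        write_chrom_sizes(fixture.chrom_sizes, sizes_path)
        pairing_path = out / "pairing.tsv"
        with open(pairing_path, "w") as fh:
            fh.write("patient_id\tcancer_library\tnormal_library\n")
            for p in range(config.n_pairs):
                patient = f"patient{p + 1:03d}"
                fh.write(f"{patient}\t{patient}.cancer\t{patient}.normal\n")
        truth_path = out / "truth.tsv"
        _write_truth(libraries, truth_path)
    return CohortBundle(
        fixture=fixture,
        outdir=out,
        gtf_path=gtf_path,
        te_bed_path=te_bed_path,
        chrom_sizes_path=sizes_path,
        pairing_path=pairing_path,
        truth_path=truth_path,
        libraries=libraries,
    )


def _write_truth(libraries: list[LibraryResult], path: Path) -> None:
    cols = [
        "library_id",
        "condition",
        "gene_id",
        "transcript_id",
        "element_id",
        "te_class",
        "ltr_subclass",
        "route",
        "n_te_fragments",
        "n_te_exon_fragments",
        "n_native_first_exon_fragments",
        "n_sense",
        "n_antisense",
        "contribution",
        "te_exon_rpkm",
        "upstream_cov_ratio",
        "upstream_exon_ratio",
        "expected_accept_relaxed",
        "expected_accept_stringent",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for res in libraries:
            for t in res.truth:
                row = [str(getattr(t, c)) for c in cols]
                fh.write("\t".join(row) + "\n")
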