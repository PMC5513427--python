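"""Cohort-level statistics over matched cancer/normal call sets.

Implements the downstream comparisons run on per-library chimera calls:
class-normalized call ratios (genomic-coverage-adjusted, scaled to the
all-class expectation in normal samples), per-pair library-size-corrected
counts, the exact binomial sign test on within-pair direction, Fisher-exact
recurrence enrichment with Benjamini-Hochberg adjustment, promoter
contribution-to-expression from peak coverage, and the correlation between
TE-promoter activity and total-expression fold change.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotations_io import GenomicInterval
from .detection import CallSet, Library, per_base_coverage

__all__ = [
    "CohortPairing",
    "SignTestResult",
    "RecurrenceRecord",
    "PromoterShare",
    "read_pairing",
    "write_pairing",
    "normalized_class_counts",
    "paired_counts",
    "sign_binomial_test",
    "recurrence_enrichment",
    "promoter_contributions",
    "exon_mean_expression",
    "spearman_fold_change",
]


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class CohortPairing:
    """Mapping patient -> (cancer library_id, normal library_id)."""

    pairs: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for patient, (cancer, normal) in self.pairs.items():
            for lib in (cancer, normal):
                if lib in seen:
                    raise CohortError(
                        f"library {lib!r} appears in more than one pair"
                    )
                seen.add(lib)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SignTestResult:
    n_pairs_total: int
    n_informative: int
    n_cancer_higher: int
    proportion_cancer_higher: float
    p_two_sided: float


@dataclass(frozen=True)
class RecurrenceRecord:
    locus: str
    gene_id: str
    n_cancer_positive: int
    n_cancer_total: int
    n_normal_positive: int
    n_normal_total: int
    p_value: float
    q_value: float
    direction: str  # cancer_enriched | normal_enriched | none
    cancer_only: bool


@dataclass(frozen=True)
class PromoterShare:
    library_id: str
    peak_te_promoter: float
    peak_native_promoter: float
    peak_common_exons: float
    te_share: float | None
    sum_over_total: float | None
    flagged: bool = False


def read_pairing(path: str | os.PathLike) -> CohortPairing:
    """Read a pairing sheet TSV: patient_id, cancer_library, normal_library."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "cancer_library", "normal_library"}
    if not required <= set(df.columns):
        raise CohortError(
            f"{path}: pairing sheet needs columns {sorted(required)}"
        )
    pairs = {
        row.patient_id: (row.cancer_library, row.normal_library)
        for row in df.itertuples()
    }
    return CohortPairing(pairs)


def write_pairing(pairing: CohortPairing, path: str | os.PathLike) -> None:
    rows = [
        {"patient_id": p, "cancer_library": c, "normal_library": n}
        for p, (c, n) in pairing.pairs.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Class-normalized counts (genomic-coverage-adjusted call densities)
# --------------------------------------------------------------------------

def _accepted_class_counts(callset: CallSet) -> dict[str, int]:
    counts: dict[str, int] = {}
    for call in callset.calls:
        counts[call.te.te_class] = counts.get(call.te.te_class, 0) + 1
        if call.te.te_class == "LTR":
            key = f"LTR:{call.te.ltr_subclass}"
            counts[key] = counts.get(key, 0) + 1
    return counts


def normalized_class_counts(
    callsets_by_condition: dict[str, list[CallSet]],
    class_coverage: dict[str, int],
    classes: tuple[str, ...] = ("LTR", "LINE", "SINE", "DNA"),
) -> dict[tuple[str, str], float]:
    """Per-(condition, class) call density relative to the normal-sample
    expectation.

    Density is mean accepted calls per library divided by the class's
    genomic coverage; the baseline is the all-class density over normal
    samples, which therefore maps to 1.0.
    """
    densities: dict[tuple[str, str], float] = {}
    for condition, callsets in callsets_by_condition.items():
        if not callsets:
            raise CohortError(f"no call sets for condition {condition!r}")
        n_libs = len(callsets)
        for cls in classes:
            cov = class_coverage.get(cls, 0)
            if cov <= 0:
                raise CohortError(f"class {cls!r} has zero genomic coverage")
            calls = sum(
                _accepted_class_counts(cs).get(cls, 0) for cs in callsets
            )
            densities[(condition, cls)] = calls / n_libs / cov
    normal_sets = callsets_by_condition.get("normal", [])
    if not normal_sets:
        raise CohortError("a 'normal' condition is required for the baseline")
    total_cov = sum(
        class_coverage.get(cls, 0) for cls in classes
    )
    total_calls = sum(
        sum(_accepted_class_counts(cs).get(cls, 0) for cls in classes)
        for cs in normal_sets
    )
    baseline = total_calls / len(normal_sets) / total_cov
    if baseline == 0:
        raise CohortError("zero baseline density in normal samples")
    return {key: d / baseline for key, d in densities.items()}


# --------------------------------------------------------------------------
# Paired counts and sign test
# --------------------------------------------------------------------------

def paired_counts(
    callsets: dict[str, CallSet],
    pairing: CohortPairing,
    te_class: str | None = "LTR",
    per: float = 1e7,
) -> pd.DataFrame:
    """Per-pair accepted-call counts of a TE class, corrected for library
    size (scaled to calls per ``per`` mapped fragments)."""
    rows = []
    for patient, (cancer_id, normal_id) in pairing.pairs.items():
        if cancer_id not in callsets or normal_id not in callsets:
            continue  # pair dropped; caller may warn
        row = {"patient_id": patient}
        for role, lib_id in (("cancer", cancer_id), ("normal", normal_id)):
            cs = callsets[lib_id]
            n = sum(
                1
                for call in cs.calls
                if te_class is None or call.te.te_class == te_class
            )
            row[f"{role}_library"] = lib_id
            row[f"{role}_count"] = n
            row[f"{role}_scaled"] = n / cs.library.total_fragments * per
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "cancer_library",
            "cancer_count",
            "cancer_scaled",
            "normal_library",
            "normal_count",
            "normal_scaled",
        ],
    )


def sign_binomial_test(paired: pd.DataFrame) -> SignTestResult:
    """Exact binomial sign test on within-pair direction at null 0.5.

    Successes are pairs with the cancer member's scaled count strictly
    higher; ties are excluded.  The two-sided p-value is twice the smaller
    tail, capped at 1 (equal to the minimum-likelihood two-sided p under
    the symmetric null).
    """
    diffs = paired["cancer_scaled"] - paired["normal_scaled"]
    n_total = len(diffs)
    informative = diffs[diffs != 0]
    n = len(informative)
    if n == 0:
        raise CohortError("sign test needs at least one informative pair")
    k = int((informative > 0).sum())
    p = exact_binomial_two_sided(k, n)
    return SignTestResult(
        n_pairs_total=n_total,
        n_informative=n,
        n_cancer_higher=k,
        proportion_cancer_higher=k / n,
        p_two_sided=p,
    )


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p as twice the smaller tail, capped at 1."""
    if not 0 <= k <= n:
        raise CohortError("require 0 <= k <= n")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2 * min(lower, upper)))


# --------------------------------------------------------------------------
# Recurrence enrichment
# --------------------------------------------------------------------------

def _locus_key(call) -> tuple[str, str]:
    te = call.te
    locus = f"{call.transcript.gene_id}|{te.repeat_name}|{te.interval.chrom}:{te.interval.start}-{te.interval.end}"
    return locus, call.transcript.gene_id


def recurrence_enrichment(
    callsets_by_condition: dict[str, list[CallSet]],
) -> list[RecurrenceRecord]:
    """Per-locus presence/absence enrichment between conditions.

    Each (gene, TE element) locus observed in any library forms a 2x2
    presence table (positive libraries per condition) tested with Fisher's
    exact test (two-sided); Benjamini-Hochberg q-values are computed across
    loci.  Loci never passing thresholds in any normal library carry a
    ``cancer_only`` flag.
    """
    cancer_sets = callsets_by_condition.get("cancer", [])
    normal_sets = callsets_by_condition.get("normal", [])
    if len(cancer_sets) < 2 or len(normal_sets) < 2:
        raise CohortError("need at least two libraries per condition")
    presence: dict[str, dict[str, set[str]]] = {}
    gene_of: dict[str, str] = {}
    for condition, callsets in (("cancer", cancer_sets), ("normal", normal_sets)):
        for cs in callsets:
            for call in cs.calls:
                locus, gene = _locus_key(call)
                gene_of[locus] = gene
                presence.setdefault(locus, {"cancer": set(), "normal": set()})[
                    condition
                ].add(cs.library_id)
    n_cancer = len(cancer_sets)
    n_normal = len(normal_sets)
    loci = sorted(presence)
    pvals = []
    for locus in loci:
        a = len(presence[locus]["cancer"])
        b = len(presence[locus]["normal"])
        table = [[a, n_cancer - a], [b, n_normal - b]]
        pvals.append(float(stats.fisher_exact(table, alternative="two-sided")[1]))
    if loci:
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        qvals = []
    records = []
    for locus, p, q in zip(loci, pvals, qvals):
        a = len(presence[locus]["cancer"])
        b = len(presence[locus]["normal"])
        if a / n_cancer > b / n_normal:
            direction = "cancer_enriched"
        elif a / n_cancer < b / n_normal:
            direction = "normal_enriched"
        else:
            direction = "none"
        records.append(
            RecurrenceRecord(
                locus=locus,
                gene_id=gene_of[locus],
                n_cancer_positive=a,
                n_cancer_total=n_cancer,
                n_normal_positive=b,
                n_normal_total=n_normal,
                p_value=p,
                q_value=float(q),
                direction=direction,
                cancer_only=(b == 0 and a > 0),
            )
        )
    return records


def recurrence_to_frame(records: list[RecurrenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in records],
        columns=[
            "locus",
            "gene_id",
            "n_cancer_positive",
            "n_cancer_total",
            "n_normal_positive",
            "n_normal_total",
            "p_value",
            "q_value",
            "direction",
            "cancer_only",
        ],
    )


# --------------------------------------------------------------------------
# Promoter contribution to expression
# --------------------------------------------------------------------------

def promoter_contributions(
    fragments,
    te_promoter: GenomicInterval,
    native_promoter: GenomicInterval,
    common_exons: list[GenomicInterval],
    library: Library,
) -> PromoterShare:
    """Peak-coverage shares of the TE and native promoters.

    Peak coverage (per-base maximum) over each promoter region measures its
    activity; peak coverage over downstream common exons measures total
    expression.  ``te_share`` is the TE promoter's fraction of summed
    promoter peaks; ``sum_over_total`` compares summed promoter activity to
    total expression.
    """
    if te_promoter.overlaps(native_promoter):
        raise CohortError("promoter intervals must be disjoint")
    peak_te = per_base_coverage(fragments, te_promoter).peak
    peak_native = per_base_coverage(fragments, native_promoter).peak
    if not common_exons:
        raise CohortError("at least one common exon is required")
    peak_common = max(
        per_base_coverage(fragments, exon).peak for exon in common_exons
    )
    denom = peak_te + peak_native
    te_share = peak_te / denom if denom > 0 else None
    sum_over_total = denom / peak_common if peak_common > 0 else None
    return PromoterShare(
        library_id=library.library_id,
        peak_te_promoter=peak_te,
        peak_native_promoter=peak_native,
        peak_common_exons=peak_common,
        te_share=te_share,
        sum_over_total=sum_over_total,
        flagged=(peak_common == 0 or denom == 0),
    )


# --------------------------------------------------------------------------
# Expression summaries and correlation
# --------------------------------------------------------------------------

def exon_mean_expression(
    per_exon_rpkm: list[float] | np.ndarray, exon_range: list[int] | range
) -> float:
    """Arithmetic mean RPKM over a 1-based selection of exons (e.g. the
    common exons shared by the native and TE-promoted isoforms)."""
    indices = sorted(set(exon_range))
    if not indices:
        raise CohortError("empty exon range")
    values = list(per_exon_rpkm)
    if indices[0] < 1 or indices[-1] > len(values):
        raise CohortError(
            f"exon range {indices} outside available exons 1..{len(values)}"
        )
    return float(np.mean([values[i - 1] for i in indices]))


def spearman_fold_change(
    te_exon_rpkm: list[float] | np.ndarray,
    total_expression_delta: list[float] | np.ndarray,
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Spearman correlation between per-patient TE-promoter exon expression
    and the within-pair change in total gene expression.

    Ranks use midranks for ties.  For n <= ``exact_max_n`` the p-value is a
    two-sided exact permutation p (enumeration of all orderings); larger n
    uses the large-sample approximation.  Returns ``(rho, p)``; ``rho`` is
    ``nan`` for a constant vector.
    """
    x = np.asarray(te_exon_rpkm, dtype=float)
    y = np.asarray(total_expression_delta, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CohortError("paired vectors of equal length required")
    n = len(x)
    if n < 3:
        raise CohortError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rho, p_approx = stats.spearmanr(x, y)
    rho = float(rho)
    if n > exact_max_n:
        return rho, float(p_approx)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    observed = abs(_pearson(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(_pearson(rx[list(perm)], ry))
        if r >= observed - 1e-12:
            count += 1
        total += 1
    return rho, count / total


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        return math.nan
    return float(a @ b) / denom
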