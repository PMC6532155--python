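"""Validation statistics for genotyped panels: marker/sample QC, the exact
Hardy–Weinberg test, and per-population polymorphism summaries.

QC removes high-missingness samples first, then markers failing call
rate, minor-allele frequency or Hardy–Weinberg equilibrium on the
retained cohort, so marker statistics reflect the samples that remain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel_io import MISSING, GenotypeMatrix, QcConfig

__all__ = [
    "QcReport",
    "PolymorphismSummary",
    "snp_call_rate",
    "genotype_maf",
    "hwe_exact_p",
    "qc_filter",
    "polymorphism_summary",
]


@dataclass
class QcReport:
    """Per-marker and per-sample statistics plus removal lists.

    Every removal carries exactly one primary reason code:
    ``sample_missing`` for samples; ``call_rate``, ``maf`` or ``hwe`` for
    markers (checked in that order).
    """

    snp_call_rate: dict[str, float] = field(default_factory=dict)
    snp_maf: dict[str, float] = field(default_factory=dict)
    snp_hwe_p: dict[str, float] = field(default_factory=dict)
    sample_missing_rate: dict[str, float] = field(default_factory=dict)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_markers: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class PolymorphismSummary:
    """Per population: average call rate (%), polymorphic-locus count
    (MAF strictly above the cutoff) and mean MAF across all loci."""

    avg_call_rate_percent: dict[str, float]
    polymorphic_count: dict[str, int]
    mean_maf: dict[str, float]
    n_loci: int


# ---------------------------------------------------------------------------
# Per-column statistics
# ---------------------------------------------------------------------------


def snp_call_rate(column: np.ndarray) -> float:
    """Fraction of samples with a non-missing genotype at a marker."""
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("call rate undefined for zero samples")
    return float(np.count_nonzero(column != MISSING) / column.size)


def genotype_maf(column: np.ndarray) -> float:
    """Minor-allele frequency over called genotypes, folded to [0, 0.5]."""
    column = np.asarray(column)
    called = column[column != MISSING]
    if called.size == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    alt = float(called.sum()) / (2 * called.size)
    return min(alt, 1.0 - alt)


def hwe_exact_p(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed count (two-sided exact test, no mid-p
    correction).  Monomorphic markers return 1 by convention.  Symmetric
    under swapping the two homozygote counts.
    """
    for c in (n_aa_hom, n_het, n_bb_hom):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    rare = 2 * min(n_aa_hom, n_bb_hom) + n_het  # minor-allele copy count
    if rare == 0 or rare == 2 * n:
        return 1.0

    # Conditional distribution of the het count via the standard two-sided
    # recurrence, anchored at (near) the mode so unnormalised values never
    # overflow: P(h-2)/P(h) = h(h-1) / [4 (hom_r+1)(hom_c+1)] and
    # P(h+2)/P(h) = 4 hom_r hom_c / [(h+2)(h+1)], with hom_r = (rare-h)/2,
    # hom_c = n - h - hom_r.
    h_obs = n_het
    h_min = rare % 2
    h_max = min(rare, 2 * n - rare)
    h_mode = int(rare * (2 * n - rare) / (2 * n))
    if (h_mode - h_min) % 2:
        h_mode += 1
    h_mode = min(max(h_mode, h_min), h_max)
    probs: dict[int, float] = {h_mode: 1.0}
    h = h_mode
    while h - 2 >= h_min:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = h_mode
    while h + 2 <= h_max:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    p_obs = probs[h_obs]
    tol = 1.0 + 1e-12  # guard against float noise in the "<= observed" rule
    p = sum(v for v in probs.values() if v <= p_obs * tol) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def _marker_hwe_p(matrix: GenotypeMatrix, j: int, per_population: bool) -> float:
    """HWE p for marker j: minimum over populations when labels exist,
    pooled otherwise (pooled HWE would conflate structure with typing
    error)."""
    col = matrix.geno[:, j]
    pops = matrix.populations
    if per_population and len(pops) > 1:
        ps = []
        labels = np.array([pop for _, pop in matrix.samples])
        for pop in pops:
            sub = col[(labels == pop) & (col != MISSING)]
            if sub.size == 0:
                continue
            ps.append(
                hwe_exact_p(
                    int(np.count_nonzero(sub == 0)),
                    int(np.count_nonzero(sub == 1)),
                    int(np.count_nonzero(sub == 2)),
                )
            )
        return min(ps) if ps else 1.0
    called = col[col != MISSING]
    if called.size == 0:
        return 1.0
    return hwe_exact_p(
        int(np.count_nonzero(called == 0)),
        int(np.count_nonzero(called == 1)),
        int(np.count_nonzero(called == 2)),
    )


def qc_filter(
    matrix: GenotypeMatrix, config: QcConfig | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply sample- then marker-level QC; idempotent on its own output.

    Samples with missing rate above ``sample_missing_max`` are removed
    first.  On the retained samples, markers are removed for call rate
    below ``snp_call_rate_min``, then MAF below ``maf_min``, then HWE
    p below ``hwe_p_min`` (within populations when labels exist).
    """
    config = config or QcConfig()
    report = QcReport()
    retained = matrix

    # Removing markers can raise a sample's missing rate and vice versa, so
    # the sample/marker passes are iterated to a fixpoint; this makes the
    # filter idempotent by construction (a second call removes nothing).
    changed = True
    while changed and retained.n_samples and retained.n_loci:
        changed = False
        miss = np.mean(retained.geno == MISSING, axis=1)
        keep_samples = []
        for i, (sid, _pop) in enumerate(retained.samples):
            report.sample_missing_rate[sid] = float(miss[i])
            if miss[i] > config.sample_missing_max:
                report.removed_samples.append((sid, "sample_missing"))
                changed = True
            else:
                keep_samples.append(i)
        retained = retained.subset(sample_idx=keep_samples)
        if not retained.n_samples:
            break

        keep_loci = []
        for j, locus in enumerate(retained.loci):
            col = retained.geno[:, j]
            sid = locus.snp_id or f"{locus.chrom}_{locus.pos}"
            rate = snp_call_rate(col)
            report.snp_call_rate[sid] = rate
            if rate < config.snp_call_rate_min:
                report.removed_markers.append((sid, "call_rate"))
                changed = True
                continue
            maf = genotype_maf(col) if rate > 0 else 0.0
            report.snp_maf[sid] = maf
            if maf < config.maf_min:
                report.removed_markers.append((sid, "maf"))
                changed = True
                continue
            p = _marker_hwe_p(retained, j, per_population=True)
            report.snp_hwe_p[sid] = p
            if p < config.hwe_p_min:
                report.removed_markers.append((sid, "hwe"))
                changed = True
                continue
            keep_loci.append(j)
        retained = retained.subset(locus_idx=keep_loci)

    if retained.n_samples and not retained.n_loci:
        pass  # all markers gone; sample stats above remain valid
    elif not retained.n_samples:
        retained = retained.subset(locus_idx=[])

    return retained, report


# ---------------------------------------------------------------------------
# Polymorphism summary
# ---------------------------------------------------------------------------


def polymorphism_summary(
    matrix: GenotypeMatrix, maf_cutoff: float = 0.05
) -> PolymorphismSummary:
    """Per-population call rate, polymorphic-locus count and mean MAF.

    Call rate is the mean per-marker call rate within the population,
    expressed as a percent.  A locus is polymorphic when its within-
    population MAF is strictly above ``maf_cutoff``.  Mean MAF averages
    over all loci (all-missing loci contribute 0).
    """
    labels = np.array([pop for _, pop in matrix.samples])
    call: dict[str, float] = {}
    poly: dict[str, int] = {}
    mean_maf: dict[str, float] = {}
    for pop in matrix.populations:
        sub = matrix.geno[labels == pop, :]
        if sub.shape[0] == 0:
            raise ValueError(f"population {pop!r} has no samples")
        rates = np.mean(sub != MISSING, axis=0)
        call[pop] = float(100.0 * rates.mean()) if matrix.n_loci else 0.0
        mafs = np.zeros(matrix.n_loci)
        for j in range(matrix.n_loci):
            col = sub[:, j]
            if np.any(col != MISSING):
                mafs[j] = genotype_maf(col)
        poly[pop] = int(np.count_nonzero(mafs > maf_cutoff))
        mean_maf[pop] = float(mafs.mean()) if matrix.n_loci else 0.0
    return PolymorphismSummary(
        avg_call_rate_percent=call,
        polymorphic_count=poly,
        mean_maf=mean_maf,
        n_loci=matrix.n_loci,
    )
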