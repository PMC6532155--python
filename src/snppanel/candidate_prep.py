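"""Candidate-marker selection: the four source-group screens.

Group 1 (resequencing) keeps markers whose minor-allele frequency differs
strongly between a focal breed and its control line; group 2 (GWAS) keeps
the top fraction of association p-values per trait; group 3 (candidate
genes) keeps consequence-ranked markers near trait genes, capped per gene;
group 4 (feed efficiency / RFI) keeps markers in the upper tail of the Fst
distribution with a large mean frequency differential between divergent
lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel_io import (
    CandidateSnp,
    DesignConfig,
    Group,
    PoolFrequencyTable,
    Priority,
    SnpLocus,
)

__all__ = [
    "BreedRoleMap",
    "AssociationTable",
    "GeneIntervalTable",
    "RfiStatTable",
    "minor_allele_frequency",
    "delta_f",
    "select_resequencing_candidates",
    "select_gwas_candidates",
    "CONSEQUENCE_RANK",
    "select_gene_candidates",
    "select_rfi_candidates",
    "wc_fst",
    "wc_fst_multilocus",
    "assemble_candidates",
    "read_association_table",
    "read_gene_intervals",
    "read_rfi_stats",
]


# ---------------------------------------------------------------------------
# Input tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreedRoleMap:
    """Which breeds are screened against which control line.

    Local breeds are contrasted with a commercial control; commercial
    lines with a local control.  No breed may be its own control.
    """

    local_breeds: tuple[str, ...]
    commercial_breeds: tuple[str, ...]
    control_for_local: str
    control_for_commercial: str

    def __post_init__(self) -> None:
        if self.control_for_local in self.local_breeds:
            raise ValueError("control_for_local cannot be one of the local breeds")
        if self.control_for_commercial in self.commercial_breeds:
            raise ValueError("control_for_commercial cannot be one of the commercial breeds")


@dataclass
class AssociationTable:
    """(locus, trait, p-value) rows from an upstream association scan."""

    rows: list[tuple[SnpLocus, str, float]]

    def __post_init__(self) -> None:
        seen: set[tuple[tuple[str, int], str]] = set()
        for locus, trait, p in self.rows:
            if not 0.0 < p <= 1.0:
                raise ValueError(f"p-value {p} for {locus.chrom}:{locus.pos} not in (0, 1]")
            key = (locus.key, trait)
            if key in seen:
                raise ValueError(f"duplicate (locus, trait) row {key}")
            seen.add(key)


@dataclass
class GeneIntervalTable:
    """1-based inclusive gene intervals: (gene_id, chrom, start, end)."""

    rows: list[tuple[str, str, int, int]]

    def __post_init__(self) -> None:
        for gene, chrom, start, end in self.rows:
            if start > end:
                raise ValueError(f"gene {gene}: start {start} > end {end}")
            if start < 1:
                raise ValueError(f"gene {gene}: coordinates are 1-based")


@dataclass
class RfiStatTable:
    """Per-locus Fst and mean frequency differential between divergent lines."""

    rows: list[tuple[SnpLocus, float, float]]  # (locus, fst, mean_delta_f)

    def __post_init__(self) -> None:
        for locus, fst, mdf in self.rows:
            if not math.isfinite(fst):
                raise ValueError(f"non-finite Fst at {locus.chrom}:{locus.pos}")
            if mdf < 0:
                raise ValueError(f"negative mean ΔF at {locus.chrom}:{locus.pos}")


# ---------------------------------------------------------------------------
# Frequency utilities
# ---------------------------------------------------------------------------


def minor_allele_frequency(f: float) -> float:
    """Fold an alternate-allele frequency to the minor-allele frequency.

    Returns ``min(f, 1 - f)``, in [0, 0.5].
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele frequency {f} outside [0, 1]")
    return min(f, 1.0 - f)


def delta_f(maf_breed: float, maf_control: float) -> float:
    """Signed minor-allele-frequency differential, breed minus control.

    Antisymmetric under argument swap; |ΔF| <= 0.5 for valid MAF inputs.
    """
    for v in (maf_breed, maf_control):
        if not 0.0 <= v <= 0.5:
            raise ValueError(f"MAF {v} outside [0, 0.5]")
    return maf_breed - maf_control


# ---------------------------------------------------------------------------
# Group 1: resequencing differentials
# ---------------------------------------------------------------------------


def select_resequencing_candidates(
    freqs: PoolFrequencyTable,
    roles: BreedRoleMap,
    config: DesignConfig,
    indel_whitelist: set[tuple[str, int]] | None = None,
) -> list[CandidateSnp]:
    """Screen pooled frequencies for breed-differential markers (group 1).

    A locus survives if, in at least one focal breed, its MAF is at least
    ``config.maf_min`` and its ΔF against the role's control meets the
    role's threshold (local vs commercial).  Chromosome-W loci are dropped.
    Indel whitelist members are emitted with priority P1; all other
    survivors are group=resequencing, priority P2.  A locus passing in
    several breeds is emitted once, with the largest ΔF as its score.
    """
    if not freqs.loci:
        raise ValueError("empty frequency table")
    for breed in (
        *roles.local_breeds,
        *roles.commercial_breeds,
        roles.control_for_local,
        roles.control_for_commercial,
    ):
        if breed not in freqs.breeds:
            raise KeyError(f"breed {breed!r} missing from frequency table")
    whitelist = indel_whitelist or set()

    freq = freqs.freq.to_numpy(float)
    col = {b: i for i, b in enumerate(freqs.breeds)}
    maf = np.where(np.isnan(freq), np.nan, np.minimum(freq, 1.0 - freq))

    contrasts: list[tuple[str, str, float]] = [
        (b, roles.control_for_local, config.delta_f_threshold_local)
        for b in roles.local_breeds
    ] + [
        (b, roles.control_for_commercial, config.delta_f_threshold_commercial)
        for b in roles.commercial_breeds
    ]

    best: dict[int, float] = {}
    for breed, control, threshold in contrasts:
        mb = maf[:, col[breed]]
        mc = maf[:, col[control]]
        df = mb - mc
        if config.delta_f_absolute:
            df = np.abs(df)
        ok = (~np.isnan(mb)) & (~np.isnan(mc)) & (mb >= config.maf_min) & (df >= threshold)
        for i in np.flatnonzero(ok):
            if i not in best or df[i] > best[i]:
                best[i] = float(df[i])

    out: list[CandidateSnp] = []
    for i in sorted(best):
        locus = freqs.loci[i]
        if locus.chrom == "W":
            continue
        is_wl = locus.key in whitelist
        out.append(
            CandidateSnp(
                locus=locus,
                group=Group.RESEQUENCING,
                priority=Priority.P1 if is_wl else Priority.P2,
                is_indel=is_wl,
                score=best[i],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Group 2: association top fraction
# ---------------------------------------------------------------------------


def select_gwas_candidates(
    assoc: AssociationTable, top_fraction: float = 0.01
) -> list[CandidateSnp]:
    """Per trait, take the ceil(fraction x n) smallest p-values; union loci.

    Ties in p are broken by (chrom, pos) for determinism.  Output is
    deduplicated by locus, group=gwas, priority=P1, score = smallest p
    over the traits that nominated the locus.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    if not assoc.rows:
        raise ValueError("empty association table")

    by_trait: dict[str, list[tuple[float, SnpLocus]]] = {}
    for locus, trait, p in assoc.rows:
        by_trait.setdefault(trait, []).append((p, locus))

    best_p: dict[tuple[str, int], tuple[float, SnpLocus]] = {}
    for trait, rows in by_trait.items():
        rows.sort(key=lambda t: (t[0], t[1].chrom, t[1].pos))
        k = math.ceil(top_fraction * len(rows))
        for p, locus in rows[:k]:
            cur = best_p.get(locus.key)
            if cur is None or p < cur[0]:
                best_p[locus.key] = (p, locus)

    return [
        CandidateSnp(locus=locus, group=Group.GWAS, priority=Priority.P1, score=p)
        for key, (p, locus) in sorted(best_p.items())
    ]


# ---------------------------------------------------------------------------
# Group 3: candidate-gene, consequence-ranked, capped
# ---------------------------------------------------------------------------

#: Consequence-class rank used to order markers within a gene (0 = best).
CONSEQUENCE_RANK: dict[str, int] = {
    "missense variant & splice region variant": 0,
    "missense variant": 0,
    "splicing": 1,
    "start/stop gained/lost/retained": 2,
    "3 prime UTR variant": 3,
    "5 prime UTR variant": 3,
    "synonymous variant": 4,
    "upstream gene variant (1 kb)": 5,
    "downstream gene variant (1 kb)": 5,
    "intron variant": 6,
    "intron variant & noncoding transcript variant": 7,
    "noncoding transcript exon variant": 7,
    "intergenic variant": 8,
    "unannotated": 9,
}


def select_gene_candidates(
    snps: list[tuple[SnpLocus, str]],
    genes: GeneIntervalTable,
    config: DesignConfig,
) -> list[CandidateSnp]:
    """Keep at most ``gene_cap`` consequence-ranked markers per gene.

    ``snps`` pairs each locus with its consequence class.  A locus counts
    for a gene when it lies within [start - gene_flank, end + gene_flank].
    Within a gene, markers are ordered by consequence rank then ascending
    position; loci nominated by several genes are deduplicated at emission.
    Output: group=candidate_gene, priority=P1.
    """
    by_chrom: dict[str, list[tuple[SnpLocus, str]]] = {}
    for locus, cls in snps:
        by_chrom.setdefault(locus.chrom, []).append((locus, cls))

    chosen: dict[tuple[str, int], SnpLocus] = {}
    for gene, chrom, start, end in genes.rows:
        lo, hi = max(1, start - config.gene_flank), end + config.gene_flank
        inside = [
            (locus, cls)
            for locus, cls in by_chrom.get(chrom, [])
            if lo <= locus.pos <= hi
        ]
        inside.sort(key=lambda t: (CONSEQUENCE_RANK.get(t[1], 9), t[0].pos))
        for locus, _cls in inside[: config.gene_cap]:
            chosen.setdefault(locus.key, locus)

    return [
        CandidateSnp(locus=locus, group=Group.CANDIDATE_GENE, priority=Priority.P1)
        for key, locus in sorted(chosen.items())
    ]


# ---------------------------------------------------------------------------
# Group 4: feed-efficiency (RFI) differentials
# ---------------------------------------------------------------------------


def select_rfi_candidates(stats: RfiStatTable, config: DesignConfig) -> list[CandidateSnp]:
    """Keep loci in the upper Fst tail with mean ΔF >= the floor (group 4).

    The Fst cut is the ``rfi_fst_quantile`` empirical quantile of the
    table's own Fst column (top 5% kept by default).  If the Fst column
    is degenerate (all identical) the quantile carries no information:
    a warning is issued and only the ΔF floor is applied.
    """
    if not stats.rows:
        raise ValueError("empty RFI statistics table")
    fst = np.array([f for _, f, _ in stats.rows], dtype=float)
    if np.all(fst == fst[0]):
        warnings.warn(
            "degenerate Fst column (all values identical); applying mean-ΔF filter only",
            UserWarning,
            stacklevel=2,
        )
        cut = -np.inf
    else:
        cut = float(np.quantile(fst, config.rfi_fst_quantile))
    out = []
    for locus, f, mdf in stats.rows:
        if f >= cut and mdf >= config.rfi_delta_f_min:
            out.append(
                CandidateSnp(locus=locus, group=Group.RFI, priority=Priority.P1, score=f)
            )
    return out


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst from allele counts
# ---------------------------------------------------------------------------


def wc_fst(count_a: tuple[int, int], count_b: tuple[int, int]) -> tuple[float, float]:
    """Two-population Weir–Cockerham Fst from allele counts.

    ``count_a`` / ``count_b`` are (reference, alternate) allele counts for
    each population.  Uses the allele-count (random-union-of-gametes) form
    of the 1984 variance-components estimator: with per-population allele
    sample sizes n_i and frequencies p_i,

        MSP = Σ n_i (p_i − p̄)² / (r − 1)
        MSG = Σ n_i p_i (1 − p_i) / Σ (n_i − 1)
        θ   = (MSP − MSG) / (MSP + (n_c − 1) MSG)

    where n_c = (n_T − Σ n_i²/n_T)/(r − 1) and r = 2.  Returns
    ``(clamped, raw)``: the raw estimate may be negative or undefined
    (NaN when both populations are fixed for the same allele); the
    clamped value lies in [0, 1] for reporting.
    """
    n1, n2 = sum(count_a), sum(count_b)
    if n1 < 1 or n2 < 1:
        raise ValueError("each population needs at least one sampled allele")
    p1, p2 = count_a[1] / n1, count_b[1] / n2
    n_t = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n_t
    nc = (n_t - (n1 * n1 + n2 * n2) / n_t)  # / (r - 1) with r = 2
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # / (r - 1)
    denom_g = (n1 - 1) + (n2 - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / denom_g if denom_g > 0 else 0.0
    denom = msp + (nc - 1) * msg
    raw = float("nan") if denom == 0 else (msp - msg) / denom
    clamped = 0.0 if math.isnan(raw) else min(1.0, max(0.0, raw))
    return clamped, raw


def _wc_components(count_a: tuple[int, int], count_b: tuple[int, int]) -> tuple[float, float]:
    n1, n2 = sum(count_a), sum(count_b)
    p1, p2 = count_a[1] / n1, count_b[1] / n2
    n_t = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n_t
    nc = n_t - (n1 * n1 + n2 * n2) / n_t
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    denom_g = (n1 - 1) + (n2 - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / denom_g if denom_g > 0 else 0.0
    return msp - msg, msp + (nc - 1) * msg


def wc_fst_multilocus(
    counts_a: list[tuple[int, int]], counts_b: list[tuple[int, int]]
) -> float:
    """Multi-locus Weir–Cockerham Fst: ratio of summed variance components.

    Summing numerators and denominators across loci before dividing is the
    standard combination; averaging per-locus ratios is biased downward at
    modest sample sizes.
    """
    if len(counts_a) != len(counts_b) or not counts_a:
        raise ValueError("need equal, non-empty per-locus count lists")
    num = den = 0.0
    for ca, cb in zip(counts_a, counts_b):
        a, d = _wc_components(ca, cb)
        num += a
        den += d
    if den == 0:
        return float("nan")
    return num / den


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

_PRIORITY_ORDER = {Priority.P1: 0, Priority.P2: 1, Priority.BACKGROUND: 2}
_GROUP_ORDER = {
    Group.GWAS: 0,
    Group.CANDIDATE_GENE: 1,
    Group.RFI: 2,
    Group.RESEQUENCING: 3,
    Group.SNPDB: 4,
}


def assemble_candidates(
    groups: list[list[CandidateSnp]],
    snpdb: list[CandidateSnp] | None = None,
) -> list[CandidateSnp]:
    """Merge group outputs into one candidate set, deduplicated by position.

    Precedence at a shared (chrom, pos): P1 > P2 > BACKGROUND, ties broken
    by group order (gwas, candidate_gene, rfi, resequencing, snpdb).  The
    winning record's ``other_groups`` lists every other source that
    nominated the position.  Conflicting alleles at one position trigger a
    warning; the higher-precedence record wins.
    """
    pooled: list[CandidateSnp] = [c for grp in groups for c in grp]
    if snpdb:
        pooled.extend(snpdb)

    by_key: dict[tuple[str, int], list[CandidateSnp]] = {}
    for c in pooled:
        by_key.setdefault(c.key, []).append(c)

    out: list[CandidateSnp] = []
    for key in sorted(by_key):
        records = sorted(
            by_key[key],
            key=lambda c: (_PRIORITY_ORDER[c.priority], _GROUP_ORDER[c.group]),
        )
        winner = records[0]
        others = tuple(
            dict.fromkeys(c.group for c in records[1:] if c.group is not winner.group)
        )
        alleles = {(c.locus.ref_allele, c.locus.alt_allele) for c in records}
        if len(alleles) > 1:
            warnings.warn(
                f"conflicting alleles at {key[0]}:{key[1]}; keeping "
                f"{winner.group.value} record",
                UserWarning,
                stacklevel=2,
            )
        if others:
            winner = replace(winner, other_groups=others)
        out.append(winner)
    return out


# ---------------------------------------------------------------------------
# Table readers (TSV formats for the selector inputs)
# ---------------------------------------------------------------------------


def read_association_table(path) -> AssociationTable:
    """Read an association TSV: chrom, pos, trait, p."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if list(df.columns) != ["chrom", "pos", "trait", "p"]:
        raise ValueError(f"{path}: expected columns chrom, pos, trait, p")
    rows = [
        (SnpLocus(r.chrom, int(r.pos), "A", "G", f"{r.chrom}_{int(r.pos)}"), r.trait, float(r.p))
        for r in df.itertuples(index=False)
    ]
    return AssociationTable(rows)


def read_gene_intervals(path) -> GeneIntervalTable:
    """Read a gene-interval TSV: gene, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    if list(df.columns) != ["gene", "chrom", "start", "end"]:
        raise ValueError(f"{path}: expected columns gene, chrom, start, end")
    return GeneIntervalTable(
        [(r.gene, r.chrom, int(r.start), int(r.end)) for r in df.itertuples(index=False)]
    )


def read_rfi_stats(path) -> RfiStatTable:
    """Read a feed-efficiency statistics TSV: chrom, pos, fst, mean_delta_f."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if list(df.columns) != ["chrom", "pos", "fst", "mean_delta_f"]:
        raise ValueError(f"{path}: expected columns chrom, pos, fst, mean_delta_f")
    return RfiStatTable(
        [
            (
                SnpLocus(r.chrom, int(r.pos), "A", "G", f"{r.chrom}_{int(r.pos)}"),
                float(r.fst),
                float(r.mean_delta_f),
            )
            for r in df.itertuples(index=False)
        ]
    )
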