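"""Seeded generators for every input the toolkit consumes.

The generators emulate the statistical structure of the design's real
inputs: multi-breed allele-frequency divergence under the
Balding–Nichols model, within-breed diploid genotypes with first-order
haplotype-copying LD, uniform missingness, and complete design fixtures
(genome layout, candidate tables for all source groups, background
database).  Every generator is a pure function of its SimConfig: the
same seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .candidate_prep import BreedRoleMap
from .datamodel_io import (
    MISSING,
    CandidateSnp,
    GenomeLayout,
    GenotypeMatrix,
    Group,
    PoolFrequencyTable,
    Priority,
    SnpLocus,
    write_candidate_table,
    write_genome_layout,
)

__all__ = [
    "SimConfig",
    "simulate_pool_frequencies",
    "default_roles",
    "simulate_genotypes",
    "make_design_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort and genome.

    Defaults mirror the study conditions: eight pooled breeds (five local,
    three commercial) of 48 diploids each, moderate breed differentiation,
    ~97.5% genotype call rate, and strong short-range LD.  The genome is a
    three-chromosome desk-scale layout; window-partitioned design still
    sees hundreds of 22 kb windows.
    """

    seed: int
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("1", 2_000_000),
        ("2", 1_500_000),
        ("3", 1_000_000),
    )
    n_loci: int = 2_000
    n_local_breeds: int = 5
    n_commercial_breeds: int = 3
    pool_size: int = 48  # diploid individuals pooled per breed
    target_fst: float = 0.15
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    n_pops: int = 3
    samples_per_pop: int = 18
    ld_copy_rate: float = 0.90
    missing_rate: float = 0.025
    genotype_spacing: int = 2_000  # bp between simulated genotyped loci
    # design-fixture candidate counts per source group; per-window densities
    # mirror the real design (~0.5 priority-1 and ~2.6 priority-2 candidates
    # per 22 kb window, dense background database)
    n_gwas: int = 30
    n_gene: int = 60
    n_rfi: int = 15
    n_resequencing: int = 530
    n_indel_whitelist: int = 5
    n_snpdb: int = 2_000
    snpdb_validated_rate: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fst < 1.0:
            raise ValueError("target_fst must lie in (0, 1)")
        if not 0.0 <= self.ld_copy_rate < 1.0:
            raise ValueError("ld_copy_rate must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def genome(self) -> GenomeLayout:
        return GenomeLayout(self.chrom_lengths)

    @property
    def breeds(self) -> list[str]:
        return [f"local_{i + 1}" for i in range(self.n_local_breeds)] + [
            f"commercial_{i + 1}" for i in range(self.n_commercial_breeds)
        ]


def _random_loci(rng: np.random.Generator, genome: GenomeLayout, n: int) -> list[SnpLocus]:
    """n unique random positions across the genome, sorted by genome order."""
    lengths = np.array([length for _, length in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    seen: set[tuple[str, int]] = set()
    out: list[tuple[int, int]] = []
    while len(out) < n:
        c = int(rng.choice(len(lengths), p=probs))
        pos = int(rng.integers(1, int(lengths[c]) + 1))
        key = (genome.names[c], pos)
        if key not in seen:
            seen.add(key)
            out.append((c, pos))
    out.sort()
    alleles = ["A", "C", "G", "T"]
    loci = []
    for c, pos in out:
        ref = alleles[int(rng.integers(4))]
        alt = alleles[(alleles.index(ref) + 1 + int(rng.integers(3))) % 4]
        chrom = genome.names[c]
        loci.append(SnpLocus(chrom, pos, ref, alt, f"{chrom}_{pos}"))
    return loci


# ---------------------------------------------------------------------------
# Pooled breed frequencies (Balding–Nichols)
# ---------------------------------------------------------------------------


def _balding_nichols(
    rng: np.random.Generator, ancestral: np.ndarray, fst: float, size: tuple[int, int]
) -> np.ndarray:
    """Draw per-population frequencies around the ancestral vector with the
    configured differentiation: Beta(p(1−F)/F, (1−p)(1−F)/F)."""
    if fst == 0.0:
        return np.broadcast_to(ancestral, size).copy()
    scale = (1.0 - fst) / fst
    return rng.beta(ancestral * scale, (1.0 - ancestral) * scale, size=size)


def simulate_pool_frequencies(config: SimConfig) -> PoolFrequencyTable:
    """Pooled per-breed alternate-allele frequency estimates.

    Ancestral frequencies are uniform on [ancestral_low, ancestral_high];
    each breed's true frequency is a Balding–Nichols draw at
    ``target_fst``; the pooled estimate adds binomial sampling noise at
    2 x pool_size allele draws.
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    loci = _random_loci(rng, genome, config.n_loci)
    ancestral = rng.uniform(config.ancestral_low, config.ancestral_high, config.n_loci)
    breeds = config.breeds
    true = _balding_nichols(
        rng, ancestral, config.target_fst, (len(breeds), config.n_loci)
    )
    n_alleles = 2 * config.pool_size
    est = rng.binomial(n_alleles, true) / n_alleles
    freq = pd.DataFrame(est.T, columns=breeds)
    return PoolFrequencyTable(
        loci=loci,
        breeds=breeds,
        freq=freq,
        pool_size={b: config.pool_size for b in breeds},
    )


def default_roles(config: SimConfig) -> BreedRoleMap:
    """Contrast map matching the simulated breed layout: local breeds are
    screened against the first commercial line and vice versa."""
    breeds = config.breeds
    local = tuple(b for b in breeds if b.startswith("local_"))
    commercial = tuple(b for b in breeds if b.startswith("commercial_"))
    return BreedRoleMap(
        local_breeds=local,
        commercial_breeds=commercial,
        control_for_local=commercial[0],
        control_for_commercial=local[0],
    )


# ---------------------------------------------------------------------------
# Genotypes with LD
# ---------------------------------------------------------------------------


def simulate_genotypes(
    config: SimConfig,
    pop_freqs: np.ndarray | None = None,
    loci: list[SnpLocus] | None = None,
) -> GenotypeMatrix:
    """Diploid dosages for ``n_pops`` populations with copying-model LD.

    Loci default to an evenly spaced grid (``genotype_spacing`` bp).  Per
    haplotype and chromosome, the first allele is Bernoulli(freq); each
    subsequent allele copies the previous locus' allele with probability
    ``ld_copy_rate``, else is drawn fresh from the population frequency.
    Dosage = sum of two haplotypes; entries are masked at
    ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed + 1)
    genome = config.genome
    if loci is None:
        loci = []
        per_chrom = max(1, config.n_loci // len(genome.chromosomes))
        for chrom, length in genome.chromosomes:
            pos = config.genotype_spacing
            count = 0
            while pos <= length and count < per_chrom:
                loci.append(SnpLocus(chrom, pos, "A", "G", f"{chrom}_{pos}"))
                pos += config.genotype_spacing
                count += 1
    n_loci = len(loci)
    if pop_freqs is None:
        ancestral = rng.uniform(config.ancestral_low, config.ancestral_high, n_loci)
        pop_freqs = _balding_nichols(
            rng, ancestral, config.target_fst, (config.n_pops, n_loci)
        )
    n_pops = pop_freqs.shape[0]
    chrom_of = np.array([genome.order_index(loc.chrom) for loc in loci])

    samples: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    for p in range(n_pops):
        freqs = pop_freqs[p]
        for s in range(config.samples_per_pop):
            haplos = np.empty((2, n_loci), dtype=np.int8)
            for h in range(2):
                draws = (rng.random(n_loci) < freqs).astype(np.int8)
                copy = rng.random(n_loci) < config.ld_copy_rate
                hap = draws.copy()
                for j in range(1, n_loci):
                    if copy[j] and chrom_of[j] == chrom_of[j - 1]:
                        hap[j] = hap[j - 1]
                haplos[h] = hap
            dosage = haplos.sum(axis=0)
            rows.append(dosage)
            samples.append((f"pop{p + 1}_s{s + 1}", f"pop{p + 1}"))
    geno = np.array(rows, dtype=np.int8)
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING
    return GenotypeMatrix(samples=samples, loci=loci, geno=geno)


# ---------------------------------------------------------------------------
# Design fixture
# ---------------------------------------------------------------------------


def make_design_fixture(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[GenomeLayout, list[CandidateSnp], list[CandidateSnp]]:
    """A complete, internally consistent design input bundle.

    Returns (genome, candidates for the four selection groups, background
    database markers).  When ``out_dir`` is given, also writes
    ``genome.tsv``, ``candidates.tsv`` and ``snpdb.tsv`` there in the
    formats the readers consume.  Candidate positions are unique across
    all groups; group sizes follow the config.
    """
    rng = np.random.default_rng(config.seed + 2)
    genome = config.genome
    total = (
        config.n_gwas
        + config.n_gene
        + config.n_rfi
        + config.n_resequencing
        + config.n_snpdb
    )
    capacity = sum(length for _, length in genome.chromosomes)
    if total > capacity // 2:
        raise ValueError("requested candidate density exceeds genome capacity")
    loci = _random_loci(rng, genome, total)
    order = rng.permutation(total)
    cursor = 0

    def take(n: int) -> list[SnpLocus]:
        nonlocal cursor
        picked = [loci[i] for i in sorted(order[cursor : cursor + n])]
        cursor += n
        return picked

    candidates: list[CandidateSnp] = []
    for locus in take(config.n_gwas):
        candidates.append(
            CandidateSnp(locus, Group.GWAS, Priority.P1, score=float(rng.uniform(1e-8, 1e-3)))
        )
    for locus in take(config.n_gene):
        candidates.append(CandidateSnp(locus, Group.CANDIDATE_GENE, Priority.P1))
    for locus in take(config.n_rfi):
        candidates.append(
            CandidateSnp(locus, Group.RFI, Priority.P1, score=float(rng.uniform(0.35, 1.0)))
        )
    reseq = take(config.n_resequencing)
    n_indel = min(config.n_indel_whitelist, len(reseq))
    indel_idx = set(rng.choice(len(reseq), size=n_indel, replace=False).tolist())
    for i, locus in enumerate(reseq):
        is_indel = i in indel_idx
        candidates.append(
            CandidateSnp(
                locus,
                Group.RESEQUENCING,
                Priority.P1 if is_indel else Priority.P2,
                is_indel=is_indel,
                score=float(rng.uniform(0.609, 0.95)),
            )
        )
    snpdb = [
        CandidateSnp(
            locus,
            Group.SNPDB,
            Priority.BACKGROUND,
            validated=bool(rng.random() < config.snpdb_validated_rate),
        )
        for locus in take(config.n_snpdb)
    ]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome_layout(genome, out / "genome.tsv")
        write_candidate_table(candidates, out / "candidates.tsv")
        write_candidate_table(snpdb, out / "snpdb.tsv")
    return genome, candidates, snpdb
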