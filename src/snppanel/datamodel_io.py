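"""Domain types and file I/O for the array-design toolkit.

All genomic coordinates are 1-based inclusive internally (VCF convention).
BED export is the single 0-based, half-open surface. Missing genotypes are
the explicit sentinel :data:`MISSING`, never conflated with homozygous
reference.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "Group",
    "Priority",
    "PassLabel",
    "GenomeLayout",
    "SnpLocus",
    "CandidateSnp",
    "PoolFrequencyTable",
    "GenotypeMatrix",
    "PanelEntry",
    "Panel",
    "AnnotationTable",
    "CONSEQUENCE_CLASSES",
    "DesignConfig",
    "SnpTableError",
    "read_genome_layout",
    "write_genome_layout",
    "read_candidate_table",
    "write_candidate_table",
    "write_panel_manifest",
    "read_panel_manifest",
    "read_genotypes",
    "write_dosage_tsv",
    "read_pool_frequency_table",
    "write_pool_frequency_table",
    "read_annotation_table",
    "write_annotation_table",
    "export_bed",
]

#: Sentinel for a missing diploid genotype in a dosage matrix.
MISSING: int = -1


class Group(str, enum.Enum):
    """Provenance of a candidate marker (the five design sources)."""

    RESEQUENCING = "resequencing"
    GWAS = "gwas"
    CANDIDATE_GENE = "candidate_gene"
    RFI = "rfi"
    SNPDB = "snpdb"


class Priority(str, enum.Enum):
    """Placement precedence: trait-linked first, differential second,
    database background last."""

    P1 = "P1"
    P2 = "P2"
    BACKGROUND = "BACKGROUND"


class PassLabel(str, enum.Enum):
    """Which design pass placed a marker on the panel."""

    PRIORITY1 = "priority1"
    PRIORITY2 = "priority2"
    BACKGROUND = "background"


class SnpTableError(ValueError):
    """Raised for malformed rows or reference mismatches in tabular input."""


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def order_index(self, chrom: str) -> int:
        return self.names.index(chrom)


# ---------------------------------------------------------------------------
# Loci and candidates
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class SnpLocus:
    """A single biallelic site: chromosome, 1-based position, alleles."""

    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    snp_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(
                f"position {self.pos} invalid: coordinates are 1-based (pos >= 1)"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class CandidateSnp:
    """A locus with design provenance: source group, priority tier, flags.

    ``score`` carries whatever statistic selected the marker (ΔF, GWAS
    p-value, or Fst).  ``other_groups`` records additional sources that
    also nominated the same position after deduplication.
    """

    locus: SnpLocus
    group: Group
    priority: Priority
    validated: bool = False
    is_indel: bool = False
    score: float | None = None
    other_groups: tuple[Group, ...] = ()

    def __post_init__(self) -> None:
        if (self.group is Group.SNPDB) != (self.priority is Priority.BACKGROUND):
            raise ValueError("group=snpdb if and only if priority=BACKGROUND")
        if self.is_indel and self.priority is not Priority.P1:
            raise ValueError("indels are only admitted via the P1 whitelist")

    @property
    def key(self) -> tuple[str, int]:
        return self.locus.key


# ---------------------------------------------------------------------------
# Pool frequencies
# ---------------------------------------------------------------------------


@dataclass
class PoolFrequencyTable:
    """Per-breed alternate-allele frequencies estimated from pooled sequencing.

    ``freq`` is a DataFrame indexed by locus position in ``loci`` order
    with one column per breed; NaN encodes an explicitly missing estimate.
    """

    loci: list[SnpLocus]
    breeds: list[str]
    freq: pd.DataFrame
    pool_size: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.freq.columns) != list(self.breeds):
            raise ValueError("freq columns must match breed list")
        if len(self.freq) != len(self.loci):
            raise ValueError("freq rows must match locus list")
        vals = self.freq.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValueError("frequencies must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """samples x loci diploid dosage matrix with values {0, 1, 2, MISSING}."""

    samples: list[tuple[str, str]]  # (sample_id, population label)
    loci: list[SnpLocus]
    geno: np.ndarray  # int8, shape (n_samples, n_loci)

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"genotype shape {self.geno.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.geno, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotypes must be 0, 1, 2 or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, pop in self.samples:
            seen.setdefault(pop)
        return list(seen)

    def subset(
        self,
        sample_idx: Sequence[int] | None = None,
        locus_idx: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx, dtype=int)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            loci=[self.loci[j] for j in li],
            geno=self.geno[np.ix_(si, li)],
        )


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelEntry:
    snp: CandidateSnp
    window_index: int
    pass_label: PassLabel


@dataclass
class Panel:
    """The designed marker set: ordered entries plus the config snapshot."""

    entries: list[PanelEntry]
    design_config: "DesignConfig"
    genome: GenomeLayout | None = None

    def __post_init__(self) -> None:
        keys = [e.snp.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("panel contains duplicate (chrom, pos)")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def loci(self) -> list[SnpLocus]:
        return [e.snp.locus for e in self.entries]

    def positions(self) -> set[tuple[str, int]]:
        return {e.snp.key for e in self.entries}


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

#: Controlled vocabulary of variant-consequence classes.
CONSEQUENCE_CLASSES: tuple[str, ...] = (
    "intergenic variant",
    "intron variant",
    "intron variant & noncoding transcript variant",
    "missense variant",
    "missense variant & splice region variant",
    "synonymous variant",
    "splicing",
    "start/stop gained/lost/retained",
    "3 prime UTR variant",
    "5 prime UTR variant",
    "upstream gene variant (1 kb)",
    "downstream gene variant (1 kb)",
    "noncoding transcript exon variant",
    "unannotated",
)


@dataclass
class AnnotationTable:
    """Map (chrom, pos) -> consequence class; unknown loci are 'unannotated'."""

    classes: dict[tuple[str, int], str]

    def __post_init__(self) -> None:
        vocab = set(CONSEQUENCE_CLASSES)
        for key, cls in self.classes.items():
            if cls not in vocab:
                raise ValueError(f"unknown consequence class {cls!r} at {key}")

    def lookup(self, chrom: str, pos: int) -> str:
        return self.classes.get((chrom, pos), "unannotated")


# ---------------------------------------------------------------------------
# Design configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QcConfig:
    """Marker/sample quality-control cut-offs."""

    snp_call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 0.001
    sample_missing_max: float = 0.10

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "maf_min", "hwe_p_min", "sample_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class DesignConfig:
    """Every tunable of the design procedure, with its published default.

    window_length
        Genomic window (bp) within which at most two markers are retained.
    delta_f_threshold_local / delta_f_threshold_commercial
        Minimum MAF differential vs the control breed for resequencing
        candidates from local breeds / commercial lines.
    maf_min
        Minimum pooled MAF for a resequencing candidate.
    gwas_top_fraction
        Fraction of smallest association p-values retained per trait.
    gene_flank
        bp added on each side of a candidate gene interval.
    gene_cap
        Maximum markers retained per candidate gene.
    rfi_fst_quantile
        Empirical Fst quantile below which feed-efficiency candidates
        are excluded (top 5% kept by default).
    rfi_delta_f_min
        Minimum mean allele-frequency differential between divergent
        feed-efficiency groups.
    """

    window_length: int = 22_000
    delta_f_threshold_local: float = 0.609
    delta_f_threshold_commercial: float = 0.731
    maf_min: float = 0.05
    gwas_top_fraction: float = 0.01
    gene_flank: int = 5_000
    gene_cap: int = 5
    rfi_fst_quantile: float = 0.95
    rfi_delta_f_min: float = 0.35
    delta_f_absolute: bool = False
    qc: QcConfig = field(default_factory=QcConfig)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        for name in ("maf_min", "gwas_top_fraction", "rfi_fst_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def with_overrides(self, **kwargs) -> "DesignConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CANDIDATE_COLUMNS = ["chrom", "pos", "ref", "alt", "group", "validated", "is_indel", "score"]
_MANIFEST_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "group",
    "priority",
    "pass",
    "window_index",
]


def read_genome_layout(path) -> GenomeLayout:
    """Read a two-column TSV (chrom, length) into a GenomeLayout."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "length": np.int64})
    if list(df.columns) != ["chrom", "length"]:
        raise SnpTableError(f"{path}: expected columns chrom, length")
    return GenomeLayout(tuple(zip(df["chrom"], df["length"].astype(int))))


def write_genome_layout(genome: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


_PRIORITY_FOR_GROUP = {
    Group.RESEQUENCING: Priority.P2,
    Group.GWAS: Priority.P1,
    Group.CANDIDATE_GENE: Priority.P1,
    Group.RFI: Priority.P1,
    Group.SNPDB: Priority.BACKGROUND,
}


def read_candidate_table(path, genome: GenomeLayout) -> list[CandidateSnp]:
    """Read a candidate-marker TSV, validating every row against the genome.

    Expected header: chrom, pos, ref, alt, group, validated, is_indel, score.
    Rows violating invariants are rejected with a message citing the
    offending (1-based, header-inclusive) line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _CANDIDATE_COLUMNS:
        raise SnpTableError(
            f"{path}: expected columns {_CANDIDATE_COLUMNS}, found {list(df.columns)}"
        )
    out: list[CandidateSnp] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path} line {i}"
        chrom = row.chrom
        if chrom not in genome:
            raise SnpTableError(f"{where}: chromosome {chrom!r} not in genome layout")
        try:
            pos = int(row.pos)
        except ValueError as exc:
            raise SnpTableError(f"{where}: position {row.pos!r} is not an integer") from exc
        if pos < 1:
            raise SnpTableError(
                f"{where}: position {pos} invalid; coordinates are 1-based (pos >= 1)"
            )
        if pos > genome.length(chrom):
            raise SnpTableError(
                f"{where}: position {pos} exceeds chromosome {chrom} length"
            )
        try:
            group = Group(row.group)
        except ValueError as exc:
            raise SnpTableError(f"{where}: unknown group {row.group!r}") from exc
        validated = _parse_bool(row.validated, where, "validated")
        is_indel = _parse_bool(row.is_indel, where, "is_indel")
        score = None if row.score in ("", "NA", "nan") else float(row.score)
        try:
            locus = SnpLocus(chrom, pos, row.ref, row.alt, f"{chrom}_{pos}")
            out.append(
                CandidateSnp(
                    locus=locus,
                    group=group,
                    priority=Priority.P1 if is_indel else _PRIORITY_FOR_GROUP[group],
                    validated=validated,
                    is_indel=is_indel,
                    score=score,
                )
            )
        except ValueError as exc:
            raise SnpTableError(f"{where}: {exc}") from exc
    return out


def _parse_bool(token: str, where: str, col: str) -> bool:
    t = token.strip().lower()
    if t in ("1", "true", "t", "yes"):
        return True
    if t in ("0", "false", "f", "no"):
        return False
    raise SnpTableError(f"{where}: column {col} has non-boolean value {token!r}")


def write_candidate_table(snps: Iterable[CandidateSnp], path) -> None:
    """Write candidates in the format :func:`read_candidate_table` reads."""
    with open(path, "w") as fh:
        fh.write("\t".join(_CANDIDATE_COLUMNS) + "\n")
        for c in snps:
            score = "" if c.score is None else repr(float(c.score))
            fh.write(
                f"{c.locus.chrom}\t{c.locus.pos}\t{c.locus.ref_allele}\t"
                f"{c.locus.alt_allele}\t{c.group.value}\t{int(c.validated)}\t"
                f"{int(c.is_indel)}\t{score}\n"
            )


def write_panel_manifest(panel: Panel, path) -> None:
    """Write the deterministic panel manifest TSV.

    Rows are sorted by (chromosome order when a genome is attached,
    otherwise chromosome name; then position); re-running on the same
    panel produces byte-identical output.
    """
    if panel.genome is not None:
        order = {name: i for i, name in enumerate(panel.genome.names)}
        sort_key = lambda e: (order[e.snp.locus.chrom], e.snp.locus.pos)
    else:
        sort_key = lambda e: (e.snp.locus.chrom, e.snp.locus.pos)
    entries = sorted(panel.entries, key=sort_key)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for e in entries:
            loc = e.snp.locus
            fh.write(
                f"{loc.snp_id}\t{loc.chrom}\t{loc.pos}\t{loc.ref_allele}\t"
                f"{loc.alt_allele}\t{e.snp.group.value}\t{e.snp.priority.value}\t"
                f"{e.pass_label.value}\t{e.window_index}\n"
            )


def read_panel_manifest(path, config: DesignConfig | None = None) -> Panel:
    """Read a manifest TSV back into a Panel (provenance preserved)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _MANIFEST_COLUMNS:
        raise SnpTableError(f"{path}: expected columns {_MANIFEST_COLUMNS}")
    entries = []
    for row in df.to_dict("records"):  # "pass" is a keyword, itertuples mangles it
        locus = SnpLocus(row["chrom"], int(row["pos"]), row["ref"], row["alt"], row["snp_id"])
        snp = CandidateSnp(
            locus=locus,
            group=Group(row["group"]),
            priority=Priority(row["priority"]),
            is_indel=False,
        )
        entries.append(PanelEntry(snp, int(row["window_index"]), PassLabel(row["pass"])))
    return Panel(entries, config or DesignConfig())


# ---------------------------------------------------------------------------
# Genotype input
# ---------------------------------------------------------------------------


def read_genotypes(
    path,
    dialect: str = "vcf",
    populations: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF or a dosage TSV.

    VCF GT fields are mapped to alternate-allele dosage {0,1,2}; any call
    containing a missing allele (``./.``, ``./0`` ...) maps to MISSING.
    Records with ploidy other than 2 raise.  ``populations`` optionally maps
    sample id -> population label (default label: ``"pop"``).
    """
    if dialect == "vcf":
        return _read_vcf(path, populations)
    if dialect == "dosage_tsv":
        return _read_dosage_tsv(path, populations)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_vcf(path, populations) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    loci: list[SnpLocus] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "N"
        loci.append(SnpLocus(var.CHROM, var.POS, var.REF, alt, var.ID or f"{var.CHROM}_{var.POS}"))
        col = np.empty(len(sample_ids), dtype=np.int8)
        for i, call in enumerate(var.genotypes):
            alleles = call[:-1]  # last element is the phasing flag
            if len(alleles) != 2:
                raise SnpTableError(
                    f"{path}: record {var.CHROM}:{var.POS} sample {sample_ids[i]} "
                    f"has ploidy {len(alleles)}; only diploid calls are supported"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                col[i] = MISSING
            else:
                col[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        columns.append(col)
    vcf.close()
    geno = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    samples = [(s, (populations or {}).get(s, "pop")) for s in sample_ids]
    return GenotypeMatrix(samples=samples, loci=loci, geno=geno)


def _read_dosage_tsv(path, populations) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    meta_cols = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != meta_cols:
        raise SnpTableError(f"{path}: expected leading columns {meta_cols}")
    sample_ids = list(df.columns[4:])
    loci = [
        SnpLocus(r.chrom, int(r.pos), r.ref, r.alt, f"{r.chrom}_{r.pos}")
        for r in df.itertuples(index=False)
    ]
    geno = np.empty((len(sample_ids), len(loci)), dtype=np.int8)
    values = df.iloc[:, 4:].to_numpy(dtype=object)
    for j in range(len(loci)):
        for i, sid in enumerate(sample_ids):
            token = values[j, i]
            if token in ("NA", ".", ""):
                geno[i, j] = MISSING
            elif token in ("0", "1", "2"):
                geno[i, j] = int(token)
            else:
                raise SnpTableError(
                    f"{path} line {j + 2}: invalid dosage {token!r} for sample {sid}"
                )
    samples = [(s, (populations or {}).get(s, "pop")) for s in sample_ids]
    return GenotypeMatrix(samples=samples, loci=loci, geno=geno)


def write_dosage_tsv(matrix: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix in the dosage_tsv dialect (MISSING -> NA)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(s for s, _ in matrix.samples) + "\n")
        for j, loc in enumerate(matrix.loci):
            vals = [
                "NA" if matrix.geno[i, j] == MISSING else str(int(matrix.geno[i, j]))
                for i in range(matrix.n_samples)
            ]
            fh.write(f"{loc.chrom}\t{loc.pos}\t{loc.ref_allele}\t{loc.alt_allele}\t" + "\t".join(vals) + "\n")


def read_pool_frequency_table(path) -> PoolFrequencyTable:
    """Read a pooled-frequency TSV: chrom, pos, ref, alt, then one column
    per breed with alternate-allele frequencies (NA = missing).  Optional
    leading comment lines ``#pool_size\tBREED\tN`` carry pool sizes."""
    pool_size: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#pool_size"):
            _tag, breed, n = line.rstrip("\n").split("\t")
            pool_size[breed] = int(n)
            body_start += 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", dtype={"chrom": str})
    meta = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != meta:
        raise SnpTableError(f"{path}: expected leading columns {meta}")
    breeds = list(df.columns[4:])
    loci = [
        SnpLocus(r.chrom, int(r.pos), r.ref, r.alt, f"{r.chrom}_{int(r.pos)}")
        for r in df.itertuples(index=False)
    ]
    freq = df[breeds].astype(float).reset_index(drop=True)
    return PoolFrequencyTable(loci=loci, breeds=breeds, freq=freq, pool_size=pool_size)


def write_pool_frequency_table(table: PoolFrequencyTable, path) -> None:
    with open(path, "w") as fh:
        for breed, n in table.pool_size.items():
            fh.write(f"#pool_size\t{breed}\t{n}\n")
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(table.breeds) + "\n")
        vals = table.freq.to_numpy(float)
        for i, loc in enumerate(table.loci):
            row = "\t".join(
                "NA" if np.isnan(v) else repr(float(v)) for v in vals[i]
            )
            fh.write(f"{loc.chrom}\t{loc.pos}\t{loc.ref_allele}\t{loc.alt_allele}\t{row}\n")


def read_annotation_table(path) -> AnnotationTable:
    """Read a consequence-annotation TSV: chrom, pos, consequence."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "consequence": str})
    if list(df.columns) != ["chrom", "pos", "consequence"]:
        raise SnpTableError(f"{path}: expected columns chrom, pos, consequence")
    return AnnotationTable(
        {(r.chrom, int(r.pos)): r.consequence for r in df.itertuples(index=False)}
    )


def write_annotation_table(table: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tconsequence\n")
        for (chrom, pos), cls in sorted(table.classes.items()):
            fh.write(f"{chrom}\t{pos}\t{cls}\n")


def export_bed(panel: Panel, path) -> None:
    """Export panel positions as BED (0-based, half-open): start=pos-1, end=pos."""
    with open(path, "w") as fh:
        for e in panel.entries:
            loc = e.snp.locus
            fh.write(f"{loc.chrom}\t{loc.pos - 1}\t{loc.pos}\t{loc.snp_id}\n")
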