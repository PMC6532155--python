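"""Published summary tables of the chicken 55K genotyping array (IASCHICK).

These are the printed per-chromosome marker counts, source-group
composition, consequence-annotation counts and cross-array overlap counts
of the released 52,184-marker panel.  They are inputs for the report
module's arithmetic (totals, percentages, overlap fractions), used to
check that the summaries this package computes reproduce the published
ones exactly.
"""

from __future__ import annotations

__all__ = [
    "PER_CHROMOSOME_COUNTS",
    "GROUP_COMPOSITION",
    "ANNOTATION_COUNTS",
    "PANEL_TOTAL",
    "ANNOTATABLE_COUNT",
    "OVERLAP_WITH_600K",
    "OVERLAP_WITH_60K",
]

#: Markers per chromosome on the released panel (Gallus_gallus-5.0).
PER_CHROMOSOME_COUNTS: dict[str, int] = {
    "1": 10228, "2": 7077, "3": 5196, "4": 4589, "5": 2705, "6": 1750,
    "7": 1684, "8": 1314, "9": 1236, "10": 1399, "11": 1373, "12": 1389,
    "13": 1041, "14": 1118, "15": 761, "16": 81, "17": 724, "18": 736,
    "19": 725, "20": 867, "21": 503, "22": 153, "23": 321, "24": 390,
    "25": 106, "26": 339, "27": 277, "28": 317, "Z": 3785,
}

#: Source-group composition of the released panel.  The resequencing group
#: is printed as three sub-counts (by plumage/line type).
GROUP_COMPOSITION: dict[str, int] = {
    "resequencing_white_feathered": 12555,
    "resequencing_yellow_feathered": 3940,
    "resequencing_cyan_shank_partridge": 2724,
    "gwas": 5980,
    "candidate_gene": 7630,
    "rfi": 943,
    "snpdb": 18412,
}

#: RFI candidate-group sub-counts before panel placement (thousands):
#: divergent feed-efficiency screens in a local and a commercial line.
RFI_CANDIDATE_SUBTOTALS_K: tuple[float, float] = (3.74, 0.58)

#: Consequence-class counts on the released panel.
ANNOTATION_COUNTS: dict[str, int] = {
    "intergenic variant": 16106,
    "intron variant": 25275,
    "intron variant & noncoding transcript variant": 3981,
    "missense variant": 590,
    "missense variant & splice region variant": 13,
    "synonymous variant": 1601,
    "splicing": 187,
    "start/stop gained/lost/retained": 12,
    "3 prime UTR variant": 1358,
    "5 prime UTR variant": 229,
    "upstream gene variant (1 kb)": 871,
    "downstream gene variant (1 kb)": 1014,
    "noncoding transcript exon variant": 871,
}

PANEL_TOTAL: int = 52184
ANNOTATABLE_COUNT: int = 52108

#: Positions shared with the 600K chicken array / the 60K bead chip.
OVERLAP_WITH_600K: int = 24227
OVERLAP_WITH_60K: int = 6740


def build_published_panel():
    """Synthetic reconstruction of the released panel's summary structure.

    Marker positions are synthetic stand-ins (the released coordinates are
    not bundled); what is faithful to the published array are the
    per-chromosome counts, the source-group composition and the
    consequence-class counts, which is exactly what the summary arithmetic
    consumes.  Returns ``(panel, annotation_table)``.
    """
    from .datamodel_io import (
        AnnotationTable,
        CandidateSnp,
        DesignConfig,
        Group,
        Panel,
        PanelEntry,
        PassLabel,
        Priority,
        SnpLocus,
    )

    group_sequence: list[Group] = (
        [Group.RESEQUENCING]
        * (
            GROUP_COMPOSITION["resequencing_white_feathered"]
            + GROUP_COMPOSITION["resequencing_yellow_feathered"]
            + GROUP_COMPOSITION["resequencing_cyan_shank_partridge"]
        )
        + [Group.GWAS] * GROUP_COMPOSITION["gwas"]
        + [Group.CANDIDATE_GENE] * GROUP_COMPOSITION["candidate_gene"]
        + [Group.RFI] * GROUP_COMPOSITION["rfi"]
        + [Group.SNPDB] * GROUP_COMPOSITION["snpdb"]
    )
    class_sequence: list[str] = [
        cls for cls, n in ANNOTATION_COUNTS.items() for _ in range(n)
    ] + ["unannotated"] * (PANEL_TOTAL - ANNOTATABLE_COUNT)

    priority_for = {
        Group.RESEQUENCING: Priority.P2,
        Group.GWAS: Priority.P1,
        Group.CANDIDATE_GENE: Priority.P1,
        Group.RFI: Priority.P1,
        Group.SNPDB: Priority.BACKGROUND,
    }
    pass_for = {
        Priority.P1: PassLabel.PRIORITY1,
        Priority.P2: PassLabel.PRIORITY2,
        Priority.BACKGROUND: PassLabel.BACKGROUND,
    }
    entries = []
    annotations: dict[tuple[str, int], str] = {}
    i = 0
    for chrom, count in PER_CHROMOSOME_COUNTS.items():
        for j in range(count):
            pos = 1000 * (j + 1)  # synthetic, evenly spaced stand-in positions
            group = group_sequence[i]
            prio = priority_for[group]
            snp = CandidateSnp(
                SnpLocus(chrom, pos, "A", "G", f"{chrom}_{pos}"), group, prio
            )
            entries.append(PanelEntry(snp, j, pass_for[prio]))
            cls = class_sequence[i]
            if cls != "unannotated":
                annotations[(chrom, pos)] = cls
            i += 1
    return Panel(entries, DesignConfig()), AnnotationTable(annotations)
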