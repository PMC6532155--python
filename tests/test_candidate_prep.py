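"""Candidate screens: frequency differentials, top fractions, gene caps,
Fst filtering and assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snppanel import (
    AssociationTable,
    CandidateSnp,
    BreedRoleMap,
    DesignConfig,
    GeneIntervalTable,
    Group,
    PoolFrequencyTable,
    Priority,
    RfiStatTable,
    SnpLocus,
    assemble_candidates,
    delta_f,
    minor_allele_frequency,
    select_gene_candidates,
    select_gwas_candidates,
    select_resequencing_candidates,
    select_rfi_candidates,
    wc_fst,
)
from tests.conftest import make_snp


class TestMafAndDeltaF:
    @pytest.mark.parametrize(
        "f,expected", [(0.9, 0.1), (0.5, 0.5), (0.05, 0.05), (0.0, 0.0), (1.0, 0.0)]
    )
    def test_folding(self, f, expected):
        assert minor_allele_frequency(f) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            minor_allele_frequency(1.2)
        with pytest.raises(ValueError):
            delta_f(0.6, 0.1)

    def test_arithmetic(self):
        assert delta_f(0.40, 0.05) == pytest.approx(0.35)

    @given(
        a=st.floats(0, 0.5, allow_nan=False),
        b=st.floats(0, 0.5, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetric_and_bounded(self, a, b):
        assert delta_f(a, b) == pytest.approx(-delta_f(b, a))
        assert abs(delta_f(a, b)) <= 0.5

    def test_threshold_application(self):
        survivors = [d for d in (0.70, 0.55) if d >= 0.609]
        assert survivors == [0.70]


def freq_table(loci, breeds, values):
    return PoolFrequencyTable(
        loci=loci,
        breeds=breeds,
        freq=pd.DataFrame(np.asarray(values, float), columns=breeds),
        pool_size={b: 48 for b in breeds},
    )


ROLES = BreedRoleMap(
    local_breeds=("loc",),
    commercial_breeds=("com",),
    control_for_local="com_ctrl",
    control_for_commercial="loc",
)
BREEDS = ["loc", "com", "com_ctrl"]


class TestResequencingScreen:
    def test_below_threshold_excluded(self, design_config):
        # local MAF 0.45 vs control 0.05: ΔF 0.40 < 0.609
        table = freq_table([SnpLocus("1", 10)], BREEDS, [[0.45, 0.5, 0.05]])
        assert select_resequencing_candidates(table, ROLES, design_config) == []

    def test_strong_differential_survives_as_p2(self, design_config):
        # local MAF 0.50 vs control fixed (MAF 0): ΔF 0.50 < 0.609 still fails;
        # lower the threshold to show the pass path and priority assignment
        cfg = design_config.with_overrides(delta_f_threshold_local=0.4)
        table = freq_table([SnpLocus("1", 10)], BREEDS, [[0.5, 0.5, 0.999]])
        out = select_resequencing_candidates(table, ROLES, cfg)
        assert len(out) == 1
        assert out[0].group is Group.RESEQUENCING
        assert out[0].priority is Priority.P2

    def test_chromosome_w_removed(self, design_config):
        cfg = design_config.with_overrides(delta_f_threshold_local=0.0)
        table = freq_table([SnpLocus("W", 10)], BREEDS, [[0.5, 0.5, 0.999]])
        assert select_resequencing_candidates(table, ROLES, cfg) == []

    def test_indel_whitelist_emitted_priority1(self, design_config):
        cfg = design_config.with_overrides(delta_f_threshold_local=0.0)
        table = freq_table([SnpLocus("1", 10)], BREEDS, [[0.5, 0.5, 0.999]])
        out = select_resequencing_candidates(table, ROLES, cfg, indel_whitelist={("1", 10)})
        assert out[0].priority is Priority.P1 and out[0].is_indel

    def test_zero_thresholds_equal_brute_force(self, rng, design_config):
        n = 1000
        chroms = np.where(rng.random(n) < 0.05, "W", "1")
        loci = [SnpLocus(str(c), i + 1) for i, c in enumerate(chroms)]
        vals = rng.random((n, 3))
        table = freq_table(loci, BREEDS, vals)
        cfg = design_config.with_overrides(
            delta_f_threshold_local=0.0, delta_f_threshold_commercial=0.0
        )
        out = {c.key for c in select_resequencing_candidates(table, ROLES, cfg)}
        maf = np.minimum(vals, 1 - vals)
        expected = set()
        for i, locus in enumerate(loci):
            if locus.chrom == "W":
                continue
            if (maf[i, 0] >= 0.05 and maf[i, 0] - maf[i, 2] >= 0) or (
                maf[i, 1] >= 0.05 and maf[i, 1] - maf[i, 0] >= 0
            ):
                expected.add(locus.key)
        assert out == expected

    def test_monotonic_in_threshold(self, rng, design_config):
        n = 500
        loci = [SnpLocus("1", i + 1) for i in range(n)]
        table = freq_table(loci, BREEDS, rng.random((n, 3)))
        counts = []
        for thr in (0.0, 0.1, 0.2, 0.3, 0.5):
            cfg = design_config.with_overrides(
                delta_f_threshold_local=thr, delta_f_threshold_commercial=thr
            )
            counts.append(len(select_resequencing_candidates(table, ROLES, cfg)))
        assert counts == sorted(counts, reverse=True)


class TestGwasScreen:
    def _table(self, rows):
        return AssociationTable(
            [(SnpLocus("1", pos), trait, p) for pos, trait, p in rows]
        )

    def test_top_fraction_counting(self, rng):
        rows = [(i + 1, "bw", float(p)) for i, p in enumerate(rng.random(200) * 0.99 + 0.005)]
        out = select_gwas_candidates(self._table(rows), 0.01)
        assert len(out) == 2
        smallest = sorted(rows, key=lambda r: r[2])[:2]
        assert {c.locus.pos for c in out} == {r[0] for r in smallest}

    def test_union_deduplicates_shared_top_snp(self):
        rows = [
            (1, "t1", 0.001), (2, "t1", 0.002), (3, "t1", 0.9), (4, "t1", 0.8),
            (1, "t2", 0.001), (5, "t2", 0.002), (3, "t2", 0.9), (6, "t2", 0.8),
        ]
        out = select_gwas_candidates(self._table(rows), 0.5)
        assert len(out) == 3  # {1, 2, 5}
        assert all(c.priority is Priority.P1 and c.group is Group.GWAS for c in out)

    def test_per_trait_ceiling(self):
        assert math.ceil(0.01 * 42_585) == 426

    def test_scaled_enumeration(self, rng):
        # 5 traits x 400 markers; per-trait take is ceil(4) = 4, union <= 20
        n, traits = 400, [f"t{k}" for k in range(5)]
        rows = []
        for t in traits:
            ps = rng.random(n)
            rows += [(i + 1, t, float(ps[i])) for i in range(n)]
        out = select_gwas_candidates(self._table(rows), 0.01)
        per_trait = {}
        for pos, t, p in rows:
            per_trait.setdefault(t, []).append((p, pos))
        expected = set()
        for t, lst in per_trait.items():
            lst.sort()
            expected |= {pos for _p, pos in lst[:4]}
        assert {c.locus.pos for c in out} == expected
        assert len(out) <= 20


class TestGeneScreen:
    def test_flank_inclusion(self, design_config):
        genes = GeneIntervalTable([("g1", "1", 10_000, 20_000)])
        snps = [(SnpLocus("1", 5_500), "intron variant")]
        out = select_gene_candidates(snps, genes, design_config)
        assert [c.locus.pos for c in out] == [5_500]

    def test_rank_then_cap(self, design_config):
        genes = GeneIntervalTable([("g1", "1", 1_000, 50_000)])
        introns = [(SnpLocus("1", 2_000 + 100 * i), "intron variant") for i in range(7)]
        missense = [(SnpLocus("1", 40_000), "missense variant")]
        out = select_gene_candidates(introns + missense, genes, design_config)
        assert len(out) == 5
        positions = {c.locus.pos for c in out}
        assert 40_000 in positions  # missense always kept
        assert positions - {40_000} == {2_000, 2_100, 2_200, 2_300}

    def test_cap_not_binding(self, design_config):
        genes = GeneIntervalTable([("g1", "1", 1_000, 50_000)])
        snps = [(SnpLocus("1", 2_000), "intron variant"), (SnpLocus("1", 3_000), "splicing")]
        assert len(select_gene_candidates(snps, genes, design_config)) == 2

    def test_overlapping_genes_deduplicated(self, design_config):
        genes = GeneIntervalTable([("g1", "1", 1_000, 20_000), ("g2", "1", 15_000, 40_000)])
        snps = [(SnpLocus("1", 16_000), "missense variant")]
        out = select_gene_candidates(snps, genes, design_config)
        assert len(out) == 1

    def test_per_gene_recount_never_exceeds_cap(self, rng, design_config):
        genes = GeneIntervalTable(
            [(f"g{k}", "1", 1 + 30_000 * k, 20_000 + 30_000 * k) for k in range(5)]
        )
        classes = ["intron variant", "missense variant", "synonymous variant", "3 prime UTR variant"]
        snps = [
            (SnpLocus("1", int(p)), classes[rng.integers(len(classes))])
            for p in sorted(rng.choice(np.arange(1, 160_000), 300, replace=False))
        ]
        out = select_gene_candidates(snps, genes, design_config)
        for gene, chrom, start, end in genes.rows:
            lo, hi = start - 5_000, end + 5_000
            n_in = sum(1 for c in out if lo <= c.locus.pos <= hi)
            # dedup means a shared flank region can hold up to 2 genes' picks
            assert n_in <= 2 * design_config.gene_cap


class TestRfiScreen:
    def test_quantile_enumeration(self, design_config):
        rows = [(SnpLocus("1", i + 1), (i + 1) / 100, 0.5) for i in range(100)]
        out = select_rfi_candidates(RfiStatTable(rows), design_config)
        assert {c.score for c in out} == {0.96, 0.97, 0.98, 0.99, 1.00}

    def test_delta_f_floor_excludes(self, design_config):
        rows = [(SnpLocus("1", i + 1), (i + 1) / 100, 0.5) for i in range(99)]
        rows.append((SnpLocus("1", 100), 1.0, 0.30))  # top Fst but weak ΔF
        out = select_rfi_candidates(RfiStatTable(rows), design_config)
        assert ("1", 100) not in {c.key for c in out}

    def test_empty_survivor_set_allowed(self, design_config):
        rows = [(SnpLocus("1", i + 1), (i + 1) / 10, 0.0) for i in range(10)]
        assert select_rfi_candidates(RfiStatTable(rows), design_config) == []

    def test_degenerate_fst_warns_and_uses_delta_f_only(self, design_config):
        rows = [
            (SnpLocus("1", 1), 0.5, 0.40),
            (SnpLocus("1", 2), 0.5, 0.10),
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            out = select_rfi_candidates(RfiStatTable(rows), design_config)
        assert [c.key for c in out] == [("1", 1)]


def oracle_wc_fst(count_a, count_b):
    """Independent route: build the allele indicator vectors and compute the
    ANOVA mean squares numerically."""
    x1 = np.repeat([0.0, 1.0], count_a)
    x2 = np.repeat([0.0, 1.0], count_b)
    n1, n2 = len(x1), len(x2)
    grand = np.concatenate([x1, x2]).mean()
    msp = n1 * (x1.mean() - grand) ** 2 + n2 * (x2.mean() - grand) ** 2
    ssg = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
    msg = ssg / (n1 - 1 + n2 - 1)
    nt = n1 + n2
    nc = nt - (n1 * n1 + n2 * n2) / nt
    denom = msp + (nc - 1) * msg
    return float("nan") if denom == 0 else (msp - msg) / denom


class TestWcFst:
    def test_no_differentiation_clamped_to_zero(self):
        clamped, raw = wc_fst((16, 16), (16, 16))
        assert raw <= 0
        assert clamped == 0.0

    def test_fixed_difference(self):
        clamped, _ = wc_fst((32, 0), (0, 32))
        assert clamped == pytest.approx(1.0)

    def test_against_anova_oracle(self, rng):
        for _ in range(1000):
            ca = (int(rng.integers(0, 40)), int(rng.integers(0, 40)))
            cb = (int(rng.integers(0, 40)), int(rng.integers(0, 40)))
            if sum(ca) < 2 or sum(cb) < 2:
                continue
            _clamped, raw = wc_fst(ca, cb)
            expected = oracle_wc_fst(ca, cb)
            if math.isnan(expected):
                assert math.isnan(raw)
            else:
                assert raw == pytest.approx(expected, abs=1e-12)

    def test_known_frequencies(self):
        # p1=0.8, p2=0.2, 16 diploids each -> strong differentiation
        clamped, raw = wc_fst((32 - 26, 26), (26, 6))
        assert raw == pytest.approx(oracle_wc_fst((6, 26), (26, 6)), abs=1e-12)
        assert clamped > 0.3


class TestAssembly:
    def test_priority_precedence(self):
        a = make_snp(pos=100, group=Group.GWAS, priority=Priority.P1)
        b = make_snp(pos=100, group=Group.RESEQUENCING, priority=Priority.P2)
        out = assemble_candidates([[a], [b]])
        assert len(out) == 1
        assert out[0].priority is Priority.P1
        assert out[0].other_groups == (Group.RESEQUENCING,)

    def test_disjoint_groups_conserved(self):
        groups = [
            [make_snp(pos=p) for p in range(1, 4)],
            [make_snp(pos=p, group=Group.RFI) for p in range(10, 14)],
            [make_snp(pos=p, group=Group.CANDIDATE_GENE) for p in range(20, 25)],
        ]
        assert len(assemble_candidates(groups)) == 12

    def test_randomized_overlap_matches_distinct_keys(self, rng):
        positions = rng.integers(1, 200, size=300)
        groups = [[], [], []]
        for p in positions:
            g = rng.integers(3)
            grp = [Group.GWAS, Group.RFI, Group.CANDIDATE_GENE][g]
            key = (("1", int(p)), grp)
            if any(c.key == ("1", int(p)) and c.group is grp for c in groups[g]):
                continue
            groups[g].append(make_snp(pos=int(p), group=grp))
        out = assemble_candidates(groups)
        distinct = {c.key for grp in groups for c in grp}
        assert len(out) == len(distinct)

    def test_conflicting_alleles_warn(self):
        a = make_snp(pos=100)
        b = CandidateSnp(
            SnpLocus("1", 100, "C", "T", "1_100"), Group.RESEQUENCING, Priority.P2
        )
        with pytest.warns(UserWarning, match="conflicting alleles"):
            out = assemble_candidates([[a], [b]])
        assert out[0].group is Group.GWAS
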