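import numpy as np
import pytest

import panelpop as pp
from panelpop.filtering import (
    FilterConfig,
    apply_site_and_sample_callrate,
    drop_mismatch_loci,
    mask_low_depth,
    recode_imbalanced_hets,
    record_level_stages,
    refilter_matrix,
    remove_nonbiallelic,
    run_filter_cascade,
)
from panelpop.simulate import InjectionConfig
from panelpop.types import RawVariantRecord


def make_record(
    chrom="A01",
    pos=100,
    ref="A",
    alts=("G",),
    gt=((0, 1),),
    ad=None,
    dp=None,
    mm=None,
):
    gt = np.array(gt, dtype=np.int32)
    n = gt.shape[0]
    n_alleles = 1 + len(alts)
    if ad is None:
        ad = np.full((n, n_alleles), 5, dtype=np.int32)
    if dp is None:
        dp = np.asarray(ad).sum(axis=1)
    return RawVariantRecord(
        chrom, pos, ref, list(alts),
        gt=gt, ad=np.asarray(ad), dp=np.asarray(dp),
        mismatches=None if mm is None else np.asarray(mm),
    )


class TestRemoveNonbiallelic:
    def test_indel_removed(self):
        kept, stage = remove_nonbiallelic([make_record(alts=("AT",))])
        assert kept == [] and stage.detail["indels"] == 1

    def test_triallelic_removed(self):
        kept, stage = remove_nonbiallelic(
            [make_record(alts=("C", "G"), ad=[[3, 3, 3]])]
        )
        assert kept == [] and stage.detail["multiallelic"] == 1

    def test_fixed_alt_removed(self):
        r = make_record(gt=((1, 1), (1, 1), (-1, -1)))
        kept, stage = remove_nonbiallelic([r])
        assert kept == [] and stage.detail["fixed_alt"] == 1

    def test_constructed_fixture_arithmetic(self):
        records = []
        for i in range(901):  # clean biallelic, polymorphic
            records.append(make_record(pos=1000 + i, gt=((0, 1), (0, 0))))
        for i in range(37):
            records.append(make_record(pos=10**6 + i, alts=("AT",)))
        for i in range(12):
            records.append(
                make_record(pos=2 * 10**6 + i, alts=("C", "G"), ad=[[3, 3, 3]])
            )
        for i in range(50):
            records.append(make_record(pos=3 * 10**6 + i, gt=((1, 1), (1, 1))))
        kept, stage = remove_nonbiallelic(records)
        assert len(records) == 1000
        assert len(kept) == 901
        assert stage.detail == {"indels": 37, "multiallelic": 12, "fixed_alt": 50}


class TestMaskLowDepth:
    def test_dp4_kept_dp3_masked(self):
        r = make_record(gt=((0, 1), (0, 1)), ad=[[2, 2], [2, 1]], dp=[4, 3])
        out, stage = mask_low_depth([r], FilterConfig())
        assert out[0].called_mask().tolist() == [True, False]
        assert stage.n_removed == 1

    def test_missing_dp_masked(self):
        r = make_record(gt=((0, 1),), dp=[-1])
        out, _ = mask_low_depth([r], FilterConfig())
        assert not out[0].called_mask()[0]

    def test_bruteforce_count(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(200):
            dp = rng.integers(0, 12, size=10)
            records.append(
                make_record(
                    pos=100 + i,
                    gt=[(0, 1)] * 10,
                    ad=np.stack([dp // 2, dp - dp // 2], axis=1),
                    dp=dp,
                )
            )
        out, stage = mask_low_depth(records, FilterConfig())
        expected = sum(int((r.dp < 4).sum()) for r in records)
        assert stage.n_removed == expected


class TestRecodeImbalancedHets:
    def test_strong_imbalance_recoded(self):
        r = make_record(gt=((0, 1),), ad=[[9, 1]], dp=[10])
        out, stage = recode_imbalanced_hets([r], FilterConfig())
        assert out[0].gt[0].tolist() == [0, 0]
        assert stage.detail["recoded"] == 1

    def test_balanced_het_unchanged(self):
        r = make_record(gt=((0, 1),), ad=[[6, 4]], dp=[10])
        out, stage = recode_imbalanced_hets([r], FilterConfig())
        assert out[0].gt[0].tolist() == [0, 1]
        assert stage.n_removed == 0

    def test_majority_alt_recode(self):
        r = make_record(gt=((0, 1),), ad=[[1, 9]], dp=[10])
        out, _ = recode_imbalanced_hets([r], FilterConfig())
        assert out[0].gt[0].tolist() == [1, 1]

    def test_missing_ad_on_het_set_missing(self):
        r = make_record(gt=((0, 1),), ad=[[-1, -1]], dp=[10])
        out, stage = recode_imbalanced_hets([r], FilterConfig())
        assert not out[0].called_mask()[0]
        assert stage.detail["set_missing"] == 1

    def test_bruteforce_10k_hets(self):
        rng = np.random.default_rng(1)
        records = []
        for i in range(500):
            dp = rng.integers(4, 30, size=20)
            alt = rng.integers(0, dp + 1)
            records.append(
                make_record(
                    pos=100 + i,
                    gt=[(0, 1)] * 20,
                    ad=np.stack([dp - alt, alt], axis=1),
                    dp=dp,
                )
            )
        out, stage = recode_imbalanced_hets(records, FilterConfig())
        expected = 0
        for r in records:
            frac = np.minimum(r.ad[:, 0], r.ad[:, 1]) / r.dp
            expected += int((frac < 0.2).sum())
        assert stage.detail["recoded"] == expected


class TestDropMismatchLoci:
    def test_boundary_3_kept_4_masked(self):
        r = make_record(gt=((0, 1), (0, 1)), ad=[[5, 5], [5, 5]], mm=[3, 4])
        out, stage = drop_mismatch_loci([r], FilterConfig())
        assert out[0].called_mask().tolist() == [True, False]
        assert stage.n_removed == 1

    def test_absent_annotation_skips_with_warning(self):
        r = make_record(gt=((0, 1),))
        with pytest.warns(UserWarning, match="skipped"):
            out, stage = drop_mismatch_loci([r], FilterConfig())
        assert out[0].called_mask()[0]
        assert stage.detail.get("skipped") == 1

    def test_planted_masked_set(self, tmp_path):
        cfg = pp.SimulationConfig(
            subpop_sizes={"P1": 40},
            n_snps={"A": 150, "C": 150},
            target_fst=0.1,
            f_is=0.5,
            call_rate=0.8,
            seed=12,
            injections=InjectionConfig(n_mismatch_entries=25),
            consistent_depths=True,
        )
        m = pp.simulate_genotypes(cfg)
        truth = pp.emit_raw_vcf(m, cfg, tmp_path / "mm.vcf")
        records = pp.read_vcf(tmp_path / "mm.vcf")
        out, stage = drop_mismatch_loci(records, FilterConfig())
        assert stage.n_removed == 25
        by_site = {(r.chrom, r.pos): r for r in out}
        for chrom, pos, sample in truth.mismatch_entries:
            assert not by_site[(chrom, pos)].called_mask()[sample]


class TestSiteAndSampleCallrate:
    def _records_with_callcounts(self, call_counts, n_samples=60):
        records = []
        for i, k in enumerate(call_counts):
            gt = [(0, 1) if j < k else (-1, -1) for j in range(n_samples)]
            # make polymorphic: one hom-ref among called
            if k >= 2:
                gt[0] = (0, 0)
            records.append(
                make_record(
                    pos=100 + i,
                    gt=gt,
                    ad=np.full((n_samples, 2), 5),
                    dp=np.full(n_samples, 10),
                )
            )
        return records

    def test_snp_called_in_30_kept_29_dropped(self):
        records = self._records_with_callcounts([30, 29])
        ids = [f"s{i}" for i in range(60)]
        config = FilterConfig(max_sample_missingness=1.0)
        matrix, report = apply_site_and_sample_callrate(records, ids, config)
        assert matrix.n_snps == 1
        assert report["site_call_rate"].n_removed == 1

    def test_sample_81pct_missing_removed(self):
        # 100 sites; one sample called at 19 (81% missing), another at 20
        n_sites = 100
        records = []
        for i in range(n_sites):
            gt = [(0, 1), (0, 0), (0, 1)]
            if i >= 19:
                gt[0] = (-1, -1)
            if i >= 20:
                gt[1] = (-1, -1)
            records.append(
                make_record(
                    pos=100 + i, gt=gt, ad=np.full((3, 2), 5), dp=np.full(3, 10)
                )
            )
        config = FilterConfig(min_samples_called=1)
        matrix, report = apply_site_and_sample_callrate(
            records, ["bad", "edge", "good"], config
        )
        assert report["sample_missingness"].n_removed == 1
        assert matrix.sample_ids == ["edge", "good"]

    def test_empty_output_raises(self):
        records = self._records_with_callcounts([5, 5])
        with pytest.raises(ValueError, match="no SNPs"):
            apply_site_and_sample_callrate(
                records, [f"s{i}" for i in range(60)], FilterConfig()
            )


@pytest.fixture(scope="module")
def synthetic_vcf(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("cascade")
    cfg = pp.SimulationConfig(
        subpop_sizes={"P1": 50},
        n_snps={"A": 300, "C": 400},
        target_fst=0.1,
        f_is=0.5,
        call_rate=0.75,
        seed=13,
        injections=InjectionConfig(
            n_indels=10,
            n_triallelic=5,
            n_fixed_alt=15,
            n_imbalanced_hets=20,
            n_mismatch_entries=18,
        ),
        consistent_depths=True,
    )
    m = pp.simulate_genotypes(cfg)
    truth = pp.emit_raw_vcf(m, cfg, tmp / "c.vcf")
    return m, truth, pp.read_vcf(tmp / "c.vcf")


class TestCascade:
    def test_report_conservation(self, synthetic_vcf):
        m, truth, records = synthetic_vcf
        matrix, report = run_filter_cascade(
            records, m.sample_ids, FilterConfig(), m.samples
        )
        for s in report.stages:
            assert s.n_input - s.n_removed == s.n_output
            assert s.n_removed >= 0

    def test_planted_removals(self, synthetic_vcf):
        m, truth, records = synthetic_vcf
        matrix, report = run_filter_cascade(
            records, m.sample_ids, FilterConfig(), m.samples
        )
        stage1 = report["nonbiallelic_fixed_alt"]
        assert stage1.detail["indels"] == 10
        assert stage1.detail["multiallelic"] == 5
        assert stage1.detail["fixed_alt"] >= 15
        assert report["het_imbalance_recode"].detail["recoded"] == 20
        assert report["mismatch_locus_mask"].n_removed == 18

    def test_record_level_idempotence(self, synthetic_vcf):
        m, truth, records = synthetic_vcf
        once = record_level_stages(records)
        twice = record_level_stages(once)
        assert len(once) == len(twice)
        assert all(a.equals(b) for a, b in zip(once, twice))

    def test_matrix_level_idempotence(self, synthetic_vcf):
        m, truth, records = synthetic_vcf
        matrix, _ = run_filter_cascade(records, m.sample_ids, FilterConfig(), m.samples)
        again = refilter_matrix(matrix, FilterConfig())
        assert again.equals(matrix)

    def test_stage_order_sensitivity(self):
        """Pinned order regression: depth-mask runs before het-recode, so a
        low-depth imbalanced het is reported as depth-masked (never as a
        recode); swapping the stages changes the reported counts."""
        r = make_record(gt=((0, 1), (0, 0)), ad=[[3, 0], [5, 5]], dp=[3, 10])
        config = FilterConfig()
        pinned, mask_stage = mask_low_depth([r.copy()], config)
        pinned, recode_stage = recode_imbalanced_hets(pinned, config)
        assert mask_stage.n_removed == 1
        assert recode_stage.detail["recoded"] == 0
        assert not pinned[0].called_mask()[0]

        swapped, recode_stage_s = recode_imbalanced_hets([r.copy()], config)
        swapped, mask_stage_s = mask_low_depth(swapped, config)
        assert recode_stage_s.detail["recoded"] == 1  # order-dependent count
        assert mask_stage_s.n_removed == 1
        # cascade enforces the pinned order
        _, report = run_filter_cascade(
            [r.copy()], ["s0", "s1"], FilterConfig(min_samples_called=1)
        )
        assert report["het_imbalance_recode"].detail["recoded"] == 0
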