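"""Generator contracts: determinism, construction invariants, and
Monte-Carlo agreement with the configured distributions."""

import numpy as np
import pandas as pd
import pytest

from mmrsclc.io import write_transcripts
from mmrsclc.signatures import CHANNELS, extract_contexts, toy_signature_matrix
from mmrsclc.synthdata import (
    SimConfig,
    inject_artifacts,
    simulate_cohort,
    simulate_coverage,
    simulate_mutations,
    simulate_transcriptome,
)
from mmrsclc.survival import derive_endpoints, km_median

from conftest import small_config


class TestTranscriptome:
    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        cfg = small_config(seed=1, n_transcripts=5)
        for d in ("a", "b"):
            tr, genome = simulate_transcriptome(cfg)
            write_transcripts(tr, genome, tmp_path / d)
        assert (tmp_path / "a" / "cds.fasta").read_bytes() == \
               (tmp_path / "b" / "cds.fasta").read_bytes()
        assert (tmp_path / "a" / "genome.fasta").read_bytes() == \
               (tmp_path / "b" / "genome.fasta").read_bytes()

    def test_different_seeds_give_different_sequences(self):
        t1, _ = simulate_transcriptome(small_config(seed=1, n_transcripts=5))
        t2, _ = simulate_transcriptome(small_config(seed=2, n_transcripts=5))
        assert [t.cds_sequence for t in t1] != [t.cds_sequence for t in t2]

    def test_cds_construction_invariants(self, transcriptome):
        _, transcripts, genome = transcriptome
        assert sum(t.is_floxed_gene for t in transcripts) == 1
        for t in transcripts:
            assert len(t.cds_sequence) % 3 == 0
            assert t.cds_sequence.startswith("ATG")
            protein = t.protein()
            assert "*" not in protein  # single terminal stop only
            # exons sorted, non-overlapping, and spelling out the CDS
            for (s1, e1), (s2, e2) in zip(t.exon_intervals, t.exon_intervals[1:]):
                assert e1 <= s2
            spliced = "".join(genome[t.chrom][s:e] for s, e in t.exon_intervals)
            assert spliced == t.cds_sequence

    def test_too_short_cds_range_rejected(self):
        with pytest.raises(ValueError, match="cds_length_range"):
            simulate_transcriptome(small_config(cds_length_range=(3, 30)))


class TestCoverage:
    def test_cn0_floxed_exon_has_zero_depth_everywhere(self):
        cfg = small_config(seed=5)
        tr, _ = simulate_transcriptome(cfg)
        _, per_base, _ = simulate_coverage(tr, cfg)
        flfl = per_base[(per_base["group"] == "RPM_flfl") & per_base["is_floxed"]]
        assert len(flfl) > 0 and (flfl["depth"] == 0).all()

    def test_mean_depth_matches_configuration(self):
        # CN=2 group over >= 10^4 bases: mean within ~3 s.e. of mean_depth,
        # after removing the per-exon bias (lognormal sigma=0.2 by default)
        cfg = small_config(seed=6, exon_bias_sigma=0.0, mean_depth=100.0,
                           n_transcripts=25)
        tr, _ = simulate_transcriptome(cfg)
        _, per_base, _ = simulate_coverage(tr, cfg)
        rp = per_base[(per_base["sample_id"] == "RP_1") & ~per_base["is_floxed"]]
        assert len(rp) >= 10_000
        assert rp["depth"].mean() == pytest.approx(100.0, abs=3.0)

    def test_cn1_vs_cn2_floxed_count_ratio_near_half(self):
        cfg = small_config(seed=8)
        tr, _ = simulate_transcriptome(cfg)
        counts, _, _ = simulate_coverage(tr, cfg)
        floxed = counts[counts["is_floxed"]]
        cn1 = floxed[floxed["group"] == "RPM_flwt"]["count"].mean()
        cn2 = floxed[floxed["group"] == "RP"]["count"].mean()
        assert cn1 / cn2 == pytest.approx(0.5, abs=0.05)

    def test_unknown_group_label_rejected(self):
        cfg = small_config(n_samples_per_group={"RP": 1, "mystery": 1},
                           mutation_rate_per_group={"RP": 10.0, "mystery": 10.0})
        tr, _ = simulate_transcriptome(cfg)
        with pytest.raises(KeyError, match="mystery"):
            simulate_coverage(tr, cfg)

    def test_exon_counts_are_per_base_sums(self, study):
        sums = study.per_base.groupby(["sample_id", "exon_id"])["depth"].sum()
        for r in study.exon_counts.sample(20, random_state=0).itertuples(index=False):
            assert sums[(r.sample_id, r.exon_id)] == r.count


class TestMutations:
    def test_pure_signature_spectrum_recovered(self):
        # all mutations from one signature: empirical 96-channel frequencies
        # land within TV distance 0.05 of that signature's column
        cfg = small_config(
            seed=9, n_transcripts=40, indel_fraction=0.0,
            n_samples_per_group={"RP": 1},
            mutation_rate_per_group={"RP": 1000.0},
            signature_mix_per_group={"RP": {"SBS21": 1.0}},
            floxed_exon_copy_number_per_group={"RP": 2},
        )
        tr, genome = simulate_transcriptome(cfg)
        variants, _ = simulate_mutations(tr, genome, cfg)
        catalog = extract_contexts(variants, genome)
        freq = catalog.iloc[0].to_numpy(float)
        freq = freq / freq.sum()
        tv = 0.5 * np.abs(freq - toy_signature_matrix()["SBS21"]).sum()
        assert tv <= 0.05

    def test_group_rate_contrast_matches_18_fold(self, study):
        counts = study.variants[
            ~study.variants["mutation_id"].str.startswith("artifact")
        ].groupby(["group", "sample_id"]).size().groupby("group").mean()
        assert counts["RPM_flfl"] / counts["RP"] == pytest.approx(18.0, rel=0.15)

    def test_zero_rate_gives_empty_table(self):
        cfg = small_config(
            n_samples_per_group={"RP": 2},
            mutation_rate_per_group={"RP": 0.0},
            floxed_exon_copy_number_per_group={"RP": 2},
        )
        tr, genome = simulate_transcriptome(cfg)
        variants, _ = simulate_mutations(tr, genome, cfg)
        assert len(variants) == 0

    def test_unknown_signature_name_rejected(self):
        cfg = small_config(
            signature_mix_per_group={"RP": {"SBS99": 1.0},
                                     "RPM_flfl": {"SBSflat": 1.0},
                                     "RPM_flwt": {"SBSflat": 1.0}})
        tr, genome = simulate_transcriptome(cfg)
        with pytest.raises(KeyError, match="SBS99"):
            simulate_mutations(tr, genome, cfg)

    def test_variant_annotations_are_self_consistent(self, study):
        real = study.variants[
            ~study.variants["mutation_id"].str.startswith("artifact")
        ]
        snv = real["var_class"] == "SNV"
        assert (real.loc[snv, "ref"].str.len() == 1).all()
        assert (real.loc[snv, "alt"].str.len() == 1).all()
        indels = real[~snv]
        shift = (indels["ref"].str.len() - indels["alt"].str.len()).abs() % 3 != 0
        assert ((indels["consequence"] == "frameshift") == shift).all()
        # no two samples share an exact true somatic allele (cohort-wide placement)
        dup = real.groupby(["chrom", "pos", "ref", "alt"])["sample_id"].nunique()
        assert (dup == 1).all()


class TestArtifacts:
    def test_zero_rates_is_identity(self, study):
        cfg = small_config(artifact_rates={"shared": 0, "blacklist": 0,
                                           "low_depth": 0})
        out, bl, labels = inject_artifacts(study.variants, cfg)
        pd.testing.assert_frame_equal(out, study.variants)
        assert bl == set() and len(labels) == 0

    def test_injected_artifacts_are_exactly_what_the_filter_removes(self, study):
        from mmrsclc.variants import filter_variants

        res = filter_variants(study.variants, study.blacklist, 30)
        removed_keys = set(zip(res.removed["sample_id"], res.removed["chrom"],
                               res.removed["pos"]))
        label_keys = set(zip(study.artifact_labels["sample_id"],
                             study.artifact_labels["chrom"],
                             study.artifact_labels["pos"]))
        assert removed_keys == label_keys

    def test_shared_artifacts_occupy_at_least_two_samples(self, study):
        shared = study.artifact_labels[
            study.artifact_labels["artifact_class"] == "shared"]
        per_locus = shared.groupby(["chrom", "pos"])["sample_id"].nunique()
        assert (per_locus >= 2).all()

    def test_low_depth_artifacts_all_below_threshold(self, study):
        low = study.artifact_labels[
            study.artifact_labels["artifact_class"] == "low_depth"]
        merged = low.merge(study.variants, on=["sample_id", "chrom", "pos",
                                               "ref", "alt"])
        assert len(merged) == len(low) and (merged["depth"] < 30).all()


class TestCohort:
    def test_km_median_matches_exponential_target(self):
        cfg = small_config(seed=4, censor_fraction=0.0,
                           n_animals_per_group={"RP": 10_000},
                           survival_params={"onset": {"RP": 258.5},
                                            "post_onset": {"RP": 55.0},
                                            "treatment": {}})
        cohort = simulate_cohort(cfg)
        rec = derive_endpoints(cohort, "post_onset")
        assert 53 <= km_median(rec).median <= 57

    def test_all_censored_cohort_flags_undefined_median(self):
        cfg = small_config(censor_fraction=1.0,
                           n_animals_per_group={"RP": 50},
                           survival_params={"onset": {"RP": 100.0},
                                            "post_onset": {"RP": 55.0},
                                            "treatment": {}})
        cohort = simulate_cohort(cfg)
        assert (cohort["end_cause"] == "unrelated").all()
        rec = derive_endpoints(cohort, "post_onset", unrelated="censor")
        res = km_median(rec)
        assert not res.median_defined and np.isnan(res.median)

    def test_negative_censor_fraction_rejected(self):
        with pytest.raises(ValueError, match="censor_fraction"):
            simulate_cohort(small_config(censor_fraction=-0.1))

    def test_null_logrank_p_is_uniform(self):
        # equal-median arms: the log-rank p over repeated cohorts should be
        # ~U(0,1); KS test must not reject at the 1% level (200 replicates)
        from scipy import stats
        from mmrsclc.survival import logrank_test

        pvals = []
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = 60
            t1 = rng.exponential(55 / np.log(2), n)
            t2 = rng.exponential(55 / np.log(2), n)
            a = pd.DataFrame({"time": t1, "event": 1})
            b = pd.DataFrame({"time": t2, "event": 1})
            pvals.append(logrank_test(a, b)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_whole_study_is_deterministic_given_seed():
    from mmrsclc.synthdata import simulate_all

    a = simulate_all(small_config(seed=42))
    b = simulate_all(small_config(seed=42))
    pd.testing.assert_frame_equal(a.variants, b.variants)
    pd.testing.assert_frame_equal(a.exon_counts, b.exon_counts)
    pd.testing.assert_frame_equal(a.cohort, b.cohort)
    assert a.blacklist == b.blacklist
    assert a.genome == b.genome
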