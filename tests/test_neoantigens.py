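"""Mutant CDS construction, trimming, 9-mer enumeration and binder calls.

Hand-oracle values were computed on the fixture CDS by manual translation of
the wild-type, missense, in-frame and shifted reading frames.
"""

import numpy as np
import pandas as pd
import pytest

from mmrsclc.neoantigens import (
    MutantSequence,
    SurrogatePredictor,
    binder_class,
    build_mutant_cds,
    classify_and_count,
    enumerate_candidates,
    trim_mutant,
)
from mmrsclc.synthdata import TranscriptModel

# 20 codons; translation MKPGFAILEDHSWYRNGLP (stop dropped)
FIXTURE_CDS = (
    "ATGAAACCCGGGTTTGCTATTCTGGAAGATCACAGTTGGTACCGTAACGGACTTCCATAA"
)
FIXTURE_UTR3 = "GGCACCTGAGGTTTAAACCCGGG"
WT_PROTEIN = "MKPGFAILEDHSWYRNGLP"


def fixture_transcript() -> TranscriptModel:
    return TranscriptModel(
        transcript_id="T1", gene_id="G1", chrom="chr1", strand="+",
        exon_intervals=[(0, 60)], cds_sequence=FIXTURE_CDS,
        utr3_sequence=FIXTURE_UTR3,
    )


class Var:
    def __init__(self, mutation_id, ref, alt, cds_pos, consequence):
        self.mutation_id, self.ref, self.alt = mutation_id, ref, alt
        self.cds_pos, self.consequence = cds_pos, consequence


class TestBuildMutantCds:
    def test_missense_single_codon_edit(self):
        # GAT -> GAA at codon 10: D -> E only
        ms = build_mutant_cds(fixture_transcript(), Var("m1", "T", "A", 30, "missense"))
        from Bio.Seq import Seq

        prot = str(Seq(ms.mutant_cds).translate())[:-1]
        assert prot == "MKPGFAILEEHSWYRNGLP"
        diffs = [i for i, (a, b) in enumerate(zip(WT_PROTEIN, prot)) if a != b]
        assert diffs == [9]

    def test_frameshift_deletion_reads_through_to_novel_stop(self):
        # 1-bp deletion at cds_pos 30: residues 1-10 intact, then novel frame
        ms = build_mutant_cds(fixture_transcript(), Var("m2", "TC", "T", 30, "frameshift"))
        from Bio.Seq import Seq

        aa = str(Seq(ms.mutant_cds).translate())
        assert aa == "MKPGFAILEDTVGTVTDFHKAPEV*"
        assert aa[:10] == WT_PROTEIN[:10]

    def test_inframe_deletion_shortens_protein_by_one(self):
        ms = build_mutant_cds(fixture_transcript(), Var("m3", "GTTT", "G", 12, "inframe"))
        from Bio.Seq import Seq

        prot = str(Seq(ms.mutant_cds).translate())[:-1]
        assert prot == "MKPGAILEDHSWYRNGLP"
        assert len(prot) == len(WT_PROTEIN) - 1

    def test_ref_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="does not match CDS"):
            build_mutant_cds(fixture_transcript(), Var("m4", "G", "A", 30, "missense"))

    def test_synonymous_is_rejected(self):
        with pytest.raises(ValueError, match="not usable"):
            build_mutant_cds(fixture_transcript(), Var("m5", "T", "A", 30, "synonymous"))


class TestTrimMutant:
    def test_missense_mid_cds_gives_33nt_window_mutant_centered(self):
        ms = build_mutant_cds(fixture_transcript(), Var("m1", "T", "A", 30, "missense"))
        trim_mutant(ms, flank_nt=13)
        assert len(ms.trimmed_nt) == 33
        assert ms.trimmed_peptide == "FAILEEHSWYR"
        assert len(ms.trimmed_peptide) == 11
        assert ms.mutated_residue_span == (5, 6)  # centered

    def test_missense_at_first_codon_clips_5prime_flank(self):
        # ATG -> TTG is a start-codon change; use codon 2 AAA -> AGA instead
        ms = build_mutant_cds(fixture_transcript(), Var("m6", "A", "G", 5, "missense"))
        trim_mutant(ms, flank_nt=13)
        lo, hi = ms.mutated_residue_span
        assert lo == 1  # codon 2, flank clipped at the CDS start
        assert ms.trimmed_peptide[lo:hi] == "R"

    def test_frameshift_keeps_entire_novel_frame_translation(self):
        ms = build_mutant_cds(fixture_transcript(), Var("m2", "TC", "T", 30, "frameshift"))
        trim_mutant(ms, wildtype_protein=WT_PROTEIN, flank_nt=13)
        # suffix from the first divergent residue equals the full novel-frame
        # translation (no 3' loss of novel sequence)
        assert ms.trimmed_peptide == "FAILEDTVGTVTDFHKAPEV"
        lo, hi = ms.mutated_residue_span
        assert ms.trimmed_peptide[lo:hi] == "TVGTVTDFHKAPEV"
        assert hi == len(ms.trimmed_peptide)

    def test_trimmed_windows_have_codon_length(self):
        for var in (Var("a", "T", "A", 30, "missense"),
                    Var("b", "GTTT", "G", 12, "inframe"),
                    Var("c", "TC", "T", 30, "frameshift")):
            ms = trim_mutant(build_mutant_cds(fixture_transcript(), var))
            assert len(ms.trimmed_nt) % 3 == 0
            assert "*" not in ms.trimmed_peptide


def brute_force_windows(peptide, span, wt, k):
    """Independent window-overlap count: every k-window that touches the span
    and is not a wild-type k-mer."""
    wt_kmers = {wt[i:i + k] for i in range(len(wt) - k + 1)}
    out = set()
    for i in range(max(0, len(peptide) - k + 1)):
        window = set(range(i, i + k))
        if window & set(range(*span)) and peptide[i:i + k] not in wt_kmers:
            out.add(peptide[i:i + k])
    return out


class TestEnumerateCandidates:
    def test_three_windows_for_centered_missense_9mer(self):
        ms = trim_mutant(build_mutant_cds(
            fixture_transcript(), Var("m1", "T", "A", 30, "missense")))
        cands = enumerate_candidates(ms, WT_PROTEIN, k=9)
        assert len(cands) == 3
        assert all("E" == c[5 - i] for i, c in enumerate(cands))

    def test_k_larger_than_peptide_gives_empty_list(self):
        ms = MutantSequence("m", "T", "missense", trimmed_peptide="SHORT",
                            mutated_residue_span=(1, 2))
        ms.trimmed_nt = "X"
        assert enumerate_candidates(ms, WT_PROTEIN, k=9) == []

    def test_no_op_edit_yields_zero_candidates(self):
        ms = MutantSequence("m", "T", "missense",
                            trimmed_peptide=WT_PROTEIN[2:13],
                            mutated_residue_span=(5, 6))
        assert enumerate_candidates(ms, WT_PROTEIN, k=9) == []

    @pytest.mark.parametrize("k", [8, 9, 14])
    def test_counts_match_brute_force_for_all_fixture_mutations(self, k):
        t = fixture_transcript()
        for var in (Var("a", "T", "A", 30, "missense"),
                    Var("b", "GTTT", "G", 12, "inframe"),
                    Var("c", "TC", "T", 30, "frameshift"),
                    Var("d", "A", "G", 5, "missense")):
            ms = trim_mutant(build_mutant_cds(t, var), wildtype_protein=WT_PROTEIN)
            cands = enumerate_candidates(ms, WT_PROTEIN, k=k)
            oracle = brute_force_windows(
                ms.trimmed_peptide, ms.mutated_residue_span, WT_PROTEIN, k)
            assert set(cands) == oracle
            assert len(cands) == len(oracle)  # deduplicated

    def test_every_candidate_contains_mutation_and_avoids_wt_kmers(self, study):
        # exhaustive per-run property on simulated coding variants
        tmap = {t.transcript_id: t for t in study.transcripts}
        coding = study.variants[
            study.variants["consequence"].isin(["missense", "inframe", "frameshift"])
        ].head(200)
        for v in coding.itertuples(index=False):
            t = tmap[v.transcript_id]
            wt = t.protein()
            ms = trim_mutant(build_mutant_cds(t, v), wildtype_protein=wt)
            wt_kmers = {wt[i:i + 9] for i in range(len(wt) - 8)}
            for c in enumerate_candidates(ms, wt, k=9):
                assert c not in wt_kmers
            n = len(ms.trimmed_peptide)
            assert len(enumerate_candidates(ms, wt, 9)) <= max(0, n - 8)


class TestPredictorAndCounts:
    def test_rank_boundaries(self):
        assert binder_class(0.49) == "strong"
        assert binder_class(0.5) == "weak"  # boundary assigned weak
        assert binder_class(1.99) == "weak"
        assert binder_class(2.0) == "non"

    def test_surrogate_is_deterministic_and_anchor_driven(self):
        p = SurrogatePredictor()
        assert p.predict(["AFAAAAAAL"]) == p.predict(["AFAAAAAAL"])
        strong = p.predict(["AFAAAAAAL"])[0]  # both anchors
        none_ = p.predict(["AAAAAAAAA"])[0]  # no anchors
        assert strong < 0.5 and none_ >= 2

    def test_planted_motif_counts_exactly(self):
        p = SurrogatePredictor()
        cands = {
            "m1": ["AFAAAAAAL", "AYAAAAAAV"],  # 2 strong
            "m2": ["AFAAAAAAM", "AAAAAAAAA"],  # 1 strong, 1 non
            "m3": ["GFCCCCCCI"],               # strong
        }
        sample_of = {"m1": "S", "m2": "S", "m3": "S"}
        scored, counts, _ = classify_and_count(cands, p, sample_of)
        assert counts.set_index("sample_id").loc["S", "strong_binders"] == 4
        assert counts.set_index("sample_id").loc["S", "neoantigenic_mutations"] == 3

    def test_hopeless_predictor_yields_no_binders(self):
        class Hopeless:
            allele = "H2-Kb"

            def predict(self, peptides):
                return [50.0] * len(peptides)

        cands = {"m1": ["AFAAAAAAL"], "m2": ["CCCCCCCCC"]}
        _, counts, _ = classify_and_count(
            cands, Hopeless(), {"m1": "S", "m2": "S"})
        row = counts.set_index("sample_id").loc["S"]
        assert row["strong_binders"] == 0 and row["weak_binders"] == 0
        assert row["neoantigenic_mutations"] == 0
        assert row["non_neoantigenic_mutations"] == 2

    def test_predictor_failure_excludes_peptide_and_reports(self):
        class Flaky:
            allele = "H2-Kb"

            def predict(self, peptides):
                if any("X" in p for p in peptides):
                    raise RuntimeError("bad residue")
                return [50.0] * len(peptides)

        cands = {"m1": ["AXAAAAAAA", "AAAAAAAAA"]}
        scored, counts, stats = classify_and_count(cands, Flaky(), {"m1": "S"})
        assert stats["n_predictor_failures"] == 1
        assert list(scored["peptide"]) == ["AAAAAAAAA"]

    def test_swapping_predictor_changes_ranks_not_candidates(self):
        ms = trim_mutant(build_mutant_cds(
            fixture_transcript(), Var("m1", "T", "A", 30, "missense")))
        cands = enumerate_candidates(ms, WT_PROTEIN, k=9)

        class Flat:
            allele = "H2-Kb"

            def predict(self, peptides):
                return [1.0] * len(peptides)

        s1, _, _ = classify_and_count({"m1": cands}, SurrogatePredictor(), {"m1": "S"})
        s2, _, _ = classify_and_count({"m1": cands}, Flat(), {"m1": "S"})
        assert list(s1["peptide"]) == list(s2["peptide"]) == cands
        assert list(s1["rank"]) != list(s2["rank"])


def test_more_mutations_never_fewer_expected_neoantigens():
    # pipeline monotonicity in expectation over replicates
    from conftest import small_config
    from mmrsclc.synthdata import simulate_mutations, simulate_transcriptome

    means = []
    for rate in (40.0, 400.0):
        neo_counts = []
        for rep in range(5):
            cfg = small_config(
                seed=100 + rep, n_transcripts=15, indel_fraction=0.1,
                n_samples_per_group={"RP": 1},
                mutation_rate_per_group={"RP": rate},
                floxed_exon_copy_number_per_group={"RP": 2},
            )
            tr, genome = simulate_transcriptome(cfg)
            variants, _ = simulate_mutations(tr, genome, cfg)
            tmap = {t.transcript_id: t for t in tr}
            coding = variants[variants["consequence"].isin(
                ["missense", "inframe", "frameshift"])]
            cands, sample_of = {}, {}
            for v in coding.itertuples(index=False):
                t = tmap[v.transcript_id]
                wt = t.protein()
                ms = trim_mutant(build_mutant_cds(t, v), wildtype_protein=wt)
                cands[v.mutation_id] = enumerate_candidates(ms, wt, 9)
                sample_of[v.mutation_id] = v.sample_id
            _, counts, _ = classify_and_count(cands, SurrogatePredictor(), sample_of)
            neo_counts.append(counts["neoantigenic_mutations"].sum())
        means.append(np.mean(neo_counts))
    assert means[1] >= means[0]
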