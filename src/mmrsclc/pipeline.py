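"""End-to-end orchestration: simulate -> filter/TMB -> copy number ->
signatures -> neoantigens -> survival, with a machine-readable report.

Every statistic in the report is recomputable from the intermediate tables
the run writes (or returns); reruns with the same config and seed are
deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .neoantigens import (
    SurrogatePredictor,
    build_mutant_cds,
    classify_and_count,
    enumerate_candidates,
    trim_mutant,
)
from .recombination import estimate_copy_number
from .signatures import (
    extract_contexts,
    fit_activities,
    kruskal_by_group,
    mmr_fraction_and_compare,
    toy_signature_matrix,
)
from .survival import derive_endpoints, km_median, logrank_test
from .synthdata import SimConfig, simulate_all
from .variants import (
    callable_bases_from_coverage,
    compute_tmb,
    filter_variants,
    summarize_variant_classes,
)

ALL_STAGES = ("variants", "recombination", "signatures", "neoantigens", "survival")


def config_from_dict(d: dict) -> SimConfig:
    known = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = SimConfig(**d)
    if "cds_length_range" in d:
        cfg.cds_length_range = tuple(d["cds_length_range"])
    return cfg


def _config_hash(config: SimConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: SimConfig | None = None,
    outdir: str | Path | None = None,
    stages: Sequence[str] = ALL_STAGES,
    k: int = 9,
    min_depth: int = 30,
) -> dict:
    """Run the full analysis on a freshly simulated cohort.

    Returns the run report: per-sample TMB, copy-number call, MMR fraction
    and binder counts; group-level Kruskal-Wallis statistics; survival
    medians and log-rank contrasts; and provenance (seed, config hash).
    ``stages`` restricts which analysis sections run (simulation always
    runs). When ``outdir`` is given, intermediates and the report are
    written there.
    """
    config = config or SimConfig()
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    study = simulate_all(config)
    groups = dict(config.samples())
    samples = pd.DataFrame(
        [{"sample_id": s, "group": g} for s, g in config.samples()]
    ).set_index("sample_id")

    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "stages": list(stages),
        },
        "n_samples": len(samples),
    }
    intermediates: dict = {"study": study}

    filter_result = None
    if "variants" in stages or "signatures" in stages or "neoantigens" in stages:
        callable_bases = callable_bases_from_coverage(study.per_base, min_depth)
        filter_result = filter_variants(
            study.variants, study.blacklist, min_depth, callable_bases
        )
        intermediates["filter_result"] = filter_result

    if "variants" in stages:
        tmb = compute_tmb(filter_result, groups=groups)
        classes = summarize_variant_classes(filter_result)
        samples = samples.join(tmb.set_index("sample_id")[["tmb", "kept_mutations"]])
        h, p = kruskal_by_group(tmb, "tmb", "group")
        report["tmb"] = {
            "kruskal_H": h, "kruskal_p": p,
            "group_means": tmb.groupby("group")["tmb"].mean().to_dict(),
        }
        intermediates["tmb"] = tmb
        intermediates["variant_classes"] = classes

    if "recombination" in stages:
        controls = [s for s, g in config.samples() if g == "RP"]
        cn = estimate_copy_number(study.exon_counts, controls)
        samples = samples.join(cn.set_index("sample_id")[["cn_hat", "call"]])
        truth = study.truth["true_copy_number"]
        rounded = cn.set_index("sample_id")["cn_hat"].round().clip(0, 2)
        report["recombination"] = {
            "cn_recovery_rate": float(
                np.mean([rounded[s] == truth[s] for s in truth])
            ),
            "control_median_cn": float(
                cn[cn["sample_id"].isin(controls)]["cn_hat"].median()
            ),
        }
        intermediates["copy_number"] = cn

    if "signatures" in stages:
        snvs = filter_result.kept[filter_result.kept["var_class"] == "SNV"]
        catalog = extract_contexts(snvs, study.genome)
        activities = fit_activities(catalog, toy_signature_matrix())
        frac, h, p = mmr_fraction_and_compare(activities, groups)
        samples = samples.join(frac.set_index("sample_id")[["mmr_fraction"]])
        report["signatures"] = {
            "kruskal_H": h, "kruskal_p": p,
            "group_median_mmr_fraction":
                frac.groupby("group")["mmr_fraction"].median().to_dict(),
        }
        intermediates["catalog"] = catalog
        intermediates["activities"] = activities

    if "neoantigens" in stages:
        tmap = {t.transcript_id: t for t in study.transcripts}
        kept = filter_result.kept
        coding = kept[kept["consequence"].isin(["missense", "inframe", "frameshift"])]
        cands, mut_sample = {}, {}
        for v in coding.itertuples(index=False):
            t = tmap[v.transcript_id]
            wt = t.protein()
            ms = trim_mutant(build_mutant_cds(t, v), wildtype_protein=wt)
            cands[v.mutation_id] = enumerate_candidates(ms, wt, k=k)
            mut_sample[v.mutation_id] = v.sample_id
        scored, counts, stats = classify_and_count(
            cands, SurrogatePredictor(), mut_sample, groups
        )
        # samples without any coding mutation still get zero counts
        counts = counts.set_index("sample_id").reindex(samples.index)
        for c in ("strong_binders", "weak_binders", "neoantigenic_mutations",
                  "non_neoantigenic_mutations"):
            counts[c] = counts[c].fillna(0).astype(int)
        samples = samples.join(counts[["strong_binders", "weak_binders",
                                       "neoantigenic_mutations",
                                       "non_neoantigenic_mutations"]])
        report["neoantigens"] = stats
        intermediates["scored_peptides"] = scored

    if "survival" in stages:
        natural = study.cohort
        onset = derive_endpoints(natural, "onset")
        post = derive_endpoints(natural, "post_onset")
        surv: dict = {"onset_median_days": {}, "post_onset_median_days": {}}
        for g, sub in onset.groupby("group"):
            surv["onset_median_days"][g] = km_median(sub).median
        for g, sub in post.groupby("group"):
            surv["post_onset_median_days"][g] = km_median(sub).median
        treat = derive_endpoints(study.treatment_cohort, "post_enrollment")
        surv["treatment"] = {}
        for g, gsub in treat.groupby("group"):
            surv["treatment"][g] = {}
            veh = gsub[gsub["arm"] == "vehicle"]
            for arm, asub in gsub.groupby("arm"):
                entry = {"median_days": km_median(asub).median, "n": len(asub)}
                if arm != "vehicle" and len(veh):
                    chi2, p = logrank_test(asub, veh)
                    entry["logrank_vs_vehicle"] = {"chi2": chi2, "p": p}
                surv["treatment"][g][arm] = entry
        report["survival"] = surv
        intermediates["endpoints"] = {"onset": onset, "post_onset": post,
                                      "treatment": treat}

    report["samples"] = samples.reset_index().to_dict(orient="records")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_vcfs(study.variants, outdir / "vcf")
        mio.write_transcripts(study.transcripts, study.genome, outdir / "reference")
        mio.write_coverage(study.exon_counts, study.per_base, outdir / "coverage")
        mio.write_blacklist(study.blacklist, outdir / "blacklist.tsv")
        study.cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
        study.treatment_cohort.to_csv(outdir / "treatment_cohort.tsv", sep="\t",
                                      index=False)
        mio.write_json(study.truth, outdir / "ground_truth.json")
        samples.reset_index().to_csv(outdir / "per_sample.tsv", sep="\t", index=False)
        mio.write_json(report, outdir / "report.json")
    return report
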