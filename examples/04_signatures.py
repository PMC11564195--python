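"""96-channel catalogs, NNLS signature refitting and the MMR fraction.

Builds trinucleotide-context catalogs from filtered SNVs, refits the
bundled (SBS15, SBS21, flat) reference by non-negative least squares, and
compares the MMR-deficiency fraction (SBS15+SBS21 share of total activity)
across genotypes with a Kruskal-Wallis test.
"""

from mmrsclc import (
    SimConfig, simulate_all, filter_variants, extract_contexts,
    fit_activities, mmr_fraction_and_compare, toy_signature_matrix,
)

study = simulate_all(SimConfig(seed=1))
kept = filter_variants(study.variants, study.blacklist, 30).kept
snvs = kept[kept["var_class"] == "SNV"]

catalog = extract_contexts(snvs, study.genome)
activities = fit_activities(catalog, toy_signature_matrix())
fractions, H, p = mmr_fraction_and_compare(activities, dict(study.config.samples()))

print("per-sample MMR-deficiency fraction (SBS15+SBS21 of total activity):")
print(fractions.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nKruskal-Wallis across genotypes: H = {H:.2f}, p = {p:.2g}")
print("fl/fl tumors are generated MMR-dominant (true fraction 0.8), RP and "
      "fl/wt mostly background (0.2): the refit recovers that contrast.")
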