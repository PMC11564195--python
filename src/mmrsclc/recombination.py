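"""Floxed-exon copy-number estimation from exome read counts.

Cre-mediated recombination deletes the floxed exon, which shows up as a drop
in sequencing coverage over that exon. The estimator is a ratio of ratios:
each sample's floxed-exon count is first normalized within the gene (to the
summed counts of the gene's other exons), and that ratio is then normalized
to the median ratio among unrecombined control samples. Scaled by 2, the
result is an estimated copy number on a 0-2 scale, where 2 means no
recombination, 1 mono-allelic and 0 bi-allelic loss. The same logic at
single-base resolution reconstructs the coverage profile the floxed exon
would have shown without recombination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["CopyNumberEstimate", "estimate_copy_number", "predicted_base_profile"]

#: cn_hat call thresholds: midpoints between the attainable levels {0, 1, 2}.
HOMOZYGOUS_MAX = 0.5
HETEROZYGOUS_MAX = 1.5


@dataclass
class CopyNumberEstimate:
    sample_id: str
    cn_hat: float
    within_gene_ratio: float
    control_ratio: float
    call: str  # homozygous_loss | heterozygous_loss | retained


def _call(cn_hat: float) -> str:
    if cn_hat < HOMOZYGOUS_MAX:
        return "homozygous_loss"
    if cn_hat < HETEROZYGOUS_MAX:
        return "heterozygous_loss"
    return "retained"


def estimate_copy_number(
    exon_counts: pd.DataFrame,
    control_samples: Iterable[str],
    gene_id: str | None = None,
) -> pd.DataFrame:
    """Estimate the floxed-exon copy number for every sample.

    Parameters
    ----------
    exon_counts
        Table with columns ``sample_id``, ``gene_id``, ``exon_id``,
        ``is_floxed``, ``count`` — one row per exon per sample. Exactly one
        exon of the target gene must be flagged floxed.
    control_samples
        Sample ids of unrecombined controls (copy number 2 by design).
    gene_id
        Restrict to this gene; default: the gene carrying the floxed exon.

    Returns a frame with per-sample ``within_gene_ratio``
    (floxed count / summed other-exon counts), the shared ``control_ratio``
    (median within-gene ratio over controls), ``cn_hat`` = 2 x ratio /
    control_ratio, and a categorical ``call``.
    """
    controls = set(control_samples)
    if not controls:
        raise ValueError("at least one control sample is required")
    if gene_id is None:
        floxed_genes = exon_counts.loc[exon_counts["is_floxed"], "gene_id"].unique()
        if len(floxed_genes) != 1:
            raise ValueError(f"expected exactly one floxed gene, got {list(floxed_genes)}")
        gene_id = floxed_genes[0]
    gene = exon_counts[exon_counts["gene_id"] == gene_id]

    ratios = {}
    for sample, sub in gene.groupby("sample_id"):
        floxed = sub.loc[sub["is_floxed"], "count"].sum()
        other = sub.loc[~sub["is_floxed"], "count"].sum()
        if sub["is_floxed"].sum() == 0 or (~sub["is_floxed"]).sum() == 0:
            raise ValueError(f"sample {sample}: needs the floxed exon and >= 1 other exon")
        if other == 0:
            raise ValueError(f"sample {sample}: zero counts on non-floxed exons")
        ratios[sample] = floxed / other

    missing = controls - set(ratios)
    if missing:
        raise ValueError(f"control samples without counts: {sorted(missing)}")
    control_ratio = float(np.median([ratios[s] for s in sorted(controls)]))
    if control_ratio == 0:
        raise ValueError("control within-gene ratio is 0; cannot normalize")

    rows = []
    for sample in sorted(ratios):
        cn = 2.0 * ratios[sample] / control_ratio
        rows.append(
            {
                "sample_id": sample,
                "within_gene_ratio": ratios[sample],
                "control_ratio": control_ratio,
                "cn_hat": cn,
                "call": _call(cn),
            }
        )
    return pd.DataFrame(rows)


def predicted_base_profile(
    per_base: pd.DataFrame,
    control_samples: Iterable[str],
    sample_id: str,
    gene_id: str | None = None,
) -> pd.DataFrame:
    """Observed vs predicted-at-CN2 coverage over the floxed exon's bases.

    For each floxed-exon base b, the expected unrecombined shape is
    r_b = median over controls of depth_ctrl(b) / m(ctrl), where m(s) is the
    median per-base depth of the gene's non-floxed exons in sample s. The
    prediction for the target sample is r_b x m(sample). Returns a frame
    with columns chrom, pos, observed, predicted.
    """
    controls = sorted(set(control_samples))
    if not controls:
        raise ValueError("at least one control sample is required")
    if gene_id is None:
        floxed_genes = per_base.loc[per_base["is_floxed"], "gene_id"].unique()
        if len(floxed_genes) != 1:
            raise ValueError(f"expected exactly one floxed gene, got {list(floxed_genes)}")
        gene_id = floxed_genes[0]
    gene = per_base[per_base["gene_id"] == gene_id]

    def other_exon_median(sample: str) -> float:
        d = gene.loc[(gene["sample_id"] == sample) & (~gene["is_floxed"]), "depth"]
        if not len(d):
            raise ValueError(f"sample {sample}: no non-floxed-exon coverage")
        return float(d.median())

    floxed = gene[gene["is_floxed"]]
    wide = floxed.pivot_table(index=["chrom", "pos"], columns="sample_id",
                              values="depth")
    ratios = []
    for c in controls:
        m = other_exon_median(c)
        if m == 0:
            raise ValueError(f"control {c}: median non-floxed-exon coverage is 0")
        ratios.append(wide[c] / m)
    r_b = pd.concat(ratios, axis=1).median(axis=1)

    m_s = other_exon_median(sample_id)
    out = pd.DataFrame(
        {
            "observed": wide[sample_id],
            "predicted": r_b * m_s,
        }
    ).reset_index()
    return out
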