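"""Somatic-variant filtering and tumor mutational burden.

Filtering mirrors a panel-of-normals-style cleanup of somatic calls:
variants seen in more than one sample are treated as recurrent artifacts or
germline leakage and removed (all occurrences), blacklisted loci (a dbSNP
stand-in) are removed, and calls below a depth threshold are removed. TMB is
the number of kept mutations per million callable bases, where a base is
callable when covered at the same depth threshold (30x by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FilterResult",
    "filter_variants",
    "compute_tmb",
    "callable_bases_from_coverage",
    "summarize_variant_classes",
]

VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "depth"]
REMOVAL_REASONS = ("recurrent", "blacklist", "depth")


@dataclass
class FilterResult:
    """Partition of a variant table into kept and removed calls.

    ``removed`` carries a ``reason`` column (recurrent | blacklist | depth;
    first matching reason in that fixed order). ``callable_bases`` and
    ``tmb`` are per-sample and populated when coverage was supplied.
    """

    kept: pd.DataFrame
    removed: pd.DataFrame
    min_depth: int
    callable_bases: dict[str, int] = field(default_factory=dict)
    tmb: dict[str, float] = field(default_factory=dict)


def _check_columns(variants: pd.DataFrame) -> None:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if len(variants) and variants["depth"].isna().any():
        bad = variants.index[variants["depth"].isna()][0]
        raise ValueError(f"variant row {bad} has no depth")


def filter_variants(
    variants: pd.DataFrame,
    blacklist: Iterable[tuple[str, int, str, str]] = (),
    min_depth: int = 30,
    callable_bases: Mapping[str, int] | None = None,
) -> FilterResult:
    """Apply the somatic-call filters and (optionally) compute per-sample TMB.

    A call is removed as ``recurrent`` when its exact (chrom, pos, ref, alt)
    allele appears in two or more distinct samples — every occurrence is
    removed; as ``blacklist`` when that allele tuple is blacklisted; as
    ``depth`` when its depth is below ``min_depth``. Reasons are assigned in
    that order (first match recorded). Empty input yields an empty result.

    When ``callable_bases`` (per-sample bases covered at >= ``min_depth``) is
    given, per-sample TMB = kept mutations / (callable bases / 1e6).
    """
    _check_columns(variants) if len(variants) else None
    variants = variants.reset_index(drop=True)
    bl = set(map(tuple, blacklist))
    if len(variants) == 0:
        empty = variants.copy()
        removed = empty.copy()
        removed["reason"] = pd.Series(dtype=object)
        return FilterResult(kept=empty, removed=removed, min_depth=min_depth)

    key = list(zip(variants["chrom"], variants["pos"], variants["ref"], variants["alt"]))
    n_samples_per_key = (
        pd.DataFrame({"key": key, "sample_id": variants["sample_id"]})
        .groupby("key")["sample_id"]
        .nunique()
    )
    recurrent = np.array([n_samples_per_key[k] >= 2 for k in key])
    blacklisted = np.array([k in bl for k in key])
    shallow = variants["depth"].to_numpy() < min_depth

    reason = np.where(
        recurrent, "recurrent", np.where(blacklisted, "blacklist",
                                         np.where(shallow, "depth", ""))
    )
    removed = variants[reason != ""].copy()
    removed["reason"] = reason[reason != ""]
    kept = variants[reason == ""].copy()

    result = FilterResult(kept=kept, removed=removed, min_depth=min_depth)
    if callable_bases is not None:
        result.callable_bases = dict(callable_bases)
        result.tmb = _tmb_table(result)
    return result


def callable_bases_from_coverage(
    per_base: pd.DataFrame, min_depth: int = 30
) -> dict[str, int]:
    """Per-sample count of bases covered at depth >= ``min_depth``."""
    ok = per_base[per_base["depth"] >= min_depth]
    counts = ok.groupby("sample_id").size()
    return {s: int(counts.get(s, 0)) for s in per_base["sample_id"].unique()}


def _tmb_table(result: FilterResult) -> dict[str, float]:
    kept_counts = result.kept.groupby("sample_id").size() if len(result.kept) else {}
    tmb = {}
    for sample, cb in result.callable_bases.items():
        if cb <= 0:
            raise ValueError(f"sample {sample}: callable_bases = 0, TMB undefined")
        n = int(kept_counts.get(sample, 0)) if len(result.kept) else 0
        tmb[sample] = n * 1e6 / cb
    return tmb


def compute_tmb(
    result: FilterResult,
    callable_bases: Mapping[str, int] | None = None,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample TMB table (mutations per megabase of callable sequence)."""
    if callable_bases is not None:
        result.callable_bases = dict(callable_bases)
    if not result.callable_bases:
        raise ValueError("callable_bases required to compute TMB")
    result.tmb = _tmb_table(result)
    kept_counts = result.kept.groupby("sample_id").size() if len(result.kept) else {}
    rows = []
    for sample in sorted(result.callable_bases):
        rows.append(
            {
                "sample_id": sample,
                "group": (groups or {}).get(sample),
                "kept_mutations": int(kept_counts.get(sample, 0)) if len(result.kept) else 0,
                "callable_bases": result.callable_bases[sample],
                "tmb": result.tmb[sample],
            }
        )
    return pd.DataFrame(rows)


def summarize_variant_classes(result: FilterResult) -> pd.DataFrame:
    """Per-sample counts of frameshift substitution/deletion/insertion events.

    "Frameshift substitutions" are counted as frameshift events whose ref and
    alt are of equal length (block substitutions shifting frame are absent in
    these data, so the column is usually zero); frameshift deletions and
    insertions are indels with a net length change not divisible by three.
    """
    kept = result.kept
    samples = sorted(kept["sample_id"].unique()) if len(kept) else []
    out = pd.DataFrame(
        0, index=pd.Index(samples, name="sample_id"),
        columns=["frameshift_substitutions", "frameshift_deletions",
                 "frameshift_insertions", "inframe_indels", "missense",
                 "synonymous"],
    )
    if not len(kept):
        return out.reset_index()
    for row in kept.itertuples(index=False):
        cons = getattr(row, "consequence", None)
        if cons == "frameshift":
            if len(row.ref) == len(row.alt):
                out.loc[row.sample_id, "frameshift_substitutions"] += 1
            elif len(row.ref) > len(row.alt):
                out.loc[row.sample_id, "frameshift_deletions"] += 1
            else:
                out.loc[row.sample_id, "frameshift_insertions"] += 1
        elif cons == "inframe":
            out.loc[row.sample_id, "inframe_indels"] += 1
        elif cons in ("missense", "synonymous"):
            out.loc[row.sample_id, cons] += 1
    return out.reset_index()
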