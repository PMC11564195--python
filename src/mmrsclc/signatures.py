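"""96-channel mutation catalogs and signature activity refitting.

Single-nucleotide variants are classified by their trinucleotide context on
the pyrimidine strand: six substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
times sixteen 5'/3' flanking-base combinations. Signature activities
(exposures, in mutation-count units) are obtained by refitting a fixed
reference signature matrix to each sample's catalog with non-negative least
squares, and the mismatch-repair-deficiency burden is summarized as the
fraction of total activity assigned to the MMR signatures SBS15 and SBS21.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CHANNELS",
    "SUBSTITUTIONS",
    "MMR_SIGNATURES",
    "SignatureMatrix",
    "ActivityVector",
    "channel_of",
    "collapse_triplet",
    "toy_signature_matrix",
    "read_signature_matrix",
    "extract_contexts",
    "fit_activities",
    "mmr_fraction_and_compare",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Canonical channel order: substitution-major, then 5' base, then 3' base
#: (A[C>A]A, A[C>A]C, ..., T[T>G]T), matching SigProfiler-style catalogs.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

#: COSMIC single-base-substitution signatures attributed to defective MMR.
MMR_SIGNATURES = ("SBS15", "SBS21")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def collapse_triplet(triplet: str) -> str:
    """Collapse a genomic trinucleotide onto the pyrimidine strand."""
    if len(triplet) != 3:
        raise ValueError(f"need a trinucleotide, got {triplet!r}")
    return triplet if triplet[1] in "CT" else revcomp(triplet)


def channel_of(ref: str, alt: str, five: str, three: str) -> str:
    """Channel label for a SNV with the given flanking bases.

    Purine-reference variants are reverse-complemented onto the pyrimidine
    strand first, so e.g. A>G with 5'T/3'C maps to G[T>C]A.
    """
    if ref in "GA":
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
        five, three = three.translate(_COMPLEMENT), five.translate(_COMPLEMENT)
    label = f"{five}[{ref}>{alt}]{three}"
    if label not in _CHANNEL_INDEX:
        raise ValueError(f"not a valid SNV channel: {label}")
    return label


@dataclass
class SignatureMatrix:
    """Reference signatures: a (96, K) column-stochastic probability matrix."""

    names: tuple[str, ...]
    probs: np.ndarray  # shape (96, K)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (96, len(self.names)):
            raise ValueError(
                f"probs must be 96 x {len(self.names)}, got {self.probs.shape}"
            )
        if (self.probs < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"signature columns must sum to 1, got {colsums}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.probs[:, self.names.index(name)]

    def mixture(self, weights: Mapping[str, float]) -> np.ndarray:
        """96-vector for a convex combination of signatures."""
        total = float(sum(weights.values()))
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        out = np.zeros(96)
        for name, w in weights.items():
            out += w * self[name]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(CHANNELS), columns=list(self.names))


_TOY_PEAKS = {
    # Synthetic stand-ins with the sparse, peaked shape of the COSMIC MMR
    # signatures (a handful of dominant contexts), not their exact values.
    "SBS15": {  # C>T dominated
        "A[C>T]G": 0.30, "G[C>T]G": 0.25, "C[C>T]G": 0.18,
        "T[C>T]G": 0.12, "G[C>T]C": 0.08, "A[C>T]A": 0.06,
    },
    "SBS21": {  # T>C dominated
        "A[T>C]A": 0.30, "G[T>C]A": 0.25, "C[T>C]T": 0.18,
        "A[T>C]G": 0.12, "T[T>C]C": 0.08, "G[T>C]G": 0.06,
    },
}


def toy_signature_matrix() -> SignatureMatrix:
    """Bundled three-signature reference for tests and simulations.

    Synthetic stand-ins for the two MMR-deficiency signatures plus a flat
    background: ``SBS15`` (C>T dominated), ``SBS21`` (T>C dominated), each
    with 99% of its mass on six fixed peak contexts and 1% spread uniformly,
    and ``SBSflat`` (uniform over all 96 channels). The columns are constants,
    chosen to be as concentrated as the COSMIC signatures of the same names
    and mutually well separated.
    """
    cols = []
    for name in ("SBS15", "SBS21"):
        col = np.full(96, 0.01 / 96)
        for ch, w in _TOY_PEAKS[name].items():
            col[_CHANNEL_INDEX[ch]] += 0.99 * w
        cols.append(col / col.sum())
    cols.append(np.full(96, 1.0 / 96))
    return SignatureMatrix(names=("SBS15", "SBS21", "SBSflat"), probs=np.column_stack(cols))


def read_signature_matrix(path) -> SignatureMatrix:
    """Read a signature TSV: first column channel labels, one column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS) - set(df.index)
    if missing:
        raise ValueError(f"signature matrix missing {len(missing)} channels")
    df = df.loc[list(CHANNELS)]
    return SignatureMatrix(names=tuple(df.columns), probs=df.to_numpy(float))


def extract_contexts(
    snvs: pd.DataFrame, genome: Mapping[str, str]
) -> pd.DataFrame:
    """Build per-sample 96-channel catalogs from SNV calls.

    Parameters
    ----------
    snvs
        Variant table restricted to SNVs, with columns ``sample_id``,
        ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    genome
        Mapping of chromosome name to sequence.

    Returns
    -------
    DataFrame with one row per sample and the 96 channels as columns; row
    sums equal the number of SNVs contributing for that sample. SNVs at a
    contig end with a missing flank are skipped (a warning reports how many).
    """
    samples = sorted(snvs["sample_id"].unique()) if len(snvs) else []
    counts = pd.DataFrame(
        0, index=pd.Index(samples, name="sample_id"), columns=list(CHANNELS)
    )
    n_skipped = 0
    for row in snvs.itertuples(index=False):
        seq = genome[row.chrom]
        i = int(row.pos) - 1  # to 0-based
        if i < 1 or i >= len(seq) - 1:
            n_skipped += 1
            continue
        if seq[i] != row.ref:
            raise ValueError(
                f"reference mismatch at {row.chrom}:{row.pos}: "
                f"variant ref {row.ref}, genome {seq[i]}"
            )
        ch = channel_of(row.ref, row.alt, seq[i - 1], seq[i + 1])
        counts.loc[row.sample_id, ch] += 1
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} SNV(s) at contig ends with missing flank")
    return counts


@dataclass
class ActivityVector:
    """Per-sample signature exposures and derived MMR fraction.

    ``mmr_fraction`` is (SBS15 + SBS21 exposure) / total exposure, or NaN
    when the total exposure is zero (flagged via ``total_zero``).
    """

    sample_id: str
    exposures: dict[str, float]
    residual_norm: float
    mmr_fraction: float = field(init=False)
    total_zero: bool = field(init=False)
    low_confidence: bool = False

    def __post_init__(self) -> None:
        total = sum(self.exposures.values())
        self.total_zero = total <= 0
        if self.total_zero:
            self.mmr_fraction = float("nan")
        else:
            mmr = sum(self.exposures.get(s, 0.0) for s in MMR_SIGNATURES)
            self.mmr_fraction = mmr / total


def fit_activities(
    catalog: pd.DataFrame | np.ndarray,
    sigs: SignatureMatrix,
    min_snvs: int = 10,
) -> list[ActivityVector]:
    """Refit signature activities per sample by non-negative least squares.

    For each sample solves min ||c - P a||_2 subject to a >= 0, where c is the
    96-channel catalog and P the signature matrix. Exposures are in mutation
    counts. Samples with fewer than ``min_snvs`` SNVs are flagged low
    confidence; all-zero catalogs get zero exposures and an undefined
    (NaN) MMR fraction.
    """
    if isinstance(catalog, np.ndarray):
        catalog = pd.DataFrame(
            np.atleast_2d(catalog), columns=list(CHANNELS),
            index=[f"sample_{i}" for i in range(np.atleast_2d(catalog).shape[0])],
        )
    if list(catalog.columns) != list(CHANNELS):
        catalog = catalog[list(CHANNELS)]
    out = []
    for sample_id, row in catalog.iterrows():
        c = row.to_numpy(float)
        total = c.sum()
        if total == 0:
            av = ActivityVector(str(sample_id), {n: 0.0 for n in sigs.names}, 0.0)
        else:
            a, rnorm = optimize.nnls(sigs.probs, c)
            av = ActivityVector(str(sample_id), dict(zip(sigs.names, a)), float(rnorm))
        av.low_confidence = total < min_snvs
        out.append(av)
    return out


def mmr_fraction_and_compare(
    activities: Sequence[ActivityVector], groups: Mapping[str, str]
) -> tuple[pd.DataFrame, float, float]:
    """Per-sample MMR fractions plus a Kruskal-Wallis test across groups.

    Samples with zero total exposure are excluded from the test with a
    warning. Returns (per-sample frame, H statistic, p value); ties are
    handled by midranks with the standard tie correction. With fewer than
    two usable groups, or all fractions identical, H = 0 and p = 1.
    """
    rows = []
    n_dropped = 0
    for av in activities:
        if av.total_zero:
            n_dropped += 1
            continue
        rows.append(
            {"sample_id": av.sample_id, "group": groups[av.sample_id],
             "mmr_fraction": av.mmr_fraction}
        )
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} sample(s) with zero total exposure")
    df = pd.DataFrame(rows, columns=["sample_id", "group", "mmr_fraction"])
    h, p = kruskal_by_group(df, "mmr_fraction", "group")
    return df, h, p


def kruskal_by_group(df: pd.DataFrame, value_col: str, group_col: str) -> tuple[float, float]:
    """Kruskal-Wallis H and p over the groups of ``df``; degenerate inputs give (0, 1)."""
    samples = [g[value_col].to_numpy(float) for _, g in df.groupby(group_col)]
    samples = [s for s in samples if len(s)]
    if len(samples) < 2:
        return 0.0, 1.0
    flat = np.concatenate(samples)
    if np.all(flat == flat[0]):  # scipy raises on all-identical values
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
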