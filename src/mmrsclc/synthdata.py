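"""Synthetic cohort generator emulating an MMR-deficient SCLC mouse study.

Generates every input the analysis pipeline consumes — a small transcriptome
with one floxed gene, per-base exome coverage with a configurable floxed-exon
copy number, somatic SNVs/indels drawn from signature mixtures, injected
filter artifacts (recurrent, blacklisted, low-depth calls), and survival
cohorts — together with ground-truth labels sufficient to score every
downstream stage.

Default parameters encode the study design this simulator emulates: three
genotype groups (RP controls, RPM Msh2 fl/fl, RPM Msh2 fl/wt) with cohort
sizes 5/9/2, an 18-fold mutation-rate contrast between fl/fl and RP, an
MMR-dominant signature mixture in fl/fl tumors only, floxed-exon copy numbers
2/0/1, and survival medians (onset 258.5 vs 285 days; post-onset 55 vs 46.5
days; treatment-arm medians per group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import (
    CHANNELS,
    SUBSTITUTIONS,
    SignatureMatrix,
    collapse_triplet,
    revcomp,
    toy_signature_matrix,
)

__all__ = [
    "SimConfig",
    "TranscriptModel",
    "simulate_transcriptome",
    "simulate_coverage",
    "simulate_mutations",
    "inject_artifacts",
    "simulate_cohort",
    "simulate_all",
]

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)

GROUPS = ("RP", "RPM_flfl", "RPM_flwt")


def _default_survival_params() -> dict:
    # Onset and post-onset medians (days) per genotype; treatment-arm
    # post-enrollment medians per genotype. fl/wt mirrors fl/fl for onset
    # (RPM animals are pooled for onset) and RP for treatment response.
    return {
        "onset": {"RP": 258.5, "RPM_flfl": 285.0, "RPM_flwt": 285.0},
        "post_onset": {"RP": 55.0, "RPM_flfl": 46.5, "RPM_flwt": 46.5},
        "treatment": {
            "RP": {"vehicle": 53.0, "chemo": 73.5, "anti-PD-1": 53.0,
                   "chemo+anti-PD-1": 75.0},
            "RPM_flfl": {"vehicle": 41.0, "chemo": 83.0, "anti-PD-1": 51.5,
                         "chemo+anti-PD-1": 85.0},
        },
    }


@dataclass
class SimConfig:
    """All knobs of the simulated study, with the emulated design as defaults."""

    seed: int = 0
    n_transcripts: int = 60
    cds_length_range: tuple[int, int] = (300, 1500)
    utr3_length: int = 400
    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"RP": 5, "RPM_flfl": 9, "RPM_flwt": 2}
    )
    mutation_rate_per_group: dict[str, float] = field(
        default_factory=lambda: {"RP": 50.0, "RPM_flfl": 900.0, "RPM_flwt": 50.0}
    )
    signature_mix_per_group: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "RP": {"SBS15": 0.10, "SBS21": 0.10, "SBSflat": 0.80},
            "RPM_flfl": {"SBS15": 0.45, "SBS21": 0.35, "SBSflat": 0.20},
            "RPM_flwt": {"SBS15": 0.10, "SBS21": 0.10, "SBSflat": 0.80},
        }
    )
    floxed_exon_copy_number_per_group: dict[str, int] = field(
        default_factory=lambda: {"RP": 2, "RPM_flfl": 0, "RPM_flwt": 1}
    )
    mean_depth: float = 100.0
    exon_bias_sigma: float = 0.2
    indel_fraction: float = 0.10
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {"shared": 0.02, "blacklist": 0.02, "low_depth": 0.02}
    )
    survival_params: dict = field(default_factory=_default_survival_params)
    n_animals_per_group: dict[str, int] = field(
        default_factory=lambda: {"RP": 10, "RPM_flfl": 12, "RPM_flwt": 2}
    )
    n_animals_per_arm: int = 8
    censor_fraction: float = 0.05
    survival_model: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.0

    def validate(self) -> None:
        if self.cds_length_range[0] < 6:
            raise ValueError("cds_length_range lower bound must be >= 6 nt")
        for g, mix in self.signature_mix_per_group.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"signature mix for {g} must sum to 1")
        for g, r in self.mutation_rate_per_group.items():
            if r < 0:
                raise ValueError(f"mutation rate for {g} must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be strictly positive")
        for g, cn in self.floxed_exon_copy_number_per_group.items():
            if cn not in (0, 1, 2):
                raise ValueError(f"copy number for {g} must be in {{0,1,2}}")
        if self.censor_fraction < 0 or self.censor_fraction > 1:
            raise ValueError("censor_fraction must be in [0, 1]")
        for section in ("onset", "post_onset"):
            for g, m in self.survival_params.get(section, {}).items():
                if m <= 0:
                    raise ValueError(f"{section} median for {g} must be positive")

    def samples(self) -> list[tuple[str, str]]:
        """(sample_id, group) pairs in a fixed order."""
        out = []
        for g in sorted(self.n_samples_per_group):
            for i in range(self.n_samples_per_group[g]):
                out.append((f"{g}_{i + 1}", g))
        return out


@dataclass
class TranscriptModel:
    """A protein-coding transcript on the simulated genome (+ strand).

    ``exon_intervals`` are half-open 0-based genomic intervals that carry the
    CDS contiguously; ``utr3_sequence`` follows the stop codon in the genome
    (used to read through frameshifts).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exon_intervals: list[tuple[int, int]]
    cds_sequence: str
    utr3_sequence: str = ""
    is_floxed_gene: bool = False
    floxed_exon_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not a multiple of 3")
        starts = [s for s, _ in self.exon_intervals]
        if starts != sorted(starts):
            raise ValueError(f"{self.transcript_id}: exons not sorted")
        cds_len = sum(e - s for s, e in self.exon_intervals)
        if cds_len != len(self.cds_sequence):
            raise ValueError(f"{self.transcript_id}: exon span != CDS length")

    @property
    def exon_ids(self) -> list[str]:
        return [f"{self.gene_id}:exon{i + 1}" for i in range(len(self.exon_intervals))]

    def genomic_pos(self, cds_pos0: int) -> int:
        """Genomic 0-based position of a 0-based CDS offset."""
        off = cds_pos0
        for s, e in self.exon_intervals:
            if off < e - s:
                return s + off
            off -= e - s
        raise IndexError(f"CDS offset {cds_pos0} out of range")

    def cds_offset(self, gpos0: int) -> int | None:
        """0-based CDS offset of a genomic position, or None if intronic."""
        off = 0
        for s, e in self.exon_intervals:
            if s <= gpos0 < e:
                return off + (gpos0 - s)
            off += e - s
        return None

    def protein(self) -> str:
        from Bio.Seq import Seq

        return str(Seq(self.cds_sequence).translate())[:-1]  # drop terminal stop


def _rng_for(config: SimConfig, stage: str) -> np.random.Generator:
    """Stage-scoped generator: deterministic fan-out of the top-level seed."""
    order = ("transcriptome", "coverage", "mutations", "artifacts", "cohort")
    ss = np.random.SeedSequence(config.seed)
    return np.random.default_rng(ss.spawn(len(order))[order.index(stage)])


def simulate_transcriptome(
    config: SimConfig,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Generate the transcript models and the genome they live on.

    Deterministic given ``config.seed``. The first transcript is the floxed
    gene ("Msh2") with a middle exon flagged as floxed. All transcripts are on
    the + strand of a single chromosome; exon chunks are at least 90 nt so
    exon-level count ratios are well conditioned.
    """
    config.validate()
    rng = _rng_for(config, "transcriptome")
    lo, hi = config.cds_length_range
    chrom = "chr1"
    pieces: list[str] = []
    cursor = 0
    transcripts: list[TranscriptModel] = []

    def emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        pieces.append(seq)
        start = cursor
        cursor += len(seq)
        return start, cursor

    for t in range(config.n_transcripts):
        cds_len = int(rng.integers(lo, hi + 1))
        cds_len -= cds_len % 3
        codons = ["ATG"]
        codons += list(rng.choice(_CODONS, size=cds_len // 3 - 2))
        codons.append(str(rng.choice(_STOPS)))
        cds = "".join(codons)
        utr3 = "".join(rng.choice(list("ACGT"), size=config.utr3_length))

        max_ex = max(1, min(8, len(cds) // 90))
        n_ex = int(rng.integers(min(3, max_ex), max_ex + 1))
        # split CDS into n_ex chunks of >= 90 nt
        if n_ex == 1:
            bounds = [0, len(cds)]
        else:
            free = len(cds) - 90 * n_ex
            cuts = np.sort(rng.integers(0, free + 1, size=n_ex - 1))
            bounds = [0]
            for i, c in enumerate(cuts):
                bounds.append(90 * (i + 1) + int(c))
            bounds.append(len(cds))

        emit("".join(rng.choice(list("ACGT"), size=int(rng.integers(200, 501)))))
        intervals = []
        for i in range(n_ex):
            chunk = cds[bounds[i]:bounds[i + 1]]
            intervals.append(emit(chunk))
            if i < n_ex - 1:
                emit("".join(rng.choice(list("ACGT"), size=int(rng.integers(100, 301)))))
        emit(utr3)

        floxed = t == 0
        transcripts.append(
            TranscriptModel(
                transcript_id=f"ENSMUST{t:05d}",
                gene_id="Msh2" if floxed else f"Gene{t}",
                chrom=chrom,
                strand="+",
                exon_intervals=intervals,
                cds_sequence=cds,
                utr3_sequence=utr3,
                is_floxed_gene=floxed,
                floxed_exon_index=len(intervals) // 2 if floxed else None,
            )
        )
    genome = {chrom: "".join(pieces)}
    return transcripts, genome


def simulate_coverage(
    transcripts: Sequence[TranscriptModel],
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Simulate per-base exome coverage and per-exon counts for every sample.

    Per-base depth is Poisson with mean ``mean_depth x exon bias x (CN/2)``,
    where the multiplicative exon bias is drawn log-normally once per exon
    (shared across samples, as capture bias largely is) and CN is the group's
    floxed-exon copy number on the floxed exon and 2 everywhere else.

    Returns (exon_counts, per_base, true_cn). ``exon_counts`` has columns
    sample_id, group, gene_id, exon_id, is_floxed, count; ``per_base`` has
    chrom, pos (0-based), gene_id, exon_id, is_floxed, sample_id, group,
    depth; ``true_cn`` maps sample_id to the generating copy number.
    """
    config.validate()
    if not any(t.is_floxed_gene for t in transcripts):
        raise ValueError("transcripts must include the floxed gene")
    for g in config.n_samples_per_group:
        if g not in config.floxed_exon_copy_number_per_group:
            raise KeyError(f"unknown group label {g!r}: no copy number configured")
    rng = _rng_for(config, "coverage")

    exon_meta = []  # (chrom, start, end, gene, exon_id, is_floxed, bias)
    for t in transcripts:
        for i, (s, e) in enumerate(t.exon_intervals):
            bias = float(np.exp(rng.normal(0.0, config.exon_bias_sigma)))
            floxed = t.is_floxed_gene and i == t.floxed_exon_index
            exon_meta.append((t.chrom, s, e, t.gene_id, t.exon_ids[i], floxed, bias))

    pb_rows = []
    true_cn: dict[str, int] = {}
    for sample_id, group in config.samples():
        cn = config.floxed_exon_copy_number_per_group[group]
        true_cn[sample_id] = cn
        for chrom, s, e, gene, exon_id, floxed, bias in exon_meta:
            lam = config.mean_depth * bias * ((cn / 2.0) if floxed else 1.0)
            depth = rng.poisson(lam, size=e - s)
            pb_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": np.arange(s, e),
                        "gene_id": gene,
                        "exon_id": exon_id,
                        "is_floxed": floxed,
                        "sample_id": sample_id,
                        "group": group,
                        "depth": depth,
                    }
                )
            )
    per_base = pd.concat(pb_rows, ignore_index=True)
    exon_counts = (
        per_base.groupby(
            ["sample_id", "group", "gene_id", "exon_id", "is_floxed"], as_index=False
        )["depth"]
        .sum()
        .rename(columns={"depth": "count"})
    )
    return exon_counts, per_base, true_cn


class ContextUnavailableError(RuntimeError):
    """No genomic site carries the trinucleotide context a channel requires."""


def _context_index(
    transcripts: Sequence[TranscriptModel], genome: Mapping[str, str]
) -> dict[str, list[tuple[str, int, str, int]]]:
    """Map pyrimidine-collapsed triplet -> exonic sites (chrom, gpos0, tid, cds0).

    Exon-edge bases are excluded so the genomic context equals the CDS
    context, keeping simulation and downstream extraction consistent.
    """
    index: dict[str, list[tuple[str, int, str, int]]] = {}
    for t in transcripts:
        seq = genome[t.chrom]
        off = 0
        for s, e in t.exon_intervals:
            for g in range(s + 1, e - 1):
                trip = seq[g - 1:g + 2]
                index.setdefault(collapse_triplet(trip), []).append(
                    (t.chrom, g, t.transcript_id, off + (g - s))
                )
            off += e - s
    return index


_COMP = str.maketrans("ACGT", "TGCA")


def _snv_consequence(t: TranscriptModel, cds0: int, alt: str) -> str:
    codon_i = cds0 // 3
    codon = t.cds_sequence[codon_i * 3:codon_i * 3 + 3]
    mcodon = codon[: cds0 % 3] + alt + codon[cds0 % 3 + 1:]
    from Bio.Seq import Seq

    aa, maa = str(Seq(codon).translate()), str(Seq(mcodon).translate())
    if aa == maa:
        return "synonymous"
    if maa == "*" or aa == "*":
        return "other"  # stop gain/loss
    return "missense"


def simulate_mutations(
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    config: SimConfig,
    sigs: SignatureMatrix | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw per-sample somatic variants from the group signature mixtures.

    SNV counts per sample are Poisson around the group rate; each SNV's
    96-channel is drawn from the group mixture and placed uniformly at an
    exonic site matching that trinucleotide context. Collisions are resampled
    against a cohort-wide occupancy set: on a real exome (three orders of
    magnitude larger than this scaled-down one) two tumors essentially never
    hit the same base, so recurrent calls are left to the artifact injector.
    A configurable fraction of events are indels (half frameshift, half
    in-frame), placed in CDS interiors. Consequences are annotated from the
    transcript models; per-variant depth is Poisson(mean_depth).

    Returns (variants, truth); ``truth`` records per-sample true SNV counts
    and the generating mixtures.
    """
    config.validate()
    sigs = sigs or toy_signature_matrix()
    for g, mix in config.signature_mix_per_group.items():
        unknown = set(mix) - set(sigs.names)
        if unknown:
            raise KeyError(f"group {g}: unknown signatures {sorted(unknown)}")
    rng = _rng_for(config, "mutations")
    index = _context_index(transcripts, genome)
    tmap = {t.transcript_id: t for t in transcripts}
    channel_triplet = [f"{c[0]}{c[2]}{c[6]}" for c in CHANNELS]  # 5' ref 3'

    rows = []
    truth_counts: dict[str, int] = {}
    mut_id = 0
    used: set[tuple[str, int]] = set()  # cohort-wide: no accidental recurrence
    for sample_id, group in config.samples():
        rate = config.mutation_rate_per_group[group]
        n = int(rng.poisson(rate))
        mix96 = sigs.mixture(config.signature_mix_per_group[group])
        n_indel = rng.binomial(n, config.indel_fraction)
        n_snv = n - n_indel
        truth_counts[sample_id] = n

        drawn = rng.choice(96, size=n_snv, p=mix96)
        for ch_i in drawn:
            trip = channel_triplet[ch_i]
            sites = index.get(trip)
            if not sites:
                raise ContextUnavailableError(
                    f"no genomic site with context for channel {CHANNELS[ch_i]}"
                )
            for _ in range(200):
                chrom, g0, tid, cds0 = sites[rng.integers(len(sites))]
                if (chrom, g0) not in used:
                    break
            else:
                continue  # context saturated; drop the event
            used.add((chrom, g0))
            ref = genome[chrom][g0]
            pyr_ref, pyr_alt = CHANNELS[ch_i][2], CHANNELS[ch_i][4]
            alt = pyr_alt if ref == pyr_ref else pyr_alt.translate(_COMP)
            t = tmap[tid]
            rows.append(
                {
                    "sample_id": sample_id, "group": group, "chrom": chrom,
                    "pos": g0 + 1, "ref": ref, "alt": alt,
                    "depth": int(rng.poisson(config.mean_depth)),
                    "var_class": "SNV",
                    "consequence": _snv_consequence(t, cds0, alt),
                    "transcript_id": tid, "cds_pos": cds0 + 1,
                    "mutation_id": f"mut{mut_id}",
                }
            )
            mut_id += 1

        for _ in range(n_indel):
            t = transcripts[rng.integers(len(transcripts))]
            frameshift = rng.random() < 0.5
            size = 1 if frameshift else 3
            is_del = rng.random() < 0.5
            # anchor + deleted bases must be contiguous within one exon
            for _ in range(100):
                ex_i = int(rng.integers(len(t.exon_intervals)))
                s, e = t.exon_intervals[ex_i]
                span = size + 1 if is_del else 1
                if e - s < span + 2:
                    continue
                g0 = int(rng.integers(s + 1, e - span))
                if (t.chrom, g0) in used:
                    continue
                break
            else:
                continue
            used.add((t.chrom, g0))
            cds0 = t.cds_offset(g0)
            seq = genome[t.chrom]
            if is_del:
                ref, alt = seq[g0:g0 + size + 1], seq[g0]
                var_class = "deletion"
            else:
                ins = "".join(rng.choice(list("ACGT"), size=size))
                ref, alt = seq[g0], seq[g0] + ins
                var_class = "insertion"
            rows.append(
                {
                    "sample_id": sample_id, "group": group, "chrom": t.chrom,
                    "pos": g0 + 1, "ref": ref, "alt": alt,
                    "depth": int(rng.poisson(config.mean_depth)),
                    "var_class": var_class,
                    "consequence": "frameshift" if frameshift else "inframe",
                    "transcript_id": t.transcript_id, "cds_pos": cds0 + 1,
                    "mutation_id": f"mut{mut_id}",
                }
            )
            mut_id += 1

    cols = ["sample_id", "group", "chrom", "pos", "ref", "alt", "depth",
            "var_class", "consequence", "transcript_id", "cds_pos", "mutation_id"]
    variants = pd.DataFrame(rows, columns=cols)
    truth = {
        "n_events": truth_counts,
        "mixtures": {g: dict(m) for g, m in config.signature_mix_per_group.items()},
    }
    return variants, truth


def inject_artifacts(
    variants: pd.DataFrame,
    config: SimConfig,
    transcripts: Sequence[TranscriptModel] | None = None,
    genome: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, set[tuple[str, int, str, str]], pd.DataFrame]:
    """Inject filter-exercising artifacts into a variant table.

    Adds (i) identical calls shared by >= 2 samples, (ii) calls whose loci go
    on a blacklist, (iii) calls with depth < 30. Counts are
    ``ceil(rate x n_real)`` per class. Returns (table, blacklist, labels)
    where ``labels`` carries one row per injected call with its ground-truth
    artifact class.
    """
    rates = config.artifact_rates
    samples = sorted(set(s for s, _ in config.samples()) | set(variants["sample_id"]))
    if rates.get("shared", 0) > 0 and len(samples) < 2:
        raise ValueError("shared-variant injection requires >= 2 samples")
    rng = _rng_for(config, "artifacts")
    n_real = len(variants)
    counts = {k: math.ceil(rates.get(k, 0.0) * n_real) if rates.get(k, 0.0) > 0 else 0
              for k in ("shared", "blacklist", "low_depth")}
    if not any(counts.values()):
        return variants.copy(), set(), pd.DataFrame(
            columns=["sample_id", "chrom", "pos", "ref", "alt", "artifact_class"]
        )

    # artifact loci: fresh exonic SNV sites not used by real calls
    if transcripts is not None and genome is not None:
        pool = [(c, g) for sites in _context_index(transcripts, genome).values()
                for (c, g, _, _) in sites]
    else:
        chroms = variants["chrom"].unique().tolist() or ["chr1"]
        pool = [(chroms[0], 10_000_000 + i) for i in range(10000)]
    taken = set(zip(variants["chrom"], variants["pos"] - 1))
    pool = [p for p in pool if p not in taken]
    rng.shuffle(pool)
    pool_iter = iter(pool)

    def fresh_site() -> tuple[str, int, str, str]:
        chrom, g0 = next(pool_iter)
        ref = genome[chrom][g0] if genome else "C"
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return chrom, g0 + 1, ref, str(alt)

    new_rows, labels = [], []
    group_of = dict(config.samples())

    def add(sample_id, chrom, pos, ref, alt, depth, klass):
        new_rows.append(
            {"sample_id": sample_id, "group": group_of.get(sample_id, "NA"),
             "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
             "depth": depth, "var_class": "SNV", "consequence": "other",
             "transcript_id": None, "cds_pos": None,
             "mutation_id": f"artifact_{klass}_{len(labels)}"}
        )
        labels.append({"sample_id": sample_id, "chrom": chrom, "pos": pos,
                       "ref": ref, "alt": alt, "artifact_class": klass})

    for _ in range(counts["shared"]):
        chrom, pos, ref, alt = fresh_site()
        k = int(rng.integers(2, min(3, len(samples)) + 1))
        for s in rng.choice(samples, size=k, replace=False):
            add(s, chrom, pos, ref, alt, int(rng.poisson(config.mean_depth)), "shared")

    blacklist: set[tuple[str, int, str, str]] = set()
    for _ in range(counts["blacklist"]):
        chrom, pos, ref, alt = fresh_site()
        blacklist.add((chrom, pos, ref, alt))
        s = samples[rng.integers(len(samples))]
        add(s, chrom, pos, ref, alt, int(rng.poisson(config.mean_depth)), "blacklist")

    for _ in range(counts["low_depth"]):
        chrom, pos, ref, alt = fresh_site()
        s = samples[rng.integers(len(samples))]
        add(s, chrom, pos, ref, alt, int(rng.integers(1, 30)), "low_depth")

    out = pd.concat([variants, pd.DataFrame(new_rows)], ignore_index=True)
    return out, blacklist, pd.DataFrame(labels)


def _draw_times(rng: np.random.Generator, median: float, n: int,
                model: str, shape: float) -> np.ndarray:
    if model == "exponential":
        return rng.exponential(median / math.log(2), size=n)
    if model == "weibull":
        scale = median / math.log(2) ** (1.0 / shape)
        return scale * rng.weibull(shape, size=n)
    raise ValueError(f"unknown survival model {model!r}")


def simulate_cohort(config: SimConfig, design: str = "natural") -> pd.DataFrame:
    """Simulate an animal event table.

    ``design="natural"`` draws tumor onset and post-onset survival per
    genotype group (arm "none"); ``design="treatment"`` draws post-enrollment
    survival for each treatment arm configured in
    ``survival_params["treatment"]``. Times come from an exponential (default)
    or Weibull model parameterized by the target median. A
    ``censor_fraction`` of animals end for unrelated causes at a uniformly
    chosen time before their disease endpoint.

    Columns: animal_id, group, arm, induction_day, onset_day, end_day,
    end_cause (disease | termination_criteria | unrelated).
    """
    config.validate()
    rng = _rng_for(config, "cohort")
    rows = []
    aid = 0

    def end_cause_and_day(onset: float, post: float) -> tuple[str, float]:
        if rng.random() < config.censor_fraction:
            return "unrelated", onset + rng.uniform(0.0, post)
        # both disease deaths and criteria-based euthanasia count as events
        return ("termination_criteria" if rng.random() < 0.3 else "disease",
                onset + post)

    if design == "natural":
        for group, n in sorted(config.n_animals_per_group.items()):
            onset_m = config.survival_params["onset"][group]
            post_m = config.survival_params["post_onset"][group]
            onsets = _draw_times(rng, onset_m, n, config.survival_model,
                                 config.weibull_shape)
            posts = _draw_times(rng, post_m, n, config.survival_model,
                                config.weibull_shape)
            for onset, post in zip(onsets, posts):
                cause, end = end_cause_and_day(onset, post)
                rows.append({"animal_id": f"A{aid}", "group": group, "arm": "none",
                             "induction_day": 0.0, "onset_day": onset,
                             "end_day": end, "end_cause": cause})
                aid += 1
    elif design == "treatment":
        for group, arms in sorted(config.survival_params["treatment"].items()):
            onset_m = config.survival_params["onset"][group]
            for arm, median in sorted(arms.items()):
                onsets = _draw_times(rng, onset_m, config.n_animals_per_arm,
                                     config.survival_model, config.weibull_shape)
                posts = _draw_times(rng, median, config.n_animals_per_arm,
                                    config.survival_model, config.weibull_shape)
                for onset, post in zip(onsets, posts):
                    cause, end = end_cause_and_day(onset, post)
                    rows.append({"animal_id": f"A{aid}", "group": group, "arm": arm,
                                 "induction_day": 0.0, "onset_day": onset,
                                 "end_day": end, "end_cause": cause})
                    aid += 1
    else:
        raise ValueError(f"unknown design {design!r}")
    return pd.DataFrame(rows)


@dataclass
class SimulatedStudy:
    """One full synthetic dataset plus the ground truth that generated it."""

    config: SimConfig
    transcripts: list[TranscriptModel]
    genome: dict[str, str]
    exon_counts: pd.DataFrame
    per_base: pd.DataFrame
    variants: pd.DataFrame
    blacklist: set[tuple[str, int, str, str]]
    artifact_labels: pd.DataFrame
    cohort: pd.DataFrame
    treatment_cohort: pd.DataFrame
    truth: dict


def simulate_all(config: SimConfig | None = None) -> SimulatedStudy:
    """Run every generator stage and bundle outputs with ground truth."""
    config = config or SimConfig()
    transcripts, genome = simulate_transcriptome(config)
    exon_counts, per_base, true_cn = simulate_coverage(transcripts, config)
    variants, mut_truth = simulate_mutations(transcripts, genome, config)
    variants, blacklist, labels = inject_artifacts(
        variants, config, transcripts, genome
    )
    cohort = simulate_cohort(config, design="natural")
    treatment = simulate_cohort(replace(config, seed=config.seed + 1),
                                design="treatment")
    truth = {
        "true_copy_number": true_cn,
        "mutations": mut_truth,
        "survival_medians": config.survival_params,
        "censor_fraction": config.censor_fraction,
    }
    return SimulatedStudy(
        config=config, transcripts=transcripts, genome=genome,
        exon_counts=exon_counts, per_base=per_base, variants=variants,
        blacklist=blacklist, artifact_labels=labels, cohort=cohort,
        treatment_cohort=treatment, truth=truth,
    )
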