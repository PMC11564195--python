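"""Candidate-neoantigen enumeration from mutant coding sequences.

For each coding mutation (missense, in-frame indel, frameshift) the mutant
CDS is reconstructed, trimmed to a short sequence containing the mutation
(13 nt flanks, extended to codon boundaries; frameshifts keep the entire
novel-frame peptide through to its stop), translated, and scanned for k-mer
windows (9-mers by default) that overlap the mutated residues and do not
occur in the wild-type protein. Candidates are scored by a pluggable
percent-rank predictor for the murine H2-Kb allele; binders are called
strong (rank < 0.5) or weak (0.5 <= rank < 2), and a mutation counts as
neoantigenic when at least one of its candidates ranks below 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .signatures import kruskal_by_group

__all__ = [
    "MutantSequence",
    "SurrogatePredictor",
    "NetMHCpanPredictor",
    "build_mutant_cds",
    "trim_mutant",
    "enumerate_candidates",
    "binder_class",
    "classify_and_count",
]

STRONG_RANK = 0.5
WEAK_RANK = 2.0


@dataclass
class MutantSequence:
    """A mutant coding sequence and its trimmed, translated form.

    ``mut_span_nt`` is the 0-based half-open edited span on ``mutant_cds``;
    ``mutated_residue_span`` the corresponding residue span on
    ``trimmed_peptide`` (for frameshifts: first divergent residue through the
    peptide end).
    """

    mutation_id: str
    transcript_id: str
    var_class: str  # missense | inframe | frameshift
    mutant_cds: str = ""
    mut_span_nt: tuple[int, int] = (0, 0)
    trimmed_nt: str = ""
    trimmed_peptide: str = ""
    mutated_residue_span: tuple[int, int] = (0, 0)


def _translate(nt: str) -> str:
    """Translate; stop at (and exclude) the first stop codon."""
    aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


def build_mutant_cds(transcript, variant) -> MutantSequence:
    """Apply a coding variant to its transcript's CDS.

    ``variant`` needs attributes ``mutation_id``, ``ref``, ``alt``,
    ``cds_pos`` (1-based; for indels the anchor-base convention: ref is the
    anchor base plus any deleted bases), and ``consequence``. For
    frameshifts, the 3' UTR is appended and the mutant sequence read through
    to the first stop of the shifted frame.
    """
    cons = variant.consequence
    if cons not in ("missense", "inframe", "frameshift"):
        raise ValueError(f"{variant.mutation_id}: consequence {cons!r} not usable "
                         "for neoantigen prediction")
    cds = transcript.cds_sequence
    p0 = int(variant.cds_pos) - 1
    ref, alt = variant.ref, variant.alt
    if cds[p0:p0 + len(ref)] != ref:
        raise ValueError(
            f"{variant.mutation_id}: ref {ref!r} does not match CDS at "
            f"position {variant.cds_pos}"
        )
    mutant = cds[:p0] + alt + cds[p0 + len(ref):]
    if len(ref) == len(alt) == 1:
        span = (p0, p0 + 1)
    elif len(alt) > len(ref):  # insertion after the anchor base
        span = (p0 + 1, p0 + len(alt))
    else:  # deletion: mark the anchor base at the junction
        span = (p0, p0 + 1)

    if cons == "frameshift":
        mutant += transcript.utr3_sequence
        aa = str(Seq(mutant[: len(mutant) - len(mutant) % 3]).translate())
        stop = aa.find("*")
        if stop < 0:
            raise ValueError(
                f"{variant.mutation_id}: no stop codon in the shifted frame"
            )
        mutant = mutant[: (stop + 1) * 3]  # include the novel stop codon
    return MutantSequence(
        mutation_id=variant.mutation_id,
        transcript_id=transcript.transcript_id,
        var_class=cons,
        mutant_cds=mutant,
        mut_span_nt=span,
    )


def trim_mutant(
    mutseq: MutantSequence,
    wildtype_protein: str | None = None,
    flank_nt: int = 13,
) -> MutantSequence:
    """Trim the mutant CDS around the mutation and translate.

    Missense/in-frame: keep ``flank_nt`` nucleotides either side of the
    edited span, widened to whole codons (13 nt -> 5 codons per side, so a
    mid-CDS SNV yields a 33-nt / 11-residue window with the mutant residue
    centered), clipped at the CDS ends. Frameshift: trim only the wild-type
    5' portion to the same codon-aligned flank and keep the entire
    novel-frame sequence to its stop; ``wildtype_protein`` (the untrimmed
    wild-type translation) locates the first divergent residue.
    """
    if not mutseq.mutant_cds:
        raise ValueError("mutant_cds not populated; run build_mutant_cds first")
    a, b = mutseq.mut_span_nt
    flank_codons = -(-flank_nt // 3)
    if mutseq.var_class == "frameshift":
        start = 3 * max(0, a // 3 - flank_codons)
        mutseq.trimmed_nt = mutseq.mutant_cds[start:]
        peptide = _translate(mutseq.trimmed_nt)
        mutseq.trimmed_peptide = peptide
        full = _translate(mutseq.mutant_cds)
        if wildtype_protein is not None:
            d = next(
                (i for i in range(len(full))
                 if i >= len(wildtype_protein) or full[i] != wildtype_protein[i]),
                len(full),
            )
        else:
            d = a // 3
        lo = max(0, min(d - start // 3, len(peptide) - 1) if peptide else 0)
        mutseq.mutated_residue_span = (lo, len(peptide))
        return mutseq

    ca, cb = a // 3, (b - 1) // 3 + 1  # codon span of the edit
    n_codons = len(mutseq.mutant_cds) // 3
    start = 3 * max(0, ca - flank_codons)
    end = 3 * min(n_codons, cb + flank_codons)
    mutseq.trimmed_nt = mutseq.mutant_cds[start:end]
    mutseq.trimmed_peptide = _translate(mutseq.trimmed_nt)
    n = len(mutseq.trimmed_peptide)
    lo, hi = ca - start // 3, cb - start // 3
    mutseq.mutated_residue_span = (min(lo, max(n - 1, 0)), max(min(hi, n), 1))
    return mutseq


def enumerate_candidates(
    mutseq: MutantSequence, wildtype_protein: str, k: int = 9
) -> list[str]:
    """All k-mer windows overlapping the mutated residues, minus self-peptides.

    Windows identical to any k-mer of the wild-type protein are excluded
    (self peptides are not neoantigens); the remainder is deduplicated
    preserving order. Peptides shorter than k give an empty list.
    """
    if not 8 <= k <= 14:
        raise ValueError(f"k must be in [8, 14], got {k}")
    pep = mutseq.trimmed_peptide
    if len(pep) < k:
        return []
    a, b = mutseq.mutated_residue_span
    wt_kmers = {wildtype_protein[i:i + k] for i in range(len(wildtype_protein) - k + 1)}
    seen, out = set(), []
    for i in range(len(pep) - k + 1):
        if i + k <= a or i >= b:  # window misses the mutated span
            continue
        w = pep[i:i + k]
        if w in wt_kmers or w in seen:
            continue
        seen.add(w)
        out.append(w)
    return out


class Predictor(Protocol):
    allele: str

    def predict(self, peptides: Sequence[str]) -> list[float]: ...


_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
# Fixed minor position-weight table; drawn once so the surrogate is a constant.
_MINOR = np.random.default_rng(2697).random((14, len(_AA)))


class SurrogatePredictor:
    """Deterministic percent-rank surrogate with H2-Kb-like anchor preferences.

    Scores a peptide by anchor residues at positions 2 and k (aromatic at the
    second position, aliphatic at the C terminus, weight 4 each) plus small
    fixed per-position weights, then maps the score monotonically to a
    percent-rank scale via ``rank = 100 x exp(-0.8 x score)``. Two anchors
    guarantee a strong binder (rank < 0.5); no anchors guarantee a
    non-binder. Exists so enumeration and counting can be tested with known
    answers; it is not an affinity model.
    """

    allele = "H2-Kb"
    anchor2 = set("FY")
    anchor_c = set("LMIV")

    def score(self, peptide: str) -> float:
        s = 0.0
        if len(peptide) >= 2 and peptide[1] in self.anchor2:
            s += 4.0
        if peptide and peptide[-1] in self.anchor_c:
            s += 4.0
        minor = [
            _MINOR[i % 14][_AA_INDEX[aa]]
            for i, aa in enumerate(peptide)
            if i not in (1, len(peptide) - 1) and aa in _AA_INDEX
        ]
        if minor:
            s += 2.0 * float(np.mean(minor))
        return s

    def predict(self, peptides: Sequence[str]) -> list[float]:
        return [100.0 * float(np.exp(-0.8 * self.score(p))) for p in peptides]


class NetMHCpanPredictor:
    """Adapter shelling out to an external ``netMHCpan`` executable.

    Optional; nothing in the package requires it. Parses the percent-rank
    column of the tool's peptide-mode output.
    """

    def __init__(self, allele: str = "H2-Kb", executable: str = "netMHCpan"):
        self.allele = allele
        self.executable = executable

    def predict(self, peptides: Sequence[str]) -> list[float]:
        import subprocess, tempfile, os

        with tempfile.NamedTemporaryFile("w", suffix=".pep", delete=False) as fh:
            fh.write("\n".join(peptides) + "\n")
            path = fh.name
        try:
            res = subprocess.run(
                [self.executable, "-p", path, "-a", self.allele, "-BA"],
                capture_output=True, text=True, check=True,
            )
        finally:
            os.unlink(path)
        ranks: dict[str, float] = {}
        for line in res.stdout.splitlines():
            parts = line.split()
            if len(parts) > 12 and parts[0].isdigit():
                ranks[parts[2]] = float(parts[12])
        return [ranks[p] for p in peptides]


def binder_class(rank: float) -> str:
    if rank < STRONG_RANK:
        return "strong"
    if rank < WEAK_RANK:
        return "weak"
    return "non"


def classify_and_count(
    candidates_per_mutation: Mapping[str, Sequence[str]],
    predictor: Predictor,
    mutation_sample: Mapping[str, str],
    groups: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Score candidates and tally binder/neoantigen counts per sample.

    A mutation is neoantigenic iff at least one of its candidate peptides has
    percent rank below 2. Peptides the predictor fails on are excluded from
    counts and reported in the stats under ``n_predictor_failures``. When
    ``groups`` maps samples to cohort labels, Kruskal-Wallis H/p are computed
    for per-sample binder and neoantigenic-mutation counts.

    Returns (scored peptides, per-sample counts, group statistics).
    """
    scored_rows, failures = [], 0
    for mut_id, peps in candidates_per_mutation.items():
        peps = list(peps)
        if not peps:
            continue
        try:
            ranks = predictor.predict(peps)
        except Exception:
            ranks = []
            for p in peps:  # retry singly so one bad peptide doesn't sink the rest
                try:
                    ranks.append(predictor.predict([p])[0])
                except Exception:
                    ranks.append(None)
                    failures += 1
        for p, r in zip(peps, ranks):
            if r is None:
                continue
            scored_rows.append(
                {"mutation_id": mut_id, "sample_id": mutation_sample[mut_id],
                 "peptide": p, "rank": float(r), "binder_class": binder_class(r)}
            )
    scored = pd.DataFrame(
        scored_rows, columns=["mutation_id", "sample_id", "peptide", "rank",
                              "binder_class"]
    )

    samples = sorted(set(mutation_sample.values()))
    counts = pd.DataFrame(
        0, index=pd.Index(samples, name="sample_id"),
        columns=["strong_binders", "weak_binders", "neoantigenic_mutations",
                 "non_neoantigenic_mutations"],
    )
    neo_by_mut: dict[str, bool] = {m: False for m in candidates_per_mutation}
    if len(scored):
        for (sample, cls), n in scored.groupby(["sample_id", "binder_class"]).size().items():
            if cls == "strong":
                counts.loc[sample, "strong_binders"] = n
            elif cls == "weak":
                counts.loc[sample, "weak_binders"] = n
        best = scored.groupby("mutation_id")["rank"].min()
        for m, r in best.items():
            neo_by_mut[m] = r < WEAK_RANK
    for m, is_neo in neo_by_mut.items():
        col = "neoantigenic_mutations" if is_neo else "non_neoantigenic_mutations"
        counts.loc[mutation_sample[m], col] += 1
    counts = counts.reset_index()

    stats: dict = {"n_predictor_failures": failures}
    if groups:
        counts["group"] = counts["sample_id"].map(groups)
        counts["binders_total"] = counts["strong_binders"] + counts["weak_binders"]
        for col in ("binders_total", "neoantigenic_mutations"):
            h, p = kruskal_by_group(counts, col, "group")
            stats[f"kruskal_{col}"] = {"H": h, "p": p}
    return scored, counts, stats
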