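"""Clonotype assignment and round-to-round enrichment ranking.

Variants are grouped into clonotypes by exact CDR3 amino-acid identity (a
single fixed framework leaves no V-gene component to the key). Enrichment of
a clonotype between two selection rounds is the log2 ratio of its relative
frequencies with an additive pseudocount, and the enrichment workflow's
candidate list takes the top-scoring clonotypes' most abundant variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class Variant:
    """A full-length amino-acid variant with per-round read counts."""

    aa_sequence: str
    cdr3: str
    counts: dict[int, int] = field(default_factory=dict)

    def count(self, rnd: int) -> int:
        return self.counts.get(rnd, 0)


@dataclass
class Clonotype:
    clonotype_id: str
    key: str  # CDR3 amino-acid sequence
    members: list[Variant] = field(default_factory=list)

    def count(self, rnd: int) -> int:
        return sum(v.count(rnd) for v in self.members)

    @property
    def total_count(self) -> int:
        return sum(sum(v.counts.values()) for v in self.members)


@dataclass(frozen=True)
class Candidate:
    aa_sequence: str
    provenance: tuple[str, ...]
    clonotype_id: str | None = None
    probability: float | None = None


def assign_clonotypes(variants: Sequence[Variant]) -> tuple[list[Clonotype], int]:
    """Partition variants into clonotypes by exact CDR3 identity.

    Variants without a CDR3 are excluded; their number is returned as the
    second element. Clonotype ids are assigned in order of decreasing total
    count (ties: lexicographic key).
    """
    groups: dict[str, list[Variant]] = {}
    skipped = 0
    for v in variants:
        if not v.cdr3:
            skipped += 1
            continue
        groups.setdefault(v.cdr3, []).append(v)
    keyed = [Clonotype("", key, members) for key, members in groups.items()]
    keyed.sort(key=lambda ct: (-ct.total_count, ct.key))
    width = max(4, len(str(len(keyed))))
    for i, ct in enumerate(keyed):
        ct.clonotype_id = f"CT{str(i).zfill(width)}"
        ct.members.sort(key=lambda v: (-sum(v.counts.values()), v.aa_sequence))
    if skipped:
        warnings.warn(f"{skipped} variants lacked a CDR3 and were excluded")
    return keyed, skipped


def compute_frequencies(counts: Mapping[str, int]) -> dict[str, float]:
    """Normalize one round's counts to relative frequencies."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("round has no reads")
    return {k: c / total for k, c in counts.items()}


def compute_enrichment(freq_a: float, freq_b: float, pseudo_freq: float) -> float:
    """log2 frequency-ratio enrichment with additive pseudo-frequency.

    ``pseudo_freq`` is the pseudocount already divided by the round total;
    the same value on both sides keeps the score finite and antisymmetric
    under swapping rounds.
    """
    if pseudo_freq <= 0:
        raise ValueError("pseudo_freq must be positive")
    return float(np.log2((freq_b + pseudo_freq) / (freq_a + pseudo_freq)))


def build_enrichment_table(
    clonotypes: Sequence[Clonotype],
    round_a: int = 3,
    round_b: int = 4,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-clonotype frequencies in two rounds and the enrichment score.

    Frequencies are computed over *all* clonotypes (they sum to 1 in each
    round); the pseudo-frequency is ``pseudocount`` divided by the geometric
    mean of the two round totals, so the score stays antisymmetric.
    """
    total_a = sum(ct.count(round_a) for ct in clonotypes)
    total_b = sum(ct.count(round_b) for ct in clonotypes)
    if total_a <= 0 or total_b <= 0:
        raise ValueError("both rounds must have reads")
    pseudo = pseudocount / float(np.sqrt(total_a * total_b))
    rows = []
    for ct in clonotypes:
        fa = ct.count(round_a) / total_a
        fb = ct.count(round_b) / total_b
        rows.append({
            "clonotype_id": ct.clonotype_id,
            "key": ct.key,
            f"count_r{round_a}": ct.count(round_a),
            f"count_r{round_b}": ct.count(round_b),
            f"freq_r{round_a}": fa,
            f"freq_r{round_b}": fb,
            "enrichment_score": compute_enrichment(fa, fb, pseudo),
        })
    df = pd.DataFrame(rows)
    df.attrs["pseudo_freq"] = pseudo
    df.attrs["rounds"] = (round_a, round_b)
    return df


def select_enrichment_candidates(
    table: pd.DataFrame,
    clonotypes: Sequence[Clonotype],
    n_top_clonotypes: int = 20,
    variants_per_clonotype: int = 3,
    min_count_a: int = 10,
) -> list[Candidate]:
    """Top clonotypes by enrichment score, top variants within each.

    Clonotypes with fewer than ``min_count_a`` reads in the earlier round
    are not ranked (scores on a handful of reads are sampling noise).
    Ties: higher later-round frequency, then lexicographic key. Within a
    clonotype, up to ``variants_per_clonotype`` variants by later-round
    count descending (ties lexicographic).
    """
    if n_top_clonotypes < 1:
        raise ValueError("n_top_clonotypes must be >= 1")
    round_a, round_b = table.attrs.get("rounds", (3, 4))
    eligible = table[table[f"count_r{round_a}"] >= min_count_a]
    ranked = eligible.sort_values(
        by=["enrichment_score", f"freq_r{round_b}", "key"],
        ascending=[False, False, True],
        kind="mergesort",
    ).head(n_top_clonotypes)
    by_id = {ct.clonotype_id: ct for ct in clonotypes}
    out: list[Candidate] = []
    for ct_id in ranked["clonotype_id"]:
        ct = by_id[ct_id]
        members = sorted(ct.members,
                         key=lambda v: (-v.count(round_b), v.aa_sequence))
        for v in members[:variants_per_clonotype]:
            out.append(Candidate(aa_sequence=v.aa_sequence,
                                 provenance=("enrichment",),
                                 clonotype_id=ct_id))
    return out


def aggregate_candidates(*candidate_lists: Iterable[Candidate]) -> list[Candidate]:
    """Union candidate lists by exact amino-acid identity.

    Provenance labels are merged; output ordered by (first nomination order
    is discarded) lexicographic sequence for determinism.
    """
    merged: dict[str, Candidate] = {}
    for lst in candidate_lists:
        for cand in lst:
            if cand.aa_sequence in merged:
                prev = merged[cand.aa_sequence]
                prov = tuple(sorted(set(prev.provenance) | set(cand.provenance)))
                merged[cand.aa_sequence] = Candidate(
                    aa_sequence=cand.aa_sequence, provenance=prov,
                    clonotype_id=prev.clonotype_id or cand.clonotype_id,
                    probability=prev.probability if prev.probability is not None
                    else cand.probability)
            else:
                prov = tuple(sorted(set(cand.provenance)))
                merged[cand.aa_sequence] = Candidate(
                    aa_sequence=cand.aa_sequence, provenance=prov,
                    clonotype_id=cand.clonotype_id,
                    probability=cand.probability)
    return [merged[k] for k in sorted(merged)]


def campaign_variants(campaign, rounds: Sequence[int] = (3, 4)) -> list[Variant]:
    """Build per-variant round counts from a simulated campaign's truth.

    Convenience for simulation studies: uses the clones' known CDR3s and
    the recorded round counts (no read-level noise).
    """
    variants = []
    for clone in campaign.clones:
        counts = {r: campaign.round_counts[r].get(clone.clone_id, 0)
                  for r in rounds}
        variants.append(Variant(aa_sequence=clone.aa_sequence,
                                cdr3=clone.cdr3, counts=counts))
    return variants
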