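"""Simulated phage-display panning campaigns with known ground truth.

The generator emulates a fixed-framework synthetic VHH library panned against
an antigen over several rounds of selection with decreasing antigen
concentration and increasing wash stringency. Every downstream stage of the
pipeline (annotation, liability screening, enrichment ranking, ML triage) can
then be scored against the planted truth.

Model
-----
A clone's per-round selection weight is its current read count times a
Langmuir fractional occupancy plus a non-specific wash-survival term:

    w = n * [ C / (C + K_D) + r_wash ]

where C is the free antigen concentration (molar), K_D the clone's
dissociation constant and r_wash the probability of non-specific retention.
Next-round counts are a multinomial draw with probabilities w / sum(w).

Ground-truth coupling between sequence and binding: binder clones draw their
CDR3 from a dedicated pool whose members carry a fixed affinity motif
(mimicking convergent selection onto a paratope chemistry), so binder status
is recoverable from sequence — the property the ML triage workflows rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import liabilities as liab
from .repertoire import PHIS4_ANCHOR, VhhRecord, FrameworkScheme, translate_region

# One codon per amino acid, chosen to keep designed sequences clear of the
# default nucleotide liability registry at codon junctions (no GGT, CAG or
# GGCC/GAATTC-prone boundaries); assembled variants are still screened.
CODON = {
    "A": "GCA", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGA", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCA",
    "S": "TCA", "T": "ACA", "W": "TGG", "Y": "TAC", "V": "GTG",
}

# Humanized VHH scaffold: human DP-47-like FR1/FR3/FR4 with a camelid FR2
# hallmark region for stability as a heavy-chain-only domain.
FR1_AA = "EVQLVESGGGLVQPGGSLRLSCAAS"
FR2_AA = "WFRQAPGKEREFVA"
FR3_AA = "RFTISRDNAKNTVYLQMNSLRAEDTAVYYCAA"
FR4_AA = "WGQGTQVTVSS"

#: CDR alphabet used for random diversity. N, D and C are excluded up front
#: (the same residues the liability screen targets); H is reserved for the
#: binder affinity motif so that composition descriptors separate classes.
CDR_ALPHABET = "AEFGIKLMPQRSTVWY"

#: Affinity motif carried by every binder-pool CDR3.
BINDER_MOTIF = "HRHW"

#: Clones at or below this K_D (molar) are binders.
BINDER_KD_CUTOFF = 100e-9

_PLANTABLE_MOTIFS = [
    ("deamidation_NG", "aa", "NG"),
    ("isomerization_DG", "aa", "DG"),
    ("nglyc_sequon", "aa", "NAS"),
    ("unpaired_cysteine", "aa", "C"),
    # 15-nt codon-aligned block containing a SfiI site (GGCCNNNNNGGCC);
    # translates to RPKRP, no stops, no protein-level registry motifs.
    ("SfiI", "nt", "AGGCCAAAAAGGCCT"),
]


def translate_aa_to_nt(aa: str) -> str:
    return "".join(CODON[res] for res in aa)


@dataclass
class LibraryDesign:
    """Design of a combinatorial fixed-framework VHH library.

    ``cdr_pools`` holds nucleotide variants for CDR1/2/3; the CDR3 pool is
    the concatenation of a non-binder sub-pool and a binder sub-pool (the
    last ``n_binder_cdr3`` entries) whose members carry ``binder_motif``.
    """

    framework_regions: tuple[str, str, str, str]
    cdr_pools: tuple[list[str], list[str], list[str]]
    anchor: str = PHIS4_ANCHOR
    liability_fraction: float = 0.0
    seed: int = 0
    n_binder_cdr3: int = 0
    binder_motif: str = BINDER_MOTIF

    @property
    def binder_cdr3_aa(self) -> set[str]:
        pool = self.cdr_pools[2]
        if self.n_binder_cdr3 == 0:
            return set()
        return {translate_region(nt)[0] for nt in pool[-self.n_binder_cdr3 :]}

    def scheme(self) -> FrameworkScheme:
        return FrameworkScheme(*(translate_region(fr)[0]
                                 for fr in self.framework_regions))


@dataclass
class SimulatedClone:
    clone_id: str
    nt_sequence: str  # anchor + coding sequence
    aa_sequence: str
    regions: dict[str, tuple[int, int]]
    kd: float | None = None
    is_binder: bool | None = None
    planted_liabilities: list[str] = field(default_factory=list)
    anchor_len: int = len(PHIS4_ANCHOR)

    @property
    def cdr3(self) -> str:
        start, end = self.regions["CDR3"]
        return self.aa_sequence[start:end]

    def coding_sequence(self) -> str:
        return self.nt_sequence[self.anchor_len:]

    def to_record(self) -> VhhRecord:
        # the record carries the expressed cassette; the anchor is a
        # primer/identification region outside the cloned insert
        return VhhRecord(read_id=self.clone_id,
                         nt_sequence=self.coding_sequence(),
                         aa_sequence=self.aa_sequence, regions=dict(self.regions))


@dataclass
class PanningConfig:
    """Round structure of a campaign: strictly decreasing antigen
    concentration (molar) and non-specific wash retention per round."""

    n_rounds: int = 4
    antigen_conc: Sequence[float] = (100e-9, 50e-9, 25e-9, 10e-9)
    wash_stringency: Sequence[float] = (1e-2, 2.154434690031884e-3,
                                        4.641588833612779e-4, 1e-4)
    reads_per_round: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if len(self.antigen_conc) != self.n_rounds:
            raise ValueError("antigen_conc length must equal n_rounds")
        if len(self.wash_stringency) != self.n_rounds:
            raise ValueError("wash_stringency length must equal n_rounds")
        if any(b >= a for a, b in zip(self.antigen_conc, self.antigen_conc[1:])):
            raise ValueError("antigen_conc must be strictly decreasing")
        if any(b >= a for a, b in
               zip(self.wash_stringency, self.wash_stringency[1:])):
            raise ValueError("wash_stringency must be strictly decreasing")


@dataclass
class PanningCampaign:
    """A simulated campaign: library + per-round counts + ground truth.

    ``round_counts[0]`` is the pre-selection (input) library sample;
    ``round_counts[r]`` for r >= 1 is the output of selection round r.
    """

    design: LibraryDesign
    clones: list[SimulatedClone]
    round_counts: list[dict[str, int]] = field(default_factory=list)

    @property
    def clone_map(self) -> dict[str, SimulatedClone]:
        return {c.clone_id: c for c in self.clones}

    def truth(self) -> dict:
        return {
            c.clone_id: {
                "kd": c.kd,
                "is_binder": c.is_binder,
                "planted_liabilities": list(c.planted_liabilities),
                "cdr3": c.cdr3,
            }
            for c in self.clones
        }

    def truth_json(self) -> str:
        return json.dumps(self.truth(), sort_keys=True)


class DegenerateRoundError(RuntimeError):
    pass


def _random_cdr_aa(rng: np.random.Generator, length: int,
                   alphabet: str = CDR_ALPHABET) -> str:
    letters = np.array(list(alphabet))
    return "".join(rng.choice(letters, size=length))


def _clean_variant(rng: np.random.Generator, length: int, registry,
                   flank_aa: tuple[str, str], motif: str | None = None,
                   max_tries: int = 200) -> str:
    """Draw a CDR amino-acid variant free of registry liabilities in context.

    The candidate is screened embedded between its flanking frameworks, at
    both protein and nucleotide level, and redrawn on any finding — the same
    screen a library designer applies to candidate diversity.
    """
    left, right = flank_aa
    for _ in range(max_tries):
        aa = _random_cdr_aa(rng, length)
        if motif is not None:
            pos = int(rng.integers(0, length - len(motif) + 1))
            aa = aa[:pos] + motif + aa[pos + len(motif) :]
        context_aa = left + aa + right
        if liab.scan_sequence(context_aa, registry, "protein"):
            continue
        context_nt = translate_aa_to_nt(context_aa)
        if liab.scan_sequence(context_nt, registry, "nucleotide"):
            continue
        return aa
    raise RuntimeError("could not draw a liability-free CDR variant")


def default_library_design(
    seed: int = 0,
    n_cdr1: int = 24,
    n_cdr2: int = 24,
    n_cdr3: int = 120,
    binder_cdr3_fraction: float = 0.1,
    cdr1_len: int = 8,
    cdr2_len: int = 8,
    cdr3_len_range: tuple[int, int] = (12, 16),
    liability_fraction: float = 0.0,
) -> LibraryDesign:
    """Build a screened combinatorial design.

    Pool members are drawn from :data:`CDR_ALPHABET` and rejected if, in
    their framework context, they match any default liability motif. A
    ``binder_cdr3_fraction`` share of the CDR3 pool carries the affinity
    motif; a clone is a true binder iff its CDR3 comes from that sub-pool.
    """
    rng = np.random.default_rng(seed)
    registry = liab.default_registry()
    frs_aa = (FR1_AA, FR2_AA, FR3_AA, FR4_AA)
    flanks = [(FR1_AA[-8:], FR2_AA[:8]), (FR2_AA[-8:], FR3_AA[:8]),
              (FR3_AA[-8:], FR4_AA[:8])]

    def pool(n: int, lengths, flank, motif=None) -> list[str]:
        seen: set[str] = set()
        out: list[str] = []
        while len(out) < n:
            length = int(rng.choice(lengths))
            aa = _clean_variant(rng, length, registry, flank, motif)
            if aa in seen:
                continue
            seen.add(aa)
            out.append(translate_aa_to_nt(aa))
        return out

    cdr1 = pool(n_cdr1, [cdr1_len], flanks[0])
    cdr2 = pool(n_cdr2, [cdr2_len], flanks[1])
    lens3 = list(range(cdr3_len_range[0], cdr3_len_range[1] + 1))
    n_binder = int(round(n_cdr3 * binder_cdr3_fraction))
    cdr3_nonbind = pool(n_cdr3 - n_binder, lens3, flanks[2])
    cdr3_bind = pool(n_binder, lens3, flanks[2], motif=BINDER_MOTIF)
    return LibraryDesign(
        framework_regions=tuple(translate_aa_to_nt(fr) for fr in frs_aa),
        cdr_pools=(cdr1, cdr2, cdr3_nonbind + cdr3_bind),
        liability_fraction=liability_fraction,
        seed=seed,
        n_binder_cdr3=n_binder,
    )


def _assemble(design: LibraryDesign, idx: tuple[int, int, int],
              clone_id: str) -> SimulatedClone:
    fr_nt = design.framework_regions
    cdr_nt = [design.cdr_pools[k][idx[k]] for k in range(3)]
    coding = (fr_nt[0] + cdr_nt[0] + fr_nt[1] + cdr_nt[1] + fr_nt[2]
              + cdr_nt[2] + fr_nt[3])
    aa, flags = translate_region(coding)
    if "internal-stop" in flags:
        raise RuntimeError("designed clone translates with an internal stop")
    lengths = [len(translate_region(s)[0]) for s in
               (fr_nt[0], cdr_nt[0], fr_nt[1], cdr_nt[1], fr_nt[2],
                cdr_nt[2], fr_nt[3])]
    names = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
    regions: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, ln in zip(names, lengths):
        regions[name] = (pos, pos + ln)
        pos += ln
    return SimulatedClone(clone_id=clone_id,
                          nt_sequence=design.anchor + coding,
                          aa_sequence=aa, regions=regions,
                          anchor_len=len(design.anchor))


def _plant_liability(clone: SimulatedClone, design: LibraryDesign,
                     rng: np.random.Generator) -> None:
    """Overwrite the start of CDR2 with one liability motif (in frame)."""
    label, level, payload = _PLANTABLE_MOTIFS[int(rng.integers(0, len(_PLANTABLE_MOTIFS)))]
    start, end = clone.regions["CDR2"]
    anchor_len = len(design.anchor)
    if level == "aa":
        aa_new = payload
        nt_new = translate_aa_to_nt(payload)
    else:
        nt_new = payload
        aa_new = translate_region(payload)[0]
    n_res = len(aa_new)
    assert end - start >= n_res
    aa = clone.aa_sequence
    clone.aa_sequence = aa[:start] + aa_new + aa[start + n_res :]
    nt_start = anchor_len + 3 * start
    nt = clone.nt_sequence
    clone.nt_sequence = nt[:nt_start] + nt_new + nt[nt_start + len(nt_new) :]
    clone.planted_liabilities.append(label)


def generate_library(design: LibraryDesign, n_clones: int) -> PanningCampaign:
    """Sample ``n_clones`` unique combinatorial clones from the design.

    About ``design.liability_fraction`` of clones get exactly one liability
    motif planted inside CDR2 (recorded as ground truth). Deterministic
    given ``design.seed``.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    pools = design.cdr_pools
    if any(len(p) == 0 for p in pools):
        raise ValueError("all CDR pools must be non-empty")
    capacity = len(pools[0]) * len(pools[1]) * len(pools[2])
    if n_clones > capacity:
        raise ValueError(f"n_clones={n_clones} exceeds pool capacity {capacity}")
    rng = np.random.default_rng(design.seed)
    combos = rng.choice(capacity, size=n_clones, replace=False)
    width = len(str(n_clones - 1))
    clones: list[SimulatedClone] = []
    for i, flat in enumerate(sorted(int(c) for c in combos)):
        i1, rem = divmod(flat, len(pools[1]) * len(pools[2]))
        i2, i3 = divmod(rem, len(pools[2]))
        clone = _assemble(design, (i1, i2, i3), f"clone{str(i).zfill(width)}")
        if design.liability_fraction > 0 and rng.random() < design.liability_fraction:
            _plant_liability(clone, design, rng)
        clones.append(clone)
    return PanningCampaign(design=design, clones=clones)


def assign_affinities(
    campaign: PanningCampaign,
    binder_fraction: float = 0.1,
    kd_binder_range: tuple[float, float] = (1e-10, 1e-8),
    kd_nonbinder_range: tuple[float, float] = (1e-6, 1e-4),
    seed: int = 0,
    by_motif: bool = True,
) -> PanningCampaign:
    """Draw per-clone dissociation constants and set binder labels.

    K_D is log-uniform within the class range (classes must not overlap;
    the binder range lies strictly below). With ``by_motif`` (default) the
    class is the ground-truth designation — CDR3 from the binder sub-pool —
    so labels are sequence-recoverable; otherwise classes are i.i.d.
    Bernoulli(``binder_fraction``).
    """
    lo_b, hi_b = kd_binder_range
    lo_n, hi_n = kd_nonbinder_range
    if not (0 < lo_b < hi_b and 0 < lo_n < hi_n):
        raise ValueError("K_D ranges must be positive and increasing")
    if hi_b >= lo_n:
        raise ValueError("binder K_D range must lie strictly below the "
                         "non-binder range")
    rng = np.random.default_rng(seed)
    binder_keys = campaign.design.binder_cdr3_aa
    for clone in campaign.clones:
        if by_motif and binder_keys:
            is_binder = clone.cdr3 in binder_keys
        else:
            is_binder = bool(rng.random() < binder_fraction)
        lo, hi = (lo_b, hi_b) if is_binder else (lo_n, hi_n)
        clone.kd = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        clone.is_binder = is_binder
    return campaign


def selection_weights(counts: np.ndarray, kds: np.ndarray,
                      antigen_conc: float, wash_retention: float) -> np.ndarray:
    """Langmuir occupancy + non-specific retention, scaled by abundance."""
    if antigen_conc <= 0:
        raise ValueError("antigen_conc must be positive")
    if not (0 < wash_retention <= 1):
        raise ValueError("wash_retention must be in (0, 1]")
    occupancy = antigen_conc / (antigen_conc + kds)
    return counts * (occupancy + wash_retention)


def simulate_round(
    counts: dict[str, int],
    clones: dict[str, SimulatedClone],
    antigen_conc: float,
    wash_retention: float,
    reads_out: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """One round of selection: multinomial draw over selection weights."""
    ids = sorted(counts)
    n = np.array([counts[i] for i in ids], dtype=float)
    kds = np.array([clones[i].kd for i in ids], dtype=float)
    w = selection_weights(n, kds, antigen_conc, wash_retention)
    total = w.sum()
    if total <= 0:
        raise DegenerateRoundError("all selection weights are zero")
    drawn = rng.multinomial(reads_out, w / total)
    return {i: int(c) for i, c in zip(ids, drawn)}


def run_panning(campaign: PanningCampaign, config: PanningConfig) -> PanningCampaign:
    """Run the full round structure, filling ``campaign.round_counts``.

    Round 0 is a uniform multinomial sample of the input library; rounds
    1..n are successive selections. Deterministic given ``config.seed``.
    """
    if any(c.kd is None for c in campaign.clones):
        raise ValueError("assign_affinities must be called before panning")
    rng = np.random.default_rng(config.seed)
    ids = [c.clone_id for c in campaign.clones]
    p0 = np.full(len(ids), 1.0 / len(ids))
    r0 = rng.multinomial(config.reads_per_round, p0)
    campaign.round_counts = [{i: int(c) for i, c in zip(ids, r0)}]
    clone_map = campaign.clone_map
    for r in range(config.n_rounds):
        nxt = simulate_round(campaign.round_counts[-1], clone_map,
                             config.antigen_conc[r], config.wash_stringency[r],
                             config.reads_per_round, rng)
        campaign.round_counts.append(nxt)
    return campaign


def simulate_campaign(
    n_clones: int = 2000,
    seed: int = 0,
    design: LibraryDesign | None = None,
    config: PanningConfig | None = None,
    liability_fraction: float = 0.0,
    **affinity_kwargs,
) -> PanningCampaign:
    """Convenience: design -> library -> affinities -> panning in one call.

    All randomness derives from ``seed`` (design, assembly, affinities and
    selection get distinct sub-seeds).
    """
    ss = np.random.SeedSequence(seed).generate_state(4)
    if design is None:
        design = default_library_design(seed=int(ss[0]) % (2**31),
                                        liability_fraction=liability_fraction)
    if config is None:
        config = PanningConfig(seed=int(ss[1]) % (2**31))
    campaign = generate_library(design, n_clones)
    assign_affinities(campaign, seed=int(ss[2]) % (2**31), **affinity_kwargs)
    run_panning(campaign, config)
    return campaign


_QUAL = "I"  # constant Phred+33 quality (Q40)
_BASES = np.array(list("ACGT"))


def emit_fastq(
    campaign: PanningCampaign,
    round_index: int,
    path,
    error_rate: float = 0.0,
    spike_in_fraction: float = 0.0,
    seed: int = 0,
) -> int:
    """Write one round's reads as FASTQ (Sanger Phred+33).

    One read per sampled clone copy; per-base substitution errors at
    ``error_rate``; read ids encode the clone id for truth tracking. A
    ``spike_in_fraction`` of additional anchor-less random reads emulates a
    sequencing-diversity spike-in (they carry no anchor and are discarded by
    the repertoire stage). Returns the number of reads written.
    """
    if round_index >= len(campaign.round_counts):
        raise IndexError(f"round {round_index} has not been simulated")
    rng = np.random.default_rng(seed)
    counts = campaign.round_counts[round_index]
    clone_map = campaign.clone_map
    n_written = 0
    with open(path, "w") as fh:
        for clone_id in sorted(counts):
            seq = clone_map[clone_id].nt_sequence
            for copy in range(counts[clone_id]):
                read = seq
                if error_rate > 0:
                    arr = np.frombuffer(read.encode(), dtype="S1").astype("U1")
                    hit = rng.random(arr.size) < error_rate
                    if hit.any():
                        arr = arr.copy()
                        # substitute with a uniformly different base
                        for pos in np.flatnonzero(hit):
                            choices = [b for b in "ACGT" if b != arr[pos]]
                            arr[pos] = choices[int(rng.integers(0, 3))]
                        read = "".join(arr)
                fh.write(f"@{clone_id}|copy{copy}\n{read}\n+\n{_QUAL * len(read)}\n")
                n_written += 1
        n_spike = int(round(spike_in_fraction * n_written))
        read_len = len(campaign.clones[0].nt_sequence)
        for j in range(n_spike):
            junk = "".join(rng.choice(_BASES, size=read_len))
            fh.write(f"@spikein{j}\n{junk}\n+\n{_QUAL * read_len}\n")
            n_written += 1
    return n_written
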