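"""Read processing for VHH amplicons: anchor location, translation, framework
annotation, ELISA hit calling and dereplication.

A VHH amplicon read carries a constant upstream anchor (the sequencing/ID
primer) followed by the VHH coding sequence: FR1-CDR1-FR2-CDR2-FR3-CDR3-FR4.
Frameworks are (near-)constant in a synthetic fixed-framework library, so CDRs
are recovered as the gaps between located frameworks. All coordinates are
0-based, half-open.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from Bio.Seq import Seq

#: Constant upstream anchor used to locate the VHH coding region in a read.
PHIS4_ANCHOR = "GCGGATAACAATTTGAATTCAAGGAGACAG"

REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


class AnchorHit(NamedTuple):
    """Location of the anchor in a read.

    ``offset`` is the 0-based position of the first base *after* the anchor,
    on the reported ``strand`` ("+" = read as given, "-" = reverse
    complement of the read).
    """

    offset: int
    strand: str


@dataclass
class VhhRecord:
    """One annotated VHH sequence.

    ``regions`` maps region name -> (start, end) half-open amino-acid
    coordinates on ``aa_sequence``. When annotation succeeds the seven
    regions tile the sequence contiguously in order.
    """

    read_id: str
    nt_sequence: str
    aa_sequence: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    qc_flags: list[str] = field(default_factory=list)

    @property
    def annotated(self) -> bool:
        return len(self.regions) == len(REGION_NAMES)

    def region_seq(self, name: str) -> str:
        start, end = self.regions[name]
        return self.aa_sequence[start:end]

    @property
    def cdr3(self) -> str | None:
        if "CDR3" not in self.regions:
            return None
        return self.region_seq("CDR3")


@dataclass(frozen=True)
class ElisaWell:
    clone_id: str
    signal: float
    background: float


@dataclass(frozen=True)
class FrameworkScheme:
    """Amino-acid framework sequences used to annotate reads."""

    fr1: str
    fr2: str
    fr3: str
    fr4: str

    @property
    def frameworks(self) -> tuple[str, str, str, str]:
        return (self.fr1, self.fr2, self.fr3, self.fr4)


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def locate_vhh(read: str, anchor: str = PHIS4_ANCHOR) -> AnchorHit | None:
    """Find the anchor on either strand and return the payload start offset.

    The forward strand is searched first; on a reverse-strand hit the offset
    refers to coordinates on the reverse complement of the read. Returns
    ``None`` when the anchor occurs on neither strand.
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    read = read.upper()
    pos = read.find(anchor)
    if pos != -1:
        return AnchorHit(pos + len(anchor), "+")
    rc = reverse_complement(read)
    pos = rc.find(anchor)
    if pos != -1:
        return AnchorHit(pos + len(anchor), "-")
    return None


def extract_vhh(read: str, anchor: str = PHIS4_ANCHOR) -> str | None:
    """Return the nucleotide payload downstream of the anchor, or ``None``."""
    hit = locate_vhh(read, anchor)
    if hit is None:
        return None
    seq = read.upper() if hit.strand == "+" else reverse_complement(read.upper())
    return seq[hit.offset :]


def translate_region(nt: str) -> tuple[str, list[str]]:
    """Frame-0 standard-code translation with QC flags.

    Trailing bases that do not complete a codon are dropped and flagged.
    Codons containing a non-ACGT base translate to ``X`` and are flagged.
    Internal (or terminal) stop codons appear as ``*`` and are flagged.
    """
    flags: list[str] = []
    nt = nt.upper()
    remainder = len(nt) % 3
    if remainder:
        flags.append("frame-remainder")
        nt = nt[: len(nt) - remainder]
    if any(base not in "ACGT" for base in nt):
        flags.append("ambiguous-base")
    aa = str(Seq(nt).translate()) if nt else ""
    if "*" in aa:
        flags.append("internal-stop")
    return aa, flags


def _fuzzy_find(haystack: str, needle: str, start: int, max_mismatch: int) -> int | str:
    """Locate ``needle`` in ``haystack[start:]`` allowing substitutions.

    Exact match wins; otherwise the unique minimal-Hamming window within
    ``max_mismatch`` is returned. Returns "missing" or "ambiguous" sentinels.
    """
    pos = haystack.find(needle, start)
    if pos != -1:
        return pos
    n = len(needle)
    best: list[int] = []
    best_mm = max_mismatch + 1
    for i in range(start, len(haystack) - n + 1):
        mm = 0
        window = haystack[i : i + n]
        for a, b in zip(window, needle):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm > max_mismatch:
            continue
        if mm < best_mm:
            best_mm = mm
            best = [i]
        elif mm == best_mm:
            best.append(i)
    if best_mm > max_mismatch:
        return "missing"
    if len(best) > 1:
        return "ambiguous"
    return best[0]


def annotate_regions(
    aa: str, scheme: FrameworkScheme, max_mismatch: int = 2
) -> tuple[dict[str, tuple[int, int]], list[str]]:
    """Annotate FR/CDR regions on a VHH amino-acid sequence.

    The four frameworks are located left to right (exact match first, then a
    unique <= ``max_mismatch``-substitution match). CDRs are the gaps between
    consecutive frameworks and must be non-empty; FR1 must start the sequence
    and FR4 must end it so that regions tile the sequence. On any failure an
    empty region map is returned together with a diagnostic flag.
    """
    frameworks = scheme.frameworks
    positions: list[tuple[int, int]] = []
    cursor = 0
    for idx, fr in enumerate(frameworks):
        res = _fuzzy_find(aa, fr, cursor, max_mismatch)
        if res == "missing":
            return {}, [f"annotation-failed:FR{idx + 1}-missing"]
        if res == "ambiguous":
            return {}, [f"annotation-failed:FR{idx + 1}-ambiguous"]
        start = int(res)
        positions.append((start, start + len(fr)))
        cursor = start + len(fr)
    if positions[0][0] != 0:
        return {}, ["annotation-failed:leading-sequence-before-FR1"]
    if positions[-1][1] != len(aa):
        return {}, ["annotation-failed:trailing-sequence-after-FR4"]
    regions: dict[str, tuple[int, int]] = {}
    for i, (start, end) in enumerate(positions):
        regions[f"FR{i + 1}"] = (start, end)
        if i < 3:
            gap = (end, positions[i + 1][0])
            if gap[1] <= gap[0]:
                return {}, [f"annotation-failed:CDR{i + 1}-empty"]
            regions[f"CDR{i + 1}"] = gap
    return regions, []


def annotate_read(
    read_id: str,
    read: str,
    scheme: FrameworkScheme,
    anchor: str = PHIS4_ANCHOR,
) -> VhhRecord | None:
    """Anchor-locate, translate and annotate one read.

    Returns ``None`` when the anchor is absent (the read is not a VHH
    amplicon); otherwise always returns a record, flagged on QC failure.
    """
    payload = extract_vhh(read, anchor)
    if payload is None:
        return None
    aa, flags = translate_region(payload)
    regions: dict[str, tuple[int, int]] = {}
    if "internal-stop" not in flags:
        regions, ann_flags = annotate_regions(aa, scheme)
        flags = flags + ann_flags
    else:
        flags = flags + ["annotation-skipped:internal-stop"]
    return VhhRecord(read_id=read_id, nt_sequence=payload, aa_sequence=aa,
                     regions=regions, qc_flags=flags)


def process_reads(
    reads: Iterable[tuple[str, str]],
    scheme: FrameworkScheme,
    anchor: str = PHIS4_ANCHOR,
) -> tuple[list[VhhRecord], dict[str, int]]:
    """Process ``(read_id, sequence)`` pairs into annotated records.

    Returns the records (annotated and flagged alike) plus an accounting
    dict; ``annotated + flagged + anchorless == total`` always holds.
    """
    records: list[VhhRecord] = []
    counts = {"total": 0, "annotated": 0, "flagged": 0, "anchorless": 0}
    for read_id, seq in reads:
        counts["total"] += 1
        rec = annotate_read(read_id, seq, scheme, anchor)
        if rec is None:
            counts["anchorless"] += 1
            continue
        records.append(rec)
        if rec.annotated and not rec.qc_flags:
            counts["annotated"] += 1
        else:
            counts["flagged"] += 1
    return records, counts


def read_fastq(path) -> list[tuple[str, str]]:
    """Load (id, sequence) pairs from a FASTQ file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def call_elisa_hits(
    wells: Sequence[ElisaWell], fold: float = 3.0, background_floor: float = 0.05
) -> set[str]:
    """Call screening hits: signal / max(background, floor) >= fold.

    The at-least-``fold``-over-background rule is inclusive at the boundary.
    The floor guards against division blow-up on blank background wells.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    hits: set[str] = set()
    for well in wells:
        if well.signal < 0 or well.background < 0:
            raise ValueError(f"negative absorbance for clone {well.clone_id}")
        if well.signal / max(well.background, background_floor) >= fold:
            hits.add(well.clone_id)
    return hits


def dereplicate(sequences: Iterable[str]) -> list[tuple[str, int]]:
    """Collapse to unique sequences with counts.

    Ordered by count descending, ties broken lexicographically.
    """
    counts = Counter(sequences)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def record_to_dict(rec: VhhRecord) -> dict:
    d = dataclasses.asdict(rec)
    d["regions"] = {k: list(v) for k, v in rec.regions.items()}
    return d
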