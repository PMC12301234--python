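"""Sequence-liability screening for manufacturability.

Synthetic antibody library design screens candidate CDR diversity against
motifs associated with manufacturing problems: post-translational-modification
hotspots (deamidation, isomerization, N-glycosylation sequons, unpaired
cysteines), cryptic splice sites, and restriction-enzyme recognition sites
used during cloning. This module provides a motif registry, overlap-complete
scanning of protein and nucleotide sequences, and a library filter with a
category-based disqualification policy.

Protein patterns are Python regular expressions over the 20-letter amino-acid
alphabet; nucleotide patterns use IUPAC wildcards (N, Y, R, ...). Matches are
reported for every position, including overlapping occurrences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .repertoire import VhhRecord

_IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


class ScanScopeError(ValueError):
    """Raised when CDR-restricted scanning is requested on an unannotated record."""


@dataclass(frozen=True)
class LiabilityMotif:
    """One liability pattern.

    ``level`` selects the alphabet ("protein" or "nucleotide"); ``category``
    is one of "ptm", "splice", "restriction". ``advisory`` motifs are
    reported but never disqualify a clone (e.g. the N-terminal pyroglutamate
    precursor, which affects assay readout, not manufacturability).
    """

    label: str
    level: str
    pattern: str
    category: str
    advisory: bool = False

    def regex(self) -> re.Pattern:
        if self.level == "nucleotide":
            body = "".join(_IUPAC_NT.get(ch, re.escape(ch)) for ch in self.pattern)
        else:
            body = self.pattern
        # lookahead makes overlapping matches visible
        return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class Finding:
    label: str
    category: str
    level: str
    start: int
    end: int
    region: str | None = None
    advisory: bool = False


@dataclass
class LiabilityReport:
    clone_id: str
    findings: list[Finding] = field(default_factory=list)

    def disqualifying(self, policy: Iterable[str]) -> list[Finding]:
        cats = set(policy)
        return [f for f in self.findings if f.category in cats and not f.advisory]


def default_registry() -> list[LiabilityMotif]:
    """The default developability motif set.

    PTM motifs follow the standard antibody-engineering set: deamidation
    (NG/NS/NT), aspartate isomerization (DG/DS/DT), N-glycosylation sequon
    N-X-S/T with X != P, and cysteine in CDR loops (scanned separately as an
    unpaired-cysteine rule). Splice motifs are the literal donor consensus
    and a polypyrimidine-tract acceptor. Restriction sites cover the cloning
    enzyme SfiI plus EcoRI and NotI.
    """
    return [
        LiabilityMotif("deamidation_NG", "protein", "NG", "ptm"),
        LiabilityMotif("deamidation_NS", "protein", "NS", "ptm"),
        LiabilityMotif("deamidation_NT", "protein", "NT", "ptm"),
        LiabilityMotif("isomerization_DG", "protein", "DG", "ptm"),
        LiabilityMotif("isomerization_DS", "protein", "DS", "ptm"),
        LiabilityMotif("isomerization_DT", "protein", "DT", "ptm"),
        LiabilityMotif("nglyc_sequon", "protein", "N[^P][ST]", "ptm"),
        LiabilityMotif("splice_donor_GGTAAG", "nucleotide", "GGTAAG", "splice"),
        LiabilityMotif("splice_donor_GGTGAG", "nucleotide", "GGTGAG", "splice"),
        LiabilityMotif("splice_acceptor", "nucleotide", "YYYYYYNCAG", "splice"),
        LiabilityMotif("SfiI", "nucleotide", "GGCCNNNNNGGCC", "restriction"),
        LiabilityMotif("EcoRI", "nucleotide", "GAATTC", "restriction"),
        LiabilityMotif("NotI", "nucleotide", "GCGGCCGC", "restriction"),
    ]


#: Categories that disqualify a clone under the default filtering policy.
DEFAULT_POLICY = frozenset({"ptm", "splice", "restriction"})


def load_registry(path) -> list[LiabilityMotif]:
    """Load a motif registry from YAML (list of label/level/pattern/category)."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [LiabilityMotif(**e) for e in entries]


def scan_sequence(seq: str, motifs: Sequence[LiabilityMotif], level: str,
                  offset: int = 0, region: str | None = None) -> list[Finding]:
    """Scan one sequence with all motifs of the given level.

    ``offset`` shifts reported coordinates into a parent sequence frame.
    """
    findings: list[Finding] = []
    for motif in motifs:
        if motif.level != level:
            continue
        for m in motif.regex().finditer(seq):
            start, matched = m.start(), m.group(1)
            findings.append(Finding(motif.label, motif.category, motif.level,
                                    offset + start, offset + start + len(matched),
                                    region, motif.advisory))
    return findings


def _unpaired_cysteines(aa: str, intervals: list[tuple[int, int, str]]) -> list[Finding]:
    """Flag cysteines in CDRs when they cannot pair among themselves.

    An odd total cysteine count across the scanned CDR intervals leaves at
    least one unpaired thiol; every CDR cysteine is then reported.
    """
    positions = []
    for start, end, name in intervals:
        for i in range(start, end):
            if aa[i] == "C":
                positions.append((i, name))
    if len(positions) % 2 == 0:
        return []
    return [Finding("unpaired_cysteine", "ptm", "protein", i, i + 1, name)
            for i, name in positions]


def scan_liabilities(
    record: VhhRecord,
    registry: Sequence[LiabilityMotif] | None = None,
    cdr_only: bool = True,
) -> LiabilityReport:
    """Scan one annotated record for liability motifs.

    Protein motifs are scanned on the amino-acid sequence — restricted to
    CDR intervals when ``cdr_only`` — while nucleotide motifs are always
    scanned on the full nucleotide sequence (a restriction or splice site is
    a problem wherever it sits). The N-terminal pyroglutamate precursor
    (E/Q at position 1) is reported as an advisory finding.
    """
    if registry is None:
        registry = default_registry()
    if not registry:
        raise ValueError("registry must be non-empty")
    findings: list[Finding] = []
    aa = record.aa_sequence
    if cdr_only:
        if not record.annotated:
            raise ScanScopeError(
                f"record {record.read_id} is unannotated; cdr_only scanning "
                "requires CDR intervals"
            )
        intervals = [(record.regions[n][0], record.regions[n][1], n)
                     for n in ("CDR1", "CDR2", "CDR3")]
        for start, end, name in intervals:
            findings += scan_sequence(aa[start:end], registry, "protein",
                                      offset=start, region=name)
        findings += _unpaired_cysteines(aa, intervals)
    else:
        findings += scan_sequence(aa, registry, "protein")
    if aa and aa[0] in "EQ":
        findings.append(Finding("pyroglutamate_precursor", "ptm", "protein",
                                0, 1, "FR1" if record.annotated else None,
                                advisory=True))
    findings += scan_sequence(record.nt_sequence, registry, "nucleotide")
    findings.sort(key=lambda f: (f.start, f.label))
    return LiabilityReport(clone_id=record.read_id, findings=findings)


@dataclass
class FilterResult:
    kept: list[VhhRecord]
    removed: list[VhhRecord]
    reports: dict[str, LiabilityReport]


def filter_library(
    records: Sequence[VhhRecord],
    registry: Sequence[LiabilityMotif] | None = None,
    policy: Iterable[str] = DEFAULT_POLICY,
    cdr_only: bool = True,
) -> FilterResult:
    """Partition records into kept/removed by liability findings.

    A record is removed iff it has at least one non-advisory finding in a
    disqualifying category. ``kept`` and ``removed`` partition the input.
    """
    policy = set(policy)
    kept: list[VhhRecord] = []
    removed: list[VhhRecord] = []
    reports: dict[str, LiabilityReport] = {}
    for rec in records:
        report = scan_liabilities(rec, registry, cdr_only=cdr_only)
        reports[rec.read_id] = report
        if report.disqualifying(policy):
            removed.append(rec)
        else:
            kept.append(rec)
    return FilterResult(kept=kept, removed=removed, reports=reports)
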