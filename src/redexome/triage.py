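"""Automated triage of predicted repeat expansions.

Short-read expansion calls need a quality review before any wet-lab
follow-up: the supporting read evidence is inspected together with the
sequencing read length, because when the pathogenic cutoff of a locus is
longer than the read length, normal and expanded alleles cannot be
cleanly distinguished. This module automates that review as a
deterministic rule engine. Each predicted expansion is classified as:

* ``pass`` — the read length exceeds the pathogenic cutoff (in bp) and
  the expanded genotype is supported by at least two high-quality reads,
  or by a large number (more than 10) of reads reaching the maximum
  measurable expansion (full-read-length in-repeat reads of pure motif);
* ``borderline`` — exactly one high-quality supporting read at a
  cutoff-shorter-than-read-length locus, or two or more high-quality
  supporting reads when the read length is shorter than the cutoff;
* ``fail`` — anything that meets neither rule;
* ``discard_interruption`` — at loci with catalogued interruption motifs
  (the CAT-in-CAG case of ATXN1), an interruption observed on a read
  supporting the expanded allele overrides everything: interrupted tracts
  are non-pathogenic and the call is discarded.

"Longer than the cutoff" is read strictly (``read_length > cutoff_bp``);
equality falls to the shorter-read branch. "More than 10" is strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .catalogue import RepeatLocus, classify_allele, cutoff_bp_of
from .errors import EvidenceError
from .caller import RepeatCall
from .simulate import ReadEvidence, SimRead

__all__ = [
    "TriageVerdict",
    "count_support",
    "detect_interruptions",
    "triage_call",
    "is_predicted_expanded",
    "CATEGORIES",
]

Category = Literal["pass", "borderline", "fail", "discard_interruption"]
CATEGORIES: tuple[str, ...] = ("pass", "borderline", "fail", "discard_interruption")


@dataclass(frozen=True)
class TriageVerdict:
    """Outcome of triaging one predicted expansion.

    The category is a pure function of the recorded rule inputs
    (``n_hq_support``, ``n_max_reads``, ``read_len_exceeds_cutoff``,
    ``interruption_found``), so verdicts are fully auditable.
    """

    sample_id: str
    gene: str
    category: Category
    n_hq_support: int
    n_max_reads: int
    read_len_exceeds_cutoff: bool
    interruption_found: bool


def is_predicted_expanded(call: RepeatCall, locus: RepeatLocus) -> bool:
    """Does the call predict at least one expanded allele?

    Lower-bound long alleles count: a ``>N`` with N at or beyond the
    cutoff is a predicted expansion.
    """
    if call.is_no_call:
        return False
    for allele in (call.allele_short, call.allele_long):
        if allele is None:
            continue
        if classify_allele(locus, allele) == "expanded":
            return True
    return False


def _supports_expanded(read: SimRead, call: RepeatCall) -> bool:
    """Is a read's evidence consistent with the call's expanded (long) allele?

    Spanning reads must agree with the exact long allele within the
    caller's one-unit cluster tolerance (or reach the bound, when the
    long allele is a lower bound). Flanking/in-repeat reads support the
    long allele when the minimum length they imply exceeds the short
    allele — such reads cannot have come from the short allele.
    """
    if call.allele_long is None:
        return False
    if read.read_class == "spanning":
        if read.implied_units is None:
            return False
        if call.long_is_lower_bound:
            return read.implied_units >= call.allele_long
        return abs(read.implied_units - call.allele_long) <= 1
    implied = read.implied_min_units or 0
    if call.allele_short is None:
        return implied > 0
    return implied > call.allele_short


def _is_max_expansion_read(read: SimRead, locus: RepeatLocus, read_length: int) -> bool:
    """In-repeat read at full read length whose content is pure motif
    (catalogued interruption units allowed)."""
    if read.read_class != "in_repeat" or not read.base_quality_ok:
        return False
    seq = read.in_tract_sequence
    if len(seq) != read_length:
        return False
    frame, mismatches = _scan_units(seq, locus.motif)
    allowed = set(locus.interruption_motifs)
    return all(unit in allowed for _, unit in mismatches)


def _scan_units(seq: str, motif: str) -> tuple[int, list[tuple[int, str]]]:
    """Decompose a sequence into motif-frame units.

    Reads may start mid-unit, so the frame offset is unknown; every offset
    is tried and the one maximising exact motif matches wins. Returns the
    chosen offset and the (unit_index, unit_sequence) list of units that
    differ from the motif. Partial units at the edges are ignored.
    """
    k = len(motif)
    best_offset, best_score, best_mismatches = 0, -1, []
    for offset in range(min(k, max(len(seq) - k + 1, 1))):
        mismatches = []
        score = 0
        index = 0
        for pos in range(offset, len(seq) - k + 1, k):
            unit = seq[pos : pos + k]
            if unit == motif:
                score += 1
            else:
                mismatches.append((index, unit))
            index += 1
        if score > best_score:
            best_offset, best_score, best_mismatches = offset, score, mismatches
    return best_offset, best_mismatches


def count_support(
    call: RepeatCall, evidence: ReadEvidence, locus: RepeatLocus
) -> tuple[int, int]:
    """Count the review's two support quantities for an expanded call.

    Returns ``(n_hq_support, n_max_reads)``: the number of high-quality
    spanning/flanking reads whose evidence is consistent with the
    expanded allele, and the number of high-quality in-repeat reads at
    full read length (reads "reaching the maximum expansion" measurable
    at this read length, pure motif up to catalogued interruption units).
    The two counts are disjoint signals — in-repeat reads are tallied
    only as maximum-expansion reads. Raises for calls that are not
    predicted expansions — triage applies only to those.
    """
    if not is_predicted_expanded(call, locus):
        raise EvidenceError(
            f"{call.sample_id}/{call.gene}: triage support applies only to "
            "predicted expansions"
        )
    n_hq = sum(
        1
        for r in evidence.reads
        if r.base_quality_ok
        and r.read_class != "in_repeat"
        and _supports_expanded(r, call)
    )
    n_max = sum(
        1
        for r in evidence.reads
        if _is_max_expansion_read(r, locus, evidence.read_length)
    )
    return n_hq, n_max


def detect_interruptions(
    evidence: ReadEvidence, locus: RepeatLocus
) -> tuple[bool, list[int]]:
    """Scan in-tract sequences for catalogued interruption motifs.

    Each read's in-tract sequence is decomposed into motif-frame units;
    any unit equal to a catalogued interruption motif (e.g. CAT inside a
    CAG tract) is reported by its unit index within the read. Loci with
    no catalogued interruption motifs always report ``(False, [])``.
    """
    if not locus.interruption_motifs:
        return False, []
    allowed = set(locus.interruption_motifs)
    positions: list[int] = []
    for read in evidence.reads:
        if len(read.in_tract_sequence) < locus.motif_length:
            continue
        _, mismatches = _scan_units(read.in_tract_sequence, locus.motif)
        positions.extend(i for i, unit in mismatches if unit in allowed)
    return bool(positions), sorted(set(positions))


def _interruption_on_supporting_read(
    call: RepeatCall, evidence: ReadEvidence, locus: RepeatLocus
) -> bool:
    if not locus.interruption_motifs:
        return False
    allowed = set(locus.interruption_motifs)
    for read in evidence.reads:
        if not _supports_expanded(read, call):
            continue
        if len(read.in_tract_sequence) < locus.motif_length:
            continue
        _, mismatches = _scan_units(read.in_tract_sequence, locus.motif)
        if any(unit in allowed for _, unit in mismatches):
            return True
    return False


def triage_call(
    call: RepeatCall,
    evidence: ReadEvidence,
    locus: RepeatLocus,
    read_length: int | None = None,
) -> TriageVerdict:
    """Apply the triage rules to one predicted expansion.

    ``read_length`` defaults to the evidence's read length. Raises for
    calls that are not predicted expansions or for loci without a
    pathogenic cutoff (no cutoff, no triage).
    """
    if read_length is None:
        read_length = evidence.read_length
    n_hq, n_max = count_support(call, evidence, locus)
    long_reads = read_length > cutoff_bp_of(locus)
    interrupted = _interruption_on_supporting_read(call, evidence, locus)

    category: Category
    if interrupted:
        category = "discard_interruption"
    elif long_reads and (n_hq >= 2 or n_max > 10):
        category = "pass"
    elif (long_reads and n_hq == 1) or (not long_reads and n_hq >= 2):
        category = "borderline"
    else:
        category = "fail"
    return TriageVerdict(
        call.sample_id, call.gene, category, n_hq, n_max, long_reads, interrupted
    )
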