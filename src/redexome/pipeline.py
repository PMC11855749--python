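"""High-level pipeline steps gluing simulation, calling, triage, metrics.

Each step is a plain function over in-memory objects; the CLI wraps them
with file I/O. The calling step feeds the genotyper the quality-filtered
read subset while pileup coverage is computed over all reads — the same
asymmetry seen between caller-reported and BAM-derived coverage in real
screens.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .caller import (
    DEFAULT_LOW_DEPTH_THRESHOLD,
    RepeatCall,
    genotype_locus,
    pileup_LC,
    quality_filtered,
)
from .catalogue import RepeatLocus
from .errors import NoThresholdError
from .simulate import ReadEvidence
from .triage import TriageVerdict, is_predicted_expanded, triage_call

__all__ = ["call_cohort", "triage_cohort"]


def call_cohort(
    evidence: Mapping[tuple[str, str], ReadEvidence],
    catalogue: Sequence[RepeatLocus],
    min_flank: int = 10,
    low_depth_threshold: float = DEFAULT_LOW_DEPTH_THRESHOLD,
) -> tuple[list[RepeatCall], dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """Genotype every sample x locus.

    Returns ``(calls, pileup_lcs, caller_lcs)``. Pileup coverage is
    computed from all reads; the caller only sees quality-passing reads.
    """
    by_gene = {l.gene: l for l in catalogue}
    calls: list[RepeatCall] = []
    pileups: dict[tuple[str, str], float] = {}
    caller_lcs: dict[tuple[str, str], float] = {}
    for key in sorted(evidence):
        ev = evidence[key]
        locus = by_gene.get(ev.gene)
        if locus is None:
            continue
        pileups[key] = round(pileup_LC(ev, locus), 2)
        call = genotype_locus(
            quality_filtered(ev), locus, min_flank, low_depth_threshold
        )
        caller_lcs[key] = call.caller_LC
        calls.append(call)
    return calls, pileups, caller_lcs


def triage_cohort(
    calls: Sequence[RepeatCall],
    evidence: Mapping[tuple[str, str], ReadEvidence],
    catalogue: Sequence[RepeatLocus],
) -> list[TriageVerdict]:
    """Triage every predicted expansion among the calls.

    Calls that predict no expansion, and loci without a pathogenic
    cutoff, are skipped (nothing to review). Triage sees the full read
    evidence, not the caller's quality-filtered subset, because the
    review is about what the reads show.
    """
    by_gene = {l.gene: l for l in catalogue}
    verdicts: list[TriageVerdict] = []
    for call in calls:
        locus = by_gene.get(call.gene)
        if locus is None or not locus.has_threshold and not locus.motif_change:
            continue
        try:
            if not is_predicted_expanded(call, locus):
                continue
        except NoThresholdError:
            continue
        ev = evidence[(call.sample_id, call.gene)]
        verdicts.append(triage_call(call, ev, locus))
    return verdicts
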