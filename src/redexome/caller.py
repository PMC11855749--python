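"""Simplified evidence-based short tandem repeat genotyper.

Given the classified read evidence at a locus, produce a diploid repeat
genotype in the style of short-read STR callers:

* spanning reads give *exact* allele sizes — they are clustered (within a
  one-unit stutter tolerance) and the two best-supported clusters become
  the called alleles;
* flanking and in-repeat reads only bound an allele from below; when that
  bound exceeds the largest spanning allele the long allele is reported as
  a lower bound and rendered ``>N`` (the notation used for alleles longer
  than any read can measure);
* the caller reports its own locus coverage (``caller_LC``, mean per-base
  depth over the reference tract computed from the reads it was given) and
  a filter status: ``NoCall`` with no reads, ``LowDepth`` below a depth
  threshold, ``PASS`` otherwise.

This is deliberately a geometry-and-counting genotyper: it has no graph
realignment and no paired-end rescue, so at loci whose cutoff exceeds the
read length it can only ever report lower bounds — exactly the read-length
limitation the triage rules are built around.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .catalogue import RepeatLocus
from .errors import EvidenceError
from .simulate import ReadEvidence, SimRead

__all__ = [
    "RepeatCall",
    "genotype_locus",
    "pileup_LC",
    "render_genotype",
    "parse_genotype",
    "quality_filtered",
    "DEFAULT_LOW_DEPTH_THRESHOLD",
    "CLUSTER_TOLERANCE_UNITS",
]

#: Calls with caller LC below this are flagged LowDepth (conventional
#: minimum depth for a confident diploid genotype; configurable per call).
DEFAULT_LOW_DEPTH_THRESHOLD = 10.0

#: Spanning reads within this many units of a better-supported allele may
#: merge into its cluster — a surrogate for PCR/sequencing stutter.
CLUSTER_TOLERANCE_UNITS = 1

#: A neighbouring unit count is absorbed as stutter only when its support
#: is at most this fraction of the peak's: stutter products are minority
#: species, whereas a genuine adjacent heterozygous allele draws roughly
#: half the spanning reads and must stay a separate cluster.
STUTTER_SUPPORT_RATIO = 0.25

FilterStatus = Literal["PASS", "LowDepth", "NoCall"]


@dataclass(frozen=True)
class RepeatCall:
    """One diploid repeat genotype call at a locus.

    ``allele_short``/``allele_long`` are repeat-unit counts; ``allele_long``
    may be a lower bound (``long_is_lower_bound``), in which case it renders
    as ``>N``. ``allele_short`` is ``None`` when no spanning read pinned an
    exact allele. ``caller_LC`` is the caller's mean depth over the locus.
    """

    sample_id: str
    gene: str
    allele_short: int | None
    allele_long: int | None
    long_is_lower_bound: bool
    n_spanning_short: int
    n_spanning_long: int
    n_flanking: int
    n_in_repeat: int
    caller_LC: float
    filter: FilterStatus

    def __post_init__(self) -> None:
        if (
            self.allele_short is not None
            and self.allele_long is not None
            and self.allele_short > self.allele_long
        ):
            raise ValueError("allele_short must not exceed allele_long")
        if min(self.n_spanning_short, self.n_spanning_long,
               self.n_flanking, self.n_in_repeat) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def is_no_call(self) -> bool:
        return self.filter == "NoCall"


def _cluster_spanning(units: Sequence[int]) -> list[tuple[int, int]]:
    """Cluster spanning-read unit counts, absorbing stutter neighbours.

    Peaks are taken in order of support (ties toward the smaller allele);
    each peak absorbs units within :data:`CLUSTER_TOLERANCE_UNITS` whose
    support is at most :data:`STUTTER_SUPPORT_RATIO` of its own, so minor
    stutter species merge while genuine adjacent heterozygous alleles —
    which carry comparable read counts — remain distinct clusters.
    Returns ``(representative_units, n_reads)`` ordered by descending
    support then ascending units.
    """
    if not units:
        return []
    counts: dict[int, int] = {}
    for u in units:
        counts[u] = counts.get(u, 0) + 1
    remaining = dict(counts)
    result: list[tuple[int, int]] = []
    while remaining:
        peak = max(remaining, key=lambda u: (remaining[u], -u))
        size = remaining.pop(peak)
        for delta in range(1, CLUSTER_TOLERANCE_UNITS + 1):
            for u in (peak - delta, peak + delta):
                if u in remaining and remaining[u] <= STUTTER_SUPPORT_RATIO * counts[peak]:
                    size += remaining.pop(u)
        result.append((peak, size))
    result.sort(key=lambda c: (-c[1], c[0]))
    return result


def _lower_bound(
    reads: Sequence[SimRead],
    read_length: int,
    motif_length: int,
    spanning_max: int | None,
) -> int | None:
    """Best lower bound on an allele implied by non-spanning reads.

    In-repeat reads imply at least ``read_length // motif_length`` units.
    A flanking read showing k complete in-tract units implies an allele
    of at least k units — the bound is k itself, not k + 1, because a
    flanking classification cannot exclude that the read in fact covered
    the whole tract without enough anchoring flank, and adding one would
    systematically fabricate expansions at loci with small cutoffs.
    Flanking evidence only counts when it shows more units than the
    largest spanning-read allele already explains (and at least one).
    """
    bound: int | None = None
    for read in reads:
        if read.read_class == "in_repeat":
            b = read_length // motif_length
        elif read.read_class == "flanking":
            observed = (
                read.implied_min_units
                if read.implied_min_units is not None
                else len(read.in_tract_sequence) // motif_length
            )
            if observed < 1:
                continue
            if spanning_max is not None and observed <= spanning_max:
                continue
            b = observed
        else:
            continue
        bound = b if bound is None else max(bound, b)
    return bound


def genotype_locus(
    evidence: ReadEvidence,
    locus: RepeatLocus,
    min_flank: int = 10,
    low_depth_threshold: float = DEFAULT_LOW_DEPTH_THRESHOLD,
) -> RepeatCall:
    """Call a diploid repeat genotype from read evidence at one locus.

    Spanning reads are clustered by implied units; the two best-supported
    clusters give the exact alleles (one cluster with no longer-allele
    signal calls a homozygote). If flanking/in-repeat reads imply a
    minimum length beyond the largest spanning allele, the long allele
    becomes that bound with ``long_is_lower_bound=True``. Empty evidence
    yields a NoCall with absent alleles.
    """
    if evidence.gene != locus.gene:
        raise EvidenceError(
            f"evidence is for {evidence.gene}, locus is {locus.gene}"
        )
    spanning = [r for r in evidence.reads if r.read_class == "spanning"]
    flanking = [r for r in evidence.reads if r.read_class == "flanking"]
    in_repeat = [r for r in evidence.reads if r.read_class == "in_repeat"]
    lc = pileup_LC(evidence, locus)

    if not evidence.reads:
        return RepeatCall(
            evidence.sample_id, locus.gene, None, None, False,
            0, 0, 0, 0, 0.0, "NoCall",
        )

    clusters = _cluster_spanning(
        [r.implied_units for r in spanning if r.implied_units is not None]
    )
    spanning_max = max((rep for rep, _ in clusters), default=None)
    bound = _lower_bound(
        flanking + in_repeat, evidence.read_length, locus.motif_length, spanning_max
    )

    allele_short: int | None
    allele_long: int | None
    n_span_short = n_span_long = 0
    long_is_bound = False

    if len(clusters) >= 2:
        (a, na), (b, nb) = clusters[0], clusters[1]
        allele_short, allele_long = min(a, b), max(a, b)
        n_span_short = na if a == allele_short else nb
        n_span_long = nb if a == allele_short else na
    elif len(clusters) == 1:
        allele_short = allele_long = clusters[0][0]
        n_span_short = n_span_long = clusters[0][1]
    else:
        allele_short = allele_long = None

    if bound is not None and (allele_long is None or bound > allele_long):
        allele_long = bound
        long_is_bound = True
        n_span_long = 0
        if allele_short is None and clusters:
            allele_short = clusters[0][0]

    filter_status: FilterStatus = "PASS" if lc >= low_depth_threshold else "LowDepth"
    return RepeatCall(
        evidence.sample_id,
        locus.gene,
        allele_short,
        allele_long,
        long_is_bound,
        n_span_short,
        n_span_long,
        len(flanking),
        len(in_repeat),
        round(lc, 2),
        filter_status,
    )


def pileup_LC(evidence: ReadEvidence, locus: RepeatLocus) -> float:
    """Mean per-base depth over the locus interval implied by the reads.

    Total locus-attributable bases divided by the catalogued reference
    interval length; 0 for empty evidence. A spanning read covers every
    reference base of the interval even when the sample's allele is
    shorter than the reference tract (the contraction aligns as a
    deletion), so it contributes at least the full interval; flanking and
    in-repeat reads contribute their in-tract bases, which for expanded
    alleles stack depth onto the reference interval exactly as
    repeat-trapped reads do in a real pileup.
    """
    if not evidence.reads:
        return 0.0
    total = 0
    for read in evidence.reads:
        if read.read_class == "spanning":
            total += max(len(read.in_tract_sequence), locus.reference_tract_bp)
        else:
            total += len(read.in_tract_sequence)
    return total / locus.reference_tract_bp


def quality_filtered(evidence: ReadEvidence) -> ReadEvidence:
    """Evidence restricted to reads passing the quality flag.

    The pipeline feeds the caller this subset (mirroring callers that only
    use reads they can confidently realign), while pileup depth is taken
    over all reads — which is why caller-reported coverage sits at or
    below pileup coverage.
    """
    return ReadEvidence(
        evidence.sample_id,
        evidence.gene,
        evidence.read_length,
        [r for r in evidence.reads if r.base_quality_ok],
    )


def render_genotype(call: RepeatCall) -> str:
    """Render a call as the conventional ``short/long`` genotype string.

    Lower-bound long alleles carry a ``>`` prefix (``23/>81``); a missing
    exact short allele renders ``.``; NoCall renders ``./.``.
    """
    if call.is_no_call:
        return "./."
    short = "." if call.allele_short is None else str(call.allele_short)
    if call.allele_long is None:
        long_ = "."
    else:
        long_ = (">" if call.long_is_lower_bound else "") + str(call.allele_long)
    return f"{short}/{long_}"


def parse_genotype(text: str) -> tuple[int | None, int | None, bool]:
    """Inverse of :func:`render_genotype`.

    Returns ``(allele_short, allele_long, long_is_lower_bound)``.
    """
    try:
        short_s, long_s = text.strip().split("/")
    except ValueError as exc:
        raise ValueError(f"malformed genotype string {text!r}") from exc
    short = None if short_s == "." else int(short_s)
    if long_s == ".":
        return short, None, False
    if long_s.startswith(">"):
        return short, int(long_s[1:]), True
    return short, int(long_s), False
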