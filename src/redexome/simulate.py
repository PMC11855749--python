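"""Seeded synthetic exome cohort generator.

Real repeat-expansion screens run on thousands of exomes captured with
different enrichment kits and sequenced at different read lengths; the raw
data are not generally redistributable. This module generates a synthetic
cohort with the same statistical structure so the whole pipeline — calling,
triage, cohort metrics — can be exercised and tested end to end:

* each sample belongs to a capture kit (:class:`KitProfile`) which fixes
  its read length and, per locus, whether the repeat region is *targeted*
  (high mean depth) or *off target* (low or zero depth);
* each sample carries a diploid repeat genotype per locus: mostly normal
  alleles, with a small per-locus probability of an expanded allele;
* read evidence is produced by placing reads of the kit's read length
  uniformly over each allele's repeat tract and classifying every read as
  spanning (contains the whole tract plus anchoring flanks), flanking
  (covers one tract boundary) or in-repeat (lies entirely inside the
  tract);
* expanded alleles at loci with catalogued interruption motifs (the CAG
  run in ATXN1, where CAT interruptions abolish pathogenicity) may carry a
  single interrupting unit, which then shows up in the simulated in-tract
  sequences.

Everything is driven by one integer seed: equal seeds give byte-identical
manifests, truth tables and evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import RepeatLocus
from .errors import ConfigError

__all__ = [
    "KitProfile",
    "SimulationConfig",
    "SimRead",
    "ReadEvidence",
    "simulate_cohort",
    "insert_interruption",
    "default_kits",
    "uniform_kits",
    "DEFAULT_EXPANSION_PROBABILITY",
    "LOCUS_EXPANSION_PROBABILITY",
]

ReadClass = Literal["spanning", "flanking", "in_repeat"]

#: Baseline per-allele expansion probability.  Chosen so that a cohort
#: screens positive at roughly the few-per-thousand sample rate seen in
#: neurogenetic referral populations.
DEFAULT_EXPANSION_PROBABILITY = 5e-4

#: Per-locus overrides: loci that dominate expansion calls in referral
#: cohorts (DMPK, HTT, GLS) and the interruption-prone ATXN1 CAG run,
#: where intermediate/interrupted alleles are common.
LOCUS_EXPANSION_PROBABILITY: dict[str, float] = {
    "ATXN1": 4e-3,
    "DMPK": 2e-3,
    "GLS": 2e-3,
    "HTT": 2e-3,
}


@dataclass(frozen=True)
class KitProfile:
    """An exome capture kit: read length, per-locus target map, depths."""

    name: str
    read_length: int
    target_status: Mapping[str, str] = field(default_factory=dict)
    mean_on_target_depth: float = 60.0
    mean_off_target_depth: float = 3.0

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ConfigError(f"kit {self.name}: read_length must be positive")
        if self.mean_on_target_depth < 0 or self.mean_off_target_depth < 0:
            raise ConfigError(f"kit {self.name}: depths must be non-negative")
        for status in self.target_status.values():
            if status not in {"target", "not_target"}:
                raise ConfigError(f"kit {self.name}: bad target status {status!r}")

    def status_of(self, gene: str) -> str:
        """Target status for a gene; unmapped genes default to 'target'."""
        return self.target_status.get(gene, "target")

    def mean_depth(self, gene: str) -> float:
        if self.status_of(gene) == "target":
            return self.mean_on_target_depth
        return self.mean_off_target_depth


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator, all with study-shaped defaults.

    ``normal_allele_mean`` defaults, per locus, to the reference repeat
    tract length in units (taken from the catalogue interval); expanded
    alleles are drawn uniformly between the pathogenic cutoff and
    ``expanded_max_factor`` times the cutoff. ``base_error_rate`` is the
    probability that a read is flagged low quality as a whole — the
    simulator's aggregate stand-in for per-base quality.
    """

    n_samples_per_kit: int = 250
    normal_allele_sd: float = 3.0
    normal_allele_mean: Mapping[str, float] = field(default_factory=dict)
    expansion_probability: Mapping[str, float] = field(
        default_factory=lambda: dict(LOCUS_EXPANSION_PROBABILITY)
    )
    default_expansion_probability: float = DEFAULT_EXPANSION_PROBABILITY
    expanded_max_factor: float = 10.0
    #: Allele-size range (units) for expansions at motif-change loci, whose
    #: unit cutoff of 0 gives no usable lower edge.
    motif_change_expansion_range: tuple[int, int] = (50, 400)
    interruption_probability: float = 0.5
    base_error_rate: float = 0.05
    min_flank: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.default_expansion_probability, self.interruption_probability,
                 self.base_error_rate, *self.expansion_probability.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.n_samples_per_kit < 0:
            raise ConfigError("n_samples_per_kit must be non-negative")
        if self.min_flank < 0:
            raise ConfigError("min_flank must be non-negative")

    def expansion_prob(self, gene: str) -> float:
        return self.expansion_probability.get(gene, self.default_expansion_probability)


@dataclass(frozen=True)
class SimRead:
    """One simulated read at a repeat locus.

    ``in_tract_sequence`` is the part of the read inside the repeat tract
    (the whole tract for spanning reads, the full read for in-repeat
    reads). ``implied_units`` is the exact allele size a spanning read
    testifies to; flanking and in-repeat reads instead carry
    ``implied_min_units``, a lower bound.
    """

    read_class: ReadClass
    in_tract_sequence: str
    base_quality_ok: bool
    implied_units: int | None = None
    implied_min_units: int | None = None


@dataclass
class ReadEvidence:
    """All simulated reads for one sample at one locus."""

    sample_id: str
    gene: str
    read_length: int
    reads: list[SimRead] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def insert_interruption(
    tract_sequence: str, motif: str, interruption: str, position: int
) -> str:
    """Replace the repeat unit at ``position`` (0-based) with an interruption.

    The tract must be a whole number of units; the interruption motif must
    match the unit length, so the tract length is unchanged.
    """
    unit = len(motif)
    if len(interruption) != unit:
        raise ValueError("interruption length must equal motif length")
    n_units = len(tract_sequence) // unit
    if len(tract_sequence) % unit:
        raise ValueError("tract length is not a whole number of units")
    if not (0 <= position < n_units):
        raise ValueError(f"position {position} outside tract of {n_units} units")
    start = position * unit
    return tract_sequence[:start] + interruption + tract_sequence[start + unit :]


def _allele_tract(locus: RepeatLocus, units: int, interruption_at: int | None) -> str:
    # N in printed motifs (GCN poly-alanine loci) is materialised as A.
    motif = locus.motif.replace("N", "A")
    tract = motif * units
    if interruption_at is not None and locus.interruption_motifs:
        tract = insert_interruption(tract, motif, locus.interruption_motifs[0], interruption_at)
    return tract


def _draw_genotype(
    rng: np.random.Generator, locus: RepeatLocus, config: SimulationConfig
) -> tuple[list[int], list[int | None]]:
    """Draw (allele units, interruption unit index or None) for two alleles."""
    ref_units = max(1, locus.reference_tract_bp // locus.motif_length)
    mean = config.normal_allele_mean.get(locus.gene, float(ref_units))
    p_exp = config.expansion_prob(locus.gene) if locus.has_threshold else 0.0
    units: list[int] = []
    interruptions: list[int | None] = []
    for _ in range(2):
        expanded = bool(rng.random() < p_exp)
        if expanded:
            if locus.motif_change:
                lo, hi = config.motif_change_expansion_range
            else:
                lo = int(locus.cutoff_units)  # type: ignore[arg-type]
                hi = max(lo, int(round(config.expanded_max_factor * lo)))
            n = int(rng.integers(lo, hi + 1))
        elif locus.motif_change:
            n = 0  # pathogenic motif absent from normal alleles
        else:
            n = int(round(rng.normal(mean, config.normal_allele_sd)))
            n = max(1, n)
            if locus.has_threshold:
                n = min(n, int(locus.cutoff_units) - 1)  # type: ignore[arg-type]
        interrupted_at: int | None = None
        if (
            expanded
            and locus.interruption_motifs
            and n >= 3
            and rng.random() < config.interruption_probability
        ):
            interrupted_at = int(rng.integers(1, n - 1))  # interior unit
        units.append(n)
        interruptions.append(interrupted_at)
    return units, interruptions


def _simulate_reads(
    rng: np.random.Generator,
    locus: RepeatLocus,
    allele_units: Sequence[int],
    interruption_at: Sequence[int | None],
    read_length: int,
    mean_depth: float,
    config: SimulationConfig,
) -> list[SimRead]:
    n_reads = int(rng.poisson(mean_depth)) if mean_depth > 0 else 0
    reads: list[SimRead] = []
    unit = locus.motif_length
    min_flank = config.min_flank
    tracts = [
        _allele_tract(locus, n, at) if n > 0 else ""
        for n, at in zip(allele_units, interruption_at)
    ]
    for _ in range(n_reads):
        which = int(rng.integers(0, 2))
        n_units = allele_units[which]
        tract = tracts[which]
        tract_bp = len(tract)
        # uniform placement with >=1 bp overlap of the tract (or of the
        # empty tract's insertion point when the allele has 0 units)
        lo, hi = -(read_length - 1), max(tract_bp - 1, 0)
        s = int(rng.integers(lo, hi + 1))
        spans = s <= -min_flank and s + read_length >= tract_bp + min_flank
        inside = s >= 0 and s + read_length <= tract_bp
        overlap = tract[max(s, 0) : min(s + read_length, tract_bp)]
        hq = bool(rng.random() >= config.base_error_rate)
        if spans:
            reads.append(
                SimRead("spanning", tract, hq, implied_units=n_units)
            )
        elif inside:
            reads.append(
                SimRead(
                    "in_repeat", overlap, hq,
                    implied_min_units=read_length // unit,
                )
            )
        else:
            reads.append(
                SimRead(
                    "flanking", overlap, hq,
                    implied_min_units=len(overlap) // unit,
                )
            )
    return reads


def simulate_cohort(
    config: SimulationConfig,
    catalogue: Sequence[RepeatLocus],
    kits: Sequence[KitProfile],
) -> tuple[pd.DataFrame, dict[tuple[str, str], ReadEvidence], pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns ``(manifest, evidence, truth)``:

    * manifest — one row per sample: ``sample_id``, ``kit``, ``read_length``;
    * evidence — ``(sample_id, gene) -> ReadEvidence`` for every pair
      (possibly with zero reads);
    * truth — one row per sample x locus with the true diploid genotype
      (``allele1_units <= allele2_units``) and interruption flag.

    Per sample x locus the read count is Poisson with the kit's mean depth
    for that locus's target status; each read is placed uniformly over the
    sampled allele tract and classified geometrically. Deterministic given
    ``config.seed``.
    """
    if not catalogue:
        raise ConfigError("catalogue must be non-empty")
    if not kits:
        raise ConfigError("at least one kit required")
    rng = np.random.default_rng(config.seed)
    manifest_rows = []
    truth_rows = []
    evidence: dict[tuple[str, str], ReadEvidence] = {}
    sample_no = 0
    for kit in kits:
        for _ in range(config.n_samples_per_kit):
            sample_no += 1
            sid = f"S{sample_no:05d}"
            manifest_rows.append(
                {"sample_id": sid, "kit": kit.name, "read_length": kit.read_length}
            )
            for locus in catalogue:
                units, interrupted_at = _draw_genotype(rng, locus, config)
                reads = _simulate_reads(
                    rng, locus, units, interrupted_at,
                    kit.read_length, kit.mean_depth(locus.gene), config,
                )
                evidence[(sid, locus.gene)] = ReadEvidence(
                    sid, locus.gene, kit.read_length, reads
                )
                a1, a2 = sorted(units)
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "gene": locus.gene,
                        "allele1_units": a1,
                        "allele2_units": a2,
                        "interrupted": any(x is not None for x in interrupted_at),
                    }
                )
    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "kit", "read_length"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "gene", "allele1_units", "allele2_units", "interrupted"],
    )
    return manifest, evidence, truth


def default_kits(catalogue: Iterable[RepeatLocus]) -> list[KitProfile]:
    """Four-kit preset shaped like common exome capture designs.

    Illustrative, not authoritative: coding repeat loci are targeted by all
    kits except a few known dropouts (the ATXN2 CAG region is poorly
    captured everywhere; HTT and CACNA1A drop out of the smaller designs);
    intronic loci are off target except NOP56 and CSTB on the SureSelect
    designs; UTR loci are targeted by the two SureSelect kits, plus DMPK on
    TruSeq. The Nextera-like focused design has zero off-target depth.
    """
    genes = {locus.gene: locus for locus in catalogue}

    def status_map(targeted: set[str]) -> dict[str, str]:
        return {
            g: ("target" if g in targeted else "not_target") for g in genes
        }

    coding = {g for g, l in genes.items() if l.region_class == "coding"}
    utr = {g for g, l in genes.items() if l.region_class in {"utr5", "utr3"}}

    v6 = (coding - {"ATXN2"}) | utr | {"NOP56", "CSTB"}
    v4 = (coding - {"ATXN2"}) | utr | {"NOP56"}
    truseq = (coding - {"ATXN2", "HTT"}) | {"DMPK"}
    nextera = coding - {"ATXN2", "HTT", "CACNA1A"}

    return [
        KitProfile("SureSelectV6", 150, status_map(v6)),
        KitProfile("SureSelectV4", 125, status_map(v4)),
        KitProfile("TruSeq", 100, status_map(truseq)),
        KitProfile("Nextera", 75, status_map(nextera), mean_off_target_depth=0.0),
    ]


def uniform_kits(
    read_lengths: Sequence[int], mean_depth: float = 60.0, prefix: str = "RL"
) -> list[KitProfile]:
    """Kits differing only in read length, everything targeted at fixed depth.

    Used to isolate the read-length effect on genotyping rate.
    """
    return [
        KitProfile(f"{prefix}{rl}", rl, {}, mean_on_target_depth=mean_depth)
        for rl in read_lengths
    ]
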