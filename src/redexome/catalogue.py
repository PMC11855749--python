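"""Repeat-expansion disease (RED) locus catalogue.

A RED locus is a short tandem repeat (STR) whose expansion beyond a
locus-specific threshold causes disease: for example the CAG repeat in *HTT*
(Huntington disease, pathogenic from 35 units / 105 bp) or the CTG repeat in
the 3'UTR of *DMPK* (myotonic dystrophy type 1). This module houses the
catalogue of such loci together with all cutoff and read-length
detectability arithmetic:

* :func:`load_catalogue` reads and validates a tab-separated catalogue;
* :func:`cutoff_bp_of` converts a repeat-unit cutoff to base pairs;
* :func:`classify_allele` applies the expanded/normal boundary;
* :func:`detectability` decides whether spanning reads of a given length
  can, in principle, resolve an expansion at the locus exactly.

The shipped default catalogue (``data/red_catalogue.tsv``) lists 26
neurological RED loci in coding, intronic and untranslated regions. Its
genomic intervals are synthetic placeholders — internally consistent
0-based half-open coordinates sized like the reference repeat tract,
sufficient for depth aggregation; users supply real build-38 coordinates by
replacing the ``chrom``/``start``/``end`` columns.

Two catalogue quirks are handled explicitly. Loci with no established
cutoff (PHOX2B, NIPA1, PABN1) carry ``NA`` and raise
:class:`~redexome.errors.NoThresholdError` from any cutoff arithmetic. The
RFC1 locus is a *motif change*: the pathogenic AAGGG motif differs from the
reference motif, so its cutoff is "any pathogenic-motif allele present" and
its printed bp cutoff is exempt from the ``units x |motif|`` consistency
check.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .errors import CatalogueFormatError, CatalogueValidationError, NoThresholdError

__all__ = [
    "RepeatLocus",
    "load_catalogue",
    "default_catalogue",
    "cutoff_bp_of",
    "classify_allele",
    "detectability",
    "region_group",
    "class_counts",
]

RegionClass = Literal["coding", "intron", "utr5", "utr3"]

#: Accepted spellings for the region-class column, mapped to canonical
#: tokens.  Catalogue tables in the literature print "Coding", "Exon",
#: "Intron", "5'UTR"/"3'UTR" (with either a prime or an apostrophe).
_REGION_ALIASES = {
    "coding": "coding",
    "exon": "coding",
    "intron": "intron",
    "intronic": "intron",
    "5'utr": "utr5",
    "5′utr": "utr5",
    "utr5": "utr5",
    "3'utr": "utr3",
    "3′utr": "utr3",
    "utr3": "utr3",
}

# IUPAC "N" appears in printed motifs such as GCN (poly-alanine loci).
_MOTIF_ALPHABET = set("ACGTN")

_REQUIRED_COLUMNS = ("gene", "motif", "cutoff_units", "cutoff_bp", "region_class")


@dataclass(frozen=True)
class RepeatLocus:
    """One catalogued RED locus.

    Coordinates are 0-based half-open. ``cutoff_units``/``cutoff_bp`` are
    the minimal abnormal allele size (absent for no-threshold loci).
    ``motif_change`` marks loci where the pathogenic motif differs from the
    reference motif (RFC1/AAGGG), exempting them from bp-consistency and
    switching allele classification to presence-of-motif.
    """

    gene: str
    disease: str
    motif: str
    cutoff_units: int | None
    cutoff_bp: int | None
    region_class: RegionClass
    chrom: str
    start: int
    end: int
    interruption_motifs: tuple[str, ...] = ()
    zygosity_requirement: Literal["monoallelic", "biallelic"] = "monoallelic"
    motif_change: bool = False
    #: Expanded iff allele >= cutoff when True (default), > cutoff when False.
    cutoff_inclusive: bool = True

    def __post_init__(self) -> None:
        if not self.motif or self.motif != self.motif.upper():
            raise CatalogueValidationError(
                f"{self.gene}: motif must be non-empty uppercase, got {self.motif!r}"
            )
        if not (1 <= len(self.motif) <= 12):
            raise CatalogueValidationError(
                f"{self.gene}: motif length must be 1-12, got {len(self.motif)}"
            )
        if set(self.motif) - _MOTIF_ALPHABET:
            raise CatalogueValidationError(
                f"{self.gene}: motif {self.motif!r} not over A/C/G/T/N"
            )
        if self.start >= self.end:
            raise CatalogueValidationError(
                f"{self.gene}: interval start {self.start} >= end {self.end}"
            )
        if (self.cutoff_units is None) != (self.cutoff_bp is None):
            raise CatalogueValidationError(
                f"{self.gene}: cutoff_units and cutoff_bp must both be present or both NA"
            )
        if (
            self.cutoff_units is not None
            and not self.motif_change
            and self.cutoff_bp != self.cutoff_units * len(self.motif)
        ):
            raise CatalogueValidationError(
                f"{self.gene}: cutoff_bp {self.cutoff_bp} != cutoff_units "
                f"{self.cutoff_units} x motif length {len(self.motif)}"
            )

    @property
    def has_threshold(self) -> bool:
        return self.cutoff_units is not None

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def reference_tract_bp(self) -> int:
        return self.end - self.start


def _parse_cutoff(value: object, gene: str, column: str) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text.upper() in {"NA", "", "NAN"}:
        return None
    try:
        number = int(float(text))
    except ValueError as exc:
        raise CatalogueFormatError(f"{gene}: {column} value {text!r} not numeric") from exc
    if number < 0:
        raise CatalogueValidationError(f"{gene}: {column} must be non-negative")
    return number


def _row_to_locus(row: pd.Series) -> RepeatLocus:
    gene = str(row["gene"]).strip()
    region_raw = str(row["region_class"]).strip().lower()
    if region_raw not in _REGION_ALIASES:
        raise CatalogueValidationError(
            f"{gene}: unknown region_class {row['region_class']!r}"
        )
    interruptions: tuple[str, ...] = ()
    if "interruption_motifs" in row.index and not pd.isna(row["interruption_motifs"]):
        text = str(row["interruption_motifs"]).strip()
        if text:
            interruptions = tuple(m.strip().upper() for m in text.split(",") if m.strip())
    zygosity = "monoallelic"
    if "zygosity" in row.index and not pd.isna(row["zygosity"]):
        zygosity = str(row["zygosity"]).strip().lower() or "monoallelic"
        if zygosity not in {"monoallelic", "biallelic"}:
            raise CatalogueValidationError(f"{gene}: bad zygosity {zygosity!r}")
    motif_change = False
    if "motif_change" in row.index and not pd.isna(row["motif_change"]):
        motif_change = str(row["motif_change"]).strip().lower() in {"true", "1", "yes"}
    return RepeatLocus(
        gene=gene,
        disease=str(row.get("disease", "")).strip(),
        motif=str(row["motif"]).strip().upper(),
        cutoff_units=_parse_cutoff(row["cutoff_units"], gene, "cutoff_units"),
        cutoff_bp=_parse_cutoff(row["cutoff_bp"], gene, "cutoff_bp"),
        region_class=_REGION_ALIASES[region_raw],
        chrom=str(row.get("chrom", "chrU")).strip(),
        start=int(row.get("start", 0)),
        end=int(row.get("end", 1)),
        interruption_motifs=interruptions,
        zygosity_requirement=zygosity,  # type: ignore[arg-type]
        motif_change=motif_change,
    )


def load_catalogue(path: str | Path) -> list[RepeatLocus]:
    """Load a locus catalogue from a tab-separated file.

    The file must carry a header naming at least ``gene``, ``motif``,
    ``cutoff_units``, ``cutoff_bp`` and ``region_class``. Rows whose bp
    cutoff disagrees with ``cutoff_units x |motif|`` are rejected unless
    flagged ``motif_change`` (the catalogue-shipped whitelist mechanism).
    Genes must be unique. An empty table (header only) loads as an empty
    list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CatalogueFormatError(
            f"catalogue {path} missing required column(s): {', '.join(missing)}"
        )
    loci = [_row_to_locus(row) for _, row in table.iterrows()]
    seen: set[str] = set()
    for locus in loci:
        if locus.gene in seen:
            raise CatalogueValidationError(f"duplicate gene in catalogue: {locus.gene}")
        seen.add(locus.gene)
    return loci


def default_catalogue() -> list[RepeatLocus]:
    """Load the 26-locus catalogue shipped with the package."""
    with resources.as_file(
        resources.files("redexome").joinpath("data/red_catalogue.tsv")
    ) as path:
        return load_catalogue(path)


def cutoff_bp_of(locus: RepeatLocus) -> int:
    """Pathogenic cutoff expressed in base pairs.

    Computed as ``cutoff_units x |motif|``; motif-change loci return their
    catalogued bp value verbatim (their unit cutoff is 0 by convention).
    """
    if not locus.has_threshold:
        raise NoThresholdError(f"{locus.gene} has no pathogenic cutoff")
    if locus.motif_change:
        return int(locus.cutoff_bp)  # type: ignore[arg-type]
    return int(locus.cutoff_units) * locus.motif_length  # type: ignore[arg-type]


def classify_allele(locus: RepeatLocus, allele_units: int) -> Literal["normal", "expanded"]:
    """Classify an allele size (in repeat units) against the locus cutoff.

    Motif-change loci are expanded whenever any pathogenic-motif repeat is
    present (allele > 0 units). Elsewhere the boundary is inclusive by
    default (allele >= cutoff is expanded), the convention of treating the
    printed cutoff as the minimal abnormal size; per-locus
    ``cutoff_inclusive=False`` switches to a strict boundary.
    """
    if allele_units < 0:
        raise ValueError("allele_units must be non-negative")
    if locus.motif_change:
        return "expanded" if allele_units > 0 else "normal"
    if not locus.has_threshold:
        raise NoThresholdError(f"{locus.gene} has no pathogenic cutoff")
    cutoff = int(locus.cutoff_units)  # type: ignore[arg-type]
    if locus.cutoff_inclusive:
        return "expanded" if allele_units >= cutoff else "normal"
    return "expanded" if allele_units > cutoff else "normal"


def detectability(
    locus: RepeatLocus, read_length: int, min_flank: int
) -> Literal["spanning_resolvable", "lower_bound_only"]:
    """Can spanning reads of this length size an expansion exactly?

    A spanning read must contain the whole pathogenic-size tract plus
    ``min_flank`` anchoring bases on each side, so a locus is
    ``spanning_resolvable`` iff ``cutoff_bp + 2*min_flank <= read_length``.
    When the cutoff exceeds what a read can span, expanded alleles can only
    be bounded from below (the caller reports ``>N`` genotypes).
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if min_flank < 0:
        raise ValueError("min_flank must be non-negative")
    if cutoff_bp_of(locus) + 2 * min_flank <= read_length:
        return "spanning_resolvable"
    return "lower_bound_only"


def region_group(region_class: str) -> str:
    """Collapse utr5/utr3 into a single 'utr' group (coding/intron/utr)."""
    return "utr" if region_class in {"utr5", "utr3"} else region_class


def class_counts(catalogue: Iterable[RepeatLocus]) -> dict[str, int]:
    """Number of loci per collapsed region group, in coding/intron/utr order."""
    counts = {"coding": 0, "intron": 0, "utr": 0}
    for locus in catalogue:
        counts[region_group(locus.region_class)] += 1
    return counts
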