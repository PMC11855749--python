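"""Cohort-level analytics over calls, verdicts and validation records.

Four views of a screened cohort:

* :func:`expansion_summary` — per-locus triage category counts with
  totals and the overall fail fraction;
* :func:`validation_summary` — bookkeeping of orthogonal PCR follow-up
  (confirmed expansions by triage category, diagnostic yield);
* :func:`genotyping_rate_table` — per locus x kit x read-length
  genotyping rate (percent of cohort samples with a quality-passing
  call) alongside mean pileup and caller-reported coverage;
* :func:`readlength_trend` — genotyping rate by genomic region class
  (coding / intron / UTR) across read-length strata, with a
  monotonicity verdict.

:func:`coverage_comparison` contrasts raw pileup depth with the depth
the caller reports from the reads it actually used, per locus x kit —
in practice the caller's figure sits at or below the pileup figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import RepeatCall
from .catalogue import RepeatLocus, region_group
from .errors import RedexomeError
from .simulate import KitProfile
from .triage import CATEGORIES, TriageVerdict

__all__ = [
    "LocusKitSummary",
    "ValidationRecord",
    "expansion_summary",
    "validation_summary",
    "genotyping_rate_table",
    "summaries_frame",
    "coverage_comparison",
    "readlength_trend",
    "zygosity_flags",
]


@dataclass(frozen=True)
class LocusKitSummary:
    """Genotyping performance of one locus under one kit/read-length stratum."""

    gene: str
    region_class: str
    kit: str
    read_length: int
    n_samples: int
    n_pass_filter: int
    genotyping_rate: float  # percent, 1 decimal
    mean_pileup_LC: float
    mean_caller_LC: float
    target_status: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.genotyping_rate <= 100.0):
            raise ValueError("genotyping_rate must lie in [0, 100]")
        if self.n_pass_filter > self.n_samples:
            raise ValueError("n_pass_filter cannot exceed n_samples")


@dataclass(frozen=True)
class ValidationRecord:
    """One PCR-validated (or refuted) expansion call.

    Only pass/borderline calls are dispatched for wet-lab validation, so
    records with other categories are rejected downstream.
    """

    sample_id: str
    gene: str
    category: Literal["pass", "borderline"]
    pcr_result: Literal["confirmed", "not_confirmed"]
    diagnostic: Literal["yes", "no", "unknown"] = "unknown"


def _locus_order(catalogue: Sequence[RepeatLocus]) -> list[RepeatLocus]:
    group_rank = {"coding": 0, "intron": 1, "utr": 2}
    return sorted(
        catalogue, key=lambda l: (group_rank[region_group(l.region_class)], l.gene)
    )


def expansion_summary(
    verdicts: Sequence[TriageVerdict], catalogue: Sequence[RepeatLocus]
) -> pd.DataFrame:
    """Per-locus triage category counts plus a TOTAL row.

    One row per catalogued locus (region-class order, then gene), columns
    ``pass``/``borderline``/``fail``/``discard_interruption`` and
    ``n_total``. ``fail_pct`` is 100 x fail / (pass + borderline + fail)
    to one decimal — interruption discards are bookkept separately from
    the fail fraction, mirroring how discarded interrupted calls are
    reported apart from failed ones. Empty input gives an all-zero table.
    """
    counts: dict[str, dict[str, int]] = {
        locus.gene: {c: 0 for c in CATEGORIES} for locus in catalogue
    }
    for v in verdicts:
        if v.gene in counts:
            counts[v.gene][v.category] += 1
    rows = []
    for locus in _locus_order(catalogue):
        c = counts[locus.gene]
        rows.append(
            {"gene": locus.gene, "region_class": region_group(locus.region_class), **c}
        )
    frame = pd.DataFrame(
        rows,
        columns=["gene", "region_class", *CATEGORIES],
    )
    total = {c: int(frame[c].sum()) for c in CATEGORIES}
    frame.loc[len(frame)] = {"gene": "TOTAL", "region_class": "", **total}
    frame["n_total"] = frame[list(CATEGORIES)].sum(axis=1)
    denom = frame["pass"] + frame["borderline"] + frame["fail"]
    with np.errstate(invalid="ignore", divide="ignore"):
        frame["fail_pct"] = (100.0 * frame["fail"] / denom).round(1)
    frame.loc[denom == 0, "fail_pct"] = np.nan
    return frame


def validation_summary(records: Sequence[ValidationRecord]) -> dict:
    """Tally PCR follow-up of pass/borderline calls.

    Returns ``n_tested``, ``n_confirmed``, ``n_confirmed_by_category``
    and ``diagnostic_yield_percent`` — 100 x diagnostic / confirmed,
    rounded to the nearest integer, or ``"NA"`` with zero confirmations.
    """
    for r in records:
        if r.category not in {"pass", "borderline"}:
            raise RedexomeError(
                f"{r.sample_id}/{r.gene}: only pass/borderline calls are "
                f"eligible for PCR validation, got {r.category!r}"
            )
    confirmed = [r for r in records if r.pcr_result == "confirmed"]
    by_cat = {
        "pass": sum(1 for r in confirmed if r.category == "pass"),
        "borderline": sum(1 for r in confirmed if r.category == "borderline"),
    }
    n_diag = sum(1 for r in confirmed if r.diagnostic == "yes")
    yield_pct: int | str
    if confirmed:
        yield_pct = int(round(100.0 * n_diag / len(confirmed)))
    else:
        yield_pct = "NA"
    return {
        "n_tested": len(records),
        "n_confirmed": len(confirmed),
        "n_confirmed_by_category": by_cat,
        "n_diagnostic": n_diag,
        "diagnostic_yield_percent": yield_pct,
    }


def genotyping_rate_table(
    calls: Sequence[RepeatCall],
    manifest: pd.DataFrame,
    catalogue: Sequence[RepeatLocus],
    kits: Mapping[str, KitProfile] | None = None,
    pileup_lcs: Mapping[tuple[str, str], float] | None = None,
) -> list[LocusKitSummary]:
    """Genotyping rate per locus x kit x read length.

    The rate is the percentage of the stratum's samples whose call at the
    locus carries filter PASS; strata and loci with zero passing calls
    are included at 0%. Mean caller coverage is averaged over the
    stratum's calls, mean pileup coverage over ``pileup_lcs`` when
    supplied. Calls from samples absent from the manifest are an error.
    """
    known = set(manifest["sample_id"])
    orphans = sorted({c.sample_id for c in calls} - known)
    if orphans:
        raise RedexomeError(f"calls reference samples not in manifest: {orphans}")
    kit_of = dict(zip(manifest["sample_id"], manifest["kit"]))
    by_key: dict[tuple[str, str], list[RepeatCall]] = {}
    for call in calls:
        by_key.setdefault((kit_of[call.sample_id], call.gene), []).append(call)
    strata = manifest.groupby(["kit", "read_length"], sort=True)["sample_id"].apply(list)
    out: list[LocusKitSummary] = []
    for (kit_name, read_length), samples in strata.items():
        sample_set = set(samples)
        for locus in _locus_order(catalogue):
            stratum_calls = [
                c
                for c in by_key.get((kit_name, locus.gene), [])
                if c.sample_id in sample_set
            ]
            n_pass = sum(1 for c in stratum_calls if c.filter == "PASS")
            caller_lcs = [c.caller_LC for c in stratum_calls]
            pile = [
                pileup_lcs[(s, locus.gene)]
                for s in samples
                if pileup_lcs and (s, locus.gene) in pileup_lcs
            ]
            status = kits[kit_name].status_of(locus.gene) if kits else "unknown"
            out.append(
                LocusKitSummary(
                    gene=locus.gene,
                    region_class=region_group(locus.region_class),
                    kit=kit_name,
                    read_length=int(read_length),
                    n_samples=len(samples),
                    n_pass_filter=n_pass,
                    genotyping_rate=round(100.0 * n_pass / len(samples), 1)
                    if samples
                    else 0.0,
                    mean_pileup_LC=float(np.mean(pile)) if pile else float("nan"),
                    mean_caller_LC=float(np.mean(caller_lcs))
                    if caller_lcs
                    else float("nan"),
                    target_status=status,
                )
            )
    return out


def summaries_frame(summaries: Sequence[LocusKitSummary]) -> pd.DataFrame:
    """Tabular view of :class:`LocusKitSummary` rows."""
    return pd.DataFrame([s.__dict__ for s in summaries])


def coverage_comparison(
    pileup_lcs: Mapping[tuple[str, str], float],
    caller_lcs: Mapping[tuple[str, str], float],
    manifest: pd.DataFrame,
    catalogue: Sequence[RepeatLocus],
) -> pd.DataFrame:
    """Mean pileup vs caller-reported coverage per locus x kit.

    Both inputs map ``(sample_id, gene)`` to a mean depth and must cover
    the same keys. The ``ratio`` column is caller/pileup (NaN where the
    locus has no coverage at all); ``ratio_gt_1`` flags strata where the
    caller somehow reports more depth than the pileup, which a
    subset-fed caller should never do.
    """
    if set(pileup_lcs) != set(caller_lcs):
        raise RedexomeError("pileup and caller coverage key sets differ")
    kit_of = dict(zip(manifest["sample_id"], manifest["kit"]))
    rows = []
    genes = [l.gene for l in _locus_order(catalogue)]
    frame = pd.DataFrame(
        [
            {
                "kit": kit_of[s],
                "gene": g,
                "pileup": pileup_lcs[(s, g)],
                "caller": caller_lcs[(s, g)],
            }
            for (s, g) in pileup_lcs
            if s in kit_of
        ]
    )
    for (kit_name, gene), grp in frame.groupby(["kit", "gene"], sort=True):
        mean_pile = float(grp["pileup"].mean())
        mean_caller = float(grp["caller"].mean())
        ratio = mean_caller / mean_pile if mean_pile > 0 else float("nan")
        rows.append(
            {
                "kit": kit_name,
                "gene": gene,
                "mean_pileup_LC": mean_pile,
                "mean_caller_LC": mean_caller,
                "ratio": ratio,
                "ratio_gt_1": bool(ratio > 1.0) if np.isfinite(ratio) else False,
            }
        )
    out = pd.DataFrame(rows)
    out["gene"] = pd.Categorical(out["gene"], categories=genes, ordered=True)
    return out.sort_values(["kit", "gene"]).reset_index(drop=True)


def readlength_trend(
    summaries: Sequence[LocusKitSummary],
) -> tuple[pd.DataFrame, dict[str, bool], bool]:
    """Mean genotyping rate per region class across read-length strata.

    Returns ``(table, per_class_verdict, overall_verdict)`` where the
    verdicts state whether mean rates are non-decreasing in read length
    within each region class (ties allowed). Requires at least two
    read-length strata.
    """
    frame = summaries_frame(list(summaries))
    if frame.empty or frame["read_length"].nunique() < 2:
        raise RedexomeError("readlength_trend requires at least two read-length strata")
    table = (
        frame.groupby(["region_class", "read_length"], sort=True)["genotyping_rate"]
        .mean()
        .reset_index(name="mean_rate")
    )
    verdicts: dict[str, bool] = {}
    for region, grp in table.groupby("region_class", sort=True):
        rates = grp.sort_values("read_length")["mean_rate"].to_numpy()
        verdicts[str(region)] = bool(np.all(np.diff(rates) >= 0))
    return table, verdicts, all(verdicts.values())


def zygosity_flags(
    calls: Sequence[RepeatCall], catalogue: Sequence[RepeatLocus]
) -> pd.DataFrame:
    """Flag monoallelic expansions at loci that require biallelic mutation.

    Some loci (the GLS 5'UTR repeat) cause disease only when both alleles
    are mutated; a single expanded allele there is reportable but not
    diagnostic on its own. Returns one row per flagged call.
    """
    from .triage import is_predicted_expanded
    from .catalogue import classify_allele

    by_gene = {l.gene: l for l in catalogue}
    rows = []
    for call in calls:
        locus = by_gene.get(call.gene)
        if locus is None or locus.zygosity_requirement != "biallelic":
            continue
        if not is_predicted_expanded(call, locus):
            continue
        short_expanded = (
            call.allele_short is not None
            and classify_allele(locus, call.allele_short) == "expanded"
        )
        rows.append(
            {
                "sample_id": call.sample_id,
                "gene": call.gene,
                "genotype_biallelic": short_expanded,
                "flag": "biallelic_requirement_met"
                if short_expanded
                else "heterozygous_at_biallelic_locus",
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "genotype_biallelic", "flag"]
    )
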