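"""Per-cohort carrier tallies, allele-frequency strings, and burden tables.

Two counting conventions coexist here and must not be conflated: the carrier
table counts alleles per variant per cohort (``alt_alleles/total_alleles``
fractions, one row per variant x cohort), while the carrier summary counts
individuals carrying at least one qualifying variant (the numerator of a
burden comparison — an individual with two different qualifying variants
counts once).  Relatives of index patients are excluded from burden
denominators via ``Individual.is_index``.

Percentages are formatted with half-up decimal rounding, the convention of
clinical genetics reports (so 12/919 prints as 1.3%, 5/242 as 2.1%).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Optional, Union

import pandas as pd

from .cohort_io import (
    FamscreenError,
    GenotypeCall,
    Individual,
    VariantRecord,
    Zygosity,
    calls_index,
)
from .assoc_stats import ContingencyTable2x2

__all__ = [
    "ScreenError",
    "CarrierRow",
    "CarrierTable",
    "CohortSummary",
    "CarrierSummary",
    "default_qualifying",
    "tally_carriers",
    "carrier_percent",
    "summarize_carriers",
    "build_burden_table",
]


class ScreenError(FamscreenError):
    pass


@dataclass(frozen=True)
class CarrierRow:
    """Counts for one (variant, cohort) cell of the carrier table."""

    n_genotyped: int
    carriers: int
    alt_alleles: int

    def __post_init__(self):
        if not (0 <= self.carriers <= self.n_genotyped):
            raise ScreenError("carriers must lie in [0, n_genotyped]")
        if not (self.carriers <= self.alt_alleles <= 2 * self.carriers):
            raise ScreenError("alt_alleles must lie in [carriers, 2*carriers]")

    @property
    def total_alleles(self) -> int:
        return 2 * self.n_genotyped

    @property
    def af_string(self) -> str:
        """Allele fraction as printed in screening reports, e.g. ``3/482``."""
        return f"{self.alt_alleles}/{self.total_alleles}"


@dataclass
class CarrierTable:
    """Rows keyed by (variant_key, cohort)."""

    rows: Mapping  # (VariantKey, cohort) -> CarrierRow

    def row(self, variant_key, cohort) -> CarrierRow:
        return self.rows[(variant_key, cohort)]

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for (key, cohort), row in sorted(self.rows.items(), key=lambda kv: (kv[0][0], kv[0][1])):
            chrom, pos, ref, alt = key
            recs.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "cohort": cohort,
                    "n_genotyped": row.n_genotyped,
                    "carriers": row.carriers,
                    "allele_frequency": row.af_string,
                }
            )
        return pd.DataFrame(
            recs,
            columns=[
                "chrom", "pos", "ref", "alt", "cohort",
                "n_genotyped", "carriers", "allele_frequency",
            ],
        )


@dataclass(frozen=True)
class CohortSummary:
    """Individual-level burden counts for one cohort group."""

    n_individuals: int
    n_carriers: int
    percent: str


@dataclass
class CarrierSummary:
    """Per-group individual-level burden counts."""

    groups: Mapping  # group label -> CohortSummary


def default_qualifying(
    maf_threshold: float = 0.01,
) -> Callable[[VariantRecord], bool]:
    """Default burden predicate: rare missense variants.

    Rare means panel_af strictly below the threshold or absent from the panel.
    """

    def predicate(v: VariantRecord) -> bool:
        from .cohort_io import Consequence

        rare = v.panel_af is None or v.panel_af < maf_threshold
        return v.consequence is Consequence.MISSENSE and rare

    return predicate


def tally_carriers(
    individuals: Iterable[Individual],
    variants: Iterable[VariantRecord],
    calls: Union[Iterable[GenotypeCall], Mapping],
    qualifying: Optional[Callable[[VariantRecord], bool]] = None,
) -> CarrierTable:
    """Count carriers and alternate alleles per qualifying variant per cohort.

    Individuals with a missing call at a variant are excluded from that
    variant's ``n_genotyped``.  Every sample appearing in ``calls`` must be in
    the cohort roster.
    """
    individuals = list(individuals)
    roster = {}
    for ind in individuals:
        if ind.cohort is None:
            raise ScreenError(f"individual {ind.id!r} has no cohort label")
        roster[ind.id] = ind.cohort
    lookup = calls_index(calls)
    for sample_id, _key in lookup:
        if sample_id not in roster:
            raise ScreenError(f"sample {sample_id!r} has genotype calls but no cohort entry")

    if qualifying is None:
        qualifying = default_qualifying()
    cohorts = sorted(set(roster.values()))
    rows: dict = {}
    for v in variants:
        if not qualifying(v):
            continue
        counts = {c: [0, 0, 0] for c in cohorts}  # n_genotyped, carriers, alt_alleles
        for ind in individuals:
            zyg = lookup.get((ind.id, v.key), Zygosity.MISSING)
            if zyg is Zygosity.MISSING:
                continue
            cell = counts[ind.cohort]
            cell[0] += 1
            if zyg.carries:
                cell[1] += 1
                cell[2] += zyg.dosage
        for cohort, (n, carr, alleles) in counts.items():
            rows[(v.key, cohort)] = CarrierRow(n, carr, alleles)
    return CarrierTable(rows=rows)


def carrier_percent(n_carriers: int, n_individuals: int, decimals: int = 1) -> str:
    """Format a carrier fraction as a half-up-rounded percent string.

    ``carrier_percent(10, 916)`` -> ``"1.1%"``.
    """
    if n_individuals <= 0:
        raise ScreenError("n_individuals must be positive")
    if not (0 <= n_carriers <= n_individuals):
        raise ScreenError("n_carriers must lie in [0, n_individuals]")
    quantum = Decimal(1).scaleb(-decimals)
    pct = (Decimal(100) * Decimal(n_carriers) / Decimal(n_individuals)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return f"{pct}%"


def summarize_carriers(
    individuals: Iterable[Individual],
    variants: Iterable[VariantRecord],
    calls: Union[Iterable[GenotypeCall], Mapping],
    groups: Mapping,
    qualifying: Optional[Callable[[VariantRecord], bool]] = None,
    include_non_index: bool = False,
    decimals: int = 1,
) -> CarrierSummary:
    """Individual-level burden summary per cohort group.

    ``groups`` maps a group label to the cohort labels it pools, e.g.
    ``{"dystonia": ["MD", "WD", "other_dystonia"], "non_dystonic": ["PD",
    "control"]}``.  An individual counts as a carrier when it carries at least
    one qualifying variant; it counts once regardless of how many it carries.
    Non-index individuals (relatives) are excluded unless requested.
    """
    if qualifying is None:
        qualifying = default_qualifying()
    lookup = calls_index(calls)
    qual_keys = [v.key for v in variants if qualifying(v)]
    by_cohort: dict = {}
    for ind in individuals:
        if not include_non_index and not ind.is_index:
            continue
        carrier = any(
            lookup.get((ind.id, key), Zygosity.MISSING).carries for key in qual_keys
        )
        n, c = by_cohort.get(ind.cohort, (0, 0))
        by_cohort[ind.cohort] = (n + 1, c + 1 if carrier else c)
    out = {}
    for label, cohorts in groups.items():
        n = sum(by_cohort.get(c, (0, 0))[0] for c in cohorts)
        carr = sum(by_cohort.get(c, (0, 0))[1] for c in cohorts)
        if n == 0:
            raise ScreenError(f"burden group {label!r} contains no individuals")
        out[label] = CohortSummary(n, carr, carrier_percent(carr, n, decimals))
    return CarrierSummary(groups=out)


def build_burden_table(
    cases_carriers: int, cases_n: int, ctrl_carriers: int, ctrl_n: int
) -> ContingencyTable2x2:
    """Arrange carrier counts as the 2x2 table feeding the exact test.

    Row 1 is cases (carriers, non-carriers); row 2 is controls.
    """
    if cases_carriers > cases_n or ctrl_carriers > ctrl_n:
        raise ScreenError("carriers cannot exceed group size")
    return ContingencyTable2x2(
        cases_carriers,
        cases_n - cases_carriers,
        ctrl_carriers,
        ctrl_n - ctrl_carriers,
    )
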