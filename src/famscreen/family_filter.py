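"""Per-family rare-variant filter cascade and cross-family gene intersection.

The discovery procedure for a dominantly inherited trait screens each family's
variant calls through an ordered cascade: (a) keep exonic or splicing sites,
(b) keep protein-changing classes (synonymous changes are discarded), (c) keep
rare variants (reference-panel allele frequency strictly below a threshold,
1% by default), and (d) keep variants shared by every definitely affected
member of the family.  Candidate genes are then the genes hit by surviving
variants in at least ``min_families_shared`` independent families.

Stages (a) and (b) are driven by one consequence filter because the class
lists nest; the cascade ledger still reports the exonic/splicing count as a
separate pre-count for transparency.

Sharing is carrier-based, not zygosity-based: a heterozygous and a homozygous
affected member both count as carrying.  Members of unknown affection status
never constrain sharing — "definitely affected" means recorded affected status
only.  Segregation reports flag phenocopy candidates (affected non-carriers)
and reduced-penetrance carriers (unaffected or unexamined carriers), both of
which occur in real dominant-dystonia pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence, Union

from .cohort_io import (
    Affection,
    Consequence,
    FamscreenError,
    GenotypeCall,
    Pedigree,
    VariantKey,
    VariantRecord,
    Zygosity,
    calls_index,
)

__all__ = [
    "FilterError",
    "MissingAfPolicy",
    "MissingGenotypePolicy",
    "FilterConfig",
    "FilterCascadeResult",
    "CandidateGeneMap",
    "SegregationReport",
    "apply_consequence_filter",
    "apply_frequency_filter",
    "shared_among_affected",
    "run_family_cascade",
    "cross_family_candidates",
    "segregation_report",
    "STAGE_NAMES",
]


class FilterError(FamscreenError):
    pass


class MissingAfPolicy(str, Enum):
    """What to do with variants absent from the frequency panel (novel)."""

    KEEP = "keep"
    DROP = "drop"


class MissingGenotypePolicy(str, Enum):
    """How an affected member's missing genotype affects the sharing filter."""

    FAIL_SHARING = "fail_sharing"  # conservative: the variant is removed
    IGNORE = "ignore"  # the member imposes no constraint


_EXONIC_SPLICING_DEFAULT = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.SYNONYMOUS,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_SITE,
    }
)

_PROTEIN_CHANGING_DEFAULT = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_SITE,
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds and policies of the discovery cascade."""

    maf_threshold: float = 0.01
    exonic_splicing_classes: frozenset = _EXONIC_SPLICING_DEFAULT
    protein_changing_classes: frozenset = _PROTEIN_CHANGING_DEFAULT
    missing_af_policy: MissingAfPolicy = MissingAfPolicy.KEEP
    missing_genotype_policy: MissingGenotypePolicy = MissingGenotypePolicy.FAIL_SHARING
    min_families_shared: int = 2

    def __post_init__(self):
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise FilterError(f"maf_threshold must lie in [0, 1], got {self.maf_threshold}")
        if self.min_families_shared < 1:
            raise FilterError("min_families_shared must be >= 1")
        allowed = self.exonic_splicing_classes | {Consequence.SPLICE_SITE}
        if not set(self.protein_changing_classes) <= allowed:
            raise FilterError(
                "protein_changing_classes must be a subset of "
                "exonic_splicing_classes plus splice_site"
            )


#: Ordered cascade stage names recorded in every FilterCascadeResult.
STAGE_NAMES = ("input", "exonic_splicing", "protein_changing", "rare", "shared_affected")


@dataclass
class FilterCascadeResult:
    """Ordered per-stage survivor counts and the final variant set of one family."""

    family_id: str
    stage_names: tuple = STAGE_NAMES
    stage_counts: tuple = ()
    final_variants: frozenset = frozenset()  # of VariantKey

    def __post_init__(self):
        counts = tuple(self.stage_counts)
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise FilterError(f"family {self.family_id!r}: stage counts must be non-increasing")
        if counts and counts[-1] != len(self.final_variants):
            raise FilterError(
                f"family {self.family_id!r}: final stage count {counts[-1]} does not "
                f"match {len(self.final_variants)} surviving variants"
            )


@dataclass
class CandidateGeneMap:
    """Gene -> families whose final variant sets hit it; shared subset alongside."""

    gene_families: Mapping  # gene -> frozenset of family ids
    shared_genes: tuple  # lexicographically sorted gene symbols
    gene_variants: Mapping = field(default_factory=dict)  # gene -> sorted variant keys


class SegregationStatus(str, Enum):
    HOM_ALT = "+/+"
    HET = "+/-"
    HOM_REF = "-/-"
    NOT_DETERMINED = "n.d."


@dataclass
class SegregationReport:
    """Per-member carrier status of one variant in one family, with flags.

    phenocopy_candidates: affected members carrying two reference alleles —
    their disease must have another cause if the variant is causal.
    reduced_penetrance_carriers: unaffected or unexamined members that carry
    the variant.  homozygous_carriers: members with two alternate alleles.
    """

    variant_key: VariantKey
    family_id: str
    status: Mapping  # individual id -> SegregationStatus
    phenocopy_candidates: frozenset
    reduced_penetrance_carriers: frozenset
    homozygous_carriers: frozenset


def apply_consequence_filter(
    variants: Iterable[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> list:
    """Keep protein-changing variants (cascade stages a+b), preserving order."""
    return [v for v in variants if v.consequence in cfg.protein_changing_classes]


def apply_frequency_filter(
    variants: Iterable[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> list:
    """Keep rare variants: panel_af strictly below the threshold (stage c).

    A missing panel frequency means the variant is novel; the default policy
    keeps it, since a causal variant may be absent from every panel.
    """
    out = []
    for v in variants:
        if v.panel_af is None:
            if cfg.missing_af_policy is MissingAfPolicy.KEEP:
                out.append(v)
        elif v.panel_af < cfg.maf_threshold:
            out.append(v)
    return out


def shared_among_affected(
    family: Pedigree,
    calls: Union[Iterable[GenotypeCall], Mapping],
    variants: Iterable[VariantRecord],
    cfg: FilterConfig = FilterConfig(),
) -> list:
    """Keep variants carried by every definitely affected family member (stage d).

    Carrying means het or hom_alt.  Unaffected and unknown-status members
    impose no constraint.  An affected member with a missing call fails the
    variant under ``fail_sharing`` (default) and is skipped under ``ignore``.
    """
    affected = family.affected
    if not affected:
        raise FilterError(f"family {family.family_id!r} has no affected members")
    lookup = calls_index(calls)
    out = []
    for v in variants:
        ok = True
        for m in affected:
            zyg = lookup.get((m.id, v.key), Zygosity.MISSING)
            if zyg is Zygosity.MISSING:
                if cfg.missing_genotype_policy is MissingGenotypePolicy.FAIL_SHARING:
                    ok = False
                    break
                continue
            if not zyg.carries:
                ok = False
                break
        if ok:
            out.append(v)
    return out


def run_family_cascade(
    family: Pedigree,
    variants: Sequence[VariantRecord],
    calls: Union[Iterable[GenotypeCall], Mapping],
    cfg: FilterConfig = FilterConfig(),
) -> FilterCascadeResult:
    """Run the full discovery cascade for one family.

    Stage order: input -> exonic/splicing pre-count -> protein-changing ->
    rare -> shared among affected.  Returns the ordered stage counts and the
    surviving variant keys.
    """
    variants = list(variants)
    lookup = calls_index(calls)
    exonic = [
        v
        for v in variants
        if v.consequence in (cfg.exonic_splicing_classes | {Consequence.SPLICE_SITE})
    ]
    protein = apply_consequence_filter(exonic, cfg)
    rare = apply_frequency_filter(protein, cfg)
    shared = shared_among_affected(family, lookup, rare, cfg)
    counts = (len(variants), len(exonic), len(protein), len(rare), len(shared))
    return FilterCascadeResult(
        family_id=family.family_id,
        stage_counts=counts,
        final_variants=frozenset(v.key for v in shared),
    )


def cross_family_candidates(
    results: Iterable[FilterCascadeResult],
    gene_lookup: Union[Mapping, Callable],
    cfg: FilterConfig = FilterConfig(),
) -> CandidateGeneMap:
    """Intersect per-family survivor sets at the gene level.

    ``gene_lookup`` maps a variant key to its gene symbol(s) (a mapping to a
    string/sequence, or a callable).  A gene enters ``shared_genes`` when its
    survivors come from at least ``min_families_shared`` distinct families.
    Genes are reported in lexicographic order for deterministic output.
    """
    results = list(results)
    if not results:
        raise FilterError("cross_family_candidates requires at least one cascade result")

    def genes_of(key: VariantKey):
        if callable(gene_lookup):
            g = gene_lookup(key)
        else:
            if key not in gene_lookup:
                raise FilterError(f"variant {key} missing from the gene lookup")
            g = gene_lookup[key]
        if g is None:
            raise FilterError(f"variant {key} missing from the gene lookup")
        if isinstance(g, str):
            return [p.strip() for p in g.split(";") if p.strip()]
        return list(g)

    gene_families: dict = {}
    gene_variants: dict = {}
    for res in results:
        for key in res.final_variants:
            for gene in genes_of(key):
                gene_families.setdefault(gene, set()).add(res.family_id)
                gene_variants.setdefault(gene, set()).add(key)
    shared = tuple(
        sorted(g for g, fams in gene_families.items() if len(fams) >= cfg.min_families_shared)
    )
    return CandidateGeneMap(
        gene_families={g: frozenset(f) for g, f in sorted(gene_families.items())},
        shared_genes=shared,
        gene_variants={g: tuple(sorted(v)) for g, v in sorted(gene_variants.items())},
    )


_ZYG_TO_STATUS = {
    Zygosity.HOM_ALT: SegregationStatus.HOM_ALT,
    Zygosity.HET: SegregationStatus.HET,
    Zygosity.HOM_REF: SegregationStatus.HOM_REF,
    Zygosity.MISSING: SegregationStatus.NOT_DETERMINED,
}


def segregation_report(
    variant_key: VariantKey,
    family: Pedigree,
    calls: Union[Iterable[GenotypeCall], Mapping],
) -> SegregationReport:
    """Carrier status of one variant across a pedigree, with anomaly flags.

    Members without a determined genotype are excluded from every flag set.
    """
    lookup = calls_index(calls)
    status = {}
    phenocopy = set()
    reduced = set()
    homozygous = set()
    for m in family.members:
        zyg = lookup.get((m.id, variant_key), Zygosity.MISSING)
        status[m.id] = _ZYG_TO_STATUS[zyg]
        if zyg is Zygosity.MISSING:
            continue
        if m.affection is Affection.AFFECTED and zyg is Zygosity.HOM_REF:
            phenocopy.add(m.id)
        if m.affection is not Affection.AFFECTED and zyg.carries:
            reduced.add(m.id)
        if zyg is Zygosity.HOM_ALT:
            homozygous.add(m.id)
    return SegregationReport(
        variant_key=variant_key,
        family_id=family.family_id,
        status=status,
        phenocopy_candidates=frozenset(phenocopy),
        reduced_penetrance_carriers=frozenset(reduced),
        homozygous_carriers=frozenset(homozygous),
    )
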