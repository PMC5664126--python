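"""Synthetic pedigrees, cohorts, and variant panels for pipeline validation.

The generator emulates the statistical structure the discovery and burden
analyses assume, at desk scale: a background panel of unlinked autosomal
variants with a configurable allele-frequency spectrum, one planted causal
missense variant in a designated gene, Mendelian transmission through
pedigrees, affection sampled from carrier status through a penetrance and a
phenocopy rate, and case/control cohorts with configurable carrier
enrichment.

Randomness is fully deterministic under a fixed seed: every family member
draws from its own sub-stream keyed by (seed, family id, member id), so
regenerating with a different family count or cohort composition never
perturbs the draws of untouched units.

The module also provides a closed-form expectation for the number of
background variants surviving the family filter cascade, used as an analytic
oracle against Monte-Carlo runs of the real pipeline.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np
from scipy.integrate import quad

from .cohort_io import (
    Affection,
    Consequence,
    GenotypeCall,
    Individual,
    Pedigree,
    Sex,
    VariantRecord,
    Zygosity,
)
from .family_filter import FilterConfig, MissingAfPolicy

__all__ = [
    "AlleleFrequencySpectrum",
    "FamilyTemplate",
    "SimulationConfig",
    "Panel",
    "StudyBundle",
    "STUDY_DESIGN",
    "study_cohort_totals",
    "total_subjects",
    "simulate_panel",
    "simulate_family",
    "simulate_cohorts",
    "simulate_study",
    "expected_background_survivors",
]

#: Assay-by-cohort composition of the emulated screening study: how many
#: subjects of each cohort were characterized by exome/genome sequencing,
#: Sanger sequencing, or an NGS gene panel.  This is the study design the
#: generator's default cohort sizes mirror (relatives of index patients are
#: kept as their own row because they are excluded from burden denominators).
STUDY_DESIGN = {
    "MD": {"ngs": 4, "sanger": 237, "gene_panel": 0},
    "MD_relatives": {"ngs": 6, "sanger": 8, "gene_panel": 0},
    "WD": {"ngs": 0, "sanger": 54, "gene_panel": 20},
    "other_dystonia": {"ngs": 0, "sanger": 378, "gene_panel": 226},
    "PD": {"ngs": 0, "sanger": 0, "gene_panel": 512},
    "control": {"ngs": 0, "sanger": 461, "gene_panel": 0},
}


def study_cohort_totals(design: Mapping = None) -> dict:
    """Per-cohort subject totals summed across assay modalities."""
    design = STUDY_DESIGN if design is None else design
    return {cohort: sum(counts.values()) for cohort, counts in design.items()}


def total_subjects(design: Mapping = None) -> int:
    """Grand total of subjects across every cohort of the study design."""
    return sum(study_cohort_totals(design).values())


def _rng(seed: int, *key) -> np.random.Generator:
    """Deterministic sub-stream for a (seed, key...) tuple."""
    tokens = [seed & 0x7FFFFFFF] + [zlib.crc32(repr(k).encode()) for k in key]
    return np.random.default_rng(tokens)


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Mixture describing background population allele frequencies.

    Point masses (a mass at 0 models variants absent from reference panels)
    plus a log-uniform continuous component on (lo, hi] — a crude but
    serviceable stand-in for the rare-skewed site-frequency spectrum of exome
    panels.  Weights must sum to 1.
    """

    point_masses: Tuple = ((0.0, 0.10),)  # (af, weight) pairs
    loguniform_weight: float = 0.90
    lo: float = 1e-4
    hi: float = 0.5

    def __post_init__(self):
        total = self.loguniform_weight + sum(w for _, w in self.point_masses)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum weights must sum to 1, got {total}")
        if not (0 < self.lo < self.hi <= 0.5):
            raise ValueError("continuous component must satisfy 0 < lo < hi <= 0.5")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        afs = np.empty(n)
        probs = [w for _, w in self.point_masses] + [self.loguniform_weight]
        comp = rng.choice(len(probs), size=n, p=probs)
        for i, (af, _) in enumerate(self.point_masses):
            afs[comp == i] = af
        cont = comp == len(self.point_masses)
        u = rng.random(cont.sum())
        afs[cont] = self.lo * (self.hi / self.lo) ** u
        return afs

    def expect(self, fn) -> float:
        """E[fn(af)] over the mixture (point sums + adaptive quadrature)."""
        total = sum(w * fn(af) for af, w in self.point_masses)
        if self.loguniform_weight > 0:
            log_ratio = np.log(self.hi / self.lo)
            integral, _ = quad(
                lambda x: fn(x) / (x * log_ratio), self.lo, self.hi, limit=200
            )
            total += self.loguniform_weight * integral
        return total

    def mean(self) -> float:
        return self.expect(lambda af: af)


@dataclass(frozen=True)
class FamilyTemplate:
    """Pedigree shape: two founders, then offspring counts per generation.

    Generation g+1 descends from the first child of generation g and a
    married-in founder spouse.
    """

    offspring: Tuple = (3,)

    def __post_init__(self):
        if not self.offspring or any(k < 1 for k in self.offspring):
            raise ValueError("each generation must have at least one offspring")


#: Non-protein-changing consequence mix used for background variants.
_NONCODING_MIX = (
    (Consequence.SYNONYMOUS, 0.4),
    (Consequence.INTRONIC, 0.4),
    (Consequence.UTR, 0.1),
    (Consequence.INTERGENIC, 0.1),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the synthetic generator.

    Defaults mirror a multi-family task-specific-dystonia study: a handful of
    small dominant pedigrees for discovery and screening cohorts of 241
    musician's dystonia (MD), 74 writer's dystonia (WD), 604 other-dystonia,
    512 Parkinson's disease, and 461 healthy-control index patients.
    Penetrance below 1 and a small phenocopy rate reflect the reduced
    penetrance and phenocopies routinely observed in dominant dystonia
    pedigrees.
    """

    seed: int = 0
    n_families: int = 2
    family_template: FamilyTemplate = FamilyTemplate()
    n_background_variants: int = 200
    af_spectrum: AlleleFrequencySpectrum = AlleleFrequencySpectrum()
    fraction_protein_changing: float = 0.4
    causal_gene: str = "GENE_CAUSAL"
    causal_af: float = 0.0
    penetrance: float = 0.9
    phenocopy_rate: float = 0.01
    cohort_sizes: Mapping = field(
        default_factory=lambda: {
            "MD": 241,
            "WD": 74,
            "other_dystonia": 604,
            "PD": 512,
            "control": 461,
        }
    )
    case_cohorts: Tuple = ("MD", "WD", "other_dystonia")
    control_cohorts: Tuple = ("PD", "control")
    case_carrier_freq: float = 0.01
    control_carrier_freq: float = 0.001

    def __post_init__(self):
        for name in (
            "fraction_protein_changing",
            "causal_af",
            "penetrance",
            "phenocopy_rate",
            "case_carrier_freq",
            "control_carrier_freq",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_families < 0 or self.n_background_variants < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class Panel:
    """A simulated variant panel: records plus the generative truth."""

    variants: list  # list[VariantRecord]; the causal record is last
    true_af: Mapping  # VariantKey -> population allele frequency
    causal_key: tuple


@dataclass
class StudyBundle:
    """Everything one simulated study comprises."""

    config: SimulationConfig
    panel: Panel
    families: list  # list[(Pedigree, list[GenotypeCall])]
    cohort_individuals: list
    cohort_calls: list


def simulate_panel(cfg: SimulationConfig) -> Panel:
    """Draw the background variant panel and append the planted causal variant.

    Background variants are unlinked autosomal SNVs, two per gene symbol, with
    allele frequencies from the configured spectrum; a frequency of exactly 0
    is recorded as missing panel_af (a novel variant).  Consequences are
    missense with probability ``fraction_protein_changing`` and otherwise a
    fixed mix of synonymous/intronic/UTR/intergenic classes.  The causal
    record is a missense variant in ``causal_gene``.
    """
    rng = _rng(cfg.seed, "panel")
    n = cfg.n_background_variants
    afs = cfg.af_spectrum.sample(rng, n)
    is_pc = rng.random(n) < cfg.fraction_protein_changing
    noncoding_classes = [c for c, _ in _NONCODING_MIX]
    noncoding_probs = [w for _, w in _NONCODING_MIX]
    nc_draw = rng.choice(len(noncoding_classes), size=n, p=noncoding_probs)

    variants = []
    true_af = {}
    bases = ("A", "C", "G", "T")
    for i in range(n):
        chrom = str(1 + i % 22)
        pos = 1_000_000 + 97 * i
        ref = bases[i % 4]
        alt = bases[(i + 1) % 4]
        cons = Consequence.MISSENSE if is_pc[i] else noncoding_classes[nc_draw[i]]
        af = float(afs[i])
        rec = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=f"GENE{i // 2:05d}",
            consequence=cons,
            panel_af=af if af > 0 else None,
        )
        variants.append(rec)
        true_af[rec.key] = af

    causal = VariantRecord(
        chrom="18",
        pos=8_609_447,
        ref="A",
        alt="G",
        gene=cfg.causal_gene,
        consequence=Consequence.MISSENSE,
        panel_af=cfg.causal_af if cfg.causal_af > 0 else None,
    )
    variants.append(causal)
    true_af[causal.key] = cfg.causal_af
    return Panel(variants=variants, true_af=true_af, causal_key=causal.key)


def _hw_genotype(rng, afs: np.ndarray) -> np.ndarray:
    """Sample an (n, 2) allele matrix under Hardy-Weinberg at frequencies afs."""
    return (rng.random((afs.size, 2)) < afs[:, None]).astype(np.int8)


def _zygosity(dosage: int) -> Zygosity:
    return (Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT)[dosage]


def simulate_family(
    cfg: SimulationConfig,
    panel: Panel,
    family_id: str = "FAM1",
    founder_carrier: bool = True,
):
    """Simulate one pedigree with genotypes for every panel variant.

    The template's first founder is made a heterozygous causal carrier (unless
    ``founder_carrier`` is False); the spouse draws the causal genotype under
    Hardy-Weinberg at ``causal_af``.  Founders draw background genotypes under
    Hardy-Weinberg at each variant's population frequency; offspring receive
    one uniformly chosen allele from each parent (Mendelian transmission, no
    linkage).  Affection is sampled per member: carriers of the causal variant
    are affected with probability ``penetrance``, non-carriers with
    probability ``phenocopy_rate``.

    Returns ``(Pedigree, list_of_GenotypeCall)``.
    """
    keys = [v.key for v in panel.variants]
    afs = np.array([panel.true_af[k] for k in keys])
    causal_idx = keys.index(panel.causal_key)

    alleles: dict = {}  # member id -> (n_variants, 2) int8

    def new_founder(member_id: str, carrier: bool) -> None:
        g = _hw_genotype(_rng(cfg.seed, family_id, member_id), afs)
        if carrier:
            g[causal_idx] = (1, 0)
        alleles[member_id] = g

    def new_child(member_id: str, father: str, mother: str) -> None:
        r = _rng(cfg.seed, family_id, member_id)
        pick = r.integers(0, 2, size=(afs.size, 2))
        g = np.empty((afs.size, 2), dtype=np.int8)
        g[:, 0] = alleles[father][np.arange(afs.size), pick[:, 0]]
        g[:, 1] = alleles[mother][np.arange(afs.size), pick[:, 1]]
        alleles[member_id] = g

    members = []

    def add(ind: Individual):
        members.append(ind)

    father_id, mother_id = f"{family_id}-I-1", f"{family_id}-I-2"
    new_founder(father_id, founder_carrier)
    new_founder(mother_id, False)
    add(Individual(father_id, family_id, sex=Sex.MALE))
    add(Individual(mother_id, family_id, sex=Sex.FEMALE))

    couple = (father_id, mother_id)
    for gen, k in enumerate(cfg.family_template.offspring, start=1):
        children = []
        for j in range(k):
            cid = f"{family_id}-G{gen}-{j + 1}"
            new_child(cid, couple[0], couple[1])
            sex = Sex.MALE if j % 2 == 0 else Sex.FEMALE
            add(Individual(cid, family_id, father_id=couple[0], mother_id=couple[1], sex=sex))
            children.append(cid)
        if gen < len(cfg.family_template.offspring):
            spouse = f"{family_id}-G{gen}-S"
            new_founder(spouse, False)
            add(Individual(spouse, family_id, sex=Sex.FEMALE))
            couple = (children[0], spouse)

    # affection from causal carrier status
    for ind in members:
        carrier = alleles[ind.id][causal_idx].sum() >= 1
        p = cfg.penetrance if carrier else cfg.phenocopy_rate
        affected = _rng(cfg.seed, family_id, ind.id, "affection").random() < p
        ind.affection = Affection.AFFECTED if affected else Affection.UNAFFECTED

    calls = [
        GenotypeCall(ind.id, keys[i], _zygosity(int(alleles[ind.id][i].sum())))
        for ind in members
        for i in range(len(keys))
    ]
    return Pedigree(family_id=family_id, members=members), calls


def simulate_cohorts(cfg: SimulationConfig, panel: Optional[Panel] = None):
    """Simulate unrelated case/control cohort individuals and their genotypes.

    Each individual in a case cohort is a heterozygous causal carrier with
    probability ``case_carrier_freq`` (``control_carrier_freq`` for control
    cohorts); background genotypes are Hardy-Weinberg at the panel
    frequencies.  Returns ``(individuals, calls)``.
    """
    if panel is None:
        panel = simulate_panel(cfg)
    keys = [v.key for v in panel.variants]
    afs = np.array([panel.true_af[k] for k in keys])
    causal_idx = keys.index(panel.causal_key)

    individuals = []
    calls = []
    for cohort in cfg.cohort_sizes:
        size = cfg.cohort_sizes[cohort]
        if cohort in cfg.case_cohorts:
            freq, affection = cfg.case_carrier_freq, Affection.AFFECTED
        elif cohort in cfg.control_cohorts:
            freq, affection = cfg.control_carrier_freq, Affection.UNAFFECTED
        else:
            raise ValueError(f"cohort {cohort!r} is neither case nor control")
        for i in range(size):
            sid = f"{cohort}-{i + 1:04d}"
            r = _rng(cfg.seed, "cohort", cohort, sid)
            g = _hw_genotype(r, afs)
            g[causal_idx] = (1, 0) if r.random() < freq else (0, 0)
            individuals.append(
                Individual(sid, cohort=cohort, affection=affection, is_index=True)
            )
            calls.extend(
                GenotypeCall(sid, keys[j], _zygosity(int(g[j].sum())))
                for j in range(len(keys))
            )
    return individuals, calls


def simulate_study(cfg: SimulationConfig) -> StudyBundle:
    """Simulate the whole study: panel, discovery families, screening cohorts."""
    panel = simulate_panel(cfg)
    families = [
        simulate_family(cfg, panel, family_id=f"FAM{i + 1}") for i in range(cfg.n_families)
    ]
    individuals, calls = simulate_cohorts(cfg, panel)
    return StudyBundle(
        config=cfg,
        panel=panel,
        families=families,
        cohort_individuals=individuals,
        cohort_calls=calls,
    )


# ---------------------------------------------------------------------------
# Closed-form cascade expectation
# ---------------------------------------------------------------------------

_HW_CACHE_DOSES = np.array([0, 1, 2])


def _hw_probs(af: float) -> np.ndarray:
    q = 1.0 - af
    return np.array([q * q, 2 * af * q, af * af])


def _binom(k: int, n: int, p: float) -> float:
    from math import comb

    return comb(n, k) * p**k * (1 - p) ** (n - k)


def expected_background_survivors(
    cfg: SimulationConfig, filter_cfg: FilterConfig = FilterConfig()
) -> float:
    """Expected background variants surviving the full family cascade.

    Computed in closed form from the generative model for a single-generation
    template (two founders, k children): the expectation factorizes as

        n_background x P(consequence qualifies) x E_af[ rare(af) x share(af) ]

    where ``share(af)`` marginalizes over the mother's causal genotype, the
    children's causal transmissions, the affection indicators they induce, and
    the founders' background genotypes at frequency ``af``.  An empty affected
    set counts as sharing vacuously (the cascade itself refuses such
    families; use penetrance high enough to make the event negligible when
    comparing against Monte-Carlo runs).  The continuous spectrum component is
    integrated by adaptive quadrature.
    """
    if len(cfg.family_template.offspring) != 1:
        raise ValueError("closed form supports single-generation templates only")
    k = cfg.family_template.offspring[0]
    pen, phi, q = cfg.penetrance, cfg.phenocopy_rate, cfg.causal_af

    # P(consequence in the qualifying set) under the generator's mix
    p_qual = 0.0
    if Consequence.MISSENSE in filter_cfg.protein_changing_classes:
        p_qual += cfg.fraction_protein_changing
    for cons, w in _NONCODING_MIX:
        if cons in filter_cfg.protein_changing_classes:
            p_qual += (1 - cfg.fraction_protein_changing) * w

    hw_causal_mother = _hw_probs(q)

    def share_given_af(af: float) -> float:
        """P(all affected members carry a background variant at frequency af)."""
        hw = _hw_probs(af)
        total = 0.0
        for gm_causal, p_gm in enumerate(hw_causal_mother):
            # child causal-carrier probability given father het, mother gm_causal
            p_child_carrier = 1.0 - 0.5 * (1.0 - gm_causal / 2.0)
            p_child_aff = p_child_carrier * pen + (1 - p_child_carrier) * phi
            p_mother_aff = pen if gm_causal >= 1 else phi
            for fa in (0, 1):  # father affected? (father is always a carrier)
                p_fa = pen if fa else 1 - pen
                for ma in (0, 1):
                    p_ma = p_mother_aff if ma else 1 - p_mother_aff
                    for j in range(k + 1):  # affected children count
                        p_j = _binom(j, k, p_child_aff)
                        weight = p_gm * p_fa * p_ma * p_j
                        if weight == 0.0:
                            continue
                        total += weight * _share_prob(hw, fa, ma, j)
        return total

    def _share_prob(hw: np.ndarray, fa: int, ma: int, j: int) -> float:
        """P(required members all carry), enumerating founder genotypes."""
        s = 0.0
        for gf, p_gf in enumerate(hw):
            if fa and gf == 0:
                continue
            for gm, p_gm in enumerate(hw):
                if ma and gm == 0:
                    continue
                p_child = 1.0 - (1.0 - gf / 2.0) * (1.0 - gm / 2.0)
                s += p_gf * p_gm * p_child**j
        return s

    thr = filter_cfg.maf_threshold
    keep_missing = filter_cfg.missing_af_policy is MissingAfPolicy.KEEP

    def integrand(af: float) -> float:
        if af == 0.0:
            rare = 1.0 if keep_missing else 0.0
        else:
            rare = 1.0 if af < thr else 0.0
        if rare == 0.0:
            return 0.0
        return share_given_af(af)

    return cfg.n_background_variants * p_qual * cfg.af_spectrum.expect(integrand)
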