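"""Readers and writers for the formats the pipeline touches.

The internal data model is deliberately small: a :class:`VariantRecord` is one
normalized biallelic variant (multi-allelic VCF records are split on read), a
:class:`GenotypeCall` is one sample's zygosity at one variant, and a
:class:`Pedigree` groups :class:`Individual` members of one family.  Variant
annotation (gene, consequence class, reference-panel allele frequency, external
predictor scores) lives in a sidecar TSV rather than in INFO fields, because
annotation dialects vary by vendor; the TSV is canonical.

Coordinates are VCF-native: 1-based, inclusive.  Indels are left-trimmed to a
minimal representation before key construction so annotation keys always match
VCF keys.  Half-calls and non-diploid genotypes map to ``missing`` — the model
is autosomal and diploid only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "FamscreenError",
    "VcfParseError",
    "PedError",
    "AnnotationError",
    "Consequence",
    "Zygosity",
    "VariantKey",
    "VariantRecord",
    "GenotypeCall",
    "Individual",
    "Pedigree",
    "Annotation",
    "normalize_variant",
    "read_vcf",
    "write_vcf",
    "read_annotation_table",
    "write_annotation_table",
    "apply_annotation",
    "read_ped",
    "write_ped",
    "read_cohort_table",
    "write_cohort_table",
    "assign_cohorts",
    "calls_index",
]


class FamscreenError(Exception):
    """Base class for all errors raised by this package."""


class VcfParseError(FamscreenError):
    pass


class PedError(FamscreenError):
    pass


class AnnotationError(FamscreenError):
    pass


class Consequence(str, Enum):
    """Functional consequence class of a variant on its gene."""

    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    UTR = "utr"
    OTHER = "other"

    @classmethod
    def from_string(cls, s: str) -> "Consequence":
        """Map a free-text consequence string to the enum; unknown -> OTHER."""
        try:
            return cls(s.strip().lower())
        except ValueError:
            return cls.OTHER


class Zygosity(str, Enum):
    """Diploid genotype class at a biallelic site.

    Reported in pedigree figures as -/- (hom_ref), +/- (het), +/+ (hom_alt).
    """

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries(self) -> bool:
        """True if at least one alternate allele is present."""
        return self in (Zygosity.HET, Zygosity.HOM_ALT)

    @property
    def dosage(self) -> Optional[int]:
        """Alternate-allele count, or None when the call is missing."""
        return {
            Zygosity.HOM_REF: 0,
            Zygosity.HET: 1,
            Zygosity.HOM_ALT: 2,
        }.get(self)

    @property
    def symbol(self) -> str:
        """Pedigree-figure notation for this genotype class."""
        return {
            Zygosity.HOM_REF: "-/-",
            Zygosity.HET: "+/-",
            Zygosity.HOM_ALT: "+/+",
            Zygosity.MISSING: "n.d.",
        }[self]


#: (chrom, pos, ref, alt) — the canonical identity of a normalized variant.
VariantKey = tuple  # tuple[str, int, str, str]


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Left-align and minimally represent a ref/alt pair.

    Shared trailing bases are trimmed first, then shared leading bases (the
    position advances with each leading trim); at least one base is kept on
    each side.  SNVs pass through unchanged.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


@dataclass(frozen=True)
class VariantRecord:
    """One normalized biallelic variant with its annotation.

    ``gene`` may hold several symbols separated by ``;`` (a variant in
    overlapping genes counts once per gene).  ``panel_af`` is the
    alternate-allele fraction in a reference panel (dbSNP/ExAC/GnomAD style);
    ``None`` means the variant is absent from the panel (novel).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequence: Consequence = Consequence.OTHER
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    panel_af: Optional[float] = None
    rsid: Optional[str] = None
    predictor_scores: Optional[Mapping[str, str]] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        if self.panel_af is not None and not (0.0 <= self.panel_af <= 1.0):
            raise ValueError(f"panel_af must lie in [0, 1], got {self.panel_af}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def genes(self) -> tuple:
        """Gene symbols annotated on this variant (possibly several)."""
        if not self.gene:
            return ()
        return tuple(g for g in (p.strip() for p in self.gene.split(";")) if g)


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid genotype class at one variant."""

    sample_id: str
    variant_key: VariantKey
    zygosity: Zygosity


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass
class Individual:
    """A study subject: pedigree position, affection status, cohort label.

    ``is_index`` marks cohort index patients (probands); relatives of an index
    patient carry ``is_index=False`` and are excluded from burden denominators.
    """

    id: str
    family_id: Optional[str] = None
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    phenotype_tag: Optional[str] = None
    cohort: Optional[str] = None
    is_index: bool = True


@dataclass
class Pedigree:
    """One family: a set of members whose parent references resolve locally."""

    family_id: str
    members: list  # list[Individual]

    def __post_init__(self):
        if not self.members:
            raise PedError(f"pedigree {self.family_id!r} has no members")
        ids = {m.id for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise PedError(
                        f"family {self.family_id!r}: member {m.id!r} references "
                        f"parent {pid!r} absent from the family"
                    )
        self._check_acyclic()

    def _check_acyclic(self):
        by_id = {m.id: m for m in self.members}
        state: dict = {}  # 0 visiting, 1 done

        for start in by_id:
            if start in state:
                continue
            stack = [(start, iter(self._parents(by_id[start])))]
            state[start] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if state.get(p) == 0:
                        raise PedError(
                            f"family {self.family_id!r}: cyclic parentage involving {p!r}"
                        )
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(self._parents(by_id[p]))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    @staticmethod
    def _parents(m: Individual):
        return [p for p in (m.father_id, m.mother_id) if p is not None]

    def member(self, individual_id: str) -> Individual:
        for m in self.members:
            if m.id == individual_id:
                return m
        raise KeyError(individual_id)

    @property
    def affected(self) -> list:
        """Members with definite affected status."""
        return [m for m in self.members if m.affection is Affection.AFFECTED]

    @property
    def founders(self) -> list:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]


@dataclass(frozen=True)
class Annotation:
    """Sidecar annotation for one variant key."""

    gene: str
    consequence: Consequence
    panel_af: Optional[float]
    predictor_scores: Mapping[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _precheck_vcf(path: Union[str, Path]) -> int:
    """Structural validation pass: constant column count, GT in FORMAT.

    Returns the number of samples.  Raises :class:`VcfParseError` naming the
    offending line for malformed bodies, before handing the file to htslib
    (whose own errors do not carry line numbers).
    """
    n_cols = None
    n_samples = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 8:
                    raise VcfParseError(f"line {lineno}: truncated #CHROM header line")
                n_cols = len(cols)
                n_samples = max(0, n_cols - 9)
                continue
            if n_cols is None:
                raise VcfParseError(f"line {lineno}: data before #CHROM header line")
            cols = line.split("\t")
            if len(cols) != n_cols:
                raise VcfParseError(
                    f"line {lineno}: expected {n_cols} columns, found {len(cols)}"
                )
            if n_samples and "GT" not in cols[8].split(":"):
                raise VcfParseError(f"line {lineno}: FORMAT lacks a GT field")
    if n_cols is None:
        raise VcfParseError(f"{path}: no #CHROM header line found")
    return n_samples


def read_vcf(path: Union[str, Path]):
    """Read a VCF (v4.2, GT required) into variants and genotype calls.

    Multi-allelic records are split into one :class:`VariantRecord` per
    alternate allele; each split pair is re-normalized.  A genotype call is
    produced for every sample x variant.  ``./.``, half-calls, and non-diploid
    genotypes become :attr:`Zygosity.MISSING`.

    Returns
    -------
    (variants, calls) : (list of VariantRecord, list of GenotypeCall)
    """
    path = str(path)
    _precheck_vcf(path)
    variants: list = []
    calls: list = []
    vcf = VCF(path)
    samples = list(vcf.samples)
    try:
        for rec in vcf:
            gts = rec.genotypes if samples else []
            for alt_idx, alt in enumerate(rec.ALT):
                key = normalize_variant(rec.CHROM, rec.POS, rec.REF, alt)
                variants.append(
                    VariantRecord(*key, rsid=rec.ID if rec.ID else None)
                )
                allele_no = alt_idx + 1
                for sample, gt in zip(samples, gts):
                    alleles = gt[:-1]  # last element is the phasing flag
                    if len(alleles) != 2 or any(a < 0 for a in alleles):
                        zyg = Zygosity.MISSING
                    else:
                        dose = sum(1 for a in alleles if a == allele_no)
                        zyg = (Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT)[dose]
                    calls.append(GenotypeCall(sample, key, zyg))
    except VcfParseError:
        raise
    except Exception as exc:  # htslib-level failures
        raise VcfParseError(f"{path}: {exc}") from exc
    finally:
        vcf.close()
    return variants, calls


_ZYG_TO_GT = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HET: "0/1",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.MISSING: "./.",
}


def write_vcf(path, variants, calls, samples: Optional[Sequence[str]] = None):
    """Write biallelic variants and genotype calls as a VCF v4.2 text file.

    ``samples`` fixes the column order; by default samples appear in first-seen
    order in ``calls``.  Variants are emitted in (chrom, pos, ref, alt) order.
    """
    if samples is None:
        seen: dict = {}
        for c in calls:
            seen.setdefault(c.sample_id, None)
        samples = list(seen)
    lookup = {(c.sample_id, c.variant_key): c.zygosity for c in calls}
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            header += ["FORMAT"] + list(samples)
        fh.write("\t".join(header) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            row = [v.chrom, str(v.pos), v.rsid or ".", v.ref, v.alt, ".", ".", "."]
            if samples:
                row.append("GT")
                for s in samples:
                    row.append(_ZYG_TO_GT[lookup.get((s, v.key), Zygosity.MISSING)])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Annotation sidecar TSV
# ---------------------------------------------------------------------------

_ANN_REQUIRED = ["chrom", "pos", "ref", "alt", "gene", "consequence", "panel_af"]
_ANN_OPTIONAL = ["hgvs_c", "hgvs_p", "rsid"]


def read_annotation_table(path) -> dict:
    """Read the sidecar annotation TSV into a map ``variant_key -> Annotation``.

    Required columns: chrom, pos, ref, alt, gene, consequence, panel_af.
    Blank panel_af means the variant is absent from the panel; unknown
    consequence strings map to ``other``.  Any additional columns are carried
    through verbatim as predictor scores.  Duplicate keys are tolerated when
    the gene agrees and rejected otherwise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANN_REQUIRED if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c not in _ANN_REQUIRED + _ANN_OPTIONAL]
    out: dict = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            pos = int(d["pos"])
        except ValueError:
            raise AnnotationError(f"{path}: non-integer position {d['pos']!r}")
        key = normalize_variant(str(d["chrom"]), pos, d["ref"], d["alt"])
        af_s = d["panel_af"].strip()
        af = float(af_s) if af_s else None
        if af is not None and not (0.0 <= af <= 1.0):
            raise AnnotationError(f"{path}: panel_af {af} out of [0, 1] for {key}")
        scores = {c: d[c] for c in extra_cols if d[c].strip() != ""}
        ann = Annotation(
            gene=d["gene"].strip(),
            consequence=Consequence.from_string(d["consequence"]),
            panel_af=af,
            predictor_scores=scores,
        )
        if key in out and out[key].gene != ann.gene:
            raise AnnotationError(
                f"{path}: duplicate annotation for {key} with conflicting genes "
                f"{out[key].gene!r} vs {ann.gene!r}"
            )
        out.setdefault(key, ann)
    return out


def write_annotation_table(path, variants: Iterable[VariantRecord]):
    """Write VariantRecords as the canonical annotation sidecar TSV."""
    score_cols: list = []
    rows = []
    variants = list(variants)
    for v in variants:
        for k in (v.predictor_scores or {}):
            if k not in score_cols:
                score_cols.append(k)
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene or "",
            "consequence": v.consequence.value,
            "panel_af": "" if v.panel_af is None else repr(float(v.panel_af)),
        }
        for k in score_cols:
            row[k] = (v.predictor_scores or {}).get(k, "")
        rows.append(row)
    pd.DataFrame(rows, columns=_ANN_REQUIRED + score_cols).to_csv(
        path, sep="\t", index=False
    )


def apply_annotation(variants: Iterable[VariantRecord], annotation: Mapping) -> list:
    """Return variants with gene/consequence/panel_af filled from the sidecar.

    Variants absent from the annotation map keep their existing fields (and
    therefore, with default OTHER consequence, drop out of consequence
    filtering downstream).
    """
    out = []
    for v in variants:
        ann = annotation.get(v.key)
        if ann is None:
            out.append(v)
        else:
            out.append(
                replace(
                    v,
                    gene=ann.gene,
                    consequence=ann.consequence,
                    panel_af=ann.panel_af,
                    predictor_scores=dict(ann.predictor_scores) or None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_CODE = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFF_CODE = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}


def read_ped(path) -> list:
    """Read a 6(+1)-column whitespace-delimited PED file into pedigrees.

    Columns: FID IID PAT MAT SEX PHENO [cohort].  PHENO 2 means affected,
    1 unaffected, 0 or -9 unknown.  "0" parent ids become None.  Individuals
    with FID "0" are singletons and form one-member pedigrees keyed by their
    own id.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 6:
                raise PedError(f"{path} line {lineno}: expected >= 6 columns, found {len(toks)}")
            rows.append((lineno, toks))

    families: dict = {}
    for lineno, toks in rows:
        fid, iid, pat, mat, sex, pheno = toks[:6]
        cohort = toks[6] if len(toks) > 6 else None
        ind = Individual(
            id=iid,
            family_id=None if fid == "0" else fid,
            father_id=None if pat == "0" else pat,
            mother_id=None if mat == "0" else mat,
            sex=_SEX_CODE.get(sex, Sex.UNKNOWN),
            affection=_AFF_CODE.get(pheno, Affection.UNKNOWN),
            cohort=cohort,
        )
        group = fid if fid != "0" else iid
        families.setdefault(group, []).append(ind)
    return [Pedigree(family_id=fid, members=members) for fid, members in families.items()]


def write_ped(path, pedigrees: Iterable[Pedigree], include_cohort: bool = False):
    """Write pedigrees back to the 6(+1)-column PED dialect read_ped accepts."""
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_code = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                row = [
                    m.family_id or "0",
                    m.id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    sex_code[m.sex],
                    aff_code[m.affection],
                ]
                if include_cohort:
                    row.append(m.cohort or "NA")
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Cohort roster TSV
# ---------------------------------------------------------------------------


def read_cohort_table(path) -> dict:
    """Read a cohort roster TSV: sample_id, cohort, optional is_index (0/1).

    Returns ``sample_id -> (cohort, is_index)``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "cohort"):
        if col not in df.columns:
            raise AnnotationError(f"{path}: missing required column {col!r}")
    out = {}
    for row in df.itertuples(index=False):
        is_index = True
        if "is_index" in df.columns:
            is_index = str(getattr(row, "is_index")).strip() not in ("0", "false", "False")
        out[row.sample_id] = (row.cohort, is_index)
    return out


def write_cohort_table(path, individuals: Iterable[Individual]):
    rows = [
        {"sample_id": i.id, "cohort": i.cohort or "NA", "is_index": int(i.is_index)}
        for i in individuals
    ]
    pd.DataFrame(rows, columns=["sample_id", "cohort", "is_index"]).to_csv(
        path, sep="\t", index=False
    )


def assign_cohorts(individuals: Iterable[Individual], roster: Mapping) -> None:
    """Apply a cohort roster to individuals in place.

    The roster wins over any cohort label already present (e.g. from a
    7-column PED).
    """
    for ind in individuals:
        if ind.id in roster:
            cohort, is_index = roster[ind.id]
            ind.cohort = cohort
            ind.is_index = is_index


def calls_index(calls: Union[Iterable[GenotypeCall], Mapping]) -> Mapping:
    """Normalize genotype calls to a ``(sample_id, variant_key) -> Zygosity`` map."""
    if isinstance(calls, Mapping):
        return calls
    return {(c.sample_id, c.variant_key): c.zygosity for c in calls}
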