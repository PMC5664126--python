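"""Reproducible pipeline runs: simulate, discover, screen, burden.

Each run is driven by one YAML config with a section per subcommand; all
paths in the config resolve relative to the config file's directory.  Every
run writes a ``manifest.json`` recording the config hash, input checksums,
tool version, and emitted reports — re-running with identical inputs yields
byte-identical outputs (no timestamps enter any report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .cohort_io import (
    FamscreenError,
    apply_annotation,
    calls_index,
    read_annotation_table,
    read_cohort_table,
    read_ped,
    read_vcf,
    write_annotation_table,
    write_cohort_table,
    write_ped,
    write_vcf,
)
from .cohort_screen import (
    build_burden_table,
    default_qualifying,
    summarize_carriers,
    tally_carriers,
)
from .assoc_stats import fisher_exact_two_tailed
from .family_filter import (
    FilterConfig,
    MissingAfPolicy,
    MissingGenotypePolicy,
    cross_family_candidates,
    run_family_cascade,
    segregation_report,
)
from .synthetic_data import (
    AlleleFrequencySpectrum,
    FamilyTemplate,
    SimulationConfig,
    simulate_study,
)

__all__ = [
    "ConfigError",
    "load_config",
    "filter_config_from_dict",
    "run_simulate",
    "run_discovery",
    "run_screen",
    "run_burden",
]

logger = logging.getLogger("famscreen")


class ConfigError(FamscreenError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config_path) -> tuple:
    """Load the YAML config; returns (config dict, base directory)."""
    config_path = Path(config_path)
    if not config_path.exists():
        raise ConfigError(f"config file not found: {config_path}")
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg, config_path.parent


def filter_config_from_dict(d: Optional[Mapping]) -> FilterConfig:
    d = dict(d or {})
    kwargs = {}
    if "maf_threshold" in d:
        kwargs["maf_threshold"] = float(d.pop("maf_threshold"))
    if "min_families_shared" in d:
        kwargs["min_families_shared"] = int(d.pop("min_families_shared"))
    if "missing_af_policy" in d:
        kwargs["missing_af_policy"] = MissingAfPolicy(d.pop("missing_af_policy"))
    if "missing_genotype_policy" in d:
        kwargs["missing_genotype_policy"] = MissingGenotypePolicy(
            d.pop("missing_genotype_policy")
        )
    if d:
        raise ConfigError(f"unknown filter option(s): {sorted(d)}")
    return FilterConfig(**kwargs)


def _resolve(base: Path, rel) -> Path:
    p = Path(rel)
    return p if p.is_absolute() else base / p


def _require(section: Mapping, key: str, where: str):
    if key not in section:
        raise ConfigError(f"config section {where!r} missing required key {key!r}")
    return section[key]


def _write_manifest(out_dir: Path, config_blob: bytes, inputs: dict, outputs: list,
                    seed: Optional[int] = None) -> Path:
    manifest = {
        "tool": "famscreen",
        "version": __version__,
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "inputs": {Path(k).name: v for k, v in sorted(inputs.items())},
        "outputs": sorted(Path(o).name for o in outputs),
    }
    if seed is not None:
        manifest["seed"] = seed
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _sim_config_from_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    d.pop("out", None)
    if "family_template" in d:
        d["family_template"] = FamilyTemplate(tuple(d["family_template"]))
    if "af_spectrum" in d:
        spec = dict(d["af_spectrum"])
        if "point_masses" in spec:
            spec["point_masses"] = tuple(tuple(pm) for pm in spec["point_masses"])
        d["af_spectrum"] = AlleleFrequencySpectrum(**spec)
    if "case_cohorts" in d:
        d["case_cohorts"] = tuple(d["case_cohorts"])
    if "control_cohorts" in d:
        d["control_cohorts"] = tuple(d["control_cohorts"])
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ConfigError(f"unknown simulate option(s): {sorted(unknown)}")
    return SimulationConfig(**d)


def run_simulate(config_path, out_dir=None) -> dict:
    """Simulate a study and write its VCF/PED/annotation/cohort fixtures."""
    cfg, base = load_config(config_path)
    section = cfg.get("simulate", {})
    sim_cfg = _sim_config_from_dict(section)
    out = Path(out_dir) if out_dir else _resolve(base, _require(section, "out", "simulate"))
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulating study with seed %d", sim_cfg.seed)

    bundle = simulate_study(sim_cfg)
    fam_variants = bundle.panel.variants
    fam_calls = [c for _, calls in bundle.families for c in calls]
    fam_samples = [m.id for ped, _ in bundle.families for m in ped.members]

    outputs = []

    def emit(name, writer, *args, **kwargs):
        path = out / name
        writer(path, *args, **kwargs)
        outputs.append(path)

    emit("discovery.vcf", write_vcf, fam_variants, fam_calls, samples=fam_samples)
    emit("families.ped", write_ped, [ped for ped, _ in bundle.families])
    emit("annotation.tsv", write_annotation_table, fam_variants)
    emit(
        "cohorts.vcf",
        write_vcf,
        fam_variants,
        bundle.cohort_calls,
        samples=[i.id for i in bundle.cohort_individuals],
    )
    emit("cohorts.tsv", write_cohort_table, bundle.cohort_individuals)

    blob = yaml.safe_dump(section, sort_keys=True).encode()
    manifest = _write_manifest(out, blob, {}, outputs, seed=sim_cfg.seed)
    return {"out_dir": str(out), "manifest": str(manifest), "outputs": [str(o) for o in outputs]}


def run_discovery(config_path, out_dir=None) -> dict:
    """Run the per-family cascade, gene intersection, and segregation reports.

    Emits: ``cascade.tsv`` (family, stage, count), ``candidate_genes.tsv``
    (gene, n_families, family ids, variant keys), one ``segregation_*.tsv``
    per shared-gene variant per family, and ``manifest.json``.
    """
    cfg, base = load_config(config_path)
    section = cfg.get("discover")
    if section is None:
        raise ConfigError("config has no 'discover' section")
    filter_cfg = filter_config_from_dict(section.get("filter"))
    vcf_path = _resolve(base, _require(section, "vcf", "discover"))
    ped_path = _resolve(base, _require(section, "ped", "discover"))
    ann_path = _resolve(base, _require(section, "annotation", "discover"))
    for p in (vcf_path, ped_path, ann_path):
        if not p.exists():
            raise ConfigError(f"input file not found: {p}")
    out = Path(out_dir) if out_dir else _resolve(base, _require(section, "out", "discover"))
    out.mkdir(parents=True, exist_ok=True)

    variants, calls = read_vcf(vcf_path)
    annotation = read_annotation_table(ann_path)
    variants = apply_annotation(variants, annotation)
    pedigrees = read_ped(ped_path)
    lookup = calls_index(calls)

    results = [run_family_cascade(ped, variants, lookup, filter_cfg) for ped in pedigrees]
    gene_lookup = {v.key: v.gene for v in variants if v.gene}
    candidates = cross_family_candidates(results, gene_lookup, filter_cfg)
    if not candidates.shared_genes:
        logger.warning("no gene shared by >= %d families", filter_cfg.min_families_shared)

    outputs = []
    cascade_rows = [
        {"family_id": r.family_id, "stage": s, "count": c}
        for r in results
        for s, c in zip(r.stage_names, r.stage_counts)
    ]
    cascade_path = out / "cascade.tsv"
    pd.DataFrame(cascade_rows, columns=["family_id", "stage", "count"]).to_csv(
        cascade_path, sep="\t", index=False
    )
    outputs.append(cascade_path)

    cand_rows = [
        {
            "gene": g,
            "n_families": len(candidates.gene_families[g]),
            "family_ids": ",".join(sorted(candidates.gene_families[g])),
            "variant_keys": ",".join(
                f"{c}:{p}:{r}:{a}" for c, p, r, a in candidates.gene_variants[g]
            ),
            "shared": int(g in candidates.shared_genes),
        }
        for g in candidates.gene_families
    ]
    cand_path = out / "candidate_genes.tsv"
    pd.DataFrame(
        cand_rows, columns=["gene", "n_families", "family_ids", "variant_keys", "shared"]
    ).to_csv(cand_path, sep="\t", index=False)
    outputs.append(cand_path)

    by_id = {ped.family_id: ped for ped in pedigrees}
    for g in candidates.shared_genes:
        seg_rows = []
        for key in candidates.gene_variants[g]:
            for fid in sorted(candidates.gene_families[g]):
                rep = segregation_report(key, by_id[fid], lookup)
                for mid, status in sorted(rep.status.items()):
                    seg_rows.append(
                        {
                            "family_id": fid,
                            "variant": f"{key[0]}:{key[1]}:{key[2]}:{key[3]}",
                            "individual": mid,
                            "status": status.value,
                            "phenocopy_candidate": int(mid in rep.phenocopy_candidates),
                            "reduced_penetrance_carrier": int(
                                mid in rep.reduced_penetrance_carriers
                            ),
                            "homozygous_carrier": int(mid in rep.homozygous_carriers),
                        }
                    )
        seg_path = out / f"segregation_{g}.tsv"
        pd.DataFrame(
            seg_rows,
            columns=[
                "family_id", "variant", "individual", "status",
                "phenocopy_candidate", "reduced_penetrance_carrier", "homozygous_carrier",
            ],
        ).to_csv(seg_path, sep="\t", index=False)
        outputs.append(seg_path)

    blob = yaml.safe_dump(section, sort_keys=True).encode()
    inputs = {str(p): _sha256(p) for p in (vcf_path, ped_path, ann_path)}
    manifest = _write_manifest(out, blob, inputs, outputs)
    return {
        "out_dir": str(out),
        "manifest": str(manifest),
        "shared_genes": list(candidates.shared_genes),
        "cascades": {r.family_id: list(r.stage_counts) for r in results},
        "outputs": [str(o) for o in outputs],
    }


def _load_cohort_inputs(section, base, where):
    vcf_path = _resolve(base, _require(section, "vcf", where))
    ann_path = _resolve(base, _require(section, "annotation", where))
    roster_path = _resolve(base, _require(section, "cohorts", where))
    for p in (vcf_path, ann_path, roster_path):
        if not p.exists():
            raise ConfigError(f"input file not found: {p}")
    variants, calls = read_vcf(vcf_path)
    variants = apply_annotation(variants, read_annotation_table(ann_path))
    roster = read_cohort_table(roster_path)
    from .cohort_io import Individual

    individuals = [
        Individual(sid, cohort=cohort, is_index=is_index)
        for sid, (cohort, is_index) in roster.items()
    ]
    inputs = {str(p): _sha256(p) for p in (vcf_path, ann_path, roster_path)}
    return variants, calls, individuals, inputs


def run_screen(config_path, out_dir=None) -> dict:
    """Tally per-variant, per-cohort carrier counts into a screening table."""
    cfg, base = load_config(config_path)
    section = cfg.get("screen")
    if section is None:
        raise ConfigError("config has no 'screen' section")
    out = Path(out_dir) if out_dir else _resolve(base, _require(section, "out", "screen"))
    out.mkdir(parents=True, exist_ok=True)
    variants, calls, individuals, inputs = _load_cohort_inputs(section, base, "screen")
    qualifying = default_qualifying(float(section.get("maf_threshold", 0.01)))
    table = tally_carriers(individuals, variants, calls, qualifying)
    path = out / "carrier_table.tsv"
    table.to_dataframe().to_csv(path, sep="\t", index=False)
    blob = yaml.safe_dump(section, sort_keys=True).encode()
    manifest = _write_manifest(out, blob, inputs, [path])
    return {"out_dir": str(out), "manifest": str(manifest), "carrier_table": str(path)}


def run_burden(config_path, out_dir=None) -> dict:
    """Individual-level burden comparison with a two-tailed Fisher exact test.

    Returns (and writes as ``burden.json``) the per-group carrier summaries,
    the 2x2 table, and the exact p-value.
    """
    cfg, base = load_config(config_path)
    section = cfg.get("burden")
    if section is None:
        raise ConfigError("config has no 'burden' section")
    out = Path(out_dir) if out_dir else _resolve(base, _require(section, "out", "burden"))
    out.mkdir(parents=True, exist_ok=True)
    variants, calls, individuals, inputs = _load_cohort_inputs(section, base, "burden")
    case_cohorts = list(_require(section, "case_cohorts", "burden"))
    control_cohorts = list(_require(section, "control_cohorts", "burden"))
    qualifying = default_qualifying(float(section.get("maf_threshold", 0.01)))
    summary = summarize_carriers(
        individuals,
        variants,
        calls,
        groups={"cases": case_cohorts, "controls": control_cohorts},
        qualifying=qualifying,
    )
    cases = summary.groups["cases"]
    controls = summary.groups["controls"]
    table = build_burden_table(
        cases.n_carriers, cases.n_individuals, controls.n_carriers, controls.n_individuals
    )
    result = fisher_exact_two_tailed(table)
    report = {
        "groups": {
            label: {
                "n_individuals": s.n_individuals,
                "n_carriers": s.n_carriers,
                "percent": s.percent,
            }
            for label, s in summary.groups.items()
        },
        "table": [[table.a, table.b], [table.c, table.d]],
        "test": "fisher_exact_two_tailed",
        "p_value": result.p_value,
        "maf_threshold": float(section.get("maf_threshold", 0.01)),
        "case_cohorts": case_cohorts,
        "control_cohorts": control_cohorts,
    }
    path = out / "burden.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    blob = yaml.safe_dump(section, sort_keys=True).encode()
    _write_manifest(out, blob, inputs, [path])
    return report
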