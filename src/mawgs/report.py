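"""Pipeline orchestration and publication-style outputs.

``run_pipeline`` ties the stages together: QC (contamination then depth
filters) -> annotation (site inventory + per-mutation classes) -> rate
and spectrum estimation with the group comparisons.  Results land in an
output directory as TSV tables (mutational-features table, rate/CI
table, region rates, 64-cell context matrices, enrichment scans), a QC
report, and one ``summary.json`` holding every reported number at full
precision.  Human-readable tables round rates to three significant
figures and ratios/chi-squares to two decimals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import io as mio
from .annotate import (
    GenomeAnnotator,
    SPECTRUM_CLASSES,
    TRANSITION_CLASSES,
    TRANSVERSION_CLASSES,
)
from .core import LineMetadata, MawgsError, MutationAnnotation, RateEstimate
from .qc import apply_qc
from .rates import (
    context_rate_matrix,
    count_comparison_test,
    effective_population_size,
    gene_enrichment_scan,
    gof_test_ns_s,
    mutation_rate,
    rate_ratio_test,
    spectrum_table,
)

log = logging.getLogger("mawgs")


@dataclass
class PipelineConfig:
    fasta: str
    gff3: str
    vcf_dir: str
    metadata: str
    out_dir: str
    min_depth: float = 30.0
    ci_level: float = 0.95
    ssr_min_copies: int = 3
    ssr_min_tract_bp: int = 5
    ssr_max_motif: int = 6
    ssr_flank_bp: int = 1
    seed: int = 0
    control_label: str = "control"
    treatment_label: str = "treatment"

    def validate(self) -> None:
        for name in ("fasta", "gff3", "metadata"):
            if not Path(getattr(self, name)).exists():
                raise MawgsError(f"config path {name}={getattr(self, name)} not found")
        if not Path(self.vcf_dir).is_dir():
            raise MawgsError(f"vcf_dir {self.vcf_dir} is not a directory")
        if self.min_depth < 0 or not 0 < self.ci_level < 1:
            raise MawgsError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise MawgsError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class ReportBundle:
    summary: dict
    paths: Dict[str, str]


@dataclass
class DesignSummary:
    per_group: pd.DataFrame
    per_line: pd.DataFrame
    warnings: List[str] = field(default_factory=list)


def summarize_experiment(metadata: Sequence[LineMetadata]) -> DesignSummary:
    """Per-group design summary: line counts, transfers, divisions
    (nominal product and metadata total), and harmonic-mean Ne.

    When a group mixes divisions-per-transfer values the group Ne is
    ill-defined; a warning is recorded and the per-line table carries
    each line's own Ne.
    """
    per_line = pd.DataFrame(
        [
            {
                "line_id": m.line_id,
                "group": m.group,
                "transfers": m.transfers,
                "divisions_per_transfer": m.divisions_per_transfer,
                "nominal_divisions": m.transfers * m.divisions_per_transfer,
                "total_divisions": m.total_divisions,
                "ne": effective_population_size(m.divisions_per_transfer),
            }
            for m in metadata
        ]
    )
    warnings: List[str] = []
    rows = []
    for grp, sub in per_line.groupby("group", sort=True):
        dpts = sorted(sub["divisions_per_transfer"].unique())
        if len(dpts) > 1:
            warnings.append(
                f"group {grp} mixes divisions_per_transfer values {dpts}; "
                "see the per-line table for individual Ne"
            )
        rows.append(
            {
                "group": grp,
                "n_lines": len(sub),
                "transfers": int(sub["transfers"].iloc[0]),
                "divisions_per_transfer": dpts[0] if len(dpts) == 1 else float("nan"),
                "nominal_divisions": int(sub["nominal_divisions"].iloc[0]),
                "total_divisions": float(sub["total_divisions"].mean()),
                "ne": effective_population_size(dpts[0]) if len(dpts) == 1 else float("nan"),
            }
        )
    return DesignSummary(
        per_group=pd.DataFrame(rows), per_line=per_line, warnings=warnings
    )


# ------------------------------------------------------------ helpers


def _sig3(x: float) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.3g}")


def _r2(x: float) -> float:
    return round(x, 2) if math.isfinite(x) else x


def _rate_dict(r: RateEstimate) -> dict:
    return {
        "m": r.m,
        "exposure": r.exposure,
        "rate": r.rate,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "level": r.level,
    }


def _fourfold_count(annotations: Sequence[MutationAnnotation]) -> int:
    return sum(1 for a in annotations if a.record.kind == "BPS" and a.at_fourfold_site)


def _features_table(
    per_group: Dict[str, dict], groups: Sequence[str]
) -> pd.DataFrame:
    rows = []
    order = (
        [("Intergenic regions", "intergenic"), ("Coding regions", "CDS"),
         ("  Synonymous", "synonymous"), ("  Non-synonymous", "non-synonymous"),
         ("Introns", "intron"), ("Transitions", "ts")]
        + [("  " + c, c) for c in TRANSITION_CLASSES]
        + [("Transversions", "tv")]
        + [("  " + c, c) for c in TRANSVERSION_CLASSES]
        + [("Insertions", "insertions"), ("Deletions", "deletions")]
    )
    for label, key in order:
        row = {"category": label}
        for g in groups:
            cnt, prop = per_group[g]["features"][key]
            row[f"{g}_count"] = cnt
            row[f"{g}_proportion"] = _r2(prop)
        rows.append(row)
    return pd.DataFrame(rows)


def _group_features(annotations: Sequence[MutationAnnotation]) -> Dict[str, tuple]:
    bps = [a for a in annotations if a.record.kind == "BPS"]
    n_bps = len(bps)
    by_region = {r: sum(1 for a in bps if a.region == r) for r in ("intergenic", "CDS", "intron")}
    coding = [a for a in bps if a.region == "CDS"]
    syn = sum(1 for a in coding if a.coding_effect == "synonymous")
    nonsyn = sum(1 for a in coding if a.coding_effect == "non-synonymous")
    spec = spectrum_table(annotations)
    n_indel = spec.insertions + spec.deletions

    def frac(n, d):
        return n / d if d else float("nan")

    out = {
        "intergenic": (by_region["intergenic"], frac(by_region["intergenic"], n_bps)),
        "CDS": (by_region["CDS"], frac(by_region["CDS"], n_bps)),
        "synonymous": (syn, frac(syn, len(coding))),
        "non-synonymous": (nonsyn, frac(nonsyn, len(coding))),
        "intron": (by_region["intron"], frac(by_region["intron"], n_bps)),
        "ts": (spec.ts_count, frac(spec.ts_count, n_bps)),
        "tv": (spec.tv_count, frac(spec.tv_count, n_bps)),
        "insertions": (spec.insertions, frac(spec.insertions, n_indel)),
        "deletions": (spec.deletions, frac(spec.deletions, n_indel)),
    }
    for c in SPECTRUM_CLASSES:
        out[c] = (spec.counts[c], spec.proportions[c])
    return out


# ------------------------------------------------------------ pipeline


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    paths: Dict[str, str] = {}
    try:
        log.info("seed=%d", config.seed)
        try:
            ref = mio.read_reference(config.fasta, config.gff3)
            by_line = mio.read_vcf_dir(config.vcf_dir)
            metadata = mio.read_metadata(config.metadata)
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            raise MawgsError(f"stage=load: {exc}") from exc

        mutations = [r for recs in by_line.values() for r in recs]

        try:
            kept, kept_mut, qc_report = apply_qc(
                mutations, metadata, min_depth=config.min_depth
            )
        except Exception as exc:
            raise MawgsError(f"stage=qc: {exc}") from exc
        for r in qc_report.removals:
            log.info("qc removal: %s", r)
        (out / "qc_report.json").write_text(
            json.dumps(
                {
                    "input_lines": len(metadata),
                    "kept_lines": len(kept),
                    "kept_by_group": {
                        g: sum(1 for m in kept if m.group == g)
                        for g in sorted({m.group for m in metadata})
                    },
                    **qc_report.to_dict(),
                },
                indent=2,
            )
        )
        (out / "qc_report.log").write_text(qc_report.to_log() + "\n")
        paths["qc_report"] = str(out / "qc_report.json")

        try:
            annot = GenomeAnnotator(
                ref,
                ssr_min_copies=config.ssr_min_copies,
                ssr_min_tract_bp=config.ssr_min_tract_bp,
                ssr_max_motif=config.ssr_max_motif,
                ssr_flank_bp=config.ssr_flank_bp,
            )
            inventory = annot.site_inventory()
            annotations = annot.classify_all(kept_mut)
        except Exception as exc:
            raise MawgsError(f"stage=annotate: {exc}") from exc
        (out / "site_inventory.json").write_text(json.dumps(inventory.to_dict(), indent=2))
        paths["site_inventory"] = str(out / "site_inventory.json")
        ann_df = pd.DataFrame(
            [
                {
                    "line_id": a.record.line_id,
                    "chromosome": a.record.chromosome,
                    "position": a.record.position,
                    "ref": a.record.ref_allele,
                    "alt": a.record.alt_allele,
                    "kind": a.record.kind,
                    "region": a.region,
                    "gene_id": a.gene_id or "",
                    "coding_effect": a.coding_effect or "",
                    "at_fourfold_site": a.at_fourfold_site,
                    "spectrum_class": a.spectrum_class or "",
                    "ts_tv": a.ts_tv or "",
                    "context": a.context or "",
                    "in_ssr": "" if a.in_ssr is None else a.in_ssr,
                }
                for a in annotations
            ],
            columns=["line_id", "chromosome", "position", "ref", "alt", "kind",
                     "region", "gene_id", "coding_effect", "at_fourfold_site",
                     "spectrum_class", "ts_tv", "context", "in_ssr"],
        )
        ann_df.to_csv(out / "annotations.tsv", sep="\t", index=False)
        paths["annotations"] = str(out / "annotations.tsv")

        groups = [g for g in (config.control_label, config.treatment_label)
                  if any(m.group == g for m in kept)]
        region_sites = inventory.sites_by_region
        per_group: Dict[str, dict] = {}
        try:
            for g in groups:
                g_lines = [m for m in kept if m.group == g]
                g_ids = {m.line_id for m in g_lines}
                g_ann = [a for a in annotations if a.record.line_id in g_ids]
                g_bps = [a for a in g_ann if a.record.kind == "BPS"]
                g_indel = [a for a in g_ann if a.record.kind != "BPS"]
                level = config.ci_level
                rates = {
                    "bps_per_site": mutation_rate(len(g_bps), g_lines, per="site", level=level),
                    "bps_per_genome": mutation_rate(len(g_bps), g_lines, per="genome", level=level),
                    "indel_per_site": mutation_rate(len(g_indel), g_lines, per="site", level=level),
                    "fourfold_per_site": mutation_rate(
                        _fourfold_count(g_ann), g_lines, per="site",
                        category_sites=inventory.fourfold_sites, level=level),
                }
                for region in ("CDS", "intron", "intergenic"):
                    rates[f"{region}_per_site"] = mutation_rate(
                        sum(1 for a in g_bps if a.region == region),
                        g_lines, per="site",
                        category_sites=region_sites[region], level=level)
                syn = sum(1 for a in g_bps if a.coding_effect == "synonymous")
                nonsyn = sum(1 for a in g_bps if a.coding_effect == "non-synonymous")
                in_ssr = sum(1 for a in g_indel if a.in_ssr)
                ctx = context_rate_matrix(g_ann, inventory, g_lines)
                enr = gene_enrichment_scan(g_ann, ref.genes, rates["bps_per_site"], g_lines)
                per_group[g] = {
                    "lines": g_lines,
                    "n_lines": len(g_lines),
                    "rates": rates,
                    "spectrum": spectrum_table(g_ann),
                    "ns_obs": nonsyn,
                    "s_obs": syn,
                    "ns_s_gof": gof_test_ns_s(
                        nonsyn, syn, inventory.nonsyn_sites, inventory.syn_sites
                    ) if nonsyn + syn > 0 else None,
                    "indels_total": len(g_indel),
                    "indels_in_ssr": in_ssr,
                    "ssr_fraction": in_ssr / len(g_indel) if g_indel else float("nan"),
                    "features": _group_features(g_ann),
                    "context_matrix": ctx,
                    "enrichment": enr,
                }
                ctx.table.to_csv(out / f"context_matrix_{g}.tsv", sep="\t", index=False)
                ctx.to_frame_16x4().to_csv(out / f"context_heatmap_{g}.tsv", sep="\t")
                enr.to_csv(out / f"enrichment_{g}.tsv", sep="\t", index=False)
                paths[f"context_matrix_{g}"] = str(out / f"context_matrix_{g}.tsv")
                paths[f"enrichment_{g}"] = str(out / f"enrichment_{g}.tsv")
        except Exception as exc:
            raise MawgsError(f"stage=rates: {exc}") from exc

        comparisons: dict = {}
        cg, tg = config.control_label, config.treatment_label
        if cg in per_group and tg in per_group:
            c, t = per_group[cg], per_group[tg]
            comparisons["ts_tv_2x2"] = count_comparison_test(
                c["spectrum"].ts_count, c["spectrum"].tv_count,
                t["spectrum"].ts_count, t["spectrum"].tv_count).to_dict()
            comparisons["ins_del_2x2"] = count_comparison_test(
                c["spectrum"].insertions, c["spectrum"].deletions,
                t["spectrum"].insertions, t["spectrum"].deletions).to_dict()
            comparisons["indel_ssr_2x2"] = count_comparison_test(
                c["indels_in_ssr"], c["indels_total"] - c["indels_in_ssr"],
                t["indels_in_ssr"], t["indels_total"] - t["indels_in_ssr"]).to_dict()
            for key in ("bps_per_site", "fourfold_per_site", "CDS_per_site",
                        "intron_per_site", "intergenic_per_site", "indel_per_site"):
                rc, rt = c["rates"][key], t["rates"][key]
                comparisons[f"rate_ratio_{key}"] = rate_ratio_test(
                    rc.m, rc.exposure, rt.m, rt.exposure).to_dict()

        design = summarize_experiment(kept)
        for w in design.warnings:
            log.warning("%s", w)

        features = _features_table(per_group, groups) if groups else pd.DataFrame()
        features.to_csv(out / "mutational_features.tsv", sep="\t", index=False)
        paths["mutational_features"] = str(out / "mutational_features.tsv")

        rate_rows = []
        for g in groups:
            for name, r in per_group[g]["rates"].items():
                rate_rows.append(
                    {"group": g, "category": name, "m": r.m,
                     "exposure": r.exposure, "rate": _sig3(r.rate),
                     "ci_low": _sig3(r.ci_low), "ci_high": _sig3(r.ci_high)}
                )
        pd.DataFrame(rate_rows).to_csv(out / "rates.tsv", sep="\t", index=False)
        paths["rates"] = str(out / "rates.tsv")
        region_rows = [
            {"group": g, "region": region,
             "rate": _sig3(per_group[g]["rates"][f"{region}_per_site"].rate),
             "ci_low": _sig3(per_group[g]["rates"][f"{region}_per_site"].ci_low),
             "ci_high": _sig3(per_group[g]["rates"][f"{region}_per_site"].ci_high)}
            for g in groups for region in ("CDS", "intron", "intergenic")
        ]
        pd.DataFrame(region_rows).to_csv(out / "region_rates.tsv", sep="\t", index=False)
        paths["region_rates"] = str(out / "region_rates.tsv")

        summary = {
            "config": dataclasses.asdict(config),
            "qc": {
                "input_lines": len(metadata),
                "kept_lines": len(kept),
                "kept_by_group": {g: per_group[g]["n_lines"] for g in groups},
                "removals": qc_report.removals,
            },
            "inventory": inventory.to_dict(),
            "design": {
                "per_group": design.per_group.to_dict(orient="records"),
                "warnings": design.warnings,
            },
            "groups": {
                g: {
                    "n_lines": per_group[g]["n_lines"],
                    "rates": {k: _rate_dict(r) for k, r in per_group[g]["rates"].items()},
                    "spectrum": per_group[g]["spectrum"].to_dict(),
                    "ns_obs": per_group[g]["ns_obs"],
                    "s_obs": per_group[g]["s_obs"],
                    "ns_s_gof": per_group[g]["ns_s_gof"].to_dict()
                    if per_group[g]["ns_s_gof"] else None,
                    "indels_total": per_group[g]["indels_total"],
                    "indels_in_ssr": per_group[g]["indels_in_ssr"],
                    "ssr_fraction": per_group[g]["ssr_fraction"],
                    "n_enriched_genes": int(per_group[g]["enrichment"]["enriched"].sum())
                    if len(per_group[g]["enrichment"]) else 0,
                }
                for g in groups
            },
            "comparisons": comparisons,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        paths["summary"] = str(out / "summary.json")
        log.info("pipeline complete: %d lines kept, %d mutations annotated",
                 len(kept), len(annotations))
        return ReportBundle(summary=summary, paths=paths)
    finally:
        log.removeHandler(fh)
        fh.close()
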