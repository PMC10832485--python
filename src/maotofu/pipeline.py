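"""End-to-end pipeline orchestration from a structured config.

Stages run in dependency order: synthetic generation (or file inputs)
-> amino-acid evaluation + volatile quantification + community
profiling -> taxa-metabolite correlation. Every stage writes its
intermediate artifacts under the output directory and contributes a
section to the consolidated :class:`RunReport`. Reports are
reproducible byte-identically from the same config and seed; the
config hash is recorded in the provenance block.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, amino_acids, community, correlation, synthetic, volatiles

__all__ = ["PipelineConfig", "RunReport", "ValidationError", "run_pipeline",
           "render_report"]

log = logging.getLogger("maotofu")


class ValidationError(ValueError):
    """Raised when a pipeline config fails validation (all errors listed)."""


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "maotofu_out"
    stages: dict[str, bool] = field(default_factory=lambda: {
        "amino_acids": True, "volatiles": True,
        "community": True, "correlation": True,
    })
    synth: synthetic.SynthConfig | None = None
    # stage parameters
    cis_ug_per_g: float = volatiles.DEFAULT_CIS_UG_PER_ML
    min_rel_pct: float = 1.0
    qc_min_len: int = 1400
    qc_max_len: int = 1800
    qc_min_acc: float = 0.90
    otu_identity: float = 0.97
    dominant_min_pct: float = 1.0
    taxa_filter_min_pct: float = 0.1
    corr_method: str = "spearman"
    rho_threshold: float = 0.6
    p_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_raw = raw.pop("synth", None)
        cfg = cls(**raw)
        if synth_raw is not None:
            cfg.synth = synthetic.SynthConfig(**synth_raw)
        return cfg

    def validate(self) -> None:
        errors: list[str] = []
        if not (0 < self.otu_identity <= 1):
            errors.append(f"otu_identity outside (0, 1]: {self.otu_identity}")
        if self.cis_ug_per_g <= 0:
            errors.append(f"cis_ug_per_g must be > 0: {self.cis_ug_per_g}")
        if self.qc_min_len > self.qc_max_len:
            errors.append("qc_min_len exceeds qc_max_len")
        if not (0 <= self.qc_min_acc <= 1):
            errors.append(f"qc_min_acc outside [0, 1]: {self.qc_min_acc}")
        if not (0 <= self.rho_threshold <= 1):
            errors.append(f"rho_threshold outside [0, 1]: {self.rho_threshold}")
        if not (0 < self.p_threshold <= 1):
            errors.append(f"p_threshold outside (0, 1]: {self.p_threshold}")
        if self.corr_method not in {"spearman", "pearson"}:
            errors.append(f"unknown corr_method: {self.corr_method!r}")
        if self.synth is not None:
            try:
                self.synth.validate()
            except synthetic.ConfigError as exc:
                errors.append(str(exc))
        if errors:
            raise ValidationError("; ".join(errors))

    def digest(self) -> str:
        # outdir is a destination, not a parameter: same config + seed must
        # hash identically wherever the artifacts land
        payload = {k: v for k, v in vars(self).items()
                   if k not in ("synth", "outdir")}
        if self.synth is not None:
            payload["synth"] = {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in vars(self.synth).items()
            }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    provenance: dict[str, Any]
    sections: dict[str, Any] = field(default_factory=dict)

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(
            {"provenance": self.provenance, "sections": self.sections},
            indent=indent, sort_keys=True, default=str,
        )


def _aa_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    synth = cfg.synth or synthetic.SynthConfig(seed=cfg.seed)
    profiles = synthetic.gen_amino_acid_profiles(synth)
    synthetic.profiles_to_tsv(profiles, outdir / "aa_profiles.tsv")
    rows = []
    for p in profiles:
        ev = amino_acids.evaluate_profile(p, with_tav=True)
        contributing = sorted(r.code for r in ev.tav_records if r.contributes)
        rows.append({
            "sample_id": ev.sample_id, "src": round(ev.src, 4),
            "limiting_aa": ev.limiting_aa,
            "eaa_taa_pct": round(ev.eaa_taa_pct, 4),
            "eaa_neaa_pct": round(ev.eaa_neaa_pct, 4),
            "taa_g_per_100g": round(ev.taa_g_per_100g, 4),
            "closeness_mu": round(ev.closeness_mu, 6),
            "taste_contributors": contributing,
        })
    pd.DataFrame(rows).to_csv(outdir / "aa_evaluation.tsv", sep="\t", index=False)
    log.info("amino_acids: evaluated %d profiles", len(rows))
    return {"n_profiles": len(rows), "evaluations": rows}


def _volatile_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    synth = cfg.synth or synthetic.SynthConfig(seed=cfg.seed)
    peaks, _truth = synthetic.gen_volatile_table(synth)
    quant = volatiles.quantify(peaks, cis=cfg.cis_ug_per_g)
    quant.to_csv(outdir / "volatile_quant.tsv", sep="\t", index=False)
    classes = volatiles.aggregate_classes(quant)
    classes.to_csv(outdir / "volatile_classes.tsv", sep="\t", index=False)
    major = volatiles.filter_relative(quant, cfg.min_rel_pct)
    major.to_csv(outdir / "volatile_major.tsv", sep="\t", index=False)
    class_counts = {
        sid: dict(zip(grp["chemical_class"], grp["n_compounds"].astype(int)))
        for sid, grp in classes.groupby("sample_id", sort=False)
    }
    log.info("volatiles: quantified %d rows, %d above %.2f%%",
             len(quant), len(major), cfg.min_rel_pct)
    return {
        "n_compound_rows": int(len(quant)),
        "n_major_rows": int(len(major)),
        "class_counts": class_counts,
    }


def _community_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    synth = cfg.synth or synthetic.SynthConfig(seed=cfg.seed)
    reads, truth, barcode_map = synthetic.gen_amplicon_reads(synth)
    synthetic.write_reads(reads, outdir / "reads.fastq", outdir / "reads_accuracy.tsv")
    by_sample, unassigned = community.demultiplex(reads, barcode_map)
    taxon_of = dict(zip(truth["read_id"], truth["species"]))
    all_passed = []
    qc_rows = []
    for sid, sample_reads in by_sample.items():
        passed, stats = community.qc_filter(
            sample_reads, cfg.qc_min_len, cfg.qc_max_len, cfg.qc_min_acc
        )
        qc_rows.append({"sample_id": sid, **vars(stats)})
        all_passed.extend(passed)
    pd.DataFrame(qc_rows).to_csv(outdir / "qc_stats.tsv", sep="\t", index=False)
    uniques = community.dereplicate(all_passed)
    uniques = community.remove_chimeras(uniques)
    otus = community.cluster_otus(uniques, cfg.otu_identity, taxon_of=taxon_of)
    otus.to_dataframe().to_csv(outdir / "otu_table.tsv", sep="\t", index=False)
    rel = community.relative_abundance(otus)
    rel.to_csv(outdir / "relative_abundance.tsv", sep="\t")
    dominant, cumulative = community.dominant_taxa(rel, cfg.dominant_min_pct)
    shannon_by_sample = {
        sid: round(community.shannon(otus.counts_matrix()[sid]), 4)
        for sid in otus.counts_matrix().columns
    }
    log.info("community: %d reads in, %d passed QC, %d OTUs",
             len(reads), len(all_passed), len(otus.otus))
    return {
        "n_reads": len(reads), "n_unassigned": unassigned,
        "n_passed_qc": len(all_passed), "n_otus": len(otus.otus),
        "dominant_taxa": {str(k): round(float(v), 4) for k, v in dominant.items()},
        "dominant_cumulative_pct": round(cumulative, 4),
        "shannon": shannon_by_sample,
    }


def _correlation_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    synth = cfg.synth or synthetic.SynthConfig(seed=cfg.seed)
    taxa, metabolites = synthetic.gen_taxa_metabolite_dataset(synth)
    rel = synthetic.to_relative_pct(taxa)
    kept = correlation.filter_taxa(rel, cfg.taxa_filter_min_pct)
    kept_raw = taxa.loc[kept.index]
    result = correlation.correlate(kept_raw, metabolites, method=cfg.corr_method)
    result.rho.to_csv(outdir / "correlation_rho.tsv", sep="\t")
    result.p.to_csv(outdir / "correlation_p.tsv", sep="\t")
    result.stars.to_csv(outdir / "correlation_stars.tsv", sep="\t")
    net = correlation.build_network(
        kept_raw, cfg.rho_threshold, cfg.p_threshold, method=cfg.corr_method
    )
    deg = correlation.degrees(net)
    deg.to_csv(outdir / "network_degrees.tsv", sep="\t", index=False)
    edges = [
        {"node1": str(a), "node2": str(b),
         "rho": round(d["rho"], 4), "p": round(d["p"], 6)}
        for a, b, d in net.edges(data=True)
    ]
    pd.DataFrame(edges, columns=["node1", "node2", "rho", "p"]).to_csv(
        outdir / "network_edges.tsv", sep="\t", index=False
    )
    hits = [
        {"taxon": str(t), "metabolite": str(m),
         "rho": round(float(result.rho.loc[t, m]), 4),
         "stars": result.stars.loc[t, m]}
        for t in result.stars.index for m in result.stars.columns
        if result.stars.loc[t, m]
    ]
    log.info("correlation: %d taxa kept, %d significant pairs, %d edges",
             len(kept_raw), len(hits), net.number_of_edges())
    return {
        "n_taxa_kept": int(len(kept_raw)),
        "significant_pairs": hits,
        "n_edges": int(net.number_of_edges()),
        "top_degrees": deg.head(5).to_dict(orient="records"),
    }


_STAGES = {
    "amino_acids": _aa_stage,
    "volatiles": _volatile_stage,
    "community": _community_stage,
    "correlation": _correlation_stage,
}


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Validate, run all enabled stages in order, and collect the report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.synth is None:
        cfg.synth = synthetic.SynthConfig(seed=cfg.seed)
    report = RunReport(provenance={
        "config_hash": cfg.digest(), "seed": cfg.seed, "version": __version__,
    })
    for name, fn in _STAGES.items():
        if not cfg.stages.get(name, True):
            report.sections[name] = {"skipped": True}
            continue
        try:
            report.sections[name] = fn(cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    (outdir / "report.json").write_text(report.to_json())
    return report


def render_report(report: RunReport, fmt: str = "json") -> str:
    """Render a report as JSON or a human-readable text summary."""
    if fmt == "json":
        return report.to_json()
    if fmt != "text":
        raise ValueError(f"unknown report format {fmt!r}")
    lines = [
        "Mao-tofu pipeline report",
        f"  config {report.provenance['config_hash']}  seed {report.provenance['seed']}",
        "",
    ]
    for name, section in report.sections.items():
        lines.append(f"[{name}]")
        if section.get("skipped"):
            lines.append("  skipped")
        elif not section:
            lines.append("  (empty)")
        else:
            for key, value in section.items():
                lines.append(f"  {key}: {value}")
        lines.append("")
    return "\n".join(lines)
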