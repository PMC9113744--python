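"""End-to-end orchestration from a single config, with a reproducible manifest.

Stages run in dependency order — qc, de, specificity, concordance,
enrichment, reports — each writing CSV artifacts into the output directory;
every threshold that affected any output, every warning, and a SHA-256
digest of each artifact are recorded in a machine-readable JSON manifest.
Any stage failure aborts the run naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    CountMatrix,
    read_counts,
    read_gene_list,
    read_gmt,
    read_sample_sheet,
    validate_design,
)
from .normalization_de import contrast_set, flag_expressed, DETable
from .specificity import (
    de_breadth_distribution,
    expression_breadth,
    specificity_summary,
)
from .concordance import direction_concordance
from .enrichment import enrich_all, rank_terms, classify_terms
from .qc_clustering import (
    all_tissue_genes,
    pca_samples,
    pearson_cluster,
    to_newick,
)

logger = logging.getLogger("thermatlas")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "top_genes_report"]

CONTROL_TEMP_DEFAULT = 22.0


@dataclass
class RunConfig:
    counts: str
    samples: str
    gmt: str | None = None
    panels: list[str] = field(default_factory=list)
    study_tables: list[str] = field(default_factory=list)
    control_temp: float = CONTROL_TEMP_DEFAULT
    treatment_temps: list[float] = field(default_factory=lambda: [10.0, 34.0])
    fc_threshold: float = 1.5
    p_de: float = 0.05
    p_go: float = 0.01
    min_count: int = 5
    min_studies: int = 4
    adjust: str = "none"
    linkage: str = "average"
    filter_rule: str = "logcpm_positive"
    enrichment_enabled: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        """Collect and raise every problem at once."""
        problems: list[str] = []
        for name in ("counts", "samples"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                problems.append(f"{name}: path does not exist: {p!r}")
        if self.enrichment_enabled:
            if not self.gmt:
                problems.append("gmt: required when enrichment is enabled")
            elif not Path(self.gmt).exists():
                problems.append(f"gmt: path does not exist: {self.gmt!r}")
        for p in [*self.panels, *self.study_tables]:
            if not Path(p).exists():
                problems.append(f"path does not exist: {p!r}")
        for name in ("fc_threshold", "p_de", "p_go"):
            if getattr(self, name) <= 0:
                problems.append(f"{name}: must be positive")
        if self.min_count < 1:
            problems.append("min_count: must be >= 1")
        if self.adjust not in ("none", "bh"):
            problems.append(f"adjust: unknown mode {self.adjust!r}")
        if problems:
            raise ValueError("invalid run config:\n  " + "\n  ".join(problems))


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str
    stages: dict[str, dict[str, str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def record(self, stage: str, outputs: dict[str, Path]) -> None:
        self.stages[stage] = {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in outputs.items()
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def top_genes_report(det: DETable, n: int = 7) -> pd.DataFrame:
    """The most up- and most down-regulated significant genes of a contrast.

    Within each direction genes are sorted by |log2FC| descending, ties by
    ascending p then gene id; at most ``n`` per direction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    frames = []
    for direction in ("up", "down"):
        sub = det.table[det.table["call"] == direction].copy()
        sub["_abs"] = sub["log2fc"].abs()
        sub = (
            sub.rename_axis("gene")
            .reset_index()
            .sort_values(
                ["_abs", "p_value", "gene"],
                ascending=[False, True, True],
                kind="mergesort",
            )
            .head(n)
        )
        sub["direction"] = direction
        frames.append(sub[["gene", "direction", "log2fc", "p_value"]])
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunManifest:
    """Execute the whole pipeline and return the populated manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)
    manifest.started = time.strftime("%Y-%m-%dT%H:%M:%S")
    collector = _WarningCollector()
    logger.addHandler(collector)
    stage = "load"
    try:
        cm = read_counts(config.counts)
        sheet = read_sample_sheet(config.samples)
        validate_design(cm, sheet)
        tissue_groups = {
            t: list(g["sample_id"]) for t, g in sheet.groupby("tissue")
        }

        stage = "qc"
        flags = flag_expressed(cm, tissue_groups, config.min_count)
        universe = all_tissue_genes(flags)
        k = min(2, len(cm.sample_ids) - 1)
        pca = pca_samples(cm, list(universe), k=k)
        clus = pearson_cluster(cm, method=config.linkage)
        qc_out = {
            "pca_coordinates": outdir / "qc_pca_coordinates.csv",
            "pca_variance": outdir / "qc_pca_variance.csv",
            "correlation": outdir / "qc_pearson_correlation.csv",
            "dendrogram": outdir / "qc_dendrogram.nwk",
        }
        pca.coordinates.to_csv(qc_out["pca_coordinates"])
        pd.DataFrame(
            {"component": [f"PC{i+1}" for i in range(len(pca.variance_explained))],
             "variance_fraction": pca.variance_explained}
        ).to_csv(qc_out["pca_variance"], index=False)
        clus.correlation.to_csv(qc_out["correlation"])
        qc_out["dendrogram"].write_text(to_newick(clus) + "\n")
        manifest.record("qc", qc_out)

        stage = "de"
        families = {}
        de_out: dict[str, Path] = {}
        for temp in config.treatment_temps:
            cs = contrast_set(
                cm,
                sheet,
                temp,
                config.control_temp,
                fc_threshold=config.fc_threshold,
                p_threshold=config.p_de,
                adjust=config.adjust,
                filter_rule=config.filter_rule,
            )
            families[temp] = cs
            for det in cs:
                name = f"de_{det.tissue}_{format(temp, 'g')}v{format(config.control_temp, 'g')}"
                path = outdir / f"{name}.csv"
                det.table.to_csv(path, index_label="gene")
                de_out[name] = path
        manifest.record("de", de_out)

        stage = "specificity"
        spec_out: dict[str, Path] = {}
        for temp, cs in families.items():
            summ = specificity_summary(cs)
            tag = format(temp, "g")
            p1 = outdir / f"specificity_per_gene_{tag}C.csv"
            p2 = outdir / f"specificity_per_tissue_{tag}C.csv"
            summ.per_gene.to_csv(p1)
            summ.per_tissue.to_csv(p2, index=False)
            spec_out[f"per_gene_{tag}"] = p1
            spec_out[f"per_tissue_{tag}"] = p2
            dist = de_breadth_distribution(summ.per_gene)
            p3 = outdir / f"de_breadth_distribution_{tag}C.csv"
            dist.rename("n_genes").to_csv(p3)
            spec_out[f"breadth_{tag}"] = p3
        eb = expression_breadth(flags)
        p4 = outdir / "expression_breadth.csv"
        eb.distribution.rename("n_genes").to_csv(p4)
        spec_out["expression_breadth"] = p4
        manifest.record("specificity", spec_out)

        stage = "concordance"
        conc_out: dict[str, Path] = {}
        if len(config.treatment_temps) >= 2:
            t_a, t_b = config.treatment_temps[:2]
            shared = set(families[t_a].tissues()) & set(families[t_b].tissues())
            for tissue in sorted(shared):
                rep = direction_concordance(
                    families[t_a].get(tissue, t_a), families[t_b].get(tissue, t_b)
                )
                path = outdir / f"concordance_{tissue}.csv"
                rep.per_gene.to_csv(path)
                conc_out[tissue] = path
        manifest.record("concordance", conc_out)

        stage = "enrichment"
        enr_out: dict[str, Path] = {}
        if config.enrichment_enabled and config.gmt:
            collection = read_gmt(config.gmt)
            tables = {}
            for temp, cs in families.items():
                enr = enrich_all(cs, collection, config.p_go)
                tables[temp] = enr
                tag = format(temp, "g")
                p1 = outdir / f"enrichment_{tag}C.csv"
                enr.table.to_csv(p1, index=False)
                p2 = outdir / f"enrichment_term_counts_{tag}C.csv"
                enr.term_counts().to_csv(p2, index=False)
                p3 = outdir / f"enrichment_top_terms_{tag}C.csv"
                rank_terms(enr).to_csv(p3, index=False)
                enr_out[f"table_{tag}"] = p1
                enr_out[f"counts_{tag}"] = p2
                enr_out[f"top_{tag}"] = p3
            if len(tables) >= 2:
                temps = sorted(tables)
                cls = classify_terms(tables[temps[0]], tables[temps[-1]])
                p4 = outdir / "term_classification.csv"
                cls.to_csv(p4)
                enr_out["classification"] = p4
        manifest.record("enrichment", enr_out)

        stage = "reports"
        rep_out: dict[str, Path] = {}
        for temp, cs in families.items():
            for det in cs:
                top = top_genes_report(det)
                name = f"top_genes_{det.tissue}_{format(temp, 'g')}C"
                path = outdir / f"{name}.csv"
                top.to_csv(path, index=False)
                rep_out[name] = path
        manifest.record("reports", rep_out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(collector)
    manifest.warnings = collector.messages
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "run_manifest.json")
    return manifest
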