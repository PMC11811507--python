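"""End-to-end pipeline: screen → partition → map enzymes → find paths → report.

Each stage consumes and produces files, so any stage can be re-run in
isolation; the run manifest captures every effective setting.  A fixed
configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .counts import count_paths, paths_to_table
from .errors import PipelineError
from .kgraph import read_graph
from .markers import (
    default_enzyme_map,
    enzymes_for_metabolites,
    partition_markers,
    read_enzyme_map,
    read_marker_list,
)
from .profiles import read_profiles
from .report import classify_enzyme_specificity, render_report
from .screening import CLASS_SHARED, screen_panel
from .templates import default_templates, enumerate_all_templates, templates_from_yaml

log = logging.getLogger("metaboreg")


@dataclass
class RunConfig:
    """Effective settings of one pipeline run."""

    profiles: str
    markers_a: str
    markers_b: str
    graph: str
    outdir: str
    enzyme_map: str | None = None  # None -> packaged default map
    templates: str | None = None  # None -> the four default templates
    alpha: float = 0.05
    rule: str = "both"
    max_intermediates: int = 1
    dedupe: str = "paths"
    min_margin: float = 1.5
    min_count: int = 1
    seed: int = 0
    figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"{path}: unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**doc)
        except TypeError as exc:
            raise PipelineError(f"{path}: {exc}") from exc

    def validate_paths(self) -> None:
        for name in ("profiles", "markers_a", "markers_b", "graph"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise PipelineError(f"config.{name}: no such file: {p}")
        for name in ("enzyme_map", "templates"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config.{name}: no such file: {p}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def run_all(config: RunConfig) -> dict:
    """Execute every pipeline stage; returns the run manifest."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        t0 = time.perf_counter()

        def done():
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

        return done

    try:
        done = stage("screen")
        profiles = read_profiles(config.profiles)
        screening = screen_panel(profiles, alpha=config.alpha, rule=config.rule)
        done()
    except Exception as exc:
        raise PipelineError(f"stage 'screen' failed: {exc}") from exc

    try:
        done = stage("partition")
        list_a = read_marker_list(config.markers_a)
        list_b = read_marker_list(config.markers_b)
        partition = partition_markers(list_a, list_b)
        done()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'partition' failed: {exc}") from exc

    try:
        done = stage("map-enzymes")
        emap = (
            read_enzyme_map(config.enzyme_map)
            if config.enzyme_map
            else default_enzyme_map()
        )
        significant = sorted(
            set(screening.classified(CLASS_SHARED))
            | set(screening.classified("A_specific"))
            | set(screening.classified("B_specific"))
        )
        enzymes, unmapped = enzymes_for_metabolites(significant, emap)
        if unmapped:
            log.warning("significant metabolites without enzyme mapping: %s",
                        unmapped)
        enzymes.to_csv(outdir / "enzymes.tsv", sep="\t", index=False)
        done()
    except Exception as exc:
        raise PipelineError(f"stage 'map-enzymes' failed: {exc}") from exc

    try:
        done = stage("find-paths")
        graph = read_graph(config.graph)
        templates = (
            templates_from_yaml(config.templates)
            if config.templates
            else default_templates(config.max_intermediates)
        )
        sources = sorted(partition.all_markers())
        targets = sorted(enzymes["enzyme_protein_id"]) if len(enzymes) else []
        paths = enumerate_all_templates(
            graph, templates, sources, targets,
            max_intermediates=config.max_intermediates,
        )
        paths_to_table(paths).to_csv(outdir / "paths.tsv", sep="\t", index=False)
        matrix = count_paths(paths, partition, emap, dedupe=config.dedupe)
        done()
    except Exception as exc:
        raise PipelineError(f"stage 'find-paths' failed: {exc}") from exc

    try:
        done = stage("report")
        calls = classify_enzyme_specificity(
            matrix, min_margin=config.min_margin, min_count=config.min_count
        )
        manifest = render_report(
            outdir,
            screening=screening,
            partition=partition,
            matrix=matrix,
            calls=calls,
            settings=config.to_dict(),
            figures=config.figures,
        )
        done()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'report' failed: {exc}") from exc
    return manifest
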