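"""End-to-end runs: input validation, stage orchestration, manifest.

All tables are UTF-8 TSV with a header row.  Peak tables carry columns
``sample  replicate  structure  area`` (structures in canonical condensed
notation; ``a``/``b`` accepted for α/β); probe tables carry ``probe  gene
array1 … arrayN`` with a separate ``array  group`` design table; category
maps carry ``gene  category``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .glycan import GlycanContext, GlycanParseError, parse_glycan, serialize_glycan
from .motifs import builtin_traits, compute_epitope_table, load_trait_library
from .quantify import (
    aggregate_replicates,
    apply_coverage_filter,
    compute_trait_abundance,
    estimate_total_content,
    normalize_within_sample,
)
from .diffexpr import run_de_screen

log = logging.getLogger("glycotrait")

__all__ = ["RunConfig", "PipelineError", "validate_inputs", "run_pipeline",
           "read_peak_table", "read_probe_matrix", "read_design", "read_categories"]


class PipelineError(RuntimeError):
    """A stage-named, user-facing pipeline failure."""


@dataclass
class RunConfig:
    peaks: Optional[Path] = None
    context: str = "O_glycan"
    traits_path: Optional[Path] = None
    reference_sample: Optional[str] = None
    coverage: float = 95.0
    probes: Optional[Path] = None
    design: Optional[Path] = None
    categories: Optional[Path] = None
    fc_threshold: float = 1.5
    alpha: float = 0.1
    seed: int = 0
    out_dir: Path = Path("glycotrait_out")

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 100:
            raise ValueError("coverage must be in (0, 100]")
        if self.fc_threshold < 1:
            raise ValueError("fc threshold must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        for name in ("peaks", "probes", "design", "categories", "traits_path"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value).resolve())
        self.out_dir = Path(self.out_dir)


# ---------------------------------------------------------------------------
# readers and validation
# ---------------------------------------------------------------------------

def read_peak_table(path, context: str = "O_glycan") -> pd.DataFrame:
    """Read and canonicalise a peak TSV; structures are re-serialised so
    table keys are canonical text."""
    table = pd.read_csv(path, sep="\t", dtype={"sample": str, "replicate": str})
    required = ["sample", "replicate", "structure", "area"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise PipelineError(f"parse: {path} lacks columns {missing}")
    ids = []
    for i, text in enumerate(table["structure"]):
        try:
            ids.append(serialize_glycan(parse_glycan(str(text), context)))
        except GlycanParseError as exc:
            raise PipelineError(
                f"parse: row {i + 2} of {path}: bad structure {text!r} ({exc})"
            ) from exc
    out = table.rename(columns={"structure": "glycan_id"}).copy()
    out["glycan_id"] = ids
    return out[["sample", "replicate", "glycan_id", "area"]]


def read_probe_matrix(path) -> tuple[pd.DataFrame, dict[str, str]]:
    table = pd.read_csv(path, sep="\t")
    if table.columns[:2].tolist() != ["probe", "gene"]:
        raise PipelineError(f"parse: {path} must start with columns probe, gene")
    matrix = table.set_index("probe").drop(columns="gene")
    probe_gene = dict(zip(table["probe"], table["gene"]))
    return matrix, probe_gene


def read_design(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    if not {"array", "group"} <= set(table.columns):
        raise PipelineError(f"parse: {path} needs columns array, group")
    return dict(zip(table["array"], table["group"]))


def read_categories(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    if not {"gene", "category"} <= set(table.columns):
        raise PipelineError(f"parse: {path} needs columns gene, category")
    return dict(zip(table["gene"], table["category"]))


def validate_inputs(
    peaks: Optional[Path] = None,
    probes: Optional[Path] = None,
    design: Optional[Path] = None,
    categories: Optional[Path] = None,
    context: str = "O_glycan",
) -> list[str]:
    """Schema report: a list of human-readable problems (empty = valid).
    Never mutates inputs."""
    problems: list[str] = []
    if peaks is not None:
        try:
            raw = pd.read_csv(peaks, sep="\t")
        except OSError as exc:
            return [f"{peaks}: unreadable ({exc})"]
        for col in ("sample", "replicate", "structure", "area"):
            if col not in raw.columns:
                problems.append(f"{peaks}: missing column {col!r}")
        if not problems:
            dupes = raw.duplicated(subset=["sample", "replicate", "structure"])
            for i in raw.index[dupes]:
                problems.append(f"{peaks}: row {i + 2}: duplicate (sample, replicate, structure)")
            for i in raw.index[raw["area"] <= 0]:
                problems.append(f"{peaks}: row {i + 2}: non-positive area {raw.at[i, 'area']}")
            for i, text in raw["structure"].items():
                try:
                    parse_glycan(str(text), context)
                except GlycanParseError as exc:
                    problems.append(f"{peaks}: row {i + 2}: bad structure {text!r} ({exc})")
    if probes is not None:
        matrix, probe_gene = read_probe_matrix(probes)
        if (matrix <= 0).any().any():
            problems.append(f"{probes}: non-positive intensities present")
        if design is not None:
            groups = read_design(design)
            unmapped = [a for a in matrix.columns if a not in groups]
            if unmapped:
                problems.append(f"{design}: arrays without a group: {unmapped}")
            elif len(set(groups[a] for a in matrix.columns)) != 2:
                problems.append(f"{design}: need exactly two groups over the arrays")
        if categories is not None:
            cats = read_categories(categories)
            unmapped_genes = sorted(set(probe_gene.values()) - set(cats))
            if unmapped_genes:
                problems.append(
                    f"{categories}: {len(unmapped_genes)} genes unmapped "
                    f"(fall into miscellaneous), e.g. {unmapped_genes[:3]}"
                )
    return problems


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages and write output TSVs plus a JSON run
    manifest; returns {output name: path}.  Deterministic: identical
    config and inputs give byte-identical outputs."""
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest: dict = {
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
        },
        "inputs": {},
    }
    for name in ("peaks", "probes", "design", "categories", "traits_path"):
        value = getattr(config, name)
        if value is not None:
            manifest["inputs"][name] = {"path": str(value), "sha256": _checksum(value)}

    if config.peaks is not None:
        log.info("stage parse: reading %s", config.peaks)
        records = read_peak_table(config.peaks, config.context)
        traits = (
            load_trait_library(config.traits_path)
            if config.traits_path is not None
            else builtin_traits()
        )
        glycans = [
            parse_glycan(gid, config.context)
            for gid in sorted(records["glycan_id"].unique())
        ]
        log.info("stage epitopes: %d structures", len(glycans))
        counts = compute_epitope_table(glycans, traits)
        log.info("stage normalize")
        rel = normalize_within_sample(records)
        rel = apply_coverage_filter(rel, config.coverage)
        per_rep = compute_trait_abundance(rel, counts)
        trait_table = aggregate_replicates(per_rep)

        rel_path = out_dir / "relabund.tsv"
        rel.sort_values(["sample", "replicate", "glycan_id"]).to_csv(
            rel_path, sep="\t", index=False, float_format="%.6f"
        )
        outputs["relabund"] = rel_path
        traits_path = out_dir / "traits.tsv"
        trait_table.sort_values(["sample", "trait"]).to_csv(
            traits_path, sep="\t", index=False, float_format="%.6f"
        )
        outputs["traits"] = traits_path
        if config.reference_sample is not None:
            total = estimate_total_content(records, config.reference_sample)
            total_path = out_dir / "total.tsv"
            total.to_csv(total_path, sep="\t", index=False, float_format="%.6f")
            outputs["total"] = total_path

    if config.probes is not None:
        if config.design is None:
            raise PipelineError("diffexpr: probe matrix given without a design table")
        log.info("stage diffexpr: reading %s", config.probes)
        matrix, probe_gene = read_probe_matrix(config.probes)
        design = read_design(config.design)
        cats = read_categories(config.categories) if config.categories else {}
        results, summary, expr = run_de_screen(
            matrix,
            probe_gene,
            design,
            category_map=cats,
            fc_threshold=config.fc_threshold,
            alpha=config.alpha,
        )
        de_path = out_dir / "de_results.tsv"
        results.sort_values("gene").to_csv(
            de_path, sep="\t", index=False, float_format="%.6g"
        )
        outputs["de_results"] = de_path
        cat_path = out_dir / "categories.tsv"
        summary.to_csv(cat_path, sep="\t", index=False)
        outputs["categories"] = cat_path
        passing = results.loc[results["passes"], "gene"].tolist()
        if len(passing) >= 2:
            from .diffexpr import export_heatmap_table

            heat_path = out_dir / "heatmap.tsv"
            export_heatmap_table(expr, passing, heat_path)
            outputs["heatmap"] = heat_path

    manifest_path = out_dir / "manifest.json"
    manifest["outputs"] = {k: str(v) for k, v in outputs.items()}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    return outputs
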