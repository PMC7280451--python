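"""Seeded generators for glycan panels, peak tables and probe matrices.

The reference panel enumerates the named O-glycan and GSL structures of the
PaTu-8988 study system (Tn, sTn, T, core 2 variants, Lewis-type and
blood-group antigens, Gb3/Gb4, GM3-like gangliosides, (neo)lacto chains),
each with epitope counts recomputed from the motif engine at build time.

Peak tables are simulated as profile fraction x total-signal scalar x
log-normal(1, CV) multiplicative noise — MS peak areas are positive and
right-skewed — and the planted per-sample trait values implied by the
noiseless profile are returned alongside.  Probe matrices are simulated on
the log2 scale (gene baseline + planted group effect + probe affinity +
Gaussian noise) and exponentiated to the intensity scale.  All generators
are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .glycan import Glycan, GlycanContext, parse_glycan, serialize_glycan
from .motifs import TraitDefinition, builtin_traits, compute_epitope_table
from .quantify import aggregate_replicates, compute_trait_abundance

__all__ = [
    "PANEL_O_GLYCANS",
    "PANEL_GSL_GLYCANS",
    "build_reference_panel",
    "default_profiles",
    "SimulationConfig",
    "simulate_peak_tables",
    "ExpressionConfig",
    "simulate_probe_matrix",
]


# O-glycans: reduced alditols rooted on GalNAc-ol (canonical notation).
PANEL_O_GLYCANS = [
    "GalNAc-ol",                                            # Tn
    "Neu5Acα2-6GalNAc-ol",                                  # sTn
    "Galβ1-3GalNAc-ol",                                     # T antigen
    "Neu5Acα2-3Galβ1-3GalNAc-ol",                           # sialyl-T
    "Neu5Acα2-3Galβ1-3(Neu5Acα2-6)GalNAc-ol",               # disialyl-T
    "Neu5Acα2-6Galβ1-3GalNAc-ol",                           # 2,6-sialyl-T
    "Galβ1-3(GlcNAcβ1-6)GalNAc-ol",                         # core 2
    "Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAc-ol",                  # core 2 + LacNAc
    "Neu5Acα2-3Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAc-ol",
    "Galβ1-3(Neu5Acα2-6Galβ1-4GlcNAcβ1-6)GalNAc-ol",        # 2,6-sialyl arm
    "Galβ1-3(Neu5Acα2-3Galβ1-4GlcNAcβ1-6)GalNAc-ol",
    "GlcNAcβ1-3GalNAc-ol",                                  # core 3
    "GlcNAcβ1-3(GlcNAcβ1-6)GalNAc-ol",                      # core 4
    "Galβ1-3(GalNAcβ1-4Galβ1-4GlcNAcβ1-6)GalNAc-ol",        # LacdiNAc-capped
    "Fucα1-2Galβ1-3GalNAc-ol",                              # blood group H core 1
    "GalNAcα1-3(Fucα1-2)Galβ1-3GalNAc-ol",                  # blood group A
    "Galβ1-3(Fucα1-2Galβ1-4GlcNAcβ1-6)GalNAc-ol",           # H type 2 on core 2
    "Galβ1-3(GalNAcα1-3(Fucα1-2)Galβ1-4GlcNAcβ1-6)GalNAc-ol",
    "Galβ1-3(Galβ1-4(Fucα1-3)GlcNAcβ1-6)GalNAc-ol",         # Lewis X on core 2
    "Galβ1-4(Fucα1-3)GlcNAcβ1-3GalNAc-ol",                  # Lewis X on core 3
    "Neu5Acα2-3Galβ1-3(Fucα1-4)GlcNAcβ1-3GalNAc-ol",        # sLeA on core 3
    "Galβ1-4GlcNAcβ1-6(Neu5Acα2-3Galβ1-3(Fucα1-4)GlcNAcβ1-3)GalNAc-ol",
]

# GSL glycans: EGCase-released, reduced; lactose core Galβ1-4Glc-ol.
PANEL_GSL_GLYCANS = [
    "Galβ1-4Glc-ol",                                        # lactose core
    "Galα1-4Galβ1-4Glc-ol",                                 # Gb3
    "GalNAcβ1-3Galα1-4Galβ1-4Glc-ol",                       # Gb4
    "Neu5Acα2-3Galβ1-4Glc-ol",                              # GM3
    "Neu5Acα2-6Galβ1-4Glc-ol",                              # 2,6-sialyllactose
    "GalNAcβ1-4(Neu5Acα2-3)Galβ1-4Glc-ol",                  # GM2
    "Galβ1-3GalNAcβ1-4(Neu5Acα2-3)Galβ1-4Glc-ol",           # GM1
    "Neu5Acα2-3Galβ1-3GalNAcβ1-4(Neu5Acα2-3)Galβ1-4Glc-ol", # GD1a
    "Fucα1-2Galβ1-3GalNAcβ1-4(Neu5Acα2-3)Galβ1-4Glc-ol",    # fucosyl-GM1
    "GlcNAcβ1-3Galβ1-4Glc-ol",                              # Lc3
    "Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol",                       # nLc4
    "Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol",             # 2,6-sialyl-nLc4
    "Neu5Acα2-3Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol",             # 2,3-sialyl-nLc4
    "Fucα1-2Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol",                # H-nLc4
    "GalNAcα1-3(Fucα1-2)Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol",    # blood group A nLc4
    "Galβ1-4(Fucα1-3)GlcNAcβ1-3Galβ1-4Glc-ol",              # Lewis X
    "Galβ1-4(Fucα1-3)GlcNAcβ1-3Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol",
    "Neu5Acα2-3Galβ1-3(Fucα1-4)GlcNAcβ1-3Galβ1-4Glc-ol",    # sLeA on Lc4
]


def build_reference_panel(
    traits: Optional[Sequence[TraitDefinition]] = None,
) -> tuple[list[Glycan], pd.DataFrame]:
    """Parse the reference structures and recompute their epitope counts
    with the motif engine.  Returns (glycans, epitope count table)."""
    glycans = [parse_glycan(s, GlycanContext.O_GLYCAN) for s in PANEL_O_GLYCANS]
    glycans += [parse_glycan(s, GlycanContext.GSL) for s in PANEL_GSL_GLYCANS]
    counts = compute_epitope_table(glycans, traits)
    return glycans, counts


def default_profiles() -> dict[str, dict[str, float]]:
    """Two-sample study conditions loosely emulating an epithelial-like
    sample (S-like: abundant core 2, T/sTn, fucosylated and 2,6-sialylated
    species, (neo)lacto GSLs) and a mesenchymal-like sample (T-like: fewer,
    shorter O-glycans dominated by 2,6-sialylated GalNAc, globosides and
    gangliosides present).  Percentages per sample sum to 100 across the
    combined O + GSL structure panel of each scope's table."""
    s_o = {
        "GalNAc-ol": 4.0,
        "Neu5Acα2-6GalNAc-ol": 7.0,
        "Galβ1-3GalNAc-ol": 6.0,
        "Neu5Acα2-3Galβ1-3GalNAc-ol": 5.0,
        "Neu5Acα2-3Galβ1-3(Neu5Acα2-6)GalNAc-ol": 5.0,
        "Neu5Acα2-6Galβ1-3GalNAc-ol": 4.0,
        "Galβ1-3(GlcNAcβ1-6)GalNAc-ol": 7.0,
        "Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAc-ol": 8.0,
        "Neu5Acα2-3Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAc-ol": 7.0,
        "Galβ1-3(Neu5Acα2-6Galβ1-4GlcNAcβ1-6)GalNAc-ol": 6.0,
        "GlcNAcβ1-3GalNAc-ol": 3.0,
        "GlcNAcβ1-3(GlcNAcβ1-6)GalNAc-ol": 3.0,
        "Galβ1-3(GalNAcβ1-4Galβ1-4GlcNAcβ1-6)GalNAc-ol": 4.0,
        "Fucα1-2Galβ1-3GalNAc-ol": 5.0,
        "GalNAcα1-3(Fucα1-2)Galβ1-3GalNAc-ol": 4.0,
        "Galβ1-3(Fucα1-2Galβ1-4GlcNAcβ1-6)GalNAc-ol": 4.0,
        "Galβ1-3(GalNAcα1-3(Fucα1-2)Galβ1-4GlcNAcβ1-6)GalNAc-ol": 3.0,
        "Galβ1-3(Galβ1-4(Fucα1-3)GlcNAcβ1-6)GalNAc-ol": 4.0,
        "Galβ1-4(Fucα1-3)GlcNAcβ1-3GalNAc-ol": 3.0,
        "Neu5Acα2-3Galβ1-3(Fucα1-4)GlcNAcβ1-3GalNAc-ol": 4.0,
        "Galβ1-4GlcNAcβ1-6(Neu5Acα2-3Galβ1-3(Fucα1-4)GlcNAcβ1-3)GalNAc-ol": 4.0,
    }
    t_o = {
        "GalNAc-ol": 4.0,
        "Neu5Acα2-6GalNAc-ol": 5.0,
        "Neu5Acα2-3Galβ1-3GalNAc-ol": 10.0,
        "Neu5Acα2-3Galβ1-3(Neu5Acα2-6)GalNAc-ol": 9.0,
        "Neu5Acα2-6Galβ1-3GalNAc-ol": 6.0,
        "Galβ1-3GalNAc-ol": 8.0,
        "Galβ1-3(GlcNAcβ1-6)GalNAc-ol": 7.0,
        "Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAc-ol": 10.0,
        "Galβ1-3(Neu5Acα2-3Galβ1-4GlcNAcβ1-6)GalNAc-ol": 9.0,
        "Galβ1-3(Neu5Acα2-6Galβ1-4GlcNAcβ1-6)GalNAc-ol": 8.0,
        "Neu5Acα2-3Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAc-ol": 9.0,
        "GlcNAcβ1-3GalNAc-ol": 5.0,
        "GlcNAcβ1-3(GlcNAcβ1-6)GalNAc-ol": 5.0,
        "Galβ1-3(GalNAcβ1-4Galβ1-4GlcNAcβ1-6)GalNAc-ol": 5.0,
    }
    s_gsl = {
        "Galβ1-4Glc-ol": 4.0,
        "Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol": 13.0,
        "Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol": 14.0,
        "Neu5Acα2-3Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol": 8.0,
        "Fucα1-2Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol": 12.0,
        "GalNAcα1-3(Fucα1-2)Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol": 7.0,
        "Galβ1-4(Fucα1-3)GlcNAcβ1-3Galβ1-4Glc-ol": 8.0,
        "Galβ1-4(Fucα1-3)GlcNAcβ1-3Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol": 6.0,
        "GlcNAcβ1-3Galβ1-4Glc-ol": 10.0,
        "Neu5Acα2-3Galβ1-3(Fucα1-4)GlcNAcβ1-3Galβ1-4Glc-ol": 8.0,
        "Neu5Acα2-3Galβ1-4Glc-ol": 4.0,
        "Neu5Acα2-6Galβ1-4Glc-ol": 6.0,
    }
    t_gsl = {
        "Galα1-4Galβ1-4Glc-ol": 6.0,
        "GalNAcβ1-3Galα1-4Galβ1-4Glc-ol": 5.0,
        "Neu5Acα2-3Galβ1-4Glc-ol": 8.0,
        "Neu5Acα2-6Galβ1-4Glc-ol": 5.0,
        "GalNAcβ1-4(Neu5Acα2-3)Galβ1-4Glc-ol": 8.0,
        "Galβ1-3GalNAcβ1-4(Neu5Acα2-3)Galβ1-4Glc-ol": 7.0,
        "Neu5Acα2-3Galβ1-3GalNAcβ1-4(Neu5Acα2-3)Galβ1-4Glc-ol": 4.0,
        "Fucα1-2Galβ1-3GalNAcβ1-4(Neu5Acα2-3)Galβ1-4Glc-ol": 4.0,
        "Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol": 14.0,
        "Neu5Acα2-3Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol": 11.0,
        "Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-4Glc-ol": 6.0,
        "Neu5Acα2-3Galβ1-3(Fucα1-4)GlcNAcβ1-3Galβ1-4Glc-ol": 6.0,
        "GlcNAcβ1-3Galβ1-4Glc-ol": 11.0,
        "Galβ1-4Glc-ol": 5.0,
    }
    return {
        "O": {"PaTuS-like": s_o, "PaTuT-like": t_o},
        "GSL": {"PaTuS-like": s_gsl, "PaTuT-like": t_gsl},
    }


@dataclass
class SimulationConfig:
    """Study conditions for the peak-table generator.

    ``profiles`` maps sample -> {glycan id -> percent of total signal}
    (each sample sums to 100); ``totals`` maps sample -> total-signal
    scalar in arbitrary area units (the between-sample quantity behind the
    estimated-total panels); triplicate design and 5% multiplicative CV by
    default."""

    profiles: Mapping[str, Mapping[str, float]]
    n_replicates: int = 3
    noise_cv: float = 0.05
    totals: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for sample, profile in self.profiles.items():
            total = sum(profile.values())
            if abs(total - 100.0) > 1e-6:
                raise ValueError(
                    f"profile for {sample!r} sums to {total}, expected 100"
                )


def simulate_peak_tables(
    panel_counts: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (peak records, planted trait table).

    Areas are profile fraction x sample total x LogNormal with unit mean
    and the configured CV; the planted traits are the noiseless profile
    pushed through the epitope-weighted trait formula."""
    known = set(panel_counts["glycan_id"])

    def canonical(text: str) -> str:
        try:
            return serialize_glycan(parse_glycan(text, GlycanContext.FREE))
        except Exception:
            return text

    profiles = {
        sample: {canonical(gid): pct for gid, pct in profile.items()}
        for sample, profile in config.profiles.items()
    }
    for sample, profile in profiles.items():
        unknown = set(profile) - known
        if unknown:
            raise ValueError(
                f"profile for {sample!r} references unknown glycans: "
                f"{sorted(unknown)[:3]}"
            )
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log(1.0 + config.noise_cv**2))
    mu = -0.5 * sigma**2  # unit-mean log-normal
    totals = config.totals or {s: 1000.0 for s in profiles}
    rows = []
    for sample in profiles:
        profile = profiles[sample]
        scale = totals.get(sample, 1000.0)
        for rep in range(1, config.n_replicates + 1):
            for gid, pct in profile.items():
                noise = rng.lognormal(mu, sigma) if sigma > 0 else 1.0
                area = pct / 100.0 * scale * noise
                rows.append((sample, f"rep{rep}", gid, area))
    records = pd.DataFrame(rows, columns=["sample", "replicate", "glycan_id", "area"])

    # planted truth: noiseless profile -> relative abundance -> trait formula
    truth_rows = []
    for sample, profile in profiles.items():
        for gid, pct in profile.items():
            truth_rows.append((sample, "planted", gid, pct))
    noiseless = pd.DataFrame(
        truth_rows, columns=["sample", "replicate", "glycan_id", "rel_abundance"]
    )
    planted = (
        compute_trait_abundance(noiseless, panel_counts)
        .rename(columns={"value": "planted_value"})
        .drop(columns="replicate")
    )
    return records, planted


@dataclass
class ExpressionConfig:
    """Study conditions for the probe-matrix generator: two groups of
    replicate arrays, a fraction of genes planted at a fold change, probe
    affinities, and Gaussian log2 noise."""

    n_genes: int = 1171
    probes_per_gene: int = 3
    n_per_group: int = 3
    planted_fraction: float = 0.10
    planted_log2_fc: float = 1.0  # linear FC 2.0
    noise_sd: float = 0.2
    baseline_log2: float = 8.0
    baseline_sd: float = 1.5
    affinity_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least two arrays per group")
        if self.n_genes < 1 or self.probes_per_gene < 1:
            raise ValueError("invalid dimensions")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted fraction must be in [0, 1]")


def simulate_probe_matrix(
    config: ExpressionConfig,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str], pd.DataFrame]:
    """Generate (probe matrix, probe->gene map, array->group map, truth).

    log2 intensity = gene baseline + group effect (planted log2 FC on the
    second group) + probe affinity + N(0, sd); exponentiated to the
    intensity scale.  ``truth`` lists each gene's planted log2 FC."""
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    n_planted = int(round(config.planted_fraction * config.n_genes))
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
    effects = np.zeros(config.n_genes)
    signs = rng.choice([-1.0, 1.0], size=n_planted)
    effects[planted_idx] = config.planted_log2_fc * signs

    arrays = [f"g1_a{i+1}" for i in range(config.n_per_group)] + [
        f"g2_a{i+1}" for i in range(config.n_per_group)
    ]
    design = {a: ("group1" if a.startswith("g1") else "group2") for a in arrays}
    group2 = np.array([design[a] == "group2" for a in arrays], dtype=float)

    baselines = rng.normal(config.baseline_log2, config.baseline_sd, config.n_genes)
    probe_rows = []
    probe_gene: dict[str, str] = {}
    data = []
    for gi, gene in enumerate(genes):
        affinities = rng.normal(0.0, config.affinity_sd, config.probes_per_gene)
        for pi in range(config.probes_per_gene):
            probe = f"{gene}_p{pi+1}"
            probe_gene[probe] = gene
            log2_signal = (
                baselines[gi]
                + affinities[pi]
                + effects[gi] * group2
                + rng.normal(0.0, config.noise_sd, len(arrays))
            )
            probe_rows.append(probe)
            data.append(np.exp2(log2_signal))
    matrix = pd.DataFrame(np.array(data), index=probe_rows, columns=arrays)
    truth = pd.DataFrame(
        {"gene": genes, "planted_log2_fc": effects, "planted": effects != 0.0}
    )
    return matrix, probe_gene, design, truth


def recover_traits(
    records: pd.DataFrame,
    panel_counts: pd.DataFrame,
    coverage: float = 100.0,
) -> pd.DataFrame:
    """Convenience: run the quantification pipeline on simulated records
    and return the aggregated trait table."""
    from .quantify import apply_coverage_filter, normalize_within_sample

    rel = normalize_within_sample(records)
    rel = apply_coverage_filter(rel, coverage)
    per_rep = compute_trait_abundance(rel, panel_counts)
    return aggregate_replicates(per_rep)
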