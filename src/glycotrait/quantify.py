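"""Relative quantification of PGC-LC-MS glycan peak areas and derived traits.

Peak areas are converted to within-replicate relative abundances (each
(sample, replicate) sums to 100%), optionally filtered to the glycans that
make up 95% of the signal, and combined with epitope counts into
epitope-weighted derived traits::

    trait(sample, replicate) = sum_g rel_abundance(g) * epitope_count(g, trait)

Replicates are aggregated as mean ± sample SD (n-1 denominator), matching
the mean + SD, N = 3 presentation of the source panels.  Estimated total
glycan content compares each sample's summed raw area against a reference
sample set to 100%.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "normalize_within_sample",
    "apply_coverage_filter",
    "estimate_total_content",
    "compute_trait_abundance",
    "aggregate_replicates",
]

PEAK_COLUMNS = ["sample", "replicate", "glycan_id", "area"]


def _check_peaks(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"peak table lacks columns {missing}")
    if records.empty:
        raise ValueError("empty peak table")
    if (records["area"] <= 0).any():
        bad = records.loc[records["area"] <= 0]
        raise ValueError(
            f"non-positive peak areas for {len(bad)} records "
            f"(first: {bad.iloc[0].to_dict()})"
        )
    dupes = records.duplicated(subset=["sample", "replicate", "glycan_id"])
    if dupes.any():
        raise ValueError(
            f"duplicate (sample, replicate, glycan) records: "
            f"{records.loc[dupes, ['sample', 'replicate', 'glycan_id']].iloc[0].tolist()}"
        )
    return records


def normalize_within_sample(records: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, replicate), express each peak area as a percentage of
    that replicate's total signal (sums to 100)."""
    records = _check_peaks(records)
    out = records.copy()
    totals = out.groupby(["sample", "replicate"])["area"].transform("sum")
    out["rel_abundance"] = 100.0 * out["area"] / totals
    return out[["sample", "replicate", "glycan_id", "rel_abundance"]]


def apply_coverage_filter(
    table: pd.DataFrame, coverage: float = 95.0
) -> pd.DataFrame:
    """Keep, per sample, the smallest top set of glycans (ranked by
    replicate-mean relative abundance) whose cumulative mean reaches
    ``coverage`` percent; the same glycan set is kept in every replicate of
    that sample.  Values are not renormalised afterwards."""
    if not 0 < coverage <= 100:
        raise ValueError("coverage must be in (0, 100]")
    if coverage == 100:
        return table.copy()
    kept_parts = []
    for sample, group in table.groupby("sample", sort=False):
        means = (
            group.groupby("glycan_id")["rel_abundance"]
            .mean()
            .sort_values(ascending=False, kind="mergesort")
        )
        cumulative = means.cumsum()
        n_keep = int(np.searchsorted(cumulative.values, coverage - 1e-12)) + 1
        n_keep = min(n_keep, len(means))
        keep = set(means.index[:n_keep])
        kept_parts.append(group[group["glycan_id"].isin(keep)])
    return pd.concat(kept_parts, ignore_index=True)


def estimate_total_content(
    records: pd.DataFrame, reference_sample: str
) -> pd.DataFrame:
    """Per sample, the replicate-mean summed peak area as a percentage of
    the reference sample's replicate-mean summed area (reference = 100)."""
    records = _check_peaks(records)
    totals = (
        records.groupby(["sample", "replicate"])["area"].sum().groupby("sample").mean()
    )
    if reference_sample not in totals.index:
        raise ValueError(f"reference sample {reference_sample!r} not in peak table")
    out = (100.0 * totals / totals[reference_sample]).rename("total_pct").reset_index()
    return out


def compute_trait_abundance(
    rel_table: pd.DataFrame, epitope_table: pd.DataFrame
) -> pd.DataFrame:
    """Epitope-weighted trait values per (sample, replicate, trait):
    sum over glycans of relative abundance x epitope count.  Glycans absent
    from the epitope table contribute 0 (with a warning)."""
    known = set(epitope_table["glycan_id"])
    missing = sorted(set(rel_table["glycan_id"]) - known)
    if missing:
        warnings.warn(
            f"{len(missing)} glycans missing from the epitope table "
            f"(e.g. {missing[0]!r}); they contribute 0 to every trait",
            stacklevel=2,
        )
    merged = rel_table.merge(
        epitope_table[["glycan_id", "trait", "count"]], on="glycan_id", how="inner"
    )
    merged["weighted"] = merged["rel_abundance"] * merged["count"]
    traits = (
        merged.groupby(["sample", "replicate", "trait"], sort=False)["weighted"]
        .sum()
        .rename("value")
        .reset_index()
    )
    # traits with zero coverage in a replicate still get an explicit 0 row
    full = (
        rel_table[["sample", "replicate"]]
        .drop_duplicates()
        .merge(
            pd.DataFrame({"trait": sorted(epitope_table["trait"].unique())}),
            how="cross",
        )
    )
    traits = full.merge(traits, on=["sample", "replicate", "trait"], how="left")
    traits["value"] = traits["value"].fillna(0.0)
    return traits


def aggregate_replicates(trait_values: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1; 0 when n = 1) and n per (sample, trait)."""
    def _sd(x: pd.Series) -> float:
        return 0.0 if len(x) < 2 else float(np.std(x, ddof=1))

    out = (
        trait_values.groupby(["sample", "trait"], sort=False)["value"]
        .agg(mean="mean", sd=_sd, n="count")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
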