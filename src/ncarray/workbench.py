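"""Reporting helpers and run-configuration plumbing tying the pipeline together.

The summaries mirror how custom-chip studies report results: candidate
composition of the chip (counts and percentage shares per source/biotype),
up/down DE counts per biotype and comparison, log2-scale frequency tables
of biotype by genomic location, and Venn-style membership tables of DE
candidates across comparisons.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "simulation_study",
    "candidate_composition",
    "combine_region_counts",
    "de_counts_by_biotype",
    "biotype_location_frequency",
    "overlap_table",
    "write_run_config",
]


def simulation_study(
    n_candidates: int = 2000,
    n_seeds: int = 50,
    base_seed: int = 0,
    n_pairs: int = 3,
    fraction_de: float = 0.1,
    effect_size: float = 1.0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Operating characteristics of the pipeline on simulated experiments.

    For each seed, one experiment at the stated DE fraction and one null
    experiment (0% DE) are simulated on a 16-block chip and pushed through
    the full analysis.  Returns pooled empirical FDR at adjusted p < alpha,
    mean sensitivity, mean absolute log2FC recovery error over DE
    candidates, and the mean fraction of null candidates with raw p < 0.05.
    """
    from .array_layout import layout_array
    from .expression_analysis import run_de_analysis
    from .hyb_simulator import TruthModel, simulate_experiment, synthetic_probe_panel

    panel = synthetic_probe_panel(n_candidates, seed=base_seed)
    design = layout_array(panel, n_blocks=16, block_rows=46, block_cols=44, seed=base_seed)
    candidates = [p.probe_id for p in panel if p.role == "signal"]

    false_calls = total_calls = 0
    sens, errs, null_rates = [], [], []
    for i in range(n_seeds):
        truth = TruthModel.generate(
            candidates, design.n_blocks, seed=base_seed + 1000 + i,
            fraction_de=fraction_de, effect_size=effect_size,
        )
        scans, sheet, tt = simulate_experiment(design, truth, n_pairs=n_pairs)
        de = run_de_analysis(scans, sheet, alpha=alpha)
        merged = de.join(tt.set_index("candidate_id"), how="inner", rsuffix="_true")
        calls = merged[merged["de_call"]]
        false_calls += int((~calls["is_de"]).sum())
        total_calls += len(calls)
        de_rows = merged[merged["is_de"]]
        sens.append(float(de_rows["de_call"].mean()))
        errs.append(float(np.abs(de_rows["log2fc"] - de_rows["log2fc_true"]).mean()))

        null_truth = TruthModel.generate(
            candidates, design.n_blocks, seed=base_seed + 5000 + i, fraction_de=0.0,
        )
        null_scans, null_sheet, _ = simulate_experiment(design, null_truth, n_pairs=n_pairs)
        null_de = run_de_analysis(null_scans, null_sheet, alpha=alpha)
        p = null_de.loc[null_de.index.isin(candidates), "p"].dropna()
        null_rates.append(float((p < 0.05).mean()))

    return {
        "empirical_fdr": false_calls / total_calls if total_calls else 0.0,
        "sensitivity": float(np.mean(sens)),
        "mean_abs_log2fc_error": float(np.mean(errs)),
        "null_raw_p_rate": float(np.mean(null_rates)),
        "n_candidates": n_candidates,
        "n_seeds": n_seeds,
    }


def candidate_composition(counts: Mapping[str, int]) -> pd.DataFrame:
    """Chip bookkeeping: per-source candidate counts, total and % share.

    The returned frame has one row per source plus a ``total`` row;
    ``share_pct`` is the percentage of the total (rounded elsewhere as
    needed; stored unrounded).
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("candidate counts must sum to a positive total")
    rows = [
        {"source": name, "count": n, "share_pct": 100.0 * n / total}
        for name, n in counts.items()
    ]
    rows.append({"source": "total", "count": total, "share_pct": 100.0})
    return pd.DataFrame(rows)


def combine_region_counts(counts: Mapping[str, int]) -> pd.DataFrame:
    """Aggregate per-region DE counts into a total row (e.g. brain regions
    of one mouse model)."""
    df = pd.DataFrame(
        [{"region": k, "n_de": int(v)} for k, v in counts.items()]
    )
    total = int(df["n_de"].sum())
    return pd.concat(
        [df, pd.DataFrame([{"region": "total", "n_de": total}])], ignore_index=True
    )


def de_counts_by_biotype(de_table: pd.DataFrame) -> pd.DataFrame:
    """Up/down-regulated candidate counts per biotype for one comparison.

    Expects the DE table of :func:`~ncarray.expression_analysis.run_de_analysis`
    (columns ``de_call``, ``log2fc``, optionally ``biotype``).
    """
    calls = de_table[de_table["de_call"]]
    biotype = calls["biotype"] if "biotype" in calls.columns else pd.Series(
        "unknown", index=calls.index
    )
    out = (
        pd.DataFrame(
            {
                "biotype": biotype,
                "direction": np.where(calls["log2fc"] > 0, "up", "down"),
            }
        )
        .groupby(["biotype", "direction"])
        .size()
        .rename("n")
        .reset_index()
    )
    return out


def biotype_location_frequency(annotations: pd.DataFrame) -> pd.DataFrame:
    """Frequency table of biotype x genomic location, with log2 frequencies.

    ``annotations`` needs columns ``biotype`` and ``location``.  Counts of
    zero have no log2 entry (NaN).
    """
    counts = (
        annotations.groupby(["biotype", "location"]).size().rename("n").reset_index()
    )
    counts["log2_n"] = np.log2(counts["n"].where(counts["n"] > 0))
    return counts


def overlap_table(memberships: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Venn-style membership table across comparisons.

    One row per candidate appearing in any comparison; one boolean column
    per comparison; ``n_comparisons`` counts memberships.
    """
    all_ids = sorted(set().union(*[set(v) for v in memberships.values()])) if memberships else []
    out = pd.DataFrame(index=pd.Index(all_ids, name="candidate_id"))
    for name, ids in memberships.items():
        out[name] = out.index.isin(set(ids))
    out["n_comparisons"] = out.sum(axis=1).astype(int)
    return out


def write_run_config(config: Mapping | object, path: str | Path) -> None:
    """Serialize the run configuration next to its outputs (reproducibility)."""

    def _default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)

    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
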