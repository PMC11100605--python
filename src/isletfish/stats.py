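"""Per-cell aggregation, localization fractions, and group statistics.

Per-cell per-gene transcript counts are split into nuclear and
cytoplasmic sub-totals; localization is summarized as the per-cell
nuclear fraction (mean +- SEM per group).  Two-group comparisons use
the Mann-Whitney U test: exact two-sided p by enumeration for small
tie-free samples, otherwise a normal approximation with tie and
continuity corrections.  No multiple-testing correction is applied;
p-values are reported per gene as-is.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import GroupResult

logger = logging.getLogger(__name__)

__all__ = [
    "per_cell_counts",
    "localization_fractions",
    "mann_whitney",
    "ctcf",
    "snr_normalize",
    "compare_groups",
    "report",
]

EXACT_MAX_N = 12


def per_cell_counts(foci: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Per-(cell, gene) transcript totals with compartment split.

    Only retained foci (non-outlier, assigned to a cell) contribute.
    Cells without foci get zero rows for every gene, so the table
    always has one row per (cell, gene).  ``is_beta`` flags cells
    classified beta; select on it for the beta-only view.
    """
    genes = sorted(foci["gene"].unique()) if len(foci) else []
    if len(foci):
        retained = foci[(~foci["outlier"].astype(bool)) & (foci["cell_id"] > 0)]
    else:
        retained = foci
    class_by_cell = dict(zip(cells["cell_id"], cells["cell_class"]))
    rows = []
    for cid in sorted(cells["cell_id"]):
        for gene in genes:
            if len(retained):
                sub = retained[(retained["cell_id"] == cid) & (retained["gene"] == gene)]
                nuc = int(sub.loc[sub["compartment"] == "nuclear", "mrna_count"].sum())
                cyt = int(sub.loc[sub["compartment"] == "cytoplasmic", "mrna_count"].sum())
            else:
                nuc = cyt = 0
            rows.append(
                {
                    "cell_id": cid,
                    "gene": gene,
                    "total": nuc + cyt,
                    "nuclear": nuc,
                    "cytoplasmic": cyt,
                    "cell_class": class_by_cell.get(cid, "unclassified"),
                    "is_beta": class_by_cell.get(cid) == "beta",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "gene", "total", "nuclear", "cytoplasmic", "cell_class", "is_beta"],
    )


def localization_fractions(count_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell nuclear fractions and their per-group summaries.

    Cells with zero transcripts for a gene are excluded.  Group
    summaries (per gene and cell class) are mean +- standard error of
    the per-cell fractions.
    """
    tab = count_table[count_table["total"] > 0].copy()
    tab["nuclear_fraction"] = tab["nuclear"] / tab["total"]
    per_cell = tab[["cell_id", "gene", "cell_class", "total", "nuclear", "nuclear_fraction"]]
    rows = []
    for (gene, cls), sub in sorted(tab.groupby(["gene", "cell_class"], sort=True)):
        frac = sub["nuclear_fraction"].to_numpy()
        sem = float(frac.std(ddof=1) / math.sqrt(frac.size)) if frac.size > 1 else np.nan
        rows.append(
            {
                "gene": gene,
                "cell_class": cls,
                "n_cells": int(frac.size),
                "mean_nuclear_fraction": float(frac.mean()),
                "sem_nuclear_fraction": sem,
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=["gene", "cell_class", "n_cells", "mean_nuclear_fraction", "sem_nuclear_fraction"],
    )
    return per_cell.reset_index(drop=True), summary


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a, from mid-rank sums."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def mann_whitney(
    sample_a,
    sample_b,
    gene: str = "",
    statistic_name: str = "mrna_count",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupResult:
    """Two-sided Mann-Whitney U test.

    The exact two-sided p-value is used when ``n_a + n_b <= 12`` and
    the pooled sample is tie-free; otherwise the normal approximation
    with tie correction and a continuity correction of 1/2 (shifted
    toward the null, so identical samples give p = 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = a.size, b.size
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size

    if n_a + n_b <= EXACT_MAX_N and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        method = "exact"
    else:
        mean_u = n_a * n_b / 2.0
        n = n_a + n_b
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts).sum()))
        var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_u <= 0:
            p = 1.0
        else:
            z = max(0.0, abs(u - mean_u) - 0.5) / math.sqrt(var_u)
            p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        method = "asymptotic"
    return GroupResult(
        gene=gene,
        statistic_name=statistic_name,
        group_a=group_a,
        group_b=group_b,
        n_a=n_a,
        n_b=n_b,
        U_statistic=u,
        p_value=p,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        method=method,
    )


def ctcf(integrated_density: float, region_area_px: float, background_mean: float) -> float:
    """Corrected total fluorescence: integrated density minus
    area times mean background.  May be negative (logged)."""
    for name, v in [
        ("integrated_density", integrated_density),
        ("region_area_px", region_area_px),
        ("background_mean", background_mean),
    ]:
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if region_area_px < 0:
        raise ValueError("region_area_px must be >= 0")
    value = float(integrated_density - region_area_px * background_mean)
    if value < 0:
        logger.warning("negative corrected fluorescence (%.3g); check background region", value)
    return value


def snr_normalize(target_counts, igg_counts) -> np.ndarray:
    """Per-marker log2 signal-to-noise against IgG negative controls.

    SNR = count / geometric_mean(IgG counts); returned on a log2 scale.
    """
    target = np.asarray(target_counts, dtype=float)
    igg = np.asarray(igg_counts, dtype=float)
    if igg.size == 0:
        raise ValueError("need at least one IgG negative control")
    if (target <= 0).any() or (igg <= 0).any():
        raise ValueError("all counts must be > 0")
    geo = float(np.exp(np.mean(np.log(igg))))
    return np.log2(target / geo)


def compare_groups(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    label_a: str = "group_a",
    label_b: str = "group_b",
    beta_only: bool = True,
    value: str = "total",
) -> pd.DataFrame:
    """Per-gene Mann-Whitney comparison of two per-cell count tables."""
    rows = []
    genes = sorted(set(counts_a["gene"]) | set(counts_b["gene"]))
    for gene in genes:
        sel_a = counts_a["gene"] == gene
        sel_b = counts_b["gene"] == gene
        if beta_only:
            sel_a &= counts_a["is_beta"]
            sel_b &= counts_b["is_beta"]
        va = counts_a.loc[sel_a, value].to_numpy()
        vb = counts_b.loc[sel_b, value].to_numpy()
        if va.size == 0 or vb.size == 0:
            continue
        res = mann_whitney(va, vb, gene=gene, statistic_name=value, group_a=label_a, group_b=label_b)
        rows.append(
            {
                "gene": res.gene,
                "statistic_name": res.statistic_name,
                "group_a": res.group_a,
                "group_b": res.group_b,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "U_statistic": res.U_statistic,
                "p_value": res.p_value,
                "median_a": res.median_a,
                "median_b": res.median_b,
                "method": res.method,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "statistic_name",
            "group_a",
            "group_b",
            "n_a",
            "n_b",
            "U_statistic",
            "p_value",
            "median_a",
            "median_b",
            "method",
        ],
    )


def report(run_dir: str | Path, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Summarize a completed pipeline run directory.

    Reads the cell, focus, and count tables written by the pipeline and
    emits per-gene per-class summary tables and localization tables.
    Deterministic: identical runs give byte-identical reports.
    """
    run_dir = Path(run_dir)
    out_dir = Path(out_dir) if out_dir is not None else run_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(run_dir / "per_cell_counts.csv")
    per_cell, summary = localization_fractions(counts)
    rows = []
    for (gene, cls), sub in sorted(counts.groupby(["gene", "cell_class"], sort=True)):
        vals = sub["total"].to_numpy(dtype=float)
        sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else np.nan
        rows.append(
            {
                "gene": gene,
                "cell_class": cls,
                "n_cells": int(vals.size),
                "mean_count": float(vals.mean()),
                "sem_count": sem,
                "median_count": float(np.median(vals)),
            }
        )
    expr = pd.DataFrame(
        rows, columns=["gene", "cell_class", "n_cells", "mean_count", "sem_count", "median_count"]
    )
    paths = {
        "expression_summary": out_dir / "expression_summary.csv",
        "localization_per_cell": out_dir / "localization_per_cell.csv",
        "localization_summary": out_dir / "localization_summary.csv",
    }
    expr.to_csv(paths["expression_summary"], index=False)
    per_cell.to_csv(paths["localization_per_cell"], index=False)
    summary.to_csv(paths["localization_summary"], index=False)
    return paths
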