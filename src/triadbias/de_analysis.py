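"""Differential-expression filtering, homeolog fold-change comparison and
gene-set enrichment.

The DEG rule is adjusted p <= alpha AND |log2 fold change| >= a minimum, both
boundaries inclusive. Enrichment is the upper-tail hypergeometric test of the
overlap between a DEG list and a gene set within a universe, with
Benjamini-Hochberg adjustment across the tested sets. ``naive_de`` is a
deliberately simple per-gene t-test on log counts for self-contained synthetic
runs; real analyses should supply a DE table produced by a dedicated
count-model tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import (
    CONDITIONS,
    HOMEOLOGS,
    DERecordSet,
    ExpressionMatrix,
    SampleSheet,
    TriadSet,
)

_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DEGFilter:
    """Thresholds defining a differentially expressed gene."""

    alpha: float = 0.05
    min_abs_log2fc: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")


def filter_degs(
    de: DERecordSet, f: DEGFilter = DEGFilter()
) -> tuple[set[str], set[str], set[str]]:
    """Partition genes into (all DEGs, up-regulated, down-regulated).

    A gene is a DEG iff padj <= alpha and |log2fc| >= min_abs_log2fc
    (inclusive on both boundaries); up means log2fc > 0. Raises if the table
    lacks adjusted p values — raw p is never silently substituted.
    """
    if not de.has_padj():
        raise ValueError("DE table has no (complete) adjusted p values")
    df = de.data
    padj = df["padj"].astype(float)
    log2fc = df["log2fc"].astype(float)
    is_deg = (padj <= f.alpha) & (np.abs(log2fc) >= f.min_abs_log2fc)
    up = set(df.loc[is_deg & (log2fc > 0), "gene_id"])
    down = set(df.loc[is_deg & (log2fc <= 0), "gene_id"])
    return up | down, up, down


def deg_table(de: DERecordSet, f: DEGFilter = DEGFilter()) -> pd.DataFrame:
    """DEG list as a frame: gene_id, log2fc, padj, direction."""
    degs, up, _ = filter_degs(de, f)
    df = de.data[de.data["gene_id"].isin(degs)].copy()
    df["direction"] = np.where(df["gene_id"].isin(up), "up", "down")
    return df[["gene_id", "log2fc", "padj", "direction"]].reset_index(drop=True)


def homeolog_fold_changes(
    de: DERecordSet,
    triads: TriadSet,
    gene_set: set[str] | None = None,
    f: DEGFilter = DEGFilter(),
) -> pd.DataFrame:
    """Per-triad stress/control fold changes of the three homeologs.

    Restricted to triads with at least one homeolog in ``gene_set`` (all triads
    when None). Triads with a homeolog absent from the DE table are flagged
    incomplete; complete triads get the homeolog with the strictly largest fold
    change (empty when tied). These rows back pairwise fold-change scatter
    plots (A vs D, B vs D, A vs B).
    """
    idx = de.data.set_index("gene_id")
    rows = []
    for t in triads:
        if gene_set is not None and not (set(t.genes) & gene_set):
            continue
        row: dict[str, object] = {"triad_id": t.triad_id}
        complete = True
        for h in HOMEOLOGS:
            g = t.gene(h)
            key = h.lower()
            if g in idx.index:
                row[f"fc_{key}"] = float(idx.at[g, "fold_change"])
                row[f"padj_{key}"] = (
                    float(idx.at[g, "padj"]) if "padj" in idx.columns else np.nan
                )
                row[f"deg_{key}"] = bool(
                    "padj" in idx.columns
                    and idx.at[g, "padj"] <= f.alpha
                    and abs(idx.at[g, "log2fc"]) >= f.min_abs_log2fc
                )
            else:
                row[f"fc_{key}"] = np.nan
                row[f"padj_{key}"] = np.nan
                row[f"deg_{key}"] = False
                complete = False
        row["complete"] = complete
        if complete:
            fcs = {h: row[f"fc_{h.lower()}"] for h in HOMEOLOGS}
            top = max(fcs.values())
            winners = [h for h, v in fcs.items() if v == top]
            row["max_homeolog"] = winners[0] if len(winners) == 1 else ""
        else:
            row["max_homeolog"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def hypergeometric_enrichment(
    degs: set[str],
    universe: set[str],
    gene_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each gene set in the DEG list.

    p = P[overlap >= k] drawing |degs| genes without replacement from a
    universe containing |set ∩ universe| set members. BH adjustment is applied
    across all tested sets.
    """
    if not universe:
        raise ValueError("empty universe")
    if not degs <= universe:
        raise ValueError("DEG list must be a subset of the universe")
    n_universe = len(universe)
    n_degs = len(degs)
    rows = []
    for name, members in gene_sets.items():
        in_universe = members & universe
        overlap = len(in_universe & degs)
        # P[X >= overlap], X ~ Hypergeom(M=universe, n=set size, N=draws)
        p = float(
            stats.hypergeom.sf(overlap - 1, n_universe, len(in_universe), n_degs)
        )
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(in_universe),
                "universe_size": n_universe,
                "n_degs": n_degs,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def naive_de(
    counts: ExpressionMatrix,
    sheet: SampleSheet,
    tissue: str | None = None,
    equal_var: bool = True,
) -> DERecordSet:
    """Per-gene two-sample t-test on log2(count + 0.5), stress vs control.

    Fold change is (stress mean + 0.5) / (control mean + 0.5) on raw counts;
    p values are BH-adjusted. This is a simple screening procedure for the
    synthetic pipeline, clearly labelled in the result's ``method`` — it does
    not model count dispersion and should not replace a dedicated DE tool on
    real data.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit={counts.unit!r}")
    if tissue is None:
        tissues = sheet.tissues
        if len(tissues) != 1:
            raise ValueError(f"tissue must be given; sheet has {tissues}")
        tissue = tissues[0]
    groups = {}
    for condition in CONDITIONS:
        samples = sheet.samples_for(tissue, condition)
        if len(samples) < 2:
            raise ValueError(
                f"need >= 2 replicates per condition for the t-test "
                f"({condition!r} has {len(samples)}); supply an external DE table"
            )
        groups[condition] = counts.values[samples].to_numpy(float)
    ctrl, strs = groups["control"], groups["stress"]
    fc = (strs.mean(axis=1) + _PSEUDOCOUNT) / (ctrl.mean(axis=1) + _PSEUDOCOUNT)
    log_ctrl = np.log2(ctrl + _PSEUDOCOUNT)
    log_strs = np.log2(strs + _PSEUDOCOUNT)
    with warnings.catch_warnings():
        # genes with (near-)constant counts trip scipy's catastrophic-
        # cancellation warning; their p values are forced to 1 below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(log_strs, log_ctrl, axis=1, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups -> no evidence
    df = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "fold_change": fc,
            "log2fc": np.log2(fc),
            "pvalue": p,
            "padj": benjamini_hochberg(p),
        }
    )
    return DERecordSet(df, method="naive-log-ttest (not a count model)")
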