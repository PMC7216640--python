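"""Relative expression values (REV) of wheat homeologs and stress-shift calls.

For a triad with homeolog TPMs (TPM_A, TPM_B, TPM_D), the relative expression
value of, say, the D homeolog is

    D% = TPM_D * 100 / (TPM_A + TPM_B + TPM_D)

computed per condition on replicate-mean TPM. A condition (e.g. long-term
salinity stress) "shifts" a homeolog's relative expression when the ratio of
its control REV to its stress REV changes by at least 20 percent in either
direction, i.e. max(r, 1/r) >= 1.2 with r = REV_control / REV_stress. Triads
where one condition's REV is exactly 0 have an undefined ratio; they are
tracked as their own outcome class and counted as shifted when the other
condition's REV is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import (
    CONDITIONS,
    GENE_COLUMNS,
    HOMEOLOGS,
    ExpressionMatrix,
    SampleSheet,
    TriadSet,
)

logger = logging.getLogger("triadbias")

DEFAULT_MIN_TOTAL_TPM = 0.5
DEFAULT_FOLD_THRESHOLD = 1.2

REV_COLUMNS = ["triad_id", "condition", "a_pct", "b_pct", "d_pct", "total_tpm"]
SHIFT_COLUMNS = [
    "triad_id",
    "homeolog",
    "rev_control",
    "rev_stress",
    "ratio",
    "significant",
    "undefined_ratio",
]

#: REV column per homeolog
PCT_COLUMNS = {"A": "a_pct", "B": "b_pct", "D": "d_pct"}


@dataclass
class ConditionMeans:
    """Replicate-mean TPM per gene and condition for one tissue."""

    means: pd.DataFrame  # index = gene ids, one column per condition
    n_replicates: dict[str, int]
    tissue: str

    def value(self, gene: str, condition: str) -> float:
        return float(self.means.at[gene, condition])

    def has_gene(self, gene: str) -> bool:
        return gene in self.means.index


def mean_by_condition(
    matrix: ExpressionMatrix, sheet: SampleSheet, tissue: str
) -> ConditionMeans:
    """Arithmetic mean of TPM across biological replicates, per condition.

    Raises if the matrix is not in TPM or the tissue is absent from the sheet.
    """
    if matrix.unit != "TPM":
        raise ValueError(f"expected a TPM matrix, got unit={matrix.unit!r}")
    if tissue not in sheet.tissues:
        raise ValueError(f"tissue {tissue!r} not in sample sheet {sheet.tissues}")
    cols = {}
    n_reps = {}
    for condition in CONDITIONS:
        samples = sheet.samples_for(tissue, condition)
        if not samples:
            continue
        missing = [s for s in samples if s not in matrix.values.columns]
        if missing:
            raise ValueError(f"samples {missing} absent from expression matrix")
        cols[condition] = matrix.values[samples].mean(axis=1)
        n_reps[condition] = len(samples)
    if not cols:
        raise ValueError(f"no samples for tissue {tissue!r}")
    return ConditionMeans(means=pd.DataFrame(cols), n_replicates=n_reps, tissue=tissue)


def triad_condition_totals(means: ConditionMeans, triads: TriadSet) -> pd.DataFrame:
    """Summed homeolog mean TPM per triad x condition (NaN if a gene is missing)."""
    rows = []
    for t in triads:
        row: dict[str, object] = {"triad_id": t.triad_id}
        complete = all(means.has_gene(g) for g in t.genes)
        for condition in means.means.columns:
            row[condition] = (
                sum(means.value(g, condition) for g in t.genes) if complete else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("triad_id")


def detect_expressed_triads(
    means: ConditionMeans,
    triads: TriadSet,
    min_total_tpm: float = DEFAULT_MIN_TOTAL_TPM,
) -> TriadSet:
    """Keep triads whose summed homeolog mean TPM exceeds the threshold in
    at least one condition. Triads with a homeolog absent from the matrix are
    reported and excluded rather than silently zeroed."""
    if min_total_tpm < 0:
        raise ValueError("min_total_tpm must be >= 0")
    totals = triad_condition_totals(means, triads)
    incomplete = totals.index[totals.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "%d triad(s) have homeologs missing from the expression matrix "
            "and were excluded (first: %s)",
            len(incomplete),
            incomplete[0],
        )
    keep = totals.index[(totals > min_total_tpm).any(axis=1) & totals.notna().all(axis=1)]
    expressed = triads.subset(list(keep), provenance="expressed")
    logger.info(
        "detected %d expressed triads of %d (min_total_tpm=%g, tissue=%s)",
        len(expressed),
        len(triads),
        min_total_tpm,
        means.tissue,
    )
    return expressed


def compute_rev(means: ConditionMeans, triads: TriadSet) -> pd.DataFrame:
    """One REV record (A%, B%, D%, total TPM) per triad per condition.

    Conditions where the triad's total TPM is 0 are omitted (and logged):
    the composition is undefined there. Percentages always sum to 100.
    """
    rows = []
    n_zero = 0
    conditions = list(means.means.columns)
    for t in triads:
        if not all(means.has_gene(g) for g in t.genes):
            logger.warning("triad %s: homeolog missing from matrix, skipped", t.triad_id)
            continue
        for condition in conditions:
            tpms = np.array([means.value(g, condition) for g in t.genes])
            total = tpms.sum()
            if total <= 0:
                n_zero += 1
                continue
            a, b, d = tpms * 100.0 / total
            rows.append(
                {
                    "triad_id": t.triad_id,
                    "condition": condition,
                    "a_pct": a,
                    "b_pct": b,
                    "d_pct": d,
                    "total_tpm": total,
                }
            )
    if n_zero:
        logger.info("%d triad x condition cells had zero total TPM (REV undefined)", n_zero)
    return pd.DataFrame(rows, columns=REV_COLUMNS)


def call_rev_shifts(
    revs: pd.DataFrame,
    homeolog: str,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Call stress-induced shifts in one homeolog's REV.

    A triad is significant when max(r, 1/r) >= fold_threshold with
    r = REV_control / REV_stress, i.e. a >= 20% change in either direction at
    the default threshold of 1.2. Triads where exactly one REV is 0 get an
    undefined ratio and count as significant; triads missing either condition
    are dropped.
    """
    if homeolog not in HOMEOLOGS:
        raise ValueError(f"homeolog must be one of {HOMEOLOGS}, got {homeolog!r}")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    col = PCT_COLUMNS[homeolog]
    wide = revs.pivot(index="triad_id", columns="condition", values=col)
    if "control" not in wide.columns or "stress" not in wide.columns:
        raise ValueError("REV records must cover both control and stress")
    wide = wide.dropna(subset=["control", "stress"])
    rc = wide["control"].to_numpy(float)
    rs = wide["stress"].to_numpy(float)
    both_pos = (rc > 0) & (rs > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(both_pos, rc / rs, np.nan)
        sym = np.maximum(ratio, 1.0 / ratio)
    one_zero = ((rc == 0) ^ (rs == 0))
    significant = np.where(both_pos, sym >= fold_threshold, one_zero)
    return pd.DataFrame(
        {
            "triad_id": wide.index,
            "homeolog": homeolog,
            "rev_control": rc,
            "rev_stress": rs,
            "ratio": ratio,
            "significant": significant.astype(bool),
            "undefined_ratio": ~both_pos,
        }
    ).reset_index(drop=True)


def shift_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-homeolog tallies of shift calls.

    Returns one row per homeolog with the number of triads evaluated, how
    many were significant / not / had undefined ratios, the significant
    fraction, and its complement (the fraction of triads whose REV changed
    by less than the threshold).
    """
    if calls.empty:
        raise ValueError("no shift calls to summarize")
    rows = []
    for homeolog, grp in calls.groupby("homeolog", sort=True):
        n = len(grp)
        n_sig = int(grp["significant"].sum())
        n_undef = int(grp["undefined_ratio"].sum())
        rows.append(
            {
                "homeolog": homeolog,
                "n_triads": n,
                "n_significant": n_sig,
                "n_not_significant": n - n_sig,
                "n_undefined_ratio": n_undef,
                "frac_significant": n_sig / n,
                "frac_below_threshold": (n - n_sig) / n,
            }
        )
    return pd.DataFrame(rows)
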