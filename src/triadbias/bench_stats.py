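"""Bench-side biochemical statistics: solute percent contributions, the
50%-change significance rule, and qPCR ΔΔCt relative expression.

Percent contribution of a solute = its molarity (μmol g⁻¹ DW) × 100 / total
molarity of all measured solutes, computed on condition means. A solute's
concentration change is called significant when the stress/control mean ratio
is >= 1.5 (up) or <= 2/3 (down) AND a two-sample t-test gives p < 0.05. The
rule is applied to concentrations; contributions are reported alongside.

Relative expression from qPCR uses fold = 2^-ΔΔCt with
ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control. With two
reference genes the reference Ct is their arithmetic mean per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CONDITIONS, TableFormatError, _read_tsv, write_table


# ---------------------------------------------------------------------------
# solutes
# ---------------------------------------------------------------------------

@dataclass
class SoluteProfile:
    """Replicate solute concentrations (μmol g⁻¹ DW) per condition.

    ``data`` is long format: solute, condition, replicate, concentration.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"solute", "condition", "replicate", "concentration"}
        missing = need - set(self.data.columns)
        if missing:
            raise TableFormatError(f"solute profile missing columns {sorted(missing)}")
        bad = set(self.data["condition"]) - set(CONDITIONS)
        if bad:
            raise TableFormatError(f"unknown condition(s) {sorted(bad)}")
        if (self.data["concentration"] < 0).any():
            raise TableFormatError("concentrations must be >= 0")

    @property
    def solutes(self) -> list[str]:
        return list(self.data["solute"].unique())

    def replicates(self, solute: str, condition: str) -> np.ndarray:
        m = (self.data["solute"] == solute) & (self.data["condition"] == condition)
        return self.data.loc[m, "concentration"].to_numpy(float)

    def condition_means(self, condition: str) -> pd.Series:
        sub = self.data[self.data["condition"] == condition]
        means = sub.groupby("solute", sort=False)["concentration"].mean()
        return means.reindex(self.solutes)

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()


def read_solute_table(path: str | Path) -> SoluteProfile:
    """Read a wide solute TSV: column ``solute``, then one column per
    condition replicate named like ``control_1``, ``stress_3``."""
    df = _read_tsv(path)
    if "solute" not in df.columns:
        raise TableFormatError(f"{path}: missing 'solute' column")
    rows = []
    for col in df.columns:
        if col == "solute":
            continue
        parts = col.rsplit("_", 1)
        if len(parts) != 2 or parts[0] not in CONDITIONS:
            raise TableFormatError(
                f"{path}: replicate column {col!r} must look like 'control_1'"
            )
        condition, rep = parts[0], int(parts[1])
        for solute, value in zip(df["solute"], df[col].astype(float)):
            rows.append(
                {
                    "solute": str(solute),
                    "condition": condition,
                    "replicate": rep,
                    "concentration": value,
                }
            )
    return SoluteProfile(pd.DataFrame(rows))


def percent_contribution(profile: SoluteProfile, condition: str) -> pd.Series:
    """Each solute's share (%) of the total molarity under one condition.

    Computed on condition means; shares always sum to 100.
    """
    means = profile.condition_means(condition)
    total = means.sum()
    if not total > 0:
        raise ValueError(f"total molarity is 0 under {condition!r}")
    return means * 100.0 / total


def significant_solute_change(
    profile: SoluteProfile,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
    welch: bool = True,
) -> pd.DataFrame:
    """Call each solute up / down / none between stress and control.

    up: stress/control mean ratio >= fold_threshold and t-test p < alpha;
    down symmetrically with ratio <= 1/fold_threshold. Welch's correction is
    the default (n = 3 replicates rarely justifies equal variances).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    rows = []
    for solute in profile.solutes:
        ctrl = profile.replicates(solute, "control")
        strs = profile.replicates(solute, "stress")
        if len(ctrl) < 2 or len(strs) < 2:
            raise ValueError(f"solute {solute!r}: need >= 2 replicates per condition")
        mc, ms = ctrl.mean(), strs.mean()
        if mc > 0:
            ratio = ms / mc
        else:
            ratio = np.inf if ms > 0 else 1.0
        if np.allclose(ctrl, ctrl[0]) and np.allclose(strs, strs[0]) and np.isclose(
            ctrl[0], strs[0]
        ):
            p = 1.0  # identical constant vectors: no evidence of change
        else:
            p = float(stats.ttest_ind(strs, ctrl, equal_var=not welch).pvalue)
            if np.isnan(p):
                p = 1.0
        if p < alpha and ratio >= fold_threshold:
            call = "up"
        elif p < alpha and ratio <= 1.0 / fold_threshold:
            call = "down"
        else:
            call = "none"
        rows.append(
            {
                "solute": solute,
                "mean_control": mc,
                "mean_stress": ms,
                "ratio": ratio,
                "pvalue": p,
                "call": call,
            }
        )
    return pd.DataFrame(rows)


def solute_report(profile: SoluteProfile, **kwargs) -> pd.DataFrame:
    """Long report: per solute x condition means, percent contributions and the
    significance call (attached to both conditions' rows)."""
    calls = significant_solute_change(profile, **kwargs).set_index("solute")
    rows = []
    for condition in CONDITIONS:
        pct = percent_contribution(profile, condition)
        means = profile.condition_means(condition)
        for solute in profile.solutes:
            rows.append(
                {
                    "solute": solute,
                    "condition": condition,
                    "mean_concentration": means[solute],
                    "percent_contribution": pct[solute],
                    "call": calls.at[solute, "call"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR ΔΔCt
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """qPCR cycle-threshold values per gene x sample, with reference gene(s)."""

    data: pd.DataFrame  # columns: gene, sample, ct
    reference_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        need = {"gene", "sample", "ct"}
        missing = need - set(self.data.columns)
        if missing:
            raise TableFormatError(f"Ct table missing columns {sorted(missing)}")
        if not np.isfinite(self.data["ct"].astype(float)).all():
            raise TableFormatError("Ct values must be finite")
        genes = set(self.data["gene"])
        for ref in self.reference_genes:
            if ref not in genes:
                raise TableFormatError(f"reference gene {ref!r} absent from Ct table")

    def ct(self, gene: str, samples: list[str]) -> np.ndarray:
        sub = self.data[(self.data["gene"] == gene) & (self.data["sample"].isin(samples))]
        if len(sub) != len(samples):
            missing = set(samples) - set(sub["sample"])
            raise ValueError(f"gene {gene!r}: missing Ct for sample(s) {sorted(missing)}")
        return sub.set_index("sample").loc[samples, "ct"].to_numpy(float)

    def reference_ct(self, samples: list[str]) -> np.ndarray:
        """Per-sample reference Ct: arithmetic mean across reference genes."""
        if not self.reference_genes:
            raise ValueError("no reference genes designated")
        mat = np.vstack([self.ct(g, samples) for g in self.reference_genes])
        return mat.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()


def read_ct_table(path: str | Path, reference_genes: list[str]) -> CtTable:
    df = _read_tsv(path)
    df = df.astype({"gene": str, "sample": str, "ct": float})
    return CtTable(df, reference_genes=list(reference_genes))


def ddct_relative_expression(
    ct: CtTable,
    target: str,
    treated_samples: list[str],
    control_samples: list[str],
    per_replicate: bool = False,
):
    """Fold change of ``target`` in treated vs control samples, 2^−ΔΔCt.

    Default: Cts are averaged per group before differencing (ΔΔCt of means).
    With ``per_replicate=True`` a ΔCt is formed per treated replicate, each is
    referenced to the mean control ΔCt, and the per-replicate folds are
    returned along with their mean — useful for error propagation.
    """
    dct_treated = ct.ct(target, treated_samples) - ct.reference_ct(treated_samples)
    dct_control = ct.ct(target, control_samples) - ct.reference_ct(control_samples)
    if per_replicate:
        folds = 2.0 ** -(dct_treated - dct_control.mean())
        return float(folds.mean()), folds
    ddct = dct_treated.mean() - dct_control.mean()
    return 2.0 ** -ddct


__all__ = [
    "SoluteProfile",
    "CtTable",
    "read_solute_table",
    "read_ct_table",
    "percent_contribution",
    "significant_solute_change",
    "solute_report",
    "ddct_relative_expression",
    "write_table",
]
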