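"""Ground-truthed synthetic wheat triad expression datasets.

The generator emulates the design the analysis expects: a set of triads whose
control compositions scatter around the seven bias-category centroids
(Dirichlet noise on the simplex), lognormal total expression per triad,
negative-binomial sequencing counts over 3 replicates x {control, stress},
a shared (triad-level) log2 condition effect that moves all three homeologs
together, and — for a configurable fraction of triads — an extra
homeolog-specific effect that genuinely changes the stress composition and so
can flip the bias category. Every draw comes from one seeded generator, so a
config plus seed reproduces the dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .hebc_classify import CATEGORIES, CENTROIDS, classify_composition
from .io_tables import (
    HOMEOLOGS,
    ExpressionMatrix,
    SampleSheet,
    Triad,
    TriadSet,
    write_table,
)
from .rev_analysis import DEFAULT_FOLD_THRESHOLD

#: fraction of the concentration given to Dirichlet components whose centroid
#: coordinate is 0, so vertex/edge categories keep full simplex support
_ZERO_FLOOR = 0.01

#: default category mix: mostly balanced, suppressed categories more common
#: than dominant ones, D-suppressed rarest of the suppressed group — the
#: pattern typical of hexaploid wheat triads
DEFAULT_CATEGORY_MIX = (0.70, 0.035, 0.035, 0.04, 0.07, 0.07, 0.05)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the triad expression simulator.

    seed is mandatory — there is no silent global randomness.
    """

    seed: int
    n_triads: int = 1000
    category_mix: tuple[float, ...] = DEFAULT_CATEGORY_MIX
    dirichlet_concentration: float = 50.0  # higher = tighter around centroids
    abundance_log_mean: float = 3.0  # ln TPM of a triad's total expression
    abundance_log_sd: float = 1.0
    nb_dispersion: float = 0.05  # var = mu + dispersion * mu^2; 0 = Poisson
    n_replicates: int = 3
    library_size: float = 2.0e7  # reads per sample (sets count depth)
    shared_effect_sd: float = 1.0  # SD of the triad-level log2 condition effect
    homeolog_effect_prob: float = 0.10  # chance of a homeolog-specific effect
    homeolog_effect_log2: float = 2.0  # magnitude of that effect
    tissue: str = "leaf"

    def validate(self) -> None:
        if self.n_triads < 1:
            raise ValueError("n_triads must be >= 1")
        mix = np.asarray(self.category_mix, float)
        if mix.shape != (7,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("category_mix must be 7 non-negative probabilities summing to 1")
        for name in (
            "dirichlet_concentration",
            "abundance_log_sd",
            "library_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.shared_effect_sd < 0:
            raise ValueError("shared_effect_sd must be >= 0")
        if not 0 <= self.homeolog_effect_prob <= 1:
            raise ValueError("homeolog_effect_prob must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


class SimulatedDataset(NamedTuple):
    triads: TriadSet
    tpm: ExpressionMatrix
    counts: ExpressionMatrix
    samples: SampleSheet
    truth: pd.DataFrame


def _dirichlet_around_centroids(
    rng: np.random.Generator, cat_idx: np.ndarray, concentration: float
) -> np.ndarray:
    """Dirichlet draws centred on each triad's category centroid.

    Parameters are centroid * concentration, with zero centroid coordinates
    floored at _ZERO_FLOOR * concentration (a Dirichlet parameter of 0 is
    undefined and would collapse support).
    """
    alpha = CENTROIDS[cat_idx] * concentration
    alpha[alpha == 0] = _ZERO_FLOOR * concentration
    gamma = rng.gamma(shape=alpha)
    return gamma / gamma.sum(axis=1, keepdims=True)


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson if 0)."""
    mu = np.maximum(mu, 1e-12)
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate (triads, TPM matrix, count matrix, sample sheet, truth table).

    The truth table records, per triad, the sampled category, the category of
    the actual (noisy) control composition, both true compositions, the
    condition effects, whether a true bias-category change was induced, and —
    per homeolog — whether the true compositions differ by the >= 20% shift
    rule. TPM is the equal-length rescaling of each sample's counts.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_triads

    cat_idx = rng.choice(len(CATEGORIES), size=n, p=np.asarray(cfg.category_mix))
    comp_control = _dirichlet_around_centroids(rng, cat_idx, cfg.dirichlet_concentration)
    total_tpm = rng.lognormal(cfg.abundance_log_mean, cfg.abundance_log_sd, size=n)
    shared_log2 = rng.normal(0.0, cfg.shared_effect_sd, size=n)
    has_extra = rng.random(n) < cfg.homeolog_effect_prob
    extra_target = rng.integers(0, 3, size=n)  # drawn for all, applied if has_extra

    mult = np.ones((n, 3))
    mult[has_extra, extra_target[has_extra]] = 2.0 ** cfg.homeolog_effect_log2
    comp_stress = comp_control * mult
    comp_stress /= comp_stress.sum(axis=1, keepdims=True)

    exp_tpm = {
        "control": total_tpm[:, None] * comp_control,
        "stress": total_tpm[:, None] * comp_control * (2.0 ** shared_log2)[:, None] * mult,
    }

    triad_ids = [f"Triad{i + 1:05d}" for i in range(n)]
    gene_ids = np.array(
        [[f"gene{i + 1:05d}{h}" for h in HOMEOLOGS] for i in range(n)]
    )
    triads = TriadSet(
        [
            Triad(tid, genes[0], genes[1], genes[2])
            for tid, genes in zip(triad_ids, gene_ids)
        ],
        provenance="synthetic",
    )

    sample_rows = []
    count_cols = {}
    for condition in ("control", "stress"):
        mu_per_gene = (exp_tpm[condition] / 1e6 * cfg.library_size).ravel()
        for rep in range(1, cfg.n_replicates + 1):
            sample = f"{cfg.tissue}_{condition}_rep{rep}"
            sample_rows.append(
                {
                    "sample_id": sample,
                    "tissue": cfg.tissue,
                    "condition": condition,
                    "replicate": rep,
                }
            )
            count_cols[sample] = _nb_counts(rng, mu_per_gene, cfg.nb_dispersion)

    all_genes = gene_ids.ravel()
    counts_df = pd.DataFrame(count_cols, index=pd.Index(all_genes, name="gene_id"))
    counts_df = counts_df.astype(float)
    col_sums = counts_df.sum(axis=0).replace(0, 1.0)
    tpm_df = counts_df / col_sums * 1e6  # equal effective lengths

    cats = np.array(CATEGORIES, dtype=object)
    true_cat_control, _ = classify_composition(comp_control)
    true_cat_stress, _ = classify_composition(comp_stress)
    truth = pd.DataFrame(
        {
            "triad_id": triad_ids,
            "category_sampled": cats[cat_idx],
            "category_true": true_cat_control,
            "category_true_stress": true_cat_stress,
            "true_hebc_change": true_cat_control != true_cat_stress,
            "comp_control_a": comp_control[:, 0],
            "comp_control_b": comp_control[:, 1],
            "comp_control_d": comp_control[:, 2],
            "comp_stress_a": comp_stress[:, 0],
            "comp_stress_b": comp_stress[:, 1],
            "comp_stress_d": comp_stress[:, 2],
            "total_tpm": total_tpm,
            "shared_log2": shared_log2,
            "extra_homeolog": np.where(
                has_extra, np.array(HOMEOLOGS, dtype=object)[extra_target], ""
            ),
            "extra_log2": np.where(has_extra, cfg.homeolog_effect_log2, 0.0),
        }
    )
    for j, h in enumerate(HOMEOLOGS):
        rc, rs = comp_control[:, j], comp_stress[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = rc / rs
            sym = np.maximum(r, 1.0 / r)
        truth[f"true_shift_{h.lower()}"] = np.where(
            (rc > 0) & (rs > 0), sym >= DEFAULT_FOLD_THRESHOLD, (rc > 0) | (rs > 0)
        )

    return SimulatedDataset(
        triads=triads,
        tpm=ExpressionMatrix(tpm_df, unit="TPM"),
        counts=ExpressionMatrix(counts_df, unit="counts"),
        samples=SampleSheet(pd.DataFrame(sample_rows)),
        truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset in the exact TSV formats the readers consume."""
    outdir = Path(outdir)
    paths = {
        "triads": write_table(dataset.triads, outdir / "triads.tsv"),
        "tpm": write_table(dataset.tpm, outdir / "tpm.tsv"),
        "counts": write_table(dataset.counts, outdir / "counts.tsv"),
        "samples": write_table(dataset.samples, outdir / "samples.tsv"),
        "truth": write_table(dataset.truth, outdir / "truth.tsv"),
    }
    return paths


def truth_report(
    truth: pd.DataFrame,
    assignments: pd.DataFrame | None = None,
    shifts: pd.DataFrame | None = None,
    changes: pd.DataFrame | None = None,
) -> dict:
    """Score pipeline outputs against the simulator's ground truth.

    assignments: control-condition category assignments (classify_hebc output);
    shifts: call_rev_shifts output (any homeologs); changes: hebc_change table.
    Returns category recovery + confusion matrix, shift sensitivity/specificity
    and bias-change sensitivity/specificity/false-positive rate, where the
    corresponding input was given.
    """
    report: dict = {}
    t = truth.set_index("triad_id")

    if assignments is not None:
        a = assignments
        if "condition" in a.columns:
            ctrl_only = a[a["condition"] == "control"]
            if not ctrl_only.empty:
                a = ctrl_only
        a = a.set_index("triad_id")["category"]
        shared = t.index.intersection(a.index)
        if len(shared) == 0:
            raise ValueError("no triad ids shared between truth and assignments")
        true_lab = t.loc[shared, "category_true"]
        pred_lab = a.loc[shared]
        report["n_scored"] = int(len(shared))
        report["category_recovery"] = float((true_lab == pred_lab).mean())
        report["confusion"] = pd.crosstab(
            true_lab.rename("true"), pred_lab.rename("assigned")
        )

    if changes is not None:
        c = changes.set_index("triad_id")
        shared = t.index.intersection(c.index)
        if len(shared) == 0:
            raise ValueError("no triad ids shared between truth and changes")
        truth_chg = t.loc[shared, "true_hebc_change"].astype(bool)
        called = c.loc[shared, "changed"].astype(bool)
        report["hebc_change"] = _binary_scores(truth_chg.to_numpy(), called.to_numpy())

    if shifts is not None:
        per_h = {}
        for h, grp in shifts.groupby("homeolog"):
            g = grp.set_index("triad_id")
            shared = t.index.intersection(g.index)
            if len(shared) == 0:
                raise ValueError(f"no shared triads for homeolog {h}")
            truth_s = t.loc[shared, f"true_shift_{str(h).lower()}"].astype(bool)
            called = g.loc[shared, "significant"].astype(bool)
            per_h[str(h)] = _binary_scores(truth_s.to_numpy(), called.to_numpy())
        report["shifts"] = per_h

    return report


def _binary_scores(truth: np.ndarray, called: np.ndarray) -> dict[str, float]:
    tp = int((truth & called).sum())
    fn = int((truth & ~called).sum())
    fp = int((~truth & called).sum())
    tn = int((~truth & ~called).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "false_positive_rate": fp / (fp + tn) if fp + tn else float("nan"),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }
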