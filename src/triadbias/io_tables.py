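"""Readers, writers and validated containers for every table the pipeline touches.

All files are tab-separated with a mandatory header row. Gene identifiers are
opaque, case-sensitive strings: the triad table is the sole source of the
A/B/D subgenome assignment, because gene-ID naming conventions vary between
annotation releases. The unit of an expression matrix (raw counts vs TPM) is
declared by the caller and never inferred — the two are numerically
indistinguishable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("triadbias")

HOMEOLOGS = ("A", "B", "D")
CONDITIONS = ("control", "stress")

#: column holding the gene of each subgenome in a triad table
GENE_COLUMNS = {"A": "gene_a", "B": "gene_b", "D": "gene_d"}


class TableFormatError(ValueError):
    """A tabular input violates its documented schema or invariants."""


# ---------------------------------------------------------------------------
# triads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Triad:
    """One A-, one B- and one D-subgenome homeolog bound under a triad id."""

    triad_id: str
    gene_a: str
    gene_b: str
    gene_d: str
    syntenic: bool = True

    def __post_init__(self) -> None:
        genes = (self.gene_a, self.gene_b, self.gene_d)
        if not self.triad_id:
            raise TableFormatError("triad_id must be non-empty")
        if any(not g for g in genes):
            raise TableFormatError(f"triad {self.triad_id!r}: empty gene id")
        if len(set(genes)) != 3:
            raise TableFormatError(
                f"triad {self.triad_id!r}: gene ids must be distinct, got {genes}"
            )

    @property
    def genes(self) -> tuple[str, str, str]:
        return (self.gene_a, self.gene_b, self.gene_d)

    def gene(self, homeolog: str) -> str:
        if homeolog not in HOMEOLOGS:
            raise ValueError(f"homeolog must be one of {HOMEOLOGS}, got {homeolog!r}")
        return getattr(self, GENE_COLUMNS[homeolog])


@dataclass
class TriadSet:
    """Ordered collection of triads; no gene participates in two triads."""

    triads: list[Triad]
    provenance: str = ""
    _by_id: dict[str, Triad] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_genes: dict[str, str] = {}
        for t in self.triads:
            if t.triad_id in seen_ids:
                raise TableFormatError(f"duplicate triad_id {t.triad_id!r}")
            seen_ids.add(t.triad_id)
            for g in t.genes:
                if g in seen_genes:
                    raise TableFormatError(
                        f"gene {g!r} appears in triads {seen_genes[g]!r} "
                        f"and {t.triad_id!r}"
                    )
                seen_genes[g] = t.triad_id
        self._by_id = {t.triad_id: t for t in self.triads}

    def __len__(self) -> int:
        return len(self.triads)

    def __iter__(self) -> Iterator[Triad]:
        return iter(self.triads)

    def __getitem__(self, triad_id: str) -> Triad:
        return self._by_id[triad_id]

    def __contains__(self, triad_id: str) -> bool:
        return triad_id in self._by_id

    def subset(self, triad_ids: Sequence[str], provenance: str = "") -> "TriadSet":
        keep = set(triad_ids)
        return TriadSet(
            [t for t in self.triads if t.triad_id in keep],
            provenance=provenance or self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "triad_id": [t.triad_id for t in self.triads],
                "gene_a": [t.gene_a for t in self.triads],
                "gene_b": [t.gene_b for t in self.triads],
                "gene_d": [t.gene_d for t in self.triads],
                "syntenic": [int(t.syntenic) for t in self.triads],
            }
        )


def read_triad_table(path: str | Path) -> TriadSet:
    """Read a triad table (columns triad_id, gene_a, gene_b, gene_d[, syntenic])."""
    df = _read_tsv(path)
    _require_columns(df, ["triad_id", "gene_a", "gene_b", "gene_d"], path)
    syntenic = (
        df["syntenic"].astype(int).astype(bool)
        if "syntenic" in df.columns
        else pd.Series(True, index=df.index)
    )
    triads = [
        Triad(
            triad_id=str(row.triad_id),
            gene_a=str(row.gene_a),
            gene_b=str(row.gene_b),
            gene_d=str(row.gene_d),
            syntenic=bool(syn),
        )
        for row, syn in zip(df.itertuples(index=False), syntenic)
    ]
    if not triads:
        logger.warning("triad table %s is empty (header only)", path)
    return TriadSet(triads, provenance=str(path))


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values.

    ``unit`` must be ``"counts"`` or ``"TPM"`` and is always declared by the
    producer of the matrix, never guessed from the numbers.
    """

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "TPM"):
            raise TableFormatError(f"unit must be 'counts' or 'TPM', got {self.unit!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise TableFormatError(f"duplicate gene id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise TableFormatError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise TableFormatError(
                f"missing value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative value {arr[r, c]} at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "gene_id", out.index)
        return out.reset_index(drop=True)


def read_expression_matrix(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene id) with a declared unit."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: expected gene_id plus >=1 sample column")
    gene_col = df.columns[0]
    values = df.set_index(gene_col)
    values.index = values.index.astype(str)
    values.index.name = "gene_id"
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableFormatError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(values=values, unit=unit)


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Per-sample tissue, condition ({control, stress}) and replicate index."""

    data: pd.DataFrame  # columns: sample_id, tissue, condition, replicate

    def __post_init__(self) -> None:
        _require_columns(self.data, ["sample_id", "tissue", "condition", "replicate"])
        if self.data["sample_id"].duplicated().any():
            dup = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise TableFormatError(f"duplicate sample id {dup!r}")
        bad = set(self.data["condition"]) - set(CONDITIONS)
        if bad:
            raise TableFormatError(
                f"unknown condition label(s) {sorted(bad)}; allowed: {list(CONDITIONS)}"
            )
        if (self.data["replicate"].astype(int) < 1).any():
            raise TableFormatError("replicate indices must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.data["tissue"].unique())

    def samples_for(self, tissue: str, condition: str) -> list[str]:
        m = (self.data["tissue"] == tissue) & (self.data["condition"] == condition)
        return list(self.data.loc[m, "sample_id"])

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "tissue", "condition", "replicate"], path)
    df = df.astype(
        {"sample_id": str, "tissue": str, "condition": str, "replicate": int}
    )
    return SampleSheet(df)


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------

#: |log2(fold_change) - log2fc| tolerated when both columns are present
_LOG2FC_ATOL = 1e-6


@dataclass
class DERecordSet:
    """Per-gene fold change (stress/control), p value and adjusted p value.

    Either ``fold_change`` or ``log2fc`` may be supplied; the missing one is
    derived. When both are present they must agree. A fold change of exactly 0
    (stress mean of 0) has no finite log2fc and is kept as -inf.
    """

    data: pd.DataFrame  # columns: gene_id, fold_change, log2fc, pvalue, padj
    method: str = "external"

    def __post_init__(self) -> None:
        df = self.data
        _require_columns(df, ["gene_id"])
        if "fold_change" not in df.columns and "log2fc" not in df.columns:
            raise TableFormatError("DE table needs fold_change and/or log2fc")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise TableFormatError(f"duplicate gene id {dup!r} in DE table")
        if "fold_change" in df.columns and (df["fold_change"] < 0).any():
            raise TableFormatError("fold_change must be non-negative")
        if "fold_change" not in df.columns:
            df["fold_change"] = np.exp2(df["log2fc"].astype(float))
        elif "log2fc" not in df.columns:
            with np.errstate(divide="ignore"):
                df["log2fc"] = np.log2(df["fold_change"].astype(float))
        else:
            fc = df["fold_change"].astype(float)
            with np.errstate(divide="ignore"):
                expected = np.log2(fc)
            got = df["log2fc"].astype(float)
            ok = np.isclose(expected, got, atol=_LOG2FC_ATOL) | (
                np.isneginf(expected) & np.isneginf(got)
            )
            if not ok.all():
                bad = df.loc[~ok, "gene_id"].iloc[0]
                raise TableFormatError(
                    f"gene {bad!r}: log2fc inconsistent with fold_change"
                )
        for col in ("pvalue", "padj"):
            if col in df.columns:
                vals = df[col].astype(float)
                if ((vals < 0) | (vals > 1)).any():
                    raise TableFormatError(f"{col} outside [0, 1]")
        self.data = df.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data["gene_id"])

    def has_padj(self) -> bool:
        return "padj" in self.data.columns and self.data["padj"].notna().all()

    def to_frame(self) -> pd.DataFrame:
        cols = ["gene_id", "fold_change", "log2fc"]
        cols += [c for c in ("pvalue", "padj") if c in self.data.columns]
        return self.data[cols].copy()


def read_de_table(path: str | Path) -> DERecordSet:
    df = _read_tsv(path)
    df.columns = [c.lower() for c in df.columns]
    df = df.rename(columns={"gene": "gene_id", "p": "pvalue", "p_value": "pvalue"})
    _require_columns(df, ["gene_id"], path)
    df["gene_id"] = df["gene_id"].astype(str)
    return DERecordSet(df)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (set_name, gene_id) -> {set name: member gene ids}."""
    df = _read_tsv(path)
    _require_columns(df, ["set_name", "gene_id"], path)
    sets: dict[str, set[str]] = {}
    for name, grp in df.groupby("set_name", sort=False):
        sets[str(name)] = set(grp["gene_id"].astype(str))
    return sets


def write_gene_sets(sets: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"set_name": name, "gene_id": g}
        for name, members in sets.items()
        for g in sorted(members)
    ]
    write_table(pd.DataFrame(rows, columns=["set_name", "gene_id"]), path)


# ---------------------------------------------------------------------------
# generic write + helpers
# ---------------------------------------------------------------------------

def write_table(obj, path: str | Path) -> Path:
    """Write any container (or plain DataFrame) as a TSV.

    Floats are serialized with repr-level precision so that a write -> read
    round trip reproduces the object exactly.
    """
    path = Path(path)
    frame = obj.to_frame() if hasattr(obj, "to_frame") else obj
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot serialize {type(obj).__name__} as a table")
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # C float parser is locale-independent (decimal point only), as required
    return pd.read_csv(path, sep="\t", header=0, dtype=None)


def _require_columns(
    df: pd.DataFrame, cols: Sequence[str], path: str | Path | None = None
) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        where = f" in {path}" if path is not None else ""
        raise TableFormatError(f"missing column(s) {missing}{where}")


def almost_equal(a: float, b: float, atol: float = 1e-9) -> bool:
    return math.isclose(a, b, rel_tol=0.0, abs_tol=atol)
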