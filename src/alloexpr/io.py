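"""Core tabular data types and TSV readers/writers.

Every analysis in this package starts from three tables: a gene-level count
matrix with a per-gene subgenome tag, a sample sheet describing the cohort
(two diploid parents plus one or more allopolyploid individuals, each with
replicates), and a one-to-one homoeolog pair table linking A-subgenome genes
to their C-subgenome counterparts.

All tables are tab-separated UTF-8 text; lines starting with ``#`` are
comments. Counts must be non-negative integers — missing or negative cells
are errors, never imputed, because downstream rules (e.g. the zero-count
silencing criterion) are undefined under missingness.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PARENT_A = "PARENT_A"
PARENT_C = "PARENT_C"
POLYPLOID = "POLYPLOID"

GENOTYPES = (PARENT_A, PARENT_C, POLYPLOID)
SUBGENOMES = ("A", "C")
# pair-level matrices (rows are homoeolog pairs spanning both subgenomes)
# carry the label "AC"
ROW_LABELS = ("A", "C", "AC")


class FormatError(ValueError):
    """A file violates the expected tabular layout or a type invariant."""


class ConfigError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-gene subgenome labels.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    subgenome
        Per-gene label in ``{"A", "C"}`` marking the subgenome of origin.
    sample_ids
        Unique sample identifiers, one per column.
    counts
        Non-negative integer matrix of shape ``(len(gene_ids), len(sample_ids))``.
    gene_lengths
        Optional per-gene length in base pairs; required only for FPKM.
    """

    gene_ids: list[str]
    subgenome: np.ndarray
    sample_ids: list[str]
    counts: np.ndarray
    gene_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.subgenome = np.asarray(self.subgenome, dtype=object)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        bad = set(self.subgenome) - set(ROW_LABELS)
        if bad:
            raise FormatError(f"unknown subgenome labels: {sorted(bad)}")
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths, dtype=np.int64)
            if len(self.gene_lengths) != len(self.gene_ids):
                raise FormatError("gene_lengths length mismatch")
            if np.any(self.gene_lengths <= 0):
                raise FormatError("gene_lengths must be positive")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in count matrix") from None

    def sample_col(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in count matrix") from None

    def sample_cols(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.sample_col(s) for s in sample_ids], dtype=np.intp)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "gene_id", self.gene_ids)
        df.insert(1, "subgenome", list(self.subgenome))
        return df


@dataclass
class SampleSheet:
    """Cohort layout: genotype, polyploid individual and replicate per sample."""

    frame: pd.DataFrame  # columns: sample_id, genotype, individual, replicate

    REQUIRED = ("sample_id", "genotype", "individual", "replicate")

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        df = df.copy()
        df["individual"] = df["individual"].fillna("").astype(str)
        df.loc[df["individual"].isin(["nan", "None"]), "individual"] = ""
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] <= 0).any():
            raise FormatError("replicate indices must be positive")
        bad = set(df["genotype"]) - set(GENOTYPES)
        if bad:
            raise FormatError(f"unknown genotypes: {sorted(bad)}")
        if df.duplicated(["genotype", "individual", "replicate"]).any():
            raise FormatError("duplicate (genotype, individual, replicate) triple")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in sheet")
        # every genotype/individual present must be replicated
        sizes = df.groupby(["genotype", "individual"]).size()
        if (sizes < 2).any():
            under = sizes[sizes < 2].index.tolist()
            raise FormatError(f"fewer than 2 replicates for: {under}")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_of(self, genotype: str, individual: str = "") -> list[str]:
        """Sample ids of one group, ordered by replicate index."""
        df = self.frame
        sel = df[(df["genotype"] == genotype) & (df["individual"] == individual)]
        if sel.empty:
            raise ConfigError(f"no samples for genotype={genotype} individual={individual!r}")
        return list(sel.sort_values("replicate")["sample_id"])

    @property
    def individuals(self) -> list[str]:
        poly = self.frame[self.frame["genotype"] == POLYPLOID]
        return sorted(poly["individual"].unique())


@dataclass
class HomoeologPairTable:
    """One-to-one A-gene <-> C-gene homoeolog correspondences.

    Retained pairs satisfy the alignment thresholds (identity > 90%,
    E-value <= 1e-10), and each gene participates in at most one pair.
    """

    frame: pd.DataFrame  # columns: pair_id, gene_A, gene_C, identity_pct, evalue

    REQUIRED = ("pair_id", "gene_A", "gene_C", "identity_pct", "evalue")

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise FormatError(f"pair table missing columns: {sorted(missing)}")
        if len(df):
            if df["pair_id"].duplicated().any():
                raise FormatError("duplicate pair_id")
            if df["gene_A"].duplicated().any() or df["gene_C"].duplicated().any():
                raise FormatError("pair table is not one-to-one")
            if (df["identity_pct"] <= 90).any():
                raise FormatError("pair with identity <= 90% retained")
            if (df["evalue"] > 1e-10).any():
                raise FormatError("pair with E-value > 1e-10 retained")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.frame["pair_id"])


@dataclass
class TraitMatrix:
    """Ordinal trait grades per polyploid individual (no missing cells)."""

    frame: pd.DataFrame  # index: individual; columns: trait names; int grades

    def __post_init__(self) -> None:
        df = self.frame
        if df.isna().any().any():
            raise FormatError("trait matrix has missing cells")
        if df.index.duplicated().any():
            raise FormatError("duplicate individuals in trait matrix")
        self.frame = df.astype(int)

    @property
    def individuals(self) -> list[str]:
        return list(self.frame.index)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_tsv(path)
    return SampleSheet(df)


def read_counts(
    path: str | Path,
    sample_sheet: SampleSheet,
    lengths: Mapping[str, int] | None = None,
) -> CountMatrix:
    """Read a counts TSV (gene_id, subgenome, one column per sample).

    Every data column must be declared in the sample sheet and vice versa;
    cells must be non-negative integers.
    """
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["gene_id", "subgenome"]:
        raise FormatError(f"{path}: first two columns must be gene_id, subgenome")
    file_samples = list(df.columns[2:])
    sheet_samples = set(sample_sheet.sample_ids)
    extra = [s for s in file_samples if s not in sheet_samples]
    if extra:
        raise ConfigError(f"samples in counts file absent from sheet: {extra}")
    absent = sheet_samples - set(file_samples)
    if absent:
        raise ConfigError(f"samples in sheet absent from counts file: {sorted(absent)}")
    raw = df[file_samples]
    try:
        counts = raw.astype(np.int64).to_numpy()
    except ValueError:
        raise FormatError(f"{path}: non-integer count cell") from None
    if (raw.astype(float).to_numpy() != counts).any():
        raise FormatError(f"{path}: fractional count cell")
    gene_ids = list(df["gene_id"])
    gene_lengths = None
    if lengths is not None:
        gene_lengths = np.array([lengths[g] for g in gene_ids], dtype=np.int64)
    return CountMatrix(
        gene_ids=gene_ids,
        subgenome=df["subgenome"].to_numpy(dtype=object),
        sample_ids=file_samples,
        counts=counts,
        gene_lengths=gene_lengths,
    )


def read_pairs(path: str | Path) -> HomoeologPairTable:
    df = _read_tsv(path)
    if len(df):
        df = df.astype({"identity_pct": float, "evalue": float})
    else:
        df["identity_pct"] = pd.Series(dtype=float)
        df["evalue"] = pd.Series(dtype=float)
    return HomoeologPairTable(df)


def read_traits(path: str | Path) -> TraitMatrix:
    df = _read_tsv(path)
    if "individual" not in df.columns:
        raise FormatError(f"{path}: trait table needs an 'individual' column")
    df = df.set_index("individual")
    try:
        df = df.astype(int)
    except ValueError:
        raise FormatError(f"{path}: non-integer trait grade") from None
    return TraitMatrix(df)


def write_table(rows: pd.DataFrame | CountMatrix, path: str | Path) -> None:
    """Write any result table (or a CountMatrix) as TSV.

    ``read_counts(write_table(cm)) == cm`` bit-exactly; header-only files are
    produced for empty result sets.
    """
    df = rows.to_frame() if isinstance(rows, CountMatrix) else rows
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def frame_to_tsv_string(df: pd.DataFrame) -> str:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    return buf.getvalue()
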