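"""Readers, writers and preprocessing for expression, clinical and GMT files.

Expression tables are genes x samples TSV with a ``gene_id`` column, a
``gene_type`` column (``lncRNA`` or ``mRNA``) and one numeric column per
sample.  Preprocessing follows the standard FPKM-style recipe: drop genes
with more than 20% missing values, fill the remaining missing values with
0, then transform to log2(x + 1).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

GENE_TYPES = ("lncRNA", "mRNA")

_STAGE_PATTERN = re.compile(r"(IV|III|II|I)", re.IGNORECASE)
_STAGE_TO_INT = {"I": 1, "II": 2, "III": 3, "IV": 4}

CLINICAL_COLUMNS = [
    "os_time",
    "os_event",
    "pfs_time",
    "pfs_event",
    "age",
    "stage",
    "tissue",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with per-gene type labels.

    ``values`` is indexed by gene id; ``gene_types`` is a Series aligned to
    the same index with entries in :data:`GENE_TYPES`.
    """

    values: pd.DataFrame
    gene_types: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise InputError("duplicate gene ids in expression matrix")
        if not self.values.index.equals(self.gene_types.index):
            self.gene_types = self.gene_types.reindex(self.values.index)
        unknown = set(self.gene_types.dropna().unique()) - set(GENE_TYPES)
        if unknown:
            raise InputError(f"unknown gene types: {sorted(unknown)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def lnc_ids(self) -> pd.Index:
        return self.values.index[self.gene_types == "lncRNA"]

    @property
    def mrna_ids(self) -> pd.Index:
        return self.values.index[self.gene_types == "mRNA"]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[gene_ids], self.gene_types.loc[gene_ids]
        )


@dataclass
class ClinicalTable:
    """Per-sample survival and covariate table indexed by sample id."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(f"clinical table missing columns: {missing}")
        if not self.data.index.is_unique:
            raise InputError("duplicate sample ids in clinical table")
        for col in ("os_time", "pfs_time"):
            if (self.data[col] <= 0).any():
                raise InputError(f"non-positive survival times in {col!r}")
        for col in ("os_event", "pfs_event"):
            if not self.data[col].isin([0, 1]).all():
                raise InputError(f"non-binary event indicator in {col!r}")
        stages = self.data["stage"].dropna()
        if not stages.isin([1, 2, 3, 4]).all():
            raise InputError("stage must be ordinal 1-4 (I-IV)")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT contents): set name -> ordered member list."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (``gene_id``, ``gene_type``, samples...).

    Gzip-compressed files are handled transparently.  Missing values are
    preserved; run :func:`filter_genes` and :func:`fill_and_log` next.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "gene_type"):
        if col not in df.columns:
            raise InputError(f"expression file {path} lacks column {col!r}")
    df = df.set_index("gene_id")
    types = df.pop("gene_type")
    return ExpressionMatrix(df.astype(float), types)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.insert(0, "gene_type", expr.gene_types)
    out.to_csv(path, sep="\t", index_label="gene_id")


def filter_genes(expr: ExpressionMatrix, max_missing: float = 0.20) -> ExpressionMatrix:
    """Drop genes whose missing fraction strictly exceeds ``max_missing``.

    Exactly 20% missing is retained; the removal rule is strict. Idempotent.
    """
    frac = expr.values.isna().mean(axis=1)
    keep = frac <= max_missing
    if not keep.any():
        logger.warning("filter_genes removed every gene")
    return ExpressionMatrix(expr.values.loc[keep], expr.gene_types.loc[keep])


def fill_and_log(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Fill remaining missing values with 0 and apply log2(x + 1).

    Raises :class:`InputError` on negative entries: FPKM-like input must be
    non-negative so the transform stays real and monotone.
    """
    vals = expr.values
    if (vals < 0).any().any():
        raise InputError("negative expression values; expected FPKM-like input")
    filled = vals.fillna(0.0)
    return ExpressionMatrix(np.log2(filled + 1.0), expr.gene_types.copy())


def preprocess(expr: ExpressionMatrix, max_missing: float = 0.20) -> ExpressionMatrix:
    """Full preprocessing: NA filter, zero fill, log2 transform."""
    return fill_and_log(filter_genes(expr, max_missing))


# ---------------------------------------------------------------------------
# clinical


def normalize_stage(value) -> float:
    """Map stage strings such as 'Stage IIIA' to ordinal 1-4 (NaN if absent)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, (int, np.integer)):
        return float(value) if value in (1, 2, 3, 4) else np.nan
    if isinstance(value, float):
        return value if value in (1.0, 2.0, 3.0, 4.0) else np.nan
    match = _STAGE_PATTERN.search(str(value))
    if match is None:
        return np.nan
    return float(_STAGE_TO_INT[match.group(1).upper()])


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV keyed by ``sample_id``; stage strings normalized."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise InputError(f"clinical file {path} lacks column 'sample_id'")
    df = df.set_index("sample_id")
    if "tissue" not in df.columns:
        df["tissue"] = "tumour"
    if "stage" in df.columns:
        df["stage"] = df["stage"].map(normalize_stage)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (set name, description, tab-separated members).

    Duplicate member ids within a set are removed, keeping first occurrence.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    text = Path(path).read_text() if not str(path).endswith(".gz") else None
    if text is None:  # pragma: no cover - gz convenience path
        import gzip

        with gzip.open(path, "rt") as fh:
            text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(f"GMT line {lineno}: fewer than 3 fields")
        name, desc, *members = fields
        if name in sets:
            raise InputError(f"GMT line {lineno}: duplicate set name {name!r}")
        seen: dict[str, None] = {}
        for m in members:
            if m and m not in seen:
                seen[m] = None
        sets[name] = list(seen)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
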