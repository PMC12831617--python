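"""Shared data model: abundance tables, phenotype labels, feature rankings.

An :class:`OmicsTable` is a samples x features abundance matrix whose
column names carry a namespace prefix encoding the omics layer
(``prot:`` proteomics, ``gly:`` glycomics, ``met:`` metabolomics), so a
merged multi-layer matrix stays self-describing.  Missing cells are NaN,
never zero.  All preprocessing statistics (imputation medians, z-score
mean/sd) are computed on a caller-designated *fit* subset of samples so
that cross-validation never leaks held-out information.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, MissingnessError, ParseError

#: canonical layer order used when concatenating layers
LAYERS = ("proteomics", "glycomics", "metabolomics")

LAYER_PREFIX: Mapping[str, str] = {
    "proteomics": "prot:",
    "glycomics": "gly:",
    "metabolomics": "met:",
}
PREFIX_LAYER = {v: k for k, v in LAYER_PREFIX.items()}

DEFAULT_MISSING_CEILING = 0.01


def layer_of(feature_id: str) -> str:
    """Omics layer encoded in a feature identifier's namespace prefix."""
    for prefix, layer in PREFIX_LAYER.items():
        if feature_id.startswith(prefix):
            return layer
    raise FormatError(f"feature {feature_id!r} carries no recognized layer prefix")


@dataclass
class OmicsTable:
    """Samples x features abundance matrix with per-feature layer annotation.

    Wraps a :class:`pandas.DataFrame` (index = sample ids, columns =
    prefixed feature ids, values = float intensities with NaN for
    missing).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dupes}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        for f in self.data.columns:
            layer_of(f)  # raises on unrecognized prefix
        self.data = self.data.astype(float)

    # -- basic views --------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def layer_of(self, feature_id: str) -> str:
        if feature_id not in self.data.columns:
            raise KeyError(feature_id)
        return layer_of(feature_id)

    @property
    def feature_layers(self) -> list[str]:
        return [layer_of(f) for f in self.data.columns]

    def layer_features(self, layer: str) -> list[str]:
        prefix = LAYER_PREFIX[layer]
        return [f for f in self.data.columns if f.startswith(prefix)]

    def missing_fraction(self) -> float:
        return float(self.data.isna().to_numpy().mean())

    def subset_features(self, features: Sequence[str]) -> "OmicsTable":
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return OmicsTable(self.data.loc[:, list(features)].copy())

    def subset_samples(self, samples: Sequence[str]) -> "OmicsTable":
        return OmicsTable(self.data.loc[list(samples)].copy())


@dataclass
class PhenotypeLabels:
    """Binary case/control assignment aligned to an OmicsTable.

    ``label`` is 1 for cases (here: HCC) and 0 for controls (cirrhosis).
    """

    sample_ids: list[str]
    label: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.label = np.asarray(self.label, dtype=int)
        if len(self.sample_ids) != self.label.shape[0]:
            raise FormatError("sample_ids and label lengths differ")
        if not set(np.unique(self.label)) <= {0, 1}:
            raise FormatError("labels must be binary 0/1")

    @property
    def n_cases(self) -> int:
        return int(self.label.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.label).sum())

    def require_both_classes(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise FormatError("both classes must be present")

    def aligned_to(self, table: OmicsTable) -> "PhenotypeLabels":
        """Reorder labels to the table's sample order."""
        if set(self.sample_ids) != set(table.sample_ids):
            extra = sorted(set(self.sample_ids) ^ set(table.sample_ids))
            raise AlignmentError(f"label/table sample mismatch: {extra}")
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in table.sample_ids]
        return PhenotypeLabels(table.sample_ids, self.label[idx])


@dataclass
class FeatureRanking:
    """Ordered feature list with importance scores and method identity.

    ``scores`` are on a method-specific scale and non-increasing along
    ``ordered_features`` (recursive-elimination methods use the
    elimination rank as the score; the native per-feature statistic is
    kept in ``raw_scores``).  ``selected`` is the top-``n_select``
    subset.
    """

    method: str
    ordered_features: list[str]
    scores: np.ndarray
    selected: list[str]
    raw_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ordered_features = list(self.ordered_features)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ordered_features) != self.scores.shape[0]:
            raise FormatError("ordered_features and scores lengths differ")
        if len(set(self.ordered_features)) != len(self.ordered_features):
            raise FormatError("ordered_features contains duplicates")
        if np.any(np.diff(self.scores) > 1e-12):
            raise FormatError("scores must be non-increasing along the ranking")
        if not set(self.selected) <= set(self.ordered_features):
            raise FormatError("selected must be a subset of ordered_features")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ordered_features) + 1),
                "feature_id": self.ordered_features,
                "layer": [layer_of(f) for f in self.ordered_features],
                "score": self.scores,
                "selected": [f in set(self.selected) for f in self.ordered_features],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------


def _sniff_sep(path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_omics_table(
    path,
    layer: str,
    missing_ceiling: float = DEFAULT_MISSING_CEILING,
) -> OmicsTable:
    """Read a delimited abundance table for one omics layer.

    First column holds sample identifiers, header row holds feature
    names; cells are numeric or empty (missing).  The layer's namespace
    prefix is applied to every feature name that does not already carry
    it.

    Raises
    ------
    ParseError
        for a non-numeric cell, naming the row and column.
    FormatError
        for duplicate feature names.
    MissingnessError
        when the missing fraction exceeds ``missing_ceiling``.
    """
    if layer not in LAYER_PREFIX:
        raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    seen: set[str] = set()
    dupes = [h for h in header if h in seen or seen.add(h)]
    if dupes:
        raise FormatError(f"duplicate feature name(s) in {path}: {dupes}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    numeric = pd.DataFrame(index=raw.index.astype(str), dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        vals = pd.to_numeric(cells.where(cells != "", other=None), errors="coerce")
        bad = vals.isna() & (cells != "")
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise ParseError(
                f"non-numeric cell at row {row!r}, column {col!r}: "
                f"{cells[bad].iloc[0]!r}"
            )
        numeric[col] = vals.to_numpy()
    prefix = LAYER_PREFIX[layer]
    numeric.columns = [c if c.startswith(prefix) else prefix + c for c in raw.columns]
    table = OmicsTable(numeric)
    frac = table.missing_fraction()
    if frac > missing_ceiling:
        raise MissingnessError(
            f"missing fraction {frac:.4f} exceeds ceiling {missing_ceiling}"
        )
    return table


def write_omics_table(table: OmicsTable, path, sep: str = "\t") -> None:
    """Write a table in the format :func:`read_omics_table` accepts.

    Values are printed with 17 significant digits so a read/write
    round-trip is value-stable well below 1e-9 relative tolerance.
    """
    table.data.to_csv(path, sep=sep, float_format="%.17g", index_label="sample_id")


def read_labels(path) -> PhenotypeLabels:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    col = df.columns[0]
    return PhenotypeLabels(df.index.astype(str).tolist(), df[col].to_numpy())


def write_labels(labels: PhenotypeLabels, path, sep: str = "\t") -> None:
    pd.DataFrame({"label": labels.label}, index=pd.Index(labels.sample_ids, name="sample_id")).to_csv(
        path, sep=sep
    )


# ---------------------------------------------------------------------------
# layer merging and leakage-safe preprocessing
# ---------------------------------------------------------------------------


def merge_layers(tables: Sequence[OmicsTable]) -> OmicsTable:
    """Column-wise concatenation of per-layer tables.

    All tables must cover the same sample set; rows are aligned to the
    first table's sample order.  Feature blocks are emitted in canonical
    layer order (proteomics, glycomics, metabolomics), preserving the
    within-layer feature order.
    """
    if not tables:
        raise ValueError("no tables to merge")
    ref = tables[0]
    ref_set = set(ref.sample_ids)
    aligned = []
    for t in tables:
        if set(t.sample_ids) != ref_set:
            offending = sorted(ref_set ^ set(t.sample_ids))
            raise AlignmentError(f"sample sets differ; offending samples: {offending}")
        aligned.append(t.data.loc[ref.sample_ids])
    order = {layer: i for i, layer in enumerate(LAYERS)}

    def block_key(df: pd.DataFrame) -> int:
        return order[layer_of(df.columns[0])] if len(df.columns) else 0

    aligned = sorted(aligned, key=block_key)
    merged = pd.concat(aligned, axis=1)
    return OmicsTable(merged)


@dataclass
class StandardizationWarningRecord:
    """Features whose fit-subset variance was zero (standardized to 0)."""

    zero_variance_features: list[str]


def impute_and_standardize(
    table: OmicsTable,
    fit_rows: Iterable[str] | None = None,
) -> tuple[OmicsTable, StandardizationWarningRecord]:
    """Median-impute then z-score every feature, leakage-safe.

    The per-feature imputation median and the z-scoring mean/sd (sample
    sd, ddof=1) are computed from ``fit_rows`` only; all rows are then
    transformed with those fit statistics.  A feature with zero variance
    on the fit rows is standardized to all zeros and reported in the
    warning record (a ``UserWarning`` is also emitted).
    """
    fit = list(fit_rows) if fit_rows is not None else table.sample_ids
    if not fit:
        raise ValueError("fit_rows must be non-empty")
    df = table.data.copy()
    fit_df = df.loc[fit]
    med = fit_df.median(axis=0, skipna=True)
    df = df.fillna(med)
    fit_filled = df.loc[fit]
    mean = fit_filled.mean(axis=0)
    sd = fit_filled.std(axis=0, ddof=1)
    flat = sd.index[(sd == 0) | sd.isna()].tolist()
    if flat:
        warnings.warn(
            f"{len(flat)} zero-variance feature(s) on fit rows standardized to 0: "
            f"{flat[:5]}{'...' if len(flat) > 5 else ''}",
            UserWarning,
            stacklevel=2,
        )
    safe_sd = sd.replace(0, 1.0).fillna(1.0)
    out = (df - mean) / safe_sd
    out.loc[:, flat] = 0.0
    return OmicsTable(out), StandardizationWarningRecord(flat)
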