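"""Data model, file I/O, preprocessing and outcome-label construction.

The pipeline works on three kinds of per-sample tables:

* omics matrices (gene expression, DNA methylation beta values) held as
  :class:`OmicsMatrix` — a samples x features float matrix with identifiers;
* a :class:`ClinicalTable` with age at diagnosis, INSS stage, MYCN status
  and the two outcome variables (overall survival time in years, vital
  status at last follow-up);
* a :class:`LabelPair` — the two aligned binary outcome labels: 5-year
  survival class (0 = short-term, 1 = long-term) and vital status
  (0 = dead, 1 = alive).

Preprocessing follows the cohort-preparation recipe: drop features whose
missing fraction exceeds a threshold (default 5%), mean-impute the rest,
min-max scale age, one-hot encode the categorical clinical fields against a
fixed vocabulary, and concatenate modality blocks (early integration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: cell contents treated as missing when reading delimited text
DEFAULT_NA_VALUES: tuple[str, ...] = ("", "NA", "NaN", "nan", "N/A", "null")

#: canonical clinical column names used throughout the package
CLINICAL_COLUMNS = (
    "sample_id",
    "age_days",
    "inss_stage",
    "mycn_status",
    "survival_years",
    "vital_status",
)
OPTIONAL_CLINICAL_COLUMNS = ("gender", "race", "risk_group")

#: default category vocabularies for one-hot encoding; fixed up front so the
#: indicator column layout is identical across data splits
DEFAULT_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "inss_stage": ("1", "2", "3", "4", "4S"),
    "mycn_status": ("amplified", "not amplified"),
    "gender": ("male", "female"),
    "risk_group": ("low", "high"),
    "vital_status": ("dead", "alive"),
}


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """A samples x features real-valued matrix with identifiers.

    Missing entries are represented as NaN until imputation; after
    preprocessing the matrix must be complete.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    modality: str = "expression"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise DataError(f"duplicate {name} identifier: {dup!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, modality: str = "expression") -> "OmicsMatrix":
        return cls(
            sample_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            modality=modality,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise DataError(f"unknown feature identifiers: {missing[:5]}")
        cols = [index[f] for f in feature_ids]
        return OmicsMatrix(self.sample_ids, list(feature_ids), self.values[:, cols], self.modality)

    def subset_samples(self, rows: Sequence[int]) -> "OmicsMatrix":
        rows = list(rows)
        return OmicsMatrix(
            [self.sample_ids[i] for i in rows],
            list(self.feature_ids),
            self.values[rows, :],
            self.modality,
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical fields including the two outcome variables."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataError(f"clinical table missing required columns: {missing}")
        dup = _first_duplicate(list(self.df["sample_id"].astype(str)))
        if dup is not None:
            raise DataError(f"duplicate sample identifier: {dup!r}")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.df["sample_id"]]

    @property
    def n_samples(self) -> int:
        return len(self.df)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        column_map: Mapping[str, str] | None = None,
        delimiter: str | None = None,
        na_values: Sequence[str] = DEFAULT_NA_VALUES,
    ) -> "ClinicalTable":
        """Read a clinical CSV/TSV; ``column_map`` maps canonical -> file column."""
        df = pd.read_csv(
            path,
            sep=delimiter,
            engine="python" if delimiter is None else "c",
            na_values=list(na_values),
            keep_default_na=False,
            dtype=str,
        )
        if column_map:
            rename = {src: canon for canon, src in column_map.items()}
            df = df.rename(columns=rename)
        for col in ("age_days", "survival_years"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="raise")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        cols = [c for c in CLINICAL_COLUMNS if c in self.df.columns]
        cols += [c for c in self.df.columns if c not in cols]
        self.df.to_csv(path, index=False, columns=cols)


@dataclass
class LabelPair:
    """The two aligned binary outcome labels.

    ``survival_label``: 0 = short-term (< threshold years), 1 = long-term.
    ``vital_label``: 0 = dead, 1 = alive at last follow-up.
    """

    survival_label: np.ndarray
    vital_label: np.ndarray
    threshold_years: float = 5.0

    def __post_init__(self) -> None:
        self.survival_label = np.asarray(self.survival_label, dtype=int)
        self.vital_label = np.asarray(self.vital_label, dtype=int)
        if self.survival_label.shape != self.vital_label.shape:
            raise DataError("label vectors must have the same length")
        for name, v in (("survival", self.survival_label), ("vital", self.vital_label)):
            if not np.isin(v, (0, 1)).all():
                raise DataError(f"{name} labels must be binary 0/1")
        if self.threshold_years <= 0:
            raise DataError("threshold_years must be positive")

    def __len__(self) -> int:
        return len(self.survival_label)

    def subset(self, rows: Sequence[int]) -> "LabelPair":
        rows = list(rows)
        return LabelPair(
            self.survival_label[rows], self.vital_label[rows], self.threshold_years
        )


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# matrix readers / writers
# ---------------------------------------------------------------------------


def read_matrix(
    path: str | Path,
    orientation: str = "samples",
    delimiter: str | None = None,
    na_values: Sequence[str] = DEFAULT_NA_VALUES,
    modality: str = "expression",
) -> OmicsMatrix:
    """Read a delimited numeric table into an :class:`OmicsMatrix`.

    Parameters
    ----------
    orientation
        ``"samples"`` if rows are samples, ``"features"`` if rows are
        features (the matrix is transposed to samples x features).
    delimiter
        Explicit delimiter; ``None`` auto-detects (CSV/TSV).

    Missing cells (empty or any sentinel in ``na_values``) are kept as NaN,
    never silently zeroed. Duplicate identifiers or non-numeric cells raise
    :class:`DataError` naming the offender.
    """
    if orientation not in ("samples", "features"):
        raise DataError(f"orientation must be 'samples' or 'features', got {orientation!r}")
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\r\n")
    if delimiter is None:
        # auto-detect among the usual delimited-text suspects
        delimiter = max((",", "\t", ";"), key=header_line.count)
    header = header_line.split(delimiter)[1:]  # first column holds identifiers
    dup = _first_duplicate(header)
    if dup is not None:
        raise DataError(f"duplicate column identifier: {dup!r}")
    raw = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        na_values=list(na_values),
        keep_default_na=False,
        dtype=str,
    )
    dup = _first_duplicate([str(i) for i in raw.index])
    if dup is not None:
        raise DataError(f"duplicate row identifier: {dup!r}")

    # parse with Python float(): exact (shortest-repr) round-trip, unlike the
    # pandas C tokenizer which can be 1 ulp off
    values = np.empty(raw.shape, dtype=float)
    cells = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = cells[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise DataError(
                    f"non-numeric cell {cell!r} at row {raw.index[i]!r}, "
                    f"column {raw.columns[j]!r}"
                ) from None
    numeric = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    if orientation == "features":
        numeric = numeric.T
    return OmicsMatrix.from_dataframe(numeric, modality=modality)


def write_matrix(m: OmicsMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write an :class:`OmicsMatrix` as delimited text (NaN -> empty cell).

    Finite values round-trip bit-for-bit through :func:`read_matrix` (floats
    are written with ``repr`` precision).
    """
    m.to_dataframe().to_csv(path, sep=delimiter, na_rep="")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def filter_missing_features(m: OmicsMatrix, max_missing_fraction: float = 0.05) -> OmicsMatrix:
    """Drop features whose missing fraction is strictly greater than the cap.

    A feature with exactly the cap fraction of missing values is retained;
    all-empty features are always removed. Column order of the survivors is
    preserved. Default cap: 5%.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise DataError("max_missing_fraction must be in [0, 1]")
    frac = np.isnan(m.values).mean(axis=0)
    keep = (frac <= max_missing_fraction) & (frac < 1.0)
    idx = np.flatnonzero(keep)
    return OmicsMatrix(
        m.sample_ids,
        [m.feature_ids[i] for i in idx],
        m.values[:, idx],
        m.modality,
    )


def impute_mean(m: OmicsMatrix) -> OmicsMatrix:
    """Replace each missing cell by the column mean of the observed values."""
    vals = m.values.copy()
    nan_mask = np.isnan(vals)
    all_missing = nan_mask.all(axis=0)
    if all_missing.any():
        bad = [m.feature_ids[i] for i in np.flatnonzero(all_missing)[:5]]
        raise DataError(f"features with no observed values (filter first): {bad}")
    if nan_mask.any():
        col_means = np.nanmean(vals, axis=0)
        rows, cols = np.nonzero(nan_mask)
        vals[rows, cols] = col_means[cols]
    return OmicsMatrix(m.sample_ids, list(m.feature_ids), vals, m.modality)


def make_labels(c: ClinicalTable, threshold_years: float = 5.0) -> LabelPair:
    """Dichotomize the two outcomes into a :class:`LabelPair`.

    Survival: short-term (0) if ``survival_years < threshold_years``, else
    long-term (1) — a survival time exactly at the threshold counts as
    long-term. Vital status: dead -> 0, alive -> 1. The two labels are
    deliberately independent: a patient can be (short-term, alive) — the
    indeterminate-survival combination — or (long-term, dead).
    """
    if threshold_years <= 0:
        raise DataError("threshold_years must be positive")
    surv = pd.to_numeric(c.df["survival_years"], errors="coerce")
    vital = c.df["vital_status"].astype(str).str.strip().str.lower()
    bad_surv = surv.isna() | ~np.isfinite(surv)
    bad_vital = ~vital.isin(["dead", "alive"])
    if bad_surv.any() or bad_vital.any():
        ids = [c.sample_ids[i] for i in np.flatnonzero(bad_surv | bad_vital)]
        raise DataError(f"missing/invalid survival time or vital status for samples: {ids}")
    survival_label = (surv.to_numpy() >= threshold_years).astype(int)
    vital_label = (vital == "alive").to_numpy().astype(int)
    return LabelPair(survival_label, vital_label, threshold_years)


def fit_encoding_stats(c: ClinicalTable, feature_set: Sequence[str]) -> dict:
    """Min-max statistics for the numeric clinical fields, fit on one split."""
    stats: dict[str, dict[str, float]] = {}
    for f in feature_set:
        if f == "age_days":
            v = pd.to_numeric(c.df[f], errors="coerce").to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                raise DataError("no finite age values to fit min-max scaling")
            stats[f] = {"min": float(v.min()), "max": float(v.max())}
    return stats


def encode_clinical(
    c: ClinicalTable,
    feature_set: Sequence[str] = ("age_days", "inss_stage", "mycn_status"),
    fit_stats: Mapping[str, Mapping[str, float]] | None = None,
    vocabularies: Mapping[str, Sequence[str]] | None = None,
) -> OmicsMatrix:
    """Encode clinical fields as a numeric feature block.

    Numeric age is min-max scaled to [0, 1] using ``fit_stats`` (from the
    training split when transforming a test split; out-of-range values are
    clamped). Categorical fields are one-hot encoded against a fixed
    vocabulary; a category outside the vocabulary (e.g. "unknown") maps to
    all-zero indicators.
    """
    vocab = dict(DEFAULT_VOCABULARIES)
    if vocabularies:
        vocab.update({k: tuple(v) for k, v in vocabularies.items()})
    available = set(c.df.columns)
    unknown = [f for f in feature_set if f not in available]
    if unknown:
        raise DataError(f"clinical fields not present: {unknown}")
    if fit_stats is None:
        fit_stats = fit_encoding_stats(c, feature_set)

    columns: list[str] = []
    blocks: list[np.ndarray] = []
    for f in feature_set:
        if f == "age_days":
            st = fit_stats.get(f)
            if st is None:
                raise DataError("fit_stats missing entry for age_days")
            lo, hi = float(st["min"]), float(st["max"])
            if hi == lo:
                raise DataError("age min equals max; cannot min-max scale")
            v = pd.to_numeric(c.df[f], errors="coerce").to_numpy(dtype=float)
            scaled = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
            columns.append(f)
            blocks.append(scaled[:, None])
        else:
            if f not in vocab:
                raise DataError(f"no vocabulary declared for categorical field {f!r}")
            cats = vocab[f]
            raw = c.df[f].astype(str).str.strip().str.lower()
            onehot = np.zeros((len(raw), len(cats)))
            for j, cat in enumerate(cats):
                onehot[:, j] = (raw == str(cat).lower()).to_numpy(dtype=float)
            columns.extend(f"{f}={cat}" for cat in cats)
            blocks.append(onehot)
    values = np.hstack(blocks) if blocks else np.empty((c.n_samples, 0))
    return OmicsMatrix(c.sample_ids, columns, values, modality="clinical-derived")


def concatenate(blocks: Sequence[OmicsMatrix]) -> OmicsMatrix:
    """Early integration: column-concatenate modality blocks.

    All blocks must have identical sample ids in identical order. Feature
    ids are prefixed with the block's modality to keep them unique.
    """
    if not blocks:
        raise DataError("no blocks to concatenate")
    if len(blocks) == 1:
        return blocks[0]
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            raise DataError("sample identifiers differ between blocks (order matters)")
    feature_ids = [f"{b.modality}:{fid}" for b in blocks for fid in b.feature_ids]
    values = np.hstack([b.values for b in blocks])
    return OmicsMatrix(ref, feature_ids, values, modality="integrated")
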