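"""Binary trait matrices and feature catalogues.

A trait matrix records, for every language (taxon) and every structural
feature, whether the feature is present, absent, or could not be coded from
the available sources (missing).  Missing is a first-class state: it is never
silently treated as absence, and downstream analyses decide how to handle it
(the signal statistic prunes missing tips, the rate model treats them as
ambiguous).

The catalogue assigns each feature to three closed classification axes:
a functional category, a language domain (level), and a part of speech.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PRESENT",
    "ABSENT",
    "MISSING",
    "FUNCTIONAL_CATEGORIES",
    "DOMAINS",
    "PARTS_OF_SPEECH",
    "MatrixValidationError",
    "FeatureMatrix",
    "FeatureCatalog",
    "read_matrix",
    "write_matrix",
    "read_catalog",
    "drop_never_present",
    "coverage_stats",
]

PRESENT = "present"
ABSENT = "absent"
MISSING = "missing"

#: Default token mapping used by the delimited-text reader.
DEFAULT_TOKENS: Mapping[str, str] = {"1": PRESENT, "0": ABSENT, "?": MISSING, "NA": MISSING}

# Closed vocabularies for the three catalogue axes.
FUNCTIONAL_CATEGORIES = frozenset(
    {
        "argument marking (core)",
        "argument marking (non-core)",
        "deixis",
        "derivation",
        "interrogation",
        "modification",
        "negation",
        "phonological distinctiveness",
        "possession",
        "quantification",
        "TAME+",
        "valency",
        "word order",
        "other",
    }
)

DOMAINS = frozenset({"phonological shape", "word", "nominal phrase", "clause", "other"})

PARTS_OF_SPEECH = frozenset(
    {
        "adjective",
        "article",
        "demonstrative",
        "noun",
        "noun/pronoun",
        "particle",
        "pronoun",
        "verb",
        "other",
        "not assignable",
    }
)

_AXIS_VOCAB = {
    "functional_category": FUNCTIONAL_CATEGORIES,
    "domain": DOMAINS,
    "part_of_speech": PARTS_OF_SPEECH,
}


class MatrixValidationError(ValueError):
    """Raised when a matrix or catalogue violates its invariants."""


@dataclass(frozen=True)
class FeatureMatrix:
    """Taxa x features grid over {present, absent, missing}.

    ``values`` is a pandas DataFrame indexed by taxon with one column per
    feature; cells hold 1.0 (present), 0.0 (absent) or NaN (missing).
    ``families`` maps every taxon to exactly one family label.
    """

    values: pd.DataFrame
    families: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = sorted(v.index[v.index.duplicated()].unique())
            raise MatrixValidationError(f"duplicate taxon identifiers: {dups}")
        if v.columns.duplicated().any():
            dups = sorted(v.columns[v.columns.duplicated()].unique())
            raise MatrixValidationError(f"duplicate feature identifiers: {dups}")
        arr = v.to_numpy(dtype=float)
        bad = ~(np.isnan(arr) | (arr == 0.0) | (arr == 1.0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixValidationError(
                f"invalid cell value {arr[i, j]!r} at taxon {v.index[i]!r}, "
                f"feature {v.columns[j]!r}"
            )
        if set(self.families.index) != set(v.index):
            missing = sorted(set(v.index) - set(self.families.index))
            extra = sorted(set(self.families.index) - set(v.index))
            raise MatrixValidationError(
                f"family labels do not match taxa (missing {missing}, extra {extra})"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_taxa(self) -> int:
        return len(self.values.index)

    @property
    def n_features(self) -> int:
        return len(self.values.columns)

    def state(self, taxon: str, feature: str) -> str:
        """The categorical state of one cell."""
        x = self.values.at[taxon, feature]
        if pd.isna(x):
            return MISSING
        return PRESENT if x == 1.0 else ABSENT

    def trait(self, feature: str) -> dict[str, str]:
        """Mapping taxon -> {present, absent, missing} for one feature."""
        col = self.values[feature]
        return {
            t: (MISSING if pd.isna(x) else (PRESENT if x == 1.0 else ABSENT))
            for t, x in col.items()
        }

    def subset_features(self, features: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values[list(features)], self.families)


@dataclass(frozen=True)
class FeatureCatalog:
    """Per-feature assignment to the three closed classification axes."""

    table: pd.DataFrame  # index: feature; columns: the three axes

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise MatrixValidationError("duplicate feature identifiers in catalogue")
        for axis, vocab in _AXIS_VOCAB.items():
            if axis not in t.columns:
                raise MatrixValidationError(f"catalogue lacks column {axis!r}")
            bad = sorted(set(t[axis]) - vocab)
            if bad:
                raise MatrixValidationError(f"unknown {axis} value(s): {bad}")

    def category(self, feature: str, axis: str) -> str:
        if axis not in _AXIS_VOCAB:
            raise KeyError(f"unknown axis {axis!r}")
        return str(self.table.at[feature, axis])

    def check_features(self, features: Sequence[str]) -> None:
        """Every listed feature must carry exactly one assignment per axis."""
        missing = sorted(set(features) - set(self.table.index))
        if missing:
            raise MatrixValidationError(f"features absent from catalogue: {missing}")

    def axis_counts(self, axis: str) -> pd.Series:
        """Feature counts per category on one axis (for coverage reports)."""
        return self.table[axis].value_counts()


def read_matrix(
    path: str | Path,
    sep: str = ",",
    tokens: Mapping[str, str] | None = None,
    taxon_column: str = "taxon",
    family_column: str = "family",
) -> FeatureMatrix:
    """Read a delimited trait matrix: one row per taxon, one column per feature.

    ``tokens`` maps input tokens to the three states; the default accepts
    1/0/? with "NA" as an alias for missing.
    """
    tokens = dict(DEFAULT_TOKENS if tokens is None else tokens)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise MatrixValidationError(f"duplicate feature identifiers: {dups}")
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (taxon_column, family_column):
        if col not in raw.columns:
            raise MatrixValidationError(f"matrix file lacks mandatory column {col!r}")
    if raw.columns.duplicated().any():
        dups = sorted(raw.columns[raw.columns.duplicated()].unique())
        raise MatrixValidationError(f"duplicate feature identifiers: {dups}")
    if raw[taxon_column].duplicated().any():
        dups = sorted(raw[taxon_column][raw[taxon_column].duplicated()])
        raise MatrixValidationError(f"duplicate taxon identifiers: {dups}")

    feature_cols = [c for c in raw.columns if c not in (taxon_column, family_column)]
    numeric = {PRESENT: 1.0, ABSENT: 0.0, MISSING: np.nan}
    data = np.empty((len(raw), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        for i, tok in enumerate(raw[col]):
            tok = tok.strip()
            if tok not in tokens:
                raise MatrixValidationError(
                    f"unknown token {tok!r} at taxon {raw[taxon_column].iloc[i]!r}, "
                    f"feature {col!r}"
                )
            data[i, j] = numeric[tokens[tok]]
    values = pd.DataFrame(data, index=list(raw[taxon_column]), columns=feature_cols)
    families = pd.Series(list(raw[family_column]), index=list(raw[taxon_column]))
    return FeatureMatrix(values, families)


def write_matrix(
    matrix: FeatureMatrix,
    path: str | Path,
    sep: str = ",",
    tokens: Mapping[str, str] = {PRESENT: "1", ABSENT: "0", MISSING: "?"},
) -> None:
    """Write a matrix in the same delimited layout ``read_matrix`` accepts."""
    out = pd.DataFrame(index=matrix.values.index)
    out["taxon"] = matrix.values.index
    out["family"] = matrix.families.reindex(matrix.values.index).to_numpy()
    for feat in matrix.features:
        col = matrix.values[feat]
        out[feat] = [
            tokens[MISSING] if pd.isna(x) else (tokens[PRESENT] if x == 1.0 else tokens[ABSENT])
            for x in col
        ]
    out.to_csv(path, sep=sep, index=False)


def read_catalog(path: str | Path, sep: str = ",") -> FeatureCatalog:
    """Read the feature catalogue (columns: feature + the three axes)."""
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "feature" not in raw.columns:
        raise MatrixValidationError("catalogue file lacks mandatory column 'feature'")
    table = raw.set_index("feature")[list(_AXIS_VOCAB)]
    return FeatureCatalog(table)


def write_catalog(catalog: FeatureCatalog, path: str | Path, sep: str = ",") -> None:
    catalog.table.rename_axis("feature").to_csv(path, sep=sep)


def drop_never_present(matrix: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Remove features with no 'present' cell anywhere (absent/missing only).

    Such features carry no information for a presence/absence analysis.
    Features that are present-or-missing everywhere (never coded absent) are
    retained.  Returns the filtered matrix and the removed feature list,
    column order preserved.
    """
    arr = matrix.values.to_numpy(dtype=float)
    has_present = np.nansum(arr == 1.0, axis=0) > 0
    kept = [f for f, k in zip(matrix.features, has_present) if k]
    removed = [f for f, k in zip(matrix.features, has_present) if not k]
    return matrix.subset_features(kept), removed


def coverage_stats(matrix: FeatureMatrix) -> dict[str, pd.Series | pd.DataFrame]:
    """Non-missing cell counts per feature and per taxon, plus threshold counts.

    ``feature_thresholds`` reports, for each codability level q (fraction of
    taxa with a non-missing value), how many features reach it — the kind of
    count used to report, e.g., how many features are codable for over half
    the sample.
    """
    notna = matrix.values.notna()
    per_feature = notna.sum(axis=0).rename("n_coded_taxa")
    per_taxon = notna.sum(axis=1).rename("n_coded_features")
    n_taxa = matrix.n_taxa
    levels = [0.5, 2 / 3, 0.75, 0.9, 0.95, 1.0]
    thresh = pd.Series(
        {q: int((per_feature >= q * n_taxa).sum()) for q in levels},
        name="n_features_codable",
    )
    return {
        "per_feature": per_feature,
        "per_taxon": per_taxon,
        "feature_thresholds": thresh,
    }
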