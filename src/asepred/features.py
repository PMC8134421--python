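"""Variant annotation feature tables.

Loads CADD-style per-variant annotation tables, applies the three named
exclusion lists (non-functional columns, columns with high missingness,
columns correlated with ASE detectability), imputes missing values and
encodes categorical/binary columns into a fully numeric model-ready
matrix.  The canonical 109-column header (107 CADD v1.4 annotation
columns plus the gene-level pLI score and the gnomAD allele frequency)
and the exclusion lists ship as package data; removing the 39 excluded
columns leaves the 70 modelling features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINDS = ("numeric", "categorical", "binary")
EXCLUSION_REASONS = ("non_functional", "high_missingness", "detectability_correlated", "none")
UNKNOWN_CATEGORY = "__unknown__"


def _data_text(name: str) -> str:
    return resources.files("asepred.data").joinpath(name).read_text()


def canonical_feature_names() -> list[str]:
    """The packaged 109-column annotation header, in file order."""
    return _data_text("features_109.txt").split()


def canonical_exclusions() -> dict[str, list[str]]:
    """The three packaged exclusion lists (39 names in total)."""
    return json.loads(_data_text("exclusions.json"))


def canonical_feature_kinds() -> dict[str, str]:
    """Column kind (numeric / categorical / binary) for the canonical header."""
    declared = json.loads(_data_text("feature_kinds.json"))
    kinds = {name: "numeric" for name in canonical_feature_names()}
    for name in declared["categorical"]:
        kinds[name] = "categorical"
    for name in declared["binary"]:
        kinds[name] = "binary"
    return kinds


@dataclass
class FeatureSpec:
    """Declared type, imputation default and exclusion status of one column."""

    name: str
    kind: str = "numeric"
    imputation_default: object | None = None
    excluded: str = "none"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name}")
        if self.excluded not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.excluded!r} for {self.name}")


def canonical_specs() -> list[FeatureSpec]:
    """FeatureSpec list for the packaged 109-column header."""
    kinds = canonical_feature_kinds()
    reasons = {}
    for reason, names in canonical_exclusions().items():
        for n in names:
            reasons[n] = reason
    return [FeatureSpec(name=n, kind=kinds[n], excluded=reasons.get(n, "none"))
            for n in canonical_feature_names()]


class FeatureMatrix:
    """SNV-by-feature table with typed columns and a missing-value mask.

    ``values`` keeps numeric columns as floats and categorical/binary
    columns as pandas string columns with NaN for missing.  The matrix is
    fully numeric (and carries an ``encoding`` dictionary) only after
    :func:`impute_and_encode`.
    """

    def __init__(self, values: pd.DataFrame, specs: list[FeatureSpec],
                 encoding: dict | None = None):
        spec_names = [s.name for s in specs]
        if list(values.columns) != spec_names:
            raise ValueError("column order of values must match specs")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique()[:5].tolist()
            raise ValueError(f"duplicate row ids: {dups}")
        self.values = values
        self.specs = {s.name: s for s in specs}
        self.encoding = encoding

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def shape(self):
        return self.values.shape

    def spec_list(self) -> list[FeatureSpec]:
        return [self.specs[c] for c in self.values.columns]

    def to_tsv(self, path, sidecar_path=None) -> None:
        """Write values as TSV; optionally a JSON sidecar with specs/encoding."""
        self.values.to_csv(path, sep="\t", index_label="locus_id", na_rep="NA")
        if sidecar_path is not None:
            meta = {
                "specs": [{"name": s.name, "kind": s.kind,
                           "imputation_default": s.imputation_default,
                           "excluded": s.excluded} for s in self.spec_list()],
                "encoding": self.encoding,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1, default=str)


def load_annotations(path, specs: list[FeatureSpec]) -> FeatureMatrix:
    """Load a tab-separated annotation table against a declared spec list.

    Unparseable cells in numeric columns become missing; columns present
    in the file but absent from the specs are a hard error.  Row ids are
    taken from a ``locus_id`` column when present, otherwise built as
    ``chr:pos:ref:alt`` from Chrom/Pos/Ref/Alt columns.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    spec_names = [s.name for s in specs]
    id_cols = [c for c in ("locus_id",) if c in raw.columns]
    unknown = [c for c in raw.columns if c not in spec_names and c not in id_cols]
    if unknown:
        raise ValueError(f"columns absent from the feature spec: {unknown}")
    missing_cols = [n for n in spec_names if n not in raw.columns]
    if missing_cols:
        raise ValueError(f"spec columns absent from the file: {missing_cols}")

    if id_cols:
        index = raw["locus_id"]
    elif all(c in raw.columns for c in ("Chrom", "Pos", "Ref", "Alt")):
        index = raw["Chrom"] + ":" + raw["Pos"] + ":" + raw["Ref"] + ":" + raw["Alt"]
    else:
        index = raw.index.astype(str)
    if index.duplicated().any():
        raise ValueError("duplicate row ids in annotation table")

    out = {}
    na_markers = {"", "NA", "NaN", "nan", "."}
    for s in specs:
        col = raw[s.name]
        cleaned = col.where(~col.isin(na_markers))
        if s.kind == "numeric":
            out[s.name] = pd.to_numeric(cleaned, errors="coerce")
        else:
            out[s.name] = cleaned
    values = pd.DataFrame(out)
    values.index = pd.Index(index.values, name="locus_id")
    return FeatureMatrix(values, specs)


def apply_exclusions(matrix: FeatureMatrix,
                     exclusion_lists: dict[str, list[str]] | None = None) -> FeatureMatrix:
    """Drop the union of the named exclusion lists from the matrix.

    ``exclusion_lists`` maps a reason tag to column names; names not in
    the matrix are an error.  Defaults to the packaged lists restricted
    to columns actually present.
    """
    if exclusion_lists is None:
        present = set(matrix.feature_names)
        exclusion_lists = {r: [n for n in names if n in present]
                           for r, names in canonical_exclusions().items()}
    drop = set()
    for reason, names in exclusion_lists.items():
        unknown = [n for n in names if n not in matrix.specs]
        if unknown:
            raise ValueError(f"exclusion list {reason!r} names unknown feature(s): {unknown}")
        logger.info("excluding %d features (%s)", len(names), reason)
        drop.update(names)
    kept_specs = []
    for s in matrix.spec_list():
        if s.name in drop:
            continue
        kept_specs.append(FeatureSpec(s.name, s.kind, s.imputation_default, "none"))
    values = matrix.values[[s.name for s in kept_specs]]
    return FeatureMatrix(values, kept_specs, encoding=matrix.encoding)


def _fit_encoding(matrix: FeatureMatrix) -> dict:
    """Derive imputation defaults and category code books from a matrix.

    Placeholder defaults when the spec declares none: column median for
    numeric, most frequent value for categorical/binary.  Categories are
    coded by alphabetical order; code ``K`` is reserved for unseen
    categories at apply time.
    """
    encoding = {"defaults": {}, "categories": {}}
    for s in matrix.spec_list():
        col = matrix.values[s.name]
        default = s.imputation_default
        if s.kind == "numeric":
            if default is None:
                med = col.median()
                default = float(med) if np.isfinite(med) else 0.0
            encoding["defaults"][s.name] = float(default)
        else:
            observed = col.dropna().astype(str)
            if default is None:
                default = observed.mode().iloc[0] if len(observed) else UNKNOWN_CATEGORY
            cats = sorted(set(observed) | {str(default)})
            if s.kind == "binary" and len(cats) > 2:
                raise ValueError(f"binary column {s.name} has >2 levels: {cats}")
            encoding["defaults"][s.name] = str(default)
            encoding["categories"][s.name] = {c: i for i, c in enumerate(cats)}
    return encoding


def impute_and_encode(matrix: FeatureMatrix, encoding: dict | None = None) -> FeatureMatrix:
    """Fill missing values and map non-numeric columns to integer codes.

    When ``encoding`` is None it is fitted from ``matrix`` (training);
    passing a stored encoding reproduces the training-time mapping at
    apply time, sending unseen categories to a reserved unknown code.
    """
    if encoding is None:
        encoding = _fit_encoding(matrix)
    out = {}
    for s in matrix.spec_list():
        col = matrix.values[s.name]
        default = encoding["defaults"][s.name]
        if s.kind == "numeric":
            out[s.name] = pd.to_numeric(col, errors="coerce").fillna(float(default))
        else:
            codes = encoding["categories"][s.name]
            unknown_code = len(codes)
            filled = col.map(lambda v: str(v), na_action="ignore").fillna(str(default))
            unseen = ~filled.isin(codes)
            if unseen.any():
                logger.warning("column %s: %d value(s) outside the training categories "
                               "mapped to the unknown code", s.name, int(unseen.sum()))
            out[s.name] = filled.map(codes).fillna(unknown_code).astype(float)
    values = pd.DataFrame(out, index=matrix.values.index)
    assert not values.isna().any().any()
    specs = [FeatureSpec(s.name, s.kind, encoding["defaults"][s.name], s.excluded)
             for s in matrix.spec_list()]
    return FeatureMatrix(values, specs, encoding=encoding)
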