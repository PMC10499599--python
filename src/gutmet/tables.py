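"""Sample-by-feature tables, TSV I/O, transforms and sample alignment.

A :class:`FeatureTable` wraps a pandas DataFrame (samples as rows, features as
columns) with a layer tag and optional per-feature annotations.  Zeros are
data (values below the limit of detection are recorded as zero); absent cells
are missing and handled complete-case per analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LAYERS = ("metabolite", "lipid", "genus", "species", "ko", "cytokine", "promoter")
#: Layers carrying relative abundances (per-sample row sums in [0, 1]).
COMPOSITIONAL_LAYERS = ("genus", "species", "ko")


class TableParseError(ValueError):
    """Raised on malformed input tables, with the offending line when known."""


@dataclass
class FeatureTable:
    values: pd.DataFrame
    layer: str
    feature_meta: pd.DataFrame | None = field(default=None)
    #: False once a transform has been applied to a compositional layer, in
    #: which case the row-sum invariant no longer holds.
    compositional: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise TableParseError(f"duplicate sample ids: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise TableParseError(f"duplicate feature ids: {dup}")
        if self.compositional and self.layer in COMPOSITIONAL_LAYERS:
            sums = self.values.sum(axis=1, skipna=True)
            if (sums > 1 + 1e-9).any():
                raise ValueError(f"compositional layer {self.layer!r} has row sums above 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, feature_ids) -> "FeatureTable":
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.loc[[f for f in feature_ids if f in self.feature_meta.index]]
        return FeatureTable(self.values.loc[:, list(feature_ids)], self.layer, meta,
                            compositional=False)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(sample_ids)], self.layer, self.feature_meta,
                            compositional=self.compositional)


def read_feature_table(path, layer: str) -> FeatureTable:
    """Read a TSV with a ``sample_id`` first column into a FeatureTable.

    Missing cells (empty or NA) are marked missing, never coerced to zero.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    num = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            s = raw.strip()
            if s in ("", "NA", "NaN", "nan"):
                num.iat[i, j] = np.nan
                continue
            try:
                num.iat[i, j] = float(s)
            except ValueError:
                raise TableParseError(
                    f"{path}: non-numeric cell {raw!r} at line {i + 2}, column {col!r}"
                ) from None
    return FeatureTable(num, layer)


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


@dataclass(frozen=True)
class TransformSpec:
    """Element- or column-wise transform applied before an analysis.

    kinds: ``log10_scale`` (log10 then per-column z-score, zeros replaced by
    half the smallest positive value in the column), ``sqrt``,
    ``arcsine_sqrt`` (for relative abundances in [0, 1]), ``rank``
    (average ranks per column) and ``zscore``.
    """

    kind: str
    pseudo_handling: str = "half_min"

    _KINDS = ("log10_scale", "sqrt", "arcsine_sqrt", "rank", "zscore")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown transform {self.kind!r}")


def apply_transform(table: FeatureTable, spec: TransformSpec) -> FeatureTable:
    X = table.values.copy()
    kind = spec.kind
    if kind == "sqrt":
        if (X < 0).any().any():
            raise ValueError("sqrt transform requires non-negative values")
        out = np.sqrt(X)
    elif kind == "arcsine_sqrt":
        if ((X < 0) | (X > 1)).any().any():
            raise ValueError("arcsine_sqrt requires values in [0, 1]")
        out = np.arcsin(np.sqrt(X))
    elif kind == "rank":
        out = X.rank(axis=0, method="average", na_option="keep")
    elif kind in ("zscore", "log10_scale"):
        if kind == "log10_scale":
            for col in X.columns:
                v = X[col]
                if (v < 0).any():
                    raise ValueError(f"log10_scale: negative values in {col!r}")
                pos = v[v > 0]
                if pos.empty:
                    raise ValueError(f"log10_scale: column {col!r} has no positive values")
                if spec.pseudo_handling != "half_min":
                    raise ValueError(f"unknown pseudo_handling {spec.pseudo_handling!r}")
                X[col] = v.where(v > 0, pos.min() / 2.0)
            X = np.log10(X)
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any() or sd.isna().any():
            bad = sd.index[(sd == 0) | sd.isna()].tolist()
            raise ValueError(f"zero-variance columns under scaling: {bad}")
        out = (X - X.mean(axis=0)) / sd
    else:  # pragma: no cover
        raise AssertionError(kind)
    return FeatureTable(out, table.layer, table.feature_meta, compositional=False)


def align_samples(tables: list[FeatureTable], phenotypes: pd.DataFrame | None = None):
    """Intersect sample ids across tables (and metadata), normalising order.

    Returns ``(aligned_tables, aligned_phenotypes, report)`` where report maps
    each input position to the number of samples it dropped.
    """
    sets = [set(t.sample_ids) for t in tables]
    if phenotypes is not None:
        sets.append(set(phenotypes.index))
    common = set.intersection(*sets) if sets else set()
    if not common:
        raise ValueError("no samples shared across the given tables")
    order = sorted(common)
    report = {i: len(t.sample_ids) - len(order) for i, t in enumerate(tables)}
    aligned = [t.subset_samples(order) for t in tables]
    pheno = phenotypes.loc[order] if phenotypes is not None else None
    for i, dropped in report.items():
        if dropped:
            log.info("align_samples: table %d dropped %d samples", i, dropped)
    return aligned, pheno, report
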