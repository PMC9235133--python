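"""Trait/metadata containers, design matrices, the count transformation,
and trait frequency classing.

Traits are integer-valued: CSS-normalized OTU abundances, standardized
genus relative abundances, or standardized alpha-diversity indices, all
multiplied by 100 and rounded so they can be treated as counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TRAIT_KINDS = ("otu", "genus", "diversity")

METADATA_COLUMNS = ("litter", "cage", "batch", "group", "weight_class")

#: Trait frequency bins in percent of animals with a nonzero record.
#: Traits present in fewer than 5% of animals are excluded from analysis.
FREQUENCY_CLASSES = (
    (5.0, 10.0, "[5,10]"),
    (10.0, 25.0, "(10,25]"),
    (25.0, 50.0, "(25,50]"),
    (50.0, 75.0, "(50,75]"),
    (75.0, 100.0, "(75,100]"),
)


@dataclass
class StudyMetadata:
    """Per-animal factors: litter, cage, batch, farm/diet/regime group,
    and weaning-weight class (all categorical)."""

    table: pd.DataFrame  # indexed by animal id, columns METADATA_COLUMNS

    def __post_init__(self):
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if len(self.table) == 0:
            raise ValueError("empty metadata")
        if self.table[list(METADATA_COLUMNS)].isna().any().any():
            bad = self.table.index[self.table[list(METADATA_COLUMNS)].isna().any(axis=1)]
            raise ValueError(f"animals with missing metadata fields: {list(bad)}")

    @property
    def animals(self) -> list[str]:
        return list(self.table.index.astype(str))

    @classmethod
    def read(cls, source) -> "StudyMetadata":
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
        if "animal" not in df.columns:
            raise ValueError("metadata table needs an 'animal' column")
        return cls(df.set_index("animal"))


@dataclass
class TraitTable:
    """Integer trait records (animals x traits) with a kind per trait."""

    values: pd.DataFrame  # indexed by animal id, integer-valued
    kinds: dict[str, str]  # trait name -> otu | genus | diversity

    def __post_init__(self):
        arr = self.values.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("trait table values must be integers")
        for t, k in self.kinds.items():
            if k not in TRAIT_KINDS:
                raise ValueError(f"unknown trait kind {k!r} for trait {t!r}")

    @property
    def animals(self) -> list[str]:
        return list(self.values.index.astype(str))

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def trait(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy(dtype=float)

    @classmethod
    def read(cls, source, kinds: dict[str, str] | None = None) -> "TraitTable":
        df = pd.read_csv(source, sep=None, engine="python")
        df = df.set_index(df.columns[0])
        df.index = df.index.astype(str)
        if kinds is None:
            kinds = {t: "otu" for t in df.columns}
        return cls(df, kinds)


@dataclass
class DesignMatrices:
    """Fixed-effects incidence X (full column rank) and the 0/1 litter and
    cage incidence matrices, all sharing one animal ordering."""

    X: np.ndarray
    Z_L: np.ndarray
    Z_C: np.ndarray
    animal_ids: list[str]
    column_names: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]


def build_design(metadata: StudyMetadata) -> DesignMatrices:
    """Build X, Z_L, Z_C from the study metadata.

    The systematic block uses full dummy coding for the farm/diet/regime
    group (acting as the model's intercept block) and drop-first treatment
    coding for batch and weight class, so X keeps full column rank without a
    redundant global intercept.  At the emulated design's level counts (6, 5, 2) this
    gives 6 + 4 + 1 = 11 columns.  A factor with a single level contributes
    no treatment columns (warned, not an error).
    """
    tbl = metadata.table
    blocks, names = [], []

    g = pd.get_dummies(tbl["group"], prefix="group", dtype=float)
    blocks.append(g.to_numpy())
    names += list(g.columns)

    for fac in ("batch", "weight_class"):
        levels = pd.unique(tbl[fac])
        if len(levels) == 1:
            warnings.warn(f"factor {fac!r} has a single level; block collapsed")
            continue
        d = pd.get_dummies(tbl[fac], prefix=fac, drop_first=True, dtype=float)
        blocks.append(d.to_numpy())
        names += list(d.columns)

    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix X is column-rank deficient")

    Z_L = pd.get_dummies(tbl["litter"], dtype=float).to_numpy()
    Z_C = pd.get_dummies(tbl["cage"], dtype=float).to_numpy()
    return DesignMatrices(X, Z_L, Z_C, list(tbl.index.astype(str)), names)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def transform_trait(values: np.ndarray, kind: str) -> np.ndarray:
    """The count transformation applied to every microbial trait.

    Genus abundances and diversity indices are standardized (mean 0, sample
    sd 1) before being multiplied by 100 and rounded to the nearest integer
    (half away from zero); CSS-normalized OTU abundances are only scaled and
    rounded, and must be non-negative.
    """
    values = np.asarray(values, dtype=float)
    if kind not in TRAIT_KINDS:
        raise ValueError(f"unknown trait kind {kind!r}")
    if kind == "otu":
        if np.any(values < 0):
            raise ValueError("otu traits (CSS-normalized counts) must be >= 0")
        return _round_half_away(values * 100.0).astype(np.int64)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError(f"constant {kind} trait cannot be standardized")
    z = (values - values.mean()) / sd
    return _round_half_away(z * 100.0).astype(np.int64)


def trait_frequency_class(values: np.ndarray) -> tuple[float, str | None, bool]:
    """Fraction of nonzero records (in percent), its frequency class, and an
    exclusion flag for traits present in fewer than 5% of the animals.

    Returns ``(percent_nonzero, class_label_or_None, excluded)``.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("empty trait vector")
    pct = 100.0 * np.count_nonzero(values) / values.size
    if pct < 5.0:
        return pct, None, True
    for lo, hi, label in FREQUENCY_CLASSES:
        # the lowest bin includes its left edge; the rest are left-open
        if (pct >= lo if lo == 5.0 else pct > lo) and pct <= hi:
            return pct, label, False
    raise AssertionError("unreachable: bins cover [5, 100]")
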