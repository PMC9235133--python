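"""Pedigree handling and the numerator relationship matrix.

The additive ("animal") model needs the expected additive-genetic
relationships among all pedigree members: the numerator relationship
matrix A, with Var(breeding values) = A * sigma2_a.  A is built by the
tabular method on a parent-before-offspring ordering of the pedigree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = "0"


class PedigreeRecord(NamedTuple):
    """One pedigree line: an animal and its sire/dam (``None`` if unknown)."""

    animal: str
    sire: str | None
    dam: str | None


class PedigreeError(ValueError):
    """Raised for malformed pedigrees (duplicates, self-parenting, cycles)."""


def read_pedigree(
    source,
    unknown_code: str = UNKNOWN,
    on_undefined_parent: str = "founder",
) -> list[PedigreeRecord]:
    """Read a 3-column animal/sire/dam table into validated records.

    Parameters
    ----------
    source
        Path or file-like object with comma- or tab-delimited text.  A header
        row is detected by the presence of the column name ``animal``.
    unknown_code
        Token coding an unknown parent (default ``"0"``).
    on_undefined_parent
        ``"founder"`` silently promotes a parent id that never appears in the
        animal column to a founder record (with a logged warning);
        ``"error"`` raises instead.
    """
    df = _read_table(source)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree table needs 3 columns (animal, sire, dam)")
    df = df.iloc[:, :3]
    df.columns = ["animal", "sire", "dam"]

    records: list[PedigreeRecord] = []
    seen: set[str] = set()
    for animal, sire, dam in df.itertuples(index=False):
        animal, sire, dam = str(animal).strip(), str(sire).strip(), str(dam).strip()
        if animal in seen:
            raise PedigreeError(f"duplicate animal id {animal!r}")
        seen.add(animal)
        sire = None if sire == unknown_code else sire
        dam = None if dam == unknown_code else dam
        if animal == sire or animal == dam:
            raise PedigreeError(f"animal {animal!r} listed as its own parent")
        records.append(PedigreeRecord(animal, sire, dam))

    undefined = {p for r in records for p in (r.sire, r.dam) if p is not None} - seen
    if undefined:
        if on_undefined_parent == "error":
            raise PedigreeError(f"parent ids never defined as animals: {sorted(undefined)}")
        logger.warning(
            "promoting %d referenced-but-undefined parent ids to founders: %s",
            len(undefined), sorted(undefined),
        )
        records = [PedigreeRecord(p, None, None) for p in sorted(undefined)] + records

    sort_pedigree(records)  # raises on cycles
    return records


def _read_table(source) -> pd.DataFrame:
    first = Path(source).read_text().splitlines()[0] if isinstance(source, (str, Path)) else None
    kwargs = dict(sep=None, engine="python", dtype=str, comment="#")
    if first is not None and "animal" in first.lower():
        return pd.read_csv(source, **kwargs)
    return pd.read_csv(source, header=None, **kwargs)


def sort_pedigree(records: Sequence[PedigreeRecord]) -> list[PedigreeRecord]:
    """Return records in topological (parents-before-offspring) order.

    The sort is stable: among animals whose parents are already placed, the
    original input order is preserved.  Raises :class:`PedigreeError` on a
    parental cycle.
    """
    by_id = {r.animal: r for r in records}
    order: list[PedigreeRecord] = []
    placed: set[str] = set()
    pending = list(records)
    while pending:
        progressed = False
        remaining = []
        for r in pending:
            parents_ready = all(
                p is None or p not in by_id or p in placed for p in (r.sire, r.dam)
            )
            if parents_ready:
                order.append(r)
                placed.add(r.animal)
                progressed = True
            else:
                remaining.append(r)
        if not progressed:
            raise PedigreeError(
                f"cycle detected among: {sorted(r.animal for r in remaining)}"
            )
        pending = remaining
    return order


@dataclass
class RelationshipMatrix:
    """The numerator relationship matrix A with its animal -> row map."""

    values: np.ndarray
    index: dict[str, int] = field(repr=False)

    @property
    def animals(self) -> list[str]:
        return sorted(self.index, key=self.index.get)

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F_i = a(i,i) - 1."""
        return np.diag(self.values) - 1.0


def build_relationship_matrix(records: Sequence[PedigreeRecord]) -> RelationshipMatrix:
    """Tabular-method A from a sorted pedigree.

    Recursion over the parent-ordered pedigree: for j < i,
    a(i,j) = 0.5*(a(j, s_i) + a(j, d_i)) and a(i,i) = 1 + 0.5*a(s_i, d_i),
    with an unknown parent contributing 0.  Founders are assumed non-inbred.
    """
    index = {r.animal: k for k, r in enumerate(records)}
    n = len(records)
    A = np.zeros((n, n))
    for i, r in enumerate(records):
        si = index.get(r.sire, -1) if r.sire is not None else -1
        di = index.get(r.dam, -1) if r.dam is not None else -1
        if si >= i or di >= i:
            raise PedigreeError("pedigree not sorted: parent after offspring")
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix(values=A, index=index)


def observation_kernel(A: RelationshipMatrix, observed: Sequence[str]) -> np.ndarray:
    """The n x n kernel Z_A A Z_A' for the observed animals (one row each)."""
    try:
        idx = np.array([A.index[a] for a in observed])
    except KeyError as e:
        raise PedigreeError(f"observed animal {e.args[0]!r} absent from pedigree") from e
    return A.values[np.ix_(idx, idx)]
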