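"""Person-by-item response matrices.

Responses are ordinal codes 0/1/2 (no / sometimes / regularly-or-more) held
in a pandas DataFrame indexed by person id, one column per item, NaN marking
a missing cell. A scale map assigns every item to exactly one subscale, and
an optional covariate table (sex, age) travels with the matrix for DIF
screening.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix"]


class ResponseMatrix:
    """Persons x items ordinal codes with scale membership and covariates.

    Parameters
    ----------
    codes : pandas.DataFrame
        Index = person ids, columns = item ids, values in {0, 1, 2} or NaN.
    scale_map : mapping of item id -> scale name
        Must cover every column.
    covariates : pandas.DataFrame, optional
        Indexed by person id with columns ``sex`` (0/1) and ``age``.
    """

    def __init__(
        self,
        codes: pd.DataFrame,
        scale_map: Mapping[str, str],
        covariates: pd.DataFrame | None = None,
    ):
        codes = codes.astype(float)
        vals = codes.to_numpy()
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            bad = np.argwhere(~np.isnan(vals) & ((vals < 0) | (vals > 2)))[0]
            raise ValueError(
                f"response codes must lie in {{0,1,2}}: person "
                f"{codes.index[bad[0]]!r}, item {codes.columns[bad[1]]!r} has "
                f"{vals[bad[0], bad[1]]!r}"
            )
        if finite.size and not np.allclose(finite, np.round(finite)):
            raise ValueError("response codes must be integers (or missing)")
        if codes.columns.duplicated().any():
            dupes = codes.columns[codes.columns.duplicated()].tolist()
            raise ValueError(f"duplicate item columns: {dupes}")
        if codes.index.duplicated().any():
            dupes = codes.index[codes.index.duplicated()].tolist()
            raise ValueError(f"duplicate person ids: {dupes}")
        missing_map = [c for c in codes.columns if c not in scale_map]
        if missing_map:
            raise ValueError(f"items absent from scale_map: {missing_map}")
        self.codes = codes
        self.scale_map = {c: scale_map[c] for c in codes.columns}
        if covariates is not None:
            covariates = covariates.loc[codes.index]
        self.covariates = covariates

    # -- basic views ---------------------------------------------------------
    @property
    def person_ids(self) -> list:
        return list(self.codes.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def n_persons(self) -> int:
        return len(self.codes)

    @property
    def n_items(self) -> int:
        return self.codes.shape[1]

    @property
    def scales(self) -> list[str]:
        out: list[str] = []
        for c in self.codes.columns:
            s = self.scale_map[c]
            if s not in out:
                out.append(s)
        return out

    @property
    def has_missing(self) -> bool:
        return bool(self.codes.isna().to_numpy().any())

    def items_in(self, scale: str) -> list[str]:
        ids = [c for c in self.codes.columns if self.scale_map[c] == scale]
        if not ids:
            raise KeyError(f"unknown scale {scale!r}")
        return ids

    def subset(self, scale: str) -> "ResponseMatrix":
        """Columns of a single scale, persons unchanged."""
        ids = self.items_in(scale)
        return ResponseMatrix(
            self.codes[ids], {i: scale for i in ids}, self.covariates
        )

    def select_persons(self, person_ids: Iterable) -> "ResponseMatrix":
        idx = list(person_ids)
        return ResponseMatrix(
            self.codes.loc[idx],
            self.scale_map,
            None if self.covariates is None else self.covariates.loc[idx],
        )

    def values_for(self, scale: str) -> np.ndarray:
        """Integer code array (persons x scale items); requires completeness."""
        sub = self.codes[self.items_in(scale)]
        if sub.isna().to_numpy().any():
            raise ValueError(
                f"scale {scale!r} contains missing cells; run complete-case "
                "filtering first"
            )
        return sub.to_numpy().astype(int)

    def __repr__(self) -> str:
        return (
            f"ResponseMatrix({self.n_persons} persons x {self.n_items} items, "
            f"scales={self.scales}, missing={self.has_missing})"
        )
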