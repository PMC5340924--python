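"""Item banks for the graded response model.

An item bank holds, for every questionnaire item, its scale membership and
the three GRM parameters: a discrimination (slope) ``alpha`` and two ordered
category thresholds ``beta1 < beta2`` on the latent-trait (theta) metric.
Three-category items (codes 0/1/2) need exactly two thresholds; the bank is
the calibrated measurement model every later stage consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = ["GrmItem", "ItemBank"]


@dataclass(frozen=True)
class GrmItem:
    """A single graded-response item.

    Parameters
    ----------
    item_id : str
        Unique identifier within a bank.
    scale : str
        Name of the subscale the item belongs to (each item belongs to
        exactly one scale).
    alpha : float
        Discrimination: logit slope per unit theta. Must be positive.
    beta1, beta2 : float
        Category thresholds in theta units: the trait levels at which the
        boundary probabilities P(X >= 1) and P(X >= 2) equal one half.
        Must satisfy ``beta1 < beta2``.
    """

    item_id: str
    scale: str
    alpha: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        # normalize numpy scalars so formatting and JSON stay portable
        object.__setattr__(self, "alpha", float(self.alpha))
        object.__setattr__(self, "beta1", float(self.beta1))
        object.__setattr__(self, "beta2", float(self.beta2))
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(
                f"item {self.item_id!r}: alpha must be positive and finite, "
                f"got {self.alpha!r}"
            )
        if not (math.isfinite(self.beta1) and math.isfinite(self.beta2)):
            raise ValueError(f"item {self.item_id!r}: thresholds must be finite")
        if not self.beta1 < self.beta2:
            raise ValueError(
                f"item {self.item_id!r}: thresholds must be ordered "
                f"beta1 < beta2, got ({self.beta1}, {self.beta2})"
            )


class ItemBank:
    """An ordered collection of :class:`GrmItem` with unique ids."""

    def __init__(self, items: Iterable[GrmItem]):
        items = tuple(items)
        if not items:
            raise ValueError("an item bank must contain at least one item")
        seen: set[str] = set()
        for it in items:
            if it.item_id in seen:
                raise ValueError(f"duplicate item id {it.item_id!r}")
            seen.add(it.item_id)
        self._items = items
        self._index = {it.item_id: i for i, it in enumerate(items)}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[GrmItem]:
        return iter(self._items)

    def __getitem__(self, key: int | str) -> GrmItem:
        if isinstance(key, str):
            try:
                return self._items[self._index[key]]
            except KeyError:
                raise KeyError(f"unknown item id {key!r}") from None
        return self._items[key]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ItemBank):
            return NotImplemented
        return self._items == other._items

    def __repr__(self) -> str:
        return f"ItemBank({len(self)} items, scales={self.scales})"

    # -- views ---------------------------------------------------------------
    @property
    def items(self) -> tuple[GrmItem, ...]:
        return self._items

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self._items]

    @property
    def scales(self) -> list[str]:
        """Scale names in first-appearance order."""
        out: list[str] = []
        for it in self._items:
            if it.scale not in out:
                out.append(it.scale)
        return out

    @property
    def scale_map(self) -> dict[str, str]:
        return {it.item_id: it.scale for it in self._items}

    def subset(self, scale: str) -> "ItemBank":
        """Return the sub-bank for one scale, preserving order."""
        items = [it for it in self._items if it.scale == scale]
        if not items:
            raise KeyError(f"unknown scale {scale!r}")
        return ItemBank(items)

    def select(self, item_ids: Iterable[str]) -> "ItemBank":
        """Return a sub-bank containing ``item_ids`` in the given order."""
        return ItemBank(self[i] for i in item_ids)

    # parameter arrays, in bank order
    @property
    def alphas(self) -> np.ndarray:
        return np.array([it.alpha for it in self._items])

    @property
    def betas1(self) -> np.ndarray:
        return np.array([it.beta1 for it in self._items])

    @property
    def betas2(self) -> np.ndarray:
        return np.array([it.beta2 for it in self._items])

    # -- frame conversion ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "scale": [it.scale for it in self._items],
                "alpha": self.alphas,
                "beta1": self.betas1,
                "beta2": self.betas2,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ItemBank":
        required = {"item_id", "scale", "alpha", "beta1", "beta2"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"item bank table missing columns {sorted(missing)}")
        return cls(
            GrmItem(
                item_id=str(row.item_id),
                scale=str(row.scale),
                alpha=float(row.alpha),
                beta1=float(row.beta1),
                beta2=float(row.beta2),
            )
            for row in frame.itertuples(index=False)
        )
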