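"""Scale metadata, Likert response matrices, and validation.

The built-in fixture describes the combined defeat (16 items) and
entrapment (16 items) questionnaire battery: every item is answered on a
five-point scale from "never" (0) to "always" (4).  Three defeat items are
positively worded and hence reverse-coded when a total score is wanted;
reverse-coding is deliberately *not* applied automatically before network
or factor analyses (see :func:`reverse_code`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Scale",
    "Subscale",
    "ItemMeta",
    "ScaleDefinition",
    "ItemResponseMatrix",
    "ValidationError",
    "SchemaError",
    "DS_ES_32",
    "load_responses",
    "write_responses",
    "reverse_code",
    "minimum_sample_rule",
]


class Scale(str, Enum):
    defeat = "defeat"
    entrapment = "entrapment"


class Subscale(str, Enum):
    defeat = "defeat"
    internal_entrapment = "internal_entrapment"
    external_entrapment = "external_entrapment"


class ValidationError(ValueError):
    """A cell violates the response range or integrality."""


class SchemaError(ValueError):
    """The file's columns do not match the scale definition."""


@dataclass(frozen=True)
class ItemMeta:
    """Metadata for one questionnaire item (1-based index)."""

    item_id: int
    text: str
    scale: Scale
    original_subscale: Subscale
    reverse_coded: bool = False


@dataclass(frozen=True)
class ScaleDefinition:
    """An ordered battery of items with a common integer response range."""

    items: tuple[ItemMeta, ...]
    response_min: int = 0
    response_max: int = 4

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_id values must be unique within a scale")
        if self.response_min >= self.response_max:
            raise ValueError("response_min must be below response_max")

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[int]:
        return [it.item_id for it in self.items]

    @property
    def column_names(self) -> list[str]:
        return [f"item_{it.item_id}" for it in self.items]

    def to_json(self) -> str:
        payload = {
            "response_min": self.response_min,
            "response_max": self.response_max,
            "items": [
                {
                    "id": it.item_id,
                    "text": it.text,
                    "scale": it.scale.value,
                    "subscale": it.original_subscale.value,
                    "reverse": it.reverse_coded,
                }
                for it in self.items
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScaleDefinition":
        payload = json.loads(text)
        items = tuple(
            ItemMeta(
                item_id=d["id"],
                text=d["text"],
                scale=Scale(d["scale"]),
                original_subscale=Subscale(d["subscale"]),
                reverse_coded=bool(d["reverse"]),
            )
            for d in payload["items"]
        )
        return cls(items=items, response_min=payload["response_min"],
                   response_max=payload["response_max"])


@dataclass(frozen=True)
class ItemResponseMatrix:
    """Complete-case participants x items integer responses."""

    values: np.ndarray
    scale: ScaleDefinition
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValidationError("response matrix must be 2-D")
        if v.shape[1] != self.scale.p:
            raise SchemaError(
                f"matrix has {v.shape[1]} columns; scale defines {self.scale.p} items"
            )
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(np.isfinite(v)) or not np.all(v == np.round(v)):
                bad = np.argwhere(~np.isfinite(v) | (v != np.round(v)))
                r, c = bad[0]
                raise ValidationError(
                    f"non-integer cell at row {r}, column {c} "
                    f"(item {self.scale.items[c].item_id})"
                )
            v = v.astype(np.int64)
        lo, hi = self.scale.response_min, self.scale.response_max
        if v.size and (v.min() < lo or v.max() > hi):
            bad = np.argwhere((v < lo) | (v > hi))
            r, c = bad[0]
            raise ValidationError(
                f"value {v[r, c]} at row {r}, column {c} "
                f"(item {self.scale.items[c].item_id}) outside range [{lo}, {hi}]"
            )
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.scale.column_names)


# --- built-in fixture -------------------------------------------------------

_DEFEAT_TEXTS = [
    "I feel that I have not made it in life",
    "I feel that I am a successful person.",
    "I feel defeated by life.",
    "I feel that I am basically a winner.",
    "I feel that I have lost my standing in the world.",
    "I feel that life has treated me like a punch-bag.",
    "I feel powerless.",
    "I feel that my confidence has been knocked out of me.",
    "I feel able to deal with whatever life throws at me.",
    "I feel that I have sunk to the bottom of the ladder.",
    "I feel completely knocked out of action.",
    "I feel that I am one of life's losers.",
    "I feel that I have given up.",
    "I feel down and out.",
    "I feel that I have lost important battles in life.",
    "I feel that there is no fight left in me.",
]

_ENTRAPMENT_TEXTS = [
    "I am in situation I feel trapped in.",
    "I have a strong desire to escape from things in my life.",
    "I am in a relationship I can't get out of.",
    "I often have the feeling that I would just like to run away.",
    "I feel powerless to change things.",
    "I feel trapped by my obligations.",
    "I can see no way out of my current situation.",
    "I would like to get away from other more powerful people in my life.",
    "I have a strong desire to get away and stay away from where I am now.",
    "I feel trapped by other people.",
    "I want to get away from myself.",
    "I feel powerless to change myself.",
    "I would like to escape from my thoughts and feelings.",
    "I feel trapped inside myself.",
    "I would like to get away from who I am and start again.",
    "I feel I'm in a deep hole I can't get out of.",
]

# Positively worded defeat items; a respondent high in defeat disagrees.
_REVERSE_IDS = {2, 4, 9}
# Items 17-26 target entrapment by external circumstances, 27-32 by one's
# own thoughts and feelings.
_EXTERNAL_IDS = set(range(17, 27))


def _build_ds_es_32() -> ScaleDefinition:
    items = []
    for i, text in enumerate(_DEFEAT_TEXTS, start=1):
        items.append(ItemMeta(i, text, Scale.defeat, Subscale.defeat,
                              reverse_coded=i in _REVERSE_IDS))
    for i, text in enumerate(_ENTRAPMENT_TEXTS, start=17):
        sub = (Subscale.external_entrapment if i in _EXTERNAL_IDS
               else Subscale.internal_entrapment)
        items.append(ItemMeta(i, text, Scale.entrapment, sub))
    return ScaleDefinition(items=tuple(items))


#: Built-in 32-item defeat + entrapment battery.
DS_ES_32: ScaleDefinition = _build_ds_es_32()


# --- operations -------------------------------------------------------------

def load_responses(
    path: str | Path,
    scale: ScaleDefinition = DS_ES_32,
    missing_policy: str = "drop_rows",
) -> ItemResponseMatrix:
    """Read a CSV of integer Likert responses and validate it.

    Columns are matched to scale items by header name (``item_<id>``);
    if the headers do not match, positional order is assumed with a
    warning.  ``missing_policy`` is ``"drop_rows"`` (complete cases, the
    count of dropped rows is logged and recorded) or ``"error"``.
    """
    if missing_policy not in ("error", "drop_rows"):
        raise ValueError("missing_policy must be 'error' or 'drop_rows'")
    df = pd.read_csv(path)
    if df.shape[1] != scale.p:
        raise SchemaError(
            f"{path}: found {df.shape[1]} columns, scale defines {scale.p} items"
        )
    expected = scale.column_names
    if set(df.columns) == set(expected):
        df = df[expected]
    else:
        logger.warning(
            "%s: headers do not match item names; matching columns by position",
            path,
        )
    incomplete = df.isna().any(axis=1)
    n_drop = int(incomplete.sum())
    if n_drop:
        if missing_policy == "error":
            row = int(np.flatnonzero(incomplete.to_numpy())[0])
            raise ValidationError(f"missing value in row {row} with policy=error")
        logger.info("%s: dropped %d incomplete rows", path, n_drop)
        df = df.loc[~incomplete]
    values = df.to_numpy()
    return ItemResponseMatrix(values=values, scale=scale, dropped_rows=n_drop)


def write_responses(matrix: ItemResponseMatrix, path: str | Path) -> None:
    """Write a response matrix as CSV with ``item_<id>`` headers."""
    matrix.to_frame().to_csv(path, index=False)


def reverse_code(matrix: ItemResponseMatrix) -> ItemResponseMatrix:
    """Flip reverse-coded items: value -> response_max - value.

    An involution: applying it twice restores the original matrix.  Not
    applied automatically anywhere — analysing raw item responses is what
    lets a wording-effect cluster of positively framed items emerge in the
    network, so recoding is an explicit opt-in.
    """
    v = matrix.values.copy()
    hi = matrix.scale.response_max + matrix.scale.response_min
    for j, item in enumerate(matrix.scale.items):
        if item.reverse_coded:
            v[:, j] = hi - v[:, j]
    return ItemResponseMatrix(values=v, scale=matrix.scale,
                              dropped_rows=matrix.dropped_rows)


def minimum_sample_rule(p: int) -> int:
    """Minimum participants to estimate a p-item network: one per free
    pairwise parameter, p(p-1)/2.  For the 32-item battery this is 496.
    """
    if p < 2:
        raise ValueError("need at least 2 items")
    return p * (p - 1) // 2
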