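"""Item bank schema and the participants-by-items response container.

The instrument is a six-subtest cognitive battery administered as a digital
game: logical reasoning (15 binary items), visuospatial attention (3 items,
continuous in [0, 1]), motion perception (5 binary), phonological awareness
(13 binary), verbal comprehension (17 binary), and working memory (1 item,
a nonnegative continuous span score). 54 items in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "ItemSchema",
    "ItemResponseDataset",
    "default_schema",
    "SUBTEST_LAYOUT",
    "SchemaError",
]

#: (subtest name, item count, measurement scale) in administration order.
SUBTEST_LAYOUT: tuple[tuple[str, int, str], ...] = (
    ("logical", 15, "binary"),
    ("visuospatial", 3, "unit_interval"),
    ("motion", 5, "binary"),
    ("phonological", 13, "binary"),
    ("verbal", 17, "binary"),
    ("working_memory", 1, "nonnegative_continuous"),
)

VALID_SCALES = {"binary", "unit_interval", "nonnegative_continuous"}


class SchemaError(ValueError):
    """Raised when data does not conform to the item schema."""


@dataclass(frozen=True)
class Item:
    name: str
    subtest: str
    scale: str


@dataclass(frozen=True)
class ItemSchema:
    """Ordered item bank; invariant: 54 items with the fixed subtest layout."""

    items: tuple[Item, ...]

    def __post_init__(self) -> None:
        for it in self.items:
            if it.scale not in VALID_SCALES:
                raise SchemaError(f"unknown scale {it.scale!r} for item {it.name}")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def binary_mask(self) -> np.ndarray:
        return np.array([it.scale == "binary" for it in self.items])

    @property
    def continuous_mask(self) -> np.ndarray:
        return ~self.binary_mask

    @property
    def scales(self) -> list[str]:
        return [it.scale for it in self.items]

    def subtest_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for it in self.items:
            counts[it.subtest] = counts.get(it.subtest, 0) + 1
        return counts


def default_schema() -> ItemSchema:
    """The 54-item battery: columns named ``<subtest>_<k>`` with k starting at 1."""
    items: list[Item] = []
    for subtest, count, scale in SUBTEST_LAYOUT:
        for k in range(1, count + 1):
            items.append(Item(name=f"{subtest}_{k}", subtest=subtest, scale=scale))
    return ItemSchema(items=tuple(items))


@dataclass
class ItemResponseDataset:
    """Participants × items responses plus age in years.

    ``responses`` is an (n, 54) float array ordered as in ``schema``;
    ``ages`` is an (n,) float vector. Optional ground-truth labels from a
    generator are carried for recovery tests but never used in fitting.
    """

    responses: np.ndarray
    ages: np.ndarray
    schema: ItemSchema = field(default_factory=default_schema)
    participant_ids: np.ndarray | None = None
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.responses.ndim != 2:
            raise SchemaError("responses must be 2-dimensional")
        if self.responses.shape[0] != self.ages.shape[0]:
            raise SchemaError("responses and ages disagree on n")
        if self.participant_ids is None:
            self.participant_ids = np.arange(self.responses.shape[0])
        self.validate()

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    def validate(self) -> None:
        if self.responses.shape[1] != self.schema.n_items:
            raise SchemaError(
                f"expected {self.schema.n_items} item columns, "
                f"got {self.responses.shape[1]}"
            )
        if np.any(self.ages < 0):
            raise SchemaError("negative age encountered")
        for j, it in enumerate(self.schema.items):
            col = self.responses[:, j]
            if it.scale == "binary":
                bad = ~np.isin(col, (0.0, 1.0))
                if bad.any():
                    raise SchemaError(
                        f"binary column {it.name!r} contains non-0/1 value "
                        f"{col[bad][0]!r}"
                    )
            elif it.scale == "unit_interval":
                if np.any((col < 0) | (col > 1)):
                    raise SchemaError(f"column {it.name!r} outside [0, 1]")
            else:  # nonnegative_continuous
                if np.any(col < 0):
                    raise SchemaError(f"column {it.name!r} has negative values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.schema.item_names)
        df.insert(0, "age", self.ages)
        df.insert(0, "participant_id", self.participant_ids)
        return df

    def to_csv(self, path, labels_path=None) -> None:
        self.to_frame().to_csv(path, index=False)
        if labels_path is not None and self.true_labels is not None:
            pd.DataFrame(
                {"participant_id": self.participant_ids, "label": self.true_labels}
            ).to_csv(labels_path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, schema: ItemSchema | None = None
    ) -> "ItemResponseDataset":
        schema = schema or default_schema()
        required = ["participant_id", "age"] + schema.item_names
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        extra = [c for c in df.columns if c not in required]
        if extra:
            raise SchemaError(f"unexpected columns: {extra}")
        return cls(
            responses=df[schema.item_names].to_numpy(dtype=float),
            ages=df["age"].to_numpy(dtype=float),
            schema=schema,
            participant_ids=df["participant_id"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path, schema: ItemSchema | None = None) -> "ItemResponseDataset":
        return cls.from_frame(pd.read_csv(path), schema=schema)
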