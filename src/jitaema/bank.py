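"""Graded-response-model item banks: validation, I/O, synthetic generation.

An item bank is an ordered collection of polytomous questions calibrated
under the graded response model (GRM).  Each item carries a discrimination
(slope) parameter ``a > 0`` and ``K - 1`` strictly increasing threshold
parameters on the z-standardized latent metric.  Banks can be read from and
written to CSV or JSON, and a synthetic generator emulates a fatigue-style
bank (by default 13 items with five response categories) for simulation
work when published calibrations are not at hand.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Item",
    "ItemBank",
    "BankValidationError",
    "BankFormatError",
    "load_bank",
    "save_bank",
    "generate_synthetic_bank",
]


class BankValidationError(ValueError):
    """An item or bank violates a GRM invariant (names the offending item)."""


class BankFormatError(ValueError):
    """A bank file could not be parsed (names the offending row/field)."""


@dataclass(frozen=True)
class Item:
    """One GRM item: discrimination ``a`` and ordered thresholds ``b``.

    Parameters are on the z-standardized latent metric.  ``thresholds`` has
    length ``n_categories - 1``; responses are 1-based categories in
    ``{1, ..., n_categories}``.
    """

    item_id: str
    discrimination: float
    thresholds: tuple[float, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(float(b) for b in self.thresholds))
        object.__setattr__(self, "discrimination", float(self.discrimination))
        if not np.isfinite(self.discrimination) or self.discrimination <= 0:
            raise BankValidationError(
                f"item {self.item_id!r}: discrimination must be > 0, got {self.discrimination}"
            )
        if len(self.thresholds) < 1:
            raise BankValidationError(
                f"item {self.item_id!r}: needs at least one threshold (K >= 2)"
            )
        diffs = np.diff(self.thresholds)
        if len(diffs) and not np.all(diffs > 0):
            raise BankValidationError(
                f"item {self.item_id!r}: thresholds must be strictly increasing, got {self.thresholds}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass
class ItemBank:
    """Ordered collection of :class:`Item` sharing one latent metric."""

    items: list[Item]
    name: str = "bank"
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise BankValidationError(f"duplicate item_ids in bank: {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def max_categories(self) -> int:
        return max(it.n_categories for it in self.items)


# ---------------------------------------------------------------------------
# File I/O.  CSV schema: item_id,model,n_categories,a,b1..b{K-1},label with
# model fixed to "graded".  JSON mirrors the same fields per item.
# ---------------------------------------------------------------------------


def _csv_header(max_k: int) -> list[str]:
    return (
        ["item_id", "model", "n_categories", "a"]
        + [f"b{i}" for i in range(1, max_k)]
        + ["label"]
    )


def save_bank(bank: ItemBank, path, format: str = "csv") -> None:
    """Write ``bank`` to ``path`` in ``csv`` or ``json`` format.

    The written file round-trips through :func:`load_bank` with full
    parameter precision (floats are serialized with ``repr``).
    """
    if format == "csv":
        max_k = bank.max_categories() if len(bank) else 2
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_csv_header(max_k))
            for it in bank:
                row = [it.item_id, "graded", it.n_categories, repr(it.discrimination)]
                row += [repr(b) for b in it.thresholds]
                row += [""] * (max_k - it.n_categories)
                row.append(it.label or "")
                writer.writerow(row)
    elif format == "json":
        payload = {
            "name": bank.name,
            "metadata": bank.metadata,
            "items": [
                {
                    "item_id": it.item_id,
                    "model": "graded",
                    "n_categories": it.n_categories,
                    "a": it.discrimination,
                    "b": list(it.thresholds),
                    "label": it.label,
                }
                for it in bank
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")


def load_bank(path, format: str = "csv") -> ItemBank:
    """Read an item bank from ``path`` (see module docstring for schemas)."""
    if format == "csv":
        return _load_csv(path)
    if format == "json":
        return _load_json(path)
    raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")


def _load_csv(path) -> ItemBank:
    items: list[Item] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "item_id" not in reader.fieldnames:
            raise BankFormatError(f"{path}: missing header with item_id column")
        for lineno, row in enumerate(reader, start=2):
            try:
                model = (row.get("model") or "graded").strip()
                if model != "graded":
                    raise BankFormatError(
                        f"{path} row {lineno}: unsupported model {model!r}"
                    )
                k = int(row["n_categories"])
                a = float(row["a"])
                bs = []
                for i in range(1, k):
                    cell = row.get(f"b{i}")
                    if cell is None or cell == "":
                        raise BankFormatError(
                            f"{path} row {lineno}: missing field b{i} for K={k}"
                        )
                    bs.append(float(cell))
            except BankFormatError:
                raise
            except (KeyError, TypeError, ValueError) as exc:
                raise BankFormatError(f"{path} row {lineno}: {exc}") from exc
            label = (row.get("label") or "").strip() or None
            items.append(Item(row["item_id"], a, tuple(bs), label))
    return ItemBank(items=items, name=str(path))


def _load_json(path) -> ItemBank:
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise BankFormatError(f"{path}: invalid JSON ({exc})") from exc
    items = []
    for i, entry in enumerate(payload.get("items", [])):
        try:
            items.append(
                Item(
                    entry["item_id"],
                    float(entry["a"]),
                    tuple(float(b) for b in entry["b"]),
                    entry.get("label"),
                )
            )
        except BankValidationError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise BankFormatError(f"{path} items[{i}]: {exc}") from exc
    return ItemBank(
        items=items,
        name=payload.get("name", str(path)),
        metadata=dict(payload.get("metadata", {})),
    )


# ---------------------------------------------------------------------------
# Synthetic bank generation
# ---------------------------------------------------------------------------


def generate_synthetic_bank(
    n_items: int = 13,
    n_categories: int = 5,
    a_range: tuple[float, float] = (1.5, 3.5),
    b_center_range: tuple[float, float] = (-1.0, 2.0),
    b_spread: float = 0.8,
    seed: int = 0,
    name: str = "synthetic-fatigue",
) -> ItemBank:
    """Generate a synthetic GRM bank emulating a momentary-fatigue scale.

    Defaults produce a 13-item five-category bank with discriminations
    uniform on ``a_range`` and threshold centers uniform on
    ``b_center_range`` — fatigue banks are typically calibrated to be most
    informative above average severity, hence the asymmetric center range.
    Each item's ``K - 1`` thresholds are evenly spaced around its center
    with total spacing governed by ``b_spread`` plus a small jittering so
    no two items are identical.  Deterministic given ``seed``.
    """
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    if n_categories < 2:
        raise ValueError(f"n_categories must be >= 2, got {n_categories}")
    if not (a_range[0] > 0 and a_range[1] >= a_range[0]):
        raise ValueError(f"invalid a_range {a_range}")
    if b_center_range[1] < b_center_range[0]:
        raise ValueError(f"invalid b_center_range {b_center_range}")
    if b_spread <= 0:
        raise ValueError(f"b_spread must be > 0, got {b_spread}")

    rng = np.random.default_rng(seed)
    width = max(1, n_items)
    a_vals = rng.uniform(a_range[0], a_range[1], size=n_items)
    centers = rng.uniform(b_center_range[0], b_center_range[1], size=n_items)
    items = []
    pad = len(str(width))
    for j in range(n_items):
        if n_categories == 2:
            bs = np.array([centers[j]])
        else:
            offsets = np.linspace(-b_spread, b_spread, n_categories - 1)
            # jitter gaps multiplicatively, preserving strict ordering
            gaps = np.diff(offsets) * rng.uniform(0.6, 1.4, size=n_categories - 2)
            bs = centers[j] + offsets[0] + np.concatenate([[0.0], np.cumsum(gaps)])
        items.append(Item(f"item{j + 1:0{pad}d}", a_vals[j], tuple(bs)))
    return ItemBank(items=items, name=name, metadata={"generator_seed": str(seed)})
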