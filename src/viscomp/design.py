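"""2AFC comparison designs and comparison/rating table I/O.

A design is a list of trials; each trial shows an observer two items and
records which one was judged more complex.  Designs are balanced so that
every item takes part in approximately the same number of comparisons and
every observer judges approximately the same number of trials, mirroring a
crowdsourced pairwise-comparison experiment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidDesignError, ValidationError

__all__ = [
    "ComparisonRecord",
    "DesignSpec",
    "generate_design",
    "read_comparisons",
    "write_comparisons",
    "read_ratings",
    "write_ratings",
]

COMPARISON_HEADER = ["observer_id", "item_a", "item_b", "chosen"]
RATING_HEADER = ["item_id", "mu", "sigma"]


@dataclass(frozen=True)
class ComparisonRecord:
    """One 2AFC trial: a pair of items, the observer, and (optionally) the choice.

    ``item_a`` vs ``item_b`` is presentation order only and carries no meaning.
    ``chosen`` is ``None`` for a design that has not been run yet.
    """

    observer_id: str
    item_a: str
    item_b: str
    chosen: str | None = None
    trial_index: int | None = None

    def __post_init__(self) -> None:
        if self.item_a == self.item_b:
            raise ValidationError(f"comparison pairs an item with itself: {self.item_a!r}")
        if self.chosen is not None and self.chosen not in (self.item_a, self.item_b):
            raise ValidationError(
                f"chosen item {self.chosen!r} is neither {self.item_a!r} nor {self.item_b!r}"
            )
        if self.trial_index is not None and self.trial_index < 0:
            raise ValidationError("trial_index must be non-negative")

    def with_choice(self, chosen: str) -> "ComparisonRecord":
        return replace(self, chosen=chosen)


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of a balanced random pairing design."""

    n_items: int
    n_comparisons: int
    n_observers: int = 1
    seed: int = 0
    item_ids: Sequence[str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_comparisons < 1:
            raise InvalidDesignError("n_comparisons must be >= 1")
        if self.n_observers < 1:
            raise InvalidDesignError("n_observers must be >= 1")
        if self.item_ids is not None and len(self.item_ids) != self.n_items:
            raise InvalidDesignError("item_ids length must equal n_items")


def default_item_ids(n_items: int) -> list[str]:
    width = max(4, len(str(n_items - 1)))
    return [f"item{i:0{width}d}" for i in range(n_items)]


def generate_design(spec: DesignSpec) -> list[ComparisonRecord]:
    """Build a balanced list of unanswered comparisons.

    Pairs are drawn in rounds of random near-perfect matchings, always serving
    the items with the lowest participation first, so that every item's
    participation count stays within one of the mean 2*n_comparisons/n_items.
    A pair repeats only when every pair available to the lowest-participation
    item has already been used.  Comparisons are dealt round-robin to
    observers, so observer loads differ by at most one.  Deterministic for a
    given seed.
    """
    if spec.n_items < 2:
        raise InvalidDesignError("a comparison design needs at least 2 items")
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_items, spec.n_comparisons
    items = list(spec.item_ids) if spec.item_ids is not None else default_item_ids(n)

    counts = np.zeros(n, dtype=np.int64)
    used: set[tuple[int, int]] = set()
    all_pairs = n * (n - 1) // 2
    pairs: list[tuple[int, int]] = []

    while len(pairs) < m:
        # order items by participation, random tie-break within equal counts
        order = np.lexsort((rng.random(n), counts)).tolist()
        while order and len(pairs) < m:
            if len(order) < 2:
                break  # odd leftover sits this round out
            a = order.pop(0)
            partner_pos = None
            for pos, b in enumerate(order):
                key = (a, b) if a < b else (b, a)
                if key not in used:
                    partner_pos = pos
                    break
            if partner_pos is None:
                # every pair involving `a` is exhausted; refill the pool if it
                # is globally exhausted, else just allow the repeat
                if len(used) >= all_pairs:
                    used.clear()
                partner_pos = 0
            b = order.pop(partner_pos)
            key = (a, b) if a < b else (b, a)
            used.add(key)
            counts[a] += 1
            counts[b] += 1
            # randomise presentation order within the pair
            pairs.append((a, b) if rng.random() < 0.5 else (b, a))

    observer_width = max(2, len(str(spec.n_observers - 1)))
    records = [
        ComparisonRecord(
            observer_id=f"obs{(t % spec.n_observers):0{observer_width}d}",
            item_a=items[a],
            item_b=items[b],
            trial_index=t,
        )
        for t, (a, b) in enumerate(pairs)
    ]
    return records


def participation_counts(records: Iterable[ComparisonRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.item_a] = counts.get(rec.item_a, 0) + 1
        counts[rec.item_b] = counts.get(rec.item_b, 0) + 1
    return counts


def write_comparisons(records: Iterable[ComparisonRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COMPARISON_HEADER)
        for rec in records:
            writer.writerow([rec.observer_id, rec.item_a, rec.item_b, rec.chosen or ""])


def read_comparisons(path: str | Path) -> list[ComparisonRecord]:
    """Read a comparison CSV, reporting malformed rows with their line numbers."""
    records: list[ComparisonRecord] = []
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file, expected header {COMPARISON_HEADER}")
        if [h.strip() for h in header] != COMPARISON_HEADER:
            raise ValidationError(f"{path}: bad header {header!r}, expected {COMPARISON_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                problems.append(f"line {lineno}: expected 4 fields, got {len(row)}")
                continue
            observer, a, b, chosen = (c.strip() for c in row)
            try:
                records.append(
                    ComparisonRecord(observer, a, b, chosen or None, trial_index=lineno - 2)
                )
            except ValidationError as exc:
                problems.append(f"line {lineno}: {exc}")
    if problems:
        raise ValidationError(f"{path}: invalid comparison rows:\n  " + "\n  ".join(problems))
    return records


def write_ratings(ratings: dict[str, tuple[float, float]], path: str | Path) -> None:
    """Write an item_id,mu,sigma table (values as repr round-trippable floats)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RATING_HEADER)
        for item_id, (mu, sigma) in ratings.items():
            writer.writerow([item_id, repr(float(mu)), repr(float(sigma))])


def read_ratings(path: str | Path) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != RATING_HEADER:
            raise ValidationError(f"{path}: bad header {header!r}, expected {RATING_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise ValidationError(f"{path}: line {lineno}: expected 3 fields")
            try:
                out[row[0].strip()] = (float(row[1]), float(row[2]))
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return out
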