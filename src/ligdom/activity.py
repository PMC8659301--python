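"""Construction of the labeled compound-target interaction dataset.

Raw bioactivity records (one xC50-type measurement in μM per row, possibly
from several sources) are collapsed into a consistent set of labeled
(compound, target) pairs:

* pairs with a median activity below 10 μM are **active**,
* pairs above 20 μM are **inactive**,
* the 10-20 μM band is ambiguous and discarded.

Duplicate measurements for the same pair are aggregated by the median
*before* classification, so a pair receives exactly one label.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from statistics import median
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ACTIVE_THRESHOLD_UM = 10.0
INACTIVE_THRESHOLD_UM = 20.0

BIOACTIVITY_COLUMNS = ["compound_id", "smiles", "target_accession", "activity_um", "source"]


class ActivityLabel(Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class BioactivityRecord:
    """A single experimentally measured compound-target activity."""

    compound_id: str
    smiles: str | None
    target_id: str
    activity_um: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.compound_id or not self.target_id:
            raise ValueError("compound_id and target_id must be non-empty")
        if not math.isfinite(self.activity_um) or self.activity_um <= 0:
            raise ValueError(f"activity must be a positive, finite μM value, got {self.activity_um!r}")


def classify_activity(
    activity_um: float,
    active_threshold: float = ACTIVE_THRESHOLD_UM,
    inactive_threshold: float = INACTIVE_THRESHOLD_UM,
) -> ActivityLabel:
    """Classify a μM activity into the active / ambiguous / inactive bands.

    Strictly below 10 μM is active, strictly above 20 μM is inactive; the
    closed band [10, 20] μM (including both boundaries) is ambiguous.
    """
    if not math.isfinite(activity_um) or activity_um <= 0:
        raise ValueError(f"activity must be a positive, finite μM value, got {activity_um!r}")
    if activity_um < active_threshold:
        return ActivityLabel.ACTIVE
    if activity_um > inactive_threshold:
        return ActivityLabel.INACTIVE
    return ActivityLabel.AMBIGUOUS


def aggregate_duplicates(values: Sequence[float]) -> float:
    """Median of replicate activity values (mean of the two central values
    for even counts)."""
    if len(values) == 0:
        raise ValueError("cannot aggregate an empty list of activities")
    return float(median(values))


@dataclass
class InteractionDataset:
    """Consistent labeled (compound, target) pairs with per-compound indexes."""

    actives: dict[str, set[str]] = field(default_factory=dict)
    inactives: dict[str, set[str]] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def add(self, compound_id: str, target_id: str, label: ActivityLabel) -> None:
        if label is ActivityLabel.ACTIVE:
            self.actives.setdefault(compound_id, set()).add(target_id)
        elif label is ActivityLabel.INACTIVE:
            self.inactives.setdefault(compound_id, set()).add(target_id)
        else:
            raise ValueError("AMBIGUOUS pairs are never stored")

    def active_targets(self, compound_id: str) -> set[str]:
        return self.actives.get(compound_id, set())

    def inactive_targets(self, compound_id: str) -> set[str]:
        return self.inactives.get(compound_id, set())

    @property
    def compounds(self) -> set[str]:
        return set(self.actives) | set(self.inactives)

    @property
    def pairs(self) -> set[tuple[str, str, ActivityLabel]]:
        out: set[tuple[str, str, ActivityLabel]] = set()
        for c, targets in self.actives.items():
            out.update((c, t, ActivityLabel.ACTIVE) for t in targets)
        for c, targets in self.inactives.items():
            out.update((c, t, ActivityLabel.INACTIVE) for t in targets)
        return out

    def known_pairs(self) -> set[tuple[str, str]]:
        """All (compound, target) pairs recorded with either label."""
        return {(c, t) for c, t, _ in self.pairs}

    def __len__(self) -> int:
        return sum(len(v) for v in self.actives.values()) + sum(len(v) for v in self.inactives.values())


def build_dataset(
    records: Iterable[BioactivityRecord],
    dedup_scope: str = "global",
    active_threshold: float = ACTIVE_THRESHOLD_UM,
    inactive_threshold: float = INACTIVE_THRESHOLD_UM,
) -> InteractionDataset:
    """Aggregate raw records into a consistent :class:`InteractionDataset`.

    With ``dedup_scope='global'`` (default) the median is taken over all
    sources jointly per (compound, target) pair, which makes contradictory
    labels impossible by construction. With ``'per_source'`` each source is
    aggregated and classified separately and pairs that end up with both
    labels are dropped (the conservative reading of a two-stage merge).
    """
    if dedup_scope not in ("global", "per_source"):
        raise ValueError(f"dedup_scope must be 'global' or 'per_source', got {dedup_scope!r}")

    by_pair: dict[tuple[str, str], dict[str, list[float]]] = {}
    n_records = 0
    for rec in records:
        n_records += 1
        key = rec.compound_id, rec.target_id
        source = rec.source if dedup_scope == "per_source" else ""
        by_pair.setdefault(key, {}).setdefault(source, []).append(rec.activity_um)

    dataset = InteractionDataset()
    n_ambiguous = 0
    n_contradictions = 0
    for (compound_id, target_id), per_source in sorted(by_pair.items()):
        labels = set()
        for values in per_source.values():
            label = classify_activity(aggregate_duplicates(values), active_threshold, inactive_threshold)
            if label is not ActivityLabel.AMBIGUOUS:
                labels.add(label)
        if not labels:
            n_ambiguous += 1
            continue
        if len(labels) > 1:
            n_contradictions += 1
            logger.warning("contradictory labels for pair (%s, %s); dropped", compound_id, target_id)
            continue
        dataset.add(compound_id, target_id, labels.pop())

    dataset.summary = {
        "n_records": n_records,
        "n_pairs": len(dataset),
        "n_actives": sum(len(v) for v in dataset.actives.values()),
        "n_inactives": sum(len(v) for v in dataset.inactives.values()),
        "n_dropped_ambiguous": n_ambiguous,
        "n_dropped_contradictions": n_contradictions,
    }
    return dataset


def read_bioactivity_tsv(path) -> list[BioactivityRecord]:
    """Read tab-separated bioactivity records.

    Expected columns: ``compound_id  smiles  target_accession  activity_um
    source`` with a header row; '#' lines are comments. Malformed rows are
    skipped with a warning and counted in the log summary.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(BIOACTIVITY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"bioactivity table {path} lacks columns: {sorted(missing)}")

    records: list[BioactivityRecord] = []
    n_skipped = 0
    for row in frame.itertuples(index=False):
        try:
            smiles = getattr(row, "smiles")
            records.append(
                BioactivityRecord(
                    compound_id=str(row.compound_id),
                    smiles=None if pd.isna(smiles) else str(smiles),
                    target_id=str(row.target_accession),
                    activity_um=float(row.activity_um),
                    source=str(row.source),
                )
            )
        except (TypeError, ValueError) as exc:
            n_skipped += 1
            logger.warning("skipping malformed bioactivity row %r: %s", tuple(row), exc)
    if n_skipped:
        logger.warning("skipped %d malformed bioactivity rows in %s", n_skipped, path)
    return records


def write_dataset_tsv(dataset: InteractionDataset, path, summary_path=None) -> None:
    """Serialize the labeled pairs as TSV, plus an optional JSON run summary."""
    rows = sorted((c, t, label.value) for c, t, label in dataset.pairs)
    frame = pd.DataFrame(rows, columns=["compound_id", "target_accession", "label"])
    frame.to_csv(path, sep="\t", index=False)
    if summary_path is not None:
        with open(summary_path, "w") as handle:
            json.dump(dataset.summary, handle, indent=2, sort_keys=True)


def read_dataset_tsv(path) -> InteractionDataset:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    dataset = InteractionDataset()
    for row in frame.itertuples(index=False):
        dataset.add(str(row.compound_id), str(row.target_accession), ActivityLabel(row.label))
    dataset.summary = {"n_pairs": len(dataset)}
    return dataset
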