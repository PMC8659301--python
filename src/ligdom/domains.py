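"""Protein domain architectures, unordered domain pairs, and hierarchy queries.

Proteins are represented by their ordered domain hits (InterPro-export
style: accession, domain id, 1-based inclusive start/end). Pair features
follow a "bag of domains" reading: order and positions are ignored, only
the set of distinct domain ids matters. The domain hierarchy groups related
entries under a common root; two domains are considered interchangeable for
hierarchy-aware scoring when they share a root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator

import pandas as pd


@dataclass(frozen=True)
class DomainHit:
    domain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise ValueError("domain_id must be non-empty")
        if self.start > self.end:
            raise ValueError(f"domain hit start {self.start} > end {self.end}")


@dataclass
class ProteinRecord:
    """A protein accession with its ordered domain annotation."""

    accession: str
    domain_hits: list[DomainHit]

    def __post_init__(self) -> None:
        self.domain_hits = sorted(self.domain_hits, key=lambda h: (h.start, h.end, h.domain_id))

    @property
    def domain_ids(self) -> frozenset[str]:
        return frozenset(h.domain_id for h in self.domain_hits)

    @property
    def architecture(self) -> tuple[str, ...]:
        """Linear arrangement of domain hits along the sequence."""
        return tuple(h.domain_id for h in self.domain_hits)


@dataclass(frozen=True)
class DomainFeature:
    """A single domain or an unordered pair of distinct domains."""

    domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.domains) not in (1, 2):
            raise ValueError("a feature holds one domain or a pair")
        if len(self.domains) == 2 and self.domains[0] == self.domains[1]:
            raise ValueError("pair features hold two distinct domain ids")
        object.__setattr__(self, "domains", tuple(sorted(self.domains)))

    @classmethod
    def single(cls, domain_id: str) -> "DomainFeature":
        return cls((domain_id,))

    @classmethod
    def pair(cls, d1: str, d2: str) -> "DomainFeature":
        return cls((d1, d2))

    @property
    def is_pair(self) -> bool:
        return len(self.domains) == 2

    def __str__(self) -> str:
        return "+".join(self.domains)

    @classmethod
    def parse(cls, text: str) -> "DomainFeature":
        return cls(tuple(text.split("+")))


class DomainHierarchy:
    """Parent map over domain ids; unknown ids are their own roots."""

    def __init__(self, parent: dict[str, str] | None = None):
        self._parent = dict(parent or {})
        self._root_cache: dict[str, str] = {}

    def root(self, domain_id: str) -> str:
        cached = self._root_cache.get(domain_id)
        if cached is not None:
            return cached
        chain = []
        current = domain_id
        while True:
            parent = self._parent.get(current, current)
            if parent == current:
                break
            chain.append(current)
            current = parent
            if current in chain:
                raise ValueError(f"cycle in domain hierarchy at {current!r}")
        for node in chain:
            self._root_cache[node] = current
        self._root_cache[domain_id] = current
        return current

    def roots_of(self, domain_ids: Iterable[str]) -> frozenset[str]:
        return frozenset(self.root(d) for d in domain_ids)

    def __contains__(self, domain_id: str) -> bool:
        return domain_id in self._parent


def same_hierarchy(d1: str, d2: str, hierarchy: DomainHierarchy) -> bool:
    """True iff the two domains sit in the same hierarchy tree (shared root)."""
    return hierarchy.root(d1) == hierarchy.root(d2)


def enumerate_domain_pairs(protein: ProteinRecord) -> set[DomainFeature]:
    """All unordered pairs of distinct domain ids present on a protein.

    Order, positions and copy numbers are ignored; a protein with k distinct
    domain ids yields k*(k-1)/2 pair features.
    """
    return {DomainFeature.pair(a, b) for a, b in combinations(sorted(protein.domain_ids), 2)}


class Proteome:
    """Indexed collection of :class:`ProteinRecord`."""

    def __init__(self, proteins: Iterable[ProteinRecord]):
        self._records: dict[str, ProteinRecord] = {}
        for p in proteins:
            if p.accession in self._records:
                raise ValueError(f"duplicate protein accession {p.accession!r}")
            self._records[p.accession] = p
        self._domain_sets = {acc: p.domain_ids for acc, p in self._records.items()}

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._records[accession]

    @property
    def accessions(self) -> set[str]:
        return set(self._records)

    def domain_set(self, accession: str) -> frozenset[str]:
        try:
            return self._domain_sets[accession]
        except KeyError:
            raise KeyError(f"unknown protein accession {accession!r}") from None

    def root_sets(self, hierarchy: DomainHierarchy) -> dict[str, frozenset[str]]:
        """Per protein, the set of hierarchy roots of its domains."""
        return {acc: hierarchy.roots_of(dset) for acc, dset in self._domain_sets.items()}

    def all_domains(self) -> set[str]:
        out: set[str] = set()
        for dset in self._domain_sets.values():
            out.update(dset)
        return out


def contains_feature(domain_set: frozenset[str], feature: DomainFeature) -> bool:
    """Exact containment: all ids of the feature are present on the protein."""
    if feature.is_pair:
        return feature.domains[0] in domain_set and feature.domains[1] in domain_set
    return feature.domains[0] in domain_set


def proteins_with_feature(proteome: Proteome, feature: DomainFeature) -> set[str]:
    """Accessions of proteins containing the feature (both ids for a pair)."""
    return {acc for acc in proteome.accessions if contains_feature(proteome.domain_set(acc), feature)}


def read_annotations_tsv(path) -> Proteome:
    """Read domain annotations: ``accession  domain_id  start  end [entry_type]``.

    When the optional ``entry_type`` column is present only rows labeled
    ``Domain`` are kept (families, sites etc. are assumed handled upstream
    otherwise).
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"accession", "domain_id", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"annotation table {path} lacks columns: {sorted(missing)}")
    if "entry_type" in frame.columns:
        frame = frame[frame["entry_type"] == "Domain"]

    hits: dict[str, list[DomainHit]] = {}
    for row in frame.itertuples(index=False):
        hits.setdefault(str(row.accession), []).append(
            DomainHit(domain_id=str(row.domain_id), start=int(row.start), end=int(row.end))
        )
    return Proteome(ProteinRecord(acc, hlist) for acc, hlist in hits.items())


def write_annotations_tsv(proteome: Proteome, path) -> None:
    rows = [
        (p.accession, h.domain_id, h.start, h.end, "Domain")
        for p in proteome
        for h in p.domain_hits
    ]
    frame = pd.DataFrame(rows, columns=["accession", "domain_id", "start", "end", "entry_type"])
    frame.sort_values(["accession", "start", "domain_id"]).to_csv(path, sep="\t", index=False)


def read_hierarchy_tsv(path) -> DomainHierarchy:
    """Read the hierarchy table: ``domain_id  parent_id`` (roots may list
    themselves or be omitted)."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"domain_id", "parent_id"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"hierarchy table {path} lacks columns: {sorted(missing)}")
    parent = {str(r.domain_id): str(r.parent_id) for r in frame.itertuples(index=False)}
    return DomainHierarchy(parent)


def write_hierarchy_tsv(hierarchy: DomainHierarchy, path) -> None:
    rows = sorted(hierarchy._parent.items())
    pd.DataFrame(rows, columns=["domain_id", "parent_id"]).to_csv(path, sep="\t", index=False)
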