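"""Circular fingerprints, Tanimoto similarity, and compound clustering.

Compounds are described by extended-connectivity fingerprints with radius 2
(ECFP4), folded to a fixed length (2048 bits by default), computed with
RDKit's Morgan generator. Clustering at Tanimoto >= 0.7 produces one
(possibly overlapping) cluster per seed compound; neighbor queries at
>= 0.8 drive similarity-based propagation of predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter goes through our own warnings

DEFAULT_N_BITS = 2048
DEFAULT_RADIUS = 2  # radius 2 == "ECFP4" (diameter 4)
CLUSTER_TANIMOTO = 0.7
PROPAGATE_TANIMOTO = 0.8


@dataclass
class Fingerprint:
    compound_id: str
    bits: ExplicitBitVect

    @property
    def n_bits(self) -> int:
        return self.bits.GetNumBits()

    @classmethod
    def from_on_bits(cls, compound_id: str, on_bits: Iterable[int], n_bits: int = DEFAULT_N_BITS) -> "Fingerprint":
        bv = ExplicitBitVect(n_bits)
        for b in on_bits:
            bv.SetBit(int(b))
        return cls(compound_id, bv)

    def to_hex(self) -> str:
        return _bitvect_to_hex(self.bits)

    @classmethod
    def from_hex(cls, compound_id: str, hex_string: str, n_bits: int) -> "Fingerprint":
        return cls(compound_id, _hex_to_bitvect(hex_string, n_bits))


def _bitvect_to_hex(bv: ExplicitBitVect) -> str:
    n = bv.GetNumBits()
    data = bytearray((n + 7) // 8)
    for b in bv.GetOnBits():
        data[b // 8] |= 1 << (b % 8)
    return data.hex()


def _hex_to_bitvect(hex_string: str, n_bits: int) -> ExplicitBitVect:
    data = bytes.fromhex(hex_string)
    bv = ExplicitBitVect(n_bits)
    for byte_index, byte in enumerate(data):
        if byte:
            for bit in range(8):
                if byte & (1 << bit):
                    bv.SetBit(byte_index * 8 + bit)
    return bv


_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return _GENERATORS[key]


def fingerprint(
    smiles: str,
    compound_id: str = "",
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> Fingerprint:
    """ECFP fingerprint of one SMILES; raises ValueError on unparseable input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {compound_id or 'compound'}: {smiles!r}")
    bv = _generator(radius, n_bits).GetFingerprint(mol)
    return Fingerprint(compound_id or smiles, bv)


def fingerprint_table(
    smiles_by_compound: Mapping[str, str],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> dict[str, Fingerprint]:
    """Fingerprints for a compound library; unparseable SMILES are skipped
    with a warning."""
    out: dict[str, Fingerprint] = {}
    for compound_id, smi in smiles_by_compound.items():
        try:
            out[compound_id] = fingerprint(smi, compound_id, radius=radius, n_bits=n_bits)
        except ValueError as exc:
            logger.warning("%s", exc)
    return out


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a&b| / |a|b|; 0.0 when both vectors are all-zero."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    if a.bits.GetNumOnBits() == 0 and b.bits.GetNumOnBits() == 0:
        return 0.0  # featureless molecules must not cluster as identical
    return float(DataStructs.TanimotoSimilarity(a.bits, b.bits))


@dataclass
class CompoundCluster:
    seed: str
    members: set[str]

    def __post_init__(self) -> None:
        self.members = set(self.members) | {self.seed}


def cluster_compounds(
    fps: Mapping[str, Fingerprint] | Sequence[Fingerprint],
    threshold: float = CLUSTER_TANIMOTO,
    mode: str = "seed",
) -> list[CompoundCluster]:
    """Cluster compounds by Tanimoto similarity.

    ``mode='seed'`` (default): one cluster per seed compound whose members
    are the seed plus every compound at Tanimoto >= threshold to it;
    clusters overlap freely. ``mode='connected_components'``: transitive
    closure of the >= threshold similarity graph, one disjoint cluster per
    component (seed = lexicographically smallest member).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if mode not in ("seed", "connected_components"):
        raise ValueError(f"unknown cluster mode {mode!r}")

    fp_list = list(fps.values()) if isinstance(fps, Mapping) else list(fps)
    ids = [fp.compound_id for fp in fp_list]
    vects = [fp.bits for fp in fp_list]

    neighbor_sets: list[set[str]] = []
    for i, bv in enumerate(vects):
        sims = DataStructs.BulkTanimotoSimilarity(bv, vects)
        neighbor_sets.append({ids[j] for j, s in enumerate(sims) if s >= threshold and j != i})

    if mode == "seed":
        return [CompoundCluster(seed=ids[i], members=neighbor_sets[i]) for i in range(len(ids))]

    index = {cid: i for i, cid in enumerate(ids)}
    seen: set[str] = set()
    clusters: list[CompoundCluster] = []
    for cid in ids:
        if cid in seen:
            continue
        component = {cid}
        stack = [cid]
        while stack:
            current = stack.pop()
            for nb in neighbor_sets[index[current]]:
                if nb not in component:
                    component.add(nb)
                    stack.append(nb)
        seen |= component
        clusters.append(CompoundCluster(seed=min(component), members=component))
    return clusters


def similar_compounds(
    query: str,
    fps: Mapping[str, Fingerprint],
    threshold: float = PROPAGATE_TANIMOTO,
) -> set[str]:
    """Compounds (excluding the query itself) at Tanimoto >= threshold to the query."""
    if query not in fps:
        raise KeyError(f"no fingerprint for query compound {query!r}")
    query_fp = fps[query]
    others = [(cid, fp) for cid, fp in fps.items() if cid != query]
    if not others:
        return set()
    sims = DataStructs.BulkTanimotoSimilarity(query_fp.bits, [fp.bits for _, fp in others])
    return {cid for (cid, _), s in zip(others, sims) if s >= threshold}


def write_fingerprint_cache(fps: Mapping[str, Fingerprint], path) -> None:
    """Serialize fingerprints as TSV with hex-encoded bit strings; the fold
    length is recorded in a header comment."""
    lengths = {fp.n_bits for fp in fps.values()}
    if len(lengths) > 1:
        raise ValueError(f"fingerprints of mixed lengths: {sorted(lengths)}")
    n_bits = lengths.pop() if lengths else DEFAULT_N_BITS
    with open(path, "w") as handle:
        handle.write(f"# n_bits={n_bits}\n")
        handle.write("compound_id\tfingerprint_hex\n")
        for cid in sorted(fps):
            handle.write(f"{cid}\t{fps[cid].to_hex()}\n")


def read_fingerprint_cache(path) -> dict[str, Fingerprint]:
    n_bits = DEFAULT_N_BITS
    fps: dict[str, Fingerprint] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "n_bits=" in line:
                    n_bits = int(line.split("n_bits=")[1])
                continue
            if not line or line.startswith("compound_id\t"):
                continue
            cid, hex_string = line.split("\t")
            fps[cid] = Fingerprint.from_hex(cid, hex_string, n_bits)
    return fps
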