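"""Deterministic synthetic chemogenomics worlds with planted ground truth.

A world consists of a proteome with domain annotations, a domain hierarchy,
a compound library with drug-like SMILES, bioactivity records, and a truth
list of planted (compound, domain) associations. Each planted association
is built constructively: the compound receives in-band active records
(< 10 μM) against proteins containing the domain and in-band inactive
records (> 20 μM) against proteins lacking it, in numbers exceeding the
eligibility floors — so with zero noise the mapping engine must recover the
association with a perfect score. Record-level label noise (band flips) and
ambiguous-band injections then degrade the signal in a controlled way.

Compound structures are drawn from a small library of hand-written
drug-like scaffolds with enumerated substituents, giving controllably
similar neighborhoods for clustering and propagation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import BioactivityRecord
from .domains import (
    DomainHierarchy,
    DomainHit,
    ProteinRecord,
    Proteome,
    write_annotations_tsv,
    write_hierarchy_tsv,
)

# Drug-like scaffolds; {R} marks the substituent attachment point.
SCAFFOLDS = [
    "CC(=O)Nc1ccc({R})cc1",
    "O=C(Nc1ccc({R})cc1)c1ccco1",
    "O=C(Nc1ccc({R})cc1)c1cccs1",
    "Cc1nnc(Nc2ccc({R})cc2)s1",
    "COc1ccc(NC(=O)c2ccc({R})cc2)cc1",
    "O=C(Nc1ccccn1)c1ccc({R})cc1",
    "CN(C)C(=O)c1ccc({R})cc1",
    "O=S(=O)(Nc1ccc({R})cc1)c1ccccc1",
    "CC(Nc1ncnc2[nH]cnc12)c1ccc({R})cc1",
    "O=C(N1CCN(C)CC1)c1ccc({R})cc1",
    "CC(=O)N1CCC(Nc2ccc({R})cc2)CC1",
    "O=C(Nc1ccc({R})cc1)C1CC1",
    "O=C(NCc1ccccc1)c1ccc({R})cc1",
    "Oc1ccc2c(c1)OC(c1ccc({R})cc1)CC2=O",
    "O=c1[nH]c2ccccc2n1Cc1ccc({R})cc1",
    "CCOC(=O)c1cc2ccc({R})cc2[nH]1",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2Cc1ccc({R})cc1",
    "O=C(Cc1ccc({R})cc1)Nc1ccccc1",
    "CC(C)Cc1ccc({R})cc1C",
    "Nc1nc2ccc({R})cc2s1",
]

SUBSTITUENTS = ["F", "Cl", "Br", "I", "C", "O", "OC", "N", "C#N", "C(F)(F)F", "CC", "OCC"]


@dataclass
class WorldConfig:
    """Study conditions for one synthetic world (defaults are the reference
    conditions used throughout the test suite)."""

    seed: int = 0
    n_domains: int = 30
    n_hierarchy_roots: int = 30
    n_proteins: int = 100
    max_domains_per_protein: int = 3
    n_compounds: int = 50
    planted_associations: int = 25
    actives_per_association: int = 8
    inactives_per_association: int = 8
    active_mu: float = 1.0       # μM log-normal location for active records
    inactive_mu: float = 100.0   # μM log-normal location for inactive records
    log_sigma: float = 0.5       # natural-log spread for both bands
    label_noise: float = 0.05    # probability that a record flips bands
    ambiguous_fraction: float = 0.05  # probability of a 10-20 μM record
    n_pathways: int = 8

    def validate(self) -> None:
        for name in ("n_domains", "n_hierarchy_roots", "n_proteins",
                     "max_domains_per_protein", "n_compounds", "n_pathways",
                     "actives_per_association", "inactives_per_association"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.planted_associations < 0 or self.planted_associations > self.n_compounds:
            raise ValueError("planted_associations must be in [0, n_compounds]")
        if self.n_hierarchy_roots > self.n_domains:
            raise ValueError("n_hierarchy_roots cannot exceed n_domains")
        if not 0 <= self.label_noise < 1 or not 0 <= self.ambiguous_fraction <= 1:
            raise ValueError("noise fractions must be in [0, 1)")
        if self.actives_per_association + self.inactives_per_association > self.n_proteins:
            raise ValueError("not enough proteins to host a planted association")
        if self.active_mu >= 10 or self.inactive_mu <= 20:
            raise ValueError("active_mu must be < 10 μM and inactive_mu > 20 μM")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    proteome: Proteome
    hierarchy: DomainHierarchy
    smiles: dict[str, str]
    records: list[BioactivityRecord]
    truth: set[tuple[str, str]]
    pathway_annotations: dict[str, set[str]] = field(default_factory=dict)


def _draw_in_band(rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float) -> float:
    """Log-normal draw redrawn until inside (lo, hi) — guarantees pre-noise
    records respect their activity band."""
    for _ in range(1000):
        v = float(np.exp(rng.normal(np.log(mu), sigma)))
        if lo < v < hi:
            return round(v, 4)
    raise RuntimeError("activity band draw failed to converge; widen the band or reduce sigma")


def _compound_smiles(index: int) -> str:
    combos = len(SCAFFOLDS) * len(SUBSTITUENTS)
    i = index % combos
    scaffold = SCAFFOLDS[i % len(SCAFFOLDS)]
    substituent = SUBSTITUENTS[(i // len(SCAFFOLDS)) % len(SUBSTITUENTS)]
    return scaffold.replace("{R}", substituent)


def generate_world(cfg: WorldConfig) -> SyntheticWorld:
    """Build a reproducible world from the config (same seed, same world)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    domains = [f"D{i:04d}" for i in range(cfg.n_domains)]
    roots = domains[: cfg.n_hierarchy_roots]
    parent = {d: d for d in roots}
    for d in domains[cfg.n_hierarchy_roots:]:
        parent[d] = roots[int(rng.integers(0, len(roots)))]
    hierarchy = DomainHierarchy(parent)

    protein_ids = [f"SYNP{i:04d}" for i in range(cfg.n_proteins)]
    protein_domains: dict[str, set[str]] = {}
    for acc in protein_ids:
        k = int(rng.integers(1, cfg.max_domains_per_protein + 1))
        chosen = rng.choice(cfg.n_domains, size=k, replace=False)
        protein_domains[acc] = {domains[int(j)] for j in chosen}

    compound_ids = [f"SYNC{i:04d}" for i in range(cfg.n_compounds)]
    smiles = {cid: _compound_smiles(i) for i, cid in enumerate(compound_ids)}

    # Plant associations; top up a domain's hosts if the random proteome
    # left it with too few proteins for the constructive guarantee.
    truth: set[tuple[str, str]] = set()
    planted_domains: list[str] = [
        domains[int(rng.integers(0, cfg.n_domains))] for _ in range(cfg.planted_associations)
    ]
    for d in sorted(set(planted_domains)):
        hosts = [acc for acc in protein_ids if d in protein_domains[acc]]
        deficit = cfg.actives_per_association - len(hosts)
        if deficit > 0:
            non_hosts = [acc for acc in protein_ids if d not in protein_domains[acc]]
            if len(non_hosts) - deficit < cfg.inactives_per_association:
                raise ValueError(f"cannot host planted domain {d}: proteome too small")
            for acc in rng.choice(len(non_hosts), size=deficit, replace=False):
                protein_domains[non_hosts[int(acc)]].add(d)

    proteins = []
    for acc in protein_ids:
        hits = [
            DomainHit(domain_id=d, start=1 + 150 * j, end=100 + 150 * j)
            for j, d in enumerate(sorted(protein_domains[acc]))
        ]
        proteins.append(ProteinRecord(acc, hits))
    proteome = Proteome(proteins)

    records: list[BioactivityRecord] = []

    def emit(compound: str, target: str, band: str) -> None:
        # Base in-band value, then ambiguous injection / band flip.
        u = rng.random(2)
        if u[0] < cfg.ambiguous_fraction:
            value = round(float(rng.uniform(10.0, 20.0)), 4)
        else:
            if u[1] < cfg.label_noise:
                band = "inactive" if band == "active" else "active"
            if band == "active":
                value = _draw_in_band(rng, cfg.active_mu, cfg.log_sigma, 1e-4, 10.0)
            else:
                value = _draw_in_band(rng, cfg.inactive_mu, cfg.log_sigma, 20.0, 1e5)
        source = "assaydb1" if rng.random() < 0.5 else "assaydb2"
        records.append(BioactivityRecord(compound, smiles[compound], target, value, source))

    for i in range(cfg.planted_associations):
        compound, d = compound_ids[i], planted_domains[i]
        truth.add((compound, d))
        hosts = sorted(acc for acc in protein_ids if d in protein_domains[acc])
        non_hosts = sorted(acc for acc in protein_ids if d not in protein_domains[acc])
        assert len(hosts) >= cfg.actives_per_association  # constructive eligibility guarantee
        assert len(non_hosts) >= cfg.inactives_per_association
        actives = rng.choice(len(hosts), size=cfg.actives_per_association, replace=False)
        inactives = rng.choice(len(non_hosts), size=cfg.inactives_per_association, replace=False)
        for j in sorted(int(a) for a in actives):
            emit(compound, hosts[j], "active")
        for j in sorted(int(a) for a in inactives):
            emit(compound, non_hosts[j], "inactive")

    # Decoy compounds: a handful of records against random proteins with
    # random band membership, mirroring the sparsely assayed long tail of
    # bioactivity databases; most end up ineligible or unmappable.
    for compound in compound_ids[cfg.planted_associations:]:
        n_rec = int(rng.integers(2, 7))
        targets = rng.choice(cfg.n_proteins, size=min(n_rec, cfg.n_proteins), replace=False)
        for j in targets:
            emit(compound, protein_ids[int(j)], "active" if rng.random() < 0.5 else "inactive")

    pathway_ids = [f"path{i:03d}" for i in range(cfg.n_pathways)]
    pathway_annotations: dict[str, set[str]] = {}
    for acc in protein_ids:
        if rng.random() < 0.1:
            continue  # leave ~10% of proteins unannotated
        k = 1 + int(rng.random() < 0.3)
        chosen = rng.choice(cfg.n_pathways, size=k, replace=False)
        pathway_annotations[acc] = {pathway_ids[int(j)] for j in chosen}

    return SyntheticWorld(
        config=cfg,
        proteome=proteome,
        hierarchy=hierarchy,
        smiles=smiles,
        records=records,
        truth=truth,
        pathway_annotations=pathway_annotations,
    )


def world_to_inputs(world: SyntheticWorld, directory) -> dict[str, Path]:
    """Write the five pipeline input files for a world; returns their paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "bioactivity": directory / "bioactivity.tsv",
        "annotations": directory / "domains.tsv",
        "hierarchy": directory / "hierarchy.tsv",
        "reference": directory / "reference.tsv",
        "pathways": directory / "pathways.tsv",
    }

    rows = [
        (r.compound_id, r.smiles, r.target_id, f"{r.activity_um:.4f}", r.source)
        for r in world.records
    ]
    pd.DataFrame(
        rows, columns=["compound_id", "smiles", "target_accession", "activity_um", "source"]
    ).to_csv(paths["bioactivity"], sep="\t", index=False)

    write_annotations_tsv(world.proteome, paths["annotations"])
    write_hierarchy_tsv(world.hierarchy, paths["hierarchy"])

    pd.DataFrame(sorted(world.truth), columns=["compound_id", "domain_id"]).to_csv(
        paths["reference"], sep="\t", index=False
    )

    pw_rows = [
        (acc, pw)
        for acc in sorted(world.pathway_annotations)
        for pw in sorted(world.pathway_annotations[acc])
    ]
    pd.DataFrame(pw_rows, columns=["target_accession", "pathway_id"]).to_csv(
        paths["pathways"], sep="\t", index=False
    )
    return paths


def replicate_configs(base: WorldConfig, n: int, seed: int) -> list[WorldConfig]:
    """n replicate configs with seeds derived from one master seed."""
    rng = np.random.default_rng(seed)
    return [replace(base, seed=int(s)) for s in rng.integers(0, 2**31 - 1, size=n)]
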