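import pytest

from ligdom.domains import DomainHierarchy, DomainHit, ProteinRecord, Proteome


def protein(accession: str, *domain_ids: str) -> ProteinRecord:
    """Protein with one synthetic hit per domain id, laid out sequentially."""
    hits = [DomainHit(d, start=1 + 150 * i, end=100 + 150 * i) for i, d in enumerate(domain_ids)]
    return ProteinRecord(accession, hits)


@pytest.fixture
def demethylase_like_proteome() -> Proteome:
    """Six proteins mirroring a lysine-demethylase-style assay panel.

    Three actives carry both the jmj-like domain (dA) and the zinc-finger-like
    domain (dB); one inactive carries dA only, one carries dB only, and one
    carries neither.
    """
    return Proteome(
        [
            protein("ACT1", "dA", "dB"),
            protein("ACT2", "dA", "dB"),
            protein("ACT3", "dA", "dB"),
            protein("INA1", "dA", "dC"),
            protein("INA2", "dB", "dC"),
            protein("INA3", "dC", "dD"),
        ]
    )


@pytest.fixture
def flat_hierarchy() -> DomainHierarchy:
    return DomainHierarchy({})
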