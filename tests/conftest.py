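"""Shared fixtures: in-memory BGC builders, random-case generators, and a
session-scoped simulated corpus."""

from __future__ import annotations

import numpy as np
import pytest

from regmech.classify import classify_bgc
from regmech.domain_scan import DEFAULT_REGISTRY, DomainArchitecture, DomainHit
from regmech.io_bgc import BGCRecord, GeneFeature, protein_id
from regmech.synthetic_data import SimConfig, simulate_bgc_set


@pytest.fixture(scope="session")
def registry():
    return DEFAULT_REGISTRY


def build_bgc(
    genes: list[tuple[set[str], int]],
    bgc_id: str = "B1",
    source: str = "MIBiG",
    product_class: str = "polyketide",
    complete: bool = True,
) -> tuple[BGCRecord, dict[str, DomainArchitecture]]:
    """Construct a BGC plus architectures from (domain_set, strand) specs."""
    features = []
    pos = 100
    for idx, (_domains, strand) in enumerate(genes):
        length = 60
        features.append(
            GeneFeature(
                gene_id=f"g{idx}",
                start=pos,
                end=pos + 3 * length + 3,
                strand=strand,
                translation="M" + "A" * (length - 1),
                rank=idx,
            )
        )
        pos += 3 * length + 103
    bgc = BGCRecord(
        bgc_id=bgc_id,
        source=source,
        product_class=product_class,
        raw_products=[],
        complete=complete,
        genes=features,
    )
    archs: dict[str, DomainArchitecture] = {}
    for gene, (domains, _strand) in zip(features, genes):
        if not domains:
            continue
        pid = protein_id(bgc_id, gene)
        hits = [
            DomainHit(pid, acc, 5 + 12 * k, 15 + 12 * k, 50.0, 1e-10, 1e-10)
            for k, acc in enumerate(sorted(domains))
        ]
        archs[pid] = DomainArchitecture(pid, set(domains), hits)
    return bgc, archs


def random_gene_specs(
    rng: np.random.Generator, max_genes: int = 8
) -> list[tuple[set[str], int]]:
    """Random small BGC content: arbitrary domain combinations and strands."""
    reg = DEFAULT_REGISTRY
    pools = [
        sorted(reg.ca_domains),
        sorted(reg.dhp_domains),
        sorted(reg.hpt_domains),
        sorted(reg.tf_domains),
        ["PF00072"],
    ]
    n = int(rng.integers(1, max_genes + 1))
    genes = []
    for _ in range(n):
        domains: set[str] = set()
        if rng.random() < 0.65:  # regulatory-ish gene
            for pool in pools:
                if rng.random() < 0.35:
                    domains.add(pool[int(rng.integers(len(pool)))])
        strand = 1 if rng.random() < 0.5 else -1
        genes.append((domains, strand))
    return genes


def mirror_specs(genes: list[tuple[set[str], int]]) -> list[tuple[set[str], int]]:
    """Reverse gene order and flip strands (reverse-complement of the locus)."""
    return [(set(d), -s) for d, s in reversed(genes)]


def classify_specs(
    genes: list[tuple[set[str], int]], max_gap: int = 0
) -> list:
    """Classify an in-memory spec list, returning annotations in rank order."""
    bgc, archs = build_bgc(genes)
    anns, _pairs = classify_bgc(bgc, archs, max_gap=max_gap)
    return sorted(anns, key=lambda a: a.rank)


@pytest.fixture(scope="session")
def sim_corpus(tmp_path_factory):
    """One simulated corpus (files + truth) shared across tests."""
    out = tmp_path_factory.mktemp("sim")
    config = SimConfig(n_bgcs=60, seed=42)
    result = simulate_bgc_set(config, out)
    return config, result, out
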