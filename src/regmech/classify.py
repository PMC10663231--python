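"""Regulatory-role and mechanism classification of BGC proteins.

The rules operate on per-protein Pfam domain *sets* plus gene-neighborhood
context:

* histidine kinase (HK): a CA (catalytic/ATPase) domain together with a
  phospho-acceptor domain — class I when a DHp-type domain is present
  (DHp takes precedence if both types occur), class II when only an
  Hpt-type domain is present;
* transcription factor (TF): any registry DNA-binding/effector domain;
* SARP: a TF carrying both the OmpR-type (PF00486) and BTAD (PF03704)
  domains;
* response regulator (RR): a TF carrying the receiver domain (PF00072)
  whose gene lies next to an HK gene on the same strand — the two genes
  form a two-component system (TCS) pair;
* HKs with no qualifying adjacent RR are orphan HKs; TFs that are not RRs
  are one-component-system (OCS) TFs.

"Next to" defaults to immediate adjacency in gene order (zero intervening
CDS), configurable via ``max_gap``; either side of the HK qualifies.
Pairing is one-to-one: the nearest candidate wins, ties broken toward the
gene downstream of the HK in its strand orientation. A protein may be both
HK and TF (hybrid); it then appears in both the HK and TF tallies, with the
mechanism of each side tracked separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .domain_scan import DEFAULT_REGISTRY, DomainArchitecture, PfamRegistry
from .io_bgc import BGCRecord, protein_id

logger = logging.getLogger(__name__)


@dataclass
class RoleFlags:
    """Domain-architecture roles of one protein (neighborhood-independent)."""

    is_HK: bool = False
    hk_class: str = "none"  # {"I", "II", "none"}
    is_TF: bool = False
    is_SARP: bool = False
    has_receiver: bool = False  # carries PF00072 (diagnostic; RR needs adjacency)


@dataclass
class RegulatoryAnnotation:
    """Full per-protein classification within its BGC.

    ``hk_mechanism`` and ``tf_mechanism`` are tracked separately so hybrid
    HK+TF proteins can occupy both registries; the scalar ``mechanism`` view
    reports the HK side for hybrids.
    """

    protein_id: str
    bgc_id: str
    rank: int
    strand: int
    is_HK: bool = False
    hk_class: str = "none"
    is_TF: bool = False
    is_RR: bool = False
    is_SARP: bool = False
    has_receiver: bool = False
    hk_mechanism: str = "none"  # {"TCS", "orphan_HK", "none"}
    tf_mechanism: str = "none"  # {"TCS", "OCS", "none"}
    hk_partner_id: str = ""
    tf_partner_id: str = ""

    @property
    def mechanism(self) -> str:
        if self.is_HK:
            return self.hk_mechanism
        if self.is_TF:
            return self.tf_mechanism
        return "none"

    @property
    def partner_id(self) -> str:
        return self.hk_partner_id or self.tf_partner_id

    def validate(self) -> None:
        if self.is_RR:
            assert self.is_TF and self.tf_mechanism == "TCS" and self.tf_partner_id
        if self.is_HK:
            assert self.hk_class in {"I", "II"}
            assert self.hk_mechanism in {"TCS", "orphan_HK"}
            if self.hk_mechanism == "orphan_HK":
                assert not self.hk_partner_id
        else:
            assert self.hk_class == "none" and self.hk_mechanism == "none"
        if self.is_TF:
            assert self.tf_mechanism in {"TCS", "OCS"}
            if self.tf_mechanism == "OCS":
                assert not self.is_RR
        else:
            assert self.tf_mechanism == "none" and not self.is_RR
        if self.is_SARP:
            assert self.is_TF


@dataclass(frozen=True)
class TCSPair:
    """An HK gene matched with its adjacent same-strand RR gene."""

    bgc_id: str
    hk_protein_id: str
    rr_protein_id: str
    adjacency_gap: int
    shared_strand: int


def classify_protein(
    arch: DomainArchitecture | None,
    registry: PfamRegistry = DEFAULT_REGISTRY,
) -> RoleFlags:
    """Assign neighborhood-independent role flags from a domain architecture.

    A protein with no surviving hits (``arch is None`` or empty set) gets all
    flags false.
    """
    flags = RoleFlags()
    if arch is None or not arch.accession_set:
        return flags
    domains = arch.accession_set
    has_ca = bool(domains & registry.ca_domains)
    has_dhp = bool(domains & registry.dhp_domains)
    has_hpt = bool(domains & registry.hpt_domains)
    if has_ca and (has_dhp or has_hpt):
        flags.is_HK = True
        # DHp defines class I and takes precedence when both types present
        flags.hk_class = "I" if has_dhp else "II"
    flags.is_TF = bool(domains & registry.tf_domains)
    flags.is_SARP = registry.sarp_pair <= domains
    flags.has_receiver = bool(domains & registry.rr_receiver)
    return flags


def _annotations_for_bgc(
    bgc: BGCRecord,
    architectures: Mapping[str, DomainArchitecture],
    registry: PfamRegistry,
) -> list[RegulatoryAnnotation]:
    anns = []
    for gene in bgc.genes:
        pid = protein_id(bgc.bgc_id, gene)
        flags = classify_protein(architectures.get(pid), registry)
        if not (flags.is_HK or flags.is_TF):
            continue
        anns.append(
            RegulatoryAnnotation(
                protein_id=pid,
                bgc_id=bgc.bgc_id,
                rank=gene.rank,
                strand=gene.strand,
                is_HK=flags.is_HK,
                hk_class=flags.hk_class,
                is_TF=flags.is_TF,
                is_SARP=flags.is_SARP,
                has_receiver=flags.has_receiver,
            )
        )
    return anns


def pair_tcs(
    bgc: BGCRecord,
    annotations: Sequence[RegulatoryAnnotation],
    max_gap: int = 0,
) -> list[TCSPair]:
    """Match HKs with adjacent same-strand receiver-carrying TFs.

    ``max_gap`` is the permitted number of intervening CDS (0 = immediately
    adjacent, the default reading of "next to"). Matching is one-to-one:
    candidate pairs are ranked by gap, then by the downstream-in-strand
    preference, and greedily accepted while both members are unmatched.
    Sets ``is_RR`` / mechanisms / partner ids on the matched annotations.
    """
    by_rank = {a.rank: a for a in annotations if a.bgc_id == bgc.bgc_id}
    hks = [a for a in by_rank.values() if a.is_HK]
    rr_candidates = [a for a in by_rank.values() if a.is_TF and a.has_receiver]

    edges: list[tuple[int, int, int, int, RegulatoryAnnotation, RegulatoryAnnotation]] = []
    for hk in hks:
        for tf in rr_candidates:
            if tf.rank == hk.rank or tf.strand != hk.strand:
                continue
            gap = abs(tf.rank - hk.rank) - 1
            if gap > max_gap:
                continue
            downstream = 0 if (tf.rank - hk.rank) * hk.strand > 0 else 1
            edges.append((gap, downstream, hk.rank, tf.rank, hk, tf))
    # (gap, downstream) uniquely orders conflicting edges; the rank keys only
    # order disjoint ones, keeping the result orientation-invariant
    edges.sort(key=lambda e: (e[0], e[1], min(e[2], e[3]), max(e[2], e[3])))

    pairs: list[TCSPair] = []
    hk_taken: set[int] = set()
    tf_taken: set[int] = set()
    for gap, _down, _hr, _tr, hk, tf in edges:
        if hk.rank in hk_taken or tf.rank in tf_taken:
            continue
        hk_taken.add(hk.rank)
        tf_taken.add(tf.rank)
        hk.hk_mechanism = "TCS"
        hk.hk_partner_id = tf.protein_id
        tf.is_RR = True
        tf.tf_mechanism = "TCS"
        tf.tf_partner_id = hk.protein_id
        pairs.append(
            TCSPair(
                bgc_id=bgc.bgc_id,
                hk_protein_id=hk.protein_id,
                rr_protein_id=tf.protein_id,
                adjacency_gap=gap,
                shared_strand=hk.strand,
            )
        )
    return pairs


def assign_mechanisms(
    annotations: Iterable[RegulatoryAnnotation],
) -> list[RegulatoryAnnotation]:
    """Finalize mechanisms after pairing: unpaired HKs become orphan HKs,
    non-RR TFs become OCS TFs. Returns the annotations for chaining."""
    anns = list(annotations)
    for a in anns:
        if a.is_HK and a.hk_mechanism == "none":
            a.hk_mechanism = "orphan_HK"
        if a.is_TF and a.tf_mechanism == "none":
            a.tf_mechanism = "OCS"
        a.validate()
    return anns


def classify_bgc(
    bgc: BGCRecord,
    architectures: Mapping[str, DomainArchitecture],
    registry: PfamRegistry = DEFAULT_REGISTRY,
    max_gap: int = 0,
) -> tuple[list[RegulatoryAnnotation], list[TCSPair]]:
    """Run the full per-BGC classification: roles, TCS pairing, mechanisms."""
    anns = _annotations_for_bgc(bgc, architectures, registry)
    pairs = pair_tcs(bgc, anns, max_gap=max_gap)
    return assign_mechanisms(anns), pairs


def classify_bgcs(
    bgcs: Sequence[BGCRecord],
    architectures: Mapping[str, DomainArchitecture],
    registry: PfamRegistry = DEFAULT_REGISTRY,
    max_gap: int = 0,
) -> tuple[list[RegulatoryAnnotation], list[TCSPair]]:
    all_anns: list[RegulatoryAnnotation] = []
    all_pairs: list[TCSPair] = []
    for bgc in bgcs:
        anns, pairs = classify_bgc(bgc, architectures, registry, max_gap)
        all_anns.extend(anns)
        all_pairs.extend(pairs)
    return all_anns, all_pairs


def filter_complete(bgcs: Sequence[BGCRecord]) -> list[BGCRecord]:
    """Keep only BGCs flagged complete; regulatory tallies use this subset."""
    kept = [b for b in bgcs if b.complete]
    logger.info("completeness filter: %d of %d BGCs kept", len(kept), len(bgcs))
    return kept


def annotations_to_frame(annotations: Sequence[RegulatoryAnnotation]) -> pd.DataFrame:
    """Tidy per-protein table (one row per regulatory protein)."""
    rows = [
        {
            "bgc_id": a.bgc_id,
            "protein_id": a.protein_id,
            "rank": a.rank,
            "strand": a.strand,
            "is_HK": a.is_HK,
            "hk_class": a.hk_class,
            "is_TF": a.is_TF,
            "is_RR": a.is_RR,
            "is_SARP": a.is_SARP,
            "has_receiver": a.has_receiver,
            "hk_mechanism": a.hk_mechanism,
            "tf_mechanism": a.tf_mechanism,
            "mechanism": a.mechanism,
            "partner_id": a.partner_id,
        }
        for a in annotations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "bgc_id", "protein_id", "rank", "strand", "is_HK", "hk_class",
            "is_TF", "is_RR", "is_SARP", "has_receiver", "hk_mechanism",
            "tf_mechanism", "mechanism", "partner_id",
        ],
    )


def pairs_to_frame(pairs: Sequence[TCSPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bgc_id": p.bgc_id,
                "hk_protein_id": p.hk_protein_id,
                "rr_protein_id": p.rr_protein_id,
                "adjacency_gap": p.adjacency_gap,
                "shared_strand": p.shared_strand,
            }
            for p in pairs
        ],
        columns=[
            "bgc_id", "hk_protein_id", "rr_protein_id",
            "adjacency_gap", "shared_strand",
        ],
    )
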