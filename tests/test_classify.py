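"""Role rules, TCS pairing, mechanism assignment, completeness filter."""

import numpy as np
import pytest

from regmech.classify import classify_bgc, filter_complete
from regmech.domain_scan import DomainArchitecture

from _oracle import oracle_classify
from conftest import build_bgc, classify_specs, mirror_specs, random_gene_specs


@pytest.mark.parametrize(
    "domains, is_hk, hk_class, is_tf, is_sarp",
    [
        ({"PF02518", "PF00512"}, True, "I", False, False),  # CA + DHp
        ({"PF02518", "PF01627"}, True, "II", False, False),  # CA + Hpt
        ({"PF02518", "PF00512", "PF01627"}, True, "I", False, False),  # DHp wins
        ({"PF00486", "PF03704"}, False, "none", True, True),  # SARP
        ({"PF02518"}, False, "none", False, False),  # CA alone is not an HK
        ({"PF00512"}, False, "none", False, False),  # DHp alone is not an HK
        ({"PF00440"}, False, "none", True, False),  # TetR-family TF
        ({"PF00072"}, False, "none", False, False),  # receiver alone is no TF
        (set(), False, "none", False, False),
        ({"PF02518", "PF07730", "PF00196"}, True, "I", True, False),  # hybrid
    ],
)
def test_classify_protein_roles(registry, domains, is_hk, hk_class, is_tf, is_sarp):
    from regmech.classify import classify_protein

    arch = DomainArchitecture("p", set(domains), []) if domains else None
    flags = classify_protein(arch, registry)
    assert (flags.is_HK, flags.hk_class, flags.is_TF, flags.is_SARP) == (
        is_hk, hk_class, is_tf, is_sarp,
    )


HK = {"PF02518", "PF00512"}
RR_TF = {"PF00072", "PF00196"}
PLAIN_TF = {"PF00196"}


def test_adjacent_same_strand_receiver_tf_forms_tcs():
    anns = classify_specs([(HK, 1), (RR_TF, 1)])
    assert anns[0].hk_mechanism == "TCS"
    assert anns[1].is_RR and anns[1].tf_mechanism == "TCS"
    assert anns[0].hk_partner_id == anns[1].protein_id
    assert anns[1].tf_partner_id == anns[0].protein_id


def test_wrong_strand_neighbor_is_not_tcs():
    anns = classify_specs([(HK, 1), (RR_TF, -1)])
    assert anns[0].hk_mechanism == "orphan_HK"
    assert not anns[1].is_RR and anns[1].tf_mechanism == "OCS"


def test_tf_without_receiver_domain_is_not_rr():
    anns = classify_specs([(HK, 1), (PLAIN_TF, 1)])
    assert anns[0].hk_mechanism == "orphan_HK"
    assert anns[1].tf_mechanism == "OCS"


def test_hk_with_no_neighbors_is_orphan():
    anns = classify_specs([(HK, 1)])
    assert anns[0].hk_mechanism == "orphan_HK" and anns[0].partner_id == ""


def test_intervening_gene_blocks_pairing_at_gap_zero_but_not_one():
    specs = [(HK, 1), (set(), 1), (RR_TF, 1)]
    anns = classify_specs(specs)
    assert anns[0].hk_mechanism == "orphan_HK"
    anns = classify_specs(specs, max_gap=1)
    assert anns[0].hk_mechanism == "TCS"


def test_rr_on_either_side_of_hk_qualifies():
    anns = classify_specs([(RR_TF, -1), (HK, -1)])
    assert anns[0].is_RR and anns[1].hk_mechanism == "TCS"


def test_pairing_is_one_to_one_downstream_preferred():
    # two receiver TFs flank one HK: the downstream one (strand +) is chosen
    anns = classify_specs([(RR_TF, 1), (HK, 1), (RR_TF, 1)])
    assert anns[1].hk_partner_id == anns[2].protein_id
    assert anns[2].is_RR and not anns[0].is_RR
    assert anns[0].tf_mechanism == "OCS"
    # on the minus strand "downstream" is the lower-rank side
    anns = classify_specs([(RR_TF, -1), (HK, -1), (RR_TF, -1)])
    assert anns[1].hk_partner_id == anns[0].protein_id


def test_mechanism_partition_example():
    anns = classify_specs([(HK, 1), (RR_TF, 1), ({"PF00440"}, -1)])
    assert sorted(a.mechanism for a in anns) == ["OCS", "TCS", "TCS"]


def test_bgc_with_no_regulatory_proteins_yields_no_annotations():
    assert classify_specs([(set(), 1), (set(), -1)]) == []


def test_hybrid_protein_occupies_both_registries():
    anns = classify_specs([({"PF02518", "PF00512", "PF00196"}, 1)])
    (a,) = anns
    assert a.is_HK and a.is_TF
    assert a.hk_mechanism == "orphan_HK" and a.tf_mechanism == "OCS"


def test_hybrid_hk_can_partner_with_adjacent_receiver_tf():
    anns = classify_specs([({"PF02518", "PF00512", "PF00440"}, 1), (RR_TF, 1)])
    assert anns[0].hk_mechanism == "TCS" and anns[0].tf_mechanism == "OCS"
    assert anns[1].is_RR


def test_filter_complete():
    complete, _ = build_bgc([(HK, 1)], bgc_id="C", complete=True)
    incomplete, _ = build_bgc([(HK, 1)], bgc_id="I", complete=False)
    assert [b.bgc_id for b in filter_complete([complete, incomplete])] == ["C"]
    assert filter_complete([complete]) == [complete]


def _assert_matches_oracle(specs, registry, max_gap=0):
    anns = classify_specs(specs, max_gap=max_gap)
    expected = oracle_classify(specs, registry, max_gap=max_gap)
    regulatory = [e for e in expected if e["is_HK"] or e["is_TF"]]
    assert len(anns) == len(regulatory)
    by_rank = {a.rank: a for a in anns}
    for rank, e in enumerate(expected):
        if not (e["is_HK"] or e["is_TF"]):
            assert rank not in by_rank
            continue
        a = by_rank[rank]
        got = (
            a.is_HK, a.hk_class, a.is_TF, a.is_RR, a.is_SARP,
            a.hk_mechanism, a.tf_mechanism,
        )
        want = (
            e["is_HK"], e["hk_class"], e["is_TF"], e["is_RR"], e["is_SARP"],
            e["hk_mechanism"], e["tf_mechanism"],
        )
        assert got == want, f"rank {rank}: {got} != {want} for {specs}"
        # partners agree as ranks
        hk_partner = int(a.hk_partner_id.split("|")[2]) if a.hk_partner_id else None
        tf_partner = int(a.tf_partner_id.split("|")[2]) if a.tf_partner_id else None
        assert hk_partner == e["hk_partner"] and tf_partner == e["tf_partner"]


def test_classifier_agrees_with_rule_oracle_small_sample(registry):
    rng = np.random.default_rng(7)
    for _ in range(500):
        _assert_matches_oracle(random_gene_specs(rng), registry)


def test_classifier_agrees_with_rule_oracle_at_wider_gap(registry):
    rng = np.random.default_rng(8)
    for _ in range(300):
        _assert_matches_oracle(random_gene_specs(rng), registry, max_gap=1)


def test_orientation_invariance_sample(registry):
    rng = np.random.default_rng(9)
    for _ in range(300):
        specs = random_gene_specs(rng)
        fwd = classify_specs(specs)
        rev = classify_specs(mirror_specs(specs))
        n = len(specs)
        fwd_by_rank = {a.rank: a for a in fwd}
        rev_by_rank = {n - 1 - a.rank: a for a in rev}
        assert set(fwd_by_rank) == set(rev_by_rank)
        for rank, a in fwd_by_rank.items():
            b = rev_by_rank[rank]
            assert (
                a.is_HK, a.hk_class, a.is_TF, a.is_RR, a.is_SARP,
                a.hk_mechanism, a.tf_mechanism,
            ) == (
                b.is_HK, b.hk_class, b.is_TF, b.is_RR, b.is_SARP,
                b.hk_mechanism, b.tf_mechanism,
            ), specs


def test_pairing_monotone_in_max_gap(registry):
    rng = np.random.default_rng(10)
    for _ in range(200):
        specs = random_gene_specs(rng)
        bgc, archs = build_bgc(specs)
        counts = []
        for gap in (0, 1, 2):
            _anns, pairs = classify_bgc(bgc, archs, max_gap=gap)
            counts.append(len(pairs))
        assert counts == sorted(counts), specs


def test_partition_invariant_random_sample(registry):
    rng = np.random.default_rng(11)
    for _ in range(300):
        anns = classify_specs(random_gene_specs(rng))
        n_hk = sum(a.is_HK for a in anns)
        n_tf = sum(a.is_TF for a in anns)
        assert n_hk == sum(a.hk_mechanism == "TCS" for a in anns) + sum(
            a.hk_mechanism == "orphan_HK" for a in anns
        )
        assert n_tf == sum(a.is_RR for a in anns) + sum(
            a.is_TF and not a.is_RR for a in anns
        )
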