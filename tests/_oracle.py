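"""Independent brute-force oracles used only by the tests.

``oracle_classify`` is a direct, self-contained transcription of the
domain-set and neighborhood rules (CA + phospho-acceptor makes an HK, DHp
before Hpt; any registry DNA-binding domain makes a TF; OmpR + BTAD makes a
SARP; a receiver-carrying TF adjacent to a same-strand HK within the gap
limit is an RR, matched one-to-one nearest-first with the downstream gene
preferred on ties). It shares no code with the implementation: roles are
recomputed from raw domain sets and the pairing is a repeated full scan for
the single best remaining candidate rather than a sorted greedy pass.

``enumerate_alignment_best`` exhaustively enumerates every global alignment
of two sequences (no dual-gap columns; affine gap runs pay open + extends)
and returns the lexicographic optimum (max score, max identities, min
columns).
"""

from __future__ import annotations

from regmech.domain_scan import PfamRegistry


def oracle_classify(
    genes: list[tuple[set[str], int]],
    registry: PfamRegistry,
    max_gap: int = 0,
) -> list[dict]:
    """Classify genes given as (domain_set, strand) in rank order."""
    n = len(genes)
    out = []
    for domains, strand in genes:
        ca = len(domains & registry.ca_domains) > 0
        dhp = len(domains & registry.dhp_domains) > 0
        hpt = len(domains & registry.hpt_domains) > 0
        is_hk = ca and (dhp or hpt)
        hk_class = "none"
        if is_hk:
            hk_class = "I" if dhp else "II"
        is_tf = len(domains & registry.tf_domains) > 0
        out.append(
            {
                "is_HK": is_hk,
                "hk_class": hk_class,
                "is_TF": is_tf,
                "is_SARP": "PF00486" in domains and "PF03704" in domains,
                "has_receiver": "PF00072" in domains,
                "is_RR": False,
                "hk_mechanism": "none",
                "tf_mechanism": "none",
                "hk_partner": None,
                "tf_partner": None,
                "strand": strand,
            }
        )

    unpaired_hks = {i for i in range(n) if out[i]["is_HK"]}
    unpaired_rrs = {
        i for i in range(n) if out[i]["is_TF"] and out[i]["has_receiver"]
    }
    while True:
        best = None
        for h in sorted(unpaired_hks):
            for t in sorted(unpaired_rrs):
                if t == h:
                    continue
                if genes[t][1] != genes[h][1]:
                    continue
                gap = abs(t - h) - 1
                if gap > max_gap:
                    continue
                downstream = (t - h) * genes[h][1] > 0
                key = (gap, 0 if downstream else 1, min(h, t), max(h, t))
                if best is None or key < best[0]:
                    best = (key, h, t)
        if best is None:
            break
        _, h, t = best
        unpaired_hks.discard(h)
        unpaired_rrs.discard(t)
        out[h]["hk_mechanism"] = "TCS"
        out[h]["hk_partner"] = t
        out[t]["is_RR"] = True
        out[t]["tf_mechanism"] = "TCS"
        out[t]["tf_partner"] = h
    for entry in out:
        if entry["is_HK"] and entry["hk_mechanism"] == "none":
            entry["hk_mechanism"] = "orphan_HK"
        if entry["is_TF"] and entry["tf_mechanism"] == "none":
            entry["tf_mechanism"] = "OCS"
    return out


def enumerate_alignment_best(
    a: str,
    b: str,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
) -> tuple[int, int, int]:
    """Exhaustive search over all global alignments.

    Returns the best ``(score, identities, columns)`` under the objective
    (max score, max identities, min columns). A gap of length L costs
    ``gap_open + (L-1) * gap_extend``; consecutive gap columns in different
    sequences are separate gaps.
    """
    n, m = len(a), len(b)
    best: list[tuple[int, int, int] | None] = [None]

    # state: last move 0=sub, 1=gap-in-b, 2=gap-in-a (for affine accounting)
    def walk(i: int, j: int, last: int, score: int, ident: int, cols: int) -> None:
        if i == n and j == m:
            cand = (score, ident, -cols)
            if best[0] is None or cand > best[0]:
                best[0] = cand
            return
        if i < n and j < m:
            eq = a[i] == b[j]
            walk(
                i + 1, j + 1, 0,
                score + (match if eq else mismatch),
                ident + (1 if eq else 0), cols + 1,
            )
        if i < n:  # consume a[i] against a gap in b
            cost = gap_extend if last == 1 else gap_open
            walk(i + 1, j, 1, score - cost, ident, cols + 1)
        if j < m:  # consume b[j] against a gap in a
            cost = gap_extend if last == 2 else gap_open
            walk(i, j + 1, 2, score - cost, ident, cols + 1)

    walk(0, 0, -1, 0, 0, 0)
    score, ident, neg_cols = best[0]
    return score, ident, -neg_cols
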