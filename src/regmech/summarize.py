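"""Distribution tables over classified BGC regulators.

All tables are tidy pandas DataFrames with explicit counts next to
percentages (one decimal place is applied only at export time, never to the
stored values). Groups with zero members are omitted rather than divided by
zero. ``family_contribution`` uses *proteins* as the denominator, so a
protein carrying two qualifying families contributes to both rows and the
column may jointly exceed 100%; that table is flagged as multi-membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import RegulatoryAnnotation
from .domain_scan import DEFAULT_REGISTRY, DomainArchitecture, PfamRegistry
from .io_bgc import BGCRecord, PRODUCT_CLASSES

OVERALL = "overall"


@dataclass
class DistributionTable:
    """Grouped counts and percentages with a provenance note."""

    table: pd.DataFrame  # columns: group, category, count, percent
    note: str = ""
    multi_membership: bool = False

    def to_csv(self, path) -> None:
        out = self.table.copy()
        if not out.empty:
            out["percent"] = out["percent"].round(1)
        header_note = f"# {self.note}\n" if self.note else ""
        with open(path, "w") as handle:
            handle.write(header_note)
            out.to_csv(handle, index=False)


def _sources_of(bgcs: Sequence[BGCRecord]) -> dict[str, str]:
    return {b.bgc_id: b.source for b in bgcs}


def _percent_rows(
    counts: Mapping[str, int], group: str, category_order: Sequence[str]
) -> list[dict]:
    total = sum(counts.values())
    if total == 0:
        return []
    rows = []
    for cat in category_order:
        n = counts.get(cat, 0)
        if n == 0:
            continue
        rows.append(
            {"group": group, "category": cat, "count": n,
             "percent": 100.0 * n / total}
        )
    return rows


def bgc_class_distribution(
    bgcs: Sequence[BGCRecord],
    annotations: Sequence[RegulatoryAnnotation],
    selector: str,
    group_by_source: bool = True,
) -> DistributionTable:
    """Product-class distribution of BGCs containing >=1 protein of a role.

    ``selector`` is ``"HK"`` or ``"TF"``. Percentages are within each source
    group (plus an overall row set), over the qualifying BGCs of that group.
    """
    if selector not in {"HK", "TF"}:
        raise ValueError(f"selector must be 'HK' or 'TF', got {selector!r}")
    attr = "is_HK" if selector == "HK" else "is_TF"
    qualifying = {a.bgc_id for a in annotations if getattr(a, attr)}
    selected = [b for b in bgcs if b.bgc_id in qualifying]

    groups: dict[str, dict[str, int]] = {}
    for b in selected:
        for g in ([b.source] if group_by_source else []) + [OVERALL]:
            groups.setdefault(g, {}).setdefault(b.product_class, 0)
            groups[g][b.product_class] += 1
    rows: list[dict] = []
    for g in sorted(k for k in groups if k != OVERALL) + [OVERALL]:
        if g in groups:
            rows.extend(_percent_rows(groups[g], g, PRODUCT_CLASSES))
    return DistributionTable(
        pd.DataFrame(rows, columns=["group", "category", "count", "percent"]),
        note=f"product-class distribution of BGCs with >=1 {selector}",
    )


def mechanism_composition(
    annotations: Sequence[RegulatoryAnnotation],
    sources: Mapping[str, str] | None = None,
) -> DistributionTable:
    """Mechanism split of HKs (TCS vs orphan) and TFs (RR vs OCS), per source
    group and overall. ``sources`` maps bgc_id -> source label; omit it for
    overall-only rows."""
    rows: list[dict] = []
    hk_counts: dict[str, dict[str, int]] = {}
    tf_counts: dict[str, dict[str, int]] = {}
    for a in annotations:
        gs = [OVERALL]
        if sources is not None:
            gs.append(sources.get(a.bgc_id, "unknown"))
        for g in gs:
            if a.is_HK:
                cat = "TCS_HK" if a.hk_mechanism == "TCS" else "orphan_HK"
                hk_counts.setdefault(g, {}).setdefault(cat, 0)
                hk_counts[g][cat] += 1
            if a.is_TF:
                cat = "RR" if a.is_RR else "OCS_TF"
                tf_counts.setdefault(g, {}).setdefault(cat, 0)
                tf_counts[g][cat] += 1
    group_order = sorted(
        set(hk_counts) | set(tf_counts), key=lambda g: (g == OVERALL, g)
    )
    for g in group_order:
        if g in hk_counts:
            rows.extend(_percent_rows(hk_counts[g], g, ["TCS_HK", "orphan_HK"]))
        if g in tf_counts:
            rows.extend(_percent_rows(tf_counts[g], g, ["RR", "OCS_TF"]))
    return DistributionTable(
        pd.DataFrame(rows, columns=["group", "category", "count", "percent"]),
        note="mechanism composition: HKs split TCS/orphan, TFs split RR/OCS; "
        "percentages within each role population",
    )


_CONTEXTS = {"TCS_HK", "orphan_HK", "RR", "OCS_TF"}


def _in_context(a: RegulatoryAnnotation, context: str) -> bool:
    if context == "TCS_HK":
        return a.is_HK and a.hk_mechanism == "TCS"
    if context == "orphan_HK":
        return a.is_HK and a.hk_mechanism == "orphan_HK"
    if context == "RR":
        return a.is_RR
    if context == "OCS_TF":
        return a.is_TF and not a.is_RR
    raise ValueError(f"unknown context {context!r}; expected one of {_CONTEXTS}")


def family_contribution(
    annotations: Sequence[RegulatoryAnnotation],
    architectures: Mapping[str, DomainArchitecture],
    context: str,
    registry: PfamRegistry = DEFAULT_REGISTRY,
) -> DistributionTable:
    """Percentage of proteins in a mechanism context carrying each family.

    HK contexts tabulate phospho-acceptor families; TF contexts tabulate the
    DNA-binding/effector families. Denominator = proteins in the context, so
    a two-family protein counts once per family (rows may jointly exceed
    100%).
    """
    if context not in _CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {_CONTEXTS}")
    members = [a for a in annotations if _in_context(a, context)]
    if context in {"TCS_HK", "orphan_HK"}:
        families = sorted(registry.phospho_acceptor_domains)
    else:
        families = sorted(registry.tf_domains)
    n = len(members)
    rows = []
    for fam in families:
        count = sum(
            1
            for a in members
            if a.protein_id in architectures
            and fam in architectures[a.protein_id].accession_set
        )
        if count:
            rows.append(
                {
                    "group": context,
                    "category": f"{registry.name_of(fam)} ({fam})",
                    "count": count,
                    "percent": 100.0 * count / n,
                }
            )
    return DistributionTable(
        pd.DataFrame(rows, columns=["group", "category", "count", "percent"]),
        note=(
            f"family contribution within {context}; denominator = {n} proteins; "
            "multi-family proteins count once per family (rows may exceed 100% jointly)"
        ),
        multi_membership=True,
    )


def regulator_census(
    bgcs: Sequence[BGCRecord],
    annotations: Sequence[RegulatoryAnnotation],
) -> pd.DataFrame:
    """Headline counts per source and overall.

    Columns: BGCs, BGCs with >=1 HK / >=1 TF / neither, HK count, TF count,
    TCS pair count, SARP count.
    """
    by_bgc: dict[str, list[RegulatoryAnnotation]] = {}
    for a in annotations:
        by_bgc.setdefault(a.bgc_id, []).append(a)

    def stats(sub: Sequence[BGCRecord]) -> dict:
        with_hk = sum(
            1 for b in sub if any(a.is_HK for a in by_bgc.get(b.bgc_id, []))
        )
        with_tf = sum(
            1 for b in sub if any(a.is_TF for a in by_bgc.get(b.bgc_id, []))
        )
        neither = sum(
            1
            for b in sub
            if not any(a.is_HK or a.is_TF for a in by_bgc.get(b.bgc_id, []))
        )
        anns = [a for b in sub for a in by_bgc.get(b.bgc_id, [])]
        return {
            "bgcs": len(sub),
            "bgcs_with_hk": with_hk,
            "bgcs_with_tf": with_tf,
            "bgcs_with_neither": neither,
            "hk_count": sum(a.is_HK for a in anns),
            "tf_count": sum(a.is_TF for a in anns),
            "tcs_pair_count": sum(
                1 for a in anns if a.is_HK and a.hk_mechanism == "TCS"
            ),
            "sarp_count": sum(a.is_SARP for a in anns),
        }

    rows = []
    for source in sorted({b.source for b in bgcs}):
        rows.append({"group": source, **stats([b for b in bgcs if b.source == source])})
    rows.append({"group": OVERALL, **stats(list(bgcs))})
    return pd.DataFrame(rows)


def summary_bundle(
    bgcs: Sequence[BGCRecord],
    annotations: Sequence[RegulatoryAnnotation],
    architectures: Mapping[str, DomainArchitecture],
    registry: PfamRegistry = DEFAULT_REGISTRY,
) -> dict[str, DistributionTable | pd.DataFrame]:
    """All standard tables keyed by name (used by the CLI and examples)."""
    sources = _sources_of(bgcs)
    bundle: dict[str, DistributionTable | pd.DataFrame] = {
        "bgc_class_with_hk": bgc_class_distribution(bgcs, annotations, "HK"),
        "bgc_class_with_tf": bgc_class_distribution(bgcs, annotations, "TF"),
        "mechanism_composition": mechanism_composition(annotations, sources),
        "census": regulator_census(bgcs, annotations),
    }
    for context in ("TCS_HK", "orphan_HK", "RR", "OCS_TF"):
        bundle[f"families_{context}"] = family_contribution(
            annotations, architectures, context, registry
        )
    return bundle
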