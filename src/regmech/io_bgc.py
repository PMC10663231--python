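"""Reading and writing biosynthetic gene cluster (BGC) records.

GenBank flat files (MIBiG entries, antiSMASH region output) are parsed into
:class:`BGCRecord` objects holding an ordered list of protein-coding genes.
Internally all coordinates are 0-based half-open; GenBank's 1-based inclusive
convention is converted at the I/O boundary (Biopython already stores feature
locations half-open, so the conversion is inherited from the parser and
re-applied symmetrically on write).

A per-BGC metadata table (CSV/TSV) supplies the source environment, the
completeness flag used to restrict downstream tallies to complete clusters,
and optional product-class overrides.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import BiopythonWarning, SeqIO

logger = logging.getLogger(__name__)

PRODUCT_CLASSES = (
    "polyketide",
    "NRP",
    "RiPP",
    "terpene",
    "saccharide",
    "alkaloid",
    "other",
)

#: Default keyword -> class mapping applied to raw product annotations
#: (antiSMASH ``/product`` qualifiers or MIBiG biosynthetic-class strings).
#: Matching is case-insensitive substring; first matching rule wins.
DEFAULT_PRODUCT_MAPPING: tuple[tuple[str, str], ...] = (
    ("pks", "polyketide"),
    ("polyketide", "polyketide"),
    ("nrps", "NRP"),
    ("nrp", "NRP"),
    ("lanthipeptide", "RiPP"),
    ("lassopeptide", "RiPP"),
    ("thiopeptide", "RiPP"),
    ("ripp", "RiPP"),
    ("terpene", "terpene"),
    ("oligosaccharide", "saccharide"),
    ("aminoglycoside", "saccharide"),
    ("saccharide", "saccharide"),
    ("alkaloid", "alkaloid"),
    ("indole", "alkaloid"),
)


@dataclass(frozen=True)
class GeneFeature:
    """One protein-coding gene inside a BGC.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    cluster record; ``rank`` is the gene-order index (sorted by start, ties
    broken longer-feature-first then lexicographic gene id). ``translation``
    carries the amino-acid sequence without a trailing stop symbol.
    """

    gene_id: str
    start: int
    end: int
    strand: int
    translation: str
    rank: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid gene span [{self.start}, {self.end}) for {self.gene_id}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")


@dataclass
class BGCRecord:
    """One biosynthetic gene cluster with its ordered genes and metadata."""

    bgc_id: str
    source: str
    product_class: str
    raw_products: list[str]
    complete: bool
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.product_class not in PRODUCT_CLASSES:
            raise ValueError(f"unknown product class {self.product_class!r}")


class MetadataTable:
    """Per-BGC metadata: source, completeness, optional product override.

    Backed by a pandas DataFrame keyed by ``bgc_id``; unknown ids looked up
    fall back to defaults (source ``unknown``, complete ``True``).
    """

    REQUIRED = ("bgc_id",)

    def __init__(self, frame: pd.DataFrame, default_complete: bool = True):
        if "bgc_id" not in frame.columns:
            raise ValueError("metadata table must have a 'bgc_id' column")
        if frame["bgc_id"].duplicated().any():
            dups = frame.loc[frame["bgc_id"].duplicated(), "bgc_id"].tolist()
            raise ValueError(f"duplicate bgc_id rows in metadata: {dups}")
        self._frame = frame.set_index("bgc_id", drop=False)
        self._default_complete = default_complete
        self._seen: set[str] = set()

    @classmethod
    def read(cls, path: str | Path, default_complete: bool = True) -> "MetadataTable":
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        frame = pd.read_csv(path, sep=sep, dtype={"bgc_id": str})
        return cls(frame, default_complete=default_complete)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def source_of(self, bgc_id: str) -> str:
        if bgc_id in self._frame.index:
            self._seen.add(bgc_id)
            val = self._frame.at[bgc_id, "source"] if "source" in self._frame else None
            if val is not None and not pd.isna(val):
                return str(val)
        return "unknown"

    def complete_of(self, bgc_id: str) -> bool:
        if bgc_id in self._frame.index and "complete" in self._frame:
            self._seen.add(bgc_id)
            val = self._frame.at[bgc_id, "complete"]
            if not pd.isna(val):
                if isinstance(val, str):
                    return val.strip().lower() in {"true", "1", "yes", "t"}
                return bool(val)
        return self._default_complete

    def product_override(self, bgc_id: str) -> str | None:
        if bgc_id in self._frame.index and "product_class" in self._frame:
            val = self._frame.at[bgc_id, "product_class"]
            if not pd.isna(val) and str(val):
                return str(val)
        return None

    def unmatched_ids(self, known: Iterable[str]) -> list[str]:
        """Metadata rows whose bgc_id never appeared in the parsed records."""
        known = set(known)
        return [i for i in self._frame.index if i not in known]


def map_product_class(
    raw_products: Sequence[str],
    mapping: Sequence[tuple[str, str]] = DEFAULT_PRODUCT_MAPPING,
    multi_product_rule: str = "first",
) -> str:
    """Map raw product annotations onto the seven canonical BGC classes.

    The default rule for multi-product records is first-wins in annotation
    order; ``multi_product_rule='vote'`` takes the most frequent mapped class
    instead (ties broken by canonical class order).
    """
    if not raw_products:
        return "other"

    def map_one(raw: str) -> str:
        low = raw.lower()
        for key, cls in mapping:
            if key in low:
                return cls
        return "other"

    if multi_product_rule == "first":
        return map_one(raw_products[0])
    if multi_product_rule == "vote":
        mapped = [map_one(r) for r in raw_products]
        counts = {c: mapped.count(c) for c in set(mapped)}
        best = max(counts.values())
        for cls in PRODUCT_CLASSES:
            if counts.get(cls) == best:
                return cls
    raise ValueError(f"unknown multi_product_rule {multi_product_rule!r}")


def _gene_sort_key(start: int, end: int, gene_id: str) -> tuple[int, int, str]:
    # equal starts: longer feature first, then lexicographic id (determinism)
    return (start, -(end - start), gene_id)


def _extract_raw_products(record) -> list[str]:
    products: list[str] = []
    for feat in record.features:
        if feat.type in {"region", "cand_cluster", "protocluster", "cluster"}:
            products.extend(feat.qualifiers.get("product", []))
    if not products:
        # MIBiG-style record-level annotation
        ann = record.annotations.get("biosyn_class") or record.annotations.get(
            "structured_comment", {}
        )
        if isinstance(ann, (list, tuple)):
            products.extend(str(a) for a in ann)
    return products


def _record_to_bgc(
    record,
    metadata: MetadataTable | None,
    mapping: Sequence[tuple[str, str]],
) -> BGCRecord:
    bgc_id = record.id or record.name
    raw_genes: list[tuple[int, int, int, str, str]] = []
    cds_index = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        loc = feat.location
        if loc is None:
            continue
        # minimal enclosing span for compound/join locations
        start, end = int(loc.start), int(loc.end)
        strand = 1 if (loc.strand is None or loc.strand >= 0) else -1
        gene_id = (
            feat.qualifiers.get("locus_tag", [None])[0]
            or feat.qualifiers.get("gene", [None])[0]
            or f"{bgc_id}_CDS{cds_index}"
        )
        cds_index += 1
        translation = feat.qualifiers.get("translation", [None])[0]
        if translation is None:
            if len(record.seq) and str(record.seq).strip("N"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", BiopythonWarning)
                    translation = str(feat.extract(record.seq).translate(table=11))
            else:
                logger.warning(
                    "CDS %s in %s has no /translation and no sequence; skipped",
                    gene_id,
                    bgc_id,
                )
                continue
        translation = translation.rstrip("*")
        if not translation:
            logger.warning("CDS %s in %s has empty translation; skipped", gene_id, bgc_id)
            continue
        raw_genes.append((start, end, strand, gene_id, translation))

    raw_genes.sort(key=lambda g: _gene_sort_key(g[0], g[1], g[3]))
    genes = [
        GeneFeature(gene_id=g[3], start=g[0], end=g[1], strand=g[2],
                    translation=g[4], rank=rank)
        for rank, g in enumerate(raw_genes)
    ]

    raw_products = _extract_raw_products(record)
    override = metadata.product_override(bgc_id) if metadata else None
    product_class = override or map_product_class(raw_products, mapping)
    source = metadata.source_of(bgc_id) if metadata else "unknown"
    complete = metadata.complete_of(bgc_id) if metadata else True
    return BGCRecord(
        bgc_id=bgc_id,
        source=source,
        product_class=product_class,
        raw_products=list(raw_products),
        complete=complete,
        genes=genes,
    )


def read_genbank_bgcs(
    paths: Sequence[str | Path],
    metadata: MetadataTable | None = None,
    mapping: Sequence[tuple[str, str]] = DEFAULT_PRODUCT_MAPPING,
) -> list[BGCRecord]:
    """Parse GenBank flat files into BGC records.

    Each GenBank record becomes one :class:`BGCRecord`. Unparseable files are
    reported and skipped; the batch continues. Records with zero CDS are kept
    with an empty gene list.
    """
    bgcs: list[BGCRecord] = []
    for path in paths:
        path = Path(path)
        try:
            records = list(SeqIO.parse(str(path), "genbank"))
        except Exception as exc:  # malformed file: report, continue batch
            logger.error("failed to parse %s: %s", path, exc)
            continue
        for record in records:
            bgcs.append(_record_to_bgc(record, metadata, mapping))
    if metadata is not None:
        unmatched = metadata.unmatched_ids([b.bgc_id for b in bgcs])
        if unmatched:
            logger.warning(
                "%d metadata rows matched no parsed BGC: %s",
                len(unmatched), ", ".join(unmatched[:10]),
            )
    return bgcs


def read_genbank_dir(
    directory: str | Path,
    metadata: MetadataTable | None = None,
    pattern: str = "*.gbk",
) -> list[BGCRecord]:
    """Convenience wrapper: parse every GenBank file in a directory (sorted)."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        paths = sorted(Path(directory).glob("*.gb")) + sorted(
            Path(directory).glob("*.gbff")
        )
    return read_genbank_bgcs(paths, metadata)


def protein_id(bgc_id: str, gene: GeneFeature) -> str:
    """Composite protein id used across the pipeline: bgc|gene|rank|strand."""
    strand = "+1" if gene.strand > 0 else "-1"
    return f"{bgc_id}|{gene.gene_id}|{gene.rank}|{strand}"


def parse_protein_id(pid: str) -> tuple[str, str, int, int]:
    """Split a composite protein id back into (bgc_id, gene_id, rank, strand)."""
    bgc_id, gene_id, rank, strand = pid.rsplit("|", 3)
    return bgc_id, gene_id, int(rank), int(strand)


def write_protein_fasta(bgcs: Sequence[BGCRecord], out: str | Path) -> int:
    """Write all gene translations as FASTA with composite headers.

    Deterministic order: input BGC order, then gene rank. Returns the number
    of sequences written; duplicate composite ids are an error.
    """
    seen: set[str] = set()
    n = 0
    with open(out, "w") as handle:
        for bgc in bgcs:
            for gene in bgc.genes:
                pid = protein_id(bgc.bgc_id, gene)
                if pid in seen:
                    raise ValueError(f"duplicate protein id {pid}")
                seen.add(pid)
                handle.write(f">{pid}\n{gene.translation}\n")
                n += 1
    return n


def to_genbank_coord(start: int, end: int) -> tuple[int, int]:
    """Convert an internal 0-based half-open span to GenBank 1-based inclusive."""
    return start + 1, end


def from_genbank_coord(start1: int, end1: int) -> tuple[int, int]:
    """Convert a GenBank 1-based inclusive span to 0-based half-open."""
    return start1 - 1, end1


def bgcs_to_json(bgcs: Sequence[BGCRecord]) -> list[dict]:
    """JSON-serializable view of a BGC list (used by the CLI records file)."""
    return [
        {
            "bgc_id": b.bgc_id,
            "source": b.source,
            "product_class": b.product_class,
            "raw_products": b.raw_products,
            "complete": b.complete,
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "translation": g.translation,
                    "rank": g.rank,
                }
                for g in b.genes
            ],
        }
        for b in bgcs
    ]


def bgcs_from_json(data: list[dict]) -> list[BGCRecord]:
    return [
        BGCRecord(
            bgc_id=d["bgc_id"],
            source=d["source"],
            product_class=d["product_class"],
            raw_products=list(d.get("raw_products", [])),
            complete=bool(d["complete"]),
            genes=[GeneFeature(**g) for g in d["genes"]],
        )
        for d in data
    ]
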