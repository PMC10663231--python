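"""Pfam domain detection on BGC proteins.

Two input modes produce the same :class:`DomainHit` stream:

* ``scan_proteins`` — profile-HMM search of a protein FASTA against an
  HMMER3 database, backed by pyhmmer. Hits are kept when the per-sequence
  E-value and the per-domain conditional E-value are both at or below the
  configured thresholds (default 0.01 / 0.01, boundary inclusive).
* ``read_hits_table`` — a precomputed TSV of hits, the engine-free path.

The :class:`PfamRegistry` holds the accession sets that drive classification:
histidine-kinase catalytic/ATPase (CA) domains, the two flavors of
phospho-acceptor domain (DHp-type and Hpt-type), transcription-factor
DNA-binding domains, the response-regulator receiver domain (PF00072) and
the OmpR+BTAD pair that defines SARPs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

_VERSION_SUFFIX = re.compile(r"\.\d+$")

DEFAULT_SEQ_EVALUE = 0.01
DEFAULT_DOM_CEVALUE = 0.01

#: accession -> (short name, description) for the default registry
FAMILY_NAMES: dict[str, str] = {
    # histidine kinase catalytic and ATP-binding (CA) domains
    "PF02518": "HATPase_c",
    "PF13581": "HATPase_c_2",
    "PF13589": "HATPase_c_3",
    "PF13749": "HATPase_c_4",
    "PF14501": "HATPase_c_5",
    # dimerization / histidine phospho-acceptor (DHp-type) domains
    "PF00512": "HisKA",
    "PF02895": "H-kinase_dim",
    "PF07536": "HWE_HK",
    "PF07568": "HisKA_2",
    "PF07730": "HisKA_3",
    "PF19191": "HEF_HK",
    # histidine phosphotransfer (Hpt-type) domains
    "PF01627": "Hpt",
    "PF10090": "HPTransfase",
    # transcription-factor DNA-binding / effector domains
    "PF00027": "cNMP_binding",
    "PF00158": "Sigma54_activat",
    "PF00165": "HTH_AraC",
    "PF00196": "LuxR_family",
    "PF00325": "Crp",
    "PF00376": "MerR",
    "PF00440": "TetR_N",
    "PF00486": "Trans_reg_C_OmpR",
    "PF08664": "YcbB",
    "PF02954": "HTH_8_Fis",
    "PF03704": "BTAD",
    "PF04397": "LytTR",
    "PF08279": "HTH_11",
    "PF08769": "Spo0A_C",
    # response-regulator receiver domain
    "PF00072": "Response_reg",
}


@dataclass(frozen=True)
class PfamRegistry:
    """Accession sets used by the classification rules.

    Defaults reproduce the published domain tables. HWE_HK and HEF_HK sit in
    the DHp-type set (they are phospho-acceptor domains of the same
    architectural role); the registry is user-extensible if a different
    placement is wanted.
    """

    ca_domains: frozenset[str] = frozenset(
        {"PF02518", "PF13581", "PF13589", "PF13749", "PF14501"}
    )
    dhp_domains: frozenset[str] = frozenset(
        {"PF00512", "PF02895", "PF07536", "PF07568", "PF07730", "PF19191"}
    )
    hpt_domains: frozenset[str] = frozenset({"PF01627", "PF10090"})
    tf_domains: frozenset[str] = frozenset(
        {
            "PF00027", "PF00158", "PF00165", "PF00196", "PF00325",
            "PF00376", "PF00440", "PF00486", "PF08664", "PF02954",
            "PF03704", "PF04397", "PF08279", "PF08769",
        }
    )
    rr_receiver: frozenset[str] = frozenset({"PF00072"})
    sarp_pair: frozenset[str] = frozenset({"PF00486", "PF03704"})
    family_names: Mapping[str, str] = field(default_factory=lambda: dict(FAMILY_NAMES))

    @property
    def phospho_acceptor_domains(self) -> frozenset[str]:
        return self.dhp_domains | self.hpt_domains

    @property
    def all_accessions(self) -> frozenset[str]:
        return (
            self.ca_domains
            | self.dhp_domains
            | self.hpt_domains
            | self.tf_domains
            | self.rr_receiver
        )

    def name_of(self, accession: str) -> str:
        return self.family_names.get(accession, accession)


DEFAULT_REGISTRY = PfamRegistry()


@dataclass(frozen=True)
class DomainHit:
    """One Pfam-family match on one protein.

    Coordinates are 0-based half-open envelope positions on the protein;
    ``seq_evalue`` is the full-sequence E-value, ``dom_cevalue`` the
    per-domain conditional E-value.
    """

    protein_id: str
    accession: str
    env_start: int
    env_end: int
    bitscore: float
    seq_evalue: float
    dom_cevalue: float

    def __post_init__(self) -> None:
        if self.env_start >= self.env_end:
            raise ValueError(
                f"empty envelope [{self.env_start}, {self.env_end}) on {self.protein_id}"
            )
        if self.seq_evalue < 0 or self.dom_cevalue < 0:
            raise ValueError("E-values must be non-negative")


@dataclass
class DomainArchitecture:
    """Surviving domain content of one protein (set + positional order)."""

    protein_id: str
    accession_set: set[str]
    ordered_hits: list[DomainHit]


def strip_version(accession: str) -> str:
    """Drop a trailing Pfam version suffix: PF02518.21 -> PF02518."""
    return _VERSION_SUFFIX.sub("", accession)


def _hit_sort_key(h: DomainHit) -> tuple[str, int, str]:
    return (h.protein_id, h.env_start, h.accession)


def filter_hits(
    hits: Iterable[DomainHit],
    seq_e: float = DEFAULT_SEQ_EVALUE,
    dom_ce: float = DEFAULT_DOM_CEVALUE,
) -> list[DomainHit]:
    """Keep hits with seq_evalue <= seq_e AND dom_cevalue <= dom_ce.

    Boundary values are retained ("0.01 or less"). Idempotent and monotone
    in both thresholds.
    """
    if seq_e <= 0 or dom_ce <= 0:
        raise ValueError("thresholds must be positive")
    return [h for h in hits if h.seq_evalue <= seq_e and h.dom_cevalue <= dom_ce]


HITS_COLUMNS = (
    "protein_id",
    "accession",
    "env_start",
    "env_end",
    "bitscore",
    "seq_evalue",
    "dom_cevalue",
)


def read_hits_table(path: str | Path) -> list[DomainHit]:
    """Read a TSV of domain hits (engine-free input path).

    Accession version suffixes are stripped; output ordering matches
    ``scan_proteins`` (protein_id, env_start, accession).
    """
    hits: list[DomainHit] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != list(HITS_COLUMNS):
            raise ValueError(
                f"unexpected hits-table header {header}; expected {list(HITS_COLUMNS)}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(HITS_COLUMNS):
                raise ValueError(f"malformed row at line {lineno}: {line!r}")
            try:
                hit = DomainHit(
                    protein_id=fields[0],
                    accession=strip_version(fields[1]),
                    env_start=int(fields[2]),
                    env_end=int(fields[3]),
                    bitscore=float(fields[4]),
                    seq_evalue=float(fields[5]),
                    dom_cevalue=float(fields[6]),
                )
            except ValueError as exc:
                raise ValueError(f"malformed row at line {lineno}: {exc}") from exc
            hits.append(hit)
    hits.sort(key=_hit_sort_key)
    return hits


def write_hits_table(hits: Sequence[DomainHit], path: str | Path) -> int:
    """Write hits as TSV (inverse of :func:`read_hits_table`)."""
    with open(path, "w") as handle:
        handle.write("\t".join(HITS_COLUMNS) + "\n")
        for h in sorted(hits, key=_hit_sort_key):
            handle.write(
                f"{h.protein_id}\t{h.accession}\t{h.env_start}\t{h.env_end}\t"
                f"{h.bitscore:g}\t{h.seq_evalue:g}\t{h.dom_cevalue:g}\n"
            )
    return len(hits)


class EngineUnavailableError(RuntimeError):
    """Raised when no HMM engine is importable; use the hits-table mode."""


def scan_proteins(
    fasta: str | Path,
    hmm_db: str | Path,
    seq_e: float = DEFAULT_SEQ_EVALUE,
    dom_ce: float = DEFAULT_DOM_CEVALUE,
) -> list[DomainHit]:
    """Search a protein FASTA against an HMMER3 profile database.

    Every domain whose full-sequence E-value and conditional E-value both
    pass the thresholds yields one :class:`DomainHit`. Profiles are expected
    to carry the Pfam accession in their ACC (preferred) or NAME field.
    """
    try:
        import pyhmmer
    except ImportError as exc:  # pragma: no cover - engine present in CI image
        raise EngineUnavailableError(
            "pyhmmer is not importable; provide a precomputed hits TSV via "
            "read_hits_table instead"
        ) from exc

    fasta = Path(fasta)
    if fasta.stat().st_size == 0:
        return []
    alphabet = pyhmmer.easel.Alphabet.amino()
    with pyhmmer.easel.SequenceFile(
        str(fasta), digital=True, alphabet=alphabet
    ) as seq_file:
        sequences = seq_file.read_block()
    if len(sequences) == 0:
        return []
    with pyhmmer.plan7.HMMFile(str(hmm_db)) as hmm_file:
        hmms = list(hmm_file)

    def _text(value) -> str:
        return value.decode() if isinstance(value, bytes) else str(value)

    hits: list[DomainHit] = []
    for top_hits in pyhmmer.hmmsearch(hmms, sequences):
        query = top_hits.query
        accession = strip_version(_text(query.accession or query.name))
        for hit in top_hits:
            if hit.evalue > seq_e:
                continue
            for domain in hit.domains:
                if domain.c_evalue > dom_ce:
                    continue
                hits.append(
                    DomainHit(
                        protein_id=_text(hit.name),
                        accession=accession,
                        env_start=domain.env_from - 1,
                        env_end=domain.env_to,
                        bitscore=float(domain.score),
                        seq_evalue=float(hit.evalue),
                        dom_cevalue=float(domain.c_evalue),
                    )
                )
    hits.sort(key=_hit_sort_key)
    return hits


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Convert HMMER3 ``--domtblout`` output into DomainHit records."""
    hits: list[DomainHit] = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            # domtblout: target name, acc, tlen, query name, q acc, qlen,
            # seq E-value, seq score, bias, #, of, c-Evalue, i-Evalue,
            # dom score, dom bias, hmm from/to, ali from/to, env from/to, ...
            accession = f[4] if f[4] != "-" else f[3]
            hits.append(
                DomainHit(
                    protein_id=f[0],
                    accession=strip_version(accession),
                    env_start=int(f[19]) - 1,
                    env_end=int(f[20]),
                    bitscore=float(f[13]),
                    seq_evalue=float(f[6]),
                    dom_cevalue=float(f[11]),
                )
            )
    hits.sort(key=_hit_sort_key)
    return hits


def assemble_architectures(
    hits: Iterable[DomainHit],
    registry: PfamRegistry = DEFAULT_REGISTRY,
) -> tuple[dict[str, DomainArchitecture], list[DomainHit]]:
    """Group filtered hits into per-protein architectures.

    Hits on accessions outside the registry are excluded from architectures
    and returned as a side list for reporting.
    """
    known = registry.all_accessions
    archs: dict[str, DomainArchitecture] = {}
    unknown: list[DomainHit] = []
    for hit in sorted(hits, key=_hit_sort_key):
        if hit.accession not in known:
            unknown.append(hit)
            continue
        arch = archs.get(hit.protein_id)
        if arch is None:
            arch = DomainArchitecture(hit.protein_id, set(), [])
            archs[hit.protein_id] = arch
        arch.accession_set.add(hit.accession)
        arch.ordered_hits.append(hit)
    for arch in archs.values():
        arch.ordered_hits.sort(key=lambda h: (h.env_start, h.accession))
    return archs, unknown
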