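"""Ground-truthed synthetic BGC fixtures.

``simulate_bgc_set`` emits the same artifact set the real pipeline consumes
— per-cluster GenBank files, a domain-hit TSV, a metadata CSV — plus a
truth table assigned *by construction* from scenario templates (never by
running the classifier on its own output). Scenarios cover every mechanism
the rules distinguish, including adversarial near-misses (receiver TF on
the wrong strand, receiver TF separated from the HK by an intervening
gene) that must not be called TCS under the default adjacency rule.

Category counts (sources, product classes, scenarios, incomplete clusters)
are allocated exactly by largest remainder, not sampled, so tests can make
exact assertions. All randomness flows from one integer seed; a fixed seed
yields byte-identical output files (the GenBank LOCUS date is pinned).

``emit_motif_fixtures`` builds toy profile HMMs from perturbed copies of
short synthetic motifs so the profile-search path can be integration-tested
without any Pfam download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .domain_scan import DEFAULT_REGISTRY, PfamRegistry

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

SCENARIOS = (
    "TCS_pair",
    "orphan_HK_classI",
    "orphan_HK_classII",
    "OCS_TF",
    "SARP_TF",
    "RR_like_wrong_strand",
    "RR_like_with_gap",
    "hybrid_HK_TF",
    "no_regulator",
)

#: genes needed by each scenario template (contiguous block)
_SCENARIO_GENES = {
    "TCS_pair": 2,
    "orphan_HK_classI": 1,
    "orphan_HK_classII": 1,
    "OCS_TF": 1,
    "SARP_TF": 1,
    "RR_like_wrong_strand": 2,
    "RR_like_with_gap": 3,
    "hybrid_HK_TF": 1,
    "no_regulator": 0,
}

#: representative raw product annotation per canonical class
CLASS_TO_RAW = {
    "polyketide": "T1PKS",
    "NRP": "NRPS",
    "RiPP": "lanthipeptide",
    "terpene": "terpene",
    "saccharide": "oligosaccharide",
    "alkaloid": "indole",
    "other": "butyrolactone",
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic corpus.

    Defaults mirror the shape of the real survey: a reference-database
    source dominating three environmental sources, product classes at the
    reference-set proportions, and a scenario mixture placing two thirds of
    histidine kinases inside two-component systems.
    """

    n_bgcs: int = 50
    sources: Mapping[str, float] = field(
        default_factory=lambda: {
            "MIBiG": 0.71, "CCB": 0.17, "rainforest": 0.07, "marine": 0.05,
        }
    )
    product_class_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "polyketide": 0.385, "NRP": 0.276, "RiPP": 0.179, "terpene": 0.019,
            "saccharide": 0.077, "alkaloid": 0.019, "other": 0.045,
        }
    )
    regulator_scenario_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "TCS_pair": 0.20,
            "orphan_HK_classI": 0.03,
            "orphan_HK_classII": 0.01,
            "OCS_TF": 0.40,
            "SARP_TF": 0.06,
            "RR_like_wrong_strand": 0.02,
            "RR_like_with_gap": 0.02,
            "hybrid_HK_TF": 0.02,
            "no_regulator": 0.24,
        }
    )
    genes_per_bgc: tuple[int, int] = (4, 10)
    incomplete_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_bgcs < 1:
            raise ValueError("n_bgcs must be >= 1")
        for name, mix in (
            ("sources", self.sources),
            ("product_class_mixture", self.product_class_mixture),
            ("regulator_scenario_mixture", self.regulator_scenario_mixture),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1")
        lo, hi = self.genes_per_bgc
        needed = max(
            _SCENARIO_GENES[s]
            for s, w in self.regulator_scenario_mixture.items()
            if w > 0
        )
        if lo < needed:
            raise ValueError(
                f"genes_per_bgc lower bound {lo} cannot host a "
                f"{needed}-gene scenario"
            )
        if not (0.0 <= self.incomplete_fraction <= 1.0):
            raise ValueError("incomplete_fraction must be in [0, 1]")


@dataclass
class TruthTable:
    """Construction-time ground truth for one simulated corpus."""

    proteins: dict[str, dict]  # protein_id -> expected flags/mechanisms
    bgcs: dict[str, dict]  # bgc_id -> product_class/complete/source/scenario

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"proteins": self.proteins, "bgcs": self.bgcs}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        data = json.loads(Path(path).read_text())
        return cls(proteins=data["proteins"], bgcs=data["bgcs"])


@dataclass
class SimResult:
    genbank_paths: list[Path]
    hits_path: Path
    metadata_path: Path
    truth_path: Path
    truth: TruthTable


def _largest_remainder(weights: Mapping[str, float], total: int) -> dict[str, int]:
    """Exact integer allocation of ``total`` across categories."""
    keys = list(weights)
    raw = np.array([weights[k] * total for k in keys])
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    # assign leftovers by largest fractional part, key order breaking ties
    order = sorted(range(len(keys)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def _scenario_domains(
    scenario: str, rng: np.random.Generator, registry: PfamRegistry
) -> list[tuple[set[str], int]]:
    """Domain sets for each scenario gene, plus a relative-strand code
    (0 = scenario strand, 1 = opposite)."""
    ca = sorted(registry.ca_domains)
    dhp = sorted(registry.dhp_domains)
    hpt = sorted(registry.hpt_domains)
    tf = sorted(registry.tf_domains)

    def pick(pool: list[str]) -> str:
        return pool[int(rng.integers(len(pool)))]

    hk1 = {pick(ca), pick(dhp)}
    if scenario == "TCS_pair":
        rr = {"PF00072", pick(tf)}
        genes = [(hk1, 0), (rr, 0)]
        if rng.integers(2):  # RR may sit on either side of the HK
            genes.reverse()
        return genes
    if scenario == "orphan_HK_classI":
        return [(hk1, 0)]
    if scenario == "orphan_HK_classII":
        return [({pick(ca), pick(hpt)}, 0)]
    if scenario == "OCS_TF":
        return [({pick(tf)}, 0)]
    if scenario == "SARP_TF":
        return [({"PF00486", "PF03704"}, 0)]
    if scenario == "RR_like_wrong_strand":
        return [(hk1, 0), ({"PF00072", pick(tf)}, 1)]
    if scenario == "RR_like_with_gap":
        return [(hk1, 0), (set(), 0), ({"PF00072", pick(tf)}, 0)]
    if scenario == "hybrid_HK_TF":
        return [({pick(ca), pick(dhp), pick(tf)}, 0)]
    if scenario == "no_regulator":
        return []
    raise ValueError(f"unknown scenario {scenario!r}")


def _expected_flags(
    domains: set[str], registry: PfamRegistry
) -> dict:
    """Scenario-template roles, written directly from the rule definitions."""
    has_ca = bool(domains & registry.ca_domains)
    has_dhp = bool(domains & registry.dhp_domains)
    has_hpt = bool(domains & registry.hpt_domains)
    is_hk = has_ca and (has_dhp or has_hpt)
    return {
        "is_HK": is_hk,
        "hk_class": ("I" if has_dhp else "II") if is_hk else "none",
        "is_TF": bool(domains & registry.tf_domains),
        "is_SARP": registry.sarp_pair <= domains,
        "has_receiver": bool(domains & registry.rr_receiver),
    }


def simulate_bgc_set(
    config: SimConfig,
    out_dir: str | Path,
    registry: PfamRegistry = DEFAULT_REGISTRY,
) -> SimResult:
    """Generate a ground-truthed corpus under ``out_dir``.

    Writes one GenBank file per BGC, ``hits.tsv``, ``metadata.csv`` and
    ``truth.json``; returns the paths plus the in-memory truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n = config.n_bgcs
    source_alloc = _largest_remainder(config.sources, n)
    scenario_alloc = _largest_remainder(config.regulator_scenario_mixture, n)
    sources: list[str] = [s for s, c in source_alloc.items() for _ in range(c)]
    scenarios: list[str] = [s for s, c in scenario_alloc.items() for _ in range(c)]
    classes: list[str] = [
        c for c, k in _largest_remainder(config.product_class_mixture, n).items()
        for _ in range(k)
    ]
    n_incomplete = round(config.incomplete_fraction * n)
    complete_flags = [False] * n_incomplete + [True] * (n - n_incomplete)
    rng.shuffle(sources)
    rng.shuffle(scenarios)
    rng.shuffle(classes)
    rng.shuffle(complete_flags)

    genbank_paths: list[Path] = []
    hit_rows: list[str] = []
    meta_rows: list[str] = []
    truth_proteins: dict[str, dict] = {}
    truth_bgcs: dict[str, dict] = {}
    registry_accs = sorted(registry.all_accessions)

    for idx in range(n):
        bgc_id = f"SYN{idx:05d}"
        scenario = scenarios[idx]
        n_genes = int(rng.integers(config.genes_per_bgc[0], config.genes_per_bgc[1] + 1))
        block = _scenario_domains(scenario, rng, registry)
        n_genes = max(n_genes, len(block))
        block_at = int(rng.integers(0, n_genes - len(block) + 1)) if block else 0
        scenario_strand = 1 if rng.integers(2) else -1

        gene_domains: list[set[str]] = []
        gene_strands: list[int] = []
        for g in range(n_genes):
            if block and block_at <= g < block_at + len(block):
                domains, rel = block[g - block_at]
                gene_domains.append(set(domains))
                gene_strands.append(scenario_strand * (-1 if rel else 1))
            else:
                gene_domains.append(set())
                gene_strands.append(1 if rng.integers(2) else -1)

        # lay out coordinates: 50-500 bp intergenic, CDS length = 3L+3
        features = []
        pos = int(rng.integers(50, 501))
        proteins: list[tuple[str, str, int]] = []  # (gene_id, translation, strand)
        for g in range(n_genes):
            length = int(rng.integers(80, 201)) + 50 * len(gene_domains[g])
            translation = _random_protein(rng, length)
            gene_id = f"{bgc_id}_G{g:02d}"
            span = 3 * length + 3
            features.append((pos, pos + span, gene_strands[g], gene_id, translation))
            proteins.append((gene_id, translation, gene_strands[g]))
            pos += span + int(rng.integers(50, 501))

        # GenBank record (ranks equal gene index: starts strictly increase)
        seq_len = pos + 50
        record = SeqRecord(
            Seq(_random_dna(rng, seq_len)),
            id=bgc_id,
            name=bgc_id,
            description="synthetic biosynthetic gene cluster",
        )
        record.annotations["molecule_type"] = "DNA"
        record.annotations["date"] = "01-JAN-2000"
        record.annotations["topology"] = "linear"
        record.features.append(
            SeqFeature(
                FeatureLocation(0, seq_len, strand=1),
                type="region",
                qualifiers={"product": [CLASS_TO_RAW[classes[idx]]]},
            )
        )
        for start, end, strand, gene_id, translation in features:
            record.features.append(
                SeqFeature(
                    FeatureLocation(start, end, strand=strand),
                    type="CDS",
                    qualifiers={
                        "locus_tag": [gene_id],
                        "translation": [translation],
                        "transl_table": ["11"],
                    },
                )
            )
        gbk_path = out_dir / f"{bgc_id}.gbk"
        SeqIO.write(record, str(gbk_path), "genbank")
        genbank_paths.append(gbk_path)

        meta_rows.append(
            f"{bgc_id},{sources[idx]},{str(complete_flags[idx]).lower()}"
        )
        truth_bgcs[bgc_id] = {
            "product_class": classes[idx],
            "complete": complete_flags[idx],
            "source": sources[idx],
            "scenario": scenario,
            "n_genes": n_genes,
        }

        # domain hits (true hits pass both thresholds; decoys fail at least one)
        pids = []
        for g, (gene_id, translation, strand) in enumerate(proteins):
            pid = f"{bgc_id}|{gene_id}|{g}|{'+1' if strand > 0 else '-1'}"
            pids.append(pid)
            offset = 5
            for acc in sorted(gene_domains[g]):
                env_start = offset
                env_end = offset + 40
                offset += 45
                bits = round(float(rng.uniform(40, 250)), 1)
                seq_e = _log_uniform(rng, 1e-30, 1e-3)
                dom_ce = _log_uniform(rng, 1e-30, 1e-3)
                hit_rows.append(
                    f"{pid}\t{acc}\t{env_start}\t{env_end}\t{bits:g}\t"
                    f"{seq_e:.3e}\t{dom_ce:.3e}"
                )
            if rng.random() < 0.3:  # decoy: fails the sequence threshold
                acc = registry_accs[int(rng.integers(len(registry_accs)))]
                seq_e = _log_uniform(rng, 0.02, 10)
                dom_ce = _log_uniform(rng, 1e-6, 10)
                hit_rows.append(
                    f"{pid}\t{acc}\t0\t30\t{round(float(rng.uniform(5, 20)), 1):g}\t"
                    f"{seq_e:.3e}\t{dom_ce:.3e}"
                )
            if rng.random() < 0.15:  # decoy: passes seq, fails domain threshold
                acc = registry_accs[int(rng.integers(len(registry_accs)))]
                seq_e = _log_uniform(rng, 1e-6, 1e-3)
                dom_ce = _log_uniform(rng, 0.02, 10)
                hit_rows.append(
                    f"{pid}\t{acc}\t0\t30\t{round(float(rng.uniform(5, 20)), 1):g}\t"
                    f"{seq_e:.3e}\t{dom_ce:.3e}"
                )

        # construction-time truth for regulatory proteins
        scenario_pids = {
            g: pids[g] for g in range(n_genes) if gene_domains[g]
        }
        for g, pid in scenario_pids.items():
            flags = _expected_flags(gene_domains[g], registry)
            entry = {
                **flags,
                "bgc_id": bgc_id,
                "scenario": scenario,
                "hk_mechanism": "none",
                "tf_mechanism": "none",
                "is_RR": False,
                "hk_partner_id": "",
                "tf_partner_id": "",
            }
            truth_proteins[pid] = entry
        if scenario == "TCS_pair":
            (g_a, _), (g_b, _) = sorted(scenario_pids.items())[:2]
            a, b = truth_proteins[pids[g_a]], truth_proteins[pids[g_b]]
            hk_entry, hk_pid = (a, pids[g_a]) if a["is_HK"] else (b, pids[g_b])
            rr_entry, rr_pid = (b, pids[g_b]) if a["is_HK"] else (a, pids[g_a])
            hk_entry["hk_mechanism"] = "TCS"
            hk_entry["hk_partner_id"] = rr_pid
            rr_entry["is_RR"] = True
            rr_entry["tf_mechanism"] = "TCS"
            rr_entry["tf_partner_id"] = hk_pid
        for entry in (truth_proteins[p] for p in scenario_pids.values()):
            if entry["is_HK"] and entry["hk_mechanism"] == "none":
                entry["hk_mechanism"] = "orphan_HK"
            if entry["is_TF"] and entry["tf_mechanism"] == "none":
                entry["tf_mechanism"] = "OCS"

    hits_path = out_dir / "hits.tsv"
    hits_path.write_text(
        "protein_id\taccession\tenv_start\tenv_end\tbitscore\tseq_evalue\t"
        "dom_cevalue\n" + "".join(r + "\n" for r in hit_rows)
    )
    metadata_path = out_dir / "metadata.csv"
    metadata_path.write_text(
        "bgc_id,source,complete\n" + "".join(r + "\n" for r in meta_rows)
    )
    truth = TruthTable(proteins=truth_proteins, bgcs=truth_bgcs)
    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)
    return SimResult(
        genbank_paths=genbank_paths,
        hits_path=hits_path,
        metadata_path=metadata_path,
        truth_path=truth_path,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# motif fixtures for the profile-HMM integration path


DEFAULT_MOTIF_FAMILIES = (
    "PF02518", "PF00512", "PF07730", "PF01627",
    "PF00072", "PF00196", "PF00440", "PF00486", "PF03704",
)


def emit_motif_fixtures(
    out_dir: str | Path,
    seed: int = 0,
    families: Sequence[str] = DEFAULT_MOTIF_FAMILIES,
    motif_length: int = 30,
    n_copies: int = 10,
    mutation_rate: float = 0.08,
    registry: PfamRegistry = DEFAULT_REGISTRY,
):
    """Build toy profile HMMs plus motif-seeded carrier proteins.

    Each family gets a random conserved motif; its HMM is trained on
    ``n_copies`` perturbed copies. Carrier proteins embed one or two motifs
    between random linkers; the expected-hit map records which accessions
    each carrier must produce at the default thresholds. Filler proteins
    carry no motif. Returns ``(fasta_path, hmm_path, expected_hits)``.
    """
    import pyhmmer

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alphabet = pyhmmer.easel.Alphabet.amino()
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)

    motifs: dict[str, str] = {}
    hmms = []
    for acc in families:
        motif = _random_protein(rng, motif_length)
        motifs[acc] = motif
        copies = []
        for c in range(n_copies):
            chars = list(motif)
            for p in range(len(chars)):
                if rng.random() < mutation_rate:
                    chars[p] = AMINO_ACIDS[int(rng.integers(20))]
            copies.append(
                pyhmmer.easel.TextSequence(
                    name=f"{acc}_seed{c}".encode(), sequence="".join(chars)
                )
            )
        msa = pyhmmer.easel.TextMSA(
            name=registry.name_of(acc).encode(), sequences=copies
        ).digitize(alphabet)
        hmm, _, _ = builder.build_msa(msa, background)
        hmm.accession = acc.encode()
        hmms.append(hmm)

    hmm_path = out_dir / "toy_profiles.hmm"
    with open(hmm_path, "wb") as handle:
        for hmm in hmms:
            hmm.write(handle)

    # carriers: one per family, plus two-motif combinations and fillers
    expected: dict[str, list[str]] = {}
    fasta_lines: list[str] = []

    def add_carrier(name: str, accs: Sequence[str]) -> None:
        parts = [_random_protein(rng, 25)]
        for acc in accs:
            parts.append(motifs[acc])
            parts.append(_random_protein(rng, 25))
        fasta_lines.append(f">{name}\n{''.join(parts)}")
        expected[name] = sorted(accs)

    for acc in families:
        add_carrier(f"carrier_{acc}", [acc])
    combos = [("PF02518", "PF00512"), ("PF00072", "PF00196"), ("PF00486", "PF03704")]
    for a, b in combos:
        if a in motifs and b in motifs:
            add_carrier(f"carrier_{a}_{b}", [a, b])
    for f in range(3):
        fasta_lines.append(f">filler_{f}\n{_random_protein(rng, 120)}")

    fasta_path = out_dir / "motif_carriers.faa"
    fasta_path.write_text("\n".join(fasta_lines) + "\n")
    return fasta_path, hmm_path, expected
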