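# Methods

## Problem and model

Biosynthetic gene clusters (BGCs) in bacteria frequently encode their own
regulators. The package classifies each cluster protein into regulatory
roles from its Pfam domain content and then into mechanisms from gene
neighborhood:

* A **histidine kinase (HK)** requires two pieces of evidence on one
  protein: a catalytic/ATP-binding (CA) domain — HATPase_c and its
  variants — and a phospho-acceptor domain. Class I HKs carry a
  DHp-type dimerization/phospho-acceptor domain (HisKA, HisKA_2, HisKA_3,
  H-kinase_dim, HWE_HK, HEF_HK); class II HKs carry an Hpt-type
  phosphotransfer domain (Hpt, HPTransfase). A CA domain alone is not an
  HK call: HATPase-like domains also occur in gyrases and chaperones.
  When both phospho-acceptor types occur on one protein the DHp evidence
  wins and the protein is class I, because DHp is the class-defining
  trait; the tie is explicit so the behavior is testable.
* A **transcription factor (TF)** carries at least one of 14 registry
  DNA-binding/effector families. The receiver domain PF00072 is
  deliberately *not* a TF domain: a bare receiver protein is not counted
  as a regulator.
* A **SARP** (antibiotic-regulatory protein of *Streptomyces* and
  relatives) is a TF with both the OmpR-type winged-helix domain
  (PF00486) and the BTAD transcriptional-activator domain (PF03704).
* A **two-component system (TCS)** is an HK gene plus a TF gene that
  carries PF00072, encoded in tandem on the same strand. "In tandem"
  defaults to zero intervening CDS; `max_gap` relaxes it. Either side of
  the HK qualifies — operon order is not enforced, because gene order
  alone does not identify the promoter. Matching is one-to-one: candidate
  pairs are ranked by gene gap, ties broken toward the gene downstream of
  the HK in its strand orientation, and accepted greedily. One-to-one
  matching keeps TCS pair counts well defined; with the two tie-break
  levels the matching is unique and invariant under mirroring the locus.
* Every HK not in a pair is an **orphan HK**; every TF that is not an RR
  is a **one-component system (OCS)** TF. A hybrid protein that is both
  HK and TF is counted in both populations, with the two mechanisms
  tracked separately (`hk_mechanism`, `tf_mechanism`); the scalar
  `mechanism` column reports the HK side for hybrids.

Domain evidence comes either from a profile-HMM search (pyhmmer) of the
cluster proteins, or from a precomputed hit table. Hits survive when the
per-sequence E-value **and** the per-domain conditional E-value are both
at or below 0.01; the boundary is inclusive ("0.01 or less"). Accession
version suffixes are stripped. Overlapping hits of one family are not
merged — every rule is a set-membership rule, so overlap is irrelevant.

## Coordinates and identifiers

Internally all genomic spans are 0-based half-open; GenBank's 1-based
inclusive convention is converted at the I/O boundary. Compound/join
locations collapse to their minimal enclosing span (adjacency logic needs
only order and strand). Gene rank sorts by start, ties broken
longer-feature-first then lexicographically. Proteins are addressed as
`bgc_id|gene_id|rank|strand` throughout; a missing locus_tag is
synthesized as `<bgc_id>_CDS<n>`.

Product classes map onto seven categories (polyketide, NRP, RiPP,
terpene, saccharide, alkaloid, other) by case-insensitive keyword rules
over the raw product annotations; for multi-product records the first
annotation wins by default (a vote rule is available). Completeness and
source come from the metadata table; records absent from the metadata
default to complete — the filter is consumed as a boolean and its
upstream computation is out of scope.

## Summaries

All tables carry raw counts next to percentages; percentages are computed
within each (source × role) group, groups with zero members are omitted
rather than divided by zero, and rounding to one decimal happens only at
CSV export. Family-contribution tables use *proteins* as the denominator:
a protein carrying two qualifying families counts once per family, so a
column may jointly exceed 100%; the table is flagged as multi-membership
in its header note.

## Phylogenies

Family trees select all proteins whose architecture contains the chosen
accession (optionally co-requiring others, e.g. the CA domain alongside
HisKA). Two routes:

* **External**: a configurable aligner command (MUSCLE-style template by
  default, any aligner accepted) followed by FastTree at its defaults;
  used for parity with the standard workflow, with provenance marked
  "external". Topologies from the two routes are not asserted equal.
* **Internal (default in tests)**: affine-gap global alignment
  (BLOSUM62; gap of length L costs 11 + (L−1)·1) giving the distance
  1 − identities / aligned columns, followed by Saitou–Nei
  neighbor-joining.

Full-length sequences are aligned by default; the domain envelope can be
excised instead when only the shared domain should drive the tree.

Numerical choices that make both primitives exactly testable:

* Co-optimal alignments can differ in identity count and alignment
  length, so the optimum is made unique lexicographically: maximize
  score, then identities, then minimize aligned columns. All three are
  additive, so the DP runs on one packed integer; the exhaustive
  enumeration oracle in the test suite applies the same objective.
* Dual-gap columns cannot occur in a pairwise global alignment, so the
  identity denominator is simply the alignment length.
* NJ breaks Q-criterion ties toward the lowest index pair; negative
  branch lengths are clamped to zero with the deficit moved to the sister
  edge; two taxa yield a single edge split evenly between the leaves; the
  final three lineages join at an unrooted trifurcation. With these rules
  the output is deterministic and invariant under taxon permutation (up
  to isomorphism), recovers additive matrices exactly, and matches
  scikit-bio's NJ on generic matrices.

## Synthetic data

The generator emulates the statistical shape of a curated-plus-
environmental survey corpus, not protein biology: clusters of 4–10
non-overlapping genes (50–500 bp intergenic, CDS length consistent with
the translation), a reference source dominating three environmental
sources (71/17/7/5%), product classes at reference-survey proportions,
and a scenario mixture placing two thirds of HKs inside TCSs while most
regulators are OCS TFs. Scenario templates (TCS pair, orphan HK class
I/II, OCS TF, SARP, hybrid, wrong-strand receiver, gapped receiver, no
regulator) assign ground truth *by construction*, never by running the
classifier on its own output. Category counts are allocated exactly by
largest remainder so tests can assert equality, and a fixed seed yields
byte-identical files (the GenBank date is pinned). True domain hits get
log-uniform E-values in [1e-30, 1e-3]; decoy hits fail at least one
threshold. Because sequences are random and domain hits are injected
rather than emitted from real profiles, passing tests demonstrate the
correctness of the rules, plumbing and statistics — not detection power
on real Pfam profiles; the toy-HMM fixtures cover the engine path with
constructed motifs for the same reason.

## Problem sizes

The test suite and the acceptance script size their inputs for exhaustive
verification at desk scale: 10,000 randomized ≤8-gene clusters for
rule-oracle equivalence, twenty 200-cluster corpora for file-level truth
recovery, 1,000 mirrored clusters for orientation invariance, 1,000 short
sequence pairs against the exhaustive alignment oracle, and twenty
6-taxon additive matrices for NJ recovery. These sizes were chosen so
each property is sampled densely while the whole suite stays fast.

## Known limitations

* Regulator detection is domain-set based; degenerate or split domains
  below the E-value thresholds are invisible, and no synteny beyond
  adjacency is used.
* The RR rule requires the receiver TF next to the HK; receiver-only
  proteins (no DNA-binding domain) are never counted, and cross-cluster
  or unlinked TCS partners are out of scope.
* Percent denominators for family tables are a package choice (proteins,
  documented above); other surveys may count domains.
* The internal tree route is a distance method; it is a deterministic
  stand-in for likelihood workflows, not a re-implementation of them.
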