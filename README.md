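# regmech

Regulatory-mechanism classification of biosynthetic gene clusters (BGCs).

Bacterial natural-product clusters are usually regulated in cis: either by
a **one-component system** (OCS) — a transcription factor (TF) that both
senses and acts — or by a **two-component system** (TCS), in which a sensor
**histidine kinase** (HK) phosphorylates an adjacent **response regulator**
(RR). `regmech` detects these regulators inside BGC GenBank records from
Pfam domain architectures and gene-neighborhood rules, tallies their
distribution across product classes and source environments, and builds
per-domain-family protein phylogenies. It is aimed at natural-product and
regulatory genomics groups mining MIBiG entries or antiSMASH output.

## Classification rules

Per protein, from the set of Pfam domains surviving the E-value filter
(per-sequence E ≤ 0.01 **and** per-domain conditional E ≤ 0.01):

* **HK** ⇔ a catalytic/ATPase (CA) domain *and* a phospho-acceptor domain.
  Class I carries a DHp-type domain (HisKA, HisKA_2, HisKA_3,
  H-kinase_dim, HWE_HK, HEF_HK); class II only an Hpt-type domain (Hpt,
  HPTransfase). DHp takes precedence when both are present.
* **TF** ⇔ any of the 14 registry DNA-binding/effector families (LuxR,
  TetR, OmpR, AraC, MerR, Crp, Fis, LytTR, BTAD, ...).
* **SARP** ⇔ a TF carrying both the OmpR-type (PF00486) and BTAD (PF03704)
  domains.
* **RR / TCS** ⇔ a TF with the receiver domain PF00072 whose gene is next
  to an HK gene on the same strand (0 intervening CDS by default,
  configurable). Pairing is one-to-one, nearest first, the downstream gene
  preferred on ties. Unpaired HKs are **orphan HKs**; all other TFs are
  **OCS** TFs.

Phylogenies per domain family run either through external engines
(aligner + FastTree) or through a built-in deterministic route:
affine-gap global alignment p-distances (BLOSUM62, open 11 / extend 1)
followed by Saitou–Nei neighbor-joining.

## Worked example

`examples/01_simulate_and_classify.py` generates a 30-cluster synthetic
corpus with known ground truth, reads it back through the normal GenBank +
hits-table path, and classifies it:

```
complete BGCs: 27  regulatory proteins: 29
TCS pairs (HK + adjacent same-strand receiver TF): 6
  SYN00000|SYN00000_G06|6|-1   TF    mechanism=OCS       RR=False SARP=False
  SYN00002|SYN00002_G00|0|+1   HKI   mechanism=TCS       RR=False SARP=False
  SYN00002|SYN00002_G01|1|+1   TF    mechanism=TCS       RR=True SARP=False
  ...
```

Each line is one regulatory gene: its `cluster|gene|rank|strand` id, the
role read off its domain set (`HKI` = class I histidine kinase), and the
mechanism implied by its neighborhood. In cluster `SYN00002` the HK at
rank 0 and the receiver-carrying TF at rank 1 sit in tandem on the plus
strand, so both are assigned to a TCS and the TF is flagged as its RR.

The other examples show the distribution tables
(`02_summarize_distributions.py` — e.g. 67.7% of HKs in a TCS for that
corpus), the family trees (`03_build_family_tree.py`) and the
pyhmmer-backed profile scanning path (`04_profile_scan.py`). The same
stages are scriptable via the `regmech` CLI
(`regmech simulate|ingest|scan|classify|summarize|phylo|run`).

## Layout

* `src/regmech/io_bgc.py` — GenBank/FASTA/metadata I/O, coordinate
  conventions, product-class mapping
* `src/regmech/domain_scan.py` — Pfam registry, E-value filtering, pyhmmer
  scanning, hit tables, architectures
* `src/regmech/classify.py` — role rules, TCS pairing, mechanisms
* `src/regmech/summarize.py` — distribution tables and censuses
* `src/regmech/phylo.py` — family selection, distances, NJ, exports
* `src/regmech/synthetic_data.py` — ground-truthed fixture generator
* `src/regmech/cli.py` — thin command-line layer
* `docs/methods.md` — models, parameters, numerical choices, limitations
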