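"""Per-domain-family phylogenies of BGC regulatory proteins.

Two routes produce a tree for the members of one Pfam family:

* an adapter around external engines (an aligner such as MUSCLE, then
  FastTree), mirroring the standard alignment+ML workflow; and
* a self-contained internal route — affine-gap global alignment
  p-distances followed by neighbor-joining — which is deterministic and
  needs no binaries.

Trees are exported as newick plus a metadata CSV (first column ``id``)
ready for tree viewers such as Microreact.
"""

from __future__ import annotations

import io
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from ._align import p_distance
from .classify import RegulatoryAnnotation
from .domain_scan import DEFAULT_REGISTRY, DomainArchitecture, PfamRegistry
from .io_bgc import BGCRecord


class EngineUnavailableError(RuntimeError):
    """An external binary is missing; the internal route is available."""


@dataclass
class FamilyMember:
    protein_id: str
    sequence: str
    source: str = "unknown"
    product_class: str = "other"
    mechanism: str = "none"
    co_accessions: tuple[str, ...] = ()


@dataclass
class FamilySelection:
    """Proteins whose architecture contains one Pfam family, with metadata."""

    accession: str
    members: list[FamilyMember]

    @property
    def ids(self) -> list[str]:
        return [m.protein_id for m in self.members]


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class Tree:
    """An (un)rooted tree over protein ids with branch lengths."""

    root: TreeNode
    provenance: str = "internal"

    @property
    def newick(self) -> str:
        buf = io.StringIO()
        self.root.write(buf)
        return buf.getvalue().strip()

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    @classmethod
    def from_newick(cls, newick: str, provenance: str = "parsed") -> "Tree":
        return cls(TreeNode.read(io.StringIO(newick)), provenance=provenance)

    def tip_distances(self) -> DistanceMatrix:
        dm = self.root.tip_tip_distances()
        ids = list(dm.ids)
        return DistanceMatrix(ids, dm.data)


def select_family(
    annotations: Sequence[RegulatoryAnnotation],
    architectures: Mapping[str, DomainArchitecture],
    sequences: Mapping[str, str],
    accession: str,
    co_require: Sequence[str] = (),
    registry: PfamRegistry = DEFAULT_REGISTRY,
    bgcs: Sequence[BGCRecord] | None = None,
) -> FamilySelection:
    """All regulatory proteins whose architecture contains ``accession``.

    ``co_require`` lists additional accessions that must also be present
    (e.g. require the CA domain alongside HisKA). ``sequences`` maps
    protein_id to the full-length amino-acid sequence.
    """
    if accession not in registry.all_accessions:
        raise ValueError(f"{accession} is not in the domain registry")
    sources = {b.bgc_id: (b.source, b.product_class) for b in bgcs} if bgcs else {}
    members: list[FamilyMember] = []
    for ann in annotations:
        arch = architectures.get(ann.protein_id)
        if arch is None or accession not in arch.accession_set:
            continue
        if any(req not in arch.accession_set for req in co_require):
            continue
        seq = sequences.get(ann.protein_id)
        if seq is None:
            raise KeyError(f"no sequence for {ann.protein_id}")
        source, product = sources.get(ann.bgc_id, ("unknown", "other"))
        members.append(
            FamilyMember(
                protein_id=ann.protein_id,
                sequence=seq,
                source=source,
                product_class=product,
                mechanism=ann.mechanism,
                co_accessions=tuple(sorted(arch.accession_set - {accession})),
            )
        )
    return FamilySelection(accession=accession, members=members)


def pairwise_distance(
    a: str,
    b: str,
    matrix="BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Alignment-based distance in [0, 1]: 1 - identity fraction over the
    aligned columns of the optimal global alignment (affine gaps)."""
    return p_distance(a, b, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)


def build_distance_matrix(
    selection: FamilySelection,
    matrix="BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> DistanceMatrix:
    ids = selection.ids
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(
                selection.members[i].sequence,
                selection.members[j].sequence,
                matrix=matrix,
                gap_open=gap_open,
                gap_extend=gap_extend,
            )
    return DistanceMatrix(ids, d)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining (Saitou-Nei) with deterministic tie handling.

    Q ties are broken toward the lowest index pair; negative branch lengths
    are clamped to zero with the deficit moved onto the sister edge. With
    two taxa the result is a single edge split evenly between the leaves so
    that the leaf-to-leaf path equals the input distance.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    d = dm.d.astype(float).copy()

    if n == 2:
        for node in nodes:
            node.length = d[0, 1] / 2.0
        root = TreeNode(children=nodes)
        return Tree(root)

    active = list(range(n))
    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair wins on ties: argmin of row-major scan
        flat = int(np.argmin(q))
        i_loc, j_loc = divmod(flat, k)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = dij / 2.0 + (r[i_loc] - r[j_loc]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])

        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for m_ in active:
            if m_ in (i, j):
                continue
            new_row[m_] = 0.5 * (d[i, m_] + d[j, m_] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [m_ for m_ in active if m_ not in (i, j)] + [len(nodes) - 1]

    # final three nodes joined at an unrooted trifurcation
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = [la, lb, lc]
    for idx in range(3):
        if lens[idx] < 0:
            deficit = -lens[idx]
            lens[idx] = 0.0
            # move the deficit to the longer of the two sister edges
            sister = max((x for x in range(3) if x != idx), key=lambda x: lens[x])
            lens[sister] += deficit
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), lens):
        node.length = ln
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root)


def build_family_tree(
    selection: FamilySelection,
    matrix="BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> Tree:
    """Internal route: p-distance matrix + neighbor-joining."""
    if len(selection.members) < 2:
        raise ValueError("need at least 2 family members to build a tree")
    return nj_tree(build_distance_matrix(selection, matrix, gap_open, gap_extend))


DEFAULT_ALIGNER_CMD = ("muscle", "-align", "{in}", "-output", "{out}")


def run_external_pipeline(
    selection: FamilySelection,
    aligner_cmd: Sequence[str] = DEFAULT_ALIGNER_CMD,
    fasttree_path: str = "fasttree",
) -> Tree:
    """Align the family with an external aligner, then build a FastTree tree.

    ``aligner_cmd`` is a command template; ``{in}`` is replaced with the
    input FASTA path and ``{out}``, if present, with the output path
    (otherwise stdout is captured). Requires >= 3 members.
    """
    if len(selection.members) < 3:
        raise ValueError("external pipeline requires at least 3 members")
    if shutil.which(aligner_cmd[0]) is None:
        raise EngineUnavailableError(
            f"aligner {aligner_cmd[0]!r} not found on PATH; use the internal "
            "route (build_family_tree) instead"
        )
    if shutil.which(fasttree_path) is None:
        raise EngineUnavailableError(
            f"{fasttree_path!r} not found on PATH; use the internal route "
            "(build_family_tree) instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        faa = tmp / "family.faa"
        aln = tmp / "family.aln"
        with open(faa, "w") as handle:
            for m in selection.members:
                handle.write(f">{m.protein_id}\n{m.sequence}\n")
        cmd = [c.replace("{in}", str(faa)).replace("{out}", str(aln)) for c in aligner_cmd]
        capture = "{out}" not in "".join(aligner_cmd)
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"aligner failed ({proc.returncode}): {proc.stderr}")
        if capture:
            aln.write_text(proc.stdout)
        proc = subprocess.run(
            [fasttree_path, str(aln)], capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise RuntimeError(f"FastTree failed ({proc.returncode}): {proc.stderr}")
        return Tree.from_newick(proc.stdout.strip(), provenance="external")


def export_tree_bundle(
    tree: Tree,
    selection: FamilySelection,
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write newick + Microreact-style metadata CSV (first column ``id``).

    Every tree leaf must have a metadata row; offenders are listed in the
    error.
    """
    out_prefix = Path(out_prefix)
    meta = {m.protein_id: m for m in selection.members}
    missing = [name for name in tree.leaf_names if name not in meta]
    if missing:
        raise ValueError(f"no metadata for tree leaves: {', '.join(missing)}")
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    nwk_path = out_prefix.with_suffix(".nwk")
    csv_path = out_prefix.with_suffix(".csv")
    nwk_path.write_text(tree.newick + "\n")
    with open(csv_path, "w") as handle:
        handle.write("id,source,product_class,mechanism,co_domains\n")
        for name in tree.leaf_names:
            m = meta[name]
            handle.write(
                f"{m.protein_id},{m.source},{m.product_class},{m.mechanism},"
                f"{';'.join(m.co_accessions)}\n"
            )
    return nwk_path, csv_path
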