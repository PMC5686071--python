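"""Readers and writers for the external formats the pipeline consumes.

Conventions
-----------
* Gene tables are GFF3-like TSVs with 1-based inclusive coordinates on
  disk; in memory every coordinate is 0-based half-open.
* Trees are Newick with branch lengths in Myr; whole-genome-duplication
  (WGD) branches carry a ``[&wgd=<tag>]`` comment on the branch.
* Negative-strand genes store their CDS already reverse-complemented,
  i.e. in coding orientation, so downstream reading-frame rules apply
  directly.

No science lives here: validation and (de)serialisation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed input file (names the offending line where possible)."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# Gene records
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = [
    "gene_id",
    "species",
    "contig",
    "start",
    "end",
    "strand",
    "exons",
    "cds",
    "protein",
]


@dataclass
class GeneRecord:
    """A candidate gene: genomic location, exon structure and CDS.

    Coordinates are 0-based half-open.  ``exons`` are sorted 5'->3' on the
    coding strand and must not overlap.  ``cds`` is stored in coding
    orientation (already reverse-complemented for minus-strand genes) and
    may contain ``N``.
    """

    gene_id: str
    species: str
    contig: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: str
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start > end")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"{self.gene_id}: exon start > end")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping/unsorted exons")
            prev_end = e
        if self.protein is not None and len(self.cds) % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3 "
                "although a protein is attached"
            )

    @property
    def n_count(self) -> int:
        return self.cds.upper().count("N")


def _parse_exons(text: str, line_no: int) -> tuple[tuple[int, int], ...]:
    exons = []
    if text.strip():
        for part in text.split(","):
            try:
                a, b = part.split("-")
                # disk 1-based inclusive -> internal 0-based half-open
                exons.append((int(a) - 1, int(b)))
            except ValueError as exc:
                raise FormatError(f"line {line_no}: bad exon field {part!r}") from exc
    return tuple(exons)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a GFF3-like TSV gene table into validated :class:`GeneRecord` s."""
    records: list[GeneRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = GENE_TABLE_COLUMNS[:-1]
        if header[: len(required)] != required:
            raise FormatError(f"line 1: expected columns {required}, got {header}")
        has_protein = len(header) > len(required) and header[len(required)] == "protein"
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(required):
                raise FormatError(f"line {line_no}: expected >= {len(required)} fields")
            gid, sp, contig, start, end, strand, exons, cds = fields[:8]
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise FormatError(f"line {line_no}: non-integer coordinate") from exc
            protein = None
            if has_protein and len(fields) > 8 and fields[8].strip():
                protein = fields[8].strip()
            records.append(
                GeneRecord(
                    gene_id=gid,
                    species=sp,
                    contig=contig,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    exons=_parse_exons(exons, line_no),
                    cds=cds.strip().upper(),
                    protein=protein,
                )
            )
    return records


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for r in records:
            exons = ",".join(f"{s + 1}-{e}" for s, e in r.exons)
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        r.species,
                        r.contig,
                        str(r.start + 1),
                        str(r.end),
                        r.strand,
                        exons,
                        r.cds,
                        r.protein or "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


class SpeciesTree:
    """Rooted, time-calibrated species tree with stable node ids.

    Thin wrapper around a :class:`dendropy.Tree`.  Node ids: leaves use
    their taxon label; internal nodes are ``N<k>`` where ``k`` is the
    postorder index under a canonical child ordering (children sorted by
    the smallest leaf label below them), so ids are a pure function of the
    topology and survive serialisation round trips.

    The branch *above* a node is identified by that node's id; WGD marks
    live on branches (``wgd_branches`` maps branch id -> tag, e.g. "3R").
    """

    def __init__(self, tree: dendropy.Tree, wgd_branches: Mapping[str, str] | None = None):
        if tree.seed_node is None:
            raise ValidationError("empty tree")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("negative branch length")
        self._tree = tree
        self._assign_ids()
        self.wgd_branches: dict[str, str] = dict(wgd_branches or {})
        for nd in tree.preorder_node_iter():
            tag = nd.annotations.get_value("wgd", None)
            if tag is not None:
                self.wgd_branches[nd.id] = str(tag)
        unknown = set(self.wgd_branches) - set(self._nodes_by_id)
        if unknown:
            raise ValidationError(f"WGD mark on unknown branch id(s): {sorted(unknown)}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            extract_comment_metadata=True,
            rooting="force-rooted",
        )
        root = tree.seed_node
        if len(root.child_nodes()) > 2:
            raise ValidationError("multifurcating root: the reference cladogram is rooted")
        return cls(tree)

    @classmethod
    def read(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text())

    # -- node identity -----------------------------------------------------

    def _assign_ids(self) -> None:
        def min_leaf(nd) -> str:
            if nd.is_leaf():
                return nd.taxon.label
            return min(min_leaf(c) for c in nd.child_nodes())

        for nd in self._tree.preorder_node_iter():
            nd._child_nodes.sort(key=min_leaf)
        counter = 0
        self._nodes_by_id: dict[str, dendropy.Node] = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                nd.id = nd.taxon.label
            else:
                counter += 1
                nd.id = f"N{counter}"
            self._nodes_by_id[nd.id] = nd

    # -- views -------------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root_id(self) -> str:
        return self._tree.seed_node.id

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def node(self, node_id: str) -> dendropy.Node:
        return self._nodes_by_id[node_id]

    def node_ids(self, order: str = "postorder") -> list[str]:
        it = (
            self._tree.postorder_node_iter()
            if order == "postorder"
            else self._tree.preorder_node_iter()
        )
        return [nd.id for nd in it]

    def children(self, node_id: str) -> list[str]:
        return [c.id for c in self._nodes_by_id[node_id].child_nodes()]

    def parent(self, node_id: str) -> str | None:
        p = self._nodes_by_id[node_id].parent_node
        return p.id if p is not None else None

    def branch_length(self, node_id: str) -> float:
        ln = self._nodes_by_id[node_id].edge.length
        return float(ln) if ln is not None else 0.0

    def depths(self) -> dict[str, float]:
        """Distance from the root to every node."""
        out = {self.root_id: 0.0}
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is not None:
                out[nd.id] = out[nd.parent_node.id] + (nd.edge.length or 0.0)
        return out

    def height(self) -> float:
        d = self.depths()
        return max(d[lf] for lf in self.leaf_labels)

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = self.depths()
        leaf_depths = [d[lf] for lf in self.leaf_labels]
        return max(leaf_depths) - min(leaf_depths) <= tol

    def mrca_depths(self, leaves: Sequence[str] | None = None):
        """Matrix of root->MRCA distances for every leaf pair (and leaf depths
        on the diagonal); the shared-path-length matrix of Brownian motion."""
        import numpy as np

        leaves = list(leaves) if leaves is not None else self.leaf_labels
        depth = self.depths()
        n = len(leaves)
        mat = np.zeros((n, n))
        # ancestors (inclusive) per leaf
        anc: dict[str, list[str]] = {}
        for lf in leaves:
            chain = []
            cur: str | None = lf
            while cur is not None:
                chain.append(cur)
                cur = self.parent(cur)
            anc[lf] = chain
        sets = {lf: set(anc[lf]) for lf in leaves}
        for i, a in enumerate(leaves):
            mat[i, i] = depth[a]
            for j in range(i + 1, n):
                b = leaves[j]
                common = next(x for x in anc[a] if x in sets[b])
                mat[i, j] = mat[j, i] = depth[common]
        return mat, leaves

    def prune_to(self, keep: Sequence[str]) -> "SpeciesTree":
        """A new tree retaining only the given leaves (suppressing any
        degree-2 nodes created); WGD marks are re-attached to the surviving
        branch that contains the marked one."""
        wgd_leafsets = []
        for bid, tag in self.wgd_branches.items():
            below = self._leafset_below(bid) & set(keep)
            if below:
                wgd_leafsets.append((below, tag))
        tree = self._tree.clone(depth=1)
        taxa = [t for t in tree.taxon_namespace if t.label in set(keep)]
        tree.retain_taxa(taxa)
        tree.purge_taxon_namespace()
        for nd in tree.preorder_node_iter():
            nd.annotations.drop()
        out = SpeciesTree(tree)
        for leafset, tag in wgd_leafsets:
            # smallest surviving clade containing the old clade
            best = None
            for nid in out.node_ids():
                ls = out._leafset_below(nid)
                if leafset <= ls and (best is None or len(ls) < len(best[1])):
                    best = (nid, ls)
            if best is not None and best[1] == leafset and best[0] != out.root_id:
                out.wgd_branches[best[0]] = tag
        return out

    def _leafset_below(self, node_id: str) -> frozenset:
        nd = self._nodes_by_id[node_id]
        if nd.is_leaf():
            return frozenset([nd.taxon.label])
        return frozenset(lf.taxon.label for lf in nd.leaf_iter())

    # -- serialisation -----------------------------------------------------

    def to_newick(self) -> str:
        for nd in self._tree.preorder_node_iter():
            nd.annotations.drop(name="wgd")
            if nd.id in self.wgd_branches:
                nd.annotations.add_new("wgd", self.wgd_branches[nd.id])
        text = self._tree.as_string(
            schema="newick",
            suppress_annotations=False,
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return text.strip() + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())


def read_tree(path: str | Path) -> SpeciesTree:
    return SpeciesTree.read(path)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Order-preserving id -> sequence mapping; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Habitat table
# ---------------------------------------------------------------------------

SALINITY_STATES = ("freshwater", "marine")
DEPTH_STATES = ("above30", "below50", "unknown")


@dataclass
class HabitatTable:
    """species -> (salinity, depth class).

    Depth classes follow the shallow/deep split used throughout: living
    depth < 30 m ("above30") vs > 50 m ("below50"); species between the
    two cut-offs, or without data, are "unknown".
    """

    salinity: dict[str, str] = field(default_factory=dict)
    depth_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, v in self.salinity.items():
            if v not in SALINITY_STATES:
                raise ValidationError(f"{sp}: bad salinity {v!r}")
        for sp, v in self.depth_class.items():
            if v not in DEPTH_STATES:
                raise ValidationError(f"{sp}: bad depth class {v!r}")

    def species(self) -> list[str]:
        return sorted(set(self.salinity) | set(self.depth_class))

    def states_for(self, comparison: str) -> dict[str, str]:
        """Leaf states for one pairwise comparison; species with unknown
        depth are simply absent from the depth mapping."""
        if comparison == "salinity":
            return dict(self.salinity)
        if comparison == "depth":
            return {s: v for s, v in self.depth_class.items() if v != "unknown"}
        raise ValueError(f"unknown comparison {comparison!r}")


def read_habitat_table(path: str | Path) -> HabitatTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    for col in ("species", "salinity", "depth_class"):
        if col not in df.columns:
            raise FormatError(f"habitat table missing column {col!r}")
    return HabitatTable(
        salinity=dict(zip(df["species"], df["salinity"])),
        depth_class=dict(zip(df["species"], df["depth_class"])),
    )


def write_habitat_table(table: HabitatTable, path: str | Path) -> None:
    rows = [
        {
            "species": sp,
            "salinity": table.salinity.get(sp, "unknown"),
            "depth_class": table.depth_class.get(sp, "unknown"),
        }
        for sp in table.species()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tuning-shift table
# ---------------------------------------------------------------------------


@dataclass
class TuningShiftTable:
    """Experimentally grounded spectral shifts of tuning-site substitutions.

    One row per substitution: opsin family, bovine-rhodopsin-numbered site,
    from/to residue and the shift of the absorbance maximum in nm (negative
    = blue shift).  Rows sharing a non-empty ``interaction_group`` interact
    non-additively: when all members co-occur the group's ``combined_shift``
    replaces the member sum.  Only shifts of at least 5 nm are admitted.
    """

    df: pd.DataFrame

    REQUIRED = ["family", "site", "from_res", "to_res", "shift_nm"]

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise FormatError(f"tuning table missing column {col!r}")
        if "interaction_group" not in self.df.columns:
            self.df["interaction_group"] = ""
        if "combined_shift" not in self.df.columns:
            self.df["combined_shift"] = float("nan")
        if "reversible" not in self.df.columns:
            self.df["reversible"] = 1
        self.df["interaction_group"] = self.df["interaction_group"].fillna("")
        self.df["site"] = self.df["site"].astype(int)
        self.df["shift_nm"] = self.df["shift_nm"].astype(float)
        if (self.df["shift_nm"].abs() < 5).any():
            raise ValidationError("tuning table contains a |shift| < 5 nm entry")
        dup = self.df.duplicated(subset=["family", "site", "from_res", "to_res"])
        if dup.any():
            raise ValidationError("duplicate (family, site, from, to) rows in tuning table")

    def lookup(self, family: str, site: int, from_res: str, to_res: str) -> float:
        """Shift for a substitution; reversible rows may be used backwards
        with the sign flipped.  KeyError if absent (never a silent zero)."""
        m = self.df[
            (self.df["family"] == family)
            & (self.df["site"] == site)
            & (self.df["from_res"] == from_res)
            & (self.df["to_res"] == to_res)
        ]
        if len(m):
            return float(m.iloc[0]["shift_nm"])
        rev = self.df[
            (self.df["family"] == family)
            & (self.df["site"] == site)
            & (self.df["from_res"] == to_res)
            & (self.df["to_res"] == from_res)
            & (self.df["reversible"].astype(int) == 1)
        ]
        if len(rev):
            return -float(rev.iloc[0]["shift_nm"])
        raise KeyError(f"no tuning entry for {family} {from_res}{site}{to_res}")

    def groups(self, family: str) -> dict[str, pd.DataFrame]:
        fam = self.df[(self.df["family"] == family) & (self.df["interaction_group"] != "")]
        return {g: sub for g, sub in fam.groupby("interaction_group")}


def read_tuning_shift_table(path: str | Path) -> TuningShiftTable:
    return TuningShiftTable(pd.read_csv(path, sep="\t", comment="#"))


# ---------------------------------------------------------------------------
# Copy-number matrix
# ---------------------------------------------------------------------------


def read_copy_number_matrix(path: str | Path) -> pd.DataFrame:
    """species x family integer count table (species as the index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_copy_number_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="species")
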