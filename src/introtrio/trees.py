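"""Reading gene trees and alignments, plus the rooting/distance primitives.

Gene trees arrive as newick, either one file per gene (``*.nwk``) or a
two-column TSV (``gene_id<TAB>newick``).  Tip labels carry taxon identity
(matched by prefix through a :class:`TaxonScheme`); internal node labels,
where numeric, are read as bootstrap supports on the 0–100 scale.

The central operation is :func:`extract_rooted_triplet`: given a gene tree
containing (possibly many) tips, keep genes present in exactly one copy per
focal taxon ("1:1:1"), decide which focal pair is sister by letting every
non-focal tip vote on the induced quartet, and record the pair support and
the pairwise patristic distances.  Trees with no context tips can fall back
to midpoint rooting of the bare 3-taxon tree.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO

from .records import Topology, TripletRecord, TripletRejection


class TreeParseError(ValueError):
    """A newick input could not be parsed; message names the gene/line."""


class MissingBranchLengthError(ValueError):
    """A distance-based operation hit an edge without a branch length."""


class UnresolvableRootError(ValueError):
    """Midpoint rooting failed (zero-length longest tip-to-tip path)."""


@dataclass(frozen=True)
class TaxonScheme:
    """Maps tip labels to the four roles by label prefix.

    ``taxon_a``/``taxon_b`` are the putative sister pair of the species
    tree, ``taxon_c`` the third ingroup taxon, ``outgroup`` the outgroup.
    A tip matching none of the prefixes is a non-focal "context" tip.
    """

    taxon_a: str
    taxon_b: str
    taxon_c: str
    outgroup: str

    def __post_init__(self) -> None:
        labels = (self.taxon_a, self.taxon_b, self.taxon_c, self.outgroup)
        if any(not lab for lab in labels):
            raise ValueError("taxon scheme labels must be non-empty")
        if len(set(labels)) != 4:
            raise ValueError(f"taxon scheme labels must be distinct: {labels}")

    @property
    def roles(self) -> dict[str, str]:
        return {
            "A": self.taxon_a,
            "B": self.taxon_b,
            "C": self.taxon_c,
            "O": self.outgroup,
        }

    def assign(self, tip_label: str) -> str | None:
        """Return 'A', 'B', 'C', 'O' or None for a tip label.

        Raises if more than one prefix matches (the scheme would be
        ambiguous for this label).
        """
        hits = [role for role, pre in self.roles.items() if tip_label.startswith(pre)]
        if len(hits) > 1:
            raise ValueError(
                f"tip label {tip_label!r} matches multiple scheme prefixes: {hits}"
            )
        return hits[0] if hits else None


@dataclass
class GeneTree:
    """A per-gene phylogeny; thin wrapper around a dendropy tree."""

    gene_id: str
    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeParseError(f"{self.gene_id}: duplicate tip labels {dupes}")
        for node in self.tree:
            ln = node.edge.length
            if ln is not None and ln < 0:
                raise TreeParseError(
                    f"{self.gene_id}: negative branch length {ln} at {node}"
                )

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def has_branch_lengths(self) -> bool:
        """True iff every non-root edge carries a length.

        Trees without lengths stay usable for the topology-only census but
        are rejected by the distance-based stages.
        """
        root = self.tree.seed_node
        for node in self.tree:
            if node is root:
                continue
            if node.edge.length is None:
                return False
        return True

    def find_leaf(self, label: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise ValueError(f"{self.gene_id}: tip {label!r} not in tree")


def parse_support(label: str | None, context: str = "") -> float | None:
    """Interpret an internal node label as bootstrap support in [0, 100].

    Values in (0, 1] are taken to be proportions and rescaled by 100 (with
    a warning), since both conventions occur in the wild.  Non-numeric or
    out-of-range labels yield None (support unknown).
    """
    if label is None or label == "":
        return None
    try:
        v = float(label)
    except ValueError:
        return None
    if 0.0 < v <= 1.0:
        warnings.warn(
            f"{context}: support {v} in (0,1] interpreted as a proportion "
            "and rescaled to percent",
            stacklevel=2,
        )
        v *= 100.0
    if v < 0.0 or v > 100.0:
        warnings.warn(f"{context}: support {v} outside [0,100] ignored", stacklevel=2)
        return None
    return v


def _parse_newick(text: str, gene_id: str) -> GeneTree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise TreeParseError(f"{gene_id}: unparsable newick: {exc}") from exc
    if next(tree.leaf_node_iter(), None) is None:
        raise TreeParseError(f"{gene_id}: empty tree")
    return GeneTree(gene_id=gene_id, tree=tree)


def read_tree_collection(path: str | Path, scheme: TaxonScheme | None = None) -> list[GeneTree]:
    """Read a gene-tree collection from a TSV file or a ``*.nwk`` directory.

    TSV: one ``gene_id<TAB>newick`` per line.  Directory: one tree per
    ``*.nwk`` file, gene_id = file stem, files taken in sorted order.
    Malformed trees raise :class:`TreeParseError` naming the gene and line;
    duplicate gene ids are an error.
    """
    path = Path(path)
    entries: list[tuple[str, str, str]] = []  # (gene_id, newick, where)
    if path.is_dir():
        for f in sorted(path.glob("*.nwk")):
            entries.append((f.stem, f.read_text().strip(), str(f)))
    else:
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t", 1)
                if len(parts) != 2:
                    raise TreeParseError(
                        f"{path}:{ln}: expected 'gene_id<TAB>newick', got {line[:40]!r}"
                    )
                entries.append((parts[0], parts[1], f"{path}:{ln}"))
    seen: set[str] = set()
    out: list[GeneTree] = []
    for gene_id, nwk, where in entries:
        if gene_id in seen:
            raise TreeParseError(f"{where}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            out.append(_parse_newick(nwk, gene_id))
        except TreeParseError as exc:
            raise TreeParseError(f"{where}: {exc}") from exc
    return out


def _edge_length(node: dendropy.Node, gene_id: str) -> float:
    ln = node.edge.length
    if ln is None:
        raise MissingBranchLengthError(
            f"{gene_id}: missing branch length on path (lengths are required "
            "for distance operations, not defaulted to 0)"
        )
    return ln


def patristic_distance(gtree: GeneTree, tip1: str, tip2: str) -> float:
    """Sum of branch lengths on the unique path between two tips."""
    if tip1 == tip2:
        gtree.find_leaf(tip1)
        return 0.0
    n1 = gtree.find_leaf(tip1)
    n2 = gtree.find_leaf(tip2)
    up1: dict[int, float] = {}
    d = 0.0
    node = n1
    while node is not None:
        up1[id(node)] = d
        if node.parent_node is not None:
            d += _edge_length(node, gtree.gene_id)
        node = node.parent_node
    d = 0.0
    node = n2
    while id(node) not in up1:
        d += _edge_length(node, gtree.gene_id)
        node = node.parent_node
    return d + up1[id(node)]


def total_tree_length(gtree: GeneTree) -> float:
    """Sum of all branch lengths in the tree."""
    total = 0.0
    root = gtree.tree.seed_node
    for node in gtree.tree:
        ln = node.edge.length
        if ln is None:
            if node is root:
                continue
            raise MissingBranchLengthError(f"{gtree.gene_id}: missing branch length")
        total += ln
    return total


def midpoint_root(gtree: GeneTree) -> tuple[GeneTree, str | None]:
    """Root at the midpoint of the longest tip-to-tip path.

    Returns the rooted tree and, when the root lands on a pendant edge, the
    label of that tip (the "midpoint-selected outgroup").  Ties are broken
    toward the lexicographically smallest tip label, for reproducibility.
    Raises :class:`UnresolvableRootError` when the longest path has zero
    length.
    """
    tips = gtree.tip_labels
    if len(tips) < 3:
        raise ValueError(f"{gtree.gene_id}: midpoint rooting needs >= 3 tips")
    if len(tips) == 3:
        x, y, z = sorted(tips)
        d = {
            frozenset((x, y)): patristic_distance(gtree, x, y),
            frozenset((x, z)): patristic_distance(gtree, x, z),
            frozenset((y, z)): patristic_distance(gtree, y, z),
        }
        pend = {
            x: 0.5 * (d[frozenset((x, y))] + d[frozenset((x, z))] - d[frozenset((y, z))]),
            y: 0.5 * (d[frozenset((x, y))] + d[frozenset((y, z))] - d[frozenset((x, z))]),
            z: 0.5 * (d[frozenset((x, z))] + d[frozenset((y, z))] - d[frozenset((x, y))]),
        }
        if max(d.values()) <= 0.0:
            raise UnresolvableRootError(
                f"{gtree.gene_id}: zero-length longest path; midpoint undefined"
            )
        pmax = max(pend.values())
        out = min(lab for lab, p in pend.items() if p == pmax)
        rest = sorted(set(tips) - {out})
        p_far = max(pend[t] for t in rest)
        tip_side = 0.5 * (pend[out] + p_far)  # root-to-outgroup-tip distance
        hub_side = pend[out] - tip_side
        nwk = (
            f"(({rest[0]}:{pend[rest[0]]!r},{rest[1]}:{pend[rest[1]]!r})"
            f":{hub_side!r},{out}:{tip_side!r});"
        )
        return _parse_newick(nwk, gtree.gene_id), out
    # larger trees: delegate to dendropy's midpoint rooting
    clone = gtree.tree.clone(depth=1)
    clone.reroot_at_midpoint(update_bipartitions=False)
    rooted = GeneTree(gene_id=gtree.gene_id, tree=clone)
    out = None
    kids = clone.seed_node.child_nodes()
    leaf_kids = [k for k in kids if k.is_leaf()]
    if len(leaf_kids) == 1:
        out = leaf_kids[0].taxon.label
    return rooted, out


def _bfs_from(gtree: GeneTree, start: dendropy.Node):
    """Predecessor map toward ``start`` and (if available) distances from it."""
    adj: dict[int, list[tuple[dendropy.Node, float | None]]] = {}
    nodes: dict[int, dendropy.Node] = {}
    for node in gtree.tree:
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        if node.parent_node is not None:
            adj.setdefault(id(node.parent_node), [])
            adj[id(node)].append((node.parent_node, node.edge.length))
            adj[id(node.parent_node)].append((node, node.edge.length))
    pred: dict[int, dendropy.Node] = {}
    dist: dict[int, float] = {id(start): 0.0}
    ok_lengths = True
    q = deque([start])
    seen = {id(start)}
    while q:
        cur = q.popleft()
        for nbr, ln in adj[id(cur)]:
            if id(nbr) in seen:
                continue
            seen.add(id(nbr))
            pred[id(nbr)] = cur
            if ln is None:
                ok_lengths = False
                dist[id(nbr)] = math.nan
            else:
                dist[id(nbr)] = dist[id(cur)] + ln
            q.append(nbr)
    return pred, dist, ok_lengths


def _chain_to_start(node: dendropy.Node, pred: dict[int, dendropy.Node]):
    chain = [node]
    while id(chain[-1]) in pred:
        chain.append(pred[id(chain[-1])])
    return chain  # node ... start


def extract_rooted_triplet(
    gtree: GeneTree,
    scheme: TaxonScheme,
    fallback_midpoint: bool = True,
) -> TripletRecord | TripletRejection:
    """Extract the rooted A/B/C triplet from a (possibly large) gene tree.

    Accepts only genes with exactly one tip per focal taxon (1:1:1).  Every
    non-focal tip votes on the induced quartet {a, b, c, o}: the vote is the
    focal pair on the far side of o's attachment point on the {a, b, c}
    spanning subtree; the majority decides the topology.  The pair support
    is the parsed label of the spanning-subtree hub node — which is the
    focal-pair MRCA under rooting at *any* concordant context tip, so no
    per-tip choice is needed.  With no context tips the record falls back
    to midpoint rooting of the bare triplet (``provenance="midpoint"``).

    Rejection reasons: ``copy-number`` (not 1:1:1), ``no-context`` (no
    non-focal tips and midpoint fallback unavailable), ``ambiguous`` (vote
    tie or all votes abstain at a polytomy).
    """
    leaves = list(gtree.tree.leaf_node_iter())
    by_role: dict[str, list[dendropy.Node]] = {"A": [], "B": [], "C": []}
    context: list[dendropy.Node] = []
    for lf in leaves:
        role = scheme.assign(lf.taxon.label)
        if role in by_role:
            by_role[role].append(lf)
        else:
            context.append(lf)  # outgroup and any other non-focal tips vote
    counts = {r: len(v) for r, v in by_role.items()}
    if any(c != 1 for c in counts.values()):
        return TripletRejection(
            gtree.gene_id, "copy-number", f"focal copy counts {counts}"
        )
    a, b, c = by_role["A"][0], by_role["B"][0], by_role["C"][0]

    pred, dist, ok_lengths = _bfs_from(gtree, a)
    path_ab = list(reversed(_chain_to_start(b, pred)))  # a ... b
    path_ac = list(reversed(_chain_to_start(c, pred)))  # a ... c
    k = 0
    while k < min(len(path_ab), len(path_ac)) and path_ab[k] is path_ac[k]:
        k += 1
    hub = path_ab[k - 1]
    span = {id(n) for n in path_ab} | {id(n) for n in path_ac}
    side: dict[int, Topology] = {}
    for n in path_ab[: k - 1]:  # a-side (excludes hub)
        side[id(n)] = Topology.BC
    for n in path_ab[k:]:  # b-side
        side[id(n)] = Topology.AC
    for n in path_ac[k:]:  # c-side
        side[id(n)] = Topology.AB

    # pairwise patristic distances among the focal tips
    if ok_lengths:
        d_ab = dist[id(b)]
        d_ac = dist[id(c)]
        d_bc = dist[id(b)] + dist[id(c)] - 2.0 * dist[id(hub)]
        total = 0.5 * (d_ab + d_ac + d_bc)
    else:
        d_ab = d_ac = d_bc = total = math.nan

    if not context:
        if fallback_midpoint and ok_lengths:
            return _midpoint_triplet_record(gtree.gene_id, d_ab, d_ac, d_bc)
        return TripletRejection(
            gtree.gene_id,
            "no-context",
            "no non-focal tips" + ("" if ok_lengths else "; no branch lengths"),
        )

    votes: dict[Topology, int] = {Topology.AB: 0, Topology.BC: 0, Topology.AC: 0}
    attach: dict[int, dendropy.Node] = {}  # context leaf -> attachment node
    for o in context:
        chain = _chain_to_start(o, pred)
        m = next(n for n in chain if id(n) in span)
        attach[id(o)] = m
        if m is hub:
            continue  # polytomy-like attachment: abstain
        votes[side[id(m)]] += 1
    best = max(votes.values())
    winners = [t for t, v in votes.items() if v == best]
    if best == 0 or len(winners) > 1:
        return TripletRejection(
            gtree.gene_id, "ambiguous", f"context votes {votes}"
        )
    topo = winners[0]

    support = parse_support(hub.label, context=gtree.gene_id)

    # zero-length internal edge between the pair MRCA (hub) and the
    # attachment of the first majority-class context tip -> UNRESOLVED
    if ok_lengths:
        o_first = next(
            o for o in context
            if attach[id(o)] is not hub and side[id(attach[id(o)])] is topo
        )
        internal = abs(dist[id(attach[id(o_first)])] - dist[id(hub)])
        if internal == 0.0:
            topo = Topology.UNRESOLVED

    rec = TripletRecord(
        gene_id=gtree.gene_id,
        topology=topo,
        support=support,
        d_ab=d_ab,
        d_ac=d_ac,
        d_bc=d_bc,
        total_length=total,
        provenance="context-rooted",
    )
    if ok_lengths:
        _attach_midpoint_metadata(rec)
    return rec


def _midpoint_metadata(d_ab: float, d_ac: float, d_bc: float):
    """Midpoint-selected outgroup of the unrooted 3-taxon star.

    The star's pendants are p_a=(d_ab+d_ac-d_bc)/2 etc.; the midpoint of the
    longest tip-to-tip path lands on the pendant of the tip with the largest
    pendant edge.  Ties go to the alphabetically first taxon key; a fully
    zero star is unresolvable (returns None).
    """
    pend = {
        "A": 0.5 * (d_ab + d_ac - d_bc),
        "B": 0.5 * (d_ab + d_bc - d_ac),
        "C": 0.5 * (d_ac + d_bc - d_ab),
    }
    if max(d_ab, d_ac, d_bc) <= 0.0:
        return None
    pmax = max(pend.values())
    out = min(t for t, p in pend.items() if p == pmax)
    return out, pend[out]


def _attach_midpoint_metadata(rec: TripletRecord) -> None:
    meta = _midpoint_metadata(rec.d_ab, rec.d_ac, rec.d_bc)
    if meta is not None:
        rec.midpoint_outgroup, rec.outgroup_branch = meta


def _midpoint_triplet_record(
    gene_id: str, d_ab: float, d_ac: float, d_bc: float
) -> TripletRecord:
    meta = _midpoint_metadata(d_ab, d_ac, d_bc)
    if meta is None:
        return TripletRecord(
            gene_id=gene_id,
            topology=Topology.UNRESOLVED,
            d_ab=d_ab,
            d_ac=d_ac,
            d_bc=d_bc,
            total_length=0.5 * (d_ab + d_ac + d_bc),
            provenance="midpoint",
        )
    out, branch = meta
    topo = {"A": Topology.BC, "B": Topology.AC, "C": Topology.AB}[out]
    return TripletRecord(
        gene_id=gene_id,
        topology=topo,
        support=None,
        d_ab=d_ab,
        d_ac=d_ac,
        d_bc=d_bc,
        total_length=0.5 * (d_ab + d_ac + d_bc),
        outgroup_branch=branch,
        midpoint_outgroup=out,
        provenance="midpoint",
    )


# ---------------------------------------------------------------------------
# alignments

@dataclass
class GeneAlignment:
    """One gene's multiple sequence alignment (equal-length rows)."""

    gene_id: str
    sequences: dict[str, str]  # original tip label -> sequence
    length: int = field(init=False)

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.sequences.values()}
        if len(lens) > 1:
            raise ValueError(f"{self.gene_id}: ragged alignment, lengths {sorted(lens)}")
        self.length = lens.pop() if lens else 0

    def row_for_role(self, scheme: TaxonScheme, role: str) -> str:
        hits = [s for lab, s in self.sequences.items() if scheme.assign(lab) == role]
        if len(hits) != 1:
            raise KeyError(
                f"{self.gene_id}: expected exactly one sequence for role {role}, "
                f"found {len(hits)}"
            )
        return hits[0]


@dataclass
class AlignmentRejection:
    gene_id: str
    reason: str


def read_alignments(
    path: str | Path, scheme: TaxonScheme
) -> tuple[list[GeneAlignment], list[AlignmentRejection]]:
    """Read per-gene FASTA alignments (a directory of ``*.fasta``/``*.fa``
    files, gene_id = stem, or a single file treated as one gene).

    A gene is rejected (not raised) when its rows have unequal length
    ("ragged") or when any of the four roles A/B/C/outgroup is not matched
    by exactly one record.
    """
    path = Path(path)
    files = (
        sorted(list(path.glob("*.fasta")) + list(path.glob("*.fa")))
        if path.is_dir()
        else [path]
    )
    alns: list[GeneAlignment] = []
    rejected: list[AlignmentRejection] = []
    for f in files:
        gene_id = f.stem
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(f), "fasta")}
        if len({len(s) for s in seqs.values()}) > 1:
            rejected.append(AlignmentRejection(gene_id, "ragged"))
            continue
        role_counts = {"A": 0, "B": 0, "C": 0, "O": 0}
        for lab in seqs:
            role = scheme.assign(lab)
            if role in role_counts:
                role_counts[role] += 1
        bad = [r for r, n in role_counts.items() if n != 1]
        if bad:
            names = {
                "A": scheme.taxon_a, "B": scheme.taxon_b,
                "C": scheme.taxon_c, "O": "outgroup",
            }
            rejected.append(
                AlignmentRejection(gene_id, f"missing {names[bad[0]]}" if role_counts[bad[0]] == 0 else f"multiple {names[bad[0]]}")
            )
            continue
        alns.append(GeneAlignment(gene_id=gene_id, sequences=seqs))
    return alns, rejected


def write_triplet_table(records, rejections, path: str | Path) -> None:
    """Normalized per-gene TSV: gene_id, topology, support, distances,
    total_length, provenance; rejected genes carry the rejection reason."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\ttopology\tsupport\td_AB\td_AC\td_BC\ttotal_length\tprovenance\n"
        )
        for r in records:
            sup = "" if r.support is None else f"{r.support:g}"
            fh.write(
                f"{r.gene_id}\t{r.topology.value}\t{sup}\t{r.d_ab:.6g}\t"
                f"{r.d_ac:.6g}\t{r.d_bc:.6g}\t{r.total_length:.6g}\t{r.provenance}\n"
            )
        for rej in rejections:
            fh.write(f"{rej.gene_id}\tREJECTED:{rej.reason}\t\t\t\t\t\t\n")
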