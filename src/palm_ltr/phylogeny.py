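"""Reverse-transcriptase phylogeny and lineage assignment.

RT amino-acid domains extracted from classified elements are placed on a
neighbor-joining tree together with labelled reference RTs; each element
takes the lineage of the smallest surrounding clade that contains references
of exactly one lineage (mixed or reference-free neighborhoods stay
undefined).

Distances are Poisson-corrected pairwise-alignment distances
(d = -ln(1 - p) over aligned non-gap columns) rather than distances from a
progressive multiple alignment: only tree topology near the labelled
references is consumed, and pairwise global alignment removes a heavy
dependency.  Neighbor joining is the canonical Saitou-Nei agglomeration
with deterministic lexicographic tie-breaking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .domains import ClassifiedElement
from .io import DomainRef

REF_PREFIX = "REF_"


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxon ids")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0) \
                or not np.all(np.isfinite(m)):
            raise ValueError("invalid distance matrix")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


@dataclass
class LineageAssignment:
    element_id: str
    lineage: str            # a named clade or "undefined"
    support: float          # distance to the nearest reference


def extract_rt(classified: ClassifiedElement, sequence: str,
               min_residues: int = 150) -> str | None:
    """Translated RT domain of an element, or None if absent/too short.

    ``sequence`` is the element's nucleotide sequence; the best RT hit's
    interval is translated in its own frame.  Only products of at least
    ``min_residues`` residues are returned.
    """
    hit = classified.census.get("RT")
    if hit is None:
        return None
    if hit.frame > 0:
        nt = sequence[hit.start:hit.end]
    else:
        from ._kmers import revcomp
        nt = revcomp(sequence[hit.start:hit.end])
    nt = nt[:len(nt) - len(nt) % 3]
    prot = str(Seq(nt).translate())
    if len(prot) < min_residues:
        return None
    return prot


def _pairwise_p_distance(a: str, b: str,
                         aligner: Align.PairwiseAligner) -> float:
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    n = same = 0
    for ca, cb in zip(sa, sb):
        if ca == "-" or cb == "-":
            continue
        n += 1
        same += ca == cb
    if n == 0:
        return 1.0
    return 1.0 - same / n


def pairwise_distance_matrix(sequences: dict[str, str],
                             poisson: bool = True,
                             max_distance: float = 5.0) -> DistanceMatrix:
    """Poisson-corrected (or raw p-) distances from global pairwise alignments."""
    ids = sorted(sequences)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    for tid in ids:
        if not sequences[tid]:
            raise ValueError(f"empty sequence for {tid}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pairwise_p_distance(sequences[ids[i]], sequences[ids[j]],
                                     aligner)
            if poisson:
                d = -math.log(1.0 - p) if p < 1.0 else max_distance
            else:
                d = p
            mat[i, j] = mat[j, i] = min(d, max_distance)
    return DistanceMatrix(ids, mat)


# ---------------------------------------------------------------------------
# neighbor joining


class _Node:
    __slots__ = ("name", "children", "min_leaf")

    def __init__(self, name: str | None,
                 children: list[tuple["_Node", float]] | None = None):
        self.name = name
        self.children = children or []
        self.min_leaf = name if name is not None else \
            min(c.min_leaf for c, _ in self.children)

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c.newick()}:{bl:.6f}"
                         for c, bl in sorted(self.children,
                                             key=lambda t: t[0].min_leaf))
        return f"({inner})"


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Canonical Saitou-Nei neighbor joining; returns an unrooted Newick tree.

    The pair minimizing the Q-criterion is joined each round; ties are broken
    by lexicographic taxon id.  Negative branch lengths are clamped to zero
    with the deficit shifted to the sister branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[_Node] = [_Node(t) for t in dm.ids]
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break on the joined taxa's smallest leaf names
        cands = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((min(nodes[active[i]].min_leaf, nodes[active[j]].min_leaf),
              max(nodes[active[i]].min_leaf, nodes[active[j]].min_leaf), i, j)
             for i, j in cands if i < j))
        i, j = best[2], best[3]
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = _Node(None, [(nodes[ai], li), (nodes[aj], lj)])
        # distances from the new internal node to the rest
        newdist = np.zeros(d.shape[0] + 1)
        for k_idx, ak in enumerate(active):
            if k_idx in (i, j):
                continue
            newdist[ak] = 0.5 * (sub[i, k_idx] + sub[j, k_idx] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = newdist[:-1]
        d[:-1, -1] = newdist[:-1]
        nodes.append(new)
        active = [a for k_idx, a in enumerate(active) if k_idx not in (i, j)]
        active.append(d.shape[0] - 1)

    # final three taxa join at one internal node with closed-form lengths
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    branches = []
    for node, bl in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        branches.append((node, max(bl, 0.0)))
    root = _Node(None, branches)
    return root.newick() + ";"


def assign_lineages(element_rts: dict[str, str],
                    reference_rts: list[DomainRef],
                    min_residues: int = 150,
                    ambiguity_margin: float = 0.05
                    ) -> list[LineageAssignment]:
    """Lineage of each element from its neighborhood in a joint NJ tree.

    References enter the tree with ids prefixed ``REF_``.  An element takes
    the lineage of the smallest clade containing it whose references are all
    of one lineage; a mixed or reference-free smallest clade leaves it
    undefined.  An element essentially equidistant between two lineages
    (runner-up lineage's nearest reference within ``ambiguity_margin`` of
    the winner's) is also left undefined, since its tree placement is then
    arbitrary.
    """
    refs = [r for r in reference_rts if r.kind == "RT"
            and len(r.sequence) >= min_residues]
    if not refs:
        raise ValueError("no RT references supplied")
    if not element_rts:
        return []
    ref_lineage = {REF_PREFIX + r.ref_id: r.lineage for r in refs}
    seqs = {REF_PREFIX + r.ref_id: r.sequence for r in refs}
    seqs.update(element_rts)
    dm = pairwise_distance_matrix(seqs)
    newick = neighbor_joining(dm)

    from skbio import TreeNode
    from io import StringIO
    tree = TreeNode.read(StringIO(newick), convert_underscores=False)
    # zero-length internal branches carry no topological signal (ties in the
    # distance matrix resolve arbitrarily): collapse them into polytomies so
    # the clade rule sees the true neighborhood
    for node in list(tree.non_tips(include_self=False)):
        if node.length is not None and node.length <= 1e-9 and node.parent:
            parent = node.parent
            parent.extend(node.children)
            parent.remove(node)

    assignments = []
    for eid in sorted(element_rts):
        i = dm.ids.index(eid)
        # an RT (near-)identical to a reference is that reference's lineage:
        # zero-length branches make its tree placement a polytomy tie
        zero = {ref_lineage[rid] for rid in ref_lineage
                if dm.matrix[i, dm.ids.index(rid)] < 1e-6}
        if zero:
            lineage = zero.pop() if len(zero) == 1 else "undefined"
            assignments.append(LineageAssignment(eid, lineage, 0.0))
            continue
        tip = tree.find(eid)
        lineage = "undefined"
        node = tip.parent
        prev = tip
        while node is not None:
            ref_tips = {t.name for t in node.tips()
                        if t.name and t.name.startswith(REF_PREFIX)}
            if ref_tips:
                lineages = {ref_lineage[t] for t in ref_tips}
                lineage = lineages.pop() if len(lineages) == 1 else "undefined"
                break
            prev = node
            node = node.parent
        i = dm.ids.index(eid)
        per_lineage: dict[str, float] = {}
        for rid, lin in ref_lineage.items():
            d = float(dm.matrix[i, dm.ids.index(rid)])
            per_lineage[lin] = min(per_lineage.get(lin, np.inf), d)
        ranked = sorted(per_lineage.items(), key=lambda kv: kv[1])
        support = ranked[0][1]
        if lineage != "undefined" and len(ranked) > 1:
            runner_up = min(d for lin, d in ranked if lin != lineage)
            if runner_up - per_lineage.get(lineage, np.inf) < ambiguity_margin:
                lineage = "undefined"
        assignments.append(LineageAssignment(eid, lineage, support))
    return assignments
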