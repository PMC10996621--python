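"""How recently did a family transpose?

Copies of a young family are nearly identical: terminal branch lengths in a
tree of the copies, pairwise substitutions/site, and 5'-vs-3' LTR divergence
of individual proviruses all approach zero. This module computes those
statistics from a consensus-anchored pseudo-alignment: each copy is globally
aligned to the family consensus and projected onto consensus columns
(insertions relative to the consensus are dropped), pairwise p-distances are
Jukes-Cantor corrected, and a neighbor-joining tree built from the distance
matrix supplies terminal branch lengths. NJ with JC distances is a
distance-based stand-in for likelihood tree inference; it is exact on
additive matrices, which is what the recency summaries consume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .annotate import InsertionCall
from .models import ErvFamilyModel
from .seq import revcomp

GAP = "-"


def _dna_aligner() -> Align.PairwiseAligner:
    # affine-gap global alignment; free terminal gaps so truncated copies
    # align to their homologous consensus window
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    _free_end_gaps(aligner)
    return aligner


def _free_end_gaps(aligner: Align.PairwiseAligner) -> None:
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython attribute names
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0


def anchor_align(copies: dict[str, str], consensus: str) -> dict[str, str]:
    """Project each copy onto consensus coordinates.

    Returns, per copy, a string of ``len(consensus)`` characters: the copy
    base aligned to each consensus column, ``-`` where the copy is deleted.
    Copies with fewer than 50% alignable (non-gap) columns are excluded with
    a warning.
    """
    aligner = _dna_aligner()
    out: dict[str, str] = {}
    for name, copy in copies.items():
        if copy == consensus:
            out[name] = copy
            continue
        aln = aligner.align(consensus, copy)[0]
        proj = [GAP] * len(consensus)
        tgt_blocks, qry_blocks = aln.aligned
        for (ts, te), (qs, qe) in zip(tgt_blocks, qry_blocks):
            proj[ts:te] = copy[qs:qe]
        projected = "".join(proj)
        alignable = len(consensus) - projected.count(GAP)
        if alignable < 0.5 * len(consensus):
            warnings.warn(f"{name}: <50% alignable to consensus; excluded")
            continue
        out[name] = projected
    return out


def p_distance(a: str, b: str, min_sites: int = 100) -> float:
    """Fraction of differing sites over shared non-gap columns."""
    if len(a) != len(b):
        raise ValueError("projections must have equal length")
    shared = 0
    diff = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        shared += 1
        if x != y:
            diff += 1
    if shared < min_sites:
        raise ValueError(f"only {shared} shared non-gap columns (< {min_sites})")
    return diff / shared


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p); defined for p < 3/4."""
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= 0.75:
        raise ValueError("Jukes-Cantor distance undefined for p >= 3/4")
    if p == 0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class DivergenceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, substitutions/site

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        self.values = v


def jc_matrix(projections: dict[str, str], min_sites: int = 100) -> DivergenceMatrix:
    """Pairwise JC distance matrix from consensus projections."""
    labels = list(projections)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(projections[labels[i]], projections[labels[j]], min_sites)
            mat[i, j] = mat[j, i] = jc_distance(p)
    return DivergenceMatrix(labels, mat)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c._nwk()}:{ln:.10g}" for c, ln in self.children)
        return f"({inner}){self.name or ''}"


@dataclass
class NjTree:
    root: TreeNode
    terminal_branch_lengths: dict[str, float]

    def newick(self) -> str:
        return self.root.newick()

    def leaf_path_lengths(self) -> dict[tuple[str, str], float]:
        """Sum of branch lengths along the path between every pair of leaves."""
        # distances from every node down to its leaves, then combine at each node
        paths: dict[tuple[str, str], float] = {}

        def collect(node: TreeNode) -> dict[str, float]:
            if not node.children:
                return {node.name: 0.0}
            sub = []
            for child, ln in node.children:
                d = {leaf: dist + ln for leaf, dist in collect(child).items()}
                sub.append(d)
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for la, da in sub[i].items():
                        for lb, db in sub[j].items():
                            key = (min(la, lb), max(la, lb))
                            paths[key] = da + db
            merged: dict[str, float] = {}
            for d in sub:
                merged.update(d)
            return merged

        collect(self.root)
        return paths


def nj_tree(matrix: DivergenceMatrix) -> NjTree:
    """Neighbor-joining tree with branch lengths.

    Standard Saitou-Nei agglomeration; exact on additive matrices. Ties in
    the Q criterion break to the lowest index pair. Negative branch lengths
    are clamped to zero (noted via a warning). With two taxa the single edge
    of length d is split d/2 + d/2.
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    D = matrix.values.astype(float).copy()
    terminal: dict[str, float] = {}

    def attach(parent: TreeNode, child: TreeNode, length: float) -> None:
        if length < -1e-12:
            warnings.warn(f"negative NJ branch length {length:.3g} clamped to 0")
        length = max(0.0, length)
        parent.children.append((child, length))
        if not child.children:
            terminal[child.name] = length

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * sub[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, bi, bj = best
        i_idx, j_idx = active[bi], active[bj]
        dij = sub[bi, bj]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        attach(parent, nodes[i_idx], li)
        attach(parent, nodes[j_idx], lj)
        # distances from the new node to the others
        new_row = np.zeros(D.shape[0] + 1)
        for bk in range(m):
            if bk in (bi, bj):
                continue
            k_idx = active[bk]
            new_row[k_idx] = 0.5 * (D[i_idx, k_idx] + D[j_idx, k_idx] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i_idx, j_idx)] + [len(nodes) - 1]

    root = TreeNode()
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        attach(root, nodes[a], la)
        attach(root, nodes[b], lb)
        attach(root, nodes[c], lc)
    elif len(active) == 2:
        a, b = active
        half = D[a, b] / 2
        attach(root, nodes[a], half)
        attach(root, nodes[b], half)
    return NjTree(root=root, terminal_branch_lengths=terminal)


@dataclass
class RecencyReport:
    terminal_branch_lengths: dict[str, float]
    median_terminal_branch: float | None
    n_below_threshold: int
    fraction_below_threshold: float
    threshold: float
    nearest_neighbor_distance: dict[str, float] = field(default_factory=dict)
    note: str = ""


def recency_stats(
    tree: NjTree,
    threshold: float = 0.01,
    matrix: DivergenceMatrix | None = None,
) -> RecencyReport:
    """Terminal-branch summary: median and fraction below ``threshold``.

    Copies separated from their nearest relative by less than ~0.01
    substitutions/site indicate transposition in the very recent past. If the
    distance matrix is supplied, per-copy nearest-neighbor distances are also
    reported.
    """
    term = dict(tree.terminal_branch_lengths)
    vals = np.array(list(term.values()), dtype=float)
    note = ""
    if vals.size == 0:
        return RecencyReport({}, None, 0, 0.0, threshold, note="no leaves")
    if vals.size == 1:
        note = "single copy: median undefined"
        median = None
    else:
        median = float(np.median(vals))
    below = int((vals < threshold).sum())
    nn: dict[str, float] = {}
    if matrix is not None and len(matrix.labels) > 1:
        v = matrix.values + np.diag([np.inf] * len(matrix.labels))
        for i, lab in enumerate(matrix.labels):
            nn[lab] = float(v[i].min())
    return RecencyReport(
        terminal_branch_lengths=term,
        median_terminal_branch=median,
        n_below_threshold=below,
        fraction_below_threshold=below / vals.size,
        threshold=threshold,
        nearest_neighbor_distance=nn,
        note=note,
    )


def ltr_ltr_divergence(call: InsertionCall, genome: dict[str, str]) -> float:
    """JC-corrected divergence between the 5' and 3' LTR of one provirus.

    LTRs are identical at integration, so their divergence dates the copy.
    """
    ltrs = [h for h in call.components if h.part == "LTR"]
    if len(ltrs) < 2:
        raise ValueError("call does not have two LTR components")
    ltrs = sorted(ltrs, key=lambda h: h.start)
    a = genome[call.chrom][ltrs[0].start : ltrs[0].end]
    b = genome[call.chrom][ltrs[-1].start : ltrs[-1].end]
    if call.strand == "-":
        a, b = revcomp(a), revcomp(b)
    if a == b:
        return 0.0
    aln = _dna_aligner().align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    shared = sum(1 for x, y in zip(sa, sb) if x != GAP and y != GAP)
    diff = sum(1 for x, y in zip(sa, sb) if x != GAP and y != GAP and x != y)
    if shared == 0:
        raise ValueError("LTRs do not align")
    return jc_distance(diff / shared)


def count_near_full_length(
    calls_by_assembly: dict[str, list[InsertionCall]], min_len: int, max_len: int
) -> dict:
    """Per-assembly count of calls within the near-full-length window."""
    counts = {
        asm: sum(1 for c in calls if min_len <= c.length <= max_len)
        for asm, calls in calls_by_assembly.items()
    }
    vals = list(counts.values())
    return {
        "counts": counts,
        "min": min(vals) if vals else 0,
        "max": max(vals) if vals else 0,
    }
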