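"""Safe-homolog context ranking and neighbor-joining trees.

A flagged allergen match is put in context by asking whether homologs from
organisms with a history of safe consumption (e.g. *Saccharomyces*) match the
query at higher identity than the allergen does; if so, the match is
"outranked" and unlikely to indicate a real cross-reactivity risk.  The same
full-length identities feed a p-distance matrix (1 − identity fraction) and a
neighbor-joining tree for visual grouping.

The NJ implementation is the textbook Saitou-Nei/Studier-Keppler algorithm
with deterministic lexicographic tie-breaking and clamping of negative branch
length estimates to zero (flagged).  On additive distance matrices it
reconstructs the generating tree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import ScoringScheme, local_align
from .records import ProteinRecord
from .screen import FullScanSummary, full_length_identity


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix: ``d = 1 − fractional full-length identity``."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("p-distances must lie in [0, 1]")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def pairwise_identity_matrix(records: Sequence[ProteinRecord],
                             scheme: ScoringScheme) -> DistanceMatrix:
    """All-vs-all full-length identities as a p-distance matrix.

    Deterministic; invariant under record reordering up to label permutation.
    """
    if len(records) < 2:
        raise ValueError("pairwise_identity_matrix: need >= 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("pairwise_identity_matrix: duplicate record ids")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = local_align(records[i], records[j], scheme)
            ident = full_length_identity(aln)
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return DistanceMatrix(labels=ids, values=d)


@dataclass
class PhyloTree:
    """Unrooted NJ tree with non-negative branch lengths, as Newick."""

    newick: str
    labels: list[str]
    n_clamped_branches: int = 0

    @property
    def has_clamped_branches(self) -> bool:
        return self.n_clamped_branches > 0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick + "\n")

    def ascii_art(self) -> str:
        """ASCII rendering for the report (via scikit-bio when available)."""
        import io
        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(self.newick))
        return str(tree.ascii_art())


class _Cluster:
    __slots__ = ("newick", "rep")

    def __init__(self, newick: str, rep: str):
        self.newick = newick  # subtree without outer branch length
        self.rep = rep        # lexicographically smallest leaf label


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Neighbor joining on a distance matrix; returns an unrooted Newick tree.

    Ties in the Q criterion are broken toward the pair whose (smallest-leaf)
    representative labels sort first; negative branch-length estimates are
    clamped to 0 and counted in ``n_clamped_branches``.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("nj_tree: need at least 3 labels")
    dist = D.values.astype(float).copy()
    if np.any(dist < 0):
        raise ValueError("nj_tree: negative distances")
    clusters = [_Cluster(label, label) for label in D.labels]
    active = list(range(n))
    clamped = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_key = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                reps = sorted((clusters[active[a]].rep, clusters[active[b]].rep))
                key = (round(q, 12), reps[0], reps[1])
                if best_key is None or key < best_key:
                    best_key = key
                    best = (a, b)
        a, b = best
        ia, ib = active[a], active[b]
        d_ab = sub[a, b]
        limb_a = _clamp(0.5 * d_ab + (r[a] - r[b]) / (2.0 * (m - 2)))
        limb_b = _clamp(0.5 * d_ab + (r[b] - r[a]) / (2.0 * (m - 2)))
        ca, cb = clusters[ia], clusters[ib]
        first, second = sorted([(ca, limb_a), (cb, limb_b)],
                               key=lambda t: t[0].rep)
        new = _Cluster(
            f"({first[0].newick}:{first[1]:.10g},{second[0].newick}:{second[1]:.10g})",
            min(ca.rep, cb.rep),
        )
        # distances from the new node to every other active cluster
        new_row = np.zeros(dist.shape[0] + 1)
        for c in range(m):
            if c in (a, b):
                continue
            ic = active[c]
            new_row[ic] = 0.5 * (dist[ia, ic] + dist[ib, ic] - d_ab)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        clusters.append(new)
        active = [i for i in active if i not in (ia, ib)] + [len(clusters) - 1]

    # three remaining clusters joined at a central node (three-point formulas)
    i, j, k = active
    dij, dik, djk = dist[i, j], dist[i, k], dist[j, k]
    li = _clamp(0.5 * (dij + dik - djk))
    lj = _clamp(0.5 * (dij + djk - dik))
    lk = _clamp(0.5 * (dik + djk - dij))
    parts = sorted(
        [(clusters[i], li), (clusters[j], lj), (clusters[k], lk)],
        key=lambda t: t[0].rep,
    )
    newick = "(" + ",".join(f"{c.newick}:{l:.10g}" for c, l in parts) + ");"
    return PhyloTree(newick=newick, labels=list(D.labels),
                     n_clamped_branches=clamped)


@dataclass
class ContextVerdict:
    """Outcome of safe-homolog context ranking for one query.

    ``outranked`` is true when some safe-set homolog matches the query at
    strictly higher full-length identity than the best allergen match does.
    """

    query_id: str
    status: str                      # "ok", "no-context", or "no-match"
    allergen_id: str | None = None
    allergen_identity: float | None = None
    safe_id: str | None = None
    safe_identity: float | None = None

    @property
    def outranked(self) -> bool:
        if self.allergen_identity is None or self.safe_identity is None:
            return False
        return self.safe_identity > self.allergen_identity


def context_rank(query: ProteinRecord, allergen_hits: FullScanSummary,
                 safe_set: Sequence[ProteinRecord],
                 scheme: ScoringScheme) -> ContextVerdict:
    """Rank the best allergen match against the best safe-set homolog.

    Identities are full-length (best local alignment over max sequence
    length), the same currency as the Aalberse rule.  An empty safe set
    yields a "no-context" verdict; a query with no allergen hits at E < 10
    yields "no-match".
    """
    if not safe_set:
        return ContextVerdict(query_id=query.id, status="no-context")
    scored = [h for h in allergen_hits.hits
              if h.evalue is not None and h.evalue < 10.0 and not h.is_empty]
    if not scored:
        return ContextVerdict(query_id=query.id, status="no-match")
    best_allergen = None
    best_allergen_ident = -1.0
    for h in scored:
        ident = full_length_identity(h)
        if ident > best_allergen_ident:
            best_allergen_ident = ident
            best_allergen = h
    best_safe_id = None
    best_safe_ident = -1.0
    for rec in safe_set:
        aln = local_align(query, rec, scheme)
        ident = full_length_identity(aln)
        if ident > best_safe_ident:
            best_safe_ident = ident
            best_safe_id = rec.id
    return ContextVerdict(
        query_id=query.id, status="ok",
        allergen_id=best_allergen.subject_id,
        allergen_identity=best_allergen_ident,
        safe_id=best_safe_id,
        safe_identity=best_safe_ident,
    )
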