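"""Downstream characterization of screened elements.

Mu elements are defined by their *internal* sequences — the DNA between
the TIRs — which are typically unrelated between elements and often carry
captured fragments of host genes (Pack-MULEs). This module clusters
internal sequences into families, detects captured host-gene fragments,
and builds a neighbor-joining tree over internal-sequence distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .seqcore import (
    Sequence,
    global_align,
    local_align,
    percent_identity,
)


@dataclass(frozen=True)
class ElementFamily:
    """A cluster of near-identical internal sequences."""

    family_id: str
    representative: str
    members: tuple[str, ...]
    representative_identity: dict[str, float]

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member")


@dataclass(frozen=True)
class CapturedFragment:
    """A host-gene fragment found inside an element's internal sequence."""

    element_id: str
    element_interval: tuple[int, int]  # on the internal sequence, half-open
    host_seq_id: str
    host_interval: tuple[int, int]
    identity_pct: float

    @property
    def length(self) -> int:
        return self.element_interval[1] - self.element_interval[0]


def cluster_elements(
    internal_seqs: list[Sequence],
    threshold_pct: float = 90.0,
    min_coverage: float = 0.9,
) -> list[ElementFamily]:
    """Greedy incremental clustering of internal sequences.

    Sequences are processed longest-first (ties by id); each joins the
    first existing family whose representative it matches at
    ``threshold_pct`` identity over at least ``min_coverage`` of the
    shorter of the two (by local alignment), otherwise it founds a new
    family. The pre-sort makes the partition independent of input order.
    """
    if not internal_seqs:
        raise ValueError("need at least one sequence")
    ordered = sorted(internal_seqs, key=lambda s: (-len(s), s.id))
    reps: list[Sequence] = []
    families: list[dict] = []
    for s in ordered:
        placed = False
        for rep, fam in zip(reps, families):
            if s.id == rep.id:
                raise ValueError(f"duplicate sequence id {s.id!r}")
            aln = local_align(rep, s)
            if aln.score <= 0:
                continue
            cols = aln.aligned_columns
            shorter = min(len(rep), len(s))
            ident = percent_identity(aln)
            if ident >= threshold_pct and cols >= min_coverage * shorter:
                fam["members"].append(s.id)
                fam["identity"][s.id] = ident
                placed = True
                break
        if not placed:
            reps.append(s)
            families.append(
                {"rep": s.id, "members": [s.id], "identity": {s.id: 100.0}}
            )
    return [
        ElementFamily(
            f"family_{i + 1}",
            fam["rep"],
            tuple(fam["members"]),
            dict(fam["identity"]),
        )
        for i, fam in enumerate(families)
    ]


def find_captured_fragments(
    internal: Sequence,
    host_genes: list[Sequence],
    min_identity_pct: float = 80.0,
    min_len: int = 50,
    max_per_host: int = 8,
) -> list[CapturedFragment]:
    """Detect host-gene fragments captured in an internal sequence.

    For each host gene, local alignments are harvested iteratively: after
    each qualifying hit the matched stretch of the internal sequence is
    masked with N and the alignment repeated, so multiple fragments from
    one gene (or from several genes on different chromosomes) can be
    found. Hits from all hosts are then selected best-score-first subject
    to non-overlap on the internal sequence.
    """
    raw: list[tuple[float, CapturedFragment]] = []
    for host in host_genes:
        work = internal.residues
        for _ in range(max_per_host):
            aln = local_align(work, host.residues)
            if aln.score <= 0:
                break
            ident = percent_identity(aln)
            a0, a1 = aln.a_interval
            if aln.aligned_columns < min_len or ident < min_identity_pct:
                break
            raw.append(
                (
                    aln.score,
                    CapturedFragment(
                        internal.id, (a0, a1), host.id, aln.b_interval, ident
                    ),
                )
            )
            work = work[:a0] + "N" * (a1 - a0) + work[a1:]
    selected: list[CapturedFragment] = []
    for _, frag in sorted(raw, key=lambda t: (-t[0], t[1].element_interval)):
        s, e = frag.element_interval
        if any(
            s < o.element_interval[1] and o.element_interval[0] < e
            for o in selected
        ):
            continue
        selected.append(frag)
    selected.sort(key=lambda f: f.element_interval)
    return selected


def distance_matrix(seqs: list[Sequence]) -> tuple[np.ndarray, list[str]]:
    """Pairwise distance d = 1 - identity/100 from global alignments."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = percent_identity(global_align(seqs[i], seqs[j]))
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return d, [s.id for s in seqs]


def nj_tree(d: np.ndarray, labels: list[str]) -> str:
    """Neighbor-joining tree as a Newick string with branch lengths.

    Negative branch lengths (possible on non-additive input) are clamped
    to zero. Requires at least three taxa and a symmetric matrix with a
    zero diagonal.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    dm = DistanceMatrix(d, ids=list(labels))
    tree = _skbio_nj(dm, neg_as_zero=True)
    return str(tree).strip()
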