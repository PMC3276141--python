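"""Sequence primitives and a self-contained pairwise alignment engine.

Everything downstream (TIR scanning, clustering, capture detection,
distance matrices, probe hybridization) goes through the Needleman-Wunsch /
Smith-Waterman implementations here; no external aligner is invoked
anywhere in the package.

Conventions fixed here and relied on everywhere else:

* DNA alphabet is ``{A, C, G, T, N}``, uppercase. ``N`` never matches
  anything, including another ``N``.
* Coordinates are 0-based, half-open.
* Percent identity = matched columns / all columns between the first and
  last column in which *both* rows carry a residue; internal gap columns
  count as mismatches, terminal overhangs are excluded.
* Dynamic-programming tie-break: diagonal (match/mismatch) is preferred
  over a gap in the second sequence, which is preferred over a gap in the
  first. This makes every alignment deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GAP = "-"


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def _check_dna(residues: str) -> str:
    residues = residues.upper()
    if not set(residues) <= DNA_ALPHABET:
        bad = sorted(set(residues) - DNA_ALPHABET)
        raise AlphabetError(f"non-DNA characters: {bad!r}")
    return residues


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over {A,C,G,T,N}, uppercase.

    Parameters
    ----------
    id : str
        Record identifier (FASTA-style).
    residues : str
        The sequence itself; case-folded to upper on construction.
    description : str
        Optional free-text description (retained through FASTA round-trips).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _check_dna(self.residues))
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item) -> str:
        return self.residues[item]

    def revcomp(self) -> "Sequence":
        return Sequence(self.id, revcomp(self.residues), self.description)


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string; N maps to N.

    Empty input is rejected: a zero-length sequence is always a bug
    upstream, not a degenerate case worth propagating.
    """
    if not s:
        raise ValueError("empty sequence")
    return _check_dna(s).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment: two equal-length gapped strings plus score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings differ in length")
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == GAP and y == GAP:
                raise ValueError("column with gap in both rows")

    @property
    def aligned_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def identity_pct(self) -> float:
        return percent_identity(self)


@dataclass(frozen=True)
class LocalAlignment(Alignment):
    """Smith-Waterman result with the matched intervals (half-open).

    ``a_interval``/``b_interval`` are (start, end) on the *ungapped*
    inputs. A zero-score alignment has empty strings and empty intervals.
    """

    a_interval: tuple[int, int] = (0, 0)
    b_interval: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.aligned_a:  # empty alignment allowed for score 0
            super().__post_init__()


def percent_identity(aln: Alignment) -> float:
    """Identity percentage under the package-wide convention.

    Terminal gap columns (overhangs where one row has no residue yet /
    anymore) are excluded; internal gap columns count as mismatches; any
    column involving ``N`` counts as a mismatch.
    """
    a, b = aln.aligned_a, aln.aligned_b
    both = [i for i in range(len(a)) if a[i] != GAP and b[i] != GAP]
    if not both:
        raise ValueError("no columns with residues in both rows")
    lo, hi = both[0], both[-1] + 1
    cols = hi - lo
    matches = sum(
        1
        for i in range(lo, hi)
        if a[i] == b[i] and a[i] != GAP and a[i] != "N"
    )
    return 100.0 * matches / cols


# ---------------------------------------------------------------------------
# Dynamic programming core
# ---------------------------------------------------------------------------
#
# The score matrix is filled row-by-row in numpy. The left-neighbour
# dependency (linear gap) is resolved with the running-maximum transform:
#     H[i, j] = max_{k <= j} ( m[k] + gap * (j - k) )
# where m[j] = max(diag, up[, 0]) — computed as a cumulative max of
# m[j] - gap*j. This is exact for linear gap penalties.


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _substitution_rows(a: str, b: str, match: float, mismatch: float) -> np.ndarray:
    av, bv = _encode(a), _encode(b)
    n_code = ord("N")
    eq = (av[:, None] == bv[None, :]) & (av[:, None] != n_code) & (bv[None, :] != n_code)
    return np.where(eq, float(match), float(mismatch))


def _fill_matrix(
    a: str, b: str, match: float, mismatch: float, gap: float, local: bool
) -> np.ndarray:
    m, n = len(a), len(b)
    S = _substitution_rows(a, b, match, mismatch)
    H = np.empty((m + 1, n + 1), dtype=np.float64)
    j_idx = np.arange(n + 1, dtype=np.float64)
    if local:
        H[0, :] = 0.0
    else:
        H[0, :] = gap * j_idx
    t = np.empty(n + 1, dtype=np.float64)
    for i in range(1, m + 1):
        diag = H[i - 1, :-1] + S[i - 1]
        up = H[i - 1, 1:] + gap
        mrow = np.maximum(diag, up)
        if local:
            np.maximum(mrow, 0.0, out=mrow)
            t[0] = 0.0
        else:
            t[0] = gap * i
        t[1:] = mrow
        t -= gap * j_idx
        np.maximum.accumulate(t, out=t)
        H[i, :] = t + gap * j_idx
    return H


def _traceback(
    H: np.ndarray,
    a: str,
    b: str,
    match: float,
    mismatch: float,
    gap: float,
    i: int,
    j: int,
    local: bool,
) -> tuple[str, str, int, int]:
    """Walk back from (i, j); returns gapped strings and the start cell.

    Preference order on score ties: diagonal, then gap in ``b`` (consume a
    residue of ``a``), then gap in ``a``.
    """
    out_a: list[str] = []
    out_b: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        h = H[i, j]
        if local and h <= eps:
            break
        if i > 0 and j > 0:
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            if abs(h - (H[i - 1, j - 1] + s)) < eps:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and abs(h - (H[i - 1, j] + gap)) < eps:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP)
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def global_align(
    a: Sequence | str,
    b: Sequence | str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Alignment:
    """Optimal Needleman-Wunsch global alignment with linear gap penalty."""
    sa = a.residues if isinstance(a, Sequence) else _check_dna(a)
    sb = b.residues if isinstance(b, Sequence) else _check_dna(b)
    if not sa or not sb:
        raise ValueError("global_align requires non-empty sequences")
    H = _fill_matrix(sa, sb, match, mismatch, gap, local=False)
    ga, gb, _, _ = _traceback(H, sa, sb, match, mismatch, gap, len(sa), len(sb), local=False)
    return Alignment(ga, gb, float(H[-1, -1]))


def local_align(
    a: Sequence | str,
    b: Sequence | str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment with linear gap penalty.

    Returns the single best-scoring local alignment together with the
    half-open intervals it covers on each input. If nothing scores above
    zero (e.g. disjoint alphabets with negative mismatch), an empty
    zero-score alignment is returned.
    """
    sa = a.residues if isinstance(a, Sequence) else _check_dna(a)
    sb = b.residues if isinstance(b, Sequence) else _check_dna(b)
    if not sa or not sb:
        raise ValueError("local_align requires non-empty sequences")
    H = _fill_matrix(sa, sb, match, mismatch, gap, local=True)
    flat = int(np.argmax(H))
    i_end, j_end = divmod(flat, H.shape[1])
    best = float(H[i_end, j_end])
    if best <= 0.0:
        return LocalAlignment("", "", 0.0)
    ga, gb, i_start, j_start = _traceback(
        H, sa, sb, match, mismatch, gap, i_end, j_end, local=True
    )
    return LocalAlignment(ga, gb, best, (i_start, i_end), (j_start, j_end))


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Orf:
    """An open reading frame.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    input and include the stop codon; ``protein`` excludes the stop.
    ``strand`` is '+' or '-', ``frame`` in {0, 1, 2} on that strand.
    """

    strand: str
    frame: int
    start: int
    end: int
    protein: str

    def __len__(self) -> int:
        return len(self.protein)


def _orfs_one_strand(dna: str, min_len_aa: int) -> list[tuple[int, int, int, str]]:
    found = []
    n = len(dna)
    for frame in range(3):
        seg_start = frame  # start of the current stop-free segment
        for pos in range(frame, n - 2, 3):
            if dna[pos : pos + 3] in _STOPS:
                atg = next(
                    (k for k in range(seg_start, pos, 3) if dna[k : k + 3] == "ATG"),
                    -1,
                )
                if atg != -1:
                    aa = (pos - atg) // 3
                    if aa >= min_len_aa:
                        prot = str(Seq(dna[atg:pos]).translate())
                        found.append((frame, atg, pos + 3, prot))
                seg_start = pos + 3
    return found


def find_orfs(s: Sequence | str, min_len_aa: int = 30) -> list[Orf]:
    """Find ORFs (first in-frame ATG to stop) on both strands.

    Only stop-terminated frames are reported; the stop codon is inside the
    DNA interval but excluded from the amino-acid count. Reverse-strand
    coordinates are mapped back onto the forward strand. Results are
    sorted by start position.
    """
    dna = s.residues if isinstance(s, Sequence) else _check_dna(s)
    n = len(dna)
    orfs = [
        Orf("+", frame, start, end, prot)
        for frame, start, end, prot in _orfs_one_strand(dna, min_len_aa)
    ]
    rc = revcomp(dna)
    orfs += [
        Orf("-", frame, n - end, n - start, prot)
        for frame, start, end, prot in _orfs_one_strand(rc, min_len_aa)
    ]
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs
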