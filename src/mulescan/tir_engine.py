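"""The Mutator-element screen: find TIR hits, pair them, validate, classify.

The screen mirrors how new Mu elements are selected from a genome
assembly. A consensus terminal-inverted-repeat (TIR) model built from
known elements is matched against the genome on both strands by seeded
local alignment; forward/reverse hit pairs become candidate elements; a
candidate is then judged on three criteria:

1. a well-conserved TIR on *both* ends (>=85% identity to the consensus
   over a full-length match),
2. perfect terminal motifs — the element starts with ``GAGATA`` and ends
   with its reverse complement ``TATCTC``,
3. a perfect 9-bp target-site duplication (TSD) in the flanking host
   sequence, the signature of a recent insertion.

Elements passing all three form the "strict" set. Candidates are also
classified structurally by TIR lengths: full/full (~210-220 bp on both
ends), long/short (~215 vs ~90 bp), short/short (~100 bp each), or SOLO
(a single TIR with no inverted partner).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum

from .seqcore import (
    GAP,
    Alignment,
    LocalAlignment,
    Sequence,
    global_align,
    local_align,
    percent_identity,
    revcomp,
)

log = logging.getLogger(__name__)

MOTIF_5P = "GAGATA"
MOTIF_3P = revcomp(MOTIF_5P)  # TATCTC
TSD_LEN = 9


class StructuralClass(str, Enum):
    FULL_FULL = "full_full"
    LONG_SHORT = "long_short"
    SHORT_SHORT = "short_short"
    SOLO = "solo"


class InconsistencyError(RuntimeError):
    """Internal state violates a screen invariant (e.g. impossible TIR length)."""


@dataclass(frozen=True)
class TirModel:
    """A consensus TIR and the sequences it was built from."""

    consensus: Sequence
    source_tirs: tuple[Sequence, ...] = ()

    def __post_init__(self) -> None:
        if not 150 <= len(self.consensus) <= 260:
            raise ValueError(
                f"consensus length {len(self.consensus)} outside [150, 260]"
            )
        if "N" in self.consensus.residues:
            raise ValueError("consensus must be over {A,C,G,T}")


@dataclass(frozen=True)
class TirHit:
    """A located match of the TIR model on one strand of a genome sequence."""

    seq_id: str
    start: int
    end: int  # half-open
    orientation: str  # "forward" | "reverse"
    identity_pct: float
    score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty hit interval")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TsdResult:
    """Comparison of the putative target-site duplication flanks.

    ``present`` is None when a flank is shorter than ``length``
    (indeterminate — the element sits too close to a contig edge to call).
    """

    present: bool | None
    length: int = TSD_LEN
    left_copy: str = ""
    right_copy: str = ""
    mismatches: int | None = None

    @property
    def indeterminate(self) -> bool:
        return self.present is None


@dataclass(frozen=True)
class MuElement:
    """A candidate element: paired (or solo) TIR hits plus validation state.

    ``start``/``end`` run from the first base of the left TIR to the last
    base of the right TIR (half-open); the TSD copies sit outside.
    """

    seq_id: str
    start: int
    end: int
    left_tir: TirHit
    right_tir: TirHit | None = None
    tir_pair_identity_pct: float | None = None
    tsd: TsdResult | None = None
    terminal_motifs_ok: bool | None = None
    structural_class: StructuralClass | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty element interval")
        if self.right_tir is not None:
            if self.right_tir.orientation == self.left_tir.orientation:
                raise ValueError("right TIR must be inverted relative to left")

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def internal_interval(self) -> tuple[int, int]:
        """The sequence between the TIRs (empty for SOLOs)."""
        if self.right_tir is None:
            return self.left_tir.end, self.left_tir.end
        return self.left_tir.end, self.right_tir.start

    @property
    def is_solo(self) -> bool:
        return self.right_tir is None

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Consensus model construction
# ---------------------------------------------------------------------------


def build_tir_model(tirs: list[Sequence]) -> TirModel:
    """Majority-rule consensus of TIR sequences.

    The longest input (ties broken by id) anchors a star alignment: every
    other sequence is globally aligned to it and its residues are projected
    onto the anchor's columns (insertions relative to the anchor are
    dropped, as are columns where gaps hold the majority). Base ties are
    broken alphabetically.
    """
    if not tirs:
        raise ValueError("need at least one TIR sequence")
    for t in tirs:
        if not 150 <= len(t) <= 260:
            raise ValueError(f"TIR {t.id!r} length {len(t)} outside [150, 260]")
    anchor = max(tirs, key=lambda t: (len(t), t.id))
    columns: list[list[str]] = [[c] for c in anchor.residues]
    for t in tirs:
        if t is anchor:
            continue
        aln = global_align(anchor, t)
        ai = 0
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if x != "-":
                columns[ai].append(y)
                ai += 1
    out = []
    half = len(tirs) / 2
    for col in columns:
        gaps = col.count("-")
        if gaps > half:
            continue
        counts = defaultdict(int)
        for c in col:
            if c in "ACGT":
                counts[c] += 1
        if not counts:
            continue
        best = max(counts.values())
        out.append(min(b for b, c in counts.items() if c == best))
    return TirModel(Sequence("consensus", "".join(out)), tuple(tirs))


# ---------------------------------------------------------------------------
# Seeded genome scan
# ---------------------------------------------------------------------------


def _kmer_index(genome: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(genome) - k + 1):
        kmer = genome[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    return index


def _seed_windows(
    query: str, index: dict[str, list[int]], k: int, margin: int
) -> list[tuple[int, int]]:
    """Merged candidate windows from exact k-mer seed matches."""
    starts = sorted(
        {gpos - qpos for qpos in range(len(query) - k + 1)
         for gpos in index.get(query[qpos : qpos + k], ())}
    )
    qlen = len(query)
    windows: list[list[int]] = []
    for s in starts:
        lo, hi = s - margin, s + qlen + margin
        if windows and lo <= windows[-1][1]:
            windows[-1][1] = max(windows[-1][1], hi)
        else:
            windows.append([lo, hi])
    return [(lo, hi) for lo, hi in windows]


def _trim_to_core(
    aln: LocalAlignment,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap: float = -3.0,
) -> tuple[int, int]:
    """Column window [i, j) of the alignment's maximal-scoring core.

    Local alignment happily extends a perfect match into unrelated flanking
    sequence as long as the net score keeps creeping up, which dilutes the
    identity of a genuinely shorter repeat (e.g. a truncated TIR) below
    threshold. Re-scoring the aligned columns with a harsher mismatch/gap
    penalty and taking the maximum-scoring contiguous run strips such
    low-identity overhangs while leaving a uniformly diverged repeat
    intact.
    """
    scores = []
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == GAP or y == GAP:
            scores.append(gap)
        elif x == y and x != "N":
            scores.append(match)
        else:
            scores.append(mismatch)
    best, best_i, best_j = float("-inf"), 0, 0
    run, run_i = 0.0, 0
    for k, s in enumerate(scores):
        if run <= 0:
            run, run_i = s, k
        else:
            run += s
        if run > best:
            best, best_i, best_j = run, run_i, k + 1
    return best_i, best_j


def scan_tirs(
    genome: Sequence,
    model: TirModel,
    min_identity_pct: float = 85.0,
    min_len: int = 180,
    seed_k: int = 12,
    dedup_palindromic: bool = True,
) -> list[TirHit]:
    """Locate TIR-model matches on both strands of a genome sequence.

    Candidate regions are seeded by exact ``seed_k``-mer matches, then each
    merged window is aligned to the consensus by Smith-Waterman. A window's
    best local alignment is kept as a hit when it reaches
    ``min_identity_pct`` over at least ``min_len`` columns. Overlapping
    hits on the same strand are merged to the best-scoring one; a
    reverse-orientation hit over the exact interval of a forward hit is
    dropped (palindromic self-match).
    """
    g = genome.residues
    index = _kmer_index(g, seed_k)
    margin = 30
    hits: list[TirHit] = []
    for orientation, query in (
        ("forward", model.consensus.residues),
        ("reverse", revcomp(model.consensus.residues)),
    ):
        for lo, hi in _seed_windows(query, index, seed_k, margin):
            lo = max(lo, 0)
            hi = min(hi, len(g))
            segment = g[lo:hi]
            if not segment:
                continue
            aln = local_align(query, segment)
            if aln.score <= 0:
                continue
            c0, c1 = _trim_to_core(aln)
            cols = c1 - c0
            if cols < min_len:
                continue
            window = Alignment(
                aln.aligned_a[c0:c1], aln.aligned_b[c0:c1], 0.0
            )
            ident = percent_identity(window)
            if ident < min_identity_pct:
                continue
            # map trimmed columns back onto the genome
            b_skip = sum(1 for ch in aln.aligned_b[:c0] if ch != GAP)
            b_len = sum(1 for ch in aln.aligned_b[c0:c1] if ch != GAP)
            b0 = aln.b_interval[0] + b_skip
            score = sum(
                1.0 if (x == y and x != "N" and x != GAP)
                else -2.0 if (x == GAP or y == GAP)
                else -1.0
                for x, y in zip(window.aligned_a, window.aligned_b)
            )
            hits.append(
                TirHit(genome.id, lo + b0, lo + b0 + b_len, orientation, ident, score)
            )
    # merge same-strand overlaps to the best-scoring hit
    merged: list[TirHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.start, h.orientation)):
        if any(
            o.orientation == h.orientation
            and h.start < o.end
            and o.start < h.end
            for o in merged
        ):
            continue
        merged.append(h)
    if dedup_palindromic:
        fwd = {(h.start, h.end) for h in merged if h.orientation == "forward"}
        merged = [
            h
            for h in merged
            if not (h.orientation == "reverse" and (h.start, h.end) in fwd)
        ]
    merged.sort(key=lambda h: (h.start, h.end, h.orientation))
    return merged


# ---------------------------------------------------------------------------
# Pairing and validation
# ---------------------------------------------------------------------------


def pair_tirs(
    hits: list[TirHit], min_span: int = 400, max_span: int = 6000
) -> list[MuElement]:
    """Form candidate elements from forward/reverse hit pairs.

    Every (forward, reverse) pair with the forward hit upstream and an
    element span within ``[min_span, max_span]`` becomes a candidate; a
    hit may appear in several candidates at this stage. Hits in no pair
    become SOLO candidates spanning just the TIR.
    """
    if len({h.seq_id for h in hits}) > 1:
        raise ValueError("hits must come from a single sequence")
    forward = [h for h in hits if h.orientation == "forward"]
    reverse = [h for h in hits if h.orientation == "reverse"]
    elements: list[MuElement] = []
    paired: set[tuple[int, int, str]] = set()
    for f in forward:
        for r in reverse:
            if r.start < f.end:
                continue
            span = r.end - f.start
            if min_span <= span <= max_span:
                elements.append(MuElement(f.seq_id, f.start, r.end, f, r))
                paired.add((f.start, f.end, f.orientation))
                paired.add((r.start, r.end, r.orientation))
    for h in hits:
        if (h.start, h.end, h.orientation) not in paired:
            # a lone hit (either strand) becomes a solo candidate whose
            # element interval is just the TIR interval
            elements.append(MuElement(h.seq_id, h.start, h.end, h))
    elements.sort(key=lambda e: (e.start, e.end))
    return elements


def check_terminal_motifs(genome: Sequence, e: MuElement) -> bool:
    """True iff the element starts with GAGATA and ends with TATCTC."""
    if e.end > len(genome) or e.start < 0:
        raise IndexError("element interval out of genome bounds")
    if len(e) < 2 * len(MOTIF_5P):
        return False
    seq = genome.residues[e.start : e.end]
    return seq.startswith(MOTIF_5P) and seq.endswith(MOTIF_3P)


def detect_tsd(
    genome: Sequence,
    e: MuElement,
    tsd_len: int = TSD_LEN,
    max_mismatch: int = 0,
) -> TsdResult:
    """Compare the two flanks for a direct target-site duplication.

    The left copy is the ``tsd_len`` bases immediately before the element,
    the right copy the ``tsd_len`` bases immediately after. With a flank
    shorter than ``tsd_len`` the result is indeterminate (present=None),
    never a confident absence.
    """
    g = genome.residues
    if e.start < tsd_len or e.end + tsd_len > len(g):
        return TsdResult(None, tsd_len)
    left = g[e.start - tsd_len : e.start]
    right = g[e.end : e.end + tsd_len]
    mm = sum(1 for x, y in zip(left, right) if x != y or x == "N")
    return TsdResult(mm <= max_mismatch, tsd_len, left, right, mm)


def tir_pair_identity(genome: Sequence, e: MuElement) -> float:
    """Percent identity of the left TIR vs the reverse-complemented right TIR."""
    if e.right_tir is None:
        raise ValueError("solo element has no TIR pair")
    g = genome.residues
    left = g[e.left_tir.start : e.left_tir.end]
    right = g[e.right_tir.start : e.right_tir.end]
    return percent_identity(global_align(left, revcomp(right)))


def classify_structure(
    e: MuElement, long_min: int = 150, short_min: int = 60
) -> StructuralClass:
    """Assign one of the four structural classes from TIR lengths."""
    if e.right_tir is None:
        if len(e.left_tir) < short_min:
            raise InconsistencyError(
                f"TIR of {len(e.left_tir)} bp below short_min={short_min}"
            )
        return StructuralClass.SOLO
    lengths = sorted((len(e.left_tir), len(e.right_tir)))
    if lengths[0] < short_min:
        raise InconsistencyError(
            f"TIR of {lengths[0]} bp below short_min={short_min}"
        )
    n_long = sum(1 for x in lengths if x >= long_min)
    if n_long == 2:
        return StructuralClass.FULL_FULL
    if n_long == 1:
        return StructuralClass.LONG_SHORT
    return StructuralClass.SHORT_SHORT


# ---------------------------------------------------------------------------
# The composed screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds of the screen in one place."""

    min_identity_pct: float = 85.0
    min_tir_len: int = 180
    seed_k: int = 12
    min_span: int = 400
    max_span: int = 6000
    tsd_len: int = TSD_LEN
    tsd_max_mismatch: int = 0
    long_min: int = 150
    short_min: int = 60


@dataclass
class ScreenResult:
    """All surviving candidates plus the strict subset and filter counts."""

    elements: list[MuElement]
    strict: list[MuElement]
    stage_counts: dict[str, int]


def _criteria(e: MuElement, cfg: ScreenConfig) -> tuple[bool, bool, bool]:
    c1 = (
        e.right_tir is not None
        and len(e.left_tir) >= cfg.long_min
        and len(e.right_tir) >= cfg.long_min
        and e.left_tir.identity_pct >= cfg.min_identity_pct
        and e.right_tir.identity_pct >= cfg.min_identity_pct
    )
    c2 = bool(e.terminal_motifs_ok)
    c3 = e.tsd is not None and e.tsd.present is True
    return c1, c2, c3


def screen_elements(
    genome: Sequence, model: TirModel, config: ScreenConfig | None = None
) -> ScreenResult:
    """Run the full screen: scan -> pair -> validate -> resolve -> classify.

    Candidates sharing a TIR hit are resolved deterministically: highest
    priority goes to TSD presence, then terminal motifs, then mean TIR
    identity, then the shorter span. The strict set contains elements
    meeting all three selection criteria (conserved full-length TIR pair,
    perfect terminal motifs, perfect TSD).
    """
    cfg = config or ScreenConfig()
    hits = scan_tirs(
        genome,
        model,
        min_identity_pct=cfg.min_identity_pct,
        min_len=cfg.min_tir_len,
        seed_k=cfg.seed_k,
    )
    candidates = pair_tirs(hits, cfg.min_span, cfg.max_span)
    # every hit also competes as a solo candidate, so a hit whose only
    # pairings are spurious (e.g. bridging two neighbouring elements) can
    # still surface as a SOLO after overlap resolution
    solo_keys = {
        (e.left_tir.start, e.left_tir.end, e.left_tir.orientation)
        for e in candidates
        if e.is_solo
    }
    for h in hits:
        if (h.start, h.end, h.orientation) not in solo_keys:
            candidates.append(MuElement(h.seq_id, h.start, h.end, h))
    validated: list[MuElement] = []
    for e in candidates:
        tsd = detect_tsd(genome, e, cfg.tsd_len, cfg.tsd_max_mismatch)
        motifs = check_terminal_motifs(genome, e)
        pair_id = None if e.is_solo else tir_pair_identity(genome, e)
        validated.append(
            replace(
                e,
                tsd=tsd,
                terminal_motifs_ok=motifs,
                tir_pair_identity_pct=pair_id,
            )
        )

    def priority(e: MuElement):
        mean_id = (
            e.left_tir.identity_pct
            if e.is_solo
            else (e.left_tir.identity_pct + e.right_tir.identity_pct) / 2
        )
        return (
            e.tsd.present is True,
            bool(e.terminal_motifs_ok),
            mean_id,
            not e.is_solo,  # prefer a TIR pair over one of its halves
            -len(e),
        )

    resolved: list[MuElement] = []
    used: set[tuple[int, int, str]] = set()
    for e in sorted(validated, key=priority, reverse=True):
        keys = [(e.left_tir.start, e.left_tir.end, e.left_tir.orientation)]
        if e.right_tir is not None:
            keys.append(
                (e.right_tir.start, e.right_tir.end, e.right_tir.orientation)
            )
        if any(k in used for k in keys):
            continue
        used.update(keys)
        resolved.append(e)

    final: list[MuElement] = []
    strict: list[MuElement] = []
    for e in sorted(resolved, key=lambda e: (e.start, e.end)):
        e = replace(
            e, structural_class=classify_structure(e, cfg.long_min, cfg.short_min)
        )
        final.append(e)
        if all(_criteria(e, cfg)):
            strict.append(e)

    counts = {
        "tir_hits": len(hits),
        "candidates": len(candidates),
        "after_overlap_resolution": len(resolved),
        "with_tsd": sum(1 for e in final if e.tsd and e.tsd.present),
        "with_motifs": sum(1 for e in final if e.terminal_motifs_ok),
        "strict": len(strict),
    }
    log.info("screen of %s: %s", genome.id, counts)
    return ScreenResult(final, strict, counts)
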