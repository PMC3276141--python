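"""Synthetic genomes with planted Mu-like elements and exact ground truth.

The generator reproduces the element anatomy the screen is built to find:
a left TIR, an internal sequence, and the reverse-complemented right TIR,
inserted into host sequence with the 9-bp target-site duplication that a
real Mutator insertion creates (the 9 bp to the right of the insertion
point are duplicated and the element lands between the copies). Planted
structural classes cover full/full, long/short, short/short and SOLO
architectures; heavily decayed TIR copies are planted as negatives that a
correctly thresholded scan must ignore; internal sequences can carry
fragments copied from synthetic host genes to emulate Pack-MULE gene
capture.

Divergence is substitution-only by default so that planted boundaries
stay exact and recovery can be scored to the base pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqcore import Sequence, revcomp
from .tir_engine import MOTIF_5P, StructuralClass, TSD_LEN, MuElement

_BASES = np.array(list("ACGT"))


class PackingError(RuntimeError):
    """Requested elements cannot be placed in the requested genome."""


@dataclass(frozen=True)
class CaptureConfig:
    """Host-gene capture settings."""

    n_host_genes: int = 3
    host_gene_len_range: tuple[int, int] = (800, 1500)
    fragment_len_range: tuple[int, int] = (150, 400)
    identity: float = 0.95
    n_elements_with_capture: int = 2


@dataclass(frozen=True)
class SimConfig:
    """Everything the generator needs; ``seed`` is mandatory.

    ``tir_template`` defaults to a random 220-mer starting with the GAGATA
    terminal motif, drawn from the same seed. ``short_right_len`` and
    ``short_len`` set the truncated TIR sizes of the long/short and
    short/short classes (~90 and ~100 bp architectures).
    """

    seed: int
    genome_len: int = 100_000
    gc_fraction: float = 0.5
    n_full_full: int = 5
    n_long_short: int = 0
    n_short_short: int = 0
    n_solo: int = 0
    n_decayed: int = 0
    decayed_identity: float = 0.75
    tir_template: Sequence | None = None
    tir_len: int = 220
    short_right_len: int = 90
    short_len: int = 100
    tir_divergence: float = 0.0
    internal_len_range: tuple[int, int] = (1000, 2100)
    tsd_len: int = TSD_LEN
    tsd_enabled: bool = True
    capture: CaptureConfig | None = None
    min_spacing: int = 50

    def __post_init__(self) -> None:
        for rate in (self.gc_fraction, self.tir_divergence):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 0.0 <= self.decayed_identity <= 1.0:
            raise ValueError("decayed_identity must lie in [0, 1]")


@dataclass(frozen=True)
class CaptureSource:
    host_seq_id: str
    host_interval: tuple[int, int]
    internal_interval: tuple[int, int]  # relative to the internal sequence
    identity: float


@dataclass(frozen=True)
class PlantedElement:
    element_id: str
    structural_class: StructuralClass
    start: int
    end: int  # on the final genome, half-open, TSD excluded
    left_tir: tuple[int, int]
    right_tir: tuple[int, int] | None
    tir_identity_left: float
    tir_identity_right: float | None
    tsd: str | None
    capture: CaptureSource | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass(frozen=True)
class SyntheticTruth:
    genome_id: str
    elements: tuple[PlantedElement, ...]
    decayed: tuple[tuple[int, int], ...]

    def by_class(self, cls: StructuralClass) -> list[PlantedElement]:
        return [e for e in self.elements if e.structural_class == cls]


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _mutate_bernoulli(rng: np.random.Generator, s: str, rate: float) -> tuple[str, float]:
    """Substitute each position independently with probability ``rate``."""
    if rate == 0.0:
        return s, 100.0
    arr = np.array(list(s))
    mask = rng.random(len(s)) < rate
    for i in np.flatnonzero(mask):
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr), 100.0 * (1 - mask.mean())


def _mutate_to_identity(rng: np.random.Generator, s: str, identity: float) -> str:
    """Substitute an exact count of positions to land on ``identity``."""
    n_mut = round((1.0 - identity) * len(s))
    arr = np.array(list(s))
    for i in rng.choice(len(s), size=n_mut, replace=False):
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def _default_template(rng: np.random.Generator, length: int, gc: float) -> str:
    return MOTIF_5P + _random_dna(rng, length - len(MOTIF_5P), gc)


@dataclass
class _Insert:
    kind: str  # class name or "decayed"
    sequence: str
    left_tir: tuple[int, int] | None
    right_tir: tuple[int, int] | None
    id_left: float
    id_right: float | None
    capture: CaptureSource | None


def _build_inserts(
    cfg: SimConfig, template: str, rng: np.random.Generator,
    host_genes: list[Sequence],
) -> list[_Insert]:
    inserts: list[_Insert] = []
    plan = (
        [(StructuralClass.FULL_FULL, cfg.tir_len, cfg.tir_len)] * cfg.n_full_full
        + [(StructuralClass.LONG_SHORT, cfg.tir_len, cfg.short_right_len)]
        * cfg.n_long_short
        + [(StructuralClass.SHORT_SHORT, cfg.short_len, cfg.short_len)]
        * cfg.n_short_short
        + [(StructuralClass.SOLO, cfg.tir_len, None)] * cfg.n_solo
    )
    n_capture = cfg.capture.n_elements_with_capture if cfg.capture else 0
    full_seen = 0
    for cls, left_len, right_len in plan:
        left, id_l = _mutate_bernoulli(rng, template[:left_len], cfg.tir_divergence)
        if cls is StructuralClass.SOLO:
            inserts.append(
                _Insert(cls.value, left, (0, len(left)), None, id_l, None, None)
            )
            continue
        right_fwd, id_r = _mutate_bernoulli(
            rng, template[:right_len], cfg.tir_divergence
        )
        internal_len = int(rng.integers(*cfg.internal_len_range, endpoint=True))
        internal = _random_dna(rng, internal_len, cfg.gc_fraction)
        capture: CaptureSource | None = None
        if (
            cls is StructuralClass.FULL_FULL
            and cfg.capture
            and full_seen < n_capture
            and host_genes
        ):
            host = host_genes[full_seen % len(host_genes)]
            lo, hi = cfg.capture.fragment_len_range
            frag_len = int(rng.integers(lo, min(hi, len(host)), endpoint=True))
            h0 = int(rng.integers(0, len(host) - frag_len, endpoint=True))
            frag = _mutate_to_identity(
                rng, host.residues[h0 : h0 + frag_len], cfg.capture.identity
            )
            if frag_len < internal_len:
                off = int(rng.integers(0, internal_len - frag_len, endpoint=True))
                internal = internal[:off] + frag + internal[off + frag_len :]
                capture = CaptureSource(
                    host.id,
                    (h0, h0 + frag_len),
                    (off, off + frag_len),
                    cfg.capture.identity,
                )
        if cls is StructuralClass.FULL_FULL:
            full_seen += 1
        seq = left + internal + revcomp(right_fwd)
        inserts.append(
            _Insert(
                cls.value,
                seq,
                (0, len(left)),
                (len(seq) - len(right_fwd), len(seq)),
                id_l,
                id_r,
                capture,
            )
        )
    for _ in range(cfg.n_decayed):
        dec = _mutate_to_identity(rng, template, cfg.decayed_identity)
        inserts.append(_Insert("decayed", dec, None, None, 0.0, None, None))
    return inserts


def simulate(
    cfg: SimConfig, genome_id: str = "synthetic_genome"
) -> tuple[Sequence, list[Sequence], SyntheticTruth]:
    """Generate (genome, host genes, ground truth), reproducibly from the seed.

    Insertion follows the target-site-duplication mechanism: at a host
    position the 9 bp to its right are duplicated and the element is
    written between the two copies, so ``detect_tsd`` holds by
    construction. With ``tsd_enabled=False`` the element is inserted
    without duplicating anything — the flanks then disagree, which is the
    negative control for the TSD criterion.
    """
    rng = np.random.default_rng(cfg.seed)
    template = (
        cfg.tir_template.residues
        if cfg.tir_template is not None
        else _default_template(rng, cfg.tir_len, cfg.gc_fraction)
    )
    host_genes = []
    if cfg.capture:
        lo, hi = cfg.capture.host_gene_len_range
        host_genes = [
            Sequence(
                f"host_gene_{i + 1}",
                _random_dna(rng, int(rng.integers(lo, hi, endpoint=True)), cfg.gc_fraction),
            )
            for i in range(cfg.capture.n_host_genes)
        ]
    base = _random_dna(rng, cfg.genome_len, cfg.gc_fraction)
    inserts = _build_inserts(cfg, template, rng, host_genes)
    total = sum(len(i.sequence) for i in inserts)
    if total >= cfg.genome_len / 2:
        raise PackingError(
            f"planted length {total} exceeds half the genome ({cfg.genome_len})"
        )

    # choose well-separated insertion points in the base genome
    gap = cfg.min_spacing
    lo_pos, hi_pos = gap, cfg.genome_len - cfg.tsd_len - gap
    if hi_pos <= lo_pos:
        raise PackingError("genome too short for any insertion")
    positions: list[int] = []
    attempts = 0
    while len(positions) < len(inserts):
        if attempts > 10_000:
            raise PackingError("could not place all inserts with required spacing")
        attempts += 1
        p = int(rng.integers(lo_pos, hi_pos))
        if all(abs(p - q) >= gap for q in positions):
            positions.append(p)
    order = sorted(range(len(inserts)), key=lambda k: positions[k])

    pieces: list[str] = []
    elements: list[PlantedElement] = []
    decayed: list[tuple[int, int]] = []
    prev = 0
    offset = 0
    for k in order:
        ins, p = inserts[k], positions[k]
        pieces.append(base[prev:p])
        if cfg.tsd_enabled:
            tsd = base[p : p + cfg.tsd_len]
            pieces.append(tsd)
            start = p + cfg.tsd_len + offset
        else:
            tsd = None
            start = p + offset
        pieces.append(ins.sequence)
        end = start + len(ins.sequence)
        if ins.kind == "decayed":
            decayed.append((start, end))
        else:
            elements.append(
                PlantedElement(
                    f"planted_{len(elements) + 1}",
                    StructuralClass(ins.kind),
                    start,
                    end,
                    (start + ins.left_tir[0], start + ins.left_tir[1]),
                    None
                    if ins.right_tir is None
                    else (start + ins.right_tir[0], start + ins.right_tir[1]),
                    ins.id_left,
                    ins.id_right,
                    tsd,
                    ins.capture,
                )
            )
        offset += len(ins.sequence) + (cfg.tsd_len if cfg.tsd_enabled else 0)
        prev = p
    pieces.append(base[prev:])
    genome = Sequence(genome_id, "".join(pieces))
    truth = SyntheticTruth(genome_id, tuple(elements), tuple(decayed))
    return genome, host_genes, truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    mean_boundary_error: float
    n_matched: int
    n_predicted: int
    n_truth: int
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def confusion_errors(self) -> int:
        return sum(v for (t, p), v in self.confusion.items() if t != p)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def score_recovery(
    predicted: list[MuElement],
    truth_elements: list[PlantedElement],
    boundary_tol: int = 0,
    min_overlap: float = 0.9,
) -> RecoveryMetrics:
    """Match predictions to planted elements and score the recovery.

    Matching is greedy one-to-one on reciprocal overlap (best first,
    requiring at least ``min_overlap`` both ways). A matched prediction
    whose boundaries deviate more than ``boundary_tol`` still counts as
    matched; the deviation feeds the mean boundary error. The confusion
    table counts (true class, predicted class) over matched pairs.
    """
    pairs = []
    for pi, p in enumerate(predicted):
        for ti, t in enumerate(truth_elements):
            ov = _reciprocal_overlap(p.interval, t.interval)
            if ov >= min_overlap:
                pairs.append((ov, pi, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    errors: list[float] = []
    confusion: dict[tuple[str, str], int] = {}
    for ov, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        p, t = predicted[pi], truth_elements[ti]
        err = (abs(p.start - t.start) + abs(p.end - t.end)) / 2
        errors.append(err)
        if p.structural_class is not None:
            key = (t.structural_class.value, p.structural_class.value)
            confusion[key] = confusion.get(key, 0) + 1
    n_matched = len(used_p)
    return RecoveryMetrics(
        precision=n_matched / len(predicted) if predicted else 1.0,
        recall=n_matched / len(truth_elements) if truth_elements else 1.0,
        mean_boundary_error=float(np.mean(errors)) if errors else 0.0,
        n_matched=n_matched,
        n_predicted=len(predicted),
        n_truth=len(truth_elements),
        confusion=confusion,
    )
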