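"""Predict Southern-blot readouts from sequence alone.

A Southern experiment for transposon display digests genomic DNA with a
restriction enzyme, separates the fragments on a gel, and probes with an
element's internal sequence. Here the same logic runs in silico: exact
restriction-site digestion, fragment sizing, and probe hybridization
scored in two tiers — *strong* for a (near-)full-length probe match,
*weak* for partial or cross-homology such as a probe's TIR stretch
matching a related element. Methylation sensitivity is deliberately not
modeled (``methylation_insensitive`` records the caveat only): all sites
are treated as cuttable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqcore import Sequence, local_align, percent_identity, revcomp


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition_site: str
    cut_offset: int  # bp into the site where the cut falls
    methylation_insensitive: bool = False

    def __post_init__(self) -> None:
        if not set(self.recognition_site) <= set("ACGT"):
            raise ValueError("recognition site must be over {A,C,G,T}")
        if not 0 <= self.cut_offset <= len(self.recognition_site):
            raise ValueError("cut offset outside recognition site")


# the five enzymes used for Mu13 presence/absence blots; offsets are the
# standard cut positions (irrelevant to sizes at gel resolution)
ENZYMES: dict[str, Enzyme] = {
    e.name: e
    for e in (
        Enzyme("EcoRI", "GAATTC", 1, methylation_insensitive=True),
        Enzyme("EcoRV", "GATATC", 3),
        Enzyme("HindIII", "AAGCTT", 1),
        Enzyme("KpnI", "GGTACC", 5),
        Enzyme("SalI", "GTCGAC", 1),
    )
}


@dataclass(frozen=True)
class DigestFragment:
    seq_id: str
    start: int
    end: int  # half-open

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass(frozen=True)
class ProbeHit:
    fragment: DigestFragment
    match_len: int
    identity_pct: float
    tier: str  # "strong" | "weak" | "none"


def digest(s: Sequence, enzyme: Enzyme) -> list[DigestFragment]:
    """Cut a linear molecule at every exact occurrence of the site.

    Cuts fall at ``site_start + cut_offset``; fragments tile the sequence
    exactly, so with k sites there are k+1 fragments (one spanning all if
    the site never occurs). Overlapping site occurrences each contribute
    a cut.
    """
    seq = s.residues
    site = enzyme.recognition_site
    cuts = []
    pos = seq.find(site)
    while pos != -1:
        cut = pos + enzyme.cut_offset
        if 0 < cut < len(seq):
            cuts.append(cut)
        pos = seq.find(site, pos + 1)
    bounds = [0] + sorted(set(cuts)) + [len(seq)]
    return [
        DigestFragment(s.id, a, b) for a, b in zip(bounds, bounds[1:]) if b > a
    ]


def probe_hybridize(
    fragments: list[DigestFragment],
    fragment_sequences: list[str],
    probe: Sequence,
    strong_min_len: int = 150,
    strong_min_id: float = 90.0,
    weak_min_len: int = 80,
    weak_min_id: float = 85.0,
) -> list[ProbeHit]:
    """Score each fragment against the probe on both strands.

    The best local alignment of probe vs fragment (taking the better
    strand) decides the tier: strong if it spans ``strong_min_len``
    columns at ``strong_min_id`` identity, else weak at the weak
    thresholds, else none.
    """
    if len(fragments) != len(fragment_sequences):
        raise ValueError("fragments and sequences out of register")
    hits: list[ProbeHit] = []
    probes = (probe.residues, revcomp(probe.residues))
    for frag, seq in zip(fragments, fragment_sequences):
        best_len, best_id, best_score = 0, 0.0, 0.0
        for p in probes:
            aln = local_align(p, seq)
            if aln.score <= 0:
                continue
            if aln.score > best_score:
                best_score = aln.score
                best_len = aln.aligned_columns
                best_id = percent_identity(aln)
        if best_len >= strong_min_len and best_id >= strong_min_id:
            tier = "strong"
        elif best_len >= weak_min_len and best_id >= weak_min_id:
            tier = "weak"
        else:
            tier = "none"
        hits.append(ProbeHit(frag, best_len, best_id, tier))
    return hits


def virtual_blot(
    genomes: list[Sequence],
    enzyme: Enzyme,
    probe: Sequence,
    **hyb_kwargs,
) -> dict[str, list[tuple[int, str]]]:
    """Digest + hybridize each genome; per genome, (fragment length, tier)
    for every hybridizing fragment, sorted by descending length (gel order).
    """
    out: dict[str, list[tuple[int, str]]] = {}
    for g in genomes:
        frags = digest(g, enzyme)
        seqs = [g.residues[f.start : f.end] for f in frags]
        hits = probe_hybridize(frags, seqs, probe, **hyb_kwargs)
        bands = [
            (h.fragment.length, h.tier) for h in hits if h.tier != "none"
        ]
        bands.sort(key=lambda t: -t[0])
        out[g.id] = bands
    return out
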