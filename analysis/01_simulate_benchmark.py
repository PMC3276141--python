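#!/usr/bin/env python
"""Build the benchmark genome: 200 kb of host sequence carrying all four
structural classes of planted Mu-like elements at zero TIR divergence
(10 full/full, 5 long/short, 5 short/short, 5 SOLO), five decayed TIR
copies as negatives, and three synthetic host genes with fragments
captured into two elements.

Writes genome, host genes, the scan TIR and the ground truth under
results/benchmark/.
"""

import dataclasses
import json
from pathlib import Path

from mulescan import CaptureConfig, Sequence, SimConfig, StructuralClass, simulate
from mulescan.io_formats import write_fasta

OUT = Path(__file__).resolve().parents[1] / "results" / "benchmark"

CONFIG = SimConfig(
    seed=101,
    genome_len=200_000,
    n_full_full=10,
    n_long_short=5,
    n_short_short=5,
    n_solo=5,
    n_decayed=5,
    tir_divergence=0.0,
    capture=CaptureConfig(n_host_genes=3, n_elements_with_capture=2),
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome, hosts, truth = simulate(CONFIG)
    write_fasta([genome], OUT / "genome.fasta")
    write_fasta(hosts, OUT / "host_genes.fasta")

    donor = truth.by_class(StructuralClass.FULL_FULL)[0]
    tir = genome.residues[donor.left_tir[0] : donor.left_tir[1]]
    write_fasta([Sequence("tir_consensus", tir)], OUT / "tir.fasta")

    internal = []
    for e in truth.elements:
        if e.structural_class is StructuralClass.SOLO:
            continue
        lo = e.left_tir[1]
        hi = e.right_tir[0]
        internal.append(Sequence(e.element_id, genome.residues[lo:hi]))
    write_fasta(internal, OUT / "internal_sequences.fasta")

    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "genome_id": truth.genome_id,
                "elements": [dataclasses.asdict(e) for e in truth.elements],
                "decayed": [list(d) for d in truth.decayed],
            },
            indent=2,
        )
        + "\n"
    )
    by_class = {
        cls.value: len(truth.by_class(cls)) for cls in StructuralClass
    }
    print(f"genome: {len(genome):,} bp -> {OUT / 'genome.fasta'}")
    print(f"planted elements by class: {by_class}; decayed TIRs: {len(truth.decayed)}")
    print(f"host genes: {len(hosts)}; internal sequences written: {len(internal)}")


if __name__ == "__main__":
    main()
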