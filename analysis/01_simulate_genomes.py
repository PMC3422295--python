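"""Simulate a two-order synthetic species panel.

Generates six GC3-tilted ("diptera-like") and four AT3-tilted
("hymenoptera-like") coding genomes plus a strongly biased reference
gene set (the CAI reference, standing in for ribosomal protein genes),
and writes them as FASTA under results/data/ together with the ground
truth profiles.
"""

import json
from pathlib import Path

from codonbias.seqio import write_cds_fasta
from codonbias.synth import generate_genes, make_profile

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
PANEL = {f"dip{i}": ("diptera_like", 100 + i) for i in range(6)} | {
    f"hym{i}": ("hymenoptera_like", 200 + i) for i in range(4)
}
GC3_BIAS = 0.8
N_GENES = 200


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truths = {}
    for sp, (preset, seed) in PANEL.items():
        profile = make_profile(
            preset, gc3_bias=GC3_BIAS, length_mean=150, species_id=sp
        )
        genes, truth = generate_genes(profile, N_GENES, seed=seed)
        write_cds_fasta(genes, OUT / f"{sp}.fasta")
        truths[sp] = {
            "preset": preset,
            "seed": seed,
            "expected_gc3": profile.expected_gc3(),
            "analytic_rscu": truth.analytic_rscu,
        }
        print(f"{sp}: {len(genes)} genes, expected GC3s {profile.expected_gc3():.3f}")
    reference = make_profile(
        "diptera_like", gc3_bias=0.95, length_mean=150, species_id="reference"
    )
    ref_genes, _ = generate_genes(reference, 40, seed=999)
    write_cds_fasta(ref_genes, OUT / "reference.fasta")
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=2)
    print(f"wrote panel to {OUT}")


if __name__ == "__main__":
    main()
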