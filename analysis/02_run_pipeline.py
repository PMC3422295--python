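"""Run the full per-species and cross-species pipeline on the panel.

Consumes the FASTA panel from 01_simulate_genomes.py and produces, under
results/pipeline/: per-species usage/RSCU tables, per-gene
ENC/CAI/SCUO/composition tables, amino-acid frequencies, SCUO bins,
boundary contexts and context residual matrices, plus the cross-species
layer (group Fisher tests, RSCU and context cluster trees, CAI-ENC
trends, composition regressions) and a manifest.
"""

from pathlib import Path

from codonbias.pipeline import RunConfig, SpeciesEntry, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    species = []
    for fasta in sorted(DATA.glob("*.fasta")):
        sp = fasta.stem
        if sp == "reference":
            continue
        species.append(
            SpeciesEntry(
                species_id=sp,
                cds_path=fasta,
                reference_path=DATA / "reference.fasta",
                group=1 if sp.startswith("dip") else 2,
            )
        )
    if not species:
        raise SystemExit("run 01_simulate_genomes.py first")
    manifest = run_pipeline(RunConfig(species=species, outdir=ROOT / "pipeline"))
    n_ok = sum("error" not in v for v in manifest["species"].values())
    print(f"pipeline finished: {n_ok}/{len(species)} species, "
          f"{len(manifest['outputs'])} output files under {ROOT/'pipeline'}")


if __name__ == "__main__":
    main()
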