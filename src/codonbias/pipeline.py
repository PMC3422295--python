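"""End-to-end orchestration of the per-species and cross-species analyses.

``run_pipeline`` reads each species' CDS FASTA, computes the full
statistic set (pooled usage/RSCU, per-gene ENC/CAI/composition/SCUO,
amino-acid frequencies, SCUO bins, context residuals, boundary
contexts), then the cross-species layer (group exact tests when groups
are given, RSCU and context cluster trees, CAI–ENC trends, composition
regressions), and writes one TSV/Newick file per product plus a JSON
manifest recording versions, seeds and input checksums.  Progress and
per-stage timings go to standard error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import cai_enc_trend, cluster_rscu, cross_group_exact_test, enc_regression
from .context import adjusted_residuals, boundary_contexts, count_codon_pairs, context_cluster_tree
from .scuo import bin_scuo, scuo_gene
from .seqio import GeneSet, read_cds_fasta, write_table
from .usage import cai, composition, count_codons, enc, aa_frequencies, rscu

log = logging.getLogger("codonbias.pipeline")


@dataclass
class SpeciesEntry:
    species_id: str
    cds_path: str | Path
    reference_path: str | Path | None = None
    group: int | None = None


@dataclass
class RunConfig:
    species: list[SpeciesEntry]
    outdir: str | Path
    alpha: float = 0.05
    seed: int = 0
    inclusive_boundaries: bool = False
    alphabet: str = "rna"  # alphabet for report tables; TSV data stays DNA-keyed
    strict: bool = False

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("species ids must be unique")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _gene_frame(genes: GeneSet, reference) -> pd.DataFrame:
    per_gene = count_codons(genes, pool=False)
    rows = []
    for g in genes:
        counts = per_gene[g.gene_id]
        comp = composition(g)
        row = {
            "gene_id": g.gene_id,
            "enc": enc(counts).enc,
            "scuo": scuo_gene(counts).scuo,
            "gc": comp.gc,
            "gc3s": comp.gc3s,
            "a3s": comp.a3s,
            "t3s": comp.t3s,
            "c3s": comp.c3s,
            "g3s": comp.g3s,
        }
        row["cai"] = cai(counts, reference).cai if reference is not None else math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns the manifest dictionary."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": {"name": "codonbias", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
        "config": {
            "alpha": config.alpha,
            "seed": config.seed,
            "inclusive_boundaries": config.inclusive_boundaries,
            "alphabet": config.alphabet,
        },
        "inputs": {},
        "species": {},
        "outputs": [],
    }
    rscu_by_species: dict = {}
    residuals_by_species: dict = {}
    trend_rows, regress_rows = [], []
    groups: dict[str, int] = {}

    for entry in config.species:
        t0 = time.perf_counter()
        try:
            genes = read_cds_fasta(entry.cds_path, species_id=entry.species_id)
            if len(genes) == 0:
                raise ValueError("no valid genes after filtering")
            manifest["inputs"][entry.species_id] = _sha256(entry.cds_path)
            reference = None
            if entry.reference_path is not None:
                ref_set = read_cds_fasta(entry.reference_path)
                reference = count_codons(ref_set, pool=True)
                manifest["inputs"][f"{entry.species_id}:reference"] = _sha256(
                    entry.reference_path
                )
            sp_dir = outdir / entry.species_id
            sp_dir.mkdir(exist_ok=True)
            pooled = count_codons(genes, pool=True)
            table = rscu(pooled)
            usage_df = pd.DataFrame(
                {
                    "count": {c: pooled.x.get(c, 0) for c in pooled.code.sense_codons},
                    "rscu": table.rscu,
                    "flag": table.flags,
                }
            )
            usage_df.index.name = "codon"
            write_table(usage_df, sp_dir / "usage.tsv", alphabet=config.alphabet)

            gene_df = _gene_frame(genes, reference)
            write_table(gene_df, sp_dir / "genes.tsv")

            aa_df = pd.DataFrame(
                sorted(aa_frequencies(genes).items()), columns=["aa", "freq"]
            ).set_index("aa")
            write_table(aa_df, sp_dir / "aa_freq.tsv")

            bins = bin_scuo(gene_df["scuo"].to_dict())
            bins_df = pd.DataFrame(
                bins.summary(), columns=["bin", "n", "mean", "variance"]
            ).set_index("bin")
            write_table(bins_df, sp_dir / "scuo_bins.tsv")

            bc = boundary_contexts(genes)
            bc_rows = [
                {"table": f"stop5_{stop}", "codon": c, "count": n}
                for stop, d in bc.stop5.items()
                for c, n in sorted(d.items())
            ] + [
                {"table": "start3", "codon": c, "count": n}
                for c, n in sorted(bc.start3.items())
            ]
            write_table(
                pd.DataFrame(bc_rows), sp_dir / "boundary.tsv", codon_columns=["codon"],
                alphabet=config.alphabet,
            )

            pairs = count_codon_pairs(
                genes, inclusive=config.inclusive_boundaries
            )
            residuals = adjusted_residuals(pairs)
            resid_df = pd.DataFrame(
                residuals.residual,
                index=pd.Index(residuals.codons5, name="codon"),
                columns=residuals.codons3,
            )
            write_table(resid_df, sp_dir / "context_residuals.tsv")

            rscu_by_species[entry.species_id] = table
            residuals_by_species[entry.species_id] = residuals
            if entry.group is not None:
                groups[entry.species_id] = entry.group
            if gene_df["cai"].notna().sum() >= 10:
                tr = cai_enc_trend(gene_df)
                trend_rows.append(
                    {
                        "species": entry.species_id,
                        "pearson_r": tr.pearson_r,
                        "inverse_fraction": tr.inverse_fraction,
                        "n": tr.n,
                    }
                )
            if gene_df["enc"].notna().sum() >= 50:
                fit = enc_regression(gene_df, drop=("t3s",))
                regress_rows.append(
                    {"species": entry.species_id, **fit.coefficients}
                )
            manifest["species"][entry.species_id] = {
                "n_genes": len(genes),
                "n_excluded": len(genes.excluded),
                "seconds": round(time.perf_counter() - t0, 3),
            }
            log.info(
                "%s: %d genes (%d excluded) in %.2fs",
                entry.species_id,
                len(genes),
                len(genes.excluded),
                time.perf_counter() - t0,
            )
        except Exception as exc:
            if config.strict:
                raise
            manifest["species"][entry.species_id] = {"error": str(exc)}
            log.warning("%s: failed (%s), skipped", entry.species_id, exc)

    t0 = time.perf_counter()
    if len(rscu_by_species) >= 3:
        clustering = cluster_rscu(rscu_by_species)
        (outdir / "rscu_species_tree.nwk").write_text(clustering.species_newick + "\n")
        (outdir / "rscu_codon_tree.nwk").write_text(clustering.codon_newick + "\n")
        newick, _, _ = context_cluster_tree(residuals_by_species)
        (outdir / "context_tree.nwk").write_text(newick + "\n")
    if trend_rows:
        write_table(
            pd.DataFrame(trend_rows).set_index("species"), outdir / "trend.tsv"
        )
    if regress_rows:
        write_table(
            pd.DataFrame(regress_rows).set_index("species"), outdir / "regression.tsv"
        )
    if groups and len(set(groups.values())) == 2:
        comparison = cross_group_exact_test(
            {s: rscu_by_species[s] for s in groups}, groups, alpha=config.alpha
        )
        fisher_df = pd.DataFrame(
            [
                {
                    "codon": t.codon,
                    "group1_frequent": t.k1,
                    "group1_rare": t.m1,
                    "group2_frequent": t.k2,
                    "group2_rare": t.m2,
                    "p": t.p,
                    "significant": t.significant,
                }
                for t in comparison.tests.values()
            ]
        ).set_index("codon")
        write_table(fisher_df, outdir / "group_fisher.tsv")
    log.info("cross-species layer in %.2fs", time.perf_counter() - t0)

    manifest["outputs"] = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        and p.name != "manifest.json"
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
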