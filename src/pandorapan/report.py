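"""End-to-end orchestration: run every stage in dependency order and render
a deterministic run report.

``run_all`` consumes a :class:`~pandorapan.config.RunConfig`; when no input
FASTA files are configured it generates a synthetic pangenome from the
config's master seed. Outputs (per-genome summary table, pangenome summary,
cluster table, accumulation curves, audit log of every filter's
before/after counts, and the resolved config) are written with fixed
ordering and no timestamps, so the same config and seed reproduce the
output byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

from pandorapan import seqio, synthetic
from pandorapan.cluster import cluster_proteins
from pandorapan.config import RunConfig
from pandorapan.orthology import best_hits, brh_groups, reciprocal
from pandorapan.pangenome import accumulation, delineate, openness
from pandorapan.utils import round_half_up


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def run_all(config: RunConfig) -> dict:
    """Execute the pipeline per config; returns the report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    audit: list[tuple[str, str, object]] = []

    # --- inputs ---------------------------------------------------------
    if config.proteome_fastas:
        genomes = seqio.read_proteomes(
            config.proteome_fastas, min_length=config.min_orf_len
        )
        truth = None
    else:
        sim = config.simulate
        genomes, truth = synthetic.generate_pangenome(
            n_genomes=sim.n_genomes,
            n_core=sim.n_core,
            n_shell=sim.n_shell,
            shell_p=sim.shell_p,
            n_cloud_per_genome=sim.n_cloud_per_genome,
            identity=sim.identity,
            paralog_prob=sim.paralog_prob,
            seed=config.seed,
        )
        synthetic.write_synthetic_dataset(
            outdir / "synthetic", genomes, truth, params={**sim.__dict__, "seed": config.seed}
        )
    genome_ids = sorted(genomes)
    genes = [g for gid in genome_ids for g in genomes[gid]]
    audit.append(("input", "n_genomes", len(genome_ids)))
    audit.append(("input", "n_proteins", len(genes)))

    # --- clustering -----------------------------------------------------
    clusters = cluster_proteins(
        genes,
        id_thresh=config.cluster_id,
        cov_thresh=config.cluster_cov,
        cov_mode=config.cluster_cov_mode,
    )
    seqio.write_clusters(clusters, outdir / "clusters.tsv")
    audit.append(("cluster", "n_input_proteins", len(genes)))
    audit.append(("cluster", "n_clusters", len(clusters)))

    # --- pangenome ------------------------------------------------------
    summary = delineate(clusters, set(genome_ids), config.genome_lengths or None)
    audit.append(("pangenome", "n_pan_clusters", summary.n_pan_clusters))
    audit.append(("pangenome", "n_core_clusters", summary.n_core_clusters))
    audit.append(("pangenome", "n_core_proteins", summary.n_core_proteins))

    with open(outdir / "per_genome.tsv", "w") as fh:
        fh.write(
            "genome_id\tgenome_length\tn_genes\tn_core_genes\tcore_pct"
            "\tn_paralog_genes\tcoding_capacity\n"
        )
        for gid in genome_ids:
            st = summary.per_genome[gid]
            glen = config.genome_lengths.get(gid, "") if config.genome_lengths else ""
            cap = "" if st.coding_capacity is None else f"{st.coding_capacity:.2f}"
            fh.write(
                f"{gid}\t{glen}\t{st.n_genes}\t{st.n_core_genes}"
                f"\t{round_half_up(100 * st.core_fraction, 1)}"
                f"\t{st.n_paralog_genes}\t{cap}\n"
            )

    # --- accumulation ---------------------------------------------------
    curves = accumulation(clusters, genome_ids, orderings="given")
    verdict = None
    if len(genome_ids) >= 3:
        verdict = openness(curves, threshold_pct=config.openness_threshold_pct)
    with open(outdir / "accumulation.tsv", "w") as fh:
        fh.write("ordering\tk\tgenome_added\tpan_k\tcore_k\n")
        for ci, curve in enumerate(curves):
            for k, (gid, p, c) in enumerate(
                zip(curve.ordering, curve.pan_k, curve.core_k), start=1
            ):
                fh.write(f"{ci}\t{k}\t{gid}\t{p}\t{c}\n")

    report = {
        "config": config.to_dict(),
        "n_genomes": len(genome_ids),
        "n_proteins": len(genes),
        "n_pan_clusters": summary.n_pan_clusters,
        "n_core_clusters": summary.n_core_clusters,
        "n_core_proteins": summary.n_core_proteins,
        "core_over_pan_pct": summary.core_over_pan_pct,
        "singleton_pct": summary.size_distribution["fractions_pct"].get(1, 0.0),
        "mean_relative_increase_pct": round_half_up(
            curves[0].mean_relative_increase, 1
        ),
        "openness": verdict,
        "per_genome": {
            gid: {
                "n_genes": st.n_genes,
                "n_core_genes": st.n_core_genes,
                "core_pct": round_half_up(100 * st.core_fraction, 1),
                "n_paralog_genes": st.n_paralog_genes,
                "coding_capacity": st.coding_capacity,
            }
            for gid, st in sorted(summary.per_genome.items())
        },
    }
    if truth is not None:
        report["planted_core_families"] = truth.planted_core
        audit.append(("truth", "planted_core_families", truth.planted_core))

    # --- optional BRH ortholog groups ------------------------------------
    if config.run_brh and len(genome_ids) >= 2:
        all_pairs = []
        for i, ga in enumerate(genome_ids):
            for gb in genome_ids[i + 1 :]:
                fwd = best_hits(genomes[ga], genomes[gb])
                rev = best_hits(genomes[gb], genomes[ga])
                all_pairs.extend(
                    reciprocal(
                        fwd,
                        rev,
                        ga,
                        gb,
                        id_thresh_pct=config.brh_id_pct,
                        cov_thresh=config.brh_cov,
                        cov_mode=config.brh_cov_mode,
                    )
                )
        groups, n_all = brh_groups(all_pairs, set(genome_ids))
        report["n_brh_pairs"] = len(all_pairs)
        report["n_brh_groups"] = len(groups)
        report["n_brh_groups_all_genomes"] = n_all
        audit.append(("brh", "n_pairs", len(all_pairs)))
        audit.append(("brh", "n_all_genome_groups", n_all))

    with open(outdir / "audit.tsv", "w") as fh:
        fh.write("stage\tmetric\tvalue\n")
        for stage, metric, value in audit:
            fh.write(f"{stage}\t{metric}\t{_fmt(value)}\n")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    config.write_yaml(outdir / "config_used.yaml")
    return report
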