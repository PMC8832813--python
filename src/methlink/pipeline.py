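"""End-to-end orchestration of the synthetic pipeline:
simulate -> annotate -> differential methylation -> differential
expression -> enrichment -> linkage -> 13-table export.

Everything is driven by one YAML-style config dict and a seed;
re-running with the same inputs is byte-deterministic.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import io as mio
from .datasets import toy_gene_sets
from .diffexpr import CountMatrix, call_degs, test_de
from .diffmeth import ContrastSpec, MethCountTable, call_dmcs, test_contrast
from .enrichment import common_pathways, gsea, ora, tissue_specific_filter
from .integration import (
    collect_dmgs,
    common_dmgs,
    dmgs_to_frame,
    expectation_regression,
    export_tables,
    link_deg_dmc,
    merge_common_dmcs,
    rank_top_dmgs,
)
from .regions import assign_sites, build_partition, split_exon150, write_gff3
from .simulate import (
    SimDesign,
    choose_planted_dmcs,
    cpg_sites,
    make_genome,
    simulate_rnaseq,
    simulate_rrbs,
    write_fasta,
)

log = logging.getLogger("methlink")

DEFAULT_CONFIG = {
    "design": {},
    "seed": 0,
    "contrasts": ["L2:L1", "L3:L1"],
    "plant": {
        "n_common_dmcs": 12,
        "n_extra_dmcs": 8,
        "dmc_effect": 40.0,
        "n_degs": 4,
        "deg_lfc": 2.0,
    },
    "thresholds": {
        "min_cov": 10,
        "high_pct": 99.9,
        "q_cut": 0.01,
        "diff_cut": 25.0,
        "deg_alpha": 0.1,
        "ora_alpha": 0.05,
        "ora_min_count": 2,
        "gsea_alpha": 0.05,
        "gsea_nes_cut": 2.0,
        "gsea_n_perm": 500,
    },
}


def _merged_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _concat_meth(a: MethCountTable, b: MethCountTable) -> MethCountTable:
    if a.sites != b.sites:
        raise ValueError("tables must share the same site list")
    return MethCountTable(
        a.sites,
        pd.concat([a.samples, b.samples], ignore_index=True),
        np.hstack([a.methylated, b.methylated]),
        np.hstack([a.coverage, b.coverage]),
    )


def _concat_counts(a: CountMatrix, b: CountMatrix) -> CountMatrix:
    if a.genes != b.genes:
        raise ValueError("matrices must share the same gene list")
    return CountMatrix(
        a.genes,
        pd.concat([a.samples, b.samples], ignore_index=True),
        np.hstack([a.counts, b.counts]),
    )


def run_all(config: dict | None, outdir) -> dict:
    """Run the full synthetic pipeline and export the 13 canonical
    tables plus the simulated inputs.  Returns a results dictionary."""
    cfg = _merged_config(config)
    seed = int(cfg["seed"])
    th = cfg["thresholds"]
    plant = cfg["plant"]
    contrasts = list(cfg["contrasts"])
    os.makedirs(outdir, exist_ok=True)

    design = SimDesign(**cfg["design"], seed=seed)
    log.info("simulating genome: %d chrom x %d bp, %d genes",
             design.n_chroms, design.chrom_length, design.n_genes)
    genome, models = make_genome(design)
    write_fasta(genome, os.path.join(outdir, "genome.fa"))
    write_gff3(models, os.path.join(outdir, "models.gff3"))

    chrom_sizes = {c: len(s) for c, s in genome.items()}
    partition = build_partition(models, chrom_sizes)
    sites = cpg_sites(genome)
    annotations = {
        a.site_id: a for a in split_exon150(assign_sites(sites, partition))
    }

    # planted truth: one shared batch drives both contrasts (common DMCs),
    # one batch is L3-only; expression effects go to the L3 contrast
    planted_common = choose_planted_dmcs(
        sites, partition, int(plant["n_common_dmcs"]),
        float(plant["dmc_effect"]), tuple(contrasts), seed=seed + 1,
        baselines=design.region_baselines,
    )
    planted_extra = choose_planted_dmcs(
        sites, partition, int(plant["n_extra_dmcs"]),
        float(plant["dmc_effect"]), (contrasts[-1],), seed=seed + 2,
        baselines=design.region_baselines,
    )
    common_sites = {s for s, _, _ in planted_common}
    planted_extra = [t for t in planted_extra if t[0] not in common_sites]
    gene_ids = sorted(models)
    rng = np.random.default_rng(seed + 3)
    deg_genes = rng.choice(
        gene_ids, size=min(int(plant["n_degs"]), len(gene_ids)), replace=False
    )
    planted_degs = [
        (str(g), contrasts[-1], float(plant["deg_lfc"])) for g in deg_genes
    ]

    meth, counts, truths = {}, {}, []
    for k, tissue in enumerate(design.tissues):
        planted_here = planted_common + planted_extra if k == 0 else []
        meth[tissue], t1 = simulate_rrbs(
            design, partition, sites, planted_here, tissue=tissue,
            seed=seed + 10 + k,
        )
        counts[tissue], t2 = simulate_rnaseq(
            design, models, planted_degs if k == 0 else [], tissue=tissue,
            seed=seed + 20 + k,
        )
        truths.extend([t1, t2])
        mio.write_coverage_tsvs(meth[tissue], os.path.join(outdir, "coverage"))
        mio.write_counts_tsv(
            counts[tissue], os.path.join(outdir, f"counts_{tissue}.tsv")
        )

    truth_rows = []
    for t in truths:
        truth_rows += [
            {"kind": "dmc", "target": s, "contrast": c, "effect": e}
            for s, c, e in t.planted_dmcs
        ] + [
            {"kind": "deg", "target": g, "contrast": c, "effect": l}
            for g, c, l in t.planted_degs
        ]
    pd.DataFrame(
        truth_rows, columns=["kind", "target", "contrast", "effect"]
    ).to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)

    tissues = list(design.tissues)
    scopes = {tissues[0]: meth[tissues[0]]}
    if len(tissues) > 1:
        scopes[tissues[1]] = meth[tissues[1]]
        scopes["G&L"] = _concat_meth(meth[tissues[0]], meth[tissues[1]])
    cm_scopes = {tissues[0]: counts[tissues[0]]}
    if len(tissues) > 1:
        cm_scopes[tissues[1]] = counts[tissues[1]]
        cm_scopes["G&L"] = _concat_counts(counts[tissues[0]],
                                          counts[tissues[1]])

    meth_results, dmcs_by_ds, degs_by_ds, de_by_ds = {}, {}, {}, {}
    for scope, table in scopes.items():
        for cname in contrasts:
            treatment, control = cname.split(":")
            spec = ContrastSpec(
                treatment, control, scope=scope,
                with_tissue=(scope == "G&L"),
            )
            res = test_contrast(
                table, spec, min_cov=th["min_cov"], high_pct=th["high_pct"]
            )
            dmcs = call_dmcs(
                res, annotations, q_cut=th["q_cut"], diff_cut=th["diff_cut"]
            )
            meth_results[(scope, cname)] = res
            dmcs_by_ds[(scope, cname)] = dmcs
            log.info("diffmeth %s %s: %d sites tested, %d DMCs",
                     scope, cname, len(res), len(dmcs))
    for scope, cm in cm_scopes.items():
        for cname in contrasts:
            treatment, control = cname.split(":")
            spec = ContrastSpec(
                treatment, control, scope=scope,
                with_tissue=(scope == "G&L"),
            )
            de = test_de(cm, spec)
            de_by_ds[(scope, cname)] = de
            degs_by_ds[(scope, cname)] = call_degs(de, alpha=th["deg_alpha"])
            log.info("diffexpr %s %s: %d DEGs", scope, cname,
                     len(degs_by_ds[(scope, cname)]))

    # enrichment (exercised on the primary tissue; outputs are extras)
    primary = tissues[0]
    collection = toy_gene_sets(gene_ids, seed=seed + 4)
    enrich_dir = os.path.join(outdir, "enrichment")
    os.makedirs(enrich_dir, exist_ok=True)
    gsea_res = {}
    for cname in contrasts:
        dmg_genes = {
            g
            for d in collect_dmgs(dmcs_by_ds[(primary, cname)], cname)
            for g in [d.gene_id]
        }
        ora_res = ora(
            dmg_genes & set(collection.universe), collection,
            min_count=th["ora_min_count"], alpha=th["ora_alpha"],
        )
        ora_res.to_csv(
            os.path.join(enrich_dir, f"ora_dmg_{primary}_{cname.replace(':', '')}.tsv"),
            sep="\t", index=False,
        )
        ranking = de_by_ds[(primary, cname)].set_index("gene")["stat"]
        gsea_res[cname] = gsea(
            ranking, collection, n_perm=int(th["gsea_n_perm"]),
            min_count=2, alpha=th["gsea_alpha"],
            nes_cut=th["gsea_nes_cut"], seed=seed + 5, keep_all=True,
        )
        gsea_res[cname].to_csv(
            os.path.join(enrich_dir, f"gsea_{primary}_{cname.replace(':', '')}.tsv"),
            sep="\t", index=False,
        )
    if len(contrasts) >= 2:
        sig = {
            c: gsea_res[c][
                (gsea_res[c]["padj"] < th["gsea_alpha"])
                & (gsea_res[c]["nes"].abs() > th["gsea_nes_cut"])
            ]
            for c in contrasts
        }
        common_pathways(sig[contrasts[0]], sig[contrasts[1]]).to_csv(
            os.path.join(enrich_dir, "gsea_common.tsv"), sep="\t", index=False
        )

    # linkage and the expectation model
    deg_sets = {k: v[["gene", "lfc", "padj"]] for k, v in degs_by_ds.items()}
    link_counts, link_details = link_deg_dmc(deg_sets, dmcs_by_ds)
    link_counts.to_csv(
        os.path.join(outdir, "link_counts.tsv"), sep="\t", index=False
    )
    try:
        adj_r2, f_p, coefs = expectation_regression(link_counts)
        with open(os.path.join(outdir, "expectation_model.json"), "w") as fh:
            json.dump(
                {"adj_r2": adj_r2, "p": f_p, "coefs": coefs.to_dict()},
                fh, indent=1, sort_keys=True,
            )
    except ValueError as err:
        log.warning("expectation model skipped: %s", err)

    # common DMCs / DMGs on the primary tissue
    l2, l3 = contrasts[0], contrasts[-1]
    common = merge_common_dmcs(dmcs_by_ds[(primary, l2)],
                               dmcs_by_ds[(primary, l3)])
    cdmg = common_dmgs(common)
    top = rank_top_dmgs(cdmg)
    top.to_csv(os.path.join(outdir, "top_common_dmgs.tsv"), sep="\t",
               index=False)

    def _flagged_sites(scope, cname):
        res = meth_results[(scope, cname)].copy()
        dmc_ids = set(dmcs_by_ds[(scope, cname)]["site"])
        res["is_dmc"] = res["site"].isin(dmc_ids)
        return res

    from .diffmeth import dmc_region_counts

    results = {
        "degs_l2": degs_by_ds[(primary, l2)],
        "degs_l3": degs_by_ds[(primary, l3)],
        "cpgs_l2": _flagged_sites(primary, l2),
        "cpgs_l3": _flagged_sites(primary, l3),
        "dmcs_region_l2": dmc_region_counts(dmcs_by_ds[(primary, l2)]),
        "dmcs_region_l3": dmc_region_counts(dmcs_by_ds[(primary, l3)]),
        "dmgs_l2": dmgs_to_frame(collect_dmgs(dmcs_by_ds[(primary, l2)], l2)),
        "dmgs_l3": dmgs_to_frame(collect_dmgs(dmcs_by_ds[(primary, l3)], l3)),
        "links_gonads": link_details[
            (link_details["deg_dataset"] == tissues[0])
            & (link_details["dmc_dataset"] == tissues[0])
        ].reset_index(drop=True),
        "links_liver": link_details[
            (link_details["deg_dataset"] == tissues[-1])
            & (link_details["dmc_dataset"] == tissues[-1])
        ].reset_index(drop=True),
        "links_gl": link_details[
            (link_details["deg_dataset"] == "G&L")
            & (link_details["dmc_dataset"] == "G&L")
        ].reset_index(drop=True)
        if len(tissues) > 1
        else link_details.iloc[0:0],
        "common_dmcs": common,
        "common_dmgs": cdmg,
    }
    table_paths = export_tables(results, os.path.join(outdir, "tables"))
    log.info("wrote %d result tables under %s", len(table_paths),
             os.path.join(outdir, "tables"))
    return {
        "design": design,
        "models": models,
        "partition": partition,
        "annotations": annotations,
        "meth": meth,
        "counts": counts,
        "dmcs": dmcs_by_ds,
        "degs": degs_by_ds,
        "link_counts": link_counts,
        "common_dmcs": common,
        "common_dmgs": cdmg,
        "top_common_dmgs": top,
        "tables": table_paths,
    }
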