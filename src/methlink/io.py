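"""Tabular interchange: bisulfite coverage TSVs, gene-count TSVs, truth
tables and YAML configs."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from .diffmeth import MethCountTable
from .diffexpr import CountMatrix

COVERAGE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "pct_methylation",
    "count_methylated",
    "count_unmethylated",
]


def write_coverage_tsvs(table: MethCountTable, outdir) -> list[str]:
    """One bisulfite coverage TSV per sample (1-based start == end for
    CpG sites); only covered sites are written."""
    os.makedirs(outdir, exist_ok=True)
    chroms = [s.split(":")[0] for s in table.sites]
    pos = [int(s.split(":")[1]) for s in table.sites]
    paths = []
    for j, sid in enumerate(table.samples["sample_id"]):
        m = table.methylated[:, j]
        c = table.coverage[:, j]
        covered = c > 0
        with np.errstate(invalid="ignore"):
            pct = np.where(covered, 100.0 * m / np.maximum(c, 1), 0.0)
        df = pd.DataFrame(
            {
                "chrom": np.array(chroms)[covered],
                "start": np.array(pos)[covered],
                "end": np.array(pos)[covered],
                "pct_methylation": np.round(pct[covered], 4),
                "count_methylated": m[covered],
                "count_unmethylated": (c - m)[covered],
            }
        )
        path = os.path.join(outdir, f"{sid}.cov.tsv")
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_coverage_tsvs(paths, metadata: pd.DataFrame) -> MethCountTable:
    """Assemble a MethCountTable from per-sample coverage TSVs; sites
    missing from a sample get coverage 0.  ``metadata`` rows (sample_id,
    tissue, diet) parallel ``paths``."""
    frames = []
    for path, sid in zip(paths, metadata["sample_id"]):
        df = pd.read_csv(path, sep="\t")
        df["site"] = df["chrom"].astype(str) + ":" + df["start"].astype(str)
        df["coverage"] = df["count_methylated"] + df["count_unmethylated"]
        frames.append(
            df.set_index("site")[["count_methylated", "coverage"]].rename(
                columns={
                    "count_methylated": f"m::{sid}",
                    "coverage": f"c::{sid}",
                }
            )
        )
    wide = pd.concat(frames, axis=1).fillna(0).astype(int)

    def sort_key(site):
        chrom, p = site.split(":")
        return (chrom, int(p))

    wide = wide.loc[sorted(wide.index, key=sort_key)]
    sids = list(metadata["sample_id"])
    meth = wide[[f"m::{s}" for s in sids]].to_numpy()
    cov = wide[[f"c::{s}" for s in sids]].to_numpy()
    return MethCountTable(
        list(wide.index), metadata.reset_index(drop=True), meth, cov
    )


def write_counts_tsv(cm: CountMatrix, path) -> None:
    df = pd.DataFrame(
        cm.counts, index=cm.genes, columns=list(cm.samples["sample_id"])
    )
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path, metadata: pd.DataFrame) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    sids = list(metadata["sample_id"])
    return CountMatrix(
        list(df.index), metadata.reset_index(drop=True),
        df[sids].to_numpy(),
    )


def write_truth_tsv(truth, path) -> None:
    rows = [
        {"kind": "dmc", "target": s, "contrast": c, "effect": e}
        for s, c, e in truth.planted_dmcs
    ] + [
        {"kind": "deg", "target": g, "contrast": c, "effect": l}
        for g, c, l in truth.planted_degs
    ]
    pd.DataFrame(rows, columns=["kind", "target", "contrast", "effect"]).to_csv(
        path, sep="\t", index=False
    )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
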