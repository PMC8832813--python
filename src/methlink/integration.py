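"""Methylation-expression integration.

DMG construction by region group, direction-matched common-DMC merging
with the Exon150 split, top-k candidate ranking, DEG:DMC linkage over all
dataset pairs, the OLS expectation model for link counts, dose-consistency
correlation, and the 13-table export.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: The ten region groups a DMG can be labeled with.  GB = exon + intron,
#: P = P250 + P1K + P5K, RS = P + flanks; composites P+GB and RS+GB union
#: their components.
REGION_GROUPS = (
    "GB",
    "intron",
    "exon",
    "P",
    "P250",
    "P1K",
    "P5K",
    "flanks",
    "P+GB",
    "RS+GB",
)

_BASE_GROUPS = {
    "EXON": ("exon", "GB", "P+GB", "RS+GB"),
    "INTRON": ("intron", "GB", "P+GB", "RS+GB"),
    "P250": ("P250", "P", "P+GB", "RS+GB"),
    "P1K": ("P1K", "P", "P+GB", "RS+GB"),
    "P5K": ("P5K", "P", "P+GB", "RS+GB"),
    "FLANK": ("flanks", "RS+GB"),
}

#: Region display names used for common-DMG ranking.
RANK_REGIONS = ("Exon", "Exon150", "Intron", "P250", "P1K", "P5K", "Flanks")

_REGION_DISPLAY = {
    "EXON": "Exon",
    "INTRON": "Intron",
    "P250": "P250",
    "P1K": "P1K",
    "P5K": "P5K",
    "FLANK": "Flanks",
}


@dataclass
class DMGRecord:
    """A gene holding >=1 DMC, with the region groups it hits."""

    gene_id: str
    dataset: str
    region_groups: dict  # group -> sorted list of site ids
    n_dmcs: int


def _region_display(row) -> str:
    if row["region"] == "EXON" and row.get("sublabel") == "EXON150":
        return "Exon150"
    return _REGION_DISPLAY.get(row["region"], row["region"])


def collect_dmgs(dmcs: pd.DataFrame, dataset: str) -> list[DMGRecord]:
    """Aggregate DMCs into DMGs.  Every gene listed on a DMC is credited;
    IGR sites contribute nothing."""
    per_gene: dict[str, dict[str, set]] = {}
    sites_per_gene: dict[str, set] = {}
    for _, row in dmcs.iterrows():
        if row["region"] == "IGR" or not row["gene_ids"]:
            continue
        groups = _BASE_GROUPS[row["region"]]
        for gid in str(row["gene_ids"]).split(","):
            g = per_gene.setdefault(gid, {})
            sites_per_gene.setdefault(gid, set()).add(row["site"])
            for grp in groups:
                g.setdefault(grp, set()).add(row["site"])
    out = []
    for gid in sorted(per_gene):
        out.append(
            DMGRecord(
                gene_id=gid,
                dataset=dataset,
                region_groups={
                    k: sorted(v) for k, v in sorted(per_gene[gid].items())
                },
                n_dmcs=len(sites_per_gene[gid]),
            )
        )
    return out


def dmg_histogram(dmgs: list[DMGRecord]) -> pd.DataFrame:
    """Per region group, how many DMGs carry 1, 2 or >=3 DMCs."""
    rows = []
    for grp in REGION_GROUPS:
        counts = [len(d.region_groups[grp]) for d in dmgs if grp in d.region_groups]
        rows.append(
            {
                "region_group": grp,
                "dmgs_1": sum(1 for c in counts if c == 1),
                "dmgs_2": sum(1 for c in counts if c == 2),
                "dmgs_3plus": sum(1 for c in counts if c >= 3),
                "n_dmgs": len(counts),
            }
        )
    return pd.DataFrame(rows)


def merge_common_dmcs(
    dmcs_a: pd.DataFrame, dmcs_b: pd.DataFrame
) -> pd.DataFrame:
    """Sites DMC in both contrasts with the same hypo/hyper direction,
    IGR excluded.  Exon sites keep their Exon150 sublabel from the shared
    annotation."""
    cols = ["site", "region", "sublabel", "gene_ids", "diff", "q", "direction"]
    a = dmcs_a[cols].rename(columns={"diff": "diff_a", "q": "q_a"})
    b = dmcs_b[["site", "diff", "q", "direction"]].rename(
        columns={"diff": "diff_b", "q": "q_b", "direction": "direction_b"}
    )
    merged = a.merge(b, on="site", how="inner")
    merged = merged[
        (merged["direction"] == merged["direction_b"])
        & (merged["region"] != "IGR")
    ].drop(columns="direction_b")
    merged["region_name"] = [
        _region_display(r) for _, r in merged.iterrows()
    ]
    merged["q_min"] = merged[["q_a", "q_b"]].min(axis=1)
    return merged.sort_values("site", kind="mergesort").reset_index(drop=True)


def common_dmgs(common: pd.DataFrame) -> pd.DataFrame:
    """Genes with >=1 common DMC, with per-region DMC counts and the
    minimum q across both contrasts."""
    rows = []
    for _, row in common.iterrows():
        for gid in str(row["gene_ids"]).split(","):
            if gid:
                rows.append(
                    {
                        "gene": gid,
                        "region_name": row["region_name"],
                        "site": row["site"],
                        "q_min": row["q_min"],
                        "direction": row["direction"],
                    }
                )
    if not rows:
        return pd.DataFrame(
            columns=["gene", "region_name", "n_dmcs", "q_min", "n_hypo",
                     "n_hyper"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["gene", "region_name"])
        .agg(
            n_dmcs=("site", "nunique"),
            q_min=("q_min", "min"),
            n_hypo=("direction", lambda d: int((d == "hypo").sum())),
            n_hyper=("direction", lambda d: int((d == "hyper").sum())),
        )
        .reset_index()
    )
    return out.sort_values(["gene", "region_name"], kind="mergesort").reset_index(
        drop=True
    )


def rank_top_dmgs(
    cdmg: pd.DataFrame, k: int = 3, regions=RANK_REGIONS
) -> pd.DataFrame:
    """Top-k common DMGs per region: sort by DMC count (desc), then
    minimum q (asc), then gene id."""
    frames = []
    for region in regions:
        sub = cdmg[cdmg["region_name"] == region]
        if sub.empty:
            continue
        sub = sub.sort_values(
            ["n_dmcs", "q_min", "gene"],
            ascending=[False, True, True],
            kind="mergesort",
        ).head(k)
        frames.append(sub)
    if not frames:
        return cdmg.iloc[0:0].copy()
    return pd.concat(frames).reset_index(drop=True)


# ---------------------------------------------------------------------------
# DEG:DMC linkage
# ---------------------------------------------------------------------------


def link_deg_dmc(
    degs_by_dataset: dict,
    dmcs_by_dataset: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DEG:DMC counts for every (DEG dataset, DMC dataset) pair sharing a
    contrast.

    ``degs_by_dataset`` maps (scope, contrast) -> DEG frame (gene, lfc,
    padj); ``dmcs_by_dataset`` maps (scope, contrast) -> DMC frame with
    gene_ids.  Returns (LinkCount table, per-gene detail rows).
    """
    contrasts = sorted({c for _, c in degs_by_dataset})
    deg_scopes = sorted({s for s, _ in degs_by_dataset})
    dmc_scopes = sorted({s for s, _ in dmcs_by_dataset})
    counts, details = [], []
    for contrast in contrasts:
        for dscope in deg_scopes:
            degs = degs_by_dataset[(dscope, contrast)]
            for mscope in dmc_scopes:
                dmcs = dmcs_by_dataset[(mscope, contrast)]
                gene2sites: dict[str, list] = {}
                gene2regions: dict[str, set] = {}
                for _, row in dmcs.iterrows():
                    if row["region"] == "IGR":
                        continue
                    for gid in str(row["gene_ids"]).split(","):
                        if gid:
                            gene2sites.setdefault(gid, []).append(row["site"])
                            gene2regions.setdefault(gid, set()).add(
                                row["region"]
                            )
                linked = sorted(set(degs["gene"]) & set(gene2sites))
                counts.append(
                    {
                        "deg_dataset": dscope,
                        "dmc_dataset": mscope,
                        "contrast": contrast,
                        "n_deg": len(set(degs["gene"])),
                        "n_dmg": len(gene2sites),
                        "n_link": len(linked),
                    }
                )
                lfc = degs.set_index("gene")["lfc"]
                for gid in linked:
                    details.append(
                        {
                            "deg_dataset": dscope,
                            "dmc_dataset": mscope,
                            "contrast": contrast,
                            "gene": gid,
                            "lfc": float(lfc.loc[gid]),
                            "n_dmcs": len(gene2sites[gid]),
                            "dmc_sites": ",".join(sorted(gene2sites[gid])),
                            "regions": ",".join(sorted(gene2regions[gid])),
                        }
                    )
    return pd.DataFrame(counts), pd.DataFrame(
        details,
        columns=[
            "deg_dataset",
            "dmc_dataset",
            "contrast",
            "gene",
            "lfc",
            "n_dmcs",
            "dmc_sites",
            "regions",
        ],
    )


def expectation_regression(links: pd.DataFrame):
    """OLS of n_link on n_deg and n_dmg after dividing each variable by
    its maximum.  Returns (adjusted R^2, overall F p-value, coefficient
    Series)."""
    import statsmodels.api as sm

    if len(links) < 4:
        raise ValueError("need at least 4 link-count rows")
    y = links["n_link"].to_numpy(dtype=float)
    x = links[["n_deg", "n_dmg"]].to_numpy(dtype=float)
    if (x.max(axis=0) == 0).any() or (x.std(axis=0) == 0).any():
        raise ValueError("zero-variance predictor")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response (all link counts equal)")
    y = y / y.max() if y.max() > 0 else y
    x = x / x.max(axis=0)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    coefs = pd.Series(model.params, index=["intercept", "n_deg", "n_dmg"])
    return float(model.rsquared_adj), float(model.f_pvalue), coefs


#: DEG:DMC counts, DEG totals and DMG totals as printed for the real
#: datasets (rows: contrast x DEG dataset x DMC dataset over gonads /
#: liver / G&L).  These published counts are inputs for the expectation
#: model; they are not reproducible from desk-scale data.
_PUBLISHED = """\
contrast,deg_dataset,dmc_dataset,n_link,n_deg,n_dmg
L2:L1,gonads,gonads,0,6,9774
L2:L1,gonads,liver,2,6,9370
L2:L1,gonads,G&L,0,6,1981
L2:L1,liver,gonads,21,129,9774
L2:L1,liver,liver,20,129,9370
L2:L1,liver,G&L,2,129,1981
L2:L1,G&L,gonads,20,105,9774
L2:L1,G&L,liver,18,105,9370
L2:L1,G&L,G&L,2,105,1981
L3:L1,gonads,gonads,26,97,9647
L3:L1,gonads,liver,26,97,9512
L3:L1,gonads,G&L,7,97,1977
L3:L1,liver,gonads,59,299,9647
L3:L1,liver,liver,72,299,9512
L3:L1,liver,G&L,16,299,1977
L3:L1,G&L,gonads,69,346,9647
L3:L1,G&L,liver,80,346,9512
L3:L1,G&L,G&L,21,346,1977
"""

PUBLISHED_LINK_TABLE = pd.read_csv(io.StringIO(_PUBLISHED))


# ---------------------------------------------------------------------------
# Dose consistency
# ---------------------------------------------------------------------------


def dose_consistency(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    mode: str = "expression",
) -> dict:
    """Pearson correlation of per-gene (or per-site) effects between two
    contrasts, over items significant in at least one of them.

    ``res_a``/``res_b`` need columns id ('gene' or 'site'), effect
    ('lfc' or 'diff') and a boolean 'significant' column.
    """
    key = "gene" if mode == "expression" else "site"
    eff = "lfc" if mode == "expression" else "diff"
    a = res_a.set_index(key)
    b = res_b.set_index(key)
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    keep = a["significant"].to_numpy() | b["significant"].to_numpy()
    xa = a[eff].to_numpy(dtype=float)[keep]
    xb = b[eff].to_numpy(dtype=float)[keep]
    finite = np.isfinite(xa) & np.isfinite(xb)
    xa, xb = xa[finite], xb[finite]
    if len(xa) < 3:
        raise ValueError("fewer than 3 effect pairs")
    r, p = stats.pearsonr(xa, xb)
    fit = stats.linregress(xa, xb)

    def summary(v):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"q1": float(q1), "median": float(med), "q3": float(q3)}

    return {
        "n_pairs": int(len(xa)),
        "pearson_r": float(r),
        "p": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "summary_a": summary(xa),
        "summary_b": summary(xb),
    }


# ---------------------------------------------------------------------------
# 13-table export
# ---------------------------------------------------------------------------

#: Export file names in the canonical order.
EXPORT_FILES = (
    "01_degs_L2L1.tsv",
    "02_degs_L3L1.tsv",
    "03_dmcs_cpgs_L2L1.tsv",
    "04_dmcs_cpgs_L3L1.tsv",
    "05_dmcs_by_region_gonad_L2L1.tsv",
    "06_dmcs_by_region_gonad_L3L1.tsv",
    "07_dmgs_L2L1.tsv",
    "08_dmgs_L3L1.tsv",
    "09_deg_dmcs_gonads.tsv",
    "10_deg_dmcs_liver.tsv",
    "11_deg_dmcs_GL.tsv",
    "12_common_dmcs.tsv",
    "13_common_dmgs.tsv",
)

_EXPORT_KEYS = (
    "degs_l2",
    "degs_l3",
    "cpgs_l2",
    "cpgs_l3",
    "dmcs_region_l2",
    "dmcs_region_l3",
    "dmgs_l2",
    "dmgs_l3",
    "links_gonads",
    "links_liver",
    "links_gl",
    "common_dmcs",
    "common_dmgs",
)


def dmgs_to_frame(dmgs: list[DMGRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene": d.gene_id,
            "dataset": d.dataset,
            "n_dmcs": d.n_dmcs,
            "region_groups": ",".join(sorted(d.region_groups)),
            "sites": ";".join(
                f"{g}:{'|'.join(s)}" for g, s in sorted(d.region_groups.items())
            ),
        }
        for d in dmgs
    ]
    return pd.DataFrame(
        rows, columns=["gene", "dataset", "n_dmcs", "region_groups", "sites"]
    )


def export_tables(results: dict, outdir) -> list[str]:
    """Write the 13 canonical TSVs from a results mapping keyed by
    ``_EXPORT_KEYS``.  Missing keys raise, naming the file; empty frames
    are written with headers only.  Row order is made deterministic."""
    import os

    os.makedirs(outdir, exist_ok=True)
    written = []
    for key, fname in zip(_EXPORT_KEYS, EXPORT_FILES):
        if key not in results or results[key] is None:
            raise ValueError(f"missing upstream result {key!r} for {fname}")
        df = results[key]
        if not df.empty:
            df = df.sort_values(list(df.columns[:2]), kind="mergesort")
        path = os.path.join(outdir, fname)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
    return written
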