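"""Gene-set enrichment: hypergeometric ORA, preranked GSEA with NES,
cross-contrast common pathways, and the two-stage tissue-specificity
filter on class/subclass-structured collections."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: frozenset
    class_: str | None = None
    subclass: str | None = None


@dataclass
class GeneSetCollection:
    """A keyed collection of gene sets over a common universe."""

    sets: dict[str, GeneSet]
    universe: frozenset

    def __post_init__(self) -> None:
        for s in self.sets.values():
            if not s.genes <= self.universe:
                extra = sorted(s.genes - self.universe)[:5]
                raise ValueError(
                    f"set {s.set_id}: members outside universe ({extra})"
                )

    @classmethod
    def from_gmt(cls, path, universe=None, sidecar=None):
        """Read GMT (set_id, description, members...) with an optional
        sidecar TSV carrying set_id, name, class, subclass columns."""
        meta = {}
        if sidecar is not None:
            df = pd.read_csv(sidecar, sep="\t", dtype=str)
            for _, row in df.iterrows():
                meta[row["set_id"]] = (
                    row.get("name"),
                    row.get("class"),
                    row.get("subclass"),
                )
        sets = {}
        members = set()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sid, desc, genes = parts[0], parts[1], parts[2:]
                name, cls_, sub = meta.get(sid, (desc, None, None))
                sets[sid] = GeneSet(
                    sid, name or desc, frozenset(genes), cls_, sub
                )
                members.update(genes)
        uni = frozenset(universe) if universe is not None else frozenset(members)
        return cls(sets=sets, universe=uni)

    def to_gmt(self, path, sidecar=None) -> None:
        with open(path, "w") as fh:
            for sid in sorted(self.sets):
                s = self.sets[sid]
                fh.write("\t".join([sid, s.name, *sorted(s.genes)]) + "\n")
        if sidecar is not None:
            rows = [
                {
                    "set_id": sid,
                    "name": s.name,
                    "class": s.class_ or "",
                    "subclass": s.subclass or "",
                }
                for sid, s in sorted(self.sets.items())
            ]
            pd.DataFrame(rows).to_csv(sidecar, sep="\t", index=False)


def ora(
    study,
    collection: GeneSetCollection,
    min_count: int = 5,
    alpha: float = 0.05,
    keep_all: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per set.

    Records are retained iff padj < alpha and overlap >= min_count
    (``keep_all`` returns every set regardless, for inspection).
    """
    study = frozenset(study)
    if not collection.universe:
        raise ValueError("empty universe")
    if not study <= collection.universe:
        extra = sorted(study - collection.universe)[:5]
        raise ValueError(f"study genes outside universe: {extra}")
    n_uni = len(collection.universe)
    n_study = len(study)
    rows = []
    for sid in sorted(collection.sets):
        s = collection.sets[sid]
        k = len(study & s.genes)
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(s.genes), n_study))
        rows.append(
            {
                "set_id": sid,
                "name": s.name,
                "test": "ora",
                "k": k,
                "study_size": n_study,
                "set_size": len(s.genes),
                "gene_ratio": f"{k}/{n_study}",
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["padj"] = []
        return out
    out["padj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    if keep_all:
        return out
    return out[(out["padj"] < alpha) & (out["k"] >= min_count)].reset_index(
        drop=True
    )


def enrichment_score(
    stats_sorted: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0
) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    ``stats_sorted`` are ranking statistics in descending order;
    ``hit_mask`` flags set members at each rank.  Hits step up by
    |stat|^weight (normalized), misses step down by 1/(N - m); the ES is
    the extremum of the running sum.
    """
    n = len(stats_sorted)
    m = int(hit_mask.sum())
    if m == 0 or m == n:
        return 0.0
    w = np.abs(stats_sorted) ** weight
    hit_total = math.fsum(w[hit_mask])  # correctly-rounded, order-free
    if hit_total == 0:
        # all member stats zero: fall back to unweighted steps
        steps = np.where(hit_mask, 1.0 / m, -1.0 / (n - m))
    else:
        steps = np.where(hit_mask, w / hit_total, -1.0 / (n - m))
    # sequential accumulation (not cumsum) so the score is reproducible
    # bit-for-bit against a step-by-step reference
    run = 0.0
    best = 0.0
    for step in steps:
        run += step
        if abs(run) > abs(best):
            best = run
    return float(best)


def gsea(
    ranked,
    collection: GeneSetCollection,
    n_perm: int = 10000,
    min_count: int = 5,
    alpha: float = 0.05,
    nes_cut: float = 2.0,
    weight: float = 1.0,
    seed: int | None = None,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-permutation null.

    ``ranked`` maps gene -> finite statistic (dict or Series), without
    duplicates.  NES = ES / mean(|same-sign permutation ES|); the
    permutation p is one-sided on the ES sign.  Records are retained iff
    padj < alpha, |NES| > nes_cut and set size >= min_count.
    """
    if isinstance(ranked, dict):
        ranked = pd.Series(ranked)
    if ranked.index.duplicated().any():
        raise ValueError("duplicate genes in ranking")
    vals = ranked.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("ranking statistics must be finite")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse",
                      stacklevel=2)
    order = np.argsort(-vals, kind="mergesort")
    genes_sorted = ranked.index.to_numpy()[order]
    stats_sorted = vals[order]
    gene_pos = {g: i for i, g in enumerate(genes_sorted)}
    n = len(genes_sorted)
    rng = np.random.default_rng(seed)

    rows = []
    for sid in sorted(collection.sets):
        s = collection.sets[sid]
        pos = [gene_pos[g] for g in s.genes if g in gene_pos]
        m = len(pos)
        if m == 0:
            continue
        hit = np.zeros(n, dtype=bool)
        hit[pos] = True
        es = enrichment_score(stats_sorted, hit, weight)
        if m == n or m < 1:
            continue
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=m, replace=False)] = True
            perm_es[b] = enrichment_score(stats_sorted, mask, weight)
        same = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same.sum())
        if n_same == 0:
            nes = 0.0
            p = 1.0 / (n_perm + 1)
        else:
            denom = np.abs(perm_es[same]).mean()
            nes = float(es / denom) if denom > 0 else 0.0
            p = (1 + int((np.abs(perm_es[same]) >= abs(es)).sum())) / (
                1 + n_same
            )
        rows.append(
            {
                "set_id": sid,
                "name": s.name,
                "test": "gsea",
                "k": m,
                "set_size": len(s.genes),
                "es": es,
                "nes": nes,
                "p": float(p),
                "direction": "up" if nes > 0 else "down",
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["padj"] = []
        return out
    out["padj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    if keep_all:
        return out
    keep = (
        (out["padj"] < alpha)
        & (out["nes"].abs() > nes_cut)
        & (out["k"] >= min_count)
    )
    return out[keep].reset_index(drop=True)


def common_pathways(res_a: pd.DataFrame, res_b: pd.DataFrame) -> pd.DataFrame:
    """Direction-matched intersection of two enrichment result frames."""
    if res_a.empty or res_b.empty:
        return res_a.iloc[0:0].copy()
    key_b = set(zip(res_b["set_id"], res_b["direction"]))
    keep = [
        (sid, d) in key_b
        for sid, d in zip(res_a["set_id"], res_a["direction"])
    ]
    return res_a[keep].reset_index(drop=True)


def tissue_specific_filter(
    res_target: pd.DataFrame,
    res_other: pd.DataFrame,
    collection: GeneSetCollection,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage specificity filter.

    Stage 1 drops sets enriched in the other tissue; stage 2 additionally
    drops sets whose subclass occurs among the other tissue's sets.
    Returns (stage1, stage2).
    """

    def subclass_of(sid):
        s = collection.sets.get(sid)
        if s is None or s.subclass is None:
            raise ValueError(f"set {sid} has no subclass in the collection")
        return s.subclass

    other_ids = set(res_other["set_id"]) if not res_other.empty else set()
    stage1 = res_target[
        ~res_target["set_id"].isin(other_ids)
    ].reset_index(drop=True)
    other_subclasses = {subclass_of(sid) for sid in other_ids}
    if stage1.empty:
        return stage1, stage1.copy()
    keep = [
        subclass_of(sid) not in other_subclasses for sid in stage1["set_id"]
    ]
    stage2 = stage1[keep].reset_index(drop=True)
    return stage1, stage2
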