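"""Gene-level differential expression.

Median-of-ratios normalization, a negative-binomial Wald GLM per gene
(group coefficient, plus tissue for the combined design) with
method-of-moments dispersion and an a/mu + b trend, BH adjustment, and
the top-variance PCA used for sample clustering.

This is a deliberately simplified re-implementation of the standard
count-based DE framework; numerical identity with any particular tool is
not claimed.  The dispersion used per gene is the maximum of the gene
estimate and the fitted trend, which keeps the null false-discovery
behavior conservative at small sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffmeth import ContrastSpec

LN2 = np.log(2.0)


@dataclass
class CountMatrix:
    """Gene x sample integer counts with tissue/diet sample metadata."""

    genes: list[str]
    samples: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match genes x samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("a sample has zero library size")

    def subset_samples(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            self.genes,
            self.samples.loc[mask].reset_index(drop=True),
            self.counts[:, mask],
        )


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over genes nonzero in all samples."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D")
    if counts.shape[1] == 1:
        return np.ones(1)
    ref_ok = (counts > 0).all(axis=1)
    if not ref_ok.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; supply a "
            "pseudo-reference or filter samples"
        )
    logs = np.log(counts[ref_ok])
    log_geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geo, axis=0))
    return sf


def _nb_irls(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    n_iter: int = 30,
    tol: float = 1e-8,
):
    """Vectorized IRLS for per-gene NB2 GLMs sharing one design matrix.

    y: (G, n) counts; x: (n, p); offset: (n,) log size factors;
    alpha: (G,) dispersions.  Returns (beta (G, p), cov (G, p, p)).
    """
    g_n, n = y.shape
    p = x.shape[1]
    beta = np.zeros((g_n, p))
    mean0 = np.maximum((y / np.exp(offset)).mean(axis=1), 1e-8)
    beta[:, 0] = np.log(mean0)
    alpha = alpha[:, None]
    for _ in range(n_iter):
        eta = beta @ x.T + offset
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha * mu)  # (G, n)
        z = (eta - offset) + (y - mu) / mu
        xtwx = np.einsum("ji,gj,jk->gik", x, w, x)
        xtwz = np.einsum("ji,gj->gi", x, w * z)
        xtwx += 1e-10 * np.eye(p)
        new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        delta = np.abs(new - beta).max()
        beta = new
        if delta < tol:
            break
    eta = beta @ x.T + offset
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha * mu)
    xtwx = np.einsum("ji,gj,jk->gik", x, w, x) + 1e-10 * np.eye(p)
    cov = np.linalg.inv(xtwx)
    return beta, cov


def _dispersion_trend(counts, sf, cells):
    """Method-of-moments per-gene dispersion with an a/mu + b trend;
    the returned value is max(gene estimate, trend)."""
    q = counts / sf  # normalized counts
    qbar = q.mean(axis=1)
    # pooled within-cell variance of normalized counts
    ss = np.zeros(counts.shape[0])
    df = 0
    for cell in np.unique(cells):
        m = cells == cell
        if m.sum() < 2:
            continue
        ss += q[:, m].var(axis=1, ddof=1) * (m.sum() - 1)
        df += m.sum() - 1
    if df == 0:
        return np.full(counts.shape[0], 0.1)
    s2 = ss / df
    inv_sf = (1.0 / sf).mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (s2 - qbar * inv_sf) / qbar**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.clip(raw, 1e-8, 50.0)
    # trend fit alpha ~ a/mu + b on informative genes
    ok = qbar > 1e-8
    if ok.sum() >= 10:
        a_mat = np.column_stack([1.0 / qbar[ok], np.ones(ok.sum())])
        coef, *_ = np.linalg.lstsq(a_mat, raw[ok], rcond=None)
        a, b = max(coef[0], 0.0), max(coef[1], 1e-8)
        trend = np.where(ok, a / np.maximum(qbar, 1e-8) + b, 0.1)
    else:
        trend = np.full(counts.shape[0], 0.1)
    return np.clip(np.maximum(raw, trend), 1e-8, 50.0)


def test_de(
    cm: CountMatrix,
    contrast: ContrastSpec,
) -> pd.DataFrame:
    """NB Wald test of the group coefficient for every gene.

    Returns gene, lfc (log2 treatment vs control), p, padj; all-zero
    genes are flagged and given lfc=0, p=1.
    """
    diets = cm.samples["diet"].to_numpy()
    mask = (diets == contrast.treatment) | (diets == contrast.control)
    sub = cm.subset_samples(mask)
    diets = sub.samples["diet"].to_numpy()
    grp = (diets == contrast.treatment).astype(float)
    if grp.sum() < 2 or (1 - grp).sum() < 2:
        raise ValueError(
            f"contrast {contrast.name}: fewer than 2 samples in a group"
        )

    x_cols = [np.ones(len(grp)), grp]
    cells = np.asarray(diets, dtype=object).copy()
    if contrast.with_tissue:
        tissues = sub.samples["tissue"].to_numpy()
        x_cols.append((tissues == tissues[0]).astype(float))
        cells = np.array(
            [f"{d}|{t}" for d, t in zip(diets, tissues)], dtype=object
        )
    x = np.column_stack(x_cols)

    counts = sub.counts.astype(float)
    sf = size_factors(sub.counts)
    offset = np.log(sf)

    nonzero = counts.sum(axis=1) > 0
    alpha = _dispersion_trend(counts[nonzero], sf, cells)
    beta, cov = _nb_irls(counts[nonzero], x, offset, alpha)
    se = np.sqrt(np.maximum(cov[:, 1, 1], 1e-300))
    wald = beta[:, 1] / se
    p_nz = 2.0 * stats.norm.sf(np.abs(wald))
    # plug-in lfc on normalized group means: exactly invariant under
    # per-sample count rescaling (the GLM coefficient is not, because raw
    # counts enter the working weights)
    q = counts[nonzero] / sf
    mean_t = q[:, grp == 1].mean(axis=1)
    mean_c = q[:, grp == 0].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc_nz = np.where(
            (mean_t > 0) & (mean_c > 0), np.log2(mean_t / mean_c), 0.0
        )
    lfc_nz = np.where(
        (mean_t > 0) & (mean_c == 0), np.inf, lfc_nz
    )
    lfc_nz = np.where(
        (mean_t == 0) & (mean_c > 0), -np.inf, lfc_nz
    )

    lfc = np.zeros(len(cm.genes))
    p = np.ones(len(cm.genes))
    stat = np.zeros(len(cm.genes))
    lfc[nonzero] = lfc_nz
    p[nonzero] = p_nz
    stat[nonzero] = wald
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": cm.genes,
            "lfc": lfc,
            "stat": stat,
            "p": p,
            "padj": padj,
            "all_zero": ~nonzero,
        }
    )


def call_degs(results: pd.DataFrame, alpha: float = 0.1) -> pd.DataFrame:
    """Genes with padj < alpha; direction column tallies up/down."""
    degs = results[results["padj"] < alpha].copy()
    degs["direction"] = np.where(degs["lfc"] > 0, "up", "down")
    return degs.reset_index(drop=True)


def expression_pca(
    cm: CountMatrix, top_n: int = 500, n_components: int = 2
) -> pd.DataFrame:
    """PCA of samples on log2(normalized + 1) counts restricted to the
    top_n highest-variance genes (all genes, with a warning, if fewer)."""
    import warnings

    from sklearn.decomposition import PCA

    if len(cm.samples) < 2:
        raise ValueError("need at least 2 samples")
    sf = size_factors(cm.counts)
    vst = np.log2(cm.counts / sf + 1.0)
    if top_n > vst.shape[0]:
        warnings.warn(
            f"top_n={top_n} exceeds gene count {vst.shape[0]}; using all",
            stacklevel=2,
        )
        top_n = vst.shape[0]
    var = vst.var(axis=1)
    idx = np.argsort(var, kind="mergesort")[::-1][:top_n]
    n_components = min(n_components, len(cm.samples), top_n)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(vst[idx].T)
    out = cm.samples.copy()
    for k in range(n_components):
        out[f"PC{k + 1}"] = scores[:, k]
    return out
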