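"""Per-CpG differential methylation testing.

Coverage filtering, binomial logistic-regression tests (pairwise and with
a tissue covariate for the combined two-tissue design), BH/Storey q-values
and DMC calling at q < 0.01 and |diff| >= 25 percentage points.

For the two-group design without covariates the likelihood-ratio test on
the group coefficient of a binomial GLM has a closed form: the group-level
MLE pools counts within each group, so the statistic equals the G-test on
the pooled 2x2 table.  That form is vectorized over sites; the covariate
design falls back to per-site statsmodels GLM fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests


@dataclass
class MethCountTable:
    """Per-CpG (methylated, coverage) counts for a set of samples.

    ``methylated`` and ``coverage`` are (n_sites, n_samples) integer
    arrays; ``samples`` carries sample_id / tissue / diet metadata.
    """

    sites: list[str]
    samples: pd.DataFrame
    methylated: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.methylated = np.asarray(self.methylated)
        self.coverage = np.asarray(self.coverage)
        n_sites, n_samples = self.methylated.shape
        if len(self.sites) != n_sites or len(self.samples) != n_samples:
            raise ValueError("shape mismatch between sites/samples and counts")
        if self.coverage.shape != self.methylated.shape:
            raise ValueError("methylated and coverage shapes differ")
        if (self.methylated < 0).any() or (self.coverage < 0).any():
            raise ValueError("negative counts")
        if (self.methylated > self.coverage).any():
            raise ValueError("methylated exceeds coverage")
        for col in ("sample_id", "tissue", "diet"):
            if col not in self.samples.columns:
                raise ValueError(f"samples metadata missing column {col!r}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def rates(self) -> np.ndarray:
        """Methylation fractions; NaN where coverage is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.coverage > 0, self.methylated / self.coverage, np.nan
            )

    def subset_sites(self, idx) -> "MethCountTable":
        idx = np.asarray(idx)
        return MethCountTable(
            [self.sites[i] for i in idx],
            self.samples,
            self.methylated[idx],
            self.coverage[idx],
        )

    def subset_samples(self, mask) -> "MethCountTable":
        mask = np.asarray(mask)
        return MethCountTable(
            self.sites,
            self.samples.loc[mask].reset_index(drop=True),
            self.methylated[:, mask],
            self.coverage[:, mask],
        )


@dataclass(frozen=True)
class ContrastSpec:
    """A treatment-vs-control comparison (control defaults to L1)."""

    treatment: str
    control: str = "L1"
    scope: str = "gonads"
    with_tissue: bool = False

    def __post_init__(self) -> None:
        if self.treatment == self.control:
            raise ValueError("treatment and control must differ")

    @property
    def name(self) -> str:
        return f"{self.treatment}:{self.control}"


def filter_coverage(
    table: MethCountTable, min_cov: int = 10, high_pct: float = 99.9
) -> MethCountTable:
    """Drop site observations with coverage <= min_cov or above the
    per-sample high_pct coverage percentile; keep only sites that remain
    observed in every sample."""
    cov = table.coverage
    keep = np.ones(cov.shape, dtype=bool)
    for j in range(cov.shape[1]):
        col = cov[:, j]
        observed = col[col > 0]
        if observed.size == 0:
            raise ValueError(
                f"sample {table.samples['sample_id'].iloc[j]!r} has no "
                "covered sites"
            )
        hi = np.percentile(observed, high_pct, method="higher")
        keep[:, j] = (col > min_cov) & (col <= hi)
    site_mask = keep.all(axis=1)
    for j in range(cov.shape[1]):
        if not keep[:, j].any():
            raise ValueError(
                f"sample {table.samples['sample_id'].iloc[j]!r} loses all "
                "sites under the coverage filter"
            )
    return table.subset_sites(np.nonzero(site_mask)[0])


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _binom_ll(m, c, p):
    """Binomial log-likelihood kernel (constant terms dropped)."""
    return xlogy(m, p) + xlogy(c - m, 1.0 - p)


def _g_test_2x2(mt, ct, mc, cc):
    """Vectorized LR chi-square of the group coefficient for pooled
    treatment/control counts.  Arrays broadcast elementwise."""
    mt, ct, mc, cc = (np.asarray(a, dtype=float) for a in (mt, ct, mc, cc))
    p_t = np.divide(mt, ct, out=np.zeros_like(mt), where=ct > 0)
    p_c = np.divide(mc, cc, out=np.zeros_like(mc), where=cc > 0)
    pool = np.divide(mt + mc, ct + cc, out=np.zeros_like(mt), where=(ct + cc) > 0)
    ll_alt = _binom_ll(mt, ct, p_t) + _binom_ll(mc, cc, p_c)
    ll_null = _binom_ll(mt, ct, pool) + _binom_ll(mc, cc, pool)
    g = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    return g, stats.chi2.sf(g, df=1)


def _binom_irls_ll(m, c, x, n_iter=40, tol=1e-10):
    """Vectorized per-site binomial GLM log-likelihoods for one shared
    design matrix.  m, c: (S, n) counts; x: (n, p).  Returns (S,) max
    log-likelihood (constant terms dropped)."""
    m = np.asarray(m, dtype=float)
    c = np.asarray(c, dtype=float)
    s_n, n = m.shape
    p = x.shape[1]
    pooled = np.clip(
        m.sum(axis=1) / np.maximum(c.sum(axis=1), 1.0), 1e-6, 1 - 1e-6
    )
    beta = np.zeros((s_n, p))
    beta[:, 0] = np.log(pooled / (1 - pooled))
    for _ in range(n_iter):
        eta = np.clip(beta @ x.T, -15, 15)
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = c * pi * (1.0 - pi)
        safe = np.maximum(w, 1e-12)
        z = eta + (m - c * pi) / safe
        xtwx = np.einsum("ji,sj,jk->sik", x, w, x) + 1e-9 * np.eye(p)
        xtwz = np.einsum("ji,sj->si", x, w * z)
        new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        delta = np.abs(new - beta).max()
        beta = np.clip(new, -20, 20)
        if delta < tol:
            break
    eta = np.clip(beta @ x.T, -15, 15)
    pi = 1.0 / (1.0 + np.exp(-eta))
    return (_binom_ll(m, c, pi)).sum(axis=1)


def _lrt_with_covariate(meth, cov, group, tissue):
    """Vectorized LR chi-square of the group coefficient adjusting for
    tissue."""
    n = len(group)
    x_alt = np.column_stack([np.ones(n), group, tissue])
    x_null = x_alt[:, [0, 2]]
    ll_alt = _binom_irls_ll(meth, cov, x_alt)
    ll_null = _binom_irls_ll(meth, cov, x_null)
    g = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    return g, stats.chi2.sf(g, df=1)


def _glm_lrt_site(m, c, group, tissue):
    """Per-site binomial GLM LRT of the group coefficient with a tissue
    covariate.  Falls back to continuity-corrected counts on degenerate
    fits."""
    import statsmodels.api as sm

    ok = c > 0
    m, c, group = m[ok], c[ok], group[ok]
    tis = tissue[ok]
    y = np.column_stack([m, c - m]).astype(float)
    x_alt = np.column_stack([np.ones(len(m)), group, tis])
    x_null = x_alt[:, [0, 2]]

    def fit(x, yy):
        res = sm.GLM(yy, x, family=sm.families.Binomial()).fit(maxiter=100)
        return res.llf, res.converged

    try:
        ll_alt, conv_a = fit(x_alt, y)
        ll_null, conv_n = fit(x_null, y)
        if not (conv_a and conv_n) or not np.isfinite(ll_alt - ll_null):
            raise FloatingPointError
    except Exception:
        # continuity correction: add half a success and half a failure
        y = np.column_stack([m + 0.5, c - m + 0.5])
        ll_alt, _ = fit(x_alt, y)
        ll_null, _ = fit(x_null, y)
    g = max(2.0 * (ll_alt - ll_null), 0.0)
    return g, stats.chi2.sf(g, df=1)


def test_site(
    methylated,
    coverage,
    group,
    tissue=None,
) -> dict:
    """Test one CpG site.

    ``group`` is a boolean/0-1 vector (1 = treatment); ``tissue`` an
    optional 0/1 covariate.  Returns diff (percentage points,
    treatment - control), p, and direction.
    """
    m = np.asarray(methylated, dtype=float)
    c = np.asarray(coverage, dtype=float)
    g = np.asarray(group, dtype=bool)
    if c[g].sum() == 0 or c[~g].sum() == 0:
        raise ValueError("each group needs at least one covered sample")
    mt, ct = m[g].sum(), c[g].sum()
    mc, cc = m[~g].sum(), c[~g].sum()
    diff = 100.0 * (mt / ct - mc / cc)
    if tissue is None:
        _, p = _g_test_2x2(mt, ct, mc, cc)
        p = float(p)
    else:
        _, p = _glm_lrt_site(m, c, g.astype(float), np.asarray(tissue, float))
    return {
        "diff": float(diff),
        "p": p,
        "direction": "hyper" if diff > 0 else "hypo",
    }


def test_contrast(
    table: MethCountTable,
    contrast: ContrastSpec,
    min_cov: int | None = 10,
    high_pct: float = 99.9,
) -> pd.DataFrame:
    """Run the per-CpG test for every site of a contrast.

    Applies the coverage filter first (pass ``min_cov=None`` to skip),
    restricts to the contrast's diet groups, and returns a frame with
    site, diff, p, q (BH by default; see :func:`adjust_qvalues`) and
    direction.
    """
    diets = table.samples["diet"].to_numpy()
    in_contrast = (diets == contrast.treatment) | (diets == contrast.control)
    sub = table.subset_samples(in_contrast)
    if min_cov is not None:
        sub = filter_coverage(sub, min_cov=min_cov, high_pct=high_pct)

    grp = (sub.samples["diet"] == contrast.treatment).to_numpy()
    if grp.sum() == 0 or (~grp).sum() == 0:
        raise ValueError(f"contrast {contrast.name}: a group has no samples")

    meth, cov = sub.methylated.astype(float), sub.coverage.astype(float)
    mt, ct = meth[:, grp].sum(axis=1), cov[:, grp].sum(axis=1)
    mc, cc = meth[:, ~grp].sum(axis=1), cov[:, ~grp].sum(axis=1)
    ok = (ct > 0) & (cc > 0)
    diff = np.where(
        ok,
        100.0
        * (
            np.divide(mt, ct, out=np.zeros_like(mt), where=ct > 0)
            - np.divide(mc, cc, out=np.zeros_like(mc), where=cc > 0)
        ),
        0.0,
    )
    if contrast.with_tissue:
        tissues = sub.samples["tissue"].to_numpy()
        tis = (tissues == tissues[0]).astype(float)
        _, p = _lrt_with_covariate(meth, cov, grp.astype(float), tis)
        p = np.where(ok, p, 1.0)
    else:
        _, p = _g_test_2x2(mt, ct, mc, cc)
        p = np.where(ok, p, 1.0)

    res = pd.DataFrame(
        {
            "site": sub.sites,
            "diff": diff,
            "p": p,
            "direction": np.where(diff > 0, "hyper", "hypo"),
        }
    )
    res["q"] = adjust_qvalues(res["p"].to_numpy())
    return res


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi0 over a lambda grid with a cubic-polynomial smoother
    evaluated at the largest lambda."""
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0s = np.array(
        [(p > lam).mean() / (1.0 - lam) for lam in lambdas]
    )
    if len(lambdas) >= 4:
        coef = np.polyfit(lambdas, pi0s, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
    else:
        pi0 = float(pi0s[-1])
    return float(min(max(pi0, 1e-8), 1.0))


def adjust_qvalues(p, method: str = "bh") -> np.ndarray:
    """FDR-scale q-values; ``bh`` (Benjamini-Hochberg step-up) or
    ``storey`` (pi0-scaled).  Output order matches input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        pi0 = storey_pi0(p)
        n = p.size
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * n * pi0 / (np.arange(n) + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty(n)
        q[order] = np.minimum(q_sorted, 1.0)
        return q
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# DMC calling
# ---------------------------------------------------------------------------


def call_dmcs(
    results: pd.DataFrame,
    annotations: dict,
    q_cut: float = 0.01,
    diff_cut: float = 25.0,
) -> pd.DataFrame:
    """Select DMCs (q < q_cut and |diff| >= diff_cut) and attach region
    annotations.  A passing site without an annotation raises."""
    hits = results[
        (results["q"] < q_cut) & (results["diff"].abs() >= diff_cut)
    ].copy()
    labels, sublabels, genes, dists = [], [], [], []
    for site in hits["site"]:
        ann = annotations.get(site)
        if ann is None:
            raise KeyError(f"no region annotation for DMC site {site}")
        labels.append(ann.label.name)
        sublabels.append(ann.sublabel or "")
        genes.append(",".join(ann.gene_ids))
        dists.append(ann.distance_to_tss)
    hits["region"] = labels
    hits["sublabel"] = sublabels
    hits["gene_ids"] = genes
    hits["distance_to_tss"] = dists
    return hits.reset_index(drop=True)


def dmc_region_counts(dmcs: pd.DataFrame) -> pd.DataFrame:
    """Counts of DMCs per region and direction."""
    if dmcs.empty:
        return pd.DataFrame(columns=["region", "hypo", "hyper"])
    tab = (
        dmcs.groupby(["region", "direction"]).size().unstack(fill_value=0)
    )
    return tab.reindex(columns=["hypo", "hyper"], fill_value=0).reset_index()


def methylation_pca(
    table: MethCountTable,
    site_idx=None,
    n_components: int = 2,
) -> pd.DataFrame:
    """PCA scores of samples on the methylation-rate matrix, optionally
    restricted to a region-defined subset of sites.  Only sites covered
    in every sample enter the decomposition."""
    from sklearn.decomposition import PCA

    sub = table if site_idx is None else table.subset_sites(site_idx)
    rates = sub.rates()
    complete = ~np.isnan(rates).any(axis=1)
    rates = rates[complete]
    if rates.shape[0] < 2:
        raise ValueError("fewer than 2 complete sites after restriction")
    n_components = min(n_components, len(sub.samples), rates.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(rates.T)
    out = sub.samples.copy()
    for k in range(n_components):
        out[f"PC{k + 1}"] = scores[:, k]
    return out
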