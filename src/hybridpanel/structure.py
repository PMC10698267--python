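"""Population structure: PCA with Tracy-Widom axis tests and admixture inference.

PCA follows the smartPCA convention: each locus column is centred by twice
the sample allele frequency and scaled by ``sqrt(p(1-p))``; missing entries
are mean-imputed (zero after centring).  Axis significance uses the
Tracy-Widom distribution of the largest eigenvalue of a null Wishart matrix,
with Patterson's effective-marker-count moment normalisation, tested
sequentially from the leading axis.

Admixture proportions are estimated by maximum likelihood under the standard
K-ancestral-pool admixture model: genotype g_il ~ Binomial(2, sum_k q_ik f_kl),
fitted by EM with guaranteed monotone log-likelihood.  Model choice across K
uses the Evanno second-difference statistic over replicate runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, GenotypePanel

# Shifted-gamma approximation to the Tracy-Widom beta=1 distribution
# (Chiani 2014): TW1 =~ Gamma(k, theta) - alpha.
_TW1_K = 46.44604884387337
_TW1_THETA = 0.18605402228279955
_TW1_ALPHA = 9.848007781128567


def tracy_widom_sf(x: float | np.ndarray) -> float | np.ndarray:
    """Upper tail P(TW1 > x) of the Tracy-Widom (beta=1) distribution."""
    return stats.gamma.sf(np.asarray(x) + _TW1_ALPHA, a=_TW1_K, scale=_TW1_THETA)


@dataclass
class PcaResult:
    coordinates: np.ndarray        # (n_samples, n_axes), eigvec * sqrt(eigval)
    eigenvalues: np.ndarray        # descending, positive part of spectrum
    variance_explained: np.ndarray  # fraction of total per axis
    tw_pvalues: np.ndarray         # per leading axis (NaN beyond the tested prefix)
    n_significant: int
    sample_ids: list[str] = field(default_factory=list)


def pca(panel: GenotypePanel, populations: list[str] | None = None,
        n_axes: int | None = None, alpha: float = 0.05) -> PcaResult:
    """Eigen-decomposition of the normalised genotype covariance across samples."""
    if populations is not None:
        mask = np.zeros(panel.n_samples, dtype=bool)
        for p in populations:
            mask |= panel.population_mask(p)
        panel = panel.subset_samples(mask)
    g = panel.genotypes.astype(float)
    called = panel.genotypes != MISSING
    g[~called] = np.nan
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_hat = np.nansum(g, axis=0) / np.maximum(2 * n_called, 1)
    poly = (p_hat > 0) & (p_hat < 1) & (n_called > 0)
    if poly.sum() < 2:
        raise ValueError("PCA needs at least 2 polymorphic loci")
    x = (g[:, poly] - 2 * p_hat[poly]) / np.sqrt(p_hat[poly] * (1 - p_hat[poly]))
    x[np.isnan(x)] = 0.0  # mean imputation post-centring
    n_loci = int(poly.sum())
    cov = x @ x.T / n_loci
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    evals = evals[pos]
    evecs = evecs[:, pos]
    if n_axes is not None:
        evals, evecs = evals[:n_axes], evecs[:, :n_axes]
    var_exp = evals / evals.sum()
    pvals, n_sig = tracy_widom_significance(evals, panel.n_samples, n_loci, alpha=alpha)
    coords = evecs * np.sqrt(np.maximum(evals, 0))
    return PcaResult(
        coordinates=coords,
        eigenvalues=evals,
        variance_explained=var_exp,
        tw_pvalues=pvals,
        n_significant=n_sig,
        sample_ids=list(panel.sample_ids),
    )


def tracy_widom_significance(
    eigenvalues: np.ndarray, n_samples: int, n_loci: int, alpha: float = 0.05
) -> tuple[np.ndarray, int]:
    """Sequential Tracy-Widom tests of the leading eigenvalues.

    At each step the largest remaining eigenvalue is tested against the null
    that the remaining spectrum is Wishart noise, using Patterson's
    moment-based effective marker count; testing stops at the first
    non-significant axis.  Returns per-axis p (NaN beyond the stop point) and
    the count of significant leading axes.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 2:
        raise ValueError("need at least 2 eigenvalues for a Tracy-Widom test")
    pvals = np.full(lam.size, np.nan)
    n_sig = 0
    for j in range(lam.size - 1):
        tail = lam[j:]
        m = tail.size
        # effective marker count from the noise spectrum (tested eigenvalue
        # excluded: a dominant signal eigenvalue would collapse the estimate)
        noise = lam[j + 1:]
        s1n = noise.sum()
        s2n = (noise**2).sum()
        denom = (noise.size - 1) * s2n - s1n**2
        n_eff = (noise.size + 1) * s1n**2 / denom if denom > 0 else float(n_loci)
        n_eff = min(n_eff, float(n_loci))
        if n_eff <= 1:
            break
        ell = m * tail[0] / tail.sum()
        mu = (np.sqrt(n_eff - 1) + np.sqrt(m)) ** 2 / n_eff
        sigma = ((np.sqrt(n_eff - 1) + np.sqrt(m)) / n_eff) * (
            1.0 / np.sqrt(n_eff - 1) + 1.0 / np.sqrt(m)
        ) ** (1.0 / 3.0)
        pvals[j] = float(tracy_widom_sf((ell - mu) / sigma))
        if pvals[j] < alpha:
            n_sig += 1
        else:
            break
    return pvals, n_sig


# ---------------------------------------------------------------------------
# admixture
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureResult:
    k: int
    q: np.ndarray              # (n_samples, K) ancestry proportions
    freqs: np.ndarray          # (K, n_loci) cluster allele frequencies
    log_likelihood: float
    n_iter: int
    converged: bool
    seed: int
    sample_ids: list[str] = field(default_factory=list)
    ll_trace: list[float] = field(default_factory=list)


def admixture_em(
    panel: GenotypePanel, k: int, seed: int = 0,
    max_iter: int = 2000, tol: float = 1e-6,
) -> AdmixtureResult:
    """Maximum-likelihood admixture proportions via EM.

    Missing genotypes are marginalised (their loci simply drop out of each
    individual's likelihood).  Non-convergence at ``max_iter`` flags the
    result rather than raising.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    g = panel.genotypes.astype(float)
    called = panel.genotypes != MISSING
    g[~called] = 0.0
    w = called.astype(float)  # mask: contribution weight per entry
    n, n_loci = g.shape
    rng = np.random.default_rng(seed)
    if k == 1:
        with np.errstate(invalid="ignore"):
            f = (g.sum(axis=0) / np.maximum(2 * w.sum(axis=0), 1)).reshape(1, -1)
        f = np.clip(f, 1e-9, 1 - 1e-9)
        q = np.ones((n, 1))
        ll = _admixture_loglik(g, w, q, f)
        return AdmixtureResult(k=1, q=q, freqs=f, log_likelihood=ll, n_iter=0,
                               converged=True, seed=seed, sample_ids=list(panel.sample_ids))
    q = rng.dirichlet(np.ones(k), size=n)
    f = rng.uniform(0.05, 0.95, size=(k, n_loci))
    ll_old = -np.inf
    n_iter = 0
    converged = False
    trace: list[float] = []
    for n_iter in range(1, max_iter + 1):
        denom_b = np.clip(q @ f, 1e-300, None)          # (n, L)
        denom_a = np.clip(q @ (1 - f), 1e-300, None)
        tb = w * g / denom_b                             # (n, L)
        ta = w * (2 - g) / denom_a
        # expected allele-origin counts
        aq = q * (tb @ f.T) + q * (ta @ (1 - f).T)       # (n, K)
        nb = f * (q.T @ tb)                              # (K, L)
        na = (1 - f) * (q.T @ ta)
        q = aq / aq.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_new = nb / np.clip(nb + na, 1e-300, None)
        f = np.clip(f_new, 1e-9, 1 - 1e-9)
        ll = _admixture_loglik(g, w, q, f)
        trace.append(ll)
        if ll - ll_old < tol and n_iter > 1:
            converged = True
            break
        ll_old = ll
    return AdmixtureResult(k=k, q=q, freqs=f, log_likelihood=ll, n_iter=n_iter,
                           converged=converged, seed=seed,
                           sample_ids=list(panel.sample_ids), ll_trace=trace)


def _admixture_loglik(g: np.ndarray, w: np.ndarray, q: np.ndarray, f: np.ndarray) -> float:
    p = np.clip(q @ f, 1e-300, 1.0)
    ln_binom = np.where(g == 1, np.log(2.0), 0.0)
    ll = w * (g * np.log(p) + (2 - g) * np.log1p(-np.clip(p, None, 1 - 1e-300)) + ln_binom)
    return float(ll.sum())


def align_replicates(results: list[AdmixtureResult]) -> list[AdmixtureResult]:
    """Resolve label switching: permute each replicate's clusters to best match
    the first replicate (minimum sum of squared q differences over K! permutations)."""
    if not results:
        return results
    ref = results[0].q
    k = results[0].k
    aligned = [results[0]]
    for res in results[1:]:
        best_perm = min(
            itertools.permutations(range(k)),
            key=lambda perm: float(((res.q[:, list(perm)] - ref) ** 2).sum()),
        )
        perm = list(best_perm)
        aligned.append(
            AdmixtureResult(
                k=res.k, q=res.q[:, perm], freqs=res.freqs[perm],
                log_likelihood=res.log_likelihood, n_iter=res.n_iter,
                converged=res.converged, seed=res.seed, sample_ids=res.sample_ids,
            )
        )
    return aligned


@dataclass
class DeltaKReport:
    table: pd.DataFrame  # columns K, mean_ll, sd_ll, delta_k
    chosen_k: int


def run_admixture_replicates(
    panel: GenotypePanel, k_values: list[int], n_replicates: int = 10, seed: int = 0,
    max_iter: int = 2000, tol: float = 1e-6,
) -> dict[int, list[AdmixtureResult]]:
    """Replicate EM runs per K with distinct seeds derived from ``seed``."""
    out: dict[int, list[AdmixtureResult]] = {}
    for k in k_values:
        out[k] = [
            admixture_em(panel, k, seed=seed + 1000 * k + r, max_iter=max_iter, tol=tol)
            for r in range(n_replicates)
        ]
    return out


def evanno_delta_k(log_likelihoods: dict[int, list[float]]) -> DeltaKReport:
    """Evanno's second-difference statistic over replicate log-likelihoods.

    Delta-K(K) = mean|L(K+1) - 2 L(K) + L(K-1)| / SD(L(K)), defined for
    interior K only; the chosen K maximises Delta-K.
    """
    ks = sorted(log_likelihoods)
    if len(ks) < 3:
        raise ValueError("Evanno Delta-K needs at least three consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    mean_ll = {k: float(np.mean(log_likelihoods[k])) for k in ks}
    sd_ll = {k: float(np.std(log_likelihoods[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            if sd_ll[k] == 0:
                raise ValueError(f"SD of replicate log-likelihoods at K={k} is zero")
            dk = abs(mean_ll[k + 1] - 2 * mean_ll[k] + mean_ll[k - 1]) / sd_ll[k]
        rows.append({"K": k, "mean_ll": mean_ll[k], "sd_ll": sd_ll[k], "delta_k": dk})
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_k"])
    chosen = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return DeltaKReport(table=table, chosen_k=chosen)


def admixture_summary(
    result: AdmixtureResult, pop_labels: list[str], threshold: float = 0.10
) -> pd.DataFrame:
    """Per-population admixture summary.

    An individual's admixture proportion is its minor-cluster ancestry
    (1 - max q); the summary reports the percentage of individuals above
    ``threshold`` plus the min/max proportion per population.
    """
    minor = 1.0 - result.q.max(axis=1)
    df = pd.DataFrame({"population": pop_labels, "minor_q": minor})
    rows = []
    for pop, grp in df.groupby("population", sort=False):
        rows.append(
            {
                "population": pop,
                "n": len(grp),
                "pct_admixed": 100.0 * float((grp["minor_q"] > threshold).mean()),
                "min_admixture": float(grp["minor_q"].min()),
                "max_admixture": float(grp["minor_q"].max()),
            }
        )
    return pd.DataFrame(rows)


def q_matrix_frame(result: AdmixtureResult, pop_labels: list[str]) -> pd.DataFrame:
    """STRUCTURE-style Q matrix: sample, population, q_1..q_K."""
    df = pd.DataFrame({"sample": result.sample_ids, "population": pop_labels})
    for k in range(result.k):
        df[f"q_{k + 1}"] = result.q[:, k]
    return df
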