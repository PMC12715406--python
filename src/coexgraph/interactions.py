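"""Gene-gene interaction networks from redundancy-derived partial correlations.

The composite redundancy table serves as a surrogate covariance in a Gaussian
copula graphical model: it is sign-adjusted by the combined Pearson correlation
of the two modalities, fed to a graphical-lasso precision estimate, and
converted to partial correlations. Contrasting two conditions' partial
correlation matrices (entrywise absolute difference) highlights interaction
shifts, with an optional permutation test for significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class PartialCorrelationNetwork:
    genes: list[str]
    theta: np.ndarray        # combined Pearson correlation
    sigma: np.ndarray        # redundancy surrogate covariance
    sigma_hat: np.ndarray    # sign-adjusted surrogate
    alpha: float
    precision: np.ndarray
    phi: np.ndarray          # partial correlations, diagonal 0

    def edge_table(self):
        import pandas as pd

        n = len(self.genes)
        rows = [
            (self.genes[i], self.genes[j], self.phi[i, j])
            for i in range(n) for j in range(i + 1, n)
        ]
        return pd.DataFrame(rows, columns=["gene_i", "gene_j", "phi"])


@dataclass
class DeltaNetwork:
    genes: list[str]
    delta_phi: np.ndarray
    p_values: Optional[np.ndarray] = None
    p_adjusted: Optional[np.ndarray] = None
    significant: Optional[np.ndarray] = None


def combined_correlation(x_sc: np.ndarray, x_srt: np.ndarray, w: float = 0.5) -> np.ndarray:
    """Theta = w * corr(X_sc) + (1-w) * corr(X_srt), Pearson over observations.

    Zero-variance genes get zero correlation rows/columns (with a warning);
    their diagonal stays 1 only when both modalities carry variance.
    """
    def corr(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sd = x.std(axis=0)
        flat = sd == 0
        if np.any(flat):
            warnings.warn(f"{int(flat.sum())} zero-variance genes; correlations set to 0")
        safe = np.where(flat, 1.0, sd)
        z = (x - x.mean(axis=0)) / safe
        c = z.T @ z / x.shape[0]
        c[flat, :] = 0.0
        c[:, flat] = 0.0
        return c

    return w * corr(x_sc) + (1 - w) * corr(x_srt)


def sign_adjust(sigma: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Entrywise sigma * sign(theta) (sign(0) := 0), diagonal kept from sigma."""
    sigma = np.asarray(sigma, dtype=float)
    adjusted = sigma * np.sign(theta)
    np.fill_diagonal(adjusted, np.diag(sigma))
    return adjusted


def redundancy_covariance(redundancy: np.ndarray) -> np.ndarray:
    """Surrogate covariance on the Gaussian-equivalent correlation scale.

    Under a Gaussian copula, mutual information and correlation are linked by
    I = -1/2 log(1 - r^2); inverting gives |r| = sqrt(1 - exp(-2 I)), which
    maps the redundancy (MI) table onto a bounded correlation-like scale with
    unit diagonal — the natural surrogate for the copula graphical model.
    """
    red = np.asarray(redundancy, dtype=float)
    sigma = np.sqrt(1.0 - np.exp(-2.0 * np.maximum(red, 0.0)))
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _load_diagonal(sigma: np.ndarray, eig_floor: float) -> np.ndarray:
    """Diagonal loading so the smallest eigenvalue is at least ``eig_floor``
    (the MI-derived surrogate need not be positive-definite)."""
    sym = (sigma + sigma.T) / 2
    lo = np.linalg.eigvalsh(sym)[0]
    if lo < eig_floor:
        sym = sym + (eig_floor - lo) * np.eye(sym.shape[0])
    return sym


def estimate_precision(sigma_hat: np.ndarray, alpha: float = 0.1) -> np.ndarray:
    """Graphical-lasso precision estimate for the penalized objective
    -log|Lambda| + tr(sigma_hat @ Lambda) + alpha * ||Lambda||_1.

    alpha = 0 reduces to the direct inverse of the (diagonally loaded) input.
    Ill-conditioned surrogates are retried with progressively stronger
    diagonal loading before giving up.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    sigma_hat = np.asarray(sigma_hat, dtype=float)
    if alpha == 0:
        return np.linalg.inv(_load_diagonal(sigma_hat, 1e-3))
    from sklearn.covariance import graphical_lasso

    err: Exception | None = None
    for eig_floor in (1e-3, 1e-2, 1e-1):
        cov = _load_diagonal(sigma_hat, eig_floor)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, precision = graphical_lasso(cov, alpha=alpha, max_iter=500)
            return precision
        except FloatingPointError as exc:
            err = exc
    raise RuntimeError(f"graphical lasso failed to converge: {err}") from err


def partial_correlation(precision: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Phi_ij = -Lambda_ij / (sqrt(Lambda_ii * Lambda_jj) + epsilon), diag 0."""
    lam = np.asarray(precision, dtype=float)
    d = np.diag(lam)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    denom = np.sqrt(np.outer(d, d)) + epsilon
    phi = -lam / denom
    np.fill_diagonal(phi, 0.0)
    return phi


def build_network(
    genes: Sequence[str],
    redundancy: np.ndarray,
    x_sc: np.ndarray,
    x_srt: np.ndarray,
    w: float = 0.5,
    alpha: float = 0.1,
    epsilon: float = 1e-6,
) -> PartialCorrelationNetwork:
    """Chain: combined correlation -> sign adjustment -> graphical lasso ->
    partial correlation."""
    theta = combined_correlation(x_sc, x_srt, w)
    sigma = redundancy_covariance(redundancy)
    sigma_hat = sign_adjust(sigma, theta)
    precision = estimate_precision(sigma_hat, alpha)
    phi = partial_correlation(precision, epsilon)
    return PartialCorrelationNetwork(
        genes=list(genes), theta=theta, sigma=sigma, sigma_hat=sigma_hat,
        alpha=alpha, precision=precision, phi=phi,
    )


def rank_interactions(
    phi: np.ndarray, genes: Sequence[str],
    top_fraction: Optional[float] = None, threshold: Optional[float] = None,
) -> list[tuple[str, str, float]]:
    """Gene pairs sorted by |phi| descending; ties broken by lexicographic
    gene-pair order. Optionally truncated to a fraction or |phi| threshold."""
    n = len(genes)
    pairs = [
        (
            -abs(phi[i, j]),
            (min(genes[i], genes[j]), max(genes[i], genes[j])),
            float(phi[i, j]),
        )
        for i in range(n) for j in range(i + 1, n)
    ]
    pairs.sort()
    out = [(p[1][0], p[1][1], p[2]) for p in pairs]
    if threshold is not None:
        out = [t for t in out if abs(t[2]) >= threshold]
    if top_fraction is not None:
        out = out[: int(np.ceil(top_fraction * len(pairs)))]
    return out


def delta_network(
    phi_a: np.ndarray,
    phi_b: np.ndarray,
    genes: Sequence[str],
    replicates_a: Optional[Sequence[np.ndarray]] = None,
    replicates_b: Optional[Sequence[np.ndarray]] = None,
    reference_delta: Optional[np.ndarray] = None,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha_level: float = 0.05,
) -> DeltaNetwork:
    """Entrywise |phi_a - phi_b| with optional significance.

    With per-condition replicate phi matrices, a paired permutation test swaps
    the condition assignment within replicate pairs to build the null of each
    entry's absolute difference. Without replicates, a reference contrast
    (e.g. a healthy-vs-healthy delta) supplies an empirical null and each
    entry gets a rank-based p-value. P-values are Benjamini-Hochberg adjusted.
    """
    phi_a, phi_b = np.asarray(phi_a), np.asarray(phi_b)
    if phi_a.shape != phi_b.shape or phi_a.shape[0] != len(genes):
        raise ValueError("condition matrices must share the gene order")
    delta = np.abs(phi_a - phi_b)
    p = padj = sig = None
    iu = np.triu_indices(len(genes), k=1)
    if replicates_a is not None and replicates_b is not None:
        if len(replicates_a) != len(replicates_b):
            raise ValueError("paired permutation requires equal replicate counts")
        rng = np.random.default_rng(seed)
        ra = np.stack(replicates_a)
        rb = np.stack(replicates_b)
        observed = np.abs(ra.mean(axis=0) - rb.mean(axis=0))[iu]
        exceed = np.ones_like(observed)
        for _ in range(n_permutations):
            flip = rng.random(ra.shape[0]) < 0.5
            pa = np.where(flip[:, None, None], rb, ra)
            pb = np.where(flip[:, None, None], ra, rb)
            null = np.abs(pa.mean(axis=0) - pb.mean(axis=0))[iu]
            exceed += null >= observed
        p_flat = exceed / (n_permutations + 1)
    elif reference_delta is not None:
        ref = np.asarray(reference_delta)[iu]
        obs = delta[iu]
        # rank-based p: fraction of reference contrasts at least as large
        order = np.sort(ref)
        p_flat = 1.0 - np.searchsorted(order, obs, side="left") / (len(order) + 1)
    else:
        p_flat = None
    if p_flat is not None:
        from statsmodels.stats.multitest import multipletests

        _, padj_flat, _, _ = multipletests(p_flat, method="fdr_bh")
        p = np.zeros_like(delta)
        padj = np.zeros_like(delta)
        p[iu] = p_flat
        padj[iu] = padj_flat
        p, padj = p + p.T, padj + padj.T
        sig = padj <= alpha_level
        np.fill_diagonal(sig, False)
    return DeltaNetwork(genes=list(genes), delta_phi=delta, p_values=p,
                        p_adjusted=padj, significant=sig)
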