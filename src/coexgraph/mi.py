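"""k-nearest-neighbor mutual information estimators (nats).

Continuous-continuous MI uses the Kraskov-Stoegbauer-Grassberger (KSG) type-1
estimator; continuous-discrete MI the Ross estimator; conditional MI with a
continuous conditioning variable the Frenzel-Pompe construction; conditional MI
given a categorical variable the exact stratification identity
I(X;Y|L) = sum_l p(l) I(X;Y | L=l) with KSG within each class.

All estimators share the Chebyshev (max) metric, break ties with seeded
uniform jitter of magnitude 1e-10, and clamp negative raw estimates to zero
(MI is nonnegative; kNN estimators can dip below zero by sampling noise).

Exact plug-in quantities on finite discrete joint distributions are provided
for property checks of the redundancy/complementarity inequality.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

_JITTER = 1e-10


def _prepare(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return x + _JITTER * rng.standard_normal(x.shape)


def mi_continuous_continuous(
    x: np.ndarray, y: np.ndarray, k: int = 3, seed: int = 0,
) -> float:
    """KSG-type kNN estimate of I(X;Y) in nats, symmetric in (x, y).

    Ties are handled with the mixed discrete-continuous correction: points
    whose k-th neighbor distance is exactly zero (probability atoms, e.g. the
    zero counts of sparse expression data) use the atom multiplicity as their
    local k and zero-radius marginal counts, which keeps independent
    zero-inflated variables near zero MI where naive jittered KSG inflates.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must share the observation set")
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    z = np.column_stack([x, y])
    tree = cKDTree(z)
    eps = tree.query(z, k=k + 1, p=np.inf)[0][:, -1]
    ties = eps == 0
    k_local = np.full(n, float(k))
    radius = np.nextafter(eps, 0)  # strictly-inside count
    if np.any(ties):
        k_local[ties] = np.asarray(
            tree.query_ball_point(z[ties], 0.0, p=np.inf, return_length=True)
        )
        radius[ties] = 0.0
    tree_x = cKDTree(x[:, None])
    tree_y = cKDTree(y[:, None])
    nx = np.asarray(tree_x.query_ball_point(x[:, None], radius, p=np.inf,
                                            return_length=True))
    ny = np.asarray(tree_y.query_ball_point(y[:, None], radius, p=np.inf,
                                            return_length=True))
    mi = np.mean(digamma(k_local) + np.log(n) - np.log(nx) - np.log(ny))
    return max(0.0, float(mi))


def mi_continuous_discrete(
    x: np.ndarray, labels: np.ndarray, k: int = 3, seed: int = 0,
) -> float:
    """Ross estimate of I(X;L) in nats for continuous x, categorical labels."""
    rng = np.random.default_rng(seed)
    x = _prepare(x, rng)
    labels = np.asarray(labels)
    n = x.shape[0]
    if labels.shape[0] != n:
        raise ValueError("x and labels must share the observation set")
    uniq, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    if len(uniq) < 2:
        return 0.0
    if np.ptp(x) == 0:
        return 0.0
    radius = np.empty(n)
    k_used = np.empty(n, dtype=int)
    for c in range(len(uniq)):
        mask = inv == c
        xc = x[mask]
        kc = min(k, counts[c] - 1)
        if kc < 1:
            # a singleton class carries no within-class neighborhood; skip it
            radius[mask] = 0.0
            k_used[mask] = 0
            continue
        if kc < k:
            warnings.warn(f"class {uniq[c]!r} has fewer than k+1 members; using k={kc}")
        sc = np.sort(xc)
        # distance to the kc-th same-class neighbor (1D Chebyshev = absolute)
        pos = np.searchsorted(sc, xc)
        d = np.empty(xc.shape[0])
        for i, (xi, p) in enumerate(zip(xc, pos)):
            # two-pointer window over sorted same-class values, skipping self
            found = 0
            dist = 0.0
            li, hj = p - 1, p + 1
            while found < kc:
                left = xi - sc[li] if li >= 0 else np.inf
                right = sc[hj] - xi if hj < len(sc) else np.inf
                if left <= right:
                    dist = left
                    li -= 1
                else:
                    dist = right
                    hj += 1
                found += 1
            d[i] = dist
        radius[mask] = np.nextafter(d, 0)  # shrink to make the count effectively strict
        k_used[mask] = kc
    valid = k_used >= 1
    if not np.any(valid):
        return 0.0
    tree = cKDTree(x[:, None])
    m = np.asarray(tree.query_ball_point(x[valid, None], radius[valid],
                                         p=np.inf, return_length=True))
    mi = (
        digamma(n)
        + np.mean(digamma(k_used[valid]))
        - np.mean(digamma(counts[inv[valid]]))
        - np.mean(digamma(np.maximum(m, 1)))
    )
    return max(0.0, float(mi))


def _cmi_continuous_z(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, k: int, seed: int,
) -> float:
    """Frenzel-Pompe kNN estimate of I(X;Y|Z) with continuous Z."""
    rng = np.random.default_rng(seed)
    x = _prepare(x, rng)
    y = _prepare(y, rng)
    z = _prepare(z, rng)
    n = x.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} observations, got {n}")
    xyz = np.column_stack([x, y, z])
    eps = cKDTree(xyz).query(xyz, k=k + 1, p=np.inf)[0][:, -1]
    eps_strict = np.nextafter(eps, 0)

    def count(sub: np.ndarray) -> np.ndarray:
        tree = cKDTree(sub)
        return np.array(tree.query_ball_point(sub, eps_strict, p=np.inf,
                                              return_length=True)) - 1

    n_xz = count(np.column_stack([x, z]))
    n_yz = count(np.column_stack([y, z]))
    n_z = count(z[:, None])
    cmi = np.mean(digamma(k) - digamma(n_xz + 1) - digamma(n_yz + 1) + digamma(n_z + 1))
    return max(0.0, float(cmi))


def _cmi_categorical_z(
    x: np.ndarray, y: np.ndarray, labels: np.ndarray, k: int, seed: int,
) -> float:
    """I(X;Y|L) = sum_l p(l) I(X;Y|L=l), KSG within each label class."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    uniq, counts = np.unique(labels, return_counts=True)
    total = 0.0
    for c, n_c in zip(uniq, counts):
        kc = min(k, int(n_c) - 2)
        if kc < 1:
            continue  # class too small to estimate; contributes ~0 mass
        mask = labels == c
        total += (n_c / n) * mi_continuous_continuous(x[mask], y[mask], k=kc, seed=seed)
    return max(0.0, total)


def conditional_mi(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, k: int = 3, seed: int = 0,
) -> float:
    """I(X;Y|Z) in nats; Z may be continuous (floats) or categorical."""
    z = np.asarray(z)
    if z.dtype.kind == "f":
        return _cmi_continuous_z(x, y, z, k, seed)
    return _cmi_categorical_z(x, y, z, k, seed)


def conditional_relevance(
    x: np.ndarray, labels: np.ndarray, g_other: np.ndarray, k: int = 3, seed: int = 0,
) -> float:
    """I(X;L | G_other) for categorical labels and a continuous conditioning gene.

    Computed through the chain rule with kNN estimates:
    I(X;L|G) = I(X; (L,G)) - I(X;G), where the mixed pair (L,G) is handled by
    stratifying over L: I(X;(L,G)) = I(X;G|L) + I(X;L).
    """
    return max(
        0.0,
        _cmi_categorical_z(x, g_other, labels, k, seed)
        + mi_continuous_discrete(x, labels, k=k, seed=seed)
        - mi_continuous_continuous(x, g_other, k=k, seed=seed),
    )


# ---------------------------------------------------------------------------
# Equal-frequency binned plug-in estimators
# ---------------------------------------------------------------------------

def equal_frequency_bins(x: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Quantile-bin a continuous vector into integer codes.

    Tied values (e.g. the zero atom of sparse counts) always share a bin, so
    the binning never manufactures distinctions finer than the data's own
    value levels — which makes plug-in MI on the codes robust to spurious
    fine-scale channels such as per-observation normalization factors.
    """
    x = np.asarray(x, dtype=float).ravel()
    qs = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(qs, x, side="right")


def plugin_mi_discrete(a: np.ndarray, b: np.ndarray, miller_madow: bool = True) -> float:
    """Plug-in MI (nats) of two integer-coded variables, with the
    Miller-Madow small-sample bias correction by default."""
    a = np.asarray(a)
    b = np.asarray(b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1)
    n = table.sum()
    p = table / n
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    nz = p > 0
    mi = float((p[nz] * np.log(p[nz] / np.outer(pi, pj)[nz])).sum())
    if miller_madow:
        mi -= ((nz.sum() - 1) - (np.count_nonzero(pi) - 1) - (np.count_nonzero(pj) - 1)) / (2 * n)
    return max(0.0, mi)


def plugin_cmi_discrete(a: np.ndarray, b: np.ndarray, labels: np.ndarray,
                        miller_madow: bool = True) -> float:
    """Plug-in I(A;B|L) = sum_l p(l) I(A;B | L=l) for integer-coded A, B."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    total = 0.0
    for lab in np.unique(labels):
        mask = labels == lab
        total += (mask.sum() / n) * plugin_mi_discrete(a[mask], b[mask], miller_madow)
    return max(0.0, total)


def differential_entropy(x: np.ndarray, k: int = 3, seed: int = 0) -> float:
    """Kozachenko-Leonenko kNN estimate of 1D differential entropy (nats).

    Used as a gene's self-information when a redundancy table needs a
    diagonal; can be negative for concentrated distributions.
    """
    rng = np.random.default_rng(seed)
    x = _prepare(x, rng)
    n = x.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} observations, got {n}")
    sx = np.sort(x)
    d = np.empty(n)
    for i in range(n):
        lo = max(0, i - k)
        hi = min(n, i + k + 1)
        window = np.abs(sx[lo:hi] - sx[i])
        d[i] = np.sort(window)[k]  # k-th nonzero neighbor (window includes self)
    d = np.maximum(d, 1e-300)
    return float(digamma(n) - digamma(k) + np.mean(np.log(2 * d)))


# ---------------------------------------------------------------------------
# Exact plug-in quantities on discrete joints
# ---------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def discrete_joint_metrics(p: np.ndarray) -> dict[str, float]:
    """Exact relevance/redundancy/complementarity of a finite joint P(gi, gj, L).

    ``p`` is a 3D array of probabilities over (gi, gj, L) summing to 1.
    Returned values are in nats.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 3 or not np.isclose(p.sum(), 1.0):
        raise ValueError("p must be a 3D joint distribution summing to 1")
    p_ij = p.sum(axis=2)
    p_il = p.sum(axis=1)
    p_jl = p.sum(axis=0)
    p_i, p_j, p_l = p_ij.sum(axis=1), p_ij.sum(axis=0), p_il.sum(axis=0)

    red = _entropy(p_i) + _entropy(p_j) - _entropy(p_ij.ravel())
    rel_i = _entropy(p_i) + _entropy(p_l) - _entropy(p_il.ravel())
    rel_j = _entropy(p_j) + _entropy(p_l) - _entropy(p_jl.ravel())
    # I(gi; gj | L) = H(gi|L) + H(gj|L) - H(gi,gj|L)
    h_l = _entropy(p_l)
    comp = (
        (_entropy(p_il.ravel()) - h_l)
        + (_entropy(p_jl.ravel()) - h_l)
        - (_entropy(p.ravel()) - h_l)
    )
    # I(gi; L | gj) = H(gi|gj) + H(L|gj) - H(gi,L|gj)
    h_j = _entropy(p_j)
    rel_i_given_j = (
        (_entropy(p_ij.ravel()) - h_j)
        + (_entropy(p_jl.ravel()) - h_j)
        - (_entropy(p.ravel()) - h_j)
    )
    h_i = _entropy(p_i)
    rel_j_given_i = (
        (_entropy(p_ij.ravel()) - h_i)
        + (_entropy(p_il.ravel()) - h_i)
        - (_entropy(p.ravel()) - h_i)
    )
    return {
        "red": red, "comp": comp,
        "rel_i": rel_i, "rel_j": rel_j,
        "rel_i_given_j": rel_i_given_j, "rel_j_given_i": rel_j_given_i,
    }


def check_theorem1(p: np.ndarray, atol: float = 1e-12) -> tuple[bool, bool]:
    """Evaluate both sides of the redundancy/complementarity equivalence.

    Returns (Red < Comp, Rel_i < Rel_i|gj AND Rel_j < Rel_j|gi) on the exact
    plug-in values of the discrete joint ``p``; the two booleans agree for
    every distribution.
    """
    m = discrete_joint_metrics(p)
    lhs = m["red"] < m["comp"] - atol
    rhs = (m["rel_i"] < m["rel_i_given_j"] - atol) and (m["rel_j"] < m["rel_j_given_i"] - atol)
    return lhs, rhs
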