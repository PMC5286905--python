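"""Independent brute-force oracles used by the test suite.

These deliberately use dense nT x nT linear algebra (and explicit allele
bookkeeping for the gene-dropping IBD oracle) so they share no code path
with the package's eigendecomposition-based implementation.
"""

import numpy as np


def dense_restricted_loglik(K, Y, Q, R):
    """REML log-likelihood from the dense formula
    -0.5 [ (nT - T) log 2pi + log|V| + log|X'V^-1 X| + y'Py ]."""
    n, T = Y.shape
    V = np.kron(K, Q) + np.kron(np.eye(n), R)
    X = np.kron(np.ones((n, 1)), np.eye(T))
    y = Y.ravel()
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        (n * T - T) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + r @ Vi @ r
    )


def dense_blup(K_full, Y_train, Q, R, mu, idx_train, idx_target):
    """Multi-trait conditional mean (K_ct (x) Q) V_tt^-1 (y - X mu),
    built and solved as one dense system."""
    n, T = Y_train.shape
    K_tt = K_full[np.ix_(idx_train, idx_train)]
    K_ct = K_full[np.ix_(idx_target, idx_train)]
    V = np.kron(K_tt, Q) + np.kron(np.eye(n), R)
    r = (Y_train - mu).ravel()
    g = np.kron(K_ct, Q) @ np.linalg.solve(V, r)
    return g.reshape(len(idx_target), T)


def gene_drop_ibd(pedigree, n_loci, rng, chunk=500):
    """Monte-Carlo estimate of the numerator relationship matrix.

    Drops uniquely labelled founder alleles down the pedigree at
    independent loci; for each pair the average (over loci) of
    (shared allele matches) / 2 estimates a_ij.  Returns (mean, se) with
    per-entry Monte-Carlo standard errors.
    """
    n = pedigree.n
    founder_allele = {}
    next_label = 0
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    done = 0
    while done < n_loci:
        m = min(chunk, n_loci - done)
        a = np.zeros((2, n, m), dtype=np.int32)
        next_label = 0
        for i in range(n):
            for which, parent in ((0, pedigree.sire[i]), (1, pedigree.dam[i])):
                if parent < 0:
                    a[which, i] = next_label
                    next_label += 1
                else:
                    coin = rng.random(m) < 0.5
                    a[which, i] = np.where(coin, a[0, parent], a[1, parent])
        for locus in range(m):
            a1 = a[0, :, locus]
            a2 = a[1, :, locus]
            share = (
                (a1[:, None] == a1[None, :]).astype(float)
                + (a1[:, None] == a2[None, :])
                + (a2[:, None] == a1[None, :])
                + (a2[:, None] == a2[None, :])
            ) / 2.0
            s1 += share
            s2 += share**2
        done += m
    mean = s1 / n_loci
    var = (s2 / n_loci - mean**2) / n_loci
    return mean, np.sqrt(np.maximum(var, 0.0))


def ols_slope(x, y):
    """Closed-form simple-regression slope cov(x, y) / var(x)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))
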