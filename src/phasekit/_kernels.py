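"""Numba kernels for the HMM inner loops and PBWT construction.

These are deliberately plain loops: the Li–Stephens recursions are run tens
of thousands of times per Gibbs sweep, so per-call overhead matters more
than vectorisation elegance.  All kernels normalise per site (rescaling) to
avoid underflow on long regions.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def pbwt_build_arrays(H):
    """Durbin's PBWT construction.

    Parameters
    ----------
    H : (n_hap, n_site) uint8 binary haplotype matrix.

    Returns
    -------
    prefix : (n_site, n_hap) int32
        ``prefix[k]`` is the ordering of haplotypes by reversed prefix after
        processing sites ``0..k`` (stable partition by allele at ``k``).
    div : (n_site, n_hap) int32
        ``div[k][i]`` is the first site of the match between sorted
        haplotype ``i`` and ``i-1``; ``div[k][0] == k+1`` (sentinel: no
        predecessor).
    """
    n, M = H.shape
    prefix = np.empty((M, n), np.int32)
    div = np.empty((M, n), np.int32)
    a = np.empty(n, np.int32)
    d = np.zeros(n, np.int32)
    for i in range(n):
        a[i] = i
    a0 = np.empty(n, np.int32)
    a1 = np.empty(n, np.int32)
    d0 = np.empty(n, np.int32)
    d1 = np.empty(n, np.int32)
    for k in range(M):
        p = k + 1
        q = k + 1
        n0 = 0
        n1 = 0
        for i in range(n):
            h = a[i]
            if d[i] > p:
                p = d[i]
            if d[i] > q:
                q = d[i]
            if H[h, k] == 0:
                a0[n0] = h
                d0[n0] = p
                n0 += 1
                p = 0
            else:
                a1[n1] = h
                d1[n1] = q
                n1 += 1
                q = 0
        for i in range(n0):
            a[i] = a0[i]
            d[i] = d0[i]
        for i in range(n1):
            a[n0 + i] = a1[i]
            d[n0 + i] = d1[i]
        for i in range(n):
            prefix[k, i] = a[i]
            div[k, i] = d[i]
    return prefix, div


@njit(cache=True, inline="always")
def _p_zero(allele, theta):
    # P(observed allele 0 | copied haplotype allele)
    if allele == 0:
        return 1.0 - theta
    return theta


@njit(cache=True)
def diploid_ffbs(H, gt, rho, theta, u_path, u_allele, greedy=False):
    """Forward-filtering backward-sampling for the diploid Li–Stephens model.

    States are ordered pairs (j, k) of conditioning haplotypes for the two
    target haplotypes; per-haplotype transitions are
    ``(1-rho) * delta + rho / K`` and genotype emissions sum the two
    orderings at heterozygous sites.

    Parameters
    ----------
    H : (K, M) uint8 conditioning haplotypes.
    gt : (M,) int8 target genotypes in {0, 1, 2}.
    rho : (M-1,) switch probabilities between adjacent sites.
    u_path, u_allele : (M,) uniforms driving the path and allele draws.

    Returns
    -------
    h0, h1 : (M,) uint8 sampled target haplotype pair (h0 + h1 == gt).
    het_prob : (M,) float64, P(h0 carries ALT | sampled state) at het sites,
        -1 elsewhere.
    """
    K, M = H.shape
    alpha = np.empty((M, K, K))
    # forward
    for m in range(M):
        g = gt[m]
        if m == 0:
            for j in range(K):
                p0j = _p_zero(H[j, 0], theta)
                for k in range(K):
                    p0k = _p_zero(H[k, 0], theta)
                    if g == 0:
                        e = p0j * p0k
                    elif g == 2:
                        e = (1.0 - p0j) * (1.0 - p0k)
                    else:
                        e = p0j * (1.0 - p0k) + (1.0 - p0j) * p0k
                    alpha[0, j, k] = e
        else:
            a = 1.0 - rho[m - 1]
            b = rho[m - 1] / K
            row = np.zeros(K)
            col = np.zeros(K)
            for j in range(K):
                for k in range(K):
                    v = alpha[m - 1, j, k]
                    row[j] += v
                    col[k] += v
            for j in range(K):
                p0j = _p_zero(H[j, m], theta)
                for k in range(K):
                    p0k = _p_zero(H[k, m], theta)
                    if g == 0:
                        e = p0j * p0k
                    elif g == 2:
                        e = (1.0 - p0j) * (1.0 - p0k)
                    else:
                        e = p0j * (1.0 - p0k) + (1.0 - p0j) * p0k
                    trans = a * a * alpha[m - 1, j, k] + a * b * (row[j] + col[k]) + b * b
                    alpha[m, j, k] = e * trans
        s = 0.0
        for j in range(K):
            for k in range(K):
                s += alpha[m, j, k]
        if s <= 0.0:
            s = 1e-300
        inv = 1.0 / s
        for j in range(K):
            for k in range(K):
                alpha[m, j, k] *= inv

    # backward pass: sample the state path (or greedily take the argmax,
    # used in late sweeps to stop re-injecting sampling noise)
    path_j = np.empty(M, np.int64)
    path_k = np.empty(M, np.int64)
    jj = K - 1
    kk = K - 1
    if greedy:
        best = -1.0
        for j in range(K):
            for k in range(K):
                if alpha[M - 1, j, k] > best:
                    best = alpha[M - 1, j, k]
                    jj = j
                    kk = k
    else:
        u = u_path[M - 1]
        acc = 0.0
        done = False
        for j in range(K):
            if done:
                break
            for k in range(K):
                acc += alpha[M - 1, j, k]
                if acc >= u:
                    jj = j
                    kk = k
                    done = True
                    break
    path_j[M - 1] = jj
    path_k[M - 1] = kk
    for m in range(M - 2, -1, -1):
        a = 1.0 - rho[m]
        b = rho[m] / K
        jn = path_j[m + 1]
        kn = path_k[m + 1]
        jj = K - 1
        kk = K - 1
        if greedy:
            best = -1.0
            for j in range(K):
                tj = b + (a if j == jn else 0.0)
                for k in range(K):
                    tk = b + (a if k == kn else 0.0)
                    w = alpha[m, j, k] * tj * tk
                    if w > best:
                        best = w
                        jj = j
                        kk = k
        else:
            tot = 0.0
            for j in range(K):
                tj = b + (a if j == jn else 0.0)
                for k in range(K):
                    tk = b + (a if k == kn else 0.0)
                    tot += alpha[m, j, k] * tj * tk
            u = u_path[m] * tot
            acc = 0.0
            done = False
            for j in range(K):
                if done:
                    break
                tj = b + (a if j == jn else 0.0)
                for k in range(K):
                    tk = b + (a if k == kn else 0.0)
                    acc += alpha[m, j, k] * tj * tk
                    if acc >= u:
                        jj = j
                        kk = k
                        done = True
                        break
        path_j[m] = jj
        path_k[m] = kk

    # allele assignment given the sampled path
    h0 = np.zeros(M, np.uint8)
    h1 = np.zeros(M, np.uint8)
    het_prob = np.full(M, -1.0)
    for m in range(M):
        g = gt[m]
        if g == 0:
            continue
        if g == 2:
            h0[m] = 1
            h1[m] = 1
            continue
        j = path_j[m]
        k = path_k[m]
        p0j = _p_zero(H[j, m], theta)
        p0k = _p_zero(H[k, m], theta)
        num = (1.0 - p0j) * p0k  # h0 = ALT, h1 = REF
        den = num + p0j * (1.0 - p0k)
        p = 0.5 if den <= 0.0 else num / den
        het_prob[m] = p
        if (p >= 0.5) if greedy else (u_allele[m] < p):
            h0[m] = 1
        else:
            h1[m] = 1
    return h0, h1, het_prob


@njit(cache=True)
def diploid_posteriors(H, gt, rho, theta):
    """Full forward-backward state posteriors for the diploid model.

    Returns gamma with shape (M, K, K), normalised per site.  Used by tests
    and diagnostics; the sampler itself uses :func:`diploid_ffbs`.
    """
    K, M = H.shape
    alpha = np.empty((M, K, K))
    emis = np.empty((M, K, K))
    for m in range(M):
        g = gt[m]
        for j in range(K):
            p0j = _p_zero(H[j, m], theta)
            for k in range(K):
                p0k = _p_zero(H[k, m], theta)
                if g == 0:
                    e = p0j * p0k
                elif g == 2:
                    e = (1.0 - p0j) * (1.0 - p0k)
                else:
                    e = p0j * (1.0 - p0k) + (1.0 - p0j) * p0k
                emis[m, j, k] = e
    for m in range(M):
        if m == 0:
            for j in range(K):
                for k in range(K):
                    alpha[0, j, k] = emis[0, j, k]
        else:
            a = 1.0 - rho[m - 1]
            b = rho[m - 1] / K
            row = np.zeros(K)
            col = np.zeros(K)
            for j in range(K):
                for k in range(K):
                    v = alpha[m - 1, j, k]
                    row[j] += v
                    col[k] += v
            for j in range(K):
                for k in range(K):
                    trans = a * a * alpha[m - 1, j, k] + a * b * (row[j] + col[k]) + b * b
                    alpha[m, j, k] = emis[m, j, k] * trans
        s = 0.0
        for j in range(K):
            for k in range(K):
                s += alpha[m, j, k]
        inv = 1.0 / max(s, 1e-300)
        for j in range(K):
            for k in range(K):
                alpha[m, j, k] *= inv
    gamma = np.empty((M, K, K))
    beta = np.ones((K, K))
    for j in range(K):
        for k in range(K):
            gamma[M - 1, j, k] = alpha[M - 1, j, k]
    for m in range(M - 2, -1, -1):
        a = 1.0 - rho[m]
        b = rho[m] / K
        Bm = np.empty((K, K))
        row = np.zeros(K)
        col = np.zeros(K)
        tot = 0.0
        for j in range(K):
            for k in range(K):
                v = emis[m + 1, j, k] * beta[j, k]
                Bm[j, k] = v
                row[j] += v
                col[k] += v
                tot += v
        s = 0.0
        for j in range(K):
            for k in range(K):
                nb = a * a * Bm[j, k] + a * b * (row[j] + col[k]) + b * b * tot
                beta[j, k] = nb
                g = alpha[m, j, k] * nb
                gamma[m, j, k] = g
                s += g
        inv = 1.0 / max(s, 1e-300)
        bs = 0.0
        for j in range(K):
            for k in range(K):
                gamma[m, j, k] *= inv
                bs += beta[j, k]
        binv = K * K / max(bs, 1e-300)
        for j in range(K):
            for k in range(K):
                beta[j, k] *= binv
    return gamma


@njit(cache=True)
def haploid_forward_backward(H, obs, rho, theta):
    """Haploid Li–Stephens forward-backward.

    Parameters
    ----------
    H : (K, M) uint8 conditioning haplotypes (the local reference panel).
    obs : (M,) uint8 observed target haplotype alleles.
    rho : (M-1,) switch probabilities.

    Returns
    -------
    gamma : (M, K) state posteriors, each row summing to 1.
    """
    K, M = H.shape
    alpha = np.empty((M, K))
    for m in range(M):
        if m == 0:
            for s in range(K):
                e = 1.0 - theta if H[s, 0] == obs[0] else theta
                alpha[0, s] = e
        else:
            a = 1.0 - rho[m - 1]
            b = rho[m - 1] / K
            for s in range(K):
                e = 1.0 - theta if H[s, m] == obs[m] else theta
                alpha[m, s] = e * (a * alpha[m - 1, s] + b)
        tot = 0.0
        for s in range(K):
            tot += alpha[m, s]
        inv = 1.0 / max(tot, 1e-300)
        for s in range(K):
            alpha[m, s] *= inv
    gamma = np.empty((M, K))
    beta = np.ones(K)
    for s in range(K):
        gamma[M - 1, s] = alpha[M - 1, s]
    for m in range(M - 2, -1, -1):
        a = 1.0 - rho[m]
        b = rho[m] / K
        tot = 0.0
        B = np.empty(K)
        for s in range(K):
            e = 1.0 - theta if H[s, m + 1] == obs[m + 1] else theta
            B[s] = e * beta[s]
            tot += B[s]
        gs = 0.0
        for s in range(K):
            beta[s] = a * B[s] + b * tot
            gamma[m, s] = alpha[m, s] * beta[s]
            gs += gamma[m, s]
        inv = 1.0 / max(gs, 1e-300)
        bs = 0.0
        for s in range(K):
            gamma[m, s] *= inv
            bs += beta[s]
        binv = K / max(bs, 1e-300)
        for s in range(K):
            beta[s] *= binv
    return gamma


@njit(cache=True)
def longest_match_through(H, cm, site, target, excl_a, excl_b):
    """Exact longest shared segment through ``site``.

    Walks left/right from ``site`` for every other haplotype, terminating at
    the first mismatch (cheap: unrelated haplotypes diverge within a few
    sites).  Returns ``(best_hap, best_length_cm)``; haplotypes mismatching
    at ``site`` itself score -1.
    """
    n, M = H.shape
    best_len = -1.0
    best_hap = -1
    for h in range(n):
        if h == target or h == excl_a or h == excl_b:
            continue
        if H[h, site] != H[target, site]:
            continue
        a = site
        while a > 0 and H[h, a - 1] == H[target, a - 1]:
            a -= 1
        b = site
        while b < M - 1 and H[h, b + 1] == H[target, b + 1]:
            b += 1
        length = cm[b] - cm[a]
        if length > best_len:
            best_len = length
            best_hap = h
    return best_hap, best_len
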