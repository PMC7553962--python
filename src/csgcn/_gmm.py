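"""Compiled 2-D Gaussian-mixture EM used by the pairwise network scan.

The network stage fits a small full-covariance GMM to every unordered
gene pair's (x, y) sample scatter — tens of thousands of fits per run —
so the EM loop is numba-compiled.  Model selection is BIC over
1..max_components; initialisation is k-means++ seeding followed by a
few Lloyd steps, with a configurable number of restarts.

The fit is cross-checked against scikit-learn's GaussianMixture in the
test suite; this module exists for speed, not for a different model.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2PI = 1.8378770664093453


@njit(cache=True)
def _kmeanspp_centers(pts, k):
    n = pts.shape[0]
    centers = np.empty((k, 2))
    i0 = np.random.randint(0, n)
    centers[0, 0] = pts[i0, 0]
    centers[0, 1] = pts[i0, 1]
    d2 = np.empty(n)
    for i in range(n):
        dx = pts[i, 0] - centers[0, 0]
        dy = pts[i, 1] - centers[0, 1]
        d2[i] = dx * dx + dy * dy
    for c in range(1, k):
        tot = d2.sum()
        if tot <= 0.0:
            j = np.random.randint(0, n)
        else:
            r = np.random.random() * tot
            acc = 0.0
            j = n - 1
            for i in range(n):
                acc += d2[i]
                if acc >= r:
                    j = i
                    break
        centers[c, 0] = pts[j, 0]
        centers[c, 1] = pts[j, 1]
        for i in range(n):
            dx = pts[i, 0] - centers[c, 0]
            dy = pts[i, 1] - centers[c, 1]
            nd = dx * dx + dy * dy
            if nd < d2[i]:
                d2[i] = nd
    return centers


@njit(cache=True)
def _lloyd(pts, centers, n_iter):
    n = pts.shape[0]
    k = centers.shape[0]
    labels = np.zeros(n, dtype=np.int64)
    for _ in range(n_iter):
        for i in range(n):
            best = 0
            bestd = 1e300
            for c in range(k):
                dx = pts[i, 0] - centers[c, 0]
                dy = pts[i, 1] - centers[c, 1]
                d = dx * dx + dy * dy
                if d < bestd:
                    bestd = d
                    best = c
            labels[i] = best
        for c in range(k):
            sx = 0.0
            sy = 0.0
            cnt = 0
            for i in range(n):
                if labels[i] == c:
                    sx += pts[i, 0]
                    sy += pts[i, 1]
                    cnt += 1
            if cnt > 0:
                centers[c, 0] = sx / cnt
                centers[c, 1] = sy / cnt
    return labels


@njit(cache=True)
def _em_once(pts, k, max_iter, tol, reg):
    """One EM run from the current numba RNG state.

    Returns (loglik, resp) with resp (n, k) posterior responsibilities;
    loglik is the total data log-likelihood at convergence.
    """
    n = pts.shape[0]
    centers = _kmeanspp_centers(pts, k)
    labels = _lloyd(pts, centers, 5)

    w = np.empty(k)
    mu = np.empty((k, 2))
    cov = np.empty((k, 3))  # c00, c11, c01
    # init moments from hard labels
    for c in range(k):
        cnt = 0
        sx = 0.0
        sy = 0.0
        for i in range(n):
            if labels[i] == c:
                cnt += 1
                sx += pts[i, 0]
                sy += pts[i, 1]
        if cnt == 0:
            j = np.random.randint(0, n)
            mu[c, 0] = pts[j, 0]
            mu[c, 1] = pts[j, 1]
            cnt = 1
        else:
            mu[c, 0] = sx / cnt
            mu[c, 1] = sy / cnt
        w[c] = cnt / n
        sxx = reg
        syy = reg
        sxy = 0.0
        for i in range(n):
            if labels[i] == c:
                dx = pts[i, 0] - mu[c, 0]
                dy = pts[i, 1] - mu[c, 1]
                sxx += dx * dx
                syy += dy * dy
                sxy += dx * dy
        cov[c, 0] = sxx / cnt + reg
        cov[c, 1] = syy / cnt + reg
        cov[c, 2] = sxy / cnt

    resp = np.empty((n, k))
    logdens = np.empty(k)
    inv00 = np.empty(k)
    inv11 = np.empty(k)
    inv01 = np.empty(k)
    lognorm = np.empty(k)
    ll_prev = -1e300
    ll = -1e300
    for _it in range(max_iter):
        # E-step: per-component precision and normalizer computed once
        for c in range(k):
            det = cov[c, 0] * cov[c, 1] - cov[c, 2] * cov[c, 2]
            if det < 1e-300:
                det = 1e-300
            inv00[c] = cov[c, 1] / det
            inv11[c] = cov[c, 0] / det
            inv01[c] = -cov[c, 2] / det
            lognorm[c] = np.log(w[c]) - 0.5 * np.log(det) - _LOG2PI
        ll = 0.0
        for i in range(n):
            mx = -1e300
            for c in range(k):
                dx = pts[i, 0] - mu[c, 0]
                dy = pts[i, 1] - mu[c, 1]
                q = dx * dx * inv00[c] + 2.0 * dx * dy * inv01[c] \
                    + dy * dy * inv11[c]
                ld = lognorm[c] - 0.5 * q
                logdens[c] = ld
                if ld > mx:
                    mx = ld
            s = 0.0
            for c in range(k):
                resp[i, c] = np.exp(logdens[c] - mx)
                s += resp[i, c]
            for c in range(k):
                resp[i, c] /= s
            ll += mx + np.log(s)
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            break
        ll_prev = ll
        # M-step
        for c in range(k):
            nk = 0.0
            sx = 0.0
            sy = 0.0
            for i in range(n):
                nk += resp[i, c]
                sx += resp[i, c] * pts[i, 0]
                sy += resp[i, c] * pts[i, 1]
            if nk < 1e-10:
                j = np.random.randint(0, n)
                mu[c, 0] = pts[j, 0]
                mu[c, 1] = pts[j, 1]
                w[c] = 1.0 / n
                cov[c, 0] = 1.0
                cov[c, 1] = 1.0
                cov[c, 2] = 0.0
                continue
            mu[c, 0] = sx / nk
            mu[c, 1] = sy / nk
            sxx = 0.0
            syy = 0.0
            sxy = 0.0
            for i in range(n):
                dx = pts[i, 0] - mu[c, 0]
                dy = pts[i, 1] - mu[c, 1]
                sxx += resp[i, c] * dx * dx
                syy += resp[i, c] * dy * dy
                sxy += resp[i, c] * dx * dy
            cov[c, 0] = sxx / nk + reg
            cov[c, 1] = syy / nk + reg
            cov[c, 2] = sxy / nk
            w[c] = nk / n
    return ll, resp


@njit(cache=True)
def fit_best_gmm(pts, max_components, restarts, max_iter, tol, reg, seed):
    """BIC-selected GMM labels for one pair's sample scatter.

    The component-count search stops as soon as BIC stops improving
    (greedy ascent; k is unimodal in BIC for these 2-D scatters), which
    keeps the all-pairs scan tractable.  Returns (labels,
    n_components, bic).  Deterministic given seed.
    """
    np.random.seed(seed)
    n = pts.shape[0]
    best_bic = 1e300
    best_k = 1
    best_labels = np.zeros(n, dtype=np.int64)
    logn = np.log(n)
    for k in range(1, max_components + 1):
        if k > n:
            break
        best_ll = -1e300
        best_resp = np.zeros((n, k))
        for _r in range(restarts if k > 1 else 1):
            ll, resp = _em_once(pts, k, max_iter, tol, reg)
            if ll > best_ll:
                best_ll = ll
                best_resp = resp
        nparams = 6 * k - 1  # 2k means + 3k covariances + (k-1) weights
        bic = -2.0 * best_ll + nparams * logn
        if bic < best_bic - 1e-9:
            best_bic = bic
            best_k = k
            lab = np.empty(n, dtype=np.int64)
            for i in range(n):
                am = 0
                mv = best_resp[i, 0]
                for c in range(1, k):
                    if best_resp[i, c] > mv:
                        mv = best_resp[i, c]
                        am = c
                lab[i] = am
            best_labels = lab
        else:
            break  # BIC worsened: stop growing the mixture
    return best_labels, best_k, best_bic
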