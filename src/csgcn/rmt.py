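"""Random-matrix-theory correlation thresholding.

The correlation cutoff tau is placed where the thresholded
correlation matrix's nearest-neighbor eigenvalue spacing distribution
(NNSD) stops looking Poisson (exponential spacings, the signature of a
modular/sparse signal matrix) and starts looking GOE-like (the
signature of noise having entered the matrix).  Scanning tau downward,
each candidate matrix keeps, for every gene pair, the largest |rho|
among its sample clusters at or above tau; eigenvalues are unfolded
with a monotone spline through the empirical spectral CDF, and the
spacings are tested against the unit-mean exponential law with a
chi-square statistic.  tau is the last threshold before the statistic
exceeds ``chi2_crit``.

``chi2_crit`` defaults to 99.607, the 99.9th percentile of chi-square
with 60 degrees of freedom — one per spacing histogram bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .network import EdgeCluster

__all__ = ["NetworkThreshold", "nnsd_chi_square", "unfold_eigenvalues",
           "rmt_threshold"]


@dataclass
class NetworkThreshold:
    tau: float | None
    scan_trace: list[tuple[float, int, float]] = field(default_factory=list)
    method: str = "rmt"
    message: str = ""


def pair_max_rho(edge_clusters: list[EdgeCluster]) -> dict[tuple[str, str], float]:
    """Max |rho| per unordered gene pair over its eligible clusters."""
    best: dict[tuple[str, str], float] = {}
    for e in edge_clusters:
        if e.rho is None:
            continue
        key = (e.gene_a, e.gene_b)
        r = abs(e.rho)
        if r > best.get(key, -1.0):
            best[key] = r
    return best


def unfold_eigenvalues(eigs: np.ndarray, n_knots: int = 20,
                       dedupe_tol: float = 1e-8) -> np.ndarray:
    """Unfolded spacings of a sorted eigenvalue set (mean spacing 1).

    Near-duplicate eigenvalues (within ``dedupe_tol``) are collapsed
    before unfolding; the cumulative spectral function is smoothed with
    a monotone (PCHIP) spline through ``n_knots`` evenly index-spaced
    knots.
    """
    e = np.sort(np.asarray(eigs, dtype=float))
    keep = np.concatenate([[True], np.diff(e) > dedupe_tol])
    e = e[keep]
    m = e.size
    if m < 3:
        return np.array([])
    cdf = (np.arange(m) + 1.0) / m
    k = min(n_knots, m)
    idx = np.unique(np.linspace(0, m - 1, k).round().astype(int))
    spline = PchipInterpolator(e[idx], cdf[idx])
    unfolded = m * np.asarray(spline(e))
    s = np.diff(unfolded)
    s = s[s >= 0]
    mean = s.mean() if s.size else 0.0
    return s / mean if mean > 0 else s


def nnsd_chi_square(spacings: np.ndarray, n_bins: int = 60,
                    s_max: float = 3.0) -> float:
    """Chi-square of a spacing sample against the unit-mean exponential.

    ``n_bins`` equal-width bins on [0, s_max] plus one tail bin; under
    exponential (Poisson-matrix) spacings the statistic is approximately
    chi-square with ~``n_bins`` degrees of freedom.
    """
    s = np.asarray(spacings, dtype=float)
    n = s.size
    if n == 0:
        return float("nan")
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs = np.histogram(s, bins=edges)[0].astype(float)
    obs_tail = float((s >= s_max).sum())
    p = np.exp(-edges[:-1]) - np.exp(-edges[1:])
    p_tail = np.exp(-s_max)
    exp_counts = np.append(n * p, n * p_tail)
    obs_all = np.append(obs, obs_tail)
    return float(np.sum((obs_all - exp_counts) ** 2 / exp_counts))


def rmt_threshold(edge_clusters: list[EdgeCluster], *,
                  scan_start: float = 0.99, scan_stop: float = 0.30,
                  scan_step: float = 0.001, chi2_crit: float = 99.607,
                  persistence: int = 3,
                  min_unique_eigenvalues: int = 100,
                  override_tau: float | None = None) -> NetworkThreshold:
    """Scan tau downward and stop just before the NNSD leaves Poisson.

    ``override_tau`` bypasses the scan entirely and is recorded
    verbatim (used to supply an externally determined cutoff).
    Thresholds whose matrix yields fewer than
    ``min_unique_eigenvalues`` distinct eigenvalues are recorded but
    cannot trigger the transition: with a short spectrum the 60-bin
    statistic's expected bin counts fall below 1 and the test is
    uninformative.  Because the statistic fluctuates while signal
    blocks are still entering the matrix, a single super-critical
    value does not stop the scan: the transition requires
    ``persistence`` consecutive finite chi2 values above ``chi2_crit``,
    and tau is the last threshold whose chi2 was sub-critical before
    that run.
    """
    if override_tau is not None:
        n_edges = sum(1 for r in pair_max_rho(edge_clusters).values()
                      if r > override_tau)
        return NetworkThreshold(tau=float(override_tau),
                                scan_trace=[(float(override_tau), n_edges,
                                             float("nan"))],
                                method="override")
    best = pair_max_rho(edge_clusters)
    if not best:
        return NetworkThreshold(tau=None, method="rmt",
                                message="no eligible clusters")
    pairs = list(best)
    rhos = np.array([best[p] for p in pairs])
    genes = sorted({g for p in pairs for g in p})
    gidx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    full = np.eye(n)
    for (a, b), r in best.items():
        full[gidx[a], gidx[b]] = full[gidx[b], gidx[a]] = r

    trace: list[tuple[float, int, float]] = []
    last_ok: float | None = None
    exceed_run = 0
    thresholds = np.arange(scan_start, scan_stop - 1e-12, -scan_step)
    for tau in thresholds:
        sel = rhos >= tau
        n_edges = int(sel.sum())
        chi2 = float("nan")
        if n_edges > 0:
            mask = full.copy()
            mask[mask < tau] = 0.0
            np.fill_diagonal(mask, 1.0)
            active = np.flatnonzero((mask != 0).sum(axis=1) > 1)
            if active.size >= 3:
                eigs = np.linalg.eigvalsh(mask[np.ix_(active, active)])
                spac = unfold_eigenvalues(eigs)
                if spac.size + 1 >= min_unique_eigenvalues:
                    chi2 = nnsd_chi_square(spac)
        trace.append((float(tau), n_edges, chi2))
        if np.isfinite(chi2):
            if chi2 > chi2_crit:
                exceed_run += 1
                if exceed_run >= persistence:
                    if last_ok is not None:
                        return NetworkThreshold(tau=last_ok, scan_trace=trace)
                    return NetworkThreshold(
                        tau=None, scan_trace=trace,
                        message="NNSD non-Poisson from the first testable "
                                "threshold")
            else:
                exceed_run = 0
                last_ok = float(tau)
    if last_ok is not None:
        return NetworkThreshold(
            tau=last_ok, scan_trace=trace,
            message="no transition found; returning lowest sub-critical tau")
    return NetworkThreshold(tau=None, scan_trace=trace,
                            message="no transition found in scan range")
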