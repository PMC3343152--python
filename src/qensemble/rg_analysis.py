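"""Radius-of-gyration statistics, mixture decomposition, and prolyl isomers.

Rg is computed over the CA atoms of the glutamine residues only
(proline segments excluded so polyQ chains compare on equal footing).
The Rg distribution is histogrammed at a fixed window and decomposed
into a sum of Gaussians by Levenberg-Marquardt least squares on the bin
densities; the chain-compaction scaling exponent nu (Rg ~ N^nu) is
estimated from pairs of chain lengths and by pooled log-log regression.
Prolyl peptide-bond cis/trans states split the ensemble into all-trans
and cis-containing sub-ensembles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .ensemble_io import ConformationEnsemble

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Mixture fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


def radius_of_gyration(points) -> float:
    """Root-mean-square distance of points from their centroid (angstrom)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("radius of gyration needs at least one point")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def rg_per_conformation(ens: ConformationEnsemble, selection=None) -> np.ndarray:
    """Rg of the glutamine CA atoms for every conformation."""
    if ens.coords is None:
        raise ValueError("Rg requires coordinates")
    if selection is None:
        selection = ens.gln_mask()
    selection = np.asarray(selection, dtype=bool)
    if not selection.any():
        raise ValueError("empty atom selection for Rg")
    ca = ens.coords[:, selection, 1, :]  # CA
    centered = ca - ca.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(np.sum(centered**2, axis=2), axis=1))


@dataclass
class RgHistogram:
    """Left-closed bins aligned to zero."""

    centers: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    window: float
    n_total: int
    edges: np.ndarray | None = None

    def __post_init__(self):
        if self.edges is None:
            half = self.window / 2.0
            self.edges = np.append(self.centers - half, self.centers[-1] + half)


def rg_histogram(values, window: float = 0.5) -> RgHistogram:
    """Histogram Rg values with bin edges at integer multiples of window."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no Rg values to histogram")
    if window <= 0:
        raise ValueError("window must be positive")
    lo = np.floor(values.min() / window) * window
    hi = np.floor(values.max() / window) * window + window
    edges = np.arange(lo, hi + window / 2, window)
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    density = counts / (values.size * window)
    return RgHistogram(centers, counts, density, window, int(values.size), edges)


@dataclass
class RgMixtureFit:
    """Gaussian-mixture decomposition of an Rg distribution."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    reduced_chi2: float            # Poisson-weighted
    reduced_chi2_unweighted: float
    histogram: RgHistogram = field(repr=False)
    sigma_floored: bool = False

    def density(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return out


def _mixture_model(params, edges, window, k):
    """Bin-averaged mixture density (CDF differences; no mid-bin bias)."""
    from scipy.stats import norm

    out = np.zeros(edges.size - 1)
    for j in range(k):
        w, m, s = params[3 * j:3 * j + 3]
        cdf = norm.cdf(edges, loc=m, scale=abs(s))
        out += w * np.diff(cdf) / window
    return out


def fit_gaussian_mixture(hist: RgHistogram, k: int = 1,
                         init=None, max_nfev: int = 500 * 3) -> RgMixtureFit:
    """Levenberg-Marquardt fit of k Gaussians to histogram densities.

    Initialization: quantile-spaced means, pooled sd, equal weights
    (overridable via ``init`` as a flat [w, mu, sigma] * k array).
    Weights are renormalized to sum to 1.  The reduced chi-square uses
    per-bin Poisson variance max(count, 1) in density units and
    dof = nonempty bins - (3k - 1); an unweighted variant (uniform
    variance from the mean bin count) is reported alongside.  Components
    whose sd collapses below window/2 trigger a bounded refit with an sd
    floor (flagged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nonempty = hist.counts > 0
    if nonempty.sum() < 3 * k + 1:
        raise ValueError(
            f"need >= {3 * k + 1} nonempty bins for k={k}, have {int(nonempty.sum())}"
        )
    x = hist.centers
    y = hist.density

    if init is None:
        # quantiles of the binned distribution
        cum = np.cumsum(hist.counts) / hist.counts.sum()
        mu0 = np.interp((np.arange(k) + 0.5) / k, cum, x)
        mean_all = np.sum(x * hist.density * hist.window)
        var_all = np.sum((x - mean_all) ** 2 * hist.density * hist.window)
        sd0 = max(np.sqrt(var_all) / max(np.sqrt(k), 1.0), hist.window)
        init = np.ravel([[1.0 / k, m, sd0] for m in mu0])
    init = np.asarray(init, dtype=float)

    sigma_counts = np.sqrt(np.maximum(hist.counts, 1.0))
    sigma_density = sigma_counts / (hist.n_total * hist.window)

    def resid(p):
        return (_mixture_model(p, hist.edges, hist.window, k) - y) / sigma_density

    res = optimize.least_squares(resid, init, method="lm", max_nfev=max_nfev)
    if not res.success:
        raise FitError(f"mixture fit did not converge: {res.message}", res.x)
    params = res.x
    sigma_floored = False
    floor = hist.window / 2.0
    if np.any(np.abs(params[2::3]) < floor):
        logger.warning("sigma collapsed below window/2; refitting with floor")
        sigma_floored = True
        lb = np.ravel([[0.0, x.min() - 10 * hist.window, floor]] * k)
        ub = np.ravel([[np.inf, x.max() + 10 * hist.window, np.inf]] * k)
        start = init.copy()
        start[2::3] = np.maximum(np.abs(start[2::3]), floor * 1.01)
        res = optimize.least_squares(resid, start, bounds=(lb, ub), max_nfev=max_nfev)
        if not res.success:
            raise FitError(f"floored refit did not converge: {res.message}", res.x)
        params = res.x

    weights = np.abs(params[0::3])
    means = params[1::3]
    sds = np.abs(params[2::3])
    order = np.argsort(means)
    weights, means, sds = weights[order], means[order], sds[order]
    weights = weights / weights.sum()

    model = _mixture_model(params, hist.edges, hist.window, k)
    dof = max(int(nonempty.sum()) - (3 * k - 1), 1)
    chi2 = float(np.sum(((y - model) / sigma_density) ** 2)) / dof
    uniform_sigma = np.sqrt(max(hist.counts.mean(), 1.0)) / (hist.n_total * hist.window)
    chi2_unw = float(np.sum(((y - model) / uniform_sigma) ** 2)) / dof
    return RgMixtureFit(k, weights, means, sds, chi2, chi2_unw, hist, sigma_floored)


def scaling_exponent(rg_by_length, pairs=None) -> dict:
    """Chain-compaction exponent nu from Rg(N) ~ N^nu.

    rg_by_length : sequence of (N, mean_Rg) with distinct positive N.
    pairs : optional list of (N_i, N_j) to report pairwise
        nu_ij = ln(Rg_i/Rg_j)/ln(N_i/N_j); defaults to all pairs.
    The pooled exponent is the least-squares slope of ln Rg on ln N,
    reported with its standard error.
    """
    data = {int(n): float(rg) for n, rg in rg_by_length}
    if len(data) < 2:
        raise ValueError("need at least two distinct chain lengths")
    if any(rg <= 0 for rg in data.values()):
        raise ValueError("Rg values must be positive")
    ns = sorted(data)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(ns) for b in ns[i + 1:]]
    pairwise = {}
    for n_i, n_j in pairs:
        if n_i == n_j:
            raise ValueError(f"equal lengths in pair ({n_i}, {n_j})")
        pairwise[(n_i, n_j)] = float(
            np.log(data[n_i] / data[n_j]) / np.log(n_i / n_j)
        )
    log_n = np.log(ns)
    log_rg = np.log([data[n] for n in ns])
    A = np.vstack([log_n, np.ones_like(log_n)]).T
    coef, residuals, *_ = np.linalg.lstsq(A, log_rg, rcond=None)
    slope = float(coef[0])
    if len(ns) > 2 and residuals.size:
        mse = residuals[0] / (len(ns) - 2)
        se = float(np.sqrt(mse / np.sum((log_n - log_n.mean()) ** 2)))
    else:
        se = 0.0
    return {"pairwise": pairwise, "pooled": slope, "pooled_se": se}


@dataclass
class ProlylIsomerState:
    """cis/trans states of the peptide bonds preceding prolines."""

    bond_positions: list[int]      # 0-based residue i of bond i -> i+1 (PRO)
    is_trans: np.ndarray           # bool (n_conformations, n_bonds)
    all_trans: np.ndarray          # bool (n_conformations,)
    trans_percent: np.ndarray      # per bond, percent


def prolyl_isomers(ens: ConformationEnsemble):
    """Classify prolyl bonds and split the ensemble by all-trans status.

    A bond is cis iff |omega| < 90 degrees; the |omega| = 90 boundary is
    assigned to trans.  Returns (state, all_trans_ensemble,
    cis_containing_ensemble); a sub-ensemble may have zero conformations.
    """
    bond_positions = [
        j - 1 for j, name in enumerate(ens.residue_names)
        if name == "PRO" and j >= 1
    ]
    if not bond_positions:
        raise ValueError("no prolines: prolyl isomer analysis is undefined")
    omega = ens.omega[:, bond_positions]
    if np.isnan(omega).any():
        raise ValueError("undefined omega for a prolyl bond")
    is_trans = np.abs(omega) >= 90.0
    all_trans = is_trans.all(axis=1)
    state = ProlylIsomerState(
        bond_positions=bond_positions,
        is_trans=is_trans,
        all_trans=all_trans,
        trans_percent=100.0 * is_trans.mean(axis=0),
    )
    ens_trans = ens.subset(np.flatnonzero(all_trans))
    ens_cis = ens.subset(np.flatnonzero(~all_trans))
    return state, ens_trans, ens_cis
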