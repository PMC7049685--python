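"""Gaussian-mixture fitting of FRET histograms.

Pooled window-mean FRET values are modelled as a 1-3 component Gaussian
mixture; peak means, widths (sigma, with FWHM as a derived convenience) and
fractional populations quantify the closed / open / scrunched populations.
Any subset of the component means can be held fixed — the constraint used to
resolve a new high-FRET population against peaks already assigned at an
earlier stalling position.

The default backend is maximum-likelihood EM on the pooled values with
seeded multi-start; a histogram-curve least-squares backend (sum of Gaussians
fitted to the binned density) is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConvergenceError, InvalidParameterError
from .models import FRETHistogram

__all__ = ["MixtureFit", "fit_gaussian_mixture"]

_VAR_FLOOR = 1e-6  # sigma floor 1e-3 FRET units


@dataclass
class MixtureFit:
    """Sorted-by-mean Gaussian mixture parameters."""

    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    fixed_mask: np.ndarray
    log_likelihood: float = float("nan")
    rss: float = float("nan")
    n_points: int = 0
    backend: str = "em"
    converged: bool = True
    flags: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.means)

    @property
    def fwhm(self) -> np.ndarray:
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.sigmas

    def pdf(self, x):
        x = np.asarray(x, dtype=float)[..., None]
        z = (x - self.means) / self.sigmas
        comp = np.exp(-0.5 * z * z) / (self.sigmas * np.sqrt(2 * np.pi))
        return (comp * self.weights).sum(axis=-1)

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "component": np.arange(self.n_components),
                "mean": self.means,
                "sigma": self.sigmas,
                "fwhm": self.fwhm,
                "weight": self.weights,
                "fixed": self.fixed_mask,
            }
        )


def _sort_fit(means, sigmas, weights, fixed):
    order = np.argsort(means, kind="stable")
    return means[order], sigmas[order], weights[order], fixed[order]


def _em(x, means0, sigmas0, weights0, fixed, tol, max_iter):
    n = x.size
    means = means0.copy()
    var = np.maximum(sigmas0**2, _VAR_FLOOR)
    w = weights0 / weights0.sum()
    ll_old = -np.inf
    xcol = x[:, None]
    converged = False
    for _ in range(max_iter):
        # E-step in a numerically safe form
        logp = (
            -0.5 * (xcol - means) ** 2 / var
            - 0.5 * np.log(2 * np.pi * var)
            + np.log(w)
        )
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        norm = p.sum(axis=1, keepdims=True)
        resp = p / norm
        ll = float(np.sum(m.ravel() + np.log(norm.ravel())))
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        new_means = (resp * xcol).sum(axis=0) / nk
        means = np.where(fixed, means, new_means)
        var = (resp * (xcol - means) ** 2).sum(axis=0) / nk
        var = np.maximum(var, _VAR_FLOOR)
        w = nk / n
        if ll - ll_old < tol * max(1.0, abs(ll)) and ll >= ll_old:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return means, np.sqrt(var), w, ll_old, converged


def _init_params(x, k, fixed_means, rng, jitter):
    sd = max(float(np.std(x)), 1e-3)
    qs = np.quantile(x, (np.arange(k) + 0.5) / k)
    means = qs + (rng.normal(0.0, jitter * sd, size=k) if jitter else 0.0)
    fixed = np.zeros(k, dtype=bool)
    if fixed_means:
        fm = np.sort(np.asarray(fixed_means, dtype=float))
        # fixed means take the components whose initial means lie closest
        free_idx = list(range(k))
        for v in fm:
            j = min(free_idx, key=lambda i: abs(means[i] - v))
            means[j] = v
            fixed[j] = True
            free_idx.remove(j)
    sigmas = np.full(k, sd / k)
    weights = np.full(k, 1.0 / k)
    return means, sigmas, weights, fixed


def _fit_histogram_backend(hist: FRETHistogram, k, fixed_means):
    centers = hist.bin_centers
    dens = hist.density
    fm = np.sort(np.asarray(fixed_means, dtype=float)) if fixed_means else np.empty(0)
    n_fixed = fm.size
    n_free = k - n_fixed
    span = centers.max() - centers.min()
    free0 = np.quantile(
        centers, (np.arange(n_free) + 0.5) / max(n_free, 1)
    ) if n_free else np.empty(0)

    def model(x, *theta):
        free_means = np.asarray(theta[:n_free])
        sigmas = np.asarray(theta[n_free : n_free + k])
        amps = np.asarray(theta[n_free + k :])
        means = np.concatenate([fm, free_means])
        y = np.zeros_like(x)
        for mu, sg, a in zip(means, sigmas, amps):
            y = y + a * np.exp(-0.5 * ((x - mu) / sg) ** 2) / (sg * np.sqrt(2 * np.pi))
        return y

    p0 = list(free0) + [span / (4 * k)] * k + [1.0 / k] * k
    lo = [centers.min()] * n_free + [1e-3] * k + [0.0] * k
    hi = [centers.max()] * n_free + [span] * k + [np.inf] * k
    popt, _ = curve_fit(model, centers, dens, p0=p0, bounds=(lo, hi), maxfev=50000)
    means = np.concatenate([fm, np.asarray(popt[:n_free])])
    sigmas = np.asarray(popt[n_free : n_free + k])
    amps = np.asarray(popt[n_free + k :])
    weights = amps / amps.sum()
    fixed = np.concatenate([np.ones(n_fixed, bool), np.zeros(n_free, bool)])
    rss = float(np.sum((model(centers, *popt) - dens) ** 2))
    means, sigmas, weights, fixed = _sort_fit(means, sigmas, weights, fixed)
    return MixtureFit(
        means=means,
        sigmas=sigmas,
        weights=weights,
        fixed_mask=fixed,
        rss=rss,
        n_points=hist.n_points,
        backend="histogram",
    )


def fit_gaussian_mixture(
    data,
    n_components: int,
    fixed_means: Optional[Sequence[float]] = None,
    seed=None,
    n_restarts: int = 10,
    tol: float = 1e-10,
    max_iter: int = 1000,
    backend: str = "em",
) -> MixtureFit:
    """Fit a 1-3 component Gaussian mixture to pooled FRET values.

    Parameters
    ----------
    data : 1-D array of pooled window-mean FRET values, or a
        :class:`FRETHistogram` (whose pooled values are used for the EM
        backend; the binned density for the histogram backend).
    fixed_means : component means to hold exactly fixed; the remaining
        ``n_components - len(fixed_means)`` means are free.
    backend : ``"em"`` (pooled maximum likelihood, default) or
        ``"histogram"`` (least squares on the binned density).

    Components are reported sorted by mean ascending.
    """
    if not 1 <= n_components <= 3:
        raise InvalidParameterError("n_components must be 1, 2 or 3")
    fixed_means = list(fixed_means) if fixed_means else []
    if len(fixed_means) > n_components:
        raise InvalidParameterError("more fixed means than components")

    hist = data if isinstance(data, FRETHistogram) else None
    if backend == "histogram":
        if hist is None:
            hist_data = np.asarray(data, dtype=float)
            density, edges = np.histogram(hist_data, bins=60, density=True)
            hist = FRETHistogram(
                bin_edges=edges,
                density=density,
                n_traces=1,
                n_points=hist_data.size,
                window=1,
                values=hist_data,
            )
        return _fit_histogram_backend(hist, n_components, fixed_means)
    if backend != "em":
        raise InvalidParameterError(f"unknown backend {backend!r}")

    if hist is not None:
        if hist.values is None:
            raise InvalidParameterError(
                "EM backend needs pooled values; this histogram carries none"
            )
        x = np.asarray(hist.values, dtype=float)
    else:
        x = np.asarray(data, dtype=float).ravel()
    if x.size < 10 * n_components:
        raise InvalidParameterError(
            f"need >= {10 * n_components} points for {n_components} components"
        )
    if fixed_means:
        lo, hi = float(x.min()), float(x.max())
        for v in fixed_means:
            if not lo - 0.5 <= v <= hi + 0.5:
                raise InvalidParameterError(
                    f"fixed mean {v} far outside the data range [{lo:.3g}, {hi:.3g}]"
                )

    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for r in range(max(1, n_restarts)):
        means0, sig0, w0, fixed = _init_params(
            x, n_components, fixed_means, rng, jitter=0.0 if r == 0 else 0.5
        )
        means, sigmas, weights, ll, conv = _em(
            x, means0, sig0, w0, fixed, tol, max_iter
        )
        any_converged = any_converged or conv
        if best is None or ll > best[3]:
            best = (means, sigmas, weights, ll, fixed, conv)
    means, sigmas, weights, ll, fixed, conv = best
    means, sigmas, weights, fixed = _sort_fit(means, sigmas, weights, fixed)
    fit = MixtureFit(
        means=means,
        sigmas=sigmas,
        weights=weights,
        fixed_mask=fixed,
        log_likelihood=ll,
        n_points=x.size,
        backend="em",
        converged=conv,
    )
    if not any_converged:
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations over {n_restarts} restarts",
            best=fit,
        )
    return fit
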