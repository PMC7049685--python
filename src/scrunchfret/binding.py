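"""Ensemble binding and kinetics analysis.

Forward models and nonlinear least-squares fits for the ensemble assays:

* quadratic tight-binding anisotropy isotherm (ligand depletion explicit),
  used when the dissociation constant is comparable to the probe
  concentration, as for the sub-nanomolar polymerase-factor-promoter complex;
* hyperbolic saturation fit for the composite Kd of the initiating NTPs
  read out by -1 2-aminopurine fluorescence;
* Michaelis-Menten fit of 2-mer RNA synthesis rate constants vs NTP
  concentration (kcat, Km, catalytic efficiency kcat/Km);
* 2-aminopurine fold-change over free DNA (promoter melting readout);
* radiometric RNA quantification from gel band intensities,
  RNA (uM) = R/(R+A) * [ATP], and the abortive(3-7mer):runoff ratio;
* single-exponential fitting of upstream bubble-collapse time courses, with
  a no-collapse verdict when the amplitude is indistinguishable from zero.

Fits use scipy.optimize.curve_fit (unweighted by default); uncertainties are
asymptotic standard errors from the fit covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import InvalidParameterError, UnitsError
from .models import TitrationDataset

__all__ = [
    "FitResult",
    "quadratic_binding_model",
    "hyperbola_model",
    "michaelis_menten_model",
    "exponential_decay_model",
    "fit_quadratic_binding",
    "fit_hyperbola",
    "fit_michaelis_menten",
    "fit_exponential_collapse",
    "fold_change",
    "quantify_rna",
    "GelLane",
    "abortive_runoff_ratio",
]


@dataclass
class FitResult:
    """Fitted parameters, asymptotic standard errors and diagnostics."""

    model: str
    params: dict
    stderr: dict
    cov: Optional[np.ndarray] = None
    warnings: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.params[key]

    def summary(self) -> str:
        lines = [f"model: {self.model}"]
        for k, v in self.params.items():
            se = self.stderr.get(k, float("nan"))
            lines.append(f"  {k} = {v:.6g} +/- {se:.3g}")
        for k, v in self.extras.items():
            lines.append(f"  {k} = {v:.6g}" if isinstance(v, float) else f"  {k} = {v}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def quadratic_binding_model(P_t, K_d, D_t, r_f, r_b, D_b=None):
    """Tight-binding (quadratic) anisotropy isotherm.

    r_obs = (Kd + Pt + Dt - sqrt((Kd + Pt + Dt)^2 - 4 Pt Dt)) / (2 Dt)
            * (r_b - r_f) + r_f

    P_t is the total titrant (protein) concentration, D_t the fixed total
    labeled-DNA concentration.  ``D_b`` substitutes a different concentration
    under the square root for comparison purposes; it defaults to D_t.
    """
    P_t = np.asarray(P_t, dtype=float)
    if D_b is None:
        D_b = D_t
    s = K_d + P_t + D_t
    disc = np.clip(s * s - 4.0 * P_t * D_b, 0.0, None)
    frac_bound = (s - np.sqrt(disc)) / (2.0 * D_t)
    return frac_bound * (r_b - r_f) + r_f


def hyperbola_model(x, F0, dF, K_d):
    """Hyperbolic saturation: F = F0 + dF * x / (K_d + x)."""
    x = np.asarray(x, dtype=float)
    return F0 + dF * x / (K_d + x)


def michaelis_menten_model(S, k_cat, K_m):
    """v = k_cat * S / (K_m + S), v in s^-1 when rates are enzyme-normalised."""
    S = np.asarray(S, dtype=float)
    return k_cat * S / (K_m + S)


def exponential_decay_model(t, amplitude, k, baseline):
    """y = baseline + amplitude * exp(-k t)."""
    t = np.asarray(t, dtype=float)
    return baseline + amplitude * np.exp(-k * t)


# ---------------------------------------------------------------------------
# Fitting helpers
# ---------------------------------------------------------------------------

def _check_unit(data: TitrationDataset, expected: Optional[str]):
    if expected is not None and data.x_unit != expected:
        raise UnitsError(
            f"dataset abscissa is in {data.x_unit!r} but the fit expects {expected!r}"
        )


def _curve_fit(fn, x, y, p0, bounds=(-np.inf, np.inf), sigma=None):
    popt, pcov = curve_fit(
        fn, x, y, p0=p0, bounds=bounds, sigma=sigma, maxfev=20000,
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    return popt, perr, pcov


def fit_quadratic_binding(
    data: TitrationDataset, D_t: float, x_unit: Optional[str] = None
) -> FitResult:
    """Fit the quadratic tight-binding isotherm for (K_d, r_f, r_b).

    D_t is the fixed total labeled-DNA concentration in the same units as the
    titration abscissa (pass ``x_unit`` to enforce the match).
    """
    _check_unit(data, x_unit)
    if len(data) < 5:
        raise InvalidParameterError("need >= 5 titration points")
    if D_t <= 0:
        raise InvalidParameterError("D_t must be > 0")
    x, y = data.x, data.y

    def fn(P_t, K_d, r_f, r_b):
        return quadratic_binding_model(P_t, K_d, D_t, r_f, r_b)

    p0 = [max(D_t / 10.0, 1e-6), float(y.min()), float(y.max())]
    popt, perr, pcov = _curve_fit(
        fn, x, y, p0, bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        sigma=data.y_err,
    )
    K_d, r_f, r_b = popt
    warnings = []
    frac_bound_max = float(
        np.max((quadratic_binding_model(x, K_d, D_t, 0.0, 1.0)))
    )
    if frac_bound_max < 0.7:
        warnings.append(
            f"titration never approaches saturation (max bound fraction "
            f"{frac_bound_max:.2f}); K_d is ill-constrained"
        )
    return FitResult(
        model="quadratic_binding",
        params={"K_d": K_d, "r_f": r_f, "r_b": r_b},
        stderr={"K_d": perr[0], "r_f": perr[1], "r_b": perr[2]},
        cov=pcov,
        warnings=warnings,
        extras={"D_t": D_t, "max_fraction_bound": frac_bound_max},
    )


def fit_hyperbola(data: TitrationDataset, x_unit: Optional[str] = None) -> FitResult:
    """Fit F = F0 + dF*x/(K_d + x); reports the half-saturation K_d."""
    _check_unit(data, x_unit)
    if len(data) < 5:
        raise InvalidParameterError("need >= 5 titration points")
    x, y = data.x, data.y
    pos = x[x > 0]
    p0 = [float(y[0]), float(y[-1] - y[0]), float(np.median(pos)) if pos.size else 1.0]
    popt, perr, pcov = _curve_fit(
        hyperbola_model, x, y, p0,
        bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
        sigma=data.y_err,
    )
    F0, dF, K_d = popt
    warnings = []
    if x.max() < K_d:
        warnings.append(
            f"max concentration {x.max():.3g} below fitted K_d {K_d:.3g}; "
            "fit is poorly constrained"
        )
    return FitResult(
        model="hyperbola",
        params={"F0": F0, "dF": dF, "K_d": K_d},
        stderr={"F0": perr[0], "dF": perr[1], "K_d": perr[2]},
        cov=pcov,
        warnings=warnings,
    )


def fit_michaelis_menten(
    data: TitrationDataset,
    limiting_enzyme: float = 1.0,
    rates_normalized: bool = True,
    x_unit: Optional[str] = None,
) -> FitResult:
    """Fit v = kcat*S/(Km+S) and report kcat, Km and kcat/Km.

    Rates are expected as per-enzyme rate constants (s^-1).  Pass
    ``rates_normalized=False`` for raw velocities (uM/s); they are divided by
    the limiting enzyme concentration (uM) first.
    """
    _check_unit(data, x_unit)
    if len(data) < 5:
        raise InvalidParameterError("need >= 5 points")
    x = data.x
    y = data.y if rates_normalized else data.y / limiting_enzyme
    pos = x[x > 0]
    p0 = [float(y.max()) or 1.0, float(np.median(pos)) if pos.size else 1.0]
    popt, perr, pcov = _curve_fit(
        michaelis_menten_model, x, y, p0,
        bounds=([1e-12, 1e-12], [np.inf, np.inf]), sigma=data.y_err,
    )
    k_cat, K_m = popt
    warnings = []
    if x.max() < K_m:
        warnings.append(
            f"max substrate {x.max():.3g} below fitted K_m {K_m:.3g}; "
            "fit is poorly constrained"
        )
    return FitResult(
        model="michaelis_menten",
        params={"k_cat": k_cat, "K_m": K_m},
        stderr={"k_cat": perr[0], "K_m": perr[1]},
        cov=pcov,
        warnings=warnings,
        extras={"efficiency": k_cat / K_m},
    )


def fit_exponential_collapse(data: TitrationDataset) -> FitResult:
    """Single-exponential fit of a bubble-collapse fluorescence time course.

    Returns amplitude, rate and baseline; the ``verdict`` extra is
    ``"no_collapse"`` when the fitted amplitude is indistinguishable from
    zero (|amplitude| < 2 x its standard error), else ``"collapse"``.
    """
    if len(data) < 10:
        raise InvalidParameterError("need >= 10 time points")
    t, y = data.x, data.y
    span = float(y.max() - y.min())
    if span < 1e-12 * max(1.0, abs(float(y.mean()))):
        # flat trace: nothing to fit
        return FitResult(
            model="exponential_decay",
            params={"amplitude": 0.0, "k": 0.0, "baseline": float(y.mean())},
            stderr={"amplitude": 0.0, "k": float("nan"), "baseline": 0.0},
            extras={"verdict": "no_collapse"},
        )
    t_span = float(t.max() - t.min()) or 1.0
    p0 = [float(y[0] - y[-1]), 3.0 / t_span, float(y[-1])]
    popt, perr, pcov = _curve_fit(
        exponential_decay_model, t, y, p0,
        bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
        sigma=data.y_err,
    )
    amplitude, k, baseline = popt
    amp_err = perr[0]
    no_collapse = (not math.isfinite(amp_err)) or abs(amplitude) < 2 * amp_err
    return FitResult(
        model="exponential_decay",
        params={"amplitude": amplitude, "k": k, "baseline": baseline},
        stderr={"amplitude": perr[0], "k": perr[1], "baseline": perr[2]},
        cov=pcov,
        extras={"verdict": "no_collapse" if no_collapse else "collapse"},
    )


# ---------------------------------------------------------------------------
# Direct computations
# ---------------------------------------------------------------------------

def fold_change(
    intensity_complex: float,
    intensity_free_dna: float,
    err_complex: Optional[float] = None,
    err_free: Optional[float] = None,
):
    """Fluorescence fold change of the complex over free DNA.

    Inputs must already be background-subtracted.  Returns the ratio, or
    (ratio, propagated standard error) when both uncertainties are given.
    """
    if intensity_free_dna <= 0:
        raise InvalidParameterError("free-DNA intensity must be > 0")
    fold = intensity_complex / intensity_free_dna
    if err_complex is None or err_free is None:
        return fold
    rel = math.sqrt(
        (err_complex / intensity_complex) ** 2 + (err_free / intensity_free_dna) ** 2
    )
    return fold, abs(fold) * rel


def quantify_rna(R: float, A: float, atp_total: float) -> float:
    """RNA synthesized (uM) = R/(R+A) * [ATP](uM) from gel band intensities."""
    if R < 0 or A < 0:
        raise InvalidParameterError("band intensities must be >= 0")
    if R + A == 0:
        raise InvalidParameterError("R + A must be > 0")
    return R / (R + A) * atp_total


@dataclass
class GelLane:
    """One quantified gel band: label ('runoff', '2mer'..'Nmer', 'free_ATP')."""

    band_label: str
    intensity: float

    def __post_init__(self):
        if self.intensity < 0:
            raise InvalidParameterError("band intensity must be >= 0")


def _mer_length(label: str) -> Optional[int]:
    if label.endswith("mer"):
        try:
            return int(label[:-3])
        except ValueError:
            return None
    return None


def abortive_runoff_ratio(
    lanes, atp_total: float, per_band_denominator: bool = False
) -> dict:
    """Quantify runoff and 3-7mer abortive RNA (uM) and their ratio.

    By default each product band b is converted as
    R_b / (R_total + A) * [ATP] with R_total the sum of all product bands, so
    band amounts are additive and bounded by [ATP]; the single-band formula
    R_b/(R_b + A)*[ATP] is available via ``per_band_denominator=True``.
    Abortive RNA sums the 3- through 7-mer bands (2-mers are excluded by
    definition).  The ratio is flagged undefined when no runoff was detected.
    """
    lanes = list(lanes)
    free = [l for l in lanes if l.band_label == "free_ATP"]
    if not free:
        raise InvalidParameterError("lanes must include a free_ATP band")
    A = sum(l.intensity for l in free)
    products = [l for l in lanes if l.band_label != "free_ATP"]
    if not products:
        raise InvalidParameterError("lanes must include at least one product band")
    r_total = sum(l.intensity for l in products)

    def band_uM(intensity):
        denom_R = intensity if per_band_denominator else r_total
        if denom_R + A == 0:
            raise InvalidParameterError("all band intensities are zero")
        return intensity / (denom_R + A) * atp_total

    runoff = sum(band_uM(l.intensity) for l in products if l.band_label == "runoff")
    has_runoff_band = any(l.band_label == "runoff" for l in products)
    abortive = sum(
        band_uM(l.intensity)
        for l in products
        if (n := _mer_length(l.band_label)) is not None and 3 <= n <= 7
    )
    out = {
        "runoff_uM": runoff if has_runoff_band else float("nan"),
        "abortive_3to7_uM": abortive,
    }
    if has_runoff_band and runoff > 0:
        out["ratio"] = abortive / runoff
        out["ratio_defined"] = True
    else:
        out["ratio"] = float("nan")
        out["ratio_defined"] = False
    return out
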