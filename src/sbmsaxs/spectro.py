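"""Formula-level spectroscopy fits.

Three experiment families share the weighted-nonlinear-least-squares
machinery here:

* **NMR relaxation** — inversion-recovery longitudinal decays fitted to
  I(t) = I0 (1 - 2 exp(-R1 t)) and CPMG transverse decays to
  I(t) = I0 exp(-R2 t), with intensity uncertainties taken from the
  spectrum signal-to-noise ratio (sigma_I = max|I| / SNR).
* **FTIR amide I** — the 1,600–1,700 cm⁻¹ band deconvolved into
  Voigt components (real Faddeeva profile; the area is a fit parameter,
  not a numerical integral), secondary-structure percentages computed
  as area fractions using the standard center assignment:
  ~1682 β-turn, ~1670 α-helix, ~1649 disordered, ~1637/~1622 β-sheet
  (each window ±8 cm⁻¹; the two β-sheet bands are pooled).
* **DLS** — second-order cumulant fit of the intensity autocorrelation
  g2(tau) = B + beta exp(-2 Gamma tau) (1 + (mu2/2) tau^2)^2 with
  Poisson-count weights, polydispersity index mu2/Gamma^2, and the
  hydrodynamic diameter from Gamma = D q^2 and Stokes–Einstein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants
from scipy.optimize import curve_fit
from scipy.special import voigt_profile
from sklearn.base import BaseEstimator


class FitError(RuntimeError):
    pass


# -- shared containers -------------------------------------------------

@dataclass
class DecaySeries:
    """Relaxation intensities vs delay time (s)."""

    t: np.ndarray
    I: np.ndarray
    snr: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.I = np.asarray(self.I, dtype=np.float64)
        if len(self.t) < 4:
            raise ValueError("need >= 4 points to fit a decay")
        if np.any(self.t < 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be >= 0 and strictly increasing")


@dataclass
class RelaxationResult:
    i0: float
    rate: float           # R1 or R2, 1/s
    stderr_rate: float
    stderr_i0: float
    model: str            # "inversion_recovery" | "cpmg_decay"
    cov: np.ndarray


def _model_inversion_recovery(t, i0, rate):
    return i0 * (1.0 - 2.0 * np.exp(-rate * t))


def _model_cpmg(t, i0, rate):
    return i0 * np.exp(-rate * t)


class RelaxationFitter(BaseEstimator):
    """Mono-exponential relaxation fits (R1 inversion recovery or R2 CPMG).

    Initialization is derivative-free and deterministic: the rate from a
    log-linear prefit, I0 from the plateau/first point.  With an SNR the
    per-point sigma is max|I|/SNR and the reported standard errors come
    from the exact covariance (absolute sigma); without one the
    covariance is scaled by the residual variance.

    Fitted attributes: ``i0_``, ``rate_``, ``stderr_rate_``, ``result_``.
    """

    def __init__(self, model: str = "inversion_recovery",
                 snr: float | None = None, maxfev: int = 10000):
        self.model = model
        self.snr = snr
        self.maxfev = maxfev

    def _initial_guess(self, t, I):
        if self.model == "cpmg_decay":
            i0 = float(I[0])
            pos = I > 0
            if np.sum(pos) >= 2:
                slope = np.polyfit(t[pos], np.log(I[pos]), 1)[0]
                rate = max(-slope, 1e-9)
            else:
                rate = 1.0 / max(t[-1], 1e-9)
            return i0, rate
        i0 = float(I[-1]) if I[-1] > 0 else float(np.max(np.abs(I)))
        y = (i0 - I) / (2.0 * i0)
        ok = y > 1e-12
        if np.sum(ok) >= 2:
            slope = np.polyfit(t[ok], np.log(y[ok]), 1)[0]
            rate = max(-slope, 1e-9)
        else:
            rate = 1.0 / max(t[-1], 1e-9)
        return i0, rate

    def fit(self, t, I=None) -> "RelaxationFitter":
        if isinstance(t, DecaySeries):
            d = t
            if d.snr is None:
                d.snr = self.snr
        else:
            d = DecaySeries(t, I, self.snr)
        t_, I_ = d.t, d.I
        fn = {"inversion_recovery": _model_inversion_recovery,
              "cpmg_decay": _model_cpmg}.get(self.model)
        if fn is None:
            raise ValueError(f"unknown relaxation model {self.model!r}")
        p0 = self._initial_guess(t_, I_)
        sigma = None
        absolute = False
        snr = d.snr if d.snr is not None else self.snr
        if snr:
            sigma = np.full_like(I_, np.max(np.abs(I_)) / snr)
            absolute = True
        try:
            popt, pcov = curve_fit(fn, t_, I_, p0=p0, sigma=sigma,
                                   absolute_sigma=absolute,
                                   maxfev=self.maxfev)
        except RuntimeError as exc:
            raise FitError(
                f"relaxation fit did not converge (start I0={p0[0]:.4g}, "
                f"rate={p0[1]:.4g} 1/s): {exc}") from exc
        err = np.sqrt(np.diag(pcov))
        self.i0_, self.rate_ = float(popt[0]), float(popt[1])
        self.stderr_i0_, self.stderr_rate_ = float(err[0]), float(err[1])
        self.result_ = RelaxationResult(
            i0=self.i0_, rate=self.rate_, stderr_rate=self.stderr_rate_,
            stderr_i0=self.stderr_i0_, model=self.model, cov=pcov)
        return self

    def predict(self, t) -> np.ndarray:
        fn = {"inversion_recovery": _model_inversion_recovery,
              "cpmg_decay": _model_cpmg}[self.model]
        return fn(np.asarray(t, dtype=np.float64), self.i0_, self.rate_)


def fit_inversion_recovery(d: DecaySeries) -> RelaxationResult:
    return RelaxationFitter("inversion_recovery", snr=d.snr).fit(d).result_


def fit_cpmg_decay(d: DecaySeries) -> RelaxationResult:
    return RelaxationFitter("cpmg_decay", snr=d.snr).fit(d).result_


# -- FTIR amide I deconvolution ----------------------------------------

AMIDE_I_RANGE = (1600.0, 1700.0)   # cm^-1

#: wavenumber -> secondary-structure assignment windows (center, half-width)
ASSIGNMENT_WINDOWS = (
    (1682.0, 8.0, "beta_turn"),
    (1670.0, 8.0, "alpha_helix"),
    (1649.0, 8.0, "disordered"),
    (1637.0, 8.0, "beta_sheet"),
    (1622.0, 8.0, "beta_sheet"),
)

STRUCTURE_CLASSES = ("beta_turn", "alpha_helix", "disordered", "beta_sheet")


def assign_center(center: float) -> str:
    """Map a band center to its secondary-structure class (nearest
    window; error when no ±8 cm⁻¹ window contains it)."""
    best = None
    for c0, hw, label in ASSIGNMENT_WINDOWS:
        dev = abs(center - c0)
        if dev <= hw and (best is None or dev < best[0]):
            best = (dev, label)
    if best is None:
        raise ValueError(
            f"band center {center:.1f} cm^-1 falls outside every "
            "assignment window (±8 cm^-1)")
    return best[1]


@dataclass
class VoigtComponent:
    center: float            # cm^-1
    gaussian_width: float    # sigma, cm^-1
    lorentzian_width: float  # gamma (HWHM), cm^-1
    area: float              # fit parameter (unit-area profile scaling)
    area_stderr: float
    assignment: str

    @property
    def amplitude(self) -> float:
        """Peak height implied by the parameters."""
        return float(self.area * voigt_profile(
            0.0, self.gaussian_width, self.lorentzian_width))


def _voigt_sum(x, *params):
    y = np.zeros_like(x)
    for k in range(0, len(params), 4):
        c, sg, gl, area = params[k:k + 4]
        y = y + area * voigt_profile(x - c, sg, gl)
    return y


class AmideIDeconvolution(BaseEstimator):
    """Nonlinear least-squares Voigt deconvolution of the amide I band.

    Band centers start at ``init_centers`` and may move at most
    ``center_tolerance`` (default ±8 cm⁻¹, matching the assignment
    windows).  Each component's area is a direct fit parameter, and its
    standard error comes from the parameter covariance matrix.

    Fitted attributes: ``components_``, ``cov_``, ``model_curve_``.
    """

    def __init__(self, init_centers, center_tolerance: float = 8.0,
                 init_gaussian_width: float = 6.0,
                 init_lorentzian_width: float = 4.0,
                 maxfev: int = 40000):
        self.init_centers = init_centers
        self.center_tolerance = center_tolerance
        self.init_gaussian_width = init_gaussian_width
        self.init_lorentzian_width = init_lorentzian_width
        self.maxfev = maxfev

    def fit(self, wavenumber, absorbance) -> "AmideIDeconvolution":
        x = np.asarray(wavenumber, dtype=np.float64)
        y = np.asarray(absorbance, dtype=np.float64)
        sel = (x >= AMIDE_I_RANGE[0]) & (x <= AMIDE_I_RANGE[1])
        if np.sum(sel) < 4 * len(self.init_centers) + 1:
            raise FitError(
                "spectrum has too few points in the amide I range for "
                f"{len(self.init_centers)} components; use fewer components")
        x, y = x[sel], y[sel]
        total = max(float(np.trapezoid(np.clip(y, 0, None), x)), 1e-12)
        p0, lo, hi = [], [], []
        for c in self.init_centers:
            p0 += [float(c), self.init_gaussian_width,
                   self.init_lorentzian_width, total / len(self.init_centers)]
            lo += [c - self.center_tolerance, 0.3, 0.3, 0.0]
            hi += [c + self.center_tolerance, 40.0, 40.0, 10.0 * total]
        try:
            popt, pcov = curve_fit(_voigt_sum, x, y, p0=p0,
                                   bounds=(lo, hi), maxfev=self.maxfev)
        except RuntimeError as exc:
            raise FitError(f"deconvolution did not converge: {exc}") from exc
        if not np.all(np.isfinite(pcov)):
            raise FitError(
                "singular parameter covariance: more components than the "
                "band can resolve; try fewer components")
        err = np.sqrt(np.diag(pcov))
        comps = []
        for k, _ in enumerate(self.init_centers):
            c, sg, gl, area = popt[4 * k:4 * k + 4]
            comps.append(VoigtComponent(
                center=float(c), gaussian_width=float(sg),
                lorentzian_width=float(gl), area=float(area),
                area_stderr=float(err[4 * k + 3]),
                assignment=assign_center(float(c))))
        self.components_ = comps
        self.cov_ = pcov
        self.x_ = x
        self.model_curve_ = _voigt_sum(x, *popt)
        self.residuals_ = y - self.model_curve_
        return self


def deconvolve_amide_I(wavenumber, absorbance, init_centers,
                       center_tolerance: float = 8.0) -> list[VoigtComponent]:
    est = AmideIDeconvolution(init_centers, center_tolerance)
    return est.fit(wavenumber, absorbance).components_


@dataclass
class SecondaryStructureReport:
    fractions: dict[str, float]       # percent per class, sums to 100
    stderr: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.fractions[key]


def structure_fractions(components: list[VoigtComponent]
                        ) -> SecondaryStructureReport:
    """Percent of each secondary-structure class from component areas
    (β-sheet bands pooled); invariant to component order."""
    if not components:
        raise ValueError("no components")
    total = sum(c.area for c in components)
    if total <= 0:
        raise ValueError("total area is not positive")
    sums = {k: 0.0 for k in STRUCTURE_CLASSES}
    errs = {k: 0.0 for k in STRUCTURE_CLASSES}
    for c in components:
        label = c.assignment or assign_center(c.center)
        if label not in sums:
            raise ValueError(f"unknown assignment {label!r}")
        sums[label] += c.area
        errs[label] += c.area_stderr ** 2
    fractions = {k: 100.0 * v / total for k, v in sums.items()}
    stderr = {k: 100.0 * np.sqrt(e) / total for k, e in errs.items()}
    return SecondaryStructureReport(fractions=fractions, stderr=stderr)


def fsd_narrow(wavenumber, absorbance, lorentzian_hwhm: float = 8.0,
               narrowing: float = 2.0) -> np.ndarray:
    """Optional Fourier self-deconvolution preprocessing.

    Divides out a Lorentzian of half-width ``lorentzian_hwhm`` in the
    Fourier domain and re-apodizes with a narrower one (factor
    ``narrowing``), sharpening overlapped bands.  Off by default in the
    deconvolution because suitable parameters are sample-dependent.
    """
    x = np.asarray(wavenumber, dtype=np.float64)
    y = np.asarray(absorbance, dtype=np.float64)
    dx = float(np.mean(np.diff(x)))
    ft = np.fft.rfft(y)
    u = np.fft.rfftfreq(len(y), d=dx)
    boost = np.exp(2.0 * np.pi * lorentzian_hwhm * (1 - 1 / narrowing) * u)
    apod = (1 - u / u.max()) ** 2 if u.max() > 0 else 1.0
    return np.fft.irfft(ft * boost * apod, n=len(y))


# -- DLS cumulants -----------------------------------------------------

@dataclass
class CumulantResult:
    gamma: float          # mean decay rate, 1/s
    mu2: float            # second cumulant, 1/s^2
    pdi: float            # mu2 / gamma^2
    baseline: float
    intercept: float      # beta
    dh: float             # hydrodynamic diameter, Å
    stderr_gamma: float
    stderr_pdi: float
    stderr_dh: float
    cov: np.ndarray


def _g2_model(tau, baseline, beta, gamma, mu2):
    g1 = np.exp(-gamma * tau) * (1.0 + 0.5 * mu2 * tau ** 2)
    return baseline + beta * g1 * g1


def hydrodynamic_diameter(gamma: float, wavelength: float = 6330.0,
                          angle: float = np.pi / 2,
                          refractive_index: float = 1.33,
                          temperature: float = 293.0,
                          viscosity: float = 1.002e-3) -> float:
    """Diameter (Å) from a DLS decay rate via Gamma = D q^2 and
    Stokes–Einstein.

    ``wavelength`` in Å (632.8 nm He-Ne by default), ``angle`` the full
    scattering angle in rad (90° detector), ``temperature`` in K,
    ``viscosity`` in Pa·s.
    """
    for name, val in (("gamma", gamma), ("wavelength", wavelength),
                      ("refractive_index", refractive_index),
                      ("temperature", temperature), ("viscosity", viscosity)):
        if val <= 0:
            raise ValueError(f"{name} must be > 0")
    q = 4.0 * np.pi * refractive_index * np.sin(angle / 2.0) / (
        wavelength * 1e-10)                      # 1/m
    D = gamma / q ** 2                           # m^2/s
    rh = constants.k * temperature / (6.0 * np.pi * viscosity * D)
    return float(2.0 * rh * 1e10)


def decay_rate_for_diameter(dh: float, **kwargs) -> float:
    """Inverse of :func:`hydrodynamic_diameter` (forward model helper)."""
    return hydrodynamic_diameter(dh, **kwargs)  # the relation is involutive


class CumulantAnalysis(BaseEstimator):
    """Second-order cumulant fit of an intensity autocorrelation.

    Weighted nonlinear least squares of
    g2 = B + beta exp(-2 Gamma tau) (1 + mu2/2 tau^2)^2 with per-point
    sigmas from a Poisson photon-count model (supplied by the caller or
    uniform); uncertainties are propagated from the parameter
    covariance into Gamma, the polydispersity index and the
    hydrodynamic diameter.

    Fitted attributes: ``gamma_``, ``pdi_``, ``dh_``, ``result_``.
    """

    def __init__(self, wavelength: float = 6330.0, angle: float = np.pi / 2,
                 refractive_index: float = 1.33, temperature: float = 293.0,
                 viscosity: float = 1.002e-3, maxfev: int = 20000):
        self.wavelength = wavelength
        self.angle = angle
        self.refractive_index = refractive_index
        self.temperature = temperature
        self.viscosity = viscosity
        self.maxfev = maxfev

    def fit(self, tau, g2, sigma=None) -> "CumulantAnalysis":
        tau = np.asarray(tau, dtype=np.float64)
        g2 = np.asarray(g2, dtype=np.float64)
        if np.any(tau <= 0) or np.any(np.diff(tau) <= 0):
            raise ValueError("tau must be positive and strictly increasing")
        head = float(np.mean(g2[:max(2, len(g2) // 20)]))
        tail = float(np.mean(g2[-max(2, len(g2) // 10):]))
        if head <= tail:
            raise FitError("correlation function does not decay")
        beta0 = head - tail
        # log-linear prefit on the early decay for Gamma
        yy = (g2 - tail) / beta0
        ok = (yy > 0.05) & (yy < 0.95)
        if np.sum(ok) >= 2:
            slope = np.polyfit(tau[ok], np.log(yy[ok]), 1)[0]
            gamma0 = max(-slope / 2.0, 1e-6)
        else:
            gamma0 = 1.0 / tau[len(tau) // 2]
        p0 = [tail, beta0, gamma0, 0.01 * gamma0 ** 2]
        lo = [0.0, 0.0, 1e-12, 0.0]
        hi = [np.inf, np.inf, np.inf, np.inf]
        absolute = sigma is not None
        try:
            popt, pcov = curve_fit(_g2_model, tau, g2, p0=p0, sigma=sigma,
                                   absolute_sigma=absolute, bounds=(lo, hi),
                                   maxfev=self.maxfev)
        except RuntimeError as exc:
            raise FitError(f"cumulant fit did not converge: {exc}") from exc
        B, beta, gamma, mu2 = (float(v) for v in popt)
        err = np.sqrt(np.diag(pcov))
        pdi = mu2 / gamma ** 2
        # first-order propagation: pdi = mu2/gamma^2, dh ∝ 1/gamma
        J = np.array([0.0, 0.0, -2.0 * mu2 / gamma ** 3, 1.0 / gamma ** 2])
        stderr_pdi = float(np.sqrt(J @ pcov @ J))
        dh = hydrodynamic_diameter(
            gamma, self.wavelength, self.angle, self.refractive_index,
            self.temperature, self.viscosity)
        stderr_dh = dh * float(err[2]) / gamma
        self.gamma_, self.mu2_, self.pdi_ = gamma, mu2, pdi
        self.baseline_, self.intercept_, self.dh_ = B, beta, dh
        self.result_ = CumulantResult(
            gamma=gamma, mu2=mu2, pdi=pdi, baseline=B, intercept=beta,
            dh=dh, stderr_gamma=float(err[2]), stderr_pdi=stderr_pdi,
            stderr_dh=stderr_dh, cov=pcov)
        return self


def fit_cumulants(tau, g2, sigma=None, **instrument) -> CumulantResult:
    return CumulantAnalysis(**instrument).fit(tau, g2, sigma=sigma).result_
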