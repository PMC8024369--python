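"""Two-state thermal-denaturation analysis of CD melting curves.

Model: a folded/unfolded equilibrium with van't Hoff enthalpy ΔH and heat
capacity change fixed to zero, so ΔG(T) = ΔH·(1 − T/Tm).  The observed
ellipticity is the population-weighted average of two linear baselines:

    θ(T) = (θN + mN·T)·f(T) + (θD + mD·T)·(1 − f(T)),
    f(T) = 1 / (1 + exp(−ΔG/(R·T))).

Six parameters (Tm, ΔH, θN, mN, θD, mD) are fit by nonlinear least squares;
standard errors come from the delete-one jackknife.  ΔTm tables against a
named parent and a synergy classification for double mutants complete the
module.  User-facing temperatures are in °C (converted to Kelvin
internally); ΔH in J/mol.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

R_GAS = 8.314  # J mol^-1 K^-1
KELVIN = 273.15


@dataclasses.dataclass
class MeltCurve:
    temperature: np.ndarray   # °C
    ellipticity: np.ndarray   # raw θ222 or normalised [θ]222
    normalised: bool = False
    label: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, float)
        self.ellipticity = np.asarray(self.ellipticity, float)
        if self.temperature.shape != self.ellipticity.shape:
            raise ValueError("temperature and ellipticity lengths differ")
        if len(self.temperature) < 8:
            raise ValueError("need at least 8 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclasses.dataclass
class MeltFitResult:
    tm: float                 # °C
    dh: float                 # J/mol at Tm
    baselines: tuple[float, float, float, float]  # θN, mN, θD, mD (per K)
    tm_se: float | None = None
    dh_se: float | None = None
    converged: bool = True
    residual_rms: float = np.nan
    label: str = ""
    se_reliable: bool = True


@dataclasses.dataclass
class StabilityRecord:
    label: str
    tm: float
    tm_se: float | None
    delta_tm: float
    reference: str


def fraction_folded(t_kelvin, tm_kelvin: float, dh: float):
    """Folded population of the two-state model (ΔCp = 0).

    ΔG = ΔH·(1 − T/Tm); K = exp(−ΔG/RT); f = 1/(1+K), evaluated in
    log-space so extreme arguments cannot overflow.  f(Tm) = 1/2 exactly.
    """
    t = np.asarray(t_kelvin, float)
    if tm_kelvin <= 0 or np.any(t <= 0):
        raise ValueError("temperatures must be positive (Kelvin)")
    dg = dh * (1.0 - t / tm_kelvin)
    x = -dg / (R_GAS * t)  # ln K
    # 1/(1+e^x) stable both directions; clip the branch that is not used
    # so np.where never evaluates exp on an overflowing argument
    out = np.where(x > 0,
                   np.exp(np.minimum(-x, 0.0)) / (1.0 + np.exp(np.minimum(-x, 0.0))),
                   1.0 / (1.0 + np.exp(np.minimum(x, 0.0))))
    return out if out.ndim else float(out)


def model_ellipticity(t_celsius, params) -> np.ndarray:
    """Two-state ellipticity with linear baselines; params in °C/J-mol units.

    params = (tm °C, dh J/mol, θN, mN, θD, mD); baseline slopes are per
    Kelvin of absolute temperature.
    """
    tm, dh, th_n, m_n, th_d, m_d = params
    t_k = np.asarray(t_celsius, float) + KELVIN
    f = fraction_folded(t_k, tm + KELVIN, dh)
    return (th_n + m_n * t_k) * f + (th_d + m_d * t_k) * (1.0 - f)


def _initial_guess(curve: MeltCurve) -> np.ndarray:
    t = curve.temperature
    y = curve.ellipticity
    dy = np.gradient(y, t)
    tm0 = float(t[np.argmax(np.abs(dy))])
    k = max(2, int(0.15 * len(t)))
    t_k = t + KELVIN
    m_n, th_n = np.polyfit(t_k[:k], y[:k], 1)
    m_d, th_d = np.polyfit(t_k[-k:], y[-k:], 1)
    return np.array([tm0, 250e3, th_n, m_n, th_d, m_d])


def fit_melt(curve: MeltCurve, max_restarts: int = 3) -> MeltFitResult:
    """Fit the 6-parameter two-state model by nonlinear least squares.

    Initialisation: Tm from the steepest finite-difference slope, ΔH at
    250 kJ/mol, baselines from linear fits to the first/last 15% of points.
    If the first solve fails, up to three jittered restarts are attempted.
    A curve with no transition in range is flagged non-converged.
    """
    t, y = curve.temperature, curve.ellipticity
    noise = np.std(np.diff(y)) / np.sqrt(2.0)
    if np.ptp(y) <= 5.0 * noise:
        return MeltFitResult(np.nan, np.nan, (np.nan,) * 4, converged=False,
                             label=curve.label)

    def resid(p):
        return model_ellipticity(t, p) - y

    p0 = _initial_guess(curve)
    lo = [t[0] - 20.0, 1e3, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [t[-1] + 20.0, 5e6, np.inf, np.inf, np.inf, np.inf]
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(1 + max_restarts):
        start = p0 if attempt == 0 else p0 * rng.normal(1.0, 0.05, size=6)
        start = np.clip(start, lo, hi)
        try:
            sol = least_squares(resid, start, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and attempt == 0:
            break
    if best is None:
        return MeltFitResult(np.nan, np.nan, (np.nan,) * 4, converged=False,
                             label=curve.label)
    p = best.x
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    return MeltFitResult(tm=float(p[0]), dh=float(p[1]),
                         baselines=tuple(float(v) for v in p[2:]),
                         converged=bool(best.success), residual_rms=rms,
                         label=curve.label)


def jackknife_errors(curve: MeltCurve, fit: MeltFitResult
                     ) -> tuple[float, float, bool]:
    """Delete-one jackknife SEs for Tm and ΔH.

    Refits are warm-started at the full-data optimum.  Returns
    (tm_se, dh_se, reliable); reliable is False when more than 10% of the
    delete-one refits fail.
    """
    if not fit.converged:
        raise ValueError("jackknife requires a converged fit")
    n = len(curve.temperature)
    if n < 10:
        raise ValueError("jackknife needs at least 10 points")
    p_full = np.array([fit.tm, fit.dh, *fit.baselines])
    lo = [curve.temperature[0] - 20.0, 1e3, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [curve.temperature[-1] + 20.0, 5e6, np.inf, np.inf, np.inf, np.inf]
    estimates = []
    failures = 0
    for i in range(n):
        t_i = np.delete(curve.temperature, i)
        y_i = np.delete(curve.ellipticity, i)

        def resid(p):
            return model_ellipticity(t_i, p) - y_i

        try:
            sol = least_squares(resid, np.clip(p_full, lo, hi),
                                bounds=(lo, hi), xtol=1e-13, ftol=1e-13)
            if not sol.success:
                raise RuntimeError
            estimates.append(sol.x[:2])
        except Exception:
            failures += 1
    reliable = failures <= 0.1 * n
    est = np.array(estimates)
    mean = est.mean(axis=0)
    m = len(est)
    se = np.sqrt((m - 1) / m * np.sum((est - mean) ** 2, axis=0))
    return float(se[0]), float(se[1]), reliable


def fit_melt_with_errors(curve: MeltCurve) -> MeltFitResult:
    fit = fit_melt(curve)
    if fit.converged and len(curve.temperature) >= 10:
        tm_se, dh_se, ok = jackknife_errors(curve, fit)
        fit = dataclasses.replace(fit, tm_se=tm_se, dh_se=dh_se,
                                  se_reliable=ok)
    return fit


def delta_tm(fits: list[MeltFitResult], reference_label: str
             ) -> list[StabilityRecord]:
    """ΔTm of every construct against a named parent (its own ΔTm is 0)."""
    ref = next((f for f in fits if f.label == reference_label), None)
    if ref is None:
        raise KeyError(f"reference {reference_label!r} not among fits")
    return [StabilityRecord(f.label, f.tm, f.tm_se, f.tm - ref.tm,
                            reference_label) for f in fits]


def synergy_classify(single_a: float, single_b: float, double: float,
                     tolerance: float = 0.5) -> str:
    """Classify a double mutant's ΔTm against its constituent singles.

    synergistic: the double exceeds the sum of the singles by more than the
    tolerance; antagonistic: it falls below the better single (or below the
    sum) by more than the tolerance; additive otherwise.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if double > single_a + single_b + tolerance:
        return "synergistic"
    if (double < max(single_a, single_b) - tolerance
            or double < single_a + single_b - tolerance):
        return "antagonistic"
    return "additive"
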