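"""Biophysical data reduction and two-state unfolding / kinetic fits.

Implements the quantitative treatment of protein stability and activity
measurements used to compare wild-type Pol III with PHP-site mutants:

* spectral centre of mass (intensity-weighted mean emission wavelength),
  the folding probe for tryptophan-fluorescence scans;
* mean residue ellipticity normalization for circular dichroism;
* two-state thermal melts: van't Hoff model with linear native/unfolded
  baselines, zero heat-capacity change, fitted for T_m and ΔH_vH;
* chemical (denaturant) unfolding: Santoro–Bolen linear extrapolation
  (ΔG_H2O, m-value) at 298.15 K, with points at or above a configurable
  denaturant concentration (default 3.0 M) excluded before fitting;
* first-order decay for exonuclease label-release kinetics and
  polymerization progress curves;
* plate-read reduction (mean of the last n of several repeated reads)
  and relative-rate summaries.

Temperatures are Celsius at every interface and kelvin internally;
energies are kJ/mol.  Non-convergence is reported through a flag on the
result, never as an exception, so batch pipelines can proceed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ValidationError

#: gas constant, kJ·mol⁻¹·K⁻¹
R_KJ = 8.314e-3
CELSIUS_OFFSET = 273.15


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class Spectrum:
    """An emission scan: wavelengths (nm, strictly increasing) vs intensity."""

    wavelengths: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.wavelengths) != len(self.intensities) or len(self.wavelengths) < 2:
            raise ValidationError("spectrum needs >= 2 matched (wavelength, intensity) points")
        if any(b <= a for a, b in zip(self.wavelengths, self.wavelengths[1:])):
            raise ValidationError("wavelengths must be strictly increasing")
        if any(i < 0 for i in self.intensities):
            raise ValidationError("negative intensity")
        if sum(self.intensities) <= 0:
            raise ValidationError("zero total intensity")


@dataclass(frozen=True)
class Trace:
    """A generic (abscissa, signal) trace; abscissa strictly increasing."""

    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValidationError("trace abscissa/signal length mismatch")
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ValidationError("trace abscissa must be strictly increasing")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.x, dtype=float), np.asarray(self.y, dtype=float)


#: thermal melt: temperature (°C) vs signal
MeltTrace = Trace
#: chemical denaturation: denaturant (M) vs signal
DenatTrace = Trace
#: kinetics: time (s) vs signal
KineticTrace = Trace


@dataclass(frozen=True)
class ThermalMeltFit:
    tm_c: float
    dh_vh_kj: float
    a_n: float
    b_n: float
    a_u: float
    b_u: float
    residual_norm: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class DenatFit:
    dg_h2o_kj: float
    m_value_kj_per_m: float
    a_n: float
    b_n: float
    a_u: float
    b_u: float
    residual_norm: float
    converged: bool
    n_excluded: int
    message: str = ""

    @property
    def cm_molar(self) -> float:
        """Denaturation midpoint C_m = ΔG_H2O / m."""
        return self.dg_h2o_kj / self.m_value_kj_per_m


@dataclass(frozen=True)
class KineticFit:
    k: float
    a0: float
    a_inf: float
    residual_norm: float
    converged: bool
    message: str = ""


# ---------------------------------------------------------------------------
# reductions

def center_of_mass(spectrum: Spectrum) -> float:
    """Intensity-weighted mean wavelength Σ(λ·I)/Σ(I), in nm."""
    lam = np.asarray(spectrum.wavelengths)
    inten = np.asarray(spectrum.intensities)
    return float(np.sum(lam * inten) / np.sum(inten))


def mean_residue_ellipticity(
    theta_mdeg: float, pathlength_cm: float, conc_molar: float, n_residues: int
) -> float:
    """CD normalization θ/(10·l·c·n), in deg·cm²·dmol⁻¹.

    θ may be any sign (zero allowed); pathlength, concentration and
    residue count must be positive.
    """
    if pathlength_cm <= 0 or conc_molar <= 0 or n_residues <= 0:
        raise ValidationError("pathlength, concentration and residue count must be positive")
    return theta_mdeg / (10.0 * pathlength_cm * conc_molar * n_residues)


def reduce_plate_reads(reads: Sequence[float], n_last: int = 5) -> float:
    """Mean of the final ``n_last`` repeated plate reads of one sample."""
    if n_last < 1:
        raise ValidationError("n_last must be >= 1")
    if len(reads) < n_last:
        raise ValidationError(f"need >= {n_last} reads, got {len(reads)}")
    return float(np.mean(np.asarray(reads, dtype=float)[-n_last:]))


def relative_rates(
    fits: Mapping[str, KineticFit], reference_id: str
) -> dict[str, float]:
    """Rate of each construct divided by the reference construct's rate."""
    if reference_id not in fits:
        raise ValidationError(f"reference {reference_id!r} not among fits")
    k_ref = fits[reference_id].k
    if k_ref <= 0:
        raise ValidationError(f"reference rate must be positive, got {k_ref}")
    return {name: fit.k / k_ref for name, fit in fits.items()}


# ---------------------------------------------------------------------------
# two-state models

def two_state_melt_signal(
    t_c: np.ndarray, tm_c: float, dh_kj: float,
    a_n: float, b_n: float, a_u: float, b_u: float,
) -> np.ndarray:
    """Observed signal of a two-state thermal melt with linear baselines.

    K(T) = exp[−ΔH_vH (1 − T/T_m) / (R T)] with T in kelvin and ΔCp = 0,
    so the unfolded fraction is K/(1+K) and equals 1/2 at T_m.
    """
    t_k = np.asarray(t_c, dtype=float) + CELSIUS_OFFSET
    tm_k = tm_c + CELSIUS_OFFSET
    k_eq = np.exp(-dh_kj * (1.0 - t_k / tm_k) / (R_KJ * t_k))
    y_n = a_n + b_n * np.asarray(t_c, dtype=float)
    y_u = a_u + b_u * np.asarray(t_c, dtype=float)
    return (y_n + y_u * k_eq) / (1.0 + k_eq)


def two_state_denat_signal(
    c: np.ndarray, dg_kj: float, m_kj: float,
    a_n: float, b_n: float, a_u: float, b_u: float,
    temperature_k: float = 298.15,
) -> np.ndarray:
    """Santoro–Bolen linear-extrapolation signal vs denaturant concentration."""
    c = np.asarray(c, dtype=float)
    k_eq = np.exp(-(dg_kj - m_kj * c) / (R_KJ * temperature_k))
    return ((a_n + b_n * c) + (a_u + b_u * c) * k_eq) / (1.0 + k_eq)


def first_order_signal(t: np.ndarray, k: float, a0: float, a_inf: float) -> np.ndarray:
    """A(t) = A∞ + (A0 − A∞)·exp(−k t)."""
    return a_inf + (a0 - a_inf) * np.exp(-k * np.asarray(t, dtype=float))


def _baseline_inits(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Linear fits to the first and last 20% of points (min 2 each)."""
    n = len(x)
    m = max(2, n // 5)
    b_n, a_n = np.polyfit(x[:m], y[:m], 1)
    b_u, a_u = np.polyfit(x[-m:], y[-m:], 1)
    return float(a_n), float(b_n), float(a_u), float(b_u)


def _midpoint_init(x: np.ndarray, y: np.ndarray) -> float:
    """Abscissa of maximum |dy/dx| by central finite differences."""
    dy = np.gradient(y, x)
    return float(x[int(np.argmax(np.abs(dy)))])


def _noise_floor(y: np.ndarray) -> float:
    """Robust noise estimate from second differences (exact-zero safe)."""
    if len(y) < 3:
        return 0.0
    d2 = np.diff(y, 2)
    return float(np.median(np.abs(d2)) / math.sqrt(6) * 1.4826)


def fit_thermal_melt(
    trace: MeltTrace, init: Mapping[str, float] | None = None
) -> ThermalMeltFit:
    """Fit T_m, van't Hoff ΔH and four baseline parameters to a melt trace.

    Initialization: T_m from the steepest-slope abscissa, baselines from
    the first/last 20% of points, ΔH_vH 300 kJ/mol unless overridden via
    ``init`` (keys tm_c, dh_kj, a_n, b_n, a_u, b_u).
    """
    x, y = trace.arrays()
    if len(x) < 8:
        raise ValidationError("thermal melt fit needs >= 8 points")
    span = float(np.ptp(y))
    if span <= 10 * _noise_floor(y) or span == 0.0:
        return ThermalMeltFit(
            tm_c=math.nan, dh_vh_kj=math.nan, a_n=math.nan, b_n=math.nan,
            a_u=math.nan, b_u=math.nan, residual_norm=math.nan,
            converged=False, message="no resolvable transition (flat trace)",
        )
    a_n, b_n, a_u, b_u = _baseline_inits(x, y)
    p0 = {
        "tm_c": _midpoint_init(x, y), "dh_kj": 300.0,
        "a_n": a_n, "b_n": b_n, "a_u": a_u, "b_u": b_u,
    }
    if init:
        p0.update(init)

    def residuals(p: np.ndarray) -> np.ndarray:
        return two_state_melt_signal(x, *p) - y

    start = np.array([p0["tm_c"], p0["dh_kj"], p0["a_n"], p0["b_n"], p0["a_u"], p0["b_u"]])
    sol = least_squares(
        residuals, start, xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20000,
        bounds=([x[0] - 20, 1.0, -np.inf, -np.inf, -np.inf, -np.inf],
                [x[-1] + 20, 5000.0, np.inf, np.inf, np.inf, np.inf]),
    )
    tm, dh, a_n, b_n, a_u, b_u = sol.x
    in_span = x[0] - 5 <= tm <= x[-1] + 5
    return ThermalMeltFit(
        tm_c=float(tm), dh_vh_kj=float(dh), a_n=float(a_n), b_n=float(b_n),
        a_u=float(a_u), b_u=float(b_u),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success and in_span),
        message=sol.message if not sol.success else "",
    )


def fit_chemical_denaturation(
    trace: DenatTrace,
    exclude_at_or_above: float = 3.0,
    temperature_c: float = 25.0,
    init: Mapping[str, float] | None = None,
) -> DenatFit:
    """Fit ΔG_H2O and m by linear extrapolation, excluding high-denaturant points.

    Points with denaturant concentration >= ``exclude_at_or_above`` molar
    are removed before fitting (their count is reported on the result),
    mirroring the practice of discarding the highest-concentration samples
    whose baseline behaviour is unreliable.
    """
    x, y = trace.arrays()
    keep = x < exclude_at_or_above
    n_excluded = int((~keep).sum())
    x, y = x[keep], y[keep]
    if len(x) < 8:
        raise ValidationError(
            f"only {len(x)} points remain after excluding denaturant >= "
            f"{exclude_at_or_above} M; need >= 8"
        )
    t_k = temperature_c + CELSIUS_OFFSET
    span = float(np.ptp(y))
    if span <= 10 * _noise_floor(y) or span == 0.0:
        return DenatFit(
            dg_h2o_kj=math.nan, m_value_kj_per_m=math.nan, a_n=math.nan,
            b_n=math.nan, a_u=math.nan, b_u=math.nan, residual_norm=math.nan,
            converged=False, n_excluded=n_excluded,
            message="no resolvable transition (flat trace)",
        )
    a_n, b_n, a_u, b_u = _baseline_inits(x, y)
    cm0 = _midpoint_init(x, y)
    # transition width -> m; ~90% of a two-state transition spans 4.4 RT/m
    width = max(0.2, float(x[-1] - x[0]) / 4)
    m0 = 4.4 * R_KJ * t_k / width
    p0 = {"dg_kj": m0 * cm0, "m_kj": m0, "a_n": a_n, "b_n": b_n, "a_u": a_u, "b_u": b_u}
    if init:
        p0.update(init)

    def residuals(p: np.ndarray) -> np.ndarray:
        return two_state_denat_signal(x, *p, temperature_k=t_k) - y

    start = np.array([p0["dg_kj"], p0["m_kj"], p0["a_n"], p0["b_n"], p0["a_u"], p0["b_u"]])
    sol = least_squares(
        residuals, start, xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20000,
        bounds=([0.0, 1e-6, -np.inf, -np.inf, -np.inf, -np.inf], np.inf),
    )
    dg, m, a_n, b_n, a_u, b_u = sol.x
    return DenatFit(
        dg_h2o_kj=float(dg), m_value_kj_per_m=float(m), a_n=float(a_n),
        b_n=float(b_n), a_u=float(a_u), b_u=float(b_u),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success and m > 0),
        n_excluded=n_excluded,
        message=sol.message if not sol.success else "",
    )


def fit_first_order_decay(trace: KineticTrace) -> KineticFit:
    """Fit a single-exponential approach A(t) = A∞ + (A0−A∞)e^{−kt}."""
    t, y = trace.arrays()
    if len(t) < 8:
        raise ValidationError("kinetic fit needs >= 8 points")
    if float(np.ptp(y)) == 0.0:
        # constant signal: zero rate, exact fit
        return KineticFit(k=0.0, a0=float(y[0]), a_inf=float(y[0]),
                          residual_norm=0.0, converged=True)
    a0, a_inf = float(y[0]), float(y[-1])
    t_span = float(t[-1] - t[0]) or 1.0
    k0 = 3.0 / t_span
    # refine k0 from the half-change time when resolvable
    half = a_inf + (a0 - a_inf) / 2
    crossing = np.nonzero((y - half) * (y[0] - half) <= 0)[0]
    if crossing.size and t[crossing[0]] > t[0]:
        k0 = math.log(2) / float(t[crossing[0]] - t[0])

    def residuals(p: np.ndarray) -> np.ndarray:
        return first_order_signal(t, *p) - y

    sol = least_squares(
        residuals, np.array([k0, a0, a_inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20000,
        bounds=([0.0, -np.inf, -np.inf], np.inf),
    )
    k, a0, a_inf = sol.x
    return KineticFit(
        k=float(k), a0=float(a0), a_inf=float(a_inf),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        message=sol.message if not sol.success else "",
    )


# ---------------------------------------------------------------------------
# trace I/O

def read_trace_csv(path) -> Trace:
    """Two-column CSV (header required): abscissa, signal."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (abscissa, signal)")
    return Trace(x=tuple(df.iloc[:, 0].astype(float)), y=tuple(df.iloc[:, 1].astype(float)))


def write_trace_csv(trace: Trace, path, names: tuple[str, str] = ("x", "y")) -> None:
    with open(path, "w") as fh:
        fh.write(f"{names[0]},{names[1]}\n")
        for a, b in zip(trace.x, trace.y):
            fh.write(f"{a:.10g},{b:.10g}\n")
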