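"""Bench-assay calculations for the AcuB/AcuC system.

Covers the arithmetic and curve fits behind the wet-lab readouts:

* nucleotide loading of purified AcuB from denatured-sample absorbances
  (A280 before/after denaturation for protein, A260 after for nucleotide);
* HPLC chromatogram peak-area ratios between co-purified nucleotides;
* dose-response IC50 fits of deacetylase inhibition (four-parameter
  logistic with the Hill slope fixed at -1, linear-regression fallback);
* nanoDSF melting temperatures as extrema of d(Em350/Em330)/dT, and a
  non-additivity test for interaction in protein mixtures;
* SEC calibration (log-linear Kav vs molecular weight) and integer
  stoichiometry inference for eluting complexes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

logger = logging.getLogger(__name__)

__all__ = [
    "EXTINCTION_COEFFS",
    "DEFAULT_NUCLEOTIDE_EPS260",
    "AbsorbanceRecord",
    "LoadingResult",
    "nucleotide_loading",
    "chromatogram_peak_ratio",
    "DoseResponseFit",
    "normalize_fluorescence",
    "dose_response_model",
    "fit_dose_response",
    "TmResult",
    "melting_temperature",
    "InteractionResult",
    "nonadditivity_interaction",
    "SECCalibration",
    "fit_sec_calibration",
    "sec_mw_and_stoichiometry",
]

#: protein molar extinction coefficients at 280 nm (M^-1 cm^-1)
EXTINCTION_COEFFS: dict[str, float] = {
    "BsAcuB": 8730.0,   # an alternative printed value is 8480
    "GsAcuB": 9970.0,
    "GsAcuB_H87W": 15470.0,
    "GsAcuB_M189R": 9970.0,
    "BsAcuC": 78520.0,
    "GsAcuC": 80800.0,
}

#: adenine-nucleotide extinction at 260 nm, M^-1 cm^-1.  The assay used an
#: experimentally determined value that is not published; this literature
#: default (AMP/ADP/ATP at neutral pH) must be confirmed or overridden for
#: quantitative loading numbers.
DEFAULT_NUCLEOTIDE_EPS260: float = 15400.0

#: monomer molecular weights (Da) used for stoichiometry inference
MONOMER_MASSES: dict[str, float] = {
    "BsAcuB": 25405.0,
    "GsAcuB": 24861.0,
    "BsAcuC": 44272.0,
    "GsAcuC": 43430.0,
}


@dataclass(frozen=True)
class AbsorbanceRecord:
    """Absorbance triple from the denaturation loading protocol."""

    a280_before: float
    a280_after: float
    a260_after: float
    eps_protein: float
    eps_nucleotide: float = DEFAULT_NUCLEOTIDE_EPS260

    def __post_init__(self) -> None:
        if self.eps_protein <= 0 or self.eps_nucleotide <= 0:
            raise ValueError("extinction coefficients must be positive")
        if min(self.a280_before, self.a280_after, self.a260_after) < 0:
            raise ValueError("absorbances must be non-negative")


@dataclass(frozen=True)
class LoadingResult:
    protein_conc_M: float
    nucleotide_conc_M: float
    loading_percent: float


def nucleotide_loading(record: AbsorbanceRecord) -> LoadingResult:
    """Nucleotide loading of a protein preparation from absorbances.

    c(protein) = (A280_before - A280_after) / eps_protein and
    c(nucleotide) = A260_after / eps_nucleotide; loading is
    100 * c(nucleotide) / c(protein).  A negative protein concentration
    is clipped to 0 with a warning; zero protein concentration makes the
    loading undefined (error).
    """
    c_prot = (record.a280_before - record.a280_after) / record.eps_protein
    if c_prot < 0:
        logger.warning("negative protein concentration %.3g clipped to 0", c_prot)
        c_prot = 0.0
    c_nuc = record.a260_after / record.eps_nucleotide
    if c_prot == 0:
        raise ZeroDivisionError("protein concentration is 0: loading undefined")
    return LoadingResult(c_prot, c_nuc, 100.0 * c_nuc / c_prot)


def chromatogram_peak_ratio(
    volume: np.ndarray,
    absorbance: np.ndarray,
    windows: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Relative peak areas of species in an A260 chromatogram.

    Each species' peak is integrated by the trapezoid rule over its
    elution-volume window after subtracting a straight-line local
    baseline drawn between the window endpoints.  Percentages are
    normalised to 100 across species; negative net areas are clipped
    to 0 before normalisation.
    """
    v = np.asarray(volume, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if v.shape != a.shape or v.ndim != 1:
        raise ValueError("volume and absorbance must be equal-length 1D arrays")
    spans = sorted(windows.values())
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        if hi1 > lo2:
            raise ValueError("peak windows overlap")
    areas = {}
    for name, (lo, hi) in windows.items():
        mask = (v >= lo) & (v <= hi)
        if mask.sum() < 2:
            raise ValueError(f"window {name!r} [{lo}, {hi}] contains <2 trace points")
        vv, aa = v[mask], a[mask]
        baseline = np.interp(vv, [vv[0], vv[-1]], [aa[0], aa[-1]])
        areas[name] = max(float(np.trapezoid(aa - baseline, vv)), 0.0)
    total = sum(areas.values())
    rows = [
        {
            "species": k,
            "area": areas[k],
            "area_percent": 100.0 * areas[k] / total if total > 0 else 0.0,
        }
        for k in windows
    ]
    return pd.DataFrame(rows)


def normalize_fluorescence(
    fluorescence: np.ndarray, mode: str = "minmax"
) -> np.ndarray:
    """Normalise raw fluorescence for dose-response fitting.

    ``mode="minmax"`` is plain min-max scaling to [0, 1] (default for
    fitting).  ``mode="literal"`` keeps the additive minimum outside the
    ratio - min + (F - min)/(max - min) - as used by the instrument
    protocol; the offset is absorbed by the fitted ``minimum`` parameter
    either way.
    """
    f = np.asarray(fluorescence, dtype=float)
    lo, hi = float(f.min()), float(f.max())
    if hi == lo:
        return np.zeros_like(f) if mode == "minmax" else np.full_like(f, lo)
    scaled = (f - lo) / (hi - lo)
    if mode == "minmax":
        return scaled
    if mode == "literal":
        return lo + scaled
    raise ValueError(f"unknown normalization mode {mode!r}")


def dose_response_model(
    conc_M: np.ndarray,
    log_ic50: float,
    minimum: float,
    maximum: float,
    hill_slope: float = -1.0,
) -> np.ndarray:
    """Four-parameter logistic response at molar concentrations.

    response = minimum + (maximum - minimum) /
               (1 + 10**((log_ic50 - log10(conc)) * hill_slope))
    """
    x = np.log10(np.asarray(conc_M, dtype=float))
    return minimum + (maximum - minimum) / (1.0 + 10.0 ** ((log_ic50 - x) * hill_slope))


@dataclass
class DoseResponseFit:
    ic50_M: float | None
    minimum: float
    maximum: float
    hill_slope: float
    fit_ok: bool
    fallback_slope: float | None = None
    residual_rms: float | None = None


def fit_dose_response(
    conc_M: np.ndarray,
    fluorescence: np.ndarray,
    normalization: str = "minmax",
    hill_slope: float = -1.0,
) -> DoseResponseFit:
    """Fit an inhibition dose-response curve with fixed Hill slope.

    Nonlinear least squares over (log10 IC50, minimum, maximum); the Hill
    slope stays fixed (default -1, simple competitive inhibition).  The
    fit uses relative (proportional-to-signal) error weighting, the usual
    error model for fluorescence intensities.  When the sigmoid fit fails
    to converge or the fitted IC50 falls more than two decades outside
    the measured concentration range, a linear regression of response vs
    log10(concentration) is reported instead (``fit_ok=False``) to
    indicate the trend only.
    """
    c = np.asarray(conc_M, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    y = normalize_fluorescence(f, normalization)
    x = np.log10(c)

    def _fallback() -> DoseResponseFit:
        lr = stats.linregress(x, y)
        return DoseResponseFit(
            ic50_M=None,
            minimum=float(y.min()),
            maximum=float(y.max()),
            hill_slope=hill_slope,
            fit_ok=False,
            fallback_slope=float(lr.slope),
        )

    p0 = (float(np.median(x)), float(y.min()), float(y.max()))
    # weights proportional to the raw signal (multiplicative-noise model)
    sigma = np.clip(np.abs(f), np.abs(f).max() * 1e-3, None)
    try:
        popt, _ = optimize.curve_fit(
            lambda cc, l, mn, mx: dose_response_model(cc, l, mn, mx, hill_slope),
            c,
            y,
            p0=p0,
            sigma=sigma,
            maxfev=10000,
        )
    except RuntimeError:
        return _fallback()
    log_ic50, mn, mx = popt
    if not (x.min() - 2.0 <= log_ic50 <= x.max() + 2.0) or mx <= mn:
        return _fallback()
    resid = y - dose_response_model(c, *popt, hill_slope)
    # suitability: the fitted transition must stand clear of the misfit
    # (a flat/noisy series can otherwise "converge" to a spurious sigmoid)
    if (mx - mn) <= 4.0 * float(np.sqrt(np.mean(resid**2))):
        return _fallback()
    return DoseResponseFit(
        ic50_M=float(10.0 ** log_ic50),
        minimum=float(mn),
        maximum=float(mx),
        hill_slope=hill_slope,
        fit_ok=True,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass
class TmResult:
    """One melting transition: Tm (deg C) at a derivative extremum."""

    tm_C: float
    magnitude: float
    extremum: str  # "max" or "min"


def melting_temperature(
    temperature_C: np.ndarray,
    ratio: np.ndarray,
    smoothing_window: int = 9,
    polyorder: int = 3,
    prominence_frac: float = 0.2,
) -> list[TmResult]:
    """Melting temperatures from a nanoDSF fluorescence-ratio curve.

    The first derivative of the Em350/Em330 ratio with respect to
    temperature is computed with a Savitzky-Golay filter (default 9-point
    window, order 3); Tm values are the local extrema of that derivative
    (maxima and minima), parabolically interpolated between grid points.
    Only extrema with prominence above ``prominence_frac`` of the largest
    absolute derivative are reported, largest magnitude first; a curve
    with no transition (e.g. a linear baseline) yields an empty list.
    """
    t = np.asarray(temperature_C, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("temperature and ratio must be equal-length 1D arrays")
    if len(t) < 11:
        raise ValueError("need at least 11 temperature points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature must be strictly increasing")
    # resample to a uniform grid so the filter's derivative scale is exact
    dt = float(np.median(np.diff(t)))
    tu = np.arange(t[0], t[-1] + dt / 2, dt)
    ru = np.interp(tu, t, r)
    win = min(smoothing_window | 1, len(tu) - (1 - len(tu) % 2))
    deriv = signal.savgol_filter(ru, win, polyorder, deriv=1, delta=dt)
    scale = float(np.max(np.abs(deriv)))
    if scale <= 0:
        return []
    results: list[TmResult] = []
    for sign, kind in ((1.0, "max"), (-1.0, "min")):
        peaks, props = signal.find_peaks(sign * deriv, prominence=prominence_frac * scale)
        for p in peaks:
            # parabolic refinement around the grid extremum
            if 0 < p < len(deriv) - 1:
                y0, y1, y2 = deriv[p - 1 : p + 2]
                denom = y0 - 2 * y1 + y2
                shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
                shift = float(np.clip(shift, -1, 1))
            else:
                shift = 0.0
            results.append(
                TmResult(
                    tm_C=float(tu[p] + shift * dt),
                    magnitude=float(abs(deriv[p])),
                    extremum=kind,
                )
            )
    results.sort(key=lambda x: -x.magnitude)
    return results


@dataclass
class InteractionResult:
    """Non-additivity of a mixture's melt-derivative signal.

    For non-interacting components the fluorescence and its temperature
    derivative are additive; a large residual after the best linear
    combination a*dA/dT + b*dB/dT therefore indicates complex formation.
    """

    a: float
    b: float
    residual_rms: float
    threshold: float
    interaction: bool
    identifiable: bool


def _derivative(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.gradient(np.asarray(y, dtype=float), np.asarray(t, dtype=float))


def nonadditivity_interaction(
    temperature_C: np.ndarray,
    mix: np.ndarray,
    component_a: np.ndarray,
    component_b: np.ndarray,
    noise_window_C: float = 10.0,
    threshold_factor: float = 3.0,
) -> InteractionResult:
    """Test whether a mixture melt curve is a linear combination of its parts.

    Least-squares coefficients (a, b) minimise
    || d(mix)/dT - a d(A)/dT - b d(B)/dT ||; the reported residual is the
    RMS misfit.  The interaction verdict compares the residual against
    ``threshold_factor`` times the RMS of high-frequency noise estimated
    from the first ``noise_window_C`` degrees of the mixture derivative
    (misfit above instrument noise = interaction).  If the component
    derivatives are collinear, only a + b is identifiable and the result
    is flagged accordingly.
    """
    t = np.asarray(temperature_C, dtype=float)
    dm = _derivative(t, mix)
    da = _derivative(t, component_a)
    db = _derivative(t, component_b)
    design = np.column_stack([da, db])
    sol, _, rank, _ = np.linalg.lstsq(design, dm, rcond=None)
    identifiable = rank == 2
    resid = dm - design @ sol
    residual_rms = float(np.sqrt(np.mean(resid**2)))
    head = t <= t[0] + noise_window_C
    seg = dm[head]
    if len(seg) >= 7:
        smooth = signal.savgol_filter(seg, min(7, len(seg) - (1 - len(seg) % 2)), 2)
        noise_rms = float(np.sqrt(np.mean((seg - smooth) ** 2)))
    else:
        noise_rms = 0.0
    threshold = threshold_factor * noise_rms
    return InteractionResult(
        a=float(sol[0]),
        b=float(sol[1]),
        residual_rms=residual_rms,
        threshold=threshold,
        interaction=bool(residual_rms > max(threshold, 1e-9)),
        identifiable=bool(identifiable),
    )


@dataclass
class SECCalibration:
    """Log-linear SEC calibration: log10(MW) = slope * Kav + intercept."""

    v0_mL: float
    vc_mL: float
    slope: float
    intercept: float
    r_squared: float
    standards: pd.DataFrame | None = None

    def kav(self, ve_mL: float) -> float:
        """Partition coefficient Kav = (Ve - V0) / (Vc - V0)."""
        if not (self.v0_mL <= ve_mL <= self.vc_mL):
            raise ValueError(
                f"elution volume {ve_mL} outside [V0={self.v0_mL}, Vc={self.vc_mL}]"
            )
        return (ve_mL - self.v0_mL) / (self.vc_mL - self.v0_mL)

    def molecular_weight(self, ve_mL: float) -> float:
        return float(10.0 ** (self.slope * self.kav(ve_mL) + self.intercept))


def fit_sec_calibration(
    mw_Da: np.ndarray,
    ve_mL: np.ndarray,
    v0_mL: float,
    vc_mL: float,
) -> SECCalibration:
    """Fit log10(MW) against Kav for a set of SEC standards."""
    mw = np.asarray(mw_Da, dtype=float)
    ve = np.asarray(ve_mL, dtype=float)
    if len(mw) < 3:
        raise ValueError("need at least 3 standards")
    if np.any(ve < v0_mL) or np.any(ve > vc_mL) or v0_mL >= vc_mL:
        raise ValueError("standards must satisfy V0 <= Ve <= Vc with V0 < Vc")
    kav = (ve - v0_mL) / (vc_mL - v0_mL)
    res = stats.linregress(kav, np.log10(mw))
    table = pd.DataFrame({"mw_Da": mw, "ve_mL": ve, "kav": kav})
    return SECCalibration(
        v0_mL=float(v0_mL),
        vc_mL=float(vc_mL),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        standards=table,
    )


def sec_mw_and_stoichiometry(
    calibration: SECCalibration,
    ve_mL: float,
    monomer_masses: dict[str, float],
    max_copies: int = 4,
) -> tuple[float, dict[str, int]]:
    """Molecular weight at an elution volume and the best integer composition.

    The apparent MW follows from the calibration line; the composition
    search enumerates all copy numbers 0..max_copies per species (at
    least one subunit total) and minimises |sum(n_i M_i) - MW|, breaking
    ties toward fewer total subunits (then lexicographically for full
    determinism).
    """
    mw = calibration.molecular_weight(ve_mL)
    names = sorted(monomer_masses)
    best: tuple[float, int, tuple[int, ...]] | None = None
    for combo in itertools.product(range(max_copies + 1), repeat=len(names)):
        if sum(combo) == 0:
            continue
        mass = sum(n * monomer_masses[k] for n, k in zip(combo, names))
        key = (abs(mass - mw), sum(combo), combo)
        if best is None or key < best:
            best = key
    assert best is not None
    return float(mw), dict(zip(names, best[2]))
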