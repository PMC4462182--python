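"""qPCR quantification mathematics.

Standard curves regress the threshold cycle Ct on log10 template copies
(slope ~ -3.32 at 100% amplification efficiency); efficiency is
``100 * (10^(-1/slope) - 1)``.  Copy numbers of plasmid standards come
from the DNA mass of the construct at 660 Da per base pair.  Melt-curve
peaks are called on the smoothed negative derivative of fluorescence
with respect to temperature; a single peak supports assay specificity.

The spike-in calibration models the matrix-dependent bias of measuring
a known added organism in an environmental matrix: a weighted linear
fit of measured vs. true log10 abundance (replicate SDs as weights)
gives coefficients (a, b) of ``LogC_m = a * LogC_real - b``, inverted
algebraically as the correction ``LogC_real = (LogC_m + b) / a``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal, stats

AVOGADRO = 6.02214076e23
DA_PER_BP = 660.0
DEFAULT_VECTOR_BP = 3973
EFFICIENCY_QC = (90.0, 110.0)
R2_QC = 0.99


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency (%) from a standard-curve slope:
    ``100 * (10^(-1/slope) - 1)``.  Requires a negative slope."""
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 100.0 * (10.0 ** (-1.0 / slope) - 1.0)


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r2: float
    efficiency: float
    se_slope: float
    se_intercept: float
    n_points: int
    log_range: tuple[float, float]
    qc_pass: bool

    def ct_for(self, copies: float) -> float:
        return self.intercept + self.slope * math.log10(copies)


def fit_standard_curve(
    points: Iterable[tuple[float, float]] | pd.DataFrame,
) -> StandardCurve:
    """Ordinary least squares of Ct on log10(copies per reaction).

    *points* is an iterable of ``(copies, ct)`` or a DataFrame with
    columns ``copies_per_ul`` and ``ct``.  At least three distinct
    concentrations are required.  QC passes iff the efficiency lies in
    the 90-110% window and r^2 > 0.99.
    """
    if isinstance(points, pd.DataFrame):
        copies = points["copies_per_ul"].to_numpy(dtype=float)
        cts = points["ct"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.size == 0:
            raise ValueError("no standard points")
        copies, cts = arr[:, 0], arr[:, 1]
    if (copies <= 0).any():
        raise ValueError("standard copy numbers must be positive")
    x = np.log10(copies)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct standard concentrations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate standards: all concentrations identical")
    res = stats.linregress(x, cts)
    r2 = float(res.rvalue**2)
    eff = efficiency_from_slope(res.slope)
    qc = EFFICIENCY_QC[0] <= eff <= EFFICIENCY_QC[1] and r2 > R2_QC
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        efficiency=eff,
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        n_points=len(x),
        log_range=(float(x.min()), float(x.max())),
        qc_pass=bool(qc),
    )


def copies_from_mass(
    conc_ng_per_ul: float, construct_length_bp: float
) -> float:
    """Copies per microlitre of a double-stranded construct from its
    concentration, assuming 660 Da per base pair."""
    if construct_length_bp <= 0:
        raise ValueError("construct length must be positive")
    if conc_ng_per_ul < 0:
        raise ValueError("concentration must be non-negative")
    grams = conc_ng_per_ul * 1e-9
    return grams / (construct_length_bp * DA_PER_BP / AVOGADRO)


def construct_length(insert_bp: int, vector_bp: int = DEFAULT_VECTOR_BP) -> int:
    """Total construct size of a cloning vector plus insert."""
    if insert_bp < 0 or vector_bp <= 0:
        raise ValueError("lengths must be positive")
    return vector_bp + insert_bp


@dataclass
class QuantResult:
    sample_id: str
    ct_mean: float
    ct_sd: float
    copies_per_reaction: float
    copies_per_unit: float
    unit: str
    below_range: bool
    above_range: bool


def quantify(
    ct: float | Sequence[float],
    curve: StandardCurve,
    dilution_factor: float = 1.0,
    matrix_amount: float = 1.0,
    sample_id: str = "",
    unit: str = "g",
) -> QuantResult:
    """Copy number of a sample from its Ct value(s) and a standard curve.

    ``copies = 10^((Ct - intercept) / slope)``, multiplied by the
    template dilution factor and divided by the grams (or ml) of matrix
    extracted.  Estimates outside the standards' span are flagged.
    """
    cts = np.atleast_1d(np.asarray(ct, dtype=float))
    ct_mean = float(cts.mean())
    ct_sd = float(cts.std(ddof=1)) if len(cts) > 1 else 0.0
    log_copies = (ct_mean - curve.intercept) / curve.slope
    copies_rxn = 10.0**log_copies
    per_unit = copies_rxn * dilution_factor / matrix_amount
    return QuantResult(
        sample_id=sample_id,
        ct_mean=ct_mean,
        ct_sd=ct_sd,
        copies_per_reaction=copies_rxn,
        copies_per_unit=per_unit,
        unit=unit,
        below_range=log_copies < curve.log_range[0],
        above_range=log_copies > curve.log_range[1],
    )


# ---------------------------------------------------------------------------
# Melt curves
# ---------------------------------------------------------------------------


@dataclass
class MeltCurve:
    temperatures: np.ndarray
    fluorescence: np.ndarray
    peaks: list[float] = field(default_factory=list)

    @property
    def single_peak(self) -> bool:
        """One melt peak supports a single specific product."""
        return len(self.peaks) == 1


def melt_peaks(
    temperatures: Sequence[float],
    fluorescence: Sequence[float],
    min_prominence: float | None = None,
    smooth_window: int = 3,
) -> MeltCurve:
    """Call melt peaks on the -dF/dT profile of a dissociation curve.

    The derivative (central differences) is smoothed with a short moving
    average (default 3 samples) and peaks above a prominence threshold
    (default 5% of the profile maximum) are reported as temperatures.
    """
    T = np.asarray(temperatures, dtype=float)
    F = np.asarray(fluorescence, dtype=float)
    if T.shape != F.shape or T.ndim != 1:
        raise ValueError("temperatures and fluorescence must be equal-length 1-D")
    if len(T) < 10:
        raise ValueError("melt-curve analysis requires at least 10 points")
    if not (np.diff(T) > 0).all():
        raise ValueError("temperatures must be strictly increasing")
    deriv = -np.gradient(F, T)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        deriv = np.convolve(deriv, kernel, mode="same")
    top = float(deriv.max(initial=0.0))
    if top <= 0.0:
        return MeltCurve(T, F, [])
    prom = min_prominence if min_prominence is not None else 0.05 * top
    idx, _ = signal.find_peaks(deriv, prominence=prom)
    return MeltCurve(T, F, [float(T[i]) for i in idx])


# ---------------------------------------------------------------------------
# Spike-in calibration
# ---------------------------------------------------------------------------


@dataclass
class SpikeCalibration:
    """Measured-vs-true log10 abundance line and its inverse correction.

    Forward model: ``LogC_m = a * LogC_real - b``; correction:
    ``LogC_real = (LogC_m + b) / a``.
    """

    a: float
    b: float
    se_a: float
    se_b: float
    r2: float
    weighted: bool
    valid_range: tuple[float, float]

    def forward(self, log_real: float) -> float:
        return self.a * log_real - self.b

    def correct(self, log_measured: float) -> tuple[float, float]:
        return correct_abundance(log_measured, self)


def fit_spike_calibration(
    pairs: Iterable[tuple[float, float] | tuple[float, float, float]] | pd.DataFrame,
) -> SpikeCalibration:
    """Weighted least squares of measured on true log10 abundance.

    *pairs* is an iterable of ``(log10_true, log10_measured[, sd])`` or
    a DataFrame with columns ``log10_true, log10_measured[, sd]``.
    Weights are 1/sd^2 when SDs are given ("errors as weight"); a zero
    or missing SD is floored to the smallest positive SD present so its
    weight stays finite.  The fitted line is inverted algebraically, so
    round-tripping forward model and correction is the identity.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs.copy()
    else:
        rows = [tuple(p) for p in pairs]
        if not rows:
            raise ValueError("no spike levels")
        cols = ["log10_true", "log10_measured", "sd"][: len(rows[0])]
        df = pd.DataFrame(rows, columns=cols)
    if len(df["log10_true"].unique()) < 3:
        raise ValueError("need at least 3 distinct spike levels")
    x = df["log10_true"].to_numpy(dtype=float)
    y = df["log10_measured"].to_numpy(dtype=float)
    weighted = "sd" in df.columns and df["sd"].notna().any()
    if weighted:
        sd = df["sd"].to_numpy(dtype=float)
        positive = sd[np.isfinite(sd) & (sd > 0)]
        floor = positive.min() if positive.size else 1.0
        sd = np.where(np.isfinite(sd) & (sd > 0), sd, floor)
        w = 1.0 / sd**2
    else:
        w = np.ones_like(x)
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = model.params
    se_int, se_slope = model.bse
    if slope <= 0:
        raise ValueError(f"spike calibration slope must be positive, got {slope:.4g}")
    return SpikeCalibration(
        a=float(slope),
        b=float(-intercept),
        se_a=float(se_slope),
        se_b=float(se_int),
        r2=float(model.rsquared),
        weighted=bool(weighted),
        valid_range=(float(x.min()), float(x.max())),
    )


def correct_abundance(
    log_measured: float, cal: SpikeCalibration
) -> tuple[float, float]:
    """True log10 abundance from a measured one: ``(LogC_m + b) / a``.

    Returns ``(value, se)`` with the SE propagated to first order from
    the calibration coefficient SEs.  Warns when the measured value is
    outside the calibration's validity range (mapped through the
    forward model).
    """
    if cal.a <= 0:
        raise ValueError("calibration slope must be positive")
    lo, hi = (cal.forward(cal.valid_range[0]), cal.forward(cal.valid_range[1]))
    if not lo <= log_measured <= hi:
        warnings.warn(
            f"measured log10 abundance {log_measured:.3g} outside the "
            f"calibration range [{lo:.3g}, {hi:.3g}]; extrapolating",
            stacklevel=2,
        )
    value = (log_measured + cal.b) / cal.a
    var = (cal.se_b / cal.a) ** 2 + (value / cal.a) ** 2 * cal.se_a**2
    return float(value), float(math.sqrt(var))
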