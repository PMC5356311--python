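"""Steady-state kinetics and stability analysis of (resurrected) peroxidases.

Units follow the conventions used for ligninolytic peroxidase kinetics:
Km in µM, kcat in s⁻¹, catalytic efficiency kcat/Km in s⁻¹·mM⁻¹ (the
µM → mM factor of 1000 is applied in exactly one place,
:func:`catalytic_efficiency`).

Biphasic ("sigmoid") saturation curves arising from two independent
oxidation sites — a high-efficiency site at the catalytic tryptophan and a
low-efficiency site at a heme access channel — are fitted as the sum of two
Michaelis–Menten terms; site 1 is always the lower-Km (high-efficiency)
site.  Stability summaries are the 10-min T50 (temperature of 50% activity
loss, by linear interpolation) and Tm (midpoint of a two-state sigmoid
fitted to a CD-vs-temperature melting profile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


class KineticsError(ValueError):
    pass


#: Product formed (or removed), detection wavelength (nm), ε (M⁻¹cm⁻¹).
EXTINCTION_TABLE = {
    "Mn3+-tartrate": (238, 6500.0),
    "veratraldehyde": (310, 9300.0),
    "coerulignone": (469, 55000.0),
    "ABTS cation radical": (436, 29300.0),
    "Reactive Black 5": (598, 30000.0),
}


def rate_from_absorbance(dA_per_s: float, epsilon: float, path_cm: float,
                         enzyme_uM: float) -> float:
    """Beer–Lambert conversion of an absorbance slope to turnover (s⁻¹)."""
    if epsilon <= 0 or path_cm <= 0 or enzyme_uM <= 0:
        raise KineticsError("epsilon, path length and enzyme concentration "
                            "must be positive")
    rate_uM_per_s = dA_per_s / (epsilon * path_cm) * 1e6
    return rate_uM_per_s / enzyme_uM


@dataclass
class KineticCurve:
    """One saturation curve: substrate concentrations (µM) vs turnover (s⁻¹)."""

    s: np.ndarray
    v: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.s.shape != self.v.shape:
            raise KineticsError("concentration and rate arrays differ in length")
        if np.any(self.s < 0):
            raise KineticsError("negative substrate concentration")
        if not np.all(np.isfinite(self.v)):
            raise KineticsError("non-finite rate")
        order = np.argsort(self.s, kind="stable")
        self.s, self.v = self.s[order], self.v[order]

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.s))


@dataclass
class KineticFit:
    model: str                       # "single" | "two-site"
    km: list[float]                  # µM; two-site ordered by Km ascending
    kcat: list[float]                # s⁻¹
    km_se: list[float]
    kcat_se: list[float]
    km_ci: list[tuple[float, float]]
    kcat_ci: list[tuple[float, float]]
    efficiency: list[float]          # s⁻¹ mM⁻¹
    rss: float
    aic: float
    n_points: int
    warnings: list[str] = field(default_factory=list)


def _mm(s, km, kcat):
    return kcat * s / (km + s)


def _two_site(s, km1, kcat1, km2, kcat2):
    return _mm(s, km1, kcat1) + _mm(s, km2, kcat2)


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def _ci(estimates, ses, df):
    t = stats.t.ppf(0.975, max(df, 1))
    return [(e - t * se, e + t * se) for e, se in zip(estimates, ses)]


def fit_michaelis_menten(curve: KineticCurve) -> KineticFit:
    """Nonlinear least-squares v = kcat·[S]/(Km+[S]).

    Initialized from the largest observed rate and the concentration nearest
    its half; 95% confidence limits from the asymptotic covariance.  A
    fitted Km beyond the highest assayed concentration triggers a
    saturation warning.
    """
    if curve.n_distinct < 5:
        raise KineticsError(
            f"need >= 5 distinct concentrations, got {curve.n_distinct}")
    kcat0 = float(curve.v.max())
    if kcat0 <= 0:
        raise KineticsError("no positive rates; nothing to fit")
    km0 = float(curve.s[np.argmin(np.abs(curve.v - kcat0 / 2))])
    km0 = max(km0, 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            _mm, curve.s, curve.v, p0=[km0, kcat0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000)
    except RuntimeError as exc:
        raise KineticsError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    km, kcat = float(popt[0]), float(popt[1])
    resid = curve.v - _mm(curve.s, *popt)
    rss = float(resid @ resid)
    n = len(curve.s)
    ses = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    warns = []
    if km > curve.s.max():
        warns.append("fitted Km exceeds the highest assayed concentration; "
                     "the curve is not saturated")
    return KineticFit("single", [km], [kcat], [float(ses[0])], [float(ses[1])],
                      _ci([km], [ses[0]], n - 2), _ci([kcat], [ses[1]], n - 2),
                      [catalytic_efficiency(km, kcat)], rss,
                      _aic(rss, n, 2), n, warns)


def fit_two_site(curve: KineticCurve) -> KineticFit:
    """Sum-of-two-Michaelis–Menten fit for biphasic saturation curves.

    Requires at least 8 distinct concentrations spanning both phases.
    Sites are reported with Km ascending (site 1 = high-efficiency site).
    Less than 5-fold Km separation triggers an ill-conditioning warning.
    """
    if curve.n_distinct < 8:
        raise KineticsError(
            f"two-site fit needs >= 8 distinct concentrations, got {curve.n_distinct}")
    single = fit_michaelis_menten(curve)
    km_g, kcat_g = single.km[0], single.kcat[0]
    starts = [
        [km_g / 50, kcat_g / 2, km_g * 50, kcat_g / 2],
        [curve.s[curve.s > 0].min(), curve.v.max() / 4, curve.s.max(), curve.v.max()],
        [km_g / 10, kcat_g / 4, km_g * 10, kcat_g],
    ]
    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                _two_site, curve.s, curve.v, p0=p0,
                bounds=([1e-12] * 4, [np.inf] * 4), maxfev=50000)
        except RuntimeError:
            continue
        resid = curve.v - _two_site(curve.s, *popt)
        rss = float(resid @ resid)
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise KineticsError("two-site fit did not converge from any start")
    popt, pcov, rss = best
    ses = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    sites = [(popt[0], popt[1], ses[0], ses[1]), (popt[2], popt[3], ses[2], ses[3])]
    sites.sort(key=lambda x: x[0])
    km = [float(s[0]) for s in sites]
    kcat = [float(s[1]) for s in sites]
    km_se = [float(s[2]) for s in sites]
    kcat_se = [float(s[3]) for s in sites]
    n = len(curve.s)
    warns = []
    if km[1] / max(km[0], 1e-300) < 5.0:
        warns.append("Km separation below 5-fold; two-site fit is ill-conditioned")
    if min(kcat) < 0.01 * sum(kcat):
        warns.append("one site carries negligible turnover; "
                     "two-site fit is ill-conditioned")
    return KineticFit("two-site", km, kcat, km_se, kcat_se,
                      _ci(km, km_se, n - 4), _ci(kcat, kcat_se, n - 4),
                      [catalytic_efficiency(a, b) for a, b in zip(km, kcat)],
                      rss, _aic(rss, n, 4), n, warns)


def select_kinetic_model(curve: KineticCurve) -> KineticFit:
    """Fit both forms and keep the one preferred by AIC."""
    single = fit_michaelis_menten(curve)
    try:
        double = fit_two_site(curve)
    except KineticsError:
        return single
    return double if double.aic < single.aic else single


def catalytic_efficiency(km_uM: float, kcat_s: float) -> float:
    """kcat/Km in s⁻¹·mM⁻¹ (the single place the 1000× unit factor lives)."""
    if km_uM <= 0:
        raise KineticsError(f"Km must be positive, got {km_uM}")
    return 1000.0 * kcat_s / km_uM


def round_sig(value: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report precision for efficiencies)."""
    if value == 0:
        return 0.0
    from math import floor, log10
    return round(value, -int(floor(log10(abs(value)))) + sig - 1)


def fold_change(value_a: float, value_b: float, mode: str = "ratio") -> float | int:
    """a/b, optionally rounded to the nearest integer ("11-fold" style)."""
    if value_b == 0:
        raise KineticsError("fold change undefined: denominator is zero")
    ratio = value_a / value_b
    if mode == "rounded":
        return int(round(ratio))
    if mode != "ratio":
        raise KineticsError(f"mode must be 'ratio' or 'rounded', got {mode!r}")
    return ratio


def relative_efficiency_profile(efficiencies: "pd.DataFrame") -> "pd.DataFrame":  # noqa: F821
    """Percent efficiencies with each substrate's maximum set to 100%.

    Input: DataFrame with enzymes as rows and substrates as columns; NaN
    means no detectable activity and is reported as 0.
    """
    import pandas as pd

    df = efficiencies.astype(float).fillna(0.0)
    out = {}
    for col in df.columns:
        mx = df[col].max()
        if not np.isfinite(mx) or mx <= 0:
            raise KineticsError(f"substrate '{col}' has no positive efficiency")
        out[col] = 100.0 * df[col] / mx
    return pd.DataFrame(out, index=df.index)


def residual_activity_profile(activities: dict, reference) -> dict:
    """Percent residual activities relative to the reference condition."""
    if reference not in activities:
        raise KineticsError(f"reference condition {reference!r} not measured")
    ref = activities[reference]
    if ref <= 0:
        raise KineticsError("reference activity must be positive")
    return {cond: 100.0 * a / ref for cond, a in activities.items()}


@dataclass
class StabilityCurve:
    """Residual activity (%) or CD signal vs pH or temperature."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise KineticsError("x and y differ in length")
        if len(self.x) < 2:
            raise KineticsError("need at least two points")
        d = np.diff(self.x)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise KineticsError("x must be strictly monotone")
        if not np.all(np.isfinite(self.y)):
            raise KineticsError("non-finite y value")


def t50_from_curve(curve: StabilityCurve) -> float:
    """Temperature of the first downward 50% crossing, by linear interpolation."""
    x, y = curve.x, curve.y
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    for i in range(len(x) - 1):
        if y[i] >= 50.0 and y[i + 1] < 50.0:
            frac = (y[i] - 50.0) / (y[i] - y[i + 1])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    raise KineticsError("no T50 in range: the curve never falls through 50%")


def _sigmoid(x, lo, hi, mid, slope):
    return lo + (hi - lo) / (1.0 + np.exp((x - mid) / slope))


def tm_from_melting(curve: StabilityCurve) -> float:
    """Midpoint of a two-state unfolding transition (4-parameter sigmoid fit).

    Invariant to uniform rescaling of the CD axis.  A flat profile (no
    transition) is an error, not a Tm.
    """
    x, y = curve.x, curve.y
    span = float(y.max() - y.min())
    if span <= 0 or span < 1e-6 * max(1.0, np.abs(y).max()):
        raise KineticsError("no unfolding transition: melting profile is flat")
    half = y.min() + span / 2.0
    mid0 = float(x[np.argmin(np.abs(y - half))])
    slope0 = (x.max() - x.min()) / 20.0
    # _sigmoid tends to `hi` at low x and `lo` at high x when slope > 0
    falling = y[0] > y[-1]
    p0 = [y.min(), y.max(), mid0, slope0] if falling else [y.max(), y.min(), mid0, slope0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(_sigmoid, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise KineticsError(f"melting-curve fit did not converge: {exc}") from exc
    lo, hi, mid, _ = popt
    if abs(hi - lo) < 0.05 * span:
        raise KineticsError("no unfolding transition: fitted amplitude is degenerate")
    if not (x.min() <= mid <= x.max()):
        raise KineticsError("fitted midpoint falls outside the measured range")
    return float(mid)


# -- synthetic curves (known-parameter study conditions for the fits) --------

def generate_mm_curve(km: float, kcat: float, concentrations=None,
                      noise_sd_frac: float = 0.0, replicates: int = 1,
                      seed: int | None = None, metadata: dict | None = None
                      ) -> KineticCurve:
    """Saturation curve from known (Km, kcat).

    Default design: 8 concentrations from Km/4 to 8·Km (log-spaced), the
    span a practitioner would use to bracket the Km; optional Gaussian noise
    with sd expressed as a fraction of kcat, per replicate.
    """
    if concentrations is None:
        concentrations = np.geomspace(km / 4.0, 8.0 * km, 8)
    s = np.repeat(np.asarray(concentrations, dtype=float), replicates)
    v = _mm(s, km, kcat)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd_frac * kcat, size=v.shape)
    return KineticCurve(s, v, metadata or {})


def generate_two_site_curve(km1: float, kcat1: float, km2: float, kcat2: float,
                            concentrations=None, noise_sd_frac: float = 0.0,
                            replicates: int = 1, seed: int | None = None
                            ) -> KineticCurve:
    """Biphasic curve from two known sites; default design spans both phases."""
    if concentrations is None:
        lo, hi = min(km1, km2), max(km1, km2)
        concentrations = np.geomspace(lo / 4.0, 8.0 * hi, 12)
    s = np.repeat(np.asarray(concentrations, dtype=float), replicates)
    v = _two_site(s, km1, kcat1, km2, kcat2)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd_frac * (kcat1 + kcat2), size=v.shape)
    return KineticCurve(s, v)


def generate_t50_curve(midpoint: float, temps=None, slope: float = 2.5,
                       noise_sd: float = 0.0, seed: int | None = None
                       ) -> StabilityCurve:
    """Residual-activity-vs-temperature curve (logistic, 100% → 0%).

    Default temperatures follow the 10-min inactivation design: 5 °C steps
    over 25–85 °C.
    """
    if temps is None:
        temps = np.arange(25.0, 90.0, 5.0)
    temps = np.asarray(temps, dtype=float)
    y = _sigmoid(temps, 0.0, 100.0, midpoint, slope)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return StabilityCurve(temps, y)


def generate_melting_curve(midpoint: float, temps=None, slope: float = 2.0,
                           baseline_folded: float = -20.0,
                           baseline_unfolded: float = -4.0,
                           noise_sd_frac: float = 0.0,
                           seed: int | None = None) -> StabilityCurve:
    """CD-at-222-nm melting profile with a known midpoint.

    Defaults emulate a 20–95 °C scan of a mostly α-helical protein (negative
    ellipticity shrinking toward the unfolded baseline); noise sd is a
    fraction of the transition amplitude.
    """
    if temps is None:
        temps = np.arange(20.0, 96.0, 1.0)
    temps = np.asarray(temps, dtype=float)
    y = _sigmoid(temps, baseline_unfolded, baseline_folded, midpoint, slope)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        amp = abs(baseline_unfolded - baseline_folded)
        y = y + rng.normal(0.0, noise_sd_frac * amp, size=y.shape)
    return StabilityCurve(temps, y)
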