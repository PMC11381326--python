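"""Mg2+ titration fitting and tertiary-contact thermodynamics.

From a construct's mutation profiles across a Mg2+ titration we compute the
relative protection of its probe adenines,

    f_i = 1 - r_i / max_i(r_i)          (r_i = mean probe reactivity),

fit the modified Hill form

    f(x) = A * (x/K)^n / (1 + (x/K)^n)

by weighted nonlinear least squares (``scipy.optimize.curve_fit``) to obtain
the midpoint K = [Mg2+]1/2, amplitude A and Hill coefficient n, estimate
errors by case-resampling bootstrap, and convert midpoints to free energies

    dG  = -R T ln(K / 1 mM),      ddG = dG - dG_reference.

K is expressed in mM inside the logarithm; the unit choice shifts every dG
by a constant and cancels exactly in ddG, the quantity used for comparing
constructs.  A fitted midpoint beyond the highest tested concentration is
flagged ``below_detection`` rather than reported as a measurement.

A single-point shortcut is also provided: ln(probe reactivity) at one Mg2+
concentration is linearly related to dG across a mutant family, so an OLS
fit on constructs with known dG yields a one-measurement dG estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .profiling import MutationProfile
from .simulate import hill_fraction

GAS_CONSTANT_KCAL = 1.987e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE_K = 293.15  # 20 C

#: 16-point Mg2+ grid (mM) used by default in simulations: a zero anchor
#: plus roughly log-spaced points up to 40 mM.
DEFAULT_MG_GRID = (
    0.0, 0.05, 0.1, 0.15, 0.25, 0.5, 0.75, 1.0,
    1.5, 2.5, 5.0, 7.5, 10.0, 15.0, 25.0, 40.0,
)

STATUS_OK = "ok"
STATUS_BELOW_DETECTION = "below_detection"
STATUS_QC_FAIL = "qc_fail"


class QCError(ValueError):
    """A titration series fails a quality-control precondition."""


# ---------------------------------------------------------------------------
# Series and protection curve
# ---------------------------------------------------------------------------


@dataclass
class TitrationPoint:
    mg: float
    profile: MutationProfile
    mask: bool = False  # True = exclude from analysis


@dataclass
class TitrationSeries:
    """Ordered (Mg2+ -> profile) measurements for one construct."""

    construct: str
    points: list[TitrationPoint]
    probe_positions: list[int]

    def __post_init__(self) -> None:
        mgs = [p.mg for p in self.points]
        if len(set(mgs)) != len(mgs):
            raise ValueError(f"{self.construct}: duplicate Mg2+ concentrations")
        if any(m < 0 for m in mgs):
            raise ValueError(f"{self.construct}: negative Mg2+ concentration")
        if sum(not p.mask for p in self.points) < 4:
            raise ValueError(
                f"{self.construct}: at least 4 unmasked titration points required"
            )
        self.points.sort(key=lambda p: p.mg)

    @property
    def unmasked(self) -> list[TitrationPoint]:
        return [p for p in self.points if not p.mask]

    @property
    def max_mg(self) -> float:
        return max(p.mg for p in self.unmasked)


@dataclass
class ProtectionCurve:
    """Relative protection f_i per unmasked titration point."""

    construct: str
    mg: np.ndarray
    f: np.ndarray
    avg_reactivity: np.ndarray
    max_reactivity: float
    f_sigma: np.ndarray | None = None          # propagated binomial SE of f
    reactivity_sigma: np.ndarray | None = None  # binomial SE of avg_reactivity

    def __len__(self) -> int:
        return len(self.mg)


def compute_protection(series: TitrationSeries) -> ProtectionCurve:
    """Reduce a titration series to its relative-protection curve.

    The mean probe reactivity is normalized by the series maximum over
    unmasked points, so f = 0 at the most reactive point (no protection) and
    f -> 1 as the probes approach full protection.
    """
    pts = series.unmasked
    mg = np.array([p.mg for p in pts])
    avg = np.array(
        [p.profile.mean_reactivity(series.probe_positions) for p in pts]
    )
    if np.any(np.isnan(avg)):
        raise QCError(f"{series.construct}: missing probe reactivity")
    rmax = float(np.max(avg))
    if rmax <= 0:
        raise QCError(f"{series.construct}: no dynamic range")
    f = 1.0 - avg / rmax
    ses = np.array(
        [p.profile.reactivity_se(series.probe_positions) for p in pts]
    )
    have_se = bool(np.all(np.isfinite(ses)))
    return ProtectionCurve(
        construct=series.construct,
        mg=mg,
        f=f,
        avg_reactivity=avg,
        max_reactivity=rmax,
        f_sigma=ses / rmax if have_se else None,
        reactivity_sigma=ses if have_se else None,
    )


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    amplitude_max: float = 1.2
    n_min: float = 0.2
    n_max: float = 10.0
    k_min: float = 1e-3  # mM
    k_max: float = 1e3   # mM
    weighted: bool = True
    max_nfev: int = 2000


@dataclass
class HillFitResult:
    construct: str
    mg_half: float = np.nan       # mM
    amplitude_A: float = np.nan
    hill_n: float = np.nan
    se_mg_half: float = np.nan
    se_A: float = np.nan
    se_n: float = np.nan
    ci_mg_half: tuple[float, float] | None = None
    n_boot: int = 0
    n_boot_failed: int = 0
    rss: float = np.nan
    status: str = STATUS_OK
    reason: str = ""
    max_tested_mg: float = np.nan
    replicates: np.ndarray | None = field(default=None, repr=False)

    def replicates_frame(self):
        """Bootstrap replicate table (A, K, n per converged replicate)."""
        import pandas as pd

        if self.replicates is None:
            raise ValueError("bootstrap was run without keep_replicates=True")
        return pd.DataFrame(
            self.replicates, columns=["amplitude_A", "mg_half_mM", "hill_n"]
        )

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def _initial_guesses(curve: ProtectionCurve, config: FitConfig) -> list[tuple]:
    a0 = float(np.clip(np.max(curve.f), 0.2, config.amplitude_max))
    # midpoint guess: mg whose f is nearest half-amplitude (positive mg only)
    pos = curve.mg > 0
    if np.any(pos):
        idx = np.argmin(np.abs(curve.f[pos] - a0 / 2))
        k0 = float(curve.mg[pos][idx])
    else:
        k0 = 1.0
    k0 = float(np.clip(k0, config.k_min * 10, config.k_max / 10))
    return [
        (a0, k0, 1.0),
        (a0, k0 * 3.0, 2.0),
        (min(1.0, config.amplitude_max), max(k0 / 3.0, config.k_min * 10), 0.7),
    ]


def fit_hill(
    curve: ProtectionCurve,
    config: FitConfig | None = None,
    max_tested_mg: float | None = None,
) -> HillFitResult:
    """Weighted least-squares fit of the modified Hill equation.

    Up to three starts are attempted (the documented initialization first);
    the best-converged fit wins.  ``status`` is ``below_detection`` when the
    fitted midpoint exceeds the highest tested concentration and
    ``qc_fail`` when no start converges.
    """
    config = config or FitConfig()
    mg = np.asarray(curve.mg, dtype=float)
    f = np.asarray(curve.f, dtype=float)
    if len(mg) < 4:
        return HillFitResult(
            construct=curve.construct, status=STATUS_QC_FAIL,
            reason="fewer than 4 points",
        )
    max_tested = float(max_tested_mg if max_tested_mg is not None else mg.max())
    sigma = None
    if config.weighted and curve.f_sigma is not None:
        sigma = np.maximum(curve.f_sigma, 1e-4)  # avoid zero-weight blowup

    bounds = (
        [1e-6, config.k_min, config.n_min],
        [config.amplitude_max, config.k_max, config.n_max],
    )
    best: tuple[float, np.ndarray] | None = None
    for p0 in _initial_guesses(curve, config):
        p0 = tuple(np.clip(p0, bounds[0], bounds[1]))
        try:
            popt, _ = curve_fit(
                hill_fraction, mg, f, p0=p0, sigma=sigma,
                absolute_sigma=sigma is not None,
                bounds=bounds, max_nfev=config.max_nfev,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((hill_fraction(mg, *popt) - f) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        return HillFitResult(
            construct=curve.construct, status=STATUS_QC_FAIL, reason="fit failed",
            max_tested_mg=max_tested,
        )
    rss, (a_hat, k_hat, n_hat) = best
    status = STATUS_BELOW_DETECTION if k_hat > max_tested else STATUS_OK
    return HillFitResult(
        construct=curve.construct,
        mg_half=float(k_hat),
        amplitude_A=float(a_hat),
        hill_n=float(n_hat),
        rss=rss,
        status=status,
        max_tested_mg=max_tested,
    )


def bootstrap_fit(
    curve: ProtectionCurve,
    fit: HillFitResult | None = None,
    n_boot: int = 100,
    seed: int | None = 0,
    config: FitConfig | None = None,
    keep_replicates: bool = False,
) -> HillFitResult:
    """Case-resampling bootstrap standard errors for a Hill fit.

    Titration points are resampled with replacement ``n_boot`` times and
    refit from the point estimate; the SE of each parameter is the standard
    deviation over converged replicates, with a 95% percentile CI on the
    midpoint.  The protection transform divides every point by the
    series-maximum reactivity, so all f values share that normalizer's
    measurement noise; case resampling alone holds it fixed and understates
    the midpoint uncertainty.  When per-point binomial SEs are available
    the normalizer is therefore additionally perturbed per replicate by its
    own SE before the transform is recomputed.  Replicates that fail to
    converge or collapse to fewer than 4 distinct points are dropped and
    counted; more than 50% failures voids the fit
    (``qc_fail: unstable fit``).
    """
    config = config or FitConfig()
    if fit is None:
        fit = fit_hill(curve, config)
    if fit.status == STATUS_QC_FAIL:
        return fit
    rng = np.random.default_rng(seed)
    mg = np.asarray(curve.mg, dtype=float)
    f = np.asarray(curve.f, dtype=float)
    react = (
        np.asarray(curve.avg_reactivity, dtype=float)
        if curve.avg_reactivity is not None
        else None
    )
    react_sigma = curve.reactivity_sigma
    f_sigma = curve.f_sigma
    rmax = curve.max_reactivity
    se_rmax = 0.0
    if react is not None and react_sigma is not None and len(react):
        se_rmax = float(react_sigma[int(np.argmax(react))])
    bounds = (
        [1e-6, config.k_min, config.n_min],
        [config.amplitude_max, config.k_max, config.n_max],
    )
    p0 = np.clip((fit.amplitude_A, fit.mg_half, fit.hill_n), bounds[0], bounds[1])
    reps = []
    n_failed = 0
    n = len(mg)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(mg[idx])) < 4:
            n_failed += 1
            continue
        if react is not None and react_sigma is not None and rmax > 0:
            rmax_b = rmax + rng.normal(0.0, se_rmax)
            if rmax_b <= 0:
                n_failed += 1
                continue
            f_b = 1.0 - react[idx] / rmax_b
            sigma_b = (
                np.maximum(react_sigma[idx] / rmax_b, 1e-4)
                if config.weighted
                else None
            )
        else:
            f_b = f[idx]
            sigma_b = (
                np.maximum(f_sigma[idx], 1e-4)
                if (config.weighted and f_sigma is not None)
                else None
            )
        try:
            popt, _ = curve_fit(
                hill_fraction, mg[idx], f_b, p0=p0,
                sigma=sigma_b,
                absolute_sigma=sigma_b is not None,
                bounds=bounds, max_nfev=config.max_nfev,
            )
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        reps.append(popt)
    if n_failed > 0.5 * n_boot:
        return replace(
            fit, status=STATUS_QC_FAIL, reason="unstable fit",
            n_boot=n_boot, n_boot_failed=n_failed,
        )
    reps_arr = np.asarray(reps)
    lo, hi = np.percentile(reps_arr[:, 1], [2.5, 97.5])
    return replace(
        fit,
        se_A=float(np.std(reps_arr[:, 0], ddof=1)),
        se_mg_half=float(np.std(reps_arr[:, 1], ddof=1)),
        se_n=float(np.std(reps_arr[:, 2], ddof=1)),
        ci_mg_half=(float(lo), float(hi)),
        n_boot=n_boot,
        n_boot_failed=n_failed,
        replicates=reps_arr if keep_replicates else None,
    )


def plot_fit(curve: ProtectionCurve, fit: HillFitResult, path=None, ax=None):
    """Protection data with the fitted Hill curve on a symlog Mg2+ axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(4.5, 3.2))
    yerr = curve.f_sigma if curve.f_sigma is not None else None
    ax.errorbar(curve.mg, curve.f, yerr=yerr, fmt="o", ms=4, color="k")
    if np.isfinite(fit.mg_half):
        grid = np.concatenate([[0.0], np.geomspace(
            max(min(curve.mg[curve.mg > 0], default=0.01), 1e-3),
            max(curve.mg.max(), 1.0), 200,
        )])
        ax.plot(grid, hill_fraction(grid, fit.amplitude_A, fit.mg_half, fit.hill_n),
                color="#d62728")
        label = f"K = {fit.mg_half:.3g} mM, n = {fit.hill_n:.2f}"
        if np.isfinite(fit.se_mg_half):
            label = f"K = {fit.mg_half:.3g} +/- {fit.se_mg_half:.2g} mM, n = {fit.hill_n:.2f}"
        ax.set_title(f"{curve.construct}: {label}", fontsize=9)
    ax.set_xscale("symlog", linthresh=max(
        float(min(curve.mg[curve.mg > 0], default=0.05)), 1e-3))
    ax.set_xlabel("[Mg2+] (mM)")
    ax.set_ylabel("relative protection f")
    ax.set_ylim(-0.05, 1.1)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


# ---------------------------------------------------------------------------
# Thermodynamics
# ---------------------------------------------------------------------------


@dataclass
class ThermoResult:
    construct: str
    dG: float                      # kcal/mol, -RT ln(K/mM)
    se_dG: float
    temperature_K: float = DEFAULT_TEMPERATURE_K
    mg_units: str = "mM"
    reference: str | None = None
    ddG: float = np.nan            # kcal/mol vs reference
    se_ddG: float = np.nan


def mg_half_to_dG(
    mg_half: float,
    se: float = 0.0,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    construct: str = "",
) -> ThermoResult:
    """Convert a midpoint (mM) to a free energy dG = -RT ln(K/mM).

    The SE is propagated by the delta method: se_dG = RT * se / K.
    """
    if mg_half <= 0:
        raise ValueError(f"mg_half must be positive, got {mg_half}")
    rt = GAS_CONSTANT_KCAL * temperature_K
    return ThermoResult(
        construct=construct,
        dG=-rt * float(np.log(mg_half)),
        se_dG=rt * se / mg_half,
        temperature_K=temperature_K,
    )


def compute_ddG(target: ThermoResult, reference: ThermoResult) -> ThermoResult:
    """ddG = dG_target - dG_reference with SEs added in quadrature."""
    if target.temperature_K != reference.temperature_K:
        raise ValueError(
            f"temperature mismatch: {target.temperature_K} != "
            f"{reference.temperature_K}"
        )
    return replace(
        target,
        reference=reference.construct,
        ddG=target.dG - reference.dG,
        se_ddG=float(np.hypot(target.se_dG, reference.se_dG)),
    )


# ---------------------------------------------------------------------------
# Single-point ln(reactivity) -> dG estimator
# ---------------------------------------------------------------------------


@dataclass
class SinglePointModel:
    slope: float
    intercept: float
    r_squared: float
    n_used: int
    excluded: list[str]
    predict: Callable[[float], tuple[float, tuple[float, float]]] = field(repr=False)

    def __call__(self, reactivity: float) -> float:
        return self.predict(reactivity)[0]


def single_point_estimator(
    reactivities: dict[str, float],
    dG_ref: dict[str, float],
    alpha: float = 0.05,
) -> SinglePointModel:
    """OLS of training dG on ln(probe reactivity) at a single Mg2+ point.

    Constructs with non-positive reactivity are excluded (log undefined).
    The returned model predicts dG for a new reactivity with a
    (1 - alpha) prediction interval.
    """
    import statsmodels.api as sm

    names = [
        n for n in reactivities
        if n in dG_ref and reactivities[n] > 0 and np.isfinite(dG_ref[n])
    ]
    excluded = sorted(set(reactivities) - set(names))
    if len(names) < 3:
        raise ValueError(
            f"single-point estimator needs >= 3 usable constructs, got {len(names)}"
        )
    x = np.log([reactivities[n] for n in names])
    y = np.array([dG_ref[n] for n in names])
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()

    def predict(reactivity: float) -> tuple[float, tuple[float, float]]:
        if reactivity <= 0:
            raise ValueError("reactivity must be positive")
        pred = res.get_prediction([1.0, np.log(reactivity)])
        frame = pred.summary_frame(alpha=alpha)
        return (
            float(frame["mean"].iloc[0]),
            (float(frame["obs_ci_lower"].iloc[0]), float(frame["obs_ci_upper"].iloc[0])),
        )

    return SinglePointModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n_used=len(names),
        excluded=excluded,
        predict=predict,
    )


# ---------------------------------------------------------------------------
# Convenience: series -> full result
# ---------------------------------------------------------------------------


def analyze_series(
    series: TitrationSeries,
    n_boot: int = 100,
    seed: int | None = 0,
    config: FitConfig | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> tuple[HillFitResult, ThermoResult | None]:
    """Protection curve -> bootstrap Hill fit -> dG for one construct."""
    try:
        curve = compute_protection(series)
    except QCError as exc:
        return (
            HillFitResult(
                construct=series.construct, status=STATUS_QC_FAIL, reason=str(exc)
            ),
            None,
        )
    fit = fit_hill(curve, config, max_tested_mg=series.max_mg)
    fit = bootstrap_fit(curve, fit, n_boot=n_boot, seed=seed, config=config)
    thermo = None
    if fit.status == STATUS_OK:
        thermo = mg_half_to_dG(
            fit.mg_half, fit.se_mg_half if np.isfinite(fit.se_mg_half) else 0.0,
            temperature_K, construct=series.construct,
        )
    return fit, thermo
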