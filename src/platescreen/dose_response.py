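"""Dilution-series design and constrained four-parameter logistic fitting.

The viability model is the standard 4PL ("variable slope") curve

    v(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

with ``top`` the viability plateau at zero dose, ``bottom`` the plateau at
saturating dose, ``IC50`` the curve midpoint (the *relative* IC50) and
``hill`` the slope of the transition. For inhibition curves hill > 0 and
v decreases monotonically from top to bottom; v(IC50) = (top + bottom)/2.

Fitting
-------
Unweighted least squares on the viability scale over all replicate wells,
with IC50 parameterized as log10(IC50) — potency is log-normally
distributed across compounds and the log parameterization both stabilizes
the optimizer and makes the Wald interval sensible. Either asymptote can
be fixed exactly (bottom to 0 for full-kill compounds, top to 1 when the
upper plateau is not reached within the tested range); fixed parameters
are removed from the optimization, not penalized.

The 95% confidence interval for IC50 is Wald-on-log: the asymptotic
standard error of log10(IC50) from the residual-variance-scaled inverse
Gauss-Newton Hessian, a t(n - p) quantile, back-transformed to uM. The
interval is therefore asymmetric around the point estimate.

Fit-quality flags mirror screening practice: ``steep_slope`` (hill > 3,
an all-or-none concentration window), ``incomplete_kill`` (the fitted
bottom plateau leaves > 5% of viability, e.g. the fraction-affected ~ 0.8
plateau typical of phase-specific cytostatics), ``high_variability``
(large replicate spread) and ``precipitation_suspect`` (viability at the
top concentration rebounds above the fitted curve, as seen with poorly
soluble compounds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, DegenerateDataError, InputError

__all__ = [
    "FourPLParams",
    "FitConstraints",
    "DilutionSeries",
    "DoseResponseFit",
    "four_pl",
    "design_dilution",
    "normalize_viability",
    "fit_4pl",
    "ic50_confidence",
    "classify_fit",
    "replicate_spread",
    "absolute_ic50",
]


@dataclass(frozen=True)
class FourPLParams:
    """4PL curve parameters; concentrations in uM, viability dimensionless."""

    top: float
    bottom: float
    ic50: float
    hill: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise InputError(f"ic50 must be > 0 uM, got {self.ic50}")


@dataclass(frozen=True)
class FitConstraints:
    """Which asymptotes are fixed (exactly) during the fit."""

    fix_bottom_zero: bool = False
    fix_top_one: bool = False


@dataclass(frozen=True)
class DilutionSeries:
    """Strictly decreasing geometric concentration series."""

    concentrations: tuple[float, ...]
    factor: int
    replicates_per_level: int = 4

    @property
    def n_levels(self) -> int:
        return len(self.concentrations)


@dataclass
class DoseResponseFit:
    """Result of a constrained 4PL fit."""

    params: FourPLParams
    constraints: FitConstraints
    converged: bool
    rss: float
    n_obs: int
    n_free: int
    ic50_ci95: tuple[float, float] = (float("nan"), float("nan"))
    se_log10_ic50: float = float("nan")
    flags: set[str] = field(default_factory=set)
    message: str = ""

    @property
    def df_resid(self) -> int:
        return self.n_obs - self.n_free


def four_pl(c, params: FourPLParams):
    """Evaluate the 4PL viability curve at concentration(s) ``c`` (uM).

    v(0) = top, v -> bottom as c -> inf (for hill > 0), v(ic50) is the
    midpoint (top + bottom)/2.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise InputError("concentrations must be >= 0")
    return _four_pl_raw(c, params.top, params.bottom, np.log10(params.ic50), params.hill)


def _four_pl_raw(c, top, bottom, log10_ic50, hill):
    c = np.asarray(c, dtype=float)
    ratio = np.zeros_like(c)
    pos = c > 0
    # (c/ic50)^hill computed in log space to dodge overflow at steep slopes
    with np.errstate(over="ignore"):
        ratio[pos] = np.exp(hill * (np.log(c[pos]) - np.log(10.0) * log10_ic50))
    out = bottom + (top - bottom) / (1.0 + ratio)
    return out if out.shape else float(out)


def design_dilution(
    top_conc: float, factor: int, n_levels: int, replicates_per_level: int = 4
) -> DilutionSeries:
    """Geometric dilution series top_conc / factor**k, k = 0..n_levels-1."""
    if factor not in (2, 3):
        raise ConfigurationError(f"dilution factor must be 2 or 3, got {factor}")
    if top_conc <= 0:
        raise InputError(f"top concentration must be > 0 uM, got {top_conc}")
    if n_levels < 1:
        raise ConfigurationError(f"need at least one level, got {n_levels}")
    if n_levels < 8:
        warnings.warn(
            f"{n_levels} concentration levels is below the recommended minimum of 8",
            stacklevel=2,
        )
    conc = tuple(top_conc / factor**k for k in range(n_levels))
    return DilutionSeries(
        concentrations=conc, factor=factor, replicates_per_level=replicates_per_level
    )


def normalize_viability(signals, untreated_signals) -> np.ndarray:
    """Viability fractions: signal / mean(untreated). Not clipped.

    Fraction affected is ``1 - viability``.
    """
    untreated = np.asarray(untreated_signals, dtype=float)
    if untreated.size < 2:
        raise InputError(
            f"need >= 2 untreated control wells, got {untreated.size}"
        )
    mean = float(np.mean(untreated))
    if mean <= 0:
        raise InputError(f"untreated control mean must be > 0, got {mean}")
    return np.asarray(signals, dtype=float) / mean


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_FTOL = 1e-12
_HILL_STARTS = (1.0, 0.5, 3.0)


def _free_names(constraints: FitConstraints) -> list[str]:
    names = []
    if not constraints.fix_top_one:
        names.append("top")
    if not constraints.fix_bottom_zero:
        names.append("bottom")
    names += ["log10_ic50", "hill"]
    return names


def _unpack(theta, constraints: FitConstraints) -> tuple[float, float, float, float]:
    it = iter(theta)
    top = 1.0 if constraints.fix_top_one else next(it)
    bottom = 0.0 if constraints.fix_bottom_zero else next(it)
    return top, bottom, next(it), next(it)


def _starting_points(conc, viab, constraints, start):
    if start is not None:
        theta0 = []
        if not constraints.fix_top_one:
            theta0.append(start.top)
        if not constraints.fix_bottom_zero:
            theta0.append(start.bottom)
        theta0 += [np.log10(start.ic50), start.hill]
        return [np.array(theta0, dtype=float)]

    top0 = 1.0 if constraints.fix_top_one else float(np.max(viab))
    bottom0 = 0.0 if constraints.fix_bottom_zero else float(min(np.min(viab), top0 - 1e-3))
    half = (top0 + bottom0) / 2.0
    levels = np.unique(conc[conc > 0])
    level_means = np.array(
        [float(np.mean(viab[conc == lv])) for lv in levels]
    )
    mid = levels[int(np.argmin(np.abs(level_means - half)))]
    points = []
    for hill0 in _HILL_STARTS:
        theta0 = []
        if not constraints.fix_top_one:
            theta0.append(top0)
        if not constraints.fix_bottom_zero:
            theta0.append(bottom0)
        theta0 += [np.log10(mid), hill0]
        points.append(np.array(theta0, dtype=float))
    return points


def fit_4pl(
    conc,
    viability,
    constraints: FitConstraints = FitConstraints(),
    start: FourPLParams | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit over individual replicate observations.

    Parameters
    ----------
    conc, viability
        Paired arrays; every replicate well is one observation (no
        pre-averaging).
    constraints
        Asymptote fixing; fixed parameters are honored exactly.
    start
        Optional explicit starting parameters. By default top/bottom start
        at the data extremes, IC50 at the tested concentration whose mean
        viability is nearest the half-range, and hill at 1, with two
        fallback hill starts (0.5 and 3) — the best resulting RSS wins.

    Non-convergence returns a fit with ``converged=False`` and diagnostics,
    never an exception; data that carry no dose-response information raise
    :class:`DegenerateDataError`.
    """
    conc = np.asarray(conc, dtype=float)
    viab = np.asarray(viability, dtype=float)
    if conc.shape != viab.shape or conc.ndim != 1:
        raise InputError("conc and viability must be equal-length 1-D arrays")
    keep = np.isfinite(conc) & np.isfinite(viab)
    conc, viab = conc[keep], viab[keep]
    if np.any(conc < 0):
        raise InputError("concentrations must be >= 0")
    n_distinct = np.unique(conc).size
    n_free = len(_free_names(constraints))
    if n_distinct < 4:
        raise InputError(
            f"need >= 4 distinct concentrations, got {n_distinct}"
        )
    if n_free > n_distinct:
        raise InputError(
            f"{n_free} free parameters exceed {n_distinct} distinct concentrations"
        )
    if np.ptp(viab) == 0:
        raise DegenerateDataError(
            "all viabilities identical: no dose-response information"
        )

    def residuals(theta):
        return _four_pl_raw(conc, *_unpack(theta, constraints)) - viab

    best = None
    for theta0 in _starting_points(conc, viab, constraints, start):
        try:
            res = optimize.least_squares(
                residuals, theta0, method="lm",
                ftol=_FTOL, xtol=_FTOL, gtol=_FTOL, max_nfev=20000,
            )
        except Exception:  # pragma: no cover - optimizer-internal failure
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:  # pragma: no cover
        params = FourPLParams(top=1.0, bottom=0.0, ic50=1.0, hill=1.0)
        return DoseResponseFit(
            params=params, constraints=constraints, converged=False,
            rss=float("inf"), n_obs=int(conc.size), n_free=n_free,
            message="optimizer failed from every start",
        )

    top, bottom, log10_ic50, hill = _unpack(best.x, constraints)
    params = FourPLParams(top=top, bottom=bottom, ic50=10.0**log10_ic50, hill=hill)
    rss = float(2.0 * best.cost)
    fit = DoseResponseFit(
        params=params,
        constraints=constraints,
        converged=bool(best.status > 0),
        rss=rss,
        n_obs=int(conc.size),
        n_free=n_free,
        message=best.message,
    )
    _attach_wald_ci(fit, best.jac, _free_names(constraints))
    return fit


def _attach_wald_ci(fit: DoseResponseFit, jac: np.ndarray, names: list[str]) -> None:
    df = fit.df_resid
    if df <= 0:
        fit.flags.add("ci_undefined")
        return
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * (fit.rss / df)
    except np.linalg.LinAlgError:
        fit.flags.add("ci_undefined")
        return
    idx = names.index("log10_ic50")
    var = cov[idx, idx]
    if not np.isfinite(var) or var < 0:
        fit.flags.add("ci_undefined")
        return
    fit.se_log10_ic50 = float(np.sqrt(var))
    fit.ic50_ci95 = ic50_confidence(fit)


def ic50_confidence(fit: DoseResponseFit, level: float = 0.95) -> tuple[float, float]:
    """Wald CI on log10(IC50), back-transformed to uM (asymmetric).

    Requires a converged fit with a defined standard error; the width
    shrinks to zero as the residual noise vanishes.
    """
    if not np.isfinite(fit.se_log10_ic50):
        return (float("nan"), float("nan"))
    tq = float(stats.t.ppf(0.5 + level / 2.0, fit.df_resid))
    log10_ic50 = np.log10(fit.params.ic50)
    half = tq * fit.se_log10_ic50
    return (10.0 ** (log10_ic50 - half), 10.0 ** (log10_ic50 + half))


# ---------------------------------------------------------------------------
# Fit classification
# ---------------------------------------------------------------------------

def replicate_spread(conc, viability) -> float:
    """Mean over concentration levels of the per-level sample SD of viability."""
    conc = np.asarray(conc, dtype=float)
    viab = np.asarray(viability, dtype=float)
    sds = []
    for lv in np.unique(conc):
        v = viab[conc == lv]
        if v.size >= 2:
            sds.append(float(np.std(v, ddof=1)))
    return float(np.mean(sds)) if sds else 0.0


def classify_fit(
    fit: DoseResponseFit,
    spread: float | None = None,
    spread_threshold: float = 0.15,
    observations: tuple[np.ndarray, np.ndarray] | None = None,
) -> set[str]:
    """Quality flags for a converged fit.

    * ``steep_slope``: hill > 3 — all-or-none concentration window.
    * ``incomplete_kill``: the bottom plateau leaves more than 5% of the
      top viability (max attainable fraction affected < 0.95).
    * ``high_variability``: mean per-concentration replicate SD above
      ``spread_threshold`` (default 0.15 viability units).
    * ``precipitation_suspect``: observed mean viability at the highest
      tested concentration rebounds > 0.2 above the fitted curve.
    """
    flags = set(fit.flags)
    p = fit.params
    if p.hill > 3.0:
        flags.add("steep_slope")
    if p.top > 0 and (p.top - p.bottom) / p.top < 0.95:
        flags.add("incomplete_kill")
    if spread is None and observations is not None:
        spread = replicate_spread(*observations)
    if spread is not None and spread > spread_threshold:
        flags.add("high_variability")
    if observations is not None:
        conc = np.asarray(observations[0], dtype=float)
        viab = np.asarray(observations[1], dtype=float)
        cmax = float(np.max(conc))
        observed_top_conc = float(np.mean(viab[conc == cmax]))
        predicted = float(four_pl(cmax, p))
        if observed_top_conc - predicted > 0.2:
            flags.add("precipitation_suspect")
    return flags


def absolute_ic50(params: FourPLParams) -> float:
    """Concentration where the fitted curve crosses viability = 0.5.

    NaN when 0.5 lies outside the (bottom, top) span — e.g. incomplete-kill
    curves that never reach 50% viability.
    """
    if not (params.bottom < 0.5 < params.top):
        return float("nan")
    x = (params.top - 0.5) / (0.5 - params.bottom)
    return float(params.ic50 * x ** (1.0 / params.hill))
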