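"""Dissociation constants from modulation-depth titrations.

A single-site 1:1 association with explicit ligand depletion (the exact
quadratic solution of the mass balance, not the excess-ligand hyperbola)
is fitted to modulation depth vs. total titrant concentration, per series
or globally with a shared K_D.  Confidence intervals come from the
profile likelihood of log10(K_D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .errors import DomainError, IllConditionedFitWarning

_LOGKD_LO, _LOGKD_HI = -14.0, -1.0
_CHI2_68, _CHI2_95 = 1.0, 3.8414588206941236  # chi2.ppf(.68..., .95, df=1)


@dataclass(frozen=True)
class TitrationPoint:
    """One titration sample: total ligand, observed depth and its SE."""

    ligand_total: float   # M
    delta: float
    delta_se: float

    def __post_init__(self):
        if self.ligand_total < 0:
            raise DomainError("ligand_total must be >= 0")
        if not 0.0 <= self.delta <= 1.0:
            raise DomainError("delta must be in [0, 1]")
        if self.delta_se <= 0:
            raise DomainError("delta_se must be positive")


@dataclass(frozen=True)
class TitrationSeries:
    """Fixed-protein titration: modulation depth vs. titrant concentration."""

    protein_total: float  # M
    points: Tuple[TitrationPoint, ...]
    label: str = ""

    def __post_init__(self):
        if self.protein_total <= 0:
            raise DomainError("protein_total must be positive")
        object.__setattr__(self, "points", tuple(self.points))

    def validate(self) -> None:
        """Enforce the design invariants (>= 4 points over >= 1 decade)."""
        if len(self.points) < 4:
            raise DomainError("a titration series needs at least 4 points")
        lig = [p.ligand_total for p in self.points if p.ligand_total > 0]
        if not lig or max(lig) / min(lig) < 10.0:
            raise DomainError("ligand concentrations must span >= 1 decade")

    @property
    def ligand(self) -> np.ndarray:
        return np.array([p.ligand_total for p in self.points])

    @property
    def delta(self) -> np.ndarray:
        return np.array([p.delta for p in self.points])

    @property
    def delta_se(self) -> np.ndarray:
        return np.array([p.delta_se for p in self.points])


@dataclass(frozen=True)
class BindingFit:
    """Result of an isotherm fit."""

    kd: float
    delta_max: float
    ci68_kd: Tuple[float, float]
    ci95_kd: Tuple[float, float]
    chi2_reduced: float
    n_points: int
    dof: int
    per_series_delta_max: Optional[Tuple[float, ...]] = None
    upper_bound_only: bool = False
    labels: Tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.kd <= 0:
            raise DomainError("kd must be positive")
        if not 0.0 < self.delta_max <= 1.0:
            raise DomainError("delta_max must be in (0, 1]")
        lo68, hi68 = self.ci68_kd
        lo95, hi95 = self.ci95_kd
        if not (lo95 <= lo68 <= self.kd <= hi68 <= hi95):
            raise DomainError("confidence intervals must nest around kd")


def fraction_bound(protein_total, ligand_total, kd):
    """Bound fraction of protein under 1:1 binding with ligand depletion.

    Exact solution of the quadratic mass balance, evaluated in the
    cancellation-free form f = 2 L / (b + sqrt(b^2 - 4 P L)) with
    b = P + L + K_D; the discriminant is expanded as
    (P - L)^2 + K_D^2 + 2 K_D (P + L) to stay non-negative in floating
    point.  Accepts scalars or arrays.
    """
    p = np.asarray(protein_total, dtype=float)
    l = np.asarray(ligand_total, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(p <= 0):
        raise DomainError("protein_total must be positive")
    if np.any(l < 0) or np.any(k < 0):
        raise DomainError("ligand_total and kd must be >= 0")
    b = p + l + k
    disc = (p - l) ** 2 + k ** 2 + 2.0 * k * (p + l)
    f = 2.0 * l / (b + np.sqrt(disc))
    out = np.clip(f, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def predict_delta(protein_total, ligand_totals, kd: float,
                  delta_max: float) -> np.ndarray:
    """Model depths: delta_max * fraction_bound(P_T, L_T, K_D)."""
    return delta_max * fraction_bound(protein_total, ligand_totals, kd)


def _profiled_chi2(series_list: Sequence[TitrationSeries],
                   share_delta_max: bool
                   ) -> Callable[[float], Tuple[float, List[float]]]:
    """chi2 as a function of log10(kd) with delta_max profiled out.

    For fixed kd the model is linear in delta_max, so the weighted
    optimum is closed-form (projected onto (0, 1]).
    """
    data = [(s.protein_total, s.ligand, s.delta, 1.0 / s.delta_se ** 2)
            for s in series_list]

    def chi2(log_kd: float) -> Tuple[float, List[float]]:
        kd = 10.0 ** log_kd
        fs = [fraction_bound(p, lig, kd) for p, lig, _, _ in data]
        if share_delta_max:
            num = sum(np.sum(w * d * f) for (_, _, d, w), f in zip(data, fs))
            den = sum(np.sum(w * f * f) for (_, _, _, w), f in zip(data, fs))
            dm = float(np.clip(num / den, 1e-12, 1.0)) if den > 0 else 1e-12
            dms = [dm] * len(data)
        else:
            dms = []
            for (_, _, d, w), f in zip(data, fs):
                den = np.sum(w * f * f)
                dm = float(np.clip(np.sum(w * d * f) / den, 1e-12, 1.0)) \
                    if den > 0 else 1e-12
                dms.append(dm)
        total = sum(np.sum(w * (d - dm * f) ** 2)
                    for (_, _, d, w), f, dm in zip(data, fs, dms))
        return float(total), dms

    return chi2


def _profile_interval(chi2: Callable[[float], Tuple[float, List[float]]],
                      log_kd_hat: float, chi2_min: float, threshold: float
                      ) -> Tuple[float, float]:
    """Profile-likelihood interval on kd at chi2_min + threshold."""

    def g(x):
        return chi2(x)[0] - chi2_min - threshold

    lo = 0.0
    x = log_kd_hat
    while x > _LOGKD_LO:
        x_prev, x = x, max(x - 0.5, _LOGKD_LO)
        if g(x) > 0:
            lo = 10.0 ** brentq(g, x, x_prev, xtol=1e-10)
            break
    hi = np.inf
    x = log_kd_hat
    while x < _LOGKD_HI:
        x_prev, x = x, min(x + 0.5, _LOGKD_HI)
        if g(x) > 0:
            hi = 10.0 ** brentq(g, x_prev, x, xtol=1e-10)
            break
    return lo, hi


def _fit(series_list: Sequence[TitrationSeries], share_delta_max: bool,
         scale_intervals: bool) -> BindingFit:
    for s in series_list:
        try:
            s.validate()
        except DomainError as exc:
            warnings.warn(f"series {s.label!r}: {exc}; fit may be "
                          "ill-conditioned", IllConditionedFitWarning,
                          stacklevel=3)
    chi2 = _profiled_chi2(series_list, share_delta_max)
    res = minimize_scalar(lambda x: chi2(x)[0], bounds=(_LOGKD_LO, _LOGKD_HI),
                          method="bounded",
                          options={"xatol": 1e-12, "maxiter": 500})
    log_kd_hat = float(res.x)
    chi2_min, dms = chi2(log_kd_hat)
    kd_hat = 10.0 ** log_kd_hat

    n_points = sum(len(s.points) for s in series_list)
    n_params = 1 + (1 if share_delta_max else len(series_list))
    dof = n_points - n_params
    chi2_red = chi2_min / dof if dof > 0 else np.nan

    # error-scaled profile thresholds (equivalent to rescaling delta_se by
    # sqrt(chi2_red)); keeps interval coverage honest when the quoted SEs
    # misestimate the true scatter
    scale = chi2_red if (scale_intervals and dof > 0 and chi2_red > 0) else 1.0
    ci68 = _profile_interval(chi2, log_kd_hat, chi2_min, _CHI2_68 * scale)
    ci95 = _profile_interval(chi2, log_kd_hat, chi2_min, _CHI2_95 * scale)
    ci68 = (max(ci68[0], ci95[0]), min(ci68[1], ci95[1]))

    upper_only = False
    fbs = np.concatenate([fraction_bound(s.protein_total, s.ligand, kd_hat)
                          for s in series_list])
    if np.all(fbs > 0.95):
        warnings.warn("all points saturated at the best fit; kd is an upper "
                      "bound only", IllConditionedFitWarning, stacklevel=3)
        upper_only = True
        ci68 = (0.0, ci68[1])
        ci95 = (0.0, ci95[1])

    return BindingFit(
        kd=kd_hat,
        delta_max=float(np.mean(dms)) if not share_delta_max else dms[0],
        ci68_kd=ci68,
        ci95_kd=ci95,
        chi2_reduced=float(chi2_red),
        n_points=n_points,
        dof=dof,
        per_series_delta_max=None if share_delta_max else tuple(dms),
        upper_bound_only=upper_only,
        labels=tuple(s.label for s in series_list),
    )


def fit_isotherm(series: TitrationSeries,
                 scale_intervals: bool = True) -> BindingFit:
    """Weighted isotherm fit of one series: (kd, delta_max) with profile CIs.

    Weights are 1/delta_se^2; kd is optimised on a log scale; 68% and 95%
    intervals use delta-chi2 thresholds of 1 and 3.84 (scaled by the
    reduced chi-square when ``scale_intervals``).
    """
    return _fit([series], share_delta_max=True,
                scale_intervals=scale_intervals)


def global_fit(series_list: Sequence[TitrationSeries],
               share_delta_max: bool = False,
               scale_intervals: bool = True) -> BindingFit:
    """Shared-kd fit across several series.

    ``share_delta_max`` ties the saturating depth across series;
    otherwise each series keeps its own (reported in
    ``per_series_delta_max``).
    """
    if len(series_list) < 2:
        raise DomainError("global_fit needs at least 2 series")
    return _fit(list(series_list), share_delta_max=share_delta_max,
                scale_intervals=scale_intervals)


def fraction_bound_root(protein_total: float, ligand_total: float,
                        kd: float) -> float:
    """Independent mass-balance oracle: solve for the complex concentration
    by bracketed root finding of (P - C)(L - C) = K_D C on [0, min(P, L)].

    Slow scalar reference used to cross-check :func:`fraction_bound`.
    """
    if ligand_total == 0:
        return 0.0

    def g(c):
        return (protein_total - c) * (ligand_total - c) - kd * c

    hi = min(protein_total, ligand_total)
    if g(hi) >= 0:
        return hi / protein_total
    c = brentq(g, 0.0, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    return c / protein_total
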