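"""Equilibrium binding analysis for EMSA titrations.

The binding of a protein P to a labelled DNA probe D is modelled as a
single reversible reaction P + D <-> PD with association rate k_a and
dissociation rate k_d. At the probe concentrations used (a few nM) the
free protein is depleted by binding, so the bound fraction is the root of
the quadratic PD^2 - (P_tot + D_tot + K_d) PD + P_tot D_tot = 0 rather
than a simple hyperbola. Fits are parametrized by k_d, baseline and
asymptote with k_a an arbitrary constant; K_d = k_d / k_a is independent
of that choice of time unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from muklock.errors import ConvergenceError, DataError


@dataclass(frozen=True)
class TitrationSeries:
    """Protein concentrations (nM), total probe DNA (nM) and responses."""

    protein_concs: np.ndarray
    dna_total: float
    responses: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.protein_concs, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "protein_concs", p)
        object.__setattr__(self, "responses", r)
        if p.ndim != 1 or p.size != r.size:
            raise DataError("protein_concs and responses must match in length")
        if np.any(p < 0):
            raise DataError("concentrations must be >= 0")
        if self.dna_total <= 0:
            raise DataError("dna_total must be positive")
        if not np.all(np.isfinite(r)):
            raise DataError("responses must be finite")


@dataclass(frozen=True)
class BindingFit:
    k_d: float
    k_a: float
    K_d: float
    baseline: float
    asymptote: float
    rss: float
    inverted: bool = False


def equilibrium_bound_fraction(p_tot, d_tot: float, K_d: float):
    """Bound fraction of DNA at equilibrium with ligand depletion.

    Solves the mass-action quadratic for the complex concentration PD and
    returns PD / d_tot, the physical root lying in [0, min(p_tot, d_tot)].
    Accepts scalar or array ``p_tot``.
    """
    p = np.asarray(p_tot, dtype=float)
    if np.any(p < 0):
        raise DataError("p_tot must be >= 0")
    if d_tot <= 0:
        raise DataError("d_tot must be positive")
    if K_d <= 0:
        raise DataError("K_d must be positive")
    b = p + d_tot + K_d
    disc = b * b - 4.0 * p * d_tot
    pd = (b - np.sqrt(np.maximum(disc, 0.0))) / 2.0
    frac = np.clip(pd / d_tot, 0.0, 1.0)
    return float(frac) if np.isscalar(p_tot) else frac


def simulate_rate_equation(
    p_tot: float,
    d_tot: float,
    k_a: float,
    k_d: float,
    t_end: float,
    steps: int = 1000,
) -> float:
    """Bound fraction from relaxing the rate equation to steady state.

    Integrates d[PD]/dt = k_a (P_tot - PD)(D_tot - PD) - k_d PD from
    PD(0) = 0. Raises :class:`ConvergenceError` when the trajectory has
    not settled at ``t_end`` (relative change per step above 1e-8).
    """
    if min(k_a, k_d) <= 0:
        raise DataError("rates must be positive")
    if d_tot <= 0:
        raise DataError("d_tot must be positive")
    if t_end <= 0:
        raise DataError("t_end must be positive")

    def rhs(_t, y):
        pd = y[0]
        return [k_a * (p_tot - pd) * (d_tot - pd) - k_d * pd]

    sol = solve_ivp(rhs, (0.0, t_end), [0.0], method="LSODA",
                    rtol=1e-11, atol=1e-13 * d_tot, dense_output=False)
    if not sol.success:
        raise ConvergenceError(f"ODE integration failed: {sol.message}")
    pd_end = float(sol.y[0, -1])
    dt = t_end / steps
    rate = abs(rhs(t_end, [pd_end])[0])
    rel_change = rate * dt / max(abs(pd_end), 1e-30)
    if rel_change > 1e-8:
        raise ConvergenceError(
            f"not converged at t_end={t_end}: relative change per step "
            f"{rel_change:.2e} > 1e-8; increase t_end"
        )
    return pd_end / d_tot


def fit_titration(
    series: TitrationSeries,
    k_a_const: float = 1.0,
    use_depletion: bool = True,
) -> BindingFit:
    """Least-squares fit of a titration to the equilibrium binding curve.

    Model: response_i = baseline + (asymptote - baseline) *
    f_eq(p_i; K_d = k_d / k_a_const). Optimization runs multi-start over
    K_d decades spanning the concentration range; the reported K_d is
    invariant under rescaling ``k_a_const`` (which only fixes the
    arbitrary time unit of k_d). ``use_depletion=False`` substitutes the
    no-depletion hyperbola p / (p + K_d).
    """
    if k_a_const <= 0:
        raise DataError("k_a_const must be positive")
    p = series.protein_concs
    y = series.responses
    if p.size < 5:
        raise DataError("need at least 5 titration points")
    pos = p[p > 0]
    if pos.size < 2 or pos.max() / pos.min() < 10:
        raise DataError("titration must span at least a 10-fold range")
    if np.var(y) < 1e-20:
        raise DataError("flat response: nothing to fit")

    def model(log10_kd, baseline, asymptote):
        K_d = 10.0 ** log10_kd
        if use_depletion:
            f = equilibrium_bound_fraction(p, series.dna_total, K_d)
        else:
            f = p / (p + K_d)
        return baseline + (asymptote - baseline) * f

    def residuals(theta):
        return model(*theta) - y

    y_lo, y_hi = float(y.min()), float(y.max())
    scale = float(pos.max())
    best = None
    for log_kd0 in np.log10(scale) + np.arange(-3.0, 3.1, 1.0):
        try:
            res = least_squares(residuals, x0=[log_kd0, y_lo, y_hi],
                                method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, res)
    if best is None:
        raise ConvergenceError("no optimizer start converged")
    rss, res = best
    log_kd, baseline, asymptote = (float(v) for v in res.x)
    K_d = 10.0 ** log_kd
    return BindingFit(k_d=K_d * k_a_const, k_a=k_a_const, K_d=K_d,
                      baseline=baseline, asymptote=asymptote, rss=rss,
                      inverted=asymptote < baseline)
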