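"""Gel densitometry and Bayesian quantification of band efficiencies.

Lane profiles are 1-D intensity traces. The background is estimated by a
moving median (robust to bands narrower than half the window), band areas
are trapezoidal integrals of the background-subtracted signal, and
replicate efficiencies get equal-tailed credible intervals under a normal
likelihood with a uniform prior on the mean and a 1/sigma^2 prior on the
standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, ndimage

from muklock.errors import DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LaneProfile:
    """A densitometry trace: strictly increasing pixel positions + intensities."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if pos.ndim != 1 or pos.size < 3 or pos.size != inten.size:
            raise DataError("profile needs >= 3 matching positions/intensities")
        if not np.all(np.diff(pos) > 0):
            raise DataError("positions must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            raise DataError("intensities must be finite")

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class BandWindow:
    """A labelled pixel interval enclosing one band."""

    label: str
    start_px: float
    end_px: float

    def __post_init__(self) -> None:
        if not self.start_px < self.end_px:
            raise DataError(f"band {self.label}: start_px must be < end_px")


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate efficiency measurements x_i."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise DataError("need at least 2 replicate values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class PosteriorSpec:
    """Prior box and grid resolution for the posterior of the mean.

    The sigma prior is fixed at density proportional to 1/sigma^2,
    truncated to [sigma_min, sigma_max] when marginalized on a grid
    (defaults: 1e-4 and 10 times the data range).
    """

    mu_prior_lo: float = 0.0
    mu_prior_hi: float = 1.0
    mu_grid: int = 2001
    sigma_grid: int = 400
    sigma_min: float | None = None
    sigma_max: float | None = None

    def __post_init__(self) -> None:
        if not self.mu_prior_lo < self.mu_prior_hi:
            raise DataError("mu prior bounds must satisfy lo < hi")
        if self.mu_grid < 200 or self.sigma_grid < 200:
            raise DataError("grids must have >= 200 points")


@dataclass(frozen=True)
class CredibleInterval:
    level: float
    lo: float
    hi: float
    posterior_mean: float
    posterior_sd: float = float("nan")
    replicate_sd: float = float("nan")


# ---------------------------------------------------------------------------
# densitometry


def moving_median_background(profile: LaneProfile, window_px: int) -> np.ndarray:
    """Centered running median of the lane with reflected edges.

    Even windows are rounded up to the next odd size (logged); the window
    must not exceed the profile length.
    """
    n = len(profile)
    if window_px < 3:
        raise DataError("median window must be >= 3 px")
    if window_px > n:
        raise DataError("median window exceeds profile length")
    if window_px % 2 == 0:
        log.info("moving_median_background: even window %d rounded up to %d",
                 window_px, window_px + 1)
        window_px += 1
        if window_px > n:
            window_px -= 2
    return ndimage.median_filter(profile.intensities, size=window_px,
                                 mode="reflect")


def quantify_bands(
    profile: LaneProfile,
    windows: Sequence[BandWindow],
    window_px: int | None = None,
) -> dict[str, float]:
    """Background-subtracted band fractions.

    Per band, the trapezoidal integral of ``max(signal - background, 0)``
    over the window; fractions are normalized to sum to 1. The default
    moving-median window is three times the widest declared band window.
    """
    if len(windows) == 0:
        raise DataError("at least one band window is required")
    labels = [w.label for w in windows]
    if len(set(labels)) != len(labels):
        raise DataError("band labels must be unique")
    sw = sorted(windows, key=lambda w: w.start_px)
    for a, b in zip(sw[:-1], sw[1:]):
        if b.start_px < a.end_px:
            raise DataError(f"band windows {a.label} and {b.label} overlap")

    pos = profile.positions
    dx = np.median(np.diff(pos))
    if window_px is None:
        widest = max(w.end_px - w.start_px for w in windows)
        window_px = max(3, int(round(3 * widest / dx)))
        window_px = min(window_px, len(profile))
    background = moving_median_background(profile, window_px)
    signal = np.clip(profile.intensities - background, 0.0, None)

    areas = {}
    for w in windows:
        if w.start_px < pos[0] or w.end_px > pos[-1]:
            raise DataError(f"band {w.label} lies outside the profile range")
        mask = (pos >= w.start_px) & (pos <= w.end_px)
        if mask.sum() < 2:
            raise DataError(f"band {w.label} covers fewer than 2 samples")
        areas[w.label] = float(np.trapezoid(signal[mask], pos[mask]))

    total = sum(areas.values())
    if total <= 0:
        raise DataError("empty lane: all band areas are zero")
    return {label: a / total for label, a in areas.items()}


# ---------------------------------------------------------------------------
# Bayesian credible intervals


def _mu_posterior_analytic(data: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Unnormalized marginal posterior of mu with sigma integrated out.

    With likelihood N(x_i | mu, sigma) and prior density 1/sigma^2 on
    sigma > 0, the sigma integral is analytic:
    p(mu | x) proportional to (sum_i (x_i - mu)^2) ** (-(n+1)/2).
    """
    n = data.size
    rss = np.sum((data[None, :] - mu[:, None]) ** 2, axis=1)
    # log-space for numerical stability at large n
    logp = -0.5 * (n + 1) * np.log(rss)
    return np.exp(logp - logp.max())


def _mu_posterior_grid(data: np.ndarray, mu: np.ndarray,
                       spec: PosteriorSpec) -> np.ndarray:
    """Marginal posterior of mu by numeric sigma integration on a log grid."""
    n = data.size
    rng = float(np.ptp(data))
    s_min = spec.sigma_min if spec.sigma_min is not None else 1e-4 * rng
    s_max = spec.sigma_max if spec.sigma_max is not None else 10.0 * rng
    sigma = np.geomspace(s_min, s_max, spec.sigma_grid)
    rss = np.sum((data[None, :] - mu[:, None]) ** 2, axis=1)
    # log joint: -n log sigma - rss/(2 sigma^2) - 2 log sigma
    logj = (-(n + 2) * np.log(sigma)[None, :]
            - rss[:, None] / (2.0 * sigma[None, :] ** 2))
    logj -= logj.max()
    return np.trapezoid(np.exp(logj), sigma, axis=1)


def posterior_mu_ci(
    data: ReplicateSet,
    spec: PosteriorSpec | None = None,
    level: float = 0.95,
    method: str = "analytic",
) -> CredibleInterval:
    """Equal-tailed credible interval for the mean of replicate measurements.

    Normal likelihood, uniform prior on mu over the spec's box, 1/sigma^2
    prior on sigma. ``method='analytic'`` uses the closed-form sigma
    marginal; ``method='grid'`` integrates sigma numerically on a
    truncated log grid (used as a cross-check).
    """
    if spec is None:
        spec = PosteriorSpec()
    x = data.values
    if np.ptp(x) == 0:
        raise DataError(
            "zero sample variance: sigma cannot be marginalized; widen the "
            "sigma grid floor or provide variable replicates"
        )
    if not 0 < level < 1:
        raise DataError("level must be in (0, 1)")

    mu = np.linspace(spec.mu_prior_lo, spec.mu_prior_hi, spec.mu_grid)
    if method == "analytic":
        dens = _mu_posterior_analytic(x, mu)
    elif method == "grid":
        dens = _mu_posterior_grid(x, mu, spec)
    else:
        raise DataError(f"unknown method {method!r}")

    norm = np.trapezoid(dens, mu)
    if norm <= 0 or not np.isfinite(norm):
        raise DataError("posterior normalization failed; widen the mu prior")
    dens = dens / norm
    cdf = integrate.cumulative_trapezoid(dens, mu, initial=0.0)
    cdf /= cdf[-1]
    lo = float(np.interp((1 - level) / 2, cdf, mu))
    hi = float(np.interp((1 + level) / 2, cdf, mu))
    mean = float(np.trapezoid(mu * dens, mu))
    post_sd = float(np.sqrt(max(np.trapezoid(mu ** 2 * dens, mu) - mean ** 2, 0.0)))
    return CredibleInterval(level=level, lo=lo, hi=hi, posterior_mean=mean,
                            posterior_sd=post_sd,
                            replicate_sd=float(np.std(x, ddof=1)))


def relative_signal_ci(
    sample: ReplicateSet,
    reference: ReplicateSet,
    level: float = 0.95,
    method: str = "analytic",
) -> CredibleInterval:
    """Credible interval for a signal relative to a reference condition.

    Per-replicate ratios ``sample_i / mean(reference)`` are the data; the
    prior on the mean is uniform over +-10 times the ratio sample mean
    (so the posterior may extend below zero for weak signals). Constant
    ratios (zero variance) yield a degenerate point interval.
    """
    ref_mean = float(np.mean(reference.values))
    if ref_mean <= 0:
        raise DataError("reference mean must be positive")
    ratios = sample.values / ref_mean
    xbar = float(np.mean(ratios))
    if np.ptp(ratios) == 0:
        v = float(ratios[0])
        return CredibleInterval(level=level, lo=v, hi=v, posterior_mean=v,
                                posterior_sd=0.0, replicate_sd=0.0)
    half = 10.0 * abs(xbar)
    if half == 0:
        half = 10.0 * float(np.std(ratios, ddof=1))
    spec = PosteriorSpec(mu_prior_lo=-half, mu_prior_hi=half)
    return posterior_mu_ci(ReplicateSet(ratios), spec, level, method=method)
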