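"""Bayesian additive mixed model of net carbonate production against live
coral cover, and its inversion to per-habitat cover thresholds.

Model (one row per transect):

    G = beta0 + f(LCC) + Habitat_h + a_country + error

where f is a penalized cubic O'Sullivan spline with five interior knots,
Habitat uses treatment contrasts, the country intercept a is a zero-mean
normal random effect, and the residual error is normal.  The O'Sullivan
construction re-expresses the penalized spline as a mixed model: a fixed
linear part [1, LCC] plus independent random-effect columns Z obtained by
spectrally transforming the B-spline basis with the integrated-squared-
second-derivative penalty, so the whole model is a Gaussian linear mixed
model and is sampled with a blocked Gibbs sampler (conjugate normal draws
for all coefficients, slice updates for the three standard deviations,
which carry half-normal priors).

The quantity of interest is the *inverse problem*: for each habitat, the
smallest live coral cover at which the expected production curve (country
effect at its prior mean of zero) crosses from negative to non-negative.
Summarizing that crossing over posterior draws gives the threshold's median
and 95% credible interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "SplineBasis", "build_spline_basis", "GammDesign", "Priors",
    "PosteriorDraws", "ThresholdPosterior", "fit_production_gamm",
    "estimate_threshold", "estimate_all_thresholds",
]


# ---------------------------------------------------------------------------
# O'Sullivan spline basis
# ---------------------------------------------------------------------------

@dataclass
class SplineBasis:
    """Cubic O'Sullivan basis: B-spline knots plus the spectral transform
    mapping the B-spline design to penalized mixed-model columns."""

    knots: np.ndarray          # full cubic knot vector
    transform: np.ndarray      # (n_bspline, n_penalized) U_+ D_+^{-1/2}
    penalty: np.ndarray        # raw penalty on B-spline coefficients
    boundary: tuple[float, float]

    @property
    def n_columns(self) -> int:
        return self.transform.shape[1]

    def bspline_design(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), *self.boundary)
        nb = len(self.knots) - 4
        cols = [BSpline(self.knots, np.eye(nb)[i], 3)(x) for i in range(nb)]
        return np.column_stack(cols)

    def design(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Fixed linear part [1, x] and penalized columns Z at ``x``."""
        x = np.asarray(x, dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        Z = self.bspline_design(x) @ self.transform
        return X, Z


def build_spline_basis(x, n_knots: int = 5,
                       boundary: tuple[float, float] | None = None) -> SplineBasis:
    """O'Sullivan basis with ``n_knots`` interior knots at covariate
    quantiles.

    Construction: cubic B-spline basis B on [boundary], penalty
    Omega = integral B''(s) B''(s)^T ds (exact, 2-point Gauss-Legendre per
    inter-knot interval since B'' is piecewise linear), eigendecomposition
    Omega = U D U'; the columns with positive eigenvalues (n_knots + 2 of
    them; the nullspace of dimension 2 is the linear part) become
    Z = B U_+ D_+^{-1/2}, whose coefficients act as iid random effects.
    """
    x = np.asarray(x, dtype=float)
    distinct = np.unique(x)
    if distinct.size < n_knots + 4:
        raise ValueError(
            f"need at least {n_knots + 4} distinct covariate values for "
            f"{n_knots} interior knots, got {distinct.size}"
        )
    if boundary is None:
        boundary = (float(distinct.min()), float(distinct.max()))
    lo, hi = boundary
    interior = np.quantile(distinct, np.linspace(0, 1, n_knots + 2)[1:-1])
    interior = interior[(interior > lo) & (interior < hi)]
    kts = np.concatenate([[lo] * 4, interior, [hi] * 4])
    nb = len(kts) - 4

    # exact integral of products of piecewise-linear second derivatives
    breaks = np.unique(kts)
    gauss_x = np.array([-1.0, 1.0]) / math.sqrt(3.0)
    omega = np.zeros((nb, nb))
    d2 = [BSpline(kts, np.eye(nb)[i], 3).derivative(2) for i in range(nb)]
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        for gx in gauss_x:
            pt = mid + half * gx
            v = np.array([f(pt) for f in d2])
            omega += half * np.outer(v, v)

    evals, evecs = np.linalg.eigh(omega)
    tol = evals.max() * 1e-10
    pos = evals > tol
    if pos.sum() != nb - 2:
        raise RuntimeError(
            f"penalty nullspace has dimension {nb - pos.sum()}, expected 2"
        )
    transform = evecs[:, pos] / np.sqrt(evals[pos])
    return SplineBasis(kts, transform, omega, (lo, hi))


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass
class GammDesign:
    """Assembled design for the production-vs-cover model."""

    y: np.ndarray
    lcc: np.ndarray
    habitat_levels: list[str]
    habitat_idx: np.ndarray
    country_levels: list[str]
    country_idx: np.ndarray
    basis: SplineBasis
    X: np.ndarray              # full design [1, lcc, hab dummies, Z, country]
    slices: dict = field(default_factory=dict)
    habitat_country: dict = field(default_factory=dict)  # modal country per habitat

    @classmethod
    def from_table(cls, table: pd.DataFrame, n_knots: int = 5,
                   boundary: tuple[float, float] = (0.0, 100.0),
                   reference_habitat: str | None = None) -> "GammDesign":
        """Build from a table with columns ``lcc`` (percent), ``net``
        (kg m^-2 y^-1), ``habitat`` and ``country``; one row per transect.

        Habitat uses treatment contrasts; the reference level defaults to the
        first sorted level.  Interior spline knots sit at LCC quantiles,
        boundary knots at the full 0-100% range so fitted curves can be
        evaluated across the whole cover grid.
        """
        for col in ("lcc", "net", "habitat", "country"):
            if col not in table.columns:
                raise ValueError(f"threshold table missing column {col!r}")
        hab_levels = sorted(table["habitat"].unique())
        if reference_habitat is not None:
            if reference_habitat not in hab_levels:
                raise ValueError(f"unknown reference habitat {reference_habitat!r}")
            hab_levels = [reference_habitat] + [h for h in hab_levels
                                                if h != reference_habitat]
        ctry_levels = sorted(table["country"].unique())
        hab_idx = np.array([hab_levels.index(h) for h in table["habitat"]])
        ctry_idx = np.array([ctry_levels.index(c) for c in table["country"]])
        lcc = table["lcc"].to_numpy(dtype=float)
        y = table["net"].to_numpy(dtype=float)

        basis = build_spline_basis(lcc, n_knots=n_knots, boundary=boundary)
        Xlin, Z = basis.design(lcc)
        H = np.zeros((len(y), len(hab_levels) - 1))
        for j in range(1, len(hab_levels)):
            H[:, j - 1] = hab_idx == j
        A = np.zeros((len(y), len(ctry_levels)))
        for j in range(len(ctry_levels)):
            A[:, j] = ctry_idx == j

        X = np.column_stack([Xlin, H, Z, A])
        n_fix = 2 + H.shape[1]
        slices = {
            "fixed": slice(0, n_fix),
            "spline": slice(n_fix, n_fix + Z.shape[1]),
            "country": slice(n_fix + Z.shape[1], X.shape[1]),
        }
        hab_country = {
            h: table.loc[table["habitat"] == h, "country"].mode().iloc[0]
            for h in hab_levels
        }
        return cls(y, lcc, hab_levels, hab_idx, ctry_levels, ctry_idx,
                   basis, X, slices, hab_country)


@dataclass(frozen=True)
class Priors:
    """Diffuse priors: Normal(0, fixed_sd) on fixed effects, half-normal
    scales on the residual, spline and country standard deviations."""

    fixed_sd: float = 100.0
    sigma_scale: float = 10.0
    sigma_u_scale: float = 10.0
    sigma_a_scale: float = 10.0


# ---------------------------------------------------------------------------
# Blocked Gibbs sampler
# ---------------------------------------------------------------------------

def _slice_sample_log_sigma(logp, u0: float, rng: np.random.Generator,
                            w: float = 1.0, max_steps: int = 50) -> float:
    """One univariate slice-sampling update (Neal 2003, stepping out)."""
    ly = logp(u0) + math.log(rng.random())
    left = u0 - w * rng.random()
    right = left + w
    for _ in range(max_steps):
        if logp(left) < ly:
            break
        left -= w
    for _ in range(max_steps):
        if logp(right) < ly:
            break
        right += w
    for _ in range(max_steps):
        u = left + (right - left) * rng.random()
        if logp(u) >= ly:
            return u
        if u < u0:
            left = u
        else:
            right = u
    return u0


@dataclass
class PosteriorDraws:
    """MCMC output: coefficient and variance draws plus diagnostics."""

    theta: np.ndarray          # (chains, draws, p)
    sigma_e: np.ndarray        # (chains, draws)
    sigma_u: np.ndarray
    sigma_a: np.ndarray
    design: GammDesign
    rhat_max: float = math.nan
    ess_min: float = math.nan

    @property
    def converged(self) -> bool:
        return bool(self.rhat_max <= 1.05)

    def flat_theta(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1])

    def _diagnose(self) -> None:
        import arviz as az
        data = {"theta": self.theta, "sigma_e": self.sigma_e[..., None],
                "sigma_u": self.sigma_u[..., None],
                "sigma_a": self.sigma_a[..., None]}
        rhats, esss = [], []
        for arr in data.values():
            r = az.rhat(az.convert_to_dataset(arr))
            e = az.ess(az.convert_to_dataset(arr))
            rhats.append(float(r["x"].max()))
            esss.append(float(e["x"].min()))
        self.rhat_max = max(rhats)
        self.ess_min = min(esss)


def fit_production_gamm(design: GammDesign, priors: Priors = Priors(),
                        chains: int = 4, draws: int = 2000,
                        warmup: int = 1000, seed: int = 0,
                        strict: bool = False) -> PosteriorDraws:
    """Blocked Gibbs sampler for the production GAMM.

    All coefficients (fixed effects, spline random effects, country
    intercepts) are drawn jointly from their conditional multivariate normal;
    the three standard deviations are updated by slice sampling on the log
    scale under half-normal priors.  With ``strict=True`` a run with
    max R-hat > 1.05 raises instead of returning.
    """
    X, y = design.X, design.y
    n, p = X.shape
    sl = design.slices
    n_fix = sl["fixed"].stop
    q_u = sl["spline"].stop - sl["spline"].start
    q_a = sl["country"].stop - sl["country"].start

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    theta_out = np.empty((chains, draws, p))
    se_out = np.empty((chains, draws))
    su_out = np.empty((chains, draws))
    sa_out = np.empty((chains, draws))

    hn = lambda s, scale: -0.5 * (s / scale) ** 2  # noqa: E731

    def _chol_with_jitter(q):
        # intercept and country columns are collinear; when sigma_e is tiny
        # the prior precision no longer regularizes Q in float64, so retry
        # with a relative ridge (affects the unidentified direction only)
        jitter = 0.0
        scale = float(np.mean(np.diag(q)))
        for _ in range(12):
            try:
                return np.linalg.cholesky(q + jitter * np.eye(p))
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-14 * scale)
        raise np.linalg.LinAlgError("conditional precision not positive definite")

    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, c]))
        sigma_e = float(np.std(y)) or 1.0
        sigma_u = 1.0
        sigma_a = 1.0
        theta = np.zeros(p)
        for it in range(warmup + draws):
            prior_prec = np.empty(p)
            prior_prec[sl["fixed"]] = priors.fixed_sd ** -2
            prior_prec[sl["spline"]] = sigma_u ** -2
            prior_prec[sl["country"]] = sigma_a ** -2
            Q = XtX / sigma_e ** 2 + np.diag(prior_prec)
            L = _chol_with_jitter(Q)
            mean = np.linalg.solve(L.T, np.linalg.solve(L, Xty / sigma_e ** 2))
            z = rng.standard_normal(p)
            theta = mean + np.linalg.solve(L.T, z)

            ssr = yty - 2.0 * theta @ Xty + theta @ XtX @ theta
            ssr = max(ssr, 1e-300)

            def lp_e(u, ssr=ssr):
                s = math.exp(u)
                return -n * u - ssr / (2 * s * s) + hn(s, priors.sigma_scale) + u

            sigma_e = math.exp(_slice_sample_log_sigma(lp_e, math.log(sigma_e), rng))

            ss_u = float(theta[sl["spline"]] @ theta[sl["spline"]])

            def lp_u(u, ss=ss_u):
                s = math.exp(u)
                return -q_u * u - ss / (2 * s * s) + hn(s, priors.sigma_u_scale) + u

            sigma_u = math.exp(_slice_sample_log_sigma(lp_u, math.log(sigma_u), rng))

            ss_a = float(theta[sl["country"]] @ theta[sl["country"]])

            def lp_a(u, ss=ss_a):
                s = math.exp(u)
                return -q_a * u - ss / (2 * s * s) + hn(s, priors.sigma_a_scale) + u

            sigma_a = math.exp(_slice_sample_log_sigma(lp_a, math.log(sigma_a), rng))

            if it >= warmup:
                k = it - warmup
                theta_out[c, k] = theta
                se_out[c, k] = sigma_e
                su_out[c, k] = sigma_u
                sa_out[c, k] = sigma_a

    post = PosteriorDraws(theta_out, se_out, su_out, sa_out, design)
    post._diagnose()
    if strict and not post.converged:
        raise RuntimeError(
            f"MCMC did not converge: max R-hat = {post.rhat_max:.3f} > 1.05"
        )
    return post


# ---------------------------------------------------------------------------
# Threshold (inverse problem)
# ---------------------------------------------------------------------------

@dataclass
class ThresholdPosterior:
    habitat: str
    draws: np.ndarray          # threshold per posterior draw; NaN = no crossing
    median: float
    ci_low: float
    ci_high: float
    flag: str = "ok"           # 'ok' | 'multimodal' | 'no finite threshold'


def _expected_curves(post: PosteriorDraws, habitat: str,
                     lcc_grid: np.ndarray,
                     country: str = "own") -> np.ndarray:
    """Expected production curve per posterior draw on the cover grid.

    Habitats are nested within country (each habitat level is surveyed in
    exactly one country), so only the curve evaluated at the habitat's own
    country intercept is identified by the data; that is the default.
    ``country='typical'`` instead sets the (recentered, zero-mean) country
    deviation to zero — harmlessly for prediction but with posterior spread
    inflated by the unidentified country contrast; a country name evaluates
    that country's curve.
    """
    design = post.design
    try:
        h = design.habitat_levels.index(habitat)
    except ValueError:
        raise ValueError(
            f"unknown habitat {habitat!r}; levels: {design.habitat_levels}"
        ) from None
    Xlin, Z = design.basis.design(lcc_grid)
    n_hab = len(design.habitat_levels) - 1
    H = np.zeros((len(lcc_grid), n_hab))
    if h > 0:
        H[:, h - 1] = 1.0
    theta = post.flat_theta()
    a = theta[:, design.slices["country"]]
    if country == "own":
        country = design.habitat_country.get(habitat)
    if country in (None, "typical"):
        offset = a.mean(axis=1)
    else:
        offset = a[:, design.country_levels.index(country)]
    grid_X = np.column_stack([Xlin, H, Z])
    core = theta[:, : grid_X.shape[1]]
    return grid_X @ core.T + offset[None, :]  # (n_grid, n_draws)


def estimate_threshold(post: PosteriorDraws, habitat: str,
                       lcc_grid: np.ndarray | None = None,
                       country: str = "own") -> ThresholdPosterior:
    """Per-habitat live-coral-cover threshold: for each posterior draw, the
    smallest cover at which the expected curve crosses from negative to
    non-negative (linear interpolation within the bracketing grid step).

    Conventions: a curve that is already non-negative at 0% cover has
    threshold 0; a draw whose curve never becomes non-negative has no
    threshold (NaN), and the result is flagged when more than half the draws
    have none.  Draws with several upward crossings flag multimodality; the
    first crossing is reported.
    """
    if lcc_grid is None:
        lcc_grid = np.arange(0.0, 100.0 + 1e-9, 0.1)
    lcc_grid = np.asarray(lcc_grid, dtype=float)
    curves = _expected_curves(post, habitat, lcc_grid, country)  # (g, d)
    neg = curves < 0.0
    nd = curves.shape[1]
    thresholds = np.full(nd, np.nan)
    up = neg[:-1] & ~neg[1:]                               # upward crossings
    n_up = up.sum(axis=0)
    multimodal = bool((n_up > 1).any())

    start_nonneg = ~neg[0]
    thresholds[start_nonneg] = 0.0
    todo = ~start_nonneg & (n_up > 0)
    if todo.any():
        first = np.argmax(up[:, todo], axis=0)             # index k: cross in (k, k+1]
        g0 = curves[first, todo]
        g1 = curves[first + 1, todo]
        x0 = lcc_grid[first]
        x1 = lcc_grid[first + 1]
        frac = np.where(g1 != g0, -g0 / (g1 - g0), 0.0)
        thresholds[todo] = x0 + frac * (x1 - x0)

    finite = thresholds[np.isfinite(thresholds)]
    if finite.size < 0.5 * nd:
        return ThresholdPosterior(habitat, thresholds, math.nan, math.nan,
                                  math.nan, flag="no finite threshold")
    med = float(np.median(finite))
    lo, hi = np.percentile(finite, [2.5, 97.5])
    flag = "multimodal" if multimodal else "ok"
    return ThresholdPosterior(habitat, thresholds, med, float(lo), float(hi), flag)


def estimate_all_thresholds(post: PosteriorDraws,
                            lcc_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Threshold summary table over all habitat levels."""
    rows = []
    for hab in post.design.habitat_levels:
        t = estimate_threshold(post, hab, lcc_grid)
        rows.append({"habitat": hab, "median": t.median, "ci_low": t.ci_low,
                     "ci_high": t.ci_high, "rhat_max": post.rhat_max,
                     "flag": t.flag})
    return pd.DataFrame(rows)
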