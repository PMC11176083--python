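"""Maximum-likelihood fitness inference from cohort VAF distributions.

For a recurrently mutated site with selection coefficient s and site mutation
rate mu, the expected number of detectable clones in an individual of age t is

    lambda(t) = Ntau * mu * [E1(f_min/phi(t)) - E1(0.5/phi(t))]

(E1 the exponential integral, phi the VAF scale from
:mod:`clonalselect.simulate`).  Under Poisson clone arrivals, a non-carrier
contributes -lambda to the site log-likelihood and a carrier with largest
observed clone at VAF f contributes log rho(f) - lambda.  The MLE over
(log s, log mu) is found by quasi-Newton optimisation with a multi-start grid;
95% CIs come from the chi-square profile likelihood.  Sites whose s CI is wider
than 0.2 are flagged for exclusion.  Ntau (HSC count x years between symmetric
divisions) is only weakly identified and is calibrated once on the cohort's
most common site, then held fixed for every other site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .simulate import clone_density, expected_detectable, phi

__all__ = [
    "SiteObservations",
    "SiteFitnessFit",
    "site_log_likelihood",
    "fit_site",
    "calibrate_ntau",
    "rank_sites",
]

_CHI2_95 = float(stats.chi2.ppf(0.95, df=1))
_CI_WIDTH_EXCLUDE = 0.2


@dataclass
class SiteObservations:
    """Cohort observations for one recurrently mutated site."""

    site_id: tuple           # (gene_id, cds_pos, ref, alt)
    ages: np.ndarray         # years, one per individual
    carrier: np.ndarray      # bool, one per individual
    vaf: np.ndarray          # max-clone VAF for carriers, NaN otherwise
    f_min: float             # detection limit

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.carrier = np.asarray(self.carrier, dtype=bool)
        self.vaf = np.asarray(self.vaf, dtype=float)
        if not (self.ages.shape == self.carrier.shape == self.vaf.shape):
            raise ValueError("ages, carrier and vaf must have one entry per individual")
        f = self.vaf[self.carrier]
        if np.any(f <= self.f_min) or np.any(f > 0.5):
            raise ValueError("carrier VAFs must lie in (f_min, 0.5]")
        # non-carrier ages aggregated on a 0.1-year grid: their likelihood term
        # is smooth in age, so binning changes it negligibly but makes each
        # evaluation O(bins) instead of O(cohort)
        binned = np.round(self.ages[~self.carrier] / 0.1) * 0.1
        self._nc_ages, self._nc_counts = np.unique(binned, return_counts=True)

    @property
    def n_carriers(self) -> int:
        return int(self.carrier.sum())


@dataclass
class SiteFitnessFit:
    """Per-site MLE of (s, mu) with 95% profile CIs."""

    site_id: tuple
    s: float
    s_ci: tuple[float, float]
    mu: float
    mu_ci: tuple[float, float]
    log_likelihood: float
    converged: bool
    excluded: bool           # s CI wider than 0.2 (or boundary/degenerate fit)
    n_carriers: int = 0


def site_log_likelihood(obs: SiteObservations, s: float, mu: float, ntau: float) -> float:
    """Log-likelihood of (s, mu) for one site given Ntau.

    Clones arrive as a Poisson process with intensity rho; the observable is
    the largest detectable clone per individual.  A non-carrier therefore
    contributes -lambda(t) (no clone above f_min) and a carrier with largest
    clone at VAF f contributes log rho(f) - Lambda(f, 0.5), the exact Poisson
    thinning term for "no clone larger than f" (it reduces to -lambda at
    f = f_min and makes the per-individual density integrate to one).
    """
    if s < 0 or mu < 0:
        raise ValueError("s and mu must be nonnegative")
    if mu == 0:
        return -np.inf if obs.n_carriers else 0.0
    lam = expected_detectable(s, mu, obs._nc_ages, ntau, obs.f_min)
    ll = -float(np.dot(np.atleast_1d(lam), obs._nc_counts))
    if obs.n_carriers:
        f = obs.vaf[obs.carrier]
        t = obs.ages[obs.carrier]
        rho = clone_density(f, s, mu, t, ntau)
        if np.any(rho <= 0):
            return -np.inf
        ph = phi(s, t, ntau)  # Lambda(f, 0.5): no clone larger than f
        lam_above = ntau * mu * (special.exp1(f / ph) - special.exp1(0.5 / ph))
        ll += float(np.sum(np.log(rho) - lam_above))
    return ll


_GRID_LOG_S = np.log(np.geomspace(0.02, 0.5, 9))
_GRID_LOG_MU = np.log(np.geomspace(1e-8, 1e-4, 9))


def _optimise(obs: SiteObservations, ntau: float):
    """MLE over (log s, log mu): coarse grid scan then Nelder-Mead polish."""

    def nll(x):
        s, mu = np.exp(x)
        if s > 5.0 or mu > 1e-2:
            return 1e12
        ll = site_log_likelihood(obs, s, mu, ntau)
        return -ll if np.isfinite(ll) else 1e12

    grid = [(ls, lm) for ls in _GRID_LOG_S for lm in _GRID_LOG_MU]
    x0 = min(grid, key=nll)
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
    s, mu = np.exp(res.x)
    return float(s), float(mu), -float(res.fun), bool(res.success)


def _profile_ci_s(obs: SiteObservations, ntau: float, s_hat: float, mu_hat: float, ll_max: float):
    """95% profile CI for s, profiling out mu (1-D Brent) at each fixed s."""

    def prof_ll(s: float) -> float:
        res = optimize.minimize_scalar(
            lambda lm: -site_log_likelihood(obs, s, float(np.exp(lm)), ntau),
            bounds=(np.log(mu_hat) - 4.0, np.log(mu_hat) + 4.0),
            method="bounded", options={"xatol": 1e-6},
        )
        return -float(res.fun)

    def dev(s: float) -> float:
        return 2.0 * (ll_max - prof_ll(s)) - _CHI2_95

    lo_b = s_hat
    while lo_b > 1e-4 and dev(lo_b / 2) < 0:
        lo_b /= 2
    lo = 0.0 if lo_b <= 1e-4 else optimize.brentq(dev, lo_b / 2, s_hat, xtol=1e-4)
    hi_b = s_hat
    while hi_b < 5.0 and dev(hi_b * 1.6) < 0:
        hi_b *= 1.6
    hi = np.inf if hi_b >= 5.0 else optimize.brentq(dev, s_hat, hi_b * 1.6, xtol=1e-4)
    return float(lo), float(hi)


def _wald_ci_logmu(obs, ntau, s_hat, mu_hat, ll_max):
    """Cheap profile-free CI for mu via a log-scale quadratic approximation."""
    h = 0.1
    f = lambda lm: site_log_likelihood(obs, s_hat, float(np.exp(lm)), ntau)
    lm = np.log(mu_hat)
    d2 = (f(lm + h) - 2 * ll_max + f(lm - h)) / h**2
    if not np.isfinite(d2) or d2 >= 0:
        return 0.0, np.inf
    se = np.sqrt(-1.0 / d2)
    return float(np.exp(lm - 1.96 * se)), float(np.exp(lm + 1.96 * se))


def fit_site(obs: SiteObservations, ntau: float, ci: bool = True) -> SiteFitnessFit:
    """MLE of (s, mu) for one site; profile CI on s and the exclusion flag."""
    if obs.n_carriers == 0:
        # boundary: mu -> 0 maximises the likelihood; nothing to estimate
        return SiteFitnessFit(obs.site_id, np.nan, (0.0, np.inf), 0.0, (0.0, np.inf),
                              0.0, converged=False, excluded=True, n_carriers=0)
    s, mu, ll, ok = _optimise(obs, ntau)
    if ci:
        s_ci = _profile_ci_s(obs, ntau, s, mu, ll)
        mu_ci = _wald_ci_logmu(obs, ntau, s, mu, ll)
    else:
        s_ci = (np.nan, np.nan)
        mu_ci = (np.nan, np.nan)
    excluded = (not ok) or (ci and (not np.isfinite(s_ci[1]) or (s_ci[1] - s_ci[0]) > _CI_WIDTH_EXCLUDE))
    return SiteFitnessFit(obs.site_id, s, s_ci, mu, mu_ci, ll, converged=ok,
                          excluded=bool(excluded), n_carriers=obs.n_carriers)


def calibrate_ntau(obs: SiteObservations, ntau_grid=None) -> tuple[float, SiteFitnessFit]:
    """Joint MLE over (Ntau, s, mu) on the cohort's most common site.

    Ntau is weakly identified (a near-ridge with mu); the maximiser over a log
    grid of Ntau (default 10^4..10^7) is returned together with the site fit at
    that Ntau.  Raises when the profile over Ntau is flat (too few carriers).
    """
    if obs.n_carriers < 5:
        raise ValueError(
            "Ntau calibration needs a well-populated site (>=5 carriers); "
            "use a larger cohort or the most recurrent site"
        )
    if ntau_grid is None:
        ntau_grid = np.geomspace(1e4, 1e7, 13)
    fits = []
    for nt in ntau_grid:
        s, mu, ll, ok = _optimise(obs, float(nt))
        fits.append((ll, float(nt), s, mu, ok))
    lls = np.array([f[0] for f in fits])
    if lls.max() - lls.min() < 0.5:
        raise ValueError("likelihood is flat in Ntau: calibration failed; fix Ntau externally")
    ll, nt, s, mu, ok = fits[int(np.argmax(lls))]
    fit = fit_site(obs, nt)
    return nt, fit


def rank_sites(records: pd.DataFrame, k: int = 150) -> list[tuple]:
    """Top-``k`` sites by cohort occurrence count, ties broken lexicographically."""
    if records.empty:
        return []
    key_cols = ["gene_id", "cds_pos", "ref", "alt"]
    counts = (
        records.groupby(key_cols, sort=False).size().reset_index(name="n")
        .sort_values(["n"] + key_cols, ascending=[False, True, True, True, True], kind="mergesort")
    )
    return [tuple(r) for r in counts[key_cols].head(k).itertuples(index=False)]


def observations_from_table(
    records: pd.DataFrame, individuals: pd.DataFrame, site: tuple, f_min: float
) -> SiteObservations:
    """Assemble :class:`SiteObservations` for one site from cohort tables.

    One entry per cohort individual; the largest VAF per individual at the site
    is used, and carriers at or below ``f_min`` (undetectable under the model)
    are treated as non-carriers.
    """
    gene_id, cds_pos, ref, alt = site
    sel = records[
        (records["gene_id"] == gene_id) & (records["cds_pos"] == cds_pos)
        & (records["ref"] == ref) & (records["alt"] == alt) & (records["vaf"] <= 0.5)
    ]
    vaf_by = sel.groupby("individual_id")["vaf"].max()
    ids = individuals["individual_id"].to_numpy()
    ages = individuals["age"].to_numpy(dtype=float)
    vaf = individuals["individual_id"].map(vaf_by).to_numpy(dtype=float)
    vaf[vaf <= f_min] = np.nan
    carrier = ~np.isnan(vaf)
    return SiteObservations((gene_id, cds_pos, ref, alt), ages, carrier, vaf, f_min)
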