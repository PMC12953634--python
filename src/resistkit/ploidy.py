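"""Allele-frequency-spectrum ploidy inference.

Heterozygous variants on a region of total copy number ``m`` have allele
fractions clustered at the lattice ``k/m`` (k = 1..m-1): a diploid region
shows one peak at 0.5, a triploid region peaks near 1/3 and 2/3, a tetraploid
region near 1/4, 1/2 and 3/4. This module builds per-chromosome AF spectra
from a heterozygous-site panel and classifies ploidy by fitting, for each
candidate ``m``, a mixture of (m-1) truncated normal components with means
FIXED at k/m, a shared free standard deviation, free mixture weights, plus a
Uniform(0,1) noise component. Candidates are compared by BIC.

The mixture fit follows the statsmodels Model/Results convention:
``AlleleFrequencyMixture(af_values, m).fit()`` returns an
:class:`AFMixtureResults` with estimates, log-likelihood, BIC and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm

from .io import VariantTable

__all__ = [
    "AFSpectrum",
    "AlleleFrequencyMixture",
    "AFMixtureResults",
    "PloidyCall",
    "expected_af_peaks",
    "filter_het_panel",
    "compute_af",
    "fit_af_mixture",
    "select_ploidy",
]


def expected_af_peaks(m: int) -> list[float]:
    """Expected heterozygous AF peak positions {k/m : k = 1..m-1}, ascending.

    m=3 gives (0.33..., 0.66...); m=4 gives (0.25, 0.5, 0.75).
    """
    if m < 2:
        raise ValueError("ploidy m must be >= 2")
    return [k / m for k in range(1, m)]


@dataclass
class AFSpectrum:
    """Allele fractions of one chromosome, for one sample."""

    chrom: str
    af_values: np.ndarray
    n_sites_used: int
    n_dropped_dp0: int = 0
    n_boundary: int = 0  # AF exactly 0 or 1, excluded from the spectrum
    subsample_seed: int | None = None


def filter_het_panel(
    panel: VariantTable,
    af_low: float = 0.25,
    af_high: float = 0.75,
    min_sample_frac: float = 0.5,
) -> np.ndarray:
    """Indices of panel sites heterozygous in enough samples.

    A site is kept when its AF lies in [af_low, af_high] in at least
    ``min_sample_frac`` (inclusive boundary) of the samples with nonzero
    depth at that site.
    """
    if not panel.sample_names:
        raise ValueError("panel has no samples")
    n = panel.n_sites
    het = np.zeros(n, dtype=float)
    covered = np.zeros(n, dtype=float)
    for s in panel.sample_names:
        _, alt_c, dp_c = panel.sample_columns(s)
        dp = panel.data[dp_c].to_numpy(dtype=float)
        alt = panel.data[alt_c].to_numpy(dtype=float)
        has = dp > 0
        af = np.divide(alt, dp, out=np.zeros(n), where=has)
        het += has & (af >= af_low) & (af <= af_high)
        covered += has
    frac = np.divide(het, covered, out=np.zeros(n), where=covered > 0)
    return np.flatnonzero((covered > 0) & (frac >= min_sample_frac))


def compute_af(table: VariantTable, sample: str) -> dict[str, AFSpectrum]:
    """Per-chromosome AF spectra for one sample.

    AF = ad_alt / dp. Sites with dp = 0 are dropped (tallied); AF exactly 0
    or 1 is excluded from the spectrum (the interior peak model cannot place
    them) but remains available to fixation logic elsewhere.
    """
    _, alt_c, dp_c = table.sample_columns(sample)
    out: dict[str, AFSpectrum] = {}
    for chrom, grp in table.data.groupby("chrom", sort=False):
        dp = grp[dp_c].to_numpy(dtype=float)
        alt = grp[alt_c].to_numpy(dtype=float)
        has = dp > 0
        af = alt[has] / dp[has]
        interior = (af > 0.0) & (af < 1.0)
        out[str(chrom)] = AFSpectrum(
            chrom=str(chrom),
            af_values=af[interior],
            n_sites_used=int(interior.sum()),
            n_dropped_dp0=int((~has).sum()),
            n_boundary=int((~interior).sum()),
        )
    return out


def _trunc_logpdf(x: np.ndarray, mu: np.ndarray, sigma: float) -> np.ndarray:
    """log density of Normal(mu, sigma) renormalised to (0, 1).

    x: (n,), mu: (m,), returns (n, m).
    """
    z = (x[:, None] - mu[None, :]) / sigma
    log_norm = norm.logpdf(z) - np.log(sigma)
    log_mass = np.log(
        np.clip(norm.cdf((1.0 - mu) / sigma) - norm.cdf(-mu / sigma), 1e-300, None)
    )
    return log_norm - log_mass[None, :]


@dataclass
class AFMixtureResults:
    """Fitted fixed-peak mixture for one candidate ploidy."""

    m: int
    component_means: np.ndarray
    component_weights: np.ndarray
    sigma: float
    uniform_weight: float
    loglik: float
    bic: float
    n_obs: int
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"Fixed-peak AF mixture (candidate ploidy m={self.m})",
            f"  n obs          {self.n_obs}",
            f"  log-likelihood {self.loglik:.3f}",
            f"  BIC            {self.bic:.3f}",
            f"  sigma          {self.sigma:.4f}",
            f"  uniform weight {self.uniform_weight:.4f}",
            f"  converged      {self.converged} ({self.n_iter} iterations)",
            "  peak   weight",
        ]
        for mu, w in zip(self.component_means, self.component_weights):
            lines.append(f"  {mu:.3f}  {w:.4f}")
        return "\n".join(lines)


class AlleleFrequencyMixture:
    """Fixed-peak truncated-normal + uniform mixture of an AF spectrum.

    Parameters
    ----------
    af_values
        Allele fractions strictly inside (0, 1).
    m
        Candidate total copy number; component means are fixed at k/m.

    The (m-1) normal components share one standard deviation; component
    weights and the Uniform(0,1) noise weight are free (summing to one).
    Fitting is by EM; the shared sigma M-step has no closed form under
    truncation and is performed by a bounded 1-D maximisation of the expected
    complete-data log-likelihood (an ECM step), which keeps the observed
    log-likelihood monotone across iterations.
    """

    # component SD must stay on the scale of an AF peak (binomial width at
    # realistic depths); far broader "peaks" would impersonate the uniform
    # noise component and destroy identifiability
    SIGMA_BOUNDS = (1e-3, 0.15)

    def __init__(self, af_values: np.ndarray, m: int):
        x = np.asarray(af_values, dtype=float)
        if m < 2:
            raise ValueError("candidate ploidy m must be >= 2")
        if np.any((x <= 0) | (x >= 1)):
            raise ValueError("AF values must lie strictly inside (0, 1)")
        if x.size < 50:
            raise ValueError(
                f"only {x.size} AF values; need >= 50 — consider pooling chromosomes"
            )
        self.x = x
        self.m = m
        self.means = np.array(expected_af_peaks(m))

    # number of free parameters: (m-1) component weights + shared sigma
    # (the uniform weight is implied by normalisation)
    @property
    def n_params(self) -> int:
        return (self.m - 1) + 1

    def _loglik(self, weights: np.ndarray, u_weight: float, sigma: float) -> tuple[float, np.ndarray]:
        log_comp = _trunc_logpdf(self.x, self.means, sigma) + np.log(
            np.clip(weights, 1e-300, None)
        )
        # uniform(0,1) has log density 0
        log_all = np.concatenate(
            [log_comp, np.full((self.x.size, 1), np.log(max(u_weight, 1e-300)))],
            axis=1,
        )
        row_ll = logsumexp(log_all, axis=1)
        resp = np.exp(log_all - row_ll[:, None])
        return float(row_ll.sum()), resp

    def fit(self, max_iter: int = 300, tol: float = 1e-6, seed: int = 0) -> AFMixtureResults:
        rng = np.random.default_rng(seed)
        k = self.m - 1
        weights = np.full(k, 0.9 / k) * (1.0 + 0.01 * rng.standard_normal(k))
        weights = np.abs(weights)
        u_weight = 0.1
        total = weights.sum() + u_weight
        weights, u_weight = weights / total, u_weight / total
        sigma = 0.05

        ll_old = -np.inf
        path = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            ll, resp = self._loglik(weights, u_weight, sigma)
            path.append(ll)
            if ll < ll_old - 1e-8:
                raise AssertionError("EM log-likelihood decreased")
            if abs(ll - ll_old) < tol:
                converged = True
                break
            ll_old = ll
            nk = resp.sum(axis=0)
            weights = nk[:k] / self.x.size
            u_weight = nk[k] / self.x.size
            # ECM step for sigma: maximise Q(sigma) given responsibilities.
            sse_k = np.array(
                [float(resp[:, j] @ (self.x - self.means[j]) ** 2) for j in range(k)]
            )
            n_k = nk[:k]

            def neg_q(s: float) -> float:
                mass = np.clip(
                    norm.cdf((1.0 - self.means) / s) - norm.cdf(-self.means / s),
                    1e-300,
                    None,
                )
                q = np.sum(-n_k * (np.log(s) + np.log(mass)) - sse_k / (2.0 * s * s))
                return -q

            res = minimize_scalar(neg_q, bounds=self.SIGMA_BOUNDS, method="bounded")
            # ECM guarantee: only move sigma if Brent actually improved Q
            # (its bounded tolerance can lose microscopically at the bounds)
            if neg_q(float(res.x)) <= neg_q(sigma):
                sigma = float(res.x)

        ll, _ = self._loglik(weights, u_weight, sigma)
        bic = -2.0 * ll + self.n_params * np.log(self.x.size)
        return AFMixtureResults(
            m=self.m,
            component_means=self.means,
            component_weights=weights,
            sigma=sigma,
            uniform_weight=u_weight,
            loglik=ll,
            bic=bic,
            n_obs=self.x.size,
            n_iter=it,
            converged=converged,
            loglik_path=np.array(path),
        )


def fit_af_mixture(
    spectrum: AFSpectrum,
    m: int,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> AFMixtureResults:
    """Fit the fixed-peak mixture for one candidate ploidy."""
    return AlleleFrequencyMixture(spectrum.af_values, m).fit(
        max_iter=max_iter, tol=tol, seed=seed
    )


@dataclass
class PloidyCall:
    """Per-chromosome ploidy classification for one sample."""

    sample: str
    best_m: dict[str, int]
    bic_by_m: dict[str, dict[int, float]]
    delta_bic: dict[str, float]  # margin to the runner-up candidate
    n_sites: dict[str, int]

    def summary(self) -> str:
        lines = [f"Ploidy call for sample {self.sample}", "  chrom  best_m  dBIC    n"]
        for chrom, m in self.best_m.items():
            lines.append(
                f"  {chrom:<6} {m:<7} {self.delta_bic[chrom]:<7.1f} {self.n_sites[chrom]}"
            )
        return "\n".join(lines)


def select_ploidy(
    table: VariantTable,
    sample: str,
    candidates: tuple[int, ...] = (2, 3, 4),
    n_subsample: int = 10_000,
    seed: int = 0,
) -> PloidyCall:
    """Classify per-chromosome ploidy by minimum BIC over candidates.

    Up to ``n_subsample`` AF values per chromosome are drawn without
    replacement (seeded, reproducible); each candidate m is fitted and the
    smallest-BIC model wins, ties broken toward the smaller m.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    spectra = compute_af(table, sample)
    best: dict[str, int] = {}
    bics: dict[str, dict[int, float]] = {}
    delta: dict[str, float] = {}
    n_sites: dict[str, int] = {}
    for chrom, spectrum in spectra.items():
        af = spectrum.af_values
        if af.size > n_subsample:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
            af = rng.choice(af, size=n_subsample, replace=False)
        sub = AFSpectrum(chrom, af, af.size, subsample_seed=seed)
        table_bic: dict[int, float] = {}
        for m in sorted(candidates):
            table_bic[m] = fit_af_mixture(sub, m, seed=seed).bic
        order = sorted(table_bic.items(), key=lambda kv: (kv[1], kv[0]))
        best[chrom] = order[0][0]
        bics[chrom] = table_bic
        delta[chrom] = (order[1][1] - order[0][1]) if len(order) > 1 else np.inf
        n_sites[chrom] = af.size
    return PloidyCall(sample, best, bics, delta, n_sites)
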