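"""Differential phospho-peptide statistics.

The core statistic is the SAM-style s0-penalised two-sample t:

    t_s0 = (mean_B - mean_A) / (se_pooled + s0)

where ``se_pooled`` is the classical pooled-variance standard error of the
mean difference and ``s0`` (default 0.1) damps features whose tiny variance
would otherwise produce huge t values from trivial differences. Significance
is controlled by permutation-based FDR: group labels are permuted (all
distinct relabellings enumerated when few, seeded sampling otherwise), and
for a cutoff c the FDR is estimated as the mean permuted exceedance count of
|t_s0| >= c divided by the observed exceedance count. The significance
cutoff is the smallest observed |t_s0| whose (isotonically cleaned) FDR
estimate is at or below the target (default 0.05).

``PhosphoDifferential(matrix, groups, s0=0.1).fit(...)`` returns a
:class:`DifferentialResults` with per-feature statistics and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "zscore_rows",
    "s0_t_statistic",
    "PhosphoDifferential",
    "DifferentialResults",
    "permutation_fdr",
    "differential_counts",
]


def zscore_rows(matrix: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, np.ndarray]:
    """Row-wise z-scoring of log2 intensities (sample-SD convention).

    Missing entries are ignored in the mean/SD and preserved in the output.
    Rows with fewer than 2 non-missing values or zero SD are left unscaled
    and flagged; returns ``(scaled, flagged)``.
    """
    values = matrix.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(values, axis=1, ddof=ddof, keepdims=True)
    n_valid = np.sum(~np.isnan(values), axis=1)
    flagged = (n_valid < 2) | (sd[:, 0] == 0) | np.isnan(sd[:, 0])
    scaled = np.where(flagged[:, None], values, (values - mean) / np.where(sd == 0, 1, sd))
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns), flagged


def _group_stats(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature n, mean, sum of squared deviations within one group."""
    sub = values[:, mask]
    valid = ~np.isnan(sub)
    n = valid.sum(axis=1)
    total = np.nansum(sub, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / n
    ss = np.nansum((sub - mean[:, None]) ** 2, axis=1)
    return n, mean, ss


def _t_s0_matrix(values: np.ndarray, mask_b: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised t_s0 and mean difference for one group labelling.

    ``mask_b`` marks group-B columns; features with < 2 valid values in
    either group come back NaN.
    """
    n_a, mean_a, ss_a = _group_stats(values, ~mask_b)
    n_b, mean_b, ss_b = _group_stats(values, mask_b)
    ok = (n_a >= 2) & (n_b >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_var = (ss_a + ss_b) / (n_a + n_b - 2)
        se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
        diff = mean_b - mean_a
        t = diff / (se + s0)
    t = np.where(ok, t, np.nan)
    diff = np.where(ok, diff, np.nan)
    return t, diff


def s0_t_statistic(
    group_a: np.ndarray, group_b: np.ndarray, s0: float = 0.1
) -> float:
    """s0-penalised pooled two-sample t for one feature.

    With s0 = 0 this is exactly the classical Student t statistic; with a
    zero-variance feature the +s0 denominator keeps it finite.
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    values = np.concatenate([a, b])[None, :]
    mask_b = np.concatenate([np.zeros(a.size, bool), np.ones(b.size, bool)])
    t, _ = _t_s0_matrix(values, mask_b, s0)
    return float(t[0])


def _distinct_relabellings(
    sample_names: list[str], n_b: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean masks of group-B membership, excluding the observed labelling.

    In a balanced design a relabelling and its complement produce identical
    |t_s0| and are collapsed. Candidates are enumerated and ordered by a
    canonical key built from sorted sample names, so the seeded subset drawn
    when the distinct set exceeds ``n_permutations`` does not depend on
    column order — the significant set is then exactly symmetric under a
    group-label swap of a balanced design.
    """
    n_samples = len(sample_names)
    pos = {name: i for i, name in enumerate(sample_names)}
    observed = frozenset(sample_names[n_samples - n_b :])
    seen: dict[tuple[str, ...], frozenset[str]] = {}
    for combo in combinations(sorted(sample_names), n_b):
        key = frozenset(combo)
        comp = frozenset(set(sample_names) - key)
        if key == observed or comp == observed:
            continue
        canon = min(
            (tuple(sorted(key)), tuple(sorted(comp))) if len(comp) == n_b
            else (tuple(sorted(key)),)
        )
        if canon not in seen:
            seen[canon] = key
        if len(seen) > 50_000:  # enumeration guard for large designs
            break
    ordered = [seen[k] for k in sorted(seen)]
    if len(ordered) > n_permutations:
        idx = rng.choice(len(ordered), size=n_permutations, replace=False)
        ordered = [ordered[i] for i in sorted(idx)]
    masks = np.zeros((len(ordered), n_samples), dtype=bool)
    for r, key in enumerate(ordered):
        for name in key:
            masks[r, pos[name]] = True
    return masks


@dataclass
class DifferentialResults:
    """Per-feature differential statistics at a permutation-FDR threshold."""

    table: pd.DataFrame  # diff, t_s0, significant, side
    s0: float
    fdr_target: float
    n_permutations_used: int
    seed: int
    cutoff: float
    n_excluded: int

    @property
    def n_up(self) -> int:
        return int((self.table["significant"] & (self.table["diff"] > 0)).sum())

    @property
    def n_down(self) -> int:
        return int((self.table["significant"] & (self.table["diff"] < 0)).sum())

    def summary(self) -> str:
        return "\n".join(
            [
                "Differential phospho analysis (s0-penalised t, permutation FDR)",
                f"  features tested        {len(self.table)}",
                f"  excluded (<2/group)    {self.n_excluded}",
                f"  s0                     {self.s0}",
                f"  FDR target             {self.fdr_target}",
                f"  permutations used      {self.n_permutations_used}",
                f"  |t_s0| cutoff          {self.cutoff if np.isfinite(self.cutoff) else 'none reached'}",
                f"  significant up (B)     {self.n_up}",
                f"  significant down (A)   {self.n_down}",
            ]
        )


class PhosphoDifferential:
    """Two-group differential model over a feature x sample intensity matrix.

    Parameters
    ----------
    matrix
        log2 intensities, features in rows, samples in columns; NaN allowed.
    groups
        Series mapping sample -> group label; exactly two labels. The second
        label in sorted order is "group B"; positive differences mean higher
        in B.
    s0
        Variance-damping constant of the t denominator.

    Features with fewer than two valid values in either group are excluded
    before permutation (keeping the permutation null exchangeable) and
    tallied in the results.
    """

    def __init__(self, matrix: pd.DataFrame, groups: pd.Series, s0: float = 0.1):
        groups = groups.reindex(matrix.columns)
        if groups.isna().any():
            raise ValueError("every sample column needs a group label")
        labels = sorted(groups.unique())
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        order = list(groups.index[groups == labels[0]]) + list(
            groups.index[groups == labels[1]]
        )
        self.matrix = matrix[order]
        self.labels = labels
        self.n_a = int((groups == labels[0]).sum())
        self.n_b = int((groups == labels[1]).sum())
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("each group needs >= 2 samples")
        self.s0 = float(s0)

    def fit(
        self,
        fdr_target: float = 0.05,
        n_permutations: int = 250,
        seed: int = 0,
    ) -> DifferentialResults:
        if self.n_a + self.n_b < 4:
            raise ValueError("need at least 4 samples in total")
        if n_permutations < 25:
            raise ValueError("n_permutations must be >= 25")
        values = self.matrix.to_numpy(dtype=float)
        mask_b = np.zeros(values.shape[1], dtype=bool)
        mask_b[self.n_a :] = True

        t_obs_all, diff_all = _t_s0_matrix(values, mask_b, self.s0)
        testable = ~np.isnan(t_obs_all)
        n_excluded = int((~testable).sum())
        t_obs = t_obs_all[testable]
        vals = values[testable]

        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 8]))
        perms = _distinct_relabellings(
            list(self.matrix.columns), self.n_b, n_permutations, rng
        )
        abs_obs = np.abs(t_obs)
        perm_abs = np.empty((len(perms), len(t_obs)))
        for i, pm in enumerate(perms):
            t_p, _ = _t_s0_matrix(vals, pm, self.s0)
            perm_abs[i] = np.abs(t_p)

        # FDR(c) = mean permuted #{|t| >= c} / observed #{|t| >= c}
        order = np.argsort(abs_obs)[::-1]
        cutoffs = abs_obs[order]
        obs_count = np.arange(1, len(cutoffs) + 1, dtype=float)
        sorted_perm = np.sort(perm_abs.ravel())
        perm_ge = len(sorted_perm) - np.searchsorted(sorted_perm, cutoffs, side="left")
        perm_count = perm_ge / max(len(perms), 1)
        fdr = np.clip(perm_count / obs_count, 0.0, 1.0)
        # isotonic clean-up: FDR monotone non-increasing in the cutoff
        fdr = np.minimum.accumulate(fdr[::-1])[::-1]

        passing = np.flatnonzero(fdr <= fdr_target)
        if passing.size:
            cutoff = float(cutoffs[passing[-1]])
            significant_testable = abs_obs >= cutoff
        else:
            cutoff = float("inf")
            significant_testable = np.zeros(len(t_obs), dtype=bool)

        significant = np.zeros(len(t_obs_all), dtype=bool)
        significant[testable] = significant_testable
        side = np.where(
            significant, np.where(diff_all > 0, "up", "down"), ""
        )
        table = pd.DataFrame(
            {
                "diff": diff_all,
                "t_s0": t_obs_all,
                "significant": significant,
                "side": side,
            },
            index=self.matrix.index,
        )
        return DifferentialResults(
            table=table,
            s0=self.s0,
            fdr_target=fdr_target,
            n_permutations_used=len(perms),
            seed=seed,
            cutoff=cutoff,
            n_excluded=n_excluded,
        )


def permutation_fdr(
    matrix: pd.DataFrame,
    groups: pd.Series,
    s0: float = 0.1,
    fdr_target: float = 0.05,
    n_permutations: int = 250,
    seed: int = 0,
) -> DifferentialResults:
    """Functional wrapper around :class:`PhosphoDifferential`."""
    return PhosphoDifferential(matrix, groups, s0=s0).fit(
        fdr_target=fdr_target, n_permutations=n_permutations, seed=seed
    )


def differential_counts(result: DifferentialResults) -> tuple[int, int]:
    """(n significant up in group B, n significant down)."""
    return result.n_up, result.n_down
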