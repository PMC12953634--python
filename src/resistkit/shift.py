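"""Parental-vs-resistant variant frequency-shift testing.

Each variant's ref/alt read counts in the parental and resistant samples form
a 2x2 table tested with a two-sided Fisher exact test; variants whose alt
allele vanished in the resistant sample are additionally tested with a
zero-read binomial model (the probability of drawing zero alt reads at the
observed depth if the parental allele fraction had persisted). The two
p-value families are Benjamini-Hochberg adjusted separately — they answer
different questions at different thresholds (Fisher q < 0.05 for frequency
change, binomial q < 0.1 for loss) — and variants are classified into
gained / lost / changed / fixed / stable categories with per-sample tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import VariantTable

__all__ = [
    "ShiftSummary",
    "fisher_shift_test",
    "loss_binomial_test",
    "adjust_fdr",
    "classify_variants",
    "fixation_fraction",
]

#: order in which mutually exclusive categories are assigned
CATEGORY_PRECEDENCE = ("lost", "gained", "fixed", "changed", "stable")


#: relative tie tolerance when summing tables "as or less probable" — the
#: conventional guard against floating-point near-ties at the observed mass
_FISHER_TIE_REL = 1e-7


def fisher_shift_test(
    ad_parental: tuple[int, int], ad_resistant: tuple[int, int]
) -> float:
    """Two-sided Fisher exact p for [[ref_p, alt_p], [ref_r, alt_r]].

    The two-sided p sums, over the hypergeometric support at the observed
    margins, the probability of every table as or less probable than the
    observed one (computed in log-gamma space; vectorised over the support,
    so a call costs tens of microseconds even at high depth). Returns NaN
    for the degenerate case where one sample has zero total depth (no
    information about a shift).
    """
    rp, ap = ad_parental
    rr, ar = ad_resistant
    if min(rp, ap, rr, ar) < 0:
        raise ValueError("negative read count")
    if rp + ap == 0 or rr + ar == 0:
        return math.nan
    n = rp + ap + rr + ar
    r1 = rp + ap  # parental row total
    c1 = rp + rr  # ref column total
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    a = np.arange(lo, hi + 1)
    log_pmf = (
        gammaln(r1 + 1) - gammaln(a + 1) - gammaln(r1 - a + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - a + 1) - gammaln(n - r1 - c1 + a + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(log_pmf)
    p_obs = pmf[rp - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_REL)].sum()))


def loss_binomial_test(expected_af: float, dp_resistant: int) -> float:
    """P(zero alt reads | depth, persisting allele) = (1 - f)^D.

    Evaluated in log space for numerical stability at high depth. A depth of
    zero returns 1 (no evidence of loss).
    """
    if not 0.0 < expected_af <= 1.0:
        raise ValueError("expected_af must be in (0, 1]")
    if dp_resistant < 0:
        raise ValueError("negative depth")
    if dp_resistant == 0:
        return 1.0
    if expected_af == 1.0:
        return 0.0
    return float(math.exp(dp_resistant * math.log1p(-expected_af)))


def adjust_fdr(pvals: np.ndarray | list[float], method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs are excluded from the ranking and returned as NaN.
    """
    if method != "BH":
        raise ValueError(f"unsupported method {method!r}")
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class ShiftSummary:
    """Per-resistant-sample tallies mirroring the variant-table report."""

    sample_pair: tuple[str, str]
    total: int
    counts: dict[str, int]
    n_novel: int
    n_novel_fixed: int
    fraction_fixed_of_novel: float
    params: dict[str, float]

    def summary(self) -> str:
        p, r = self.sample_pair
        lines = [
            f"Variant frequency shifts: {p} -> {r}",
            f"  variants tested      {self.total}",
        ]
        for cat in CATEGORY_PRECEDENCE:
            lines.append(f"  {cat:<20} {self.counts.get(cat, 0)}")
        frac = self.fraction_fixed_of_novel
        frac_s = "n/a" if math.isnan(frac) else f"{frac:.3f}"
        lines.append(f"  novel variants       {self.n_novel}")
        lines.append(f"  novel fixed          {self.n_novel_fixed} (fraction {frac_s})")
        return "\n".join(lines)


def classify_variants(
    parental: VariantTable,
    resistant: VariantTable,
    sample_pair: tuple[str, str],
    alpha_fisher: float = 0.05,
    alpha_binom: float = 0.1,
    fixation_af: float = 0.95,
) -> tuple[pd.DataFrame, ShiftSummary]:
    """Test and classify every variant of a parental/resistant pair.

    Tables are outer-joined on the variant key; a variant absent from one
    table contributes zero alt reads at zero depth there. Categories
    (mutually exclusive, assigned in precedence order lost > gained > fixed >
    changed > stable):

    * lost — alt present in parental, zero alt reads in resistant, and the
      zero-read binomial q < ``alpha_binom``;
    * gained — zero alt reads in parental, present in resistant, Fisher
      q < ``alpha_fisher``;
    * fixed — resistant AF >= ``fixation_af`` while the parental AF was below
      it (novel or intermediate-frequency variant driven to fixation);
    * changed — any other variant with Fisher q < ``alpha_fisher``;
    * stable — the rest.

    An ``is_fixed`` flag records the fixation condition independently of the
    exclusive category, and feeds :func:`fixation_fraction`.
    """
    p_name, r_name = sample_pair
    merged = parental.merge(resistant)
    _, p_alt, p_dp = merged.sample_columns(p_name)
    _, r_alt, r_dp = merged.sample_columns(r_name)

    df = merged.data
    ap = df[p_alt].to_numpy(dtype=int)
    dpp = df[p_dp].to_numpy(dtype=int)
    ar = df[r_alt].to_numpy(dtype=int)
    dpr = df[r_dp].to_numpy(dtype=int)
    rp = dpp - ap
    rr = dpr - ar

    with np.errstate(invalid="ignore", divide="ignore"):
        af_p = np.divide(ap, dpp, out=np.full(len(df), np.nan), where=dpp > 0)
        af_r = np.divide(ar, dpr, out=np.full(len(df), np.nan), where=dpr > 0)

    fisher_p = np.array(
        [fisher_shift_test((int(a), int(b)), (int(c), int(d)))
         for a, b, c, d in zip(rp, ap, rr, ar)]
    )
    loss_candidate = (ap > 0) & (dpp > 0) & (ar == 0)
    binom_p = np.full(len(df), np.nan)
    for i in np.flatnonzero(loss_candidate):
        binom_p[i] = loss_binomial_test(float(af_p[i]), int(dpr[i]))

    q_fisher = adjust_fdr(fisher_p)
    q_binom = adjust_fdr(binom_p)

    novel = (ap == 0) & (ar > 0)
    is_fixed = (
        (dpr > 0)
        & (af_r >= fixation_af)
        & (np.isnan(af_p) | (af_p < fixation_af))
    )
    # NaN q-values compare False, so untestable variants never reach significance
    sig_fisher = q_fisher < alpha_fisher
    sig_binom = q_binom < alpha_binom

    category = np.full(len(df), "stable", dtype=object)
    lost = loss_candidate & sig_binom
    gained = novel & sig_fisher & ~lost
    fixed = is_fixed & ~lost & ~gained
    changed = sig_fisher & ~lost & ~gained & ~fixed
    category[changed] = "changed"
    category[fixed] = "fixed"
    category[gained] = "gained"
    category[lost] = "lost"

    results = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "ref": df["ref"],
            "alt": df["alt"],
            "af_parental": af_p,
            "af_resistant": af_r,
            "fisher_p": fisher_p,
            "q_fisher": q_fisher,
            "binom_loss_p": binom_p,
            "q_binom": q_binom,
            "category": category,
            "is_novel": novel,
            "is_fixed": is_fixed,
        }
    )

    counts = {cat: int((category == cat).sum()) for cat in CATEGORY_PRECEDENCE}
    n_novel = int(novel.sum())
    n_novel_fixed = int((novel & is_fixed).sum())
    frac = n_novel_fixed / n_novel if n_novel > 0 else math.nan
    summary = ShiftSummary(
        sample_pair=sample_pair,
        total=len(df),
        counts=counts,
        n_novel=n_novel,
        n_novel_fixed=n_novel_fixed,
        fraction_fixed_of_novel=frac,
        params={
            "alpha_fisher": alpha_fisher,
            "alpha_binom": alpha_binom,
            "fixation_af": fixation_af,
        },
    )
    return results, summary


def fixation_fraction(results: pd.DataFrame) -> float:
    """Fraction of novel (gained-in-resistant) variants that reached fixation.

    Returns NaN when there are no novel variants.
    """
    if results.empty:
        raise ValueError("empty result table")
    novel = results["is_novel"].to_numpy(dtype=bool)
    if novel.sum() == 0:
        return math.nan
    fixed = results["is_fixed"].to_numpy(dtype=bool)
    return float((novel & fixed).sum() / novel.sum())
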