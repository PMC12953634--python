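"""Dose-response pharmacology and combination-synergy scoring.

Monotherapy viability is normalised to percent-of-control (POC), fitted with
a four-parameter logistic (4PL) by multi-start least squares, and summarised
by a span-normalised trapezoid AUC of mean POC over log10 dose (a 0-100-like
quantity: 100 = no response anywhere, 0 = complete kill everywhere). Screen
hits require both an AUC separation from fibroblast controls larger than a
threshold (default 50) and the SD-aware inequality

    AUC_fib - Sd(AUC_fib) > AUC_line + Sd(AUC_line)

in at least ``min_lines`` tumour cell lines.

Combination grids (rows = drug A doses, columns = drug B doses, POC values)
are scored against three reference models — Bliss independence, Loewe
additivity and Zero Interaction Potency (ZIP) — as excess-over-expected
surfaces in percentage points of inhibition, summarised by the most
synergistic area (MSA): the best mean excess over a small contiguous dose
window (3x3 by default). MSA > 10 is the conventional synergy call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "DoseResponseCurve",
    "FourPL",
    "FourPLResults",
    "HitCall",
    "SynergyResult",
    "normalize_poc",
    "fit_4pl",
    "compute_auc",
    "call_hits",
    "bliss_excess",
    "loewe_excess",
    "zip_delta",
    "msa_score",
    "score_synergy",
    "tumour_volume",
    "ddcq_fold_change",
]


@dataclass
class DoseResponseCurve:
    """Replicate POC measurements over an ascending dose series."""

    doses_uM: np.ndarray
    poc: np.ndarray  # (n_doses, n_replicates)
    cell_line: str = ""
    compound: str = ""

    def __post_init__(self) -> None:
        self.doses_uM = np.asarray(self.doses_uM, dtype=float)
        self.poc = np.atleast_2d(np.asarray(self.poc, dtype=float))
        if self.poc.shape[0] != self.doses_uM.size:
            self.poc = self.poc.T
        if self.poc.shape[0] != self.doses_uM.size:
            raise ValueError("POC matrix does not match dose series")
        if np.any(self.doses_uM <= 0):
            raise ValueError("doses must be positive (vehicle handled upstream)")
        order = np.argsort(self.doses_uM)
        self.doses_uM = self.doses_uM[order]
        self.poc = self.poc[order]

    @property
    def mean_poc(self) -> np.ndarray:
        return self.poc.mean(axis=1)


def normalize_poc(
    raw: np.ndarray,
    vehicle: np.ndarray,
    doses_uM: np.ndarray,
    cell_line: str = "",
    compound: str = "",
) -> DoseResponseCurve:
    """POC = 100 * raw / mean(vehicle)."""
    vehicle = np.asarray(vehicle, dtype=float)
    v = vehicle.mean()
    if v <= 0:
        raise ValueError("vehicle mean must be positive")
    return DoseResponseCurve(
        np.asarray(doses_uM, float), 100.0 * np.asarray(raw, float) / v,
        cell_line, compound,
    )


def _four_pl(d: np.ndarray, top: float, bottom: float, log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(d) - log_ic50)))


@dataclass
class FourPLResults:
    """Fitted four-parameter logistic with dose-range diagnostics."""

    top: float
    bottom: float
    ic50_uM: float
    hill: float
    rss: float
    converged: bool
    ic50_extrapolated: bool
    auc: float
    auc_sd: float
    n_doses: int

    def summary(self) -> str:
        ic50 = f"{self.ic50_uM:.4g} uM" + (
            " (extrapolated)" if self.ic50_extrapolated else ""
        )
        return "\n".join(
            [
                "4PL dose-response fit",
                f"  top     {self.top:.2f} POC",
                f"  bottom  {self.bottom:.2f} POC",
                f"  IC50    {ic50}",
                f"  hill    {self.hill:.3f}",
                f"  RSS     {self.rss:.4g}",
                f"  AUC     {self.auc:.1f} +/- {self.auc_sd:.1f}",
            ]
        )

    def predict(self, doses_uM: np.ndarray) -> np.ndarray:
        return _four_pl(
            np.asarray(doses_uM, float),
            self.top,
            self.bottom,
            np.log10(self.ic50_uM),
            self.hill,
        )

    def inverse_dose(self, poc: float) -> float:
        """Dose giving the requested POC (requires poc strictly between asymptotes)."""
        lo, hi = sorted((self.bottom, self.top))
        if not lo < poc < hi:
            raise ValueError("POC outside the response range of the fit")
        frac = (self.top - poc) / (poc - self.bottom)
        return float(self.ic50_uM * frac ** (1.0 / self.hill))

    @property
    def absolute_ic50_uM(self) -> float:
        """Dose at which the fitted curve crosses POC = 50.

        The assay definition of IC50: the concentration halving the control
        signal. It equals the fitted inflection ``ic50_uM`` only when the
        asymptotes are exactly 100 and 0; as an estimator it is also more
        stable, because errors in top/bottom/hill largely cancel at the
        50-percent crossing. NaN when the fitted curve never reaches POC 50.
        """
        try:
            return self.inverse_dose(50.0)
        except ValueError:
            return float("nan")


class FourPL:
    """Four-parameter logistic model of a POC dose-response curve.

    ``fit()`` runs a multi-start trust-region least-squares on log10 dose:
    IC50 starts at every observed dose, hill at {1, 2, -1, -2}; the best-RSS
    solution wins. At least 4 distinct doses are required.
    """

    def __init__(self, curve: DoseResponseCurve):
        if np.unique(curve.doses_uM).size < 4:
            raise ValueError("need >= 4 distinct doses for a 4PL fit")
        self.curve = curve

    def fit(self) -> FourPLResults:
        d = np.repeat(self.curve.doses_uM, self.curve.poc.shape[1])
        y = self.curve.poc.ravel()

        def residuals(theta: np.ndarray) -> np.ndarray:
            return _four_pl(d, *theta) - y

        y_hi, y_lo = float(np.max(y)), float(np.min(y))
        best = None
        for ic50_start in np.unique(self.curve.doses_uM):
            for hill_start in (1.0, 2.0, -1.0, -2.0):
                theta0 = np.array([y_hi, y_lo, np.log10(ic50_start), hill_start])
                try:
                    res = least_squares(
                        residuals,
                        theta0,
                        bounds=(
                            [-50.0, -50.0, -12.0, -10.0],
                            [250.0, 250.0, 12.0, 10.0],
                        ),
                        method="trf",
                        max_nfev=2000,
                    )
                except Exception:  # noqa: BLE001 - a start may fail; others run
                    continue
                if best is None or res.cost < best.cost:
                    best = res
        if best is None:
            return FourPLResults(
                np.nan, np.nan, np.nan, np.nan, np.nan, False, True,
                *compute_auc(self.curve), self.curve.doses_uM.size,
            )
        top, bottom, log_ic50, hill = best.x
        if top < bottom:  # (top, bottom, hill) -> (bottom, top, -hill) is the same curve
            top, bottom, hill = bottom, top, -hill
        ic50 = float(10.0 ** log_ic50)
        extrapolated = not (
            self.curve.doses_uM.min() <= ic50 <= self.curve.doses_uM.max()
        )
        auc, auc_sd = compute_auc(self.curve)
        return FourPLResults(
            top=float(top),
            bottom=float(bottom),
            ic50_uM=ic50,
            hill=float(hill),
            rss=float(2.0 * best.cost),
            converged=bool(best.success),
            ic50_extrapolated=extrapolated,
            auc=auc,
            auc_sd=auc_sd,
            n_doses=self.curve.doses_uM.size,
        )


def fit_4pl(curve: DoseResponseCurve) -> FourPLResults:
    return FourPL(curve).fit()


def compute_auc(curve: DoseResponseCurve) -> tuple[float, float]:
    """Span-normalised trapezoid AUC of POC over log10 dose, with SD.

    One AUC is computed per replicate series; the mean and SD across
    replicates are returned. Constant POC = 100 gives AUC = 100 on any grid.
    """
    if curve.doses_uM.size < 2:
        raise ValueError("need >= 2 doses for an AUC")
    x = np.log10(curve.doses_uM)
    span = x[-1] - x[0]
    rep_auc = np.trapezoid(curve.poc, x, axis=0) / span
    return float(rep_auc.mean()), float(rep_auc.std(ddof=1) if rep_auc.size > 1 else 0.0)


@dataclass
class HitCall:
    """Screen hit decision for one compound against one tumour type."""

    per_line: pd.DataFrame  # auc_line, sd_line, eq1_pass, auc_diff_pass, line_pass
    auc_fib: float
    sd_fib: float
    hit: bool
    n_lines_passing: int
    min_lines: int
    auc_diff_threshold: float

    def summary(self) -> str:
        lines = [
            "Screen hit call",
            f"  fibroblast AUC  {self.auc_fib:.1f} +/- {self.sd_fib:.1f}",
            f"  lines passing   {self.n_lines_passing} (required {self.min_lines})",
            f"  hit             {self.hit}",
        ]
        return "\n".join(lines)


def call_hits(
    tumour_aucs: dict[str, tuple[float, float]],
    fibroblast: tuple[float, float],
    auc_diff_threshold: float = 50.0,
    min_lines: int = 2,
) -> HitCall:
    """Two-step screen hit rule against the fibroblast reference.

    A line passes when (i) AUC_fib - Sd_fib > AUC_line + Sd_line and (ii)
    AUC_fib - AUC_line > ``auc_diff_threshold``. The compound is a hit when
    at least ``min_lines`` lines pass (set ``min_lines=1`` for compounds
    screened in a single line).
    """
    auc_fib, sd_fib = fibroblast
    if np.isnan(sd_fib) or any(np.isnan(sd) for _, sd in tumour_aucs.values()):
        raise ValueError("missing SDs; provide replicate AUC SDs for the Eq-style rule")
    rows = []
    for line, (auc, sd) in sorted(tumour_aucs.items()):
        eq1 = (auc_fib - sd_fib) > (auc + sd)
        diff = (auc_fib - auc) > auc_diff_threshold
        rows.append(
            {
                "cell_line": line,
                "auc_line": auc,
                "sd_line": sd,
                "eq1_pass": bool(eq1),
                "auc_diff_pass": bool(diff),
                "line_pass": bool(eq1 and diff),
            }
        )
    per_line = pd.DataFrame(rows).set_index("cell_line")
    n_pass = int(per_line["line_pass"].sum())
    return HitCall(
        per_line=per_line,
        auc_fib=auc_fib,
        sd_fib=sd_fib,
        hit=n_pass >= min_lines,
        n_lines_passing=n_pass,
        min_lines=min_lines,
        auc_diff_threshold=auc_diff_threshold,
    )


def _grid_inhibition(grid: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(doses_a, doses_b, fractional inhibition) from a POC grid with 0-dose rows."""
    doses_a = grid.index.to_numpy(dtype=float)
    doses_b = grid.columns.to_numpy(dtype=float)
    if 0.0 not in doses_a or 0.0 not in doses_b:
        raise ValueError("grid must include the zero-dose monotherapy row/column")
    y = np.clip(1.0 - grid.to_numpy(dtype=float) / 100.0, 0.0, 1.0)
    return doses_a, doses_b, y


def bliss_excess(grid: pd.DataFrame) -> np.ndarray:
    """Observed minus Bliss-independence expectation, in percentage points.

    Expectation uses the observed monotherapy rows/columns:
    E(a, b) = yA(a) + yB(b) - yA(a) yB(b). Monotherapy cells are zero by
    construction.
    """
    doses_a, doses_b, y = _grid_inhibition(grid)
    ia = int(np.flatnonzero(doses_a == 0)[0])
    ib = int(np.flatnonzero(doses_b == 0)[0])
    y_a = y[:, ib]
    y_b = y[ia, :]
    expected = y_a[:, None] + y_b[None, :] - y_a[:, None] * y_b[None, :]
    return 100.0 * (y - expected)


def loewe_excess(
    grid: pd.DataFrame, fit_a: FourPLResults, fit_b: FourPLResults
) -> np.ndarray:
    """Observed minus Loewe-additive expectation, in percentage points.

    The expected response y at (a, b) solves a/DA(y) + b/DB(y) = 1 with
    DX(y) the inverse 4PL dose of drug X; solved by root bracketing on the
    shared response range to 1e-6. Cells where no root exists in range take
    the nearest boundary response.
    """
    doses_a, doses_b, y_obs = _grid_inhibition(grid)
    for f in (fit_a, fit_b):
        if not np.isfinite(f.ic50_uM) or f.hill <= 0 and f.top <= f.bottom:
            raise ValueError("Loewe needs monotone, converged monotherapy fits")

    def poc_to_inhib(poc: float) -> float:
        return float(np.clip(1.0 - poc / 100.0, 0.0, 1.0))

    # shared achievable POC range (open interval for invertibility)
    lo_poc = max(min(fit_a.top, fit_a.bottom), min(fit_b.top, fit_b.bottom)) + 1e-9
    hi_poc = min(max(fit_a.top, fit_a.bottom), max(fit_b.top, fit_b.bottom)) - 1e-9

    expected = np.zeros_like(y_obs)
    for i, a in enumerate(doses_a):
        for j, b in enumerate(doses_b):
            if a == 0 and b == 0:
                expected[i, j] = 0.0
                continue
            if b == 0:
                expected[i, j] = poc_to_inhib(float(fit_a.predict(np.array([a]))[0]))
                continue
            if a == 0:
                expected[i, j] = poc_to_inhib(float(fit_b.predict(np.array([b]))[0]))
                continue

            def g(poc: float, a: float = a, b: float = b) -> float:
                return a / fit_a.inverse_dose(poc) + b / fit_b.inverse_dose(poc) - 1.0

            g_lo, g_hi = g(lo_poc), g(hi_poc)
            if g_lo * g_hi > 0:
                # no root in range: saturate at the nearer boundary
                poc_star = lo_poc if abs(g_lo) < abs(g_hi) else hi_poc
            else:
                poc_star = brentq(g, lo_poc, hi_poc, xtol=1e-6)
            expected[i, j] = poc_to_inhib(float(poc_star))
    return 100.0 * (y_obs - expected)


def _fit_logistic_inhibition(
    doses: np.ndarray, y: np.ndarray, floor: float, ceil: float = 1.0
) -> np.ndarray | None:
    """Fit y(d) = floor + (ceil - floor) / (1 + (ic50/d)^hill) over positive doses.

    Returns fitted responses at ``doses`` or None when unfittable.
    """
    pos = doses > 0
    if pos.sum() < 4 or ceil - floor < 1e-9:
        return None
    d = doses[pos]
    t = y[pos]

    def resid(theta: np.ndarray) -> np.ndarray:
        log_ic50, hill = theta
        return floor + (ceil - floor) / (
            1.0 + 10.0 ** (-hill * (np.log10(d) - log_ic50))
        ) - t

    best = None
    for ic50_start in (d.min(), np.median(d), d.max()):
        for hill_start in (0.5, 1.0, 2.0):
            try:
                res = least_squares(
                    resid,
                    np.array([np.log10(ic50_start), hill_start]),
                    bounds=([-12.0, 0.01], [12.0, 10.0]),
                    max_nfev=1000,
                )
            except Exception:  # noqa: BLE001
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        return None
    log_ic50, hill = best.x
    out = np.full(doses.size, floor)
    out[pos] = floor + (ceil - floor) / (
        1.0 + 10.0 ** (-hill * (np.log10(d) - log_ic50))
    )
    return out


def zip_delta(grid: pd.DataFrame) -> np.ndarray:
    """ZIP delta surface in percentage points.

    Marginal monotherapy logistic fits (inhibition scale, 0 to 1) give the
    zero-interaction expectation yA + yB - yA yB. For every positive partner
    dose, a conditional logistic is refitted along the other drug's doses
    with the partner-induced inhibition as the fixed lower asymptote and full
    inhibition as the upper; the delta at a cell is the mean of the two
    conditional fitted responses minus the expectation. Rows/columns too
    sparse to fit conditionally are flagged NaN.
    """
    doses_a, doses_b, y = _grid_inhibition(grid)
    ia = int(np.flatnonzero(doses_a == 0)[0])
    ib = int(np.flatnonzero(doses_b == 0)[0])
    y_a_fit = _fit_logistic_inhibition(doses_a, y[:, ib], floor=0.0)
    y_b_fit = _fit_logistic_inhibition(doses_b, y[ia, :], floor=0.0)
    if y_a_fit is None or y_b_fit is None:
        raise ValueError("monotherapy series too sparse for ZIP marginal fits")
    expected = y_a_fit[:, None] + y_b_fit[None, :] - y_a_fit[:, None] * y_b_fit[None, :]

    cond_along_a = np.full(y.shape, np.nan)  # A varies, B fixed per column
    for j, b in enumerate(doses_b):
        if b == 0:
            cond_along_a[:, j] = y_a_fit
            continue
        fitted = _fit_logistic_inhibition(doses_a, y[:, j], floor=float(y_b_fit[j]))
        if fitted is not None:
            cond_along_a[:, j] = fitted
    cond_along_b = np.full(y.shape, np.nan)
    for i, a in enumerate(doses_a):
        if a == 0:
            cond_along_b[i, :] = y_b_fit
            continue
        fitted = _fit_logistic_inhibition(doses_b, y[i, :], floor=float(y_a_fit[i]))
        if fitted is not None:
            cond_along_b[i, :] = fitted

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        combined = np.nanmean(np.stack([cond_along_a, cond_along_b]), axis=0)
    delta = 100.0 * (combined - expected)
    # zero interaction on monotherapy rows/columns by construction
    delta[ia, :] = 0.0
    delta[:, ib] = 0.0
    return delta


def msa_score(excess: np.ndarray, window: int = 3) -> float:
    """Most synergistic area: best mean over a window x window submatrix.

    Operates on the strictly-positive-dose interior the caller passes in.
    When the surface is smaller than the window, the largest available square
    is used.
    """
    ex = np.asarray(excess, dtype=float)
    if ex.size == 0:
        raise ValueError("empty excess surface")
    w = min(window, ex.shape[0], ex.shape[1])
    best = -np.inf
    for i in range(ex.shape[0] - w + 1):
        for j in range(ex.shape[1] - w + 1):
            block = ex[i : i + w, j : j + w]
            if np.isnan(block).all():
                continue
            best = max(best, float(np.nanmean(block)))
    return best


@dataclass
class SynergyResult:
    """Per-model synergy surfaces and MSA scores for one combination grid."""

    grid: pd.DataFrame
    surfaces: dict[str, np.ndarray]
    msa: dict[str, float]
    msa_window: int

    def summary(self) -> str:
        lines = ["Combination synergy scores (MSA > 10 indicates synergy)"]
        for model, score in self.msa.items():
            verdict = "synergy" if score > 10 else "no synergy"
            lines.append(f"  {model:<6} MSA = {score:6.2f}  ({verdict})")
        return "\n".join(lines)


def score_synergy(
    grid: pd.DataFrame,
    models: tuple[str, ...] = ("bliss", "loewe", "zip"),
    msa_window: int = 3,
) -> SynergyResult:
    """Score a POC combination grid under the requested reference models."""
    doses_a = grid.index.to_numpy(dtype=float)
    doses_b = grid.columns.to_numpy(dtype=float)
    interior_a = doses_a > 0
    interior_b = doses_b > 0
    surfaces: dict[str, np.ndarray] = {}
    msa: dict[str, float] = {}
    for model in models:
        if model == "bliss":
            surf = bliss_excess(grid)
        elif model == "zip":
            surf = zip_delta(grid)
        elif model == "loewe":
            mono_a = DoseResponseCurve(
                doses_a[interior_a], grid.to_numpy()[interior_a][:, ~interior_b]
            )
            mono_b = DoseResponseCurve(
                doses_b[interior_b], grid.to_numpy()[~interior_a][:, interior_b].T
            )
            surf = loewe_excess(grid, fit_4pl(mono_a), fit_4pl(mono_b))
        else:
            raise ValueError(f"unknown synergy model {model!r}")
        surfaces[model] = surf
        msa[model] = msa_score(surf[np.ix_(interior_a, interior_b)], msa_window)
    return SynergyResult(grid=grid, surfaces=surfaces, msa=msa, msa_window=msa_window)


def tumour_volume(length_mm: float, width_mm: float) -> float:
    """Calliper tumour volume: length x width^2 / 2 (mm^3)."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("length and width must be positive")
    if width_mm > length_mm:
        warnings.warn("width exceeds length; inputs may be swapped", stacklevel=2)
    return length_mm * width_mm**2 / 2.0


def ddcq_fold_change(
    cq_target_treated: float,
    cq_ref_treated: float,
    cq_target_control: float,
    cq_ref_control: float,
) -> float:
    """Comparative Cq expression fold change, 2^-ddCq."""
    for v in (cq_target_treated, cq_ref_treated, cq_target_control, cq_ref_control):
        if not np.isfinite(v):
            raise ValueError("Cq values must be finite")
    ddcq = (cq_target_treated - cq_ref_treated) - (cq_target_control - cq_ref_control)
    return float(2.0 ** (-ddcq))
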