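"""Synthetic data with known ground truth.

Everything the analysis stages consume can be generated here: clonal tumour
genomes (copy-number segments plus somatic SNVs with explicit allele copy
configuration), sequencing observables derived from them (per-site allele
depths and per-window read counts), log2 phospho-intensity matrices, and
dose-response / combination-viability grids.

The sampling model for sequencing observables:

* per-site total depth DP ~ NegativeBinomial with mean
  ``mean_depth * site_total_copies / base_ploidy``; ``depth_dispersion`` is
  the coefficient of variation of the gamma mixing distribution, i.e. the
  relative extra-Poisson depth noise (0 degenerates to Poisson),
* alt depth AD_alt ~ Binomial(DP, alt_copies / site_total_copies), or
  Beta-Binomial with intraclass correlation ``af_overdispersion`` when that
  is positive,
* per 50 kbp window, read count ~ NegativeBinomial with mean proportional to
  the length-weighted mean copy number of the window.

All outputs are fully determined by ``(seed, sample_name)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import VariantTable, WindowCountTable

__all__ = [
    "SimConfig",
    "CloneGenome",
    "ResistanceEventSet",
    "simulate_parental",
    "derive_resistant",
    "sample_sequencing",
    "make_panel_sites",
    "simulate_phospho",
    "simulate_drug_screen",
    "simulate_combination",
    "dilution_series",
    "four_pl_poc",
    "FourPLParams",
]

#: read length assumed when converting mean per-site depth into an expected
#: per-window read count (paired-end 150 bp sequencing).
READ_LENGTH_BP = 150

#: correlation length of the multiplicative depth bias; windows average
#: window_size / scale independent bias fluctuations.
DEPTH_BIAS_SCALE_BP = 1_000


def _sample_rng(seed: int, sample_name: str) -> np.random.Generator:
    """Generator deterministically derived from (seed, sample_name)."""
    digest = hashlib.sha256(sample_name.encode()).digest()
    name_key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), name_key]))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated sequencing experiment.

    ``mean_depth`` is the expected per-site read depth for a region at the
    parental base ploidy; regions at other copy numbers scale proportionally.
    ``depth_dispersion`` is the relative extra-Poisson depth noise: the CV of
    the gamma mixing distribution of the negative-binomial depth model
    (0 = Poisson). ``af_overdispersion`` is the
    beta-binomial intraclass correlation rho for allele depths (0 = binomial).
    ``gc_bias`` optionally injects a multiplicative GC-dependent bias into
    window counts (0 = unbiased) so that GC correction can be exercised on
    data with known truth.
    """

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 10_000_000),)
    base_ploidy: int = 2
    window_size_bp: int = 50_000
    mean_depth: float = 60.0
    depth_dispersion: float = 0.2
    af_overdispersion: float = 0.0
    n_het_sites_per_chrom: int = 10_000
    n_somatic_snvs: int = 1_000
    gc_bias: float = 0.0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.base_ploidy < 1:
            raise ValueError("base_ploidy must be >= 1")
        if self.window_size_bp < 1:
            raise ValueError("window_size_bp must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        if not 0 <= self.af_overdispersion < 1:
            raise ValueError("af_overdispersion must be in [0, 1)")


@dataclass
class SNV:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    alt_copies: int
    site_total_copies: int


@dataclass
class CloneGenome:
    """Ground truth of one tumour clone.

    ``segments`` are (chrom, start, end, total_copies) tiles covering each
    chromosome with 0-based half-open coordinates; ``snvs`` carry explicit
    allele copy configuration (``alt_copies`` of ``site_total_copies``).
    """

    chrom_lengths: dict[str, int]
    segments: list[tuple[str, int, int, int]]
    snvs: list[SNV] = field(default_factory=list)

    def copy_number_at(self, chrom: str, pos: int) -> int:
        for c, s, e, cn in self.segments:
            if c == chrom and s <= pos < e:
                return cn
        raise KeyError(f"position {chrom}:{pos} not covered by any segment")

    def validate(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            tiles = sorted(
                (s, e, cn) for c, s, e, cn in self.segments if c == chrom
            )
            if not tiles:
                raise ValueError(f"chromosome {chrom} has no segments")
            if tiles[0][0] != 0 or tiles[-1][1] != length:
                raise ValueError(f"segments do not span chromosome {chrom}")
            for (s0, e0, _), (s1, _, _) in zip(tiles, tiles[1:]):
                if e0 != s1:
                    raise ValueError(f"segments overlap or leave a gap on {chrom}")
            for _, _, cn in tiles:
                if cn < 0:
                    raise ValueError("negative copy number")
        for v in self.snvs:
            if not 0 <= v.alt_copies <= v.site_total_copies:
                raise ValueError(
                    f"SNV {v.chrom}:{v.pos} alt_copies outside [0, total]"
                )


@dataclass(frozen=True)
class ResistanceEventSet:
    """Genomic changes that turn a parental clone into a resistant one."""

    whole_genome_duplication: bool = False
    segmental_events: tuple[tuple[str, int, int, int], ...] = ()
    snv_gains: int = 0
    snv_losses: int = 0
    snv_fixations: int = 0


_BASES = np.array(list("ACGT"))


def simulate_parental(config: SimConfig) -> CloneGenome:
    """Clonal parental genome at the configured base ploidy.

    Somatic SNVs are placed uniformly at random over the genome; each gets
    ``alt_copies`` drawn uniformly from ``{1..base_ploidy}``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    chrom_lengths = dict(config.chromosomes)
    segments = [
        (name, 0, length, config.base_ploidy) for name, length in config.chromosomes
    ]
    names = [n for n, _ in config.chromosomes]
    lengths = np.array([l for _, l in config.chromosomes], dtype=float)
    snvs: list[SNV] = []
    if config.n_somatic_snvs > 0:
        chrom_idx = rng.choice(
            len(names), size=config.n_somatic_snvs, p=lengths / lengths.sum()
        )
        positions = rng.integers(0, lengths[chrom_idx].astype(np.int64))
        alt_copies = rng.integers(1, config.base_ploidy + 1, size=config.n_somatic_snvs)
        ref_i = rng.integers(0, 4, size=config.n_somatic_snvs)
        alt_i = (ref_i + rng.integers(1, 4, size=config.n_somatic_snvs)) % 4
        seen: set[tuple[str, int]] = set()
        for ci, pos, ac, ri, ai in zip(chrom_idx, positions, alt_copies, ref_i, alt_i):
            key = (names[ci], int(pos))
            if key in seen:  # keep sites unique
                continue
            seen.add(key)
            snvs.append(
                SNV(names[ci], int(pos), _BASES[ri], _BASES[ai],
                    int(ac), config.base_ploidy)
            )
        snvs.sort(key=lambda v: (v.chrom, v.pos))
    genome = CloneGenome(chrom_lengths, segments, snvs)
    genome.validate()
    return genome


def _split_segments(
    segments: list[tuple[str, int, int, int]],
    chrom: str,
    start: int,
    end: int,
    delta: int,
) -> list[tuple[str, int, int, int]]:
    out: list[tuple[str, int, int, int]] = []
    for c, s, e, cn in segments:
        if c != chrom or e <= start or s >= end:
            out.append((c, s, e, cn))
            continue
        if s < start:
            out.append((c, s, start, cn))
        lo, hi = max(s, start), min(e, end)
        new_cn = cn + delta
        if new_cn < 0:
            raise ValueError(
                f"segmental event {chrom}:{start}-{end} delta={delta} "
                f"would produce negative copy number"
            )
        out.append((c, lo, hi, new_cn))
        if e > end:
            out.append((c, end, e, cn))
    return out


def derive_resistant(
    parental: CloneGenome, events: ResistanceEventSet, seed: int
) -> CloneGenome:
    """Apply resistance-associated genomic events to a parental clone.

    Order of operations: whole-genome duplication (doubles every segment's
    copy number and every SNV's alt and total copies — allele fractions are
    preserved), then segmental gains/losses (segments are split at event
    boundaries), then SNV gains (novel variants at ``alt_copies=1``), losses
    (``alt_copies`` set to 0) and fixations (``alt_copies`` set to the site
    total).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    segments = list(parental.segments)
    snvs = [replace(v) for v in parental.snvs]

    if events.whole_genome_duplication:
        segments = [(c, s, e, 2 * cn) for c, s, e, cn in segments]
        for v in snvs:
            v.alt_copies *= 2
            v.site_total_copies *= 2

    for chrom, start, end, delta in events.segmental_events:
        segments = _split_segments(segments, chrom, start, end, delta)

    genome = CloneGenome(parental.chrom_lengths, segments, snvs)
    # re-sync SNV totals with the (possibly changed) covering segment
    for v in snvs:
        total = genome.copy_number_at(v.chrom, v.pos)
        v.site_total_copies = total
        v.alt_copies = min(v.alt_copies, total)

    if events.snv_gains > 0:
        names = list(parental.chrom_lengths)
        lengths = np.array([parental.chrom_lengths[n] for n in names], float)
        existing = {(v.chrom, v.pos) for v in snvs}
        n_new = 0
        while n_new < events.snv_gains:
            ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
            pos = int(rng.integers(0, int(lengths[ci])))
            if (names[ci], pos) in existing:
                continue
            existing.add((names[ci], pos))
            ri = int(rng.integers(0, 4))
            ai = (ri + int(rng.integers(1, 4))) % 4
            total = genome.copy_number_at(names[ci], pos)
            snvs.append(SNV(names[ci], pos, _BASES[ri], _BASES[ai], 1, total))
            n_new += 1

    carriers = [i for i, v in enumerate(snvs) if v.alt_copies > 0]
    if events.snv_losses > len(carriers):
        raise ValueError("snv_losses exceeds available SNVs")
    if events.snv_losses > 0:
        for i in rng.choice(carriers, size=events.snv_losses, replace=False):
            snvs[i].alt_copies = 0
    # fixation is idempotent on already-fixed variants; targets are any carriers
    remaining = [i for i, v in enumerate(snvs) if v.alt_copies > 0]
    if events.snv_fixations > len(remaining):
        raise ValueError("snv_fixations exceeds available SNVs")
    if events.snv_fixations > 0:
        for i in rng.choice(remaining, size=events.snv_fixations, replace=False):
            snvs[i].alt_copies = snvs[i].site_total_copies

    snvs.sort(key=lambda v: (v.chrom, v.pos))
    genome = CloneGenome(parental.chrom_lengths, segments, snvs)
    genome.validate()
    return genome


def make_panel_sites(
    config: SimConfig, seed: int | None = None
) -> list[tuple[str, int]]:
    """Germline-like heterozygous panel sites, shared across samples.

    ``n_het_sites_per_chrom`` positions per chromosome, uniformly placed.
    These stand in for a population SNV panel used to build B-allele-frequency
    spectra; every simulated sample carries them.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed if seed is None else seed), 2])
    )
    sites: list[tuple[str, int]] = []
    for name, length in config.chromosomes:
        pos = np.sort(
            rng.choice(length, size=min(config.n_het_sites_per_chrom, length),
                       replace=False)
        )
        sites.extend((name, int(p)) for p in pos)
    return sites


def _nbinom_draw(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture.

    ``cv`` is the coefficient of variation of the gamma mixing distribution
    (the extra-Poisson relative depth noise), so var = mu + (cv * mu)^2;
    cv = 0 degenerates to Poisson. At 60x mean depth, cv = 0.2 gives a depth
    SD of ~14 reads, typical of a well-behaved WGS library.
    """
    mean = np.asarray(mean, dtype=float)
    if cv <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / cv**2, mean * cv**2)
    return rng.poisson(lam)


def _alt_depth(
    rng: np.random.Generator, dp: np.ndarray, p: np.ndarray, rho: float
) -> np.ndarray:
    if rho <= 0:
        return rng.binomial(dp, p)
    conc = (1.0 - rho) / rho
    a = np.clip(p * conc, 1e-9, None)
    b = np.clip((1.0 - p) * conc, 1e-9, None)
    return rng.binomial(dp, rng.beta(a, b))


def sample_sequencing(
    clone: CloneGenome,
    panel_sites: list[tuple[str, int]],
    config: SimConfig,
    sample_name: str,
    site_catalog: list[tuple[str, int, str, str]] | None = None,
) -> tuple[VariantTable, WindowCountTable]:
    """Draw sequencing observables for one sample of a clone.

    Returns a single-sample :class:`VariantTable` covering the clone's somatic
    SNVs plus the germline-like panel sites (panel alt copies drawn uniformly
    from ``{1..m-1}`` at local copy number ``m``, so expected allele fractions
    sit at the ``k/m`` peaks), and a :class:`WindowCountTable` of per-window
    read counts proportional to local copy number.

    ``site_catalog`` emulates joint calling: every (chrom, pos0, ref, alt)
    listed is emitted even when this clone carries no alt allele there
    (reference-only coverage at the local copy number), so parental samples
    report read support at sites private to a resistant derivative.
    """
    rng = _sample_rng(config.seed, sample_name)

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    alt_copies: list[int] = []
    totals: list[int] = []

    for chrom, pos in panel_sites:
        m = clone.copy_number_at(chrom, pos)
        k = int(rng.integers(1, m)) if m >= 2 else (1 if m == 1 else 0)
        chroms.append(chrom)
        positions.append(pos)
        refs.append("A")
        alts.append("G")
        alt_copies.append(k)
        totals.append(m)
    carried = {(v.chrom, v.pos): v for v in clone.snvs}
    for v in clone.snvs:
        chroms.append(v.chrom)
        positions.append(v.pos)
        refs.append(v.ref)
        alts.append(v.alt)
        alt_copies.append(v.alt_copies)
        totals.append(v.site_total_copies)
    if site_catalog is not None:
        for chrom, pos, ref, alt in site_catalog:
            if (chrom, pos) in carried:
                continue  # already emitted with this clone's configuration
            chroms.append(chrom)
            positions.append(pos)
            refs.append(ref)
            alts.append(alt)
            alt_copies.append(0)
            totals.append(clone.copy_number_at(chrom, pos))

    totals_arr = np.array(totals, dtype=float)
    alt_arr = np.array(alt_copies, dtype=float)
    mean_dp = config.mean_depth * totals_arr / config.base_ploidy
    dp = _nbinom_draw(rng, mean_dp, config.depth_dispersion)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals_arr > 0, alt_arr / np.where(totals_arr > 0, totals_arr, 1), 0.0)
    ad_alt = np.where(dp > 0, _alt_depth(rng, dp, p, config.af_overdispersion), 0)
    ad_alt = np.where(totals_arr == 0, 0, ad_alt)
    ad_ref = dp - ad_alt

    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(positions) + 1,  # VCF is 1-based
            "ref": refs,
            "alt": alts,
            f"{sample_name}.ad_ref": ad_ref.astype(int),
            f"{sample_name}.ad_alt": ad_alt.astype(int),
            f"{sample_name}.dp": dp.astype(int),
        }
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    variants = VariantTable(df, [sample_name])

    rows = []
    base_window_mean = config.mean_depth * config.window_size_bp / READ_LENGTH_BP
    gc_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 3]))
    for chrom, length in clone.chrom_lengths.items():
        starts = np.arange(0, length, config.window_size_bp)
        ends = np.minimum(starts + config.window_size_bp, length)
        gc = np.clip(gc_rng.normal(0.45, 0.05, size=len(starts)), 0.2, 0.8)
        seg = sorted(
            (s, e, cn) for c, s, e, cn in clone.segments if c == chrom
        )
        seg_starts = np.array([s for s, _, _ in seg])
        seg_ends = np.array([e for _, e, _ in seg])
        seg_cn = np.array([cn for _, _, cn in seg], dtype=float)
        mean_cn = np.empty(len(starts))
        for i, (ws, we) in enumerate(zip(starts, ends)):
            overlap = np.clip(
                np.minimum(seg_ends, we) - np.maximum(seg_starts, ws), 0, None
            )
            mean_cn[i] = float(np.sum(overlap * seg_cn) / (we - ws))
        mu = (
            base_window_mean
            * ((ends - starts) / config.window_size_bp)
            * mean_cn
            / config.base_ploidy
        )
        if config.gc_bias != 0.0:
            mu = mu * np.clip(1.0 + config.gc_bias * (gc - 0.45) / 0.05, 0.05, None)
        # depth bias is correlated over ~DEPTH_BIAS_SCALE_BP, so a window
        # averages window/scale independent fluctuations: its relative
        # extra-Poisson noise shrinks by the square root of that ratio
        n_eff = max(1.0, config.window_size_bp / DEPTH_BIAS_SCALE_BP)
        counts = _nbinom_draw(rng, mu, config.depth_dispersion / np.sqrt(n_eff))
        for s, e, c, g in zip(starts, ends, counts, gc):
            rows.append((chrom, int(s), int(e), int(c), float(g)))
    windows = WindowCountTable(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "gc"])
    )
    return variants, windows


def simulate_phospho(
    n_features: int,
    n_per_group: int,
    frac_differential: float,
    effect_size_sd_units: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Log2 phospho-intensity matrix with planted group differences.

    Exactly ``round(frac_differential * n_features)`` features receive a mean
    shift of ``effect_size_sd_units`` (in units of the within-group SD) in
    group B. Returns ``(matrix, groups, truth)`` where ``truth`` is the
    boolean ground-truth differential label per feature.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0 <= frac_differential <= 1:
        raise ValueError("frac_differential must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    n_samples = 2 * n_per_group
    values = rng.normal(20.0, 1.0, size=(n_features, n_samples))
    n_diff = int(round(frac_differential * n_features))
    truth = np.zeros(n_features, dtype=bool)
    if n_diff > 0:
        idx = rng.choice(n_features, size=n_diff, replace=False)
        truth[idx] = True
        values[np.ix_(idx, np.arange(n_per_group, n_samples))] += effect_size_sd_units
    samples = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    matrix = pd.DataFrame(
        values, index=[f"pep{i + 1}" for i in range(n_features)], columns=samples
    )
    groups = pd.Series(
        ["A"] * n_per_group + ["B"] * n_per_group, index=samples, name="group"
    )
    return matrix, groups, truth


@dataclass(frozen=True)
class FourPLParams:
    """Four-parameter logistic curve on the percent-of-control scale."""

    top: float = 100.0
    bottom: float = 0.0
    ic50_uM: float = 1.0
    hill: float = 1.0


def four_pl_poc(dose_uM: np.ndarray | float, p: FourPLParams) -> np.ndarray:
    """POC(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill); POC(0) = top."""
    d = np.asarray(dose_uM, dtype=float)
    out = np.full(d.shape if d.ndim else (), p.top, dtype=float)
    pos = d > 0
    out = np.where(
        pos,
        p.bottom + (p.top - p.bottom) / (1.0 + (np.where(pos, d, 1.0) / p.ic50_uM) ** p.hill),
        p.top,
    )
    return out


def dilution_series(top_dose_uM: float, dilution_factor: float, n_doses: int) -> np.ndarray:
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    return top_dose_uM / dilution_factor ** np.arange(n_doses, dtype=float)


def simulate_drug_screen(
    ic50s_by_line: dict[str, float],
    top_dose_uM: float = 100.0,
    dilution_factor: float = 5.0,
    n_doses: int = 7,
    hill: float = 1.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    n_replicates: int = 3,
) -> dict[str, "pd.DataFrame"]:
    """Monotherapy viability screen: one POC table per cell line.

    Each table has one row per dose (descending 1:``dilution_factor`` series
    from ``top_dose_uM``) and ``n_replicates`` POC columns, generated from a
    4PL (bottom 0, top 100) with multiplicative noise of the given CV.
    """
    doses = dilution_series(top_dose_uM, dilution_factor, n_doses)
    out: dict[str, pd.DataFrame] = {}
    for i, (line, ic50) in enumerate(sorted(ic50s_by_line.items())):
        if ic50 <= 0:
            raise ValueError(f"non-positive ic50 for {line}")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5, i]))
        params = FourPLParams(ic50_uM=ic50, hill=hill)
        mean = four_pl_poc(doses, params)
        reps = mean[:, None] * (
            1.0 + noise_cv * rng.standard_normal((n_doses, n_replicates))
            if noise_cv > 0
            else np.ones((n_doses, n_replicates))
        )
        out[line] = pd.DataFrame(
            np.clip(reps, 0.0, None),
            index=pd.Index(doses, name="dose_uM"),
            columns=[f"rep{r + 1}" for r in range(n_replicates)],
        )
    return out


def simulate_combination(
    curve_a: FourPLParams,
    curve_b: FourPLParams,
    doses_a: np.ndarray,
    doses_b: np.ndarray,
    synergy_delta: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Combination POC grid under Bliss independence plus constant synergy.

    Rows are drug-A doses, columns drug-B doses (each must include 0 so the
    monotherapy series are embedded). With ``synergy_delta = 0`` combined
    fractional inhibition follows Bliss independence of the two monotherapy
    inhibitions; a nonzero delta adds that many percentage points of extra
    inhibition at every strictly-positive dose pair.
    """
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    if 0.0 not in doses_a or 0.0 not in doses_b:
        raise ValueError("dose grids must include zero dose for each drug")
    y_a = 1.0 - four_pl_poc(doses_a, curve_a) / 100.0
    y_b = 1.0 - four_pl_poc(doses_b, curve_b) / 100.0
    y = y_a[:, None] + y_b[None, :] - y_a[:, None] * y_b[None, :]
    interior = (doses_a[:, None] > 0) & (doses_b[None, :] > 0)
    y = np.clip(y + interior * synergy_delta / 100.0, 0.0, 1.0)
    poc = 100.0 * (1.0 - y)
    if noise_cv > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))
        poc = np.clip(poc * (1.0 + noise_cv * rng.standard_normal(poc.shape)), 0.0, None)
    return pd.DataFrame(
        poc,
        index=pd.Index(doses_a, name="dose_a_uM"),
        columns=pd.Index(doses_b, name="dose_b_uM"),
    )
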