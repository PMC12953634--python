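"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes the requested stages in dependency order on fully
simulated inputs — simulate, cnv, ploidy, shift, phospho, screen, synergy —
and writes every stage's inputs/outputs plus a single JSON run manifest. One
global seed fans out to per-stage seeds through a counter-based derivation
recorded in the manifest, so a manifest suffices to reproduce a run.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .cnv import call_states, count_to_ratio, segment_track, segments_to_frame
from .io import (
    VariantTable,
    WindowCountTable,
    write_vcf,
    write_window_counts,
)
from .pharm import call_hits, fit_4pl, score_synergy, DoseResponseCurve
from .phospho import permutation_fdr
from .ploidy import select_ploidy
from .shift import classify_variants, fixation_fraction
from .simulate import (
    FourPLParams,
    ResistanceEventSet,
    SimConfig,
    derive_resistant,
    dilution_series,
    make_panel_sites,
    sample_sequencing,
    simulate_combination,
    simulate_drug_screen,
    simulate_parental,
    simulate_phospho,
)

logger = logging.getLogger("resistkit")

ALL_STAGES = ("simulate", "cnv", "ploidy", "shift", "phospho", "screen", "synergy")

#: per-stage seed offsets for the counter-based fan-out
_STAGE_OFFSET = {name: 100 + i for i, name in enumerate(ALL_STAGES)}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1_000 + _STAGE_OFFSET[stage]) % (2**31 - 1)


def run_pipeline(
    config: dict,
    outdir: str | Path,
    stages: tuple[str, ...] = ALL_STAGES,
    seed: int | None = None,
) -> dict:
    """Run the requested stages and return the manifest (also written as JSON)."""
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in ALL_STAGES if s in stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    global_seed = int(config.get("seed", 0) if seed is None else seed)

    manifest: dict = {
        "tool": "resistkit",
        "version": __version__,
        "global_seed": global_seed,
        "stages": {},
    }

    sim_state: dict = {}
    for stage in stages:
        t0 = time.perf_counter()
        s_seed = stage_seed(global_seed, stage)
        logger.info("stage=%s seed=%d starting", stage, s_seed)
        runner = _STAGE_RUNNERS[stage]
        try:
            headline = runner(config, outdir, s_seed, sim_state)
        except Exception:
            logger.exception("stage=%s failed", stage)
            manifest["stages"][stage] = {"seed": s_seed, "status": "failed"}
            _write_manifest(manifest, outdir, partial=True)
            raise
        manifest["stages"][stage] = {
            "seed": s_seed,
            "status": "ok",
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "headline": headline,
        }
    _write_manifest(manifest, outdir, partial=False)
    return manifest


def _write_manifest(manifest: dict, outdir: Path, partial: bool) -> None:
    name = "manifest.json.partial" if partial else "manifest.json"
    (outdir / name).write_text(json.dumps(manifest, indent=2, default=str))


def _stage_simulate(config: dict, outdir: Path, seed: int, state: dict) -> dict:
    sim = SimConfig(
        seed=seed,
        chromosomes=(("chr1", 5_000_000), ("chr2", 5_000_000)),
        base_ploidy=int(config.get("base_ploidy", 2)),
        window_size_bp=int(config.get("window_size_bp", 50_000)),
        mean_depth=float(config.get("mean_depth", 60.0)),
        depth_dispersion=float(config.get("depth_dispersion", 0.2)),
        af_overdispersion=float(config.get("af_overdispersion", 0.0)),
        n_het_sites_per_chrom=min(int(config.get("n_het_sites_per_chrom", 10_000)), 4000),
        n_somatic_snvs=min(int(config.get("n_somatic_snvs", 1_000)), 1000),
    )
    parental = simulate_parental(sim)
    events = ResistanceEventSet(
        whole_genome_duplication=True,
        segmental_events=(("chr1", 0, 1_000_000, -1), ("chr2", 2_000_000, 3_000_000, 1)),
        snv_gains=200,
        snv_fixations=40,
        snv_losses=50,
    )
    resistant = derive_resistant(parental, events, seed + 1)
    panel = make_panel_sites(sim)
    # joint-calling catalog: every somatic site of either clone is genotyped
    # in both samples, so sites private to one report ref coverage in the other
    catalog = sorted(
        {(v.chrom, v.pos, v.ref, v.alt) for v in parental.snvs + resistant.snvs}
    )
    var_p, win_p = sample_sequencing(parental, panel, sim, "parental", catalog)
    var_r, win_r = sample_sequencing(resistant, panel, sim, "resistant", catalog)
    # somatic-only views: the shift test compares somatic variants, not the
    # germline-like panel (whose allele configuration is drawn per sample)
    panel_pos = {(c, p + 1) for c, p in panel}
    som_mask_p = ~var_p.data.set_index(["chrom", "pos"]).index.isin(panel_pos)
    som_mask_r = ~var_r.data.set_index(["chrom", "pos"]).index.isin(panel_pos)
    som_p = VariantTable(var_p.data[som_mask_p].reset_index(drop=True), ["parental"])
    som_r = VariantTable(var_r.data[som_mask_r].reset_index(drop=True), ["resistant"])
    write_vcf(var_p, outdir / "parental.vcf")
    write_vcf(var_r, outdir / "resistant.vcf")
    write_window_counts(win_p, outdir / "parental_windows.tsv")
    write_window_counts(win_r, outdir / "resistant_windows.tsv")
    truth = {
        "parental_ploidy": sim.base_ploidy,
        "resistant_segments": [list(s) for s in resistant.segments],
        "events": {
            "wgd": events.whole_genome_duplication,
            "snv_gains": events.snv_gains,
            "snv_fixations": events.snv_fixations,
            "snv_losses": events.snv_losses,
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    state.update(
        sim=sim, parental=parental, resistant=resistant, panel=panel,
        var_p=var_p, var_r=var_r, win_p=win_p, win_r=win_r,
        som_p=som_p, som_r=som_r,
    )
    return {
        "n_panel_sites": len(panel),
        "n_somatic_snvs": len(parental.snvs),
        "files": ["parental.vcf", "resistant.vcf", "parental_windows.tsv",
                  "resistant_windows.tsv", "truth.json"],
    }


def _require_sim(state: dict, stage: str) -> None:
    if "sim" not in state:
        raise RuntimeError(f"stage {stage!r} requires the simulate stage first")


def _stage_cnv(config: dict, outdir: Path, seed: int, state: dict) -> dict:
    _require_sim(state, "cnv")
    ploidy = 2 * state["sim"].base_ploidy  # resistant clone carries a WGD
    track = count_to_ratio(state["win_r"], ploidy)
    segments = call_states(segment_track(track), ploidy)
    frame = segments_to_frame(segments)
    frame.to_csv(outdir / "segments.tsv", sep="\t", index=False)
    return {
        "normalisation_ploidy": ploidy,
        "n_segments": len(segments),
        "states": frame["state"].value_counts().to_dict(),
    }


def _stage_ploidy(config: dict, outdir: Path, seed: int, state: dict) -> dict:
    _require_sim(state, "ploidy")
    call = select_ploidy(
        state["var_r"],
        "resistant",
        candidates=tuple(config.get("candidates", (2, 3, 4))),
        n_subsample=min(int(config.get("n_subsample", 10_000)), 4000),
        seed=seed,
    )
    report = {
        "best_m": call.best_m,
        "delta_bic": call.delta_bic,
        "bic_by_m": {c: {str(m): b for m, b in d.items()} for c, d in call.bic_by_m.items()},
    }
    (outdir / "ploidy.json").write_text(json.dumps(report, indent=2))
    return {"best_m": call.best_m}


def _stage_shift(config: dict, outdir: Path, seed: int, state: dict) -> dict:
    _require_sim(state, "shift")
    results, summary = classify_variants(
        state["som_p"],
        state["som_r"],
        ("parental", "resistant"),
        alpha_fisher=float(config.get("alpha_fisher", 0.05)),
        alpha_binom=float(config.get("alpha_binom", 0.1)),
        fixation_af=float(config.get("fixation_af", 0.95)),
    )
    results.to_csv(outdir / "shift.tsv", sep="\t", index=False)
    frac = fixation_fraction(results)
    return {
        "category_counts": summary.counts,
        "fraction_fixed_of_novel": None if np.isnan(frac) else round(frac, 4),
    }


def _stage_phospho(config: dict, outdir: Path, seed: int, state: dict) -> dict:
    matrix, groups, truth = simulate_phospho(
        n_features=1000, n_per_group=3, frac_differential=0.1,
        effect_size_sd_units=3.0, seed=seed,
    )
    matrix.to_csv(outdir / "phospho_matrix.csv")
    res = permutation_fdr(
        matrix, groups,
        s0=float(config.get("s0", 0.1)),
        fdr_target=float(config.get("fdr_target", 0.05)),
        n_permutations=int(config.get("n_permutations", 250)),
        seed=seed,
    )
    res.table.to_csv(outdir / "phospho_results.tsv", sep="\t")
    return {
        "n_up": res.n_up,
        "n_down": res.n_down,
        "n_true_differential": int(truth.sum()),
        "n_permutations_used": res.n_permutations_used,
    }


def _stage_screen(config: dict, outdir: Path, seed: int, state: dict) -> dict:
    # two potent lines, one resistant line, and a largely unresponsive
    # fibroblast control, so both arms of the hit rule are exercised
    screens = simulate_drug_screen(
        {"DFT_line1": 0.1, "DFT_line2": 0.2, "DFT_line3": 30.0, "FIB": 300.0},
        seed=seed,
    )
    aucs: dict[str, tuple[float, float]] = {}
    ic50s: dict[str, float] = {}
    for line, table in screens.items():
        curve = DoseResponseCurve(
            table.index.to_numpy(), table.to_numpy(), cell_line=line
        )
        fit = fit_4pl(curve)
        aucs[line] = (fit.auc, fit.auc_sd)
        ic50s[line] = fit.ic50_uM
    fib = aucs.pop("FIB")
    hit = call_hits(
        aucs, fib,
        auc_diff_threshold=float(config.get("auc_diff_threshold", 50.0)),
        min_lines=int(config.get("min_lines", 2)),
    )
    hit.per_line.to_csv(outdir / "screen_hits.tsv", sep="\t")
    return {
        "ic50_uM": {k: round(v, 4) for k, v in ic50s.items()},
        "hit": hit.hit,
        "n_lines_passing": hit.n_lines_passing,
    }


def _stage_synergy(config: dict, outdir: Path, seed: int, state: dict) -> dict:
    doses = np.concatenate([[0.0], dilution_series(100.0, 5.0, 7)[::-1]])
    grid = simulate_combination(
        FourPLParams(ic50_uM=1.0), FourPLParams(ic50_uM=5.0),
        doses, doses, synergy_delta=10.0, noise_cv=0.0, seed=seed,
    )
    grid.to_csv(outdir / "combination_grid.csv")
    result = score_synergy(grid, msa_window=int(config.get("msa_window", 3)))
    return {"msa": {k: round(v, 3) for k, v in result.msa.items()}}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "cnv": _stage_cnv,
    "ploidy": _stage_ploidy,
    "shift": _stage_shift,
    "phospho": _stage_phospho,
    "screen": _stage_screen,
    "synergy": _stage_synergy,
}
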