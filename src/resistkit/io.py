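"""Readers and writers for the pipeline's file interfaces.

Variant tables use a minimal VCF v4.2 dialect: bi-allelic SNVs only, with
per-sample ``GT:AD:DP`` FORMAT fields (AD as "ref,alt"). Window counts are
4/5-column TSVs (chrom, start, end, count[, gc]) with 0-based half-open
coordinates. Intensity matrices and dose grids are CSV with a header row.
All readers validate strictly and raise instead of coercing.

Internal coordinates are 0-based half-open; VCF positions are converted at
the file boundary. Samples are treated as female (XX): Y-chromosome rows are
dropped on read to avoid copy-number artefacts from a missing chromosome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

__all__ = [
    "VariantTable",
    "WindowCountTable",
    "read_vcf",
    "write_vcf",
    "read_window_counts",
    "write_window_counts",
    "read_matrix",
    "load_config",
    "FormatError",
]

_Y_NAMES = frozenset({"Y", "chrY", "ChrY", "CHRY"})


class FormatError(ValueError):
    """Malformed or out-of-dialect input file."""


@dataclass
class VariantTable:
    """Per-site, per-sample allele depths.

    ``data`` columns: chrom, pos (1-based), ref, alt, then per sample
    ``<name>.ad_ref``, ``<name>.ad_alt``, ``<name>.dp``.
    """

    data: pd.DataFrame
    sample_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.sample_names:
            for suffix in ("ad_ref", "ad_alt", "dp"):
                col = f"{s}.{suffix}"
                if col not in self.data.columns:
                    raise FormatError(f"missing column {col}")
            ad = self.data[f"{s}.ad_ref"] + self.data[f"{s}.ad_alt"]
            bad = ad > self.data[f"{s}.dp"]
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                rec = self.data.iloc[i]
                raise FormatError(
                    f"AD sum exceeds DP for sample {s} at {rec['chrom']}:{rec['pos']}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def sample_columns(self, sample: str) -> tuple[str, str, str]:
        if sample not in self.sample_names:
            raise KeyError(f"unknown sample {sample!r}")
        return f"{sample}.ad_ref", f"{sample}.ad_alt", f"{sample}.dp"

    def merge(self, other: "VariantTable") -> "VariantTable":
        """Outer join on variant key; absent sites get zero depth."""
        merged = self.data.merge(
            other.data, on=["chrom", "pos", "ref", "alt"], how="outer"
        )
        for s in self.sample_names + other.sample_names:
            for suffix in ("ad_ref", "ad_alt", "dp"):
                col = f"{s}.{suffix}"
                merged[col] = merged[col].fillna(0).astype(int)
        merged = merged.sort_values(["chrom", "pos"], kind="stable").reset_index(
            drop=True
        )
        return VariantTable(merged, self.sample_names + other.sample_names)


@dataclass
class WindowCountTable:
    """Per-window read counts; 0-based half-open, non-overlapping windows."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "count"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"window table missing columns: {sorted(missing)}")
        if (self.data["count"] < 0).any():
            row = self.data.index[self.data["count"] < 0][0]
            raise FormatError(f"negative count at row {row}")
        if (self.data["end"] <= self.data["start"]).any():
            row = self.data.index[self.data["end"] <= self.data["start"]][0]
            raise FormatError(f"empty or inverted window at row {row}")
        for chrom, grp in self.data.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            overlap = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
            if overlap.any():
                j = int(np.flatnonzero(overlap)[0])
                a, b = g.index[j], g.index[j + 1]
                raise FormatError(
                    f"overlapping windows on {chrom}: rows {a} and {b}"
                )

    @property
    def has_gc(self) -> bool:
        return "gc" in self.data.columns and self.data["gc"].notna().all()


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write the minimal VCF dialect (uncompressed, GT:AD:DP)."""
    path = Path(path)
    chroms = list(dict.fromkeys(table.data["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_names)
            + "\n"
        )
        for _, row in table.data.iterrows():
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                ".",
                row["ref"],
                row["alt"],
                ".",
                "PASS",
                ".",
                "GT:AD:DP",
            ]
            for s in table.sample_names:
                ar = int(row[f"{s}.ad_ref"])
                aa = int(row[f"{s}.ad_alt"])
                dp = int(row[f"{s}.dp"])
                gt = "./." if dp == 0 else ("0/1" if 0 < aa < dp else ("1/1" if aa > 0 else "0/0"))
                fields.append(f"{gt}:{ar},{aa}:{dp}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> VariantTable:
    """Read the minimal VCF dialect via pysam.

    Multi-allelic records are rejected (dialect restriction); missing AD/DP
    raises a :class:`FormatError` naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if "AD" not in vf.header.formats or "DP" not in vf.header.formats:
        raise FormatError(f"{path}: FORMAT must declare AD and DP")
    rows = []
    for rec in vf:
        if rec.chrom in _Y_NAMES:
            continue
        if rec.alts is None or len(rec.alts) != 1:
            raise FormatError(
                f"{path}: multi-allelic record at {rec.chrom}:{rec.pos} "
                f"is outside the supported dialect"
            )
        row: dict[str, object] = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            "alt": rec.alts[0],
        }
        for s in samples:
            fmt = rec.samples[s]
            ad = fmt.get("AD")
            dp = fmt.get("DP")
            if ad is None or dp is None or ad[0] is None:
                raise FormatError(
                    f"{path}: missing AD/DP for sample {s} at {rec.chrom}:{rec.pos}"
                )
            if len(ad) != 2:
                raise FormatError(
                    f"{path}: AD with {len(ad)} entries at {rec.chrom}:{rec.pos}"
                )
            row[f"{s}.ad_ref"] = int(ad[0])
            row[f"{s}.ad_alt"] = int(ad[1])
            row[f"{s}.dp"] = int(dp)
        rows.append(row)
    vf.close()
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt"]
            + [f"{s}.{x}" for s in samples for x in ("ad_ref", "ad_alt", "dp")]
        )
    return VariantTable(df, samples)


def write_window_counts(table: WindowCountTable, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "count"] + (["gc"] if table.has_gc else [])
    table.data[cols].to_csv(path, sep="\t", index=False)


def read_window_counts(path: str | Path) -> WindowCountTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: cannot parse window TSV ({exc})") from exc
    for col in ("start", "end", "count"):
        if col in df.columns and not pd.api.types.is_integer_dtype(df[col]):
            raise FormatError(f"{path}: column {col} must be integer")
    df = df[~df["chrom"].isin(_Y_NAMES)].reset_index(drop=True)
    return WindowCountTable(df)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Labelled numeric matrix from CSV (first column = row ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, index_col=0)
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        bad = df[non_numeric[0]]
        offending = bad[pd.to_numeric(bad, errors="coerce").isna() & bad.notna()]
        line = int(df.index.get_loc(offending.index[0])) + 2 if len(offending) else "?"
        raise FormatError(
            f"{path}: non-numeric cell in column {non_numeric[0]!r} (line {line})"
        )
    return df


_CONFIG_DEFAULTS: dict[str, object] = {
    "seed": 0,
    "window_size_bp": 50_000,
    "base_ploidy": 2,
    "mean_depth": 60.0,
    "depth_dispersion": 0.2,
    "af_overdispersion": 0.0,
    "n_het_sites_per_chrom": 10_000,
    "n_somatic_snvs": 1_000,
    "alpha_fisher": 0.05,
    "alpha_binom": 0.1,
    "fixation_af": 0.95,
    "s0": 0.1,
    "fdr_target": 0.05,
    "n_permutations": 250,
    "msa_window": 3,
    "auc_diff_threshold": 50.0,
    "min_lines": 2,
    "candidates": [2, 3, 4],
    "n_subsample": 10_000,
}


def load_config(path: str | Path | None) -> dict[str, object]:
    """Load a YAML/JSON run configuration, filling documented defaults.

    Unknown keys are rejected so typos fail loudly.
    """
    cfg = dict(_CONFIG_DEFAULTS)
    if path is None:
        return cfg
    path = Path(path)
    text = path.read_text()
    user = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if user is None:
        return cfg
    if not isinstance(user, dict):
        raise FormatError(f"{path}: config must be a mapping")
    unknown = set(user) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise FormatError(f"{path}: unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg
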