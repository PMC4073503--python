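"""Readers and writers for the pipeline's on-disk table formats.

All tables are UTF-8 text with a header row; tab-separated for genomic
tables (marker map, genotypes, signals, windows, regions) and
comma-separated for phenotypes and fermentation curves.  Missing values are
written as "NA".  Floats are written with 12 significant digits so
parse-then-serialize round-trips are stable.  Schema violations raise
:class:`~segscan.errors.SchemaError` with a 1-based line number (header is
line 1) whenever a specific row is at fault.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .bsa import QTLRegion
from .errors import SchemaError
from .ferment import FermentationCurve
from .simulate import MarkerMap, SegregantGenotype

FLOAT_FMT = "%.12g"
NA = "NA"

PHENOTYPE_GROUPS = {"parentA", "parentB", "segregant", "hybrid"}
SIGNAL_SAMPLES = {"parentA", "parentB", "bulk_low", "bulk_high"}


def _read(path, sep, columns, **kw) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, keep_default_na=False, na_values=[NA], **kw)
    except Exception as exc:  # pandas parse failure
        raise SchemaError(f"cannot parse table: {exc}", path=str(path)) from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}", path=str(path), line=1)
    return df


def _line(row_index: int) -> int:
    """1-based file line of a dataframe row (header occupies line 1)."""
    return int(row_index) + 2


def _check_unique(df, column, path):
    dup = df[column].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(
            f"duplicate {column} {df[column].iloc[i]!r}", path=str(path), line=_line(i)
        )


def _write(df: pd.DataFrame, path, sep):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT, na_rep=NA)


# -- marker map ---------------------------------------------------------------

MAP_COLUMNS = ["marker", "chrom", "pos", "allele_A", "allele_B"]


def read_marker_map(path, genetic_rate: float = 0.35) -> MarkerMap:
    df = _read(path, "\t", MAP_COLUMNS, dtype={"chrom": str})
    _check_unique(df, "marker", path)
    for chrom, grp in df.groupby("chrom", sort=False):
        bad = np.flatnonzero(np.diff(grp["pos"].to_numpy()) <= 0)
        if bad.size:
            raise SchemaError(
                f"positions not strictly increasing on {chrom}",
                path=str(path),
                line=_line(grp.index[bad[0] + 1]),
            )
    return MarkerMap(
        ids=df["marker"].to_numpy(str),
        chromosome=df["chrom"].to_numpy(str),
        position_bp=df["pos"].to_numpy(np.int64),
        allele_A=df["allele_A"].to_numpy(str),
        allele_B=df["allele_B"].to_numpy(str),
        genetic_rate=genetic_rate,
    )


def write_marker_map(marker_map: MarkerMap, path):
    _write(marker_map.to_frame(), path, "\t")


# -- genotype matrix ----------------------------------------------------------


def read_genotypes(path) -> list[SegregantGenotype]:
    df = _read(path, "\t", ["marker"])
    _check_unique(df, "marker", path)
    strains = [c for c in df.columns if c != "marker"]
    if not strains:
        raise SchemaError("genotype matrix has no strain columns", path=str(path), line=1)
    out = []
    for s in strains:
        vals = df[s].to_numpy(str)
        bad = ~np.isin(vals, ("A", "B"))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"genotype of {s!r} must be 'A' or 'B', got {vals[i]!r}",
                path=str(path),
                line=_line(i),
            )
        out.append(SegregantGenotype(s, vals))
    return out


def write_genotypes(population: list[SegregantGenotype], marker_map: MarkerMap, path):
    data = {"marker": marker_map.ids}
    for seg in population:
        data[seg.strain_id] = seg.origin
    _write(pd.DataFrame(data), path, "\t")


# -- phenotypes ---------------------------------------------------------------

PHENOTYPE_COLUMNS = ["strain", "co2_at_checkpoint", "group"]


def read_phenotypes(path) -> pd.DataFrame:
    df = _read(path, ",", PHENOTYPE_COLUMNS, dtype={"strain": str, "group": str})
    _check_unique(df, "strain", path)
    bad = ~df["group"].isin(PHENOTYPE_GROUPS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"unknown group {df['group'].iloc[i]!r}", path=str(path), line=_line(i)
        )
    return df[PHENOTYPE_COLUMNS]


def write_phenotypes(df: pd.DataFrame, path):
    _write(df[PHENOTYPE_COLUMNS], path, ",")


# -- fermentation curves ------------------------------------------------------


def read_curve(path, volume_L: float | None = None) -> FermentationCurve:
    """Read a curve CSV with columns (time_h, co2_g_per_L) or (time_h,
    mass_g); the mass form requires ``volume_L``."""
    df = _read(path, ",", ["time_h"])
    if "co2_g_per_L" in df.columns:
        return FermentationCurve(df["time_h"].to_numpy(float), df["co2_g_per_L"].to_numpy(float))
    if "mass_g" in df.columns:
        if volume_L is None:
            raise SchemaError(
                "mass_g curve requires a fermenter volume", path=str(path), line=1
            )
        from .ferment import co2_from_mass

        return co2_from_mass(df["time_h"].to_numpy(float), df["mass_g"].to_numpy(float), volume_L)
    raise SchemaError("curve needs a co2_g_per_L or mass_g column", path=str(path), line=1)


def write_curve(curve: FermentationCurve, path):
    df = pd.DataFrame({"time_h": curve.time_h, "co2_g_per_L": curve.co2_cumulative})
    if curve.rate is not None:
        df["rate_g_per_L_h"] = curve.rate
    _write(df, path, ",")


def write_curves(curves: dict[str, FermentationCurve], path):
    """Long-format table of several strains' curves (strain, time_h, co2)."""
    frames = [
        pd.DataFrame(
            {"strain": name, "time_h": c.time_h, "co2_g_per_L": c.co2_cumulative}
        )
        for name, c in curves.items()
    ]
    _write(pd.concat(frames, ignore_index=True), path, ",")


# -- allelic-difference signals ----------------------------------------------

SIGNAL_COLUMNS = ["probe", "chrom", "pos", "sample", "block", "d"]


def read_signals(path) -> pd.DataFrame:
    df = _read(path, "\t", SIGNAL_COLUMNS, dtype={"probe": str, "chrom": str, "sample": str})
    bad = ~df["sample"].isin(SIGNAL_SAMPLES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"unknown sample {df['sample'].iloc[i]!r}", path=str(path), line=_line(i)
        )
    return df[SIGNAL_COLUMNS]


def write_signals(df: pd.DataFrame, path):
    _write(df[SIGNAL_COLUMNS], path, "\t")


# -- scan outputs -------------------------------------------------------------


def write_windows(windows: pd.DataFrame, path):
    _write(windows, path, "\t")


def regions_to_frame(regions: list[QTLRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "n_probes": r.n_probes,
                "peak_probe": r.peak_probe,
                "min_adjusted_p": r.min_adjusted_p,
                "mean_bulk_difference": r.mean_bulk_difference,
                "bulk_low_enriched": r.enriched.get("bulk_low") or NA,
                "bulk_high_enriched": r.enriched.get("bulk_high") or NA,
            }
            for r in regions
        ],
        columns=[
            "chrom",
            "start_bp",
            "end_bp",
            "n_probes",
            "peak_probe",
            "min_adjusted_p",
            "mean_bulk_difference",
            "bulk_low_enriched",
            "bulk_high_enriched",
        ],
    )


def write_regions_tsv(regions: list[QTLRegion], path):
    _write(regions_to_frame(regions), path, "\t")


def bed_score(adjusted_p: float) -> float:
    """-log10 adjusted p, capped for p == 0 or missing."""
    if adjusted_p is None or math.isnan(adjusted_p):
        return 0.0
    if adjusted_p <= 0.0:
        return 999.0
    return min(999.0, -math.log10(adjusted_p))


def write_regions_bed(regions: list[QTLRegion], path):
    """BED (0-based half-open): a 1-based inclusive span [s, e] becomes
    (s - 1, e)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for i, r in enumerate(regions, start=1):
            score = FLOAT_FMT % bed_score(r.min_adjusted_p)
            fh.write(
                f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\tregion_{i}\t{score}\n"
            )


def read_regions_bed(path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise SchemaError("BED line needs 5 fields", path=str(path), line=ln)
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "name": parts[3],
                    "score": float(parts[4]),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
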