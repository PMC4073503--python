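"""Bulk-segregant QTL scan on allele-specific microarray signals.

Pipeline, mirroring two-colour allele-specific CGH practice:

1. per-block centring of log2(green/red) ratios;
2. allelic difference d = centred ratio of the A-allele probe minus the
   B-allele probe at each biallelic locus;
3. a single affine normalization anchoring the parental means at +1.5
   (parent A, high capacity) and -1.5 (parent B);
4. probe filtering by a one-tailed Welch t-test of parental separation
   (Benjamini-Hochberg adjusted p < 0.05 by default);
5. a sliding-window (20 informative probes) paired t-test of the
   bulk-high minus bulk-low difference, BH-adjusted genome-wide;
6. region calling: probes inside significant windows whose bulk difference
   exceeds a stated fraction (default 1/3) of the local parental
   difference, merged into intervals, with the enriched parental origin
   reported per bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import genome
from .errors import (
    ConfigError,
    DegenerateNormalizationError,
    InputError,
    StructuralError,
)

PARENT_A = "parentA"
PARENT_B = "parentB"
BULK_LOW = "bulk_low"
BULK_HIGH = "bulk_high"
ANCHOR = 1.5


@dataclass(frozen=True)
class ScanParameters:
    """Tunable thresholds of the two-stage scan."""

    window_size: int = 20
    probe_alpha: float = 0.05
    window_alpha: float = 0.01
    parental_fraction: float = 1.0 / 3.0
    step: int = 1
    merge_gap: int = 2

    def __post_init__(self):
        if not (0 < self.probe_alpha < 1 and 0 < self.window_alpha < 1):
            raise ConfigError("alphas must lie in (0, 1)")
        if not (0 < self.parental_fraction <= 1):
            raise ConfigError("parental_fraction must lie in (0, 1]")
        if self.window_size < 2:
            raise ConfigError("window_size must be >= 2")
        if self.step < 1:
            raise ConfigError("step must be >= 1")
        if self.merge_gap < 0:
            raise ConfigError("merge_gap must be >= 0")


@dataclass
class QTLRegion:
    """A called interval with its peak probe and direction of enrichment."""

    chromosome: str
    start_bp: int
    end_bp: int
    n_probes: int
    peak_probe: str
    min_adjusted_p: float
    mean_bulk_difference: float
    #: enriched parental origin per bulk, e.g. {"bulk_high": "A",
    #: "bulk_low": "B"}; None marks an ambiguous (exactly zero mean) bulk.
    enriched: dict = field(default_factory=dict)
    member_probes: list = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def center_log_ratios(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-block centred log2(green/red) ratios.

    Grouping is by block, and additionally by sample when a ``sample``
    column is present (each hybridization is centred independently).
    Returns the input with a ``ratio`` column added; each group's centred
    ratios sum to zero.
    """
    for col in ("probe", "block", "green", "red"):
        if col not in raw.columns:
            raise InputError(f"raw intensity table lacks column {col!r}")
    if (raw["green"] <= 0).any() or (raw["red"] <= 0).any():
        raise InputError("intensities must be positive to take log ratios")
    out = raw.copy()
    ratio = np.log2(out["green"] / out["red"])
    keys = ["sample", "block"] if "sample" in out.columns else ["block"]
    out["ratio"] = ratio - ratio.groupby([out[k] for k in keys]).transform("mean")
    return out


def allelic_difference(centered: pd.DataFrame, pair_index: pd.DataFrame) -> pd.DataFrame:
    """Per-locus allelic difference d = ratio(A probe) - ratio(B probe).

    ``pair_index`` columns: locus, probe_A, probe_B, chrom, pos.  The
    difference is taken within each (sample,) block.  Output columns match
    the allelic-difference table schema (probe, chrom, pos, sample, block,
    d) with the locus id as the probe id.
    """
    for col in ("locus", "probe_A", "probe_B", "chrom", "pos"):
        if col not in pair_index.columns:
            raise InputError(f"pair index lacks column {col!r}")
    keys = ["sample", "block"] if "sample" in centered.columns else ["block"]
    piv = centered.pivot_table(index=keys, columns="probe", values="ratio")
    missing = [
        p
        for p in pd.concat([pair_index["probe_A"], pair_index["probe_B"]]).unique()
        if p not in piv.columns
    ]
    if missing:
        raise StructuralError(f"probe(s) missing from intensity table: {missing[:5]}")
    rows = []
    for _, pr in pair_index.iterrows():
        d = piv[pr["probe_A"]] - piv[pr["probe_B"]]
        if d.isna().any():
            raise StructuralError(f"incomplete probe pair for locus {pr['locus']!r}")
        frame = d.rename("d").reset_index()
        if "sample" not in frame.columns:
            frame["sample"] = "sample"
        frame.insert(0, "probe", pr["locus"])
        frame.insert(1, "chrom", pr["chrom"])
        frame.insert(2, "pos", pr["pos"])
        rows.append(frame[["probe", "chrom", "pos", "sample", "block", "d"]])
    return pd.concat(rows, ignore_index=True)


def parental_affine(table: pd.DataFrame, anchor: float = ANCHOR) -> tuple[float, float]:
    """Gain and offset of the affine map sending the raw parental means to
    +anchor (parent A) and -anchor (parent B)."""
    mean_a = table.loc[table["sample"] == PARENT_A, "d"].mean()
    mean_b = table.loc[table["sample"] == PARENT_B, "d"].mean()
    if np.isnan(mean_a) or np.isnan(mean_b):
        raise InputError("table lacks parentA and/or parentB rows")
    if mean_a == mean_b:
        raise DegenerateNormalizationError(
            "parental means coincide; the anchor normalization is undefined"
        )
    gain = 2.0 * anchor / (mean_a - mean_b)
    offset = anchor - gain * mean_a
    return float(gain), float(offset)


def normalize_parental(table: pd.DataFrame, anchor: float = ANCHOR) -> pd.DataFrame:
    """Apply the parental-anchor affine map to every sample's d values.

    After this, the mean over all parent-A rows is exactly +1.5 and over
    all parent-B rows exactly -1.5; bulks are transformed with the same
    gain and offset so mixtures stay comparable to the parental anchors.
    """
    gain, offset = parental_affine(table, anchor)
    out = table.copy()
    out["d"] = gain * out["d"] + offset
    out.attrs["normalization"] = {"gain": gain, "offset": offset}
    return out


def probe_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-probe mean d for each sample, ordered genome-wise.

    Returns one row per probe with columns chrom, pos and one column per
    sample, sorted by karyotype chromosome order then position.
    """
    piv = table.pivot_table(index=["probe", "chrom", "pos"], columns="sample", values="d")
    piv = piv.reset_index()
    piv["_ck"] = piv["chrom"].map(lambda c: genome.chrom_sort_key(c)[0])
    piv = piv.sort_values(["_ck", "chrom", "pos"]).drop(columns="_ck").reset_index(drop=True)
    piv.columns.name = None
    return piv


def select_parental_probes(table: pd.DataFrame, probe_alpha: float = 0.05) -> pd.DataFrame:
    """Informative probes: one-tailed Welch test of parental separation.

    Per probe, tests H1: mean d(parentA) > mean d(parentB) over replicate
    blocks, then Benjamini-Hochberg adjusts across all probes.  Returns a
    per-probe frame (probe, chrom, pos, t, p, p_adj, selected).
    """
    pa = table[table["sample"] == PARENT_A].pivot_table(index="probe", columns="block", values="d")
    pb = table[table["sample"] == PARENT_B].pivot_table(index="probe", columns="block", values="d")
    if pa.shape[1] < 2 or pb.shape[1] < 2:
        raise InputError("need >= 2 replicate blocks per parent for the probe test")
    pb = pb.loc[pa.index]
    t, p = stats.ttest_ind(
        pa.to_numpy(), pb.to_numpy(), axis=1, equal_var=False, alternative="greater"
    )
    coords = (
        table[["probe", "chrom", "pos"]].drop_duplicates("probe").set_index("probe").loc[pa.index]
    )
    out = pd.DataFrame(
        {
            "probe": pa.index,
            "chrom": coords["chrom"].to_numpy(),
            "pos": coords["pos"].to_numpy(),
            "t": t,
            "p": p,
        }
    )
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["selected"] = out["p_adj"] < probe_alpha
    out["_ck"] = out["chrom"].map(lambda c: genome.chrom_sort_key(c)[0])
    return out.sort_values(["_ck", "chrom", "pos"]).drop(columns="_ck").reset_index(drop=True)


@dataclass
class WindowScanResult:
    """Sliding-window statistics plus the per-probe frame they were built on.

    ``windows`` columns: chrom, start_idx, end_idx (positions in the
    chromosome's informative-probe order, end inclusive), start_bp, end_bp,
    n_probes, t, p, p_adj, truncated.  ``probes`` has one row per
    informative probe with per-sample means, the bulk difference ``diff``
    and the parental difference ``parent_diff``.
    """

    windows: pd.DataFrame
    probes: pd.DataFrame


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t of per-probe bulk differences against zero, vectorised
    over windows (rows).  Zero-variance windows get p=0 when the mean is
    nonzero, p=1 otherwise."""
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degenerate = sd == 0.0
    if degenerate.any():
        t = np.where(degenerate, np.where(mean != 0, np.inf, 0.0) * np.sign(mean), t)
        p = np.where(degenerate, np.where(mean != 0, 0.0, 1.0), p)
    return t, p


def window_scan(
    table: pd.DataFrame,
    informative_probes,
    params: ScanParameters = ScanParameters(),
) -> WindowScanResult:
    """Sliding-window paired t-tests of bulk_high - bulk_low differences.

    Windows of ``params.window_size`` consecutive informative probes are
    built per chromosome (step ``params.step``); a chromosome with fewer
    informative probes than the window yields a single truncated window
    (flagged), and chromosomes with fewer than 2 are skipped.  P-values are
    BH-adjusted genome-wide across all windows.
    """
    pm = probe_means(table)
    keep = pm["probe"].isin(set(informative_probes))
    pm = pm[keep].reset_index(drop=True)
    for col in (BULK_HIGH, BULK_LOW, PARENT_A, PARENT_B):
        if col not in pm.columns:
            raise InputError(f"table lacks sample {col!r}")
    pm["diff"] = pm[BULK_HIGH] - pm[BULK_LOW]
    pm["parent_diff"] = pm[PARENT_A] - pm[PARENT_B]

    records = []
    for chrom, grp in pm.groupby("chrom", sort=False):
        vals = grp["diff"].to_numpy()
        pos = grp["pos"].to_numpy()
        n = len(vals)
        if n < 2:
            continue
        w = min(params.window_size, n)
        truncated = n < params.window_size
        view = np.lib.stride_tricks.sliding_window_view(vals, w)[:: params.step]
        t, p = _paired_t(view)
        starts = np.arange(0, n - w + 1, params.step)
        for s, tv, pv in zip(starts, t, p):
            records.append(
                (chrom, int(s), int(s + w - 1), int(pos[s]), int(pos[s + w - 1]), w, tv, pv, truncated)
            )
    windows = pd.DataFrame(
        records,
        columns=[
            "chrom",
            "start_idx",
            "end_idx",
            "start_bp",
            "end_bp",
            "n_probes",
            "t",
            "p",
            "truncated",
        ],
    )
    if len(windows):
        windows["p_adj"] = multipletests(windows["p"], method="fdr_bh")[1]
    else:
        windows["p_adj"] = pd.Series(dtype=float)
    return WindowScanResult(windows=windows, probes=pm)


def _direction(mean_d: float) -> str | None:
    if mean_d > 0:
        return "A"
    if mean_d < 0:
        return "B"
    return None


def assign_direction(region: QTLRegion, table: pd.DataFrame) -> dict:
    """Enriched parental origin per bulk over the region's probes.

    A bulk whose mean normalized allelic difference across the region is
    positive carries predominantly parent-A alleles, negative parent-B;
    an exact zero is flagged as ambiguous (None).
    """
    inside = (
        (table["chrom"] == region.chromosome)
        & (table["pos"] >= region.start_bp)
        & (table["pos"] <= region.end_bp)
    )
    out = {}
    for bulk in (BULK_LOW, BULK_HIGH):
        mean_d = table.loc[inside & (table["sample"] == bulk), "d"].mean()
        out[bulk] = _direction(float(mean_d))
    return out


def call_regions(
    scan: WindowScanResult,
    params: ScanParameters = ScanParameters(),
) -> list[QTLRegion]:
    """Merge retained probes into QTL regions.

    A probe is retained when (a) it is covered by at least one window with
    BH-adjusted p < ``params.window_alpha`` and (b) its absolute bulk
    difference exceeds ``params.parental_fraction`` times the absolute
    parental difference at that probe.  Retained probes on a chromosome are
    merged into one region while consecutive retained probes are separated
    by at most ``params.merge_gap`` non-retained informative probes.
    """
    pm = scan.probes
    windows = scan.windows
    regions: list[QTLRegion] = []
    for chrom, grp in pm.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        n = len(grp)
        covered = np.zeros(n, dtype=bool)
        wchrom = windows[(windows["chrom"] == chrom) & (windows["p_adj"] < params.window_alpha)]
        for _, wrow in wchrom.iterrows():
            covered[int(wrow["start_idx"]) : int(wrow["end_idx"]) + 1] = True
        strong = (
            grp["diff"].abs().to_numpy()
            > params.parental_fraction * grp["parent_diff"].abs().to_numpy()
        )
        retained = covered & strong
        idx = np.flatnonzero(retained)
        if idx.size == 0:
            continue
        runs: list[list[int]] = [[int(idx[0])]]
        for i in idx[1:]:
            if i - runs[-1][-1] - 1 <= params.merge_gap:
                runs[-1].append(int(i))
            else:
                runs.append([int(i)])
        wall = windows[windows["chrom"] == chrom]
        for run in runs:
            members = grp.iloc[run]
            peak_row = members.loc[members["diff"].abs().idxmax()]
            overlap = wall[
                (wall["start_idx"] <= run[-1]) & (wall["end_idx"] >= run[0])
            ]
            min_p = float(overlap["p_adj"].min()) if len(overlap) else float("nan")
            mean_diff = float(members["diff"].mean())
            region = QTLRegion(
                chromosome=chrom,
                start_bp=int(members["pos"].iloc[0]),
                end_bp=int(members["pos"].iloc[-1]),
                n_probes=len(run),
                peak_probe=str(peak_row["probe"]),
                min_adjusted_p=min_p,
                mean_bulk_difference=mean_diff,
                member_probes=members["probe"].tolist(),
            )
            region.enriched = {
                BULK_LOW: _direction(float(members[BULK_LOW].mean())),
                BULK_HIGH: _direction(float(members[BULK_HIGH].mean())),
            }
            regions.append(region)
    return regions


def scan_table(
    table: pd.DataFrame,
    params: ScanParameters = ScanParameters(),
) -> tuple[pd.DataFrame, WindowScanResult, list[QTLRegion]]:
    """Convenience wrapper: normalize, filter probes, scan, call regions.

    Returns (per-probe parental-test frame, window scan result, regions).
    """
    normalized = normalize_parental(table)
    probes = select_parental_probes(normalized, params.probe_alpha)
    informative = probes.loc[probes["selected"], "probe"]
    scan = window_scan(normalized, informative, params)
    regions = call_regions(scan, params)
    return probes, scan, regions
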