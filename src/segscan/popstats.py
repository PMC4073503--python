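"""Quantitative-genetics summaries of the segregant population.

Broad-sense heritability is estimated from the excess of segregant
phenotypic variance over the environmental variance seen in replicate
parental measurements:

    H2 = ((Var_seg - Var_env) / Var_seg) * 100

with Var_env the df-weighted pooled variance of the two parental replicate
sets.  Transgressive segregants lie at least two pooled-parental standard
deviations beyond the nearer parental mean on either side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedStatisticError


@dataclass(frozen=True)
class HeritabilityResult:
    H2_percent: float
    var_seg: float
    var_env: float
    #: True when Var_env exceeds Var_seg, i.e. the unclipped estimate is
    #: negative and should be read as "no detectable genetic variance".
    negative_estimate: bool


@dataclass(frozen=True)
class TransgressionResult:
    n_high: int
    n_low: int
    percent: float
    sigma: float
    thresholds: tuple[float, float]  # (low_cut, high_cut)


def _check_groups(seg, rep_a, rep_b):
    seg = np.asarray(seg, dtype=float)
    rep_a = np.asarray(rep_a, dtype=float)
    rep_b = np.asarray(rep_b, dtype=float)
    for name, arr in (("segregant", seg), ("parentA", rep_a), ("parentB", rep_b)):
        if len(arr) < 2:
            raise InputError(f"need >= 2 values in the {name} group")
    return seg, rep_a, rep_b


def pooled_variance(a: np.ndarray, b: np.ndarray) -> float:
    """Degrees-of-freedom weighted pooled sample variance of two groups."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(
        ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
        / (len(a) + len(b) - 2)
    )


def heritability(segregant_values, parentA_replicates, parentB_replicates) -> HeritabilityResult:
    """Broad-sense heritability of the checkpoint phenotype (percent)."""
    seg, rep_a, rep_b = _check_groups(segregant_values, parentA_replicates, parentB_replicates)
    var_seg = float(np.var(seg, ddof=1))
    if var_seg == 0.0:
        raise UndefinedStatisticError("segregant variance is zero; H2 undefined")
    var_env = pooled_variance(rep_a, rep_b)
    h2 = (var_seg - var_env) / var_seg * 100.0
    return HeritabilityResult(h2, var_seg, var_env, negative_estimate=h2 < 0.0)


def transgression(segregant_values, parentA_replicates, parentB_replicates) -> TransgressionResult:
    """Count segregants beyond both parents by at least 2 pooled-parental SD.

    Boundaries are inclusive ("at least 2 sigma").
    """
    seg, rep_a, rep_b = _check_groups(segregant_values, parentA_replicates, parentB_replicates)
    sigma = float(np.sqrt(pooled_variance(rep_a, rep_b)))
    mean_a, mean_b = float(np.mean(rep_a)), float(np.mean(rep_b))
    high_cut = max(mean_a, mean_b) + 2.0 * sigma
    low_cut = min(mean_a, mean_b) - 2.0 * sigma
    n_high = int(np.sum(seg >= high_cut))
    n_low = int(np.sum(seg <= low_cut))
    percent = 100.0 * (n_high + n_low) / len(seg)
    return TransgressionResult(n_high, n_low, percent, sigma, (low_cut, high_cut))


def select_bulks(
    phenotype_table: pd.DataFrame,
    k: int = 15,
    value_column: str = "co2_at_checkpoint",
) -> tuple[list[str], list[str]]:
    """The k lowest- and k highest-phenotype segregants (bulk membership).

    Rows with ``group`` other than "segregant" are ignored when a group
    column is present.  Ties are broken by strain id so the selection is
    deterministic: the low bulk prefers lexicographically smaller ids, the
    high bulk larger ones, keeping the bulks disjoint whenever 2k <= n.
    """
    df = phenotype_table
    if "group" in df.columns:
        df = df[df["group"] == "segregant"]
    if df["strain"].duplicated().any():
        dup = df["strain"][df["strain"].duplicated()].iloc[0]
        raise InputError(f"duplicate strain id {dup!r} in phenotype table")
    n = len(df)
    if 2 * k > n:
        raise InputError(f"cannot draw two disjoint bulks of {k} from {n} segregants")
    asc = df.sort_values([value_column, "strain"], ascending=[True, True])
    desc = df.sort_values([value_column, "strain"], ascending=[False, False])
    low = asc["strain"].head(k).tolist()
    high = desc["strain"].head(k).tolist()
    return low, high
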