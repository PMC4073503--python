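"""Synthetic two-parent yeast cross, phenotypes, and pooled array signals.

This module generates every input the downstream analysis consumes:

* a biallelic marker map over the 16 yeast chromosomes;
* F2 haploid segregants produced by simulated meioses (Haldane model,
  crossovers as a Poisson process along the genetic map);
* quantitative phenotypes (CO2 produced by a fixed fermentation checkpoint)
  under a planted additive QTL architecture, calibrated to a target
  broad-sense heritability;
* fermentation curves consistent with those phenotypes;
* allele-specific microarray signals for the two parents and two
  phenotype-extreme segregant pools, on the normalized allelic-difference
  scale where a pure high-capacity-parent (A) pool sits at +1.5 and a pure
  low-capacity-parent (B) pool at -1.5.

Parent A is the high-fermentation-capacity founder (haploid 2029-C5),
parent B the low-capacity founder (1782-B1).  All randomness flows through
an explicit ``numpy.random.Generator`` so every output is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from . import genome
from .errors import ConfigError, InputError, StructuralError
from .ferment import FermentationCurve

ORIGIN_A = "A"
ORIGIN_B = "B"

#: normalized allelic difference of a pool containing only parent-A alleles
ANCHOR = 1.5

#: d = _SLOPE * f + _INTERCEPT maps pool A-allele frequency f to the
#: normalized allelic-difference scale (f=1 -> +1.5, f=0 -> -1.5).
_SLOPE = 2 * ANCHOR
_INTERCEPT = -ANCHOR

SAMPLES = ("parentA", "parentB", "bulk_low", "bulk_high")

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass(frozen=True)
class MarkerMap:
    """Ordered biallelic marker coordinates plus a uniform genetic rate.

    Markers are stored grouped by chromosome (karyotype order) with strictly
    increasing positions inside each chromosome.  ``genetic_rate`` is the
    genome-wide map expansion in cM per kb; the yeast genome averages about
    0.35 cM/kb, which is the default used by :meth:`default_map`.
    """

    ids: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_A: np.ndarray
    allele_B: np.ndarray
    genetic_rate: float = 0.35

    def __post_init__(self):
        n = len(self.ids)
        for name in ("chromosome", "position_bp", "allele_A", "allele_B"):
            if len(getattr(self, name)) != n:
                raise StructuralError(f"marker map field '{name}' has wrong length")
        if n == 0:
            raise InputError("marker map is empty")
        if self.genetic_rate < 0:
            raise ConfigError("genetic_rate must be non-negative")
        if np.any(self.allele_A == self.allele_B):
            bad = self.ids[self.allele_A == self.allele_B][0]
            raise InputError(f"marker {bad!r} is not biallelic (allele_A == allele_B)")
        if np.any(self.position_bp < 1):
            raise InputError("marker positions must be >= 1 (1-based)")
        for chrom, sl in self.chrom_slices.items():
            pos = self.position_bp[sl]
            if np.any(np.diff(pos) <= 0):
                raise InputError(
                    f"positions not strictly increasing on {chrom}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    @cached_property
    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome, in order of appearance."""
        slices: dict[str, slice] = {}
        chroms = self.chromosome
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                if chroms[start] in slices:
                    raise InputError(
                        f"chromosome {chroms[start]} occurs in non-contiguous blocks"
                    )
                slices[chroms[start]] = slice(start, i)
                start = i
        return slices

    @cached_property
    def _recomb_fractions(self) -> dict[str, np.ndarray]:
        out = {}
        for chrom, sl in self.chrom_slices.items():
            gaps_kb = np.diff(self.position_bp[sl]) / 1000.0
            d_morgans = gaps_kb * self.genetic_rate / 100.0
            out[chrom] = 0.5 * (1.0 - np.exp(-2.0 * d_morgans))
        return out

    def recombination_fractions(self, chrom: str) -> np.ndarray:
        """Haldane recombination fraction between adjacent markers of one
        chromosome: r = (1 - exp(-2 d)) / 2 with d the map distance in
        Morgans (gap_kb * rate_cM_per_kb / 100)."""
        return self._recomb_fractions[chrom]

    def nearest_marker(self, chrom: str, position_bp: int) -> int:
        """Global index of the marker on ``chrom`` closest to ``position_bp``."""
        if chrom not in self.chrom_slices:
            raise InputError(f"chromosome {chrom!r} not on the map")
        sl = self.chrom_slices[chrom]
        pos = self.position_bp[sl]
        return sl.start + int(np.argmin(np.abs(pos.astype(np.int64) - position_bp)))

    @classmethod
    def default_map(cls, n_markers: int = 6318, genetic_rate: float = 0.35) -> "MarkerMap":
        """Evenly spaced markers allocated to the 16 chromosomes in
        proportion to their physical length (6,318 biallelic probe pairs by
        default, matching an 8x15K allele-specific design)."""
        if n_markers < len(genome.CHROMOSOMES):
            raise ConfigError("need at least one marker per chromosome")
        sizes = np.array([genome.CHROMOSOME_SIZES_BP[c] for c in genome.CHROMOSOMES], float)
        quota = n_markers * sizes / sizes.sum()
        counts = np.floor(quota).astype(int)
        counts = np.maximum(counts, 1)
        # largest-remainder top-up to hit the exact total
        remainder = quota - np.floor(quota)
        short = n_markers - counts.sum()
        if short > 0:
            for i in np.argsort(-remainder)[:short]:
                counts[i] += 1
        elif short < 0:
            for i in np.argsort(remainder):
                if counts[i] > 1 and short < 0:
                    counts[i] -= 1
                    short += 1
        ids, chroms, pos, a_allele, b_allele = [], [], [], [], []
        k = 0
        for chrom, size, cnt in zip(genome.CHROMOSOMES, sizes, counts):
            p = np.round((np.arange(1, cnt + 1)) * size / (cnt + 1)).astype(np.int64)
            p = np.maximum.accumulate(np.maximum(p, 1))  # guard tiny chromosomes
            for j in range(cnt):
                pair = _ALLELE_PAIRS[(k + j) % len(_ALLELE_PAIRS)]
                ids.append(f"m{k + j + 1:05d}")
                a_allele.append(pair[0])
                b_allele.append(pair[1])
            chroms.extend([chrom] * cnt)
            pos.extend(p.tolist())
            k += cnt
        return cls(
            ids=np.array(ids),
            chromosome=np.array(chroms),
            position_bp=np.array(pos, dtype=np.int64),
            allele_A=np.array(a_allele),
            allele_B=np.array(b_allele),
            genetic_rate=genetic_rate,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.ids,
                "chrom": self.chromosome,
                "pos": self.position_bp,
                "allele_A": self.allele_A,
                "allele_B": self.allele_B,
            }
        )


@dataclass
class SegregantGenotype:
    """Per-marker parental origin ('A' or 'B') of one haploid segregant."""

    strain_id: str
    origin: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype="<U1")
        bad = ~np.isin(self.origin, (ORIGIN_A, ORIGIN_B))
        if bad.any():
            raise InputError(
                f"{self.strain_id}: origins must be 'A' or 'B' at every marker"
            )

    def __len__(self) -> int:
        return len(self.origin)


def founder_genotype(marker_map: MarkerMap, origin: str, strain_id: str) -> SegregantGenotype:
    """A pure parental haploid: the same origin at every marker."""
    if origin not in (ORIGIN_A, ORIGIN_B):
        raise InputError("founder origin must be 'A' or 'B'")
    return SegregantGenotype(strain_id, np.full(marker_map.n_markers, origin, dtype="<U1"))


@dataclass(frozen=True)
class QTLLocus:
    chromosome: str
    position_bp: int
    effect_size: float
    beneficial_origin: str


@dataclass(frozen=True)
class QTLEffectModel:
    """Additive planted-QTL architecture for the fermentation phenotype.

    ``baseline`` is the phenotype (g/L CO2 at the checkpoint) of a segregant
    carrying no beneficial allele; each locus adds ``effect_size`` when the
    segregant's origin at the nearest mapped marker equals
    ``beneficial_origin``.  ``target_H2`` sets the broad-sense heritability
    the generator calibrates its environmental noise to; ``env_sd_parent``
    optionally overrides the parental measurement noise (``None`` means the
    parents share the segregants' derived environmental sd).
    """

    loci: tuple[QTLLocus, ...]
    baseline: float = 25.0
    target_H2: float = 0.98
    env_sd_parent: float | None = None

    def __post_init__(self):
        if not (0.0 < self.target_H2 <= 1.0):
            raise ConfigError("target_H2 must lie in (0, 1]")
        for locus in self.loci:
            if locus.beneficial_origin not in (ORIGIN_A, ORIGIN_B):
                raise ConfigError("beneficial_origin must be 'A' or 'B'")
        if self.env_sd_parent is not None and self.env_sd_parent < 0:
            raise ConfigError("env_sd_parent must be non-negative")

    @classmethod
    def default_model(cls) -> "QTLEffectModel":
        """Four QTL: two on chrVII with opposite beneficial origins, one
        each on chrXIII and chrXIV.  Three beneficial alleles come from the
        low-capacity parent B; the single large-effect beneficial A allele
        makes parent A the higher parent under additivity."""
        return cls(
            loci=(
                QTLLocus("chrVII", 683_000, 1.2, ORIGIN_B),
                QTLLocus("chrVII", 748_000, 4.0, ORIGIN_A),
                QTLLocus("chrXIII", 450_000, 1.0, ORIGIN_B),
                QTLLocus("chrXIV", 400_000, 0.8, ORIGIN_B),
            ),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale knobs: 133 F2 segregants, two pools of 15, 8 replicate
    blocks per array, probe noise 0.1 log-ratio units, 3 fermentations per
    parent."""

    seed: int = 0
    n_segregants: int = 133
    bulk_size: int = 15
    n_blocks: int = 8
    probe_noise_sd: float = 0.1
    n_parent_replicates: int = 3

    def __post_init__(self):
        if min(self.n_segregants, self.bulk_size, self.n_blocks) < 1:
            raise ConfigError("all counts must be positive")
        if self.n_parent_replicates < 2:
            raise ConfigError("need >= 2 parental replicates")
        if 2 * self.bulk_size > self.n_segregants:
            raise ConfigError("2 * bulk_size must not exceed n_segregants")
        if self.probe_noise_sd < 0:
            raise ConfigError("probe_noise_sd must be non-negative")


def simulate_meiosis(
    parent1: SegregantGenotype,
    parent2: SegregantGenotype,
    marker_map: MarkerMap,
    rng: np.random.Generator,
) -> SegregantGenotype:
    """One recombinant haploid from a parent1 x parent2 diploid.

    Crossovers follow a Poisson process along the genetic map (no
    interference), which for adjacent markers at map distance d Morgans is
    equivalent to an independent strand switch with Haldane probability
    r = (1 - exp(-2d)) / 2.  Each chromosome starts from either parental
    strand with probability 1/2.
    """
    n = marker_map.n_markers
    if len(parent1) != n or len(parent2) != n:
        raise StructuralError("parent genotypes do not match the marker map length")
    use_p2 = np.empty(n, dtype=bool)
    for chrom, sl in marker_map.chrom_slices.items():
        m = sl.stop - sl.start
        start = rng.integers(0, 2)
        if m == 1:
            state = np.array([start])
        else:
            switches = rng.random(m - 1) < marker_map.recombination_fractions(chrom)
            state = (start + np.concatenate(([0], np.cumsum(switches)))) % 2
        use_p2[sl] = state.astype(bool)
    origin = np.where(use_p2, parent2.origin, parent1.origin)
    return SegregantGenotype("recombinant", origin)


def make_f2_population(
    marker_map: MarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SegregantGenotype]:
    """F2 haploid segregants from an A x B founder cross.

    F1 haploids are meiotic products of the founder hybrid; each F2 diploid
    is a random pairing of two independently generated F1 haploids, and one
    haploid spore is sampled from it by a second meiosis.
    """
    if config.n_segregants < 1:
        raise ConfigError("n_segregants must be >= 1")
    founder_a = founder_genotype(marker_map, ORIGIN_A, "2029-C5")
    founder_b = founder_genotype(marker_map, ORIGIN_B, "1782-B1")
    population = []
    for i in range(config.n_segregants):
        f1_a = simulate_meiosis(founder_a, founder_b, marker_map, rng)
        f1_b = simulate_meiosis(founder_a, founder_b, marker_map, rng)
        spore = simulate_meiosis(f1_a, f1_b, marker_map, rng)
        spore.strain_id = f"seg{i + 1:03d}"
        population.append(spore)
    return population


def genetic_values(
    population: list[SegregantGenotype],
    model: QTLEffectModel,
    marker_map: MarkerMap,
) -> np.ndarray:
    """Additive genetic value of each segregant under the planted model."""
    idx = [marker_map.nearest_marker(l.chromosome, l.position_bp) for l in model.loci]
    g = np.full(len(population), model.baseline, dtype=float)
    for locus, i in zip(model.loci, idx):
        carriers = np.array([seg.origin[i] == locus.beneficial_origin for seg in population])
        g += locus.effect_size * carriers
    return g


def _founder_value(model: QTLEffectModel, origin: str) -> float:
    return model.baseline + sum(
        l.effect_size for l in model.loci if l.beneficial_origin == origin
    )


def assign_phenotypes(
    population: list[SegregantGenotype],
    model: QTLEffectModel,
    config: SimulationConfig,
    marker_map: MarkerMap,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phenotypes for the segregants plus replicate parental measurements.

    Environmental noise sd is derived from the realized genetic variance
    Vg so that the expected broad-sense heritability equals
    ``model.target_H2``: sigma^2 = Vg (1 - H2) / H2.  When Vg is zero the
    derivation is vacuous and ``env_sd_parent`` (if set) is used instead.
    Parental replicates get sd ``env_sd_parent``, defaulting to the
    segregants' derived sd so both estimates see the same environment.

    Returns a table with columns ``strain``, ``group`` (parentA / parentB /
    segregant) and ``co2_at_checkpoint``.
    """
    g = genetic_values(population, model, marker_map)
    var_g = float(np.var(g, ddof=1)) if len(g) > 1 else 0.0
    if var_g > 0:
        sigma = float(np.sqrt(var_g * (1.0 - model.target_H2) / model.target_H2))
    else:
        sigma = model.env_sd_parent or 0.0
    sigma_parent = model.env_sd_parent if model.env_sd_parent is not None else sigma

    rows = []
    values = g + rng.normal(0.0, sigma, size=len(g)) if sigma > 0 else g.copy()
    for seg, v in zip(population, values):
        rows.append((seg.strain_id, "segregant", v))
    for origin, group, name in ((ORIGIN_A, "parentA", "2029-C5"), (ORIGIN_B, "parentB", "1782-B1")):
        mu = _founder_value(model, origin)
        reps = mu + (
            rng.normal(0.0, sigma_parent, size=config.n_parent_replicates)
            if sigma_parent > 0
            else np.zeros(config.n_parent_replicates)
        )
        for j, v in enumerate(reps, start=1):
            rows.append((f"{name}_rep{j}", group, v))
    return pd.DataFrame(rows, columns=["strain", "group", "co2_at_checkpoint"])


def simulate_fermentation_curve(
    phenotype: float,
    duration_h: float = 120.0,
    step_min: float = 20.0,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    checkpoint_h: float = 89.0,
) -> FermentationCurve:
    """Cumulative CO2 curve whose noiseless value at ``checkpoint_h`` equals
    ``phenotype`` exactly.

    The shape is a growth-phase ramp (Gaussian saturation over ~18 h)
    multiplied by a slowly rising stationary-phase term, so the production
    rate peaks at the end of growth and declines to a capacity-dependent
    stationary rate.  Sampling every ``step_min`` minutes from t=0.
    """
    if duration_h <= 0:
        raise InputError("duration_h must be positive")
    t = np.arange(0.0, round(duration_h * 60.0) + 0.5, step_min) / 60.0

    def shape(x):
        return (1.0 - np.exp(-((x / 18.0) ** 2))) * (0.55 + 0.45 * x / checkpoint_h)

    co2 = phenotype * shape(t) / shape(checkpoint_h)
    if noise_sd > 0:
        if rng is None:
            raise InputError("noise_sd > 0 requires an rng")
        co2 = co2 + rng.normal(0.0, noise_sd, size=t.shape)
    return FermentationCurve(time_h=t, co2_cumulative=co2)


def pool_allele_frequency(bulk: list[SegregantGenotype]) -> np.ndarray:
    """Per-marker frequency of the parent-A origin across pool members."""
    if not bulk:
        raise InputError("bulk is empty")
    stack = np.stack([seg.origin == ORIGIN_A for seg in bulk])
    return stack.mean(axis=0)


def expected_allelic_difference(freq_a: np.ndarray) -> np.ndarray:
    """Affine map from pool A-allele frequency to the normalized
    allelic-difference scale: d = 3 f - 1.5."""
    return _SLOPE * np.asarray(freq_a, float) + _INTERCEPT


def simulate_pool_signals(
    bulk: list[SegregantGenotype],
    marker_map: MarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample: str = "bulk_high",
) -> pd.DataFrame:
    """Noisy allelic-difference rows for one pooled hybridization.

    Each probe's expected value is the affine image of the pool's A-allele
    frequency; one replicate per array block is emitted with Gaussian probe
    noise ``config.probe_noise_sd``.
    """
    d0 = expected_allelic_difference(pool_allele_frequency(bulk))
    n = marker_map.n_markers
    frames = []
    for block in range(1, config.n_blocks + 1):
        d = d0 + (
            rng.normal(0.0, config.probe_noise_sd, size=n)
            if config.probe_noise_sd > 0
            else 0.0
        )
        frames.append(
            pd.DataFrame(
                {
                    "probe": marker_map.ids,
                    "chrom": marker_map.chromosome,
                    "pos": marker_map.position_bp,
                    "sample": sample,
                    "block": block,
                    "d": d,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_signal_table(
    population: list[SegregantGenotype],
    low_ids: list[str],
    high_ids: list[str],
    marker_map: MarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Full allelic-difference table: both parents (pools of one pure
    founder each) and the two phenotype-extreme bulks."""
    by_id = {seg.strain_id: seg for seg in population}
    missing = [s for s in list(low_ids) + list(high_ids) if s not in by_id]
    if missing:
        raise InputError(f"bulk members not in population: {missing[:3]}")
    pools = {
        "parentA": [founder_genotype(marker_map, ORIGIN_A, "2029-C5")],
        "parentB": [founder_genotype(marker_map, ORIGIN_B, "1782-B1")],
        "bulk_low": [by_id[s] for s in low_ids],
        "bulk_high": [by_id[s] for s in high_ids],
    }
    return pd.concat(
        [
            simulate_pool_signals(pool, marker_map, config, rng, sample=name)
            for name, pool in pools.items()
        ],
        ignore_index=True,
    )


@dataclass
class SimulatedStudy:
    """Bundle of all artifacts from one simulated cross-and-scan study."""

    marker_map: MarkerMap
    population: list[SegregantGenotype]
    phenotypes: pd.DataFrame
    low_bulk: list[str]
    high_bulk: list[str]
    signals: pd.DataFrame


def simulate_study(
    config: SimulationConfig,
    model: QTLEffectModel | None = None,
    marker_map: MarkerMap | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedStudy:
    """End-to-end generator: cross, phenotypes, bulk selection, signals."""
    from . import popstats

    if model is None:
        model = QTLEffectModel.default_model()
    if marker_map is None:
        marker_map = MarkerMap.default_map()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    population = make_f2_population(marker_map, config, rng)
    phenotypes = assign_phenotypes(population, model, config, marker_map, rng)
    low, high = popstats.select_bulks(phenotypes, k=config.bulk_size)
    signals = simulate_signal_table(population, low, high, marker_map, config, rng)
    return SimulatedStudy(marker_map, population, phenotypes, low, high, signals)
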