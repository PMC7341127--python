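"""Synthetic RIAIL panels with known ground truth.

Generates two-parent recombinant-mosaic genotype panels, quantitative traits
with planted QTL, expression panels with local/distant eQTL and a regulatory
hotspot, and drug-like traits mediated by the expression of a gene under that
hotspot.  Every generator is seeded and returns the planted truth alongside
the data, so each downstream analysis stage can be tested for recovery.

Model choices
-------------
* Crossovers per chromosome are Poisson with mean
  ``map_expansion * length_cM / 100`` and breakpoints uniform in genetic
  distance (Haldane model, no interference).  ``map_expansion`` absorbs the
  map-expanding effect of advanced intercrossing before inbreeding.
* Genotypes are coded 0 (parent A) / 1 (parent B); the missing sentinel is
  ``-1``.  Correlation-based mapping is invariant to affine recoding, and
  0/1 matches homozygous inbred biology.
* Trait noise is Gaussian; noise variance is scaled against the realized
  genetic variance on the panel so the expected heritability matches the
  target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1
"""Sentinel for a missing genotype call."""

#: Default chromosome labels, nematode-style (5 autosomes + X).
CHROM_LABELS = ("I", "II", "III", "IV", "V", "X")

MAP_COLUMNS = ("marker", "chrom", "cm", "bp")


def _chrom_names(n: int) -> list[str]:
    if n <= len(CHROM_LABELS):
        return list(CHROM_LABELS[:n])
    return [f"chr{i + 1}" for i in range(n)]


def validate_marker_map(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Check a marker map for the invariants the scans rely on.

    Requires columns ``marker, chrom, cm, bp``; unique marker ids; strictly
    increasing genetic and physical positions within each chromosome;
    ``cm >= 0`` and ``bp >= 1``.  Returns the validated frame.
    """
    missing_cols = set(MAP_COLUMNS) - set(marker_map.columns)
    if missing_cols:
        raise ValueError(f"marker map missing columns: {sorted(missing_cols)}")
    if marker_map["marker"].duplicated().any():
        dup = marker_map.loc[marker_map["marker"].duplicated(), "marker"].iloc[0]
        raise ValueError(f"duplicate marker id: {dup!r}")
    if (marker_map["cm"] < 0).any():
        raise ValueError("genetic positions must be >= 0 cM")
    if (marker_map["bp"] < 1).any():
        raise ValueError("physical positions must be >= 1 (1-based)")
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        for col in ("cm", "bp"):
            v = grp[col].to_numpy()
            if np.any(np.diff(v) <= 0):
                raise ValueError(
                    f"{col} positions not strictly increasing on chromosome {chrom}"
                )
    return marker_map


@dataclass
class GenotypePanel:
    """Lines x markers panel of parental-allele codes plus its marker map.

    ``genotypes``: DataFrame indexed by line id with one int column per
    marker; values in {0, 1, -1} (missing).  ``marker_map``: one row per
    marker with columns ``marker, chrom, cm, bp``, in genome order matching
    the genotype columns.
    """

    genotypes: pd.DataFrame
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        validate_marker_map(self.marker_map)
        if list(self.genotypes.columns) != list(self.marker_map["marker"]):
            raise ValueError("genotype columns must match marker map order")
        values = self.genotypes.to_numpy()
        bad = ~np.isin(values, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid allele code {values[i, j]!r} at line "
                f"{self.genotypes.index[i]!r}, marker {self.genotypes.columns[j]!r}"
            )

    @property
    def lines(self) -> pd.Index:
        return self.genotypes.index

    @property
    def markers(self) -> pd.Index:
        return self.genotypes.columns

    @property
    def n_lines(self) -> int:
        return len(self.genotypes)

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def allele_matrix(self) -> np.ndarray:
        """Float matrix with missing calls as NaN."""
        g = self.genotypes.to_numpy(dtype=float)
        g[g == MISSING] = np.nan
        return g

    def marker_info(self, marker: str) -> pd.Series:
        rows = self.marker_map[self.marker_map["marker"] == marker]
        if rows.empty:
            raise KeyError(f"unknown marker id: {marker!r}")
        return rows.iloc[0]

    def genotype_at(self, marker: str) -> pd.Series:
        """Genotype column at ``marker`` as float with NaN for missing."""
        if marker not in self.genotypes.columns:
            raise KeyError(f"unknown marker id: {marker!r}")
        g = self.genotypes[marker].astype(float)
        return g.mask(g == MISSING)


@dataclass
class SimulationSpec:
    """Ground-truth description of one simulated study."""

    n_lines: int = 300
    qtl_effects: list[tuple[str, float]] = field(default_factory=list)
    heritability_target: float = 0.5
    hotspot_locus: str | None = None
    n_hotspot_genes: int = 0
    mediation_paths: tuple[float, float, float] = (0.8, 0.5, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heritability_target <= 1.0:
            raise ValueError("heritability_target must be in [0, 1]")


def generate_marker_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    chrom_length_cm: float = 50.0,
    bp_per_cm: float = 40_000.0,
    spacing: str = "even",
    seed: int | None = None,
) -> pd.DataFrame:
    """Build a marker map with evenly or uniformly-randomly spaced markers.

    Genetic positions span ``[0, chrom_length_cm]`` per chromosome; physical
    positions are affinely related, ``bp = round(cm * bp_per_cm) + 1``
    (1-based origin).

    Parameters
    ----------
    spacing : {"even", "random"}
        ``even`` partitions the chromosome uniformly (first marker at 0 cM,
        last at ``chrom_length_cm``); ``random`` draws sorted uniform
        positions.
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("need at least one chromosome and one marker per chromosome")
    if chrom_length_cm <= 0 or bp_per_cm <= 0:
        raise ValueError("chrom_length_cm and bp_per_cm must be positive")
    if spacing not in ("even", "random"):
        raise ValueError(f"unknown spacing {spacing!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in _chrom_names(n_chromosomes):
        if spacing == "even":
            if markers_per_chromosome == 1:
                cm = np.array([0.0])
            else:
                cm = np.linspace(0.0, chrom_length_cm, markers_per_chromosome)
        else:
            # resample on the rare event that rounding to bp collides
            while True:
                cm = np.sort(rng.uniform(0.0, chrom_length_cm, markers_per_chromosome))
                bp_try = np.round(cm * bp_per_cm).astype(np.int64) + 1
                if np.all(np.diff(bp_try) > 0) or markers_per_chromosome == 1:
                    break
        bp = np.round(cm * bp_per_cm).astype(np.int64) + 1
        for i in range(markers_per_chromosome):
            rows.append((f"{chrom}_{i + 1:04d}", chrom, float(cm[i]), int(bp[i])))
    return pd.DataFrame(rows, columns=list(MAP_COLUMNS))


def simulate_riail_genotypes(
    marker_map: pd.DataFrame,
    n_lines: int,
    map_expansion: float = 4.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> GenotypePanel:
    """Simulate a panel of recombinant inbred mosaic genotypes.

    Each line is built chromosome by chromosome: the starting parental allele
    is Bernoulli(1/2); the crossover count is Poisson with mean
    ``map_expansion * chrom_length_cM / 100``; breakpoints fall uniformly in
    genetic distance and alleles alternate at each breakpoint (Haldane, no
    interference).  Lines are independent given the seed.

    ``map_expansion`` (>= 1 for RIAILs; default 4) models the denser
    breakpoints produced by advanced intercrossing before inbreeding.
    """
    validate_marker_map(marker_map)
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if map_expansion < 0:
        raise ValueError("map_expansion must be nonnegative")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    chroms = marker_map["chrom"].unique()
    cols: list[np.ndarray] = []
    for chrom in chroms:
        pos = marker_map.loc[marker_map["chrom"] == chrom, "cm"].to_numpy()
        length = pos.max() if len(pos) else 0.0
        mean_xo = map_expansion * length / 100.0
        geno = np.empty((n_lines, len(pos)), dtype=np.int8)
        for i in range(n_lines):
            start = int(rng.integers(0, 2))
            n_xo = rng.poisson(mean_xo) if mean_xo > 0 else 0
            if n_xo == 0:
                geno[i] = start
            else:
                breaks = np.sort(rng.uniform(0.0, length, n_xo))
                # parity of breakpoints to the left of each marker flips the allele
                crossings = np.searchsorted(breaks, pos, side="right")
                geno[i] = (start + crossings) % 2
        cols.append(geno)
    genotypes = np.concatenate(cols, axis=1)
    if missing_rate > 0:
        mask = rng.random(genotypes.shape) < missing_rate
        genotypes = np.where(mask, MISSING, genotypes).astype(np.int8)
    frame = pd.DataFrame(
        genotypes,
        index=pd.Index([f"RIAIL_{i + 1:04d}" for i in range(n_lines)], name="line"),
        columns=list(marker_map["marker"]),
    )
    return GenotypePanel(frame, marker_map.reset_index(drop=True))


def _genetic_value(panel: GenotypePanel, qtl_effects: Iterable[tuple[str, float]]) -> np.ndarray:
    g_total = np.zeros(panel.n_lines)
    for marker, effect in qtl_effects:
        g = panel.genotype_at(marker).to_numpy()
        if np.isnan(g).any():
            # mean-impute so the genetic value is defined for every line
            g = np.where(np.isnan(g), np.nanmean(g), g)
        g_total += effect * g
    return g_total


def simulate_trait(
    panel: GenotypePanel,
    qtl_effects: Sequence[tuple[str, float]],
    heritability_target: float,
    seed: int | None = None,
    name: str = "trait",
) -> pd.Series:
    """Simulate an additive quantitative trait with planted QTL.

    The trait is ``sum_k effect_k * genotype_k`` plus Gaussian noise scaled
    so the genetic fraction of variance matches ``heritability_target`` in
    expectation (noise variance ``var(G) * (1 - h2) / h2`` against the
    realized genetic variance on this panel).  With no effects or ``h2 = 0``
    the trait is standard-normal noise; ``h2 = 1`` gives the noise-free
    genetic value.
    """
    if not 0.0 <= heritability_target <= 1.0:
        raise ValueError("heritability_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g_total = _genetic_value(panel, qtl_effects)
    var_g = float(np.var(g_total))
    if heritability_target == 0.0 or var_g == 0.0:
        values = rng.standard_normal(panel.n_lines)
    elif heritability_target == 1.0:
        values = g_total
    else:
        noise_sd = np.sqrt(var_g * (1.0 - heritability_target) / heritability_target)
        values = g_total + rng.normal(0.0, noise_sd, panel.n_lines)
    return pd.Series(values, index=panel.lines, name=name)


def simulate_expression_panel(
    panel: GenotypePanel,
    n_probes: int,
    local_fraction: float = 0.3,
    hotspot_locus: str | None = None,
    n_hotspot_genes: int = 0,
    effect_size: float | Callable[[np.random.Generator], float] = 1.0,
    local_window_bp: int = 500_000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an expression panel with local eQTL, one hotspot, and nulls.

    Probe classes:

    * ``hotspot`` — ``n_hotspot_genes`` probes driven by the genotype at
      ``hotspot_locus`` but located on other chromosomes, so their eQTL are
      distant and pile up in one genomic bin;
    * ``local`` — a ``local_fraction`` share of the remainder, each driven by
      a randomly chosen marker and placed within ``local_window_bp`` of it;
    * ``null`` — the rest, pure noise.

    Expression is ``effect * genotype + N(0, 1)``; effect magnitudes come
    from ``effect_size`` (a constant or a callable drawing from a
    distribution) with random sign.

    Returns ``(expression, probe_positions, truth)``: lines x probes values,
    per-probe genomic starts (``probe, chrom, start``), and the planted truth
    (``probe, cls, causal_marker, effect``).
    """
    if n_probes < 0:
        raise ValueError("n_probes must be nonnegative")
    if n_hotspot_genes > n_probes:
        raise ValueError("n_hotspot_genes cannot exceed n_probes")
    if not 0.0 <= local_fraction <= 1.0:
        raise ValueError("local_fraction must be in [0, 1]")
    if hotspot_locus is None and n_hotspot_genes > 0:
        raise ValueError("hotspot_locus required when n_hotspot_genes > 0")
    if hotspot_locus is not None:
        hotspot_info = panel.marker_info(hotspot_locus)  # raises KeyError if absent
    rng = np.random.default_rng(seed)

    draw_effect: Callable[[], float]
    if callable(effect_size):
        draw_effect = lambda: float(effect_size(rng))  # noqa: E731
    else:
        draw_effect = lambda: float(effect_size)  # noqa: E731

    n_local = int(round(local_fraction * (n_probes - n_hotspot_genes)))
    classes = (
        ["hotspot"] * n_hotspot_genes
        + ["local"] * n_local
        + ["null"] * (n_probes - n_hotspot_genes - n_local)
    )
    rng.shuffle(classes)

    mmap = panel.marker_map
    chrom_max_bp = mmap.groupby("chrom", sort=False)["bp"].max()
    g_all = panel.allele_matrix()
    marker_index = {m: j for j, m in enumerate(panel.markers)}

    expr = np.empty((panel.n_lines, n_probes))
    pos_rows = []
    truth_rows = []
    for p, cls in enumerate(classes):
        probe = f"probe_{p + 1:05d}"
        effect = 0.0
        causal = ""
        if cls == "hotspot":
            causal = str(hotspot_locus)
            # place the probe on another chromosome: its eQTL is distant
            others = [c for c in chrom_max_bp.index if c != hotspot_info["chrom"]]
            chrom = others[rng.integers(len(others))] if others else hotspot_info["chrom"]
            start = int(rng.integers(1, chrom_max_bp[chrom] + 1))
            effect = draw_effect() * (1 if rng.random() < 0.5 else -1)
        elif cls == "local":
            row = mmap.iloc[int(rng.integers(len(mmap)))]
            causal = row["marker"]
            chrom = row["chrom"]
            offset = int(rng.integers(-local_window_bp, local_window_bp + 1))
            start = int(max(1, row["bp"] + offset))
            effect = draw_effect() * (1 if rng.random() < 0.5 else -1)
        else:
            row = mmap.iloc[int(rng.integers(len(mmap)))]
            chrom = row["chrom"]
            start = int(rng.integers(1, chrom_max_bp[chrom] + 1))
        noise = rng.standard_normal(panel.n_lines)
        if cls == "null":
            expr[:, p] = noise
        else:
            g = g_all[:, marker_index[causal]]
            g = np.where(np.isnan(g), np.nanmean(g), g)
            expr[:, p] = effect * g + noise
        pos_rows.append((probe, chrom, start))
        truth_rows.append((probe, cls, causal, effect))

    expression = pd.DataFrame(
        expr, index=panel.lines, columns=[r[0] for r in pos_rows]
    )
    probe_positions = pd.DataFrame(pos_rows, columns=["probe", "chrom", "start"])
    truth = pd.DataFrame(truth_rows, columns=["probe", "cls", "causal_marker", "effect"])
    return expression, probe_positions, truth


def simulate_mediated_trait(
    panel: GenotypePanel,
    qtl_marker: str,
    a: float,
    b: float,
    c_prime: float,
    noise_sd: float = 0.5,
    mediator: pd.Series | None = None,
    seed: int | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Simulate a trait mediated by expression under a QTL.

    Structural model::

        mediator  = a * genotype + N(0, noise_sd)
        phenotype = b * mediator + c_prime * genotype + N(0, noise_sd)

    so the ground-truth indirect effect is ``a * b``, the direct effect is
    ``c_prime`` and the total effect ``a * b + c_prime``.  Pass ``mediator``
    to reuse an existing expression column (it must align to the panel
    lines); otherwise the mediator is generated.

    Returns ``(phenotype, mediator)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    g = panel.genotype_at(qtl_marker)
    g = g.fillna(g.mean())
    if mediator is None:
        mediator = a * g + rng.normal(0.0, noise_sd, panel.n_lines)
        mediator.name = "mediator"
    else:
        if len(mediator) != panel.n_lines or not mediator.index.equals(panel.lines):
            raise ValueError("mediator expression does not align to panel lines")
    phenotype = b * mediator + c_prime * g + rng.normal(0.0, noise_sd, panel.n_lines)
    phenotype.name = "phenotype"
    return phenotype, mediator


def simulate_replicated_trait(
    n_strains: int,
    n_replicates: int,
    heritability: float,
    seed: int | None = None,
    strain_sd: float = 1.0,
) -> pd.DataFrame:
    """Replicated strain measurements with a known broad-sense heritability.

    Strain effects ~ N(0, strain_sd^2); within-strain noise variance set to
    ``strain_sd^2 * (1 - h2) / h2`` so the intraclass correlation equals
    ``heritability`` (``h2 = 0`` gives pure noise, ``h2 = 1`` no noise).
    Returns a long-format frame with columns ``strain, replicate, value``.
    """
    if not 0.0 <= heritability <= 1.0:
        raise ValueError("heritability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if heritability == 0.0:
        strain_effects = np.zeros(n_strains)
        noise_sd = 1.0
    elif heritability == 1.0:
        strain_effects = rng.normal(0.0, strain_sd, n_strains)
        noise_sd = 0.0
    else:
        strain_effects = rng.normal(0.0, strain_sd, n_strains)
        noise_sd = strain_sd * np.sqrt((1.0 - heritability) / heritability)
    rows = []
    for s in range(n_strains):
        values = strain_effects[s] + rng.normal(0.0, noise_sd, n_replicates)
        for r, v in enumerate(values):
            rows.append((f"strain_{s + 1:03d}", f"rep_{r + 1:02d}", float(v)))
    return pd.DataFrame(rows, columns=["strain", "replicate", "value"])
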