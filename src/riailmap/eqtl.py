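"""Panel-scale eQTL mapping and hotspot detection.

Maps thousands of expression probes against the genotype panel with a
block-matrix LOD scan, chooses the genome-wide threshold by a permutation
false-discovery-rate procedure, classifies each eQTL as local or distant
(within 1 Mb of the probe start on the same chromosome, or not), and tests
for hotspots — genomic bins holding more distant eQTL than a
Bonferroni-corrected Poisson upper percentile would allow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from riailmap.linkage import (
    _pairwise_stats,
    _standardize_columns,
    lod_from_r,
    variance_explained_from_lod,
)
from riailmap.sim import GenotypePanel

LOCAL_WINDOW_BP = 1_000_000
"""An eQTL is local when its peak lies within this distance of the probe start."""

EQTL_COLUMNS = (
    "probe",
    "probe_chrom",
    "probe_start",
    "peak_marker",
    "peak_chrom",
    "peak_cm",
    "peak_bp",
    "lod",
    "variance_explained",
    "classification",
)


def _max_lod_per_probe(
    g: np.ndarray, expr: np.ndarray, block: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Genome-max LOD and argmax marker index for every expression column.

    Complete data goes through a standardized matrix product per block of
    probes; probes or genotypes with missing values fall back to
    pairwise-complete per-probe scans.
    """
    n, n_probes = expr.shape
    max_lod = np.empty(n_probes)
    argmax = np.empty(n_probes, dtype=int)
    clean = not np.isnan(g).any()
    gz = _standardize_columns(g) if clean else None
    for lo in range(0, n_probes, block):
        hi = min(lo + block, n_probes)
        chunk = expr[:, lo:hi]
        if clean and not np.isnan(chunk).any():
            r = gz.T @ _standardize_columns(chunk) / n  # markers x probes
            lods = np.asarray(lod_from_r(r, n))
            argmax[lo:hi] = lods.argmax(axis=0)
            max_lod[lo:hi] = lods.max(axis=0)
        else:
            for p in range(lo, hi):
                r, nn = _pairwise_stats(g, expr[:, p])
                lods = np.asarray(lod_from_r(r, nn))
                lods[np.isnan(r)] = np.nan
                argmax[p] = int(np.nanargmax(lods))
                max_lod[p] = lods[argmax[p]]
    return max_lod, argmax


def classify_eqtl(
    peak_chrom: str, peak_bp: int, probe_chrom: str, probe_start: int
) -> str:
    """Classify one eQTL as ``local`` or ``distant``.

    Local means the peak marker sits on the probe's chromosome within
    1 Mb of the probe's genomic start; anything else — including any
    cross-chromosome linkage — is distant.
    """
    if peak_chrom == probe_chrom and abs(int(peak_bp) - int(probe_start)) <= LOCAL_WINDOW_BP:
        return "local"
    return "distant"


def map_expression_panel(
    panel: GenotypePanel,
    expression: pd.DataFrame,
    probe_positions: pd.DataFrame,
    threshold: float,
    block: int = 512,
) -> pd.DataFrame:
    """Map every probe and report those whose genome-max LOD reaches threshold.

    ``expression`` is lines x probes; ``probe_positions`` carries one row per
    probe with columns ``probe, chrom, start``.  Returns one row per reported
    eQTL with the peak marker, LOD, variance explained, and local/distant
    classification.
    """
    if not expression.index.equals(panel.lines):
        raise ValueError("expression lines do not align to the genotype panel")
    positions = probe_positions.set_index("probe")
    unknown = expression.columns.difference(positions.index)
    if len(unknown):
        raise ValueError(f"probes without genomic positions: {list(unknown[:3])}...")
    g = panel.allele_matrix()
    expr = expression.to_numpy(dtype=float)
    max_lod, argmax = _max_lod_per_probe(g, expr, block=block)
    mmap = panel.marker_map.reset_index(drop=True)
    n = panel.n_lines
    rows = []
    for p, probe in enumerate(expression.columns):
        if not (max_lod[p] >= threshold):
            continue
        peak = mmap.iloc[argmax[p]]
        pos = positions.loc[probe]
        rows.append(
            (
                probe,
                pos["chrom"],
                int(pos["start"]),
                peak["marker"],
                peak["chrom"],
                float(peak["cm"]),
                int(peak["bp"]),
                float(max_lod[p]),
                float(variance_explained_from_lod(max_lod[p], n)),
                classify_eqtl(peak["chrom"], peak["bp"], pos["chrom"], pos["start"]),
            )
        )
    return pd.DataFrame(rows, columns=list(EQTL_COLUMNS))


def permutation_fdr_threshold(
    panel: GenotypePanel,
    expression: pd.DataFrame,
    n_perm: int = 10,
    grid: np.ndarray | None = None,
    target_fdr: float = 0.05,
    seed: int | None = None,
    joint: bool = True,
    full: bool = False,
):
    """Choose a genome-wide LOD threshold by permutation FDR.

    For each grid threshold ``t``, the FDR estimate is the mean number of
    probes whose genome-max LOD exceeds ``t`` across ``n_perm`` permutations
    of the line labels, divided by the number of observed probes exceeding
    ``t``.  The whole expression matrix is permuted jointly by default,
    preserving inter-probe correlation (``joint=False`` shuffles each probe
    independently).  Returns the smallest grid value with FDR below
    ``target_fdr`` (NaN when no grid value qualifies); with ``full=True``
    also returns the per-threshold FDR table.

    Where the observed count is zero, the FDR is defined as 0 if the
    permuted mean is also zero and +inf otherwise.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if grid is None:
        grid = np.round(np.arange(2.0, 10.0 + 1e-9, 0.01), 2)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if not expression.index.equals(panel.lines):
        raise ValueError("expression lines do not align to the genotype panel")
    rng = np.random.default_rng(seed)
    g = panel.allele_matrix()
    expr = expression.to_numpy(dtype=float)
    n = expr.shape[0]

    obs_max, _ = _max_lod_per_probe(g, expr)
    perm_max = np.empty((n_perm, expr.shape[1]))
    for k in range(n_perm):
        if joint:
            permuted = expr[rng.permutation(n)]
        else:
            permuted = np.empty_like(expr)
            for j in range(expr.shape[1]):
                permuted[:, j] = expr[rng.permutation(n), j]
        perm_max[k], _ = _max_lod_per_probe(g, permuted)

    # count(> t) via sorted arrays: size - searchsorted(sorted, t, 'right')
    obs_sorted = np.sort(obs_max)
    obs_count = obs_sorted.size - np.searchsorted(obs_sorted, grid, side="right")
    perm_sorted = np.sort(perm_max.ravel())
    perm_count = (perm_sorted.size - np.searchsorted(perm_sorted, grid, side="right")) / n_perm

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(
            obs_count > 0,
            perm_count / np.maximum(obs_count, 1),
            np.where(perm_count == 0, 0.0, np.inf),
        )
    passing = np.nonzero(fdr < target_fdr)[0]
    threshold = float(grid[passing[0]]) if passing.size else float("nan")
    if full:
        table = pd.DataFrame(
            {"threshold": grid, "n_observed": obs_count, "n_permuted_mean": perm_count, "fdr": fdr}
        )
        return threshold, table
    return threshold


def poisson_critical_count(lam: float, n_bins: int, percentile: float = 0.99) -> int:
    """Smallest count k with Poisson CDF(k; lam) >= 1 - (1 - percentile)/n_bins.

    The Bonferroni correction divides the upper tail mass across the
    ``n_bins`` genomic bins being tested.
    """
    if lam < 0 or n_bins < 1:
        raise ValueError("lam must be >= 0 and n_bins >= 1")
    q = 1.0 - (1.0 - percentile) / n_bins
    return int(stats.poisson.ppf(q, lam))


def genome_bins(marker_map: pd.DataFrame, bin_cm: float = 5.0) -> pd.DataFrame:
    """Partition each chromosome into half-open genetic bins of ``bin_cm``.

    Bins run [0, w), [w, 2w), ... ; the final (possibly partial) bin is kept
    and extends past the last marker so every marker falls in some bin.
    """
    if bin_cm <= 0:
        raise ValueError("bin_cm must be positive")
    rows = []
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        max_cm = float(grp["cm"].max())
        n = int(np.floor(max_cm / bin_cm)) + 1
        for i in range(n):
            rows.append((chrom, i * bin_cm, (i + 1) * bin_cm))
    return pd.DataFrame(rows, columns=["chrom", "start_cm", "end_cm"])


@dataclass
class HotspotScan:
    """Distant-eQTL counts per genomic bin with the Poisson significance test.

    ``bins`` columns: ``chrom, start_cm, end_cm, count, significant``.
    ``lam`` is the Poisson mean (counted eQTL / total bins), and a bin is
    significant when its count strictly exceeds ``critical_count``.
    """

    bins: pd.DataFrame
    lam: float
    critical_count: int
    n_counted: int

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def significant_bins(self) -> pd.DataFrame:
        return self.bins[self.bins["significant"]]


def _assign_bins(records: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Bin index for each record by its peak genetic position."""
    idx = np.empty(len(records), dtype=int)
    for i, (_, rec) in enumerate(records.iterrows()):
        sel = bins[
            (bins["chrom"] == rec["peak_chrom"])
            & (bins["start_cm"] <= rec["peak_cm"])
            & (rec["peak_cm"] < bins["end_cm"])
        ]
        if sel.empty:
            raise ValueError(
                f"peak at {rec['peak_chrom']}:{rec['peak_cm']} cM falls in no bin"
            )
        idx[i] = sel.index[0]
    return idx


def detect_hotspots(
    records: pd.DataFrame,
    marker_map: pd.DataFrame,
    bin_cm: float = 5.0,
    percentile: float = 0.99,
    lod_floor: float | None = None,
    lambda_all: bool = False,
) -> HotspotScan:
    """Find genomic bins with an excess of distant eQTL.

    The genome is divided into ``bin_cm`` genetic bins; distant eQTL are
    counted into bins by their peak marker's genetic position.  Counts are
    compared against ``poisson_critical_count`` with mean
    ``counted eQTL / total bins``; a bin is a hotspot when its count strictly
    exceeds that critical value.

    ``lod_floor`` drops records with peak LOD not exceeding the floor before
    counting (robustness filter).  ``lambda_all=False`` (default) computes
    the Poisson mean from the distant records being binned;
    ``lambda_all=True`` uses all records passing the floor instead.
    """
    bins = genome_bins(marker_map, bin_cm=bin_cm)
    filtered = records
    if lod_floor is not None:
        filtered = filtered[filtered["lod"] > lod_floor]
    distant = filtered[filtered["classification"] == "distant"]
    counts = np.zeros(len(bins), dtype=int)
    if len(distant):
        np.add.at(counts, _assign_bins(distant, bins), 1)
    n_for_lambda = len(filtered) if lambda_all else len(distant)
    lam = n_for_lambda / len(bins) if len(bins) else 0.0
    critical = poisson_critical_count(lam, len(bins), percentile=percentile)
    out = bins.copy()
    out["count"] = counts
    out["significant"] = counts > critical
    return HotspotScan(bins=out, lam=float(lam), critical_count=critical, n_counted=len(distant))


def hotspot_permutation_check(
    distant_records: pd.DataFrame,
    marker_map: pd.DataFrame,
    n_datasets: int = 10,
    bin_cm: float = 5.0,
    percentile: float = 0.99,
    lod_floor: float | None = None,
    seed: int | None = None,
) -> list[int]:
    """Count spurious hotspots in datasets with scattered eQTL positions.

    Each permuted dataset keeps the total number of counted distant eQTL but
    assigns every record to a uniformly random genomic bin, then re-runs the
    Poisson test with the same mean.  Returns the number of significant bins
    per permuted dataset; under the Bonferroni correction the expectation is
    below one per dataset.
    """
    if n_datasets < 0:
        raise ValueError("n_datasets must be nonnegative")
    rng = np.random.default_rng(seed)
    bins = genome_bins(marker_map, bin_cm=bin_cm)
    filtered = distant_records
    if lod_floor is not None:
        filtered = filtered[filtered["lod"] > lod_floor]
    distant = filtered[filtered["classification"] == "distant"]
    total = len(distant)
    lam = total / len(bins) if len(bins) else 0.0
    critical = poisson_critical_count(lam, len(bins), percentile=percentile)
    out = []
    for _ in range(n_datasets):
        assignment = rng.integers(0, len(bins), total)
        counts = np.bincount(assignment, minlength=len(bins))
        out.append(int(np.sum(counts > critical)))
    return out
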