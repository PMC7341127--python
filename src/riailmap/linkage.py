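"""Single-trait linkage mapping by marker regression.

The scan statistic is the closed-form LOD score

    LOD = -n * ln(1 - R^2) / (2 * ln 10)

where ``R`` is the Pearson correlation between the genotypes at a marker and
the trait over the ``n`` lines with complete data at that marker.  Genome-wide
significance comes from permuting trait values across lines and taking the
(1 - alpha) quantile of per-permutation genome-max LOD scores.  Multiple QTL
are found by a forward search: the peak marker is absorbed as a cofactor (the
trait is residualized on the genotypes of all selected peaks) and the scan is
repeated until nothing exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from riailmap.sim import GenotypePanel

#: Floor on 1 - R^2: a perfectly correlated marker yields a large finite LOD
#: (about n * 3.47) rather than infinity.
ONE_MINUS_R2_FLOOR = 1e-16

MIN_COMPLETE_PAIRS = 3


def lod_from_r(r: np.ndarray | float, n: np.ndarray | int) -> np.ndarray | float:
    """Closed-form LOD score from a Pearson correlation over n lines.

    ``1 - r^2`` is floored at ``ONE_MINUS_R2_FLOOR`` so perfect correlation
    never produces an infinite LOD.
    """
    one_minus = np.maximum(1.0 - np.square(r), ONE_MINUS_R2_FLOOR)
    return -np.asarray(n, dtype=float) * np.log(one_minus) / (2.0 * np.log(10.0))


def variance_explained_from_lod(lod: np.ndarray | float, n: np.ndarray | int) -> np.ndarray | float:
    """Fraction of trait variance explained by a marker: 1 - 10^(-2 LOD / n).

    Exact inverse of :func:`lod_from_r`; round-trips the peak R^2.
    """
    return 1.0 - np.power(10.0, -2.0 * np.asarray(lod, dtype=float) / np.asarray(n, dtype=float))


@dataclass
class LODScan:
    """Per-marker scan result for one trait.

    ``table`` columns: ``marker, chrom, cm, bp, n, r, lod``.  Markers that are
    monomorphic among complete pairs, or have fewer than 3 complete pairs,
    carry NaN ``r`` and ``lod``.
    """

    trait: str
    table: pd.DataFrame

    @property
    def lod(self) -> pd.Series:
        return self.table.set_index("marker")["lod"]

    def peak(self) -> pd.Series:
        """Row of the genome-wide maximum LOD (ties: lowest genomic coordinate)."""
        lods = self.table["lod"].to_numpy()
        if np.all(np.isnan(lods)):
            raise ValueError("scan has no defined LOD scores")
        idx = int(np.nanargmax(lods))
        return self.table.iloc[idx]

    def max_lod(self) -> float:
        return float(np.nanmax(self.table["lod"].to_numpy()))


@dataclass
class QTLAnnotation:
    """One detected QTL with its confidence interval and effect estimates."""

    trait: str
    peak_marker: str
    chrom: str
    peak_cm: float
    peak_bp: int
    peak_lod: float
    threshold: float
    ci_left: str
    ci_right: str
    ci_left_bp: int
    ci_right_bp: int
    variance_explained: float
    allelic_effect: float
    parent_of_resistance: str
    n: int


def _pairwise_stats(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlation of each genotype column with y.

    Returns (r, n) per marker; NaN r where n < 3 or either side is constant.
    """
    valid = ~np.isnan(g) & ~np.isnan(y)[:, None]
    n = valid.sum(axis=0).astype(float)
    gz = np.where(valid, g, 0.0)
    yz = np.where(valid, y[:, None], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mg = gz.sum(axis=0) / n
        my = yz.sum(axis=0) / n
        gc = np.where(valid, g - mg, 0.0)
        yc = np.where(valid, y[:, None] - my, 0.0)
        sxy = (gc * yc).sum(axis=0)
        sxx = (gc * gc).sum(axis=0)
        syy = (yc * yc).sum(axis=0)
        r = sxy / np.sqrt(sxx * syy)
    r[(n < MIN_COMPLETE_PAIRS) | (sxx <= 0) | (syy <= 0)] = np.nan
    return r, n


def lod_scan(panel: GenotypePanel, trait: pd.Series | np.ndarray) -> LODScan:
    """Scan every marker against one trait.

    The correlation at each marker uses the lines with a non-missing genotype
    at that marker and a finite trait value, so ``n`` may vary across markers.
    """
    y = _align_trait(panel, trait)
    if np.all(np.isnan(y)):
        raise ValueError("trait has no finite values")
    g = panel.allele_matrix()
    r, n = _pairwise_stats(g, y)
    with np.errstate(invalid="ignore"):
        lod = lod_from_r(r, n)
    table = panel.marker_map.reset_index(drop=True).copy()
    table["n"] = n.astype(int)
    table["r"] = r
    table["lod"] = lod
    name = getattr(trait, "name", None) or "trait"
    return LODScan(trait=str(name), table=table)


def _align_trait(panel: GenotypePanel, trait: pd.Series | np.ndarray) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = panel.lines.difference(trait.index)
        if len(missing) == len(panel.lines):
            raise ValueError("trait shares no lines with the panel")
        return trait.reindex(panel.lines).to_numpy(dtype=float)
    y = np.asarray(trait, dtype=float)
    if len(y) != panel.n_lines:
        raise ValueError(f"trait length {len(y)} != number of lines {panel.n_lines}")
    return y


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    """Z-score columns (population SD); constant columns become all-zero."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, np.inf)
    return (x - mu) / sd


def max_lod_permutations(
    panel: GenotypePanel,
    trait: pd.Series | np.ndarray,
    n_perm: int,
    seed: int | None = None,
) -> np.ndarray:
    """Genome-wide max LOD for each of ``n_perm`` trait permutations.

    Lines with a missing trait value are dropped before permuting.  With
    complete genotypes the scan of all permutations is a single standardized
    matrix product; with missing genotypes it falls back to per-permutation
    pairwise-complete scans.
    """
    rng = np.random.default_rng(seed)
    y = _align_trait(panel, trait)
    keep = ~np.isnan(y)
    y = y[keep]
    g = panel.allele_matrix()[keep]
    n = len(y)
    if n < MIN_COMPLETE_PAIRS:
        raise ValueError("fewer than 3 lines with finite trait values")
    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = y[rng.permutation(n)]
    if not np.isnan(g).any():
        gz = _standardize_columns(g)
        pz = _standardize_columns(perms)
        r = gz.T @ pz / n  # markers x permutations
        lods = lod_from_r(r, n)
        return np.asarray(lods).max(axis=0)
    maxima = np.empty(n_perm)
    for k in range(n_perm):
        r, nn = _pairwise_stats(g, perms[:, k])
        maxima[k] = np.nanmax(lod_from_r(r, nn))
    return maxima


def permutation_threshold(
    panel: GenotypePanel,
    trait: pd.Series | np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Genome-wide LOD threshold at error rate ``alpha`` by trait permutation.

    Permutes the trait values across lines ``n_perm`` times, records the
    genome-wide maximum LOD of each permuted scan, and returns the empirical
    ``1 - alpha`` quantile of those maxima.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives an unstable threshold quantile; use >= 100",
            stacklevel=2,
        )
    maxima = max_lod_permutations(panel, trait, n_perm, seed=seed)
    # "higher" picks the order statistic itself, giving an exactly level-alpha
    # test under exchangeability of the observed and permuted traits
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


def annotate_qtl(
    scan: LODScan,
    peak_marker: str,
    panel: GenotypePanel,
    trait: pd.Series | np.ndarray,
    threshold: float = 0.0,
    drop: float = 1.5,
) -> QTLAnnotation:
    """Annotate a scan peak with its LOD-drop interval and effect estimates.

    The confidence interval walks outward from the peak along its chromosome;
    each bound is the first marker whose LOD falls strictly below
    ``peak_lod - drop`` (that marker is included as the bound — the
    "proximal" convention).  If the chromosome end is reached first, the
    terminal marker is the bound.  Markers with undefined LOD are skipped
    during the walk.

    ``variance_explained`` is ``1 - 10^(-2 LOD / n)`` at the peak;
    ``allelic_effect`` is ``mean(trait | allele B) - mean(trait | allele A)``
    and ``parent_of_resistance`` names the parent whose allele raises the
    trait.
    """
    table = scan.table
    rows = table.index[table["marker"] == peak_marker]
    if len(rows) == 0:
        raise KeyError(f"peak marker {peak_marker!r} not in scan")
    peak_idx = int(rows[0])
    peak_row = table.loc[peak_idx]
    peak_lod = float(peak_row["lod"])
    if np.isnan(peak_lod):
        raise ValueError(f"peak marker {peak_marker!r} has undefined LOD")
    chrom_table = table[table["chrom"] == peak_row["chrom"]]
    cutoff = peak_lod - drop

    def _walk(indices: list[int]) -> int:
        bound = peak_idx
        for i in indices:
            bound = i
            lod_i = table.at[i, "lod"]
            if not np.isnan(lod_i) and lod_i < cutoff:
                return i
        return bound

    chrom_idx = list(chrom_table.index)
    at = chrom_idx.index(peak_idx)
    left = _walk(chrom_idx[at - 1 :: -1] if at > 0 else [])
    right = _walk(chrom_idx[at + 1 :])

    y = _align_trait(panel, trait)
    g = panel.genotype_at(peak_marker).to_numpy()
    ok = ~np.isnan(g) & ~np.isnan(y)
    mean_b = float(np.mean(y[ok & (g == 1)])) if np.any(ok & (g == 1)) else np.nan
    mean_a = float(np.mean(y[ok & (g == 0)])) if np.any(ok & (g == 0)) else np.nan
    allelic_effect = mean_b - mean_a
    n = int(peak_row["n"])
    return QTLAnnotation(
        trait=scan.trait,
        peak_marker=str(peak_row["marker"]),
        chrom=str(peak_row["chrom"]),
        peak_cm=float(peak_row["cm"]),
        peak_bp=int(peak_row["bp"]),
        peak_lod=peak_lod,
        threshold=float(threshold),
        ci_left=str(table.at[left, "marker"]),
        ci_right=str(table.at[right, "marker"]),
        ci_left_bp=int(table.at[left, "bp"]),
        ci_right_bp=int(table.at[right, "bp"]),
        variance_explained=float(variance_explained_from_lod(peak_lod, n)),
        allelic_effect=allelic_effect,
        parent_of_resistance="B" if allelic_effect >= 0 else "A",
        n=n,
    )


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1, covariates]; NaN covariates mean-imputed."""
    x = np.column_stack([np.ones(len(y)), covariates])
    col_mean = np.nanmean(x, axis=0)
    nan_at = np.isnan(x)
    if nan_at.any():
        x[nan_at] = np.take(col_mean, np.nonzero(nan_at)[1])
    ok = ~np.isnan(y)
    beta, *_ = np.linalg.lstsq(x[ok], y[ok], rcond=None)
    resid = np.full_like(y, np.nan)
    resid[ok] = y[ok] - x[ok] @ beta
    return resid


def forward_search(
    panel: GenotypePanel,
    trait: pd.Series | np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    max_qtl: int = 10,
    seed: int | None = None,
    threshold: float | None = None,
    recompute_threshold: bool = False,
    drop: float = 1.5,
) -> list[QTLAnnotation]:
    """Iterative genome scan with detected QTL absorbed as cofactors.

    Each iteration scans the current trait; if the genome-wide max LOD
    exceeds the significance threshold, the peak marker is recorded as a QTL
    and the *original* trait is residualized on the genotype columns of all
    selected peaks (OLS with intercept) before rescanning.  The search stops
    when no marker exceeds the threshold or ``max_qtl`` QTL are found.

    By default the permutation threshold is computed once on the original
    trait and reused across iterations; ``recompute_threshold=True`` re-runs
    the permutations on each residualized trait instead.  Duplicate
    (collinear) cofactor columns are dropped with a warning.
    """
    y0 = _align_trait(panel, trait)
    name = getattr(trait, "name", None) or "trait"
    if threshold is None:
        threshold = permutation_threshold(panel, y0, n_perm=n_perm, alpha=alpha, seed=seed)
    results: list[QTLAnnotation] = []
    cofactor_markers: list[str] = []
    current = y0
    thr = threshold
    g_matrix = panel.allele_matrix()
    marker_pos = {m: j for j, m in enumerate(panel.markers)}
    while len(results) < max_qtl:
        current_series = pd.Series(current, index=panel.lines, name=name)
        scan = lod_scan(panel, current_series)
        lods = scan.table["lod"].to_numpy()
        if np.all(np.isnan(lods)) or np.nanmax(lods) <= thr:
            break
        peak_marker = str(scan.table.iloc[int(np.nanargmax(lods))]["marker"])
        results.append(
            annotate_qtl(scan, peak_marker, panel, current_series, threshold=thr, drop=drop)
        )
        if peak_marker in cofactor_markers:
            warnings.warn(
                f"peak {peak_marker!r} already a cofactor; stopping search", stacklevel=2
            )
            break
        cofactor_markers.append(peak_marker)
        cols = g_matrix[:, [marker_pos[m] for m in cofactor_markers]]
        # drop duplicated genotype columns (perfectly collinear cofactors)
        _, unique_idx = np.unique(cols, axis=1, return_index=True)
        if len(unique_idx) < cols.shape[1]:
            warnings.warn("dropping duplicate cofactor genotype column", stacklevel=2)
            cols = cols[:, np.sort(unique_idx)]
        current = _residualize(y0, cols)
        if recompute_threshold:
            thr = permutation_threshold(panel, current, n_perm=n_perm, alpha=alpha, seed=seed)
    return results
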