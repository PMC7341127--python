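"""Processing of replicated fitness-assay phenotypes into mappable traits.

High-throughput assays measure each strain in control and drug conditions
with several replicates per condition.  The mapped trait is the residual of
the drug-condition values after regressing out each strain's mean control
value — this isolates variation caused by the drug from baseline growth
differences.  The module also provides the derived optical-density trait,
0-1 normalization for plotting, broad-sense heritability from replicated
strain measurements, and Tukey HSD pairwise strain contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def derive_norm_ext(median_ext, median_tof):
    """Length-normalized optical density: median.EXT / median.TOF.

    Optical density scales with animal length, so the quotient isolates
    density per unit length.  ``median_tof`` must be strictly positive.
    """
    ext = np.asarray(median_ext, dtype=float)
    tof = np.asarray(median_tof, dtype=float)
    if np.any(tof <= 0):
        raise ValueError("median.TOF must be strictly positive")
    out = ext / tof
    if isinstance(median_ext, pd.Series):
        return pd.Series(out, index=median_ext.index, name="median.norm.EXT")
    return out if out.ndim else float(out)


def regress_control(
    drug: pd.DataFrame,
    control_means: pd.Series | dict,
    strain_col: str = "strain",
    value_col: str = "value",
) -> pd.Series:
    """Residual drug phenotypes after regressing on strain control means.

    Fits one ordinary-least-squares line of the drug-condition replicate
    values on each strain's mean control value, pooled across all strains,
    and returns the residuals (aligned to ``drug``'s rows).  When every
    control mean is identical the design collapses; the fit falls back to
    the intercept-only model and residuals are deviations from the drug
    mean.

    Raises ``ValueError`` if any drug strain lacks a control mean.
    """
    control_means = pd.Series(control_means)
    strains = drug[strain_col]
    missing = set(strains.unique()) - set(control_means.index)
    if missing:
        raise ValueError(f"strains without control data: {sorted(missing)[:5]}")
    x = control_means.reindex(strains).to_numpy(dtype=float)
    y = drug[value_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        resid = y - y.mean()
    else:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
    return pd.Series(resid, index=drug.index, name=f"{value_col}_residual")


def normalize_unit_interval(values) -> pd.Series | np.ndarray:
    """Affinely rescale values so the minimum maps to 0 and the maximum to 1.

    Used for plotting residual traits on a common scale.  A constant vector
    has no scale and raises ``ValueError``.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        raise ValueError("cannot normalize a constant vector")
    out = (x - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


@dataclass
class HeritabilityEstimate:
    """Broad-sense heritability from replicated strain measurements.

    ``H2 = strain_variance / (strain_variance + residual_variance)``, the
    intraclass correlation of the random-intercept model
    ``phenotype ~ 1 + (1 | strain)``; negative strain-variance estimates are
    truncated at zero before forming the ratio.
    """

    H2: float
    strain_variance: float
    residual_variance: float
    method: str


def _anova_variance_components(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """One-way random-effects components by the ANOVA method of moments."""
    labels, inverse = np.unique(groups, return_inverse=True)
    k = len(labels)
    n_i = np.bincount(inverse).astype(float)
    n_total = n_i.sum()
    grand = values.mean()
    group_means = np.bincount(inverse, weights=values) / n_i
    ss_between = float(np.sum(n_i * (group_means - grand) ** 2))
    ss_within = float(np.sum((values - group_means[inverse]) ** 2))
    ms_between = ss_between / (k - 1)
    df_within = n_total - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    # average group size correcting for imbalance
    n0 = (n_total - np.sum(n_i**2) / n_total) / (k - 1)
    sigma_strain = max(0.0, (ms_between - ms_within) / n0)
    return sigma_strain, ms_within


def broad_sense_heritability(
    values,
    strains,
    method: str = "reml",
) -> HeritabilityEstimate:
    """Broad-sense heritability H2 of a trait from replicated strains.

    Fits the random-intercept model ``phenotype ~ 1 + (1 | strain)`` by REML
    (``method="reml"``, via statsmodels MixedLM) or by the one-way ANOVA
    method of moments (``method="anova"``; identical expectation for
    balanced designs).  REML falls back to the ANOVA estimator if the mixed
    model fails to converge or the data are noise-free.

    Returns the variance components and ``H2`` clipped to [0, 1].
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(strains)
    if len(y) != len(g):
        raise ValueError("values and strains must align")
    ok = ~np.isnan(y)
    y, g = y[ok], g[ok]
    if len(np.unique(g)) < 2:
        raise ValueError("need at least 2 strains to estimate heritability")
    if method not in ("reml", "anova"):
        raise ValueError(f"unknown method {method!r}")

    used = method
    if method == "reml":
        try:
            import statsmodels.api as sm

            with np.errstate(all="ignore"):
                model = sm.MixedLM(y, np.ones((len(y), 1)), groups=g)
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = model.fit(reml=True)
            sigma_strain = float(np.asarray(fit.cov_re)[0, 0])
            sigma_resid = float(fit.scale)
            if not (np.isfinite(sigma_strain) and np.isfinite(sigma_resid)):
                raise RuntimeError("non-finite variance components")
        except Exception:
            sigma_strain, sigma_resid = _anova_variance_components(y, g)
            used = "anova"
    else:
        sigma_strain, sigma_resid = _anova_variance_components(y, g)

    sigma_strain = max(0.0, sigma_strain)
    sigma_resid = max(0.0, sigma_resid)
    denom = sigma_strain + sigma_resid
    h2 = float(np.clip(sigma_strain / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return HeritabilityEstimate(
        H2=h2,
        strain_variance=sigma_strain,
        residual_variance=sigma_resid,
        method=used,
    )


def pairwise_strain_comparison(values, strains) -> pd.DataFrame:
    """Tukey-HSD-adjusted p-values for all pairwise strain contrasts.

    Runs the studentized-range test on the one-way model
    ``phenotype ~ strain`` and returns a symmetric strain x strain matrix of
    adjusted p-values with 1.0 on the diagonal.  Raises ``ValueError`` on
    zero-variance input, where the test statistic is undefined.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    y = np.asarray(values, dtype=float)
    g = np.asarray(strains, dtype=object)
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 strains")
    if np.ptp(y) == 0:
        raise ValueError("trait has zero variance; contrasts undefined")
    res = pairwise_tukeyhsd(y, g)
    mat = pd.DataFrame(1.0, index=labels, columns=labels)
    summary = np.asarray(res.summary().data[1:], dtype=object)
    for row in summary:
        g1, g2, p = str(row[0]), str(row[1]), float(row[3])
        mat.loc[g1, g2] = p
        mat.loc[g2, g1] = p
    return mat
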