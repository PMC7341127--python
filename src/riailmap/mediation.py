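"""Causal mediation analysis for QTL effects transmitted through expression.

Decomposes the total effect of a biallelic QTL genotype on a phenotype into a
direct effect and an indirect effect carried by a mediator (a gene-expression
probe), using three ordinary-least-squares fits::

    mediator  model:  expression ~ genotype          -> slope a
    outcome   model:  phenotype  ~ expression + genotype -> slopes b, c'
    total     model:  phenotype  ~ genotype          -> slope c

The indirect (mediated) effect is ``a * b``; with OLS on a common sample the
decomposition ``c = c' + a * b`` holds exactly.  Inference is by
nonparametric bootstrap: lines are resampled with replacement and the
indirect effect recomputed, giving a percentile confidence interval and a
two-sided sign-based p-value.

:func:`mediate_panel` runs the analysis for every candidate probe under one
QTL and ranks probes by the absolute indirect effect; probes at or above the
90th percentile of that distribution are flagged as prioritized mediators.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from riailmap.sim import GenotypePanel


@dataclass
class MediationResult:
    """Effect decomposition for one (QTL, mediator, phenotype) triple.

    ``mediated_proportion`` is ``indirect / total``; under inconsistent
    mediation (direct and indirect effects of opposite sign, or indirect
    larger than total) it falls outside [0, 1] and ``proportion_interpretable``
    is False — the proportion is then reported but should not be used for
    ranking.
    """

    total_effect: float
    direct_effect: float
    indirect_effect: float
    expression_effect: float  # slope of phenotype on expression (b)
    mediated_proportion: float
    proportion_interpretable: bool
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    seed: int | None


def _mediation_slopes(
    g: np.ndarray, m: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """(a, b, c_prime, total) from the three OLS fits on centered data."""
    gc = g - g.mean()
    mc = m - m.mean()
    yc = y - y.mean()
    sgg = gc @ gc
    smm = mc @ mc
    sgm = gc @ mc
    a = sgm / sgg
    total = (gc @ yc) / sgg
    det = smm * sgg - sgm**2
    b = (sgg * (mc @ yc) - sgm * (gc @ yc)) / det
    c_prime = (smm * (gc @ yc) - sgm * (mc @ yc)) / det
    return a, b, c_prime, total


def mediate(
    genotype: pd.Series | np.ndarray,
    mediator: pd.Series | np.ndarray,
    phenotype: pd.Series | np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MediationResult:
    """Estimate the mediated (indirect) effect of a QTL through one probe.

    Lines with a missing value in any of the three vectors are dropped.  The
    bootstrap resamples lines with replacement ``n_boot`` times and
    recomputes ``a * b``; the p-value is the two-sided sign test
    ``2 * min(frac <= 0, frac >= 0)`` with a half-count continuity correction
    for the finite number of resamples, and the confidence interval is the
    percentile 95% interval.

    Raises ``ValueError`` when only one genotype class is present or the
    mediator has zero variance.
    """
    g = np.asarray(genotype, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if not (len(g) == len(m) == len(y)):
        raise ValueError("genotype, mediator and phenotype must align on lines")
    ok = ~(np.isnan(g) | np.isnan(m) | np.isnan(y))
    g, m, y = g[ok], m[ok], y[ok]
    n = len(g)
    if n < 3:
        raise ValueError("fewer than 3 complete observations")
    if np.unique(g).size < 2:
        raise ValueError("genotype has a single class; mediation model is degenerate")
    if np.var(m) == 0:
        raise ValueError("mediator has zero variance")

    a, b, c_prime, total = _mediation_slopes(g, m, y)
    indirect = a * b
    proportion = indirect / total if total != 0 else np.nan
    interpretable = bool(np.isfinite(proportion) and 0.0 <= proportion <= 1.0)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    gb, mb, yb = g[idx], m[idx], y[idx]
    gc = gb - gb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sgg = np.einsum("ij,ij->i", gc, gc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sgm = np.einsum("ij,ij->i", gc, mc)
    sgy = np.einsum("ij,ij->i", gc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    det = smm * sgg - sgm**2
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = (sgm / sgg) * ((sgg * smy - sgm * sgy) / det)
    boot = boot[np.isfinite(boot)]  # degenerate resamples (single class) dropped
    n_eff = len(boot)
    if n_eff:
        frac_le = (np.sum(boot <= 0) + 0.5) / (n_eff + 1)
        frac_ge = (np.sum(boot >= 0) + 0.5) / (n_eff + 1)
        p_value = float(min(1.0, 2.0 * min(frac_le, frac_ge)))
        ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    else:
        p_value, ci_low, ci_high = np.nan, np.nan, np.nan

    return MediationResult(
        total_effect=float(total),
        direct_effect=float(c_prime),
        indirect_effect=float(indirect),
        expression_effect=float(b),
        mediated_proportion=float(proportion),
        proportion_interpretable=interpretable,
        p_value=p_value,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n=n,
        n_boot=n_boot,
        seed=seed,
    )


def _probe_seed(master_seed: int | None, probe: str) -> int | None:
    """Stable per-probe seed: master seed combined with a hash of the probe id."""
    if master_seed is None:
        return None
    h = zlib.crc32(probe.encode())
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1)[0] % (2**31))


def mediate_panel(
    panel: GenotypePanel,
    qtl_marker: str,
    expression: pd.DataFrame,
    candidate_probes: list[str],
    phenotype: pd.Series,
    n_boot: int = 1000,
    seed: int | None = None,
    percentile_flag: float = 90.0,
) -> pd.DataFrame:
    """Rank candidate mediator probes for one QTL-phenotype pair.

    Runs :func:`mediate` per probe with the genotype at ``qtl_marker``, then
    ranks probes by ``|indirect_effect|``.  ``percentile`` is the mean-rank
    percentile of each probe's score within the candidate set; probes with
    percentile >= ``percentile_flag`` are flagged ``prioritized``.  Per-probe
    seeds derive from the master seed by stable hashing of the probe id, so
    results do not depend on candidate order.

    Returns one row per probe, sorted by descending ``abs_indirect``.
    """
    if not candidate_probes:
        raise ValueError("candidate probe set is empty")
    missing = [p for p in candidate_probes if p not in expression.columns]
    if missing:
        raise KeyError(f"probes absent from expression table: {missing[:3]}")
    g = panel.genotype_at(qtl_marker)
    y = phenotype.reindex(panel.lines)
    rows = []
    for probe in candidate_probes:
        res = mediate(
            g.to_numpy(),
            expression[probe].reindex(panel.lines).to_numpy(),
            y.to_numpy(),
            n_boot=n_boot,
            seed=_probe_seed(seed, probe),
        )
        rows.append(
            {
                "probe": probe,
                "total_effect": res.total_effect,
                "direct_effect": res.direct_effect,
                "indirect_effect": res.indirect_effect,
                "expression_effect": res.expression_effect,
                "mediated_proportion": res.mediated_proportion,
                "proportion_interpretable": res.proportion_interpretable,
                "p_value": res.p_value,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    table = pd.DataFrame(rows)
    table["abs_indirect"] = table["indirect_effect"].abs()
    scores = table["abs_indirect"].to_numpy()
    table["percentile"] = [
        stats.percentileofscore(scores, s, kind="mean") for s in scores
    ]
    table["prioritized"] = table["percentile"] >= percentile_flag
    return table.sort_values("abs_indirect", ascending=False).reset_index(drop=True)
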