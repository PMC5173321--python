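"""Negative-binomial differential expression for transcript-cluster counts.

A self-contained two-group NB testing stack mirroring the analysis contract of
irradiation-ablation and FACS cell-sorting studies:

1. low-expression filtering (CPM >= 1 in >= 3 samples),
2. median-of-ratios size factors,
3. method-of-moments dispersion with shrinkage toward the common value,
4. an exact conditional two-group test on library-equalised counts,
5. Benjamini-Hochberg FDR, and
6. RUV-style removal of unwanted variation from negative-control clusters.

Counts follow NB(mu, phi) with variance mu + phi * mu**2.  All contrasts are
two-group; multi-factor designs are out of scope.  The downstream category
classifier consumes only the (direction, FDR, fold-change) triple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
#: enumeration cap for the exact test; larger totals use a normal approximation
_MAX_ENUMERATION = 2_000_000


class DEError(ValueError):
    pass


@dataclass
class DispersionEstimate:
    """Per-cluster raw and shrunken NB dispersions plus the common value."""

    phi_raw: pd.Series
    phi_shrunk: pd.Series
    phi_common: float
    prior_df: float


@dataclass
class DEResult:
    """Per-cluster log2FC (A over B), p-value, BH FDR and call direction."""

    table: pd.DataFrame
    contrast: str
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)

    @property
    def up(self) -> set[str]:
        t = self.table
        return set(t.index[t["direction"] == "up"])

    @property
    def down(self) -> set[str]:
        t = self.table
        return set(t.index[t["direction"] == "down"])


def cpm_filter(counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 3) -> pd.DataFrame:
    """Drop clusters without >= min_cpm counts-per-million in >= min_samples samples."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise DEError("library sizes (column sums) must be positive")
    cpm = counts / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("cpm_filter removed every cluster", stacklevel=2)
    return counts.loc[keep]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean one.

    The pseudo-reference is the per-cluster geometric mean over clusters with
    all-positive counts; when none exist, falls back to column-sum ratios.
    """
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if positive.any():
        logs = np.log(values[positive])
        ref = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - ref, axis=0))
    else:
        colsum = values.sum(axis=0)
        if (colsum <= 0).any():
            raise DEError("cannot estimate size factors: empty column and no positive clusters")
        factors = colsum
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    prior_df: float = 10.0,
    groups: list[list[str]] | None = None,
) -> DispersionEstimate:
    """Method-of-moments NB dispersion with shrinkage toward the common median.

    phi_g = max(floor, (var - mean) / mean^2) on size-factor-normalised counts;
    with ``groups`` the variance is pooled within groups (residual df n - G) so
    genuine between-group signal does not inflate the estimate.  Shrinkage:
    phi~_g = (df * phi_g + prior_df * phi0) / (df + prior_df).
    """
    n = counts.shape[1]
    if n < 2:
        raise DEError("dispersion requires at least two samples")
    norm = counts / size_factors.reindex(counts.columns)
    x = norm.to_numpy(dtype=float)
    if groups is None:
        resid_df = n - 1
        var = x.var(axis=1, ddof=1)
    else:
        cols = list(counts.columns)
        ss = np.zeros(x.shape[0])
        used = 0
        for g in groups:
            idx = [cols.index(s) for s in g]
            xg = x[:, idx]
            ss += ((xg - xg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            used += len(idx)
        resid_df = used - len(groups)
        if resid_df <= 0:
            raise DEError("not enough replication to estimate dispersion")
        var = ss / resid_df
    mean = x.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mean > 0, (var - mean) / np.maximum(mean, 1e-300) ** 2, 0.0)
    phi_raw = pd.Series(np.maximum(phi, DISPERSION_FLOOR), index=counts.index, name="phi_raw")
    # common value from the unfloored estimates: per-cluster flooring truncates
    # the noise distribution and a median/mean of floored values is biased
    phi_common = float(max(DISPERSION_FLOOR, np.mean(phi[mean > 0]))) if (mean > 0).any() else DISPERSION_FLOOR
    shrunk = (resid_df * phi_raw + prior_df * phi_common) / (resid_df + prior_df)
    phi_shrunk = pd.Series(
        np.maximum(shrunk, DISPERSION_FLOOR), index=counts.index, name="phi_shrunk"
    )
    return DispersionEstimate(phi_raw, phi_shrunk, phi_common, prior_df)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _exact_nb_pvalue(sum_a: float, sum_b: float, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact conditional p for a two-group NB split of a total.

    Conditional on t = sum_a + sum_b, enumerates the probability of every
    group-A total under equal means, summing outcomes no more likely than the
    observed one (with a small relative tolerance for ties).
    """
    t = int(round(sum_a + sum_b))
    if t == 0:
        return 1.0
    mu = t / (n_a + n_b)
    phi = max(phi, DISPERSION_FLOOR)
    r_a, r_b = n_a / phi, n_b / phi
    if t > _MAX_ENUMERATION:
        # conditional split is approximately Gaussian at such totals
        p_frac = n_a / (n_a + n_b)
        var = t * p_frac * (1 - p_frac) * (1 + phi * mu)
        z = (sum_a - t * p_frac) / np.sqrt(var)
        return float(min(1.0, 2 * stats.norm.sf(abs(z))))
    x = np.arange(t + 1)
    p_a = n_a / phi / (n_a / phi + n_a * mu)
    p_b = n_b / phi / (n_b / phi + n_b * mu)
    logpmf = stats.nbinom.logpmf(x, r_a, p_a) + stats.nbinom.logpmf(t - x, r_b, p_b)
    logpmf -= logpmf.max()
    pmf = np.exp(logpmf)
    total = pmf.sum()
    obs = pmf[int(round(sum_a))]
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-12)].sum() / total))


def nb_exact_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersion: DispersionEstimate,
    group_a: list[str],
    group_b: list[str],
    contrast: str | None = None,
    alpha: float = 0.05,
) -> DEResult:
    """Exact conditional NB test of group A versus group B (A is the numerator).

    Counts are equalised to a common effective library size by rescaling with
    the size factors and deterministic half-away-from-zero rounding, then the
    group totals are compared conditionally on their sum.  FDR is BH over the
    tested clusters; direction is 'ns' unless fdr <= alpha.
    """
    if not group_a or not group_b:
        raise DEError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise DEError("groups must be disjoint")
    missing = (set(group_a) | set(group_b)) - set(counts.columns)
    if missing:
        raise DEError(f"samples not in count matrix: {sorted(missing)}")
    absent = counts.index.difference(dispersion.phi_shrunk.index)
    if len(absent):
        raise DEError(f"clusters missing from dispersion table: {list(absent[:5])}")

    sf = size_factors.reindex(counts.columns)
    pseudo = _round_half_away((counts / sf).to_numpy(dtype=float))
    cols = list(counts.columns)
    ia = [cols.index(s) for s in group_a]
    ib = [cols.index(s) for s in group_b]
    sums_a = pseudo[:, ia].sum(axis=1)
    sums_b = pseudo[:, ib].sum(axis=1)
    mean_a = sums_a / len(ia)
    mean_b = sums_b / len(ib)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))

    phi = dispersion.phi_shrunk.reindex(counts.index).to_numpy()
    pvals = np.array(
        [
            _exact_nb_pvalue(sums_a[i], sums_b[i], len(ia), len(ib), phi[i])
            for i in range(len(counts))
        ]
    )
    fdr = bh_adjust(pvals)
    direction = np.where(
        fdr <= alpha, np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "ns")), "ns"
    )
    table = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "fdr": fdr, "direction": direction},
        index=counts.index,
    )
    table.index.name = "cluster_id"
    name = contrast or "A_vs_B"
    return DEResult(table=table, contrast=name, group_a=list(group_a), group_b=list(group_b))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, in input order, clipped to [0, 1]."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DEError("empty p-value list")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DEError("p-values must lie in [0, 1]")
    return np.clip(multipletests(p, method="fdr_bh")[1], 0.0, 1.0)


def ruv_adjust(
    counts: pd.DataFrame, control_ids: list[str], k: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Remove k unwanted-variation factors estimated from negative controls.

    Factors W (samples x k) are the leading per-sample singular directions of
    the centred log(count + 1) sub-matrix of control clusters.  Every
    cluster's log-counts are regressed on W; the intercept plus residual is
    exponentiated, rounded and floored at zero.  k = 0 returns the input.
    """
    if k < 0:
        raise DEError("k must be >= 0")
    if k == 0:
        return counts.copy(), np.zeros((counts.shape[1], 0))
    missing = set(control_ids) - set(counts.index)
    if missing:
        raise DEError(f"control clusters absent from matrix: {sorted(missing)[:5]}")
    if len(control_ids) < k + 1:
        raise DEError(f"need at least {k + 1} control clusters for k={k}")

    log_all = np.log(counts.to_numpy(dtype=float) + 1.0)
    ctrl = np.log(counts.loc[control_ids].to_numpy(dtype=float) + 1.0)
    ctrl_centered = ctrl - ctrl.mean(axis=1, keepdims=True)
    # samples x controls orientation: left-singular vectors are per sample
    u, s, _ = np.linalg.svd(ctrl_centered.T, full_matrices=False)
    w = u[:, :k]

    design = np.column_stack([np.ones(counts.shape[1]), w])
    beta, *_ = np.linalg.lstsq(design, log_all.T, rcond=None)
    adjusted_log = log_all - (w @ beta[1:, :]).T
    adjusted = np.maximum(_round_half_away(np.exp(adjusted_log) - 1.0), 0.0)
    out = pd.DataFrame(adjusted.astype(np.int64), index=counts.index, columns=counts.columns)
    return out, w


def empirical_controls(
    results: list[DEResult], universe: pd.Index, min_p: float = 0.5
) -> list[str]:
    """Clusters with first-pass p > min_p in every contrast: RUV negative controls."""
    keep = pd.Series(True, index=universe)
    for res in results:
        keep &= res.table["pvalue"].reindex(universe) > min_p
    return list(universe[keep.fillna(False)])
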