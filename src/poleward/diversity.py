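"""Alpha/beta diversity, evenness, ordination and covariate selection.

Shannon diversity H' = -sum p_i ln p_i (nats) is the per-station alpha
diversity.  Beta diversity between stations is Bray-Curtis dissimilarity
on (optionally Hellinger-transformed) abundances.  Per-feature evenness
across stations uses a dispersion index: Pielou's J' of the feature's
abundance profile over the stations it occupies.  Covariate selection for
H' ~ environment is stepwise backward elimination of a Gaussian linear
model; single-constraint canonical correspondence analysis quantifies the
fraction of community inertia each environmental variable explains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

from .errors import InputError, ModelError


def shannon(counts) -> float:
    """Shannon diversity H' in nats of one station's abundance vector."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise InputError("negative abundances in Shannon input")
    total = c.sum()
    if total <= 0:
        raise InputError("all-zero abundance vector has undefined Shannon diversity")
    p = c[c > 0] / total
    return float(-np.sum(p * np.log(p)))


def shannon_per_station(table: pd.DataFrame) -> pd.Series:
    """H' for every station row of a stations × features table."""
    return pd.Series(
        {sid: shannon(row.to_numpy()) for sid, row in table.iterrows()}, name="H_prime"
    )


def dispersion_evenness(table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature occupancy and dispersion evenness across stations.

    Occupancy is the number of stations where the feature is present
    (abundance > 0).  The dispersion index is Pielou's J' of the feature's
    abundances across occupied stations, ``H'/ln(occupancy)``, set to 1 by
    convention at occupancy 1 (a feature seen once is trivially even).
    Returns a DataFrame indexed by feature with columns ``occupancy``,
    ``dispersion`` and ``total_abundance``.
    """
    if table.size == 0:
        raise InputError("empty feature table")
    rows = {}
    for feat in table.columns:
        v = table[feat].to_numpy(dtype=float)
        occ = int((v > 0).sum())
        if occ <= 1:
            j = 1.0
        else:
            j = shannon(v[v > 0]) / np.log(occ)
        rows[feat] = {"occupancy": occ, "dispersion": j, "total_abundance": v.sum()}
    return pd.DataFrame.from_dict(rows, orient="index")


def _check_positive_rows(table: pd.DataFrame) -> None:
    sums = table.sum(axis=1)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise InputError(f"station(s) with zero total abundance: {list(zero[:5])}")


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity BC_ij = sum|n_ik-n_jk| / sum(n_ik+n_jk)."""
    _check_positive_rows(table)
    d = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    out = pd.DataFrame(d, index=table.index, columns=table.index)
    out.attrs["metric"] = "bray_curtis"
    return out


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of row-relative abundances."""
    _check_positive_rows(table)
    out = np.sqrt(table.div(table.sum(axis=1), axis=0))
    out.attrs.update(table.attrs)
    return out


def glm_backward_select(
    response: pd.Series,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list[str], pd.Series, pd.Series]:
    """Stepwise backward elimination of a Gaussian linear model.

    Refits ``response ~ 1 + covariates`` and repeatedly drops the covariate
    with the largest p-value >= ``alpha`` (ties broken by column order) until
    every remaining covariate is significant or none remain.

    Returns ``(selected names, coefficients incl. intercept, p-values)``.
    """
    y = np.asarray(response, dtype=float)
    X = covariates.astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ModelError(
            f"need more stations ({len(y)}) than covariates+1 ({X.shape[1] + 1})"
        )
    remaining = list(X.columns)
    while remaining:
        design = sm.add_constant(X[remaining], has_constant="add")
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            raise ModelError(f"rank-deficient design with covariates {remaining}")
        fit = sm.OLS(y, design).fit()
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()  # first occurrence wins ties -> column order
        if pvals[worst] >= alpha:
            remaining.remove(worst)
        else:
            return remaining, fit.params, fit.pvalues
    # Nothing significant: intercept-only model.
    fit = sm.OLS(y, np.ones((len(y), 1))).fit()
    params = pd.Series(fit.params, index=["const"])
    pvals = pd.Series(fit.pvalues, index=["const"])
    return [], params, pvals


def cca_inertia_fraction(table: pd.DataFrame, env) -> float:
    """Fraction of community inertia explained by a single constraint.

    Textbook canonical correspondence analysis with one environmental
    variable: the table is chi-square standardized, regressed (with row
    weights) onto the standardized constraint, and the constrained inertia
    is reported as a fraction of total inertia.
    """
    Y = table.to_numpy(dtype=float)
    if np.any(Y < 0):
        raise InputError("CCA requires a non-negative table")
    total = Y.sum()
    if total <= 0:
        raise InputError("CCA requires a positive grand total")
    z = np.asarray(env, dtype=float)
    if z.shape[0] != Y.shape[0]:
        raise InputError("environment vector length does not match station count")
    if np.ptp(z) == 0:
        raise ModelError("constraint is constant across stations")

    P = Y / total
    r = P.sum(axis=1)  # station weights
    c = P.sum(axis=0)
    keep = c > 0
    P, c = P[:, keep], c[keep]
    expected = np.outer(r, c)
    Q = (P - expected) / np.sqrt(expected)
    total_inertia = float(np.sum(Q**2))
    if total_inertia == 0:
        return 0.0

    zc = z - np.average(z, weights=r)
    sd = np.sqrt(np.average(zc**2, weights=r))
    if sd == 0:
        raise ModelError("constraint is constant under station weights")
    x = np.sqrt(r) * (zc / sd)  # weighted, standardized constraint
    proj = np.outer(x, x @ Q) / (x @ x)
    constrained = float(np.sum(proj**2))
    return constrained / total_inertia
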