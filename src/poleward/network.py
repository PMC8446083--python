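"""Weighted co-occurrence networks: soft-power adjacency, topological overlap,
module detection, eigengenes and module-environment correlation.

Feature profiles (log10-scaled abundances across stations) are turned into a
weighted network by raising the Pearson correlation to a soft power (11 for
combined 16S/18S taxa, 12 for Pfams).  The topological overlap measure (TOM)
rewards nodes that share neighbourhoods; hierarchical clustering of 1 - TOM
cut at a fixed height yields modules, each summarized by its eigengene (first
principal component of the standardized member profiles), which is then
correlated with environmental covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigError, InputError

#: Module names in decreasing-size order, following the conventional palette.
MODULE_PALETTE: tuple[str, ...] = (
    "turquoise",
    "blue",
    "brown",
    "yellow",
    "green",
    "red",
    "black",
    "pink",
    "magenta",
    "purple",
)

GREY = "grey"


@dataclass
class NetworkConfig:
    """Knobs of the co-occurrence analysis.

    ``soft_power`` defaults to 12 (the Pfam analysis); use 11 for the combined
    taxon analysis.  ``adjacency_type`` is "unsigned" (|r|^beta, the literal
    published formula) or "signed" (((1+r)/2)^beta, which separates
    anti-correlated regimes).  ``cut_height`` is the dissimilarity (1 - TOM)
    at which the dendrogram is cut; clusters below ``min_module_size`` are
    relabelled grey.
    """

    soft_power: int = 12
    adjacency_type: str = "unsigned"
    linkage_method: str = "average"
    cut_height: float = 0.99
    min_module_size: int = 3
    log_transform: bool = True
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ConfigError(f"soft_power must be >= 1, got {self.soft_power}")
        if not 0 < self.cut_height <= 1:
            raise ConfigError(f"cut_height must be in (0, 1], got {self.cut_height}")
        if self.min_module_size < 2:
            raise ConfigError(f"min_module_size must be >= 2, got {self.min_module_size}")
        if self.adjacency_type not in ("unsigned", "signed"):
            raise ConfigError(f"adjacency_type must be unsigned|signed, got {self.adjacency_type!r}")


def log_profiles(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log10(x + pseudocount) profiles used for correlation."""
    return np.log10(table + pseudocount)


def soft_adjacency(
    table: pd.DataFrame,
    beta: int,
    adjacency_type: str = "unsigned",
) -> pd.DataFrame:
    """Soft-threshold adjacency from Pearson correlations of feature profiles.

    ``table`` is stations × features (already log-transformed if desired).
    Unsigned: ``|r|**beta``; signed: ``((1+r)/2)**beta``.  Diagonal is 1.
    """
    if table.shape[0] < 3:
        raise InputError("need at least 3 stations to correlate features")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0)
    dead = [f for f, s in zip(table.columns, sd) if s == 0]
    if dead:
        raise InputError(f"zero-variance feature(s), exclude before adjacency: {dead[:5]}")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    if adjacency_type == "unsigned":
        a = np.abs(r) ** beta
    elif adjacency_type == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ConfigError(f"unknown adjacency_type {adjacency_type!r}")
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=table.columns, columns=table.columns)


def tom_matrix(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap measure of a weighted network.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and connectivity ``k_i = sum_{u != i} a_iu``;
    the diagonal is 1.
    """
    A = adjacency.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1]:
        raise InputError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise InputError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise InputError("adjacency entries must lie in [0, 1]")
    n = A.shape[0]
    Aoff = A - np.diag(np.diag(A))
    k = Aoff.sum(axis=1)
    L = Aoff @ Aoff  # L[i,j] includes u=i,j terms only via zeroed diagonal: none
    num = L + Aoff
    den = np.minimum.outer(k, k) + 1.0 - Aoff
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    return pd.DataFrame(T, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom: pd.DataFrame, config: NetworkConfig) -> pd.Series:
    """Cluster 1 - TOM and label modules by decreasing size.

    Average-linkage (configurable) hierarchical clustering of the TOM
    dissimilarity, cut at ``config.cut_height``; clusters smaller than
    ``config.min_module_size`` become grey.  Surviving modules are named
    "turquoise", "blue", ... in decreasing size order.
    """
    features = list(tom.columns)
    if len(features) < config.min_module_size:
        warnings.warn("fewer features than min_module_size; all features are grey")
        return pd.Series(GREY, index=features, name="module")
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method=config.linkage_method)
    raw = fcluster(Z, t=config.cut_height, criterion="distance")
    labels = pd.Series(raw, index=features)
    sizes = labels.value_counts()
    keep = sizes[sizes >= config.min_module_size]
    # Decreasing size; ties by first appearance along the feature order.
    order = sorted(
        keep.index, key=lambda c: (-keep[c], int(np.argmax(labels.to_numpy() == c)))
    )
    name_of = {
        c: (MODULE_PALETTE[i] if i < len(MODULE_PALETTE) else f"module{i + 1}")
        for i, c in enumerate(order)
    }
    return labels.map(lambda c: name_of.get(c, GREY)).rename("module")


def module_eigengene(table: pd.DataFrame, labels: pd.Series, module: str) -> pd.Series:
    """First principal component of a module's standardized member profiles.

    The eigengene is scaled to unit sample variance and sign-oriented so that
    its mean correlation with the member profiles is positive.
    """
    members = [f for f in table.columns if labels.get(f) == module]
    if not members:
        raise InputError(f"no module named {module!r} among labels")
    if len(members) < 2:
        raise InputError(f"module {module!r} has fewer than 2 members")
    X = table[members].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise InputError(f"zero-variance member in module {module!r}")
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    e = U[:, 0]
    e = e / e.std(ddof=1)
    corrs = [np.corrcoef(e, Z[:, j])[0, 1] for j in range(Z.shape[1])]
    if np.mean(corrs) < 0:
        e = -e
    return pd.Series(e, index=table.index, name=f"ME_{module}")


def module_eigengenes(table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Eigengene per non-grey module, stations × modules."""
    modules = [m for m in pd.unique(labels) if m != GREY]
    return pd.DataFrame({m: module_eigengene(table, labels, m) for m in modules})


def module_trait_correlation(
    eigengenes: pd.DataFrame, env: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p between each eigengene and each covariate.

    p-values come from the exact t transform ``t = r sqrt((n-2)/(1-r^2))``
    with n-2 degrees of freedom.  Only stations shared by both tables are
    used; fewer than 4 shared stations is an error.
    """
    shared = eigengenes.index.intersection(env.index)
    if len(shared) < 4:
        raise InputError(f"only {len(shared)} shared stations; need >= 4")
    E = eigengenes.loc[shared]
    V = env.loc[shared]
    r = pd.DataFrame(index=E.columns, columns=V.columns, dtype=float)
    p = pd.DataFrame(index=E.columns, columns=V.columns, dtype=float)
    for m in E.columns:
        for cov in V.columns:
            rr, pp = stats.pearsonr(E[m], V[cov].astype(float))
            r.loc[m, cov], p.loc[m, cov] = rr, pp
    return r, p


def node_geography(table: pd.DataFrame, labels: pd.Series, module: str) -> pd.Series:
    """Per-station percentage of a module's total abundance pool.

    ``100 * (station sum over member features) / (grand sum over members)``;
    the percentages sum to 100 across stations.
    """
    members = [f for f in table.columns if labels.get(f) == module]
    if not members:
        raise InputError(f"no module named {module!r} among labels")
    station_sums = table[members].sum(axis=1)
    total = station_sums.sum()
    if total <= 0:
        raise InputError(f"module {module!r} has zero total abundance")
    return (100.0 * station_sums / total).rename(f"pct_{module}")
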