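"""Copy-number models and abundance-table normalization.

Two routes produce per-feature rRNA gene copy numbers:

* **16S** — strain records are averaged per species (rrnDB style), species
  values are propagated up the taxonomy, and missing taxa are imputed from
  their nearest valued ancestor.
* **18S** — no copy-number database exists for most eukaryotes, so copies are
  predicted from genome size through a log-log power law
  ``log10(copies) = slope * log10(genome size, Mbp) + intercept``
  fit on a reference table of species with both quantities known.

Normalization divides each feature's abundance by its copy number (to
approximate organismal abundance), then rescales every station row to hits
per million.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError, NormalizationError, TaxonomyError
from .taxonomy import Taxonomy


@dataclass(frozen=True)
class CopyNumberModel:
    """OLS fit of log10(copy number) on log10(genome size in Mbp)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    x_units: str = "Mbp"

    def predict(self, genome_size: float) -> float:
        return predict_copy_number(self, genome_size)


def fit_copy_number_model(
    genome_sizes: Iterable[float], copy_numbers: Iterable[float]
) -> CopyNumberModel:
    """Fit the genome-size → copy-number power law by OLS on log10 scales.

    Parameters are strictly positive; genome sizes are in Mbp.  Returns the
    slope, intercept, coefficient of determination and number of points.
    """
    x = np.asarray(list(genome_sizes), dtype=float)
    y = np.asarray(list(copy_numbers), dtype=float)
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.size} genome sizes vs {y.size} copy numbers")
    if x.size < 3:
        raise InputError("need at least 3 points to fit the copy-number model")
    if np.any(x <= 0) or np.any(y <= 0):
        raise InputError("genome sizes and copy numbers must be strictly positive")
    lx, ly = np.log10(x), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return CopyNumberModel(float(slope), float(intercept), float(r2), int(x.size))


def predict_copy_number(model: CopyNumberModel, genome_size: float) -> float:
    """Evaluate the power law: ``10**(slope*log10(G) + intercept)`` copies."""
    if genome_size <= 0:
        raise InputError(f"genome size must be positive, got {genome_size}")
    return float(10.0 ** (model.slope * np.log10(genome_size) + model.intercept))


def average_copy_numbers_by_species(
    entries: Iterable[tuple[str, float]],
) -> dict[str, float]:
    """Collapse strain-level records to one arithmetic-mean copy number per species."""
    totals: dict[str, list[float]] = {}
    n = 0
    for species, value in entries:
        totals.setdefault(str(species), []).append(float(value))
        n += 1
    if n == 0:
        raise InputError("no copy-number entries supplied")
    return {sp: sum(v) / len(v) for sp, v in totals.items()}


def normalize_by_copy_number(
    table: pd.DataFrame, copies: Mapping[str, float]
) -> pd.DataFrame:
    """Divide each feature column by its copy number.

    ``table`` is stations × features.  Every feature must have a strictly
    positive copy number; order of stations and features is preserved.
    """
    missing = [f for f in table.columns if f not in copies]
    if missing:
        raise NormalizationError(f"no copy number for feature(s): {missing[:5]}")
    divisors = np.array([float(copies[f]) for f in table.columns])
    bad = [f for f, d in zip(table.columns, divisors) if not d > 0]
    if bad:
        raise NormalizationError(f"non-positive copy number for feature(s): {bad[:5]}")
    out = table.div(pd.Series(divisors, index=table.columns), axis=1)
    out.attrs.update(table.attrs)
    return out


def hits_per_million(table: pd.DataFrame) -> pd.DataFrame:
    """Rescale every station row to sum to 1e6 (hits per million)."""
    sums = table.sum(axis=1)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise NormalizationError(f"station(s) with zero total abundance: {list(zero[:5])}")
    out = table.div(sums, axis=0) * 1e6
    out.attrs.update(table.attrs)
    return out


def _nc_label(name: str) -> str:
    return f"Nc. {name}"


def _u_label(name: str) -> str:
    return f"U. {name}"


def aggregate_to_rank(
    table: pd.DataFrame,
    taxonomy: Taxonomy,
    rank: str,
    root_label: str | None = None,
) -> tuple[pd.DataFrame, float]:
    """Aggregate feature columns to a target taxonomic rank.

    Features (columns, named by taxonomy node id or node name) are regrouped:

    * a feature at or below a node of the target rank is summed into that
      node's name;
    * a feature below the rank boundary whose lineage *lacks* the target rank
      is summed under ``"Nc. <name>"`` of its nearest ancestor above the
      boundary ("Nc." = no class) — abundance sitting directly on that
      ancestor is *not* included;
    * a feature on an internal node strictly between the target rank and the
      root keeps its own name prefixed ``"U. "`` (unknown below that level);
    * abundance assigned to the root node itself (``root_label`` or the tree
      root) is dropped, and the dropped fraction of total abundance returned.

    Returns ``(aggregated table, dropped_fraction)``.
    """
    target_pos = taxonomy.rank_position(rank)
    if target_pos is None:
        raise TaxonomyError(f"rank {rank!r} is not in the taxonomy's rank order")
    root_id = taxonomy.root if root_label is None else taxonomy.id_for_name(root_label)

    groups: dict[str, np.ndarray] = {}
    dropped = np.zeros(len(table.index))
    total = float(table.to_numpy().sum())
    for feat in table.columns:
        nid = feat if feat in taxonomy else taxonomy.id_for_name(str(feat))
        col = table[feat].to_numpy(dtype=float)
        if nid == root_id:
            dropped += col
            continue
        lineage = taxonomy.lineage(nid)
        at_rank = next((a for a in lineage if taxonomy.rank[a] == rank), None)
        if at_rank is not None:
            label = taxonomy.name[at_rank]
        else:
            own_pos = taxonomy.rank_position(taxonomy.rank[nid])
            if own_pos is None:
                raise TaxonomyError(
                    f"feature {feat!r} has unordered rank {taxonomy.rank[nid]!r}"
                )
            if own_pos > target_pos:
                # Leaf-side lineage that skips the target rank entirely.
                anc = next(
                    a
                    for a in lineage[1:]
                    if (p := taxonomy.rank_position(taxonomy.rank[a])) is not None
                    and p < target_pos
                )
                label = _nc_label(taxonomy.name[anc])
            else:
                # Internal node between the target rank and the root.
                label = _u_label(taxonomy.name[nid])
        groups[label] = groups.get(label, 0) + col

    out = pd.DataFrame(groups, index=table.index)
    out.attrs.update(table.attrs)
    dropped_fraction = float(dropped.sum()) / total if total > 0 else 0.0
    return out, dropped_fraction
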