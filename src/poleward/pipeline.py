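"""End-to-end pipeline: simulate → normalize → diversity → network → breakpoint → project.

Each stage reads its inputs from, and writes its artifacts to, a working
directory, so stages can be run independently (a missing upstream artifact
raises an error naming the stage that produces it).  Every stage writes a
JSON run report with the parameters, seed and package version, enough to
re-execute the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breakpoints import (
    DEFAULT_TEMPERATURE_WINDOW,
    bag_outliers,
    fit_breakpoint,
    presence_absence,
    sorensen_matrix,
    station_beta,
)
from .climate import BandThresholds, band_shift_summary, bias_correct, classify_bands
from .diversity import cca_inertia_fraction, glm_backward_select, shannon_per_station
from .errors import PolewardError
from .io import (
    read_environment,
    read_feature_table,
    read_taxonomy,
    write_distance_matrix,
    write_environment,
    write_feature_table,
    write_run_report,
    write_taxonomy,
)
from .network import (
    NetworkConfig,
    log_profiles,
    module_eigengenes,
    module_trait_correlation,
    node_geography,
    soft_adjacency,
    tom_matrix,
)
from .normalize import (
    average_copy_numbers_by_species,
    fit_copy_number_model,
    hits_per_million,
    normalize_by_copy_number,
    predict_copy_number,
)
from .simulate import TransectConfig, simulate_sst_grids, simulate_transect
from .taxonomy import Taxonomy, impute_missing_attribute

log = logging.getLogger("poleward")

STAGES = ("simulate", "normalize", "diversity", "network", "breakpoint", "project", "all")

ENV_COVARIATES = ("temperature", "salinity", "nitrate_nitrite", "phosphate", "silicate")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "poleward_out"
    seed: int = 0
    transect: TransectConfig = field(default_factory=TransectConfig)
    network: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(
            soft_power=12, adjacency_type="signed", min_module_size=5
        )
    )
    breakpoint_axis: str = "temperature"  # or "altered_latitude"
    beta_reduction: str = "mean"
    remove_outliers: bool = True
    temperature_window: tuple[float, float] = DEFAULT_TEMPERATURE_WINDOW
    thresholds: BandThresholds = field(default_factory=BandThresholds)
    warming_offset: float = 3.0
    grid_shape: tuple[int, int] = (60, 72)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _report(config: PipelineConfig, stage: str, payload: dict) -> dict:
    return {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.digest(),
        "version": __version__,
        "parameters": config.to_dict(),
        **payload,
    }


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise PolewardError(
            f"missing artifact {path.name!r}; run the {produced_by!r} stage first"
        )
    return path


def stage_simulate(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.transect.seed = config.seed
    data = simulate_transect(config.transect)
    write_feature_table(data.table_16S, out / "table_16S.tsv")
    write_feature_table(data.table_18S, out / "table_18S.tsv")
    write_feature_table(data.table_pfam, out / "table_pfam.tsv")
    write_environment(data.env, out / "environment.tsv")
    write_taxonomy(data.taxonomy, out / "taxonomy.tsv")
    data.copy_reference_18S.to_csv(out / "copy_reference_18S.tsv", sep="\t", index=False)
    data.rrndb_like_16S.to_csv(out / "rrndb_like_16S.tsv", sep="\t", index=False)
    truth = {
        "threshold_T": data.truth.threshold_T,
        "module_membership": data.truth.module_membership,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    report = _report(config, "simulate", {"n_stations": len(data.env)})
    write_run_report(report, out / "report_simulate.json")
    return report


def _augmented_taxonomy(taxonomy: Taxonomy, species_names) -> Taxonomy:
    """Attach rrnDB-style species records under their genus nodes by name prefix."""
    df = taxonomy.to_frame()
    extra = []
    for sp in species_names:
        genus = sp.rsplit("_sp", 1)[0]
        if genus in taxonomy and sp not in taxonomy:
            extra.append((sp, genus, "species", sp))
    if extra:
        df = pd.concat(
            [df, pd.DataFrame(extra, columns=["node_id", "parent_id", "rank", "name"])],
            ignore_index=True,
        )
    return Taxonomy(df)


def stage_normalize(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    t16 = read_feature_table(_require(out / "table_16S.tsv", "simulate"))
    t18 = read_feature_table(_require(out / "table_18S.tsv", "simulate"))
    tpf = read_feature_table(_require(out / "table_pfam.tsv", "simulate"))
    taxonomy = read_taxonomy(_require(out / "taxonomy.tsv", "simulate"))
    ref18 = pd.read_csv(_require(out / "copy_reference_18S.tsv", "simulate"), sep="\t")
    rrndb = pd.read_csv(_require(out / "rrndb_like_16S.tsv", "simulate"), sep="\t")

    # 16S: strain -> species averages, propagate through the taxonomy, impute.
    species_means = average_copy_numbers_by_species(
        list(zip(rrndb["species"], rrndb["copy_number"]))
    )
    tax_aug = _augmented_taxonomy(taxonomy, species_means)
    known = {sp: v for sp, v in species_means.items() if sp in tax_aug}
    copies16 = impute_missing_attribute(tax_aug, known, list(t16.columns))
    t16n = hits_per_million(normalize_by_copy_number(t16, copies16))

    # 18S: fit the genome-size law on the reference table, impute missing
    # genome sizes from relatives, predict copies, divide, rescale.
    complete = ref18.dropna(subset=["genome_size_Mbp", "copy_number"])
    model = fit_copy_number_model(complete["genome_size_Mbp"], complete["copy_number"])
    known_sizes = {
        str(r["name"]): float(r["genome_size_Mbp"])
        for _, r in ref18.iterrows()
        if pd.notna(r["genome_size_Mbp"]) and str(r["name"]) in taxonomy
    }
    sizes = impute_missing_attribute(taxonomy, known_sizes, list(t18.columns))
    copies18 = {f: predict_copy_number(model, g) for f, g in sizes.items()}
    t18n = hits_per_million(normalize_by_copy_number(t18, copies18))

    tpfn = hits_per_million(tpf)

    write_feature_table(t16n, out / "normalized_16S.tsv")
    write_feature_table(t18n, out / "normalized_18S.tsv")
    write_feature_table(tpfn, out / "normalized_pfam.tsv")
    report = _report(
        config,
        "normalize",
        {
            "copy_number_model": {
                "slope": model.slope,
                "intercept": model.intercept,
                "r_squared": model.r_squared,
                "n_points": model.n_points,
            }
        },
    )
    write_run_report(report, out / "report_normalize.json")
    return report


def stage_diversity(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    env = read_environment(_require(out / "environment.tsv", "simulate"))
    results: dict = {}
    shannon_frames = {}
    for name in ("16S", "18S"):
        table = read_feature_table(_require(out / f"normalized_{name}.tsv", "normalize"))
        h = shannon_per_station(table)
        shannon_frames[name] = h
        covs = env[list(ENV_COVARIATES)]
        selected, params, pvals = glm_backward_select(h.loc[env.index], covs)
        cca = {
            cov: cca_inertia_fraction(table.loc[env.index], env[cov])
            for cov in ENV_COVARIATES
        }
        results[name] = {
            "glm_selected": selected,
            "glm_coefficients": {k: float(v) for k, v in params.items()},
            "cca_inertia_fraction": cca,
            "shannon_temperature_r": float(
                np.corrcoef(h.loc[env.index], env["temperature"])[0, 1]
            ),
        }
    pd.DataFrame(shannon_frames).to_csv(out / "shannon.tsv", sep="\t", index_label="station_id")
    report = _report(config, "diversity", {"diversity": results})
    write_run_report(report, out / "report_diversity.json")
    return report


def stage_network(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    table = read_feature_table(_require(out / "normalized_pfam.tsv", "normalize"))
    env = read_environment(_require(out / "environment.tsv", "simulate"))
    profiles = (
        log_profiles(table, config.network.pseudocount)
        if config.network.log_transform
        else table
    )
    keep = profiles.columns[profiles.std(axis=0) > 0]
    profiles = profiles[keep]
    adj = soft_adjacency(profiles, config.network.soft_power, config.network.adjacency_type)
    tom = tom_matrix(adj)
    from .network import detect_modules

    labels = detect_modules(tom, config.network)
    eigengenes = module_eigengenes(profiles, labels)
    covs = env[["altered_latitude", *ENV_COVARIATES]]
    r, p = module_trait_correlation(eigengenes, covs)
    geography = {
        m: node_geography(table, labels, m).to_dict()
        for m in eigengenes.columns
    }
    labels.to_frame().to_csv(out / "module_membership.tsv", sep="\t", index_label="feature")
    eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index_label="station_id")
    write_distance_matrix(tom, out / "tom.tsv")
    r.to_csv(out / "module_trait_r.tsv", sep="\t", index_label="module")
    p.to_csv(out / "module_trait_p.tsv", sep="\t", index_label="module")
    report = _report(
        config,
        "network",
        {
            "n_modules": int(len(eigengenes.columns)),
            "module_sizes": labels.value_counts().to_dict(),
            "temperature_r": {m: float(r.loc[m, "temperature"]) for m in r.index},
            "node_geography_pct": geography,
        },
    )
    write_run_report(report, out / "report_network.json")
    return report


def breakpoint_analysis(
    table: pd.DataFrame,
    env: pd.DataFrame,
    axis: str = "temperature",
    search_range: tuple[float, float] | None = None,
    reduction: str = "mean",
    remove_outliers: bool = True,
) -> dict:
    """Presence-absence → Sørensen → per-station beta → bagplot → broken stick."""
    pa = presence_absence(table)
    keep = pa.index[pa.sum(axis=1) > 0]
    pa = pa.loc[keep]
    dist = sorensen_matrix(pa)
    beta = station_beta(dist, reduction=reduction)
    x = env.loc[beta.index, axis].astype(float)
    if search_range is not None:
        inside = (x >= search_range[0]) & (x <= search_range[1])
        x, beta = x[inside], beta[inside]
    flagged = (
        bag_outliers(x.to_numpy(), beta.to_numpy())
        if remove_outliers
        else np.zeros(len(x), dtype=bool)
    )
    fit = fit_breakpoint(x.to_numpy()[~flagged], beta.to_numpy()[~flagged], search_range)
    return {
        "axis": axis,
        "psi": fit.psi,
        "coefficients": list(fit.coefficients),
        "mse": fit.mse,
        "p_value": fit.p_value,
        "n_used": fit.n_used,
        "n_flagged": int(flagged.sum()),
        "flagged_stations": list(beta.index[flagged]),
        "search_range": list(fit.search_range),
        "notes": fit.notes,
    }


def stage_breakpoint(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    env = read_environment(_require(out / "environment.tsv", "simulate"))
    analyses: dict = {}
    for name in ("16S", "18S", "pfam"):
        table = read_feature_table(_require(out / f"normalized_{name}.tsv", "normalize"))
        window = config.temperature_window if name in ("16S", "18S") else None
        analyses[name] = breakpoint_analysis(
            table,
            env,
            axis=config.breakpoint_axis,
            search_range=window if config.breakpoint_axis == "temperature" else None,
            reduction=config.beta_reduction,
            remove_outliers=config.remove_outliers,
        )
    rows = pd.DataFrame(
        {
            name: {"psi": a["psi"], "mse": a["mse"], "p_value": a["p_value"], "n_used": a["n_used"]}
            for name, a in analyses.items()
        }
    ).T
    rows.to_csv(out / "breakpoints.tsv", sep="\t", index_label="dataset")
    report = _report(config, "breakpoint", {"breakpoints": analyses})
    write_run_report(report, out / "report_breakpoint.json")
    return report


def stage_project(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    n_lat, n_lon = config.grid_shape
    obs, hist, proj, _ice = simulate_sst_grids(
        n_lat, n_lon, config.warming_offset, seed=config.seed
    )
    corrected = bias_correct(obs, hist, proj)
    before = classify_bands(obs, config.thresholds)
    after = classify_bands(corrected, config.thresholds)
    summary = band_shift_summary(before, after, obs.latitudes, lat_band=(40.0, 60.0))
    summary["transition_counts"] = summary["transition_counts"].tolist()
    report = _report(config, "project", {"band_shift_40_60N": summary})
    write_run_report(report, out / "report_project.json")
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "normalize": stage_normalize,
    "diversity": stage_diversity,
    "network": stage_network,
    "breakpoint": stage_breakpoint,
    "project": stage_project,
}


def run_pipeline(config: PipelineConfig, stage: str = "all") -> dict:
    """Run one stage or the full chain; returns the (final) run report.

    The "all" report collects the headline quantities: recovered breakpoints,
    module count, and the sign of each module's temperature correlation.
    """
    if stage not in STAGES:
        raise PolewardError(f"unknown stage {stage!r}; choose from {STAGES}")
    if stage != "all":
        t0 = time.time()
        report = _STAGE_FUNCS[stage](config)
        log.info("stage %s finished in %.2fs", stage, time.time() - t0)
        return report
    reports = {}
    for s in ("simulate", "normalize", "diversity", "network", "breakpoint", "project"):
        t0 = time.time()
        reports[s] = _STAGE_FUNCS[s](config)
        log.info("stage %s finished in %.2fs", s, time.time() - t0)
    summary = _report(
        config,
        "all",
        {
            "planted_threshold_T": config.transect.threshold_T,
            "recovered_psi": {
                k: v["psi"] for k, v in reports["breakpoint"]["breakpoints"].items()
            },
            "n_modules": reports["network"]["n_modules"],
            "module_temperature_r_sign": {
                m: ("+" if r > 0 else "-")
                for m, r in reports["network"]["temperature_r"].items()
            },
        },
    )
    write_run_report(summary, Path(config.outdir) / "report_all.json")
    return summary
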