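"""Synthetic pole-to-pole transects with planted ground truth.

The generator emulates the structure of a latitudinal ocean transect sampled
at the chlorophyll maximum: a monotone temperature gradient from pole to
equator, nutrient concentrations anti-correlated with temperature (cold
upper waters are nutrient rich), salinity positively correlated, and two
latent community regimes — cold and warm — that switch at a configurable
temperature threshold psi*.  Every feature's expected abundance follows a
logistic occupancy curve in temperature centred at psi* (rising for warm
features, falling for cold ones); observed abundances add multiplicative
lognormal noise and a detection limit, so presence-absence turnover
concentrates near the planted threshold and the beta-diversity breakpoint
is identifiable by construction.

18S species additionally carry genome sizes and rRNA copy numbers obeying a
planted power law ``log10(copies) = slope*log10(Mbp) + intercept + noise``,
with a configurable fraction of species masked to exercise imputation; 16S
genera carry rrnDB-style strain-level copy-number records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import SEA_ICE_TEMPERATURE, ClimateGrid
from .errors import ConfigError, GridError
from .taxonomy import Taxonomy


@dataclass
class TransectConfig:
    """Parameters of a synthetic transect; defaults are the study conditions."""

    n_stations: int = 40
    lat_range: tuple[float, float] = (-75.0, 75.0)
    T_pole: float = -1.5
    T_equator: float = 28.0
    threshold_T: float = 14.0
    n_cold_taxa: int = 12
    n_warm_taxa: int = 16
    n_shared_taxa: int = 10
    n_pfams_per_module: int = 40
    occupancy_scale: float = 1.5  # deg C; steepness of the logistic turnover
    noise_sd: float = 0.2  # lognormal sigma on log10 abundance
    env_noise_sd: float = 0.1  # deg C jitter on temperature
    copy_slope: float = 0.66
    copy_intercept: float = 0.75
    copy_noise_sd: float = 0.35  # tuned so the refit law has R^2 near 0.55
    missing_fraction: float = 0.3  # species lacking genome size / copy number
    base_abundance: float = 100.0
    detection_limit: float = 10.0  # abundance below this reads as absent
    dropout: float = 0.03  # per-cell probability of a sampling miss (false absence)
    seed: int = 0

    def validate(self) -> None:
        if self.n_stations < 8:
            raise ConfigError(f"n_stations must be >= 8, got {self.n_stations}")
        if not (-90 <= self.lat_range[0] < self.lat_range[1] <= 90):
            raise ConfigError(f"lat_range must be increasing within [-90, 90], got {self.lat_range}")
        if not self.T_pole < self.threshold_T < self.T_equator:
            raise ConfigError(
                "threshold_T must satisfy T_pole < threshold_T < T_equator, got "
                f"T_pole={self.T_pole}, threshold_T={self.threshold_T}, T_equator={self.T_equator}"
            )
        for name in ("n_cold_taxa", "n_warm_taxa", "n_shared_taxa", "n_pfams_per_module"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.occupancy_scale <= 0:
            raise ConfigError(f"occupancy_scale must be > 0, got {self.occupancy_scale}")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigError(f"missing_fraction must be in [0, 1), got {self.missing_fraction}")
        if not 0 <= self.dropout < 1:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated transect."""

    threshold_T: float
    module_membership: dict[str, str]  # feature -> cold | warm | none
    copy_numbers: dict[str, float]  # feature -> true copies per genome
    genome_sizes: dict[str, float]  # 18S feature -> Mbp


@dataclass
class TransectData:
    """All artifacts of one simulated transect."""

    table_16S: pd.DataFrame
    table_18S: pd.DataFrame
    table_pfam: pd.DataFrame
    env: pd.DataFrame
    taxonomy: Taxonomy
    truth: SyntheticTruth
    copy_reference_18S: pd.DataFrame  # name, genome_size_Mbp, copy_number (NaN = missing)
    rrndb_like_16S: pd.DataFrame  # species, copy_number (strain-level records)

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {"16S": self.table_16S, "18S": self.table_18S, "pfam": self.table_pfam}


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _environment(config: TransectConfig, rng: np.random.Generator) -> pd.DataFrame:
    lats = np.linspace(config.lat_range[1], config.lat_range[0], config.n_stations)
    max_abs = np.abs(lats).max()
    frac = np.abs(lats) / max_abs  # 0 at equator-most, 1 at pole-most station
    T_true = config.T_equator + (config.T_pole - config.T_equator) * frac
    T = T_true + rng.normal(0, config.env_noise_sd, size=lats.size)
    span = config.T_equator - config.T_pole
    cold_frac = (config.T_equator - T_true) / span  # 1 at the pole, 0 at the equator
    env = pd.DataFrame(
        {
            "latitude": lats,
            "altered_latitude": 90.0 - lats,
            "temperature": T,
            "salinity": 33.0 + 2.5 * (1 - cold_frac) + rng.normal(0, 0.35, lats.size),
            "nitrate_nitrite": np.clip(16.0 * cold_frac + rng.normal(0, 2.5, lats.size), 0, None),
            "phosphate": np.clip(1.5 * cold_frac + rng.normal(0, 0.25, lats.size), 0, None),
            "silicate": np.clip(30.0 * cold_frac + rng.normal(0, 5.0, lats.size), 0, None),
        },
        index=[f"st{i + 1:02d}" for i in range(lats.size)],
    )
    env.index.name = "station_id"
    return env


def _abundances(
    T: np.ndarray,
    features: list[str],
    membership: dict[str, str],
    config: TransectConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    cols = {}
    for f in features:
        base = config.base_abundance * 10 ** rng.uniform(-0.5, 0.5)
        role = membership[f]
        noise = 10 ** rng.normal(0, config.noise_sd, size=T.size)
        if role in ("warm", "cold"):
            sign = 1.0 if role == "warm" else -1.0
            frac = _logistic(sign * (T - config.threshold_T) / config.occupancy_scale)
            obs = base * frac * noise
            # Each feature's presence boundary falls where its expected
            # abundance crosses the detection limit, spreading turnover over
            # a few degrees around the planted threshold.
            obs[obs < config.detection_limit] = 0.0
        else:  # ubiquitous background taxa
            obs = 0.6 * base * noise
        if config.dropout > 0 and config.noise_sd > 0:
            # Sampling stochasticity: occasional false absences, as in real
            # amplicon/transcript data.  Off in the noiseless regime.
            obs = np.where(rng.random(T.size) < config.dropout, 0.0, obs)
        cols[f] = obs
    return pd.DataFrame(cols)


def _taxonomy_frame(
    genera_16S: list[str], species_18S: list[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    rows = [("root", "root", "root", "root"),
            ("d_bacteria", "root", "domain", "Bacteria"),
            ("d_eukaryota", "root", "domain", "Eukaryota")]
    n_classes = 4
    for d, short in (("d_bacteria", "b"), ("d_eukaryota", "e")):
        for c in range(n_classes):
            rows.append((f"c_{short}{c}", d, "class", f"Class_{short}{c}"))
    species_genus: dict[str, str] = {}
    for i, g in enumerate(genera_16S):
        rows.append((g, f"c_b{i % n_classes}", "genus", g))
    for i, s in enumerate(species_18S):
        genus = f"g_e{i}"
        rows.append((genus, f"c_e{i % n_classes}", "genus", genus))
        rows.append((s, genus, "species", s))
        species_genus[s] = genus
    df = pd.DataFrame(rows, columns=["node_id", "parent_id", "rank", "name"])
    return df, species_genus


def simulate_transect(config: TransectConfig | None = None) -> TransectData:
    """Generate one transect: three abundance tables, environment, taxonomy, truth.

    Deterministic for a fixed ``config.seed``.
    """
    config = config or TransectConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    env = _environment(config, rng)
    T = env["temperature"].to_numpy()

    genera = (
        [f"g_cold{i:02d}" for i in range(config.n_cold_taxa)]
        + [f"g_warm{i:02d}" for i in range(config.n_warm_taxa)]
        + [f"g_shared{i:02d}" for i in range(config.n_shared_taxa)]
    )
    species = (
        [f"s_cold{i:02d}" for i in range(config.n_cold_taxa)]
        + [f"s_warm{i:02d}" for i in range(config.n_warm_taxa)]
        + [f"s_shared{i:02d}" for i in range(config.n_shared_taxa)]
    )
    pfams = [f"PF_cold{i:03d}" for i in range(config.n_pfams_per_module)] + [
        f"PF_warm{i:03d}" for i in range(config.n_pfams_per_module)
    ]

    def role_of(name: str) -> str:
        if "cold" in name:
            return "cold"
        if "warm" in name:
            return "warm"
        return "none"

    membership = {f: role_of(f) for f in genera + species + pfams}

    t16 = _abundances(T, genera, membership, config, rng)
    t18 = _abundances(T, species, membership, config, rng)
    tpf = _abundances(T, pfams, membership, config, rng)
    for t in (t16, t18, tpf):
        t.index = env.index
    t16.attrs["feature_kind"] = "taxon_16S"
    t18.attrs["feature_kind"] = "taxon_18S"
    tpf.attrs["feature_kind"] = "pfam"

    tax_df, _ = _taxonomy_frame(genera, species)
    taxonomy = Taxonomy(tax_df)

    # Planted copy-number law for 18S species: log10(copies) ~ slope*log10(G)+intercept.
    log_g = rng.uniform(1.0, 3.0, size=len(species))  # 10 - 1000 Mbp
    log_c = (
        config.copy_slope * log_g
        + config.copy_intercept
        + rng.normal(0, config.copy_noise_sd, size=len(species))
    )
    genome_sizes = dict(zip(species, 10.0**log_g))
    copies_18S = dict(zip(species, 10.0**log_c))
    missing = rng.random(len(species)) < config.missing_fraction
    copy_reference = pd.DataFrame(
        {
            "name": species,
            "genome_size_Mbp": [np.nan if m else genome_sizes[s] for s, m in zip(species, missing)],
            "copy_number": [np.nan if m else copies_18S[s] for s, m in zip(species, missing)],
        }
    )

    # rrnDB-style strain records for the 16S genera.
    copies_16S = {g: float(10 ** rng.uniform(0.0, 1.0)) for g in genera}  # 1 - 10 copies
    strain_rows = []
    for g in genera:
        for sp_idx in range(int(rng.integers(1, 4))):
            sp_name = f"{g}_sp{sp_idx}"
            for _strain in range(int(rng.integers(1, 4))):
                strain_rows.append(
                    (sp_name, max(1.0, copies_16S[g] * 10 ** rng.normal(0, 0.05)))
                )
    rrndb_like = pd.DataFrame(strain_rows, columns=["species", "copy_number"])

    truth = SyntheticTruth(
        threshold_T=config.threshold_T,
        module_membership=membership,
        copy_numbers={**copies_18S, **copies_16S},
        genome_sizes=genome_sizes,
    )
    return TransectData(
        table_16S=t16,
        table_18S=t18,
        table_pfam=tpf,
        env=env,
        taxonomy=taxonomy,
        truth=truth,
        copy_reference_18S=copy_reference,
        rrndb_like_16S=rrndb_like,
    )


def simulate_sst_grids(
    n_lat: int,
    n_lon: int,
    warming_offset: float,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> tuple[ClimateGrid, ClimateGrid, ClimateGrid, np.ndarray]:
    """Observed, modelled-historical and projected SST grids plus an ice mask.

    The observed climatology is a zonal temperature profile with a small
    longitudinal ripple; the model historical field adds a smooth bias; the
    projection is the historical field plus ``warming_offset`` (plus noise).
    The ice mask marks cells whose observed climatology is below the freezing
    proxy (-1.8 deg C).
    """
    if n_lat < 2 or n_lon < 2:
        raise GridError(f"grid must be at least 2x2, got {n_lat}x{n_lon}")
    rng = np.random.default_rng(seed)
    lats = np.linspace(-89.0, 89.0, n_lat)
    lons = np.linspace(0.0, 358.0, n_lon)
    frac = (np.abs(lats) / 90.0)[:, None]
    ripple = 0.5 * np.sin(np.deg2rad(lons))[None, :]
    obs = 29.0 - 33.0 * frac**1.3 + ripple + rng.normal(0, noise_sd, (n_lat, n_lon))
    bias = 0.8 * np.cos(np.deg2rad(lats))[:, None] + rng.normal(0, noise_sd, (n_lat, n_lon))
    hist = obs + bias
    proj = hist + warming_offset + rng.normal(0, noise_sd, (n_lat, n_lon))
    ice = obs < SEA_ICE_TEMPERATURE
    grid_obs = ClimateGrid(lats, lons, obs, "observed climatology", ice)
    grid_hist = ClimateGrid(lats, lons, hist, "model historical", ice)
    grid_proj = ClimateGrid(lats, lons, proj, "model projection", ice)
    return grid_obs, grid_hist, grid_proj, ice
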