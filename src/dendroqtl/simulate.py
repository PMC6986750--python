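"""Synthetic genotypes, weather and ring widths with planted QTL signal.

The generator emulates the three inputs of the analysis at configurable
scale: (1) a pseudo-testcross clonal mapping population genotyped on two
parental linkage maps, (2) daily weather with two-state Markov-chain
wet/dry spell structure, and (3) per-tree annual ring widths in which a
clone's drought sensitivity is controlled by planted QTLs.  Every
generator is a pure function of its parameters and a seed, and the
planted truth (QTL positions, effects, per-QTL PVE) is emitted alongside
the data so downstream recovery can be scored against it.

Default scale mirrors the study design this pipeline targets: 139 clones
x 3 clonal replicates, two linkage maps of 11 groups with ~1.5 cM marker
spacing (~450 markers each at desk scale), ~11 ring years, and a growth
model in which the March dry-period index (threshold 4 days) drives
year-to-year growth through a log-linear link.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import find_dry_spells, linear_detrend, monthly_dry_index
from .qtl import haldane_cm_to_r

__all__ = [
    "MapSpec",
    "TruthModel",
    "WeatherParams",
    "default_map_pair",
    "simulate_genotypes",
    "simulate_daily_climate",
    "simulate_sensitivities",
    "simulate_ring_widths",
    "build_truth_for_pve",
    "simulate_dataset",
    "write_dataset",
]


@dataclass
class MapSpec:
    """One parental linkage map: groups of ordered marker positions (cM)."""

    map_label: str
    linkage_groups: list[tuple[str, float, np.ndarray]]  # (label, length cM, positions)

    def __post_init__(self) -> None:
        if not self.linkage_groups:
            raise ValueError("map has no linkage groups")
        for label, length, pos in self.linkage_groups:
            pos = np.asarray(pos, dtype=float)
            if pos.size == 0:
                raise ValueError(f"{self.map_label}/{label}: no markers")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{self.map_label}/{label}: positions not strictly increasing")
            if pos[0] < 0 or pos[-1] > length:
                raise ValueError(f"{self.map_label}/{label}: positions outside [0, {length}]")

    @property
    def n_markers(self) -> int:
        return sum(len(p) for _, _, p in self.linkage_groups)

    def marker_frame(self, prefix: str) -> pd.DataFrame:
        rows = []
        k = 0
        for label, _, pos in self.linkage_groups:
            for p in pos:
                rows.append((f"{prefix}{k:04d}", label, self.map_label, float(p)))
                k += 1
        return pd.DataFrame(rows, columns=["marker", "linkage_group", "map_label", "position_cM"])


def default_map_pair(
    n_groups: int = 11, group_length_cm: float = 60.0, spacing_cm: float = 1.5
) -> tuple[MapSpec, MapSpec]:
    """Two parental maps with evenly spaced markers (~1.5 cM apart)."""
    def build(label: str) -> MapSpec:
        groups = []
        for g in range(n_groups):
            pos = np.arange(0.0, group_length_cm + 1e-9, spacing_cm)
            groups.append((f"LG{g + 1:02d}", group_length_cm, pos))
        return MapSpec(map_label=label, linkage_groups=groups)
    return build("P1"), build("P2")


@dataclass
class QTLEffect:
    map_label: str
    linkage_group: str
    position_cM: float
    alpha: float


@dataclass
class TruthModel:
    """Generative parameters that downstream stages must recover."""

    qtl_effects: list[QTLEffect] = field(default_factory=list)
    clone_noise_sd: float = 0.2
    ar1_phi: float = 0.3
    noise_sd: float = 0.15
    growth_curve: tuple[float, float, float, float] = (120.0, 1.2, 0.12, 40.0)
    climate_variable: str = "dry_period"
    climate_threshold: int = 4
    climate_month: int = 3
    link_scale: float = 1.0

    def __post_init__(self) -> None:
        if not abs(self.ar1_phi) < 1:
            raise ValueError("|ar1_phi| must be < 1")
        A, b, c, d = self.growth_curve
        t = np.arange(1, 61, dtype=float)
        if np.any(A * t**b * np.exp(-c * t) + d <= 0):
            raise ValueError("growth curve must stay positive over simulated ages")


@dataclass
class WeatherParams:
    """Two-state (wet/dry) Markov-chain weather generator parameters.

    ``p_wet_given_wet`` and ``p_wet_given_dry`` are 12-vectors of monthly
    transition probabilities; precipitation on wet days is gamma-distributed;
    temperature is a seasonal sinusoid plus white noise.
    """

    p_wet_given_wet: np.ndarray = field(
        default_factory=lambda: np.full(12, 0.50))
    p_wet_given_dry: np.ndarray = field(
        default_factory=lambda: np.full(12, 0.25))
    precip_shape: float = 0.9
    precip_scale_mm: float = 12.0
    temp_mean_c: float = 15.0
    temp_amplitude_c: float = 10.0
    temp_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        self.p_wet_given_wet = np.asarray(self.p_wet_given_wet, dtype=float)
        self.p_wet_given_dry = np.asarray(self.p_wet_given_dry, dtype=float)
        for v in (self.p_wet_given_wet, self.p_wet_given_dry):
            if v.shape != (12,) or np.any((v < 0) | (v > 1)):
                raise ValueError("transition probabilities must be 12 values in [0, 1]")
        if self.precip_shape <= 0 or self.precip_scale_mm <= 0:
            raise ValueError("precipitation gamma parameters must be positive")


def simulate_genotypes(map_spec: MapSpec, n_clones: int, seed: int) -> pd.DataFrame:
    """1:1-segregating 0/1 genotypes along one parental map.

    Markers within a linkage group follow a Markov chain whose switch
    probability between adjacent markers is the Haldane recombination
    fraction of their cM distance; linkage groups and clones are
    independent.  Returns a marker table (marker, linkage_group, map_label,
    position_cM, one column per clone) with codes "het"/"hom".
    """
    if n_clones < 2:
        raise ValueError("need at least 2 clones")
    rng = np.random.default_rng(seed)
    frames = []
    k = 0
    for label, _, pos in map_spec.linkage_groups:
        pos = np.asarray(pos, dtype=float)
        m = pos.size
        g = np.empty((n_clones, m), dtype=int)
        g[:, 0] = rng.random(n_clones) < 0.5
        r = haldane_cm_to_r(np.diff(pos))
        for j in range(1, m):
            flip = rng.random(n_clones) < r[j - 1]
            g[:, j] = np.where(flip, 1 - g[:, j - 1], g[:, j - 1])
        meta = pd.DataFrame({
            "marker": [f"{map_spec.map_label}_m{k + j:04d}" for j in range(m)],
            "linkage_group": label,
            "map_label": map_spec.map_label,
            "position_cM": pos,
        })
        codes = pd.DataFrame(np.where(g.T == 1, "hom", "het"),
                             columns=[f"cl{c:04d}" for c in range(n_clones)])
        frames.append(pd.concat([meta, codes], axis=1))
        k += m
    return pd.concat(frames, ignore_index=True)


def _days_of_year(year: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")


def simulate_daily_climate(
    years: "range | list[int]", params: WeatherParams = None, seed: int = 0
) -> pd.DataFrame:
    """Daily weather table (date, tmean_c, precip_mm) for whole calendar years."""
    years = sorted(set(int(y) for y in years))
    if len(years) < 2:
        raise ValueError("need at least 2 calendar years (traits use a prior year)")
    if params is None:
        params = WeatherParams()
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(np.concatenate([_days_of_year(y).values for y in years]))
    n = len(dates)
    months = dates.month.to_numpy()

    wet = np.empty(n, dtype=bool)
    p0 = params.p_wet_given_dry[months[0] - 1]
    wet[0] = rng.random() < p0 / max(1.0 - params.p_wet_given_wet[months[0] - 1] + p0, 1e-12)
    u = rng.random(n)
    for i in range(1, n):
        m = months[i] - 1
        p = params.p_wet_given_wet[m] if wet[i - 1] else params.p_wet_given_dry[m]
        wet[i] = u[i] < p

    precip = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet:
        precip[wet] = rng.gamma(params.precip_shape, params.precip_scale_mm, size=n_wet)
        precip[wet] = np.maximum(precip[wet], 0.1)  # a wet day records measurable rain

    doy = dates.dayofyear.to_numpy()
    temp = (params.temp_mean_c
            - params.temp_amplitude_c * np.cos(2 * np.pi * (doy - 15) / 365.25)
            + rng.normal(0.0, params.temp_noise_sd, size=n))
    return pd.DataFrame({"date": dates, "tmean_c": temp, "precip_mm": precip})


def simulate_sensitivities(
    genotypes: pd.DataFrame, truth: TruthModel, seed: int
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-clone true sensitivity s_c = sum_j alpha_j x_cj + eta_c.

    Each planted QTL is matched to the nearest marker of its map/group;
    the realised assignment (marker used, realised variance contribution)
    is returned alongside the sensitivities.
    """
    meta_cols = ["marker", "linkage_group", "map_label", "position_cM"]
    clone_cols = [c for c in genotypes.columns if c not in meta_cols]
    rng = np.random.default_rng(seed)
    n = len(clone_cols)
    s = rng.normal(0.0, truth.clone_noise_sd, size=n)
    assignments = []
    for q in truth.qtl_effects:
        block = genotypes[(genotypes["map_label"] == q.map_label)
                          & (genotypes["linkage_group"] == q.linkage_group)]
        if block.empty:
            raise ValueError(f"no markers on {q.map_label}/{q.linkage_group}")
        i = (block["position_cM"] - q.position_cM).abs().idxmin()
        row = genotypes.loc[i]
        x = (genotypes.loc[i, clone_cols].to_numpy() == "hom").astype(float)
        s = s + q.alpha * x
        assignments.append({
            "map_label": q.map_label, "linkage_group": q.linkage_group,
            "target_position_cM": q.position_cM,
            "marker": row["marker"], "marker_position_cM": float(row["position_cM"]),
            "alpha": q.alpha, "marker_var": float(np.var(x)),
        })
    sens = pd.Series(s, index=pd.Index(clone_cols, name="clone_id"), name="sensitivity")
    assign = pd.DataFrame(assignments)
    if len(assign):
        var_s = float(np.var(sens.to_numpy()))
        assign["realized_pve_pct"] = 100.0 * assign["alpha"] ** 2 * assign["marker_var"] / var_s
    return sens, assign


def build_truth_for_pve(
    pve_targets: list[tuple[str, str, float, float]],
    total_var: float = 1.0,
    marker_var: float = 0.25,
    **kwargs,
) -> TruthModel:
    """Construct a TruthModel planting given per-QTL PVE fractions.

    ``pve_targets`` is a list of (map_label, linkage_group, position_cM,
    pve_fraction); effects are alpha_j = +/- sqrt(pve_j * total_var /
    marker_var) (sign alternating from negative, so the major drought QTL
    is negative as a drought response should be), and the clone noise sd
    absorbs the remaining variance.  Exact only when QTLs segregate
    independently, which holds when they sit on distinct linkage groups.
    """
    total_pve = sum(p for *_, p in pve_targets)
    if total_pve >= 1:
        raise ValueError("total planted PVE must be < 1")
    effects = []
    for j, (map_label, group, pos, pve) in enumerate(pve_targets):
        alpha = np.sqrt(pve * total_var / marker_var)
        sign = -1.0 if j % 2 == 0 else 1.0
        effects.append(QTLEffect(map_label, group, pos, sign * alpha))
    noise_sd = float(np.sqrt(total_var * (1.0 - total_pve)))
    return TruthModel(qtl_effects=effects, clone_noise_sd=noise_sd, **kwargs)


def _march_index_z(daily: pd.DataFrame, truth: TruthModel, years: list[int]) -> pd.Series:
    """Standardised driving climate index per ring year (detrended)."""
    spells = find_dry_spells(daily)
    mat = monthly_dry_index(spells, truth.climate_threshold, daily["date"].dt.year.unique())
    if len(mat.index) >= 3:
        mat = linear_detrend(mat)
    z = mat[truth.climate_month].loc[years].to_numpy(dtype=float)
    sd = z.std()
    if sd <= 0:
        return pd.Series(np.zeros(len(years)), index=years)
    return pd.Series((z - z.mean()) / sd, index=years)


def simulate_ring_widths(
    sensitivities: pd.Series,
    daily: pd.DataFrame,
    truth: TruthModel,
    ring_years: "list[int] | range",
    n_replicates: int = 3,
    site: str = "S1",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-tree annual ring widths driven by age trend, climate and noise.

    For replicate tree r of clone c, the basal area increment in ring year
    Y at age t is  g(t) * exp(s_c * link_scale * z_Y + eps_{r,t})  where
    g is the Hugershoff age curve, z the standardised driving climate
    index and eps an AR(1) noise series independent across trees.  BAI is
    converted back to ring widths through the cumulative radius, so the
    emitted table has the same shape as a measured ring-width file
    (tree_id, clone_id, site, year, width_mm).
    """
    ring_years = sorted(int(y) for y in ring_years)
    clim_years = set(daily["date"].dt.year.unique().tolist())
    need = set(ring_years) | {ring_years[0] - 1}
    if not need <= clim_years:
        raise ValueError(f"climate missing years {sorted(need - clim_years)}")
    rng = np.random.default_rng(seed)
    z = _march_index_z(daily, truth, ring_years)
    A, b, c, d = truth.growth_curve
    t = np.arange(1, len(ring_years) + 1, dtype=float)
    g = A * t**b * np.exp(-c * t) + d

    rows = []
    for clone_id, s_c in sensitivities.items():
        for r in range(n_replicates):
            eps = np.empty(len(ring_years))
            innov = rng.normal(0.0, truth.noise_sd, size=len(ring_years))
            eps[0] = innov[0] / max(np.sqrt(1 - truth.ar1_phi**2), 1e-6)
            for i in range(1, len(ring_years)):
                eps[i] = truth.ar1_phi * eps[i - 1] + innov[i]
            bai = g * np.exp(s_c * truth.link_scale * z.to_numpy() + eps)
            radius = np.sqrt(np.cumsum(bai) / np.pi)
            widths = np.diff(radius, prepend=0.0)
            tree_id = f"{clone_id}_r{r + 1}"
            for year, w in zip(ring_years, widths):
                rows.append((tree_id, clone_id, site, year, float(w)))
    return pd.DataFrame(rows, columns=["tree_id", "clone_id", "site", "year", "width_mm"])


@dataclass
class DatasetConfig:
    """Scale and planted architecture of one synthetic dataset."""

    n_clones: int = 139
    n_replicates: int = 3
    n_groups: int = 11
    group_length_cm: float = 60.0
    spacing_cm: float = 1.5
    ring_years: tuple[int, int] = (2006, 2016)     # inclusive span
    site: str = "S1"
    pve_major: float = 0.124
    pve_minor: tuple[float, ...] = (0.029, 0.027, 0.025, 0.021, 0.018, 0.018,
                                    0.016, 0.015, 0.015, 0.012, 0.010, 0.009)
    link_scale: float = 1.0
    noise_sd: float = 0.15
    ar1_phi: float = 0.3

    def planted_targets(self, maps: tuple[MapSpec, MapSpec]):
        """Place the major QTL and the minors on distinct linkage groups,
        alternating between the two maps, at mid-group positions."""
        targets = []
        pves = [self.pve_major, *self.pve_minor]
        for j, pve in enumerate(pves):
            spec = maps[j % 2]
            label, length, _ = spec.linkage_groups[(j // 2) % len(spec.linkage_groups)]
            targets.append((spec.map_label, label, length / 2.0, pve))
        return targets


def simulate_dataset(config: DatasetConfig = None, seed: int = 0) -> dict:
    """Generate a full linked dataset: genotypes, climate, rings, truth.

    Returns a dict with keys ``genotypes`` (both maps concatenated),
    ``climate`` (daily table), ``rings`` (ring-width table),
    ``sensitivities`` (planted per-clone values) and ``truth`` (planted
    parameters including realised per-QTL PVE).
    """
    if config is None:
        config = DatasetConfig()
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(5)
    maps = default_map_pair(config.n_groups, config.group_length_cm, config.spacing_cm)
    geno = pd.concat(
        [simulate_genotypes(maps[0], config.n_clones, int(seeds[0])),
         simulate_genotypes(maps[1], config.n_clones, int(seeds[1]))],
        ignore_index=True,
    )
    truth = build_truth_for_pve(
        config.planted_targets(maps),
        link_scale=config.link_scale, noise_sd=config.noise_sd, ar1_phi=config.ar1_phi,
    )
    y0, y1 = config.ring_years
    climate = simulate_daily_climate(range(y0 - 1, y1 + 1), seed=int(seeds[2]))
    sens, assign = simulate_sensitivities(geno, truth, seed=int(seeds[3]))
    rings = simulate_ring_widths(
        sens, climate, truth, ring_years=range(y0, y1 + 1),
        n_replicates=config.n_replicates, site=config.site, seed=int(seeds[4]),
    )
    return {
        "genotypes": geno,
        "climate": climate,
        "rings": rings,
        "sensitivities": sens,
        "truth": truth,
        "truth_assignments": assign,
        "config": config,
    }


def write_dataset(data: dict, out_dir: "str | Path") -> dict[str, Path]:
    """Write the three input CSVs plus truth.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "rings": out / "ring_widths.csv",
        "markers": out / "marker_genotypes.csv",
        "climate": out / "daily_climate.csv",
        "truth": out / "truth.json",
    }
    data["rings"].to_csv(paths["rings"], index=False)
    data["genotypes"].to_csv(paths["markers"], index=False)
    climate = data["climate"].copy()
    climate["date"] = climate["date"].dt.strftime("%Y-%m-%d")
    climate.to_csv(paths["climate"], index=False)
    truth = data["truth"]
    payload = {
        "qtl_effects": data["truth_assignments"].to_dict(orient="records"),
        "clone_noise_sd": truth.clone_noise_sd,
        "ar1_phi": truth.ar1_phi,
        "noise_sd": truth.noise_sd,
        "growth_curve": list(truth.growth_curve),
        "climate_variable": truth.climate_variable,
        "climate_threshold": truth.climate_threshold,
        "climate_month": truth.climate_month,
        "link_scale": truth.link_scale,
        "sensitivities": {k: float(v) for k, v in data["sensitivities"].items()},
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths
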