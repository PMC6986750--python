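"""Pipeline orchestration: simulate -> rings -> climate -> sensitivity -> qtl.

One config drives the whole run; every stage writes its CSV outputs in a
fixed dialect (comma-separated, header row, ISO-8601 dates, '.' decimal)
and a manifest records seeds, row counts and exclusions so a rerun with
the same config reproduces every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import qtl as qtl_mod
from . import rings as rings_mod
from . import sensitivity as sens_mod
from .simulate import DatasetConfig, simulate_dataset, write_dataset

__all__ = ["RunConfig", "run_full_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Everything a full run needs; loadable from YAML."""

    out_dir: str = "dendroqtl_run"
    # either paths to the three inputs, or a simulation block
    rings_csv: str = None
    markers_csv: str = None
    climate_csv: str = None
    simulate: dict = None            # DatasetConfig fields
    site: str = "S1"
    thresholds: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    wet_cutoff: float = 0.0
    detrend_mode: str = "ratio"
    detrend_climate: bool = True
    phenotype_variable: str = "dry_period"
    phenotype_threshold: int = 4
    phenotype_month: str = "c03"
    alpha_traits: float = 0.05
    alpha_qtl: float = 0.01
    cv_folds: int = 5
    eblasso_a: float = 10.0
    eblasso_b: float = 0.1
    select_hyperparams: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        if self.phenotype_threshold not in tuple(self.thresholds):
            raise ValueError(
                f"phenotype threshold {self.phenotype_threshold} not in "
                f"configured thresholds {self.thresholds}"
            )

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in payload:
            payload["thresholds"] = tuple(payload["thresholds"])
        return cls(**payload)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded,
        so runs into different directories compare equal)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_inputs(
    rings: "pd.DataFrame | None" = None,
    markers: "pd.DataFrame | None" = None,
    climate: "pd.DataFrame | None" = None,
) -> list[str]:
    """Schema / consistency checks; returns a list of violation messages."""
    violations: list[str] = []
    if rings is not None:
        need = {"tree_id", "clone_id", "site", "year", "width_mm"}
        miss = need - set(rings.columns)
        if miss:
            violations.append(f"rings: missing columns {sorted(miss)}")
        else:
            bad = rings.index[~(rings["width_mm"] > 0)].tolist()
            for i in bad[:10]:
                violations.append(f"rings row {i}: non-positive width")
    if climate is not None:
        need = {"date", "tmean_c", "precip_mm"}
        miss = need - set(climate.columns)
        if miss:
            violations.append(f"climate: missing columns {sorted(miss)}")
        else:
            dates = pd.to_datetime(climate["date"]).sort_values()
            gaps = dates.diff().dropna()
            for ts in dates[1:][gaps.to_numpy() > pd.Timedelta(days=1)]:
                violations.append(f"climate: gap before {ts.date()}")
            neg = climate.index[climate["precip_mm"] < 0].tolist()
            for i in neg[:10]:
                violations.append(f"climate row {i}: negative precipitation")
    if markers is not None:
        need = {"marker", "linkage_group", "map_label", "position_cM"}
        miss = need - set(markers.columns)
        if miss:
            violations.append(f"markers: missing columns {sorted(miss)}")
        else:
            clone_cols = [c for c in markers.columns if c not in need]
            valid = {"het", "hom", "", "na", "nan", "missing", "-", "none", "0", "1"}
            for col in clone_cols:
                vals = markers[col].astype(str).str.strip().str.lower()
                bad = markers.index[~vals.isin(valid)].tolist()
                for i in bad[:5]:
                    violations.append(
                        f"markers row {i}, clone {col}: code {markers.loc[i, col]!r} "
                        "outside {het, hom, missing}"
                    )
    if rings is not None and markers is not None and not violations:
        need = {"marker", "linkage_group", "map_label", "position_cM"}
        ring_clones = set(rings["clone_id"].astype(str))
        geno_clones = {c for c in markers.columns if c not in need}
        only_rings = sorted(ring_clones - geno_clones)
        if only_rings:
            violations.append(f"clones in rings but not genotypes: {only_rings[:10]}")
    return violations


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order and write all outputs.

    Returns a dict with the manifest and in-memory stage results
    (chronologies, traits, counts, QTLResult, LODProfile).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                      "stages": {}, "outputs": {}}

    def rel(p) -> str:
        p = Path(p)
        try:
            return str(p.relative_to(out))
        except ValueError:
            return str(p)

    # --- stage 0: obtain inputs -------------------------------------------
    if config.simulate is not None:
        ds_cfg = DatasetConfig(**config.simulate)
        data = simulate_dataset(ds_cfg, seed=config.seed)
        paths = write_dataset(data, out / "inputs")
        rings_df = data["rings"]
        markers_df = data["genotypes"]
        climate_df = data["climate"]
        manifest["outputs"]["inputs"] = {k: rel(v) for k, v in paths.items()}
    else:
        if not (config.rings_csv and config.markers_csv and config.climate_csv):
            raise ValueError("provide either a simulate block or all three input paths")
        rings_df = pd.read_csv(config.rings_csv)
        markers_df = pd.read_csv(config.markers_csv, dtype=str)
        for c in ("position_cM",):
            markers_df[c] = markers_df[c].astype(float)
        climate_df = pd.read_csv(config.climate_csv)
    climate_df = climate_df.copy()
    climate_df["date"] = pd.to_datetime(climate_df["date"])

    violations = validate_inputs(rings_df, markers_df, climate_df)
    if violations:
        raise ValueError("input validation failed:\n  " + "\n  ".join(violations))
    manifest["stages"]["inputs"] = {
        "ring_rows": len(rings_df), "markers": len(markers_df), "climate_days": len(climate_df),
    }

    # --- stage 1: ring processing -----------------------------------------
    chronologies = rings_mod.process_ring_table(rings_df, detrend_mode=config.detrend_mode)
    chron_frame = rings_mod.chronologies_to_frame(chronologies)
    chron_path = out / "clone_chronologies.csv"
    chron_frame.to_csv(chron_path, index=False)
    manifest["stages"]["rings"] = {"clones": len(chronologies)}
    manifest["outputs"]["chronologies"] = rel(chron_path)

    # --- stage 2: climate matrices ----------------------------------------
    temp, prec = climate_mod.monthly_aggregate(climate_df)
    spells = climate_mod.find_dry_spells(climate_df, wet_cutoff=config.wet_cutoff)
    years = sorted(climate_df["date"].dt.year.unique())
    matrices: dict[tuple[str, "int | None"], pd.DataFrame] = {
        ("temperature", None): temp,
        ("precipitation", None): prec,
    }
    admissibility = {}
    for k in config.thresholds:
        mat = climate_mod.monthly_dry_index(spells, k, years)
        admissibility[k] = climate_mod.admissible_threshold(mat)
        matrices[("dry_period", k)] = mat
    if config.detrend_climate:
        matrices = {key: climate_mod.linear_detrend(m) for key, m in matrices.items()}
    clim_dir = out / "climate_matrices"
    clim_dir.mkdir(exist_ok=True)
    for (var, k), mat in matrices.items():
        name = var if k is None else f"{var}_k{k}"
        mat.to_csv(clim_dir / f"{name}.csv")
    manifest["stages"]["climate"] = {
        "years": len(years), "dry_spells": len(spells),
        "threshold_admissible": {str(k): bool(v) for k, v in admissibility.items()},
    }
    manifest["outputs"]["climate_dir"] = rel(clim_dir)

    # --- stage 3: sensitivity traits --------------------------------------
    traits = sens_mod.compute_traits(chronologies, matrices)
    traits_path = out / "sensitivity_traits.csv"
    traits.to_csv(traits_path, index=False)
    counts = sens_mod.significance_counts(traits, alpha=config.alpha_traits)
    counts_path = out / "significance_counts.csv"
    counts.to_csv(counts_path, index=False)
    manifest["stages"]["sensitivity"] = {
        "traits": len(traits), "missing": int(traits["r"].isna().sum()),
    }
    manifest["outputs"]["traits"] = rel(traits_path)
    manifest["outputs"]["counts"] = rel(counts_path)

    # --- stage 4: QTL mapping ---------------------------------------------
    phenotype = sens_mod.select_qtl_phenotype(
        traits, config.phenotype_variable, config.phenotype_threshold,
        config.phenotype_month,
    )
    genotypes = qtl_mod.encode_genotypes(markers_df)
    result = qtl_mod.map_qtls(
        genotypes, phenotype,
        a=config.eblasso_a, b=config.eblasso_b, alpha=config.alpha_qtl,
        cv_folds=config.cv_folds, seed=config.seed,
        select_hyperparams=config.select_hyperparams,
    )
    qtl_path = out / "qtl_table.csv"
    result.table.to_csv(qtl_path, index=False)
    summary_path = out / "qtl_summary.json"
    summary_path.write_text(json.dumps({
        "n_qtls": result.n_qtls,
        "pve_all_pct": result.pve_all_pct,
        "cv_accuracy_r": None if np.isnan(result.cv_accuracy_r) else result.cv_accuracy_r,
        "a": result.a, "b": result.b, "alpha": result.alpha, "seed": result.seed,
        "excluded_markers": genotypes.excluded.to_dict(orient="records"),
        "phenotype_clones": int(phenotype.size),
    }, indent=1, default=str))

    lod = qtl_mod.interval_mapping_scan(genotypes, phenotype, step=1.0)
    lod_path = out / "lod_profile.csv"
    lod.table.to_csv(lod_path, index=False)
    manifest["stages"]["qtl"] = {
        "clones": int(phenotype.size), "markers": len(genotypes.marker_names),
        "significant": result.n_qtls,
    }
    manifest["outputs"].update({"qtl_table": rel(qtl_path), "qtl_summary": rel(summary_path),
                                "lod_profile": rel(lod_path)})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "manifest": manifest,
        "chronologies": chronologies,
        "traits": traits,
        "counts": counts,
        "qtl_result": result,
        "lod_profile": lod,
    }
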