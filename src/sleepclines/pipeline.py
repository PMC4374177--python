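"""End-to-end orchestration: simulate -> metrics -> clines -> ramping -> enrichment.

A run is described by one configuration mapping (usually loaded from YAML);
every stage writes its table into the output directory and a provenance
record (config hash, package/library versions, seeds) accompanies the
results so that reruns with identical configuration are exactly
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cline import hourly_cline_scan, regress_on_latitude
from .dam import write_phenotype_table
from .enrichment import (
    direction_summary,
    enrichment_report,
    flag_outlier_windows,
    timepoint_overlap_summary,
)
from .rhythm import compute_ramping_profile, population_ramping, ramping_cline_scan
from .simulate import (
    TIMEPOINTS,
    BehaviorParams,
    ClineConfig,
    GenomeFixtureConfig,
    simulate_gene_fixture,
    simulate_population_set,
)
from .sleep import aggregate, filter_individuals, phenotype_table

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "results",
    "behavior": {},  # BehaviorParams overrides
    "cline": {},  # ClineConfig overrides (lines_per_pop, flies_per_line, ...)
    "genome": {},  # GenomeFixtureConfig overrides
    "bout_threshold": 5,
    "attribution": "split",
    "alpha": 0.05,
    "bonferroni_m": 24,
    "outlier_fraction": 0.05,
}

_STAGES = ("simulate", "sleep_metrics", "cline", "ramping", "enrich")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_config(config: dict) -> dict:
    """Merge with defaults and reject unknown top-level keys."""
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**DEFAULT_CONFIG, **config}
    if merged["attribution"] not in ("split", "start"):
        raise ValueError("attribution must be 'split' or 'start'")
    if not 0 < merged["alpha"] < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return merged


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Run every stage on a synthetic study and write all tables.

    Returns a summary dict (also written as ``report.json``).  Reruns with
    the same config and seed reproduce every numeric output exactly.
    """
    config = validate_config(config)
    out = Path(output_dir or config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    report: dict = {"config_hash": _config_hash(config), "seed": seed}

    stage = "simulate"
    try:
        cline_kwargs = dict(config["cline"])
        if "populations" in cline_kwargs:
            cline_kwargs["populations"] = tuple(
                (str(p), float(l)) for p, l in cline_kwargs["populations"]
            )
        cline_cfg = ClineConfig(seed=seed, **cline_kwargs)
        params = BehaviorParams(**config["behavior"])
        series, truth = simulate_population_set(cline_cfg, params)
        truth.to_csv(out / "truth.csv", index=False)
        report["n_flies_simulated"] = len(series)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "sleep_metrics"
    try:
        kept, discarded = filter_individuals(series)
        discarded.to_csv(out / "discarded_flies.csv", index=False)
        flies = phenotype_table(
            kept, threshold=config["bout_threshold"], attribution=config["attribution"]
        )
        lines, pops = aggregate(flies)
        write_phenotype_table(flies, out / "fly_phenotypes.csv")
        write_phenotype_table(lines, out / "line_phenotypes.csv")
        write_phenotype_table(pops, out / "population_phenotypes.csv")
        report["n_flies_kept"] = len(kept)
        report["n_flies_discarded"] = len(discarded)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "cline"
    try:
        rows = []
        for metric in (
            "locomotor_activity",
            "walking_speed",
            "avg_sleep_bout_duration",
            "sleep_duration",
            "sleep_bout_number",
        ):
            for phase in ("photophase", "scotophase"):
                res = regress_on_latitude(
                    pops["latitude"], pops[f"{metric}_{phase}"], metric, phase
                )
                rows.append(res.__dict__)
        cline_table = pd.DataFrame(rows)
        cline_table.to_csv(out / "cline_regressions.csv", index=False)
        hourly = pops.set_index("population_id")[
            [f"hourly_bout_ZT{h:02d}" for h in range(24)]
        ]
        lat_map = dict(zip(pops["population_id"], pops["latitude"]))
        scan = hourly_cline_scan(hourly, lat_map, alpha=config["alpha"])
        scan.to_csv(out / "hourly_cline_scan.csv", index=False)
        night = cline_table[
            (cline_table["metric"] == "avg_sleep_bout_duration")
            & (cline_table["phase"] == "scotophase")
        ].iloc[0]
        report["night_bout_cline"] = {
            "slope": night["slope"],
            "r_squared": night["r_squared"],
            "p_value": night["p_value"],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "ramping"
    try:
        by_line: dict[str, list] = {}
        for s in kept:
            by_line.setdefault(s.line_id, []).append(s)
        profiles = [compute_ramping_profile(v, k) for k, v in sorted(by_line.items())]
        prof_rows = []
        for p in profiles:
            for zt, a, nrm in zip(
                p.bin_start_zt,
                p.activity,
                p.normalized if p.defined else [np.nan] * len(p.activity),
            ):
                prof_rows.append(
                    {"line_id": p.line_id, "bin_start_zt": zt, "activity": a,
                     "normalized": nrm}
                )
        pd.DataFrame(prof_rows).to_csv(out / "ramping_profiles.csv", index=False)
        pop_of_line = {s.line_id: s.population_id for s in kept}
        pop_curves: dict[str, np.ndarray] = {}
        for pop in sorted({s.population_id for s in kept}):
            pop_profiles = [p for p in profiles if pop_of_line[p.line_id] == pop]
            pop_curves[pop] = population_ramping(pop_profiles)
        ramp_scan = ramping_cline_scan(pop_curves, lat_map)
        ramp_scan.to_csv(out / "ramping_cline_scan.csv", index=False)
        report["ramping_max_r_squared"] = float(np.nanmax(ramp_scan["r_squared"]))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "enrich"
    try:
        genome_cfg = GenomeFixtureConfig(
            seed=seed,
            outlier_fraction=config["outlier_fraction"],
            **config["genome"],
        )
        genes, windows = simulate_gene_fixture(genome_cfg)
        genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        windows.to_csv(out / "fst_windows.tsv", sep="\t", index=False)
        windows = flag_outlier_windows(windows, config["outlier_fraction"])
        enr = enrichment_report(genes, windows)
        report["enrichment"] = enr.__dict__
        venn = timepoint_overlap_summary(genes[genes["expressed"]])
        venn.rename("n_genes").to_csv(out / "timepoint_venn.csv")
        dir_rows = [direction_summary(genes, t) for t in TIMEPOINTS]
        pd.DataFrame(dir_rows).to_csv(out / "direction_summary.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    import scipy

    report["versions"] = {
        "sleepclines": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
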