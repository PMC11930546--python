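"""End-to-end pipeline: simulate (or load) -> filter -> fit -> report.

``run_pipeline`` executes the survival fit and the population-genetic
summary chain from one seeded :class:`RunConfig`, writes every tabular
output, and records a machine-readable manifest (inputs, seeds, per-stage
row counts, output checksums).  Identical config + inputs give identical
manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    read_population_map,
    read_survival_records,
    read_vcf,
    write_population_map,
    write_survival_records,
    write_vcf,
)
from .popgen import (
    DEFAULT_SPLIT_LATITUDE,
    amova,
    diversity_summary,
    filter_sites_max_missing,
    ibd_regression,
    pairwise_fst,
    pca_genotypes,
    per_snp_fst_histogram,
    tajimas_d,
    wc_fst,
)
from .survival import DEFAULT_VELOCITY_KM_PER_DAY, summarize_experiment
from .synthetic_data import (
    DemographySimConfig,
    SurvivalSimConfig,
    simulate_invasion_panel,
    simulate_survival,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("invadrift")


@dataclass
class RunConfig:
    """Pipeline configuration; all randomness is seeded explicitly."""

    output_dir: str = "invadrift-run"
    seed: int = 0
    # inputs: leave None to simulate
    vcf_path: str | None = None
    popmap_path: str | None = None
    survival_records_path: str | None = None
    scenario: str = "single_founder"
    # analysis parameters
    max_missing_fraction: float = 0.20
    n_permutations: int = 999
    ci_level: float = 0.95
    velocity_km_per_day: float = DEFAULT_VELOCITY_KM_PER_DAY
    split_latitude: float = DEFAULT_SPLIT_LATITUDE
    pca_components: int = 2
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }

    stage = "inputs"
    try:
        if config.survival_records_path:
            records = read_survival_records(config.survival_records_path)
        else:
            records = simulate_survival(SurvivalSimConfig(seed=config.seed))
            write_survival_records(records, out / "survival_records.csv")
        if config.vcf_path:
            panel = read_vcf(config.vcf_path)
            popmap = read_population_map(config.popmap_path)
        else:
            panel, popmap = simulate_invasion_panel(
                DemographySimConfig(scenario=config.scenario, seed=config.seed)
            )
            write_vcf(panel, out / "synthetic_panel.vcf")
            write_population_map(popmap, out / "population_map.csv")
        for ind in panel.individual_ids:
            if ind not in popmap.individual_to_population:
                raise KeyError(f"individual {ind!r} missing from population map")
        manifest["stages"][stage] = {
            "n_survival_records": len(records),
            "n_individuals": panel.n_individuals,
            "n_sites": panel.n_sites,
        }

        stage = "survival"
        report = summarize_experiment(
            records,
            velocity_km_per_day=config.velocity_km_per_day,
            ci_level=config.ci_level,
        )
        report.to_display().to_csv(out / "survival_report.csv", index=False)
        report.table.to_json(out / "survival_report.json", orient="records", indent=2)
        manifest["stages"][stage] = {"rows": len(report.table)}

        stage = "filter"
        panel = filter_sites_max_missing(panel, config.max_missing_fraction)
        manifest["stages"][stage] = {"n_sites_kept": panel.n_sites}

        stage = "diversity"
        div = diversity_summary(panel, popmap)
        (out / "diversity.json").write_text(
            json.dumps(
                {"H_O": div.h_obs, "H_S": div.h_s, "H_T": div.h_t, "F_IS": div.f_is},
                indent=2,
            )
        )
        taj = tajimas_d(panel)
        (out / "tajimas_d.json").write_text(
            json.dumps(
                {"D": taj.d, "S": taj.s_segregating, "pi": taj.pi, "n": taj.n_chromosomes},
                indent=2,
            )
        )
        manifest["stages"][stage] = {"segregating_sites": taj.s_segregating}

        stage = "fst"
        overall = wc_fst(panel, popmap)
        pd.DataFrame({"site": panel.site_ids, "theta": overall.per_site}).to_csv(
            out / "per_snp_theta.tsv", sep="\t", index=False
        )
        counts, edges = per_snp_fst_histogram(overall)
        pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}).to_csv(
            out / "per_snp_theta_histogram.csv", index=False
        )
        pw = pairwise_fst(panel, popmap, n_permutations=config.n_permutations, seed=config.seed)
        pw.pairwise.clip(lower=0).round(4).to_csv(out / "pairwise_fst.csv")
        pw.pairwise_p.round(4).to_csv(out / "pairwise_fst_p.csv")
        manifest["stages"][stage] = {
            "overall_theta": overall.overall,
            "pairwise_rows": len(pw.pairwise),
        }

        stage = "amova"
        am = amova(
            panel,
            popmap,
            n_permutations=config.n_permutations,
            seed=config.seed,
            split_latitude=config.split_latitude,
        )
        am.table.to_csv(out / "amova.csv", index=False)
        manifest["stages"][stage] = {"rows": len(am.table)}

        stage = "ibd"
        ibd = ibd_regression(pw, popmap)
        (out / "ibd.json").write_text(
            json.dumps(
                {
                    "slope_per_km": ibd.slope,
                    "intercept": ibd.intercept,
                    "r_squared_adj": ibd.r_squared_adj,
                    "p_value": ibd.p_value,
                    "note": "pairs are non-independent; see mantel option",
                },
                indent=2,
            )
        )
        ibd.distance_km.round(1).to_csv(out / "pairwise_distance_km.csv")
        manifest["stages"][stage] = {"pairs": int(len(ibd.distance_km) * (len(ibd.distance_km) - 1) / 2)}

        stage = "pca"
        scores, pct = pca_genotypes(panel, n_components=config.pca_components)
        scores.assign(population=[popmap.individual_to_population[i] for i in scores.index]).to_csv(
            out / "pca_scores.csv"
        )
        manifest["stages"][stage] = {"pct_variance": list(map(float, pct))}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
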