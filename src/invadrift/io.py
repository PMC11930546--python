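"""Readers and writers for the package's file formats.

VCF genotypes are read with cyvcf2 (GT field only; multiallelic and indel
records skipped, half-calls treated as missing).  Synthetic panels are
written as minimal uncompressed VCF 4.2.  Population maps and survival
records travel as UTF-8 comma-separated files with a header row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .popgen import MISSING, GenotypePanel, PopulationMap
from .survival import SurvivalRecord, TreatmentLabel

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "read_survival_records",
    "write_survival_records",
]

logger = logging.getLogger("invadrift")


def read_vcf(path: str | Path) -> GenotypePanel:
    """Load biallelic SNP genotypes from a VCF 4.x file.

    Multiallelic or non-SNP records are skipped (a count is logged);
    ``./.`` and half-calls become missing.  Site order follows the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    individuals = list(vcf.samples)
    rows: list[np.ndarray] = []
    site_ids: list[str] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        gts = np.asarray(var.genotypes, dtype=int)  # (n, 3): allele1, allele2, phased
        a1, a2 = gts[:, 0], gts[:, 1]
        g = np.where((a1 < 0) | (a2 < 0), MISSING, a1 + a2).astype(np.int8)
        rows.append(g)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        site_ids.append(vid)
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records in %s", skipped, path)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    genotypes = np.stack(rows, axis=1)
    return GenotypePanel(genotypes, individuals, site_ids)


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as minimal uncompressed VCF 4.2 (GT only, A/C alleles)."""
    path = Path(path)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=invadrift-synthetic\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids)
            + "\n"
        )
        for j, site in enumerate(panel.site_ids):
            gts = "\t".join(gt_strings[int(v)] for v in panel.genotypes[:, j])
            fh.write(f"1\t{j + 1}\t{site}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a population map CSV: individual_id, population, latitude,
    longitude [, region]."""
    df = pd.read_csv(path)
    required = {"individual_id", "population", "latitude", "longitude"}
    if not required.issubset(df.columns):
        raise ValueError(f"population map must have columns {sorted(required)}")
    mapping = dict(zip(df["individual_id"].astype(str), df["population"].astype(str)))
    coords = {}
    regions = {}
    for _, row in df.drop_duplicates("population").iterrows():
        coords[str(row["population"])] = (float(row["latitude"]), float(row["longitude"]))
        if "region" in df.columns and pd.notna(row.get("region")):
            regions[str(row["population"])] = str(row["region"])
    return PopulationMap(mapping, coords, regions)


def write_population_map(popmap: PopulationMap, path: str | Path) -> None:
    rows = []
    for ind, pop in popmap.individual_to_population.items():
        lat, lon = popmap.population_coords[pop]
        row = {"individual_id": ind, "population": pop, "latitude": lat, "longitude": lon}
        if popmap.regions:
            row["region"] = popmap.regions.get(pop, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


_SURVIVAL_COLUMNS = [
    "individual_id",
    "experiment_id",
    "replicate_id",
    "temperature_c",
    "light",
    "outcome",
    "event_day",
]


def read_survival_records(path: str | Path) -> list[SurvivalRecord]:
    """Read survival records CSV (one row per individual)."""
    df = pd.read_csv(path)
    missing = set(_SURVIVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survival records CSV missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SurvivalRecord(
                individual_id=str(row["individual_id"]),
                replicate_id=str(row["replicate_id"]),
                treatment=TreatmentLabel(float(row["temperature_c"]), str(row["light"])),
                outcome=str(row["outcome"]),
                event_day=float(row["event_day"]),
                experiment_id=str(row["experiment_id"]),
            )
        )
    return records


def write_survival_records(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    rows = [
        {
            "individual_id": r.individual_id,
            "experiment_id": r.experiment_id,
            "replicate_id": r.replicate_id,
            "temperature_c": r.treatment.temperature_c,
            "light": r.treatment.light,
            "outcome": r.outcome,
            "event_day": r.event_day,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_SURVIVAL_COLUMNS).to_csv(path, index=False)
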