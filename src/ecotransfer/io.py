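"""Table schemas, CSV readers/writers and validation.

The interchange format is plain CSV, one file per table, with the column
names below.  Exports from PREDICTS-style flat tables are accepted through
a rename map (``SS -> study_id``, ``SSBS -> site_id``, ...).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import pandas as pd

SCHEMAS: Dict[str, list] = {
    "studies": ["study_id", "taxon_group", "sampling_method", "sampling_unit",
                "is_abundance", "sampling_start_month", "duration_days",
                "accessibility_m", "ruggedness"],
    "sites": ["site_id", "study_id", "lat", "lon", "sampling_start_month",
              "sampling_effort", "extent_m"],
    "assemblage": ["site_id", "taxon_id", "measurement"],
    "spectra": ["site_id", "month_index", "band", "reflectance"],
}

#: accepted aliases for PREDICTS-style exports
RENAME_MAP = {
    "SS": "study_id",
    "SSBS": "site_id",
    "Latitude": "lat",
    "Longitude": "lon",
    "Taxon_name_entered": "taxon_id",
    "Measurement": "measurement",
    "Sampling_effort": "sampling_effort",
}


def write_tables(dataset: Dict[str, pd.DataFrame], out_dir) -> None:
    """Write the input tables of a dataset as CSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in SCHEMAS:
        if name in dataset:
            df = dataset[name]
            df.to_csv(out_dir / f"{name}.csv", index=False,
                      columns=[c for c in SCHEMAS[name] if c in df.columns])


def read_tables(in_dir) -> Dict[str, pd.DataFrame]:
    """Read and validate the input tables from a directory of CSV files.

    Checks schema columns, id uniqueness and referential integrity
    (site -> study, assemblage/spectra -> site); raises a single error
    listing every violation found.
    """
    in_dir = Path(in_dir)
    found = {name: in_dir / f"{name}.csv" for name in SCHEMAS
             if (in_dir / f"{name}.csv").exists()}
    if not found:
        raise FileNotFoundError(f"no input tables found in {in_dir}")

    tables: Dict[str, pd.DataFrame] = {}
    problems = []
    for name, path in found.items():
        df = pd.read_csv(path).rename(columns=RENAME_MAP)
        missing = [c for c in SCHEMAS[name] if c not in df.columns]
        if missing:
            problems.append(f"{name}.csv: missing columns {missing}")
            continue
        tables[name] = df

    if "studies" in tables:
        dup = tables["studies"]["study_id"].duplicated()
        if dup.any():
            problems.append(
                f"studies.csv: duplicate study_id "
                f"{tables['studies'].loc[dup, 'study_id'].tolist()}")
    if "sites" in tables:
        dup = tables["sites"]["site_id"].duplicated()
        if dup.any():
            problems.append(
                f"sites.csv: duplicate site_id "
                f"{tables['sites'].loc[dup, 'site_id'].tolist()}")
        if "studies" in tables:
            known = set(tables["studies"]["study_id"])
            orphan = tables["sites"][~tables["sites"]["study_id"].isin(known)]
            for _, row in orphan.iterrows():
                problems.append(f"sites.csv: site {row['site_id']!r} "
                                f"references unknown study {row['study_id']!r}")
    if "sites" in tables:
        known_sites = set(tables["sites"]["site_id"])
        for name in ("assemblage", "spectra"):
            if name not in tables:
                continue
            orphan = tables[name][~tables[name]["site_id"].isin(known_sites)]
            for idx, row in orphan.iterrows():
                problems.append(f"{name}.csv row {idx}: unknown site "
                                f"{row['site_id']!r}")

    if problems:
        raise ValueError("input validation failed:\n  " + "\n  ".join(problems))
    return tables


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
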