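"""File I/O: NONMEM-style concentration datasets, genotype tables, configs.

Dataset dialect (comma-separated, header required):

    ID,TIME,AMT,DV,MDV,EVID,WT[,covariate...]

EVID=1 rows with AMT > 0 are oral doses (mg); EVID=0 rows are observations
with DV in ng/ml (MDV=0) or "." for a planned-but-missing value (MDV=1).
TIME is hours since the subject's first dose; WT (kg) and covariate
columns are constant within a subject.  The writer emits the same dialect
and round-trips exactly.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .data import Dataset, SubjectData
from .hwe import GenotypeCounts
from .pk import DoseEvent

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_genotype_table",
    "write_genotype_table",
    "load_config",
    "config_hash",
]

_REQUIRED = ["ID", "TIME", "AMT", "DV", "MDV", "EVID", "WT"]


def read_dataset(path: str | Path) -> Dataset:
    """Read a NONMEM-style CSV dataset."""
    df = pd.read_csv(
        path,
        dtype={"ID": str},
        na_values=["."],
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    cov_cols = [c for c in df.columns if c not in _REQUIRED]
    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        doses = []
        times, concs = [], []
        for _, row in grp.iterrows():
            if int(row["EVID"]) == 1 and float(row["AMT"]) > 0:
                doses.append(DoseEvent(time=float(row["TIME"]), amount=float(row["AMT"])))
            elif int(row["EVID"]) == 0:
                times.append(float(row["TIME"]))
                dv = row["DV"]
                concs.append(np.nan if int(row["MDV"]) == 1 or pd.isna(dv) else float(dv))
        subjects.append(
            SubjectData(
                id=str(sid),
                weight=float(grp["WT"].iloc[0]),
                doses=doses,
                obs_times=np.array(times),
                obs_conc=np.array(concs),
                covariates={c: float(grp[c].iloc[0]) for c in cov_cols},
            )
        )
    return Dataset(subjects)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in the same dialect ``read_dataset`` accepts."""
    cov_cols = dataset.covariate_names()
    rows: list[dict[str, Any]] = []
    for s in dataset:
        base = {"ID": s.id, "WT": repr(s.weight)}
        base.update({c: repr(s.covariates.get(c, 0.0)) for c in cov_cols})
        events = [("dose", d.time, d) for d in s.doses]
        events += [("obs", t, i) for i, t in enumerate(s.obs_times)]
        events.sort(key=lambda e: (e[1], 0 if e[0] == "dose" else 1))
        for kind, t, payload in events:
            row = dict(base)
            row["TIME"] = repr(float(t))
            if kind == "dose":
                row.update(AMT=repr(float(payload.amount)), DV=".", MDV="1", EVID="1")
            else:
                conc = s.obs_conc[payload]
                row.update(
                    AMT="0",
                    DV="." if not np.isfinite(conc) else repr(float(conc)),
                    MDV="1" if not np.isfinite(conc) else "0",
                    EVID="0",
                )
            rows.append(row)
    cols = _REQUIRED + cov_cols
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def _is_het(genotype: str) -> bool:
    alleles = genotype.replace("|", "/").split("/")
    if len(alleles) != 2:
        raise ValueError(f"genotype {genotype!r} is not biallelic")
    return alleles[0] != alleles[1]


def read_genotype_table(path: str | Path) -> list[GenotypeCounts]:
    """Read a genotype count table: columns variant,genotype,count.

    Each variant needs one heterozygous row and up to two homozygous rows
    (e.g. A/A, A/G, G/G); absent classes count 0.  Homozygote order follows
    first appearance in the file.
    """
    df = pd.read_csv(path)
    for col in ("variant", "genotype", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = []
    for variant, grp in df.groupby("variant", sort=False):
        hom_counts: list[int] = []
        het = 0
        for _, row in grp.iterrows():
            if _is_het(str(row["genotype"])):
                het += int(row["count"])
            else:
                hom_counts.append(int(row["count"]))
        if len(hom_counts) > 2:
            raise ValueError(f"{variant}: more than two homozygous classes")
        while len(hom_counts) < 2:
            hom_counts.append(0)
        out.append(GenotypeCounts(str(variant), hom_counts[0], het, hom_counts[1]))
    return out


def write_genotype_table(variants: list[GenotypeCounts], path: str | Path) -> None:
    rows = []
    for g in variants:
        rows += [
            {"variant": g.variant, "genotype": "A/A", "count": g.n_hom_ref},
            {"variant": g.variant, "genotype": "A/a", "count": g.n_het},
            {"variant": g.variant, "genotype": "a/a", "count": g.n_hom_alt},
        ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping, embedded in outputs."""
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
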