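"""Cohort directory layout: read/write subjects, connectomes, signals, FC.

A cohort directory contains:

* ``subjects.tsv`` — id, group, age, sex, education and one z-score
  column per cognitive domain;
* ``<id>_sc_fa.tsv`` / ``<id>_tract_len.tsv`` — square tab-delimited
  matrices with node labels as header row and index column;
* ``<id>_timeseries.npy`` or ``.tsv`` — channels x samples array
  (TSV variant has a node-label header row);
* ``<id>_fc_<band>.tsv`` — optional per-band rescaled FC matrices;
* ``cohort.yaml`` — config snapshot for provenance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fc import FCMatrix, FrequencyBand, SourceTimeSeries
from .sc import StructuralConnectome, read_connectome, write_connectome
from .synth import (
    Cohort,
    CohortConfig,
    CohortRecord,
    Subject,
    config_from_dict,
    config_to_dict,
)
from .stats import COGNITIVE_DOMAINS

__all__ = ["write_cohort", "read_cohort", "write_fc_matrix", "read_fc_matrix"]

Z_COLUMNS = [f"z_{d}" for d in COGNITIVE_DOMAINS]


def write_fc_matrix(fc: FCMatrix, path) -> None:
    labels = fc.node_labels or [f"ch{i}" for i in range(fc.n_nodes)]
    pd.DataFrame(fc.values, index=labels, columns=labels).to_csv(path, sep="\t")


def read_fc_matrix(path, band: FrequencyBand, rescaled: bool = True) -> FCMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FCMatrix(
        values=df.to_numpy(dtype=float),
        band=band,
        rescaled=rescaled,
        node_labels=list(df.columns),
    )


def write_cohort(
    cohort: Cohort, directory, timeseries_format: str = "npy"
) -> Path:
    """Write a cohort to a directory; returns the directory path."""
    if timeseries_format not in ("npy", "tsv"):
        raise ValueError("timeseries_format must be 'npy' or 'tsv'")
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for rec in cohort.records:
        s = rec.subject
        row = {
            "id": s.id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "education": s.education,
        }
        row.update(dict(zip(Z_COLUMNS, s.domain_z)))
        rows.append(row)
        write_connectome(
            rec.connectome, out / f"{s.id}_sc_fa.tsv", out / f"{s.id}_tract_len.tsv"
        )
        if rec.timeseries is not None:
            if timeseries_format == "npy":
                np.save(out / f"{s.id}_timeseries.npy", rec.timeseries.data)
            else:
                pd.DataFrame(
                    rec.timeseries.data.T, columns=rec.timeseries.channel_labels
                ).to_csv(out / f"{s.id}_timeseries.tsv", sep="\t", index=False)
        for band_name, fc in rec.fc.items():
            write_fc_matrix(fc, out / f"{s.id}_fc_{band_name}.tsv")
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)
    with open(out / "cohort.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(cohort.config), fh, sort_keys=False)
    return out


def _read_timeseries(directory: Path, sid: str, config: CohortConfig):
    npy = directory / f"{sid}_timeseries.npy"
    tsv = directory / f"{sid}_timeseries.tsv"
    if npy.exists():
        return SourceTimeSeries(
            data=np.load(npy),
            sampling_rate=config.sampling_rate,
            channel_labels=config.node_labels(),
        )
    if tsv.exists():
        df = pd.read_csv(tsv, sep="\t")
        return SourceTimeSeries(
            data=df.to_numpy(dtype=float).T,
            sampling_rate=config.sampling_rate,
            channel_labels=list(df.columns),
        )
    return None


def read_cohort(directory, bands: tuple[FrequencyBand, ...] = ()) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`.

    ``bands`` selects which per-band FC matrix files to look for; when
    empty, any stored FC matrices are ignored.
    """
    directory = Path(directory)
    cfg_path = directory / "cohort.yaml"
    if not cfg_path.exists():
        raise FileNotFoundError(f"no cohort.yaml in {directory}")
    with open(cfg_path) as fh:
        config = config_from_dict(yaml.safe_load(fh))
    subjects = pd.read_csv(directory / "subjects.tsv", sep="\t")
    missing = [c for c in ("id", "group", "age", "sex", "education") if c not in subjects]
    if missing:
        raise ValueError(f"subjects.tsv missing columns: {missing}")

    records = []
    for _, row in subjects.iterrows():
        sid = str(row["id"])
        z = row[[c for c in Z_COLUMNS if c in subjects.columns]].to_numpy(dtype=float)
        subject = Subject(
            id=sid,
            group=str(row["group"]),
            age=float(row["age"]),
            sex=int(row["sex"]),
            education=str(row["education"]),
            domain_z=z,
        )
        connectome = read_connectome(
            directory / f"{sid}_sc_fa.tsv", directory / f"{sid}_tract_len.tsv"
        )
        rec = CohortRecord(subject=subject, connectome=connectome)
        rec.timeseries = _read_timeseries(directory, sid, config)
        for band in bands:
            fc_path = directory / f"{sid}_fc_{band.name}.tsv"
            if fc_path.exists():
                rec.fc[band.name] = read_fc_matrix(fc_path, band)
        records.append(rec)
    return Cohort(config=config, records=records)
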