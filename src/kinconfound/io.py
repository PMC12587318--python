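"""Readers/writers for the pipeline's text formats, config and run logs.

Conventions, declared once: UTF-8 text, "." decimal separator, "NA" for
missing values, missing parents encoded as "0" in pedigree files.  Every
writer is atomic (write to a temporary file, then rename) and every
stochastic run can log its parameters, seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .synthetic import GeneticCorrelationSet, Pedigree, TransmissionParams

__all__ = [
    "write_pedigree", "read_pedigree",
    "write_pairs", "read_pairs",
    "write_questionnaire", "read_questionnaire",
    "write_rg_set", "read_rg_set",
    "write_json", "read_config", "write_config", "config_hash",
]

NA = "NA"


def _with_ext(prefix, ext: str):
    return Path(str(prefix) + ext)

MISSING_PARENT = "0"

_PED_FIXED = ["id", "father_id", "mother_id", "sex", "birth_year", "surname"]
_PED_LATENT = ["generation", "T", "G", "C", "E"]


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _frame_to_text(df: pd.DataFrame, sep: str) -> str:
    # repr() gives the shortest decimal that round-trips the float exactly
    return df.to_csv(
        sep=sep, index=False, na_rep=NA, lineterminator="\n",
        float_format=lambda v: repr(float(v)),
    )


def write_pedigree(pedigree: Pedigree, path, *, include_latent: bool = True) -> None:
    """Write a pedigree as PED-like TSV.

    Column order: id, father_id, mother_id, sex, birth_year, surname, one
    column per phenotype measure, wealth, probated; latent columns
    (generation, T, G, C, E) are appended when ``include_latent`` (the
    default, so that write-then-read round-trips the full structure).
    Missing parents are encoded as "0".
    """
    df = pedigree.individuals.copy()
    cols = list(_PED_FIXED) + list(pedigree.measures)
    for c in ("wealth", "probated", "period_minimum"):
        if c in df.columns:
            cols.append(c)
    if include_latent:
        cols += [c for c in _PED_LATENT if c in df.columns]
    df = df[cols]
    for c in ("father_id", "mother_id"):
        df[c] = df[c].fillna(MISSING_PARENT)
    header = {
        "generations": pedigree.generations,
        "seed": pedigree.seed,
        "measures": list(pedigree.measures),
        "t2": pedigree.params.t2,
        "m": pedigree.params.m,
        "h2_share": pedigree.params.h2_share,
        "t2_schedule": list(pedigree.t2_schedule) if pedigree.t2_schedule else None,
    }
    text = "#kinconfound-pedigree " + json.dumps(header) + "\n" + _frame_to_text(df, "\t")
    _atomic_write(path, text)


def read_pedigree(path) -> Pedigree:
    """Read a PED-like TSV written by :func:`write_pedigree`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if not first.startswith("#kinconfound-pedigree"):
        raise ConfigurationError(
            f"{path}: line 1, column 1: missing pedigree header"
        )
    meta = json.loads(first.split(" ", 1)[1])
    df = pd.read_csv(
        path, sep="\t", skiprows=1, na_values=[NA], keep_default_na=False,
        float_precision="round_trip",
        dtype={"id": str, "father_id": str, "mother_id": str,
               "sex": str, "surname": str},
    )
    for c in ("father_id", "mother_id"):
        df[c] = df[c].replace(MISSING_PARENT, None)
    if "probated" in df.columns:
        df["probated"] = df["probated"].astype(bool)
    params = TransmissionParams(
        t2=meta["t2"], m=meta["m"], h2_share=meta["h2_share"]
    )
    return Pedigree(
        individuals=df,
        generations=int(meta["generations"]),
        params=params,
        seed=meta.get("seed"),
        measures=tuple(meta.get("measures", ("status",))),
        t2_schedule=tuple(meta["t2_schedule"]) if meta.get("t2_schedule") else None,
    )


def write_pairs(pairs: pd.DataFrame, path) -> None:
    _atomic_write(path, _frame_to_text(pairs, ","))


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False,
                     float_precision="round_trip",
                     dtype={"id_a": str, "id_b": str, "relationship": str,
                            "surname": str})
    from .estimation import PAIR_COLUMNS

    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: line 1: pair table lacks columns {missing}"
        )
    return df


def write_questionnaire(records: pd.DataFrame, path) -> None:
    _atomic_write(path, _frame_to_text(records, ","))


def read_questionnaire(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False,
                     float_precision="round_trip",
                     dtype={"id": str, "sex": str})
    for col in ("n_partners_total", "n_same_sex_partners", "age_first_sex"):
        if col not in df.columns:
            raise ConfigurationError(
                f"{path}: line 1: questionnaire lacks column {col!r}"
            )
    return df


def write_rg_set(rg_set: GeneticCorrelationSet, path_prefix) -> None:
    """Write a correlation set as <prefix>.R.csv, <prefix>.V.csv and a JSON
    sidecar <prefix>.json naming labels and n_effective."""
    prefix = Path(path_prefix)
    r_df = pd.DataFrame(rg_set.R, index=rg_set.labels, columns=rg_set.labels)
    _atomic_write(_with_ext(prefix, ".R.csv"), r_df.to_csv(lineterminator="\n"))
    if rg_set.V is not None:
        _atomic_write(
            _with_ext(prefix, ".V.csv"),
            pd.DataFrame(rg_set.V).to_csv(index=False, lineterminator="\n"),
        )
    sidecar = {
        "labels": list(rg_set.labels),
        "n_effective": rg_set.n_effective,
        "has_sampling_covariance": rg_set.V is not None,
        "v_order": "row-major upper triangle of R",
    }
    _atomic_write(_with_ext(prefix, ".json"), json.dumps(sidecar, indent=2) + "\n")


def read_rg_set(path_prefix) -> GeneticCorrelationSet:
    prefix = Path(path_prefix)
    with open(_with_ext(prefix, ".json"), encoding="utf-8") as fh:
        sidecar = json.load(fh)
    r_df = pd.read_csv(_with_ext(prefix, ".R.csv"), index_col=0,
                       float_precision="round_trip")
    V = None
    v_path = _with_ext(prefix, ".V.csv")
    if sidecar.get("has_sampling_covariance") and v_path.exists():
        V = pd.read_csv(v_path, float_precision="round_trip").to_numpy(dtype=float)
    return GeneticCorrelationSet(
        labels=tuple(sidecar["labels"]),
        R=r_df.to_numpy(dtype=float),
        V=V,
        n_effective=sidecar.get("n_effective"),
    )


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON-serializable: {type(o)}")

    _atomic_write(path, json.dumps(obj, indent=2, default=default) + "\n")


def read_config(path) -> dict:
    """Parse a flat key=value config file (``#`` starts a comment).

    Values are parsed as int, then float, then left as strings; "NA"
    becomes None.
    """
    out: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(
                    f"{path}: line {lineno}, column 1: expected key=value"
                )
            key, value = (s.strip() for s in line.split("=", 1))
            if value == NA:
                out[key] = None
                continue
            for cast in (int, float):
                try:
                    out[key] = cast(value)
                    break
                except ValueError:
                    continue
            else:
                out[key] = value
    return out


def write_config(config: dict, path) -> None:
    lines = [
        f"{k}={NA if v is None else v}" for k, v in sorted(config.items())
    ]
    _atomic_write(path, "\n".join(lines) + "\n")


def config_hash(config: dict) -> str:
    """Stable short hash identifying a run configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
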