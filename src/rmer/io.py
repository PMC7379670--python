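"""Readers, writers, run configuration and fixture generation.

Removal data travel as CSV with one row per occasion and 1-based
``(primary, secondary)`` indexing; an optional ``effort`` column in {0, 1}
flags missed visits (count forced to zero, capture probability forced to
zero in every model).  Extra numeric columns are treated as per-occasion
covariates.  Results are written as JSON with full-precision floats and a
schema version tag.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .likelihood import RemovalData
from .model_spec import RobustDesign
from .scenarios import SCENARIO_NAMES, scenario

__all__ = [
    "read_removal_csv",
    "write_removal_csv",
    "load_config",
    "write_result_json",
    "generate_fixtures",
]

RESULT_SCHEMA_VERSION = 1

log = logging.getLogger("rmer")


def read_removal_csv(path, covariate: Optional[str] = None) -> RemovalData:
    """Read removal counts (and optionally one covariate column) from CSV.

    Expects columns ``primary``, ``secondary``, ``count`` and optionally
    ``effort``; rows with ``effort = 0`` become missing occasions.  Raises
    on duplicate occasions, negative counts or gaps in the secondary
    numbering within a primary.
    """
    df = pd.read_csv(path)
    for col in ("primary", "secondary", "count"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if df.duplicated(["primary", "secondary"]).any():
        dup = df[df.duplicated(["primary", "secondary"])].iloc[0]
        raise ValueError(f"duplicate occasion ({int(dup.primary)},{int(dup.secondary)})")
    if (df["count"] < 0).any():
        raise ValueError("negative removal count")
    df = df.sort_values(["primary", "secondary"], kind="stable").reset_index(drop=True)
    primaries = sorted(df["primary"].unique())
    if primaries != list(range(1, len(primaries) + 1)):
        raise ValueError("primary periods must be numbered 1..T without gaps")
    k = []
    for i in primaries:
        secs = df.loc[df["primary"] == i, "secondary"].tolist()
        if secs != list(range(1, len(secs) + 1)):
            raise ValueError(f"secondary occasions of primary {i} must be 1..k_{i}")
        k.append(len(secs))
    missing = set()
    if "effort" in df.columns:
        for _, row in df[df["effort"] == 0].iterrows():
            missing.add((int(row["primary"]), int(row["secondary"])))
            if row["count"] != 0:
                raise ValueError("non-zero count at a zero-effort occasion")
    design = RobustDesign(tuple(k), frozenset(missing))
    counts = df["count"].to_numpy(dtype=np.int64)
    covs = None
    if covariate is not None:
        if covariate not in df.columns:
            raise ValueError(f"covariate column {covariate!r} not in file")
        covs = df[covariate].to_numpy(dtype=float)
    return RemovalData(design, counts, covariates=covs)


def write_removal_csv(data: RemovalData, path, covariate_name: str = "z") -> None:
    """Write a RemovalData back to the CSV layout read by read_removal_csv."""
    mask = data.design.missing_mask()
    df = pd.DataFrame(data.design.occasions(), columns=["primary", "secondary"])
    df["count"] = data.counts
    df["effort"] = (~mask).astype(int)
    if data.covariates is not None:
        df[covariate_name] = data.covariates
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def write_result_json(obj: dict, path) -> None:
    out = {"schema_version": RESULT_SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialise {type(x)}")


def generate_fixtures(out_dir, seed: int = 0, K: int = 20) -> list:
    """Write one simulated dataset plus truth JSON per scenario preset.

    Deterministic for a given seed: preset ``name`` gets the child stream
    indexed by its position in ``SCENARIO_NAMES``.  Returns the written
    paths.
    """
    from .simulate import simulate_scenario

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(seed).spawn(len(SCENARIO_NAMES))
    written = []
    for name, child in zip(SCENARIO_NAMES, children):
        scn = scenario(name, K=K)
        rng = np.random.default_rng(child)
        datasets = simulate_scenario(scn, rng=rng)
        truth = {
            "scenario": name,
            "seed": seed,
            "K": K,
            "populations": [
                {
                    "N": int(n),
                    "pi": par.pi,
                    "phi12": par.phi12,
                    "phi21": par.phi21,
                    "p": float(par.p[0]),
                }
                for n, par in zip(scn.N, scn.truths)
            ],
        }
        for w, ds in enumerate(datasets):
            suffix = "" if len(datasets) == 1 else f"-pop{w + 1}"
            csv_path = out_dir / f"{name}{suffix}.csv"
            write_removal_csv(ds, csv_path)
            written.append(csv_path)
        truth_path = out_dir / f"{name}-truth.json"
        write_result_json(truth, truth_path)
        written.append(truth_path)
        log.info("fixture %s written (seed=%s)", name, seed)
    return written
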