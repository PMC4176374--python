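"""CSV/JSON/YAML serialization and provenance records.

All tabular outputs are plain CSV with units embedded in the column names
(force_pN, J_molar, dwell_s); metadata travels in JSON sidecars. Every CLI
run emits a provenance record (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import SurvivalDataset

SURVIVAL_COLUMNS = ["condition", "size_bp", "molecule_id", "dwell_s", "censored"]


def write_survival_csv(dataset: SurvivalDataset, path: str | Path) -> None:
    dataset.data.to_csv(path, index=False, columns=SURVIVAL_COLUMNS)
    meta = dict(dataset.meta)
    if dataset.dimer_dwells_s is not None:
        meta["dimer_dwells_s"] = list(map(float, dataset.dimer_dwells_s))
    Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_survival_csv(path: str | Path) -> SurvivalDataset:
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"survival CSV missing columns: {missing}")
    if "censored" not in df.columns:
        df["censored"] = False
    meta_path = Path(path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    dimer = meta.pop("dimer_dwells_s", None)
    return SurvivalDataset(
        data=df,
        dimer_dwells_s=np.asarray(dimer, dtype=float) if dimer else None,
        meta=meta,
    )


def write_fit_json(fit, report, path: str | Path) -> None:
    """Serialize a Bell fit and (optionally) a transition report."""
    payload = {
        "tau0_s": fit.tau0,
        "se_tau0_s": fit.se_tau0,
        "delta_r0_nm": fit.delta_r0,
        "se_delta_r0_nm": fit.se_delta_r0,
        "rmse": fit.rmse,
        "fit_range_bp": list(fit.fit_range_bp),
        "n_points": fit.n_points,
    }
    if report is not None:
        payload["critical_size_bp"] = report.critical_size_bp
        payload["plateau_rmse"] = report.plateau_rmse
        payload["jump_factor"] = report.jump_factor
        payload["rmse_curve"] = report.rmse_curve.to_dict(orient="records")
    Path(path).write_text(json.dumps(payload, indent=1))


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def provenance_record(config: dict, seed: int) -> dict:
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "kinkloop_version": __version__,
        "numpy_version": np.__version__,
    }
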