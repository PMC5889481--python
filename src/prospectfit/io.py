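"""CSV/YAML data contracts, pipeline configuration and the dataset adapter.

All tables exchanged between stages are plain CSV with fixed headers:

* CE table: participant_id, group, [drug_order,] drug, domain,
  gamble_index, ce  — signed euros, negative in the loss domain.
* parameter table: participant_id, group, [drug_order,] drug, domain,
  alpha, w26, w16, w36, w46, w56, delta, gamma, resnorm1, resnorm2,
  excluded, exclusion_reason.
* stat results: contrast, z, p_uncorr, p_corr, cle, n.

Configuration is a small YAML file mapped onto :class:`PipelineConfig`;
each run writes a JSON manifest (seed, config hash, package versions) next
to its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import gamble_menu

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "load_config",
    "read_ce_table",
    "write_ce_table",
    "read_param_table",
    "write_param_table",
    "write_trial_log",
    "write_manifest",
    "adapt_figshare_dataset",
]

CE_COLUMNS = ["participant_id", "group", "drug", "domain", "gamble_index", "ce"]
DRUGS = ("placebo", "sulpiride")
DOMAINS = ("gain", "loss")


class SchemaError(ValueError):
    """A table violates its CSV contract; message names the offending rows."""


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end synthetic pipeline."""

    seed: int = 0
    out_dir: str = "prospectfit_out"
    weighting_form: str = "lattimore"
    fix_alpha: bool = False
    n_restarts: int = 200
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    recovery_sims: int = 200
    recovery_restarts: int = 20
    noise_se: float | None = None

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = PipelineConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _validate_ce_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in CE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing columns {missing}")
    menu = {g.index: g for g in gamble_menu("gain")}
    problems = []
    idx = pd.to_numeric(df["gamble_index"], errors="coerce")
    bad = df.index[~idx.isin(list(menu))]
    problems += [f"row {i}: unknown gamble_index {df.loc[i, 'gamble_index']}" for i in bad]
    df = df.copy()
    df["gamble_index"] = idx
    ok = df.index.difference(bad)
    for i in ok:
        g = menu[int(df.loc[i, "gamble_index"])]
        ce = float(df.loc[i, "ce"])
        domain = df.loc[i, "domain"]
        if domain not in DOMAINS:
            problems.append(f"row {i}: unknown domain {domain!r}")
            continue
        if domain == "loss" and ce > 0:
            problems.append(f"row {i}: loss-domain CE must be <= 0, got {ce}")
        if domain == "gain" and ce < 0:
            problems.append(f"row {i}: gain-domain CE must be >= 0, got {ce}")
        if not (0 <= abs(ce) <= g.x):
            problems.append(f"row {i}: |CE|={abs(ce)} outside [0, {g.x}] for gamble {g.index}")
    dup = df.duplicated(subset=["participant_id", "drug", "domain", "gamble_index"])
    problems += [f"row {i}: duplicate key" for i in df.index[dup]]
    if problems:
        raise SchemaError(f"{source}: " + "; ".join(problems[:20]))
    df["gamble_index"] = df["gamble_index"].astype(int)
    return df


def read_ce_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a certainty-equivalent table CSV."""
    df = pd.read_csv(path)
    return _validate_ce_frame(df, str(path))


def write_ce_table(df: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a CE table; CE rounded to cents."""
    df = _validate_ce_frame(df, "ce_table")
    df = df.assign(ce=df["ce"].round(2))
    df.to_csv(path, index=False)


def read_param_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"participant_id", "drug", "domain", "alpha", "delta", "gamma", "excluded"}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_param_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_trial_log(trials, path: str | Path) -> None:
    """Write TrialRecord rows as a CSV trial log."""
    pd.DataFrame([t.__dict__ for t in trials]).to_csv(path, index=False)


def write_manifest(config: PipelineConfig, path: str | Path, extra: dict | None = None) -> None:
    import prospectfit

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": {
            "prospectfit": getattr(prospectfit, "__version__", "unknown"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def adapt_figshare_dataset(path: str | Path) -> pd.DataFrame:
    """Adapt a locally downloaded copy of the study's deposited raw data.

    Never downloads anything.  If ``path`` does not exist a clean
    "dataset not present" error is raised — the pipeline remains fully
    testable on synthetic data.  If present, any CSV matching the package's
    CE schema is adapted directly; Matlab ``.mat`` containers are loaded and
    searched for a per-participant CE array (participants x gambles, per
    drug and domain).  Anything else raises an unsupported-format error
    listing what was found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"dataset not present at {path}; download the deposited archive "
            "manually and point the adapter at the extracted directory"
        )
    candidates = sorted(path.rglob("*")) if path.is_dir() else [path]
    csvs = [p for p in candidates if p.suffix.lower() == ".csv"]
    for p in csvs:
        try:
            return read_ce_table(p)
        except (SchemaError, Exception):  # noqa: BLE001 - try next candidate
            continue
    mats = [p for p in candidates if p.suffix.lower() == ".mat"]
    for p in mats:
        table = _try_adapt_mat(p)
        if table is not None:
            return table
    found = sorted({p.suffix or p.name for p in candidates if p.is_file()})
    raise SchemaError(
        f"unsupported dataset layout under {path}: no adaptable CE data; "
        f"found file types {found}"
    )


def _try_adapt_mat(path: Path) -> pd.DataFrame | None:
    try:
        from scipy.io import loadmat

        data = loadmat(path, squeeze_me=True)
    except Exception:
        return None
    rows = []
    for key, val in data.items():
        if key.startswith("__"):
            continue
        arr = np.asarray(val, dtype=float) if np.ndim(val) else None
        if arr is None or arr.ndim != 2 or arr.shape[1] != 10:
            continue
        # interpret as participants x 10 CEs; condition read from the name
        drug = "sulpiride" if "sulp" in key.lower() else "placebo"
        domain = "loss" if "loss" in key.lower() else "gain"
        sign = -1.0 if domain == "loss" else 1.0
        for p_i, ce_row in enumerate(arr):
            for g_i, ce in enumerate(ce_row, start=1):
                rows.append(
                    {
                        "participant_id": f"p{p_i + 1:03d}",
                        "group": "",
                        "drug": drug,
                        "domain": domain,
                        "gamble_index": g_i,
                        "ce": sign * abs(ce),
                    }
                )
    if not rows:
        return None
    return _validate_ce_frame(pd.DataFrame(rows), str(path))
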