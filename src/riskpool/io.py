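"""Reading, writing, validation, and configuration plumbing.

Session logs and metric tables travel as UTF-8 CSV with a mandatory
header; every file this package writes carries ``#``-prefixed comment
lines recording the producing command, the seed, and a hash of the
configuration, so any output can be traced back to its inputs.  A
column-mapping file (YAML) adapts externally produced tables — e.g. the
deposited supplementary spreadsheet of the original experiment — to the
package schema.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .engine import (
    GameConfig,
    HIGH_VOLATILITY,
    LOW_VOLATILITY,
    LOG_COLUMNS,
    ShockModel,
    VolatilityRegime,
)
from .errors import ConfigError, ValidationError

__all__ = [
    "ColumnMapping",
    "read_session_log",
    "write_session_log",
    "write_table",
    "read_table",
    "validate_log",
    "game_config_from_yaml",
    "game_config_to_dict",
    "config_hash",
]

_REQUIRED_NUMERIC = ["stock_pre", "harvest", "requested", "received", "given",
                     "shock", "stock_post"]
_NONNEGATIVE = ["harvest", "requested", "received", "given", "stock_pre", "stock_post"]


# ---------------------------------------------------------------------------
# column mapping for external tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnMapping:
    """Adapter from an external table's columns to the package schema.

    ``columns`` maps source column name -> schema field; ``multipliers``
    rescales a mapped field (units conversion); ``conditions`` maps source
    condition labels onto the ``control``/``primed`` labels the stats
    module expects.  Every mandatory field must be mapped exactly once.
    """

    columns: Dict[str, str]
    multipliers: Dict[str, float] = field(default_factory=dict)
    conditions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        targets = list(self.columns.values())
        dupes = {t for t in targets if targets.count(t) > 1}
        if dupes:
            raise ConfigError(f"schema fields mapped more than once: {sorted(dupes)}")

    @classmethod
    def from_yaml(cls, path) -> "ColumnMapping":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            columns=dict(raw.get("columns", {})),
            multipliers={k: float(v) for k, v in (raw.get("multipliers") or {}).items()},
            conditions=dict(raw.get("conditions") or {}),
        )

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise ValidationError(f"source columns not found: {missing}")
        out = df.rename(columns=self.columns)[list(self.columns.values())].copy()
        for col, k in self.multipliers.items():
            if col in out.columns:
                out[col] = out[col].astype(float) * k
        if self.conditions and "condition" in out.columns:
            out["condition"] = out["condition"].map(
                lambda v: self.conditions.get(v, v)
            )
        return out


# ---------------------------------------------------------------------------
# session logs
# ---------------------------------------------------------------------------

def validate_log(df: pd.DataFrame) -> pd.DataFrame:
    """Schema and invariant checks for a session log.

    Verifies required columns, finite non-negative amounts, and pairwise
    transfer symmetry (what one player gave, the partner received in the
    same period).  Raises :class:`ValidationError` naming every violating
    row.
    """
    missing = [c for c in LOG_COLUMNS if c not in df.columns and c not in ("treatment",)]
    if missing:
        raise ValidationError(f"log is missing required columns: {missing}")
    if "treatment" not in df.columns:
        df = df.assign(treatment=df["condition"])

    problems: List[str] = []
    values = df[_REQUIRED_NUMERIC].to_numpy(dtype=float)
    bad_finite = ~np.isfinite(values).all(axis=1)
    for i in df.index[bad_finite]:
        problems.append(f"row {i}: non-finite numeric value")
    for col in _NONNEGATIVE:
        neg = df[col].to_numpy(dtype=float) < 0
        for i in df.index[neg]:
            problems.append(f"row {i}: {col} < 0")

    # transfer symmetry within (session, round, period) pairs
    key = ["session", "round", "period"]
    mirror = df.set_index(key + ["player_id"])["given"]
    idx = pd.MultiIndex.from_arrays([df[c] for c in key] + [df["partner_id"]])
    partner_given = mirror.reindex(idx).to_numpy()
    received = df["received"].to_numpy(dtype=float)
    ok = np.isfinite(partner_given)
    asym = ok & (np.abs(partner_given - received) > 1e-6)
    for i in df.index[np.asarray(asym)]:
        problems.append(f"row {i}: received does not match partner's given")

    if problems:
        raise ValidationError(
            "session log failed validation:\n  " + "\n  ".join(problems[:50])
            + ("" if len(problems) <= 50 else f"\n  ... {len(problems) - 50} more")
        )
    return df


def _comment_header(command: Optional[str], seed, cfg_hash: Optional[str]) -> str:
    lines = []
    if command:
        lines.append(f"# command: {command}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash:
        lines.append(f"# config_hash: {cfg_hash}")
    return "".join(line + "\n" for line in lines)


def write_table(
    df: pd.DataFrame,
    path,
    command: Optional[str] = None,
    seed=None,
    cfg_hash: Optional[str] = None,
) -> None:
    """Write any tidy table as CSV with provenance comment headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_comment_header(command, seed, cfg_hash))
        df.to_csv(fh, index=False)


def write_session_log(df: pd.DataFrame, path, **kwargs) -> None:
    """Validate and write a session log as CSV (fixed column order)."""
    df = validate_log(df)
    write_table(df[LOG_COLUMNS], path, **kwargs)


def read_table(path, mapping: Optional[ColumnMapping] = None) -> pd.DataFrame:
    """Read a CSV or spreadsheet table, applying a column mapping if given."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, comment="#")
    if mapping is not None:
        df = mapping.apply(df)
    return df


def read_session_log(path, mapping: Optional[ColumnMapping] = None) -> pd.DataFrame:
    """Read and validate a session log (CSV, or spreadsheet via mapping)."""
    df = read_table(path, mapping)
    if "practice" in df.columns:
        df["practice"] = df["practice"].astype(bool)
    if "alive_post" in df.columns:
        df["alive_post"] = df["alive_post"].astype(bool)
    return validate_log(df)


def detect_granularity(df: pd.DataFrame) -> str:
    """Classify an imported table as a period-level ``"log"`` or a
    player-level ``"metrics"`` table based on which schema fields it has."""
    if {"period", "given", "received"}.issubset(df.columns):
        return "log"
    from .metrics import METRIC_VARIABLES

    if set(METRIC_VARIABLES).intersection(df.columns):
        return "metrics"
    raise ValidationError(
        "table matches neither the session-log nor the metrics schema"
    )


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_REGIMES = {"high": HIGH_VOLATILITY, "low": LOW_VOLATILITY}


def _regime_from(obj) -> VolatilityRegime:
    if isinstance(obj, str):
        try:
            return _REGIMES[obj]
        except KeyError:
            raise ConfigError(f"unknown regime label {obj!r}") from None
    return VolatilityRegime(
        rate=float(obj["rate"]),
        lower=float(obj["lower"]),
        upper=float(obj["upper"]),
        label=str(obj.get("label", "")),
    )


def game_config_from_yaml(path) -> GameConfig:
    """Build a :class:`GameConfig` from a YAML file whose keys match the
    config fields; regimes may be given as ``high``/``low`` labels or as
    full parameter mappings."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    raw = dict(raw.get("game", raw))
    kwargs = {}
    simple = [
        "n_rounds", "periods_per_round", "practice_periods", "death_threshold",
        "death_grace", "initial_stock", "units_per_dollar", "show_up_fee",
        "integer_stocks", "high_first",
    ]
    for key in simple:
        if key in raw:
            kwargs[key] = raw[key]
    if "regimes_by_round" in raw and raw["regimes_by_round"] is not None:
        kwargs["regimes_by_round"] = tuple(
            _regime_from(r) for r in raw["regimes_by_round"]
        )
    if "shock_model" in raw and raw["shock_model"] is not None:
        sm = raw["shock_model"]
        kwargs["shock_model"] = ShockModel(
            distribution=str(sm.get("distribution", "normal")),
            scale=float(sm.get("scale", 2.0)),
        )
    unknown = set(raw) - set(simple) - {"regimes_by_round", "shock_model"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return GameConfig(**kwargs)


def game_config_to_dict(config: GameConfig) -> dict:
    d = asdict(config)
    d["shock_model"] = asdict(config.shock_model)
    if config.regimes_by_round is not None:
        d["regimes_by_round"] = [asdict(r) for r in config.regimes_by_round]
    return d


def config_hash(config: GameConfig) -> str:
    """Short stable hash of a configuration, for provenance headers."""
    payload = json.dumps(game_config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
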