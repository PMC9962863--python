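"""Configuration loading, bundled defaults and result export.

Parameter files are YAML mappings keyed by the standard symbol names
(``CL_E``, ``T_MP``, ``Smax_RM2``, ...), so a config file doubles as a
machine-readable parameter table.  Time-denominated entries may be
written either as a bare number in the canonical unit (hours) or as
``{value: 10.6, unit: day}`` and are converted on load.  Unknown keys
are rejected by name.
"""

from __future__ import annotations

import hashlib
import importlib.resources as resources
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .hematopoiesis import PDParameterSet
from .pk import (
    ConcProfile,
    DoseEvent,
    EpoHumanPK,
    EpoRatPK,
    RomiHumanPK,
    RomiRatPK,
)
from .regimens import RegimenSpec, SimulationBands

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "load_pd_params",
    "load_pk_params",
    "load_regimen_specs",
    "load_dose_table",
    "default_human_pd",
    "default_rat_pd",
    "default_human_pk",
    "default_rat_pk",
    "default_regimens",
    "export_profile",
    "export_trajectory",
    "export_verdicts",
    "export_bands",
    "export_params",
    "read_params",
]

_VERSION = "0.1.0"


class ConfigError(ValueError):
    pass


# symbol name -> (dataclass field, kind); kind "time" allows unit conversion
_PD_SYMBOLS: dict[str, tuple[str, str]] = {
    "T_MP": ("t_mp", "time"),
    "T_PLT": ("t_plt", "time"),
    "PLT0": ("plt0", "plain"),
    "T_RBC": ("t_rbc", "time"),
    "T_RET": ("t_ret", "time"),
    "RBC0": ("rbc0", "plain"),
    "KE": ("ke", "plain"),
    "KM": ("km_diff", "plain"),
    "Smax_RM1": ("smax_rm1", "plain"),
    "Smax_RM2": ("smax_rm2", "plain"),
    "Smax_EPO1": ("smax_epo1", "plain"),
    "SC50_RM": ("sc50_rm", "plain"),
    "SC50_EPO": ("sc50_epo", "plain"),
    "Imax_EPO": ("imax_epo", "plain"),
    "IC50_EPO": ("ic50_epo", "plain"),
    "MCH": ("mch", "plain"),
    "T_EP": ("t_ep", "time"),
    "n_MK": ("n_mk", "int"),
    "n_PLT": ("n_plt", "int"),
    "n_ery_precursors": ("n_ery_precursors", "int"),
}

_PD_REQUIRED = {
    s for s, (f, _) in _PD_SYMBOLS.items()
    if f not in ("t_ep", "n_mk", "n_plt", "n_ery_precursors")
}

_TIME_UNITS = {
    "h": 1.0, "hr": 1.0, "hour": 1.0, "hours": 1.0,
    "d": 24.0, "day": 24.0, "days": 24.0,
}

_PK_CLASSES = {
    "epo_human": EpoHumanPK,
    "romi_human": RomiHumanPK,
    "epo_rat": EpoRatPK,
    "romi_rat": RomiRatPK,
}


def _as_hours(symbol: str, raw: Any) -> float:
    if isinstance(raw, Mapping):
        extra = set(raw) - {"value", "unit"}
        if extra:
            raise ConfigError(
                f"unknown keys {sorted(extra)} in entry for {symbol!r}"
            )
        if "value" not in raw:
            raise ConfigError(f"entry for {symbol!r} lacks 'value'")
        unit = str(raw.get("unit", "h")).lower()
        if unit not in _TIME_UNITS:
            raise ConfigError(
                f"unsupported unit {unit!r} for {symbol!r} (use h or day)"
            )
        return float(raw["value"]) * _TIME_UNITS[unit]
    return float(raw)


def load_pd_params(mapping: Mapping[str, Any]) -> PDParameterSet:
    """Build a :class:`PDParameterSet` from a symbol-keyed mapping."""
    unknown = set(mapping) - set(_PD_SYMBOLS)
    if unknown:
        raise ConfigError(f"unknown PD parameter key(s): {sorted(unknown)}")
    missing = _PD_REQUIRED - set(mapping)
    if missing:
        raise ConfigError(f"missing PD parameter(s): {sorted(missing)}")
    kwargs: dict[str, Any] = {}
    for symbol, raw in mapping.items():
        field_name, kind = _PD_SYMBOLS[symbol]
        if kind == "time":
            kwargs[field_name] = _as_hours(symbol, raw)
        elif kind == "int":
            kwargs[field_name] = int(raw)
        else:
            kwargs[field_name] = float(raw)
    return PDParameterSet(**kwargs)


def load_pk_params(mapping: Mapping[str, Any], model: str):
    """Build a PK parameter set (``model`` one of epo_human, romi_human,
    epo_rat, romi_rat) from a symbol-keyed mapping."""
    try:
        cls = _PK_CLASSES[model]
    except KeyError:
        raise ConfigError(
            f"unknown PK model {model!r}; expected one of {sorted(_PK_CLASSES)}"
        ) from None
    valid = {f.name for f in fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} key(s): {sorted(unknown)}"
        )
    missing = valid - set(mapping)
    if missing:
        raise ConfigError(
            f"missing {cls.__name__} parameter(s): {sorted(missing)}"
        )
    return cls(**{k: float(v) for k, v in mapping.items()})


def _bundled(name: str) -> dict:
    with resources.files("hemoscale.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def default_human_pd() -> PDParameterSet:
    """Scaled human PD parameter set shipped with the package."""
    return load_pd_params(_bundled("human_pd.yaml"))


def default_rat_pd() -> PDParameterSet:
    """Healthy-rat PD parameter set (synthetic MCH fixture, see file)."""
    return load_pd_params(_bundled("rat_pd.yaml"))


def default_human_pk() -> tuple[EpoHumanPK, RomiHumanPK]:
    raw = _bundled("human_pk.yaml")
    return (
        load_pk_params(raw["epo"], "epo_human"),
        load_pk_params(raw["romi"], "romi_human"),
    )


def default_rat_pk() -> tuple[EpoRatPK, RomiRatPK]:
    """Synthetic rat PK fixtures bundled for study generation."""
    raw = _bundled("rat_pk_synthetic.yaml")
    return (
        load_pk_params(raw["epo"], "epo_rat"),
        load_pk_params(raw["romi"], "romi_rat"),
    )


def load_regimen_specs(raw: Mapping[str, Any]) -> dict[int, RegimenSpec]:
    defaults = dict(raw.get("defaults", {}))
    out: dict[int, RegimenSpec] = {}
    for rid, entry in raw["regimens"].items():
        merged = {**defaults, **entry}
        try:
            out[int(rid)] = RegimenSpec(**merged)
        except TypeError as exc:
            raise ConfigError(f"bad regimen {rid}: {exc}") from exc
    return out


def default_regimens() -> dict[int, RegimenSpec]:
    """The eight bundled candidate combination regimens."""
    return load_regimen_specs(_bundled("regimens.yaml"))


def load_dose_table(path: str | Path, body_weight: float) -> list[DoseEvent]:
    """Read a delimited dose schedule: time_h, drug, route, dose_per_kg."""
    df = pd.read_csv(path, comment="#")
    required = {"time_h", "drug", "route", "dose_per_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"dose table missing column(s): {sorted(missing)}")
    return [
        DoseEvent(
            time=float(r.time_h),
            drug=str(r.drug),
            route=str(r.route),
            amount_per_kg=float(r.dose_per_kg),
            body_weight=body_weight,
        )
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class RunConfig:
    """Top-level run settings for the command-line entry points."""

    pd_params: PDParameterSet
    pk_epo: EpoHumanPK
    pk_romi: RomiHumanPK
    regimens: dict[int, RegimenSpec]
    seed: int = 0
    threshold: float = 0.35
    replicates: int = 200
    out_dir: str = "results"
    reproducible: bool = True
    config_hash: str = ""


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a run configuration; ``None`` gives the bundled defaults.

    Recognized top-level sections: ``pd`` (symbol-keyed human PD),
    ``pk_epo``/``pk_romi`` (symbol-keyed human PK), ``regimens``
    (``defaults`` + per-id entries) and scalar ``seed``, ``threshold``,
    ``replicates``, ``out_dir``.  Missing sections fall back to the
    bundled tables.
    """
    raw: dict[str, Any] = {}
    digest = "bundled"
    if path is not None:
        text = Path(path).read_text()
        digest = hashlib.sha1(text.encode()).hexdigest()[:12]
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError("config root must be a mapping")
        known = {
            "pd", "pk_epo", "pk_romi", "regimens", "seed", "threshold",
            "replicates", "out_dir",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    pk_epo_d, pk_romi_d = default_human_pk()
    return RunConfig(
        pd_params=(
            load_pd_params(raw["pd"]) if "pd" in raw else default_human_pd()
        ),
        pk_epo=(
            load_pk_params(raw["pk_epo"], "epo_human")
            if "pk_epo" in raw else pk_epo_d
        ),
        pk_romi=(
            load_pk_params(raw["pk_romi"], "romi_human")
            if "pk_romi" in raw else pk_romi_d
        ),
        regimens=(
            load_regimen_specs(raw["regimens"])
            if "regimens" in raw else default_regimens()
        ),
        seed=int(raw.get("seed", 0)),
        threshold=float(raw.get("threshold", 0.35)),
        replicates=int(raw.get("replicates", 200)),
        out_dir=str(raw.get("out_dir", "results")),
        config_hash=digest,
    )


# ---------------------------------------------------------------------------
# export

def _header(seed: int | None, config_hash: str, reproducible: bool) -> str:
    lines = [f"# hemoscale v{_VERSION}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config_hash:
        lines.append(f"# config_hash={config_hash}")
    if not reproducible:
        import datetime

        lines.append(f"# written={datetime.datetime.now().isoformat()}")
    return "\n".join(lines) + "\n"


def _write_csv(df: pd.DataFrame, path: Path, seed, config_hash, reproducible):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed, config_hash, reproducible))
        df.to_csv(fh, index=False, float_format="%.10g")


def export_profile(
    profile: ConcProfile, path: str | Path, *, seed=None,
    config_hash: str = "", reproducible: bool = True,
) -> None:
    df = pd.DataFrame(
        {
            "time_h": profile.time,
            "drug": profile.drug,
            "conc": profile.free_conc,
            "unit": profile.unit,
        }
    )
    _write_csv(df, Path(path), seed, config_hash, reproducible)


def export_trajectory(
    traj, path: str | Path, *, seed=None, config_hash: str = "",
    reproducible: bool = True,
) -> None:
    _write_csv(traj.to_frame(), Path(path), seed, config_hash, reproducible)


def export_verdicts(
    table: pd.DataFrame, path: str | Path, *, seed=None,
    config_hash: str = "", reproducible: bool = True,
) -> None:
    cols = [
        "regimen_id", "first_crossing_day", "peak_hgb", "peak_hgb_day",
        "acceptable",
    ]
    out = table[cols] if all(c in table.columns for c in cols) else table
    _write_csv(out, Path(path), seed, config_hash, reproducible)


def export_bands(
    bands: SimulationBands, path: str | Path, *, seed=None,
    config_hash: str = "", reproducible: bool = True,
) -> None:
    data = {"time_h": bands.time}
    data.update(bands.bands)
    _write_csv(pd.DataFrame(data), Path(path), seed, config_hash, reproducible)


def export_params(params, path: str | Path) -> None:
    """Write any parameter dataclass as YAML, lossless on round trip."""
    payload = {k: v for k, v in asdict(params).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"class": type(params).__name__, "params": payload}, fh,
            sort_keys=False,
        )


def read_params(path: str | Path):
    """Inverse of :func:`export_params`."""
    raw = yaml.safe_load(Path(path).read_text())
    cls_name = raw["class"]
    classes = {
        "PDParameterSet": PDParameterSet,
        "EpoHumanPK": EpoHumanPK,
        "RomiHumanPK": RomiHumanPK,
        "EpoRatPK": EpoRatPK,
        "RomiRatPK": RomiRatPK,
    }
    if cls_name not in classes:
        raise ConfigError(f"unknown parameter class {cls_name!r}")
    return classes[cls_name](**raw["params"])
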