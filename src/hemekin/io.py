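"""Delimited-text readers/writers, structured-text configs, run manifests.

All tabular data are comma-delimited text with a mandatory header;
numbers are serialized with 17 significant digits so write -> read
round-trips are lossless. Configs are YAML mappings validated against
per-kind schemas: defaults applied, invariants checked, unknown keys
rejected (never silently ignored).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import Conditions
from .equilibrium import BindingCurve, MWCParams, TTSParams
from .geminate import EnthalpyDistribution, KineticScheme, SurvivalCurve
from .kramers import KramersParams
from .relaxation import SubstateEnsemble


class ParseError(ValueError):
    """Malformed tabular input; the message names the offending line."""


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


@dataclass
class Trace:
    """Generic (abscissa, ordinate, optional noise-sd) series."""

    x: np.ndarray
    y: np.ndarray
    sd: np.ndarray | None = None
    xlabel: str = "x"
    ylabel: str = "y"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


def read_trace(
    path,
    columns: tuple[str, str] = ("time", "value"),
    require_nonneg_x: bool = True,
    require_monotone_x: bool = True,
) -> Trace:
    """Read a 2- or 3-column delimited trace with header validation.

    The header must begin with the expected column names (an optional
    third ``sd`` column is accepted). Non-numeric cells, negative or
    non-monotone abscissa values raise :class:`ParseError` naming the
    1-based file line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    got = [c.strip() for c in df.columns]
    if len(got) < 2 or tuple(got[:2]) != tuple(columns):
        raise ParseError(
            f"{path}: expected header starting with {','.join(columns)!r}, got {','.join(got)!r}"
        )
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows after the header (empty trace)")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}, line {r + 2}: non-numeric value {df.iat[r, c]!r} in column {got[c]!r}"
        )
    # convert through Python's float() for exact (round-trip) parsing;
    # pandas' fast parser can be off by one ulp
    exact = lambda col: np.array([float(v) for v in col], dtype=float)
    x = exact(df.iloc[:, 0])
    y = exact(df.iloc[:, 1])
    if require_nonneg_x and np.any(x < 0):
        r = int(np.argwhere(x < 0)[0][0])
        raise ParseError(f"{path}, line {r + 2}: negative {columns[0]} value {x[r]}")
    if require_monotone_x and x.size > 1 and np.any(np.diff(x) < 0):
        r = int(np.argwhere(np.diff(x) < 0)[0][0]) + 1
        raise ParseError(f"{path}, line {r + 2}: {columns[0]} values not ascending")
    sd = exact(df.iloc[:, 2]) if num.shape[1] >= 3 else None
    return Trace(x=x, y=y, sd=sd, xlabel=columns[0], ylabel=columns[1])


def write_trace(trace: Trace, path) -> None:
    """Write a trace as CSV with lossless (17 significant digit) floats."""
    cols = {trace.xlabel: trace.x, trace.ylabel: trace.y}
    if trace.sd is not None:
        cols["sd"] = trace.sd
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


# convenience wrappers for the two most common trace flavors -----------------


def read_binding_curve(path) -> BindingCurve:
    tr = read_trace(path, columns=("pressure", "saturation"), require_monotone_x=False)
    return BindingCurve(p=tr.x, y=tr.y, sd=tr.sd)


def write_binding_curve(curve: BindingCurve, path) -> None:
    write_trace(Trace(curve.p, curve.y, curve.sd, "pressure", "saturation"), path)


def read_survival_curve(path, temperature: float | None = None) -> SurvivalCurve:
    tr = read_trace(path, columns=("time", "survival"))
    return SurvivalCurve(t=tr.x, N=tr.y, sd=tr.sd, temperature=temperature)


def write_survival_curve(curve: SurvivalCurve, path) -> None:
    write_trace(Trace(curve.t, curve.N, curve.sd, "time", "survival"), path)


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

# schema: kind -> (required keys, {optional key: default})
_SCHEMAS: dict[str, tuple[set[str], dict]] = {
    "mwc": ({"L", "K_T", "K_R"}, {"n_subunits": 4, "pressure_unit": "torr"}),
    "tts": ({"L", "l_T", "l_R", "K_t", "K_r"}, {"n_subunits": 4, "pressure_unit": "torr"}),
    "enthalpy": (
        {"A"},
        {"H": None, "g": None, "mean": None, "sd": None,
         "h_min": None, "h_max": None, "n_bins": 32},
    ),
    "ensemble": (
        {"mu", "s", "k0", "T"},
        {"e_dagger": None, "n_substates": 64, "span": 5.0},
    ),
    "scheme": ({"states", "rates", "initial"}, {"absorbing": []}),
    "kramers": ({"C", "sigma"}, {"E_0": 0.0, "T": 293.15}),
}


def _validated_mapping(raw: dict, kind: str, path) -> dict:
    required, optional = _SCHEMAS[kind]
    unknown = set(raw) - required - set(optional) - {"model", "kind"}
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)} for kind {kind!r}")
    missing = required - set(raw)
    if missing:
        raise ConfigError(f"{path}: missing required key(s) {sorted(missing)} for kind {kind!r}")
    out = dict(optional)
    out.update({k: v for k, v in raw.items() if k not in ("model", "kind")})
    for k, v in out.items():
        # YAML 1.1 parses "1.0e9" (no sign) as a string; coerce numeric-looking
        # scalars so scientific notation works either way
        if isinstance(v, str) and k != "pressure_unit":
            try:
                out[k] = float(v)
            except ValueError:
                pass
    return out


def load_config(path, kind: str | None = None):
    """Load and validate a YAML config, returning the model object.

    The kind may be given explicitly or as a ``model:``/``kind:`` key in
    the file (one of mwc, tts, enthalpy, ensemble, scheme, kramers).
    Defaults are applied; invariant violations and unknown keys raise
    :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    kind = kind or raw.get("model") or raw.get("kind")
    if kind not in _SCHEMAS:
        raise ConfigError(f"{path}: unknown or missing model kind {kind!r}")
    cfg = _validated_mapping(raw, kind, path)
    try:
        if kind == "mwc":
            return MWCParams(**cfg)
        if kind == "tts":
            return TTSParams(**cfg)
        if kind == "enthalpy":
            if cfg["H"] is not None and cfg["g"] is not None:
                return EnthalpyDistribution(H=np.asarray(cfg["H"], dtype=float),
                                            g=np.asarray(cfg["g"], dtype=float), A=cfg["A"])
            if cfg["mean"] is not None and cfg["sd"] is not None:
                return EnthalpyDistribution.gaussian(
                    cfg["mean"], cfg["sd"], cfg["A"],
                    h_min=cfg["h_min"], h_max=cfg["h_max"], n_bins=cfg["n_bins"],
                )
            raise ConfigError(f"{path}: enthalpy config needs (H, g) or (mean, sd)")
        if kind == "ensemble":
            return SubstateEnsemble(
                mu=cfg["mu"], s=cfg["s"], k0=cfg["k0"], cond=Conditions(T=cfg["T"]),
                e_dagger=cfg["e_dagger"], n_substates=cfg["n_substates"], span=cfg["span"],
            )
        if kind == "scheme":
            rates = {(r["from"], r["to"]): float(r["rate"]) for r in cfg["rates"]}
            return KineticScheme(
                states=list(cfg["states"]), rates=rates,
                initial={k: float(v) for k, v in cfg["initial"].items()},
                absorbing=frozenset(cfg["absorbing"]),
            )
        if kind == "kramers":
            return KramersParams(C=cfg["C"], sigma=cfg["sigma"], E_0=cfg["E_0"],
                                 cond=Conditions(T=cfg["T"]))
    except ConfigError:
        raise
    except (ValueError, TypeError, KeyError) as exc:
        raise ConfigError(f"{path}: invalid {kind!r} config: {exc}") from exc
    raise AssertionError("unreachable")


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance record emitted by every CLI run."""

    command: str
    config_sha256: str | None
    seed: int | None
    version: str
    started: str
    finished: str = ""


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def start_manifest(command: str, config_path=None, seed: int | None = None) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        config_sha256=sha256_of(config_path) if config_path else None,
        seed=seed,
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )


def write_manifest(manifest: RunManifest, path) -> None:
    manifest.finished = datetime.now(timezone.utc).isoformat()
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
        fh.write("\n")
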