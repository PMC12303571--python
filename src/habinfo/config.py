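"""Flat key-value configuration with a JSON mirror for provenance.

Config files are INI-style, one section per concern::

    [model]
    beta = 3.0
    sigma = 0.6

    [protocol]
    H_max = 10
    T_s = 100
    Delta_T = 100
    n_stimuli = 20

    [solver]
    n_quad = 64

Values are coerced to bool/int/float where possible.  Every run echoes its
fully-resolved configuration (defaults included) to ``provenance.json`` next
to its outputs, together with a content hash, so artifacts are traceable.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Dict, Optional

from .params import ModelParams, SignalProtocol, derive_energies

__all__ = [
    "load_config",
    "params_from_config",
    "protocol_from_config",
    "solver_kwargs_from_config",
    "resolved_config",
    "config_hash",
    "write_provenance",
]


def _coerce(v: str) -> Any:
    s = v.strip()
    low = s.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    if low in ("none", "null", ""):
        return None
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        pass
    return s


def load_config(path) -> Dict[str, Dict[str, Any]]:
    """Read an INI config into a nested dict with coerced values."""
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")
    return {sec: {k: _coerce(v) for k, v in cp[sec].items()} for sec in cp.sections()}


def _filtered(cls, section: Dict[str, Any], what: str) -> Dict[str, Any]:
    names = {f.name for f in dataclasses.fields(cls)}
    bad = set(section) - names
    if bad:
        raise ValueError(
            f"unknown {what} config keys: {sorted(bad)}; valid: {sorted(names)}"
        )
    return section


def params_from_config(cfg: Dict[str, Dict[str, Any]], **overrides) -> ModelParams:
    sec = dict(cfg.get("model", {}))
    sec.update({k: v for k, v in overrides.items() if v is not None})
    sec.pop("v", None), sec.pop("c", None)  # derived fields are never read
    sec = {("DeltaE" if k == "deltae" else "N_S" if k == "n_s" else
            "Gamma_S0" if k == "gamma_s0" else "H_ref" if k == "h_ref" else
            "U_mean_passive" if k == "u_mean_passive" else
            "U_mean_active" if k == "u_mean_active" else k): v
           for k, v in sec.items()}
    return derive_energies(ModelParams(**_filtered(ModelParams, sec, "model")))


def protocol_from_config(cfg: Dict[str, Dict[str, Any]], **overrides) -> SignalProtocol:
    sec = dict(cfg.get("protocol", {}))
    sec.update({k: v for k, v in overrides.items() if v is not None})
    sec = {("H_min" if k == "h_min" else "H_max" if k == "h_max" else
            "T_s" if k == "t_s" else "Delta_T" if k == "delta_t" else k): v
           for k, v in sec.items()}
    return SignalProtocol(**_filtered(SignalProtocol, sec, "protocol"))


_SOLVER_KEYS = ("n_quad", "propagator_n", "jump_factor", "u_grid_sigmas")


def solver_kwargs_from_config(cfg: Dict[str, Dict[str, Any]]) -> Dict[str, Any]:
    sec = cfg.get("solver", {})
    bad = set(sec) - set(_SOLVER_KEYS)
    if bad:
        raise ValueError(f"unknown solver config keys: {sorted(bad)}")
    return dict(sec)


def resolved_config(params: ModelParams, protocol: Optional[SignalProtocol] = None,
                    solver_kwargs: Optional[dict] = None, **extra) -> dict:
    """Fully-resolved effective configuration (no silent defaults)."""
    out = {"model": dataclasses.asdict(params)}
    if protocol is not None:
        out["protocol"] = dataclasses.asdict(protocol)
    if solver_kwargs is not None:
        out["solver"] = dict(solver_kwargs)
    out.update(extra)
    return out


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(outdir, cfg: dict, seed: Optional[int] = None) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    doc = {"config": cfg, "config_hash": config_hash(cfg),
           "package_version": __version__, "seed": seed}
    path = outdir / "provenance.json"
    path.write_text(json.dumps(doc, indent=2, default=str))
    return path
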