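"""Tabular file formats, run configuration and provenance.

All tables are tab-delimited text with ``#`` comment lines and a header
row.  Schemas (column name -> type):

* ``decay``      residue, delay_s, intensity, sigma
* ``noe``        residue, i_sat, i_ref, sigma_sat, sigma_ref
* ``cpmg``       residue, field_mhz, nu_cpmg_hz, intensity, replicate
* ``shift``      residue, ph, dH_ppm, dN_ppm, status, peakset
* ``rates``      residue, ph, field_mhz, r1, r1_err, r2, r2_err,
                 noe, noe_err, r2_over_r1, r2_over_r1_err, peak_set
* ``dispersion`` residue, field_mhz, nu_cpmg_hz, r2eff, r2eff_err
* ``modelfree``  residue, model_id, S2, S2_err, tau_e_ps, tau_e_err_ps,
                 Rex, Rex_err, S2f, S2f_err, chi2, status

Writers emit a deterministic column order and fixed decimal formatting,
plus provenance comments (config hash, seed), so identical results give
byte-identical files.
"""

from __future__ import annotations

import hashlib
import io as _io
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SCHEMAS",
    "RunConfig",
    "read_peak_table",
    "write_peak_table",
    "write_report",
]

_F = float
_I = int
_S = str

SCHEMAS: dict[str, dict[str, type]] = {
    "decay": {"residue": _I, "delay_s": _F, "intensity": _F, "sigma": _F},
    "noe": {"residue": _I, "i_sat": _F, "i_ref": _F,
            "sigma_sat": _F, "sigma_ref": _F},
    "cpmg": {"residue": _I, "field_mhz": _F, "nu_cpmg_hz": _F,
             "intensity": _F, "replicate": _I},
    "shift": {"residue": _I, "ph": _F, "dH_ppm": _F, "dN_ppm": _F,
              "status": _S, "peakset": _S},
    "rates": {"residue": _I, "ph": _F, "field_mhz": _F,
              "r1": _F, "r1_err": _F, "r2": _F, "r2_err": _F,
              "noe": _F, "noe_err": _F,
              "r2_over_r1": _F, "r2_over_r1_err": _F, "peak_set": _S},
    "dispersion": {"residue": _I, "field_mhz": _F, "nu_cpmg_hz": _F,
                   "r2eff": _F, "r2eff_err": _F},
    "modelfree": {"residue": _I, "model_id": _S, "S2": _F, "S2_err": _F,
                  "tau_e_ps": _F, "tau_e_err_ps": _F,
                  "Rex": _F, "Rex_err": _F, "S2f": _F, "S2f_err": _F,
                  "chi2": _F, "status": _S},
}

#: key columns whose combination must be unique per schema
_KEYS: dict[str, list[str]] = {
    "decay": ["residue", "delay_s"],
    "noe": ["residue"],
    "cpmg": ["residue", "field_mhz", "nu_cpmg_hz", "replicate"],
    "shift": ["residue", "ph", "peakset"],
    "rates": ["residue", "ph", "field_mhz", "peak_set"],
    "dispersion": ["residue", "field_mhz", "nu_cpmg_hz"],
    "modelfree": ["residue"],
}


class TableFormatError(ValueError):
    """Raised for malformed peak tables (message names the line)."""


def read_peak_table(path, schema_id: str) -> pd.DataFrame:
    """Read and validate a tab-delimited peak table.

    Checks the header against the schema, converts column types,
    rejects malformed rows and duplicate key combinations with the
    offending line number.  An empty data section yields an empty
    (typed) table.
    """
    if schema_id not in SCHEMAS:
        raise TableFormatError(f"unknown schema {schema_id!r}")
    schema = SCHEMAS[schema_id]
    path = Path(path)
    header: list[str] | None = None
    rows, line_nos = [], []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [p.strip() for p in parts]
                if header != list(schema):
                    raise TableFormatError(
                        f"{path}:{lineno}: header {header} does not match "
                        f"schema {schema_id!r} {list(schema)}"
                    )
                continue
            if len(parts) != len(schema):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(schema)} fields, "
                    f"got {len(parts)}"
                )
            row = {}
            for (name, typ), value in zip(schema.items(), parts):
                value = value.strip()
                try:
                    if typ is _S:
                        row[name] = value
                    elif value.lower() in ("nan", "na", ""):
                        row[name] = math.nan
                        if typ is _I:
                            raise ValueError("integer field empty")
                    else:
                        row[name] = typ(value)
                except ValueError as exc:
                    raise TableFormatError(
                        f"{path}:{lineno}: bad value {value!r} for "
                        f"column {name!r} ({exc})"
                    ) from None
            rows.append(row)
            line_nos.append(lineno)
    if header is None:
        raise TableFormatError(f"{path}: no header row found")
    df = pd.DataFrame(rows, columns=list(schema))
    if df.empty:
        return df.astype({k: (v if v is not _S else object)
                          for k, v in schema.items()}, errors="ignore")
    keys = _KEYS[schema_id]
    dup = df.duplicated(subset=keys, keep="first")
    if dup.any():
        first_bad = int(np.nonzero(dup.to_numpy())[0][0])
        raise TableFormatError(
            f"{path}:{line_nos[first_bad]}: duplicate key "
            f"{tuple(df.iloc[first_bad][keys])} for columns {keys}"
        )
    return df


_FMT = {_I: "{:d}", _F: "{:.6f}", _S: "{}"}


def _format_value(v, typ) -> str:
    if typ is _S:
        return str(v)
    if typ is _I:
        return "{:d}".format(int(v))
    x = float(v)
    if math.isnan(x):
        return "nan"
    return "{:.6f}".format(x)


def write_peak_table(
    df: pd.DataFrame, path, schema_id: str,
    comments: list[str] | None = None,
) -> None:
    """Write a table in a declared schema, deterministically.

    Columns are emitted in schema order with fixed decimal formatting;
    ``comments`` become leading ``#`` lines.
    """
    if schema_id not in SCHEMAS:
        raise TableFormatError(f"unknown schema {schema_id!r}")
    schema = SCHEMAS[schema_id]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing columns {missing}")
    buf = _io.StringIO()
    for c in comments or ():
        buf.write(f"# {c}\n")
    buf.write("\t".join(schema) + "\n")
    for _, row in df.iterrows():
        buf.write("\t".join(
            _format_value(row[name], typ) for name, typ in schema.items()
        ) + "\n")
    Path(path).write_text(buf.getvalue())


@dataclass
class RunConfig:
    """Everything a run needs: spin constants, experiment designs,
    fitting options, and the master seed.  Round-trips losslessly
    through YAML."""

    # spin constants
    gamma_ratio: float = -9.8655
    r_nh: float = 1.02
    csa_n: float = -160.0
    fields: list[float] = field(default_factory=lambda: [800.2, 600.13])
    # experiment design
    r1_delays: list[float] = field(default_factory=lambda: [
        0.01, 0.06, 0.14, 0.26, 0.42, 0.62, 0.88, 1.2])
    r2_delays: list[float] = field(default_factory=lambda: [
        0.008, 0.017, 0.034, 0.051, 0.085, 0.119, 0.153, 0.2])
    nu_cpmg: list[float] = field(default_factory=lambda: [
        0, 50, 100, 100, 150, 200, 250, 300, 350, 400, 450, 500, 600, 750])
    t_relax: float = 0.060
    # fitting options
    alpha: float = 0.05
    n_monte_carlo: int = 500
    csp_weight: float = 0.2
    sigma_floor: float = 0.0
    noise: float = 0.02
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise TableFormatError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def spin_system(self, field_1h: float):
        from .spin import SpinSystem

        return SpinSystem(field_1h, self.gamma_ratio, self.r_nh, self.csa_n)

    def cpmg_design(self):
        from .spin import CpmgDesign

        return CpmgDesign(self.t_relax, tuple(float(n) for n in self.nu_cpmg),
                          tuple(self.fields))


def write_report(
    results: pd.DataFrame, path, schema_id: str, config: RunConfig
) -> None:
    """Write a result table with provenance comments (config hash, seed).

    Identical results and config give byte-identical files.
    """
    write_peak_table(
        results, path, schema_id,
        comments=[f"config_hash={config.config_hash}",
                  f"seed={config.seed}"],
    )
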