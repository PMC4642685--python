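"""CSV interchange formats, configuration files and run manifests.

All files are plain CSV with an optional metadata header of ``#``-prefixed
lines (``# key: value``).  Rates may be stored per person-year (default) or
per 100 person-years (``units: per100py`` in the metadata or the ``units``
argument); they are converted to per person-year on read and the declared
unit is restored on write, so round trips are lossless to within one unit
in the last place.

Schemas
-------
rate table       a[, t], rate
cross-section    a, p1, se1, p2, se2[, n]   (se columns may be omitted if n given)
estimates        a, lambda0[, sd_lambda0], lambda1[, sd_lambda1], flags
                 [, log_dr, sd_log_dr]
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from . import __version__
from .core import (ConfigurationError, DomainError, RateSurface,
                   per100_to_rate, rate_to_per100)
from .direct import CrossSection, IncidenceEstimate

_UNITS = ("per_py", "per100py")


def _read_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _write_csv(path, frame: pd.DataFrame, meta: dict):
    meta = {"writer": f"undx {__version__}", **meta}
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)


def _check_units(units):
    if units not in _UNITS:
        raise ConfigurationError(f"units must be one of {_UNITS}, got {units!r}")


def read_rate_table(path, units: str | None = None):
    """Read an age(-time) rate table into a :class:`RateSurface`.

    Columns ``a, rate`` give an age profile (constant in time); columns
    ``a, t, rate`` a rectangular (t, a) table interpolated bilinearly.
    Units are taken from the ``units`` argument, else from the file's
    metadata header, defaulting to per person-year.
    """
    meta = _read_metadata(path)
    units = units or meta.get("units", "per_py")
    _check_units(units)
    df = pd.read_csv(path, comment="#")
    if "a" not in df.columns or "rate" not in df.columns:
        raise ConfigurationError(f"{path}: need columns 'a' and 'rate'")
    bad = df.index[df["rate"] < 0]
    if len(bad):
        raise DomainError(f"{path}: negative rate at data row {bad[0]}")
    rate = df["rate"].to_numpy(dtype=float)
    if units == "per100py":
        rate = per100_to_rate(rate)
    if "t" in df.columns:
        from scipy.interpolate import RegularGridInterpolator

        pivot = df.pivot(index="t", columns="a", values="rate")
        if pivot.isna().any().any():
            raise ConfigurationError(f"{path}: (t, a) table is not rectangular")
        values = pivot.to_numpy(dtype=float)
        if units == "per100py":
            values = per100_to_rate(values)
        interp = RegularGridInterpolator(
            (pivot.index.to_numpy(float), pivot.columns.to_numpy(float)),
            values, bounds_error=False, fill_value=None)

        def fn(t, a, _f=interp):
            pts = np.column_stack([np.ravel(np.asarray(t, float) + 0.0 * np.asarray(a, float)),
                                   np.ravel(np.asarray(a, float) + 0.0 * np.asarray(t, float))])
            out = _f(pts)
            return out.reshape(np.broadcast_shapes(np.shape(t), np.shape(a)))

        return RateSurface(fn=fn, name=str(path))
    ages = df["a"].to_numpy(dtype=float)
    if len(np.unique(ages)) != len(ages):
        dup = ages[pd.Series(ages).duplicated()][0]
        raise ConfigurationError(f"{path}: duplicate age {dup}")
    order = np.argsort(ages)
    return RateSurface.from_age_profile(ages[order], rate[order], name=str(path))


def write_rate_table(path, ages, rates, units: str = "per_py", meta=None):
    _check_units(units)
    values = rate_to_per100(rates) if units == "per100py" else np.asarray(rates, float)
    _write_csv(path, pd.DataFrame({"a": ages, "rate": values}),
               {"units": units, **(meta or {})})


def read_cross_section(path, t: float | None = None) -> CrossSection:
    """Read a survey wave (columns a, p1, se1, p2, se2[, n]).

    The wave time is taken from the ``t`` argument or the metadata header.
    Missing standard-error columns are filled from binomial sampling theory
    when ``n`` is present.
    """
    meta = _read_metadata(path)
    if t is None:
        if "t" not in meta:
            raise ConfigurationError(f"{path}: wave time not given (argument or '# t:')")
        t = float(meta["t"])
    df = pd.read_csv(path, comment="#")
    for col in ("a", "p1", "p2"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing column {col}")
    bad = df.index[df["p1"] + df["p2"] > 1 + 1e-9]
    if len(bad):
        raise DomainError(
            f"{path}: p1 + p2 > 1 at data row {bad[0]} (a={df['a'][bad[0]]})")
    kw = {}
    for col, key in (("se1", "se1"), ("se2", "se2"), ("n", "n")):
        if col in df.columns:
            kw[key] = df[col].to_numpy(dtype=float)
    return CrossSection(t=float(t), ages=df["a"].to_numpy(dtype=float),
                        p1=df["p1"].to_numpy(dtype=float),
                        p2=df["p2"].to_numpy(dtype=float), **kw)


def write_cross_section(path, cs: CrossSection, meta=None):
    _write_csv(path, cs.to_frame(), {"t": cs.t, **(meta or {})})


def read_mortality_table(path):
    """Read mortality vectors (columns a, mu, mu1, mu2, optional se_*).

    Returns a dict of per-age arrays, rates per person-year (or converted
    from a ``units: per100py`` header).
    """
    meta = _read_metadata(path)
    units = meta.get("units", "per_py")
    _check_units(units)
    df = pd.read_csv(path, comment="#")
    for col in ("a", "mu", "mu1", "mu2"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing column {col}")
    out = {"a": df["a"].to_numpy(dtype=float)}
    for col in df.columns:
        if col == "a":
            continue
        vals = df[col].to_numpy(dtype=float)
        out[col] = per100_to_rate(vals) if units == "per100py" else vals
    return out


def write_estimates(path, est: IncidenceEstimate, units: str = "per_py",
                    extra_columns: dict | None = None, meta=None):
    """Write an estimate table with flags and a metadata header."""
    _check_units(units)
    frame = est.to_frame()
    for col in ("lambda0", "lambda1", "sd_lambda0", "sd_lambda1"):
        if col in frame.columns and units == "per100py":
            frame[col] = rate_to_per100(frame[col].to_numpy())
    for key, vals in (extra_columns or {}).items():
        frame[key] = vals
    _write_csv(path, frame, {"t_prime": est.t_prime, "units": units,
                             **(meta or {})})


def write_manifest(path, config: dict):
    """JSON run manifest: inputs, configuration, seed and versions."""
    payload = {"undx_version": __version__, **config}
    pathlib.Path(path).write_text(json.dumps(payload, indent=2, default=str)
                                  + "\n")


def load_config(path) -> dict:
    """Read a YAML or JSON configuration file."""
    text = pathlib.Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
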