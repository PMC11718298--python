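"""Readers and writers for the package's small text formats.

- gallery CSV: RFC-4180 with a header row, one record per row;
- counts CSV: two columns ``set_size,count``, one row per distinct size,
  canonically ordered by ``set_size`` (so write -> read -> write is
  byte-identical);
- curve CSV: columns ``n,kappa`` with an optional ``reps`` column;
- fit JSON: fitted parameters in both units plus diagnostics and a
  provenance block (package version, config hash, seed, units).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .galleries import AnonymitySetCounts, CorrectnessCurve
from .params import InfoParams, PYParams, nats_to_bits

__all__ = [
    "read_gallery_csv",
    "read_counts_csv",
    "write_counts_csv",
    "read_curve_csv",
    "write_curve_csv",
    "fit_to_dict",
    "write_fit_json",
    "read_fit_json",
    "provenance_block",
    "config_hash",
]


class ParseError(ValueError):
    """A malformed input file."""


def config_hash(config: dict) -> str:
    """Short deterministic hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def provenance_block(seed=None, units: str = "nats", config: dict | None = None) -> dict:
    return {
        "package": "reidscale",
        "version": __version__,
        "seed": seed,
        "units": units,
        "config_hash": config_hash(config or {}),
    }


def read_gallery_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype="object", keep_default_na=True)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed CSV: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty gallery file") from exc
    if df.shape[0] == 0:
        raise ParseError(f"{path}: gallery has a header but no records")
    return df.infer_objects()


def read_counts_csv(path) -> AnonymitySetCounts:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: malformed counts CSV: {exc}") from exc
    required = {"set_size", "count"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: counts CSV needs columns {sorted(required)}, found {list(df.columns)}"
        )
    try:
        return AnonymitySetCounts(dict(zip(df["set_size"].astype(int), df["count"].astype(int))))
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: invalid counts: {exc}") from exc


def write_counts_csv(counts: AnonymitySetCounts, path) -> None:
    s, m = counts.size_arrays()
    pd.DataFrame({"set_size": s, "count": m}).to_csv(path, index=False)


def read_curve_csv(path) -> CorrectnessCurve:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: malformed curve CSV: {exc}") from exc
    required = {"n", "kappa"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: curve CSV needs columns {sorted(required)}, found {list(df.columns)}"
        )
    df = df.sort_values("n")
    reps = df["reps"].to_numpy() if "reps" in df.columns else None
    try:
        return CorrectnessCurve(df["n"].to_numpy(float), df["kappa"].to_numpy(float), reps)
    except ValueError as exc:
        raise ParseError(f"{path}: invalid curve: {exc}") from exc


def write_curve_csv(curve: CorrectnessCurve, path) -> None:
    data = {"n": curve.n.astype(np.int64), "kappa": curve.kappa}
    if curve.reps is not None:
        data["reps"] = curve.reps
    pd.DataFrame(data).to_csv(path, index=False)


def fit_to_dict(
    info: InfoParams,
    py: PYParams | None = None,
    loglik: float | None = None,
    converged: bool = True,
    kl_bits: float | None = None,
    seed=None,
    units: str = "bits",
    extra: dict | None = None,
) -> dict:
    """Serializable record of a fitted model, reporting h in both units."""
    out = {
        "h_nats": info.h,
        "h_bits": nats_to_bits(info.h),
        "gamma": info.gamma,
        "d": py.d if py is not None else None,
        "alpha": py.alpha if py is not None else None,
        "loglik": loglik,
        "converged": bool(converged),
        "kl_bits": kl_bits,
        "seed": seed,
        "provenance": provenance_block(seed=seed, units=units, config=extra or {}),
    }
    if extra:
        out.update(extra)
    return out


def write_fit_json(fit: dict, path) -> None:
    Path(path).write_text(json.dumps(fit, indent=2, sort_keys=True, default=float) + "\n")


def read_fit_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed fit JSON: {exc}") from exc
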