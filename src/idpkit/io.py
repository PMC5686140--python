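"""Readers and writers for the toolkit's file formats.

FASTA goes through :mod:`idpkit.sequence`; this module handles 3-column
SAXS ``.dat`` files (q, I, sigma; sigma optional; ``#`` comments), P(r)
tables and structured CSV/JSON reports with stable key ordering.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError
from .saxs import ScatteringCurve, PofR

# q_max above this in an allegedly Å^-1 file suggests nm^-1 data
_NM_HEURISTIC_QMAX = 1.5


def read_saxs_dat(path, units: str = "auto") -> ScatteringCurve:
    """Read a 2- or 3-column scattering curve (q, I[, sigma]).

    ``units`` is ``"A"`` (Å^-1), ``"nm"`` (nm^-1, converted to Å^-1 on
    read) or ``"auto"``: files whose q_max exceeds 1.5 are assumed to be
    in nm^-1 and converted, and the decision is recorded in the curve
    metadata.
    """
    try:
        data = np.loadtxt(str(path), comments="#", ndmin=2)
    except ValueError as err:
        raise InputError(f"cannot parse {path}: {err}") from None
    if data.shape[1] < 2:
        raise InputError(f"{path}: fewer than 2 numeric columns")
    q, intensity = data[:, 0], data[:, 1]
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    if np.any(np.diff(q) <= 0):
        raise InputError(f"{path}: q is not strictly increasing")
    meta = {"path": str(path), "units_in": units}
    if units == "auto":
        units = "nm" if q.max() > _NM_HEURISTIC_QMAX else "A"
        meta["units_detected"] = f"{units}^-1"
    if units == "nm":
        q = q / 10.0
        if sigma is not None:
            sigma = sigma.copy()
        meta["unit_converted"] = "nm^-1 -> A^-1"
    elif units != "A":
        raise InputError(f"unknown unit flag {units!r}; use 'A', 'nm' or 'auto'")
    return ScatteringCurve(q, intensity, sigma, label=str(path), meta=meta)


def write_saxs_dat(curve: ScatteringCurve, path, header: str = "") -> None:
    """Write a curve as whitespace-separated columns (q in Å^-1)."""
    cols = [curve.q, curve.intensity]
    names = "q_A^-1 I"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        names += " sigma"
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# {names}\n")
        np.savetxt(fh, np.column_stack(cols), fmt="%.8e")


def write_pr_table(pr: PofR, path) -> None:
    """Write a P(r) table with its derived parameters in the header."""
    with open(path, "w") as fh:
        fh.write(f"# Dmax_A {pr.dmax:.4f}\n")
        fh.write(f"# Rg_A {pr.rg:.4f}\n")
        fh.write(f"# I0 {pr.i0:.6e}\n")
        fh.write("# r_A P(r)\n")
        np.savetxt(fh, np.column_stack([pr.r, pr.p]), fmt="%.6e")


def _plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def write_report(obj, path=None, fmt: str = "json"):
    """Serialize a report (dict or dataclass) to JSON or a one-row CSV.

    Key order is preserved as given.  Returns the serialized text; also
    writes to ``path`` if provided.
    """
    data = _plain(obj)
    if fmt == "json":
        text = json.dumps(data, indent=2)
    elif fmt == "csv":
        if not isinstance(data, dict):
            raise InputError("csv reports require a flat mapping")
        text = pd.DataFrame([data]).to_csv(index=False)
    else:
        raise InputError(f"unknown report format {fmt!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
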