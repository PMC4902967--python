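"""Tabular I/O helpers: field-data F_IS, de Finetti export, CSV headers.

The field-data helper turns per-locus observed/expected heterozygosity
tables (as reported in population-genetic studies) into per-locus F_IS
values.  The de Finetti export maps biallelic genotype frequencies
``(nu_aa, nu_aA, nu_AA)`` onto the standard equilateral-triangle plane,
together with the Hardy-Weinberg parabola ``nu_aA = 2p(1-p)`` and F_IS
iso-lines, as plottable CSV tables.

All CSV output goes through :func:`write_csv`, which prepends ``#``
header comment lines carrying the tool version, resolved parameters and
seed, and is read back losslessly by :func:`read_csv`.
"""

from __future__ import annotations

import math

from pathlib import Path

import numpy as np
import pandas as pd

from .state_space import ModelParams, StateSpace, as_counts, fis_from_counts

__all__ = [
    "TableFormatError",
    "fis_from_het_table",
    "definetti_export",
    "hwe_parabola",
    "fis_isoline",
    "ternary_xy",
    "write_csv",
    "read_csv",
]

class TableFormatError(ValueError):
    """Malformed tabular input; carries per-row error messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("malformed table:\n" + "\n".join(errors))

def fis_from_het_table(table: "pd.DataFrame | str | Path") -> pd.DataFrame:
    """Per-locus F_IS from a table of observed/expected heterozygosities.

    Expects columns ``Ho`` and ``He`` (case-insensitive; a CSV path is read
    first).  Returns a copy with added columns ``fis`` (``(He - Ho)/He``;
    NaN where undefined) and ``fis_defined`` (False where ``He = 0``).
    Rows with missing or out-of-range values raise
    :class:`TableFormatError` listing the offending line numbers.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, comment="#")
    df = table.copy()
    cols = {c.lower(): c for c in df.columns}
    if "ho" not in cols or "he" not in cols:
        raise TableFormatError(["table must have columns 'Ho' and 'He'"])
    ho_col, he_col = cols["ho"], cols["he"]
    errors = []
    for pos, (idx, row) in enumerate(df.iterrows(), start=2):  # header = line 1
        for col in (ho_col, he_col):
            v = row[col]
            if pd.isna(v):
                errors.append(f"line {pos}: missing {col}")
            elif not isinstance(v, (int, float, np.integer, np.floating)):
                errors.append(f"line {pos}: non-numeric {col} = {v!r}")
            elif not 0.0 <= float(v) <= 1.0:
                errors.append(f"line {pos}: {col} = {v} outside [0, 1]")
    if errors:
        raise TableFormatError(errors)
    ho = df[ho_col].astype(float).to_numpy()
    he = df[he_col].astype(float).to_numpy()
    defined = he > 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = np.where(defined, (he - ho) / np.where(defined, he, 1.0), np.nan)
    df["fis"] = fis
    df["fis_defined"] = defined
    return df

def ternary_xy(nu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Planar projection of (nu_aa, nu_aA, nu_AA) onto the equilateral
    triangle with corners aa=(0,0), AA=(1,0), aA=(1/2, sqrt(3)/2)."""
    nu = np.asarray(nu, dtype=float)
    x = nu[..., 2] + 0.5 * nu[..., 1]
    y = (math.sqrt(3.0) / 2.0) * nu[..., 1]
    return x, y

def hwe_parabola(num: int = 201) -> pd.DataFrame:
    """The Hardy-Weinberg reference curve nu_aA = 2p(1-p), sampled in p."""
    p = np.linspace(0.0, 1.0, num)
    nu = np.stack([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2], axis=1)
    x, y = ternary_xy(nu)
    return pd.DataFrame(
        {"p": p, "nu_aa": nu[:, 0], "nu_aA": nu[:, 1], "nu_AA": nu[:, 2], "x": x, "y": y}
    )

def fis_isoline(fis: float, num: int = 201) -> pd.DataFrame:
    """Curve of constant F_IS: nu_aA = 2p(1-p)(1-fis) over allele frequency p.

    ``fis = 0`` is exactly the Hardy-Weinberg parabola.
    """
    if not -1.0 <= fis <= 1.0:
        raise ValueError(f"fis must lie in [-1, 1], got {fis}")
    p = np.linspace(0.0, 1.0, num)
    het = 2.0 * p * (1.0 - p) * (1.0 - fis)
    nu_aa = np.clip(1.0 - p - het / 2.0, 0.0, 1.0)
    nu_AA = np.clip(p - het / 2.0, 0.0, 1.0)
    nu = np.stack([nu_aa, het, nu_AA], axis=1)
    x, y = ternary_xy(nu)
    return pd.DataFrame(
        {"p": p, "fis": fis, "nu_aa": nu[:, 0], "nu_aA": nu[:, 1], "nu_AA": nu[:, 2], "x": x, "y": y}
    )

def definetti_export(
    source,
    params: ModelParams,
    space: StateSpace | None = None,
) -> pd.DataFrame:
    """Ternary coordinates of states or of a state distribution (n = 2 only).

    ``source`` is a single count vector, an array of count vectors, or a
    probability vector over ``space`` (then a ``weight`` column carries
    the probabilities).  Columns: nu_aa, nu_aA, nu_AA, x, y, fis, weight.
    """
    if params.n != 2:
        raise ValueError("de Finetti export is biallelic-only (n = 2)")
    weights = None
    if space is not None and not isinstance(source, (list, tuple)) and np.ndim(source) == 1 \
            and np.shape(source)[0] == len(space):
        weights = np.asarray(source, dtype=float)
        counts = space.states
    else:
        counts = np.atleast_2d(as_counts(source))
    nu = counts / counts.sum(axis=1, keepdims=True)
    x, y = ternary_xy(nu)
    _, _, _, fis, defined, _, _ = fis_from_counts(counts, params)
    df = pd.DataFrame(
        {
            "nu_aa": nu[:, 0],
            "nu_aA": nu[:, 1],
            "nu_AA": nu[:, 2],
            "x": x,
            "y": y,
            "fis": [float(v) if ok else None for v, ok in zip(np.atleast_1d(fis), np.atleast_1d(defined))],
        }
    )
    df["weight"] = weights if weights is not None else 1.0
    return df

def _header_lines(meta: dict) -> list[str]:
    from . import __version__

    lines = [f"# fisdyn {__version__}"]
    for key, value in meta.items():
        lines.append(f"# {key} = {value}")
    return lines

def write_csv(df: pd.DataFrame, path: "str | Path", meta: dict | None = None) -> None:
    """Write a CSV with ``#`` header comments (version + run metadata).

    Fixed dialect: comma separator, '.' decimal, UTF-8, header row.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for line in _header_lines(meta or {}):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)

def read_csv(path: "str | Path") -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv` (comments skipped)."""
    return pd.read_csv(path, comment="#")
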