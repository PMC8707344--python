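"""Supramolecular chirality of helix-like peptide nanotube coils.

A coil (one helical turn) of a self-assembled peptide nanotube is described
by the ordered sequence of dipole-moment vectors ``D_i`` of its constituent
molecules — here 12 phenylalanine molecules per coil, dipoles in Debye.
The handedness of the supramolecular arrangement is measured the same way
as a Calpha trace, by summing scalar triple products of consecutive
vectors:

    c_total = sum_{i=1..n-2} (D_i x D_{i+1}) . D_{i+2}      [Debye^3]

Note the upper bound n-2: the dipole vectors themselves are the sequence
elements (one per molecule), not difference vectors between points, so a
sequence of n molecules yields n-2 consecutive triples.  Normalizing by the
cube of the mean dipole magnitude D_av gives a dimensionless, scale-free
measure:

    c_norm = c_total / D_av^3.

Positive c_norm is classified D (right-handed), negative L.  The dipole
vectors are inputs — typically produced by a quantum-chemical or
force-field calculation — read here from delimited tables with one row per
molecule in coil order.  Reference tables for one coil of L-phenylalanine
and D-phenylalanine nanotubes (12 molecules each, dipoles from RM1 and
Amber calculations) ship with the package; see :func:`load_reference_table`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .core import Handedness, classify_handedness, mixed_product, DEFAULT_EPSILON
from .errors import InvalidInputError, StructureParseError

__all__ = [
    "DipoleSequence",
    "CoilChiralityResult",
    "dipole_magnitudes",
    "c_total",
    "c_norm",
    "read_dipole_table",
    "load_reference_table",
    "REFERENCE_TABLES",
]

#: Packaged per-molecule dipole tables: one nanotube coil of 12 phenylalanine
#: molecules each, for the L-F and D-F assemblies, with dipoles from a
#: semi-empirical (RM1) and a force-field (Amber) calculation.
REFERENCE_TABLES = (
    "phe_nanotube_LF_rm1",
    "phe_nanotube_LF_amber",
    "phe_nanotube_DF_rm1",
    "phe_nanotube_DF_amber",
)

#: Labels of summary rows recognized in dipole tables and kept as metadata.
_SUMMARY_LABELS = {"dsum", "dcoil", "dav"}

_DEFAULT_COLUMNS = {"index": "i", "dx": "Dx", "dy": "Dy", "dz": "Dz",
                    "magnitude": "D"}


@dataclass(frozen=True)
class DipoleSequence:
    """Ordered per-molecule dipole vectors of one nanotube coil.

    ``dipoles`` is an (n, 3) array in Debye, one row per molecule in coil
    order.  ``printed_magnitudes`` holds the magnitude column of the source
    table when present (for cross-checking against recomputed norms);
    ``summary`` holds any Dsum/Dcoil/Dav rows of the source as metadata —
    they are never part of the sequence.
    """

    dipoles: np.ndarray
    source_label: str = ""
    printed_magnitudes: Optional[np.ndarray] = None
    summary: Dict[str, dict] = field(default_factory=dict)

    def __init__(self, dipoles, source_label="", printed_magnitudes=None,
                 summary=None):  # noqa: D107
        arr = np.asarray(dipoles, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise InvalidInputError(
                f"dipoles must have shape (n, 3), got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("dipole components must be finite")
        arr.setflags(write=False)
        object.__setattr__(self, "dipoles", arr)
        object.__setattr__(self, "source_label", source_label)
        object.__setattr__(
            self,
            "printed_magnitudes",
            None if printed_magnitudes is None
            else np.asarray(printed_magnitudes, dtype=float),
        )
        object.__setattr__(self, "summary", dict(summary or {}))

    def __len__(self) -> int:
        return len(self.dipoles)


@dataclass(frozen=True)
class CoilChiralityResult:
    """Chirality of one coil from its dipole sequence."""

    n: int
    c_total: float  # Debye^3
    d_av: float     # Debye
    c_norm: float   # dimensionless
    sign: str
    symbol: str


def dipole_magnitudes(seq: DipoleSequence) -> np.ndarray:
    """Euclidean norms |D_i| in coil order (Debye)."""
    if len(seq) == 0:
        raise InvalidInputError("empty dipole sequence")
    return np.linalg.norm(seq.dipoles, axis=1)


def c_total(seq: DipoleSequence) -> float:
    """Sum of mixed products over the n - 2 consecutive dipole triples."""
    if len(seq) < 3:
        raise InvalidInputError(
            f"need at least 3 dipoles for a triple product, got {len(seq)}"
        )
    d = seq.dipoles
    return float(np.einsum("ij,ij->i", np.cross(d[:-2], d[1:-1]), d[2:]).sum())


def c_norm(seq: DipoleSequence, epsilon: float = DEFAULT_EPSILON) -> CoilChiralityResult:
    """Normalized coil chirality c_total / D_av^3, with sign classification.

    D_av is the arithmetic mean of the full-precision dipole magnitudes.
    The result is invariant under uniform scaling of all dipoles and under
    any proper rotation; a mirror flips its sign exactly.
    """
    total = c_total(seq)
    d_av = float(dipole_magnitudes(seq).mean())
    if d_av <= 0.0:
        raise InvalidInputError("mean dipole magnitude must be positive")
    norm = total / d_av ** 3
    hand: Handedness = classify_handedness(norm, epsilon)
    return CoilChiralityResult(
        n=len(seq), c_total=total, d_av=d_av, c_norm=norm,
        sign=hand.sign, symbol=hand.symbol,
    )


def _is_summary_label(cell) -> bool:
    return str(cell).strip().lower().lstrip("*") .rstrip("*") in _SUMMARY_LABELS


def read_dipole_table(
    source: Union[str, Path, io.TextIOBase],
    column_map: Optional[Dict[str, str]] = None,
    source_label: str = "",
) -> DipoleSequence:
    """Read an ordered dipole table from delimited text (CSV or TSV).

    The table must carry columns for the molecule index and the Cartesian
    dipole components in Debye; ``column_map`` maps the roles ``index``,
    ``dx``, ``dy``, ``dz`` and optionally ``magnitude`` to the file's
    header names (default: i, Dx, Dy, Dz, D).  Rows appear in coil order.
    Summary rows labelled Dsum, Dcoil or Dav in the index column are parsed
    into :attr:`DipoleSequence.summary` and excluded from the sequence.

    Raises :class:`StructureParseError` for non-numeric component cells
    (with the offending row number) and duplicate molecule indices.
    """
    cols = dict(_DEFAULT_COLUMNS)
    cols.update(column_map or {})
    try:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str,
                         skipinitialspace=True)
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise StructureParseError(f"cannot parse dipole table: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    required = [cols["index"], cols["dx"], cols["dy"], cols["dz"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StructureParseError(
            f"dipole table lacks required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    has_mag = cols.get("magnitude") in df.columns

    dipoles, printed, indices = [], [], []
    summary: Dict[str, dict] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        idx_cell = rec[cols["index"]]
        if _is_summary_label(idx_cell):
            key = str(idx_cell).strip().strip("*").lower()
            summary[key] = {
                role: _maybe_float(rec.get(cols.get(role, ""), None))
                for role in ("dx", "dy", "dz", "magnitude")
            }
            continue
        try:
            idx = int(str(idx_cell).strip())
        except ValueError as exc:
            raise StructureParseError(
                f"row {row_no}: index cell {idx_cell!r} is neither an "
                f"integer nor a recognized summary label"
            ) from exc
        if idx in indices:
            raise StructureParseError(f"row {row_no}: duplicate index {idx}")
        indices.append(idx)
        try:
            vec = [float(rec[cols[ax]]) for ax in ("dx", "dy", "dz")]
        except (TypeError, ValueError) as exc:
            raise StructureParseError(
                f"row {row_no}: non-numeric dipole component"
            ) from exc
        dipoles.append(vec)
        if has_mag:
            printed.append(_maybe_float(rec[cols["magnitude"]]))
    if not dipoles:
        raise StructureParseError("dipole table contains no molecule rows")
    return DipoleSequence(
        dipoles,
        source_label=source_label,
        printed_magnitudes=printed if has_mag else None,
        summary=summary,
    )


def _maybe_float(cell):
    try:
        return float(str(cell).strip())
    except (TypeError, ValueError):
        return float("nan")


def load_reference_table(name: str) -> DipoleSequence:
    """Load one of the packaged phenylalanine-nanotube dipole tables.

    ``name`` is one of :data:`REFERENCE_TABLES`, e.g.
    ``"phe_nanotube_LF_rm1"`` for the L-phenylalanine coil with RM1 dipoles.
    """
    if name not in REFERENCE_TABLES:
        raise InvalidInputError(
            f"unknown reference table {name!r}; choose from {REFERENCE_TABLES}"
        )
    ref = resources.files("chiracal.data").joinpath(f"{name}.csv")
    with ref.open("r") as fh:
        return read_dipole_table(fh, source_label=name)
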