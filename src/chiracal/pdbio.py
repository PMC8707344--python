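"""Reading Calpha chains from PDB/mmCIF files and writing CA-only traces.

Parsing is delegated to gemmi; this module only turns a parsed structure
plus a residue-range selection into the ordered :class:`PointChain` the
chirality measure consumes.  Residue numbers follow author numbering, as
secondary-structure elements are conventionally cited (e.g. "helix,
residues 45-50").

Missing residues inside a requested range are a hard error: a silent gap
changes the difference-vector geometry and hence the chirality value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import gemmi

from .core import PointChain
from .errors import (
    ChainNotFoundError,
    InvalidInputError,
    MissingAtomError,
    MissingResidueError,
    StructureParseError,
)

__all__ = [
    "ResidueRange",
    "read_structure",
    "read_ca_chain",
    "ranges_from_helix_records",
    "write_ca_pdb",
]

logger = logging.getLogger(__name__)

#: Standard PDB helix-class codes -> element type labels.
_HELIX_CLASS_NAMES = {
    gemmi.Helix.HelixClass.RAlpha: "alpha_helix",      # PDB class 1
    gemmi.Helix.HelixClass.R310: "three_ten_helix",    # PDB class 5
    gemmi.Helix.HelixClass.RPi: "pi_helix",            # PDB class 3
}

ELEMENT_TYPES = (
    "alpha_helix",
    "three_ten_helix",
    "pi_helix",
    "alpha_turn",
    "beta_turn",
    "omega_loop",
    "other",
)


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive author-numbered residue range on one chain."""

    chain_id: str
    start: int
    end: int
    start_icode: str = ""
    end_icode: str = ""
    label: str = ""
    element_type: Optional[str] = None

    def __post_init__(self):
        if self.start > self.end:
            raise InvalidInputError(
                f"start {self.start} > end {self.end} in range {self!r}"
            )
        if self.element_type is not None and self.element_type not in ELEMENT_TYPES:
            raise InvalidInputError(
                f"unknown element_type {self.element_type!r}"
            )

    @classmethod
    def parse(cls, text: str, **kwargs) -> "ResidueRange":
        """Parse 'CHAIN:START-END', e.g. 'A:8-13' (inclusive bounds)."""
        try:
            chain, span = text.split(":", 1)
            start_s, end_s = span.split("-", 1)
            return cls(chain_id=chain, start=int(start_s), end=int(end_s), **kwargs)
        except (ValueError, IndexError) as exc:
            raise InvalidInputError(
                f"cannot parse range {text!r}; expected CHAIN:START-END"
            ) from exc

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.start}-{self.end}"


def read_structure(source: Union[str, Path]) -> gemmi.Structure:
    """Read a structure from a path (PDB or mmCIF) or PDB-format text."""
    if isinstance(source, Path) or "\n" not in str(source):
        path = Path(source)
        if not path.exists():
            raise InvalidInputError(f"no such file: {path}")
        try:
            st = gemmi.read_structure(str(path))
        except (RuntimeError, ValueError) as exc:
            raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    else:
        try:
            st = gemmi.read_pdb_string(str(source))
        except (RuntimeError, ValueError) as exc:
            raise StructureParseError(f"cannot parse PDB text: {exc}") from exc
    st.setup_entities()
    return st


def _pick_ca(residue: gemmi.Residue) -> Optional[gemmi.Atom]:
    """One CA per residue: blank altloc, then 'A', else highest occupancy."""
    cas = [a for a in residue if a.name == "CA" and a.element.name == "C"]
    if not cas:
        # fall back on name only (some CA-only trace files omit the element)
        cas = [a for a in residue if a.name == "CA"]
    if not cas:
        return None
    blanks = [a for a in cas if a.altloc in ("\0", "", " ")]
    if blanks:
        return blanks[0]
    for a in cas:
        if a.altloc == "A":
            return a
    return max(cas, key=lambda a: a.occ)


def read_ca_chain(
    source: Union[str, Path, gemmi.Structure],
    residue_range: ResidueRange,
    model: int = 1,
) -> PointChain:
    """Ordered Calpha positions for every residue in an inclusive range.

    Parameters
    ----------
    source
        Path to a PDB/mmCIF file, PDB-format text, or an already parsed
        ``gemmi.Structure``.
    residue_range
        Chain and author-numbered residue span to extract.
    model
        1-based model number (model 1 by default, the convention for
        multi-model NMR entries).

    Raises
    ------
    ChainNotFoundError, MissingResidueError, MissingAtomError
        When the selection cannot be satisfied exactly; a gap is never
        silently bridged.
    """
    st = source if isinstance(source, gemmi.Structure) else read_structure(source)
    if model < 1 or model > len(st):
        raise InvalidInputError(
            f"model {model} not in structure with {len(st)} model(s)"
        )
    chain = st[model - 1].find_chain(residue_range.chain_id)
    if chain is None:
        available = [c.name for c in st[model - 1]]
        raise ChainNotFoundError(
            f"chain {residue_range.chain_id!r} not found; available: {available}"
        )

    points, labels = [], []
    seen_nums = set()
    for residue in chain:
        num = residue.seqid.num
        if residue_range.start <= num <= residue_range.end:
            if num in seen_nums and not residue.seqid.icode.strip():
                continue  # altloc-split residue duplicates; CA policy handles atoms
            ca = _pick_ca(residue)
            if ca is None:
                info = gemmi.find_tabulated_residue(residue.name)
                if info is not None and not info.is_amino_acid():
                    continue  # ligand/water sharing the number range
                raise MissingAtomError(
                    f"residue {residue.name} {residue_range.chain_id}{num}"
                    f"{residue.seqid.icode.strip()} has no CA atom"
                )
            seen_nums.add(num)
            points.append([ca.pos.x, ca.pos.y, ca.pos.z])
            labels.append(
                (
                    residue_range.chain_id,
                    num,
                    residue.seqid.icode.strip(),
                    residue.name,
                )
            )
    expected = set(range(residue_range.start, residue_range.end + 1))
    missing = sorted(expected - seen_nums)
    if missing:
        raise MissingResidueError(
            f"residues missing from range {residue_range}: {missing}"
        )
    return PointChain(points, labels)


def ranges_from_helix_records(
    source: Union[str, Path, gemmi.Structure],
) -> List[ResidueRange]:
    """One :class:`ResidueRange` per HELIX record in the header.

    Helix classes follow the PDB format codes: 1 -> alpha_helix,
    5 -> three_ten_helix, 3 -> pi_helix; anything else -> other.
    Records that cannot be interpreted are skipped with a logged warning.
    """
    st = source if isinstance(source, gemmi.Structure) else read_structure(source)
    ranges = []
    for i, hel in enumerate(st.helices):
        try:
            if hel.start.chain_name != hel.end.chain_name:
                raise ValueError("helix spans two chains")
            ranges.append(
                ResidueRange(
                    chain_id=hel.start.chain_name,
                    start=hel.start.res_id.seqid.num,
                    end=hel.end.res_id.seqid.num,
                    start_icode=(hel.start.res_id.seqid.icode or "").strip(),
                    end_icode=(hel.end.res_id.seqid.icode or "").strip(),
                    label=f"helix_{i + 1}",
                    element_type=_HELIX_CLASS_NAMES.get(hel.pdb_helix_class, "other"),
                )
            )
        except (ValueError, InvalidInputError) as exc:
            logger.warning("skipping malformed HELIX record %d: %s", i + 1, exc)
    return ranges


def write_ca_pdb(chain: PointChain, chain_id: str = "A", resname: str = "GLY") -> str:
    """Serialize a point chain as CA-only PDB ATOM records.

    Residues are numbered 1..n with the given (dummy) residue name, so
    generated ideal helices round-trip through :func:`read_ca_chain`
    at the PDB fixed-format precision of 3 decimals.
    """
    st = gemmi.Structure()
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain_id)
    for i, (x, y, z) in enumerate(chain.coords, start=1):
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(x, y, z)
        atom.occ = 1.0
        res.add_atom(atom)
        gchain.add_residue(res)
    model.add_chain(gchain)
    st.add_model(model)
    return st.make_pdb_string()
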