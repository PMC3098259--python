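"""Structure input/output, van der Waals radius assignment and atom selection.

Structures are stored column-wise (parallel numpy arrays) because every
downstream stage — plane marching, hydrogen-bond scans, pore oracles —
operates on whole coordinate blocks at once.  PDB parsing and writing are
delegated to :mod:`biotite.structure.io.pdb`; this module adds the pieces
that format library does not carry for us: element fallback from atom
names, altloc reduction, per-model time metadata (REMARK 100 lines) for
simulation ensembles, VDW radius assignment and a small selection
language.

Units are Å for lengths and ps for times throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "VdwTable",
    "ParseError",
    "SelectionError",
    "read_pdb",
    "read_ensemble",
    "write_pdb",
    "write_ensemble",
    "assign_vdw",
    "select_atoms",
    "selection_mask",
]

WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL"})

# Bondi (1964) element radii in Å; hydrogen overridden to 1.09 Å, the value
# used for channel clearance work (Bondi's own H is 1.20 Å).
BONDI_RADII = {
    "H": 1.09,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "FE": 2.05,
    "MN": 2.05,
    "SE": 1.90,
}

_TWO_LETTER_ELEMENTS = frozenset(
    {"CL", "BR", "ZN", "MG", "NA", "FE", "MN", "SE", "CA", "NI", "CU", "CO"}
)


class ParseError(ValueError):
    """Raised for malformed structure files; carries the offending line number."""


class SelectionError(ValueError):
    """Raised for syntactically invalid selection expressions."""


@dataclass(frozen=True)
class Atom:
    """A single atom view; see :class:`Structure` for the columnar storage."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    element: str
    position: np.ndarray
    vdw_radius: float | None = None


@dataclass
class Structure:
    """Columnar atom collection for one model.

    ``vdw`` is NaN until :func:`assign_vdw` has been applied.
    """

    serial: np.ndarray
    name: np.ndarray
    residue_name: np.ndarray
    chain: np.ndarray
    residue_number: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    vdw: np.ndarray
    model_id: int = 1
    source: str = ""

    def __post_init__(self) -> None:
        n = len(self.serial)
        if n == 0:
            raise ValueError("a Structure must contain at least one atom")
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        self.vdw = np.asarray(self.vdw, dtype=float).reshape(n)
        assigned = self.vdw[~np.isnan(self.vdw)]
        if assigned.size and (np.any(assigned <= 0) or np.any(assigned > 3.0)):
            raise ValueError("assigned VDW radii must lie in (0, 3.0] Å")

    def __len__(self) -> int:
        return len(self.serial)

    def __iter__(self) -> Iterator[Atom]:
        return (self.atom(i) for i in range(len(self)))

    def atom(self, i: int) -> Atom:
        v = float(self.vdw[i])
        return Atom(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            residue_name=str(self.residue_name[i]),
            chain=str(self.chain[i]),
            residue_number=int(self.residue_number[i]),
            element=str(self.element[i]),
            position=self.coords[i].copy(),
            vdw_radius=None if np.isnan(v) else v,
        )

    def subset(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return Structure(
            serial=self.serial[idx].copy(),
            name=self.name[idx].copy(),
            residue_name=self.residue_name[idx].copy(),
            chain=self.chain[idx].copy(),
            residue_number=self.residue_number[idx].copy(),
            element=self.element[idx].copy(),
            coords=self.coords[idx].copy(),
            vdw=self.vdw[idx].copy(),
            model_id=self.model_id,
            source=self.source,
        )

    def copy(self) -> "Structure":
        return self.subset(np.ones(len(self), dtype=bool))

    @property
    def has_vdw(self) -> bool:
        return not np.any(np.isnan(self.vdw))

    @staticmethod
    def from_atoms(atoms: Sequence[Atom], model_id: int = 1, source: str = "") -> "Structure":
        return Structure(
            serial=np.array([a.serial for a in atoms], dtype=int),
            name=np.array([a.name for a in atoms], dtype=object),
            residue_name=np.array([a.residue_name for a in atoms], dtype=object),
            chain=np.array([a.chain for a in atoms], dtype=object),
            residue_number=np.array([a.residue_number for a in atoms], dtype=int),
            element=np.array([a.element for a in atoms], dtype=object),
            coords=np.array([a.position for a in atoms], dtype=float),
            vdw=np.array(
                [np.nan if a.vdw_radius is None else a.vdw_radius for a in atoms],
                dtype=float,
            ),
            model_id=model_id,
            source=source,
        )


@dataclass
class Ensemble:
    """An ordered series of identically indexed frames (e.g. simulation snapshots)."""

    frames: list[Structure]
    frame_times: np.ndarray  # ps, strictly increasing

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frames) != len(self.frame_times):
            raise ValueError("frame_times length must equal frame count")
        if len(self.frames) == 0:
            raise ValueError("an Ensemble needs at least one frame")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        n0 = len(self.frames[0])
        for k, fr in enumerate(self.frames):
            if len(fr) != n0:
                raise ValueError(
                    f"frame {k + 1} has {len(fr)} atoms, expected {n0}"
                )

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class VdwTable:
    """Van der Waals radii: per-element values plus per-atom-name overrides."""

    elements: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    name_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "H" not in self.elements:
            raise ValueError("VdwTable must contain a hydrogen entry")
        for key, val in {**self.elements, **self.name_overrides}.items():
            if val <= 0:
                raise ValueError(f"VDW radius for {key!r} must be positive")

    def lookup(self, element: str, name: str = "") -> float | None:
        if name and name.upper() in self.name_overrides:
            return self.name_overrides[name.upper()]
        return self.elements.get(element.upper())

    @classmethod
    def default(cls) -> "VdwTable":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VdwTable":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        elements = dict(BONDI_RADII)
        elements.update({str(k).upper(): float(v) for k, v in (data.get("elements") or {}).items()})
        overrides = {str(k).upper(): float(v) for k, v in (data.get("name_overrides") or {}).items()}
        return cls(elements=elements, name_overrides=overrides)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when the element column is blank.

    Follows the usual convention: strip digits/primes, honour two-letter
    elements, and map leading-digit names (e.g. ``1HG1``) to hydrogen.
    """
    name = atom_name.strip().upper()
    if not name:
        return ""
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    letters = re.sub(r"[^A-Z]", "", name)
    if not letters:
        return ""
    if letters[:2] in _TWO_LETTER_ELEMENTS and len(atom_name.strip()) > 2:
        return letters[:2]
    return letters[0]


def _validate_pdb_lines(lines: list[str]) -> None:
    for ln, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise ParseError(
                        f"line {ln}: malformed coordinate field {fieldtxt!r}"
                    ) from None


_TIME_REMARK = re.compile(
    r"^REMARK\s+100\s+FRAME\s+(\d+)\s+TIME_PS\s+([-0-9.eE+]+)"
)


def _scan_time_remarks(lines: Iterable[str]) -> dict[int, float]:
    times: dict[int, float] = {}
    for line in lines:
        m = _TIME_REMARK.match(line)
        if m:
            times[int(m.group(1))] = float(m.group(2))
    return times


def _atom_array_to_structure(array, model_id: int, source: str) -> Structure:
    import biotite.structure as struc

    n = array.array_length()
    if n == 0:
        raise ParseError(f"model {model_id} contains no atoms")
    elements = []
    for el, nm in zip(array.element, array.atom_name):
        el = str(el).strip().upper()
        elements.append(el if el else _infer_element(str(nm)))
    serial = (
        array.get_annotation("atom_id")
        if "atom_id" in array.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    return Structure(
        serial=np.asarray(serial, dtype=int),
        name=np.asarray([str(x) for x in array.atom_name], dtype=object),
        residue_name=np.asarray([str(x) for x in array.res_name], dtype=object),
        chain=np.asarray([str(x) for x in array.chain_id], dtype=object),
        residue_number=np.asarray(array.res_id, dtype=int),
        element=np.asarray(elements, dtype=object),
        coords=np.asarray(array.coord, dtype=float),
        vdw=np.full(n, np.nan),
        model_id=model_id,
        source=source,
    )


def read_pdb(path: str | Path, model: int = 1) -> Structure:
    """Read one model of a PDB file.

    Waters and hetero groups are retained; for alternate locations only the
    first conformer is kept so that downstream geometry sees a single
    conformation.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    pdb = PDBFile.read(str(path))
    _validate_pdb_lines(pdb.lines)
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    array = pdb.get_structure(model=model, altloc="first", extra_fields=["atom_id"])
    return _atom_array_to_structure(array, model_id=model, source=str(path))


def read_ensemble(path: str | Path, stride_ps: float = 10.0) -> Ensemble:
    """Read a multi-model PDB as an ensemble of frames.

    Frame times come from ``REMARK 100 FRAME k TIME_PS t`` header lines when
    present, otherwise they default to ``frame_index * stride_ps``.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    pdb = PDBFile.read(str(path))
    _validate_pdb_lines(pdb.lines)
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ParseError(f"{path}: no models found")
    frames = [
        _atom_array_to_structure(
            pdb.get_structure(model=m, altloc="first", extra_fields=["atom_id"]),
            model_id=m,
            source=str(path),
        )
        for m in range(1, n_models + 1)
    ]
    counts = {len(fr) for fr in frames}
    if len(counts) > 1:
        n0 = len(frames[0])
        bad = [fr.model_id for fr in frames if len(fr) != n0]
        raise ParseError(
            f"{path}: models {bad} differ in atom count from model 1 ({n0} atoms)"
        )
    remark_times = _scan_time_remarks(pdb.lines)
    times = np.array(
        [remark_times.get(m, (m - 1) * stride_ps) for m in range(1, n_models + 1)],
        dtype=float,
    )
    return Ensemble(frames=frames, frame_times=times)


def _structure_to_atom_array(structure: Structure):
    import biotite.structure as struc

    n = len(structure)
    array = struc.AtomArray(n)
    array.coord = structure.coords.astype(np.float32)
    array.chain_id = np.array([c[:4] for c in structure.chain.astype(str)])
    array.res_id = structure.residue_number.astype(int)
    array.res_name = structure.residue_name.astype(str)
    array.atom_name = structure.name.astype(str)
    array.element = structure.element.astype(str)
    array.hetero = np.array(
        [rn in WATER_RESIDUE_NAMES or rn in ("SAH", "SAM") for rn in structure.residue_name],
        dtype=bool,
    )
    array.set_annotation("atom_id", structure.serial.astype(int))
    return array


def write_pdb(structure: Structure, path: str | Path) -> None:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_structure_to_atom_array(structure))
    pdb.write(str(path))


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write a multi-model PDB with per-frame time remarks."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arrays = [_structure_to_atom_array(fr) for fr in ensemble.frames]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    remarks = [
        f"REMARK 100 FRAME {k + 1} TIME_PS {t:.6g}"
        for k, t in enumerate(ensemble.frame_times)
    ]
    pdb.lines = remarks + pdb.lines
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# VDW assignment
# ---------------------------------------------------------------------------

def assign_vdw(structure: Structure, table: VdwTable | None = None) -> Structure:
    """Return a copy of ``structure`` with every atom's VDW radius assigned.

    Name-level overrides win over element entries.  Idempotent: reapplying
    the same table yields the same radii.
    """
    table = table or VdwTable.default()
    out = structure.copy()
    radii = np.empty(len(out), dtype=float)
    for i in range(len(out)):
        r = table.lookup(str(out.element[i]), str(out.name[i]))
        if r is None:
            raise ValueError(
                f"no VDW radius for atom {out.serial[i]} "
                f"({out.name[i]} / element {out.element[i]!r}); "
                "add an element entry or a name override to the table"
            )
        radii[i] = r
    out.vdw = radii
    return out


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------
#
# Grammar:
#   expr     := term ("or" term)*
#   term     := factor ("and" factor)*
#   factor   := "not" factor | "(" expr ")" | predicate
#   predicate:= "all" | "none" | "water" | "protein"
#            |  ("name"|"resname"|"chain"|"element") VALUE+
#            |  "resnum" (INT | INT:INT)+
#
# Multiple values in one predicate are OR-ed ("name CA NZ" matches either).

_TOKEN = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or", "not", "(", ")"}
_PREDICATE_KEYS = {"name", "resname", "chain", "element", "resnum"}
_NULLARY = {"all", "none", "water", "protein"}

_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE MLZ MLY M3L HSD HSE HSP""".split()
)


class _Tokens:
    def __init__(self, text: str):
        self.items: list[tuple[str, int]] = [
            (m.group(0), m.start()) for m in _TOKEN.finditer(text)
        ]
        self.pos = 0
        self.text = text

    def peek(self) -> str | None:
        return self.items[self.pos][0] if self.pos < len(self.items) else None

    def next(self) -> tuple[str, int]:
        if self.pos >= len(self.items):
            raise SelectionError(
                f"unexpected end of selection at position {len(self.text)}"
            )
        tok = self.items[self.pos]
        self.pos += 1
        return tok


def _parse_expr(tokens: _Tokens, structure: Structure) -> np.ndarray:
    mask = _parse_term(tokens, structure)
    while tokens.peek() == "or":
        tokens.next()
        mask = mask | _parse_term(tokens, structure)
    return mask


def _parse_term(tokens: _Tokens, structure: Structure) -> np.ndarray:
    mask = _parse_factor(tokens, structure)
    while tokens.peek() == "and":
        tokens.next()
        mask = mask & _parse_factor(tokens, structure)
    return mask


def _parse_factor(tokens: _Tokens, structure: Structure) -> np.ndarray:
    tok, pos = tokens.next()
    if tok == "not":
        return ~_parse_factor(tokens, structure)
    if tok == "(":
        mask = _parse_expr(tokens, structure)
        closer, cpos = tokens.next()
        if closer != ")":
            raise SelectionError(f"expected ')' at position {cpos}")
        return mask
    if tok == ")":
        raise SelectionError(f"unmatched ')' at position {pos}")
    low = tok.lower()
    n = len(structure)
    if low in _NULLARY:
        if low == "all":
            return np.ones(n, dtype=bool)
        if low == "none":
            return np.zeros(n, dtype=bool)
        resnames = np.char.upper(structure.residue_name.astype(str))
        if low == "water":
            return np.isin(resnames, list(WATER_RESIDUE_NAMES))
        return np.isin(resnames, list(_AMINO_ACIDS))
    if low not in _PREDICATE_KEYS:
        raise SelectionError(f"unknown selection keyword {tok!r} at position {pos}")
    values: list[str] = []
    while True:
        nxt = tokens.peek()
        if nxt is None or nxt.lower() in _KEYWORDS | _PREDICATE_KEYS | _NULLARY or nxt in "()":
            break
        values.append(tokens.next()[0])
    if not values:
        raise SelectionError(f"predicate {tok!r} at position {pos} needs a value")
    if low == "resnum":
        mask = np.zeros(n, dtype=bool)
        for v in values:
            if ":" in v:
                try:
                    lo_s, hi_s = v.split(":")
                    lo_i, hi_i = int(lo_s), int(hi_s)
                except ValueError:
                    raise SelectionError(f"bad residue range {v!r}") from None
                mask |= (structure.residue_number >= lo_i) & (
                    structure.residue_number <= hi_i
                )
            else:
                try:
                    mask |= structure.residue_number == int(v)
                except ValueError:
                    raise SelectionError(f"bad residue number {v!r}") from None
        return mask
    column = {
        "name": structure.name,
        "resname": structure.residue_name,
        "chain": structure.chain,
        "element": structure.element,
    }[low]
    column = np.char.upper(column.astype(str))
    return np.isin(column, [v.upper() for v in values])


def selection_mask(structure: Structure, selector: str) -> np.ndarray:
    """Compile ``selector`` against ``structure`` and return a boolean mask."""
    tokens = _Tokens(selector)
    if tokens.peek() is None:
        raise SelectionError("empty selection expression")
    mask = _parse_expr(tokens, structure)
    if tokens.peek() is not None:
        tok, pos = tokens.next()
        raise SelectionError(f"unexpected token {tok!r} at position {pos}")
    return mask


def select_atoms(structure: Structure, selector: str) -> Structure | None:
    """Return the sub-structure matching ``selector`` (order preserved).

    Returns ``None`` for an empty match, since a Structure cannot be empty.
    """
    mask = selection_mask(structure, selector)
    if not mask.any():
        return None
    return structure.subset(mask)
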