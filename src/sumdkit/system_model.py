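"""Domain types for molecular systems: atoms, topologies, frames, selections.

Unit conventions used throughout the package: coordinates and distances in
Å, time in ps, masses in amu, charges in elementary charge units, energies
in kcal/mol. Atom indices are 0-based and contiguous; residues are keyed by
``(chain_id, residue_index, residue_name)`` because PDB residue numbers
repeat across chains.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "SelectionError",
    "SelectionSyntaxError",
    "ELEMENT_MASSES",
    "center_of_mass",
    "com_distance",
    "select",
]

#: Default atomic masses (amu) used when a parameter sidecar omits them.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845,
}

ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class AtomRecord:
    """One atom with identity, mass and nonbonded parameters.

    ``lj_epsilon`` (kcal/mol) and ``lj_rmin_half`` (Å) are the CHARMM-style
    Lennard-Jones well depth and half-minimum distance.
    """

    atom_index: int
    atom_name: str
    residue_name: str
    residue_index: int
    chain_id: str
    element: str
    mass: float
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 1.0

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"atom {self.atom_index}: mass must be > 0, got {self.mass}")
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.atom_index}: lj_epsilon must be >= 0")
        if not self.lj_rmin_half > 0:
            raise ValueError(f"atom {self.atom_index}: lj_rmin_half must be > 0")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_index, self.residue_name)


class Topology:
    """An ordered atom list plus the residue grouping derived from it."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        atoms = list(atoms)
        for i, a in enumerate(atoms):
            if a.atom_index != i:
                raise ValueError(
                    f"atom indices must be 0-based and contiguous; position {i} "
                    f"holds atom_index {a.atom_index}"
                )
        self.atoms: list[AtomRecord] = atoms
        self.residue_groups: dict[ResidueKey, list[int]] = {}
        for a in atoms:
            self.residue_groups.setdefault(a.residue_key, []).append(a.atom_index)
        self._masses = np.array([a.mass for a in atoms], dtype=float)
        self._charges = np.array([a.charge for a in atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return self._masses

    @property
    def charges(self) -> np.ndarray:
        return self._charges

    def residue_of(self, atom_index: int) -> ResidueKey:
        return self.atoms[atom_index].residue_key


@dataclass
class Frame:
    """One time-stamped coordinate set (Å) with an optional orthorhombic box."""

    time: float
    coordinates: np.ndarray
    box_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.time < 0:
            raise ValueError(f"frame time must be >= 0, got {self.time}")
        if self.box_lengths is not None:
            self.box_lengths = np.asarray(self.box_lengths, dtype=float)
            if self.box_lengths.shape != (3,) or not np.all(self.box_lengths > 0):
                raise ValueError("box_lengths must be three positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


class Trajectory:
    """Ordered frames sharing one topology; times must strictly increase."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("a trajectory needs at least one frame")
        for f in frames:
            if f.n_atoms != topology.n_atoms:
                raise ValueError(
                    f"frame has {f.n_atoms} atoms but topology has {topology.n_atoms}"
                )
        times = [f.time for f in frames]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must strictly increase along a trajectory")
        self.topology = topology
        self.frames: list[Frame] = frames

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


class SelectionError(ValueError):
    """A selection resolved to no atoms or used invalid indices."""


class SelectionSyntaxError(ValueError):
    """A selection expression failed to parse; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Selection:
    """A labelled set of atom indices into one topology."""

    label: str
    atom_indices: frozenset[int]

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise SelectionError(f"selection {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.atom_indices)

    @property
    def sorted_indices(self) -> np.ndarray:
        return np.array(sorted(self.atom_indices), dtype=int)

    def validate(self, topology: Topology) -> None:
        bad = [i for i in self.atom_indices if not 0 <= i < topology.n_atoms]
        if bad:
            raise SelectionError(
                f"selection {self.label!r} has indices outside the topology: {sorted(bad)[:5]}"
            )


# ---------------------------------------------------------------------------
# Mass-weighted geometry
# ---------------------------------------------------------------------------

def center_of_mass(frame: Frame, sel: Selection, topology: Topology) -> np.ndarray:
    """Mass-weighted mean position Σ mᵢxᵢ / Σ mᵢ of the selected atoms (Å)."""
    sel.validate(topology)
    idx = sel.sorted_indices
    masses = topology.masses[idx]
    total = masses.sum()
    if total <= 0:
        raise ValueError(f"selection {sel.label!r} has zero total mass")
    return masses @ frame.coordinates[idx] / total


def com_distance(
    frame: Frame, ligand: Selection, site: Selection, topology: Topology
) -> float:
    """Euclidean distance (Å) between the centers of mass of two selections.

    The selections must be disjoint: an atom contributing to both centers
    would make the supervision metric ambiguous.
    """
    shared = ligand.atom_indices & site.atom_indices
    if shared:
        raise SelectionError(
            f"selections {ligand.label!r} and {site.label!r} overlap on atoms "
            f"{sorted(shared)[:5]}"
        )
    d = center_of_mass(frame, ligand, topology) - center_of_mass(frame, site, topology)
    return float(np.linalg.norm(d))


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------
#
#   expr     := term ("or" term)*
#   term     := factor ("and" factor)*
#   factor   := "not" factor | "(" expr ")" | primitive | "all"
#   primitive:= keyword value+         keyword ∈ {resname, resid, name,
#                                                 chain, element}
#   resid values may be single integers or inclusive ranges "a:b".

_KEYWORDS = {"resname", "resid", "name", "chain", "element"}
_RESERVED = _KEYWORDS | {"and", "or", "not", "all", "(", ")"}

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]


class _Parser:
    def __init__(self, expression: str, topology: Topology):
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.topology = topology
        self.expression = expression

    def _peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        tok = self._peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", len(self.expression))
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionSyntaxError("empty selection expression", 0)
        mask = self._expr()
        tok = self._peek()
        if tok is not None:
            raise SelectionSyntaxError(f"unexpected token {tok[0]!r}", tok[1])
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while (tok := self._peek()) is not None and tok[0] == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while (tok := self._peek()) is not None and tok[0] == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok = self._next()
        word, start = tok
        if word == "not":
            return ~self._factor()
        if word == "(":
            mask = self._expr()
            closing = self._next()
            if closing[0] != ")":
                raise SelectionSyntaxError("expected ')'", closing[1])
            return mask
        if word == "all":
            return np.ones(self.topology.n_atoms, dtype=bool)
        if word in _KEYWORDS:
            return self._primitive(word, start)
        raise SelectionSyntaxError(f"unexpected token {word!r}", start)

    def _values(self, keyword: str, start: int) -> list[str]:
        values = []
        while (tok := self._peek()) is not None and tok[0] not in _RESERVED:
            values.append(self._next()[0])
        if not values:
            raise SelectionSyntaxError(f"keyword {keyword!r} needs at least one value", start)
        return values

    def _primitive(self, keyword: str, start: int) -> np.ndarray:
        values = self._values(keyword, start)
        atoms = self.topology.atoms
        if keyword == "resid":
            wanted: set[int] = set()
            for v in values:
                if ":" in v:
                    lo, _, hi = v.partition(":")
                    try:
                        wanted.update(range(int(lo), int(hi) + 1))
                    except ValueError:
                        raise SelectionSyntaxError(f"bad resid range {v!r}", start) from None
                else:
                    try:
                        wanted.add(int(v))
                    except ValueError:
                        raise SelectionSyntaxError(f"bad resid value {v!r}", start) from None
            return np.array([a.residue_index in wanted for a in atoms])
        getters = {
            "resname": lambda a: a.residue_name,
            "name": lambda a: a.atom_name,
            "chain": lambda a: a.chain_id,
            "element": lambda a: a.element.upper(),
        }
        get = getters[keyword]
        vals = {v.upper() for v in values} if keyword == "element" else set(values)
        return np.array([get(a) in vals for a in atoms])


def select(topology: Topology, expression: str, label: str | None = None) -> Selection:
    """Resolve a selection-grammar expression against a topology.

    Deterministic: the same expression on the same topology always yields
    the same atom set. Raises :class:`SelectionSyntaxError` on malformed
    input and :class:`SelectionError` if no atom matches.
    """
    mask = _Parser(expression, topology).parse()
    indices = frozenset(int(i) for i in np.flatnonzero(mask))
    if not indices:
        raise SelectionError(f"selection {expression!r} matches no atoms")
    return Selection(label=label if label is not None else expression, atom_indices=indices)
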