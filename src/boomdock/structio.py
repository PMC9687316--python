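"""Structure I/O, per-residue confidence tracks and confident-fragment extraction.

Predicted structures arrive as PDB files whose B-factor column carries the
per-residue confidence score (pLDDT, 0-100).  This module reads single- and
multi-model PDB text into light domain objects, recovers the confidence
track, and extracts the high-confidence fragments that are used downstream as
docking receptors and ligands.  Waters and other hetero records are dropped
at parse time, matching how the docking preprocessing treats its inputs.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb


class ParseError(ValueError):
    """Raised for malformed or inconsistent structure input."""


#: Standard three-letter to one-letter amino-acid codes.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "SOL"}


@dataclass
class Atom:
    """A single atom with coordinates in Angstrom.

    ``bscore`` is whatever the B-factor column carried -- for predicted
    models this is the per-residue confidence value.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bscore: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} has non-finite or misshapen coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial} has an empty element symbol")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def one_letter(self) -> str:
        """One-letter code, or 'X' for a non-standard residue."""
        return THREE_TO_ONE.get(self.name3.upper(), "X")

    @property
    def is_standard(self) -> bool:
        return self.name3.upper() in THREE_TO_ONE

    def coord_array(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)


@dataclass
class Structure:
    """An ordered collection of chains of residues."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    title: str = ""

    def __post_init__(self):
        seen: set[tuple[str, int, str]] = set()
        for res in self.residues:
            if res.key in seen:
                raise ValueError(f"duplicate residue {res.key} in structure {self.id!r}")
            seen.add(res.key)
            if not res.atoms:
                raise ValueError(f"residue {res.key} has no atoms")

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for res in self.residues:
            if res.chain_id not in out:
                out.append(res.chain_id)
        return out

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def subset_chains(self, chain_ids) -> "Structure":
        chain_ids = set(chain_ids)
        residues = [r for r in self.residues if r.chain_id in chain_ids]
        if not residues:
            raise ValueError(f"no residues in chains {sorted(chain_ids)}")
        return Structure(id=self.id, residues=residues, title=self.title)

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain_id, number, icode):
                return r
        raise KeyError(f"residue {(chain_id, number, icode)} not in structure {self.id!r}")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def iter_atoms(self):
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    def coords(self) -> np.ndarray:
        """All atom coordinates in file order, shape (n_atoms, 3)."""
        return np.array([a.coords for _, a in self.iter_atoms()], dtype=float).reshape(-1, 3)

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of this structure with every atom's coordinates replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape ({self.n_atoms}, 3)")
        residues: list[Residue] = []
        i = 0
        for res in self.residues:
            atoms = []
            for a in res.atoms:
                atoms.append(Atom(a.serial, a.name, a.element, coords[i].copy(),
                                  a.occupancy, a.bscore))
                i += 1
            residues.append(Residue(res.chain_id, res.number, res.icode, res.name3, atoms))
        return Structure(id=id or self.id, residues=residues, title=self.title)

    def sequence(self, chain_id: str | None = None) -> str:
        residues = self.residues if chain_id is None else self.chain(chain_id)
        return "".join(r.one_letter for r in residues)


@dataclass
class ConfidenceTrack:
    """Per-residue confidence in [0, 100], keyed by (chain_id, residue number)."""

    scores: dict[tuple[str, int], float]
    chain_order: list[str]

    def __post_init__(self):
        for key, score in self.scores.items():
            if not (0.0 <= score <= 100.0):
                raise ValueError(f"confidence {score} for residue {key} outside [0, 100]")

    def chain_numbers(self, chain_id: str) -> list[int]:
        return sorted(n for (c, n) in self.scores if c == chain_id)

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self.scores[key]

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class FragmentSpec:
    """A fragment as an ordered list of inclusive residue-number intervals."""

    fragment_id: str
    chain_id: str
    runs: list[tuple[int, int]]

    def __post_init__(self):
        runs = [(int(s), int(e)) for s, e in self.runs]
        for s, e in runs:
            if s > e:
                raise ValueError(f"fragment {self.fragment_id}: run ({s}, {e}) has start > end")
        for (_, e0), (s1, _) in zip(runs, runs[1:]):
            if s1 <= e0:
                raise ValueError(f"fragment {self.fragment_id}: runs overlap or are unsorted")
        self.runs = runs

    @property
    def n_residues(self) -> int:
        return sum(e - s + 1 for s, e in self.runs)

    def to_json(self) -> str:
        return json.dumps({"fragment_id": self.fragment_id, "chain": self.chain_id,
                           "runs": [list(r) for r in self.runs]})

    @classmethod
    def from_json(cls, text: str) -> "FragmentSpec":
        obj = json.loads(text)
        return cls(obj["fragment_id"], obj["chain"], [tuple(r) for r in obj["runs"]])


@dataclass
class PoseEnsemble:
    """M conformations of one complex sharing a single atom topology."""

    complex_id: str
    topology: Structure
    frames: np.ndarray  # (M, n_atoms, 3), Angstrom

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (M, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")

    @property
    def count(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i],
                                         id=f"{self.complex_id}[{i}]")


# ---------------------------------------------------------------------------
# Parsing

def _validate_atom_lines(pdb_text: str) -> list[int]:
    """Cheap sanity scan; returns per-MODEL ATOM/HETATM record counts.

    A file without MODEL records yields a single count.  Raises ParseError
    naming the first malformed ATOM line.
    """
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    n_atom_lines = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            n_atom_lines += 1
            if len(line) < 54:
                raise ParseError(f"malformed {rec} record on line {lineno}: too short")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise ParseError(f"malformed {rec} record on line {lineno}: {exc}") from exc
            current += 1
    if saw_model and in_model:
        counts.append(current)  # unterminated final MODEL
    if not saw_model:
        counts = [current]
    if n_atom_lines == 0:
        raise ParseError("input contains no ATOM records")
    return counts


def _atoms_to_structure(arr: bst.AtomArray, structure_id: str) -> Structure:
    mask = ~arr.hetero & ~np.isin(arr.res_name, list(_WATER_NAMES))
    arr = arr[mask]
    if arr.array_length() == 0:
        raise ParseError("no polymer ATOM records after removing waters and hetero atoms")
    residues: list[Residue] = []
    current: Residue | None = None
    for i in range(arr.array_length()):
        key = (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.ins_code[i]).strip())
        if current is None or current.key != key:
            current = Residue(key[0], key[1], key[2], str(arr.res_name[i]))
            residues.append(current)
        current.atoms.append(Atom(
            serial=int(arr.atom_id[i]) if "atom_id" in arr.get_annotation_categories() else i + 1,
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]) or str(arr.atom_name[i])[0],
            coords=np.array(arr.coord[i], dtype=float),
            occupancy=float(arr.occupancy[i]) if "occupancy" in arr.get_annotation_categories() else 1.0,
            bscore=float(arr.b_factor[i]) if "b_factor" in arr.get_annotation_categories() else 0.0,
        ))
    return Structure(id=structure_id, residues=residues)


_EXTRA_FIELDS = ["b_factor", "occupancy", "atom_id"]


def read_structure(pdb_text: str, structure_id: str = "structure") -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Waters and HETATM records are excluded; the B-factor column is preserved
    per atom as ``bscore``; the highest-occupancy altloc is kept (first
    encountered on a tie).
    """
    if not pdb_text.strip():
        raise ParseError("empty input")
    _validate_atom_lines(pdb_text)
    pdb = bpdb.PDBFile.read(io.StringIO(pdb_text))
    arr = pdb.get_structure(model=1, altloc="occupancy", extra_fields=_EXTRA_FIELDS)
    return _atoms_to_structure(arr, structure_id)


def read_ensemble(pdb_text: str, complex_id: str = "ensemble") -> PoseEnsemble:
    """Parse multi-model PDB text into a :class:`PoseEnsemble`.

    All MODEL blocks must share the same atom count and ordering; a mismatch
    is reported with the offending model number.
    """
    if not pdb_text.strip():
        raise ParseError("empty input")
    counts = _validate_atom_lines(pdb_text)
    for model_no, count in enumerate(counts, start=1):
        if count != counts[0]:
            raise ParseError(
                f"model {model_no} has {count} atoms, expected {counts[0]} as in model 1")
    pdb = bpdb.PDBFile.read(io.StringIO(pdb_text))
    stack = pdb.get_structure(model=None, altloc="occupancy", extra_fields=_EXTRA_FIELDS)
    first = stack[0] if isinstance(stack, bst.AtomArrayStack) else stack
    mask = ~first.hetero & ~np.isin(first.res_name, list(_WATER_NAMES))
    topology = _atoms_to_structure(first, complex_id)
    coords = stack.coord if isinstance(stack, bst.AtomArrayStack) else stack.coord[np.newaxis]
    frames = coords[:, mask, :] if coords.ndim == 3 else coords[np.newaxis, mask, :]
    return PoseEnsemble(complex_id=complex_id, topology=topology, frames=frames)


def write_structure(structure: Structure) -> str:
    """Serialize a :class:`Structure` back to PDB text."""
    arr = _structure_to_atom_array(structure)
    pdb = bpdb.PDBFile()
    pdb.set_structure(arr)
    return "\n".join(pdb.lines) + "\n"


def write_ensemble(ensemble: PoseEnsemble) -> str:
    """Serialize a :class:`PoseEnsemble` to multi-model PDB text."""
    arr = _structure_to_atom_array(ensemble.topology)
    stack = bst.from_template(arr, ensemble.frames)
    pdb = bpdb.PDBFile()
    pdb.set_structure(stack)
    return "\n".join(pdb.lines) + "\n"


def _structure_to_atom_array(structure: Structure) -> bst.AtomArray:
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.add_annotation("occupancy", dtype=float)
    arr.add_annotation("b_factor", dtype=float)
    arr.add_annotation("atom_id", dtype=int)
    i = 0
    for res, atom in structure.iter_atoms():
        arr.chain_id[i] = res.chain_id
        arr.res_id[i] = res.number
        arr.ins_code[i] = res.icode
        arr.res_name[i] = res.name3
        arr.hetero[i] = False
        arr.atom_name[i] = atom.name
        arr.element[i] = atom.element
        arr.coord[i] = atom.coords
        arr.occupancy[i] = atom.occupancy
        arr.b_factor[i] = atom.bscore
        arr.atom_id[i] = atom.serial
        i += 1
    return arr


# ---------------------------------------------------------------------------
# Confidence tracks and fragments

def confidence_track(structure: Structure) -> ConfidenceTrack:
    """Per-residue confidence = mean of the residue's atom B-factor values.

    Predicted models write the same per-residue value on every atom, in
    which case the mean is exact; for mixed inputs it is a robust summary.
    """
    scores = {
        (res.chain_id, res.number): float(np.mean([a.bscore for a in res.atoms]))
        for res in structure.residues
    }
    return ConfidenceTrack(scores=scores, chain_order=structure.chain_ids)


def extract_confident_fragments(
    track: ConfidenceTrack,
    threshold: float = 90.0,
    merge_gap: int = 15,
    inclusive: bool = False,
) -> list[FragmentSpec]:
    """Find high-confidence fragments of a confidence track.

    Maximal runs of consecutive residues with score above ``threshold``
    (strictly above by default; ``inclusive=True`` uses >=) are located per
    chain; runs separated by at most ``merge_gap`` low-confidence residues
    are grouped into one multi-run fragment, a larger gap starts a new
    fragment.  Fragments are ordered by chain and first residue.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    passes = (lambda s: s >= threshold) if inclusive else (lambda s: s > threshold)
    fragments: list[FragmentSpec] = []
    for chain_id in track.chain_order:
        numbers = track.chain_numbers(chain_id)
        # maximal runs of consecutive numbering with passing score
        runs: list[tuple[int, int]] = []
        start = prev = None
        for n in numbers:
            ok = passes(track[(chain_id, n)])
            if ok and start is not None and n == prev + 1:
                prev = n
            elif ok:
                if start is not None:
                    runs.append((start, prev))
                start = prev = n
            else:
                if start is not None:
                    runs.append((start, prev))
                start = prev = None
        if start is not None:
            runs.append((start, prev))
        # group runs separated by <= merge_gap missing/low residues
        groups: list[list[tuple[int, int]]] = []
        for run in runs:
            if groups and run[0] - groups[-1][-1][1] - 1 <= merge_gap:
                groups[-1].append(run)
            else:
                groups.append([run])
        for k, group in enumerate(groups, start=1):
            fragments.append(FragmentSpec(
                fragment_id=f"{chain_id}_frag{k}", chain_id=chain_id, runs=group))
    return fragments


def carve_fragment(structure: Structure, spec: FragmentSpec) -> Structure:
    """Extract exactly the residues in ``spec.runs`` (coordinates unchanged)."""
    chain = {r.number: r for r in structure.chain(spec.chain_id)}
    residues: list[Residue] = []
    for start, end in spec.runs:
        for n in range(start, end + 1):
            if n not in chain:
                raise KeyError(
                    f"fragment {spec.fragment_id}: interval ({start}, {end}) references "
                    f"residue {n} absent from chain {spec.chain_id!r}")
            residues.append(chain[n])
    return Structure(id=f"{structure.id}:{spec.fragment_id}", residues=residues,
                     title=structure.title)
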