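"""Trajectory metrics for peptide-complex evaluation: RMSD with independent
fit/measure selections, per-residue RMSF, hydrogen bonds and hydrophobic
contacts.

RMSD conventions follow the usual complex analysis: each frame is least-
squares fitted to the reference over the *fit* selection only (e.g. the
receptor protein), and the deviation is measured over the *measure*
selection (e.g. all peptide atoms) — so fitting on the protein while
measuring the peptide deliberately retains the peptide's translational
motion.  Consumed models carry no hydrogens, so the hydrogen-bond test is
distance-only between donor/acceptor heavy atoms taken from per-residue
templates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .geometry import kabsch
from .structio import Atom, Residue, Structure

A_PER_NM = 10.0

AtomPredicate = Callable[[Residue, Atom], bool]

#: Main-chain heavy-atom names; everything else is side chain.
MAIN_CHAIN = {"N", "CA", "C", "O", "OXT"}

#: Heavy atoms that bear a polar hydrogen, per residue type (plus the
#: backbone amide N for every residue except proline).
DONOR_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}

#: Lone-pair acceptors per residue type (plus backbone O/OXT everywhere).
ACCEPTOR_ATOMS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"}, "CYS": {"SG"},
}


def select_all(res: Residue, atom: Atom) -> bool:
    return True


def select_chains(chain_ids) -> AtomPredicate:
    chain_ids = set(chain_ids)
    return lambda res, atom: res.chain_id in chain_ids


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology."""

    topology: Structure
    frames: np.ndarray  # (M, n_atoms, 3), Angstrom
    frame_interval_ps: float = 2.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (M, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps

    def atom_mask(self, selection: AtomPredicate | None) -> np.ndarray:
        if selection is None:
            return np.ones(self.topology.n_atoms, dtype=bool)
        mask = np.array([selection(res, atom)
                         for res, atom in self.topology.iter_atoms()], dtype=bool)
        if not mask.any():
            raise ValueError("atom selection is empty")
        return mask


@dataclass
class RMSDSeries:
    times_ps: np.ndarray
    values_nm: np.ndarray
    fit_selection: str = "all"
    measure_selection: str = "all"


@dataclass
class RMSFProfile:
    values_nm: dict[tuple[str, int], float]


@dataclass
class HBond:
    donor_residue: tuple[str, int]
    donor_atom: str
    acceptor_residue: tuple[str, int]
    acceptor_atom: str
    distance: float


@dataclass
class HydrophobicContact:
    receptor_residue: tuple[str, int]
    receptor_atom: str
    receptor_chain_part: str  # "main" or "side"
    ligand_residue: tuple[str, int]
    ligand_atom: str
    ligand_chain_part: str
    distance: float


def rmsd_series(traj: Trajectory, reference: int | np.ndarray = 0,
                fit_selection: AtomPredicate | None = None,
                measure_selection: AtomPredicate | None = None,
                fit_label: str = "all", measure_label: str = "all") -> RMSDSeries:
    """Per-frame RMSD (nm) after fitting each frame on the reference over
    ``fit_selection`` and measuring over ``measure_selection``."""
    fit_mask = traj.atom_mask(fit_selection)
    measure_mask = traj.atom_mask(measure_selection)
    ref = traj.frames[reference] if isinstance(reference, (int, np.integer)) \
        else np.asarray(reference, dtype=float)
    if ref.shape != (traj.topology.n_atoms, 3):
        raise ValueError("reference must cover the full topology")
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        rot, trans = kabsch(traj.frames[i][fit_mask], ref[fit_mask])
        moved = traj.frames[i][measure_mask] @ rot.T + trans
        diff = moved - ref[measure_mask]
        values[i] = np.sqrt(np.mean(np.sum(diff ** 2, axis=1))) / A_PER_NM
    return RMSDSeries(times_ps=traj.times(), values_nm=values,
                      fit_selection=fit_label, measure_selection=measure_label)


def rmsf_profile(traj: Trajectory, fit_selection: AtomPredicate | None = None,
                 n_fit_passes: int = 2) -> RMSFProfile:
    """Per-residue RMSF (nm) about the time-average structure.

    Frames are iteratively superposed on their running time-average over the
    fit selection (two passes by default); RMSF of a residue is the root
    mean square displacement over all its atoms and all frames.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for RMSF")
    fit_mask = traj.atom_mask(fit_selection)
    coords = traj.frames.copy()
    mean = coords[0]
    for _ in range(n_fit_passes):
        for i in range(coords.shape[0]):
            rot, trans = kabsch(coords[i][fit_mask], mean[fit_mask])
            coords[i] = coords[i] @ rot.T + trans
        mean = coords.mean(axis=0)
    sq = np.sum((coords - mean) ** 2, axis=2)  # (M, n_atoms)
    values: dict[tuple[str, int], float] = {}
    i = 0
    for res in traj.topology.residues:
        n = len(res.atoms)
        values[(res.chain_id, res.number)] = float(
            np.sqrt(np.mean(sq[:, i:i + n]))) / A_PER_NM
        i += n
    return RMSFProfile(values_nm=values)


def _polar_atoms(residue: Residue, role: str) -> list[Atom]:
    if role == "donor":
        names = set(DONOR_ATOMS.get(residue.name3.upper(), set()))
        if residue.name3.upper() != "PRO":
            names.add("N")
    else:
        names = set(ACCEPTOR_ATOMS.get(residue.name3.upper(), set())) | {"O", "OXT"}
    return [a for a in residue.atoms
            if a.name in names and a.element.upper() in ("N", "O", "S")]


def hydrogen_bonds(complexed: Structure, receptor_chains, ligand_chains,
                   d_max: float = 3.5) -> list[HBond]:
    """Cross-chain donor-acceptor heavy-atom pairs within ``d_max`` Å.

    Distance-only criterion over template donors/acceptors (no angle test:
    the consumed models have no hydrogens).
    """
    receptor_chains, ligand_chains = set(receptor_chains), set(ligand_chains)
    if receptor_chains & ligand_chains:
        raise ValueError("chain sets overlap")
    rec = [r for r in complexed.residues if r.chain_id in receptor_chains]
    lig = [r for r in complexed.residues if r.chain_id in ligand_chains]
    bonds: list[HBond] = []
    for donors, acceptors in ((rec, lig), (lig, rec)):
        for rd in donors:
            for atom_d in _polar_atoms(rd, "donor"):
                for ra in acceptors:
                    for atom_a in _polar_atoms(ra, "acceptor"):
                        d = float(np.linalg.norm(atom_d.coords - atom_a.coords))
                        if d <= d_max:
                            bonds.append(HBond(
                                donor_residue=(rd.chain_id, rd.number),
                                donor_atom=atom_d.name,
                                acceptor_residue=(ra.chain_id, ra.number),
                                acceptor_atom=atom_a.name, distance=d))
    return bonds


def hydrophobic_contacts(complexed: Structure, receptor_chains, ligand_chains,
                         d_max: float = 4.0, permissive: bool = False,
                         scheme=None) -> list[HydrophobicContact]:
    """Cross-chain hydrophobic atom contacts within ``d_max`` Å.

    Default: carbon-carbon heavy-atom pairs.  ``permissive=True`` counts any
    heavy-atom pair between two apolar-classified residues (LigPlot-style;
    requires a residue class ``scheme``).  Each atom is annotated as
    main-chain (N, CA, C, O, OXT) or side-chain.
    """
    receptor_chains, ligand_chains = set(receptor_chains), set(ligand_chains)
    if receptor_chains & ligand_chains:
        raise ValueError("chain sets overlap")
    if permissive and scheme is None:
        from .interface import ResidueClassScheme
        scheme = ResidueClassScheme.default()
    rec = [r for r in complexed.residues if r.chain_id in receptor_chains]
    lig = [r for r in complexed.residues if r.chain_id in ligand_chains]

    def eligible(res: Residue, atom: Atom) -> bool:
        if not atom.is_heavy:
            return False
        if permissive:
            return scheme.of(res.one_letter) == "apolar"
        return atom.element.upper() == "C"

    lig_atoms = [(res, a) for res in lig for a in res.atoms if eligible(res, a)]
    if not lig_atoms:
        return []
    tree = cKDTree(np.array([a.coords for _, a in lig_atoms]))
    contacts: list[HydrophobicContact] = []
    for res in rec:
        for atom in res.atoms:
            if not eligible(res, atom):
                continue
            for j in tree.query_ball_point(atom.coords, d_max):
                lres, latom = lig_atoms[j]
                d = float(np.linalg.norm(atom.coords - latom.coords))
                contacts.append(HydrophobicContact(
                    receptor_residue=(res.chain_id, res.number),
                    receptor_atom=atom.name,
                    receptor_chain_part="main" if atom.name in MAIN_CHAIN else "side",
                    ligand_residue=(lres.chain_id, lres.number),
                    ligand_atom=latom.name,
                    ligand_chain_part="main" if latom.name in MAIN_CHAIN else "side",
                    distance=d))
    return contacts
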