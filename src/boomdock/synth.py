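"""Synthetic input generators with stored ground truth.

Every input class the pipeline consumes can be generated offline with a
known answer: confidence tracks with planted high-confidence segments,
two-chain complexes with a geometrically controlled interface, docked-pose
ensembles with planted cluster structure, trajectories with controlled
per-residue jitter, and ideal-geometry peptide chains.  All randomness comes
from one seeded generator per call, so a fixed seed reproduces outputs
bit-identically.

Toy chains are built from ideal amino-acid geometry (internal coordinates),
not fetched structures.  In :func:`make_toy_complex` the two "chains" are
rows of ideal alanine residues at controlled separations rather than a
single docked conformation — an idealized arrangement that makes the true
contact set exact by construction (and verified by a brute-force scan).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import fitted_rmsd
from .structio import (Atom, ConfidenceTrack, ONE_TO_THREE, PoseEnsemble, Residue,
                       Structure, confidence_track)
from .trajectory import Trajectory

# Ideal backbone internal coordinates (lengths Å, angles degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
OMEGA = 180.0

#: Backbone dihedrals (phi, psi) per conformation name.
CONFORMATIONS = {"extended": (-120.0, 120.0), "helical": (-57.0, -47.0)}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors (natural extension reference
    frame): |cd| = bond, angle(b,c,d), torsion(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(torsion),
        np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_peptide_chain(sequence: str, conformation: str = "extended",
                       chain_id: str = "A", start_number: int = 1,
                       bscore: float = 0.0) -> Structure:
    """Ideal-geometry heavy-atom peptide (N, CA, C, O and CB except glycine).

    ``conformation`` picks backbone dihedrals: "extended" (phi/psi
    -120/+120) or "helical" (-57/-47).
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for code in sequence:
        if code not in ONE_TO_THREE:
            raise ValueError(f"unknown one-letter code {code!r}")
    if conformation not in CONFORMATIONS:
        raise ValueError(f"unknown conformation {conformation!r}")
    phi, psi = CONFORMATIONS[conformation]

    # backbone N, CA, C positions by chained NeRF placement
    backbone: list[np.ndarray] = [
        np.array([0.0, 0.0, 0.0]),
        np.array([BOND_N_CA, 0.0, 0.0]),
    ]
    backbone.append(_nerf(np.array([0.0, 1.0, 0.0]), backbone[0], backbone[1],
                          BOND_CA_C, ANGLE_N_CA_C, 180.0))
    for _ in range(1, len(sequence)):
        n_i = _nerf(backbone[-3], backbone[-2], backbone[-1],
                    BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = _nerf(backbone[-2], backbone[-1], n_i,
                     BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _nerf(backbone[-1], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.extend([n_i, ca_i, c_i])

    residues: list[Residue] = []
    serial = 1
    for i, code in enumerate(sequence):
        n, ca, c = backbone[3 * i], backbone[3 * i + 1], backbone[3 * i + 2]
        atoms = [Atom(serial, "N", "N", n, 1.0, bscore),
                 Atom(serial + 1, "CA", "C", ca, 1.0, bscore),
                 Atom(serial + 2, "C", "C", c, 1.0, bscore)]
        serial += 3
        # carbonyl O anti to the next amide nitrogen
        o = _nerf(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        atoms.append(Atom(serial, "O", "O", o, 1.0, bscore))
        serial += 1
        if code != "G":
            cb = _nerf(c, n, ca, BOND_CA_CB, ANGLE_N_CA_CB, 122.6)
            atoms.append(Atom(serial, "CB", "C", cb, 1.0, bscore))
            serial += 1
        residues.append(Residue(chain_id, start_number + i, "", ONE_TO_THREE[code], atoms))
    return Structure(id=f"peptide_{sequence[:8]}", residues=residues)


# ---------------------------------------------------------------------------
# Confidence tracks

def make_confidence_track(n_residues: int, segments: list[tuple[int, int]],
                          seed: int = 0, start_number: int = 1,
                          chain_id: str = "A"):
    """Poly-alanine chain whose B-factors plant a confidence track.

    Scores are > 90 exactly on the planted segments (inclusive residue-number
    intervals) and <= 90 elsewhere.  Returns ``(structure, track, truth)``
    where truth is the sorted segment list.
    """
    rng = np.random.default_rng(seed)
    segments = sorted((int(s), int(e)) for s, e in segments)
    end_number = start_number + n_residues - 1
    for (s, e) in segments:
        if s > e or s < start_number or e > end_number:
            raise ValueError(f"segment ({s}, {e}) outside chain numbering "
                             f"[{start_number}, {end_number}]")
    for (_, e0), (s1, _) in zip(segments, segments[1:]):
        if s1 <= e0:
            raise ValueError("segments overlap")
    planted = {n for s, e in segments for n in range(s, e + 1)}
    structure = make_peptide_chain("A" * n_residues, "extended",
                                   chain_id=chain_id, start_number=start_number)
    residues = []
    for res in structure.residues:
        score = rng.uniform(90.5, 99.5) if res.number in planted else rng.uniform(50.0, 90.0)
        atoms = [Atom(a.serial, a.name, a.element, a.coords, a.occupancy, float(score))
                 for a in res.atoms]
        residues.append(Residue(res.chain_id, res.number, res.icode, res.name3, atoms))
    structure = Structure(id="confidence_chain", residues=residues)
    return structure, confidence_track(structure), segments


# ---------------------------------------------------------------------------
# Toy complexes

def _single_alanine(chain_id: str, number: int) -> Residue:
    return make_peptide_chain("A", chain_id=chain_id, start_number=number).residues[0]


def _transformed_residue(res: Residue, rot: np.ndarray, trans: np.ndarray,
                         serial0: int) -> Residue:
    atoms = [Atom(serial0 + k, a.name, a.element, rot @ a.coords + trans,
                  a.occupancy, a.bscore) for k, a in enumerate(res.atoms)]
    return Residue(res.chain_id, res.number, res.icode, res.name3, atoms)


def make_toy_complex(n_receptor: int, n_ligand: int,
                     contact_pairs: list[tuple[int, int]],
                     target_distance: float = 4.5,
                     clearance: float = 6.5,
                     spacing: float = 12.0,
                     far_offset: float = 30.0,
                     seed: int = 0):
    """Two-chain complex in which exactly the requested residue pairs touch.

    Chains R (receptor) and L (ligand) are rows of ideal alanine residues
    ``spacing`` Å apart.  For each requested (receptor_number,
    ligand_number) pair the ligand residue is placed opposite its partner so
    their minimal heavy-atom distance equals ``target_distance``; every other
    cross-chain residue pair is kept beyond ``clearance`` (so neither the
    5.5 Å contact rule nor surface burial can see it).  The construction is
    verified by a brute-force distance scan.  Returns ``(structure, truth)``
    with truth the sorted requested pair list.
    """
    if target_distance < 2.5:
        raise ValueError("target distance must be >= 2.5 A (no clashes)")
    if target_distance > 5.5:
        raise ValueError("target distance must be <= 5.5 A to create a contact")
    pairs = sorted((int(i), int(j)) for i, j in contact_pairs)
    rec_used = [i for i, _ in pairs]
    lig_used = [j for _, j in pairs]
    if len(set(rec_used)) != len(rec_used) or len(set(lig_used)) != len(lig_used):
        raise ValueError("contact pairs must use distinct residues on each side")
    for i, j in pairs:
        if not (1 <= i <= n_receptor and 1 <= j <= n_ligand):
            raise ValueError(f"contact pair ({i}, {j}) outside chain lengths")

    template = _single_alanine("R", 1)
    identity = np.eye(3)
    flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()

    residues: list[Residue] = []
    serial = 1
    rec_positions: dict[int, Residue] = {}
    for i in range(1, n_receptor + 1):
        res = _transformed_residue(
            Residue("R", i, "", "ALA", template.atoms), identity,
            np.array([spacing * (i - 1), 0.0, 0.0]), serial)
        serial += len(res.atoms)
        residues.append(res)
        rec_positions[i] = res

    contact_of = {j: i for i, j in pairs}
    lig_residues: list[Residue] = []
    for j in range(1, n_ligand + 1):
        if j in contact_of:
            i = contact_of[j]
            # face the partner: flip the template so the side chains meet
            trans = np.array([spacing * (i - 1), target_distance + 6.0, 0.0])
            res = _transformed_residue(Residue("L", j, "", "ALA", template.atoms),
                                       flip, trans, serial)
            # slide along -y (bisection) until the minimal heavy-atom
            # distance equals the target exactly
            partner = rec_positions[i].coord_array(heavy_only=True)
            own = res.coord_array(heavy_only=True)

            def min_dist(t):
                shifted = own - np.array([0.0, t, 0.0])
                return np.min(np.linalg.norm(
                    shifted[:, None, :] - partner[None, :, :], axis=2))

            lo, hi = 0.0, float(trans[1])
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if min_dist(mid) > target_distance:
                    lo = mid
                else:
                    hi = mid
            res = _transformed_residue(res, identity, np.array([0.0, -hi, 0.0]), serial)
        else:
            trans = np.array([spacing * (j - 1), far_offset, 0.0])
            res = _transformed_residue(Residue("L", j, "", "ALA", template.atoms),
                                       flip, trans, serial)
        serial += len(res.atoms)
        lig_residues.append(res)
    residues.extend(lig_residues)
    structure = Structure(id="toy_complex", residues=residues)

    # brute-force verification of the planted truth
    found: list[tuple[int, int]] = []
    for r in structure.chain("R"):
        rc = r.coord_array(heavy_only=True)
        for l in structure.chain("L"):
            lc = l.coord_array(heavy_only=True)
            d = np.min(np.linalg.norm(rc[:, None, :] - lc[None, :, :], axis=2))
            if d <= 5.5:
                found.append((r.number, l.number))
            elif d <= clearance and (r.number, l.number) not in pairs:
                raise ValueError(
                    f"infeasible placement: pair ({r.number}, {l.number}) at {d:.2f} A "
                    f"violates the {clearance} A clearance")
            if d < 2.0:
                raise ValueError(f"clash between residues ({r.number}, {l.number})")
    if sorted(found) != pairs:
        raise ValueError(f"infeasible placement: planted {pairs}, realised {sorted(found)}")
    return structure, pairs


# ---------------------------------------------------------------------------
# Pose ensembles

def make_pose_ensemble(sizes: list[int], spread_nm: float = 0.05,
                       separation_nm: float = 1.0, n_residues: int = 20,
                       seed: int = 0):
    """Pose ensemble with planted cluster structure.

    Cluster centers are random internal deformations of an extended
    reference chain (rigid transforms would vanish under superposition),
    mutually at least ``separation_nm`` apart in fitted RMSD
    (``separation_nm`` must be >= 4x the spread); members perturb their
    center by Gaussian noise scaled to an RMSD at most ``spread_nm``.
    Returns ``(ensemble, truth)`` where truth is a list of frozensets of
    pose indices, one per planted cluster.
    """
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be positive")
    if spread_nm < 0:
        raise ValueError("spread must be >= 0")
    if separation_nm < 4 * spread_nm:
        raise ValueError("separation must be at least 4x the spread")
    rng = np.random.default_rng(seed)
    topology = make_peptide_chain("A" * n_residues, "extended", chain_id="A")
    ref = topology.coords()

    centers: list[np.ndarray] = [ref]
    deform_scale = 2.0 * separation_nm * 10.0  # Å, raw RMSD of the deformation
    for _ in range(1, len(sizes)):
        for _attempt in range(200):
            noise = rng.standard_normal(ref.shape)
            noise *= deform_scale / np.sqrt(np.mean(np.sum(noise ** 2, axis=1)))
            cand = ref + noise
            if all(fitted_rmsd(cand, c) / 10.0 >= separation_nm for c in centers):
                centers.append(cand)
                break
        else:
            raise ValueError("infeasible geometry: could not separate cluster centers")

    n_total = sum(sizes)
    order = rng.permutation(n_total)
    frames = np.empty((n_total, ref.shape[0], 3))
    truth: list[set[int]] = []
    k = 0
    for center, size in zip(centers, sizes):
        members = set()
        for m in range(size):
            idx = int(order[k]); k += 1
            if m == 0:
                frames[idx] = center
            else:
                noise = rng.standard_normal(ref.shape)
                target = rng.uniform(0.2, 0.9) * spread_nm * 10.0  # Å
                norm = np.sqrt(np.mean(np.sum(noise ** 2, axis=1)))
                frames[idx] = center + (noise * (target / norm) if norm > 0 else 0.0)
            members.add(idx)
        truth.append(frozenset(members))
    ensemble = PoseEnsemble(complex_id="planted_ensemble", topology=topology,
                            frames=frames)
    return ensemble, truth


# ---------------------------------------------------------------------------
# Trajectories

def make_trajectory(n_frames: int, sigma_nm, structure: Structure | None = None,
                    n_residues: int = 5, drift: tuple[str, np.ndarray] | None = None,
                    frame_interval_ps: float = 2.0, seed: int = 0):
    """Trajectory of a reference structure with per-residue Gaussian jitter.

    ``sigma_nm`` is a scalar or a mapping ``(chain_id, number) -> nm`` giving
    the per-coordinate standard deviation of each residue's jitter.
    ``drift`` optionally rigidly displaces one chain by a constant vector
    (Å) in every frame after the first.  Returns ``(trajectory, truth)``
    where truth maps residue keys to their planted sigma (nm).
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    topology = structure or make_peptide_chain("A" * n_residues, "extended", chain_id="A")
    keys = [(r.chain_id, r.number) for r in topology.residues]
    if np.isscalar(sigma_nm):
        sigma = {key: float(sigma_nm) for key in keys}
    else:
        sigma = {key: float(sigma_nm.get(key, 0.0)) for key in keys}
    if any(s < 0 for s in sigma.values()):
        raise ValueError("sigma must be >= 0")
    per_atom_sigma = np.concatenate(
        [np.full(len(r.atoms), sigma[(r.chain_id, r.number)] * 10.0)
         for r in topology.residues])
    ref = topology.coords()
    frames = ref[None, :, :] + rng.standard_normal((n_frames, ref.shape[0], 3)) \
        * per_atom_sigma[None, :, None]
    if drift is not None:
        chain_id, vector = drift
        mask = np.array([r.chain_id == chain_id for r, _ in topology.iter_atoms()])
        if not mask.any():
            raise ValueError(f"drift chain {chain_id!r} not in topology")
        frames[1:, mask, :] += np.asarray(vector, dtype=float)
    traj = Trajectory(topology=topology, frames=frames,
                      frame_interval_ps=frame_interval_ps)
    return traj, sigma
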