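"""Interface analysis: SASA, ΔSASA interface residues, classified interfacial
contacts and a contact-based binding-affinity model with Kd conversion.

The interface of a docked complex is characterised two ways.  Geometrically,
a residue is interfacial when it buries surface on binding: ΔSASA =
SASA(own chain set alone) − SASA(complex) > 0.  Energetically, interfacial
contacts (cross-chain residue pairs with any heavy-atom distance ≤ 5.5 Å)
are counted per polarity class pair and fed, together with the composition
of the non-interacting surface (NIS), into a published linear model for the
binding free energy ΔG (kcal/mol), converted to a dissociation constant via
ΔG = RT·ln Kd at 298.15 K.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .geometry import sphere_points
from .structio import Structure

#: Gas constant in kcal · mol⁻¹ · K⁻¹.
GAS_CONSTANT = 1.9872e-3

_CLASS_PAIR_KEYS = ("cc", "cp", "ca", "pp", "pa", "aa")


def _load_data(name: str) -> dict:
    with resources.files("boomdock.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass
class RadiusSet:
    """Van der Waals radii per element plus the solvent probe radius (Å)."""

    radii: dict[str, float]
    probe: float = 1.4

    def __post_init__(self):
        if self.probe <= 0 or any(r <= 0 for r in self.radii.values()):
            raise ValueError("radii and probe must be positive")
        self.radii = {k.upper(): float(v) for k, v in self.radii.items()}

    @classmethod
    def default(cls) -> "RadiusSet":
        cfg = _load_data("vdw_radii.json")
        return cls(radii=cfg["radii"], probe=cfg["probe"])

    def radius(self, element: str, atom_label: str = "") -> float:
        try:
            return self.radii[element.upper()]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for element {element!r}"
                + (f" (atom {atom_label})" if atom_label else "")) from None


@dataclass
class SASAResult:
    """Solvent-accessible areas in Å²: per atom (file order) and per residue."""

    atom_areas: np.ndarray
    residue_areas: dict[tuple[str, int], float]

    def total(self) -> float:
        return float(self.atom_areas.sum())


@dataclass
class DeltaSASAProfile:
    """Per-residue buried area (unbound − bound, Å²) and the interface set."""

    delta: dict[tuple[str, int], float]
    interface: set[tuple[str, int]]


@dataclass
class ResidueClassScheme:
    """Total polarity classification of the 20 standard residues."""

    classes: dict[str, str]  # one-letter -> {"polar", "apolar", "charged"}

    def __post_init__(self):
        valid = {"polar", "apolar", "charged"}
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.classes)
        if missing:
            raise ValueError(f"classification missing residues: {sorted(missing)}")
        bad = set(self.classes.values()) - valid
        if bad:
            raise ValueError(f"unknown residue classes: {sorted(bad)}")

    @classmethod
    def default(cls) -> "ResidueClassScheme":
        cfg = _load_data("affinity_model.json")["classes"]
        return cls(classes={aa: cl for cl, aas in cfg.items() for aa in aas})

    def of(self, one_letter: str) -> str:
        try:
            return self.classes[one_letter.upper()]
        except KeyError:
            raise KeyError(f"no polarity class for residue code {one_letter!r}") from None


def class_pair_key(class_a: str, class_b: str) -> str:
    """Unordered class-pair key: cc, cp, ca, pp, pa or aa."""
    letters = "".join(sorted(c[0] for c in (class_a, class_b)))
    key = {"cc": "cc", "cp": "cp", "ac": "ca", "pp": "pp", "ap": "pa", "aa": "aa"}[letters]
    return key


@dataclass
class ContactTable:
    """Interfacial contact counts per class pair plus the raw pair list."""

    counts: dict[str, int]
    pairs: list[tuple[tuple[str, int], tuple[str, int], float]]  # (receptor, ligand, min dist Å)
    threshold: float

    def __post_init__(self):
        for key in _CLASS_PAIR_KEYS:
            self.counts.setdefault(key, 0)
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("contact counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def polar_polar(self, fold_charged: bool = False) -> int:
        """The "Polar: Polar" column; ``fold_charged=True`` folds charged
        residues into polar (pp + cp + cc)."""
        if fold_charged:
            return self.counts["pp"] + self.counts["cp"] + self.counts["cc"]
        return self.counts["pp"]

    def apolar_apolar(self) -> int:
        return self.counts["aa"]


@dataclass
class AffinityModel:
    """Linear ΔG model over contact class counts and NIS percentages."""

    contact_weights: dict[str, float]
    nis_weights: dict[str, float]
    intercept: float
    temperature: float = 298.15

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @classmethod
    def default(cls) -> "AffinityModel":
        cfg = _load_data("affinity_model.json")
        return cls(contact_weights=dict(cfg["contact_weights"]),
                   nis_weights=dict(cfg["nis_weights"]),
                   intercept=float(cfg["intercept"]),
                   temperature=float(cfg["temperature_K"]))


@dataclass
class InterfaceReport:
    complex_id: str
    profile: DeltaSASAProfile
    contacts: ContactTable
    dg: float
    kd: float
    temperature: float
    nis: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)

def sasa(structure: Structure, radii: RadiusSet | None = None,
         n_points: int = 960) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area.

    For each atom, a deterministic near-uniform grid of ``n_points`` points
    is placed on the sphere of radius r_vdw + probe; the accessible area is
    the fraction of points not inside any neighbour's expanded sphere times
    the full sphere area.
    """
    radii = radii or RadiusSet.default()
    atoms = list(structure.iter_atoms())
    centers = np.array([a.coords for _, a in atoms], dtype=float).reshape(-1, 3)
    expanded = np.array(
        [radii.radius(a.element, f"{res.chain_id}/{res.number}/{a.name}") + radii.probe
         for res, a in atoms])
    unit = sphere_points(n_points)
    tree = cKDTree(centers)
    r_max = expanded.max()
    atom_areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = centers[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(centers[i], expanded[i] + r_max)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(centers[j] - centers[i])
            if d >= expanded[i] + expanded[j]:
                continue
            blocked = np.einsum("ij,ij->i", pts - centers[j], pts - centers[j]) \
                < expanded[j] ** 2
            accessible &= ~blocked
            if not accessible.any():
                break
        atom_areas[i] = accessible.sum() / n_points * 4.0 * np.pi * expanded[i] ** 2
    residue_areas: dict[tuple[str, int], float] = {}
    for (res, _), area in zip(atoms, atom_areas):
        key = (res.chain_id, res.number)
        residue_areas[key] = residue_areas.get(key, 0.0) + float(area)
    return SASAResult(atom_areas=atom_areas, residue_areas=residue_areas)


def _check_chain_sets(structure: Structure, receptor_chains, ligand_chains):
    receptor_chains, ligand_chains = set(receptor_chains), set(ligand_chains)
    if not receptor_chains or not ligand_chains:
        raise ValueError("both chain sets must be non-empty")
    if receptor_chains & ligand_chains:
        raise ValueError(f"chain sets overlap: {sorted(receptor_chains & ligand_chains)}")
    present = set(structure.chain_ids)
    uncovered = present - receptor_chains - ligand_chains
    if uncovered:
        raise ValueError(f"chains {sorted(uncovered)} assigned to neither side")
    return receptor_chains, ligand_chains


def delta_sasa(complexed: Structure, receptor_chains, ligand_chains,
               radii: RadiusSet | None = None, n_points: int = 960,
               eps: float = 1e-6) -> DeltaSASAProfile:
    """Per-residue ΔSASA = SASA(own side alone) − SASA(complex), same
    coordinates; the interface set is every residue with ΔSASA > 0."""
    receptor_chains, ligand_chains = _check_chain_sets(complexed, receptor_chains, ligand_chains)
    radii = radii or RadiusSet.default()
    bound = sasa(complexed, radii, n_points).residue_areas
    delta: dict[tuple[str, int], float] = {}
    for side in (receptor_chains, ligand_chains):
        unbound = sasa(complexed.subset_chains(side), radii, n_points).residue_areas
        for key, area in unbound.items():
            delta[key] = area - bound[key]
    interface = {key for key, d in delta.items() if d > eps}
    return DeltaSASAProfile(delta=delta, interface=interface)


# ---------------------------------------------------------------------------
# Contacts and affinity

def interfacial_contacts(complexed: Structure, receptor_chains, ligand_chains,
                         scheme: ResidueClassScheme | None = None,
                         threshold: float = 5.5) -> ContactTable:
    """Cross-chain residue pairs with any heavy-atom distance ≤ ``threshold``,
    counted once per residue pair and classified by the polarity classes of
    the two residues."""
    receptor_chains, ligand_chains = _check_chain_sets(complexed, receptor_chains, ligand_chains)
    scheme = scheme or ResidueClassScheme.default()
    rec = [r for r in complexed.residues if r.chain_id in receptor_chains]
    lig = [r for r in complexed.residues if r.chain_id in ligand_chains]
    counts = {k: 0 for k in _CLASS_PAIR_KEYS}
    pairs: list[tuple[tuple[str, int], tuple[str, int], float]] = []
    lig_coords = [l.coord_array(heavy_only=True) for l in lig]
    lig_trees = [cKDTree(c) if len(c) else None for c in lig_coords]
    for r in rec:
        rc = r.coord_array(heavy_only=True)
        if not len(rc):
            continue
        for l, tree in zip(lig, lig_trees):
            if tree is None:
                continue
            d = tree.query(rc, k=1)[0].min()
            if d <= threshold:
                counts[class_pair_key(scheme.of(r.one_letter), scheme.of(l.one_letter))] += 1
                pairs.append(((r.chain_id, r.number), (l.chain_id, l.number), float(d)))
    return ContactTable(counts=counts, pairs=pairs, threshold=threshold)


def nis_percentages(complexed: Structure, radii: RadiusSet | None = None,
                    scheme: ResidueClassScheme | None = None,
                    rel_threshold: float | None = None,
                    n_points: int = 960) -> dict[str, float]:
    """Composition of the non-interacting surface of the complex.

    Residues whose relative SASA in the complex is at least ``rel_threshold``
    (relative to the residue-type maximum accessible area) count as surface;
    the returned percentages are the apolar and charged shares of that set.
    """
    cfg = _load_data("affinity_model.json")
    scheme = scheme or ResidueClassScheme.default()
    if rel_threshold is None:
        rel_threshold = float(cfg["nis_rel_sasa_threshold"])
    max_asa = cfg["max_asa"]
    areas = sasa(complexed, radii, n_points).residue_areas
    surface: list[str] = []
    for res in complexed.residues:
        ref = max_asa.get(res.one_letter)
        if ref is None:
            continue
        if areas[(res.chain_id, res.number)] / ref >= rel_threshold:
            surface.append(scheme.of(res.one_letter))
    if not surface:
        return {"apolar": 0.0, "charged": 0.0}
    return {
        "apolar": 100.0 * sum(c == "apolar" for c in surface) / len(surface),
        "charged": 100.0 * sum(c == "charged" for c in surface) / len(surface),
    }


def binding_affinity(table: ContactTable, nis: dict[str, float] | None,
                     model: AffinityModel) -> float:
    """ΔG (kcal/mol) from the linear contact/NIS model."""
    dg = model.intercept
    for key, count in table.counts.items():
        if key not in model.contact_weights:
            raise KeyError(f"affinity model has no weight for contact class {key!r}")
        dg += model.contact_weights[key] * count
    for key, value in (nis or {}).items():
        if key not in model.nis_weights:
            raise KeyError(f"affinity model has no weight for NIS term {key!r}")
        dg += model.nis_weights[key] * value
    return float(dg)


def kd_from_dg(dg: float, temperature: float = 298.15) -> float:
    """Dissociation constant (M) from ΔG via ΔG = RT·ln Kd."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(dg / (GAS_CONSTANT * temperature))


def dg_from_kd(kd: float, temperature: float = 298.15) -> float:
    """Inverse conversion, ΔG = RT·ln Kd (kcal/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return GAS_CONSTANT * temperature * math.log(kd)


def analyze_interface(complexed: Structure, receptor_chains, ligand_chains,
                      radii: RadiusSet | None = None,
                      scheme: ResidueClassScheme | None = None,
                      model: AffinityModel | None = None,
                      contact_threshold: float = 5.5,
                      n_points: int = 960) -> InterfaceReport:
    """Full interface report: ΔSASA profile, contact table, ΔG and Kd."""
    radii = radii or RadiusSet.default()
    scheme = scheme or ResidueClassScheme.default()
    model = model or AffinityModel.default()
    profile = delta_sasa(complexed, receptor_chains, ligand_chains, radii, n_points)
    contacts = interfacial_contacts(complexed, receptor_chains, ligand_chains,
                                    scheme, contact_threshold)
    nis = nis_percentages(complexed, radii, scheme, n_points=n_points)
    dg = binding_affinity(contacts, nis, model)
    kd = kd_from_dg(dg, model.temperature)
    return InterfaceReport(complex_id=complexed.id, profile=profile, contacts=contacts,
                           dg=dg, kd=kd, temperature=model.temperature, nis=nis)


def report_json(report: InterfaceReport) -> dict:
    """JSON-ready interface report, including both polar:polar conventions."""
    return {
        "complex": report.complex_id,
        "temperature_K": report.temperature,
        "dG_kcal_per_mol": report.dg,
        "Kd_M": report.kd,
        "nis_percent": report.nis,
        "contacts": {
            "threshold_A": report.contacts.threshold,
            "counts": dict(report.contacts.counts),
            "polar_polar": report.contacts.polar_polar(),
            "polar_polar_folding_charged": report.contacts.polar_polar(fold_charged=True),
            "apolar_apolar": report.contacts.apolar_apolar(),
            "pairs": [
                {"receptor": list(r), "ligand": list(l), "min_distance_A": d}
                for r, l, d in report.contacts.pairs
            ],
        },
        "delta_sasa": {f"{c}:{n}": d for (c, n), d in sorted(report.profile.delta.items())},
        "interface_residues": sorted(f"{c}:{n}" for c, n in report.profile.interface),
    }
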