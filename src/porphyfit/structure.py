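"""Binding-pocket structural analysis for porphyrin–protein complexes.

Operations mirror how a heme pocket is characterized from a deposited
crystal structure: the residue contact shell at a heavy-atom cutoff
(4.0 Å by default), geometric hydrogen-bond inference (the models are
hydrogen-free, so a donor–acceptor distance plus an angle proxy at the
acceptor is used), π-stacking between protein aromatics and the four pyrrole
rings, Kabsch Cα superposition, and the in-plane rotation of the porphyrin
between two superposed complexes.

Porphyrin ring naming: the chemical-component heme atom names NA–ND define
pyrrole rings that are reported with the conventional Fischer numerals
I–IV (A→I, B→II, C→III, D→IV).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "StructureModel",
    "ContactReport",
    "HydrogenBond",
    "StackingContact",
    "SuperpositionResult",
    "PlaneRotation",
    "parse_structure",
    "contact_residues",
    "detect_hbonds",
    "detect_pi_stacking",
    "superpose_ca",
    "heme_plane_rotation",
    "kabsch",
]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
WATERS = {"HOH", "WAT", "DOD"}

# Geometric hydrogen-bond donor/acceptor heavy atoms for protein residues.
PROTEIN_DONORS = {
    ("*", "N"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("TRP", "NE1"),
    ("ASN", "ND2"), ("GLN", "NE2"),
}
PROTEIN_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}

AROMATIC_RINGS = {
    "PHE": {"ring": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]},
    "TYR": {"ring": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]},
    "HIS": {"ring": ["CG", "ND1", "CD2", "CE1", "NE2"]},
    "TRP": {
        "pyrrole": ["CG", "CD1", "NE1", "CE2", "CD2"],
        "benzene": ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
    },
}

PORPHYRIN_RINGS = {
    "I": ["NA", "C1A", "C2A", "C3A", "C4A"],
    "II": ["NB", "C1B", "C2B", "C3B", "C4B"],
    "III": ["NC", "C1C", "C2C", "C3C", "C4C"],
    "IV": ["ND", "C1D", "C2D", "C3D", "C4D"],
}
# 24-atom macrocycle core: 4 pyrrole N, 16 pyrrole C, 4 meso C
PORPHYRIN_CORE = sorted(
    {a for ring in PORPHYRIN_RINGS.values() for a in ring}
    | {"CHA", "CHB", "CHC", "CHD"}
)


@dataclass(frozen=True)
class Atom:
    chain: str
    resname: str
    resnum: int
    icode: str
    name: str
    element: str
    pos: tuple[float, float, float]
    hetero: bool
    occupancy: float = 1.0

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)

    @property
    def residue_key(self) -> tuple[str, str, int, str]:
        return (self.chain, self.resname, self.resnum, self.icode)

    def describe(self) -> str:
        ic = self.icode.strip()
        return f"{self.chain}/{self.resname}{self.resnum}{ic}/{self.name}"


@dataclass
class StructureModel:
    """Flat atom list with per-residue indexing (coordinates in Å)."""

    atoms: list[Atom]
    name: str = ""

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not np.all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates on {a.describe()}")

    def __len__(self) -> int:
        return len(self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element not in {"H", "D"}]

    def residues(self) -> dict[tuple, list[Atom]]:
        res: dict[tuple, list[Atom]] = {}
        for a in self.atoms:
            res.setdefault(a.residue_key, []).append(a)
        return res

    def select(self, selector: str) -> list[Atom]:
        """Atoms matching a ``chain:resname:resnum`` selector; '*' wildcards."""
        parts = selector.split(":")
        if len(parts) != 3:
            raise ValueError("selector must be 'chain:resname:resnum' (use * as wildcard)")
        chain, resname, resnum = (p.strip() for p in parts)
        out = []
        for a in self.atoms:
            if chain not in ("*", "") and a.chain != chain:
                continue
            if resname not in ("*", "") and a.resname != resname.upper():
                continue
            if resnum not in ("*", "") and a.resnum != int(resnum):
                continue
            out.append(a)
        return out

    def ca_atoms(self, chains: list[str] | None = None) -> list[Atom]:
        return [
            a for a in self.atoms
            if a.name == "CA" and a.element == "C" and a.resname in AMINO_ACIDS
            and (chains is None or a.chain in chains)
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        atoms = [
            Atom(a.chain, a.resname, a.resnum, a.icode, a.name, a.element,
                 tuple(rotation @ a.xyz + translation), a.hetero, a.occupancy)
            for a in self.atoms
        ]
        return StructureModel(atoms, name=self.name)


def parse_structure(path, fmt: str | None = None) -> StructureModel:
    """Load a PDB or mmCIF file into a StructureModel.

    The first model is used; alternate locations are resolved to the
    highest-occupancy conformer per atom name.
    """
    path = str(path)
    if fmt is not None and fmt.lower() not in {"pdb", "mmcif", "cif"}:
        raise ValueError(f"unknown format {fmt!r}")
    try:
        if fmt is None:
            st = gemmi.read_structure(path)
        elif fmt.lower() == "pdb":
            st = gemmi.read_pdb(path)
        else:
            st = gemmi.make_structure_from_block(gemmi.cif.read(path).sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            best: dict[str, gemmi.Atom] = {}
            for at in residue:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in best.values():
                atoms.append(Atom(
                    chain=chain.name,
                    resname=residue.name,
                    resnum=residue.seqid.num,
                    icode=residue.seqid.icode.strip(),
                    name=at.name,
                    element=at.element.name,
                    pos=(at.pos.x, at.pos.y, at.pos.z),
                    hetero=het,
                    occupancy=at.occ,
                ))
    if not atoms:
        raise ValueError(f"{path}: no atoms found")
    return StructureModel(atoms, name=st.name or path)


# ---------------------------------------------------------------------------
# Contact shell
# ---------------------------------------------------------------------------

@dataclass
class ContactReport:
    """Ligand contact shell with interaction annotations."""

    cutoff: float
    contacts: list[dict]                      # amino-acid residues
    waters: list[dict] = field(default_factory=list)
    others: list[dict] = field(default_factory=list)
    hydrogen_bonds: list["HydrogenBond"] = field(default_factory=list)
    stacking: list["StackingContact"] = field(default_factory=list)

    @property
    def residue_names(self) -> list[str]:
        return [f"{c['resname']}{c['resnum']}" for c in self.contacts]

    def to_dict(self) -> dict:
        return {
            "cutoff_angstrom": self.cutoff,
            "n_contact_residues": len(self.contacts),
            "contacts": self.contacts,
            "waters": self.waters,
            "others": self.others,
            "hydrogen_bonds": [hb.to_dict() for hb in self.hydrogen_bonds],
            "pi_stacking": [s.to_dict() for s in self.stacking],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_table(self) -> str:
        lines = [f"{'chain':>5} {'residue':>10} {'min_dist_A':>10}"]
        for c in self.contacts:
            lines.append(f"{c['chain']:>5} {c['resname'] + str(c['resnum']):>10} "
                         f"{c['min_distance']:>10.2f}")
        return "\n".join(lines)


def _ligand_atoms(model: StructureModel, ligand_selector: str) -> list[Atom]:
    lig = [a for a in model.select(ligand_selector) if a.element not in {"H", "D"}]
    if not lig:
        raise ValueError(f"ligand selector {ligand_selector!r} matched no heavy atoms")
    return lig


def contact_residues(model: StructureModel, ligand_selector: str,
                     cutoff: float = 4.0) -> ContactReport:
    """Residues with any heavy atom within ``cutoff`` of any ligand heavy atom.

    Amino acids form the census; waters and other non-protein entities are
    listed separately.  Hydrogens are excluded on both sides.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    lig = _ligand_atoms(model, ligand_selector)
    lig_keys = {a.residue_key for a in lig}
    tree = cKDTree(np.array([a.xyz for a in lig]))
    buckets: dict[tuple, float] = {}
    for a in model.heavy_atoms():
        if a.residue_key in lig_keys:
            continue
        d, _ = tree.query(a.xyz)
        if d <= cutoff:
            key = a.residue_key
            buckets[key] = min(buckets.get(key, np.inf), float(d))
    contacts, waters, others = [], [], []
    for (chain, resname, resnum, icode), dist in sorted(
            buckets.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[0][3])):
        entry = {"chain": chain, "resname": resname, "resnum": resnum,
                 "icode": icode, "min_distance": dist}
        if resname in AMINO_ACIDS:
            contacts.append(entry)
        elif resname in WATERS:
            waters.append(entry)
        else:
            others.append(entry)
    return ContactReport(cutoff=cutoff, contacts=contacts, waters=waters, others=others)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HydrogenBond:
    donor: str
    acceptor: str
    distance: float
    angle: float | None  # donor–acceptor–antecedent angle, degrees

    def to_dict(self) -> dict:
        return {"donor": self.donor, "acceptor": self.acceptor,
                "distance": self.distance, "angle": self.angle}


def _is_protein_donor(a: Atom) -> bool:
    return ("*", a.name) in PROTEIN_DONORS or (a.resname, a.name) in PROTEIN_DONORS


def _is_protein_acceptor(a: Atom) -> bool:
    return ("*", a.name) in PROTEIN_ACCEPTORS or (a.resname, a.name) in PROTEIN_ACCEPTORS


def _antecedent(atom: Atom, residue_atoms: list[Atom]) -> Atom | None:
    """Nearest covalently bonded heavy atom in the same residue."""
    best, best_d = None, 1.8
    for other in residue_atoms:
        if other is atom or other.element in {"H", "D"}:
            continue
        d = float(np.linalg.norm(atom.xyz - other.xyz))
        if d < best_d:
            best, best_d = other, d
    return best


def _angle(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    v1 = p1 - vertex
    v2 = p2 - vertex
    cosang = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def detect_hbonds(model: StructureModel, ligand_selector: str,
                  d_max: float = 3.5, angle_min: float = 90.0) -> list[HydrogenBond]:
    """Geometric protein–ligand hydrogen bonds (heavy atoms only).

    A donor–acceptor pair is reported when the heavy-atom distance is
    ≤ ``d_max`` and, where an acceptor antecedent can be identified, the
    donor–acceptor–antecedent angle is ≥ ``angle_min`` (a proxy for a
    plausible hydrogen position; the crystallographic models carry no
    hydrogens).  Ligand N/O/S atoms are treated as both potential donors and
    acceptors, since protonation is not resolved.
    """
    lig = _ligand_atoms(model, ligand_selector)
    lig_keys = {a.residue_key for a in lig}
    residues = model.residues()
    lig_polar = [a for a in lig if a.element in {"N", "O", "S"}]
    protein_atoms = [a for a in model.heavy_atoms()
                     if a.resname in AMINO_ACIDS and a.residue_key not in lig_keys]
    if not lig_polar:
        return []
    tree = cKDTree(np.array([a.xyz for a in lig_polar]))
    bonds: list[HydrogenBond] = []
    for pa in protein_atoms:
        donor_ok = _is_protein_donor(pa)
        acceptor_ok = _is_protein_acceptor(pa)
        if not donor_ok and not acceptor_ok:
            continue
        for j in tree.query_ball_point(pa.xyz, d_max):
            la = lig_polar[j]
            d = float(np.linalg.norm(pa.xyz - la.xyz))
            if d > d_max or d < 0.5:
                continue
            if donor_ok:
                ante = _antecedent(la, residues[la.residue_key])
                ang = _angle(pa.xyz, la.xyz, ante.xyz) if ante is not None else None
                if ang is None or ang >= angle_min:
                    bonds.append(HydrogenBond(pa.describe(), la.describe(), d, ang))
            if acceptor_ok:
                ante = _antecedent(pa, residues[pa.residue_key])
                ang = _angle(la.xyz, pa.xyz, ante.xyz) if ante is not None else None
                if ang is None or ang >= angle_min:
                    bonds.append(HydrogenBond(la.describe(), pa.describe(), d, ang))
    bonds.sort(key=lambda b: (b.distance, b.donor, b.acceptor))
    return bonds


# ---------------------------------------------------------------------------
# Pi stacking
# ---------------------------------------------------------------------------

@dataclass
class StackingContact:
    residue: str
    residue_ring: str
    porphyrin_ring: str
    centroid_distance: float
    interplanar_angle: float

    def to_dict(self) -> dict:
        return {"residue": self.residue, "residue_ring": self.residue_ring,
                "porphyrin_ring": self.porphyrin_ring,
                "centroid_distance": self.centroid_distance,
                "interplanar_angle": self.interplanar_angle}


def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit plane: returns (centroid, unit normal from SVD)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[2]


def _ring_geometry(atoms_by_name: dict[str, Atom], names: list[str]):
    if any(n not in atoms_by_name for n in names):
        return None
    pts = np.array([atoms_by_name[n].xyz for n in names])
    centroid, normal = _fit_plane(pts)
    return centroid, normal


def detect_pi_stacking(model: StructureModel, ligand_selector: str,
                       centroid_max: float = 5.5,
                       tilt_max: float = 30.0) -> list[StackingContact]:
    """Protein aromatic rings stacked on the porphyrin pyrrole rings.

    Reports pairs with ring-centroid distance ≤ ``centroid_max`` and
    interplanar angle ≤ ``tilt_max`` (parallel and parallel-displaced
    geometries; T-shaped contacts are deliberately excluded).
    """
    lig = _ligand_atoms(model, ligand_selector)
    lig_by_name = {a.name: a for a in lig}
    porph_rings = {}
    for label, names in PORPHYRIN_RINGS.items():
        geo = _ring_geometry(lig_by_name, names)
        if geo is None:
            warnings.warn(f"porphyrin ring {label}: atoms missing, skipped", stacklevel=2)
            continue
        porph_rings[label] = geo
    if not porph_rings:
        raise ValueError("no porphyrin ring atoms found in ligand selection")
    out: list[StackingContact] = []
    for key, res_atoms in model.residues().items():
        chain, resname, resnum, icode = key
        if resname not in AROMATIC_RINGS:
            continue
        by_name = {a.name: a for a in res_atoms}
        for ring_label, names in AROMATIC_RINGS[resname].items():
            geo = _ring_geometry(by_name, names)
            if geo is None:
                warnings.warn(
                    f"{resname}{resnum}: ring {ring_label} atoms missing, skipped",
                    stacklevel=2)
                continue
            c1, n1 = geo
            for plabel, (c2, n2) in porph_rings.items():
                dist = float(np.linalg.norm(c1 - c2))
                if dist > centroid_max:
                    continue
                cosang = abs(float(np.clip(n1 @ n2, -1.0, 1.0)))
                tilt = float(np.degrees(np.arccos(cosang)))
                if tilt <= tilt_max:
                    out.append(StackingContact(
                        residue=f"{chain}/{resname}{resnum}{icode}",
                        residue_ring=ring_label, porphyrin_ring=plabel,
                        centroid_distance=dist, interplanar_angle=tilt))
    out.sort(key=lambda s: (s.centroid_distance, s.residue))
    return out


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, proper orthonormal
    translation: np.ndarray   # Å
    rmsd: float               # Å
    n_atoms: int
    pairing: str

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(reference: np.ndarray, mobile: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid transform mapping ``mobile`` onto ``reference``.

    Returns (R, t, rmsd) with x_ref ≈ R @ x_mob + t; R is proper
    (det = +1, reflections excluded).
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    cr = ref.mean(axis=0)
    cm = mob.mean(axis=0)
    h = (mob - cm).T @ (ref - cr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if s[1] + s[2] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set; superposition ill-defined")
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cr - rot @ cm
    moved = mob @ rot.T + t
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum() / n))
    return rot, t, rmsd


def _pair_by_resnum(ref_ca: list[Atom], mob_ca: list[Atom]) -> list[tuple[Atom, Atom]]:
    def index(atoms):
        idx = {}
        for a in atoms:
            idx.setdefault((a.resnum, a.icode), a)
        return idx
    ri = index(ref_ca)
    mi = index(mob_ca)
    keys = sorted(set(ri) & set(mi))
    return [(ri[k], mi[k]) for k in keys]


def _pair_by_alignment(ref_ca: list[Atom], mob_ca: list[Atom]) -> list[tuple[Atom, Atom]]:
    from Bio import Align
    from Bio.Data.PDBData import protein_letters_3to1

    def seq(atoms):
        return "".join(protein_letters_3to1.get(a.resname, "X") for a in atoms)

    aligner = Align.PairwiseAligner(scoring="blastp")
    aligner.mode = "global"
    aln = aligner.align(seq(ref_ca), seq(mob_ca))[0]
    pairs = []
    for (rs, re_), (ms, me) in zip(*aln.aligned):
        for k in range(re_ - rs):
            pairs.append((ref_ca[rs + k], mob_ca[ms + k]))
    return pairs


def superpose_ca(reference: StructureModel, mobile: StructureModel,
                 pairing: str = "by_resnum",
                 ref_chains: list[str] | None = None,
                 mob_chains: list[str] | None = None) -> SuperpositionResult:
    """Least-squares Cα superposition (Kabsch) of two models.

    ``by_resnum`` pairs residues sharing (residue number, insertion code)
    across the selected chains — appropriate for structures on the same
    author numbering; ``by_alignment`` pairs via global sequence alignment.
    """
    ref_ca = reference.ca_atoms(ref_chains)
    mob_ca = mobile.ca_atoms(mob_chains)
    if pairing == "by_resnum":
        pairs = _pair_by_resnum(ref_ca, mob_ca)
    elif pairing == "by_alignment":
        pairs = _pair_by_alignment(ref_ca, mob_ca)
    else:
        raise ValueError("pairing must be by_resnum or by_alignment")
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} paired Cα atoms; need >= 3")
    ref_xyz = np.array([a.xyz for a, _ in pairs])
    mob_xyz = np.array([b.xyz for _, b in pairs])
    rot, t, rmsd = kabsch(ref_xyz, mob_xyz)
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd,
                               n_atoms=len(pairs),
                               pairing=f"{pairing} ({len(pairs)} Cα pairs)")


# ---------------------------------------------------------------------------
# Heme plane rotation
# ---------------------------------------------------------------------------

@dataclass
class PlaneRotation:
    in_plane_deg: float     # rotation of the Fe(or centroid)->NA vector, in A's plane
    normal_tilt_deg: float  # angle between oriented plane normals
    n_core_atoms: tuple[int, int]


def _porphyrin_frame(model: StructureModel, ligand_selector: str):
    lig = {a.name: a for a in _ligand_atoms(model, ligand_selector)}
    core = [lig[n].xyz for n in PORPHYRIN_CORE if n in lig]
    if len(core) < 6:
        raise ValueError("porphyrin core atoms missing from ligand selection")
    pts = np.array(core)
    centroid, normal = _fit_plane(pts)
    # Orient the normal with the NA/NB atom order so a mirrored porphyrin
    # reports a flipped plane rather than an arbitrary SVD sign.
    if "NA" in lig and "NB" in lig:
        sense = np.cross(lig["NA"].xyz - centroid, lig["NB"].xyz - centroid)
        if sense @ normal < 0:
            normal = -normal
    origin = lig["FE"].xyz if "FE" in lig else centroid
    if "NA" not in lig:
        raise ValueError("porphyrin NA atom required as the in-plane reference")
    ref_vec = lig["NA"].xyz - origin
    return centroid, normal, ref_vec, len(core)


def heme_plane_rotation(complex_a: StructureModel, complex_b: StructureModel,
                        ligand_a: str, ligand_b: str,
                        superpose: bool = True,
                        pairing: str = "by_resnum",
                        ref_chains: list[str] | None = None,
                        mob_chains: list[str] | None = None) -> PlaneRotation:
    """In-plane rotation of B's porphyrin relative to A's after superposition.

    The proteins are Cα-superposed first (B onto A), then a best-fit plane is
    put through each 24-atom porphyrin core and the iron→NA reference vector
    of B is projected into A's plane; the reported angle is the unsigned
    in-plane rotation between the two projected reference vectors, with the
    tilt between the oriented plane normals reported separately.
    """
    b = complex_b
    if superpose:
        sup = superpose_ca(complex_a, complex_b, pairing=pairing,
                           ref_chains=ref_chains, mob_chains=mob_chains)
        b = complex_b.transformed(sup.rotation, sup.translation)
    _, n_a, v_a, na_atoms = _porphyrin_frame(complex_a, ligand_a)
    _, n_b, v_b, nb_atoms = _porphyrin_frame(b, ligand_b)
    # Project both reference vectors into A's plane
    pa = v_a - (v_a @ n_a) * n_a
    pb = v_b - (v_b @ n_a) * n_a
    if np.linalg.norm(pa) < 1e-9 or np.linalg.norm(pb) < 1e-9:
        raise ValueError("reference vector degenerate after projection")
    cosang = np.clip(pa @ pb / (np.linalg.norm(pa) * np.linalg.norm(pb)), -1.0, 1.0)
    in_plane = float(np.degrees(np.arccos(cosang)))
    tilt = float(np.degrees(np.arccos(np.clip(n_a @ n_b, -1.0, 1.0))))
    return PlaneRotation(in_plane_deg=in_plane, normal_tilt_deg=tilt,
                         n_core_atoms=(na_atoms, nb_atoms))
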