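"""Coarse-grained DNA and protein bead models.

The DNA double helix is reduced to one pseudo-residue per base pair: a
pseudo-backbone bead (PB) on the helix axis and a pseudo-phosphate bead (PP)
carrying the charge of the two nucleotides (-2e), placed at the phosphate
radius of B-form DNA.  The protein is three beads: one large protein-body
bead (PBP, neutral) and two positively charged DNA-binding beads (DBP)
separated by exactly one helical pitch so that both can face the
phosphate-free side of the groove simultaneously.

Geometry constants (helical rise 3.38 Å, twist 36°, phosphate radius
8.973 Å) correspond to canonical B-DNA with a 33.8 Å pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KBT

# --- canonical geometry -----------------------------------------------------

#: Helical rise per base pair, Å.
RISE = 3.38
#: Helical twist per base pair, degrees.
TWIST_DEG = 36.0
#: Radial distance of the pseudo-phosphate from the helix axis, Å.
PHOSPHATE_RADIUS = 8.973
#: Helix pitch, Å (10 residues).
PITCH = 10 * RISE
#: PBP–DBP equilibrium bond length, Å.
PBP_DBP_BOND = 41.59
#: DBP–DBP equilibrium bond length, Å (one pitch).
DBP_DBP_BOND = 33.8
#: Axial offset of each DBP from the protein centre, Å (half the DBP spacing).
DBP_Z_OFFSET = DBP_DBP_BOND / 2.0


class InvalidModelError(ValueError):
    """Raised when model construction parameters are inconsistent."""


class PlacementError(ValueError):
    """Raised when protein placement on the DNA is sterically impossible."""


@dataclass(frozen=True)
class BeadSpec:
    """Per-bead-type parameters: excluded-volume radius, Stokes radius, charge."""

    name: str
    sigma: float          # excluded-volume radius, Å
    stokes_radius: float  # hydrodynamic radius, Å
    charge: float         # effective charge, units of e

    def __post_init__(self):
        if not (self.sigma > 0 and self.stokes_radius > 0):
            raise InvalidModelError(
                f"bead {self.name!r}: radii must be positive "
                f"(sigma={self.sigma}, a={self.stokes_radius})")
        if not np.isfinite(self.charge):
            raise InvalidModelError(f"bead {self.name!r}: non-finite charge")


#: Default bead parameter table.
BEAD_TABLE = {
    "PP": BeadSpec("PP", sigma=10.4, stokes_radius=7.0, charge=-2.0),
    "PB": BeadSpec("PB", sigma=2.5, stokes_radius=7.0, charge=0.0),
    "PBP": BeadSpec("PBP", sigma=27.6, stokes_radius=40.0, charge=0.0),
    "DBP": BeadSpec("DBP", sigma=6.0, stokes_radius=8.0, charge=8.0),
}


@dataclass
class Topology:
    """Bonded interaction lists referencing bead indices.

    ``bonds``:    (nb, 2) int indices with ``bond_k`` (kcal/mol/Å²), ``bond_r0`` (Å)
    ``angles``:   (na, 3) int indices with ``angle_k`` (kcal/mol), ``angle_t0`` (rad)
    ``torsions``: (nt, 4) int indices with ``torsion_k`` (kcal/mol), ``torsion_p0`` (rad)
    """

    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), np.int64))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), np.int64))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_t0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    torsions: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), np.int64))
    torsion_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    torsion_p0: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def shifted(self, offset: int) -> "Topology":
        return Topology(self.bonds + offset, self.bond_k.copy(), self.bond_r0.copy(),
                        self.angles + offset, self.angle_k.copy(), self.angle_t0.copy(),
                        self.torsions + offset, self.torsion_k.copy(), self.torsion_p0.copy())

    @staticmethod
    def merge(a: "Topology", b: "Topology") -> "Topology":
        return Topology(
            np.vstack([a.bonds, b.bonds]), np.concatenate([a.bond_k, b.bond_k]),
            np.concatenate([a.bond_r0, b.bond_r0]),
            np.vstack([a.angles, b.angles]), np.concatenate([a.angle_k, b.angle_k]),
            np.concatenate([a.angle_t0, b.angle_t0]),
            np.vstack([a.torsions, b.torsions]),
            np.concatenate([a.torsion_k, b.torsion_k]),
            np.concatenate([a.torsion_p0, b.torsion_p0]))

    def validate(self, n_beads: int) -> None:
        for arr in (self.bonds, self.angles, self.torsions):
            if arr.size and (arr.min() < 0 or arr.max() >= n_beads):
                raise InvalidModelError("topology references invalid bead index")


@dataclass
class SystemSpec:
    """A complete simulation system: bead parameters, coordinates, topology.

    Bead-wise arrays: ``positions`` (N, 3) Å, ``sigma``/``stokes``/``charge``
    (N,), ``molecule`` (N,) molecule index, ``residue`` (N,) serial residue
    index within its molecule (used by the nonbonded exclusion rule),
    ``names`` length-N list of bead-type names.
    """

    positions: np.ndarray
    sigma: np.ndarray
    stokes: np.ndarray
    charge: np.ndarray
    molecule: np.ndarray
    residue: np.ndarray
    names: list
    topology: Topology

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def __post_init__(self):
        n = self.n_beads
        for arr, nm in ((self.sigma, "sigma"), (self.stokes, "stokes"),
                        (self.charge, "charge"), (self.molecule, "molecule"),
                        (self.residue, "residue")):
            if len(arr) != n:
                raise InvalidModelError(f"array {nm} length {len(arr)} != {n} beads")
        self.topology.validate(n)

    def copy(self) -> "SystemSpec":
        return SystemSpec(self.positions.copy(), self.sigma.copy(), self.stokes.copy(),
                          self.charge.copy(), self.molecule.copy(), self.residue.copy(),
                          list(self.names), self.topology)


@dataclass
class DnaModel(SystemSpec):
    """Built CG-DNA: beads ordered PB[0..n-1] then PP[0..n-1], axis along Z."""

    n_residues: int = 0


@dataclass
class ProteinModel(SystemSpec):
    """Built CG-protein: beads ordered [PBP, DBP, DBP], axis direction +X."""

    a_pbp: float = 0.0
    q_dbp: float = 0.0


def dna_bead_positions(n_residues: int) -> tuple[np.ndarray, np.ndarray]:
    """Ideal helical coordinates of the PB and PP beads, centred at the origin.

    Residue α sits at z = (α - (n-1)/2)·rise; the PP azimuth advances 36°
    per residue (right-handed helix).
    """
    alpha = np.arange(n_residues)
    z = (alpha - (n_residues - 1) / 2.0) * RISE
    phi = np.deg2rad(TWIST_DEG) * alpha
    pb = np.column_stack([np.zeros(n_residues), np.zeros(n_residues), z])
    pp = np.column_stack([PHOSPHATE_RADIUS * np.cos(phi),
                          PHOSPHATE_RADIUS * np.sin(phi), z])
    return pb, pp


def build_dna(n_residues: int, *, backbone_theta0_deg: float = 180.0,
              bead_table: dict | None = None) -> DnaModel:
    """Construct an ideal n-residue CG-DNA with its full bonded topology.

    Parameters
    ----------
    n_residues
        Number of pseudo-residues (one per base pair); must be >= 3 so that
        the backbone angle and torsion terms are defined.
    backbone_theta0_deg
        Equilibrium angle of the PB(α-1)–PB(α)–PB(α+1) backbone bending
        term.  The straight-chain convention (180°, the default) makes the
        ideal build the energy minimum and yields the intended worm-like
        chain stiffness; the printed table value 32.7° is exposed here for
        exact-replication experiments but appears to be an erratum (it is
        incompatible with a straight ground state and with the quoted 50 nm
        persistence length).
    """
    if n_residues < 3:
        raise InvalidModelError("CG-DNA needs at least 3 residues "
                                "(angle/torsion terms undefined below that)")
    table = bead_table or BEAD_TABLE
    n = int(n_residues)
    pb, pp = dna_bead_positions(n)
    pos = np.vstack([pb, pp])
    names = ["PB"] * n + ["PP"] * n
    sig = np.array([table[x].sigma for x in names])
    sto = np.array([table[x].stokes_radius for x in names])
    chg = np.array([table[x].charge for x in names])
    mol = np.zeros(2 * n, np.int64)
    res = np.concatenate([np.arange(n), np.arange(n)])

    kbb = 100.0 * KBT / RISE ** 2
    kpb = 100.0 * KBT / PHOSPHATE_RADIUS ** 2
    twist = np.deg2rad(TWIST_DEG)
    th0 = np.deg2rad(backbone_theta0_deg)

    bonds, bk, br = [], [], []
    angles, ak, at = [], [], []
    tors, tk, tp = [], [], []
    for a in range(n):
        bonds.append((n + a, a)); bk.append(kpb); br.append(PHOSPHATE_RADIUS)
        if a + 1 < n:
            bonds.append((a, a + 1)); bk.append(kbb); br.append(RISE)
            angles.append((n + a, a, a + 1)); ak.append(100.0); at.append(np.pi / 2)
            angles.append((a, a + 1, n + a + 1)); ak.append(100.0); at.append(np.pi / 2)
            tors.append((n + a, a, a + 1, n + a + 1)); tk.append(131.6); tp.append(twist)
        if 0 < a < n - 1:
            angles.append((a - 1, a, a + 1)); ak.append(87.7); at.append(th0)

    topo = Topology(np.array(bonds, np.int64), np.array(bk), np.array(br),
                    np.array(angles, np.int64), np.array(ak), np.array(at),
                    np.array(tors, np.int64), np.array(tk), np.array(tp))
    return DnaModel(pos, sig, sto, chg, mol, res, names, topo, n_residues=n)


def build_protein(a_pbp: float = 40.0, q_dbp: float = 8.0, *,
                  bead_table: dict | None = None) -> ProteinModel:
    """Construct the three-bead CG-protein in its body frame.

    The two DBP beads sit on the (local) helix-axis line at z = ±16.9 Å and
    the PBP bead on the +X axis at the distance that closes both PBP–DBP
    bonds (41.59 Å) exactly, i.e. x = sqrt(41.59² - 16.9²) ≈ 38.0 Å from the
    DBP line.  When the protein is docked with the DBP line at the phosphate
    radius, the PBP centre ends up ≈47 Å from the DNA axis.  The DBP
    separation equals one helical pitch so both beads share the same helix
    phase.
    """
    if not (a_pbp > 0):
        raise InvalidModelError(f"a_pbp must be positive, got {a_pbp}")
    if not np.isfinite(q_dbp):
        raise InvalidModelError("q_dbp must be finite")
    table = bead_table or BEAD_TABLE
    x = np.sqrt(PBP_DBP_BOND ** 2 - DBP_Z_OFFSET ** 2)
    pos = np.array([[x, 0.0, 0.0],
                    [0.0, 0.0, DBP_Z_OFFSET],
                    [0.0, 0.0, -DBP_Z_OFFSET]])
    names = ["PBP", "DBP", "DBP"]
    pbp = replace(table["PBP"], stokes_radius=float(a_pbp))
    dbp = replace(table["DBP"], charge=float(q_dbp))
    specs = [pbp, dbp, dbp]
    topo = Topology(
        bonds=np.array([[0, 1], [0, 2], [1, 2]], np.int64),
        bond_k=np.array([1.0, 1.0, 1.0]),
        bond_r0=np.array([PBP_DBP_BOND, PBP_DBP_BOND, DBP_DBP_BOND]))
    return ProteinModel(
        pos, np.array([s.sigma for s in specs]),
        np.array([s.stokes_radius for s in specs]),
        np.array([s.charge for s in specs]),
        np.zeros(3, np.int64), np.arange(3, dtype=np.int64), names, topo,
        a_pbp=float(a_pbp), q_dbp=float(q_dbp))


def _min_dbp_pp_distance(dna_pp: np.ndarray, dbp: np.ndarray) -> float:
    d = np.linalg.norm(dbp[:, None, :] - dna_pp[None, :, :], axis=-1)
    return float(d.min())


def assemble_system(dna: DnaModel, protein: ProteinModel, *,
                    azimuth_deg: float | None = None, z_offset: float = 0.0,
                    radial_offset: float = 0.0,
                    clash_tolerance: float = 2.5) -> SystemSpec:
    """Dock the protein onto the DNA and merge into one system.

    The protein body frame is rotated about Z by the azimuth and translated
    so its DBP line lies at the phosphate radius (plus ``radial_offset``)
    with the protein centre at height ``z_offset``.  When no azimuth is
    given it is chosen to maximise the clearance between the DBP beads and
    the phosphate helix, which places each DBP in the groove diametrically
    opposite the local phosphate phase.

    Raises :class:`PlacementError` if the protein would extend past the DNA
    ends or if any excluded-volume overlap exceeds ``clash_tolerance`` (Å).
    """
    n = dna.n_residues
    half = (n - 1) / 2.0 * RISE
    if abs(z_offset) + DBP_Z_OFFSET > half:
        raise PlacementError(
            f"z_offset {z_offset} places the protein beyond the DNA ends "
            f"(half-length {half:.1f} Å)")

    pp = dna.positions[n:]
    radius = PHOSPHATE_RADIUS + radial_offset

    def place(phi_deg):
        phi = np.deg2rad(phi_deg)
        rot = np.array([[np.cos(phi), -np.sin(phi), 0.0],
                        [np.sin(phi), np.cos(phi), 0.0],
                        [0.0, 0.0, 1.0]])
        local = protein.positions @ rot.T
        shift = np.array([radius * np.cos(phi), radius * np.sin(phi), z_offset])
        return local + shift

    if azimuth_deg is None:
        cands = np.linspace(0.0, 360.0, 721)
        scores = [_min_dbp_pp_distance(pp, place(c)[1:]) for c in cands]
        azimuth_deg = float(cands[int(np.argmax(scores))])
    prot_pos = place(azimuth_deg)

    # steric screen against the configured tolerance
    merged_sigma = np.concatenate([dna.sigma, protein.sigma])
    pos = np.vstack([dna.positions, prot_pos])
    nd = dna.n_beads
    worst = (None, 0.0)
    for i in range(nd, nd + 3):
        d = np.linalg.norm(pos[:nd] - pos[i], axis=1)
        overlap = (merged_sigma[:nd] + merged_sigma[i]) - d
        j = int(np.argmax(overlap))
        if overlap[j] > worst[1]:
            worst = ((j, i), float(overlap[j]))
    if worst[1] > clash_tolerance:
        raise PlacementError(
            f"steric clash: beads {worst[0]} overlap by {worst[1]:.2f} Å "
            f"(> tolerance {clash_tolerance} Å)")

    topo = Topology.merge(dna.topology, protein.topology.shifted(nd))
    return SystemSpec(
        pos,
        merged_sigma,
        np.concatenate([dna.stokes, protein.stokes]),
        np.concatenate([dna.charge, protein.charge]),
        np.concatenate([dna.molecule, protein.molecule + dna.molecule.max() + 1]),
        np.concatenate([dna.residue, protein.residue]),
        list(dna.names) + list(protein.names),
        topo)
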