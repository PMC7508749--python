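"""Sugar-backbone geometry of nucleic-acid crystal structures.

Per-nucleotide dihedrals (epsilon, zeta, gamma, chi and the five furanose
ring torsions), the pseudorotation phase/amplitude of the sugar pucker, the
BI/BII phosphate classification, C1'-C1' distances across base pairs, a
filter for wobble G.T mismatches flanked by Watson-Crick pairs on both
sides, and rigid least-squares superposition onto an idealized base-pair
triplet.

Base-pair classification is consumed from an annotation table (DSSR-style
CSV with columns chain1, resnum1, chain2, resnum2, pair_class); detecting
pairs from coordinates is deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "dihedral", "wrap360", "wrap180",
    "classify_backbone", "pseudorotation", "residue_torsions",
    "NucleotideCoords", "ResidueGeometry", "BasePairRecord",
    "c1c1_distance", "find_flanked_mismatches", "superpose",
    "load_nucleotides", "survey_structure",
]

# nonstandard atom-name spellings seen in older PDB entries
ATOM_ALIASES = {
    "O1'": "O4'",
    "O3*": "O3'", "O4*": "O4'", "O5*": "O5'",
    "C1*": "C1'", "C2*": "C2'", "C3*": "C3'", "C4*": "C4'", "C5*": "C5'",
    "O2*": "O2'",
}

PURINES = {"A", "G", "DA", "DG", "ADE", "GUA"}
PYRIMIDINES = {"C", "T", "U", "DC", "DT", "DU", "CYT", "THY", "URA"}

RING_TORSION_ATOMS = {
    "nu0": ("C4'", "O4'", "C1'", "C2'"),
    "nu1": ("O4'", "C1'", "C2'", "C3'"),
    "nu2": ("C1'", "C2'", "C3'", "C4'"),
    "nu3": ("C2'", "C3'", "C4'", "O4'"),
    "nu4": ("C3'", "C4'", "O4'", "C1'"),
}


def wrap360(angle: float) -> float:
    """Wrap an angle in degrees to [0, 360)."""
    a = float(np.mod(angle, 360.0))
    return 0.0 if a >= 360.0 else a   # mod of a tiny negative rounds to 360


def wrap180(angle: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = np.mod(angle, 360.0)
    return float(a - 360.0 if a > 180.0 else a)


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle (degrees, (-180, 180]) in the IUPAC sign convention:
    positive for a clockwise rotation of p4 relative to p1 looking p2->p3."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or nb2 < 1e-12:
        raise ValueError("dihedral undefined: collinear or coincident points")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = np.degrees(np.arctan2(y, x))
    return wrap180(ang)


def classify_backbone(epsilon: float, zeta: float) -> tuple[str, float]:
    """BI/BII phosphate classification from the epsilon-zeta difference.

    Both torsions are first wrapped to [0, 360); the difference
    epsilon - zeta is wrapped to [0, 360); the phosphate is BII if the
    difference lies in the closed window [20, 200] degrees, else BI.
    Returns (label, wrapped difference).
    """
    if not (np.isfinite(epsilon) and np.isfinite(zeta)):
        raise ValueError("epsilon and zeta must be finite")
    diff = wrap360(wrap360(epsilon) - wrap360(zeta))
    label = "BII" if 20.0 <= diff <= 200.0 else "BI"
    return label, diff


def pseudorotation(nu: np.ndarray | list[float]) -> tuple[float, float]:
    """Pseudorotation phase P (degrees, [0, 360)) and amplitude nu_max of a
    furanose ring from its five torsions nu0..nu4.

    Uses the convention nu_j = nu_max * cos(P + 144 deg * (j - 2)) — i.e.
    nu2 = nu_max * cos(P) — recovered by least-squares projection onto the
    cosine basis, which round-trips ideal inputs exactly and degrades
    gracefully for slightly non-ideal rings.  C3'-endo sits near P = 18 deg,
    C2'-endo near P = 162 deg.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (5,):
        raise ValueError("expected the five ring torsions nu0..nu4")
    if np.all(np.abs(nu) < 1e-9):
        raise ValueError("pseudorotation undefined: planar ring (all nu ~ 0)")
    x = np.radians(144.0 * (np.arange(5) - 2))
    c = (2.0 / 5.0) * np.sum(nu * np.cos(x))
    s = -(2.0 / 5.0) * np.sum(nu * np.sin(x))
    numax = float(np.hypot(c, s))
    p = wrap360(np.degrees(np.arctan2(s, c)))
    return p, numax


def nu_from_pseudorotation(p: float, numax: float) -> np.ndarray:
    """Ideal ring torsions for a given (P, nu_max) — inverse of
    :func:`pseudorotation` on ideal sugars."""
    j = np.arange(5)
    return numax * np.cos(np.radians(p + 144.0 * (j - 2)))


@dataclass
class NucleotideCoords:
    """Atom coordinates of one nucleotide plus the 5'-bridging atoms of the
    following residue (needed for epsilon and zeta)."""

    chain: str
    resnum: int
    base: str
    atoms: dict[str, np.ndarray]
    next_atoms: dict[str, np.ndarray] = field(default_factory=dict)
    model: int = 1
    structure: str = ""

    def __post_init__(self) -> None:
        self.atoms = {ATOM_ALIASES.get(k, k): np.asarray(v, dtype=float)
                      for k, v in self.atoms.items()}
        self.next_atoms = {ATOM_ALIASES.get(k, k): np.asarray(v, dtype=float)
                           for k, v in self.next_atoms.items()}


@dataclass
class ResidueGeometry:
    """Computed geometry for one nucleotide; absent torsions are NaN."""

    chain: str
    resnum: int
    base: str
    epsilon: float = np.nan
    zeta: float = np.nan
    gamma: float = np.nan
    chi: float = np.nan
    nu: np.ndarray = field(default_factory=lambda: np.full(5, np.nan))
    pucker_phase: float = np.nan
    pucker_amplitude: float = np.nan
    eps_minus_zeta: float = np.nan
    backbone_class: str = ""


def _get(nt: NucleotideCoords, *names, nxt: bool = False):
    src = nt.next_atoms if nxt else nt.atoms
    try:
        return [src[n] for n in names]
    except KeyError:
        return None


def residue_torsions(nt: NucleotideCoords) -> ResidueGeometry:
    """All backbone/sugar torsions that the present atoms allow.

    epsilon = C4'-C3'-O3'-P(+1), zeta = C3'-O3'-P(+1)-O5'(+1),
    gamma = O5'-C5'-C4'-C3', chi = O4'-C1'-N9-C4 (purines) or
    O4'-C1'-N1-C2 (pyrimidines), plus the five ring torsions and the
    derived pseudorotation and BI/BII class.  Torsions whose atoms are
    missing (e.g. epsilon/zeta of a 3'-terminal residue) are left NaN.
    """
    geo = ResidueGeometry(chain=nt.chain, resnum=nt.resnum, base=nt.base)

    pts = _get(nt, "O5'", "C5'", "C4'", "C3'")
    if pts:
        geo.gamma = dihedral(*pts)

    base = nt.base.strip().upper()
    if base in PURINES:
        glyco = ("O4'", "C1'", "N9", "C4")
    else:
        glyco = ("O4'", "C1'", "N1", "C2")
    pts = _get(nt, *glyco)
    if pts:
        geo.chi = dihedral(*pts)

    nus = np.full(5, np.nan)
    for k, name in enumerate(("nu0", "nu1", "nu2", "nu3", "nu4")):
        pts = _get(nt, *RING_TORSION_ATOMS[name])
        if pts:
            nus[k] = dihedral(*pts)
    geo.nu = nus
    if np.all(np.isfinite(nus)):
        geo.pucker_phase, geo.pucker_amplitude = pseudorotation(nus)

    ez = _get(nt, "C4'", "C3'", "O3'")
    p_next = _get(nt, "P", nxt=True)
    o5_next = _get(nt, "O5'", nxt=True)
    if ez and p_next:
        geo.epsilon = dihedral(ez[0], ez[1], ez[2], p_next[0])
        if o5_next:
            geo.zeta = dihedral(ez[1], ez[2], p_next[0], o5_next[0])
    if np.isfinite(geo.epsilon) and np.isfinite(geo.zeta):
        geo.backbone_class, geo.eps_minus_zeta = classify_backbone(
            geo.epsilon, geo.zeta)
    return geo


@dataclass
class BasePairRecord:
    """One base pair from the annotation table."""

    chain1: str
    resnum1: int
    chain2: str
    resnum2: int
    pair_class: str            # WC | wobble | other
    base1: str = ""
    base2: str = ""
    duplex_id: str = ""


def c1c1_distance(bp: BasePairRecord,
                  residues: dict[tuple[str, int], NucleotideCoords]) -> float:
    """Euclidean C1'-C1' distance (Angstrom) across a base pair."""
    try:
        r1 = residues[(bp.chain1, bp.resnum1)]
        r2 = residues[(bp.chain2, bp.resnum2)]
    except KeyError as exc:
        raise KeyError(f"residue {exc} not found in coordinate set") from None
    a = _get(r1, "C1'")
    b = _get(r2, "C1'")
    if a is None or b is None:
        raise ValueError("C1' atom missing on one side of the pair")
    return float(np.linalg.norm(a[0] - b[0]))


def _is_gt_wobble(bp: BasePairRecord) -> bool:
    if bp.pair_class.lower() != "wobble":
        return False
    if not (bp.base1 and bp.base2):
        return True   # no base identities supplied; class alone decides
    b1 = bp.base1.strip().upper().lstrip("D")
    b2 = bp.base2.strip().upper().lstrip("D")
    return {b1, b2} == {"G", "T"}


def find_flanked_mismatches(pairs: list[BasePairRecord],
                            n_flank: int = 2) -> list[BasePairRecord]:
    """Wobble G.T/T.G pairs with at least *n_flank* consecutive Watson-Crick
    pairs immediately on both sides, mimicking a duplex-interior context.

    *pairs* must be ordered 5'->3' within each duplex (``duplex_id`` groups
    independent duplexes); terminal and near-terminal mismatches are
    excluded by construction.
    """
    hits: list[BasePairRecord] = []
    groups: dict[str, list[BasePairRecord]] = {}
    for bp in pairs:
        groups.setdefault(bp.duplex_id, []).append(bp)
    for group in groups.values():
        for i, bp in enumerate(group):
            if not _is_gt_wobble(bp):
                continue
            if i < n_flank or i + n_flank >= len(group):
                continue
            before = group[i - n_flank:i]
            after = group[i + 1:i + 1 + n_flank]
            if all(b.pair_class.upper() == "WC" for b in before + after):
                hits.append(bp)
    return hits


def superpose(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares rigid superposition of matched point sets (Kabsch).

    Returns (rotation matrix, translation, rmsd) such that
    ``moving @ R.T + t`` best fits ``fixed``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[0] < 3:
        raise ValueError("need two equal (n>=3, 3) point sets")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    m0 = moving - mc
    f0 = fixed - fc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2:
        warnings.warn("degenerate (collinear) point set in superposition",
                      stacklevel=2)
    rot, _ = Rotation.align_vectors(f0, m0)
    R = rot.as_matrix()
    t = fc - R @ mc
    diff = (m0 @ R.T) - f0
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# structure file handling (gemmi)

def load_nucleotides(path: str, model_index: int = 0,
                     all_models: bool = False) -> dict:
    """Read a PDB/mmCIF file and return nucleotide coordinate records.

    Returns ``{(chain, resnum): NucleotideCoords}`` for the selected model
    (first by default), or ``{model_num: {...}}`` when ``all_models`` —
    the latter enables running the same geometry code over MD-snapshot
    multi-model files.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()

    def one_model(model) -> dict[tuple[str, int], NucleotideCoords]:
        out: dict[tuple[str, int], NucleotideCoords] = {}
        for chain in model:
            residues = list(chain)
            for i, res in enumerate(residues):
                atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z])
                         for a in res}
                nxt = {}
                if i + 1 < len(residues):
                    for a in residues[i + 1]:
                        if ATOM_ALIASES.get(a.name, a.name) in ("P", "O5'"):
                            nxt[a.name] = np.array([a.pos.x, a.pos.y, a.pos.z])
                out[(chain.name, res.seqid.num)] = NucleotideCoords(
                    chain=chain.name, resnum=res.seqid.num, base=res.name,
                    atoms=atoms, next_atoms=nxt, model=model.num,
                    structure=st.name)
        return out

    if all_models:
        return {m.num: one_model(m) for m in st}
    return one_model(st[model_index])


def survey_structure(path: str, structure_id: str = "",
                     model_index: int = 0) -> pd.DataFrame:
    """Per-residue geometry table for one coordinate file.

    Columns: structure, chain, resnum, base, epsilon, zeta, eps_minus_zeta,
    backbone_class, pucker_phase, pucker_amplitude, chi, gamma.
    """
    residues = load_nucleotides(path, model_index=model_index)
    rows = []
    for (chain, resnum), nt in residues.items():
        g = residue_torsions(nt)
        rows.append({
            "structure": structure_id or nt.structure,
            "chain": chain, "resnum": resnum, "base": nt.base,
            "epsilon": g.epsilon, "zeta": g.zeta,
            "eps_minus_zeta": g.eps_minus_zeta,
            "backbone_class": g.backbone_class,
            "pucker_phase": g.pucker_phase,
            "pucker_amplitude": g.pucker_amplitude,
            "chi": g.chi, "gamma": g.gamma,
        })
    return pd.DataFrame(rows)


def read_bp_annotation(path: str) -> list[BasePairRecord]:
    """Read a DSSR-style base-pair annotation CSV.

    Required columns: chain1, resnum1, chain2, resnum2, pair_class;
    optional: base1, base2, duplex_id, resolution.  Rows failing a
    ``resolution <= 3.0`` filter (when the column exists) are dropped,
    mirroring the survey's resolution cut.
    """
    df = pd.read_csv(path, comment="#")
    required = {"chain1", "resnum1", "chain2", "resnum2", "pair_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if "resolution" in df.columns:
        df = df[df["resolution"] <= 3.0]
    return [
        BasePairRecord(
            chain1=str(r.chain1), resnum1=int(r.resnum1),
            chain2=str(r.chain2), resnum2=int(r.resnum2),
            pair_class=str(r.pair_class),
            base1=str(getattr(r, "base1", "") or ""),
            base2=str(getattr(r, "base2", "") or ""),
            duplex_id=str(getattr(r, "duplex_id", "") or ""),
        )
        for r in df.itertuples(index=False)
    ]
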