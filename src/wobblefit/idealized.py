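"""Synthetic idealized nucleic-acid geometry with controlled torsions.

Builds nucleotides atom by atom from internal coordinates (bond lengths,
bond angles, torsions) so that every construction parameter — sugar pucker
phase/amplitude, epsilon/zeta (hence the BI/BII class), gamma, chi — is
known exactly and can be compared against what the survey code measures.
The furanose ring is laid out as a regular pentagon with out-of-plane
displacements calibrated to a target pseudorotation state; residues are
chained through the phosphodiester junction with prescribed epsilon, zeta
and alpha; a complementary strand is positioned so C1'-C1' distances across
pairs sit near the canonical ~10.5 A.

Everything produced here is synthetic, idealized geometry: it carries
B-form-like torsions and realistic bond lengths but is not a refined
crystal structure.  It exists to exercise the survey pipeline end to end
(file I/O included) without external coordinate data.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.optimize import least_squares

from .survey import NucleotideCoords, dihedral, pseudorotation, superpose

__all__ = ["SugarPucker", "NucleotideParams", "build_nucleotide",
           "build_strand", "idealized_duplex", "idealized_triplet",
           "write_pdb", "C2_ENDO", "C3_ENDO", "BI_JUNCTION", "BII_JUNCTION"]

RING_ORDER = ("C1'", "C2'", "C3'", "C4'", "O4'")
PURINE_BASES = {"DA", "DG"}

# canonical pucker states (phase deg, amplitude deg, delta deg)
C2_ENDO = (162.0, 35.0, 143.0)
C3_ENDO = (18.0, 38.0, 85.0)
# epsilon/zeta pairs giving wrapped differences of 280 (BI) and 90 (BII)
BI_JUNCTION = (190.0, 270.0)
BII_JUNCTION = (260.0, 170.0)


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from A-B-C with |CD| = bond, angle(BCD) = angle and
    torsion(ABCD) = torsion, consistent with :func:`survey.dihedral`."""
    th = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * (-np.cos(th) * bc + np.sin(th) * (np.cos(phi) * m + np.sin(phi) * n))
    return c + d


def _ring_coords(phase: float, amplitude: float) -> dict[str, np.ndarray]:
    """Pentagon-plus-pucker ring whose measured pseudorotation matches the
    target (phase, amplitude) — the construction phase and z-scale are
    calibrated numerically against the analysis-side convention."""
    radius = 1.48 / (2.0 * np.sin(np.pi / 5.0))
    ang = 2.0 * np.pi * np.arange(5) / 5.0

    def coords(construct_phase, zscale):
        z = zscale * np.cos(2.0 * ang + construct_phase)
        pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), z])
        return {name: pts[i] for i, name in enumerate(RING_ORDER)}

    def measured(construct_phase, zscale):
        atoms = coords(construct_phase, zscale)
        ring = [atoms[n] for n in RING_ORDER] + [atoms[RING_ORDER[0]]]
        # nu_k is the torsion about bond (ring[k+1], ring[k+2]) in the
        # C1'..O4' ordering: nu0 = C4'-O4'-C1'-C2' etc.
        seq = [atoms["C4'"], atoms["O4'"], atoms["C1'"], atoms["C2'"],
               atoms["C3'"], atoms["C4'"], atoms["O4'"], atoms["C1'"]]
        nu = [dihedral(seq[k], seq[k + 1], seq[k + 2], seq[k + 3])
              for k in range(5)]
        return pseudorotation(nu)

    # coarse scan then refine
    best = None
    for cp in np.linspace(0.0, 2.0 * np.pi, 37):
        p, _ = measured(cp, 0.4)
        err = abs((p - phase + 180.0) % 360.0 - 180.0)
        if best is None or err < best[1]:
            best = (cp, err)

    def resid(x):
        p, nm = measured(x[0], x[1])
        dp = (p - phase + 180.0) % 360.0 - 180.0
        return [dp, nm - amplitude]

    sol = least_squares(resid, x0=[best[0], 0.4], xtol=1e-12, ftol=1e-12)
    return coords(sol.x[0], sol.x[1])


@dataclass
class SugarPucker:
    phase: float = 162.0
    amplitude: float = 35.0
    delta: float = 143.0


@dataclass
class NucleotideParams:
    """Construction parameters for one nucleotide (all torsions degrees)."""

    base: str = "DG"
    pucker: SugarPucker = None
    chi: float = 250.0
    gamma: float = 54.0
    beta: float = 171.0
    # junction into the NEXT residue
    epsilon: float = BI_JUNCTION[0]
    zeta: float = BI_JUNCTION[1]
    alpha: float = 300.0

    def __post_init__(self):
        if self.pucker is None:
            self.pucker = SugarPucker()


def build_nucleotide(params: NucleotideParams) -> dict[str, np.ndarray]:
    """One nucleotide (with its own 5' phosphate) in a local frame."""
    atoms = _ring_coords(params.pucker.phase, params.pucker.amplitude)
    c1, c2, c3, c4, o4 = (atoms[n] for n in RING_ORDER)

    # nu3 locates the ring O4' about the C3'-C4' bond; the exocyclic C5'
    # sits on the other tetrahedral slot
    nu3 = dihedral(c2, c3, c4, o4)
    atoms["C5'"] = _nerf(c2, c3, c4, 1.51, 115.0, nu3 - 122.0)
    atoms["O5'"] = _nerf(c3, c4, atoms["C5'"], 1.44, 110.5, params.gamma)
    atoms["P"] = _nerf(c4, atoms["C5'"], atoms["O5'"], 1.59, 120.0, params.beta)
    atoms["O3'"] = _nerf(atoms["C5'"], c4, c3, 1.42, 110.0, params.pucker.delta)

    # glycosidic nitrogen opposite the ring oxygen, then the chi-defining
    # base carbon
    nu1 = dihedral(o4, c1, c2, c3)
    n_name = "N9" if params.base in PURINE_BASES else "N1"
    c_name = "C4" if params.base in PURINE_BASES else "C2"
    atoms[n_name] = _nerf(c3, c2, c1, 1.48, 113.0, -nu1 + 118.0)
    atoms[c_name] = _nerf(o4, c1, atoms[n_name], 1.37, 126.0, params.chi)
    return atoms


def build_strand(param_list: list[NucleotideParams]) -> list[dict[str, np.ndarray]]:
    """Chain nucleotides 5'->3' honoring each junction's epsilon/zeta/alpha.

    The next residue is rigidly placed so its (P, O5', C5') land on the
    positions dictated by the junction torsions — an exact three-point
    superposition because the internal geometry matches by construction.
    """
    residues = [build_nucleotide(param_list[0])]
    for i in range(1, len(param_list)):
        prev = residues[-1]
        pars = param_list[i - 1]
        p_t = _nerf(prev["C4'"], prev["C3'"], prev["O3'"], 1.60, 119.0,
                    pars.epsilon)
        o5_t = _nerf(prev["C3'"], prev["O3'"], p_t, 1.59, 104.0, pars.zeta)
        c5_t = _nerf(prev["O3'"], p_t, o5_t, 1.44, 120.0, pars.alpha)

        nxt = build_nucleotide(param_list[i])
        moving = np.array([nxt["P"], nxt["O5'"], nxt["C5'"]])
        fixed = np.array([p_t, o5_t, c5_t])
        R, t, _ = superpose(moving, fixed)
        residues.append({k: R @ v + t for k, v in nxt.items()})
    return residues


_COMPLEMENT = {"DG": "DC", "DC": "DG", "DA": "DT", "DT": "DA"}


def idealized_duplex(bases: list[str],
                     params1: list[NucleotideParams] | None = None,
                     params2: list[NucleotideParams] | None = None,
                     c1c1: float = 10.5) -> dict[tuple[str, int], NucleotideCoords]:
    """A duplex of len(bases) pairs: strand A runs 5'->3' with the given
    bases, strand B carries the complement (antiparallel).  Strand B is
    rigidly positioned so paired C1' atoms sit ~*c1c1* Angstrom apart along
    the C1'->base direction of strand A."""
    n = len(bases)
    if params1 is None:
        params1 = [NucleotideParams(base=b) for b in bases]
    for p, b in zip(params1, bases):
        p.base = b
    comp = [_COMPLEMENT[b] for b in bases][::-1]
    if params2 is None:
        params2 = [NucleotideParams(base=b) for b in comp]
    for p, b in zip(params2, comp):
        p.base = b

    strand1 = build_strand(params1)
    strand2 = build_strand(params2)

    # targets: across each pair, c1c1 away along the glycosidic direction
    targets, moving = [], []
    for j in range(n):
        r1 = strand1[j]
        n_name = "N9" if bases[j] in PURINE_BASES else "N1"
        u = r1[n_name] - r1["C1'"]
        u = u / np.linalg.norm(u)
        targets.append(r1["C1'"] + c1c1 * u)
        moving.append(strand2[n - 1 - j]["C1'"])
    R, t, _ = superpose(np.array(moving), np.array(targets))
    strand2 = [{k: R @ v + t for k, v in res.items()} for res in strand2]

    # exact separation for the central pair (the mismatch slot in triplets)
    jc = n // 2
    r1c = strand1[jc]["C1'"]
    r2c = strand2[n - 1 - jc]["C1'"]
    d = r2c - r1c
    shift = (c1c1 / np.linalg.norm(d) - 1.0) * d
    strand2 = [{k: v + shift for k, v in res.items()} for res in strand2]

    out: dict[tuple[str, int], NucleotideCoords] = {}
    for strand, chain, blist, plist in ((strand1, "A", bases, params1),
                                        (strand2, "B", comp, params2)):
        for i, res in enumerate(strand):
            nxt = {}
            if i + 1 < len(strand):
                nxt = {"P": strand[i + 1]["P"], "O5'": strand[i + 1]["O5'"]}
            out[(chain, i + 1)] = NucleotideCoords(
                chain=chain, resnum=i + 1, base=blist[i],
                atoms=dict(res), next_atoms=nxt, structure="idealized")
    return out


def idealized_triplet(center: str = "DG") -> dict[tuple[str, int], NucleotideCoords]:
    """The idealized three-pair reference: a central G-C pair (by default)
    flanked by one Watson-Crick pair on each side, B-form-like throughout.
    Used as the fixed frame for superposing mismatch triplets."""
    return idealized_duplex(["DC", center, "DA"])


def write_pdb(residues: dict[tuple[str, int], NucleotideCoords], path: str) -> None:
    """Write a residue set to a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = "idealized"
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for (chain_name, resnum) in sorted(residues):
        nt = residues[(chain_name, resnum)]
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name)
        res = gemmi.Residue()
        res.name = nt.base
        res.seqid = gemmi.SeqId(resnum, " ")
        for aname, pos in nt.atoms.items():
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(aname.strip("0123456789'*")[0])
            atom.pos = gemmi.Position(*pos)
            res.add_atom(atom)
        chains[chain_name].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
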