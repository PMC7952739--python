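"""Build a one-bead-per-residue structure-based model from a crystal structure.

The chain is coarse-grained to its CA positions.  Domains are assigned from
residue ranges; designated linker/tail residues are flexible and receive no
native-referenced (structure-based) terms beyond their backbone bonds.  The
b and b' domains keep distinct labels for geometry but share one folded unit
for contact construction, so native contacts may span the b/b' interface but
never connect a, b-b' and a'.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.spatial.distance import pdist, squareform
from Bio.SeqUtils import seq1

from .structure_io import Structure

__all__ = [
    "CGChain",
    "DomainDefinition",
    "Topology",
    "TopologyParams",
    "er60_domain_definition",
    "build_cg_chain",
    "define_domains",
    "build_topology",
    "assign_charges",
]

logger = logging.getLogger(__name__)

POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")


@dataclass
class CGChain:
    """Ordered CA beads of one protein chain.

    ``domain`` holds labels from {a, b, bp, ap, linker, ctail} ('' before
    assignment); ``folded_unit`` is -1 for flexible beads and a shared id for
    beads that belong to the same folded block (b and b' share one).
    """

    res_id: np.ndarray
    res_code: np.ndarray
    coord: np.ndarray
    charge: np.ndarray = None
    domain: np.ndarray = None
    flexible: np.ndarray = None
    folded_unit: np.ndarray = None

    def __post_init__(self) -> None:
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.res_code = np.asarray(self.res_code, dtype=object)
        self.coord = np.asarray(self.coord, dtype=float)
        n = len(self.res_id)
        if self.coord.shape != (n, 3):
            raise ValueError("coord must be (n_beads, 3)")
        if self.charge is None:
            self.charge = np.zeros(n)
        if self.domain is None:
            self.domain = np.array([""] * n, dtype=object)
        if self.flexible is None:
            self.flexible = np.zeros(n, dtype=bool)
        if self.folded_unit is None:
            self.folded_unit = np.full(n, -1, dtype=int)

    @property
    def n_beads(self) -> int:
        return len(self.res_id)

    def domain_indices(self, label: str, include_flexible: bool = True) -> np.ndarray:
        idx = np.nonzero(self.domain == label)[0]
        if not include_flexible:
            idx = idx[~self.flexible[idx]]
        return idx

    @property
    def sequence(self) -> str:
        return "".join(self.res_code)


@dataclass
class DomainDefinition:
    """Residue ranges (inclusive, structure numbering) per domain label."""

    ranges: dict
    flexible_labels: frozenset = frozenset({"linker", "ctail"})
    # b and b' fold together; a' and its flexible C-tail are separate labels
    folded_units: tuple = (("a",), ("b", "bp"), ("ap",))

    def label_of(self, res_id: int) -> str | None:
        for label, spans in self.ranges.items():
            for lo, hi in spans:
                if lo <= res_id <= hi:
                    return label
        return None


def er60_domain_definition() -> DomainDefinition:
    """The shipped default domain boundaries for mature human ER-60."""
    raw = json.loads(
        resources.files("cgsaxs.data").joinpath("er60_domains.json").read_text()
    )
    ranges = {k: [tuple(span) for span in v] for k, v in raw["ranges"].items()}
    return DomainDefinition(ranges=ranges,
                            flexible_labels=frozenset(raw["flexible_labels"]))


def build_cg_chain(structure: Structure, chain_id: str | None = None) -> CGChain:
    """One bead per residue at the CA position of the selected chain."""
    ca = structure.select_ca(chain_id)
    res_id = ca.res_id
    uniq, counts = np.unique(res_id, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1]
        raise ValueError(f"duplicate CA records for residues {dup.tolist()}")
    gaps = np.nonzero(np.diff(res_id) > 1)[0]
    if gaps.size:
        missing = [f"{res_id[g]+1}..{res_id[g+1]-1}" for g in gaps]
        logger.warning("chain has numbering gaps (no CA) at: %s", ", ".join(missing))
    codes = np.array([seq1(rn.capitalize()) for rn in ca.res_name], dtype=object)
    if np.any(codes == "X"):
        bad = ca.res_name[codes == "X"]
        raise ValueError(f"non-standard residues without CA mapping: {set(bad)}")
    return CGChain(res_id=res_id, res_code=codes, coord=ca.coord.copy())


def define_domains(chain: CGChain, definition: DomainDefinition) -> CGChain:
    """Return a copy of the chain with domain labels, flexibility and units set."""
    for label, spans in definition.ranges.items():
        for lo, hi in spans:
            if not np.any((chain.res_id >= lo) & (chain.res_id <= hi)):
                raise ValueError(f"boundary range {lo}-{hi} ({label}) matches no residue")
    domain = np.empty(chain.n_beads, dtype=object)
    for i, rid in enumerate(chain.res_id):
        label = definition.label_of(int(rid))
        if label is None:
            raise ValueError(f"residue {rid} not covered by any domain range")
        domain[i] = label
    flexible = np.array([d in definition.flexible_labels for d in domain], dtype=bool)
    unit_of = {}
    for uid, labels in enumerate(definition.folded_units):
        for lbl in labels:
            unit_of[lbl] = uid
    folded_unit = np.array(
        [-1 if flexible[i] else unit_of.get(domain[i], -1) for i in range(chain.n_beads)],
        dtype=int,
    )
    return replace(chain, domain=domain, flexible=flexible, folded_unit=folded_unit)


@dataclass
class TopologyParams:
    """Force-field strengths, in kBT at 300 K and Angstrom."""

    k_bond: float = 100.0        # kBT/A^2
    k_angle: float = 20.0        # kBT/rad^2, native angles
    k_dihedral: float = 1.0      # kBT, native dihedrals
    eps_contact: float = 2.0     # kBT per native contact
    k_angle_flex: float = 5.0    # kBT/rad^2, generic loop angle
    theta0_flex: float = np.deg2rad(120.0)


@dataclass
class Topology:
    """Structure-based terms of the CG model, as index/parameter arrays.

    Angle rows carry a ``native`` flag: non-native rows are the generic loop
    angle that only prevents chain collapse and references no native geometry.
    ``exclusions`` lists pairs (1-2, 1-3 and native-contact pairs) omitted
    from the non-bonded terms.
    """

    bond_idx: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_idx: np.ndarray
    angle_theta0: np.ndarray
    angle_k: np.ndarray        # nominal stiffness, kBT/rad^2 at theta0
    angle_kcos: np.ndarray     # stiffness of the cos-form actually evaluated
    angle_native: np.ndarray
    dihedral_idx: np.ndarray
    dihedral_phi0: np.ndarray
    dihedral_k: np.ndarray
    contact_idx: np.ndarray
    contact_r0: np.ndarray
    contact_eps: np.ndarray
    exclusions: set = field(default_factory=set)

    @property
    def n_contacts(self) -> int:
        return len(self.contact_r0)


def _angle(p1, p2, p3) -> float:
    v1, v2 = p1 - p2, p3 - p2
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _dihedral(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def build_topology(chain: CGChain, contact_cutoff: float = 6.5,
                   params: TopologyParams | None = None) -> Topology:
    """Native-geometry bonds/angles/dihedrals/contacts for the chain.

    Native contacts: CA-CA distance <= ``contact_cutoff`` in the reference
    structure, |i-j| >= 4, both beads in the same folded unit.  Angles and
    dihedrals are built only where all member beads are non-flexible; triplets
    containing a flexible bead get the weak generic angle instead.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    p = params or TopologyParams()
    n = chain.n_beads
    x = chain.coord

    bond_idx = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    bond_r0 = np.linalg.norm(x[1:] - x[:-1], axis=1)
    bond_k = np.full(n - 1, p.k_bond)

    # Angles are evaluated as E = 1/2 k_cos (cos t - cos t0)^2, which matches
    # a harmonic in theta near t0 (k_cos = k/sin^2 t0) and remains finite at
    # collinear geometries; sin^2 is floored so nearly straight native
    # triples get a soft, not infinite, stiffness.
    angle_idx, angle_theta0, angle_k, angle_kcos, angle_native = [], [], [], [], []
    for i in range(n - 2):
        trip = (i, i + 1, i + 2)
        if not chain.flexible[list(trip)].any():
            theta0, k = _angle(x[i], x[i + 1], x[i + 2]), p.k_angle
            native = True
        else:
            theta0, k = p.theta0_flex, p.k_angle_flex
            native = False
        angle_idx.append(trip)
        angle_theta0.append(theta0)
        angle_k.append(k)
        angle_kcos.append(k / max(np.sin(theta0) ** 2, 0.1))
        angle_native.append(native)

    # Dihedrals only where the native inner angles are far from collinear;
    # a degenerate reference makes the torsion undefined.
    dihedral_idx, dihedral_phi0, dihedral_k = [], [], []
    for i in range(n - 3):
        quad = (i, i + 1, i + 2, i + 3)
        if chain.flexible[list(quad)].any():
            continue
        t1 = _angle(x[i], x[i + 1], x[i + 2])
        t2 = _angle(x[i + 1], x[i + 2], x[i + 3])
        if min(np.sin(t1), np.sin(t2)) < 0.3:
            continue
        dihedral_idx.append(quad)
        dihedral_phi0.append(_dihedral(x[i], x[i + 1], x[i + 2], x[i + 3]))
        dihedral_k.append(p.k_dihedral)

    dmat = squareform(pdist(x))
    contact_idx, contact_r0 = [], []
    for i in range(n):
        ui = chain.folded_unit[i]
        if ui < 0:
            continue
        for j in range(i + 4, n):
            if chain.folded_unit[j] == ui and dmat[i, j] <= contact_cutoff:
                contact_idx.append((i, j))
                contact_r0.append(dmat[i, j])

    exclusions = set()
    for i in range(n - 1):
        exclusions.add((i, i + 1))
    for i in range(n - 2):
        exclusions.add((i, i + 2))
    exclusions.update(contact_idx)

    return Topology(
        bond_idx=bond_idx, bond_r0=bond_r0, bond_k=bond_k,
        angle_idx=np.array(angle_idx, dtype=int).reshape(-1, 3),
        angle_theta0=np.array(angle_theta0), angle_k=np.array(angle_k),
        angle_kcos=np.array(angle_kcos),
        angle_native=np.array(angle_native, dtype=bool),
        dihedral_idx=np.array(dihedral_idx, dtype=int).reshape(-1, 4),
        dihedral_phi0=np.array(dihedral_phi0), dihedral_k=np.array(dihedral_k),
        contact_idx=np.array(contact_idx, dtype=int).reshape(-1, 2),
        contact_r0=np.array(contact_r0),
        contact_eps=np.full(len(contact_r0), p.eps_contact),
        exclusions=exclusions,
    )


def assign_charges(chain: CGChain, mode: str = "loops-explicit+surface-proxy",
                   burial_neighbors: int = 14, burial_radius: float = 10.0) -> CGChain:
    """Assign +/-1 elementary charges to the beads.

    Flexible-loop beads always follow the explicit rule: +1 per Lys, -1 per
    Asp/Glu.  Folded-region charges depend on ``mode``:

    ``loops-explicit+surface-proxy``
        Titratable beads (Lys/Arg +1, Asp/Glu -1) are charged only when
        surface-exposed, using a burial proxy: a CA with more than
        ``burial_neighbors`` neighbour CAs within ``burial_radius`` is
        considered buried and left neutral.
    ``all-titratable``
        Every Lys/Arg is +1 and every Asp/Glu is -1.

    Histidine is left neutral (pH 7.4).
    """
    if mode not in ("loops-explicit+surface-proxy", "all-titratable"):
        raise ValueError(f"unknown charge mode {mode!r}")
    if not chain.domain.all():
        raise ValueError("domains must be defined before charge assignment")
    n = chain.n_beads
    charge = np.zeros(n)
    if mode == "loops-explicit+surface-proxy":
        dmat = squareform(pdist(chain.coord))
        n_neigh = (dmat < burial_radius).sum(axis=1) - 1
        exposed = n_neigh <= burial_neighbors
    else:
        exposed = np.ones(n, dtype=bool)
    for i in range(n):
        code = chain.res_code[i]
        if chain.flexible[i]:
            if code == "K":
                charge[i] = +1.0
            elif code in NEGATIVE_RESIDUES:
                charge[i] = -1.0
        elif exposed[i]:
            if code in POSITIVE_RESIDUES:
                charge[i] = +1.0
            elif code in NEGATIVE_RESIDUES:
                charge[i] = -1.0
    out = replace(chain, charge=charge)
    logger.info("assigned charges (%s): total %+.0f e", mode, charge.sum())
    return out
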