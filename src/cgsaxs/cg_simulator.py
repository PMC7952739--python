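"""Energies, forces and Langevin dynamics for the CG structure-based model.

Units: energy in kBT at 300 K, length in Angstrom, bead mass 1, time in the
reduced unit sqrt(m A^2 / kBT).  The potential is the native-referenced
(Go-type) sum of harmonic bonds/angles, 1-cos dihedrals and 12-10 native
contacts, plus repulsive excluded volume, Debye-Hueckel screened
electrostatics at the configured ionic strength, and an optional short-range
hydrophobic well (off by default).  Flexible loop beads carry no
native-referenced term beyond their backbone bonds; a weak generic angle
keeps loops from collapsing.

The integrator is the BAOAB splitting of Langevin dynamics; with friction 0
it reduces exactly to velocity Verlet, which the energy-drift test exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .cg_builder import CGChain, Topology

__all__ = [
    "SimulationParams",
    "Trajectory",
    "COMDistanceRestraint",
    "potential_energy",
    "forces",
    "run_langevin",
    "native_contact_fraction",
    "expected_frame_count",
    "merge_trajectories",
]

# e^2/(4 pi eps0 kB) in Angstrom*Kelvin: Bjerrum length = _BJERRUM_AK/(eps_r*T)
_BJERRUM_AK = 1.671e5
# particles per A^3 for a 1 mol/L solution
_MOLAR_PER_A3 = 6.02214076e-4

HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWYC")


@dataclass
class SimulationParams:
    """Knobs of one Langevin run (defaults follow the 300 K, 150 mM setup)."""

    temperature: float = 300.0       # K
    dt: float = 0.01                 # reduced time units
    friction: float = 0.5            # 1/reduced time
    n_steps: int = 0
    save_interval: int = 500
    seed: int = 0
    ionic_strength: float = 0.150    # mol/L
    dielectric: float = 78.0
    contacts: bool = True
    excluded_volume: bool = True
    electrostatics: bool = True
    hydrophobic: bool = False
    generic_angles: bool = True   # weak non-native loop angle term
    sigma_ev: float = 4.0            # A
    eps_ev: float = 0.2              # kBT
    eps_hp: float = 0.2              # kBT
    r_on_hp: float = 6.0             # A
    blowup_threshold: float = 1.0e5  # A

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.save_interval <= 0:
            raise ValueError("save_interval must be positive")
        if self.electrostatics and self.ionic_strength <= 0:
            raise ValueError("ionic strength must be > 0 with electrostatics on")

    @property
    def kT(self) -> float:
        """Thermal energy in units of kBT at 300 K."""
        return self.temperature / 300.0

    @property
    def bjerrum_length(self) -> float:
        return _BJERRUM_AK / (self.dielectric * 300.0)

    @property
    def debye_length(self) -> float:
        kappa2 = 8.0 * np.pi * self.bjerrum_length * _MOLAR_PER_A3 * self.ionic_strength
        return 1.0 / np.sqrt(kappa2)


@dataclass
class COMDistanceRestraint:
    """Harmonic restraint on the COM-COM distance of two bead groups.

    Used by the synthetic two-state generator only; production sampling runs
    without it and tests can recognise restrained trajectories through the
    metadata recorded on the Trajectory.
    """

    idx_a: np.ndarray
    idx_b: np.ndarray
    target: float   # A
    k: float = 1.0  # kBT/A^2

    def describe(self) -> dict:
        return {"type": "com_distance", "target": float(self.target),
                "k": float(self.k), "n_a": int(len(self.idx_a)),
                "n_b": int(len(self.idx_b))}

    def energy_forces(self, coords: np.ndarray):
        ca = coords[self.idx_a].mean(axis=0)
        cb = coords[self.idx_b].mean(axis=0)
        d = ca - cb
        dist = float(np.linalg.norm(d))
        dev = dist - self.target
        e = 0.5 * self.k * dev * dev
        f = np.zeros_like(coords)
        if dist > 1e-12:
            g = self.k * dev * d / dist
            f[self.idx_a] -= g / len(self.idx_a)
            f[self.idx_b] += g / len(self.idx_b)
        return e, f


class _System:
    """Precomputed index arrays for fast vectorized energy/force evaluation."""

    def __init__(self, chain: CGChain, topology: Topology, params: SimulationParams):
        self.chain = chain
        self.top = topology
        self.params = params
        n = chain.n_beads
        iu, ju = np.triu_indices(n, k=1)
        excl = topology.exclusions
        keep = np.array([(i, j) not in excl for i, j in zip(iu, ju)], dtype=bool)
        self.ev_i, self.ev_j = iu[keep], ju[keep]

        # electrostatics: charged pairs, excluding 1-2/1-3 but not contacts
        q = chain.charge
        qq = q[iu] * q[ju]
        near = (ju - iu) <= 2
        em = (qq != 0) & ~near
        self.el_i, self.el_j, self.el_qq = iu[em], ju[em], qq[em]

        hydro = np.array([c in HYDROPHOBIC_RESIDUES for c in chain.res_code])
        hm = hydro[iu] & hydro[ju] & ~near
        self.hp_i, self.hp_j = iu[hm], ju[hm]

        self.kappa = 1.0 / params.debye_length
        # prefactor so that U [kBT at 300 K] = pref * q1q2 * exp(-kappa r)/r
        self.elec_pref = _BJERRUM_AK / (params.dielectric * 300.0)

    # --- individual terms -------------------------------------------------

    def _pair_dist(self, coords, ii, jj):
        d = coords[ii] - coords[jj]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        if r.size and r.min() < 1e-9:
            raise ValueError("overlapping beads (r = 0) in pair interaction")
        return d, r

    def energy_forces(self, coords: np.ndarray):
        p = self.params
        top = self.top
        f = np.zeros_like(coords)
        comp = {}

        # bonds: E = 1/2 k (r - r0)^2
        d, r = self._pair_dist(coords, top.bond_idx[:, 0], top.bond_idx[:, 1])
        dev = r - top.bond_r0
        comp["bond"] = float(np.sum(0.5 * top.bond_k * dev * dev))
        g = (top.bond_k * dev / r)[:, None] * d
        np.add.at(f, top.bond_idx[:, 0], -g)
        np.add.at(f, top.bond_idx[:, 1], g)

        # angles: E = 1/2 k_cos (cos theta - cos theta0)^2 — harmonic-
        # equivalent near theta0, finite at collinear geometries
        angle_rows = np.ones(len(top.angle_idx), dtype=bool)
        if not p.generic_angles:
            angle_rows &= top.angle_native
        if angle_rows.any():
            i, j, k = top.angle_idx[angle_rows].T
            u = coords[i] - coords[j]
            v = coords[k] - coords[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh, vh = u / nu[:, None], v / nv[:, None]
            cos = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
            kcos = top.angle_kcos[angle_rows]
            dcos = cos - np.cos(top.angle_theta0[angle_rows])
            comp["angle"] = float(np.sum(0.5 * kcos * dcos * dcos))
            dEdcos = kcos * dcos
            # dcos/dri = (vh - cos*uh)/nu ; dcos/drk = (uh - cos*vh)/nv
            di = (vh - cos[:, None] * uh) / nu[:, None]
            dk = (uh - cos[:, None] * vh) / nv[:, None]
            np.add.at(f, i, -dEdcos[:, None] * di)
            np.add.at(f, k, -dEdcos[:, None] * dk)
            np.add.at(f, j, dEdcos[:, None] * (di + dk))
        else:
            comp["angle"] = 0.0

        # dihedrals: E = k (1 - cos(phi - phi0))
        if len(top.dihedral_idx):
            i, j, k, l = top.dihedral_idx.T
            b1 = coords[j] - coords[i]
            b2 = coords[k] - coords[j]
            b3 = coords[l] - coords[k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            m1 = np.cross(n1, b2 / nb2[:, None])
            x = np.einsum("ij,ij->i", n1, n2)
            y = np.einsum("ij,ij->i", m1, n2)
            phi = np.arctan2(y, x)
            comp["dihedral"] = float(
                np.sum(top.dihedral_k * (1.0 - np.cos(phi - top.dihedral_phi0)))
            )
            dEdp = top.dihedral_k * np.sin(phi - top.dihedral_phi0)
            # clamp against transient collinear geometries
            n1sq = np.clip(np.einsum("ij,ij->i", n1, n1), 1e-2, None)
            n2sq = np.clip(np.einsum("ij,ij->i", n2, n2), 1e-2, None)
            # exact torsion gradient for b1 = rj - ri, b2 = rk - rj, b3 = rl - rk
            dphi_i = (nb2 / n1sq)[:, None] * n1
            dphi_l = -(nb2 / n2sq)[:, None] * n2
            t = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
            s = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
            dphi_j = -(1.0 + t) * dphi_i + s * dphi_l
            dphi_k = t * dphi_i - (1.0 + s) * dphi_l
            g = dEdp[:, None]
            np.add.at(f, i, -g * dphi_i)
            np.add.at(f, j, -g * dphi_j)
            np.add.at(f, k, -g * dphi_k)
            np.add.at(f, l, -g * dphi_l)
        else:
            comp["dihedral"] = 0.0

        # native contacts: 12-10 well with minimum -eps at r0
        if p.contacts and top.n_contacts:
            d, r = self._pair_dist(coords, top.contact_idx[:, 0], top.contact_idx[:, 1])
            s = top.contact_r0 / r
            s10 = s ** 10
            s12 = s10 * s * s
            comp["contact"] = float(np.sum(top.contact_eps * (5 * s12 - 6 * s10)))
            dEdr = top.contact_eps * 60.0 * (s10 - s12) / r
            g = (dEdr / r)[:, None] * d
            np.add.at(f, top.contact_idx[:, 0], -g)
            np.add.at(f, top.contact_idx[:, 1], g)
        else:
            comp["contact"] = 0.0

        # excluded volume: E = eps (sigma/r)^12, repulsive only
        if p.excluded_volume and self.ev_i.size:
            d, r = self._pair_dist(coords, self.ev_i, self.ev_j)
            s12 = (p.sigma_ev / r) ** 12
            comp["excluded_volume"] = float(p.eps_ev * np.sum(s12))
            dEdr = -12.0 * p.eps_ev * s12 / r
            g = (dEdr / r)[:, None] * d
            np.add.at(f, self.ev_i, -g)
            np.add.at(f, self.ev_j, g)
        else:
            comp["excluded_volume"] = 0.0

        # Debye-Hueckel electrostatics
        if p.electrostatics and self.el_i.size:
            d, r = self._pair_dist(coords, self.el_i, self.el_j)
            e = self.elec_pref * self.el_qq * np.exp(-self.kappa * r) / r
            comp["electrostatic"] = float(np.sum(e))
            dEdr = -e * (self.kappa + 1.0 / r)
            g = (dEdr / r)[:, None] * d
            np.add.at(f, self.el_i, -g)
            np.add.at(f, self.el_j, g)
        else:
            comp["electrostatic"] = 0.0

        # optional hydrophobic well: smooth switch from -eps to 0 around r_on
        if p.hydrophobic and self.hp_i.size:
            d, r = self._pair_dist(coords, self.hp_i, self.hp_j)
            th = np.tanh(r - p.r_on_hp)
            comp["hydrophobic"] = float(np.sum(-p.eps_hp * 0.5 * (1.0 - th)))
            dEdr = p.eps_hp * 0.5 * (1.0 - th * th)
            g = (dEdr / r)[:, None] * d
            np.add.at(f, self.hp_i, -g)
            np.add.at(f, self.hp_j, g)
        else:
            comp["hydrophobic"] = 0.0

        comp["total"] = float(sum(comp.values()))
        return comp, f


def potential_energy(chain: CGChain, topology: Topology, coords: np.ndarray,
                     params: SimulationParams | None = None) -> dict:
    """Energy decomposition at ``coords`` (components sum to ``total``)."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    comp, _ = _System(chain, topology, params or SimulationParams()).energy_forces(coords)
    return comp


def forces(chain: CGChain, topology: Topology, coords: np.ndarray,
           params: SimulationParams | None = None) -> np.ndarray:
    """Per-bead force triples: the negative gradient of :func:`potential_energy`."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    _, f = _System(chain, topology, params or SimulationParams()).energy_forces(coords)
    return f


@dataclass
class Trajectory:
    """Frames saved every ``save_interval`` steps of one or more runs."""

    frames: np.ndarray          # (n_frames, n_beads, 3)
    steps: np.ndarray           # per-frame MD step index
    run_ids: np.ndarray         # per-frame run id
    seed: int
    params: SimulationParams
    potential: np.ndarray = None
    kinetic: np.ndarray = None
    temperature: np.ndarray = None   # instantaneous, K
    restraint: dict | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            self.frames = self.frames.reshape((0, 0, 3)) if self.frames.size == 0 \
                else self.frames
        self.steps = np.asarray(self.steps, dtype=int)
        self.run_ids = np.asarray(self.run_ids, dtype=int)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def save(self, basename: str) -> None:
        """Persist as <basename>.npz plus a JSON metadata sidecar."""
        np.savez_compressed(
            basename + ".npz", frames=self.frames.astype(np.float32),
            steps=self.steps, run_ids=self.run_ids,
            potential=self.potential if self.potential is not None else np.array([]),
            kinetic=self.kinetic if self.kinetic is not None else np.array([]),
            temperature=self.temperature if self.temperature is not None else np.array([]),
        )
        meta = {"seed": int(self.seed), "params": asdict(self.params),
                "restraint": self.restraint}
        with open(basename + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, basename: str) -> "Trajectory":
        data = np.load(basename + ".npz")
        with open(basename + ".json") as fh:
            meta = json.load(fh)
        return cls(
            frames=data["frames"].astype(float), steps=data["steps"],
            run_ids=data["run_ids"], seed=meta["seed"],
            params=SimulationParams(**meta["params"]),
            potential=data["potential"] if data["potential"].size else None,
            kinetic=data["kinetic"] if data["kinetic"].size else None,
            temperature=data["temperature"] if data["temperature"].size else None,
            restraint=meta["restraint"],
        )


def expected_frame_count(n_steps: int, save_interval: int, n_runs: int = 1) -> int:
    """Number of snapshots a sampling protocol produces.

    One frame per completed ``save_interval`` block per run:
    floor(n_steps / save_interval) * n_runs.
    """
    if save_interval <= 0:
        raise ValueError("save_interval must be positive")
    return (n_steps // save_interval) * n_runs


def run_langevin(chain: CGChain, topology: Topology, params: SimulationParams,
                 coords0: np.ndarray | None = None,
                 restraint: COMDistanceRestraint | None = None,
                 run_id: int = 0) -> Trajectory:
    """Sample the canonical ensemble at ``params.temperature`` with BAOAB.

    Frames (and per-frame energies / instantaneous kinetic temperature) are
    recorded every ``save_interval`` steps, the first one after the first
    full interval.  The same seed and parameters give bitwise-identical
    trajectories.  Numerical blow-up aborts with the offending step index.
    """
    x = np.array(chain.coord if coords0 is None else coords0, dtype=float)
    n = chain.n_beads
    system = _System(chain, topology, params)
    rng = np.random.default_rng(params.seed)
    kT = params.kT
    dt = params.dt
    c1 = np.exp(-params.friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)

    v = rng.standard_normal((n, 3)) * np.sqrt(kT)

    def eval_forces(xx):
        comp, ff = system.energy_forces(xx)
        if restraint is not None:
            er, fr = restraint.energy_forces(xx)
            comp["restraint"] = er
            comp["total"] += er
            ff = ff + fr
        return comp, ff

    comp, f = eval_forces(x)
    frames, steps, epot, ekin, temps = [], [], [], [], []
    for step in range(1, params.n_steps + 1):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        if c2 > 0.0:
            v = c1 * v + c2 * rng.standard_normal((n, 3))
        x += 0.5 * dt * v
        comp, f = eval_forces(x)
        v += 0.5 * dt * f
        if not np.all(np.isfinite(x)) or np.abs(x).max() > params.blowup_threshold:
            raise RuntimeError(f"numerical blow-up at step {step}")
        if step % params.save_interval == 0:
            frames.append(x.copy())
            steps.append(step)
            epot.append(comp["total"])
            ke = 0.5 * float(np.sum(v * v))
            ekin.append(ke)
            temps.append(300.0 * 2.0 * ke / (3.0 * n))
    frames = np.array(frames) if frames else np.zeros((0, n, 3))
    return Trajectory(
        frames=frames, steps=np.array(steps, dtype=int),
        run_ids=np.full(len(steps), run_id, dtype=int), seed=params.seed,
        params=params, potential=np.array(epot), kinetic=np.array(ekin),
        temperature=np.array(temps),
        restraint=restraint.describe() if restraint is not None else None,
    )


def merge_trajectories(trajectories: list) -> Trajectory:
    """Concatenate trajectories (e.g. independent runs) into one frame set."""
    if not trajectories:
        raise ValueError("no trajectories to merge")
    first = trajectories[0]
    return Trajectory(
        frames=np.concatenate([t.frames for t in trajectories]),
        steps=np.concatenate([t.steps for t in trajectories]),
        run_ids=np.concatenate([t.run_ids for t in trajectories]),
        seed=first.seed, params=first.params,
        potential=np.concatenate([t.potential for t in trajectories]),
        kinetic=np.concatenate([t.kinetic for t in trajectories]),
        temperature=np.concatenate([t.temperature for t in trajectories]),
        restraint=first.restraint,
    )


def native_contact_fraction(topology: Topology, coords: np.ndarray,
                            tolerance: float = 1.2,
                            contact_subset: np.ndarray | None = None) -> float:
    """Fraction of native contacts formed (r < tolerance * r0)."""
    if topology.n_contacts == 0:
        raise ValueError("topology has no native contacts")
    idx = topology.contact_idx
    r0 = topology.contact_r0
    if contact_subset is not None:
        idx, r0 = idx[contact_subset], r0[contact_subset]
    d = coords[idx[:, 0]] - coords[idx[:, 1]]
    r = np.linalg.norm(d, axis=1)
    return float(np.mean(r < tolerance * r0))
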