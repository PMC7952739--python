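"""Ground-truth synthetic inputs for the whole pipeline.

The generator builds a U-shaped four-domain toy protein (compact
lattice-serpentine domain blobs joined by flexible linkers) whose domain-COM
geometry (theta1, theta2, phi, D) is placed analytically, samples two
conformational sub-states that differ mainly in the edge-domain COM distance
D (a harmonically restrained Langevin run per state), and synthesizes noisy
"experimental" SAXS profiles contaminated by a small dimer/trimer fraction.
Every output is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation
from Bio.SeqUtils import seq3

from .cg_builder import (CGChain, DomainDefinition, Topology, build_cg_chain,
                         define_domains)
from .cg_simulator import (COMDistanceRestraint, SimulationParams, Trajectory,
                           run_langevin)
from .domain_geometry import com_angle, com_dihedral, domain_com
from .saxs_calc import (MixtureComponent, MixtureSpec, coordinate_rg,
                        debye_profile, mixture_profile)
from .structure_io import SAXSProfile, Structure, sequence_average_mass

__all__ = [
    "ToySpec",
    "ExperimentSpec",
    "make_toy_protein",
    "make_two_state_ensemble",
    "synthesize_experiment",
]

_CA_SPACING = 3.8  # A

# deterministic pseudo-sequences; folded domains get a mix including
# titratable and hydrophobic residues, loops carry Lys/Glu to exercise the
# explicit loop-charge rule
_DOMAIN_CYCLE = "ADSTKVLGEQ"
_LINKER_CYCLE = "KGEG"
_TAIL_CYCLE = "GSKE"


@dataclass
class ToySpec:
    """Construction parameters of the toy protein.

    The default target COM geometry reproduces the domain geometry of the
    full-length ER-60 crystal structure (72.0 deg, 132.6 deg, 62.2 deg, 54.5 A), so the default
    toy doubles as a synthetic crystal surrogate.
    """

    beads_per_domain: int = 30
    linker_length: int = 2
    ctail_length: int = 6
    theta1: float = 72.0     # deg, a-b-b'
    theta2: float = 132.6    # deg, b-b'-a'
    phi: float = 62.2        # deg, a-b-b'-a'
    d_aa: float = 54.5       # A, a-a' COM distance
    bb_separation: float = 16.0  # A, b to b' COM distance
    min_separation: float = 3.0  # A
    jitter: float = 0.02     # A, deterministic from seed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beads_per_domain < 1 or self.linker_length < 1:
            raise ValueError("bead counts must be >= 1")
        if not (0 < self.theta1 < 180 and 0 < self.theta2 < 180):
            raise ValueError("target angles must lie in (0, 180)")
        if not (-180 < self.phi <= 180):
            raise ValueError("target dihedral must lie in (-180, 180]")


def _serpentine_blob(n: int, spacing: float = _CA_SPACING) -> np.ndarray:
    """n chain-ordered points on a compact cubic-lattice serpentine, COM at 0.

    Consecutive beads are exactly ``spacing`` apart and no two beads come
    closer than ``spacing`` (simple cubic lattice), so each domain blob is
    self-avoiding and compact by construction.  The walk enters at the
    bottom (-z) layer and exits at the top (+z) layer.
    """
    side = max(1, int(np.ceil(n ** (1.0 / 3.0))))
    pts = []
    for i in range(n):
        z, j = divmod(i, side * side)
        if z % 2 == 1:  # odd layers retrace the even-layer pattern backwards
            j = side * side - 1 - j
        y, x = divmod(j, side)
        if y % 2 == 1:
            x = side - 1 - x
        pts.append((x, y, z))
    out = spacing * np.array(pts, dtype=float)
    return out - out.mean(axis=0)


def _rotation_z_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to ``direction`` (minimal rotation)."""
    d = direction / np.linalg.norm(direction)
    rot, _ = Rotation.align_vectors(d[None, :], np.array([[0.0, 0.0, 1.0]]))
    return rot.as_matrix()


def _place_fourth(a, b, c, length, angle_deg, dihedral_deg):
    """NeRF placement: point d with |cd| = length, angle(b,c,d), dihedral(a,b,c,d)."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)
    d_local = np.array([
        -length * np.cos(theta),
        length * np.sin(theta) * np.cos(phi),
        -length * np.sin(theta) * np.sin(phi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def _solve_domain_coms(spec: ToySpec) -> dict:
    """Analytic COM placement realizing the target (theta1, theta2, phi, D)."""
    b = np.zeros(3)
    bp = np.array([spec.bb_separation, 0.0, 0.0])

    def build(arm):
        t1 = np.deg2rad(spec.theta1)
        a = b + arm * np.array([np.cos(t1), np.sin(t1), 0.0])
        ap = _place_fourth(a, b, bp, arm, spec.theta2, spec.phi)
        return a, ap

    def gap(arm):
        a, ap = build(arm)
        return float(np.linalg.norm(a - ap)) - spec.d_aa

    lo, hi = 2.0, 500.0
    if gap(lo) * gap(hi) > 0:
        raise ValueError(
            "infeasible target geometry: no arm length realizes the requested "
            "D; try a larger d_aa or smaller bb_separation")
    arm = brentq(gap, lo, hi)
    a, ap = build(arm)
    return {"a": a, "b": b, "bp": bp, "ap": ap, "arm": arm}


def _bridge(p_start, p_end, n_beads, perp):
    """n interior beads between two points, zig-zagged off the straight line."""
    pts = []
    for i in range(1, n_beads + 1):
        frac = i / (n_beads + 1)
        base = p_start + frac * (p_end - p_start)
        pts.append(base + ((-1) ** i) * 1.2 * perp)
    return np.array(pts).reshape(-1, 3)


def make_toy_protein(spec: ToySpec | None = None):
    """Build the toy protein; returns (Structure, CGChain, DomainDefinition).

    The realized domain-COM geometry matches the requested one to within a
    fraction of a percent (domain shells are exactly COM-centred; only the
    seeded coordinate jitter perturbs it).  Raises if the requested geometry
    is infeasible or beads come closer than ``spec.min_separation``.
    """
    spec = spec or ToySpec()
    coms = _solve_domain_coms(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.beads_per_domain

    axes = {
        "a": coms["b"] - coms["a"],
        "b": coms["bp"] - coms["a"],
        "bp": coms["ap"] - coms["b"],
        "ap": coms["ap"] - coms["bp"],
    }
    shells = {}
    for lbl in ("a", "b", "bp", "ap"):
        shell = _serpentine_blob(n) @ _rotation_z_to(axes[lbl]).T
        shells[lbl] = shell - shell.mean(axis=0) + coms[lbl]

    perp = np.cross(axes["b"], axes["bp"])
    perp /= np.linalg.norm(perp)

    segments = [
        ("a", shells["a"]),
        ("linker", _bridge(shells["a"][-1], shells["b"][0], spec.linker_length, perp)),
        ("b", shells["b"]),
        ("bp", shells["bp"]),
        ("linker", _bridge(shells["bp"][-1], shells["ap"][0], spec.linker_length, perp)),
        ("ap", shells["ap"]),
    ]
    if spec.ctail_length:
        tail_dir = axes["ap"] / np.linalg.norm(axes["ap"])
        start = shells["ap"][-1]
        tail = np.array([
            start + (i + 1) * _CA_SPACING * tail_dir
            + ((-1) ** i) * 1.2 * perp
            for i in range(spec.ctail_length)
        ])
        segments.append(("ctail", tail))

    coords, labels = [], []
    for lbl, seg in segments:
        coords.append(seg)
        labels.extend([lbl] * len(seg))
    coords = np.concatenate(coords)
    coords = coords + rng.normal(0.0, spec.jitter, coords.shape)

    min_sep = pdist(coords).min()
    if min_sep < spec.min_separation:
        raise ValueError(
            f"generated beads come within {min_sep:.2f} A "
            f"(< {spec.min_separation} A); try a larger d_aa")

    seq = []
    counters = {}
    for lbl in labels:
        cycle = {"linker": _LINKER_CYCLE, "ctail": _TAIL_CYCLE}.get(lbl, _DOMAIN_CYCLE)
        k = counters.get(lbl, 0)
        seq.append(cycle[k % len(cycle)])
        counters[lbl] = k + 1

    n_total = len(coords)
    structure = Structure(
        atom_name=np.array(["CA"] * n_total, dtype=object),
        res_id=np.arange(1, n_total + 1),
        res_name=np.array([seq3(c).upper() for c in seq], dtype=object),
        chain_id=np.array(["A"] * n_total, dtype=object),
        coord=coords,
        title="cgsaxs synthetic four-domain toy protein",
    )

    ranges = {}
    pos = 1
    for lbl, seg in segments:
        span = (pos, pos + len(seg) - 1)
        ranges.setdefault(lbl, []).append(span)
        pos += len(seg)
    definition = DomainDefinition(ranges=ranges)

    chain = define_domains(build_cg_chain(structure), definition)

    realized = _toy_geometry(chain)
    targets = (spec.theta1, spec.theta2, spec.phi, spec.d_aa)
    for name, got, want in zip(("theta1", "theta2", "phi", "D"), realized, targets):
        tol = 2.0 if name != "D" else 0.02 * spec.d_aa
        if abs(got - want) > tol:
            raise AssertionError(
                f"generator self-check failed: {name} = {got:.2f}, target {want}")
    return structure, chain, definition


def _toy_geometry(chain: CGChain):
    c = {lbl: domain_com(chain, chain.coord, lbl) for lbl in ("a", "b", "bp", "ap")}
    return (com_angle(c["a"], c["b"], c["bp"]),
            com_angle(c["b"], c["bp"], c["ap"]),
            com_dihedral(c["a"], c["b"], c["bp"], c["ap"]),
            float(np.linalg.norm(c["a"] - c["ap"])))


def make_two_state_ensemble(chain: CGChain, topology: Topology,
                            open_d: float = 60.0, closed_d: float = 48.0,
                            n_frames: int = 80, seed: int = 0,
                            params: SimulationParams | None = None,
                            k_restraint: float = 1.0,
                            equilibration_steps: int = 2000,
                            save_interval: int = 100):
    """Sample "open" and "closed" sub-state ensembles of the a-a' distance.

    Each state is a Langevin run under a harmonic COM-distance restraint on
    the a/a' domains (restraint metadata is recorded on the trajectory so
    production paths can exclude restrained data).  Returns
    (open_trajectory, closed_trajectory).
    """
    if open_d <= closed_d:
        raise ValueError("open_d must exceed closed_d")
    base = params or SimulationParams()
    idx_a = chain.domain_indices("a", include_flexible=False)
    idx_ap = chain.domain_indices("ap", include_flexible=False)
    out = []
    for state_id, target in enumerate((open_d, closed_d)):
        p = replace(base,
                    n_steps=equilibration_steps + n_frames * save_interval,
                    save_interval=save_interval,
                    seed=seed + state_id)
        restraint = COMDistanceRestraint(idx_a=idx_a, idx_b=idx_ap,
                                         target=target, k=k_restraint)
        traj = run_langevin(chain, topology, p, restraint=restraint,
                            run_id=state_id)
        n_equil = equilibration_steps // save_interval
        traj = Trajectory(
            frames=traj.frames[n_equil:], steps=traj.steps[n_equil:],
            run_ids=traj.run_ids[n_equil:], seed=traj.seed, params=traj.params,
            potential=traj.potential[n_equil:], kinetic=traj.kinetic[n_equil:],
            temperature=traj.temperature[n_equil:], restraint=traj.restraint,
        )
        mean_d = _mean_edge_distance(chain, traj)
        if abs(mean_d - target) > 0.05 * target:
            raise RuntimeError(
                f"restrained ensemble missed its target D: {mean_d:.1f} vs "
                f"{target:.1f} A; the target may be unreachable for this chain")
        out.append(traj)
    return tuple(out)


def _mean_edge_distance(chain: CGChain, trajectory: Trajectory) -> float:
    d = [np.linalg.norm(domain_com(chain, f, "a") - domain_com(chain, f, "ap"))
         for f in trajectory.frames]
    return float(np.mean(d))


@dataclass
class ExperimentSpec:
    """Conditions of one synthetic SAXS experiment.

    Defaults emulate realistic SEC-purified conditions: ~96 wt% monomer contaminated by
    3 wt% dimer and 1 wt% trimer, multiplicative Gaussian noise with
    relative SD sigma(q) = a + b q, and a q grid of 150 points on
    0.01-0.30 1/A.
    """

    noise_a: float = 0.01
    noise_b: float = 0.05     # per 1/A
    weights: tuple = (0.96, 0.03, 0.01)   # monomer, dimer, trimer wt fractions
    q_min: float = 0.01
    q_max: float = 0.30
    n_q: int = 150
    open_d: float = 60.0      # A, "open"-state target (mimics oxidized)
    closed_d: float = 48.0    # A, "closed"-state target (mimics reduced)
    rg_window_halfwidth: float = 0.4   # A, Rg screening window half-width
    chi2_max: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-6:
            raise ValueError("weight fractions must sum to 1")
        if self.noise_a < 0 or self.noise_b < 0:
            raise ValueError("noise coefficients must be >= 0")

    @property
    def q_grid(self) -> np.ndarray:
        return np.linspace(self.q_min, self.q_max, self.n_q)


def _aggregate_coords(frame: np.ndarray, order: int) -> np.ndarray:
    """Rigid side-by-side copies of a frame at contact distance."""
    centered = frame - frame.mean(axis=0)
    extent = centered[:, 0].max() - centered[:, 0].min()
    shift = extent + _CA_SPACING
    return np.concatenate([centered + k * shift * np.array([1.0, 0.0, 0.0])
                           for k in range(order)])


def synthesize_experiment(ensemble: Trajectory, chain: CGChain,
                          spec: ExperimentSpec | None = None):
    """Noisy, aggregate-contaminated "observed" profile for one ensemble.

    Returns (observed, truth, mixture_spec): ``truth`` is the ensemble-
    averaged monomer Debye profile; dimer/trimer contributions come from
    rigid side-by-side copies of the median-Rg frame; ``observed`` is the
    weight-fraction mixture with multiplicative Gaussian noise and a sigma
    column equal to the noise SD.  The mixture spec carries the measured
    aggregate Rg values.
    """
    spec = spec or ExperimentSpec()
    if ensemble.n_frames == 0:
        raise ValueError("ensemble has no frames")
    q = spec.q_grid
    profiles = [debye_profile(f, q_grid=q) for f in ensemble.frames]
    truth_i = np.mean([p.I for p in profiles], axis=0)
    truth = SAXSProfile(q=q, I=truth_i, label="monomer truth",
                        provenance="synthetic")

    rgs = np.array([coordinate_rg(f) for f in ensemble.frames])
    rep = ensemble.frames[int(np.argsort(rgs)[len(rgs) // 2])]
    m1 = sequence_average_mass(chain.sequence)

    components, comp_profiles = [], []
    for order, weight in zip((1, 2, 3), spec.weights):
        if weight == 0:
            continue
        if order == 1:
            components.append(MixtureComponent(order=1, weight=weight, mass=m1,
                                               rg=float(np.mean(rgs))))
            comp_profiles.append(truth)
        else:
            coords = _aggregate_coords(rep, order)
            components.append(MixtureComponent(
                order=order, weight=weight, mass=order * m1,
                rg=coordinate_rg(coords)))
            comp_profiles.append(debye_profile(coords, q_grid=q))
    mixture = MixtureSpec(components=components)
    mixed = mixture_profile(comp_profiles, mixture)

    rng = np.random.default_rng(spec.seed)
    rel = spec.noise_a + spec.noise_b * q
    if np.any(rel > 0):
        noisy = mixed.I * (1.0 + rel * rng.standard_normal(len(q)))
        sigma = rel * mixed.I
        sigma[sigma <= 0] = np.finfo(float).tiny
    else:
        noisy = mixed.I.copy()
        sigma = None
    observed = SAXSProfile(q=q, I=noisy, sigma=sigma, label="observed",
                           provenance="synthetic")
    return observed, truth, mixture
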