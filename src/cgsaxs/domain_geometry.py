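"""Inter-domain conformation analytics for four-domain (a, b, b', a') chains.

Each frame is reduced to domain centres of mass (equal bead masses, flexible
linker/tail beads excluded), from which the two inter-domain angles
theta1 = theta(a-b-b'), theta2 = theta(b-b'-a'), the four-domain dihedral
phi(a-b-b'-a') and the edge-domain distance D(a-a') are computed.  Ensembles
are summarised by b-b'-superposed averaged COM ("ball-and-stick") models,
1-d histograms and normalized 2-d frequency/difference maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .cg_builder import CGChain

__all__ = [
    "GEOMETRY_COLUMNS",
    "AveragedModel",
    "domain_com",
    "com_angle",
    "com_dihedral",
    "kabsch_superpose",
    "geometry_table",
    "averaged_com_model",
    "com_shift",
    "frequency_maps",
]

GEOMETRY_COLUMNS = ("theta1", "theta2", "phi", "D")


def domain_com(chain: CGChain, coords: np.ndarray, label: str,
               mass_weighted: bool = False) -> np.ndarray:
    """Centre of mass of one domain's non-flexible beads."""
    idx = chain.domain_indices(label, include_flexible=False)
    if idx.size == 0:
        raise ValueError(f"domain {label!r} has no (non-flexible) beads")
    coords = np.asarray(coords, dtype=float)
    if mass_weighted:
        from Bio.SeqUtils import molecular_weight
        w = np.array([molecular_weight(chain.res_code[i], seq_type="protein",
                                       monoisotopic=False) for i in idx])
        return np.average(coords[idx], axis=0, weights=w)
    return coords[idx].mean(axis=0)


def com_angle(p1, p2, p3) -> float:
    """Angle at p2 between (p1-p2) and (p3-p2), in degrees [0, 180]."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length vector in angle computation")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def com_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral of the four points, right-handed, in (-180, 180].

    0 deg is the planar cis arrangement, 180 deg planar trans.
    """
    p = [np.asarray(x, float) for x in (p1, p2, p3, p4)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise ValueError("middle vector has zero length")
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate (collinear) points in dihedral")
    m1 = np.cross(n1, b2 / nb2)
    phi = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return float(phi if phi != -180.0 else 180.0)


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray,
                     selection: np.ndarray | None = None):
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns (rotation matrix R, translation t, rmsd) with the fitted mobile
    coordinates given by mobile @ R.T + t; the RMSD is over the selection.
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if selection is None:
        sel_ref, sel_mob = ref, mob
    else:
        sel_ref, sel_mob = ref[selection], mob[selection]
    if len(sel_ref) != len(sel_mob):
        raise ValueError("selections must have equal length")
    if len(sel_ref) < 3:
        raise ValueError("superposition needs at least 3 points")
    cref = sel_ref.mean(axis=0)
    cmob = sel_mob.mean(axis=0)
    # align_vectors solves the Kabsch problem with a proper rotation
    rot, _ = Rotation.align_vectors(sel_ref - cref, sel_mob - cmob)
    R = rot.as_matrix()
    t = cref - cmob @ R.T
    fitted = sel_mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - sel_ref) ** 2, axis=1))))
    return R, t, rmsd


def _frame_geometry(coms: dict) -> tuple:
    a, b, bp, ap = coms["a"], coms["b"], coms["bp"], coms["ap"]
    return (
        com_angle(a, b, bp),
        com_angle(b, bp, ap),
        com_dihedral(a, b, bp, ap),
        float(np.linalg.norm(a - ap)),
    )


def geometry_table(chain: CGChain, frames, mass_weighted: bool = False) -> pd.DataFrame:
    """Per-frame (theta1, theta2, phi, D) with mean/SD summary in ``attrs``."""
    rows = []
    for coords in frames:
        coms = {lbl: domain_com(chain, coords, lbl, mass_weighted)
                for lbl in ("a", "b", "bp", "ap")}
        rows.append(_frame_geometry(coms))
    table = pd.DataFrame(rows, columns=list(GEOMETRY_COLUMNS))
    if len(table):
        table.attrs["summary"] = {
            col: (float(table[col].mean()),
                  float(table[col].std(ddof=1)) if len(table) > 1 else 0.0)
            for col in GEOMETRY_COLUMNS
        }
    return table


@dataclass
class AveragedModel:
    """Domain COMs averaged over an ensemble after b-b' superposition."""

    coms: dict           # label -> (3,) averaged COM
    spread: dict         # label -> RMS deviation of per-frame COMs (A)
    n_frames: int

    def geometry(self) -> tuple:
        """(theta1, theta2, phi, D) of the averaged COM model."""
        return _frame_geometry(self.coms)


def averaged_com_model(chain: CGChain, frames,
                       reference_frame: np.ndarray) -> AveragedModel:
    """Average each domain COM over frames after superposing b-b' beads."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to average")
    sel = np.concatenate([
        chain.domain_indices("b", include_flexible=False),
        chain.domain_indices("bp", include_flexible=False),
    ])
    labels = ("a", "b", "bp", "ap")
    per_frame = {lbl: [] for lbl in labels}
    ref = np.asarray(reference_frame, float)
    for coords in frames:
        R, t, _ = kabsch_superpose(ref, coords, selection=sel)
        fitted = np.asarray(coords, float) @ R.T + t
        for lbl in labels:
            per_frame[lbl].append(domain_com(chain, fitted, lbl))
    coms, spread = {}, {}
    for lbl in labels:
        pts = np.array(per_frame[lbl])
        coms[lbl] = pts.mean(axis=0)
        spread[lbl] = float(np.sqrt(np.mean(np.sum((pts - coms[lbl]) ** 2, axis=1))))
    return AveragedModel(coms=coms, spread=spread, n_frames=len(frames))


def com_shift(model_a: AveragedModel, model_b: AveragedModel, domain: str) -> float:
    """Distance (A) between the averaged COMs of one domain in two models."""
    if domain not in model_a.coms or domain not in model_b.coms:
        raise ValueError(f"domain {domain!r} missing from an averaged model")
    return float(np.linalg.norm(model_a.coms[domain] - model_b.coms[domain]))


def frequency_maps(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   parameters: tuple = ("theta2", "D"),
                   bin_widths: tuple = (5.0, 1.0)):
    """Normalized 2-d frequency maps of two ensembles plus their difference.

    Returns (map_a, map_b, difference, x_edges, y_edges); each map sums to 1
    and the difference is map_a - map_b on shared bins covering both tables.
    """
    px, py = parameters
    wx, wy = bin_widths
    if wx <= 0 or wy <= 0:
        raise ValueError("bin widths must be positive")
    if not len(table_a) or not len(table_b):
        raise ValueError("both tables must be non-empty")
    all_x = np.concatenate([table_a[px], table_b[px]])
    all_y = np.concatenate([table_a[py], table_b[py]])
    x_edges = np.arange(np.floor(all_x.min() / wx) * wx,
                        all_x.max() + wx, wx)
    y_edges = np.arange(np.floor(all_y.min() / wy) * wy,
                        all_y.max() + wy, wy)
    map_a, _, _ = np.histogram2d(table_a[px], table_a[py], bins=(x_edges, y_edges))
    map_b, _, _ = np.histogram2d(table_b[px], table_b[py], bins=(x_edges, y_edges))
    map_a /= map_a.sum()
    map_b /= map_b.sum()
    return map_a, map_b, map_a - map_b, x_edges, y_edges
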