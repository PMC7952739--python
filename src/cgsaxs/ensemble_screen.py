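"""Score trajectory frames against a target SAXS profile and select models.

Every snapshot gets a coordinate Rg and a scale-fitted chi-square against
the target; models are selected by the strict double criterion
chi2 < chi2_max and rg_min < Rg < rg_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cg_builder import CGChain
from .cg_simulator import Trajectory
from .saxs_calc import chi_square, coordinate_rg, debye_profile, guinier_fit
from .structure_io import SAXSProfile

__all__ = ["ScreeningCriteria", "score_frames", "select_models", "apply_criteria"]

# Screening compares model and target only up to this q by default; the
# high-q tail of a CA bead model is not meaningful.
DEFAULT_Q_MAX = 0.25


@dataclass
class ScreeningCriteria:
    """Strict selection thresholds: chi2 < chi2_max and rg_min < Rg < rg_max."""

    chi2_max: float
    rg_min: float
    rg_max: float

    def __post_init__(self) -> None:
        if self.chi2_max <= 0:
            raise ValueError("chi2_max must be positive")
        if not self.rg_min < self.rg_max:
            raise ValueError("rg_min must be below rg_max")


def score_frames(trajectory: Trajectory, chain: CGChain, target: SAXSProfile,
                 q_max: float = DEFAULT_Q_MAX, form_factors=None,
                 rg_from_guinier: bool = False) -> pd.DataFrame:
    """Per-frame screen table: run id, step, Rg, chi2, fitted scale.

    Rg is the coordinate Rg of the snapshot by default (deterministic and
    noise-free); ``rg_from_guinier`` switches to a Guinier fit of the
    computed model profile instead.
    """
    if trajectory.n_frames == 0:
        raise ValueError("trajectory has no frames to score")
    qsel = target.q[target.q <= q_max]
    if qsel.size < 2:
        raise ValueError("target has no points below q_max")
    tgt = SAXSProfile(q=qsel, I=target.I[target.q <= q_max],
                      sigma=None if target.sigma is None
                      else target.sigma[target.q <= q_max],
                      label=target.label, provenance=target.provenance)
    rows = []
    for k in range(trajectory.n_frames):
        coords = trajectory.frames[k]
        try:
            model = debye_profile(coords, form_factors, tgt.q)
            chi2, scale = chi_square(model, tgt)
            rg = guinier_fit(model).rg if rg_from_guinier else coordinate_rg(coords)
        except ValueError as exc:
            raise ValueError(f"scoring failed at frame {k}: {exc}") from exc
        rows.append((int(trajectory.run_ids[k]), int(trajectory.steps[k]),
                     rg, chi2, scale))
    return pd.DataFrame(rows, columns=["run_id", "step", "rg", "chi2", "scale"])


def select_models(table: pd.DataFrame, criteria: ScreeningCriteria) -> np.ndarray:
    """Indices of frames meeting all criteria (strict inequalities), in order."""
    mask = (
        (table["chi2"].to_numpy() < criteria.chi2_max)
        & (table["rg"].to_numpy() > criteria.rg_min)
        & (table["rg"].to_numpy() < criteria.rg_max)
    )
    return np.nonzero(mask)[0]


def apply_criteria(table: pd.DataFrame, criteria: ScreeningCriteria) -> pd.DataFrame:
    """Return a copy of the screen table with the ``selected`` flag column."""
    out = table.copy()
    out["selected"] = False
    out.loc[select_models(table, criteria), "selected"] = True
    return out
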