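"""Readers and writers for the formats the pipeline touches.

PDB structures (single- and multi-model) are parsed with biotite; SAXS curves
are plain 3-column text (q [1/A], I, sigma) with ``#`` comments.  A small
sequence utility computes average molecular masses the way they are reported
for intact-protein mass spectrometry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import molecular_weight, seq3
from biotite.structure import Atom, array as atom_array, stack as atom_stack
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Structure",
    "SAXSProfile",
    "read_structure",
    "read_models",
    "write_ensemble",
    "read_saxs",
    "write_saxs",
    "sequence_average_mass",
]

# Mass of two hydrogens lost when one disulfide bond forms.
_H2_MASS = 2 * 1.00794

# Domain label <-> PDB chain-id encoding used by the multi-model ensemble
# writer (PDB chain ids are a single character).
DOMAIN_CHAIN_IDS = {"a": "A", "b": "B", "bp": "C", "ap": "D", "linker": "X", "ctail": "Y"}
CHAIN_ID_DOMAINS = {v: k for k, v in DOMAIN_CHAIN_IDS.items()}


@dataclass
class Structure:
    """One model of a PDB entry, column-oriented.

    Coordinates are in Angstrom.  Residue numbers within a chain must be
    non-decreasing and all coordinates finite.
    """

    atom_name: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray
    title: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.ndim != 2 or self.coord.shape[1] != 3:
            raise ValueError("coord must be an (N, 3) array")
        if len(self.atom_name) == 0:
            raise ValueError("structure contains no atoms")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates in structure")
        for cid in np.unique(self.chain_id):
            rid = self.res_id[self.chain_id == cid]
            if np.any(np.diff(rid.astype(int)) < 0):
                raise ValueError(f"residue numbers decrease within chain {cid!r}")

    def __len__(self) -> int:
        return len(self.atom_name)

    def select_ca(self, chain_id: str | None = None) -> "Structure":
        """Return the CA-only substructure, optionally restricted to one chain."""
        mask = self.atom_name == "CA"
        if chain_id is not None:
            mask &= self.chain_id == chain_id
        if not mask.any():
            raise ValueError("no CA atoms match the selection")
        return Structure(
            self.atom_name[mask], self.res_id[mask], self.res_name[mask],
            self.chain_id[mask], self.coord[mask], self.title,
        )


@dataclass
class SAXSProfile:
    """A small-angle scattering curve I(q) with optional uncertainties.

    q is in 1/Angstrom and strictly increasing; sigma shares the units of I.
    ``provenance`` records whether the curve is experimental, model-derived
    or synthetic.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    provenance: str = "model"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ValueError("q and I must be 1-d arrays of equal length")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.I))):
            raise ValueError("non-finite values in profile")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return len(self.q)


def _as_text_stream(source):
    if isinstance(source, str):
        return open(source, "r"), True
    return source, False


def _structure_from_atom_array(arr, title: str) -> Structure:
    return Structure(
        atom_name=np.asarray(arr.atom_name, dtype=object),
        res_id=np.asarray(arr.res_id, dtype=int),
        res_name=np.asarray(arr.res_name, dtype=object),
        chain_id=np.asarray(arr.chain_id, dtype=object),
        coord=np.asarray(arr.coord, dtype=float),
        title=title,
    )


def _find_bad_atom_line(text: str) -> str | None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                return f"line {lineno}: {line.rstrip()}"
    return None


def read_models(source) -> list[Structure]:
    """Read every MODEL of a PDB file into a list of :class:`Structure`.

    ``source`` is a path or an open text stream.  Alternate locations other
    than '' / 'A' are dropped.
    """
    stream, opened = _as_text_stream(source)
    try:
        text = stream.read()
    finally:
        if opened:
            stream.close()
    pdb = PDBFile.read(io.StringIO(text))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError("PDB input contains no ATOM records")
    title = " ".join(
        line[10:].strip() for line in text.splitlines() if line.startswith("TITLE")
    )
    models = []
    for i in range(1, n_models + 1):
        try:
            arr = pdb.get_structure(model=i, altloc="first")
        except Exception as exc:  # re-raise with the offending line if we can find it
            bad = _find_bad_atom_line(text)
            if bad is not None:
                raise ValueError(f"malformed PDB coordinate field at {bad}") from exc
            raise
        if arr.array_length() == 0:
            raise ValueError("PDB model contains no atoms")
        models.append(_structure_from_atom_array(arr, title))
    return models


def read_structure(source) -> Structure:
    """Read a PDB file and return its first (or only) model."""
    return read_models(source)[0]


def write_ensemble(frames, chain, stream) -> None:
    """Write an ensemble of CG conformations as a multi-model PDB.

    One CA pseudo-atom per bead; the bead's domain label is encoded in the
    chain-id column via :data:`DOMAIN_CHAIN_IDS`.  ``frames`` is an iterable
    of (n_beads, 3) coordinate arrays, ``chain`` a
    :class:`cgsaxs.cg_builder.CGChain`.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    n = chain.n_beads
    for k, f in enumerate(frames):
        if f.shape != (n, 3):
            raise ValueError(f"frame {k} has shape {f.shape}, expected ({n}, 3)")

    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w"), True
    try:
        if not frames:
            stream.write("TITLE     empty ensemble (0 models)\nEND\n")
            return
        chain_ids = [DOMAIN_CHAIN_IDS.get(lbl, "Z") for lbl in chain.domain]
        res_names = [seq3(code).upper() for code in chain.res_code]
        template = []
        for i in range(n):
            template.append(Atom(
                [0.0, 0.0, 0.0], atom_name="CA", element="C",
                res_id=int(chain.res_id[i]), res_name=res_names[i],
                chain_id=chain_ids[i],
            ))
        arr = atom_array(template)
        arrays = []
        for f in frames:
            a = arr.copy()
            a.coord = f
            arrays.append(a)
        pdb = PDBFile()
        pdb.set_structure(atom_stack(arrays))
        stream.write("\n".join(pdb.lines) + "\n")
    finally:
        if close:
            stream.close()


def read_saxs(source, q_unit: str = "1/A") -> SAXSProfile:
    """Read a whitespace-delimited q/I[/sigma] file.

    ``q_unit`` may be ``"1/A"`` (default) or ``"1/nm"``; nm^-1 inputs are
    converted to A^-1 on read.
    """
    stream, opened = _as_text_stream(source)
    try:
        data = np.loadtxt(stream, comments="#", ndmin=2)
    finally:
        if opened:
            stream.close()
    if data.shape[1] not in (2, 3):
        raise ValueError(f"expected 2 or 3 columns, got {data.shape[1]}")
    q = data[:, 0]
    if q_unit == "1/nm":
        q = q / 10.0
    elif q_unit != "1/A":
        raise ValueError(f"unknown q unit {q_unit!r}")
    sigma = data[:, 2] if data.shape[1] == 3 else None
    return SAXSProfile(q=q, I=data[:, 1], sigma=sigma, provenance="experimental")


def write_saxs(profile: SAXSProfile, stream) -> None:
    """Write a profile in the same 3-column dialect with a provenance header."""
    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w"), True
    try:
        stream.write(f"# cgsaxs SAXS profile  label={profile.label!r}  "
                     f"provenance={profile.provenance}\n")
        stream.write("# q[1/A]  I  sigma\n" if profile.sigma is not None
                     else "# q[1/A]  I\n")
        cols = (profile.q, profile.I) if profile.sigma is None else \
               (profile.q, profile.I, profile.sigma)
        np.savetxt(stream, np.column_stack(cols), fmt="%.8e")
    finally:
        if close:
            stream.close()


def sequence_average_mass(sequence: str, n_disulfides: int = 0) -> float:
    """Average molecular mass (Da) of a peptide with ``n_disulfides`` S-S bonds.

    Uses standard average residue masses plus one water; each disulfide bond
    removes two hydrogens (2 x 1.008 Da).
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be >= 0")
    if 2 * n_disulfides > sequence.count("C"):
        raise ValueError("more disulfides than cysteine pairs")
    try:
        mass = molecular_weight(sequence, seq_type="protein", monoisotopic=False)
    except ValueError as exc:
        raise ValueError(f"unknown residue letter in sequence: {exc}") from exc
    return mass - n_disulfides * _H2_MASS
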