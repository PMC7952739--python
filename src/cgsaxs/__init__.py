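"""cgsaxs: coarse-grained conformational sampling and SAXS ensemble screening.

Infer the solution-state domain conformations of multi-domain proteins by
structure-based coarse-grained Langevin sampling, per-snapshot Debye SAXS
profiles, chi-square/Rg screening against a target scattering curve, and
inter-domain geometry analytics.  A synthetic-data generator provides every
input with known ground truth.
"""

__version__ = "0.1.0"

from importlib import resources


def er60_mature_sequence() -> str:
    """Mature human ER-60 sequence (Ser25-Leu505, 481 aa)."""
    return er60_precursor_sequence()[24:]


def er60_precursor_sequence() -> str:
    """Full human ER-60/PDIA3 precursor sequence (505 aa)."""
    text = resources.files("cgsaxs.data").joinpath("er60_sequence.txt").read_text()
    return "".join(line.strip() for line in text.splitlines()
                   if line.strip() and not line.startswith("#"))
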