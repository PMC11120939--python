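"""Single-chain Cα traces in PDB format, with per-residue pLDDT.

AlphaFold-style model files store the predicted local distance difference
test (pLDDT, 0-100) in the B-factor column; this module reads one Cα per
residue (first model, first chain) via gemmi, writes CA-only fixed-column
ATOM records, and summarizes pLDDT with the conventional confidence bins
(<50 very low, [50,70) low, [70,90] confident, >90 very high).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .errors import PdbFormatError, ValidationError

__all__ = ["CaTrace", "PlddtSummary", "read_pdb_ca", "write_ca_pdb",
           "plddt_summary"]

logger = logging.getLogger(__name__)


@dataclass
class CaTrace:
    """Ordered Cα coordinates for one chain.

    ``plddt`` may be ``None`` when the source carries no per-residue
    confidence.  Residue numbers must be strictly increasing.
    """

    model_id: str
    residue_numbers: np.ndarray  # (n,) int
    residue_names: list[str]     # three-letter codes
    coords: np.ndarray           # (n, 3) float, Å
    plddt: np.ndarray | None = None  # (n,) float in [0, 100]

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_numbers)
        if self.coords.shape != (n, 3):
            raise ValidationError(
                f"{self.model_id}: coords shape {self.coords.shape} "
                f"inconsistent with {n} residues"
            )
        if len(self.residue_names) != n:
            raise ValidationError(f"{self.model_id}: residue_names length mismatch")
        if n and np.any(np.diff(self.residue_numbers) <= 0):
            raise ValidationError(
                f"{self.model_id}: residue numbers not strictly increasing"
            )
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if self.plddt.shape != (n,):
                raise ValidationError(f"{self.model_id}: plddt length mismatch")
            if n and (self.plddt.min() < 0 or self.plddt.max() > 100):
                raise ValidationError(
                    f"{self.model_id}: pLDDT values outside [0, 100]"
                )

    def __len__(self) -> int:
        return len(self.residue_numbers)


@dataclass(frozen=True)
class PlddtSummary:
    mean: float
    fraction_very_high: float  # > 90
    fraction_confident: float  # [70, 90]
    fraction_low: float        # [50, 70)
    fraction_very_low: float   # < 50

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "fraction_very_high": self.fraction_very_high,
            "fraction_confident": self.fraction_confident,
            "fraction_low": self.fraction_low,
            "fraction_very_low": self.fraction_very_low,
        }


def read_pdb_ca(path: str | Path) -> CaTrace:
    """Extract the Cα trace of the first model / first chain of a PDB file.

    Alternate locations resolve to the blank or 'A' record; a residue with
    no CA atom is a hard error (a Cα trace with holes would silently break
    the index-based residue correspondence used downstream).  The B-factor
    column is copied into ``plddt``.
    """
    path = Path(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PdbFormatError(f"{path}: unreadable PDB file: {exc}") from exc
    if len(structure) == 0 or len(structure[0]) == 0:
        raise PdbFormatError(f"{path}: no models/chains with ATOM records")
    model = structure[0]
    if len(model) > 1:
        logger.warning(
            "%s: %d chains present; using the first (%s) only",
            path.name, len(model), model[0].name,
        )
    chain = model[0]

    numbers, names, coords, plddt = [], [], [], []
    for residue in chain:
        ca = None
        for atom in residue:
            if atom.name == "CA" and atom.altloc in ("\0", "", "A"):
                ca = atom
                if atom.altloc in ("\0", ""):
                    break
        if ca is None:
            raise PdbFormatError(
                f"{path}: residue {residue.name} {residue.seqid.num} "
                "has no CA atom"
            )
        numbers.append(residue.seqid.num)
        names.append(residue.name)
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        plddt.append(ca.b_iso)

    if not numbers:
        raise PdbFormatError(f"{path}: no residues found")
    plddt_arr = np.asarray(plddt, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        valid = plddt_arr.min() >= 0 and plddt_arr.max() <= 100
    return CaTrace(
        model_id=path.stem,
        residue_numbers=np.asarray(numbers, int),
        residue_names=names,
        coords=np.asarray(coords, float),
        plddt=plddt_arr if valid else None,
    )


def write_ca_pdb(trace: CaTrace, path: str | Path) -> None:
    """Write a CA-only PDB file; pLDDT goes into the B-factor column."""
    if len(trace) == 0:
        raise ValidationError("cannot write an empty trace")
    if np.any(trace.coords >= 10000) or np.any(trace.coords <= -1000):
        raise ValidationError(
            "coordinate magnitude exceeds the PDB %8.3f column width"
        )
    b = trace.plddt if trace.plddt is not None else np.zeros(len(trace))
    lines = []
    for k in range(len(trace)):
        x, y, z = trace.coords[k]
        lines.append(
            f"ATOM  {k + 1:5d}  CA  {trace.residue_names[k]:>3s} A"
            f"{trace.residue_numbers[k]:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b[k]:6.2f}"
            f"          {'C':>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def plddt_summary(trace: CaTrace) -> PlddtSummary:
    """Mean pLDDT and confidence-bin fractions (cut points 50/70/90)."""
    if trace.plddt is None:
        raise ValidationError(
            f"{trace.model_id}: no pLDDT values available for summary"
        )
    p = trace.plddt
    n = len(p)
    return PlddtSummary(
        mean=float(p.mean()),
        fraction_very_high=float(np.count_nonzero(p > 90) / n),
        fraction_confident=float(
            np.count_nonzero((p >= 70) & (p <= 90)) / n
        ),
        fraction_low=float(np.count_nonzero((p >= 50) & (p < 70)) / n),
        fraction_very_low=float(np.count_nonzero(p < 50) / n),
    )
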