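"""Coding-DNA variants and their protein consequences.

This module applies HGVS c. variants to a coding sequence (CDS), translates
wild-type and mutant alleles with the standard genetic code, and derives the
protein-level consequence in HGVS p. nomenclature, including the frameshift
``fs*N`` arithmetic used to describe premature-termination variants such as
the exon-12 ARHGAP31 truncations associated with Adams-Oliver syndrome
(e.g. c.2193del -> p.(Thr732Glnfs*26), a loss of 688 C-terminal residues).

Coordinates are coding-DNA coordinates throughout: position 1 is the A of
the initiator ATG, ranges are 1-based and inclusive.  Intronic/UTR syntax is
out of scope and rejected explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import (
    AlphabetError,
    HgvsParseError,
    UnsupportedSyntaxError,
    ValidationError,
)

__all__ = [
    "CodingSequence",
    "CdnaVariant",
    "ProteinConsequence",
    "GENETIC_CODE",
    "AA3",
    "parse_cdna_variant",
    "apply_variant",
    "translate",
    "protein_consequence",
    "read_cds_fasta",
    "read_variant_lines",
    "consequence_table",
]

# Standard genetic code (NCBI table 1), codon order T,C,A,G on each base.
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: _AA_ORDER[i * 16 + j * 4 + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

AA3: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


def _check_alphabet(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise AlphabetError(
            f"{what} contains non-ACGT character(s): {sorted(bad)}"
        )


@dataclass(frozen=True)
class CodingSequence:
    """A validated protein-coding sequence in coding coordinates.

    Invariants enforced on construction: length >= 6 and divisible by 3,
    starts with ATG, ends with a stop codon, and contains no internal
    in-frame stop codon.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        _check_alphabet(self.bases, f"CDS {self.id!r}")
        n = len(self.bases)
        if n < 6 or n % 3:
            raise ValidationError(
                f"CDS {self.id!r}: length {n} must be >= 6 and divisible by 3"
            )
        if not self.bases.startswith("ATG"):
            raise ValidationError(f"CDS {self.id!r} does not start with ATG")
        if self.bases[-3:] not in STOP_CODONS:
            raise ValidationError(
                f"CDS {self.id!r} does not end with a stop codon"
            )
        for i in range(0, n - 3, 3):
            if self.bases[i : i + 3] in STOP_CODONS:
                raise ValidationError(
                    f"CDS {self.id!r}: internal stop codon at c.{i + 1}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_codons(self) -> int:
        return len(self.bases) // 3

    def codon(self, residue: int) -> str:
        """Codon for 1-based residue number."""
        return self.bases[3 * residue - 3 : 3 * residue]


@dataclass(frozen=True)
class CdnaVariant:
    """A parsed HGVS c. variant on a coding sequence."""

    raw: str
    kind: str  # substitution | deletion | insertion | duplication | delins
    start: int
    end: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {
            "substitution", "deletion", "insertion", "duplication", "delins",
        }:
            raise ValidationError(f"unknown variant kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.raw}: invalid range {self.start}_{self.end}"
            )
        if self.kind == "substitution" and (
            len(self.ref_allele) != 1 or len(self.alt_allele) != 1
        ):
            raise ValidationError(
                f"{self.raw}: substitution needs single-base ref and alt"
            )
        if self.kind == "insertion":
            if self.end != self.start + 1:
                raise ValidationError(
                    f"{self.raw}: insertion range must be adjacent positions"
                )
            if not self.alt_allele:
                raise ValidationError(f"{self.raw}: insertion without bases")


_PREFIX_RE = re.compile(r"^[A-Za-z][\w.]*:(?=c\.)")
_SUB_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$")
_INS_RE = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")
_DUP_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?dup([ACGT]*)$")
_DELINS_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?delins([ACGT]+)$")
_INTRONIC_RE = re.compile(r"c\.\d+[+-]\d+")


def parse_cdna_variant(text: str) -> CdnaVariant:
    """Parse an HGVS c. description (supported subset).

    Supported: ``c.NR>A``, ``c.Ndel[SEQ]``, ``c.N_Mdel[SEQ]``,
    ``c.N_MinsSEQ``, ``c.Ndup[SEQ]``, ``c.N_Mdup[SEQ]``, ``c.N_MdelinsSEQ``.
    A leading ``transcript:`` prefix is stripped; the original string is kept
    verbatim in ``raw``.
    """
    raw = text.strip()
    body = _PREFIX_RE.sub("", raw)
    if _INTRONIC_RE.search(body):
        raise UnsupportedSyntaxError(
            f"{raw!r}: intronic/offset positions are not supported"
        )
    if not body.startswith("c."):
        raise HgvsParseError(f"{raw!r}: expected a 'c.' coding description")

    if m := _SUB_RE.match(body):
        pos = int(m.group(1))
        return CdnaVariant(raw, "substitution", pos, pos,
                           m.group(2), m.group(3))
    if m := _DELINS_RE.match(body):  # before del: 'delins' contains 'del'
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return CdnaVariant(raw, "delins", start, end, "", m.group(3))
    if m := _DEL_RE.match(body):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return CdnaVariant(raw, "deletion", start, end, m.group(3), "")
    if m := _INS_RE.match(body):
        return CdnaVariant(raw, "insertion", int(m.group(1)),
                           int(m.group(2)), "", m.group(3))
    if m := _DUP_RE.match(body):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return CdnaVariant(raw, "duplication", start, end, "", m.group(3))
    raise HgvsParseError(f"unrecognized HGVS syntax: {body!r}")


def _check_bounds(cds: CodingSequence, v: CdnaVariant) -> None:
    if v.end > len(cds):
        raise ValidationError(
            f"{v.raw}: position {v.end} beyond CDS length {len(cds)}"
        )


def _check_ref(cds: CodingSequence, v: CdnaVariant, expected: str) -> None:
    observed = cds.bases[v.start - 1 : v.end]
    if observed != expected:
        raise ValidationError(
            f"{v.raw}: reference allele mismatch at c.{v.start}: "
            f"expected {expected!r}, CDS has {observed!r}"
        )


def apply_variant(cds: CodingSequence, v: CdnaVariant) -> str:
    """Return the edited coding nucleotide sequence (frame not re-checked)."""
    _check_bounds(cds, v)
    s = cds.bases
    i, j = v.start - 1, v.end  # python slice of the affected span
    if v.kind == "substitution":
        _check_ref(cds, v, v.ref_allele)
        return s[:i] + v.alt_allele + s[j:]
    if v.kind == "deletion":
        if v.ref_allele:
            _check_ref(cds, v, v.ref_allele)
        return s[:i] + s[j:]
    if v.kind == "insertion":
        # bases inserted between start and end (= start + 1)
        return s[: v.start] + v.alt_allele + s[v.start :]
    if v.kind == "duplication":
        segment = s[i:j]
        if v.alt_allele and v.alt_allele != segment:
            raise ValidationError(
                f"{v.raw}: duplicated bases {v.alt_allele!r} do not match "
                f"CDS span {segment!r}"
            )
        return s[:j] + segment + s[j:]
    if v.kind == "delins":
        return s[:i] + v.alt_allele + s[j:]
    raise ValidationError(f"unknown kind {v.kind!r}")  # pragma: no cover


def translate(nt: str) -> tuple[str, bool]:
    """Translate frame 0 with the standard code up to the first stop.

    Returns ``(residues_before_stop, stop_reached)``.  A trailing partial
    codon is ignored.
    """
    _check_alphabet(nt, "nucleotide sequence")
    if len(nt) < 3:
        raise ValidationError("sequence shorter than one codon")
    protein = []
    for k in range(0, len(nt) - 2, 3):
        aa = GENETIC_CODE[nt[k : k + 3]]
        if aa == "*":
            return "".join(protein), True
        protein.append(aa)
    return "".join(protein), False


@dataclass(frozen=True)
class ProteinConsequence:
    """Protein-level consequence of a coding variant.

    ``stop_offset`` is the N of ``fs*N``: the stop-codon position in the
    shifted reading frame counting the first changed residue as 1.  For a
    frameshift, ``mutant_length = (first_changed - 1) + (stop_offset - 1)``.
    """

    hgvs_p: str
    category: str  # synonymous | missense | nonsense | frameshift |
    #                stop_loss | no_protein | inframe_indel
    mutant_protein: str
    first_changed: int | None
    stop_offset: int | None
    wt_length: int
    mutant_length: int
    residues_lost: int
    last_exon_truncation: bool = False
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.category == "frameshift" and self.stop_offset is not None:
            expected = (self.first_changed - 1) + (self.stop_offset - 1)
            if self.mutant_length != expected:
                raise ValidationError(
                    "frameshift arithmetic violated: "
                    f"mutant_length {self.mutant_length} != {expected}"
                )


def _aa3(aa: str) -> str:
    return AA3[aa]


def protein_consequence(
    cds: CodingSequence,
    v: CdnaVariant,
    last_exon_truncation: bool = False,
) -> ProteinConsequence:
    """Compare wild-type and mutant translations and name the consequence.

    Frameshifts are named ``p.(Xpos Y fs*N)`` with three-letter codes; a
    frameshift whose first changed codon is itself the new stop is rendered
    nonsense-style, ``p.(Xpos*)``.  Truncation statistics (``residues_lost``)
    are relative to the wild-type protein length.
    """
    wt_prot, _ = translate(cds.bases)
    mut_nt = apply_variant(cds, v)
    mut_prot, mut_stop = translate(mut_nt)
    wt_len, mut_len = len(wt_prot), len(mut_prot)
    frame_shifted = (len(mut_nt) - len(cds.bases)) % 3 != 0

    def build(hgvs_p, category, first_changed, stop_offset, warning=None):
        return ProteinConsequence(
            hgvs_p=hgvs_p,
            category=category,
            mutant_protein=mut_prot,
            first_changed=first_changed,
            stop_offset=stop_offset,
            wt_length=wt_len,
            mutant_length=mut_len,
            residues_lost=wt_len - mut_len,
            last_exon_truncation=last_exon_truncation,
            warning=warning,
        )

    if mut_prot == wt_prot and mut_stop:
        return build("p.(=)", "synonymous", None, None)

    # first differing residue, 1-based; prefix agreement -> min length + 1
    first = next(
        (k + 1 for k, (x, y) in enumerate(zip(wt_prot, mut_prot)) if x != y),
        min(wt_len, mut_len) + 1,
    )

    if first == 1 and v.start <= 3:
        return build("p.(Met1?)", "no_protein", 1, None)

    if not mut_stop:
        return build(
            "p.?", "stop_loss", first if first <= mut_len + 1 else None, None,
            warning="mutant allele lacks an in-frame stop codon; "
            "no extension nomenclature attempted",
        )

    wt_res = wt_prot[first - 1] if first <= wt_len else "*"

    if frame_shifted:
        if first > mut_len:
            # the first changed codon is the new stop: nonsense-style name
            return build(
                f"p.({_aa3(wt_res)}{first}*)", "frameshift", first, 1
            )
        stop_offset = mut_len - first + 2
        mut_res = mut_prot[first - 1]
        return build(
            f"p.({_aa3(wt_res)}{first}{_aa3(mut_res)}fs*{stop_offset})",
            "frameshift", first, stop_offset,
        )

    if mut_len < wt_len and mut_prot == wt_prot[:mut_len]:
        if first != mut_len + 1:  # pragma: no cover - implied by prefix
            raise AssertionError
        return build(f"p.({_aa3(wt_res)}{first}*)", "nonsense", first, None)

    if mut_len == wt_len:
        # same length, in frame: substitution-like change(s)
        diffs = [k for k in range(wt_len) if wt_prot[k] != mut_prot[k]]
        if len(diffs) == 1:
            k = diffs[0]
            return build(
                f"p.({_aa3(wt_prot[k])}{k + 1}{_aa3(mut_prot[k])})",
                "missense", k + 1, None,
            )
        return build("p.?", "inframe_indel", first, None)

    # in-frame indel: best-effort deletion/insertion naming
    if mut_len < wt_len:
        k = wt_len - mut_len
        if mut_prot == wt_prot[: first - 1] + wt_prot[first - 1 + k :]:
            if k == 1:
                name = f"p.({_aa3(wt_res)}{first}del)"
            else:
                last = wt_prot[first - 2 + k]
                name = f"p.({_aa3(wt_res)}{first}_{_aa3(last)}{first - 1 + k}del)"
            return build(name, "inframe_indel", first, None)
    return build("p.?", "inframe_indel", first, None)


# ---------------------------------------------------------------------------
# file-level helpers


def read_cds_fasta(path: str | Path) -> CodingSequence:
    """Read a single-record FASTA file as a CodingSequence."""
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    raise ValidationError(
                        f"{path}: expected a single FASTA record"
                    )
                header = line[1:].split()[0]
            else:
                chunks.append(line.upper())
    if header is None:
        raise ValidationError(f"{path}: no FASTA record found")
    return CodingSequence(header, "".join(chunks))


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def read_variant_lines(path: str | Path) -> list[CdnaVariant]:
    """One HGVS c. string per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(parse_cdna_variant(line))
    return out


def consequence_table(
    cds: CodingSequence, variants: Iterable[CdnaVariant]
) -> pd.DataFrame:
    """Tabulate consequences: one row per variant."""
    rows = []
    for v in variants:
        c = protein_consequence(cds, v)
        rows.append(
            {
                "raw": v.raw,
                "kind": v.kind,
                "hgvs_p": c.hgvs_p,
                "category": c.category,
                "wt_length": c.wt_length,
                "mutant_length": c.mutant_length,
                "residues_lost": c.residues_lost,
                "stop_offset": c.stop_offset,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "raw", "kind", "hgvs_p", "category", "wt_length",
            "mutant_length", "residues_lost", "stop_offset",
        ],
    )
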