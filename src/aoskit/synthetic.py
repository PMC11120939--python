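"""Synthetic inputs with known ground truth.

Structure predictions for ARHGAP31 variants were never deposited, and
patient qPCR data are not public; every pipeline input can therefore be
generated here with controlled properties: ideal helices and random-coil
Cα traces, rigid-plus-noise perturbations, truncate-and-refold variant
emulators (native prefix, divergent tail, lowered pLDDT on the tail),
random coding sequences with planted variants of known category, and Ct
tables with planted group fold changes.

All generators are pure functions of their arguments including the seed
(numpy PCG64 ``default_rng``), so outputs are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .expression import CtTable
from .seq_variants import (
    GENETIC_CODE,
    STOP_CODONS,
    CdnaVariant,
    CodingSequence,
    apply_variant,
    parse_cdna_variant,
    protein_consequence,
    translate,
)
from .structure_io import CaTrace

__all__ = [
    "SimulationConfig",
    "make_helix",
    "make_coil",
    "perturb",
    "truncate_and_refold",
    "random_cds",
    "plant_variant",
    "simulate_ct_table",
    "surrogate_cds",
    "SURROGATE_VARIANTS",
    "make_variant_structure_set",
    "example_gene_table",
]

CA_CA_DISTANCE = 3.8  # Å, canonical consecutive Cα spacing


@dataclass
class SimulationConfig:
    """Knobs for the generators; the defaults are the study conditions.

    Helix geometry uses the ideal α-helix (radius 2.3 Å, rise 1.5 Å per
    residue, twist 100°), which puts consecutive Cα atoms ~3.8 Å apart.
    The Ct-table defaults mirror a family study: 3 reference genes and
    4 targets across 4 carriers and 6 controls, with ~0.8 cycles of
    sample-loading spread and 0.3 cycles of technical noise.
    """

    seed: int
    n_residues: int = 200
    helix_radius: float = 2.3
    helix_rise: float = 1.5
    helix_twist_deg: float = 100.0
    coil_step: float = CA_CA_DISTANCE
    noise_sigma: float = 0.0
    truncation_point: int | None = None
    tail_length: int = 0
    cds_codons: int = 100
    ct_noise_sd: float = 0.3
    loading_sd: float = 0.8
    n_carrier: int = 4
    n_control: int = 6
    fold_changes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory for reproducibility")
        for name in ("n_residues", "cds_codons", "n_carrier", "n_control"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def make_helix(
    n: int,
    radius: float = 2.3,
    rise: float = 1.5,
    twist_deg: float = 100.0,
    model_id: str = "helix",
) -> CaTrace:
    """Ideal α-helical Cα spiral; deterministic."""
    if n < 1:
        raise ValidationError("helix needs at least one residue")
    k = np.arange(n)
    theta = np.deg2rad(twist_deg) * k
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * k]
    )
    return CaTrace(
        model_id=model_id,
        residue_numbers=k + 1,
        residue_names=["ALA"] * n,
        coords=coords,
        plddt=np.full(n, 95.0),
    )


def make_coil(
    n: int,
    step: float = CA_CA_DISTANCE,
    seed: int = 0,
    start: np.ndarray | None = None,
    model_id: str = "coil",
) -> CaTrace:
    """Random walk with fixed step length and uniform random directions."""
    if n < 1:
        raise ValidationError("coil needs at least one residue")
    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    origin = np.zeros(3) if start is None else np.asarray(start, float)
    coords = origin + step * np.cumsum(directions, axis=0)
    return CaTrace(
        model_id=model_id,
        residue_numbers=np.arange(1, n + 1),
        residue_names=["GLY"] * n,
        coords=coords,
        plddt=np.full(n, 40.0),
    )


def perturb(
    trace: CaTrace,
    sigma: float,
    rigid: bool = True,
    seed: int = 0,
    model_id: str | None = None,
) -> CaTrace:
    """Random proper rotation + translation, then iid Gaussian noise.

    With ``rigid=False`` the pose is left unchanged and only noise is
    added, which is the configuration used for noise-calibration checks
    (E[d^2] = 3 sigma^2 per residue).
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    coords = trace.coords.copy()
    if rigid:
        rotation = Rotation.random(rng=rng).as_matrix()
        translation = rng.uniform(-20.0, 20.0, size=3)
        centroid = coords.mean(axis=0)
        coords = (coords - centroid) @ rotation.T + centroid + translation
    if sigma > 0:
        coords = coords + rng.normal(scale=sigma, size=coords.shape)
    return CaTrace(
        model_id=model_id or f"{trace.model_id}_perturbed",
        residue_numbers=trace.residue_numbers.copy(),
        residue_names=list(trace.residue_names),
        coords=coords,
        plddt=None if trace.plddt is None else trace.plddt.copy(),
    )


def truncate_and_refold(
    trace: CaTrace,
    point: int,
    tail_length: int = 0,
    seed: int = 0,
    model_id: str | None = None,
    tail_plddt: float = 35.0,
) -> CaTrace:
    """Emulate a truncating/frameshift variant structure.

    Keeps residues 1..point-1 bit-identical, then grows a fresh random-coil
    tail of ``tail_length`` residues from the last kept position (first
    tail residue one Cα-Cα step away).  Tail residues are labelled UNK and
    given low pLDDT, mirroring how predictors score novel frameshift tails.
    """
    if not 1 <= point <= len(trace) + 1:
        raise ValidationError(
            f"truncation point {point} out of range 1..{len(trace) + 1}"
        )
    keep = point - 1
    if keep + tail_length < 1:
        raise ValidationError("resulting trace would be empty")
    coords = trace.coords[:keep]
    names = list(trace.residue_names[:keep])
    plddt = (
        trace.plddt[:keep] if trace.plddt is not None
        else np.full(keep, 90.0)
    )
    if tail_length > 0:
        anchor = coords[-1] if keep else np.zeros(3)
        tail = make_coil(tail_length, seed=seed, start=anchor)
        coords = np.vstack([coords, tail.coords])
        names += ["UNK"] * tail_length
        plddt = np.concatenate([plddt, np.full(tail_length, tail_plddt)])
    return CaTrace(
        model_id=model_id or f"{trace.model_id}_trunc{point}",
        residue_numbers=np.arange(1, keep + tail_length + 1),
        residue_names=names,
        coords=coords,
        plddt=plddt,
    )


_NON_STOP_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)
_STOP_LIST = sorted(STOP_CODONS)


def random_cds(n_codons: int, seed: int = 0, cds_id: str | None = None) -> CodingSequence:
    """ATG + random non-stop codons + one stop codon."""
    if n_codons < 2:
        raise ValidationError("a CDS needs at least start + stop codons")
    rng = np.random.default_rng(seed)
    body = rng.choice(_NON_STOP_CODONS, size=n_codons - 2)
    stop = rng.choice(_STOP_LIST)
    bases = "ATG" + "".join(body) + str(stop)
    return CodingSequence(cds_id or f"synthetic_cds_{seed}", bases)


def _has_frame_stop(nt: str) -> bool:
    return any(nt[i : i + 3] in STOP_CODONS for i in range(0, len(nt) - 2, 3))


def plant_variant(
    cds: CodingSequence, kind: str, seed: int = 0, max_tries: int = 500
) -> tuple[CdnaVariant, str]:
    """Draw a variant guaranteed to have the requested consequence category.

    ``kind`` is one of synonymous / missense / nonsense / frameshift.  The
    guarantee is established constructively (codon arithmetic plus, for
    frameshifts, a direct scan for a downstream stop in the shifted frame),
    not by consulting the consequence engine, so the returned expected
    category can serve as an independent oracle in tests.
    """
    if kind not in {"synonymous", "missense", "nonsense", "frameshift"}:
        raise ValidationError(f"unsupported planted kind {kind!r}")
    rng = np.random.default_rng(seed)
    n_codons = cds.n_codons
    for _ in range(max_tries):
        # pick an internal codon (not initiator, not stop)
        res = int(rng.integers(2, n_codons))
        codon = cds.codon(res)
        pos_in_codon = int(rng.integers(0, 3))
        cpos = 3 * (res - 1) + pos_in_codon + 1  # coding coordinate
        old = codon[pos_in_codon]
        if kind == "frameshift":
            # 1-bp deletion; require a stop in the shifted downstream frame
            # and a changed residue before it (not merely a lost stop).
            edited = cds.bases[: cpos - 1] + cds.bases[cpos:]
            if not _has_frame_stop(edited):
                continue
            mut_prot, _ = translate(edited)
            wt_prot, _ = translate(cds.bases)
            if mut_prot == wt_prot:
                continue
            first = next(
                (k for k, (x, y) in enumerate(zip(wt_prot, mut_prot)) if x != y),
                min(len(wt_prot), len(mut_prot)),
            )
            if first >= len(mut_prot) + 1 and len(mut_prot) >= len(wt_prot):
                continue
            return CdnaVariant(f"c.{cpos}del", "deletion", cpos, cpos), kind
        for new in "ACGT":
            if new == old:
                continue
            mutated = codon[:pos_in_codon] + new + codon[pos_in_codon + 1 :]
            wt_aa = GENETIC_CODE[codon]
            mut_aa = GENETIC_CODE[mutated]
            ok = (
                (kind == "synonymous" and mut_aa == wt_aa)
                or (kind == "missense" and mut_aa not in (wt_aa, "*"))
                or (kind == "nonsense" and mut_aa == "*" and wt_aa != "*")
            )
            if ok:
                return (
                    CdnaVariant(f"c.{cpos}{old}>{new}", "substitution",
                                cpos, cpos, old, new),
                    kind,
                )
    raise ValidationError(
        f"could not plant a {kind} variant in CDS {cds.id!r} "
        f"({n_codons} codons)"
    )


_REFERENCE_GENES = ("B2M", "ACTB", "GAPDH")
_TARGET_GENES = ("ARHGAP31", "CDC42", "RAC1", "CCND1")


def simulate_ct_table(config: SimulationConfig) -> CtTable:
    """Simulate a qPCR Ct table with a known group effect.

    Reference genes share a per-sample loading offset (RNA input) plus
    technical noise; target genes add a group fold change on the log2/Ct
    scale (carriers' Ct drops by log2(fold)).  ``config.fold_changes``
    maps target gene -> fold (default 1.0 = null).
    """
    rng = np.random.default_rng(config.seed)
    genes = list(_REFERENCE_GENES) + list(_TARGET_GENES)
    samples = [f"carrier_{i+1}" for i in range(config.n_carrier)] + [
        f"control_{i+1}" for i in range(config.n_control)
    ]
    groups = pd.Series(
        ["carrier"] * config.n_carrier + ["control"] * config.n_control,
        index=samples, name="group",
    )
    base = {g: rng.uniform(18.0, 28.0) for g in genes}
    loading = rng.normal(0.0, config.loading_sd, size=len(samples))
    ct = pd.DataFrame(index=samples, columns=genes, dtype=float)
    for j, g in enumerate(genes):
        noise = rng.normal(0.0, config.ct_noise_sd, size=len(samples))
        shift = np.zeros(len(samples))
        fold = config.fold_changes.get(g, 1.0)
        if g in _TARGET_GENES and fold != 1.0:
            shift = np.where(
                groups.to_numpy() == "carrier", -np.log2(fold), 0.0
            )
        ct[g] = base[g] + loading + noise + shift
    return CtTable(
        ct=ct,
        groups=groups,
        reference_genes=list(_REFERENCE_GENES),
        target_genes=list(_TARGET_GENES),
    )


# ---------------------------------------------------------------------------
# Surrogate ARHGAP31 coding sequence (synthetic)

#: the five published exon-12 variants and their printed consequences
SURROGATE_VARIANTS: dict[str, str] = {
    "c.2047C>T": "p.(Gln683*)",
    "c.2063_2064insTT": "p.(Ser689*)",
    "c.2182C>T": "p.(Gln728*)",
    "c.2193del": "p.(Thr732Glnfs*26)",
    "c.3260del": "p.(Lys1087Serfs*4)",
}

# codon overrides on a GCT (Ala) filler; see surrogate_cds docstring
_SURROGATE_CODONS = {
    683: "CAG",   # Gln; C>T at c.2047 creates a TAG stop
    688: "CTG",   # Leu; TT insertion after c.2063 leaves Leu intact...
    689: "AGC",   # Ser; ...and makes the next shifted codon TGA
    728: "CAG",   # Gln; C>T at c.2182 creates a TAG stop
    731: "GGG",   # Gly; third-base deletion at c.2193 keeps Gly (GGA)
    732: "ACA",   # Thr; shifted frame reads CAG = Gln at residue 732
    757: "GTA",   # Val; shifted frame reads TAA here -> fs*26 stop
    758: "ACC",   # Thr (supplies the A of that TAA)
    1087: "AAG",  # Lys; deleting c.3260 shifts to AGT.. = Ser
    1088: "TGC",  # Cys (supplies the T of that Ser codon)
    1090: "GTA",  # Val; shifted frame reads TAA here -> fs*4 stop
    1091: "ACT",  # Thr (supplies the A of that TAA)
}


def surrogate_cds() -> CodingSequence:
    """Synthetic surrogate for the ARHGAP31 coding sequence (NM_020754.4).

    This is NOT the real transcript sequence (which is not redistributed
    here); it is a deterministic 4335-nt synthetic CDS with the real
    wild-type protein length (1444 residues) engineered so that the five
    published exon-12 variants reproduce their printed protein
    consequences exactly:

    * c.2047C>T        -> p.(Gln683*)
    * c.2063_2064insTT -> p.(Ser689*)
    * c.2182C>T        -> p.(Gln728*)
    * c.2193del        -> p.(Thr732Glnfs*26)  (688 residues lost)
    * c.3260del        -> p.(Lys1087Serfs*4)

    Use ``scripts/fetch_reference_cds.py`` to obtain the real sequence when
    network access to NCBI is available; it is a drop-in replacement.
    """
    n_codons = 1445  # 1444 residues + stop
    codons = ["GCT"] * n_codons
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for residue, codon in _SURROGATE_CODONS.items():
        codons[residue - 1] = codon
    return CodingSequence("NM_020754.4_surrogate", "".join(codons))


def make_variant_structure_set(
    seed: int = 0,
    cds: CodingSequence | None = None,
    scale: float = 1.0,
    backbone_sigma: float = 0.5,
) -> dict[str, CaTrace]:
    """Build the six-structure demo set: wild type plus five variants.

    The wild-type fold is a lightly perturbed ideal helix of the wild-type
    protein length; each variant keeps the native prefix up to its first
    changed residue and carries a refolded random-coil tail of the length
    its consequence dictates (zero for nonsense variants).  ``scale`` < 1
    shrinks all lengths proportionally for quick demonstrations.
    """
    rng = np.random.default_rng(seed)
    cds = cds or surrogate_cds()
    consequences = {
        raw: protein_consequence(cds, parse_cdna_variant(raw))
        for raw in SURROGATE_VARIANTS
    }
    wt_len = next(iter(consequences.values())).wt_length
    n_wt = max(int(round(wt_len * scale)), 10)
    wt = perturb(
        make_helix(n_wt, model_id="WT"),
        sigma=backbone_sigma, rigid=False,
        seed=int(rng.integers(2**31)), model_id="WT",
    )
    structures = {"WT": wt}
    for raw, cons in consequences.items():
        prefix = int(round((cons.first_changed - 1) * scale))
        total = int(round(cons.mutant_length * scale))
        tail = max(total - prefix, 0)
        structures[cons.hgvs_p] = truncate_and_refold(
            wt, prefix + 1, tail_length=tail,
            seed=int(rng.integers(2**31)), model_id=cons.hgvs_p,
        )
    return structures


def example_gene_table() -> pd.DataFrame:
    """Synthetic OMIM-gene table for the CNV/LOH demonstration.

    Approximate hg19 spans (BED convention, 0-based half-open): the six
    cadherin-cluster/PRDM9/PMCHL1 genes fall inside the chr5 p14-p15 LOH
    interval, POTEG inside the chr14 q11 gain, and two extra genes lie
    outside both.  Coordinates are rounded/representative, not authoritative
    annotation.
    """
    rows = [
        ("chr5", 19473095, 20575982, "CDH18"),
        ("chr5", 21750907, 22853429, "CDH12"),
        ("chr5", 22130000, 22141000, "PMCHL1"),
        ("chr5", 23507723, 23528706, "PRDM9"),
        ("chr5", 24487209, 24645087, "CDH10"),
        ("chr5", 26880680, 27038809, "CDH9"),
        ("chr5", 1253287, 1295162, "TERT"),
        ("chr5", 140114110, 140891641, "PCDHA1"),
        ("chr14", 19553395, 19623313, "POTEG"),
        ("chr14", 23016447, 23083689, "ABHD4"),
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
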