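"""Reference-gene qPCR normalization and group comparison.

Implements the geNorm-style workflow used to quantify transcripts against a
panel of housekeeping genes: per-gene relative quantities
``Q = E^(minCt - Ct)``, the pairwise-variation stability measure ``M``
(mean SD of log2 ratios against every other candidate reference), a
geometric-mean normalization factor ``NF`` over the reference genes, and a
nonparametric carriers-versus-controls comparison per target gene (exact
two-sided Wilcoxon rank-sum; appropriate at family-study sample sizes such
as 4 carriers vs 6 controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "CtTable",
    "NormalizedExpression",
    "relative_quantity",
    "genorm_stability",
    "rank_reference_genes",
    "normalized_expression",
    "compare_groups",
    "read_ct_table",
    "write_ct_table",
]


@dataclass
class CtTable:
    """Quantification cycles for samples x genes.

    ``ct`` is a DataFrame indexed by sample with one column per gene;
    ``groups`` maps each sample to 'carrier' or 'control';
    ``efficiency`` is the amplification efficiency E per gene (default 2.0,
    i.e. perfect doubling per cycle).
    """

    ct: pd.DataFrame
    groups: pd.Series
    reference_genes: list[str]
    target_genes: list[str]
    efficiency: dict[str, float] | float = 2.0

    def __post_init__(self) -> None:
        genes = set(self.ct.columns)
        if not set(self.reference_genes) <= genes:
            raise ValidationError("reference genes missing from Ct table")
        if not set(self.target_genes) <= genes:
            raise ValidationError("target genes missing from Ct table")
        if len(self.reference_genes) < 2:
            raise ValidationError("need at least two reference genes")
        if self.ct[self.reference_genes].isna().any().any():
            raise ValidationError("missing Ct for a reference gene")
        if (self.ct <= 0).any().any():
            raise ValidationError("Ct values must be positive")
        if not self.groups.index.equals(self.ct.index):
            self.groups = self.groups.reindex(self.ct.index)
            if self.groups.isna().any():
                raise ValidationError("every sample needs a group label")

    def eff(self, gene: str) -> float:
        if isinstance(self.efficiency, dict):
            e = float(self.efficiency.get(gene, 2.0))
        else:
            e = float(self.efficiency)
        if e <= 1.0:
            raise ValidationError(
                f"amplification efficiency for {gene} must be > 1"
            )
        return e


@dataclass
class NormalizedExpression:
    """Per-sample relative quantities, NF, normalized targets and M."""

    q: pd.DataFrame            # relative quantities, all genes
    nf: pd.Series              # geometric-mean normalization factor
    normalized: pd.DataFrame   # Q(target) / NF
    stability: pd.Series       # geNorm M per reference gene
    groups: pd.Series


def relative_quantity(table: CtTable) -> pd.DataFrame:
    """Q(s, g) = E_g^(minCt_g - Ct(s, g)); best-expressed sample has Q = 1."""
    q = {}
    for gene in table.ct.columns:
        e = table.eff(gene)
        ct = table.ct[gene].astype(float)
        q[gene] = np.power(e, ct.min() - ct)
    return pd.DataFrame(q, index=table.ct.index)


def genorm_stability(
    table: CtTable, reference_genes: list[str] | None = None
) -> pd.Series:
    """geNorm stability M per candidate reference gene.

    ``M_j`` is the mean, over the other candidates k, of the standard
    deviation (n-1 denominator) across samples of ``log2(Q_j / Q_k)``.
    Lower M means more stable expression relative to the panel.
    """
    refs = reference_genes or table.reference_genes
    if len(refs) < 2:
        raise ValidationError("stability needs >= 2 candidate references")
    q = relative_quantity(table)[refs]
    if (q <= 0).any().any():
        raise ValidationError("zero relative quantity for a reference gene")
    logq = np.log2(q)
    m = {}
    for j in refs:
        sds = [
            float(np.std(logq[j] - logq[k], ddof=1))
            for k in refs if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="M")


def rank_reference_genes(table: CtTable) -> pd.DataFrame:
    """Stepwise geNorm exclusion: repeatedly drop the least stable gene.

    Returns one row per exclusion step with the gene removed and its M at
    removal; the final two genes (M undefined individually beyond their
    mutual SD) are listed last with their joint M.
    """
    remaining = list(table.reference_genes)
    rows = []
    step = 0
    while len(remaining) > 2:
        m = genorm_stability(table, remaining)
        worst = m.idxmax()
        rows.append({"step": step, "gene": worst, "M": float(m[worst]),
                     "remaining": len(remaining)})
        remaining.remove(worst)
        step += 1
    m = genorm_stability(table, remaining)
    for gene in remaining:
        rows.append({"step": step, "gene": gene, "M": float(m[gene]),
                     "remaining": 2})
    return pd.DataFrame(rows)


def normalized_expression(table: CtTable) -> NormalizedExpression:
    """Normalize target quantities by the geometric mean of the references."""
    q = relative_quantity(table)
    refs = q[table.reference_genes]
    if (refs <= 0).any().any():
        raise ValidationError("reference gene with zero relative quantity")
    nf = np.exp(np.log(refs).mean(axis=1))
    nf.name = "NF"
    normalized = q[table.target_genes].div(nf, axis=0)
    return NormalizedExpression(
        q=q,
        nf=nf,
        normalized=normalized,
        stability=genorm_stability(table),
        groups=table.groups,
    )


def compare_groups(
    norm: NormalizedExpression,
    groups: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Carriers-vs-controls comparison per target gene.

    Reports the median fold change (carrier/control) and a two-sided
    Wilcoxon rank-sum p-value (exact when the data permit).  P-values are
    deliberately unadjusted across targets; "no significant difference" is
    the conclusion when p >= alpha.
    """
    g = groups if groups is not None else norm.groups
    carriers = g.index[g == "carrier"]
    controls = g.index[g == "control"]
    if len(carriers) == 0 or len(controls) == 0:
        raise ValidationError("both groups must be nonempty")
    rows = []
    for gene in norm.normalized.columns:
        x = norm.normalized.loc[carriers, gene].to_numpy(float)
        y = norm.normalized.loc[controls, gene].to_numpy(float)
        method = "exact" if len(np.unique(np.concatenate([x, y]))) == len(x) + len(y) else "auto"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        med_y = float(np.median(y))
        fold = float(np.median(x)) / med_y if med_y > 0 else np.inf
        rows.append(
            {
                "gene": gene,
                "n_carrier": len(x),
                "n_control": len(y),
                "median_fold_change": fold,
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            }
        )
    return pd.DataFrame(rows)


def read_ct_table(path: str | Path) -> CtTable:
    """Read a TSV Ct table.

    Layout: one row per sample with columns ``sample``, ``group``, then one
    column per gene; reference genes are marked by a ``ref:`` prefix in the
    header (e.g. ``ref:ACTB``), all other gene columns are targets.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "group" not in df.columns:
        raise ValidationError(f"{path}: need 'sample' and 'group' columns")
    df = df.set_index("sample")
    groups = df.pop("group")
    refs = [c for c in df.columns if c.startswith("ref:")]
    if not refs:
        raise ValidationError(f"{path}: no reference gene columns (ref:NAME)")
    df = df.rename(columns={c: c[4:] for c in refs})
    reference = [c[4:] for c in refs]
    targets = [c for c in df.columns if c not in reference]
    return CtTable(
        ct=df.astype(float),
        groups=groups,
        reference_genes=reference,
        target_genes=targets,
    )


def write_ct_table(table: CtTable, path: str | Path) -> None:
    df = table.ct.copy()
    df = df.rename(columns={g: f"ref:{g}" for g in table.reference_genes})
    df.insert(0, "group", table.groups)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
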