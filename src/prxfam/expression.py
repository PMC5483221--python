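"""Meta-expression aggregation, pattern classification, and co-expression.

A meta-expression compendium is a genes x samples matrix of log2
intensities with a sample -> tissue map. Tissue means summarise each
gene's anatomical profile; a simple threshold rule classifies genes as
ubiquitous, tissue-preferential, or suppressed; and Pearson correlation
against a bait gene ranks co-expressed partners. Small helpers implement
the 2^-dCt / 2^-ddCt relative-quantification arithmetic used to validate
array calls by qPCR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ConstantProfileError(ValueError):
    """Correlation requested against a constant (zero-variance) vector."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities plus a sample -> tissue map."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    tissue_map: pd.Series  # index = sample ids, values = tissue labels

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = set(v.columns) - set(self.tissue_map.index)
        if missing:
            raise ValueError(f"samples without tissue label: {sorted(missing)}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("non-finite expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.tissue_map[s], None)
        return list(seen)


@dataclass(frozen=True)
class ExpressionClassCall:
    """Pattern call for one gene.

    ``cls`` is one of ``ubiquitous``, ``tissue-preferential``,
    ``suppressed``; ``preferred_tissue`` is set iff preferential.
    ``score`` is the max-vs-median-of-rest difference in log2 units.
    """

    gene_id: str
    cls: str
    preferred_tissue: str | None
    score: float


@dataclass
class CoexpressionGroup:
    """Bait gene plus the k best-correlated partners, PCC-ranked."""

    bait: str
    members: list[tuple[str, float]]  # (gene_id, pcc), non-increasing pcc

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.members]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference cycle thresholds."""

    ct_target: float
    ct_ref: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_ref <= 0:
            raise ValueError("cycle numbers must be positive")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_ref


def aggregate_tissue_means(m: ExpressionMatrix) -> pd.DataFrame:
    """Mean log2 intensity per (gene, tissue).

    Every tissue label that appears in the map must have at least one
    sample column; tissue order follows first appearance in the sample
    columns, so sample order within a tissue is irrelevant to values.
    """
    tissues = m.tissues
    for t in set(m.tissue_map.values):
        cols = [s for s in m.values.columns if m.tissue_map[s] == t]
        if not cols:
            raise ValueError(f"tissue {t!r} has no samples")
    out = pd.DataFrame(index=m.values.index, columns=tissues, dtype=float)
    for t in tissues:
        cols = [s for s in m.values.columns if m.tissue_map[s] == t]
        out[t] = m.values[cols].mean(axis=1)
    return out


def classify_pattern(
    profiles: pd.DataFrame,
    delta: float = 2.0,
    floor: float = 6.0,
) -> list[ExpressionClassCall]:
    """Classify each gene's tissue profile.

    suppressed if the maximum tissue mean is below ``floor``;
    tissue-preferential if (max mean - median of the remaining means)
    >= ``delta``, preferred tissue = argmax; otherwise ubiquitous.
    The specificity score is that max-minus-median difference either way.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 tissues to classify")
    calls = []
    for gene, row in profiles.iterrows():
        vals = row.to_numpy(dtype=float)
        imax = int(np.argmax(vals))
        rest = np.delete(vals, imax)
        score = float(vals[imax] - np.median(rest))
        if vals[imax] < floor:
            calls.append(ExpressionClassCall(str(gene), "suppressed", None, score))
        elif score >= delta:
            calls.append(
                ExpressionClassCall(
                    str(gene), "tissue-preferential", str(profiles.columns[imax]), score
                )
            )
        else:
            calls.append(ExpressionClassCall(str(gene), "ubiquitous", None, score))
    return calls


def calls_to_frame(calls: list[ExpressionClassCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.cls, c.preferred_tissue or "", c.score) for c in calls],
        columns=["gene_id", "class", "preferred_tissue", "score"],
    )


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises :class:`ConstantProfileError` on a zero-variance vector
    rather than silently returning 0 or NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ConstantProfileError("correlation undefined for constant vector")
    r = float((xc @ yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


def top_k_coexpressed(m: ExpressionMatrix, bait: str, k: int) -> CoexpressionGroup:
    """The k genes best correlated with ``bait`` across all samples.

    Ranking is by PCC, non-increasing; ties break lexicographically on
    gene id for determinism. Genes with constant profiles are skipped
    (their correlation is undefined); a constant bait raises.
    """
    if bait not in m.values.index:
        raise KeyError(f"bait {bait!r} not in expression matrix")
    if k >= len(m.values.index):
        raise ValueError("k must be smaller than the number of genes")
    bait_profile = m.values.loc[bait].to_numpy(dtype=float)
    if np.std(bait_profile) == 0.0:
        raise ConstantProfileError(f"bait {bait!r} constant across samples")
    scored: list[tuple[str, float]] = []
    for gene in m.values.index:
        if gene == bait:
            continue
        try:
            r = pearson(bait_profile, m.values.loc[gene].to_numpy(dtype=float))
        except ConstantProfileError:
            continue
        scored.append((str(gene), r))
    scored.sort(key=lambda gr: (-gr[1], gr[0]))
    return CoexpressionGroup(bait=bait, members=scored[:k])


def relative_expression(ct: CtRecord) -> float:
    """2^-dCt relative expression level."""
    return float(2.0 ** (-ct.delta_ct))


def fold_change(treated: CtRecord, control: CtRecord) -> float:
    """2^-ddCt fold change of treated over control."""
    return float(2.0 ** (-(treated.delta_ct - control.delta_ct)))


def read_expression_tsv(values_path, tissue_map_path) -> ExpressionMatrix:
    """Load a compendium: values TSV (first column gene id, header =
    sample ids) plus a two-column sample_id/tissue map TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    tmap_df = pd.read_csv(tissue_map_path, sep="\t")
    tmap = pd.Series(
        tmap_df.iloc[:, 1].astype(str).to_numpy(),
        index=tmap_df.iloc[:, 0].astype(str),
    )
    return ExpressionMatrix(values=values, tissue_map=tmap)


def write_expression_tsv(m: ExpressionMatrix, values_path, tissue_map_path) -> None:
    m.values.to_csv(values_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample_id": m.tissue_map.index, "tissue": m.tissue_map.values}
    ).to_csv(tissue_map_path, sep="\t", index=False)
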