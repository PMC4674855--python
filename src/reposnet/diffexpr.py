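"""Per-contrast differential expression and cross-dataset combination rules.

Implements the signature-extraction stage: probe collapsing, a moderated
two-sample t-test with empirical-Bayes variance shrinkage, Benjamini–
Hochberg FDR control, up/down calls from the sign of the log2 fold
change, and the rules for combining multiple datasets of one disease
(union, direction must agree) or multiple timepoints of one drug
treatment (intersection, direction must agree).

The moderated test shrinks each gene's pooled variance s_g^2 towards a
prior s0^2 fitted by moments on the log variances, exactly in the style
of the empirical-Bayes linear-model approach standard for microarray
contrasts: the posterior variance is

    s_post^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

with d = n1 + n2 - 2 residual degrees of freedom, and the moderated t
statistic is referred to a t distribution on d0 + d degrees of freedom.
(d0, s0^2) are obtained by matching the first two moments of
log(s_g^2) to a scaled F distribution. Welch's t-test is available as a
plain alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionStudy, FormatError, ProbeAnnotation

__all__ = [
    "DiffExprRecord",
    "ContrastResult",
    "GeneSignature",
    "collapse_probes",
    "differential_expression",
    "combine_disease_datasets",
    "combine_drug_timepoints",
    "bh_qvalues",
    "trigamma_inverse",
    "fit_f_dist",
]


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]

#: Variance floor: a zero pooled variance with a nonzero mean difference
#: would give p = 0; flooring at machine-epsilon scale avoids that.
_VAR_FLOOR = np.finfo(float).eps ** 2

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class DiffExprRecord:
    """One gene's differential-expression result for one contrast."""

    gene: str
    log2fc: float
    p_value: float
    q_value: float
    direction: str | None  # "up" | "down" | None when log2fc == 0
    significant: bool


@dataclass
class ContrastResult:
    """All genes of one contrast with their statistics and significance calls."""

    study_id: str
    table: pd.DataFrame  # columns: gene, log2fc, p_value, q_value, direction, significant
    q_threshold: float

    @property
    def records(self) -> list[DiffExprRecord]:
        return [
            DiffExprRecord(
                gene=r.gene,
                log2fc=r.log2fc,
                p_value=r.p_value,
                q_value=r.q_value,
                direction=None if pd.isna(r.direction) else r.direction,
                significant=bool(r.significant),
            )
            for r in self.table.itertuples(index=False)
        ]

    def significant_directions(self) -> dict[str, str]:
        """Significant genes with a defined direction (log2fc != 0)."""
        sig = self.table[self.table.significant & self.table.direction.notna()]
        return dict(zip(sig.gene, sig.direction))


@dataclass
class GeneSignature:
    """A combined significant gene set with directions and provenance."""

    label: str
    directions: dict[str, str]
    conflicting: set[str] = field(default_factory=set)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def genes(self) -> set[str]:
        return set(self.directions)


def collapse_probes(study: ExpressionStudy, ann: ProbeAnnotation) -> ExpressionStudy:
    """Collapse probe-level rows to gene symbols.

    Probes without a gene symbol are removed; probes sharing a symbol are
    replaced by their per-sample arithmetic mean.
    """
    symbols = pd.Series(
        {p: ann.mapping.get(p) for p in study.matrix.index}, dtype=object
    )
    keep = symbols.dropna()
    if keep.empty:
        raise FormatError("no probe in the study maps to a gene symbol")
    collapsed = study.matrix.loc[keep.index].groupby(keep).mean()
    collapsed = collapsed.sort_index()
    return ExpressionStudy(
        matrix=collapsed,
        groups=dict(study.groups),
        study_id=study.study_id,
        condition_name=study.condition_name,
        dose=study.dose,
        timepoint=study.timepoint,
    )


def trigamma_inverse(y: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.max(np.abs(dif) / np.maximum(x, 1e-12)) < 1e-12:
            break
    return x


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-fit a scaled F prior to gene-wise variances.

    Matches mean and variance of log(s2) against the theoretical moments
    of log of a scaled F variate; returns (d0, s0sq) where d0 may be
    ``inf`` when the empirical spread is no wider than sampling noise
    alone (all extra variation explained by the chi-square, so the prior
    is a point mass).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, _VAR_FLOOR)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    if e.size < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(np.var(e, ddof=1))
    resid = e_var - float(special.polygamma(1, df / 2.0))
    if resid <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * float(trigamma_inverse(resid)[0])
    s0sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def differential_expression(
    study: ExpressionStudy,
    q_threshold: float = 0.01,
    method: str = "moderated",
) -> ContrastResult:
    """Test every gene for differential expression between the two groups.

    log2fc = mean(condition) − mean(reference); two-sided p-value from
    the moderated (default) or Welch t-test; q-values by Benjamini–
    Hochberg step-up over all genes of the study; significant iff
    q < ``q_threshold``; direction from the sign of log2fc (undefined,
    and excluded from up/down sets, when log2fc is exactly 0).
    """
    if not 0.0 < q_threshold < 1.0:
        raise ValueError("q_threshold must lie in (0, 1)")
    if method not in ("moderated", "welch"):
        raise ValueError(f"unknown method {method!r}")
    ref = study.matrix[study.reference_samples].to_numpy(dtype=float)
    cond = study.matrix[study.condition_samples].to_numpy(dtype=float)
    n1, n2 = cond.shape[1], ref.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples for variance estimation")

    lfc = cond.mean(axis=1) - ref.mean(axis=1)
    if method == "moderated":
        df_resid = n1 + n2 - 2
        pooled = ((n1 - 1) * cond.var(axis=1, ddof=1) + (n2 - 1) * ref.var(axis=1, ddof=1)) / df_resid
        d0, s0sq = fit_f_dist(pooled, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(pooled, s0sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0sq + df_resid * pooled) / (d0 + df_resid)
            df_total = d0 + df_resid
        s2_post = np.maximum(s2_post, _VAR_FLOOR)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = lfc / se
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        t, p = stats.ttest_ind(cond, ref, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)

    q = bh_qvalues(p)
    direction = np.where(lfc > 0, UP, np.where(lfc < 0, DOWN, None))
    table = pd.DataFrame(
        {
            "gene": study.matrix.index,
            "log2fc": lfc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "significant": q < q_threshold,
        }
    ).reset_index(drop=True)
    return ContrastResult(study_id=study.study_id, table=table, q_threshold=q_threshold)


def _combine(
    results: list[ContrastResult],
    label: str,
    mode: str,
) -> GeneSignature:
    if not results:
        raise ValueError("need at least one contrast to combine")
    per_study = [(r.study_id, r.significant_directions()) for r in results]
    if mode == "union":
        candidates: set[str] = set()
        for _, d in per_study:
            candidates |= set(d)
    else:  # intersection
        candidates = set(per_study[0][1])
        for _, d in per_study[1:]:
            candidates &= set(d)
    directions: dict[str, str] = {}
    conflicting: set[str] = set()
    provenance: dict[str, list[str]] = {}
    for gene in sorted(candidates):
        dirs = {d[gene] for _, d in per_study if gene in d}
        provenance[gene] = [sid for sid, d in per_study if gene in d]
        if len(dirs) == 1:
            directions[gene] = next(iter(dirs))
        else:
            conflicting.add(gene)
    for gene in conflicting:
        provenance.pop(gene, None)
    return GeneSignature(
        label=label, directions=directions, conflicting=conflicting, provenance=provenance
    )


def combine_disease_datasets(results: list[ContrastResult], label: str = "") -> GeneSignature:
    """Union of significant genes across datasets of one disease.

    A gene significant in several datasets keeps its direction only when
    all of them agree; disagreeing genes are flagged ``conflicting`` and
    excluded from the signature. Per-gene provenance records which
    datasets contributed.
    """
    return _combine(results, label or results[0].study_id if results else label, "union")


def combine_drug_timepoints(results: list[ContrastResult], label: str = "") -> GeneSignature:
    """Intersection of significant genes over all timepoints of one drug
    treatment, with direction required to agree across timepoints.

    Multiple dosages are *not* combined — each dosage is a separate drug
    signature; this function is for repeated measurements of one dosage.
    """
    return _combine(results, label or results[0].study_id if results else label, "intersection")
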