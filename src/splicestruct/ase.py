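"""Outlier-based alternative-splicing-event (ASE) calling.

An ASE is a splice junction whose normalized usage is aberrantly high in
tumor samples relative to normals.  The pipeline is:

1. normalize junction counts to log RPM-per-expression:
   ``ln((RPM + pc) / (gene expression + pc))``, so junction usage is
   comparable across samples of different library size and gene expression;
2. set a per-junction Tukey upper fence ``Q3 + k * IQR`` from the NORMAL
   samples and flag every sample strictly above it as an outlier;
3. call a junction an ASE when tumor samples are significantly enriched
   among its outliers (one-sided Fisher exact test) and the tumor outlier
   fraction exceeds the normal one;
4. count, per sample, the ASEs for which that sample is an outlier, and
   compare these per-sample burdens between groups (high-ASE split at
   median + k·SD; expression split at a z-score threshold, Student's t).

The fence/Fisher construction is this package's own reconstruction of
upper-tail outlier statistics commonly used for tumor-vs-normal splice
variant screens; both the fence multiplier and the significance level are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneExpressionMatrix, JunctionCountMatrix, JunctionID

__all__ = [
    "NormalizedJunctionMatrix",
    "OutlierResult",
    "AseCall",
    "SampleAseCount",
    "normalize_junctions",
    "call_outliers",
    "select_ases",
    "count_ases_per_sample",
    "assign_high_ase_group",
    "compare_expression_groups",
]


@dataclass
class NormalizedJunctionMatrix:
    """Log-scale junction usage: RPM divided by gene expression.

    Same junction/sample layout as the source counts; values are finite
    everywhere thanks to the pseudocount in numerator and denominator.
    """

    junctions: list[JunctionID]
    samples: list[str]
    values: np.ndarray
    pseudocount: float
    library_sizes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.samples)
        df.insert(0, "gene", [j.gene for j in self.junctions])
        df.insert(0, "junction_id", [str(j) for j in self.junctions])
        return df


@dataclass
class OutlierResult:
    """Per-junction outlier flags plus the fences that produced them."""

    junctions: list[JunctionID]
    samples: list[str]
    is_outlier: np.ndarray
    fences: np.ndarray
    normal_samples: list[str]
    tumor_samples: list[str]
    k_fence: float


@dataclass
class AseCall:
    junction: JunctionID
    n_outlier_tumor: int
    n_outlier_normal: int
    n_tumor: int
    n_normal: int
    fence: float
    p_enrichment: float
    is_ase: bool


@dataclass
class SampleAseCount:
    sample: str
    n_ases: int
    high_ase: bool | None = None
    high_expression: bool | None = None


def normalize_junctions(
    counts: JunctionCountMatrix,
    expr: GeneExpressionMatrix,
    pseudocount: float = 1.0,
) -> NormalizedJunctionMatrix:
    """Normalize junction counts by library size and gene expression.

    ``value = ln((count / library_size * 1e6 + pc) / (expression + pc))``
    with the library size taken as the per-sample total junction count.
    Every junction's gene must be present in the expression matrix and all
    count samples must appear in it.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    missing_genes = sorted(set(j.gene for j in counts.junctions) - set(expr.genes))
    if missing_genes:
        raise KeyError(f"genes absent from expression matrix: {missing_genes}")
    missing_samples = [s for s in counts.samples if s not in expr.samples]
    if missing_samples:
        raise KeyError(f"samples absent from expression matrix: {missing_samples}")
    lib = counts.counts.sum(axis=0).astype(float)
    lib[lib == 0] = 1.0  # empty sample: RPM of 0 stays 0
    rpm = counts.counts / lib * 1e6
    gene_row = {g: i for i, g in enumerate(expr.genes)}
    col_of = [expr.samples.index(s) for s in counts.samples]
    e = np.vstack(
        [expr.values[gene_row[j.gene], col_of] for j in counts.junctions]
    )
    values = np.log((rpm + pseudocount) / (e + pseudocount))
    return NormalizedJunctionMatrix(
        junctions=list(counts.junctions),
        samples=list(counts.samples),
        values=values,
        pseudocount=pseudocount,
        library_sizes=lib,
    )


def call_outliers(
    norm: NormalizedJunctionMatrix,
    normal_samples: list[str],
    tumor_samples: list[str],
    k_fence: float = 1.5,
) -> OutlierResult:
    """Flag samples above the per-junction Tukey upper fence of the normals.

    The fence is ``Q3 + k_fence * IQR`` with quartiles computed over the
    normal samples only (linear interpolation); any sample — tumor or
    normal — strictly above the fence is an outlier for that junction.
    Only the upper tail is fenced: the screen targets junctions gained in
    tumors, not lost.
    """
    if not normal_samples or not tumor_samples:
        raise ValueError("both sample groups must be non-empty")
    if len(normal_samples) < 3:
        raise ValueError("need at least 3 normal samples for stable quartiles")
    unknown = [s for s in normal_samples + tumor_samples if s not in norm.samples]
    if unknown:
        raise ValueError(f"unknown samples: {unknown}")
    col = {s: i for i, s in enumerate(norm.samples)}
    normal_vals = norm.values[:, [col[s] for s in normal_samples]]
    q1 = np.percentile(normal_vals, 25, axis=1)
    q3 = np.percentile(normal_vals, 75, axis=1)
    fences = q3 + k_fence * (q3 - q1)
    ordered = list(normal_samples) + list(tumor_samples)
    vals = norm.values[:, [col[s] for s in ordered]]
    return OutlierResult(
        junctions=list(norm.junctions),
        samples=ordered,
        is_outlier=vals > fences[:, None],
        fences=fences,
        normal_samples=list(normal_samples),
        tumor_samples=list(tumor_samples),
        k_fence=k_fence,
    )


def select_ases(outliers: OutlierResult, alpha: float = 0.05) -> list[AseCall]:
    """Call ASEs: junctions with tumor-enriched outliers.

    Per junction, a one-sided Fisher exact test on the 2x2 table
    (outlier / non-outlier x tumor / normal); a junction is an ASE when
    ``p < alpha`` and the tumor outlier fraction exceeds the normal one.
    """
    n_t = len(outliers.tumor_samples)
    n_n = len(outliers.normal_samples)
    t_idx = [outliers.samples.index(s) for s in outliers.tumor_samples]
    n_idx = [outliers.samples.index(s) for s in outliers.normal_samples]
    calls: list[AseCall] = []
    for r, junction in enumerate(outliers.junctions):
        t_out = int(outliers.is_outlier[r, t_idx].sum())
        n_out = int(outliers.is_outlier[r, n_idx].sum())
        _, p = stats.fisher_exact(
            [[t_out, n_t - t_out], [n_out, n_n - n_out]], alternative="greater"
        )
        calls.append(
            AseCall(
                junction=junction,
                n_outlier_tumor=t_out,
                n_outlier_normal=n_out,
                n_tumor=n_t,
                n_normal=n_n,
                fence=float(outliers.fences[r]),
                p_enrichment=float(p),
                is_ase=bool(p < alpha and t_out / n_t > n_out / n_n),
            )
        )
    return calls


def count_ases_per_sample(
    calls: list[AseCall], outliers: OutlierResult
) -> list[SampleAseCount]:
    """Per sample, the number of ASEs for which that sample is an outlier."""
    ase_rows = [
        i
        for i, (c, j) in enumerate(zip(calls, outliers.junctions))
        if c.is_ase and str(c.junction) == str(j)
    ]
    if len(ase_rows) != sum(c.is_ase for c in calls):
        raise ValueError("calls do not align with the outlier matrix")
    sub = outliers.is_outlier[ase_rows, :] if ase_rows else np.zeros((0, len(outliers.samples)), bool)
    totals = sub.sum(axis=0)
    return [
        SampleAseCount(sample=s, n_ases=int(t)) for s, t in zip(outliers.samples, totals)
    ]


def assign_high_ase_group(
    counts: list[SampleAseCount], k_sd: float = 0.5
) -> dict[str, bool]:
    """Split samples into high/normal ASE-burden groups.

    A sample is "high" when its ASE count strictly exceeds
    ``median + k_sd * SD`` over all samples (sample SD).  The default
    ``k_sd = 0.5`` is deliberately mild; 0 and 1.0 are sensible
    alternatives and give similar splits on clearly bimodal burdens.
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 samples")
    values = np.array([c.n_ases for c in counts], dtype=float)
    cutoff = np.median(values) + k_sd * values.std(ddof=1)
    labels = {c.sample: bool(c.n_ases > cutoff) for c in counts}
    for c in counts:
        c.high_ase = labels[c.sample]
    return labels


@dataclass
class GroupComparison:
    n_high: int
    n_other: int
    mean_difference: float
    t_statistic: float
    p_value: float


def compare_expression_groups(
    counts: list[SampleAseCount],
    zscores: dict[str, float],
    z_threshold: float = 2.0,
) -> GroupComparison:
    """Compare ASE burden between expression-defined sample groups.

    Samples with gene-expression z-score above ``z_threshold`` form the
    high-expression group; the two groups' ASE counts are compared with a
    two-sided two-sample Student's t-test.  Both groups must have at least
    two samples.
    """
    missing = [c.sample for c in counts if c.sample not in zscores]
    if missing:
        raise ValueError(f"samples without z-score: {missing}")
    high = [c for c in counts if zscores[c.sample] > z_threshold]
    other = [c for c in counts if zscores[c.sample] <= z_threshold]
    if len(high) < 2 or len(other) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (high={len(high)}, other={len(other)})"
        )
    for c in counts:
        c.high_expression = zscores[c.sample] > z_threshold
    x = np.array([c.n_ases for c in high], dtype=float)
    y = np.array([c.n_ases for c in other], dtype=float)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return GroupComparison(
        n_high=len(high),
        n_other=len(other),
        mean_difference=float(x.mean() - y.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )


def calls_to_frame(calls: list[AseCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "junction_id": [str(c.junction) for c in calls],
            "gene": [c.junction.gene for c in calls],
            "n_outlier_tumor": [c.n_outlier_tumor for c in calls],
            "n_outlier_normal": [c.n_outlier_normal for c in calls],
            "n_tumor": [c.n_tumor for c in calls],
            "n_normal": [c.n_normal for c in calls],
            "fence": [c.fence for c in calls],
            "p_enrichment": [c.p_enrichment for c in calls],
            "is_ase": [c.is_ase for c in calls],
        }
    )


def sample_counts_to_frame(counts: list[SampleAseCount]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample for c in counts],
            "n_ases": [c.n_ases for c in counts],
            "high_ase": [c.high_ase for c in counts],
            "high_expression": [c.high_expression for c in counts],
        }
    )
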