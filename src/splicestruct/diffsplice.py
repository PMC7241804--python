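"""Per-gene differential splice-structure testing.

A gene with *n* splice junctions is summarized per sample by its vector of
junction-spanning read counts ``c = (c1, ..., cn)``.  Because we are after
changes in junction *usage*, not expression level, each vector is reduced
to a composition ``x = c / sum(c)`` (after pseudocounting), which lives on
the simplex and is mapped to unconstrained coordinates by the additive
log-ratio (alr) transform

    y_i = ln(x_i / x_n),   i = 1..n-1,

with the last junction as the reference part.  Between two conditions with
``n_r`` replicates each, the group difference of alr vectors is assessed by
a two-sample Hotelling T² statistic, whose scaled version is referred to an
F distribution with ``(n - 1, 2*n_r - n + 1)`` degrees of freedom.  The
denominator df imposes a testability bound: p-values exist only when
``2*n_r - n + 1 > 0``, i.e. for at most ``2*n_r`` junctions.  Genes over
the bound are not discarded; their smallest junctions are amalgamated into
a single bin so that exactly ``max_bins`` (default 6) compositional parts
remain, which keeps the hypothesis testable at ``n_r = 3``.

Junctions are first filtered to those "in use" (per-condition mean count at
or above a threshold, default 3, in at least one condition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import JunctionCountMatrix, JunctionID

__all__ = [
    "SpliceStructure",
    "DiffspliceConfig",
    "GeneTestResult",
    "filter_in_use",
    "amalgamate",
    "normalize_pattern",
    "alr_transform",
    "max_testable_junctions",
    "hotelling_t2",
    "test_gene",
    "run_dataset",
    "structures_from_matrix",
]

STATUS_TESTED = "tested"
STATUS_UNTESTABLE_DF = "untestable_df"
STATUS_UNTESTABLE_SINGLE = "untestable_single_junction"
STATUS_SINGULAR_PINV = "singular_covariance_pinv"

AMALGAM_LABEL = "AMALGAM"


@dataclass
class DiffspliceConfig:
    """Tunable parameters of the splice-structure test.

    min_mean_count
        A junction is "in use" when its mean count reaches this value in at
        least one condition (``in_use_rule="any"``) or in both
        (``"both"``).  Default 3.
    max_bins
        Genes with more in-use junctions than this are reduced to exactly
        ``max_bins`` compositional parts by amalgamating the smallest
        junctions into one bin.  Default 6, the largest testable dimension
        at three replicates per condition.
    pseudocount
        Offset added to every count before closure so the alr transform is
        defined in the presence of zeros.  Default 0.5.
    pinv_tolerance
        Relative singular-value cutoff for the pseudo-inverse fallback when
        the pooled covariance is numerically singular.
    """

    min_mean_count: float = 3.0
    max_bins: int = 6
    pseudocount: float = 0.5
    alpha: float = 0.05
    pinv_tolerance: float = 1e-12
    in_use_rule: str = "any"

    def __post_init__(self) -> None:
        if self.min_mean_count < 0:
            raise ValueError("min_mean_count must be >= 0")
        if self.max_bins < 2:
            raise ValueError("max_bins must be >= 2")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.in_use_rule not in ("any", "both"):
            raise ValueError("in_use_rule must be 'any' or 'both'")


@dataclass
class SpliceStructure:
    """One gene's junction-count vectors across the samples of a two-group design.

    ``counts`` is junctions x samples; ``condition_of`` must assign every
    sample to one of exactly two condition labels, with ``n_r`` samples
    each.
    """

    gene: str
    junctions: list[JunctionID]
    samples: list[str]
    counts: np.ndarray
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.junctions), len(self.samples)):
            raise ValueError("counts must be a junctions x samples matrix")
        missing = [s for s in self.samples if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        labels = sorted({self.condition_of[s] for s in self.samples})
        if len(labels) != 2:
            raise ValueError(f"exactly two conditions required, got {labels}")
        sizes = [sum(self.condition_of[s] == lab for s in self.samples) for lab in labels]
        if sizes[0] != sizes[1]:
            raise ValueError(f"unequal group sizes {dict(zip(labels, sizes))}")

    @property
    def conditions(self) -> tuple[str, str]:
        return tuple(sorted({self.condition_of[s] for s in self.samples}))  # type: ignore[return-value]

    @property
    def n_r(self) -> int:
        return len(self.samples) // 2

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    def group_columns(self, condition: str) -> np.ndarray:
        # columns ordered by sample name so results are bitwise invariant
        # under permutations of the input sample order
        idx = sorted(
            (i for i, s in enumerate(self.samples) if self.condition_of[s] == condition),
            key=lambda i: self.samples[i],
        )
        return self.counts[:, idx]


@dataclass
class GeneTestResult:
    gene: str
    n_junctions_total: int
    n_junctions_used: int
    amalgamated: bool
    T2: float | None
    F_stat: float | None
    df1: int | None
    df2: int | None
    p_value: float | None
    status: str
    q_value: float | None = None


def filter_in_use(structure: SpliceStructure, cfg: DiffspliceConfig) -> SpliceStructure:
    """Drop junctions that are not "in use".

    A junction is kept when its mean count is >= ``cfg.min_mean_count`` in
    at least one condition (or in both, under ``in_use_rule="both"``).
    Junction order is preserved.  Condition-specific junctions — in heavy
    use in one condition, absent in the other — are exactly the interesting
    signal, hence the at-least-one default.
    """
    a, b = structure.conditions
    mean_a = structure.group_columns(a).mean(axis=1)
    mean_b = structure.group_columns(b).mean(axis=1)
    if cfg.in_use_rule == "any":
        keep = (mean_a >= cfg.min_mean_count) | (mean_b >= cfg.min_mean_count)
    else:
        keep = (mean_a >= cfg.min_mean_count) & (mean_b >= cfg.min_mean_count)
    idx = np.flatnonzero(keep)
    return replace(
        structure,
        junctions=[structure.junctions[i] for i in idx],
        counts=structure.counts[idx, :],
    )


def amalgamate(
    structure: SpliceStructure, cfg: DiffspliceConfig
) -> tuple[SpliceStructure, bool]:
    """Reduce a gene to at most ``max_bins`` compositional parts.

    When the gene has more junctions than ``max_bins``, the
    ``max_bins - 1`` junctions with the largest overall mean count are kept
    (ties broken by original order) and all remaining counts are summed,
    per sample, into one synthetic bin, so per-sample totals are conserved
    exactly.  Returns the (possibly unchanged) structure and whether
    amalgamation occurred.
    """
    n = structure.n_junctions
    if n <= cfg.max_bins:
        return structure, False
    overall_mean = structure.counts.mean(axis=1)
    order = np.argsort(-overall_mean, kind="stable")
    kept = np.sort(order[: cfg.max_bins - 1])
    rest = np.sort(order[cfg.max_bins - 1 :])
    amalgam_counts = structure.counts[rest, :].sum(axis=0, keepdims=True)
    template = structure.junctions[0]
    amalgam_id = JunctionID(
        chrom=AMALGAM_LABEL, start=1, end=2, gene=template.gene, strand="unknown"
    )
    return (
        replace(
            structure,
            junctions=[structure.junctions[i] for i in kept] + [amalgam_id],
            counts=np.vstack([structure.counts[kept, :], amalgam_counts]),
        ),
        True,
    )


def normalize_pattern(c: np.ndarray, cfg: DiffspliceConfig | None = None) -> np.ndarray:
    """Close a count vector to a strictly positive composition.

    ``x_i = (c_i + pseudocount) / sum_j (c_j + pseudocount)``; the
    pseudocount keeps every part strictly positive so the subsequent log
    ratios are finite.
    """
    cfg = cfg or DiffspliceConfig()
    c = np.asarray(c, dtype=float)
    if c.ndim != 1 or c.size < 2:
        raise ValueError("count vector must be 1-D with at least two junctions")
    shifted = c + cfg.pseudocount
    return shifted / shifted.sum()


def alr_transform(x: np.ndarray, reference_index: int = -1) -> np.ndarray:
    """Additive log-ratio transform of a composition.

    Maps an n-part composition to n-1 unconstrained coordinates
    ``ln(x_i / x_ref)`` for all parts except the reference (default: the
    last part), preserving the original part order.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("alr transform requires strictly positive components")
    ref = range(x.size)[reference_index]
    others = [i for i in range(x.size) if i != ref]
    return np.log(x[others] / x[ref])


def max_testable_junctions(n_r: int) -> int:
    """Largest junction count n with positive denominator df, 2*n_r - n + 1 > 0.

    Equals ``2*n_r``: at three replicates per condition only genes with
    fewer than 7 junctions admit a p-value.
    """
    if n_r < 2:
        raise ValueError("need at least 2 replicates per condition")
    return 2 * n_r


def hotelling_t2(
    Y_A: np.ndarray,
    Y_B: np.ndarray,
    n_r: int,
    cfg: DiffspliceConfig | None = None,
) -> tuple[float, float, int, int, float | None, str]:
    """Two-sample Hotelling T² on alr vectors, with the F null used here.

    ``Y_A`` and ``Y_B`` are ``n_r x p`` arrays of alr coordinates
    (``p = n - 1`` for an n-junction gene).  Returns
    ``(T2, F_stat, df1, df2, p_value, status)`` with

        T2 = (n_r/2) * d' S^{-1} d,
        F  = T2 * df2 / ((2*n_r - 2) * df1),
        df1 = n - 1,  df2 = 2*n_r - n + 1,

    where ``d`` is the difference of group means and ``S`` the pooled
    sample covariance (divisor ``2*n_r - 2``).  When ``S`` is numerically
    singular — unavoidable when p exceeds the pooled-covariance rank
    ``2*n_r - 2``, e.g. six bins at three replicates — the Moore-Penrose
    pseudo-inverse is used and the result is status-flagged.
    """
    cfg = cfg or DiffspliceConfig()
    Y_A = np.atleast_2d(np.asarray(Y_A, dtype=float))
    Y_B = np.atleast_2d(np.asarray(Y_B, dtype=float))
    if Y_A.shape != (n_r, Y_A.shape[1]) or Y_B.shape != Y_A.shape:
        raise ValueError("both groups need n_r vectors of equal dimension")
    p = Y_A.shape[1]
    if p == 0:
        return math.nan, math.nan, 0, 2 * n_r, None, STATUS_UNTESTABLE_SINGLE
    n = p + 1
    df1 = p
    df2 = 2 * n_r - n + 1
    if df2 <= 0:
        return math.nan, math.nan, df1, df2, None, STATUS_UNTESTABLE_DF

    d = Y_A.mean(axis=0) - Y_B.mean(axis=0)
    ca = Y_A - Y_A.mean(axis=0)
    cb = Y_B - Y_B.mean(axis=0)
    S = (ca.T @ ca + cb.T @ cb) / (2 * n_r - 2)

    status = STATUS_TESTED
    rank = np.linalg.matrix_rank(S, tol=cfg.pinv_tolerance * max(1.0, float(np.abs(S).max())))
    if rank < p:
        quad = float(d @ np.linalg.pinv(S, rcond=cfg.pinv_tolerance) @ d)
        status = STATUS_SINGULAR_PINV
    else:
        quad = float(d @ np.linalg.solve(S, d))
    T2 = (n_r * n_r / (2 * n_r)) * quad
    T2 = max(T2, 0.0)
    F_stat = T2 * df2 / ((2 * n_r - 2) * df1)
    p_value = float(stats.f.sf(F_stat, df1, df2))
    return T2, F_stat, df1, df2, p_value, status


def test_gene(structure: SpliceStructure, cfg: DiffspliceConfig | None = None) -> GeneTestResult:
    """Run the full per-gene pipeline: filter, amalgamate, close, alr, T².

    Untestable genes are reported via ``status`` flags, never exceptions.
    ``df1`` refers to the alr dimension actually tested, i.e. bins minus
    one after any amalgamation.
    """
    cfg = cfg or DiffspliceConfig()
    n_total = structure.n_junctions
    used = filter_in_use(structure, cfg)
    n_used = used.n_junctions
    if n_used <= 1:
        return GeneTestResult(
            gene=structure.gene,
            n_junctions_total=n_total,
            n_junctions_used=n_used,
            amalgamated=False,
            T2=None,
            F_stat=None,
            df1=None,
            df2=None,
            p_value=None,
            status=STATUS_UNTESTABLE_SINGLE,
        )
    binned, amalgamated = amalgamate(used, cfg)
    n_bins = binned.n_junctions
    n_r = binned.n_r
    df2 = 2 * n_r - n_bins + 1
    if df2 <= 0:
        return GeneTestResult(
            gene=structure.gene,
            n_junctions_total=n_total,
            n_junctions_used=n_used,
            amalgamated=amalgamated,
            T2=None,
            F_stat=None,
            df1=n_bins - 1,
            df2=df2,
            p_value=None,
            status=STATUS_UNTESTABLE_DF,
        )
    a, b = binned.conditions
    Y = {}
    for cond in (a, b):
        cols = binned.group_columns(cond)
        Y[cond] = np.vstack(
            [alr_transform(normalize_pattern(cols[:, i], cfg)) for i in range(cols.shape[1])]
        )
    T2, F_stat, df1, df2, p_value, status = hotelling_t2(Y[a], Y[b], n_r, cfg)
    return GeneTestResult(
        gene=structure.gene,
        n_junctions_total=n_total,
        n_junctions_used=n_used,
        amalgamated=amalgamated,
        T2=T2,
        F_stat=F_stat,
        df1=df1,
        df2=df2,
        p_value=p_value,
        status=status,
    )


def structures_from_matrix(matrix: JunctionCountMatrix) -> list[SpliceStructure]:
    """Split a junction-count matrix into per-gene splice structures."""
    by_gene: dict[str, list[int]] = {}
    for i, j in enumerate(matrix.junctions):
        by_gene.setdefault(j.gene, []).append(i)
    return [
        SpliceStructure(
            gene=gene,
            junctions=[matrix.junctions[i] for i in rows],
            samples=list(matrix.samples),
            counts=matrix.counts[rows, :],
            condition_of=dict(matrix.condition_of),
        )
        for gene, rows in by_gene.items()
    ]


_RESULT_COLUMNS = [
    "gene",
    "n_junctions_total",
    "n_junctions_used",
    "amalgamated",
    "T2",
    "F_stat",
    "df1",
    "df2",
    "p_value",
    "q_value",
    "status",
]


def run_dataset(
    matrix: JunctionCountMatrix, cfg: DiffspliceConfig | None = None
) -> pd.DataFrame:
    """Test every gene in a dataset and attach Benjamini-Hochberg q-values.

    Requires exactly two conditions with equal replicate counts.  The
    returned table is sorted by p-value ascending (undefined p last), ties
    broken by gene symbol; q-values are computed over the genes with a
    defined p-value only.
    """
    cfg = cfg or DiffspliceConfig()
    results = [test_gene(s, cfg) for s in structures_from_matrix(matrix)]
    df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "n_junctions_total": r.n_junctions_total,
                "n_junctions_used": r.n_junctions_used,
                "amalgamated": r.amalgamated,
                "T2": r.T2,
                "F_stat": r.F_stat,
                "df1": r.df1,
                "df2": r.df2,
                "p_value": r.p_value,
                "q_value": np.nan,
                "status": r.status,
            }
            for r in results
        ],
        columns=_RESULT_COLUMNS,
    )
    defined = df["p_value"].notna()
    if defined.any():
        _, q, _, _ = multipletests(df.loc[defined, "p_value"], method="fdr_bh")
        df.loc[defined, "q_value"] = q
    df = df.sort_values(
        ["p_value", "gene"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return df


def write_results(df: pd.DataFrame, path) -> None:
    """Write a results table as TSV with undefined values serialized as NA."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")
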