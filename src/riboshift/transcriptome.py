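"""Expression-analysis statistics for the genotype x cold-shift design.

The transcriptome layer of a shift study is a probe x sample matrix over a
3 genotypes x 3 timepoints x 3 replicates design.  Processing follows the
standard microarray path: quantile normalization across samples, averaging
of redundant probes per gene model, and log2 fold changes relative to a
reference condition (non-acclimated wild type, or the wild type of the same
timepoint).  On top of that sit four inference tools:

* Welch's unequal-variance t test for pairwise group comparisons;
* balanced two-factor ANOVA (genotype, time, interaction);
* parametric gene-set enrichment (PAGE): for a set of m genes with mean
  log2-FC Sm against a global fold-change distribution with mean mu and
  standard deviation delta, z = (Sm - mu) * sqrt(m) / delta, with
  Benjamini-Hochberg FDR control across all tested sets and a minimum
  usable set size of 10;
* a constitutive-change screen: genes shifted in the same direction with
  P < 0.05 in every pairwise mutant-vs-wild-type comparison, in both mutant
  genotypes at all timepoints.

Expression values are treated as log2 after normalization; a flag handles
linear-scale input where noted.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 10


# --------------------------------------------------------------------------
# normalization and probe handling
# --------------------------------------------------------------------------


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample has identical order statistics.

    Rank r in each column is replaced by the mean over columns of the r-th
    order statistic; tied values within a column receive the mean of the
    quantile means their ranks span.
    """
    if matrix.shape[1] < 2:
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    order_stat_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = order_stat_means
        # ties share the mean of the quantile means they cover
        s = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Average redundant probes per gene model.

    Probes absent from the map are dropped with a warning; the result is a
    gene x sample matrix.
    """
    if len(probe_to_gene) == 0:
        raise ValueError("probe-to-gene map is empty")
    mapped = matrix.index.intersection(probe_to_gene.index)
    dropped = matrix.index.difference(probe_to_gene.index)
    if len(dropped):
        logger.warning("%d unmapped probe(s) dropped", len(dropped))
    sub = matrix.loc[mapped]
    return sub.groupby(probe_to_gene.loc[mapped]).mean()


# --------------------------------------------------------------------------
# pairwise statistics
# --------------------------------------------------------------------------


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's heteroscedastic two-sample t test (two-sided).

    Returns (t, P) with Welch-Satterthwaite degrees of freedom.  When both
    groups have zero variance, P is 1 for equal means and 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def log2fc(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    condition: tuple[str, str],
    reference: tuple[str, str],
    linear_input: bool = False,
) -> pd.DataFrame:
    """Per-gene log2-FC of one (genotype, timepoint) condition vs a reference.

    Values are assumed log2 (set ``linear_input`` to log-transform first).
    Returns per gene the difference of group means, its standard error and
    the Welch two-sided P value.
    """
    meta = metadata.set_index("sample") if "sample" in metadata.columns else metadata

    def group(cond: tuple[str, str]) -> pd.DataFrame:
        g, t = cond
        samples = meta.index[(meta["genotype"] == g) & (meta["timepoint"] == t)]
        if len(samples) < 2:
            raise ValueError(f"condition {cond} has fewer than 2 replicates")
        sub = matrix[samples]
        return np.log2(sub) if linear_input else sub

    x, y = group(condition), group(reference)
    nx, ny = x.shape[1], y.shape[1]
    fc = x.mean(axis=1) - y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se = np.sqrt(vx / nx + vy / ny)
    with warnings.catch_warnings():
        # near-identical replicate values trigger a scipy precision warning;
        # the degenerate zero-variance cases are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = pd.Series(t_res.pvalue, index=matrix.index)
    # degenerate zero-variance genes: P=1 when means equal, else 0
    degenerate = (vx == 0) & (vy == 0)
    p[degenerate & (fc == 0)] = 1.0
    p[degenerate & (fc != 0)] = 0.0
    return pd.DataFrame({"log2_fc": fc, "se": se, "p_value": p})


def reference_normalize(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    reference: tuple[str, str] = ("Col-0", "0d"),
) -> pd.DataFrame:
    """Express every sample per gene relative to the mean of a reference condition.

    With log2 input this subtracts the per-gene mean of the reference
    samples (e.g. non-acclimated wild type), turning the matrix into log2
    fold changes against that baseline.
    """
    meta = metadata.set_index("sample") if "sample" in metadata.columns else metadata
    g, t = reference
    refs = meta.index[(meta["genotype"] == g) & (meta["timepoint"] == t)]
    if len(refs) == 0:
        raise ValueError(f"no samples for reference condition {reference}")
    return matrix.sub(matrix[refs].mean(axis=1), axis=0)


# --------------------------------------------------------------------------
# two-factor ANOVA
# --------------------------------------------------------------------------


def two_way_anova(
    values: pd.DataFrame | pd.Series,
    genotype: pd.Series,
    time: pd.Series,
) -> pd.DataFrame:
    """Balanced two-factor fixed-effects ANOVA per gene.

    ``values`` is gene x sample (a Series is treated as a single gene);
    ``genotype`` and ``time`` give the factor level per sample.  Returns per
    gene the F statistics and P values for genotype, time and their
    interaction, tested against the residual mean square.  The design must
    be balanced (equal replication in every cell) with >= 2 replicates per
    cell; in that case type-I/II/III sums of squares coincide.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame().T
    genotype = pd.Series(genotype)
    time = pd.Series(time)
    a_levels = genotype.unique()
    b_levels = time.unique()
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("each factor needs at least two levels")
    counts = pd.crosstab(genotype, time)
    if counts.to_numpy().min() < 2:
        raise ValueError("need >= 2 replicates per design cell")
    if counts.to_numpy().std() != 0:
        raise ValueError("design must be balanced (equal replicates per cell)")
    r = int(counts.iloc[0, 0])
    a, b = len(a_levels), len(b_levels)

    y = values.to_numpy(dtype=float)  # genes x samples
    grand = y.mean(axis=1, keepdims=True)

    cell_means = np.empty((y.shape[0], a, b))
    a_means = np.empty((y.shape[0], a))
    b_means = np.empty((y.shape[0], b))
    for i, ga in enumerate(a_levels):
        sel_a = (genotype == ga).to_numpy()
        a_means[:, i] = y[:, sel_a].mean(axis=1)
        for j, tb in enumerate(b_levels):
            sel = sel_a & (time == tb).to_numpy()
            cell_means[:, i, j] = y[:, sel].mean(axis=1)
    for j, tb in enumerate(b_levels):
        b_means[:, j] = y[:, (time == tb).to_numpy()].mean(axis=1)

    ss_a = r * b * ((a_means - grand) ** 2).sum(axis=1)
    ss_b = r * a * ((b_means - grand) ** 2).sum(axis=1)
    inter = (
        cell_means
        - a_means[:, :, None]
        - b_means[:, None, :]
        + grand[:, :, None]
    )
    ss_ab = r * (inter**2).sum(axis=(1, 2))
    fitted = np.empty_like(y)
    for i, ga in enumerate(a_levels):
        for j, tb in enumerate(b_levels):
            sel = ((genotype == ga) & (time == tb)).to_numpy()
            fitted[:, sel] = cell_means[:, i, j][:, None]
    ss_e = ((y - fitted) ** 2).sum(axis=1)

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (r - 1)
    mse = ss_e / df_e
    with np.errstate(divide="ignore", invalid="ignore"):
        f_a = (ss_a / df_a) / mse
        f_b = (ss_b / df_b) / mse
        f_ab = (ss_ab / df_ab) / mse
    out = pd.DataFrame(
        {
            "F_genotype": f_a,
            "P_genotype": stats.f.sf(f_a, df_a, df_e),
            "F_time": f_b,
            "P_time": stats.f.sf(f_b, df_b, df_e),
            "F_interaction": f_ab,
            "P_interaction": stats.f.sf(f_ab, df_ab, df_e),
        },
        index=values.index,
    )
    # all-equal (zero-variance) genes: F = 0, P = 1
    zero = ss_e + ss_a + ss_b + ss_ab == 0
    out.loc[zero, ["F_genotype", "F_time", "F_interaction"]] = 0.0
    out.loc[zero, ["P_genotype", "P_time", "P_interaction"]] = 1.0
    return out


# --------------------------------------------------------------------------
# gene-set enrichment (PAGE) and FDR
# --------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (set name, description, members per line)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (monotone, order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def page_enrichment(
    fc: pd.Series,
    sets: dict[str, list[str]],
    min_set_size: int = MIN_SET_SIZE,
    two_sided: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Parametric analysis of gene set enrichment over one log2-FC vector.

    For each set with at least ``min_set_size`` genes present in ``fc``:
    z = (Sm - mu) * sqrt(m) / delta, with mu and delta the mean and standard
    deviation of all fold changes; P from the standard normal (two-sided by
    default, upper-tail with ``two_sided=False``); BH-FDR across all tested
    sets; significance at FDR-adjusted P < ``alpha``.
    """
    fc = fc.dropna()
    if len(fc) < min_set_size:
        raise ValueError("fold-change vector smaller than the minimum set size")
    mu = float(fc.mean())
    delta = float(fc.std(ddof=0))
    if delta == 0:
        raise ValueError("global fold-change standard deviation is zero")
    rows = []
    for name, members in sets.items():
        present = fc.index.intersection(pd.Index(members).unique())
        m = len(present)
        if m < min_set_size:
            logger.info("gene set %s skipped: %d mapped genes < %d", name, m, min_set_size)
            continue
        sm = float(fc.loc[present].mean())
        z = (sm - mu) * np.sqrt(m) / delta
        p = 2.0 * stats.norm.sf(abs(z)) if two_sided else float(stats.norm.sf(z))
        rows.append({"set": name, "m": m, "set_mean_fc": sm, "z": z, "p_value": p})
    result = pd.DataFrame(rows, columns=["set", "m", "set_mean_fc", "z", "p_value"])
    if len(result):
        result["fdr"] = bh_fdr(result["p_value"])
        result["significant"] = result["fdr"] < alpha
    else:
        result["fdr"] = []
        result["significant"] = []
    return result.set_index("set")


# --------------------------------------------------------------------------
# constitutive-change screen
# --------------------------------------------------------------------------


def constitutive_screen(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    wildtype: str = "Col-0",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes constitutively changed in both mutants at every timepoint.

    A gene passes when every pairwise Welch comparison of each mutant
    genotype against the wild type at the same timepoint has P < ``alpha``
    and all comparisons agree in fold-change direction (a constitutive
    accumulation or depletion).  Genes missing any comparison are excluded.
    Returns the passing genes with their direction and the maximum P over
    the comparisons.
    """
    meta = metadata.set_index("sample") if "sample" in metadata.columns else metadata
    mutants = [g for g in meta["genotype"].unique() if g != wildtype]
    timepoints = list(meta["timepoint"].unique())
    if not mutants or not timepoints:
        raise ValueError("metadata must define mutant genotypes and timepoints")

    sign_ok = pd.Series(True, index=matrix.index)
    all_sig = pd.Series(True, index=matrix.index)
    first_sign: pd.Series | None = None
    max_p = pd.Series(0.0, index=matrix.index)
    for mut in mutants:
        for tp in timepoints:
            res = log2fc(matrix, meta, (mut, tp), (wildtype, tp))
            sign = np.sign(res["log2_fc"])
            if first_sign is None:
                first_sign = sign
            sign_ok &= (sign == first_sign) & (sign != 0)
            all_sig &= res["p_value"] < alpha
            max_p = np.maximum(max_p, res["p_value"])
    passing = matrix.index[sign_ok & all_sig]
    direction = first_sign.loc[passing].map({1.0: "increase", -1.0: "decrease"})
    return pd.DataFrame(
        {"direction": direction, "max_p": max_p.loc[passing]}, index=passing
    ).sort_index()
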