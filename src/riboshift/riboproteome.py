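"""Compositional analysis of fraction-wise ribo-proteome LFQ tables.

The input is a protein x fraction matrix of label-free quantification (LFQ)
abundances from sucrose-gradient fractions of one sample (genotype at one
temperature), linked to an annotation catalog.  The analysis:

1. assigns a gradient identity (30S/40S, 50S, 60S, 60S/80S, polysome) to
   each fraction from the across-fraction distribution of summed RP-class
   abundances and the positions of the pre-60S markers eIF6A and NMD3;
2. normalizes protein abundances within each non-translating fraction to
   the summed abundance of the reference RP class (60S RPs for the 60S
   compartment, 40S RPs for the 30S/40S fraction), giving compositional
   shares that are invariant to per-fraction loading;
3. filters proteins whose raw abundance does not peak in the compartment's
   fractions (guards against co-purification artifacts);
4. calls per-protein changes between mutant and wild type: presence/absence
   status (``+`` / ``-``) or a numeric log2 fold change classified at |1|;
5. selects changes shared in direction between two independent experiments
   (and optionally both temperatures) — selection is purely this
   shared-direction rule, no significance testing is applied.

Detection is binary at LFQ > 0; an LFQ of 0 means not detected.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationCatalog

logger = logging.getLogger(__name__)

FRACTION_LABELS = ("30S/40S", "50S", "60S", "60S/80S", "polysome")

#: class weights used to score a fraction's across-gradient abundance share
#: for each candidate identity label
_LABEL_WEIGHTS: dict[str, dict[str, float]] = {
    "30S/40S": {"RP40S": 1.0, "RP30S_org": 1.0, "eIF3": 0.5},
    "50S": {"RP50S_org": 1.0, "eIF3": 0.25},
    "60S": {"RP60S": 0.7, "biogenesis": 1.0},
    "60S/80S": {"RP60S": 0.7, "biogenesis": 0.5, "RP40S": 0.3},
    "polysome": {"RP40S": 0.5, "RP60S": 0.5},
}


@dataclass
class FractionTable:
    """Protein x fraction LFQ matrix of one sample with its annotation link."""

    data: pd.DataFrame
    catalog: AnnotationCatalog
    genotype: str = ""
    temperature: str = ""
    experiment: str = ""

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)) or (values < 0).any():
            raise ValueError("LFQ abundances must be finite and >= 0")

    def classes(self) -> pd.Series:
        """RP class per protein row (unknown identifiers are 'other')."""
        from .annotation import classify

        return pd.Series(
            {pid: classify(self.catalog, pid) for pid in self.data.index}, name="rp_class"
        )

    def class_sums(self) -> pd.DataFrame:
        """Summed LFQ abundance per RP class (rows) per fraction (columns)."""
        return self.data.groupby(self.classes()).sum()


@dataclass
class FractionIdentity:
    """Assigned gradient labels and the evidence behind them."""

    labels: dict[str, str]  # fraction -> identity label (unassigned fractions absent)
    evidence: pd.DataFrame = field(repr=False, default=None)

    def fractions_for(self, *wanted: str) -> list[str]:
        return [f for f, lab in self.labels.items() if lab in wanted]


def assign_fractions(table: FractionTable) -> FractionIdentity:
    """Assign gradient identities to fractions by RP-class evidence.

    For every class the across-fraction share profile (class sum per
    fraction / class total) is computed; each (fraction, label) pair is
    scored by the label's class weights.  Labels are then assigned by the
    order-preserving injective assignment that maximizes the total score,
    subject to sedimentation order and to the marker constraint: fractions
    holding the abundance maximum of eIF6A or NMD3 (pre-60S markers) are
    eligible only for the 60S and 60S/80S labels.
    """
    class_sums = table.class_sums()
    rp_classes_present = [c for c in class_sums.index if c != "other"]
    if not any(c.startswith("RP") for c in rp_classes_present):
        raise ValueError("no ribosomal proteins detected; cannot assign fractions")

    totals = class_sums.sum(axis=1)
    shares = class_sums.div(totals.where(totals > 0), axis=0).fillna(0.0)

    fractions = list(table.data.columns)
    score = pd.DataFrame(0.0, index=fractions, columns=list(FRACTION_LABELS))
    for label, weights in _LABEL_WEIGHTS.items():
        for cls, w in weights.items():
            if cls in shares.index:
                score[label] += w * shares.loc[cls]

    marker_fracs: set[str] = set()
    for marker in table.catalog.markers("pre60S_marker"):
        if marker.protein_id in table.data.index:
            row = table.data.loc[marker.protein_id]
            if row.max() > 0:
                marker_fracs.add(row.idxmax())

    n_f, n_l = len(fractions), len(FRACTION_LABELS)
    k = min(n_f, n_l)
    best: tuple[float, dict[str, str]] | None = None
    for f_idx in itertools.combinations(range(n_f), k):
        for l_idx in itertools.combinations(range(n_l), k):
            assignment = {fractions[fi]: FRACTION_LABELS[li] for fi, li in zip(f_idx, l_idx)}
            if any(
                f in marker_fracs and lab not in ("60S", "60S/80S")
                for f, lab in assignment.items()
            ):
                continue
            total = sum(score.at[f, lab] for f, lab in assignment.items())
            if best is None or total > best[0]:
                best = (total, assignment)
    if best is None:
        raise ValueError("no admissible fraction assignment found")
    return FractionIdentity(labels=best[1], evidence=score)


def total_rp_summary(table: FractionTable) -> pd.Series:
    """Summed LFQ abundance per RP class across all fractions of the sample."""
    return table.class_sums().sum(axis=1)


@dataclass
class NormalizedShareTable:
    """Per-protein abundance shares relative to the reference RP-class sum."""

    shares: pd.DataFrame  # protein x fraction (compartment fractions only)
    compartment: str  # "60S" | "40S"
    reference_sums: pd.Series  # per fraction: the divisor used
    excluded_fractions: list[str] = field(default_factory=list)


def normalize_shares(
    table: FractionTable,
    identity: FractionIdentity,
    compartment: str,
) -> NormalizedShareTable:
    """Divide each fraction by the summed abundance of its reference RP class.

    The 60S compartment uses the fractions labeled 60S and 60S/80S with the
    sum of all detected 60S RPs as divisor, excluding all 40S RPs from the
    analysis; the 40S compartment uses the 30S/40S fraction with the sum of
    all 40S RPs, excluding all 60S RPs.  Fractions whose reference sum is
    zero are excluded with a warning.
    """
    if compartment == "60S":
        fracs = identity.fractions_for("60S", "60S/80S")
        ref_class, drop_class = "RP60S", "RP40S"
    elif compartment == "40S":
        fracs = identity.fractions_for("30S/40S")
        ref_class, drop_class = "RP40S", "RP60S"
    else:
        raise ValueError("compartment must be '60S' or '40S'")
    if not fracs:
        raise ValueError(f"no fractions assigned to the {compartment} compartment")

    classes = table.classes()
    sub = table.data.loc[classes != drop_class, fracs]
    ref_ids = [p for p in sub.index if classes[p] == ref_class]
    ref_sums = sub.loc[ref_ids].sum(axis=0)

    excluded = [f for f in fracs if ref_sums[f] <= 0]
    for f in excluded:
        logger.warning("fraction %s has zero %s reference sum; excluded", f, ref_class)
    kept = [f for f in fracs if f not in excluded]
    shares = sub[kept].div(ref_sums[kept], axis=1)
    return NormalizedShareTable(
        shares=shares,
        compartment=compartment,
        reference_sums=ref_sums[kept],
        excluded_fractions=excluded,
    )


def combine_60s_fractions(shares: NormalizedShareTable) -> pd.Series:
    """Combine per-protein shares across the 60S and 60S/80S fractions.

    The combined value is the mean over the two fractions; a protein missing
    (or zero) in one fraction contributes 0 there with the divisor kept at
    the number of compartment fractions, so single-fraction detections are
    down-weighted rather than inflated.
    """
    if shares.compartment != "60S":
        raise ValueError("combine_60s_fractions applies to the 60S compartment")
    n = len(shares.shares.columns)
    return shares.shares.fillna(0.0).sum(axis=1) / n


def abundance_max_filter(
    table: FractionTable,
    identity: FractionIdentity,
    protein_id: str,
    compartment: str,
) -> bool:
    """Raw-abundance location filter against co-purification artifacts.

    60S compartment: keep the protein only if its raw LFQ maximum over the
    non-translating fractions lies in the 60S or 60S/80S fractions and not
    in the 30S/40S or 50S fraction (ties resolve against inclusion).
    40S compartment: keep only if the protein is more abundant in the
    30S/40S fraction than in the 60S fraction.
    """
    if protein_id not in table.data.index:
        return False
    row = table.data.loc[protein_id]
    if compartment == "60S":
        inside = identity.fractions_for("60S", "60S/80S")
        outside = identity.fractions_for("30S/40S", "50S")
        in_max = row[inside].max() if inside else 0.0
        out_max = row[outside].max() if outside else 0.0
        return bool(in_max > 0 and in_max > out_max)
    if compartment == "40S":
        f40 = identity.fractions_for("30S/40S")
        f60 = identity.fractions_for("60S")
        v40 = row[f40].max() if f40 else 0.0
        v60 = row[f60].max() if f60 else 0.0
        return bool(v40 > 0 and v40 > v60)
    raise ValueError("compartment must be '60S' or '40S'")


def call_changes(mutant: pd.Series, wildtype: pd.Series) -> pd.DataFrame:
    """Per-protein compositional change calls of mutant vs wild type.

    Presence in the mutant with absence in the wild type is accumulation
    (``+``); the reverse is decrease (``-``); when both are detected the
    call is the numeric log2 fold change, classified as strong beyond
    |log2-FC| = 1 (a fold change of 0 counts as weak_up by convention).
    Proteins absent from both are reported with status ``NA``.
    """
    proteins = mutant.index.union(wildtype.index)
    m = mutant.reindex(proteins, fill_value=0.0)
    w = wildtype.reindex(proteins, fill_value=0.0)
    rows = []
    for pid in proteins:
        mv, wv = float(m[pid]), float(w[pid])
        if mv > 0 and wv == 0:
            status, fc, mag = "+", np.nan, "presence"
        elif mv == 0 and wv > 0:
            status, fc, mag = "-", np.nan, "absence"
        elif mv == 0 and wv == 0:
            status, fc, mag = "NA", np.nan, "NA"
        else:
            fc = float(np.log2(mv / wv))
            status = "numeric"
            if fc > 1:
                mag = "strong_up"
            elif fc >= 0:
                mag = "weak_up"
            elif fc >= -1:
                mag = "weak_down"
            else:
                mag = "strong_down"
        rows.append(
            {"protein_id": pid, "status": status, "log2_fc": fc, "magnitude_class": mag}
        )
    return pd.DataFrame(rows).set_index("protein_id")


_UP = {"+", "strong_up", "weak_up"}
_DOWN = {"-", "strong_down", "weak_down"}


def call_direction(call_row: pd.Series) -> str | None:
    """Unified direction of a change call: increase, decrease, or None.

    A numeric call with log2-FC exactly 0 (arising only in noise-free data)
    has no direction; the weak_up boundary convention applies to magnitude
    classification, not to direction matching.
    """
    if call_row["status"] == "numeric" and call_row["log2_fc"] == 0:
        return None
    key = call_row["status"] if call_row["status"] in ("+", "-") else call_row["magnitude_class"]
    if key in _UP:
        return "increase"
    if key in _DOWN:
        return "decrease"
    return None


def _directions(calls: pd.DataFrame) -> pd.Series:
    return calls.apply(call_direction, axis=1)


def select_shared(
    calls_ds1: pd.DataFrame,
    calls_ds2: pd.DataFrame,
    mode: str = "cold_only",
    cold: str = "10C",
    warm: str = "20C",
) -> pd.DataFrame:
    """Select change calls shared in direction between two experiments.

    ``calls_ds1`` / ``calls_ds2`` carry one call per (protein, temperature)
    with a ``temperature`` column.  ``cold_only`` keeps proteins whose cold
    calls agree in direction between the experiments; ``both_temperatures``
    additionally requires the same direction at the warm temperature in both
    experiments.  Categorical (``+``/``-``) and numeric calls agree when they
    point the same way.
    """
    if mode not in ("cold_only", "both_temperatures"):
        raise ValueError("mode must be 'cold_only' or 'both_temperatures'")

    def by_temp(calls: pd.DataFrame, temp: str) -> pd.Series:
        sub = calls[calls["temperature"] == temp]
        return _directions(sub).groupby(sub.index).first()

    d1_cold, d2_cold = by_temp(calls_ds1, cold), by_temp(calls_ds2, cold)
    proteins = d1_cold.index.intersection(d2_cold.index)
    rows = []
    for pid in proteins:
        dir1, dir2 = d1_cold[pid], d2_cold[pid]
        if dir1 is None or dir1 != dir2:
            continue
        if mode == "both_temperatures":
            d1_warm, d2_warm = by_temp(calls_ds1, warm), by_temp(calls_ds2, warm)
            if d1_warm.get(pid) != dir1 or d2_warm.get(pid) != dir1:
                continue
        rows.append({"protein_id": pid, "direction": dir1})
    report = pd.DataFrame(rows, columns=["protein_id", "direction"]).set_index("protein_id")
    report.attrs["n_increase"] = int((report["direction"] == "increase").sum())
    report.attrs["n_decrease"] = int((report["direction"] == "decrease").sum())
    report.attrs["mode"] = mode
    return report


def transcript_protein_association(
    calls: pd.DataFrame,
    catalog: AnnotationCatalog,
    fc_transcripts: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Join protein change calls with transcript log2-FC by gene model.

    ``fc_transcripts`` is indexed by gene model with columns ``log2_fc`` and
    ``p_value``.  Protein calls without a transcript record are retained
    with null transcript columns; a match is concordant when both changes
    point the same way and the transcript change is significant.
    """
    rows = []
    for pid, call in calls.iterrows():
        entry = catalog.get(str(pid))
        gene = entry.gene_model if entry is not None else None
        prot_dir = call_direction(call)
        if gene is not None and gene in fc_transcripts.index:
            t = fc_transcripts.loc[gene]
            t_fc = float(t["log2_fc"])
            t_p = float(t["p_value"])
            t_dir = "increase" if t_fc > 0 else ("decrease" if t_fc < 0 else None)
            concordant = bool(prot_dir is not None and prot_dir == t_dir and t_p < alpha)
        else:
            t_fc, t_p, concordant = np.nan, np.nan, False
        rows.append(
            {
                "protein_id": pid,
                "gene_model": gene,
                "protein_direction": prot_dir,
                "transcript_log2_fc": t_fc,
                "transcript_p": t_p,
                "concordant": concordant,
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def compositional_calls(
    tables: dict[tuple[str, str], FractionTable],
    compartment: str,
    wildtype: str = "Col-0",
    exclude_classes: tuple[str, ...] = (),
    contaminants: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Full compositional pipeline of one experiment: calls per temperature.

    ``tables`` maps (genotype, temperature) to a :class:`FractionTable`;
    exactly one genotype must be the wild type.  For each temperature the
    mutant is compared with the wild type after fraction assignment,
    reference normalization and (for the 60S compartment) combination of
    the 60S and 60S/80S fractions.  Proteins failing the raw abundance-
    maximum filter in both samples are dropped, as are the classes in
    ``exclude_classes`` and the explicit ``contaminants`` list (used for the
    40S compartment, where organellar RPs and known contaminants co-purify).
    """
    genotypes = sorted({g for g, _ in tables})
    mutants = [g for g in genotypes if g != wildtype]
    if wildtype not in genotypes or len(mutants) != 1:
        raise ValueError("tables must cover one wild type and one mutant genotype")
    mutant = mutants[0]
    temperatures = sorted({t for _, t in tables})

    all_calls = []
    for temp in temperatures:
        t_mut, t_wt = tables[(mutant, temp)], tables[(wildtype, temp)]
        id_mut, id_wt = assign_fractions(t_mut), assign_fractions(t_wt)

        def combined(table: FractionTable, identity: FractionIdentity) -> pd.Series:
            shares = normalize_shares(table, identity, compartment)
            if compartment == "60S":
                return combine_60s_fractions(shares)
            return shares.shares.iloc[:, 0]

        c_mut, c_wt = combined(t_mut, id_mut), combined(t_wt, id_wt)
        calls = call_changes(c_mut, c_wt)
        keep = [
            pid
            for pid in calls.index
            if abundance_max_filter(t_mut, id_mut, pid, compartment)
            or abundance_max_filter(t_wt, id_wt, pid, compartment)
        ]
        calls = calls.loc[keep]
        classes = t_mut.classes().reindex(calls.index).fillna("other")
        if exclude_classes:
            calls = calls.loc[~classes.loc[calls.index].isin(exclude_classes)]
        if contaminants:
            calls = calls.loc[~calls.index.isin(contaminants)]
        calls = calls[calls["status"] != "NA"].copy()
        calls["temperature"] = temp
        all_calls.append(calls)
    return pd.concat(all_calls)
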