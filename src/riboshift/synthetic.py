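"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the three data layers of a REIL-type cold
acclimation study:

* :func:`generate_trace` — sucrose-gradient A254 traces: Gaussian peaks for
  the 40S/60S/80S/polysome complexes over a drifting baseline, plus a paired
  blank trace, with closed-form peak areas as truth;
* :func:`generate_lfq_experiment` — fraction-wise label-free quantification
  (LFQ) tables: each protein follows the gradient profile of its RP class,
  planted multiplicative changes model compositional shifts in mutants,
  log-normal noise models measurement error, and a detection-limit censor
  maps low values to 0 (non-detection);
* :func:`generate_expression` — log2 expression matrices over a
  genotype x timepoint x replicate design with planted gene-set shifts and
  constitutively shifted genes.

Each generator returns a ground-truth ledger listing every planted effect
exactly once, so downstream stages can be scored for recovery.  All
randomness flows from the integer seed in the config; the same seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationCatalog, make_catalog
from .profiles import COMPLEX_ORDER, Trace

# --------------------------------------------------------------------------
# sucrose-gradient traces
# --------------------------------------------------------------------------

#: default peak layout on the normalized [0, 1] gradient axis
#: (label, center, amplitude in absorbance units, width as position sd)
DEFAULT_PEAKS: tuple[tuple[str, float, float, float], ...] = (
    ("40S", 0.22, 0.25, 0.025),
    ("60S", 0.40, 0.50, 0.030),
    ("80S", 0.58, 1.00, 0.035),
    ("polysome", 0.76, 0.45, 0.040),
    ("polysome", 0.88, 0.25, 0.045),
)

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass
class TraceConfig:
    """Parameters of one synthetic gradient trace.

    Gradient position is normalized to [0, 1] with 0 at the gradient top
    (low sucrose); complexes appear in sedimentation order
    40S < 60S < 80S < polysome n-mers.  The baseline models sucrose
    absorbance drift; ``noise_sd`` is additive Gaussian noise per point.
    """

    n_points: int = 400
    peaks: Sequence[tuple[str, float, float, float]] = DEFAULT_PEAKS
    baseline_slope: float = 0.10
    baseline_offset: float = 0.05
    noise_sd: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 100:
            raise ValueError("n_points must be >= 100")
        centers = [p[1] for p in self.peaks]
        if sorted(centers) != centers:
            raise ValueError("peak centers must increase in sedimentation order")
        if any(p[3] <= 0 for p in self.peaks):
            raise ValueError("peak widths must be positive")


def generate_trace(config: TraceConfig) -> tuple[Trace, Trace, pd.DataFrame]:
    """Generate a sample trace, a paired blank, and the closed-form truth.

    The truth table carries one row per complex with the analytic Gaussian
    area ``amplitude * width * sqrt(2*pi)`` (summed over peaks sharing a
    label, e.g. polysome n-mers) and an ``overlap_warning`` flag set when
    two adjacent peak centers are closer than their combined width, which
    makes valley-based integration ambiguous.
    """
    rng = np.random.default_rng(config.seed)
    x = np.linspace(0.0, 1.0, config.n_points)
    baseline = config.baseline_offset + config.baseline_slope * x
    signal = np.zeros_like(x)
    for _, center, amp, width in config.peaks:
        signal += amp * np.exp(-0.5 * ((x - center) / width) ** 2)
    sample_noise = rng.normal(0.0, config.noise_sd, config.n_points) if config.noise_sd else 0.0
    blank_noise = rng.normal(0.0, config.noise_sd, config.n_points) if config.noise_sd else 0.0
    sample = Trace(x, baseline + signal + sample_noise, role="sample")
    blank = Trace(x, baseline + blank_noise, role="blank")

    overlap = False
    for (_, c1, _, w1), (_, c2, _, w2) in zip(config.peaks[:-1], config.peaks[1:]):
        if (c2 - c1) < (w1 + w2):
            overlap = True
    areas: dict[str, float] = {}
    for label, _, amp, width in config.peaks:
        areas[label] = areas.get(label, 0.0) + amp * width * SQRT_2PI
    truth = pd.DataFrame(
        {
            "complex": list(areas),
            "area": list(areas.values()),
            "overlap_warning": overlap,
        }
    )
    return sample, blank, truth


# --------------------------------------------------------------------------
# study-level trace design: genotype x timepoint planted log2 fold changes
# --------------------------------------------------------------------------

#: planted per-complex log2-FC vs wild type: (genotype, day) -> {complex: fc}.
#: Emulates the qualitative dynamics of REIL-deficient lines: roughly
#: two-fold subunit over-accumulation before cold shift, transient subunit
#: depletion at day 1, persistent 80S depletion (up to four-fold) in lines
#: lacking functional REIL2, near-parallel 40S/60S behaviour, and a partly
#: decoupled 80S pool.
STUDY_TIMEPOINTS = (0, 1, 3, 7, 21)
STUDY_GENOTYPES = ("reil1-1", "reil2-1", "reil2-2", "reil1-1 reil2-1", "reil1-1 reil2-2")
STUDY_COMPLEX_LOG2FC: dict[tuple[str, int], dict[str, float]] = {
    ("reil1-1", 0): {"40S": 1.0, "60S": 1.0, "80S": 0.0, "polysome": 0.0},
    ("reil1-1", 1): {"40S": 0.8, "60S": 0.9, "80S": -0.3, "polysome": 0.0},
    ("reil1-1", 3): {"40S": 0.9, "60S": 1.0, "80S": -0.2, "polysome": 0.0},
    ("reil1-1", 7): {"40S": 1.0, "60S": 1.0, "80S": 0.0, "polysome": 0.0},
    ("reil1-1", 21): {"40S": 1.0, "60S": 1.1, "80S": -0.3, "polysome": -0.1},
    ("reil2-1", 0): {"40S": 1.0, "60S": 1.0, "80S": 0.0, "polysome": 0.0},
    ("reil2-1", 1): {"40S": 0.2, "60S": 0.3, "80S": -1.2, "polysome": -0.1},
    ("reil2-1", 3): {"40S": 0.4, "60S": 0.5, "80S": -1.0, "polysome": -0.1},
    ("reil2-1", 7): {"40S": 0.8, "60S": 0.9, "80S": -1.0, "polysome": 0.0},
    ("reil2-1", 21): {"40S": 1.0, "60S": 1.0, "80S": -1.2, "polysome": -0.1},
    ("reil2-2", 0): {"40S": 0.9, "60S": 1.0, "80S": 0.0, "polysome": 0.0},
    ("reil2-2", 1): {"40S": 0.1, "60S": 0.2, "80S": -1.0, "polysome": -0.1},
    ("reil2-2", 3): {"40S": 0.3, "60S": 0.4, "80S": -0.9, "polysome": 0.0},
    ("reil2-2", 7): {"40S": 0.7, "60S": 0.8, "80S": -1.1, "polysome": -0.1},
    ("reil2-2", 21): {"40S": 0.9, "60S": 1.0, "80S": -1.0, "polysome": -0.1},
    ("reil1-1 reil2-1", 0): {"40S": 1.0, "60S": 1.1, "80S": 0.0, "polysome": 0.0},
    ("reil1-1 reil2-1", 1): {"40S": -0.3, "60S": -0.2, "80S": -2.0, "polysome": -0.2},
    ("reil1-1 reil2-1", 3): {"40S": 0.2, "60S": 0.3, "80S": -1.8, "polysome": -0.2},
    ("reil1-1 reil2-1", 7): {"40S": 0.6, "60S": 0.7, "80S": -1.9, "polysome": -0.1},
    ("reil1-1 reil2-1", 21): {"40S": 0.9, "60S": 1.0, "80S": -2.0, "polysome": -0.2},
    ("reil1-1 reil2-2", 0): {"40S": 1.1, "60S": 1.2, "80S": 0.1, "polysome": 0.0},
    ("reil1-1 reil2-2", 1): {"40S": -0.4, "60S": -0.3, "80S": -1.9, "polysome": -0.2},
    ("reil1-1 reil2-2", 3): {"40S": 0.1, "60S": 0.2, "80S": -1.7, "polysome": -0.2},
    ("reil1-1 reil2-2", 7): {"40S": 0.5, "60S": 0.6, "80S": -1.8, "polysome": -0.1},
    ("reil1-1 reil2-2", 21): {"40S": 0.8, "60S": 0.9, "80S": -1.9, "polysome": -0.2},
}


def study_trace_config(genotype: str, day: int, seed: int, noise_sd: float = 0.004) -> TraceConfig:
    """TraceConfig for one genotype/timepoint of the emulated shift study.

    Peak amplitudes of the default wild-type layout are scaled by the
    planted log2-FC of :data:`STUDY_COMPLEX_LOG2FC`; the wild type itself
    uses the layout unchanged.
    """
    if genotype in ("Col-0", "wildtype"):
        fcs: dict[str, float] = {}
    else:
        try:
            fcs = STUDY_COMPLEX_LOG2FC[(genotype, day)]
        except KeyError as exc:
            raise ValueError(f"no planted design for {genotype!r} at day {day}") from exc
    peaks = tuple(
        (label, center, amp * float(2.0 ** fcs.get(label, 0.0)), width)
        for label, center, amp, width in DEFAULT_PEAKS
    )
    return TraceConfig(peaks=peaks, noise_sd=noise_sd, seed=seed)


# --------------------------------------------------------------------------
# fraction-wise LFQ proteome tables
# --------------------------------------------------------------------------

#: fraction labels of the default synthetic layout, in sedimentation order.
#: The fifth (80S) fraction is generated but, as in typical non-translating
#: ribo-proteome designs, not assigned a compositional role downstream.
DEFAULT_FRACTIONS = ("F1", "F2", "F3", "F4", "F5", "F6")
DEFAULT_FRACTION_IDENTITY = ("30S/40S", "50S", "60S", "60S/80S", "80S", "polysome")

#: relative abundance of each RP class across the six fractions
DEFAULT_CLASS_PROFILES: Mapping[str, tuple[float, ...]] = {
    "RP40S": (1.0, 0.20, 0.05, 0.40, 0.50, 0.60),
    "RP60S": (0.05, 0.15, 1.0, 0.90, 0.60, 0.60),
    "RP30S_org": (1.0, 0.30, 0.05, 0.02, 0.01, 0.05),
    "RP50S_org": (0.20, 1.0, 0.10, 0.05, 0.02, 0.05),
    "biogenesis": (0.02, 0.05, 1.0, 0.80, 0.10, 0.02),
    "eIF3": (1.0, 0.60, 0.10, 0.05, 0.02, 0.10),
    "other": (0.30, 0.30, 0.30, 0.30, 0.30, 0.30),
}


def simulated_catalog(
    n_rp60: int = 24,
    n_rp40: int = 16,
    n_org30: int = 8,
    n_org50: int = 8,
    n_biogenesis: int = 10,
    n_eif3: int = 6,
    n_other: int = 8,
) -> AnnotationCatalog:
    """A synthetic protein catalog with the class structure of a root
    ribo-proteome: cytosolic 60S/40S RP families with paralog pairs,
    organellar RPs, pre-60S biogenesis factors (including the eIF6A and NMD3
    markers), eIF3 subunits and co-purifying contaminants."""
    rows: list[dict] = []

    def add(prefix: str, n: int, rp_class: str, family_prefix: str) -> None:
        for i in range(n):
            fam = f"{family_prefix}{i // 2 + 1}"
            rows.append(
                dict(
                    protein_id=f"{prefix}{i + 1}",
                    gene_model=f"SYN_{prefix}{i + 1}",
                    rp_class=rp_class,
                    family=fam,
                    paralog=f"{fam}{'AB'[i % 2]}",
                    marker_role="none",
                    paralog_specific=(i % 3 != 2),
                )
            )

    add("L", n_rp60, "RP60S", "uL")
    add("S", n_rp40, "RP40S", "uS")
    add("PS", n_org30, "RP30S_org", "pS")
    add("PL", n_org50, "RP50S_org", "pL")
    add("EIF3", n_eif3, "eIF3", "eIF3-")
    add("CONT", n_other, "other", "cont")
    # biogenesis factors: the two pre-60S markers first, then generic factors
    biog_names = ["eIF6A", "NMD3", "RLP24", "NOG1", "NOG2", "MAK16", "RSA4", "EBP2", "HAS1", "NSA2"]
    for i in range(n_biogenesis):
        name = biog_names[i] if i < len(biog_names) else f"BGF{i + 1}"
        rows.append(
            dict(
                protein_id=name,
                gene_model=f"SYN_{name}",
                rp_class="biogenesis",
                family=name,
                paralog=name,
                marker_role="pre60S_marker" if name in ("eIF6A", "NMD3") else "none",
                paralog_specific=True,
            )
        )
    return make_catalog(rows)


@dataclass
class ProteomeSimConfig:
    """Parameters of one synthetic fraction-wise LFQ experiment.

    ``planted_changes`` are (protein_id, genotype, temperature, effect)
    where effect is a multiplicative factor on that protein's abundance in
    that condition, or the string ``"absent"`` (protein censored to 0
    everywhere in that condition).  ``censor_threshold`` is the detection
    limit in LFQ units: values below it are reported as exactly 0, matching
    LFQ tables where non-detection is 0.  ``noise_cv`` is the coefficient of
    variation of mean-preserving multiplicative log-normal noise.
    """

    catalog: AnnotationCatalog = field(default_factory=simulated_catalog)
    fraction_profiles: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROFILES)
    )
    fractions: Sequence[str] = DEFAULT_FRACTIONS
    genotypes: Sequence[str] = ("Col-0", "reil1-1 reil2-2")
    temperatures: Sequence[str] = ("20C", "10C")
    planted_changes: Sequence[tuple[str, str, str, float | str]] = ()
    censor_threshold: float = 0.0
    noise_cv: float = 0.2
    experiment: str = "DS1"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.catalog) == 0:
            raise ValueError("catalog is empty")
        if self.censor_threshold < 0:
            raise ValueError("censor_threshold must be >= 0")
        for protein, genotype, temperature, effect in self.planted_changes:
            if protein not in self.catalog:
                raise ValueError(f"planted change names unknown protein {protein!r}")
            if genotype not in self.genotypes:
                raise ValueError(f"planted change names unknown genotype {genotype!r}")
            if temperature not in self.temperatures:
                raise ValueError(f"planted change names unknown temperature {temperature!r}")
            if not (effect == "absent" or (isinstance(effect, (int, float)) and effect > 0)):
                raise ValueError(f"invalid effect {effect!r} for {protein}")


#: per-class log10 LFQ base-abundance ranges.  In ribosome preparations the
#: structural RPs are the most abundant proteins; biogenesis factors, eIF3
#: subunits and co-purified contaminants sit lower in the dynamic range.
_CLASS_ABUNDANCE_RANGE: Mapping[str, tuple[float, float]] = {
    "RP60S": (4.0, 6.0),
    "RP40S": (4.0, 6.0),
    "RP30S_org": (3.5, 5.0),
    "RP50S_org": (3.5, 5.0),
    "biogenesis": (3.5, 5.5),
    "eIF3": (3.5, 5.5),
    "other": (3.0, 5.0),
}


def _base_abundances(config: ProteomeSimConfig) -> pd.Series:
    """Per-protein base LFQ abundance, log-uniform within its class range.

    Drawn from a dedicated stream of the config seed so that the no-noise
    expectation is reproducible independently of the noise draws.
    """
    rng = np.random.default_rng([config.seed, 101])
    out = {}
    for e in config.catalog.entries:
        lo, hi = _CLASS_ABUNDANCE_RANGE.get(e.rp_class, (3.0, 5.0))
        out[e.protein_id] = 10.0 ** rng.uniform(lo, hi)
    return pd.Series(out)


def expected_lfq_table(config: ProteomeSimConfig, genotype: str, temperature: str) -> pd.DataFrame:
    """Deterministic (noise- and censor-free) expectation of one condition's table."""
    base = _base_abundances(config)
    effects = pd.Series(1.0, index=base.index)
    absent = pd.Series(False, index=base.index)
    for protein, g, t, effect in config.planted_changes:
        if g == genotype and t == temperature:
            if effect == "absent":
                absent[protein] = True
            else:
                effects[protein] *= float(effect)
    rows = {}
    for pid in base.index:
        cls = config.catalog.get(pid).rp_class
        profile = np.asarray(config.fraction_profiles.get(cls, config.fraction_profiles["other"]), dtype=float)
        vals = base[pid] * effects[pid] * profile
        if absent[pid]:
            vals = np.zeros_like(vals)
        rows[pid] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(config.fractions))


def generate_lfq_experiment(
    config: ProteomeSimConfig,
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Generate LFQ tables per (genotype, temperature) plus the truth ledger.

    Noise is mean-preserving log-normal with coefficient of variation
    ``noise_cv``; after noise, values below ``censor_threshold`` are set to
    exactly 0.  The ledger lists every planted change once, with the change
    call expected from a mutant-vs-wild-type comparison.
    """
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    for gi, genotype in enumerate(config.genotypes):
        for ti, temperature in enumerate(config.temperatures):
            expected = expected_lfq_table(config, genotype, temperature)
            rng = np.random.default_rng([config.seed, 7, gi, ti])
            if config.noise_cv > 0:
                noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, expected.shape))
            else:
                noise = 1.0
            table = expected * noise
            table[table < config.censor_threshold] = 0.0
            tables[(genotype, temperature)] = table

    wildtype = config.genotypes[0]
    ledger_rows = []
    for protein, genotype, temperature, effect in config.planted_changes:
        if effect == "absent":
            status = "-" if genotype != wildtype else "+"
            direction = "decrease" if status == "-" else "increase"
            log2_fc = np.nan
        else:
            log2_fc = float(np.log2(effect))
            direction = "increase" if log2_fc > 0 else "decrease"
            status = "numeric"
        ledger_rows.append(
            {
                "experiment": config.experiment,
                "protein_id": protein,
                "genotype": genotype,
                "temperature": temperature,
                "effect": effect,
                "expected_status": status,
                "expected_direction": direction,
                "expected_log2_fc": log2_fc,
            }
        )
    ledger = pd.DataFrame(
        ledger_rows,
        columns=[
            "experiment",
            "protein_id",
            "genotype",
            "temperature",
            "effect",
            "expected_status",
            "expected_direction",
            "expected_log2_fc",
        ],
    )
    return tables, ledger


# --------------------------------------------------------------------------
# expression matrices
# --------------------------------------------------------------------------


@dataclass
class ExpressionSimConfig:
    """Parameters of one synthetic expression study.

    The default design mirrors a shift experiment with 3 genotypes
    (wild type plus two allelic double mutants) x 3 timepoints x 3 biological
    replicates.  ``planted_set_shifts`` add a mean log2 shift to all genes of
    a set in one (genotype, timepoint) condition; ``planted_constitutive``
    genes carry a per-gene log2 effect in *both* mutant genotypes at *all*
    timepoints.  ``residual_sd`` is the replicate noise in log2 units.
    """

    n_genes: int = 2000
    genotypes: Sequence[str] = ("Col-0", "DKO1", "DKO2")
    timepoints: Sequence[str] = ("0d", "1d", "7d")
    n_replicates: int = 3
    set_definitions: Mapping[str, Sequence[str]] = field(default_factory=dict)
    planted_set_shifts: Sequence[tuple[str, tuple[str, str], float]] = ()
    planted_constitutive: Mapping[str, float] = field(default_factory=dict)
    residual_sd: float = 0.25
    probes_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        genes = set(self.gene_ids())
        for name, members in self.set_definitions.items():
            unknown = set(members) - genes
            if unknown:
                raise ValueError(
                    f"gene set {name!r} references unknown gene(s): {sorted(unknown)[:3]}"
                )
        planted_sets = {s for s, _, _ in self.planted_set_shifts}
        for name in planted_sets:
            if name not in self.set_definitions:
                raise ValueError(f"planted shift names unknown set {name!r}")
            if len(self.set_definitions[name]) < 10:
                raise ValueError(f"planted set {name!r} has fewer than 10 genes")
        unknown_const = set(self.planted_constitutive) - genes
        if unknown_const:
            raise ValueError(f"constitutive genes not in matrix: {sorted(unknown_const)[:3]}")

    def gene_ids(self) -> list[str]:
        return [f"GENE{i:05d}" for i in range(self.n_genes)]


@dataclass
class ExpressionSim:
    """Result bundle of :func:`generate_expression`."""

    matrix: pd.DataFrame  # probe (or gene) x sample, log2 scale
    metadata: pd.DataFrame  # sample, genotype, timepoint, replicate
    truth: pd.DataFrame  # planted-effect ledger
    probe_to_gene: pd.Series  # probe -> gene map (identity when 1 probe/gene)


def generate_expression(config: ExpressionSimConfig) -> ExpressionSim:
    """Generate a log2 expression matrix with planted set and constitutive effects.

    Expression = per-gene baseline + cold-response time trend (shared across
    genotypes) + planted set shifts + planted constitutive mutant effects
    + N(0, residual_sd) replicate noise.
    """
    rng = np.random.default_rng([config.seed, 11])
    genes = config.gene_ids()
    baseline = pd.Series(rng.normal(8.0, 2.0, config.n_genes), index=genes)
    # mild shared cold-response trend so timepoints differ, as in a real shift
    time_trend = {tp: i * 0.05 for i, tp in enumerate(config.timepoints)}

    wildtype = config.genotypes[0]
    mutant_genotypes = [g for g in config.genotypes if g != wildtype]

    columns = []
    meta_rows = []
    gene_index = {g: i for i, g in enumerate(genes)}

    noise_rng = np.random.default_rng([config.seed, 13])
    cols = []
    for genotype in config.genotypes:
        for tp in config.timepoints:
            effect = np.zeros(config.n_genes)
            for set_name, (g, t), shift in config.planted_set_shifts:
                if g == genotype and t == tp:
                    for gene in config.set_definitions[set_name]:
                        effect[gene_index[gene]] += shift
            if genotype in mutant_genotypes:
                for gene, shift in config.planted_constitutive.items():
                    effect[gene_index[gene]] += shift
            mean = baseline.to_numpy() + time_trend[tp] + effect
            for rep in range(1, config.n_replicates + 1):
                noise = noise_rng.normal(0.0, config.residual_sd, config.n_genes) if config.residual_sd else 0.0
                cols.append(mean + noise)
                sample = f"{genotype}_{tp}_r{rep}"
                columns.append(sample)
                meta_rows.append(
                    {"sample": sample, "genotype": genotype, "timepoint": tp, "replicate": rep}
                )
    matrix = pd.DataFrame(np.column_stack(cols), index=genes, columns=columns)
    metadata = pd.DataFrame(meta_rows)

    ledger_rows = [
        {
            "kind": "set_shift",
            "target": set_name,
            "genotype": g,
            "timepoint": t,
            "log2_effect": shift,
        }
        for set_name, (g, t), shift in config.planted_set_shifts
    ] + [
        {
            "kind": "constitutive",
            "target": gene,
            "genotype": "both_mutants",
            "timepoint": "all",
            "log2_effect": shift,
        }
        for gene, shift in config.planted_constitutive.items()
    ]
    truth = pd.DataFrame(
        ledger_rows, columns=["kind", "target", "genotype", "timepoint", "log2_effect"]
    )

    if config.probes_per_gene > 1:
        probe_rows = []
        probe_names = []
        probe_gene = []
        probe_rng = np.random.default_rng([config.seed, 17])
        values = matrix.to_numpy()
        for i, gene in enumerate(genes):
            for p in range(config.probes_per_gene):
                jitter = probe_rng.normal(0.0, 0.05, matrix.shape[1])
                probe_rows.append(values[i] + jitter)
                probe_names.append(f"{gene}_p{p + 1}")
                probe_gene.append(gene)
        matrix = pd.DataFrame(np.vstack(probe_rows), index=probe_names, columns=columns)
        probe_to_gene = pd.Series(probe_gene, index=probe_names, name="gene")
    else:
        probe_to_gene = pd.Series(genes, index=genes, name="gene")

    return ExpressionSim(matrix=matrix, metadata=metadata, truth=truth, probe_to_gene=probe_to_gene)


# --------------------------------------------------------------------------
# study-level default configurations
# --------------------------------------------------------------------------

#: the two paired proteome experiments: wild type vs one allelic double mutant
STUDY_PROTEOME_DESIGN = {
    "DS1": ("Col-0", "reil1-1 reil2-2"),
    "DS2": ("Col-0", "reil1-1 reil2-1"),
}


def study_planted_proteome_changes(
    mutant: str,
    up_factor: float = 2.2,
    down_factor: float = 0.45,
    biogenesis_factor: float = 2.5,
) -> list[tuple[str, str, str, float | str]]:
    """Planted compositional changes of one double-mutant experiment.

    Emulates the hallmark pattern of REIL-deficient lines: pre-60S
    biogenesis factors (eIF6A, NMD3, RLP24 and further factors) accumulate
    in the non-translating 60S fractions in the cold, a subset of 60S RP
    paralogs shifts up and a complementary subset down, eIF3 subunits and
    some 40S RPs accumulate in the 30S/40S fraction, and one factor present
    only in the mutant yields a presence call.  All factors give
    |log2-FC| >= 1 so the planted set is recoverable by the shared-direction
    rule.
    """
    changes: list[tuple[str, str, str, float | str]] = []
    both_temp = ["eIF6A", "NMD3", "RLP24"]
    cold_only_biog = ["NOG2", "MAK16", "RSA4", "EBP2", "HAS1", "NSA2"]
    for pid in both_temp:
        changes.append((pid, mutant, "10C", biogenesis_factor))
        changes.append((pid, mutant, "20C", biogenesis_factor))
    for pid in cold_only_biog:
        changes.append((pid, mutant, "10C", biogenesis_factor))
    for pid in ["L1", "L3", "L5", "L7"]:  # 60S paralogs shifting up in the cold
        changes.append((pid, mutant, "10C", up_factor))
    for pid in ["L2", "L4", "L6", "L8"]:  # 60S paralogs shifting down
        changes.append((pid, mutant, "10C", down_factor))
    for pid in ["S1", "S3", "EIF31", "EIF32"]:  # 40S-compartment accumulation
        changes.append((pid, mutant, "10C", up_factor))
    for pid in ["S2", "S4"]:
        changes.append((pid, mutant, "10C", down_factor))
    # a biogenesis factor detected only in the mutant: presence call "+"
    changes.append(("NOG1", "Col-0", "10C", "absent"))
    changes.append(("NOG1", "Col-0", "20C", "absent"))
    return changes


def study_proteome_config(
    experiment: str,
    seed: int,
    catalog: AnnotationCatalog | None = None,
    noise_cv: float = 0.2,
    censor_threshold: float = 0.0,
) -> ProteomeSimConfig:
    """Default config of one paired ribo-proteome experiment (DS1 or DS2)."""
    wildtype, mutant = STUDY_PROTEOME_DESIGN[experiment]
    return ProteomeSimConfig(
        catalog=catalog if catalog is not None else simulated_catalog(),
        genotypes=(wildtype, mutant),
        planted_changes=tuple(study_planted_proteome_changes(mutant)),
        noise_cv=noise_cv,
        censor_threshold=censor_threshold,
        experiment=experiment,
        seed=seed,
    )


def censor_threshold_for_rate(config: ProteomeSimConfig, rate: float = 0.10) -> float:
    """Detection limit that censors the given share of all expected LFQ values.

    Computed from the noise-free expectation over all conditions so the
    threshold itself is independent of the noise draws.
    """
    pooled = np.concatenate(
        [
            expected_lfq_table(config, g, t).to_numpy().ravel()
            for g in config.genotypes
            for t in config.temperatures
        ]
    )
    pooled = pooled[pooled > 0]
    return float(np.quantile(pooled, rate))


def study_expression_config(seed: int, n_genes: int = 2000) -> ExpressionSimConfig:
    """Default config of the emulated transcriptome study.

    3 genotypes x 3 timepoints x 3 replicates; three 50-gene sets carry a
    +0.5 or -0.5 log2 shift in the double mutants (emulating ribosome- and
    development-related ontology responses); six genes carry constitutive
    log2 shifts in both mutants at all timepoints (emulating the
    constitutively activated transcripts such as the eIF3C2 and NUC2
    paralog responses).
    """
    rng = np.random.default_rng([seed, 23])
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    picks = rng.choice(n_genes, size=150 + 6, replace=False)
    sets = {
        "SET_RIBOSOME": [genes[i] for i in picks[0:50]],
        "SET_COLD": [genes[i] for i in picks[50:100]],
        "SET_DEVELOPMENT": [genes[i] for i in picks[100:150]],
    }
    constitutive_genes = [genes[i] for i in picks[150:156]]
    shifts = []
    for g in ("DKO1", "DKO2"):
        for tp in ("0d", "1d", "7d"):
            shifts.append(("SET_RIBOSOME", (g, tp), 0.5))
            shifts.append(("SET_DEVELOPMENT", (g, tp), -0.5))
        shifts.append(("SET_COLD", (g, "7d"), 0.5))
    shifts.append(("SET_COLD", ("Col-0", "7d"), 0.5))
    constitutive = {g: e for g, e in zip(constitutive_genes, (3.0, 2.5, 2.0, 1.5, 1.2, 1.0))}
    return ExpressionSimConfig(
        n_genes=n_genes,
        set_definitions=sets,
        planted_set_shifts=tuple(shifts),
        planted_constitutive=constitutive,
        seed=seed,
    )
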