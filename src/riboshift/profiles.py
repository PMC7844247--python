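"""Quantification of ribosome complexes from sucrose-gradient A254 traces.

A polysome profile is a continuous absorbance trace (254 nm) recorded while
a sucrose density gradient is pumped through a flow cell.  RNA-containing
complexes sediment in a fixed order — 40S small subunit, 60S large subunit,
80S monosome, then polysomes — so the trace shows a characteristic peak
sequence over a sucrose baseline.  Quantification proceeds in four steps:

1. subtract the blank trace recorded from a non-sample gradient of the same
   centrifugation run;
2. segment the corrected trace into complex regions at the absorbance
   valleys between expected peak positions;
3. integrate each region (trapezoid rule, negative values clipped to zero);
4. compare genotypes as log2 ratios of areas against the wild type of the
   same time point.

Areas are relative quantities in absorbance x position units; samples are
assumed to have been loaded at equal fresh weight, so no between-sample
rescaling is applied here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical sedimentation order of the quantified complexes
COMPLEX_ORDER = ("40S", "60S", "80S", "polysome")


@dataclass
class Trace:
    """One A254 absorbance trace over a gradient.

    Positions are gradient coordinates increasing from the top (low sucrose)
    to the bottom of the gradient; by convention they are normalized to
    [0, 1] but any strictly increasing coordinate works.
    """

    positions: np.ndarray
    absorbance: np.ndarray
    role: str = "sample"  # sample | blank
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.absorbance.shape:
            raise ValueError("positions and absorbance must be 1-D arrays of equal length")
        if len(self.positions) < 2:
            raise ValueError("a trace needs at least two points")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("trace positions must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("trace absorbance must be finite")

    def write_csv(self, path) -> None:
        pd.DataFrame({"position": self.positions, "a254": self.absorbance}).to_csv(
            path, index=False
        )

    @classmethod
    def read_csv(cls, path, role: str = "sample", label: str = "") -> "Trace":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), role=role, label=label)


@dataclass
class PeakSegmentation:
    """Ordered, non-overlapping complex intervals on a trace."""

    boundaries: list[tuple[str, float, float]]
    method: str = "valley"

    def __post_init__(self) -> None:
        prev_right = -np.inf
        for label, left, right in self.boundaries:
            if right <= left:
                raise ValueError(f"empty interval for {label}")
            if left < prev_right:
                raise ValueError(f"interval for {label} overlaps its predecessor")
            prev_right = right

    def interval(self, label: str) -> tuple[float, float]:
        for lab, left, right in self.boundaries:
            if lab == label:
                return left, right
        raise KeyError(label)


def subtract_blank(sample: Trace, blank: Trace, floor: float | None = None) -> Trace:
    """Subtract a blank-gradient trace from a sample trace.

    The blank is linearly interpolated onto the sample grid.  ``floor``
    optionally clips the corrected absorbance from below (integration applies
    its own clipping at zero, so the default keeps the raw difference).
    """
    lo = max(sample.positions[0], blank.positions[0])
    hi = min(sample.positions[-1], blank.positions[-1])
    if lo >= hi:
        raise ValueError("sample and blank trace domains do not overlap")
    interp = np.interp(sample.positions, blank.positions, blank.absorbance)
    corrected = sample.absorbance - interp
    if floor is not None:
        corrected = np.maximum(corrected, floor)
    return Trace(sample.positions, corrected, role="sample", label=sample.label)


def _valley(trace: Trace, left_anchor: float, right_anchor: float) -> float:
    """Position of the absorbance minimum between two anchors (midpoint on ties)."""
    mask = (trace.positions >= left_anchor) & (trace.positions <= right_anchor)
    if not mask.any():
        return 0.5 * (left_anchor + right_anchor)
    seg_pos = trace.positions[mask]
    seg_abs = trace.absorbance[mask]
    min_val = seg_abs.min()
    at_min = seg_pos[np.isclose(seg_abs, min_val)]
    if len(at_min) > 1 and np.isclose(seg_abs, min_val).all():
        # flat valley: tie-break at the anchor midpoint
        return 0.5 * (left_anchor + right_anchor)
    return float(at_min.mean())


def auto_anchors(trace: Trace, n_peaks: int = 4) -> list[float]:
    """Locate the ``n_peaks`` most prominent peaks, returned in position order.

    The trace is lightly smoothed (moving average over ~2% of its length)
    before peak picking so measurement noise does not create spurious local
    maxima.  Supplying anchors from configuration is preferred when the
    expected peak positions are known.
    """
    from scipy.signal import find_peaks

    y = trace.absorbance
    window = max(3, len(y) // 50)
    kernel = np.ones(window) / window
    smooth = np.convolve(y, kernel, mode="same")
    peaks, props = find_peaks(smooth, prominence=0.01 * (smooth.max() - smooth.min()))
    if len(peaks) < n_peaks:
        raise ValueError(f"found only {len(peaks)} peaks, need {n_peaks}")
    top = peaks[np.argsort(props["prominences"])[::-1][:n_peaks]]
    return sorted(float(trace.positions[i]) for i in top)


def segment_peaks(
    trace: Trace,
    anchors: Sequence[float],
    labels: Sequence[str] = COMPLEX_ORDER,
    limits: tuple[float, float] | None = None,
) -> PeakSegmentation:
    """Segment a corrected trace into complex regions.

    ``anchors`` are the expected peak centers in sedimentation order (40S
    first).  The boundary between adjacent complexes is the absorbance
    minimum between their anchors; the outermost boundaries default to the
    trace ends.  The last region (polysomes) extends to the dense end of the
    trace, i.e. everything sedimenting deeper than the 80S right boundary.
    """
    anchors = [float(a) for a in anchors]
    if len(anchors) != len(labels):
        raise ValueError("one anchor per complex label required")
    if sorted(anchors) != anchors:
        raise ValueError("anchors must be in increasing (sedimentation) order")
    if anchors[0] < trace.positions[0] or anchors[-1] > trace.positions[-1]:
        raise ValueError("anchors outside the trace domain")
    left_lim, right_lim = limits if limits is not None else (
        float(trace.positions[0]),
        float(trace.positions[-1]),
    )
    cuts = [left_lim]
    for a, b in zip(anchors[:-1], anchors[1:]):
        cuts.append(_valley(trace, a, b))
    cuts.append(right_lim)
    boundaries = [
        (lab, cuts[i], cuts[i + 1]) for i, lab in enumerate(labels)
    ]
    return PeakSegmentation(boundaries)


def integrate(trace: Trace, seg: PeakSegmentation) -> pd.Series:
    """Trapezoidal peak areas per complex, plus their sum as ``total``.

    A negative interval area (possible after blank subtraction) is clipped
    to zero — areas are physical quantities.  Clipping at the area level
    rather than per point keeps the integral unbiased under zero-mean
    noise.
    """
    y = trace.absorbance
    areas = {}
    for label, left, right in seg.boundaries:
        mask = (trace.positions >= left) & (trace.positions <= right)
        xs = trace.positions[mask]
        ys = y[mask]
        # include exact interval endpoints by interpolation for grid independence
        if len(xs) == 0 or xs[0] > left:
            xs = np.insert(xs, 0, left)
            ys = np.insert(ys, 0, np.interp(left, trace.positions, y))
        if xs[-1] < right:
            xs = np.append(xs, right)
            ys = np.append(ys, np.interp(right, trace.positions, y))
        areas[label] = max(float(np.trapezoid(ys, xs)), 0.0)
    out = pd.Series(areas, name=trace.label)
    out["total"] = float(sum(areas.values()))
    return out


def quantify_trace(
    sample: Trace,
    blank: Trace,
    anchors: Sequence[float] | None = None,
) -> pd.Series:
    """Blank-subtract, segment and integrate one trace in a single call."""
    corrected = subtract_blank(sample, blank)
    if anchors is None:
        anchors = auto_anchors(corrected, n_peaks=len(COMPLEX_ORDER))
    seg = segment_peaks(corrected, anchors)
    return integrate(corrected, seg)


def relative_abundance(mutant: pd.Series, wildtype: pd.Series) -> pd.Series:
    """log2(mutant area / wild-type area) per complex and for the total.

    Entries where the wild-type area is zero are NaN (flagged, not dropped).
    """
    common = [c for c in mutant.index if c in wildtype.index]
    out = {}
    for c in common:
        wt = wildtype[c]
        if wt <= 0:
            logger.warning("wild-type area for %s is zero; log2-FC undefined", c)
            out[c] = np.nan
        elif mutant[c] <= 0:
            out[c] = -np.inf
        else:
            out[c] = float(np.log2(mutant[c] / wt))
    return pd.Series(out, name=mutant.name)


def log2fc_table(
    areas: pd.DataFrame,
    metadata: pd.DataFrame,
    reference_genotype: str = "Col-0",
) -> pd.DataFrame:
    """Per (mutant, timepoint, complex) log2-FC against the reference genotype.

    ``areas`` is sample x complex; ``metadata`` maps sample label to
    genotype and timepoint.  Each mutant is compared with the reference of
    the same timepoint.
    """
    meta = metadata.set_index("sample") if "sample" in metadata.columns else metadata
    rows = []
    for tp, grp in meta.groupby("timepoint", sort=False):
        refs = grp.index[grp["genotype"] == reference_genotype]
        if len(refs) == 0:
            raise ValueError(f"no {reference_genotype} sample at timepoint {tp}")
        ref = areas.loc[refs].mean(axis=0)
        for label in grp.index[grp["genotype"] != reference_genotype]:
            fc = relative_abundance(areas.loc[label], ref)
            for cplx, value in fc.items():
                rows.append(
                    {
                        "sample": label,
                        "genotype": meta.loc[label, "genotype"],
                        "timepoint": tp,
                        "complex": cplx,
                        "log2_fc": value,
                    }
                )
    return pd.DataFrame(rows)


def correlate_complexes(fc: pd.DataFrame, a: str, b: str) -> float:
    """Pearson correlation of log2-FC values of two complexes across samples."""
    wide = fc.pivot_table(index="sample", columns="complex", values="log2_fc")
    if a == b:
        n = wide[a].dropna().shape[0]
        if n < 3:
            raise ValueError("need at least 3 paired observations")
        return 1.0
    paired = wide[[a, b]].dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 paired observations")
    if paired[a].std() == 0 or paired[b].std() == 0:
        logger.warning("zero variance in %s or %s; correlation undefined", a, b)
        return float("nan")
    r, _ = stats.pearsonr(paired[a], paired[b])
    return float(r)


def kcl_sensitivity(normal: pd.Series, elevated: pd.Series) -> dict[str, float]:
    """Quantify the KCl-sensitive monosome pool from a paired 200/400 mM run.

    Non-translating 80S monosomes dissociate into 40S and 60S subunits at
    elevated KCl; translating ribosomes resist.  The sensitive share is the
    relative loss of 80S area at 400 mM, with the concomitant subunit gains
    reported alongside.
    """
    a80 = normal["80S"]
    if a80 <= 0:
        logger.warning("80S area is zero at normal KCl; sensitivity undefined")
        return {
            "sensitive_share_80S": float("nan"),
            "gain_40S": float("nan"),
            "gain_60S": float("nan"),
            "sign_consistent": False,
        }
    share = (a80 - elevated["80S"]) / a80
    gain_40 = float(elevated["40S"] - normal["40S"])
    gain_60 = float(elevated["60S"] - normal["60S"])
    return {
        "sensitive_share_80S": float(share),
        "gain_40S": gain_40,
        "gain_60S": gain_60,
        # a KCl-sensitive pool dissociates: 80S down, both subunits up
        "sign_consistent": bool(share > 0 and gain_40 > 0 and gain_60 > 0),
    }


def detect_halfmer_shoulder(trace: Trace, seg: PeakSegmentation) -> bool:
    """Qualitative flag for a half-mer shoulder between 80S and the polysomes.

    Half-mers (a stalled 40S preinitiation complex on an mRNA that also
    carries assembled 80S ribosomes) appear as extra local maxima between
    the 80S peak and the first polysome peak.  This is a presence flag only.
    """
    left80, right80 = seg.interval("80S")
    left_p, right_p = seg.interval("polysome")

    def apex(left: float, right: float) -> int:
        idx = np.flatnonzero((trace.positions >= left) & (trace.positions <= right))
        return int(idx[np.argmax(trace.absorbance[idx])])

    i80, ip = apex(left80, right80), apex(left_p, right_p)
    y = trace.absorbance[i80 + 1 : ip]
    if len(y) < 3:
        return False
    # any local maximum strictly between the two apexes = shoulder present;
    # require 5% of the smaller apex height to ignore numerical ripple
    floor = 0.05 * min(trace.absorbance[i80], trace.absorbance[ip])
    interior = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] > floor)) + 1
    return len(interior) > 0
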