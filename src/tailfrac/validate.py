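"""Validation-assay arithmetic: ePAT traces, qPCR estimates, segregation tests.

These are the small, exactly-specified computations used to corroborate the
sequencing-based tail-length calls: normalization and differencing of
tail-extension-PCR (ePAT) electropherograms, the efficiency^(-ct) qPCR
abundance proxy, and chi-square goodness-of-fit tests of observed genotype
segregation against Mendelian expectations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .errors import ConfigError, DataValidationError


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def qpcr_abundance(efficiency: float, ct: float) -> float:
    """Reference-free qPCR abundance proxy ``efficiency ** (-ct)``.

    ``efficiency`` is the per-cycle amplification factor in (1, 2];
    a ct difference of 1 at efficiency 2 corresponds to a 2-fold ratio.
    """
    if efficiency <= 1.0:
        raise ConfigError(f"PCR efficiency must exceed 1, got {efficiency}")
    if ct <= 0:
        raise ConfigError(f"ct must be positive, got {ct}")
    return float(efficiency) ** (-float(ct))


# ---------------------------------------------------------------------------
# ePAT electropherograms
# ---------------------------------------------------------------------------

@dataclass
class EPATTrace:
    """One electrophoretic trace: product size grid vs band intensity."""

    sample_id: str
    assay: str                 # "ePAT" or "control"
    genotype: str
    replicate: int
    size_grid: np.ndarray      # bp, strictly increasing
    intensity: np.ndarray      # arbitrary units, >= 0
    roi: tuple | None = None   # (lo, hi) bp interval; None -> full grid

    def __post_init__(self):
        self.size_grid = np.asarray(self.size_grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.size_grid.shape != self.intensity.shape:
            raise DataValidationError("size grid and intensity differ in length")
        if np.any(np.diff(self.size_grid) <= 0):
            raise DataValidationError("size grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise DataValidationError("intensities must be non-negative")

    def roi_mask(self) -> np.ndarray:
        if self.roi is None:
            return np.ones_like(self.size_grid, dtype=bool)
        lo, hi = self.roi
        mask = (self.size_grid >= lo) & (self.size_grid <= hi)
        if not mask.any():
            raise DataValidationError(f"region of interest {self.roi} empty on grid")
        return mask


def epat_normalize(trace: EPATTrace) -> EPATTrace:
    """Divide every intensity by the mean intensity inside the region of interest.

    After normalization the ROI mean is exactly 1; the operation is
    idempotent and invariant to rescaling the input intensities.
    """
    mask = trace.roi_mask()
    mean = trace.intensity[mask].mean()
    if mean == 0:
        raise DataValidationError(
            f"trace {trace.sample_id!r}: ROI mean intensity is zero")
    return EPATTrace(trace.sample_id, trace.assay, trace.genotype,
                     trace.replicate, trace.size_grid,
                     trace.intensity / mean, trace.roi)


def epat_difference(epat_traces: Sequence[EPATTrace],
                    control_traces: Sequence[EPATTrace],
                    roi: tuple | None = None) -> dict:
    """Replicate-mean normalized ePAT minus replicate-mean normalized control.

    Traces are grouped by genotype; all grids must be identical.  Returns
    ``{genotype: (size_grid, difference_curve)}``.
    """
    if not epat_traces or not control_traces:
        raise DataValidationError("need at least one trace per assay")
    grid = epat_traces[0].size_grid
    for t in list(epat_traces) + list(control_traces):
        if t.size_grid.shape != grid.shape or not np.allclose(t.size_grid, grid):
            raise DataValidationError(
                f"trace {t.sample_id!r}: size grid mismatch")
    out = {}
    genotypes = {t.genotype for t in epat_traces}
    for gt in sorted(genotypes):
        ep = [t for t in epat_traces if t.genotype == gt]
        ct = [t for t in control_traces if t.genotype == gt]
        if not ct:
            raise DataValidationError(f"no control traces for genotype {gt!r}")
        if roi is not None:
            ep = [EPATTrace(t.sample_id, t.assay, t.genotype, t.replicate,
                            t.size_grid, t.intensity, roi) for t in ep]
            ct = [EPATTrace(t.sample_id, t.assay, t.genotype, t.replicate,
                            t.size_grid, t.intensity, roi) for t in ct]
        ep_mean = np.mean([epat_normalize(t).intensity for t in ep], axis=0)
        ct_mean = np.mean([epat_normalize(t).intensity for t in ct], axis=0)
        out[gt] = (grid.copy(), ep_mean - ct_mean)
    return out


def epat_shift_statistic(diff_curve_a, diff_curve_b, size_grid=None) -> float:
    """Signed shift score between two ePAT-minus-control difference curves.

    Score = intensity-weighted mean product size of the positive part of
    curve A minus that of curve B.  Positive means curve A is shifted to
    longer products (longer tails).  Antisymmetric by construction; returns
    NaN with a warning when a curve has no positive part.
    """
    def _unpack(c):
        if isinstance(c, tuple):
            return np.asarray(c[0], float), np.asarray(c[1], float)
        return np.asarray(size_grid, float), np.asarray(c, float)

    grid_a, a = _unpack(diff_curve_a)
    grid_b, b = _unpack(diff_curve_b)
    if grid_a.shape != grid_b.shape or not np.allclose(grid_a, grid_b):
        raise DataValidationError("difference curves on different grids")

    def _centroid(grid, curve):
        pos = np.clip(curve, 0.0, None)
        total = pos.sum()
        if total == 0:
            warnings.warn("difference curve has no positive part", stacklevel=3)
            return np.nan
        return float((grid * pos).sum() / total)

    return _centroid(grid_a, a) - _centroid(grid_b, b)


# ---------------------------------------------------------------------------
# segregation chi-square
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def expected_counts(n: float, ratio: Sequence[float], rounded: bool = False):
    """Expected class counts for ``n`` offspring under the given segregation weights.

    ``ratio`` are positive class weights (e.g. (1, 2, 1)); ``rounded=True``
    rounds each expectation to the nearest integer for display parity with
    printed tables.
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    w = np.asarray(ratio, dtype=float)
    if np.any(w <= 0):
        raise ConfigError("segregation weights must be positive")
    exp = n * w / w.sum()
    if rounded:
        exp = np.round(exp)
    return exp


def chi_square_gof(observed: Sequence[float], ratio: Sequence[float] | None = None,
                   expected: Sequence[float] | None = None) -> ChiSquareResult:
    """Chi-square goodness of fit of observed counts against expected weights.

    Expectations come from :func:`expected_counts` (unrounded) when ``ratio``
    is given; passing ``expected`` directly overrides them — this is the
    table-parity mode used to reproduce published tables that print rounded
    expectations.  ``df`` is the number of classes minus one and the p-value
    is the upper chi-square tail.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ConfigError("need at least two classes")
    if obs.sum() <= 0:
        raise ConfigError("observed counts sum to zero")
    if expected is None:
        if ratio is None:
            raise ConfigError("provide either ratio or expected")
        expected = expected_counts(obs.sum(), ratio)
    exp = np.asarray(expected, dtype=float)
    if exp.shape != obs.shape:
        raise DataValidationError(
            f"class count mismatch: {obs.size} observed vs {exp.size} expected")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    return ChiSquareResult(stat, df, float(chi2.sf(stat, df)))
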