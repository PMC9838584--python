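"""Synthetic clinical cohort linking sector-wise angle closure to IOP.

The generator emulates the structure of a population AS-OCT study: each
eye carries AOD500 (angle opening distance at 500 um from the scleral
spur) in eight sectors spaced 45 degrees apart, and one tonometry IOP.
A sector counts as closed when its AOD500 falls below a detection
threshold (0.04 mm by default, about one pixel of the imaging system).

Each synthetic eye is built from the mechanistic outflow model:

* a closed-sector count drawn from a distribution heavily massed at 0
  (most eyes have open angles);
* a per-eye baseline mobility multiplier K0 (log-normal) scaling both
  outflow pathways, and a per-eye severity R — both drawn independently
  of the extent of closure, which is the structural assumption under
  which the conditional mean of IOP given extent reproduces the
  single-eye model curve;
* IOP from the lumped outflow balance at the eye's (K0, R, extent),
  plus Gaussian measurement noise.

Closure extent maps to the quarter model as (count/8) of the
circumference, i.e. 90 deg * count / 8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ahflow import lumped_model
from ahflow.materials import (ClosureScenario, PorousRegionParams,
                              pa_to_mmhg)

log = logging.getLogger(__name__)

#: Closure detection threshold on AOD500, mm.
DEFAULT_AOD500_THRESHOLD_MM = 0.04

#: Default closed-sector count distribution over {0..8}: heavily massed
#: at zero closed sectors with a thin tail of extensive closure, the
#: shape seen in population angle-imaging studies.
DEFAULT_COUNT_DISTRIBUTION = (0.80, 0.08, 0.04, 0.025, 0.02,
                              0.015, 0.01, 0.006, 0.004)


@dataclass
class CohortParams:
    """Synthetic cohort configuration.

    ``severity_mean``/``severity_log_sd`` parameterize the per-eye
    outflow facility reduction factor (log-normal around the mean, a
    point mass when the log-SD is 0); ``baseline_mobility_dispersion``
    is the log-SD of the per-eye mobility multiplier K0.  Both are
    drawn independently of the closed-sector count by construction.
    """

    n_eyes: int = 2395
    closed_sector_count_distribution: tuple = DEFAULT_COUNT_DISTRIBUTION
    aod500_open_mean_mm: float = 0.25
    aod500_open_sd_mm: float = 0.10
    aod500_closed_max_mm: float = 0.035
    baseline_mobility_dispersion: float = 0.30
    severity_mean: float = 1.6
    severity_log_sd: float = 0.0
    iop_measurement_noise_sd: float = 2.0       # mmHg
    seed: int = 0
    lumped: lumped_model.LumpedConfig = field(
        default_factory=lumped_model.LumpedConfig)

    def __post_init__(self):
        dist = np.asarray(self.closed_sector_count_distribution, dtype=float)
        if dist.shape != (9,) or np.any(dist < 0):
            raise ValueError("count distribution needs 9 non-negative masses")
        if not np.isclose(dist.sum(), 1.0):
            raise ValueError("count distribution must sum to 1")
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be positive")
        for name in ("baseline_mobility_dispersion", "severity_log_sd",
                     "iop_measurement_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.severity_mean < 1.0:
            raise ValueError("severity_mean must be >= 1")


@dataclass
class SyntheticEye:
    """One synthetic record: 8 AOD500 values (mm) and measured IOP."""

    eye_id: int
    aod500_mm: np.ndarray
    true_closed_sectors: tuple
    iop_mmhg: float
    k0: float
    severity: float

    def __post_init__(self):
        self.aod500_mm = np.asarray(self.aod500_mm, dtype=float)
        if self.aod500_mm.shape != (8,):
            raise ValueError("aod500_mm must have 8 sector values")


def model_iop_mmhg(count: int, k0: float, severity: float,
                   lumped_cfg: lumped_model.LumpedConfig) -> float:
    """Noise-free model IOP (mmHg) for a closed-sector count.

    The baseline mobility multiplier ``k0`` scales alpha of both
    pathways; the extent is ``count/8`` of the circumference.
    """
    scen = ClosureScenario(extent_deg=90.0 * count / 8.0,
                           reduction_factor=max(severity, 1.0))
    cfg = replace(
        lumped_cfg,
        tm=replace(lumped_cfg.tm, params=PorousRegionParams(
            lumped_cfg.tm.params.alpha * k0, lumped_cfg.tm.params.beta)),
        cb=replace(lumped_cfg.cb, params=PorousRegionParams(
            lumped_cfg.cb.params.alpha * k0, lumped_cfg.cb.params.beta)),
        scenario=scen)
    return pa_to_mmhg(lumped_model.solve_iop(cfg))


def generate_cohort(params: CohortParams) -> list[SyntheticEye]:
    """Generate a reproducible synthetic cohort (fixed by ``params.seed``)."""
    rng = np.random.default_rng(params.seed)
    counts = rng.choice(9, size=params.n_eyes,
                        p=np.asarray(params.closed_sector_count_distribution))
    k0 = np.exp(rng.normal(0.0, params.baseline_mobility_dispersion,
                           params.n_eyes))
    if params.severity_log_sd > 0:
        severity = 1.0 + (params.severity_mean - 1.0) * np.exp(
            rng.normal(0.0, params.severity_log_sd, params.n_eyes))
    else:
        severity = np.full(params.n_eyes, params.severity_mean)
    noise = rng.normal(0.0, params.iop_measurement_noise_sd, params.n_eyes)

    eyes = []
    for i in range(params.n_eyes):
        closed = tuple(sorted(rng.choice(8, size=counts[i], replace=False)))
        aod = rng.normal(params.aod500_open_mean_mm,
                         params.aod500_open_sd_mm, 8)
        aod = np.clip(aod, DEFAULT_AOD500_THRESHOLD_MM + 0.005, None)
        for s in closed:
            aod[s] = rng.uniform(0.0, params.aod500_closed_max_mm)
        iop = model_iop_mmhg(counts[i], k0[i], severity[i], params.lumped)
        eyes.append(SyntheticEye(
            eye_id=i, aod500_mm=aod, true_closed_sectors=closed,
            iop_mmhg=iop + noise[i], k0=float(k0[i]),
            severity=float(severity[i])))
    return eyes


def detect_closed_sectors(eye: SyntheticEye,
                          threshold_mm: float = DEFAULT_AOD500_THRESHOLD_MM
                          ) -> int:
    """Count sectors with AOD500 strictly below the threshold.

    The boundary value (AOD500 == threshold) counts as open.  Raises
    ``ValueError`` for missing (non-finite) sector values; cohort-level
    pipelines exclude such eyes and log the reason.
    """
    if not np.all(np.isfinite(eye.aod500_mm)):
        raise ValueError(f"eye {eye.eye_id}: missing AOD500 sector value")
    return int(np.sum(eye.aod500_mm < threshold_mm))


def detect_cohort(eyes, threshold_mm: float = DEFAULT_AOD500_THRESHOLD_MM):
    """Detected counts for a cohort; eyes with missing data are dropped.

    Returns ``(kept_eyes, counts)``.
    """
    kept, counts = [], []
    for eye in eyes:
        try:
            counts.append(detect_closed_sectors(eye, threshold_mm))
        except ValueError as err:
            log.warning("excluding eye: %s", err)
            continue
        kept.append(eye)
    return kept, np.asarray(counts, dtype=int)


GROUP_LABELS = ("0", "1", "2", "3", "4", "5", "6", "7-8")


@dataclass
class BinnedIOPStats:
    """Box-plot statistics of IOP (mmHg) for one closed-sector group."""

    group: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float


def bin_and_summarize(eyes, counts) -> list[BinnedIOPStats]:
    """Group eyes by detected closed-sector count and summarize IOP.

    Groups are {0,...,6, "7-8"} (the two most extensive-closure groups
    are merged because they are sparsely populated).  Quartiles use
    linear interpolation; whiskers follow the Tukey convention: the
    lowest datum at or above Q1 - 1.5 IQR and the highest datum at or
    below Q3 + 1.5 IQR.  Empty groups are omitted (never zero-filled).
    """
    counts = np.asarray(counts)
    iops = np.asarray([e.iop_mmhg for e in eyes])
    if counts.shape != iops.shape:
        raise ValueError("counts and eyes must align")
    stats = []
    for gi, label in enumerate(GROUP_LABELS):
        sel = counts >= 7 if label == "7-8" else counts == gi
        x = iops[sel]
        if x.size == 0:
            continue
        q1, med, q3 = np.percentile(x, (25, 50, 75))
        iqr = q3 - q1
        in_lo = x[x >= q1 - 1.5 * iqr]
        in_hi = x[x <= q3 + 1.5 * iqr]
        stats.append(BinnedIOPStats(
            group=label, n=int(x.size), mean=float(x.mean()),
            median=float(med), q1=float(q1), q3=float(q3),
            whisker_lo=float(in_lo.min()), whisker_hi=float(in_hi.max())))
    return stats


def group_extent_quarter_deg(label: str) -> float:
    """Quarter-model extent representing a closed-sector group."""
    count = 7.5 if label == "7-8" else float(label)
    return 90.0 * count / 8.0


def fit_reduction_factor(stats: list[BinnedIOPStats], curves) -> float:
    """Reduction factor whose model curve best matches the group means.

    ``curves`` is a family of :class:`~ahflow.closure_study.IOPCurve`
    over a grid of R; the best R minimizes the squared error between
    group mean IOP and the curve IOP interpolated at the group extents.
    A single-candidate grid is returned as-is (with a warning).
    """
    if not stats:
        raise ValueError("no groups to fit")
    if len(curves) == 1:
        log.warning("fit_reduction_factor: degenerate single-R grid")
    extents = np.array([group_extent_quarter_deg(s.group) for s in stats])
    means = np.array([s.mean for s in stats])
    best_r, best_err = None, np.inf
    for curve in curves:
        pred = np.interp(extents, curve.extents_deg_quarter,
                         curve.iop_mmhg)
        err = float(np.sum((pred - means) ** 2))
        if err < best_err:
            best_r, best_err = curve.reduction_factor, err
    return best_r


def cohort_to_frame(eyes) -> pd.DataFrame:
    """One row per eye: id, 8 AOD500 columns (mm), IOP (mmHg)."""
    rows = []
    for e in eyes:
        row = {"eye_id": e.eye_id}
        row.update({f"aod500_s{i}_mm": e.aod500_mm[i] for i in range(8)})
        row["iop_mmhg"] = e.iop_mmhg
        rows.append(row)
    return pd.DataFrame(rows)


def stats_to_frame(stats) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats])
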