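"""Raw-measurement processing: histology counts, BV/TV, tumor fluorescence.

Converts the three kinds of raw in-vivo measurements into the normalized
per-day time series (mean +/- standard error) the calibration likelihood
consumes:

* slide-level histology cell counts -> concentrations (fM), with bone-
  perimeter normalization for osteoblast/osteoclast counts;
* per-mouse BV/TV bone-volume fractions -> relative bone density (%);
* longitudinal tumor fluorescence -> tumor concentration (fM) via
  exponential fits anchored at the injected 1 fM at day 0.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .protocols import OBSERVABLES

__all__ = [
    "SlideRecord",
    "FluorescenceSeries",
    "StudyDataset",
    "counts_to_concentration",
    "perimeter_normalize",
    "normalize_bone_density",
    "fit_tumor_fluorescence",
    "fluorescence_to_concentration",
    "adjust_error_bars",
    "assemble_datasets",
]

log = logging.getLogger(__name__)

CELL_TYPES = ("tumor", "OB", "OC")


@dataclass(frozen=True)
class SlideRecord:
    """One histology measurement: a cell count within a region of interest."""

    mouse_id: str
    day: float
    cell_type: str
    count: float
    area_um2: float
    perimeter_um: Optional[float] = None
    thickness_um: float = 5.0

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.area_um2 <= 0 or self.thickness_um <= 0:
            raise ValueError("area and thickness must be positive")
        if self.cell_type in ("OB", "OC"):
            if self.perimeter_um is None or self.perimeter_um <= 0:
                raise ValueError("OB/OC records require a positive bone perimeter")


def counts_to_concentration(record: SlideRecord) -> float:
    """Cell concentration in fM from a raw slide count.

    ``[X] = X / (N_A * A * h)`` with the region-of-interest volume
    ``A * h`` taken in liters (1 um^3 = 1e-15 L).
    """
    volume_L = record.area_um2 * record.thickness_um * 1e-15
    molar = record.count / (Avogadro * volume_L)
    return molar * 1e15  # mol/L -> fM


def perimeter_normalize(conc_fM: float, P_i: float, P_bar: float) -> float:
    """Scale an OB/OC concentration by mean-to-slide bone-perimeter ratio.

    Slides that happen to contain more bone perimeter tend to show more
    bone-lining cells; ``X' = X * P_bar / P_i`` removes that sampling
    artifact.  Never applied to tumor counts.
    """
    if P_i <= 0 or P_bar <= 0:
        raise ValueError("bone perimeters must be positive")
    return conc_fM * P_bar / P_i


def normalize_bone_density(bvtv_values, baseline_values) -> np.ndarray:
    """Per-mouse BV/TV converted to relative bone density (%) of baseline mean."""
    baseline = np.asarray(baseline_values, dtype=float)
    if baseline.size == 0:
        raise ValueError("baseline group is empty")
    base = float(baseline.mean())
    if base <= 0:
        raise ValueError("baseline mean BV/TV must be positive")
    return 100.0 * np.asarray(bvtv_values, dtype=float) / base


@dataclass
class FluorescenceSeries:
    """Longitudinal mean tumor fluorescence for one treatment condition."""

    condition: str  # 'untreated' | 'ZA'
    days: np.ndarray
    values: np.ndarray
    A: Optional[float] = None  # fitted pre-exponential (day-0 fluorescence)
    b: Optional[float] = None  # fitted growth rate, 1/day
    excluded_from_fit: np.ndarray = None  # bool mask aligned with days

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("fluorescence values must be non-negative")
        if self.excluded_from_fit is None:
            self.excluded_from_fit = np.zeros(self.days.shape, dtype=bool)
        else:
            self.excluded_from_fit = np.asarray(self.excluded_from_fit, dtype=bool)

    def model_values(self, days) -> np.ndarray:
        if self.A is None or self.b is None:
            raise ValueError("series has not been fitted")
        return self.A * np.exp(self.b * np.asarray(days, dtype=float))


def fit_tumor_fluorescence(
    untreated: FluorescenceSeries,
    treated: FluorescenceSeries,
    output_days: Sequence[float] = (0.0, 7.0, 14.0, 21.0, 28.0),
):
    """Exponential fits linking the two fluorescence series at day 0.

    The untreated series is fit as ``F(t) = A * exp(b t)`` by least squares
    on log-transformed means over its non-excluded points (days 14/21/28 in
    the reference design).  The treated series shares the pre-exponential
    ``A`` (the same number of cells is injected in both arms) and its rate
    is pinned by the day-28 point alone: ``b_ZA = ln(F28 / A) / 28``; its
    earlier points are kept but flagged ``excluded_from_fit`` (they sit near
    the detection limit).  Both series are returned extended onto
    ``output_days``, using measured values where available (and not
    excluded) and model values elsewhere.
    """
    fit_mask = ~untreated.excluded_from_fit
    days_u = untreated.days[fit_mask]
    vals_u = untreated.values[fit_mask]
    if days_u.size < 2:
        raise ValueError("untreated series needs >= 2 points for the exponential fit")
    if np.any(vals_u <= 0):
        raise ValueError("fluorescence must be positive for the log-linear fit")
    b, logA = np.polyfit(days_u, np.log(vals_u), 1)
    A = float(np.exp(logA))

    # treated: keep only the final measured point; earlier ones are near the
    # detection floor and are excluded from the fit
    excluded_t = np.asarray(treated.excluded_from_fit, dtype=bool).copy()
    last_day = float(treated.days.max())
    excluded_t |= treated.days < last_day
    f_last = float(treated.values[treated.days == last_day][0])
    if f_last <= 0:
        raise ValueError("treated anchor fluorescence must be positive")
    b_za = math.log(f_last / A) / last_day

    def _extend(series, A, b, excluded):
        days = np.asarray(output_days, dtype=float)
        values = A * np.exp(b * days)
        new_excluded = np.ones(days.shape, dtype=bool)
        for i, d in enumerate(days):
            j = np.where(series.days == d)[0]
            if j.size and not excluded[j[0]]:
                values[i] = series.values[j[0]]
                new_excluded[i] = False
        return FluorescenceSeries(
            condition=series.condition,
            days=days,
            values=values,
            A=A,
            b=b,
            excluded_from_fit=new_excluded,
        )

    fitted_u = _extend(untreated, A, float(b), untreated.excluded_from_fit)
    fitted_t = _extend(treated, A, float(b_za), excluded_t)
    return fitted_u, fitted_t


def fluorescence_to_concentration(series: FluorescenceSeries) -> np.ndarray:
    """Tumor concentration (fM) as the fluorescence ratio to day 0.

    1 fM of cells is injected at day 0, so concentration = F(day) / A fM;
    day 0 maps to exactly 1 fM.
    """
    if series.A is None or series.A == 0:
        raise ValueError("series must be fitted with A > 0")
    return series.values / series.A


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class StudyDataset:
    """One observable time series (mean +/- SE) bound to a protocol."""

    label: str
    observable: str
    days: np.ndarray
    means: np.ndarray
    ses: np.ndarray
    tumor_type: str  # 'bone_adapted' | 'parental'
    protocol: str  # 'i' | 'ii' | 'iii'

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        if self.observable not in OBSERVABLES:
            raise ValueError(f"unknown observable {self.observable!r}")
        if self.protocol not in ("i", "ii", "iii"):
            raise ValueError("protocol must be 'i', 'ii' or 'iii'")
        if not (self.days.shape == self.means.shape == self.ses.shape):
            raise ValueError("days, means and ses must have matching shapes")
        if np.any(self.ses <= 0):
            raise ValueError("standard errors must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "observable": self.observable,
            "days": self.days.tolist(),
            "means": self.means.tolist(),
            "ses": self.ses.tolist(),
            "tumor_type": self.tumor_type,
            "protocol": self.protocol,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyDataset":
        return cls(
            label=d["label"],
            observable=d["observable"],
            days=np.asarray(d["days"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            ses=np.asarray(d["ses"], dtype=float),
            tumor_type=d["tumor_type"],
            protocol=d["protocol"],
        )


ERROR_BAR_POLICIES = ("extracted", "measured")


def adjust_error_bars(dataset: StudyDataset, policy: str) -> StudyDataset:
    """Apply the error-bar policy for figure-extracted (parental) data.

    ``extracted``: bone-density SEs are set to 5 percentage points and
    tumor SEs to 5% of each mean -- the published error bars are too wide
    for the time points to constrain the fit, so they are replaced while the
    means are preserved.  ``measured`` leaves the sigma/sqrt(n) errors of
    in-house data untouched.
    """
    if policy not in ERROR_BAR_POLICIES:
        raise ValueError(f"unknown error-bar policy {policy!r}")
    if policy == "measured":
        return dataset
    if dataset.observable == "bone_density_pct":
        ses = np.full_like(dataset.means, 5.0)
    elif dataset.observable == "tumor_fM":
        ses = 0.05 * dataset.means
        if np.any(ses <= 0):
            raise ValueError("tumor mean of 0 yields an invalid zero SE")
    else:
        ses = dataset.ses
    return replace(dataset, ses=ses)


def _mean_se(values: np.ndarray):
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        return float(values.mean()) if n else np.nan, np.nan
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(n))


def slide_concentrations(slides: Sequence[SlideRecord]) -> pd.DataFrame:
    """Per-slide concentrations (fM) with perimeter normalization for OB/OC.

    The mean perimeter is pooled per cell type over all slides of the study.
    """
    rows = []
    for rec in slides:
        rows.append(
            {
                "mouse_id": rec.mouse_id,
                "day": rec.day,
                "cell_type": rec.cell_type,
                "conc_fM": counts_to_concentration(rec),
                "perimeter_um": rec.perimeter_um,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for ct in ("OB", "OC"):
        sel = df["cell_type"] == ct
        if sel.any():
            p_bar = df.loc[sel, "perimeter_um"].mean()
            df.loc[sel, "conc_fM"] = [
                perimeter_normalize(c, p, p_bar)
                for c, p in zip(df.loc[sel, "conc_fM"], df.loc[sel, "perimeter_um"])
            ]
    return df


def assemble_datasets(
    slides: Sequence[SlideRecord],
    bvtv: Optional[pd.DataFrame],
    extracted: Optional[pd.DataFrame],
    baseline_tumor_days: Sequence[float] = (7.0,),
) -> List[StudyDataset]:
    """Aggregate raw inputs into the full set of calibration datasets.

    * ``slides``: histology records for the in-house (bone-adapted) study ->
      OC, OB and tumor concentration series (mean +/- sigma/sqrt(n) over
      slides per day).
    * ``bvtv``: columns (mouse_id, day, group, bvtv) with group in
      {'control', 'tumor'}; the baseline pool is all control mice plus
      tumor-cohort mice at ``baseline_tumor_days`` (no tumor detectable by
      histology at those days) -> bone-density series.
    * ``extracted``: columns (study, condition, observable, day, mean, se)
      of figure-extracted parental data; grouped into one dataset per
      (condition, observable) with the 'extracted' error-bar policy applied.

    For the full study design this yields nine datasets.  Groups with a
    single observation have no defined SE; the point is dropped with a
    logged warning.
    """
    datasets: List[StudyDataset] = []

    obs_by_cell = {"OC": "OC_fM", "OB": "OB_fM", "tumor": "tumor_fM"}
    if slides:
        conc = slide_concentrations(slides)
        log.info("processed %d slide records", len(conc))
        for ct in ("OC", "OB", "tumor"):
            sub = conc[conc["cell_type"] == ct]
            if sub.empty:
                continue
            days, means, ses = [], [], []
            for day, grp in sub.groupby("day"):
                m, se = _mean_se(grp["conc_fM"].to_numpy())
                if not np.isfinite(se):
                    log.warning(
                        "dropping %s day %g: single observation, SE undefined", ct, day
                    )
                    continue
                days.append(day), means.append(m), ses.append(se)
            if days:
                datasets.append(
                    StudyDataset(
                        label=f"bone_adapted:untreated:{obs_by_cell[ct]}",
                        observable=obs_by_cell[ct],
                        days=np.array(days),
                        means=np.array(means),
                        ses=np.array(ses),
                        tumor_type="bone_adapted",
                        protocol="i",
                    )
                )

    if bvtv is not None and len(bvtv):
        log.info("processed %d BV/TV rows", len(bvtv))
        is_baseline = (bvtv["group"] == "control") | (
            (bvtv["group"] == "tumor") & bvtv["day"].isin(baseline_tumor_days)
        )
        baseline = bvtv.loc[is_baseline, "bvtv"].to_numpy()
        tumor = bvtv[bvtv["group"] == "tumor"]
        days, means, ses = [], [], []
        for day, grp in tumor.groupby("day"):
            pct = normalize_bone_density(grp["bvtv"].to_numpy(), baseline)
            m, se = _mean_se(pct)
            if not np.isfinite(se):
                log.warning("dropping bone density day %g: SE undefined", day)
                continue
            days.append(day), means.append(m), ses.append(se)
        if days:
            datasets.append(
                StudyDataset(
                    label="bone_adapted:untreated:bone_density_pct",
                    observable="bone_density_pct",
                    days=np.array(days),
                    means=np.array(means),
                    ses=np.array(ses),
                    tumor_type="bone_adapted",
                    protocol="i",
                )
            )

    if extracted is not None and len(extracted):
        log.info("processed %d extracted rows", len(extracted))
        proto_by_condition = {"untreated": "i", "ZA": "ii", "ZA_no_tumor": "iii"}
        for (cond, obs), grp in extracted.groupby(["condition", "observable"]):
            grp = grp.sort_values("day")
            ses = grp["se"].to_numpy(dtype=float)
            if np.any(~np.isfinite(ses)) or np.any(ses <= 0):
                ses = np.maximum(np.nan_to_num(ses, nan=1.0), 1e-6)
            ds = StudyDataset(
                label=f"parental:{cond}:{obs}",
                observable=obs,
                days=grp["day"].to_numpy(dtype=float),
                means=grp["mean"].to_numpy(dtype=float),
                ses=ses,
                tumor_type="parental",
                protocol=proto_by_condition[cond],
            )
            datasets.append(adjust_error_bars(ds, "extracted"))

    return datasets
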