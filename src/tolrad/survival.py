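"""Surviving fractions from CFU assays and D10 estimation.

A colony-forming-unit assay measures survival after irradiation relative
to a sham (0 Gy) control: within each biological replicate the mean sham
plate count is the baseline, and each dosed technical replicate yields a
surviving fraction count/baseline.  The default dose-response model is
the classical single-hit log-linear survival curve

    log10 S(d) = -d / D10,

under which D10 — the decimal reduction dose — is well defined and
S(D10) = 0.1 by construction.  An optional two-parameter logistic fit in
log dose is available for curves with a shoulder.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BiologicalReplicate",
    "SurvivalAssay",
    "D10Fit",
    "surviving_fraction",
    "fit_d10",
    "predict_survival",
    "read_assay_csv",
    "write_assay_csv",
]


@dataclass
class BiologicalReplicate:
    """One biological replicate: sham counts plus dosed counts per dose (Gy)."""

    sham_counts: list[int]
    dosed_counts: dict[float, list[int]]

    def __post_init__(self) -> None:
        if not self.sham_counts:
            raise ValueError("sham_counts must be non-empty")
        if any(d <= 0 for d in self.dosed_counts):
            raise ValueError("doses must be > 0 Gy (0 Gy rows are sham)")


@dataclass
class SurvivalAssay:
    """CFU counts (dilution/plating-adjusted) for ≥1 biological replicate."""

    biological_replicates: list[BiologicalReplicate]

    def __post_init__(self) -> None:
        if not self.biological_replicates:
            raise ValueError("need at least one biological replicate")


@dataclass
class D10Fit:
    """A fitted survival curve summarised by its D10 (Gy).

    slope_per_gy is the log10-survival slope, equal to -1/d10_gy.
    """

    d10_gy: float
    slope_per_gy: float
    fit_points: list[tuple[float, float]]
    residual_sd: float
    n_dropped: int = 0
    model: str = "loglinear"


def surviving_fraction(assay: SurvivalAssay) -> list[tuple[float, float, int]]:
    """Per-technical-replicate surviving fractions with sham baselining.

    Returns (dose_gy, fraction, biological_replicate_index) tuples; the
    baseline is the mean sham count of the same biological replicate.
    Fractions may exceed 1.
    """
    out: list[tuple[float, float, int]] = []
    for rep_id, rep in enumerate(assay.biological_replicates):
        baseline = float(np.mean(rep.sham_counts))
        if baseline <= 0:
            raise ValueError(f"biological replicate {rep_id}: zero sham baseline")
        for dose in sorted(rep.dosed_counts):
            for count in rep.dosed_counts[dose]:
                out.append((dose, count / baseline, rep_id))
    return out


def fit_d10(points: list[tuple[float, float]], model: str = "loglinear") -> D10Fit:
    """Estimate D10 from (dose, surviving fraction) points.

    The default log-linear model is a least-squares line through the
    origin in (dose, log10 S) space — zero-dose survival is 1 by
    construction — giving D10 = -1/slope.  Points with fraction ≤ 0
    cannot be log-transformed; they are dropped with a warning and
    counted in ``n_dropped``.  ``model="logistic"`` instead fits a
    two-parameter logistic in log dose and reads D10 off where the fitted
    curve crosses S = 0.1.
    """
    pts = [(float(d), float(s)) for d, s in points]
    kept = [(d, s) for d, s in pts if s > 0 and d > 0]
    n_dropped = sum(1 for _, s in pts if s <= 0)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} point(s) with surviving fraction <= 0")
    if not kept:
        raise ValueError("no usable points: all surviving fractions <= 0")
    doses = np.array([d for d, _ in kept])
    logs = np.log10([s for _, s in kept])
    if model == "loglinear":
        slope = float(np.sum(doses * logs) / np.sum(doses**2))
        if slope >= 0:
            raise ValueError("no dose-dependent killing detected (fitted slope >= 0)")
        d10 = -1.0 / slope
        resid = logs - slope * doses
        residual_sd = float(np.std(resid, ddof=1)) if len(kept) > 1 else 0.0
        return D10Fit(
            d10_gy=d10,
            slope_per_gy=slope,
            fit_points=kept,
            residual_sd=residual_sd,
            n_dropped=n_dropped,
            model="loglinear",
        )
    if model == "logistic":
        if len({d for d, _ in kept}) < 2:
            raise ValueError("logistic fit needs at least 2 distinct doses")

        def logistic(logd, logm, b):
            return 1.0 / (1.0 + np.exp(b * (logd - logm)))

        logd = np.log(doses)
        p0 = (float(np.median(logd)), 2.0)
        popt, _ = curve_fit(logistic, logd, 10.0**logs, p0=p0, maxfev=10000)
        logm, b = popt
        if b <= 0:
            raise ValueError("no dose-dependent killing detected (fitted slope >= 0)")
        # S = 0.1  =>  logd = logm + ln(9)/b
        d10 = float(np.exp(logm + np.log(9.0) / b))
        resid = logs - np.log10(logistic(logd, *popt))
        residual_sd = float(np.std(resid, ddof=1)) if len(kept) > 1 else 0.0
        return D10Fit(
            d10_gy=d10,
            slope_per_gy=-1.0 / d10,
            fit_points=kept,
            residual_sd=residual_sd,
            n_dropped=n_dropped,
            model="logistic",
        )
    raise ValueError(f"unknown model {model!r}; use 'loglinear' or 'logistic'")


def predict_survival(fit: D10Fit, dose: float) -> float:
    """Surviving fraction at ``dose`` under the log-linear model: 10^(-dose/D10)."""
    if dose < 0:
        raise ValueError("dose must be >= 0 Gy")
    return float(10.0 ** (-dose / fit.d10_gy))


def read_assay_csv(path: str | Path) -> SurvivalAssay:
    """Read an assay CSV: biological_rep, dose_gy, technical_rep, cfu_count.

    Rows with dose 0 are the sham controls of their biological replicate.
    """
    path = Path(path)
    shams: dict[str, list[int]] = {}
    dosed: dict[str, dict[float, list[int]]] = {}
    order: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"biological_rep", "dose_gy", "technical_rep", "cfu_count"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            rep = row["biological_rep"]
            if rep not in shams:
                shams[rep] = []
                dosed[rep] = {}
                order.append(rep)
            dose = float(row["dose_gy"])
            count = int(row["cfu_count"])
            if dose == 0:
                shams[rep].append(count)
            else:
                dosed[rep].setdefault(dose, []).append(count)
    reps = [
        BiologicalReplicate(sham_counts=shams[r], dosed_counts=dosed[r]) for r in order
    ]
    return SurvivalAssay(biological_replicates=reps)


def write_assay_csv(assay: SurvivalAssay, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["biological_rep", "dose_gy", "technical_rep", "cfu_count"])
        for rep_id, rep in enumerate(assay.biological_replicates):
            for t, c in enumerate(rep.sham_counts):
                writer.writerow([rep_id, 0, t, c])
            for dose in sorted(rep.dosed_counts):
                for t, c in enumerate(rep.dosed_counts[dose]):
                    writer.writerow([rep_id, dose, t, c])
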