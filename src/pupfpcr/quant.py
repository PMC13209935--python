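"""qPCR quantification: standard curves, proportion back-calculation,
limit of detection, accuracy/precision metrics, ENGL compliance.

The quantitative model is the standard-curve relation

    y = a * x + b,        x = log10(template amount)

with y the cycle threshold (Ct), a the slope (cycles per ten-fold
dilution; a = -3.32 at 100% amplification efficiency) and b the
intercept.  Inverting it for a mixture calibrated on the fraction of
total DNA gives the detected proportion

    C = 10^((y - b) / a) * 100%.

Accuracy is relative deviation R.D. = 100 * |detected - actual| /
actual; precision is relative standard deviation R.S.D. = 100 * sd /
mean over replicates.  The ENGL (European Network of GMO Laboratories)
acceptance thresholds for quantitative food-authenticity PCR are reused:
standard-curve R^2 >= 0.98, R.D. <= 25%, R.S.D. <= 25%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UNDETECTED",
    "CtMeasurement",
    "StandardCurve",
    "MixtureResult",
    "EnglThresholds",
    "EnglReport",
    "fit_standard_curve",
    "proportion_from_ct",
    "determine_lod",
    "relative_deviation",
    "relative_sd",
    "quantify_mixture",
    "read_ct_csv",
    "write_ct_csv",
]

#: sentinel for "no signal within the run" — deliberately not a Ct of 40
UNDETECTED = None

TOTAL_CYCLES = 40.0


@dataclass(frozen=True)
class CtMeasurement:
    """One well: sample, fluorescence channel (species label), replicate
    index (>= 1) and the Ct, or None when no signal crossed threshold."""

    sample_id: str
    channel: str
    replicate: int
    ct: float | None

    def __post_init__(self):
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")
        if self.ct is not None and not (0.0 < self.ct < TOTAL_CYCLES):
            raise ValueError(f"ct {self.ct} outside (0, {TOTAL_CYCLES})")

    @property
    def detected(self) -> bool:
        return self.ct is not None


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares fit of Ct against log10 amount.

    slope_a < 0 for a valid dilution series; efficiency = 10^(-1/a) - 1
    (1.0 == 100%).
    """

    slope_a: float
    intercept_b: float
    r_squared: float
    n_points: int
    slope_stderr: float = float("nan")
    intercept_stderr: float = float("nan")

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("a standard curve needs >= 2 points")

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope_a) - 1.0

    def ct_of(self, log10_x: float) -> float:
        return self.slope_a * log10_x + self.intercept_b

    def summary(self) -> str:
        return (
            f"StandardCurve: Ct = {self.slope_a:.4f} * log10(x) + {self.intercept_b:.4f}\n"
            f"  n = {self.n_points}, R^2 = {self.r_squared:.4f}, "
            f"efficiency = {100 * self.efficiency:.1f}%\n"
            f"  se(slope) = {self.slope_stderr:.4f}, se(intercept) = {self.intercept_stderr:.4f}"
        )


@dataclass(frozen=True)
class EnglThresholds:
    """Acceptance limits for quantitative food-authenticity PCR."""

    min_r2: float = 0.98
    max_rd_pct: float = 25.0
    max_rsd_pct: float = 25.0

    def __post_init__(self):
        if min(self.min_r2, self.max_rd_pct, self.max_rsd_pct) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class MixtureResult:
    species: str
    actual_pct: float
    replicate_pcts: list[float]
    detected_pct: float | None
    rd_pct: float | None
    rsd_pct: float | None
    over_100_flag: bool = False

    @property
    def detected(self) -> bool:
        return self.detected_pct is not None


@dataclass
class EnglReport:
    thresholds: EnglThresholds
    curve_failures: dict[str, float] = field(default_factory=dict)
    rd_failures: dict[str, float] = field(default_factory=dict)
    rsd_failures: dict[str, float] = field(default_factory=dict)

    @property
    def compliant(self) -> bool:
        return not (self.curve_failures or self.rd_failures or self.rsd_failures)


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of Ct on log10 amount.

    r_squared is the squared Pearson correlation of the fitted line
    (exactly 1 for a two-point fit).
    """
    if len(points) < 2:
        raise ValueError("need >= 2 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("all x values identical; cannot fit a slope")
    res = stats.linregress(x, y)
    r2 = 1.0 if len(points) == 2 else float(res.rvalue) ** 2
    return StandardCurve(
        slope_a=float(res.slope),
        intercept_b=float(res.intercept),
        r_squared=r2,
        n_points=len(points),
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
    )


def proportion_from_ct(ct: float, curve: StandardCurve) -> float:
    """Detected proportion C = 100 * 10^((ct - b) / a), for a curve
    calibrated on x = log10(fraction of total DNA).

    Values above 100% are possible for noisy Cts and are returned
    unclamped; callers flag them.
    """
    if curve.slope_a == 0:
        raise ValueError("degenerate curve: zero slope")
    return 100.0 * 10.0 ** ((ct - curve.intercept_b) / curve.slope_a)


def determine_lod(
    series: dict[float, list[CtMeasurement]],
    ct_cutoff: float = 36.0,
) -> float | None:
    """Limit of detection: the lowest concentration level at which every
    replicate produced a signal below the Ct cutoff; None when no level
    qualifies."""
    if not series:
        raise ValueError("need at least one concentration level")
    if len(set(series)) != len(series):
        raise ValueError("concentration levels must be distinct")
    qualifying = [
        conc
        for conc, reps in series.items()
        if reps and all(m.detected and m.ct < ct_cutoff for m in reps)
    ]
    return min(qualifying) if qualifying else None


def relative_deviation(actual_pct: float, detected_pct: float) -> float:
    """Accuracy: R.D. = 100 * |detected - actual| / actual (percent)."""
    if actual_pct <= 0:
        raise ValueError("actual proportion must be positive")
    return 100.0 * abs(detected_pct - actual_pct) / actual_pct


def relative_sd(replicate_values: list[float]) -> float:
    """Precision: R.S.D. = 100 * sample sd (n-1) / mean (percent)."""
    if len(replicate_values) < 2:
        raise ValueError("need >= 2 replicate values")
    mean = float(np.mean(replicate_values))
    if mean == 0:
        raise ValueError("mean of replicates is zero")
    return 100.0 * float(np.std(replicate_values, ddof=1)) / mean


def quantify_mixture(
    ct_table: list[CtMeasurement],
    curves: dict[str, StandardCurve],
    actual: dict[str, float],
    thresholds: EnglThresholds | None = None,
) -> tuple[list[MixtureResult], EnglReport]:
    """Convert a replicate Ct table into per-species detected
    proportions with accuracy/precision metrics and an ENGL compliance
    report.

    Each replicate Ct is converted to a proportion before averaging, so
    R.S.D. is well-defined over replicate proportions.  Species whose
    replicates are all undetected (or which have no channel in the
    table) are reported as not detected; no normalisation across
    species is applied.
    """
    thresholds = thresholds or EnglThresholds()
    by_channel: dict[str, list[CtMeasurement]] = {}
    for m in ct_table:
        by_channel.setdefault(m.channel, []).append(m)
    missing = sorted(set(by_channel) - set(curves))
    if missing:
        raise ValueError(f"no standard curve for channel(s) {missing}")

    report = EnglReport(thresholds=thresholds)
    for sp, curve in curves.items():
        if curve.r_squared < thresholds.min_r2:
            report.curve_failures[sp] = curve.r_squared

    results: list[MixtureResult] = []
    for sp in actual:
        reps = [m for m in by_channel.get(sp, []) if m.detected]
        if not reps:
            results.append(MixtureResult(sp, actual[sp], [], None, None, None))
            continue
        curve = curves[sp]
        pcts = [proportion_from_ct(m.ct, curve) for m in reps]
        detected_pct = float(np.mean(pcts))
        rd = relative_deviation(actual[sp], detected_pct)
        rsd = relative_sd(pcts) if len(pcts) >= 2 else None
        results.append(
            MixtureResult(
                species=sp,
                actual_pct=actual[sp],
                replicate_pcts=pcts,
                detected_pct=detected_pct,
                rd_pct=rd,
                rsd_pct=rsd,
                over_100_flag=any(p > 100.0 for p in pcts),
            )
        )
        if rd > thresholds.max_rd_pct:
            report.rd_failures[sp] = rd
        if rsd is not None and rsd > thresholds.max_rsd_pct:
            report.rsd_failures[sp] = rsd
    return results, report


def results_to_tsv(results: list[MixtureResult], report: EnglReport) -> str:
    """Tabular mixture report: one row per species (undetected species
    shown as em-dash cells), followed by an ENGL pass/fail block."""
    out = ["species\tactual_pct\tdetected_pct\trd_pct\trsd_pct"]
    for r in results:
        if not r.detected:
            out.append(f"{r.species}\t{r.actual_pct:g}\t—\t—\t—")
        else:
            rsd = f"{r.rsd_pct:.2f}" if r.rsd_pct is not None else "."
            out.append(
                f"{r.species}\t{r.actual_pct:g}\t{r.detected_pct:.2f}"
                f"\t{r.rd_pct:.2f}\t{rsd}"
            )
    out.append("")
    out.append(f"ENGL_compliant\t{report.compliant}")
    for label, failures in (
        ("r2_below_min", report.curve_failures),
        ("rd_above_max", report.rd_failures),
        ("rsd_above_max", report.rsd_failures),
    ):
        for sp, v in sorted(failures.items()):
            out.append(f"{label}\t{sp}\t{v:.4f}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# CSV I/O (columns: sample,channel,replicate,ct — empty ct = undetected)


def read_ct_csv(path: str | Path) -> list[CtMeasurement]:
    df = pd.read_csv(path, dtype={"sample": str, "channel": str},
                     float_precision="round_trip")
    required = {"sample", "channel", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        ct = None if pd.isna(row.ct) else float(row.ct)
        out.append(CtMeasurement(str(row.sample), str(row.channel), int(row.replicate), ct))
    return out


def write_ct_csv(measurements: list[CtMeasurement], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample": [m.sample_id for m in measurements],
            "channel": [m.channel for m in measurements],
            "replicate": [m.replicate for m in measurements],
            "ct": [m.ct for m in measurements],
        }
    )
    df.to_csv(path, index=False)
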