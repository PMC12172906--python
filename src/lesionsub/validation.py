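"""Validation protocol: transitivity, accuracy, ICC, and atrophy compounding.

Reproducibility is assessed as the agreement between the direct one-step
TLVC (first-to-last visit) and the indirect multi-step TLVC (sum of the
yearly TLVCs): the intraclass correlation for absolute agreement, the SD of
the transitivity error Δ_trans = TLVC_multi − TLVC_one, and Spearman
correlations of |Δ_trans| against atrophy and lesion-volume factors.
Accuracy compares the one-step TLVC with the manually measured lesion volume
change (mean difference, paired t-test, ICC, Spearman correlations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntervalMeasurements",
    "ICCResult",
    "ValidationReport",
    "multi_step_tlvc",
    "compound_volume_change",
    "icc_absolute_agreement",
    "spearman",
    "transitivity_report",
    "accuracy_report",
    "estimated_yearly_lvc",
    "measurements_to_frame",
    "frame_to_measurements",
]

ALPHA = 0.05


@dataclass
class IntervalMeasurements:
    """One subject-interval record of the validation table (volumes in mL,
    atrophy in %)."""

    subject: str
    interval: str
    tlvc_one_step: float
    tlvc_yearly_steps: list[float] = field(default_factory=list)
    manual_lvc: float | None = None
    manual_lesion_volume_avg: float | None = None
    pbvc_yearly: list[float] = field(default_factory=list)
    pvvc_yearly: list[float] = field(default_factory=list)

    @property
    def tlvc_multi_step(self) -> float:
        return multi_step_tlvc(self.tlvc_yearly_steps)

    @property
    def pbvc(self) -> float | None:
        return compound_volume_change(self.pbvc_yearly) if self.pbvc_yearly else None

    @property
    def pvvc(self) -> float | None:
        return compound_volume_change(self.pvvc_yearly) if self.pvvc_yearly else None


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95


@dataclass
class ValidationReport:
    kind: str
    n: int
    icc: ICCResult
    mean_difference: float
    sd_of_difference: float
    paired_t_p: float | None = None
    degenerate_variance: bool = False
    spearman_rs: dict[str, tuple[float, float]] = field(default_factory=dict)
    alpha: float = ALPHA

    def significant(self, factor: str) -> bool:
        return self.spearman_rs[factor][1] < self.alpha

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n": self.n,
            "icc": self.icc.estimate,
            "icc_ci": [self.icc.ci_low, self.icc.ci_high],
            "mean_difference_ml": self.mean_difference,
            "sd_of_difference_ml": self.sd_of_difference,
            "paired_t_p": self.paired_t_p,
            "degenerate_variance": self.degenerate_variance,
            "spearman": {
                k: {"rs": v[0], "p": v[1]} for k, v in self.spearman_rs.items()
            },
        }


def multi_step_tlvc(yearly: list[float]) -> float:
    """Indirect multi-step TLVC: the sum of the consecutive yearly TLVCs."""
    if len(yearly) == 0:
        raise ValueError("at least one yearly TLVC is required")
    return float(np.sum(yearly))


def compound_volume_change(yearly_pct: list[float]) -> float:
    """Multiplicative compounding of yearly percentage volume changes:
    ((1 + x1/100)···(1 + xN/100) − 1)·100."""
    vals = np.asarray(yearly_pct, dtype=float)
    if vals.size == 0:
        raise ValueError("at least one yearly percentage is required")
    if np.any(vals <= -100):
        raise ValueError("percentage changes must be > -100")
    return float((np.prod(1.0 + vals / 100.0) - 1.0) * 100.0)


def icc_absolute_agreement(x, y, confidence: float = 0.95) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC —
    ICC(A,1) in McGraw & Wong terms — with an F-based confidence interval.

    ``x`` and ``y`` are the paired measurements of the two methods/raters.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("at least 3 paired observations are required")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing values are not allowed")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise ValueError("degenerate data: zero between-subject variance")
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    alpha = 1.0 - confidence
    if mse == 0:
        return ICCResult(float(icc), float(icc), float(icc), confidence)
    # Satterthwaite df for the A,1 interval (McGraw & Wong)
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lo = hi = 1.0
    return ICCResult(float(icc), float(lo), float(hi), confidence)


def spearman(x, y, exact_below: int = 20, seed: int = 0) -> tuple[float, float]:
    """Spearman correlation; the p-value uses the large-sample t
    approximation, or an exact/permutation null for small n (< 20)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rs, p_asym = stats.spearmanr(x, y)
    n = x.size
    if n >= exact_below or not np.isfinite(rs):
        return float(rs), float(p_asym)
    if n <= 8:
        # exhaustive permutation null of the rank correlation
        from itertools import permutations

        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(_rank_corr(rx, ry))
        count = total = 0
        for perm in permutations(range(n)):
            r = _rank_corr(rx, ry[list(perm)])
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        return float(rs), count / total
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(_rank_corr(rx, ry))
    draws = 20000
    hits = 0
    for _ in range(draws):
        r = _rank_corr(rx, rng.permutation(ry))
        if abs(r) >= obs - 1e-12:
            hits += 1
    return float(rs), (hits + 1) / (draws + 1)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom > 0 else 0.0


def _factor_columns(records: list[IntervalMeasurements]) -> dict[str, np.ndarray]:
    cols = {}
    pbvc = [r.pbvc for r in records]
    pvvc = [r.pvvc for r in records]
    vol = [r.manual_lesion_volume_avg for r in records]
    lvc = [r.manual_lvc for r in records]
    for name, vals in (
        ("pbvc", pbvc),
        ("pvvc", pvvc),
        ("manual_lesion_volume", vol),
        ("manual_lvc", lvc),
    ):
        if all(v is not None for v in vals):
            cols[name] = np.asarray(vals, dtype=float)
    return cols


def transitivity_report(records: list[IntervalMeasurements]) -> ValidationReport:
    """Reproducibility: agreement between multi-step and one-step TLVC.

    Reports ICC(A,1), the SD (and mean) of Δ_trans = multi-step − one-step,
    and Spearman correlations of |Δ_trans| against whichever factors are
    present on the records (PBVC, PVVC, lesion volume, manual LVC).
    """
    one = np.array([r.tlvc_one_step for r in records], dtype=float)
    multi = np.array([r.tlvc_multi_step for r in records], dtype=float)
    delta = multi - one
    icc = icc_absolute_agreement(one, multi)
    rs = {
        name: spearman(np.abs(delta), vals)
        for name, vals in _factor_columns(records).items()
    }
    return ValidationReport(
        kind="transitivity",
        n=len(records),
        icc=icc,
        mean_difference=float(delta.mean()),
        sd_of_difference=float(delta.std(ddof=1)) if len(records) > 1 else 0.0,
        spearman_rs=rs,
    )


def accuracy_report(records: list[IntervalMeasurements]) -> ValidationReport:
    """Accuracy: agreement between one-step TLVC and manual LVC.

    Reports ICC(A,1), the mean difference Δ_acc = TLVC_one − manual LVC with
    a two-sided paired t-test, and Spearman correlations of Δ_acc against the
    available factors.
    """
    if any(r.manual_lvc is None for r in records):
        raise ValueError("every record needs a manual LVC for the accuracy report")
    one = np.array([r.tlvc_one_step for r in records], dtype=float)
    manual = np.array([r.manual_lvc for r in records], dtype=float)
    delta = one - manual
    icc = icc_absolute_agreement(one, manual)
    degenerate = bool(np.allclose(delta, delta[0]))
    if degenerate:
        p = 1.0 if np.allclose(delta, 0.0) else None
    else:
        p = float(stats.ttest_rel(one, manual).pvalue)
    rs = {
        name: spearman(delta, vals)
        for name, vals in _factor_columns(records).items()
    }
    return ValidationReport(
        kind="accuracy",
        n=len(records),
        icc=icc,
        mean_difference=float(delta.mean()),
        sd_of_difference=float(delta.std(ddof=1)) if len(records) > 1 else 0.0,
        paired_t_p=p,
        degenerate_variance=degenerate,
        spearman_rs=rs,
    )


def estimated_yearly_lvc(
    median_lesion_volume_ml: float, annual_change_fraction: float = 0.10
) -> float:
    """Reference scale for the method's error: the expected yearly lesion
    volume change given a cohort's median lesion volume and a fractional
    annual change rate (about 10%/year in untreated early MS)."""
    if median_lesion_volume_ml < 0:
        raise ValueError("median lesion volume must be >= 0")
    return median_lesion_volume_ml * annual_change_fraction


# --- tidy CSV interface ----------------------------------------------------

def measurements_to_frame(records: list[IntervalMeasurements]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "subject": r.subject,
                "interval": r.interval,
                "tlvc_one_step": r.tlvc_one_step,
                "tlvc_yearly_steps": ";".join(f"{v:.10g}" for v in r.tlvc_yearly_steps),
                "manual_lvc": r.manual_lvc,
                "manual_lesion_volume_avg": r.manual_lesion_volume_avg,
                "pbvc_yearly": ";".join(f"{v:.10g}" for v in r.pbvc_yearly),
                "pvvc_yearly": ";".join(f"{v:.10g}" for v in r.pvvc_yearly),
            }
        )
    return pd.DataFrame(rows)


def _split(cell) -> list[float]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return [float(v) for v in str(cell).split(";")]


def frame_to_measurements(df: pd.DataFrame) -> list[IntervalMeasurements]:
    records = []
    for _, row in df.iterrows():
        records.append(
            IntervalMeasurements(
                subject=str(row["subject"]),
                interval=str(row["interval"]),
                tlvc_one_step=float(row["tlvc_one_step"]),
                tlvc_yearly_steps=_split(row.get("tlvc_yearly_steps")),
                manual_lvc=(
                    None
                    if pd.isna(row.get("manual_lvc"))
                    else float(row["manual_lvc"])
                ),
                manual_lesion_volume_avg=(
                    None
                    if pd.isna(row.get("manual_lesion_volume_avg"))
                    else float(row["manual_lesion_volume_avg"])
                ),
                pbvc_yearly=_split(row.get("pbvc_yearly")),
                pvvc_yearly=_split(row.get("pvvc_yearly")),
            )
        )
    return records
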