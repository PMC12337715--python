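"""Agreement metrics between observed and expected measurement vectors.

The validation harness compares a rater's measurements (a human examiner
reading cursors, or the automatic marker) against analytic expectations,
label by label, and summarizes with:

* **MAD** — mean absolute deviation, mean(|obs - exp|), in the measures'
  own mixed units (each label carries its unit);
* **MAPE** — mean absolute error relative to the expected value. Stored as
  a dimensionless *fraction*; reports render both the fraction and
  fraction x 100 with explicit tags, because validation literature often
  prints the fraction with a percent sign;
* **Pearson r** — product-moment correlation across labels;
* **ICC** — two-way, absolute-agreement, single-measure intraclass
  correlation (ICC(A,1) in the McGraw–Wong taxonomy) across >=2 raters.

Vectors must share labels in the same order; anything else is an
:class:`~eptools.errors.AlignmentError` rather than a silent reindex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AlignmentError, DegenerateInputError, ParameterError

__all__ = [
    "MeasurementVector",
    "AgreementReport",
    "mad",
    "mape",
    "pearson_r",
    "icc",
    "build_phase1_report",
    "render_comparison_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeasurementVector:
    """Named measurement values; labels carry the units (mixed units allowed)."""

    labels: tuple[str, ...]
    values: tuple[float, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ParameterError("labels and values differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_pairs(cls, pairs, name: str = "") -> "MeasurementVector":
        labels, values = zip(*pairs) if pairs else ((), ())
        return cls(tuple(labels), tuple(float(v) for v in values), name=name)

    def subset(self, labels) -> "MeasurementVector":
        index = dict(zip(self.labels, self.values))
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise AlignmentError(f"labels not present: {missing}")
        return MeasurementVector(
            tuple(labels), tuple(index[lab] for lab in labels), name=self.name
        )

    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class AgreementReport:
    """Per-label deviations plus the summary agreement metrics."""

    group: str
    rater: str
    deviations: dict[str, float]
    mad: float
    mape: float | None
    pearson_r: float | None
    icc: float | None = None
    n: int = 0

    def summary_lines(self) -> list[str]:
        out = [f"group={self.group} rater={self.rater} n={self.n}"]
        out.append(f"  MAD  = {self.mad:.4f}")
        if self.mape is not None:
            out.append(
                f"  MAPE = {self.mape:.4f} (fraction) = {self.mape * 100:.2f} %"
            )
        if self.pearson_r is not None:
            out.append(f"  Pearson r = {self.pearson_r:.3f}")
        if self.icc is not None:
            out.append(f"  ICC(A,1) = {self.icc:.3f}")
        return out


def _aligned(observed: MeasurementVector, expected: MeasurementVector) -> None:
    if observed.labels != expected.labels:
        raise AlignmentError(
            "observed and expected vectors must share labels in the same order"
        )
    if len(observed) < 1:
        raise ParameterError("need at least one label")


def mad(observed: MeasurementVector, expected: MeasurementVector) -> float:
    """Mean absolute deviation, mean(|observed - expected|)."""
    _aligned(observed, expected)
    return float(np.mean(np.abs(observed.array() - expected.array())))


def mape(
    observed: MeasurementVector,
    expected: MeasurementVector,
    zero_policy: str = "error",
) -> float:
    """Mean absolute error relative to expected, as a dimensionless fraction.

    ``zero_policy="skip"`` drops labels whose expected value is 0;
    ``"error"`` raises on them.
    """
    _aligned(observed, expected)
    obs = observed.array()
    exp = expected.array()
    zero = exp == 0.0
    if zero.any():
        if zero_policy == "error":
            bad = [lab for lab, z in zip(expected.labels, zero) if z]
            raise DegenerateInputError(
                f"expected value is 0 for {bad}; use zero_policy='skip'"
            )
        if zero_policy != "skip":
            raise ParameterError(f"unknown zero_policy {zero_policy!r}")
        obs, exp = obs[~zero], exp[~zero]
        if len(exp) == 0:
            raise DegenerateInputError("all expected values are 0")
    return float(np.mean(np.abs(obs - exp) / np.abs(exp)))


def pearson_r(observed: MeasurementVector, expected: MeasurementVector) -> float:
    """Product-moment correlation between the two vectors."""
    _aligned(observed, expected)
    if len(observed) < 3:
        raise ParameterError("pearson_r needs at least 3 labels")
    obs = observed.array()
    exp = expected.array()
    if np.ptp(obs) == 0.0 or np.ptp(exp) == 0.0:
        raise DegenerateInputError("pearson_r needs nonzero variance on both sides")
    return float(stats.pearsonr(obs, exp).statistic)


def icc(raters: list[MeasurementVector]) -> float:
    """Two-way, absolute-agreement, single-measure ICC — ICC(A,1).

    Subjects are the shared labels (rows), raters the vectors (columns).
    From the two-way ANOVA mean squares with n subjects and k raters,

        ICC(A,1) = (MSR - MSE) /
                   (MSR + (k-1)*MSE + (k/n)*(MSC - MSE))

    where MSR, MSC, MSE are the row (subject), column (rater) and residual
    mean squares.
    """
    if len(raters) < 2:
        raise ParameterError("icc needs at least 2 raters")
    labels = raters[0].labels
    if len(labels) < 2:
        raise ParameterError("icc needs at least 2 subjects (labels)")
    for r in raters[1:]:
        if r.labels != labels:
            raise AlignmentError("all raters must share labels in the same order")
    data = np.column_stack([r.array() for r in raters])  # n subjects x k raters
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise DegenerateInputError("icc undefined: zero total variance")
    return float((msr - mse) / denom)


def build_phase1_report(
    expected: MeasurementVector,
    raters: dict[str, MeasurementVector],
    groups: dict[str, list[str]],
) -> dict[tuple[str, str], AgreementReport]:
    """One AgreementReport per (group, rater) against the expected vector.

    ``groups`` partitions the expected labels (overlap is an error; an
    empty group is skipped with a warning). Pearson r and ICC are reported
    where defined (>=3 labels with variance; >=2 raters), otherwise left
    as None.
    """
    seen: set[str] = set()
    for name, labels in groups.items():
        overlap = seen.intersection(labels)
        if overlap:
            raise ParameterError(f"groups overlap on labels {sorted(overlap)}")
        seen.update(labels)
    reports: dict[tuple[str, str], AgreementReport] = {}
    for gname, labels in groups.items():
        if not labels:
            logger.warning("group %r is empty; excluded from report", gname)
            continue
        exp_g = expected.subset(labels)
        rater_subsets = {rn: rv.subset(labels) for rn, rv in raters.items()}
        group_icc = None
        if len(rater_subsets) >= 2 and len(labels) >= 2:
            try:
                group_icc = icc(list(rater_subsets.values()))
            except DegenerateInputError:
                group_icc = None
        for rname, obs_g in rater_subsets.items():
            devs = {
                lab: abs(o - e)
                for lab, o, e in zip(labels, obs_g.values, exp_g.values)
            }
            try:
                r = pearson_r(obs_g, exp_g)
            except (ParameterError, DegenerateInputError):
                r = None
            try:
                frac = mape(obs_g, exp_g, zero_policy="skip")
            except DegenerateInputError:
                frac = None
            reports[(gname, rname)] = AgreementReport(
                group=gname,
                rater=rname,
                deviations=devs,
                mad=mad(obs_g, exp_g),
                mape=frac,
                pearson_r=r,
                icc=group_icc,
                n=len(labels),
            )
    return reports


def render_comparison_table(
    expected: MeasurementVector, raters: dict[str, MeasurementVector]
) -> str:
    """Plain-text table: one row per measure, expected column then raters."""
    names = list(raters)
    width = max((len(lab) for lab in expected.labels), default=8)
    header = ["Measure".ljust(width), "Expected".rjust(10)] + [
        n.rjust(max(10, len(n))) for n in names
    ]
    lines = ["  ".join(header)]
    for lab, exp_val in zip(expected.labels, expected.values):
        row = [lab.ljust(width), f"{exp_val:.4g}".rjust(10)]
        for n in names:
            v = raters[n].subset([lab]).values[0]
            row.append(f"{v:.4g}".rjust(max(10, len(n))))
        lines.append("  ".join(row))
    return "\n".join(lines)
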