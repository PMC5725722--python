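"""Agreement statistics between the two anatomy conditions.

The two reconstruction conditions (displaced "template" anatomy vs the true
"native" anatomy) are treated as two fixed raters scoring the same items, so
consistency is the two-way mixed, single-measure intraclass correlation
ICC(3,1):

    ICC = (MS_rows - MS_err) / (MS_rows + (k - 1) * MS_err)

from the two-way ANOVA without interaction on the n x k table (k = 2). The
consistency form ignores an additive rater bias and can be negative. 95%
confidence bounds follow the McGraw & Wong F-based construction. ICC point
estimates are banded into the conventional qualitative ratings. Agreement is
additionally summarized by Bland-Altman limits (mean difference +/- 1.96 SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "ICCResult",
    "BlandAltmanResult",
    "icc31",
    "rate_icc",
    "bland_altman",
    "pearson",
    "regional_consistency",
    "global_consistency",
    "distance_vs_icc",
]

#: Rating bands, closed on the right: (0.80, 1] very good ... <= 0.20 poor.
RATING_EDGES = ((0.80, "very good"), (0.60, "good"), (0.40, "moderate"),
                (0.20, "fair"))

GLOBAL_MEASURES = (
    "power", "pli", "clustering", "path_length", "modularity",
    "n_modules", "mst_leaf_fraction", "mst_diameter",
)

REGIONAL_MEASURES = ("power", "pli", "mst_degree")


@dataclass
class PairedMeasurements:
    """Aligned per-item values under the template (a) and native (b) condition."""

    values_a: np.ndarray
    values_b: np.ndarray
    item_ids: np.ndarray | None = None
    level: str = "global_subject"

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, float)
        self.values_b = np.asarray(self.values_b, float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("paired value vectors must be 1-D and equal length")
        if not (np.all(np.isfinite(self.values_a)) and np.all(np.isfinite(self.values_b))):
            raise ValueError("missing/non-finite values after pairing")

    @property
    def n(self) -> int:
        return self.values_a.size


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    rating: str
    not_reliable: bool = False


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_outside: int
    means: np.ndarray | None = None
    diffs: np.ndarray | None = None


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------

def rate_icc(icc: float) -> str:
    """Qualitative rating band of an ICC value (bands closed on the right)."""
    if icc > 1 + 1e-12:
        raise ValueError("ICC cannot exceed 1")
    for edge, label in RATING_EDGES:
        if icc > edge:
            return label
    return "poor"


def icc31(pairs: PairedMeasurements, alpha: float = 0.05) -> ICCResult:
    """ICC(3,1): two-way mixed model, consistency, single measure, k = 2 raters.

    The n x 2 table is decomposed into row (item), column (rater) and
    residual mean squares; ``ICC = (MSR - MSE) / (MSR + (k-1) MSE)``. The
    1 - alpha confidence interval is the McGraw & Wong case-3 F-based
    interval. Negative values are rated "poor" and flagged not reliable.
    """
    a, b = pairs.values_a, pairs.values_b
    n = pairs.n
    k = 2
    if n < 3:
        raise ValueError("ICC needs at least 3 items")
    table = np.column_stack([a, b])
    grand = table.mean()
    if np.allclose(table, grand, atol=0) and table.std() == 0:
        raise ValueError("constant data: ICC undefined")

    row_means = table.mean(axis=1)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    # for k = 2 the residual SS reduces exactly to half the variance of the
    # paired differences; this form is exact for identical/shifted raters
    d = a - b
    ss_err = 0.5 * np.sum((d - d.mean()) ** 2)
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if msr + (k - 1) * mse == 0:
        raise ValueError("constant data: ICC undefined")
    if mse == 0:
        icc, lo, hi = 1.0, 1.0, 1.0
    else:
        icc = (msr - mse) / (msr + (k - 1) * mse)
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_obs = msr / mse
        fu = sps.f.ppf(1 - alpha / 2, df1, df2)
        fl = sps.f.ppf(1 - alpha / 2, df2, df1)
        f_low = f_obs / fu
        f_up = f_obs * fl
        lo = (f_low - 1) / (f_low + k - 1)
        hi = (f_up - 1) / (f_up + k - 1)
    icc = float(icc)
    return ICCResult(
        icc=icc,
        ci_low=float(min(lo, icc)),
        ci_high=float(max(hi, icc)),
        rating=rate_icc(icc),
        not_reliable=icc < 0,
    )


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman agreement: limits at mean difference +/- 1.96 sample SD.

    Differences are template minus native (a - b); the SD uses the n-1
    denominator; ``n_outside`` counts points strictly outside the limits.
    """
    if pairs.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = pairs.values_a - pairs.values_b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff
    outside = int(np.sum((d < loa_low) | (d > loa_high)))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        n_outside=outside,
        means=(pairs.values_a + pairs.values_b) / 2,
        diffs=d,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# table-level wiring
# ---------------------------------------------------------------------------

def _paired_pivot(table: pd.DataFrame, index_cols: list[str]) -> pd.DataFrame:
    """Pivot a long table with a 'condition' column into template/native pairs."""
    need = set(index_cols + ["condition", "value"])
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")
    wide = table.pivot_table(index=index_cols, columns="condition",
                             values="value", aggfunc="first")
    for cond in ("template", "native"):
        if cond not in wide.columns:
            raise ValueError(f"missing condition {cond!r} in table")
    if wide[["template", "native"]].isna().any().any():
        raise ValueError("epoch misalignment between conditions")
    return wide


def regional_consistency(measure_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(measure, band, ROI) ICC across pooled epochs.

    ``measure_table`` is long-format with columns subject, condition, roi,
    band, epoch, measure, value; epochs are pooled across subjects (items =
    subject x epoch), mirroring a regions-by-pooled-epochs design. Returns
    one row per (measure, band, roi) with the ICC, CI and rating.
    """
    rows = []
    for (measure, band, roi), sub in measure_table.groupby(
        ["measure", "band", "roi"], sort=True
    ):
        wide = _paired_pivot(sub, ["subject", "epoch"])
        pairs = PairedMeasurements(
            wide["template"].to_numpy(), wide["native"].to_numpy(),
            level="regional_epoch",
        )
        try:
            res = icc31(pairs)
        except ValueError as exc:
            warnings.warn(f"ICC skipped for {measure}/{band}/roi{roi}: {exc}",
                          stacklevel=2)
            continue
        rows.append(
            {
                "measure": measure, "band": band, "roi": roi, "n": pairs.n,
                "icc": res.icc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "rating": res.rating, "not_reliable": res.not_reliable,
            }
        )
    return pd.DataFrame(rows)


def global_consistency(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(measure, band) subject-level ICC and Bland-Altman statistics.

    ``subject_table`` is long-format with columns subject, condition, band,
    measure, value, holding epoch-averaged global measures per subject.
    """
    rows = []
    for (measure, band), sub in subject_table.groupby(["measure", "band"], sort=True):
        wide = _paired_pivot(sub, ["subject"])
        pairs = PairedMeasurements(
            wide["template"].to_numpy(), wide["native"].to_numpy(),
            level="global_subject",
        )
        try:
            ba = bland_altman(pairs)
            res = icc31(pairs)
        except ValueError as exc:
            warnings.warn(f"global ICC skipped for {measure}/{band}: {exc}",
                          stacklevel=2)
            continue
        rows.append(
            {
                "measure": measure, "band": band, "n": pairs.n,
                "icc": res.icc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "rating": res.rating, "not_reliable": res.not_reliable,
                "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                "n_outside": ba.n_outside,
            }
        )
    return pd.DataFrame(rows)


def distance_vs_icc(distances: pd.DataFrame, iccs: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between per-ROI voxel distance and per-ROI power ICC.

    ``distances`` has columns band, roi, distance_mm (mean representative-
    voxel displacement); ``iccs`` has band, roi, icc (relative power).
    Degenerate bands (constant distances, e.g. a zero-displacement run) are
    skipped with a warning. Returns one row per band with r and p.
    """
    merged = distances.merge(iccs, on=["band", "roi"], how="inner")
    rows = []
    for band, sub in merged.groupby("band", sort=True):
        try:
            r, p = pearson(sub["distance_mm"].to_numpy(), sub["icc"].to_numpy())
        except ValueError as exc:
            warnings.warn(f"distance-vs-ICC skipped for band {band}: {exc}",
                          stacklevel=2)
            continue
        rows.append({"band": band, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)
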