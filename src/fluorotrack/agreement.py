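"""Agreement statistics between two landmark annotations.

Quantifies how well two annotation sources agree — an automatic detector
against manual ground truth, or rater against rater (intra/inter) — with
the statistics conventional for method-agreement studies:

* Dice overlap of the label discs, per label;
* per-landmark distance summaries: mean ± SD of |Δx|, |Δy| and the
  Euclidean distance, in pixels and millimetres, optionally stratified
  by pulse rate;
* Bland–Altman mean difference with 95% limits of agreement
  (mean ± 1.96·SD of the signed differences, sample SD);
* intraclass correlation per coordinate, defaulting to the two-way
  random-effects, absolute-agreement, single-measure form ICC(2,1) with
  an F-based 95% confidence interval;
* detection-failure tables per label stratified by pulse rate.

Frames with a failure in either annotation are excluded pairwise per
landmark (not listwise across landmarks); exclusion counts are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .labels import LABEL_SCHEME, LandmarkLabel, as_label
from .landmarks import LandmarkSet
from .maskcodec import LabelMask
from .volume import PseudoVolume

__all__ = [
    "dice",
    "distance_stats",
    "bland_altman",
    "BlandAltman",
    "icc",
    "ICCResult",
    "failure_table",
    "compare_raters",
    "AgreementReport",
]


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


def _as_array(mask) -> np.ndarray:
    if isinstance(mask, LabelMask):
        return mask.pixels
    if isinstance(mask, PseudoVolume):
        return mask.voxels
    return np.asarray(mask)


def dice(a, b, label: "int | str | LandmarkLabel") -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of one label in two masks.

    Defined as 1.0 when the label is empty in both masks and 0.0 when it
    is empty in exactly one.
    """
    arr_a, arr_b = _as_array(a), _as_array(b)
    if arr_a.shape != arr_b.shape:
        raise ValidationError(f"mask shapes differ: {arr_a.shape} vs {arr_b.shape}")
    if isinstance(label, (str, LandmarkLabel)):
        label = LABEL_SCHEME[as_label(label)]
    in_a = arr_a == label
    in_b = arr_b == label
    na, nb = int(in_a.sum()), int(in_b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(in_a & in_b))
    return 2.0 * inter / (na + nb)


# ---------------------------------------------------------------------------
# Distance statistics
# ---------------------------------------------------------------------------


def _paired_diffs(
    a: Sequence[LandmarkSet], b: Sequence[LandmarkSet], label: LandmarkLabel
) -> tuple[np.ndarray, np.ndarray, list[int], int]:
    """Signed (a − b) per-frame differences for one landmark.

    Returns (dx, dy, frames_compared, n_excluded); frames where the
    landmark is missing in either annotation are excluded pairwise.
    """
    if len(a) != len(b):
        raise ValidationError(f"sequences differ in length: {len(a)} vs {len(b)}")
    dx, dy, frames = [], [], []
    excluded = 0
    for i, (sa, sb) in enumerate(zip(a, b)):
        la, lb = sa.get(label), sb.get(label)
        if la is None or lb is None:
            excluded += 1
            continue
        dx.append(la.x - lb.x)
        dy.append(la.y - lb.y)
        frames.append(i)
    return np.asarray(dx), np.asarray(dy), frames, excluded


def _mean_sd(v: np.ndarray) -> tuple[float, float]:
    if v.size == 0:
        return float("nan"), float("nan")
    return float(np.mean(v)), float(np.std(v, ddof=1)) if v.size > 1 else 0.0


def distance_stats(
    a: Sequence[LandmarkSet],
    b: Sequence[LandmarkSet],
    mm_per_px: float | None = None,
    stratify_by_pulse_rate: bool = False,
) -> pd.DataFrame:
    """Per-landmark |Δx|, |Δy| and Euclidean distance summaries.

    One row per (landmark, stratum); strata are ``"all"`` plus one per
    pulse rate when requested. Distances are reported in px, and in mm
    when a calibration scale is supplied.
    """
    strata: dict[str, np.ndarray] = {"all": np.ones(len(a), dtype=bool)}
    if stratify_by_pulse_rate:
        rates = np.array([s.meta.pulse_rate_hz for s in a])
        for r in sorted(set(rates)):
            strata[f"{r:g} Hz"] = rates == r

    rows = []
    for label in LandmarkLabel:
        dx, dy, frames, excluded = _paired_diffs(a, b, label)
        frame_idx = np.asarray(frames, dtype=int)
        for name, in_stratum in strata.items():
            sel = in_stratum[frame_idx] if frame_idx.size else np.zeros(0, dtype=bool)
            sdx, sdy = np.abs(dx[sel]), np.abs(dy[sel])
            eucl = np.hypot(dx[sel], dy[sel])
            n_frames_in_stratum = int(in_stratum.sum())
            row = {
                "landmark": label.value,
                "stratum": name,
                "n": int(sel.sum()),
                "n_excluded": n_frames_in_stratum - int(sel.sum()),
            }
            for key, v in (("abs_dx", sdx), ("abs_dy", sdy), ("euclidean", eucl)):
                m, s = _mean_sd(v)
                row[f"mean_{key}_px"], row[f"sd_{key}_px"] = m, s
                if mm_per_px is not None:
                    row[f"mean_{key}_mm"] = m * mm_per_px
                    row[f"sd_{key}_mm"] = s * mm_per_px
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bland–Altman limits of agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n: int


def bland_altman(signed_diffs: Sequence[float]) -> BlandAltman:
    """Mean difference and 95% limits of agreement (mean ± 1.96·SD).

    Uses the sample SD (n − 1 denominator) and the conventional fixed
    1.96 multiplier.
    """
    v = np.asarray(signed_diffs, dtype=float)
    if v.size < 2:
        raise ValidationError("bland_altman needs at least 2 differences")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    half = 1.96 * sd
    return BlandAltman(mean, mean - half, mean + half, sd, int(v.size))


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    value: float
    ci_lower: float
    ci_upper: float
    form: str
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def icc(ratings, form: str = "a-1", alpha: float = 0.05) -> ICCResult:
    """Intraclass correlation of an n×k rating matrix (no missing cells).

    ``form="a-1"`` is the default two-way random-effects,
    absolute-agreement, single-measure coefficient
    (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n); ``form="c-1"`` is
    the consistency variant (MSR − MSE) / (MSR + (k−1)·MSE). Confidence
    intervals use the standard F-based constructions. Input with zero
    variance everywhere is reported as a degenerate perfect agreement.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ratings must be a 2D (subjects × raters) matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValidationError(f"need >= 3 subjects and >= 2 raters, got {n}×{k}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("ratings contain missing/non-finite cells; filter rows first")
    if form not in ("a-1", "c-1"):
        raise ValidationError(f"unknown ICC form {form!r}; expected 'a-1' or 'c-1'")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((x - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    if sst == 0.0:
        return ICCResult(1.0, 1.0, 1.0, form, n, k, degenerate=True)

    if form == "c-1":
        denom = msr + (k - 1) * mse
        value = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0.0:
            return ICCResult(1.0, 1.0, 1.0, form, n, k, degenerate=True)
        fval = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = fval / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = fval * stats.f.ppf(1 - alpha / 2, df2, df1)
        return ICCResult(
            float(value), float((fl - 1) / (fl + k - 1)), float((fu - 1) / (fu + k - 1)),
            form, n, k,
        )

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = (msr - mse) / denom if denom > 0 else 1.0
    if value >= 1.0 - 1e-12:
        return ICCResult(min(float(value), 1.0), 1.0, 1.0, form, n, k, degenerate=True)

    # F-based interval for the absolute-agreement single-measure form,
    # with a Satterthwaite degrees-of-freedom approximation
    a = k * value / (n * (1.0 - value))
    b = 1.0 + k * value * (n - 1) / (n * (1.0 - value))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v_df = num / den if den > 0 else float((n - 1) * (k - 1))
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v_df)
    f2 = stats.f.ppf(1 - alpha / 2, v_df, n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    lower = float(lower) if np.isfinite(lower) else -1.0
    upper = float(upper) if np.isfinite(upper) else 1.0
    lower = min(lower, float(value))
    upper = max(upper, float(value))
    return ICCResult(float(value), lower, upper, form, n, k)


# ---------------------------------------------------------------------------
# Failure bookkeeping
# ---------------------------------------------------------------------------


def failure_table(sets: Sequence[LandmarkSet]) -> pd.DataFrame:
    """Counts of detection failures per landmark, stratified by pulse rate.

    One row per landmark; one column per pulse rate present plus a
    ``total`` column whose entries equal the per-stratum sums.
    """
    rates = sorted({s.meta.pulse_rate_hz for s in sets})
    cols = [f"{r:g} Hz" for r in rates]
    counts = {label.value: {c: 0 for c in cols} for label in LandmarkLabel}
    for s in sets:
        col = f"{s.meta.pulse_rate_hz:g} Hz"
        for label in s.failures:
            counts[label.value][col] += 1
    df = pd.DataFrame.from_dict(counts, orient="index", columns=cols)
    df.index.name = "landmark"
    df["total"] = df.sum(axis=1)
    return df


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    """Complete agreement analysis between two annotation sources."""

    distances: pd.DataFrame
    loa: pd.DataFrame
    icc_table: pd.DataFrame
    dice_per_label: dict[str, float] = field(default_factory=dict)
    failures_a: pd.DataFrame | None = None
    failures_b: pd.DataFrame | None = None
    n_frames: int = 0
    mm_per_px: float | None = None

    def summary(self) -> dict:
        mean_dice = (
            float(np.mean(list(self.dice_per_label.values()))) if self.dice_per_label else None
        )
        overall = self.distances[self.distances["stratum"] == "all"]
        return {
            "n_frames": self.n_frames,
            "mm_per_px": self.mm_per_px,
            "mean_dice": mean_dice,
            "dice_per_label": self.dice_per_label,
            "mean_euclidean_px_per_landmark": dict(
                zip(overall["landmark"], overall["mean_euclidean_px"])
            ),
            "n_failures_a": None if self.failures_a is None else int(self.failures_a["total"].sum()),
            "n_failures_b": None if self.failures_b is None else int(self.failures_b["total"].sum()),
        }

    def save(self, out_dir: "str | Path") -> None:
        """Write the report as CSV tables plus a JSON summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.distances.to_csv(out / "distances.csv", index=False)
        self.loa.to_csv(out / "limits_of_agreement.csv", index=False)
        self.icc_table.to_csv(out / "icc.csv", index=False)
        if self.dice_per_label:
            pd.Series(self.dice_per_label, name="dice").rename_axis("landmark").to_csv(
                out / "dice.csv"
            )
        if self.failures_a is not None:
            self.failures_a.to_csv(out / "failures_a.csv")
        if self.failures_b is not None:
            self.failures_b.to_csv(out / "failures_b.csv")
        (out / "summary.json").write_text(json.dumps(self.summary(), indent=1))


def compare_raters(
    a: Sequence[LandmarkSet],
    b: Sequence[LandmarkSet],
    masks_a: "PseudoVolume | None" = None,
    masks_b: "PseudoVolume | None" = None,
    mm_per_px: float | None = None,
    icc_form: str = "a-1",
    stratify_by_pulse_rate: bool = True,
) -> AgreementReport:
    """Run the full agreement suite on any annotation pair.

    Works identically for automatic-vs-ground-truth, intra-rater and
    inter-rater comparisons. Dice is computed only when both label
    volumes are supplied.
    """
    if len(a) != len(b):
        raise ValidationError(f"annotation lengths differ: {len(a)} vs {len(b)}")

    distances = distance_stats(a, b, mm_per_px, stratify_by_pulse_rate)

    scale = mm_per_px if mm_per_px is not None else 1.0
    unit = "mm" if mm_per_px is not None else "px"
    loa_rows, icc_rows = [], []
    for label in LandmarkLabel:
        dx, dy, frames, _ = _paired_diffs(a, b, label)
        for axis, diffs in (("x", dx), ("y", dy)):
            if diffs.size >= 2:
                ba = bland_altman(diffs * scale)
                loa_rows.append(
                    {
                        "landmark": label.value,
                        "axis": axis,
                        "unit": unit,
                        "mean_diff": ba.mean_diff,
                        "loa_lower": ba.loa_lower,
                        "loa_upper": ba.loa_upper,
                        "n": ba.n,
                    }
                )
            vals_a, vals_b = [], []
            for i in frames:
                la, lb = a[i].get(label), b[i].get(label)
                vals_a.append(la.x if axis == "x" else la.y)
                vals_b.append(lb.x if axis == "x" else lb.y)
            if len(vals_a) >= 3:
                r = icc(np.column_stack([vals_a, vals_b]) * scale, form=icc_form)
                icc_rows.append(
                    {
                        "landmark": label.value,
                        "axis": axis,
                        "icc": r.value,
                        "ci_lower": r.ci_lower,
                        "ci_upper": r.ci_upper,
                        "degenerate": r.degenerate,
                        "n": r.n_subjects,
                    }
                )

    dice_per_label: dict[str, float] = {}
    if masks_a is not None and masks_b is not None:
        for label, value in LABEL_SCHEME.items():
            present = (masks_a.voxels == value).any() or (masks_b.voxels == value).any()
            if present:
                dice_per_label[label.value] = dice(masks_a, masks_b, value)

    return AgreementReport(
        distances=distances,
        loa=pd.DataFrame(loa_rows),
        icc_table=pd.DataFrame(icc_rows),
        dice_per_label=dice_per_label,
        failures_a=failure_table(a),
        failures_b=failure_table(b),
        n_frames=len(a),
        mm_per_px=mm_per_px,
    )
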