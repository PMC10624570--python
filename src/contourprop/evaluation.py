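"""Geometric metrics and the two-stage statistical evaluation protocol.

Per fraction, predicted contours are compared with ground truth via the Dice
similarity coefficient (DSC), the 95th-percentile Hausdorff distance (HD95)
and the average symmetric surface distance (HDavg), all in millimetres on
the voxel grid.  HD95 is the maximum of the two directed 95th percentiles
(linear-interpolation percentiles) and HDavg the mean of the two directed
mean surface distances; surface voxels are foreground voxels with at least
one face-adjacent background neighbour.

To avoid biasing towards patients with many fractions, metrics are first
averaged per patient; cohort mean and SD are then taken over the per-patient
means.  Normality of the per-patient means is checked with a one-sample
Kolmogorov--Smirnov test against a normal with estimated parameters, and
methods are compared with two-sided paired t-tests at alpha = 0.05.

The rectum is evaluated only on axial slices spanning the PTV plus a 15 mm
margin above and below its ends (10 slices at 1.5 mm thickness); bladder and
CTV are evaluated on the full grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats


class DegenerateInputWarning(UserWarning):
    pass


@dataclass
class EvalRecord:
    patient: str
    fraction: int
    structure: str
    method: str
    dsc: float
    hd95_mm: float
    hdavg_mm: float


@dataclass
class CohortStats:
    """Per-patient means and their cohort-level summary for one metric."""

    per_patient: pd.DataFrame  # index: patient, columns: methods
    cohort_mean: pd.Series
    cohort_sd: pd.Series
    normality_p: pd.Series
    pairwise: pd.DataFrame  # columns: method_a, method_b, t, p, significant
    alpha: float = 0.05


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A&B| / (|A|+|B|); two empty masks
    compare as 1.0 (degenerate, warned)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks have different shapes")
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        warnings.warn("both masks empty; DSC defined as 1.0",
                      DegenerateInputWarning)
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / (sa + sb)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 face-adjacent background neighbour."""
    mask = np.asarray(mask, dtype=bool)
    footprint = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=footprint, border_value=0)
    return mask & ~eroded


def surface_distances(a: np.ndarray, b: np.ndarray, spacing
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Directed Euclidean mm distances surface(A)->surface(B) and back."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks have different shapes")
    if a.sum() == 0:
        raise ValueError("mask 'a' is empty")
    if b.sum() == 0:
        raise ValueError("mask 'b' is empty")
    sa, sb = _surface(a), _surface(b)
    dist_to_sb = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_sa = ndimage.distance_transform_edt(~sa, sampling=spacing)
    return dist_to_sb[sa], dist_to_sa[sb]


def hd95(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Max of the two directed 95th-percentile surface distances, mm."""
    d_ab, d_ba = surface_distances(a, b, spacing)
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def hd_avg(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Mean of the two directed mean surface distances, mm."""
    d_ab, d_ba = surface_distances(a, b, spacing)
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def rectum_eval_region(ptv: np.ndarray, slice_thickness_mm: float,
                       margin_mm: float = 15.0) -> tuple[int, int]:
    """Axial slice range [zmin-k, zmax+k] (inclusive) spanning the PTV plus
    `margin_mm` above and below, clamped to the volume."""
    ptv = np.asarray(ptv, dtype=bool)
    if ptv.sum() == 0:
        raise ValueError("PTV mask is empty")
    z_any = np.nonzero(ptv.any(axis=(0, 1)))[0]
    k = int(round(margin_mm / slice_thickness_mm))
    zmin = max(int(z_any[0]) - k, 0)
    zmax = min(int(z_any[-1]) + k, ptv.shape[2] - 1)
    return zmin, zmax


def crop_to_slices(mask: np.ndarray, z_range: tuple[int, int]) -> np.ndarray:
    out = np.zeros_like(mask)
    out[:, :, z_range[0]:z_range[1] + 1] = mask[:, :, z_range[0]:z_range[1] + 1]
    return out


def evaluate_structure(pred: np.ndarray, truth: np.ndarray, spacing,
                       ) -> tuple[float, float, float]:
    """(DSC, HD95, HDavg) for one predicted mask; empty predictions give
    DSC 0 and missing (NaN) distances."""
    d = dsc(pred, truth)
    if np.asarray(pred).sum() == 0 or np.asarray(truth).sum() == 0:
        if np.asarray(pred).sum() != np.asarray(truth).sum():
            warnings.warn("empty mask; distances reported as missing",
                          DegenerateInputWarning)
            return 0.0, float("nan"), float("nan")
        return d, 0.0, 0.0
    d_ab, d_ba = surface_distances(pred, truth, spacing)
    h95 = float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))
    havg = float((d_ab.mean() + d_ba.mean()) / 2.0)
    return d, h95, havg


def records_to_frame(records: list[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def aggregate(records: list[EvalRecord] | pd.DataFrame, metric: str = "dsc",
              structure: str | None = None, alpha: float = 0.05) -> CohortStats:
    """Fraction-level -> per-patient mean -> cohort mean/SD over patients.

    Patients carry equal weight regardless of their fraction counts.  Also
    runs the normality check on per-patient means and all pairwise paired
    t-tests between methods.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if structure is not None:
        df = df[df["structure"] == structure]
    if df.empty:
        raise ValueError("no records to aggregate")
    counts = df.groupby("patient")[metric].count()
    if (counts == 0).any():
        raise ValueError("a patient has zero records")
    per_patient = (df.groupby(["patient", "method"])[metric].mean()
                   .unstack("method"))
    cohort_mean = per_patient.mean(axis=0)
    cohort_sd = per_patient.std(axis=0, ddof=1)
    methods = list(per_patient.columns)
    normality = {}
    for m in methods:
        vals = per_patient[m].dropna().to_numpy()
        normality[m] = normality_test(vals) if len(vals) >= 3 else float("nan")
    rows = []
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            sub = per_patient[[ma, mb]].dropna()
            if len(sub) >= 2:
                t, p, sig = paired_test(sub[ma].to_numpy(), sub[mb].to_numpy(),
                                        alpha=alpha)
            else:
                t, p, sig = float("nan"), float("nan"), False
            rows.append({"method_a": ma, "method_b": mb, "t": t, "p": p,
                         "significant": sig})
    return CohortStats(per_patient=per_patient, cohort_mean=cohort_mean,
                       cohort_sd=cohort_sd, normality_p=pd.Series(normality),
                       pairwise=pd.DataFrame(rows), alpha=alpha)


def normality_test(values) -> float:
    """One-sample KS test against a normal with the sample's mean and SD.

    Parameters are estimated from the data (Lilliefors-style caveat: the
    plain KS p-value is conservative in that setting)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("constant sample; normality test degenerate",
                      DegenerateInputWarning)
        return float("nan")
    return float(stats.kstest(values, "norm", args=(values.mean(), sd)).pvalue)


def paired_test(method_a, method_b, alpha: float = 0.05
                ) -> tuple[float, float, bool]:
    """Two-sided paired t-test on per-patient means; returns (t, p, significant).

    Zero-variance differences are degenerate: all-zero differences give
    (0, 1, False) with a warning."""
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two aligned per-patient vectors of length >= 2")
    diff = a - b
    if diff.std(ddof=1) == 0:
        warnings.warn("zero-variance differences; t-test degenerate",
                      DegenerateInputWarning)
        if np.allclose(diff, 0):
            return 0.0, 1.0, False
        return float("inf") * np.sign(diff.mean()), 0.0, True
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def render_report(records: list[EvalRecord] | pd.DataFrame,
                  structures=("bladder", "rectum", "ctv"),
                  metrics=("dsc", "hd95_mm", "hdavg_mm"),
                  alpha: float = 0.05) -> str:
    """Markdown table of mean (SD) per method x structure x metric, with the
    best method per column bolded (highest DSC, lowest distances)."""
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    methods = sorted(df["method"].unique())
    header = ["Method"]
    for s in structures:
        for m in metrics:
            header.append(f"{s} {m}")
    lines = ["| " + " | ".join(header) + " |",
             "|" + "---|" * len(header)]
    cells: dict[tuple[str, str, str], tuple[float, float]] = {}
    best: dict[tuple[str, str], str] = {}
    for s in structures:
        for m in metrics:
            col_means = {}
            for meth in methods:
                st = aggregate(df[df["method"] == meth], metric=m, structure=s,
                               alpha=alpha) if not df[(df["method"] == meth)
                                                      & (df["structure"] == s)].empty else None
                if st is None:
                    continue
                mean = float(st.cohort_mean.iloc[0])
                sd = float(st.cohort_sd.iloc[0]) if len(st.per_patient) > 1 else 0.0
                cells[(meth, s, m)] = (mean, sd)
                col_means[meth] = mean
            if col_means:
                pick = max if m == "dsc" else min
                best[(s, m)] = pick(col_means, key=col_means.get)
    for meth in methods:
        row = [meth]
        for s in structures:
            for m in metrics:
                if (meth, s, m) in cells:
                    mean, sd = cells[(meth, s, m)]
                    txt = f"{mean:.3f} ({sd:.3f})"
                    if best.get((s, m)) == meth:
                        txt = f"**{txt}**"
                    row.append(txt)
                else:
                    row.append("-")
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"
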