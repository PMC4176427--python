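"""Per-sample quality-control metrics computed from a compact summary.

The workhorse display for spotting failed arrays is the scatter of
log2 median methylated against log2 median unmethylated intensity: good
samples cluster at high intensity, degraded or failed hybridizations
drift toward the origin.  Density curves of Beta / M-values per stratum
are reconstructed from the stored quantile vectors, so plotting never
needs the full probe-level matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import QCSummary

DEFAULT_QC_CUTOFF = 10.5
#: intensity floor applied before log2 so zero medians stay finite
INTENSITY_FLOOR = 1.0


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    median_log2_meth: float
    median_log2_unmeth: float
    mean_negative_control: float  # NaN when no NEGATIVE controls are stored
    flagged: bool = False
    flag_reason: str = ""


@dataclass(frozen=True)
class DensityCurve:
    sample_id: str
    measure: str
    stratum: str
    grid: np.ndarray
    density: np.ndarray


def median_channel_intensities(summary: QCSummary) -> list[SampleQC]:
    """log2 medians of the M and U channels over all autosomal probes.

    Medians are read from the stored quantile vectors at p = 0.5.  A zero
    median is floored at one intensity unit before log2 and the sample is
    flagged with reason ``zero_median``.
    """
    if summary.label != "raw":
        raise ValueError("median channel intensities require a raw-labelled summary")
    if summary.is_empty_stratum("autosomal"):
        raise ValueError("autosomal stratum is empty")
    med_m = summary.quantile_at("autosomal", "M", 0.5)
    med_u = summary.quantile_at("autosomal", "U", 0.5)

    neg = pd.Series(np.nan, index=summary.sample_ids)
    if summary.controls is not None:
        sub = summary.controls[summary.controls["control_type"] == "NEGATIVE"]
        neg.update(sub.set_index("sample_id")["mean_combined"])

    out = []
    for s in summary.sample_ids:
        floored = med_m[s] < INTENSITY_FLOOR or med_u[s] < INTENSITY_FLOOR
        out.append(
            SampleQC(
                sample_id=s,
                median_log2_meth=float(np.log2(max(med_m[s], INTENSITY_FLOOR))),
                median_log2_unmeth=float(np.log2(max(med_u[s], INTENSITY_FLOOR))),
                mean_negative_control=float(neg[s]),
                flagged=bool(floored),
                flag_reason="zero_median" if floored else "",
            )
        )
    return out


def flag_low_quality(qc: list[SampleQC], cutoff: float = DEFAULT_QC_CUTOFF) -> list[SampleQC]:
    """Flag samples whose mean log2 median intensity falls below ``cutoff``.

    The criterion is (median_log2_meth + median_log2_unmeth) / 2 < cutoff;
    flags already present (e.g. ``zero_median``) are preserved.
    """
    out = []
    for q in qc:
        if (q.median_log2_meth + q.median_log2_unmeth) / 2.0 < cutoff:
            reason = q.flag_reason or "low_median_intensity"
            if q.flag_reason and "low_median_intensity" not in q.flag_reason:
                reason = q.flag_reason + ";low_median_intensity"
            out.append(replace(q, flagged=True, flag_reason=reason))
        else:
            out.append(q)
    return out


def qc_frame(qc: list[SampleQC]) -> pd.DataFrame:
    """Tabular view of SampleQC records, indexed by sample."""
    return pd.DataFrame([q.__dict__ for q in qc]).set_index("sample_id")


# ---------------------------------------------------------------------------
# density reconstruction
# ---------------------------------------------------------------------------


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9 min(sd, IQR/1.34) n^(-1/5), with a
    small floor so constant pseudo-samples still yield a finite curve."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    candidates = [x for x in (sd, (q75 - q25) / 1.34) if x > 0]
    spread = min(candidates) if candidates else 0.0
    bw = 0.9 * spread * n ** (-0.2)
    if bw <= 0:
        c = float(values[0]) if n else 0.0
        bw = 1e-6 * max(1.0, abs(c))
    return float(bw)


def gaussian_kde_curve(values: np.ndarray, grid: np.ndarray, bandwidth: float | None = None) -> np.ndarray:
    """Equal-weight Gaussian KDE of ``values`` evaluated on ``grid``."""
    values = np.asarray(values, dtype=float)
    if bandwidth is None:
        bandwidth = silverman_bandwidth(values)
    z = (np.asarray(grid, dtype=float)[:, None] - values[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (values.size * bandwidth * np.sqrt(2 * np.pi))
    return dens


def density_curves(
    summary: QCSummary,
    measure: str = "Beta",
    stratum: str = "autosomal",
    n_grid: int = 512,
    bandwidth: float | None = None,
) -> list[DensityCurve]:
    """Per-sample KDE of a measure, reconstructed from stored quantiles.

    The quantile vector is treated as an equal-weight pseudo-sample of the
    underlying probe-level distribution; the bandwidth follows Silverman's
    rule on that pseudo-sample unless given explicitly.  All samples share
    one grid spanning the joint range padded by three bandwidths.
    """
    if summary.is_empty_stratum(stratum):
        raise ValueError(f"stratum {stratum!r} is empty")
    tab = summary.quantiles[stratum][measure]
    vals = tab.to_numpy()
    bws = [
        bandwidth if bandwidth is not None else silverman_bandwidth(vals[:, j])
        for j in range(vals.shape[1])
    ]
    pad = 3.0 * max(bws)
    grid = np.linspace(vals.min() - pad, vals.max() + pad, n_grid)
    return [
        DensityCurve(
            sample_id=str(col),
            measure=measure,
            stratum=stratum,
            grid=grid,
            density=gaussian_kde_curve(vals[:, j], grid, bws[j]),
        )
        for j, col in enumerate(tab.columns)
    ]
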