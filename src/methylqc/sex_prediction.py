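"""Sex prediction from sex-chromosome copy-number dosage.

Females carry two X chromosomes and no Y, males one of each, so the
difference between the median log2 total intensity (copy number, M + U)
of chrY probes and that of chrX probes separates the sexes into two
well-spaced clusters.  The cutoff between clusters can be supplied
manually or found automatically by one-dimensional 2-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import QCSummary

AUTO = "AUTO"


@dataclass(frozen=True)
class SexCall:
    sample_id: str
    xy_diff: float
    predicted_sex: str  # "M" or "F"
    cutoff_used: float
    reported_sex: str = "NA"  # "M", "F" or "NA"
    mismatch: bool = False


def sex_difference(summary: QCSummary) -> pd.Series:
    """Per-sample log2(median CN chrY) - log2(median CN chrX).

    Medians are read from the stored p = 0.5 copy-number quantiles of the
    pooled sex-chromosome strata.
    """
    for stratum in ("chrX", "chrY"):
        if summary.is_empty_stratum(stratum):
            raise ValueError(
                f"stratum {stratum!r} is empty; sex prediction needs both chrX and chrY probes"
            )
    med_x = summary.quantile_at("chrX", "CN", 0.5)
    med_y = summary.quantile_at("chrY", "CN", 0.5)
    diffs = np.log2(med_y) - np.log2(med_x)
    diffs.name = "xy_diff"
    return diffs


def two_means_1d(values: np.ndarray) -> tuple[float, float]:
    """1-D 2-means with deterministic initialization at (min, max).

    Lloyd iterations to convergence; returns the two centers sorted
    ascending.  Raises when the values cannot form two clusters.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("automatic cutoff needs at least 2 samples")
    if np.ptp(v) == 0:
        raise ValueError("cannot separate clusters: all differences identical")
    lo, hi = float(v.min()), float(v.max())
    for _ in range(1000):
        # nearest-center assignment; midpoint acts as the boundary
        right = v >= (lo + hi) / 2.0
        new_lo = v[~right].mean() if (~right).any() else lo
        new_hi = v[right].mean() if right.any() else hi
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = float(new_lo), float(new_hi)
    return lo, hi


def predict_sex(diffs: pd.Series, cutoff: float | str = AUTO) -> list[SexCall]:
    """Threshold the chrY-minus-chrX differences into M/F calls.

    Manual mode thresholds at the given cutoff; AUTO mode runs 2-means and
    places the cutoff at the midpoint of the two centers, labelling the
    cluster with the larger center male.  A difference exactly equal to
    the cutoff is called male.
    """
    values = diffs.to_numpy(dtype=float)
    if isinstance(cutoff, str):
        if cutoff != AUTO:
            raise ValueError(f"cutoff must be a number or {AUTO!r}, got {cutoff!r}")
        lo, hi = two_means_1d(values)
        cut = (lo + hi) / 2.0
    else:
        cut = float(cutoff)
    return [
        SexCall(
            sample_id=str(s),
            xy_diff=float(d),
            predicted_sex="M" if d >= cut else "F",
            cutoff_used=cut,
        )
        for s, d in diffs.items()
    ]


def attach_reported_sex(calls: list[SexCall], phenotypes) -> list[SexCall]:
    """Fill ``reported_sex`` and ``mismatch`` from a phenotype table."""
    t = phenotypes.table
    reported = t["reported_sex"] if "reported_sex" in t.columns else pd.Series(dtype=object)
    out = []
    for c in calls:
        rep = reported.get(c.sample_id)
        rep = "NA" if rep is None or pd.isna(rep) else str(rep)
        out.append(
            SexCall(
                sample_id=c.sample_id,
                xy_diff=c.xy_diff,
                predicted_sex=c.predicted_sex,
                cutoff_used=c.cutoff_used,
                reported_sex=rep,
                mismatch=rep != "NA" and rep != c.predicted_sex,
            )
        )
    return out


def sex_mismatches(calls: list[SexCall]) -> list[SexCall]:
    """Calls whose reported sex is known and disagrees with the prediction."""
    return [c for c in calls if c.mismatch]


def calls_frame(calls: list[SexCall]) -> pd.DataFrame:
    """Tabular view: sample_id, xy_diff, predicted_sex, reported_sex, mismatch."""
    columns = ["sample_id", "xy_diff", "predicted_sex", "reported_sex", "mismatch"]
    if not calls:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "xy_diff": c.xy_diff,
                "predicted_sex": c.predicted_sex,
                "reported_sex": c.reported_sex,
                "mismatch": c.mismatch,
            }
            for c in calls
        ]
    )
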