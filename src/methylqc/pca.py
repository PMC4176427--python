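"""Principal component analysis of autosomal Beta values.

Batch and plate effects on 450k arrays typically dominate the leading
principal components of the most variable probes; projecting samples onto
those components and testing score/covariate association is the standard
first look at unwanted structure.  Probes are mean-centered but not
scaled: Beta values already share the [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_TOP = 20_000
SLIDE_ROWS = 6  # 450k slide geometry: 6 rows x 2 columns = 12 samples
SLIDE_COLS = 2


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray  # per retained component, non-increasing
    selected_probe_ids: list[str]
    n_top: int = DEFAULT_N_TOP

    def equals(self, other: "PCAResult") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.scores, other.scores)
            and np.array_equal(self.explained_variance_ratio, other.explained_variance_ratio)
            and list(self.selected_probe_ids) == list(other.selected_probe_ids)
            and self.n_top == other.n_top
        )


def select_top_variable(beta: pd.DataFrame, n_top: int = DEFAULT_N_TOP) -> list[str]:
    """IDs of the ``n_top`` probes with largest across-sample variance.

    Population (ddof=0) variance; ties at the boundary are broken by
    lexicographic probe ID so the selection is deterministic.  If fewer
    than ``n_top`` probes exist, all are returned (still variance-sorted).
    """
    if beta.shape[0] == 0:
        raise ValueError("empty Beta matrix")
    var = beta.to_numpy().var(axis=1, ddof=0)
    order = sorted(range(len(var)), key=lambda i: (-var[i], str(beta.index[i])))
    return [str(beta.index[i]) for i in order[: min(n_top, len(var))]]


def run_pca(beta_subset: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of a probes x samples Beta matrix via SVD of the centered data.

    Each probe is centered to mean zero across samples; no variance
    scaling.  Retains ``min(10, n_samples - 1)`` components by default.
    Component signs are fixed so the largest-magnitude entry of each score
    column is positive, making stored results reproducible bit-for-bit.
    """
    n_samples = beta_subset.shape[1]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = beta_subset.to_numpy(dtype=float).T  # samples x probes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total_var = float((s**2).sum())
    if n_components is None:
        n_components = min(10, n_samples - 1)
    n_components = min(n_components, len(s))
    scores = u[:, :n_components] * s[:n_components]
    # deterministic sign: largest-|entry| of each score column positive
    for j in range(scores.shape[1]):
        k = int(np.argmax(np.abs(scores[:, j])))
        if scores[k, j] < 0:
            scores[:, j] = -scores[:, j]
    if total_var > 0:
        ratio = (s[:n_components] ** 2) / total_var
    else:
        ratio = np.zeros(n_components)
    return PCAResult(
        sample_ids=[str(c) for c in beta_subset.columns],
        scores=scores,
        explained_variance_ratio=ratio,
        selected_probe_ids=[str(i) for i in beta_subset.index],
        n_top=beta_subset.shape[0],
    )


def pc_association(pca: PCAResult, covariate: Sequence) -> pd.DataFrame:
    """One-way ANOVA of each PC score column on a categorical covariate.

    Returns a frame indexed PC1.. with columns ``F``, ``p`` and
    ``degenerate``.  Perfect group separation (zero within-group variance
    with distinct means) yields infinite F; it is reported as p = 0 with
    the degenerate flag set.
    """
    cov = pd.Series(list(covariate), index=pca.sample_ids)
    levels = cov.dropna().unique()
    if len(levels) < 2:
        raise ValueError(f"covariate needs >= 2 levels, got {list(levels)}")
    counts = cov.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"each covariate level needs >= 2 samples; too small: {list(small.index)}")
    rows = []
    for j in range(pca.scores.shape[1]):
        groups = [pca.scores[(cov == lv).to_numpy(), j] for lv in levels]
        with np.errstate(divide="ignore", invalid="ignore"):
            f, p = stats.f_oneway(*groups)
        degenerate = False
        if not np.isfinite(f):
            means = [g.mean() for g in groups]
            if np.ptp(means) > 0:  # separated groups, zero within-variance
                f, p, degenerate = np.inf, 0.0, True
            else:  # all values identical
                f, p, degenerate = 0.0, 1.0, True
        rows.append({"F": float(f), "p": float(p), "degenerate": degenerate})
    return pd.DataFrame(rows, index=[f"PC{j + 1}" for j in range(len(rows))])


@dataclass
class ArrayLayout:
    """Physical slide positions (6 rows x 2 columns) with a covariate value
    per sample, for design-confounding displays."""

    table: pd.DataFrame  # index sample_id; columns slide, row, col, covariate


def array_layout(phenotypes, covariate: str) -> ArrayLayout:
    """Parse Sentrix positions ``R01C01``..``R06C02`` into slide coordinates."""
    t = phenotypes.table
    for col in ("slide", "array_position"):
        if col not in t.columns:
            raise ValueError(f"phenotypes lack required column {col!r}")
    if covariate not in t.columns:
        raise ValueError(
            f"covariate {covariate!r} not in phenotypes; available: {list(t.columns)}"
        )
    rows, cols = [], []
    for sample, pos in t["array_position"].items():
        m = None
        if isinstance(pos, str) and len(pos) == 6 and pos[0] == "R" and pos[3] == "C":
            try:
                m = (int(pos[1:3]), int(pos[4:6]))
            except ValueError:
                m = None
        if m is None:
            raise ValueError(f"malformed array_position {pos!r} for sample {sample!r}")
        r, c = m
        if not (1 <= r <= SLIDE_ROWS and 1 <= c <= SLIDE_COLS):
            raise ValueError(
                f"array_position {pos!r} for sample {sample!r} outside the "
                f"{SLIDE_ROWS}x{SLIDE_COLS} slide"
            )
        rows.append(r)
        cols.append(c)
    out = pd.DataFrame(
        {"slide": t["slide"], "row": rows, "col": cols, "covariate": t[covariate]},
        index=t.index,
    )
    dup = out.duplicated(subset=["slide", "row", "col"])
    if dup.any():
        raise ValueError(
            f"duplicate (slide, position) assignments for samples: {list(out.index[dup])}"
        )
    return ArrayLayout(table=out)
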