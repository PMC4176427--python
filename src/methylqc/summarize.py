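"""Intensity transforms and reduction of full matrices to compact summaries.

The raw array yields a methylated (M) and an unmethylated (U) intensity
per probe.  Derived measures:

* copy number      CN    = M + U
* Beta value       Beta  = M / (M + U + offset),        offset 100
* M-value          M-val = log2((M + eps) / (U + eps)), eps 1

For already-normalized Beta input the M-value is the logit,
log2(Beta / (1 - Beta)), with Beta clipped away from {0, 1}.

Summaries store, per sample, the quantile vector of each measure within
six probe strata: autosomal Infinium I split by color channel (IGrn,
IRed), autosomal Infinium II, pooled chrX, pooled chrY, and all-autosomal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pca as _pca
from .io import (
    STRATA,
    ControlTable,
    PhenotypeTable,
    ProbeManifest,
    QCSummary,
    SignalSet,
)

logger = logging.getLogger(__name__)

DEFAULT_BETA_OFFSET = 100.0
DEFAULT_MVALUE_EPSILON = 1.0
DEFAULT_N_QUANTILES = 500
#: clip bound for logit of normalized Beta values
NORMALIZED_LOGIT_CLIP = 1e-6


def _default_probs() -> np.ndarray:
    return np.linspace(0.0, 1.0, DEFAULT_N_QUANTILES)


@dataclass
class TransformParams:
    """Constants of the intensity transforms and the quantile grid."""

    beta_offset: float = DEFAULT_BETA_OFFSET
    mvalue_epsilon: float = DEFAULT_MVALUE_EPSILON
    quantile_probs: np.ndarray = field(default_factory=_default_probs)
    n_top_probes: int = _pca.DEFAULT_N_TOP

    def __post_init__(self) -> None:
        if self.beta_offset < 0:
            raise ValueError("beta_offset must be >= 0")
        if self.mvalue_epsilon <= 0:
            raise ValueError("mvalue_epsilon must be > 0")
        probs = np.asarray(self.quantile_probs, dtype=float)
        if probs[0] != 0.0 or probs[-1] != 1.0 or np.any(np.diff(probs) <= 0):
            raise ValueError("quantile_probs must be strictly increasing from 0 to 1")
        self.quantile_probs = probs

    def record(self) -> dict:
        return {
            "beta_offset": self.beta_offset,
            "mvalue_epsilon": self.mvalue_epsilon,
            "n_quantiles": int(len(self.quantile_probs)),
            "n_top_probes": int(self.n_top_probes),
            "normalized_logit_clip": NORMALIZED_LOGIT_CLIP,
        }


# ---------------------------------------------------------------------------
# elementwise transforms
# ---------------------------------------------------------------------------


def compute_cn(meth, unmeth):
    """Copy number CN = M + U, elementwise."""
    meth, unmeth = np.asarray(meth, dtype=float), np.asarray(unmeth, dtype=float)
    if meth.shape != unmeth.shape:
        raise ValueError(f"shape mismatch: {meth.shape} vs {unmeth.shape}")
    return meth + unmeth


def compute_beta(meth, unmeth, beta_offset: float = DEFAULT_BETA_OFFSET):
    """Beta = M / (M + U + offset); with offset 0 and M = U = 0 the value is 0."""
    if beta_offset < 0:
        raise ValueError("beta_offset must be >= 0")
    meth, unmeth = np.asarray(meth, dtype=float), np.asarray(unmeth, dtype=float)
    denom = meth + unmeth + beta_offset
    with np.errstate(invalid="ignore"):
        out = np.where(denom > 0, meth / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def compute_mvalue(meth, unmeth, mvalue_epsilon: float = DEFAULT_MVALUE_EPSILON):
    """M-value = log2((M + eps) / (U + eps)); antisymmetric in (M, U)."""
    if mvalue_epsilon <= 0:
        raise ValueError("mvalue_epsilon must be > 0")
    meth, unmeth = np.asarray(meth, dtype=float), np.asarray(unmeth, dtype=float)
    return np.log2(meth + mvalue_epsilon) - np.log2(unmeth + mvalue_epsilon)


def beta_to_mvalue(beta, clip: float = NORMALIZED_LOGIT_CLIP):
    """logit2 of Beta, with Beta clipped to [clip, 1 - clip]."""
    b = np.clip(np.asarray(beta, dtype=float), clip, 1.0 - clip)
    return np.log2(b) - np.log2(1.0 - b)


def quantile_summary(values, probs) -> np.ndarray:
    """Linear-interpolation (type-7) sample quantiles of a 1-D vector."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot summarize an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return np.quantile(values, np.asarray(probs, dtype=float), method="linear")


# ---------------------------------------------------------------------------
# stratified summarization
# ---------------------------------------------------------------------------


def _quantile_table(matrix: pd.DataFrame, probs: np.ndarray) -> pd.DataFrame:
    arr = np.quantile(matrix.to_numpy(dtype=float), probs, axis=0, method="linear")
    return pd.DataFrame(arr, index=probs, columns=list(matrix.columns))


def _stratify(
    measures: dict[str, pd.DataFrame],
    manifest: ProbeManifest,
    probs: np.ndarray,
) -> dict[str, dict[str, pd.DataFrame]]:
    quantiles: dict[str, dict[str, pd.DataFrame]] = {}
    probe_index = next(iter(measures.values())).index
    for stratum in STRATA:
        ids = probe_index.intersection(manifest.stratum_probes(stratum))
        if len(ids) == 0:
            logger.warning("stratum %s has zero probes; recorded as empty", stratum)
            quantiles[stratum] = {}
            continue
        quantiles[stratum] = {
            name: _quantile_table(mat.loc[ids], probs) for name, mat in measures.items()
        }
    return quantiles


def _check_manifest_covers(signals_index: pd.Index, manifest: ProbeManifest) -> None:
    missing = signals_index.difference(manifest.table.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} probes absent from manifest; first offenders: "
            f"{list(missing[:10])}"
        )


def summarize_controls(controls: ControlTable) -> pd.DataFrame:
    """Per (sample, control_type) mean green, mean red and combined mean."""
    t = controls.table
    if len(t) == 0:
        raise ValueError("control table is empty")
    g = (
        t.groupby(["sample_id", "control_type"], sort=True)[["green", "red"]]
        .mean()
        .reset_index()
        .rename(columns={"green": "mean_green", "red": "mean_red"})
    )
    g["mean_combined"] = (g["mean_green"] + g["mean_red"]) / 2.0
    return g


def summarize_raw(
    signals: SignalSet,
    manifest: ProbeManifest,
    controls: ControlTable,
    phenotypes: PhenotypeTable,
    params: TransformParams | None = None,
) -> QCSummary:
    """Reduce a raw experiment to its stratified quantile summary.

    Computes M, U, CN, Beta and M-value per probe, takes per-sample
    quantile vectors within each stratum, averages control intensities per
    control type, and runs PCA on the most variable autosomal Beta values.
    """
    params = params or TransformParams()
    _check_manifest_covers(signals.meth.index, manifest)
    sample_set = set(signals.sample_ids)
    for name, other in (
        ("phenotypes", set(phenotypes.sample_ids)),
        ("controls", set(controls.sample_ids)),
    ):
        diff = sample_set ^ other
        if diff:
            raise ValueError(f"sample sets differ between signals and {name}: {sorted(diff)}")

    meth, unmeth = signals.meth, signals.unmeth
    cols = list(meth.columns)
    measures = {
        "M": meth,
        "U": unmeth,
        "CN": pd.DataFrame(compute_cn(meth, unmeth), index=meth.index, columns=cols),
        "Beta": pd.DataFrame(
            compute_beta(meth, unmeth, params.beta_offset), index=meth.index, columns=cols
        ),
        "MValue": pd.DataFrame(
            compute_mvalue(meth, unmeth, params.mvalue_epsilon), index=meth.index, columns=cols
        ),
    }
    quantiles = _stratify(measures, manifest, params.quantile_probs)

    auto_ids = meth.index.intersection(manifest.stratum_probes("autosomal"))
    pca_result = None
    if len(auto_ids) and signals.n_samples >= 2:
        beta_auto = measures["Beta"].loc[auto_ids]
        top = _pca.select_top_variable(beta_auto, params.n_top_probes)
        pca_result = _pca.run_pca(beta_auto.loc[top])
        pca_result.n_top = int(params.n_top_probes)

    pheno = phenotypes.table.reindex(signals.sample_ids)
    return QCSummary(
        label="raw",
        sample_ids=signals.sample_ids,
        quantile_probs=params.quantile_probs,
        quantiles=quantiles,
        phenotypes=PhenotypeTable(table=pheno),
        controls=summarize_controls(controls),
        pca=pca_result,
        parameters=params.record(),
    )


def summarize_normalized(
    beta_norm: pd.DataFrame,
    manifest: ProbeManifest,
    phenotypes: PhenotypeTable,
    params: TransformParams | None = None,
) -> QCSummary:
    """Summarize an externally normalized Beta matrix (probes x samples).

    Only Beta and M-value (logit2 of Beta) strata are stored; raw channel
    measures and control summaries do not exist for normalized data.
    """
    params = params or TransformParams()
    arr = beta_norm.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("normalized Beta contains non-finite values")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("normalized Beta values must lie in [0, 1]")
    _check_manifest_covers(beta_norm.index, manifest)

    cols = list(beta_norm.columns)
    measures = {
        "Beta": beta_norm,
        "MValue": pd.DataFrame(beta_to_mvalue(arr), index=beta_norm.index, columns=cols),
    }
    quantiles = _stratify(measures, manifest, params.quantile_probs)

    auto_ids = beta_norm.index.intersection(manifest.stratum_probes("autosomal"))
    pca_result = None
    if len(auto_ids) and beta_norm.shape[1] >= 2:
        beta_auto = beta_norm.loc[auto_ids]
        top = _pca.select_top_variable(beta_auto, params.n_top_probes)
        pca_result = _pca.run_pca(beta_auto.loc[top])
        pca_result.n_top = int(params.n_top_probes)

    pheno = phenotypes.table.reindex(cols)
    return QCSummary(
        label="normalized",
        sample_ids=cols,
        quantile_probs=params.quantile_probs,
        quantiles=quantiles,
        phenotypes=PhenotypeTable(table=pheno),
        controls=None,
        pca=pca_result,
        parameters=params.record(),
    )
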