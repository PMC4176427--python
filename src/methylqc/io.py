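"""Readers, writers and domain containers for 450k-style QC data.

External files are RFC-4180 CSV or tab-separated UTF-8 text with a
mandatory header row; ``.`` or the empty string are the NA tokens.  The
compact QC summary is serialized as a single ``.zip`` archive holding a
``metadata.json`` document plus one TSV payload table per
(stratum, measure), with deterministic byte layout so that repeated
writes of the same summary are byte-identical.
"""

from __future__ import annotations

import io as _stdio
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pca import PCAResult

SCHEMA_VERSION = "1"

#: stratum vocabulary, in storage order.  Autosomal type-I probes are kept
#: separate by color channel; sex-chromosome strata pool both chemistries.
STRATA = ("IGrn", "IRed", "II", "chrX", "chrY", "autosomal")
RAW_MEASURES = ("M", "U", "CN", "Beta", "MValue")
NORMALIZED_MEASURES = ("Beta", "MValue")

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("chrX", "chrY")

_NA_TOKENS = ("", ".")


class FormatError(ValueError):
    """Raised when an input file violates the expected format or an invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class SignalSet:
    """Paired methylated/unmethylated intensity matrices (probes x samples)."""

    meth: pd.DataFrame
    unmeth: pd.DataFrame

    def __post_init__(self) -> None:
        if self.meth.shape != self.unmeth.shape:
            raise FormatError(
                f"meth shape {self.meth.shape} != unmeth shape {self.unmeth.shape}"
            )
        if not self.meth.index.equals(self.unmeth.index):
            raise FormatError("meth and unmeth probe IDs differ")
        if not self.meth.columns.equals(self.unmeth.columns):
            raise FormatError("meth and unmeth sample IDs differ")
        for name, df in (("meth", self.meth), ("unmeth", self.unmeth)):
            _check_intensity_frame(df, name)
        if self.meth.index.has_duplicates:
            dups = self.meth.index[self.meth.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe IDs: {dups[:10]}")
        if self.meth.columns.has_duplicates:
            dups = self.meth.columns[self.meth.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups[:10]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.meth.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def n_probes(self) -> int:
        return self.meth.shape[0]

    @property
    def n_samples(self) -> int:
        return self.meth.shape[1]


@dataclass
class ProbeManifest:
    """Per-probe chemistry type, color channel and chromosome.

    ``channel`` is ``None`` exactly for Infinium II probes, which read out
    in both colors.
    """

    table: pd.DataFrame  # index: probe_id; columns: infinium_type, channel, chromosome

    def __post_init__(self) -> None:
        t = self.table
        required = {"infinium_type", "channel", "chromosome"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe IDs in manifest: {dups[:10]}")
        bad_type = t.index[~t["infinium_type"].isin(["I", "II"])]
        if len(bad_type):
            raise FormatError(f"infinium_type must be I or II; offenders: {list(bad_type[:10])}")
        bad_chrom = t.index[~t["chromosome"].isin(CHROMOSOMES)]
        if len(bad_chrom):
            raise FormatError(f"unknown chromosome for probes: {list(bad_chrom[:10])}")
        is_ii = t["infinium_type"] == "II"
        ch = t["channel"]
        bad_ii = t.index[is_ii & ch.notna()]
        if len(bad_ii):
            raise FormatError(
                f"type II probes must have channel NA; offenders: {list(bad_ii[:10])}"
            )
        bad_i = t.index[~is_ii & ~ch.isin(["Grn", "Red"])]
        if len(bad_i):
            raise FormatError(
                f"type I probes need channel Grn or Red; offenders: {list(bad_i[:10])}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def stratum_probes(self, stratum: str) -> pd.Index:
        """Probe IDs belonging to a stratum of the fixed vocabulary."""
        t = self.table
        if stratum == "autosomal":
            return t.index[t["chromosome"].isin(AUTOSOMES)]
        if stratum in ("chrX", "chrY"):
            return t.index[t["chromosome"] == stratum]
        auto = t["chromosome"].isin(AUTOSOMES)
        if stratum == "II":
            return t.index[auto & (t["infinium_type"] == "II")]
        if stratum == "IGrn":
            return t.index[auto & (t["infinium_type"] == "I") & (t["channel"] == "Grn")]
        if stratum == "IRed":
            return t.index[auto & (t["infinium_type"] == "I") & (t["channel"] == "Red")]
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


@dataclass
class ControlTable:
    """Long-format control-probe intensities: one row per (control, sample)."""

    table: pd.DataFrame  # columns: control_id, control_type, sample_id, green, red

    def __post_init__(self) -> None:
        t = self.table
        required = {"control_id", "control_type", "sample_id", "green", "red"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"control table missing columns: {sorted(missing)}")
        for col in ("green", "red"):
            vals = t[col].to_numpy()
            if not np.issubdtype(vals.dtype, np.number):
                raise FormatError(f"control {col} intensities must be numeric")
            if not np.all(np.isfinite(vals)):
                raise FormatError(f"non-finite control {col} intensity")
            if np.any(vals < 0):
                raise FormatError(f"negative control {col} intensity")
        dup = t.duplicated(subset=["control_id", "sample_id"])
        if dup.any():
            pairs = t.loc[dup, ["control_id", "sample_id"]].to_records(index=False)
            raise FormatError(f"duplicate (control_id, sample) pairs: {list(pairs[:10])}")

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.table["sample_id"]))


@dataclass
class PhenotypeTable:
    """Sample covariates; ``reported_sex``, ``slide`` and ``array_position``
    are reserved optional columns."""

    table: pd.DataFrame  # index: sample_id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs in phenotypes: {dups[:10]}")
        if "reported_sex" in self.table.columns:
            sex = self.table["reported_sex"]
            bad = self.table.index[~(sex.isin(["M", "F"]) | sex.isna())]
            if len(bad):
                raise FormatError(
                    f"reported_sex must be M, F or NA; offenders: {list(bad[:10])}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class QCSummary:
    """Compact probe-type-stratified summary of a 450k experiment.

    Stores, per stratum and measure, a quantile table (probabilities x
    samples) instead of the full probe-level matrices, so the archive size
    scales with sample count and quantile-grid size only.
    """

    label: str  # "raw" or "normalized"
    sample_ids: list[str]
    quantile_probs: np.ndarray
    quantiles: dict[str, dict[str, pd.DataFrame]]  # stratum -> measure -> table
    phenotypes: PhenotypeTable
    controls: pd.DataFrame | None = None  # sample_id, control_type, mean_green, mean_red, mean_combined
    pca: PCAResult | None = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("raw", "normalized"):
            raise ValueError(f"label must be 'raw' or 'normalized', got {self.label!r}")
        probs = np.asarray(self.quantile_probs, dtype=float)
        if probs.ndim != 1 or len(probs) < 2:
            raise ValueError("quantile_probs must be a 1-D grid")
        if probs[0] != 0.0 or probs[-1] != 1.0 or np.any(np.diff(probs) <= 0):
            raise ValueError("quantile_probs must be strictly increasing from 0 to 1")
        self.quantile_probs = probs
        for stratum, measures in self.quantiles.items():
            for measure, tab in measures.items():
                if list(tab.columns) != list(self.sample_ids):
                    raise ValueError(
                        f"{stratum}/{measure}: columns do not match sample_ids"
                    )
                arr = tab.to_numpy()
                if arr.shape[0] != len(probs):
                    raise ValueError(f"{stratum}/{measure}: wrong number of rows")
                if np.any(np.diff(arr, axis=0) < 0):
                    raise ValueError(f"{stratum}/{measure}: quantiles not non-decreasing")
                if measure == "Beta" and (arr.min() < 0 or arr.max() > 1):
                    raise ValueError(f"{stratum}/Beta: quantiles outside [0, 1]")
                if measure in ("M", "U", "CN") and arr.min() < 0:
                    raise ValueError(f"{stratum}/{measure}: negative quantiles")

    @property
    def strata(self) -> list[str]:
        return list(self.quantiles)

    def measures(self, stratum: str) -> list[str]:
        return list(self.quantiles[stratum])

    def is_empty_stratum(self, stratum: str) -> bool:
        return len(self.quantiles.get(stratum, {})) == 0

    def quantile_at(self, stratum: str, measure: str, prob: float) -> pd.Series:
        """Per-sample quantile at probability ``prob``, interpolated on the
        stored grid when ``prob`` is not a grid point."""
        if self.is_empty_stratum(stratum):
            raise ValueError(f"stratum {stratum!r} is empty")
        tab = self.quantiles[stratum][measure]
        probs = self.quantile_probs
        vals = tab.to_numpy()
        out = np.array([np.interp(prob, probs, vals[:, j]) for j in range(vals.shape[1])])
        return pd.Series(out, index=tab.columns, name=f"{measure}@{prob}")

    def equals(self, other: "QCSummary") -> bool:
        """Field-for-field equality, floating point compared bit-identically."""
        if self.label != other.label or self.sample_ids != other.sample_ids:
            return False
        if not np.array_equal(self.quantile_probs, other.quantile_probs):
            return False
        if self.parameters != other.parameters:
            return False
        if self.strata != other.strata:
            return False
        for stratum in self.strata:
            if self.measures(stratum) != other.measures(stratum):
                return False
            for measure in self.measures(stratum):
                a, b = self.quantiles[stratum][measure], other.quantiles[stratum][measure]
                if list(a.columns) != list(b.columns) or not np.array_equal(
                    a.to_numpy(), b.to_numpy()
                ):
                    return False
        if (self.controls is None) != (other.controls is None):
            return False
        if self.controls is not None and not self.controls.equals(other.controls):
            return False
        if (self.pca is None) != (other.pca is None):
            return False
        if self.pca is not None and not self.pca.equals(other.pca):
            return False
        return self.phenotypes.table.equals(other.phenotypes.table)


# ---------------------------------------------------------------------------
# flat-file readers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=index_col,
        float_precision="round_trip",
        na_values=list(_NA_TOKENS),
        keep_default_na=False,
    )


def _check_intensity_frame(df: pd.DataFrame, name: str) -> None:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        raise FormatError(f"{name}: non-numeric intensity column(s): {list(bad[:10])}")
    finite = np.isfinite(arr)
    if not finite.all():
        i, j = np.argwhere(~finite)[0]
        raise FormatError(
            f"{name}: missing or non-finite intensity at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{name}: negative intensity at probe {df.index[i]!r}, sample {df.columns[j]!r}"
        )


def read_signal_set(meth_path: str | Path, unmeth_path: str | Path) -> SignalSet:
    """Read paired M/U matrices; probe/sample order is taken from the meth
    file and the unmeth matrix is reindexed to match by ID."""
    meth = _read_table(meth_path, index_col=0)
    unmeth = _read_table(unmeth_path, index_col=0)
    sym_samples = set(meth.columns) ^ set(unmeth.columns)
    if sym_samples:
        raise FormatError(f"sample sets differ between meth and unmeth: {sorted(sym_samples)}")
    sym_probes = set(meth.index) ^ set(unmeth.index)
    if sym_probes:
        raise FormatError(
            f"probe sets differ between meth and unmeth: {sorted(sym_probes)[:10]}"
        )
    unmeth = unmeth.reindex(index=meth.index, columns=meth.columns)
    return SignalSet(meth=_coerce_numeric(meth, "meth"), unmeth=_coerce_numeric(unmeth, "unmeth"))


def _coerce_numeric(df: pd.DataFrame, name: str) -> pd.DataFrame:
    try:
        return df.astype(float)
    except (ValueError, TypeError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise FormatError(
                    f"{name}: non-numeric intensity at probe {df.index[bad.argmax()]!r}, "
                    f"sample {col!r}"
                ) from None
        raise


_CHROM_ALIASES = {c.removeprefix("chr"): c for c in CHROMOSOMES}


def read_manifest(path: str | Path) -> ProbeManifest:
    """Read a probe manifest, normalizing bare chromosome tokens to the
    ``chr``-prefixed vocabulary (``X`` -> ``chrX``)."""
    t = _read_table(path)
    if "probe_id" not in t.columns:
        raise FormatError("manifest must have a probe_id column")
    t = t.set_index("probe_id")
    chrom = t["chromosome"].astype(str).map(lambda c: _CHROM_ALIASES.get(c, c))
    t = t.assign(chromosome=chrom)
    t["channel"] = t["channel"].where(t["channel"].notna(), None)
    return ProbeManifest(table=t)


def read_controls(path: str | Path) -> ControlTable:
    return ControlTable(table=_read_table(path))


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    t = _read_table(path)
    if "sample_id" not in t.columns:
        raise FormatError("phenotype table must have a sample_id column")
    return PhenotypeTable(table=t.set_index("sample_id"))


def export_sample_list(
    sample_ids: Sequence[str],
    reason: str,
    path: str | Path,
    *,
    known: Iterable[str] | None = None,
) -> None:
    """Write a ``sample_id,reason`` CSV for exclusion in downstream analyses.

    When ``known`` is given, every exported ID must belong to it.
    """
    if known is not None:
        unknown = [s for s in sample_ids if s not in set(known)]
        if unknown:
            raise FormatError(f"unknown sample IDs: {unknown}")
    lines = ["sample_id,reason"] + [f"{s},{reason}" for s in sample_ids]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# summary archive
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    # repr of a Python float is the shortest string that round-trips exactly
    return repr(float(x))


def _frame_to_tsv(df: pd.DataFrame, index_name: str) -> str:
    out = _stdio.StringIO()
    out.write(index_name + "\t" + "\t".join(str(c) for c in df.columns) + "\n")
    arr = df.to_numpy()
    idx = list(df.index)
    numeric = np.issubdtype(arr.dtype, np.number)
    for i in range(arr.shape[0]):
        cells = [
            _fmt(v) if numeric or isinstance(v, float) else ("" if pd.isna(v) else str(v))
            for v in arr[i]
        ]
        out.write(str(idx[i]) + "\t" + "\t".join(cells) + "\n")
    return out.getvalue()


def _mixed_to_tsv(df: pd.DataFrame, index_name: str) -> str:
    out = _stdio.StringIO()
    out.write(index_name + "\t" + "\t".join(str(c) for c in df.columns) + "\n")
    for idx, row in df.iterrows():
        cells = []
        for v in row:
            if pd.isna(v):
                cells.append("")
            elif isinstance(v, (float, np.floating)):
                cells.append(_fmt(v))
            else:
                cells.append(str(v))
        out.write(str(idx) + "\t" + "\t".join(cells) + "\n")
    return out.getvalue()


def _zip_writestr(zf: zipfile.ZipFile, name: str, data: str) -> None:
    # fixed timestamp so repeated writes are byte-identical
    info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
    info.compress_type = zipfile.ZIP_DEFLATED
    info.external_attr = 0o644 << 16
    zf.writestr(info, data.encode("utf-8"))


def write_summary(summary: QCSummary, path: str | Path) -> None:
    """Serialize a :class:`QCSummary` to a deterministic zip archive."""
    meta = {
        "schema_version": SCHEMA_VERSION,
        "label": summary.label,
        "parameters": summary.parameters,
        "sample_ids": list(summary.sample_ids),
        "quantile_probs": [_fmt(p) for p in summary.quantile_probs],
        "strata": [[s, summary.measures(s)] for s in summary.strata],
        "has_controls": summary.controls is not None,
        "has_pca": summary.pca is not None,
        "phenotype_dtypes": {
            str(c): _dtype_kind(summary.phenotypes.table[c])
            for c in summary.phenotypes.table.columns
        },
    }
    with zipfile.ZipFile(path, "w") as zf:
        _zip_writestr(zf, "metadata.json", json.dumps(meta, indent=1, sort_keys=True))
        for stratum in summary.strata:
            for measure in summary.measures(stratum):
                tab = summary.quantiles[stratum][measure]
                _zip_writestr(zf, f"quantiles/{stratum}__{measure}.tsv", _frame_to_tsv(tab, "prob"))
        if summary.controls is not None:
            _zip_writestr(
                zf,
                "controls.tsv",
                _mixed_to_tsv(summary.controls.reset_index(drop=True), "row"),
            )
        _zip_writestr(zf, "phenotypes.tsv", _mixed_to_tsv(summary.phenotypes.table, "sample_id"))
        if summary.pca is not None:
            p = summary.pca
            scores = pd.DataFrame(
                p.scores,
                index=p.sample_ids,
                columns=[f"PC{i + 1}" for i in range(p.scores.shape[1])],
            )
            _zip_writestr(zf, "pca/scores.tsv", _frame_to_tsv(scores, "sample_id"))
            var = pd.DataFrame(
                {"explained_variance_ratio": p.explained_variance_ratio},
                index=[f"PC{i + 1}" for i in range(len(p.explained_variance_ratio))],
            )
            _zip_writestr(zf, "pca/variance.tsv", _frame_to_tsv(var, "component"))
            _zip_writestr(
                zf,
                "pca/selected_probes.txt",
                "\n".join([str(p.n_top)] + list(p.selected_probe_ids)) + "\n",
            )


def _dtype_kind(col: pd.Series) -> str:
    kind = col.dtype.kind
    return {"f": "float", "i": "int", "u": "int", "b": "bool"}.get(kind, "str")


def _restore_dtype(col: pd.Series, kind: str) -> pd.Series:
    if kind == "float":
        return col.astype(float)
    if kind == "int":
        return col.astype("int64")
    if kind == "bool":
        return col.map({"True": True, "False": False}) if col.dtype == object else col.astype(bool)
    # str: undo any numeric inference, keeping NA as NA
    return col.where(col.isna(), col.astype(str)).astype(object)


def _read_member(zf: zipfile.ZipFile, name: str) -> str:
    try:
        return zf.read(name).decode("utf-8")
    except KeyError:
        raise FormatError(f"summary archive is missing member {name!r}") from None


def _tsv_to_frame(text: str, numeric: bool) -> pd.DataFrame:
    df = pd.read_csv(
        _stdio.StringIO(text),
        sep="\t",
        index_col=0,
        float_precision="round_trip",
        na_values=list(_NA_TOKENS),
        keep_default_na=False,
    )
    if numeric:
        df = df.astype(float)
    return df


def read_summary(path: str | Path) -> QCSummary:
    """Read a summary archive written by :func:`write_summary`."""
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(_read_member(zf, "metadata.json"))
        if meta.get("schema_version") != SCHEMA_VERSION:
            raise FormatError(
                f"summary schema version {meta.get('schema_version')!r} != {SCHEMA_VERSION!r}"
            )
        probs = np.array([float(p) for p in meta["quantile_probs"]])
        quantiles: dict[str, dict[str, pd.DataFrame]] = {}
        for stratum, measures in meta["strata"]:
            quantiles[stratum] = {}
            for measure in measures:
                text = _read_member(zf, f"quantiles/{stratum}__{measure}.tsv")
                tab = _tsv_to_frame(text, numeric=True)
                tab.columns = [str(c) for c in tab.columns]
                quantiles[stratum][measure] = tab
        controls = None
        if meta["has_controls"]:
            controls = _tsv_to_frame(_read_member(zf, "controls.tsv"), numeric=False)
            controls = controls.reset_index(drop=True)
            for col in ("sample_id", "control_type"):
                controls[col] = controls[col].astype(str)
            for col in ("mean_green", "mean_red", "mean_combined"):
                controls[col] = controls[col].astype(float)
        pheno = _tsv_to_frame(_read_member(zf, "phenotypes.tsv"), numeric=False)
        pheno.index = pheno.index.astype(str)
        for col, kind in meta.get("phenotype_dtypes", {}).items():
            pheno[col] = _restore_dtype(pheno[col], kind)
        pca = None
        if meta["has_pca"]:
            scores = _tsv_to_frame(_read_member(zf, "pca/scores.tsv"), numeric=True)
            var = _tsv_to_frame(_read_member(zf, "pca/variance.tsv"), numeric=True)
            probe_lines = _read_member(zf, "pca/selected_probes.txt").splitlines()
            pca = PCAResult(
                sample_ids=[str(s) for s in scores.index],
                scores=scores.to_numpy(),
                explained_variance_ratio=var["explained_variance_ratio"].to_numpy(),
                selected_probe_ids=probe_lines[1:],
                n_top=int(probe_lines[0]),
            )
    return QCSummary(
        label=meta["label"],
        sample_ids=[str(s) for s in meta["sample_ids"]],
        quantile_probs=probs,
        quantiles=quantiles,
        phenotypes=PhenotypeTable(table=pheno),
        controls=controls,
        pca=pca,
        parameters=meta["parameters"],
    )
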