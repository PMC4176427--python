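"""Seeded generator of 450k-like datasets for tests and demos.

The generator emulates the structure the QC pipeline assumes: probes on
autosomes and sex chromosomes in two Infinium chemistries, a trimodal
methylation landscape (unmethylated, hemimethylated, methylated CpGs),
multiplicative lognormal intensity noise, X/Y dosage differences between
the sexes, additive Beta-scale batch shifts, globally dimmed low-quality
arrays, and negative control probes near background.  A truth record
carries every injected effect so recovery tests never peek at internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ControlTable, PhenotypeTable, ProbeManifest, SignalSet

_LN2 = float(np.log(2.0))

#: Beta mixture: modes and weights of the unmethylated / methylated /
#: hemimethylated CpG populations
BETA_MODES = (0.1, 0.9, 0.5)
BETA_WEIGHTS = (0.45, 0.45, 0.10)
BETA_MODE_SD = 0.03
#: log2-sd of per-probe brightness around the baseline intensity
PROBE_CN_SD_LOG2 = 0.5
#: negative controls sit near background, ~2% of the baseline
NEGATIVE_CONTROL_FRACTION = 0.02
N_NEGATIVE_CONTROLS = 60
N_BISULFITE_CONTROLS = 10


@dataclass
class SimParams:
    """Knobs of the simulated study; defaults give a clean mid-size cohort."""

    n_probes_autosomal: int = 2000
    n_probes_x: int = 300
    n_probes_y: int = 100
    fraction_type1: float = 0.3
    n_samples: int = 8
    sex_vector: Sequence[str] | None = None  # explicit "M"/"F" per sample
    sex_ratio: float = 0.5  # fraction male when sex_vector is None
    batch_labels: Sequence[str] | None = None  # per-sample; None = single batch
    batch_shift_beta: float = 0.0
    batch_probe_fraction: float = 0.0
    sex_log2_shift: float = 1.5  # chrY copy-number separation, log2 units
    noise_sd_log2: float = 0.3
    baseline_intensity: float = 5000.0
    n_low_quality: int = 0
    low_quality_factor: float = 0.15
    n_sex_flips: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_type1", "sex_ratio", "batch_probe_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.low_quality_factor < 1.0:
            raise ValueError("low_quality_factor must be in (0, 1)")
        for name in (
            "n_probes_autosomal",
            "n_probes_x",
            "n_probes_y",
            "n_samples",
            "n_low_quality",
            "n_sex_flips",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")
        if self.n_sex_flips > self.n_samples:
            raise ValueError("n_sex_flips cannot exceed n_samples")
        if self.batch_labels is not None and len(self.batch_labels) != self.n_samples:
            raise ValueError("batch_labels must have one entry per sample")
        if self.sex_vector is not None and len(self.sex_vector) != self.n_samples:
            raise ValueError("sex_vector must have one entry per sample")


@dataclass
class SimulatedDataset:
    signals: SignalSet
    manifest: ProbeManifest
    controls: ControlTable
    phenotypes: PhenotypeTable
    truth: dict = field(default_factory=dict)


def _make_manifest(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_probes_autosomal + params.n_probes_x + params.n_probes_y
    probe_ids = [f"cg{i:07d}" for i in range(n)]
    chroms = (
        [f"chr{(i % 22) + 1}" for i in range(params.n_probes_autosomal)]
        + ["chrX"] * params.n_probes_x
        + ["chrY"] * params.n_probes_y
    )
    is_type1 = rng.random(n) < params.fraction_type1
    channel: list[str | None] = []
    flip = 0
    types = []
    for t1 in is_type1:
        if t1:
            types.append("I")
            channel.append("Grn" if flip % 2 == 0 else "Red")
            flip += 1
        else:
            types.append("II")
            channel.append(None)
    return pd.DataFrame(
        {"infinium_type": types, "channel": channel, "chromosome": chroms},
        index=pd.Index(probe_ids, name="probe_id"),
    )


def generate_dataset(params: SimParams) -> SimulatedDataset:
    """Generate one cohort; identical params (incl. seed) give identical data.

    Draw order is fixed — probes, then samples, then controls — so the
    whole dataset is reproducible from the single seed.
    """
    rng = np.random.default_rng(params.seed)
    n_samples = params.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]

    # --- probes ---
    manifest = _make_manifest(params, rng)
    n_probes = len(manifest)
    mode_idx = rng.choice(len(BETA_MODES), size=n_probes, p=BETA_WEIGHTS)
    beta_probe = np.clip(
        np.array(BETA_MODES)[mode_idx] + rng.normal(0.0, BETA_MODE_SD, n_probes),
        0.001,
        0.999,
    )
    cn_probe = params.baseline_intensity * np.exp(
        rng.normal(0.0, PROBE_CN_SD_LOG2 * _LN2, n_probes)
    )
    autosomal = manifest["chromosome"].str.removeprefix("chr").str.isdigit().to_numpy()
    n_batch_probes = int(round(params.batch_probe_fraction * autosomal.sum()))
    batch_probe_idx = rng.choice(np.flatnonzero(autosomal), size=n_batch_probes, replace=False)
    batch_probe_mask = np.zeros(n_probes, dtype=bool)
    batch_probe_mask[batch_probe_idx] = True

    # --- samples ---
    if params.sex_vector is not None:
        true_sex = np.array(list(params.sex_vector))
    else:
        n_male = int(round(params.sex_ratio * n_samples))
        true_sex = np.array(["M"] * n_male + ["F"] * (n_samples - n_male))
        rng.shuffle(true_sex)
    batch = (
        np.array(list(params.batch_labels))
        if params.batch_labels is not None
        else np.array(["B1"] * n_samples)
    )
    batch_levels = list(dict.fromkeys(batch))
    in_second_batch = batch == batch_levels[1] if len(batch_levels) > 1 else np.zeros(n_samples, bool)

    beta = np.tile(beta_probe[:, None], (1, n_samples))
    if params.batch_shift_beta != 0.0 and in_second_batch.any():
        shifted = np.ix_(batch_probe_mask, in_second_batch)
        beta[shifted] = np.clip(beta[shifted] + params.batch_shift_beta, 0.0, 1.0)

    cn = np.tile(cn_probe[:, None], (1, n_samples))
    is_male = true_sex == "M"
    is_y = (manifest["chromosome"] == "chrY").to_numpy()
    is_x = (manifest["chromosome"] == "chrX").to_numpy()
    cn[np.ix_(is_y, is_male)] *= 2.0**params.sex_log2_shift
    cn[np.ix_(is_x, is_male)] *= 0.5

    sigma = params.noise_sd_log2 * _LN2
    eps_m = rng.normal(0.0, sigma, (n_probes, n_samples))
    eps_u = rng.normal(0.0, sigma, (n_probes, n_samples))
    meth = cn * beta * np.exp(eps_m)
    unmeth = cn * (1.0 - beta) * np.exp(eps_u)

    low_quality_ids: list[str] = []
    if params.n_low_quality > 0:
        lq = rng.choice(n_samples, size=params.n_low_quality, replace=False)
        meth[:, lq] *= params.low_quality_factor
        unmeth[:, lq] *= params.low_quality_factor
        low_quality_ids = sorted(sample_ids[i] for i in lq)

    reported = true_sex.copy()
    flipped_ids: list[str] = []
    if params.n_sex_flips > 0:
        fl = rng.choice(n_samples, size=params.n_sex_flips, replace=False)
        for i in fl:
            reported[i] = "F" if reported[i] == "M" else "M"
        flipped_ids = sorted(sample_ids[i] for i in fl)

    # --- controls ---
    neg_level = NEGATIVE_CONTROL_FRACTION * params.baseline_intensity
    rows = []
    for k in range(N_NEGATIVE_CONTROLS):
        g = neg_level * np.exp(rng.normal(0.0, sigma, n_samples))
        r = neg_level * np.exp(rng.normal(0.0, sigma, n_samples))
        for j, s in enumerate(sample_ids):
            rows.append((f"neg{k:03d}", "NEGATIVE", s, g[j], r[j]))
    for k in range(N_BISULFITE_CONTROLS):
        g = params.baseline_intensity * np.exp(rng.normal(0.0, sigma, n_samples))
        r = params.baseline_intensity * np.exp(rng.normal(0.0, sigma, n_samples))
        for j, s in enumerate(sample_ids):
            rows.append((f"bsc{k:03d}", "BISULFITE_CONVERSION_I", s, g[j], r[j]))
    controls = pd.DataFrame(
        rows, columns=["control_id", "control_type", "sample_id", "green", "red"]
    )
    if params.n_low_quality > 0:
        dim = controls["sample_id"].isin(low_quality_ids)
        controls.loc[dim, ["green", "red"]] *= params.low_quality_factor

    # --- phenotypes: slide layout fills 6x2 slides in sample order ---
    slides = [f"6800{i // 12 + 1:04d}" for i in range(n_samples)]
    positions = [f"R{(i % 12) % 6 + 1:02d}C{(i % 12) // 6 + 1:02d}" for i in range(n_samples)]
    phenotypes = pd.DataFrame(
        {
            "reported_sex": reported,
            "plate": batch,
            "slide": slides,
            "array_position": positions,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth = {
        "true_sex": dict(zip(sample_ids, true_sex.tolist())),
        "flipped_samples": flipped_ids,
        "low_quality_samples": low_quality_ids,
        "batch_labels": dict(zip(sample_ids, batch.tolist())),
        "batch_probe_ids": sorted(manifest.index[batch_probe_mask].tolist()),
        "seed": params.seed,
    }

    cols = pd.Index(sample_ids)
    return SimulatedDataset(
        signals=SignalSet(
            meth=pd.DataFrame(meth, index=manifest.index, columns=cols),
            unmeth=pd.DataFrame(unmeth, index=manifest.index, columns=cols),
        ),
        manifest=ProbeManifest(table=manifest),
        controls=ControlTable(table=controls),
        phenotypes=PhenotypeTable(table=phenotypes),
        truth=truth,
    )


PRESETS = {
    # minimal clean cohort: no batch, no flips, no failures
    "clean_small": SimParams(
        n_probes_autosomal=1600,
        n_probes_x=300,
        n_probes_y=100,
        n_samples=8,
        seed=11,
    ),
    # two ten-sample plates with a Beta-scale batch shift on 30% of probes
    "fig2_batch": SimParams(
        n_probes_autosomal=4000,
        n_probes_x=300,
        n_probes_y=100,
        n_samples=20,
        batch_labels=["P1"] * 10 + ["P2"] * 10,
        batch_shift_beta=0.1,
        batch_probe_fraction=0.3,
        seed=22,
    ),
    # 40-sample sex-prediction cohort with one mislabelled sample
    "fig4_sex": SimParams(
        n_probes_autosomal=2000,
        n_probes_x=400,
        n_probes_y=150,
        n_samples=40,
        sex_log2_shift=1.5,
        noise_sd_log2=0.3,
        n_sex_flips=1,
        seed=44,
    ),
}


def preset(name: str, seed: int | None = None) -> SimParams:
    """A documented parameter bundle; ``seed`` overrides the preset's own."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    params = PRESETS[name]
    return replace(params) if seed is None else replace(params, seed=seed)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset in the flat-file formats the io readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "meth": out / "meth.tsv",
        "unmeth": out / "unmeth.tsv",
        "manifest": out / "manifest.tsv",
        "controls": out / "controls.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.json",
    }
    dataset.signals.meth.rename_axis("probe_id").to_csv(paths["meth"], sep="\t")
    dataset.signals.unmeth.rename_axis("probe_id").to_csv(paths["unmeth"], sep="\t")
    man = dataset.manifest.table.copy()
    man["channel"] = man["channel"].fillna("")
    man.rename_axis("probe_id").to_csv(paths["manifest"], sep="\t")
    dataset.controls.table.to_csv(paths["controls"], sep="\t", index=False)
    dataset.phenotypes.table.rename_axis("sample_id").to_csv(paths["phenotypes"], sep="\t")
    paths["truth"].write_text(json.dumps(dataset.truth, indent=1, sort_keys=True))
    return paths
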