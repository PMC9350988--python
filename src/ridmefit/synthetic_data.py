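"""Synthetic titration datasets with the statistical structure of a
low-concentration RIDME binding study.

The default emulation: one pseudo-titration series at 100 nM protein and
two replicate series at 50 nM, each with ten log-spaced Cu(II)-NTA
concentrations from 100 nM to 8.1 uM, roughly 60 h signal averaging per
sample, and per-trace white noise scaling inversely with the detected
spin concentration and with the square root of averaging time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import dipolar_core as dc
from .binding_analysis import fraction_bound
from .errors import DomainError

#: Reference RMS noise of a normalised trace at ``CONC_REF`` spin
#: concentration and ``TIME_REF_H`` of averaging.  Calibration constant
#: chosen so the default 100 nM series has mean sensitivity ~ 20; it is
#: not an experimentally reported value.
NOISE_REF_DEFAULT = 0.0146
CONC_REF_M = 1.0e-7
TIME_REF_H = 60.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Complete recipe for one synthetic titration series."""

    protein_total: float                    # M
    ligand_concs: Tuple[float, ...]         # M
    true_kd: float = 7.0e-8                 # M
    true_delta_max: float = 0.35
    dist_mean: float = 2.5                  # nm
    dist_sd: float = 0.15                   # nm
    bg_k: float = 0.05                      # us^(-d/3)
    bg_d: float = 3.0
    noise_ref: float = NOISE_REF_DEFAULT
    conc_ref: float = CONC_REF_M            # M
    time_ref_h: float = TIME_REF_H
    averaging_time_h: float = 60.0
    t_max: float = 2.5                      # us
    dt: float = dc.DEFAULT_DT_US            # us
    r_min: float = dc.DEFAULT_R_MIN_NM
    r_max: float = dc.DEFAULT_R_MAX_NM
    dr: float = dc.DEFAULT_DR_NM
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        lig = tuple(float(x) for x in self.ligand_concs)
        object.__setattr__(self, "ligand_concs", lig)
        if self.protein_total <= 0 or any(x <= 0 for x in lig):
            raise DomainError("all concentrations must be positive")
        if not 4 <= len(lig) <= 20:
            raise DomainError("need between 4 and 20 ligand concentrations")


def default_designs(seed: int = 1, true_kd: float = 7.0e-8,
                    true_delta_max: float = 0.35,
                    noise_ref: float = NOISE_REF_DEFAULT
                    ) -> List[ExperimentDesign]:
    """The three-series emulation: 100 nM once, 50 nM twice.

    Each series titrates ten log-spaced ligand concentrations from
    1e-7 to 8.1e-6 M at ~60 h averaging per sample, with distinct seeds
    derived from ``seed``.
    """
    ligands = tuple(np.logspace(np.log10(1.0e-7), np.log10(8.1e-6), 10))
    common = dict(ligand_concs=ligands, true_kd=true_kd,
                  true_delta_max=true_delta_max, noise_ref=noise_ref)
    return [
        ExperimentDesign(protein_total=1.0e-7, seed=seed, label="100nM",
                         **common),
        ExperimentDesign(protein_total=5.0e-8, seed=seed + 1, label="50nM_a",
                         **common),
        ExperimentDesign(protein_total=5.0e-8, seed=seed + 2, label="50nM_b",
                         **common),
    ]


def noise_model(spin_conc: float, averaging_time: float,
                noise_ref: float = NOISE_REF_DEFAULT,
                conc_ref: float = CONC_REF_M,
                time_ref: float = TIME_REF_H) -> float:
    """RMS noise of a normalised trace at given concentration and time.

    sigma = noise_ref * (conc_ref / spin_conc) * sqrt(time_ref / time):
    inversely proportional to spin concentration, improving with the
    square root of averaging time.
    """
    if spin_conc <= 0 or averaging_time <= 0:
        raise DomainError("spin_conc and averaging_time must be positive")
    if noise_ref < 0 or conc_ref <= 0 or time_ref <= 0:
        raise DomainError("reference parameters must be positive")
    return noise_ref * (conc_ref / spin_conc) * np.sqrt(
        time_ref / averaging_time)


@dataclass(frozen=True)
class TitrationDataset:
    """Generated traces plus manifest and the generating ground truth."""

    design: ExperimentDesign
    traces: Tuple[dc.DipolarTrace, ...]
    manifest: pd.DataFrame = field(compare=False)
    truth: dict = field(compare=False)
    dist: dc.DistanceDistribution = field(compare=False)
    kernel: dc.DipolarKernel = field(compare=False)


def _sample_seeds(design_seed: int, n: int) -> list:
    """Deterministic per-sample seed sequences derived from the design seed."""
    return np.random.SeedSequence(design_seed).spawn(n)


def true_deltas(design: ExperimentDesign) -> np.ndarray:
    """Ground-truth modulation depths implied by the design."""
    return design.true_delta_max * fraction_bound(
        design.protein_total, np.array(design.ligand_concs), design.true_kd)


def generate_titration(design: ExperimentDesign,
                       kernel: Optional[dc.DipolarKernel] = None
                       ) -> TitrationDataset:
    """Simulate one full titration series.

    For each ligand concentration: the true depth follows the depletion
    isotherm, the trace is background times form factor, and white noise
    is added at the level set by the noise model (spin concentration =
    protein concentration; the detected nitroxide does not change on
    titrant addition).  Per-sample seeds are spawned deterministically
    from ``design.seed``.
    """
    r = dc.default_r_grid(design.r_min, design.r_max, design.dr)
    t = dc.default_t_grid(design.t_max, design.dt)
    if kernel is None or kernel.t_grid.shape != t.shape or \
            not np.allclose(kernel.t_grid, t) or \
            not np.allclose(kernel.r_grid, r):
        kernel = dc.build_kernel(t, r)
    dist = dc.DistanceDistribution.gaussian(design.dist_mean, design.dist_sd, r)
    bg = dc.BackgroundModel(k=design.bg_k, d=design.bg_d)
    deltas = true_deltas(design)
    sigma = noise_model(design.protein_total, design.averaging_time_h,
                        design.noise_ref, design.conc_ref, design.time_ref_h)
    seeds = _sample_seeds(design.seed, len(deltas))

    traces, rows = [], []
    for i, (lig, delta) in enumerate(zip(design.ligand_concs, deltas)):
        meta = dc.TraceMeta(protein_conc=design.protein_total,
                            titrant_conc=lig,
                            averaging_time=design.averaging_time_h)
        ff = dc.simulate_form_factor(dist, float(delta), kernel, meta=meta)
        raw = dc.apply_background(ff, bg)
        noisy = dc.add_noise(raw, sigma, seeds[i])
        traces.append(noisy)
        rows.append({
            "series_label": design.label,
            "sample_id": f"{design.label}_{i:02d}",
            "protein_conc_M": design.protein_total,
            "ligand_conc_M": lig,
            "averaging_time_h": design.averaging_time_h,
        })

    truth = {
        "design": _design_record(design),
        "noise_rms": float(sigma),
        "delta_true": [float(d) for d in deltas],
    }
    return TitrationDataset(design=design, traces=tuple(traces),
                            manifest=pd.DataFrame(rows), truth=truth,
                            dist=dist, kernel=kernel)


def _design_record(design: ExperimentDesign) -> dict:
    rec = asdict(design)
    rec["ligand_concs"] = list(design.ligand_concs)
    return rec


def verify_dataset(dataset: TitrationDataset) -> bool:
    """Recompute the ground-truth depths from the manifest and compare
    exactly against the serialised record."""
    d = dataset.design
    recomputed = d.true_delta_max * fraction_bound(
        np.array(dataset.manifest["protein_conc_M"]),
        np.array(dataset.manifest["ligand_conc_M"]), d.true_kd)
    return bool(np.array_equal(recomputed,
                               np.array(dataset.truth["delta_true"])))


def write_dataset(dataset: TitrationDataset, outdir) -> pd.DataFrame:
    """Write traces (ASCII), manifest CSV and ground-truth JSON to a
    directory; returns the manifest with resolved trace paths."""
    from .io_cli import write_trace  # local import avoids a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest.copy()
    paths = []
    for trace, sample_id in zip(dataset.traces, manifest["sample_id"]):
        path = outdir / f"{sample_id}.dat"
        write_trace(trace, path)
        paths.append(path.name)
    manifest["trace_path"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
    return manifest
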