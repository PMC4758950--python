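"""Assay-realistic synthetic datasets: sampled, noisy tip-position traces
for every condition of the packaged parameter tables, and single-molecule
run tables.

What is emulated: 10-minute dynamic-microtubule assays sampled at a fixed
frame interval with Gaussian tip-localization noise, at the per-condition
dynamic-instability rates of the packaged porcine and yeast tables; and
single-molecule motility assays with exponential run lengths, Gaussian
velocities, exponential end residence, and competing photobleaching.
What is not: images (traces only), drift, tracking failures, or any
length-dependent noise.

Generated bundles keep the assay configuration (seeds, noise, frame
interval) in ``manifest.json`` and the generating dynamics parameters in
a separate ``truth.json``; analysis code reads only the former.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .params import DynamicsParams, MotorParams
from .simulate import (
    MotorRun,
    Trajectory,
    simulate_dynamic_instability,
    simulate_single_molecule_runs,
    substreams,
)
from . import tables

__all__ = [
    "AssayConfig",
    "SampledTrace",
    "generate_assay",
    "generate_run_table",
    "make_fixture_suite",
    "n_microtubules_for_row",
    "traces_to_frame",
    "frame_to_traces",
]

MANIFEST_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AssayConfig:
    """One dynamic-microtubule assay condition.

    ``duration`` is in minutes, ``frame_interval`` in seconds,
    ``position_noise_sd`` in um.  Defaults (2 s frames, 0.05 um noise)
    are the package's stand-ins for unpublished acquisition parameters:
    2 s still resolves a typical multi-micron shrinkage excursion into
    several frames, and 0.05 um is the scale of diffraction-limited tip
    localization.
    """

    species: str = "porcine"
    tubulin_conc: float = 12.0    # uM
    kip2_conc: float = 0.0        # nM
    n_microtubules: int = 20
    duration: float = 10.0        # min
    frame_interval: float = 2.0   # s
    position_noise_sd: float = 0.05  # um
    seed: int = 0

    def __post_init__(self):
        if self.species not in ("porcine", "yeast"):
            raise ValueError("species must be 'porcine' or 'yeast'")
        if self.duration <= 0 or self.frame_interval <= 0:
            raise ValueError("duration and frame_interval must be > 0")
        if self.frame_interval >= self.duration * 60.0:
            raise ValueError("frame_interval must be shorter than the assay")
        if self.n_microtubules < 1:
            raise ValueError("n_microtubules must be >= 1")
        if self.position_noise_sd < 0:
            raise ValueError("position_noise_sd must be >= 0")


@dataclass
class SampledTrace:
    """A sampled tip-position time series for one microtubule.

    ``frame_times`` in seconds, uniformly spaced; ``tip_positions`` in um
    measured from the seed end (noisy, clipped below at -3 noise SD).
    """

    mt_id: str
    frame_times: np.ndarray
    tip_positions: np.ndarray
    condition: AssayConfig | None = None

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.tip_positions = np.asarray(self.tip_positions, dtype=float)
        if len(self.frame_times) != len(self.tip_positions):
            raise ValueError("times and positions must have equal length")
        dts = np.diff(self.frame_times)
        if len(dts) and not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("frame spacing must be uniform")

    @property
    def frame_interval(self) -> float:
        """Frame spacing in seconds."""
        return float(self.frame_times[1] - self.frame_times[0])


def generate_assay(config: AssayConfig, d: DynamicsParams = None, *,
                   simulator=None, return_truth: bool = False):
    """Generate sampled, noisy tip traces for one assay condition.

    Each microtubule is simulated with :func:`simulate_dynamic_instability`
    at rates ``d`` (or by ``simulator(rng)``, any callable returning a
    :class:`~kip2mt.simulate.Trajectory`, e.g. a closure over
    ``simulate_coupled``), sampled at ``config.frame_interval``, and
    perturbed by independent Gaussian localization noise.

    Returns a list of :class:`SampledTrace`; with ``return_truth=True``
    returns ``(traces, trajectories)`` so tests can score the analysis
    against the generating event log.
    """
    if (d is None) == (simulator is None):
        raise ValueError("provide exactly one of d or simulator")
    streams = substreams(config.seed, 2 * config.n_microtubules)
    t_s = np.arange(0.0, config.duration * 60.0 + 1e-9, config.frame_interval)
    t_min = t_s / 60.0
    traces, truths = [], []
    for i in range(config.n_microtubules):
        rng_sim, rng_noise = streams[2 * i], streams[2 * i + 1]
        if simulator is not None:
            traj = simulator(rng_sim)
        else:
            traj = simulate_dynamic_instability(d, config.duration, rng_sim)
        pos = traj.length_at(t_min)
        if config.position_noise_sd > 0:
            pos = pos + rng_noise.normal(0.0, config.position_noise_sd, pos.shape)
            pos = np.maximum(pos, -3.0 * config.position_noise_sd)
        traces.append(SampledTrace(f"mt{i:03d}", t_s, pos, config))
        truths.append(traj)
    return (traces, truths) if return_truth else traces


def traces_to_frame(traces: list[SampledTrace]) -> pd.DataFrame:
    """Stack traces into the on-disk long format
    (columns mt_id, time_s, position_um)."""
    return pd.concat(
        [pd.DataFrame({"mt_id": tr.mt_id, "time_s": tr.frame_times,
                       "position_um": tr.tip_positions}) for tr in traces],
        ignore_index=True)


def frame_to_traces(df: pd.DataFrame,
                    condition: AssayConfig | None = None) -> list[SampledTrace]:
    """Inverse of :func:`traces_to_frame`."""
    return [SampledTrace(str(mt), g["time_s"].to_numpy(),
                         g["position_um"].to_numpy(), condition)
            for mt, g in df.groupby("mt_id", sort=True)]


def generate_run_table(m: MotorParams, n: int, seed: int, *,
                       track_length: float | None = None,
                       dropout_below: float | None = None,
                       dropout_frac: float = 0.5) -> pd.DataFrame:
    """Single-molecule run records in the CSV schema used by the
    exponential fits.

    Columns: ``run_um``, ``run_s``, ``end_dwell_s``, ``reached_end``,
    ``run_censored`` (photobleached while running), ``dwell_censored``
    (photobleached while dwelling at the end).  ``dropout_below`` emulates
    the under-detection of very short runs by discarding a fraction
    ``dropout_frac`` of runs shorter than the threshold (um).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng_runs, rng_drop = substreams(seed, 2)
    runs = simulate_single_molecule_runs(m, n, rng_runs, track_length=track_length)
    df = pd.DataFrame({
        "run_um": [r.run_distance for r in runs],
        "run_s": [r.run_time for r in runs],
        "end_dwell_s": [r.end_dwell for r in runs],
        "reached_end": [r.reached_end for r in runs],
        "run_censored": [r.terminated_by == "bleach" and not r.reached_end
                         for r in runs],
        "dwell_censored": [r.reached_end and r.terminated_by == "bleach"
                           for r in runs],
    })
    if dropout_below is not None:
        short = df["run_um"] < dropout_below
        drop = short & (rng_drop.uniform(size=len(df)) < dropout_frac)
        df = df[~drop].reset_index(drop=True)
    return df


def n_microtubules_for_row(row: pd.Series, duration: float = 10.0) -> int:
    """Microtubule count that makes an assay of ``duration`` minutes yield
    roughly the event counts printed in a table row.

    Sized so that both the expected number of growth phases
    (~ n_mt * (1 + f * T)) and of catastrophes (~ n_mt * f * T) reach the
    printed ns; at least 20 microtubules, matching typical assay practice.
    """
    f = float(row["cat_freq"]) if not pd.isna(row["cat_freq"]) else 0.0
    n_growth = float(row["growth_n"])
    need = n_growth / (1.0 + f * duration)
    if f > 0 and not pd.isna(row.get("cat_n")):
        need = max(need, float(row["cat_n"]) / (f * duration))
    return max(20, math.ceil(need))


def make_fixture_suite(seed: int, out_dir, *, overwrite: bool = False,
                       species: tuple[str, ...] = ("porcine", "yeast"),
                       kip2_concs: dict | None = None,
                       scale: float = 1.0,
                       frame_interval: float = 2.0,
                       position_noise_sd: float = 0.05,
                       duration: float = 10.0,
                       motor: MotorParams = MotorParams(),
                       n_runs: int = 2000) -> Path:
    """Write one dataset per table row (plus a single-molecule run table)
    under ``out_dir``; returns the output path.

    Per condition: ``traces_<species>_<conc>nM.csv`` in the long trace
    schema, a ``manifest.json`` recording every assay assumption and seed,
    and a separate ``truth.json`` holding the generating parameters (the
    analysis pipeline must never read the latter).  ``scale`` multiplies
    the per-condition microtubule counts (e.g. 0.25 for a quick look);
    ``kip2_concs`` optionally restricts conditions, e.g.
    ``{"porcine": [0, 40]}``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    conditions, truth = [], []
    for sp_i, sp in enumerate(species):
        tbl = tables.load_table(sp)
        for _, row in tbl.iterrows():
            conc = float(row["kip2_nM"])
            if kip2_concs is not None and sp in kip2_concs \
                    and conc not in kip2_concs[sp]:
                continue
            n_mt = max(5, round(scale * n_microtubules_for_row(row, duration)))
            cond_seed = int(np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(sp_i, int(conc))
            ).generate_state(1)[0] % (2**31))
            cfg = AssayConfig(species=sp, tubulin_conc=float(row["tubulin_uM"]),
                              kip2_conc=conc, n_microtubules=n_mt,
                              duration=duration, frame_interval=frame_interval,
                              position_noise_sd=position_noise_sd, seed=cond_seed)
            d = tables.generating_params(row, sp)
            traces = generate_assay(cfg, d)
            fname = f"traces_{sp}_{conc:g}nM.csv"
            traces_to_frame(traces).to_csv(out / fname, index=False,
                                           float_format="%.6f")
            conditions.append({"file": fname, **asdict(cfg)})
            truth.append({"file": fname, "species": sp, "kip2_nM": conc,
                          "dynamics": asdict(d)})
    run_seed = int(root.generate_state(1)[0] % (2**31))
    run_df = generate_run_table(motor, n_runs, run_seed)
    run_df.to_csv(out / "single_molecule_runs.csv", index=False,
                  float_format="%.6f")
    manifest = {
        "schema": "kip2mt.fixture_manifest",
        "version": MANIFEST_SCHEMA_VERSION,
        "root_seed": seed,
        "scale": scale,
        "conditions": conditions,
        "single_molecule": {"file": "single_molecule_runs.csv",
                            "n": n_runs, "seed": run_seed},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "truth.json").write_text(json.dumps(
        {"schema": "kip2mt.fixture_truth", "version": MANIFEST_SCHEMA_VERSION,
         "conditions": truth, "motor": asdict(motor)},
        indent=2, sort_keys=True))
    return out
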