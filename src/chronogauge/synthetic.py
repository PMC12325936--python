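"""Synthetic multi-experiment circadian expression data.

Generates genes x samples TPM-like matrices with known ground truth:
rhythmic genes follow 24-h cosines with gene-specific phase, amplitude
and mesor; experiments add per-gene batch offsets; light-dark (LD)
experiments can damp the waveform during simulated darkness to mimic
the waveform mismatch between free-running and square-wave entrained
conditions; background genes carry no rhythm.  Values are truncated at
zero (TPM is non-negative).

The default training-like layout mirrors a 4-experiment design (two
continuous-light, two light-dark, 14 timepoints each, 56 samples with
balanced LL/LD counts) with at least 25 rhythmic genes per 4-h phase
bin plus non-rhythmic background genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_scaling import ExpressionMatrix
from .rhythmicity import N_PHASE_BINS, RhythmicityTable


@dataclass
class ExperimentDesign:
    """One simulated time-course experiment."""

    n_timepoints: int = 14
    interval_h: float = 2.0
    start_h: float = 0.0
    light_regime: str = "LL"  # LL (free-running) or LD (light-dark cycle)
    waveform: str = "sinusoid"  # "sinusoid" or "clipped-LD"
    batch_offset_sd: float = 0.5
    replicates: int = 1
    photoperiod_h: float = 12.0


@dataclass
class SimConfig:
    """Ground-truth generative settings for a simulated study."""

    n_rhythmic: int = 150
    n_noise: int = 300
    amplitude_range: tuple = (1.0, 4.0)
    mesor_range: tuple = (3.0, 10.0)
    noise_sd: float = 0.3  # expression noise as a fraction of amplitude
    background_sd: float | None = None  # absolute sd of non-rhythmic genes
    experiments: list = field(default_factory=lambda: [ExperimentDesign()])
    seed: int = 0
    noise_seed: int | None = None  # separate stream so test sets share gene truth
    dark_damping: float = 0.7
    balanced_phases: bool = True

    def __post_init__(self):
        if self.n_rhythmic < 0 or self.n_noise < 0 or self.noise_sd < 0:
            raise ValueError("invalid simulation config")


def _gene_truth(cfg: SimConfig):
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_rhythmic
    if cfg.balanced_phases and n > 0:
        # round-robin over the six 4-h bins, uniform within bin
        bins = np.arange(n) % N_PHASE_BINS
        phases = bins * 4.0 + rng.uniform(0.0, 4.0, size=n)
    else:
        phases = rng.uniform(0.0, 24.0, size=n)
    amps = rng.uniform(*cfg.amplitude_range, size=n)
    mesors_r = rng.uniform(*cfg.mesor_range, size=n)
    mesors_n = rng.uniform(*cfg.mesor_range, size=cfg.n_noise)
    return phases, amps, mesors_r, mesors_n


def _waveform(t_h, phase, exp: ExperimentDesign, dark_damping: float):
    base = np.cos(2.0 * np.pi * (t_h[None, :] - phase[:, None]) / 24.0)
    if exp.light_regime == "LD" and exp.waveform == "clipped-LD":
        dark = np.mod(t_h, 24.0) >= exp.photoperiod_h
        base = base * np.where(dark[None, :], dark_damping, 1.0)
    return base


def simulate(cfg: SimConfig) -> tuple[ExpressionMatrix, RhythmicityTable]:
    """Simulate a study and return the matrix plus its truth table.

    The truth table is a :class:`RhythmicityTable` whose extra columns
    include ``amplitude``, ``mesor`` and ``rhythmic``; rhythmic genes
    get a nominal Q of 1e-9 and background genes 1.0, so it can stand
    in directly for an externally computed rhythmicity prior.
    """
    phases, amps, mesors_r, mesors_n = _gene_truth(cfg)
    gene_ids = [f"RG{i:04d}" for i in range(cfg.n_rhythmic)] + [
        f"NG{i:04d}" for i in range(cfg.n_noise)
    ]
    noise_seed = cfg.seed if cfg.noise_seed is None else cfg.noise_seed
    nominal_amp = float(np.mean(cfg.amplitude_range))
    blocks, meta = [], []
    for e_idx, exp in enumerate(cfg.experiments):
        rng = np.random.default_rng([noise_seed, e_idx])
        t_h = exp.start_h + exp.interval_h * np.arange(exp.n_timepoints)
        n_cols = exp.n_timepoints * exp.replicates
        t_all = np.repeat(t_h, exp.replicates)
        batch = rng.normal(0.0, exp.batch_offset_sd, size=len(gene_ids))
        rows = np.empty((len(gene_ids), n_cols))
        if cfg.n_rhythmic:
            w = _waveform(np.asarray(t_all, dtype=float), phases, exp, cfg.dark_damping)
            sig = mesors_r[:, None] + amps[:, None] * w
            eps = rng.normal(0.0, 1.0, size=sig.shape) * (cfg.noise_sd * amps)[:, None]
            rows[: cfg.n_rhythmic] = sig + eps
        if cfg.n_noise:
            bg_sd = cfg.background_sd
            if bg_sd is None:
                bg_sd = cfg.noise_sd * nominal_amp
            eps = rng.normal(0.0, bg_sd, size=(cfg.n_noise, n_cols))
            rows[cfg.n_rhythmic:] = mesors_n[:, None] + eps
        rows += batch[:, None]
        np.maximum(rows, 0.0, out=rows)
        blocks.append(rows)
        for j, th in enumerate(t_all):
            rep = j % exp.replicates
            sid = f"e{e_idx}_t{th:g}_r{rep}"
            meta.append(
                {
                    "sample_id": sid,
                    "time_h": float(np.mod(th, 24.0)),
                    "experiment_id": f"exp{e_idx}",
                    "light_regime": exp.light_regime,
                    "platform": "rnaseq",
                    "genotype": "WT",
                }
            )
    values = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(gene_ids, name="gene_id"),
        columns=[r["sample_id"] for r in meta],
    )
    samples = pd.DataFrame(meta).set_index("sample_id")
    truth = pd.DataFrame(
        {
            "q_value": np.concatenate(
                [np.full(cfg.n_rhythmic, 1e-9), np.ones(cfg.n_noise)]
            ),
            "phase_h": np.concatenate([np.mod(phases, 24.0), np.zeros(cfg.n_noise)]),
            "period_h": 24.0,
            "amplitude": np.concatenate([amps, np.zeros(cfg.n_noise)]),
            "mesor": np.concatenate([mesors_r, mesors_n]),
            "rhythmic": np.concatenate(
                [np.ones(cfg.n_rhythmic, bool), np.zeros(cfg.n_noise, bool)]
            ),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ExpressionMatrix(values, samples), RhythmicityTable(truth)


def training_config(seed: int = 0, noise_sd: float = 0.3) -> SimConfig:
    """Four-experiment training-like design (2 LL + 2 LD, 56 samples)."""
    # 14 timepoints spaced 24/14 h keep all times distinct on the 24-h
    # circle, so 2 LL + 2 LD experiments give 28 + 28 replicate-free samples
    step = 24.0 / 14.0
    return SimConfig(
        n_rhythmic=150,
        n_noise=300,
        noise_sd=noise_sd,
        seed=seed,
        experiments=[
            ExperimentDesign(14, step, 0.0, "LL", "sinusoid", 0.4),
            ExperimentDesign(14, step, 0.9, "LL", "sinusoid", 0.6),
            ExperimentDesign(14, step, 0.0, "LD", "clipped-LD", 0.4),
            ExperimentDesign(14, step, 0.9, "LD", "clipped-LD", 0.6),
        ],
    )


def make_training_like(seed: int = 0, noise_sd: float = 0.3):
    """Simulate the default training-like study; returns (matrix, truth)."""
    return simulate(training_config(seed=seed, noise_sd=noise_sd))


def make_test_like(seed: int = 0, noise_sd: float = 0.3, n_timepoints: int = 12):
    """Held-out samples sharing gene truth with :func:`make_training_like`.

    Same gene-parameter seed, but fresh noise/batch draws and shifted
    sampling times, so the samples are unseen.
    """
    cfg = training_config(seed=seed, noise_sd=noise_sd)
    cfg.noise_seed = seed + 777
    cfg.experiments = [
        ExperimentDesign(n_timepoints, 2.0, 0.5, "LL", "sinusoid", 0.5),
        ExperimentDesign(n_timepoints, 2.0, 1.5, "LD", "clipped-LD", 0.5),
    ]
    return simulate(cfg)
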