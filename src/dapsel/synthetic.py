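"""Synthetic log-intensity datasets with the crossed batch structure the
analysis assumes.

Each entry is

    log-intensity[feature k, group g, replicate j]
        = baseline + group effect (signal features only) + b_j + s_kj + e,

with b_j ~ N(0, sigma_r^2) a per-replicate (batch) effect shared across
groups (replicate 1 of every group was processed together), s_kj ~
N(0, sigma_s^2) a feature x replicate interaction, and e ~ N(0, sigma_e^2)
residual noise.  A sparse subset of features carries a group-associated
mean shift; half the signal features are shifted up and half down so both
directions are represented.  For the 2x2 factorial each signal feature is
assigned to one factorial axis (genotype or treatment) and shifted in the
first level of that axis; for a plain two-group design the shift applies to
the first group.  Ground truth (signal ids, signed effects, realized random
effects) is returned alongside the matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import IntensityMatrix, SampleMeta, STANDARD_GROUPS, write_intensity_table


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``n_features`` defaults to the full design scale (about 3,000 proteins on
    12 samples); tests typically pass 500.  All SDs are on the log-intensity
    scale.  ``seed`` is required: generation is a pure function of the config.
    """

    n_groups: int = 4
    n_reps_per_group: int = 3
    n_features: int = 3000
    n_signal: int = 30
    effect_size: float = 2.0
    sigma_r: float = 0.3
    sigma_s: float = 0.5
    sigma_e: float = 1.0
    baseline_mean: float = 15.0
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimConfig.seed is required (no implicit nondeterminism)")
        if self.n_groups < 1 or self.n_reps_per_group < 1 or self.n_features < 1:
            raise ValueError("counts must be >= 1")
        if self.n_signal < 0 or self.n_signal > self.n_features:
            raise ValueError("need 0 <= n_signal <= n_features")
        if min(self.sigma_r, self.sigma_s, self.sigma_e) < 0:
            raise ValueError("SDs must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of one generated dataset."""

    signal_ids: list[str]
    true_effects: pd.Series          # feature id -> signed shift (y=1 side)
    signal_axes: pd.Series           # feature id -> axis carrying the effect
    true_batch_offsets: dict         # {"b": Series by replicate, "s": DataFrame feat x rep}
    group_assignment: pd.Series      # sample id -> group label

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signal_ids": self.signal_ids,
            "true_effects": {k: float(v) for k, v in self.true_effects.items()},
            "signal_axes": dict(self.signal_axes),
            "b": {str(k): float(v) for k, v in self.true_batch_offsets["b"].items()},
            "group_assignment": dict(self.group_assignment),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _group_labels(n_groups: int) -> list[str]:
    if n_groups == 4:
        return list(STANDARD_GROUPS)
    return [f"G{i + 1}" for i in range(n_groups)]


def _sample_meta(config: SimConfig) -> list[SampleMeta]:
    labels = _group_labels(config.n_groups)
    out = []
    for g in labels:
        if config.n_groups == 4:
            genotype, treatment = g[0], g[1:]
        else:
            genotype, treatment = g, "none"
        for j in range(1, config.n_reps_per_group + 1):
            out.append(
                SampleMeta(
                    sample_id=f"{g}-{j}",
                    group=g,
                    genotype=genotype,
                    treatment=treatment,
                    replicate=j,
                )
            )
    return out


def generate_dataset(config: SimConfig) -> tuple[IntensityMatrix, SimTruth]:
    """Draw one dataset under the generative model; returns matrix + truth."""
    rng = np.random.default_rng(config.seed)
    p, G, J = config.n_features, config.n_groups, config.n_reps_per_group
    samples = _sample_meta(config)
    feature_ids = [f"m.{k + 1:06d}" for k in range(p)]

    # signal features: uniform subset, half +effect and half -effect
    sig_idx = np.sort(rng.choice(p, size=config.n_signal, replace=False))
    signs = np.ones(config.n_signal)
    signs[: config.n_signal // 2] = -1.0
    rng.shuffle(signs)
    effects = signs * config.effect_size

    # factorial designs split the signal between the two axes
    if G == 4:
        axes = rng.choice(np.array(["genotype", "treatment"]), size=config.n_signal)
    else:
        axes = np.array(["group"] * config.n_signal)

    b = rng.normal(0.0, config.sigma_r, size=J)                 # replicate batches
    s = rng.normal(0.0, config.sigma_s, size=(p, J))            # feature x replicate
    e = rng.normal(0.0, config.sigma_e, size=(p, G * J))

    mat = np.full((p, G * J), config.baseline_mean)
    rep_of = np.array([sm.replicate - 1 for sm in samples])
    mat += b[rep_of][None, :]
    mat += s[:, rep_of]
    mat += e

    genotypes = [sm.genotype for sm in samples]
    treatments = [sm.treatment for sm in samples]
    first_geno = genotypes[0]
    first_trt = treatments[0]
    first_group = samples[0].group
    for idx, eff, axis in zip(sig_idx, effects, axes):
        if axis == "genotype":
            mask = np.array([g == first_geno for g in genotypes])
        elif axis == "treatment":
            mask = np.array([t == first_trt for t in treatments])
        else:
            mask = np.array([sm.group == first_group for sm in samples])
        mat[idx, mask] += eff

    values = pd.DataFrame(mat, index=feature_ids, columns=[sm.sample_id for sm in samples])
    data = IntensityMatrix(values, samples)

    signal_ids = [feature_ids[i] for i in sig_idx]
    truth = SimTruth(
        signal_ids=signal_ids,
        true_effects=pd.Series(effects, index=signal_ids, dtype=float),
        signal_axes=pd.Series(axes, index=signal_ids, dtype=object),
        true_batch_offsets={
            "b": pd.Series(b, index=range(1, J + 1)),
            "s": pd.DataFrame(s, index=feature_ids, columns=range(1, J + 1)),
        },
        group_assignment=pd.Series(
            {sm.sample_id: sm.group for sm in samples}, dtype=object
        ),
    )
    return data, truth


def generate_null_dataset(config: SimConfig) -> tuple[IntensityMatrix, SimTruth]:
    """As :func:`generate_dataset` with no group effects anywhere."""
    return generate_dataset(replace(config, n_signal=0))


def write_dataset(
    data: IntensityMatrix,
    truth: SimTruth,
    matrix_path: str | Path,
    meta_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write matrix TSV + metadata CSV (+ optional truth JSON sidecar)."""
    write_intensity_table(data, matrix_path, meta_path)
    if truth_path is not None:
        truth.to_json(truth_path)
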