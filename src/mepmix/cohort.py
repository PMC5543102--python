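"""Synthetic trial-level MEP cohorts with a known subgroup structure.

The generator emulates a paired-cTBS study design: per subject, two
baseline blocks (B1, B2) and six post-interventional blocks (P1..P6) of
peak-to-peak MEP amplitudes, 21 trials per block.  Each subject carries a
latent plasticity effect drawn from a Gaussian mixture on the percent-of-
baseline scale, so the subject-level "overall MEP change" distribution is
tri-modal by construction and every downstream stage (density estimation,
mixture fitting, subgroup assignment) can be exercised against known
ground truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BLOCKS",
    "BASELINE_BLOCKS",
    "POST_BLOCKS",
    "GeneratorConfig",
    "ConfigError",
    "generate_cohort",
    "sample_overall_changes",
]

BASELINE_BLOCKS = ("B1", "B2")
POST_BLOCKS = ("P1", "P2", "P3", "P4", "P5", "P6")
BLOCKS = BASELINE_BLOCKS + POST_BLOCKS

#: Mixture of subject-level plasticity effects (% of baseline): a small
#: responder mode showing MEP depression, a dominant no-change mode near
#: 100%, and a paradox-facilitation mode.  Baseline amplitudes ~1 mV.
DEFAULT_COMPONENT_MEANS = (69.7, 115.1, 158.4)
DEFAULT_COMPONENT_SDS = (4.2, 13.0, 26.4)
DEFAULT_COMPONENT_WEIGHTS = (0.19, 0.55, 0.26)

#: Floor for truncating baseline draws (mV); MEP amplitudes are physical
#: positive quantities and target amplitudes sit near 1 mV.
_BASELINE_FLOOR_MV = 0.1


class ConfigError(ValueError):
    """A generator configuration violates one of its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions of a 31-subject paired-cTBS
    cohort: a tri-modal subject effect on the percent scale, baseline
    amplitudes of 0.99 +/- 0.17 mV between subjects, and 21-trial blocks.
    ``trial_cv`` is the within-block coefficient of variation of single
    trials around the block's expected amplitude; 0.2 puts simulated
    baseline block SDs in the 0.14-0.26 mV range seen in practice.
    """

    n_subjects: int = 31
    component_means: tuple[float, ...] = DEFAULT_COMPONENT_MEANS
    component_sds: tuple[float, ...] = DEFAULT_COMPONENT_SDS
    component_weights: tuple[float, ...] = DEFAULT_COMPONENT_WEIGHTS
    baseline_mean: float = 0.99
    baseline_between_subject_sd: float = 0.17
    trial_cv: float = 0.2
    n_trials_per_block: int = 21
    contamination_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "component_means", tuple(float(m) for m in self.component_means))
        object.__setattr__(self, "component_sds", tuple(float(s) for s in self.component_sds))
        object.__setattr__(self, "component_weights", tuple(float(w) for w in self.component_weights))
        self.validate()

    def validate(self) -> None:
        k = len(self.component_means)
        if k < 1 or len(self.component_sds) != k or len(self.component_weights) != k:
            raise ConfigError(
                "component_means, component_sds and component_weights must have "
                f"equal length >= 1, got {k}/{len(self.component_sds)}/{len(self.component_weights)}"
            )
        if any(w <= 0 for w in self.component_weights):
            raise ConfigError("all component_weights must be > 0")
        if abs(sum(self.component_weights) - 1.0) > 1e-9:
            raise ConfigError(
                f"component_weights must sum to 1 within 1e-9, got {sum(self.component_weights)!r}"
            )
        if any(s < 0 for s in self.component_sds):
            raise ConfigError("component_sds must be >= 0")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.n_trials_per_block < 2:
            raise ConfigError("n_trials_per_block must be >= 2 (first trial is discarded downstream)")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be > 0")
        if self.baseline_between_subject_sd < 0:
            raise ConfigError("baseline_between_subject_sd must be >= 0")
        if self.trial_cv < 0:
            raise ConfigError("trial_cv must be >= 0")
        if not (0 <= self.contamination_rate < 1):
            raise ConfigError("contamination_rate must satisfy 0 <= rate < 1")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        """Load a config from a YAML mapping with GeneratorConfig field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("component_means", "component_sds", "component_weights"):
            d[key] = list(d[key])
        return d


def _truncated_normal(rng: np.random.Generator, mean, sd, lower: float) -> np.ndarray:
    """Draw N(mean, sd) elementwise, redrawing values at or below ``lower``."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = rng.normal(mean, sd)
    bad = out <= lower
    # Rejection sampling; the floors are many SDs below the means in any
    # realistic configuration, so this loop almost never iterates.
    for _ in range(1000):
        if not bad.any():
            break
        out = np.where(bad, rng.normal(mean, sd), out)
        bad = out <= lower
    if bad.any():
        raise ConfigError("could not draw positive amplitudes; check mean/sd configuration")
    return out


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort at trial level.

    Returns ``(trials, truth)``: a long-format trial table with columns
    ``subject_id, block, trial, amplitude_mv, prestim_flag`` and a
    ground-truth sidecar with ``subject_id, true_component, true_effect_pct``.

    Per subject: a mixture component is drawn by the configured weights, the
    subject's true effect (% of baseline) from that component, and a
    baseline amplitude from the between-subject distribution (truncated at
    0.1 mV).  Baseline-block trials scatter around the baseline and
    post-block trials around baseline x effect/100, both with SD equal to
    ``trial_cv`` times the block's expected amplitude and truncated at 0.
    Trials are flagged as contaminated (pre-stimulus muscle activity)
    independently at ``contamination_rate``.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    nt = config.n_trials_per_block

    components = rng.choice(len(config.component_weights), size=n, p=config.component_weights)
    effects = rng.normal(
        np.asarray(config.component_means)[components],
        np.asarray(config.component_sds)[components],
    )
    baselines = _truncated_normal(
        rng,
        np.full(n, config.baseline_mean),
        np.full(n, config.baseline_between_subject_sd),
        _BASELINE_FLOOR_MV,
    )

    subject_ids = np.array([f"S{i + 1:02d}" for i in range(n)])
    rows_per_subject = len(BLOCKS) * nt

    # Expected amplitude per (subject, block): baseline blocks at b,
    # post blocks at b * effect / 100.
    block_mult = np.array([1.0 if b in BASELINE_BLOCKS else np.nan for b in BLOCKS])
    expected = np.empty((n, len(BLOCKS)))
    for j, b in enumerate(BLOCKS):
        expected[:, j] = baselines if b in BASELINE_BLOCKS else baselines * effects / 100.0
    del block_mult

    mean_grid = np.repeat(expected[:, :, None], nt, axis=2)  # (subject, block, trial)
    amplitudes = _truncated_normal(rng, mean_grid, config.trial_cv * mean_grid, 0.0)
    flags = rng.random(size=mean_grid.shape) < config.contamination_rate

    trials = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, rows_per_subject),
            "block": np.tile(np.repeat(np.array(BLOCKS), nt), n),
            "trial": np.tile(np.arange(1, nt + 1), n * len(BLOCKS)),
            "amplitude_mv": amplitudes.ravel(),
            "prestim_flag": flags.ravel(),
        }
    )
    truth = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "true_component": components + 1,  # 1-based, ascending-mean convention
            "true_effect_pct": effects,
        }
    )
    return trials, truth


def sample_overall_changes(config: GeneratorConfig, n: int) -> np.ndarray:
    """Draw ``n`` i.i.d. subject-level overall MEP changes (% of baseline).

    Fast path sampling directly from the configured Gaussian mixture,
    bypassing trial-level noise.  Deterministic given ``config.seed``.
    """
    config.validate()
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(config.seed)
    components = rng.choice(len(config.component_weights), size=n, p=config.component_weights)
    return rng.normal(
        np.asarray(config.component_means)[components],
        np.asarray(config.component_sds)[components],
    )


def write_cohort_csv(trials: pd.DataFrame, truth: pd.DataFrame, trials_path, truth_path) -> None:
    trials.to_csv(trials_path, index=False)
    truth.to_csv(truth_path, index=False)
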