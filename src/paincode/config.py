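"""Analysis configuration.

All tunable constants of the analysis pipeline live in one frozen dataclass so
that every stage (binning, responsiveness thresholds, decoder settings,
session filters) is driven from a single validated object.  Randomized stages
never share a generator: child seeds are spawned from ``rng_seed`` via
:func:`numpy.random.SeedSequence` so each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is invalid or inconsistent."""


def _check_divides(bin_size: float, window: float, name: str) -> int:
    n = window / bin_size
    if abs(n - round(n)) > 1e-9:
        raise ConfigError(
            f"{name}={bin_size} does not divide the {window} s window into an "
            f"integer number of bins"
        )
    return int(round(n))


@dataclass(frozen=True)
class PipelineConfig:
    """Constants of the spike-train analysis pipeline.

    Attributes
    ----------
    psth_bin_size_s:
        Bin width for peristimulus time histograms (200 ms).
    decode_bin_size_s:
        Bin width of the cumulative decoding windows (100 ms).
    window_s:
        Half-width of the analysis window around stimulus onset: spikes are
        analysed on ``[-window_s, +window_s)`` seconds.
    z_threshold_abs, z_threshold_lower:
        Responsiveness thresholds: at least two post-stimulus bins must reach
        ``|z| >= z_threshold_abs`` and, conditionally, at least two bins must
        satisfy ``z - Z_SEM > z_threshold_lower``.
    cv_folds, mc_repeats:
        Cross-validation folds and Monte-Carlo repetitions (fold assignments
        are reshuffled each repeat) for the decoder.
    n_permutations:
        Label permutations used to estimate the empirical chance level.
    min_units_per_session:
        Sessions with fewer simultaneously recorded units are excluded from
        population decoding.
    min_peak_rate_hz:
        Units whose trial-averaged peak firing rate stays below this value are
        dropped before analysis.
    baseline_sd_mode:
        ``"bins"`` (default): baseline mean/SD taken across the pre-stimulus
        bins of the trial-averaged rate.  ``"trials"``: SD pooled across
        per-trial baseline bin rates.
    svm_kernel, svm_degree, svm_coef0, svm_c:
        Maximum-margin classifier settings; polynomial kernel of degree 3 with
        unit independent term by default, with a linear fallback.
    pairing:
        How LS and HS trials are paired for the per-unit intensity comparison:
        ``"rank"`` (sorted within condition) or ``"index"`` (trial order).
    """

    psth_bin_size_s: float = 0.2
    decode_bin_size_s: float = 0.1
    window_s: float = 5.0
    z_threshold_abs: float = 2.33
    z_threshold_lower: float = 1.645
    cv_folds: int = 5
    mc_repeats: int = 100
    n_permutations: int = 500
    min_units_per_session: int = 5
    min_peak_rate_hz: float = 1.0
    baseline_sd_mode: str = "bins"
    svm_kernel: str = "poly"
    svm_degree: int = 3
    svm_coef0: float = 1.0
    svm_c: float = 1.0
    pairing: str = "index"
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cv_folds", "mc_repeats", "n_permutations",
                     "min_units_per_session", "svm_degree"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2 (a single fold leaves no held-out data)")
        for name in ("psth_bin_size_s", "decode_bin_size_s", "window_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        _check_divides(self.psth_bin_size_s, self.window_s, "psth_bin_size_s")
        _check_divides(self.decode_bin_size_s, self.window_s, "decode_bin_size_s")
        if self.baseline_sd_mode not in ("bins", "trials"):
            raise ConfigError("baseline_sd_mode must be 'bins' or 'trials'")
        if self.svm_kernel not in ("poly", "linear"):
            raise ConfigError("svm_kernel must be 'poly' or 'linear'")
        if self.pairing not in ("rank", "index"):
            raise ConfigError("pairing must be 'rank' or 'index'")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")

    @property
    def n_psth_bins_per_side(self) -> int:
        return _check_divides(self.psth_bin_size_s, self.window_s, "psth_bin_size_s")

    @property
    def n_decode_bins(self) -> int:
        return _check_divides(self.decode_bin_size_s, self.window_s, "decode_bin_size_s")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one root seed."""
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]
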