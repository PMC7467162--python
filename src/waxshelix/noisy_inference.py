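"""Monte-Carlo error propagation through trained models.

An experimental SWAXS point is treated as one draw from an independent
normal law centered on the measured intensity with standard deviation
``alpha * sigma(q)``; sampling many whole profiles and pushing each
through a trained model yields a *distribution* of descriptor predictions
rather than a single number.  For noisy data the mode (most probable
value) of that distribution is the robust summary — the mean is dragged by
the tails — so both are reported, together with the spread.

Negative sampled intensities, frequent at high q for large ``alpha``, are
unphysical and have no logarithm; each point is drawn from the
positive-truncated normal instead (equivalent to redrawing until
positive), keeping all n curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .boosted_models import ModelBundle
from .scattering import ScatteringProfile

#: The documented error-level presets.
ALPHA_PRESETS = {"low": 0.2, "medium": 1.0, "high": 2.0}
DEFAULT_N_SAMPLES = 5000
MIN_RECOMMENDED_SAMPLES = 1000
FALLBACK_BINS = 50


class InferenceError(ValueError):
    pass


def resolve_alpha(alpha: float | str) -> float:
    """Accept a numeric error level or one of the low/medium/high presets."""
    if isinstance(alpha, str):
        try:
            return ALPHA_PRESETS[alpha]
        except KeyError:
            raise InferenceError(
                f"unknown alpha preset {alpha!r}; presets are {sorted(ALPHA_PRESETS)}"
            ) from None
    if alpha < 0:
        raise InferenceError("alpha must be non-negative")
    return float(alpha)


def sample_noisy_profiles(
    profile: ScatteringProfile,
    alpha: float | str,
    n: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` noisy log10-intensity feature vectors from one profile.

    Every q point is sampled independently from
    Normal(I(q), alpha * sigma(q)) truncated to positive intensities.
    ``alpha = 0`` returns n identical copies of the measured profile.
    """
    alpha = resolve_alpha(alpha)
    if profile.sigma is None:
        raise InferenceError(
            "profile has no sigma column: error propagation needs per-point "
            "experimental errors; supply a 3-column (q, I, sigma) profile"
        )
    if n < 1:
        raise InferenceError("need at least one sample")
    if n < MIN_RECOMMENDED_SAMPLES:
        warnings.warn(
            f"n = {n} noisy profiles is below the recommended "
            f"{MIN_RECOMMENDED_SAMPLES}; prediction statistics will be poor",
            stacklevel=2,
        )
    intensity = profile.intensity
    if np.any(intensity <= 0):
        raise InferenceError("measured intensities must be positive")
    scale = alpha * profile.sigma
    draws = np.tile(intensity, (n, 1)).astype(float)
    active = scale > 0
    if alpha > 0 and active.any():
        rng = np.random.default_rng(seed)
        a = -intensity[active] / scale[active]  # truncate at zero intensity
        draws[:, active] = truncnorm.rvs(
            a, np.inf, loc=intensity[active], scale=scale[active],
            size=(n, int(active.sum())), random_state=rng,
        )
    return np.log10(draws)


@dataclass
class PredictionDistribution:
    """Sampled predictions of one descriptor for one noisy profile."""

    descriptor: str
    alpha: float
    samples: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mode: float
    mean: float
    sd: float

    @property
    def n(self) -> int:
        return len(self.samples)


def _histogram(samples: np.ndarray, bins) -> tuple[np.ndarray, np.ndarray]:
    """Freedman-Diaconis histogram with a fixed-count fallback."""
    if bins == "fd":
        iqr = np.subtract(*np.percentile(samples, [75, 25]))
        if iqr <= 0 or np.ptp(samples) == 0:
            bins = FALLBACK_BINS
    counts, edges = np.histogram(samples, bins=bins)
    return counts, edges


def predict_distribution(
    bundle: ModelBundle,
    samples: np.ndarray,
    alpha: float = np.nan,
    bins="fd",
) -> PredictionDistribution:
    """Histogram/mode/mean/sd of the model outputs over sampled profiles.

    For the A-form classifier the histogram is the class-frequency table
    and the mode is the modal class.  Mode ties break toward the smaller
    value.
    """
    preds = np.asarray(bundle.predict(samples), dtype=float)
    if bundle.task == "classification":
        edges = np.arange(-0.5, 12.5)
        counts, _ = np.histogram(preds, bins=edges)
        mode = float(np.argmax(counts))  # argmax takes the first (smallest) tie
    else:
        counts, edges = _histogram(preds, bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mode = float(centers[np.argmax(counts)])
    return PredictionDistribution(
        descriptor=bundle.descriptor,
        alpha=float(alpha),
        samples=preds,
        bin_edges=edges,
        counts=counts,
        mode=mode,
        mean=float(preds.mean()),
        sd=float(preds.std()),
    )


def predict_conditions_report(
    bundles: dict[str, ModelBundle],
    profiles: list[ScatteringProfile],
    alpha: float | str = "medium",
    n: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> pd.DataFrame:
    """Mode/mean/sd summary per descriptor per experimental-style profile."""
    alpha_value = resolve_alpha(alpha)
    alpha_name = alpha if isinstance(alpha, str) else next(
        (k for k, v in ALPHA_PRESETS.items() if v == alpha_value), "custom"
    )
    rows = []
    for i, profile in enumerate(profiles):
        samples = sample_noisy_profiles(profile, alpha_value, n=n, seed=seed + i)
        for name, bundle in bundles.items():
            dist = predict_distribution(bundle, samples, alpha=alpha_value)
            rows.append(
                {
                    "profile": profile.conformation_id or f"profile{i}",
                    "condition": profile.condition,
                    "descriptor": name,
                    "alpha": alpha_value,
                    "alpha_preset": alpha_name,
                    "n_samples": dist.n,
                    "mode": dist.mode,
                    "mean": dist.mean,
                    "sd": dist.sd,
                }
            )
    return pd.DataFrame(rows)
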