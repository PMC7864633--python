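"""Pulse-convolution forward model for MS2 nascent-transcription traces.

A promoter that is ON during one frame of length ``dt_s`` loads polymerases at
rate ``r`` (expressed in fluorescence AU per minute), producing a pulse of
height ``(r / 60) * dt_s`` that persists at the locus for the polymerase
transit time ``t_elong_s`` — i.e. for ``w = round(t_elong_s / dt_s)`` frames.
The observable fluorescence is the sum of all pulses still transiting the
gene, so a state sequence maps to fluorescence by a ``w``-frame moving-sum
convolution.  With two post-replication sister promoters the pulse height is
doubled when both are ON; fluorescence is linear in the promoter-ON count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelConfig", "fluorescence_from_states", "expected_mean_fluorescence"]


@dataclass(frozen=True)
class ModelConfig:
    """Forward-model configuration.

    Parameters
    ----------
    dt_s:
        Frame interval in seconds (analysis grid; 20 s by default).
    t_elong_s:
        Polymerase transit (elongation/dwell) time in seconds.  The default
        140 s corresponds to a ~6.6 kb construct transcribed at ~2.7 kb/min.
    n_promoters:
        Number of promoter copies contributing to the locus signal (2 after
        replication of the sister chromatids).
    r_au_per_min:
        Polymerase loading rate of a single ON promoter, folded together with
        the fluorescence-per-polymerase proportionality into AU/min.
    """

    dt_s: float = 20.0
    t_elong_s: float = 140.0
    n_promoters: int = 2
    r_au_per_min: float = 67.0

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError(f"dt_s must be positive, got {self.dt_s}")
        if self.t_elong_s <= 0:
            raise ValueError(f"t_elong_s must be positive, got {self.t_elong_s}")
        if self.n_promoters not in (1, 2):
            raise ValueError(f"n_promoters must be 1 or 2, got {self.n_promoters}")
        if self.r_au_per_min < 0:
            raise ValueError(f"r_au_per_min must be >= 0, got {self.r_au_per_min}")

    @property
    def w(self) -> int:
        """Pulse length in frames: t_elong / dt rounded to nearest, ties up."""
        # floor(x + 0.5) implements round-half-up
        return max(1, int(np.floor(self.t_elong_s / self.dt_s + 0.5)))

    @property
    def pulse_height_au(self) -> float:
        """Fluorescence contributed per frame by one ON promoter, (r/60)*dt."""
        return self.r_au_per_min / 60.0 * self.dt_s


def _validate_states(s: np.ndarray, n_promoters: int) -> np.ndarray:
    s = np.asarray(s)
    if s.ndim != 1 or s.size < 1:
        raise ValueError("promoter path must be a non-empty 1-D sequence")
    if not np.all(np.equal(np.mod(s, 1), 0)):
        raise ValueError("promoter states must be integral")
    s = s.astype(np.int64)
    if s.min() < 0 or s.max() > n_promoters:
        raise ValueError(
            f"promoter states must lie in [0, {n_promoters}], "
            f"got range [{s.min()}, {s.max()}]"
        )
    return s


def fluorescence_from_states(s, config: ModelConfig = ModelConfig()) -> np.ndarray:
    """Noiseless fluorescence of a promoter-ON-count path.

    ``F_t = (r/60) * dt * sum_{i=0}^{w-1} s_{t-i}``, with history before the
    trace start treated as OFF.  Output has the same length as ``s``.
    """
    s = _validate_states(s, config.n_promoters)
    kernel = np.ones(config.w)
    full = np.convolve(s.astype(float), kernel)  # length T + w - 1
    return config.pulse_height_au * full[: s.size]


def expected_mean_fluorescence(
    kon_per_min: float, koff_per_min: float, config: ModelConfig = ModelConfig()
) -> float:
    """Stationary mean of the noiseless forward model.

    The ON occupancy of a telegraph promoter is ``kon / (kon + koff)``, each ON
    frame contributes a pulse integrating to ``(r/60) * dt * w`` AU over its
    lifetime, and promoters are independent, giving

    ``<F> = n_promoters * r * (t_elong/60) * kon / (kon + koff)``

    (using ``w * dt ≈ t_elong``; exactly ``w * dt`` on the frame grid).
    """
    if kon_per_min < 0 or koff_per_min < 0:
        raise ValueError("rates must be non-negative")
    if kon_per_min == 0 and koff_per_min == 0:
        raise ValueError("kon = koff = 0: stationary occupancy undefined")
    occupancy = kon_per_min / (kon_per_min + koff_per_min)
    return config.n_promoters * config.pulse_height_au * config.w * occupancy
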