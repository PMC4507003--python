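"""Imaging protocols for single-particle tracking acquisitions.

Continuous imaging acquires frames back to back at a fixed frame rate;
time-lapse imaging keeps the short exposure but inserts dark gaps between
frames, stretching the observation window in wall-clock time while the
fluorophore only bleaches during exposures. That asymmetry is what makes
long binding events measurable despite photobleaching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Frame interval of the reference continuous acquisition (197 frames/s).
CONTINUOUS_INTERVAL_S: float = 1.0 / 197.0

#: Exposure time used in every protocol (s).
DEFAULT_EXPOSURE_S: float = 0.005


@dataclass(frozen=True)
class ImagingProtocol:
    """One single-molecule imaging protocol.

    Parameters
    ----------
    exposure_s : float
        Duration of each frame's exposure (s).
    interval_s : float
        Time between consecutive frame starts (s); ``interval_s - exposure_s``
        is the dark gap.
    pixel_um : float
        Camera pixel size in the sample plane (μm).
    loc_sigma_um : float
        Localization error standard deviation per axis (μm).
    bleach_rate_continuous : float
        Ensemble fluorescence decay rate measured under *continuous*
        imaging (1/s).  Bleaching happens during exposures only, so the
        per-frame bleach probability is the same for every protocol that
        shares the exposure, regardless of dark-gap length.
    label : str
        Short protocol name used in tables ("continuous", "tl_0.5", ...).
    """

    exposure_s: float
    interval_s: float
    pixel_um: float = 0.160
    loc_sigma_um: float = 0.025
    bleach_rate_continuous: float = 0.34
    label: str = field(default="custom")

    def __post_init__(self) -> None:
        if not self.exposure_s > 0:
            raise ValueError("exposure_s must be > 0")
        if self.interval_s < self.exposure_s:
            raise ValueError("interval_s must be >= exposure_s")
        if self.loc_sigma_um < 0:
            raise ValueError("loc_sigma_um must be >= 0")
        if self.bleach_rate_continuous < 0:
            raise ValueError("bleach_rate_continuous must be >= 0")

    @property
    def dark_s(self) -> float:
        """Dark-gap duration between exposures (s)."""
        return self.interval_s - self.exposure_s

    def frame_bleach_probability(
        self, reference_interval_s: float = CONTINUOUS_INTERVAL_S
    ) -> float:
        """Per-frame bleaching probability.

        Calibrated so that under continuous imaging (one frame every
        ``reference_interval_s``) the ensemble intensity decays at
        ``bleach_rate_continuous``.  The same per-frame probability applies
        to time-lapse frames: the fluorophore survives dark gaps intact.
        """
        return 1.0 - math.exp(-self.bleach_rate_continuous * reference_interval_s)

    def effective_bleach_rate(self) -> float:
        """Bleach rate per second of *event duration* under this protocol.

        An event spanning duration t covers t/interval frames, each with
        the per-frame bleach probability, so the observed event-survival
        is depressed by exp(-p_b t / interval).  Under continuous imaging
        this equals ``bleach_rate_continuous``; time-lapse protocols
        bleach slower per wall-clock second by the duty-cycle ratio.
        """
        return self.frame_bleach_probability() / self.interval_s


def continuous(
    frame_rate_hz: float = 197.0,
    exposure_s: float = DEFAULT_EXPOSURE_S,
    loc_sigma_um: float = 0.025,
    bleach_rate_continuous: float = 0.34,
) -> ImagingProtocol:
    """Continuous acquisition (default 197 frames/s, 5 ms exposure)."""
    return ImagingProtocol(
        exposure_s=exposure_s,
        interval_s=1.0 / frame_rate_hz,
        loc_sigma_um=loc_sigma_um,
        bleach_rate_continuous=bleach_rate_continuous,
        label="continuous",
    )


def timelapse(
    dark_s: float,
    exposure_s: float = DEFAULT_EXPOSURE_S,
    loc_sigma_um: float = 0.025,
    bleach_rate_continuous: float = 0.34,
) -> ImagingProtocol:
    """Time-lapse acquisition with dark gaps of ``dark_s`` seconds."""
    return ImagingProtocol(
        exposure_s=exposure_s,
        interval_s=exposure_s + dark_s,
        loc_sigma_um=loc_sigma_um,
        bleach_rate_continuous=bleach_rate_continuous,
        label=f"tl_{dark_s:g}",
    )


def standard_protocols() -> dict[str, ImagingProtocol]:
    """The four acquisition protocols of the study design."""
    out = {"continuous": continuous()}
    for dark in (0.1, 0.5, 1.0):
        p = timelapse(dark)
        out[p.label] = p
    return out
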