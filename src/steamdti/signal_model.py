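"""Steady-state signal equations for spin-echo and stimulated-echo DTI.

A spin-echo (SE) diffusion sequence refocuses transverse magnetization, so
its steady-state signal is governed by T1 saturation and T2 decay over the
echo time TE.  A stimulated-echo (STEAM) sequence stores magnetization
longitudinally during the mixing time TM; only half of it is recalled, T1
(not T2) decay applies during TM, and the longitudinal recovery window
shrinks to TR - TM.  These closed forms predict the SNR penalty of STEAM
relative to SE for given tissue relaxation times, and the free-diffusion
length sqrt(6 D t) connects the encoding time to the displacement scale
probed, which for skeletal muscle is compared against the ~25 um myofiber
diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import ValidationError

__all__ = [
    "SequenceKind",
    "SequenceTiming",
    "TissueRelaxation",
    "steady_state_signal",
    "predicted_snr_ratio",
    "free_diffusion_length",
]


class SequenceKind(str, Enum):
    SE = "SE"
    STEAM = "STEAM"


@dataclass(frozen=True)
class SequenceTiming:
    """Timing parameters of one diffusion sequence, all in milliseconds.

    For STEAM the mixing time defaults to the diffusion encoding time
    (the encoding interval is realized by storing magnetization during TM).
    For SE the mixing time must be absent.
    """

    kind: SequenceKind
    repetition_time: float  # TR
    echo_time: float  # TE
    encoding_time: float  # Delta
    mixing_time: Optional[float] = None  # TM, STEAM only

    def __post_init__(self) -> None:
        kind = SequenceKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if not self.echo_time > 0:
            raise ValidationError("echo_time must be > 0")
        if not self.repetition_time > self.echo_time:
            raise ValidationError("repetition_time must exceed echo_time")
        if not self.encoding_time > 0:
            raise ValidationError("encoding_time must be > 0")
        if kind is SequenceKind.SE:
            if self.mixing_time is not None:
                raise ValidationError("mixing_time must be absent for SE")
        else:
            if self.mixing_time is None:
                object.__setattr__(self, "mixing_time", self.encoding_time)
            if not 0 < self.mixing_time < self.repetition_time:
                raise ValidationError(
                    "mixing_time must satisfy 0 < TM < repetition_time"
                )


@dataclass(frozen=True)
class TissueRelaxation:
    """Longitudinal and transverse relaxation times, milliseconds."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not self.t2 > 0:
            raise ValidationError("t2 must be > 0")
        if not self.t1 > self.t2:
            raise ValidationError("t1 must exceed t2")


def steady_state_signal(timing: SequenceTiming, relax: TissueRelaxation) -> float:
    """Steady-state signal as a fraction of equilibrium magnetization.

    SE:    (1 - exp(-TR/T1)) * exp(-TE/T2)
    STEAM: 1/2 * (1 - exp(-(TR-TM)/T1)) * exp(-TM/T1) * exp(-TE/T2)

    The factor 1/2 is the stimulated-echo recall loss; T1 decay applies
    during the mixing time because magnetization is stored longitudinally.
    """
    t2_decay = math.exp(-timing.echo_time / relax.t2)
    if timing.kind is SequenceKind.SE:
        recovery = 1.0 - math.exp(-timing.repetition_time / relax.t1)
        return recovery * t2_decay
    tm = timing.mixing_time
    recovery = 1.0 - math.exp(-(timing.repetition_time - tm) / relax.t1)
    return 0.5 * recovery * math.exp(-tm / relax.t1) * t2_decay


def predicted_snr_ratio(
    reference: SequenceTiming,
    comparator: SequenceTiming,
    relax: TissueRelaxation,
) -> float:
    """Theoretical SNR of *reference* relative to *comparator*, in percent.

    Assumes identical acquisition bandwidth and noise level, so the SNR
    ratio equals the steady-state signal ratio.
    """
    return 100.0 * steady_state_signal(reference, relax) / steady_state_signal(
        comparator, relax
    )


def free_diffusion_length(diffusivity: float, time: float) -> float:
    """Three-dimensional RMS displacement sqrt(6 D t), in micrometers.

    Parameters
    ----------
    diffusivity : mm^2/s
    time : ms
    """
    if diffusivity < 0:
        raise ValidationError("diffusivity must be >= 0")
    if not time > 0:
        raise ValidationError("time must be > 0")
    length_mm = math.sqrt(6.0 * diffusivity * time / 1000.0)
    return length_mm * 1000.0
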