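"""Shoulder DTI protocol constants shipped as a versioned YAML resource.

The protocol defines the five acquired series (one spin-echo and four
stimulated-echo series with encoding times 100/200/400/600 ms), their
timings, the effective background b-values of the nominally unweighted
volumes, and the per-sequence reference SNR levels used as defaults by the
study simulator.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache
from typing import Dict, List

import yaml

from .signal_model import SequenceKind, SequenceTiming, TissueRelaxation

__all__ = [
    "load_protocol",
    "sequence_names",
    "sequence_timing",
    "tissue_relaxation",
    "reference_snr",
    "background_b_samples",
]


@lru_cache(maxsize=1)
def load_protocol() -> dict:
    ref = importlib.resources.files("steamdti.resources") / "protocol.yaml"
    return yaml.safe_load(ref.read_text())


def sequence_names() -> List[str]:
    """Series identifiers in acquisition order: SE, STEAM100..STEAM600."""
    return list(load_protocol()["sequences"].keys())


def sequence_timing(name: str) -> SequenceTiming:
    block = load_protocol()["sequences"][name]
    kind = SequenceKind(block["kind"])
    return SequenceTiming(
        kind=kind,
        repetition_time=block["tr_ms"],
        echo_time=block["te_ms"],
        encoding_time=block["delta_ms"],
        mixing_time=block["delta_ms"] if kind is SequenceKind.STEAM else None,
    )


def tissue_relaxation() -> TissueRelaxation:
    t = load_protocol()["tissue"]
    return TissueRelaxation(t1=t["t1_ms"], t2=t["t2_ms"])


def reference_snr() -> Dict[str, float]:
    """Reported mean SNR per sequence (study reference levels)."""
    return {
        name: block["snr_reference"]
        for name, block in load_protocol()["sequences"].items()
    }


def background_b_samples() -> List[tuple]:
    """(mixing time ms, effective b s/mm^2) pairs for the STEAM series."""
    out = []
    for block in load_protocol()["sequences"].values():
        if block["kind"] == "STEAM":
            out.append((float(block["delta_ms"]), float(block["b0_effective"])))
    return out
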