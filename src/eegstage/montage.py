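"""Fixed 19-electrode 10-20 montage and diagnostic class labels.

Every stage of the pipeline assumes this exact electrode set in this exact
order; recordings read from disk are permuted into it on ingest.
"""

from __future__ import annotations

CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "F3", "C3", "P3", "O1", "F7", "T3", "T5",
    "Fz", "Cz", "Pz",
    "Fp2", "F4", "C4", "P4", "O2", "F8", "T4", "T6",
)
N_CHANNELS = len(CANONICAL_CHANNELS)

#: Diagnostic classes, in the fixed order used for confusion matrices,
#: metric tables and the softmax head: healthy subject, mild cognitive
#: impairment, Alzheimer's disease.
LABELS: tuple[str, ...] = ("HS", "MCI", "AD")

#: Sampling rates accepted on ingest (Hz). Everything is 256 Hz after
#: preprocessing.
INGEST_RATES: frozenset[int] = frozenset({256, 1024})
TARGET_FS = 256

# Electrode groups used by the synthetic generator's spatial weighting.
FRONTAL = ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz")
POSTERIOR = ("O1", "O2", "P3", "P4", "Pz", "T5", "T6")


def channel_index(name: str) -> int:
    """Position of an electrode in the canonical order (case-insensitive)."""
    lowered = [c.lower() for c in CANONICAL_CHANNELS]
    try:
        return lowered.index(name.strip().lower())
    except ValueError:
        raise KeyError(f"{name!r} is not one of the 19 montage electrodes") from None
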