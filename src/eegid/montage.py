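"""Frozen channel montage.

The recorded montage has 20 channels of the international 10-20 layout;
after re-referencing to the mastoid mean the two mastoids are dropped,
leaving 18 analysis channels in a fixed order. All pair indexing downstream
(cross-spectrum, coherence) depends on this order being stable.
"""

from __future__ import annotations

# Analysis order is frozen: feature rows and channel-pair rows are indexed
# by position in this list across runs, files and sessions.
ANALYSIS_CHANNELS: tuple[str, ...] = (
    "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4",
    "Pz", "P3", "P4",
    "PO7", "PO8", "TP7", "TP8",
    "Oz", "O1", "O2",
)

REFERENCE_CHANNELS: tuple[str, str] = ("M1", "M2")

RECORDED_CHANNELS: tuple[str, ...] = ANALYSIS_CHANNELS + REFERENCE_CHANNELS

N_ANALYSIS = len(ANALYSIS_CHANNELS)  # 18
N_RECORDED = len(RECORDED_CHANNELS)  # 20
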