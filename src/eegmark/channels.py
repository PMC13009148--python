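"""Canonical 10-channel montage shared by all sites.

The six sites record with different caps (19-58 electrodes); their overlap is
exactly ten 10-20 positions, and every stage of the pipeline works on this
fixed, ordered subset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: The shared channel set, in the fixed order the classifier input uses.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "F7", "F4", "P3", "O1", "F3", "C4", "F8", "O2", "P4", "C3",
)

#: Standard 10-20 lobe assignment for the ten shared electrodes.
LOBE_MAP: dict[str, str] = {
    "F7": "frontal", "F3": "frontal", "F4": "frontal", "F8": "frontal",
    "C3": "central", "C4": "central",
    "P3": "parietal", "P4": "parietal",
    "O1": "occipital", "O2": "occipital",
}

LOBES: tuple[str, ...] = ("frontal", "central", "parietal", "occipital")

# Common vendor prefixes/suffixes seen on EDF channel labels.
_LABEL_RE = re.compile(
    r"^(?:EEG[ _])?([A-Z]{1,2}[0-9]{0,2}Z?)(?:[-_](?:REF|LE|RE|A1|A2|AVG|M1|M2))?$",
    re.IGNORECASE,
)


def normalize_label(label: str) -> str:
    """Map a vendor channel label onto its bare 10-20 name.

    'EEG F7-REF' -> 'F7', 'f7' -> 'F7'.  Labels that do not look like a
    10-20 electrode are returned stripped and upper-cased unchanged.
    """
    stripped = label.strip()
    m = _LABEL_RE.match(stripped)
    if m:
        return m.group(1).upper()
    return stripped.upper()


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel names plus their lobe tags."""

    names: tuple[str, ...] = CANONICAL_CHANNELS
    lobe_map: dict[str, str] = field(default_factory=lambda: dict(LOBE_MAP))

    def __post_init__(self) -> None:
        if tuple(self.names) != CANONICAL_CHANNELS:
            raise ValueError(
                f"channel layout must be exactly {CANONICAL_CHANNELS} in order"
            )
        missing = [c for c in self.names if c not in self.lobe_map]
        if missing:
            raise ValueError(f"channels without a lobe tag: {missing}")

    def lobe_channels(self, lobe: str) -> list[str]:
        return [c for c in self.names if self.lobe_map[c] == lobe]
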