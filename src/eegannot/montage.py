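"""The 19-channel subset of the international 10-20 system used throughout the package.

The classifier operates on 19 standard channels in a fixed order; recordings from
higher-density caps (e.g. 64-channel BioSemi layouts) are reduced to this montage.
Older nomenclature for the temporal electrodes (T3/T4/T5/T6) and its modern
equivalent (T7/T8/P7/P8) are treated as aliases.
"""

from __future__ import annotations

# Fixed channel order expected by the network input (do not reorder).
STANDARD_19: tuple[str, ...] = (
    "Fp1", "F7", "T3", "T5", "F3", "C3", "P3", "O1",
    "Fp2", "F8", "T4", "T6", "F4", "C4", "P4", "O2",
    "Fz", "Cz", "Pz",
)

# Modern-name equivalents accepted when selecting channels.
ALIASES: dict[str, str] = {
    "t7": "T3",
    "t8": "T4",
    "p7": "T5",
    "p8": "T6",
}

#: Channels over the posterior scalp, where the resting alpha rhythm dominates.
POSTERIOR: tuple[str, ...] = ("P3", "P4", "Pz", "O1", "O2", "T5", "T6")

#: Frontal channels, the main site of ocular artifacts.
FRONTAL: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F8")

#: Temporal-chain channels, the main site of muscle artifacts.
TEMPORAL: tuple[str, ...] = ("T3", "T4", "T5", "T6", "F7", "F8")


def canonical_name(name: str) -> str:
    """Map a channel name to its canonical montage spelling, if it has one.

    Matching is case-insensitive and resolves the T3/T7-style aliases; names
    outside the 19-channel montage are returned unchanged (stripped).
    """
    key = name.strip().lower()
    if key in ALIASES:
        return ALIASES[key]
    for std in STANDARD_19:
        if key == std.lower():
            return std
    return name.strip()
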