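"""10-20 montage bookkeeping: the 30-channel layout and its brain-region partition.

Channel order follows the acquisition layout (frontal to frontal, wrapping
around the scalp), which is also the row order used for selection matrices.
"""

from __future__ import annotations

#: The 30 scalp channels, in montage (selection-matrix row) order.
MONTAGE_30: tuple[str, ...] = (
    "Fp1", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "CP5", "CP1",
    "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8", "CP6", "CP2",
    "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4", "F8", "Fp2", "Fz",
)

#: Brain-region partition of the montage (total and disjoint).
REGIONS: dict[str, frozenset[str]] = {
    "frontal": frozenset(
        {"Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
         "FC1", "FC2", "FC5", "FC6", "FT9", "FT10"}
    ),
    "central": frozenset({"C3", "C4", "Cz", "CP1", "CP2", "CP5", "CP6"}),
    "parietal": frozenset({"Pz", "P3", "P4", "P7", "P8"}),
    "occipital": frozenset({"O1", "Oz", "O2"}),
    "temporal": frozenset({"T7", "T8"}),
}


def default_region_map() -> dict[str, str]:
    """Map every montage channel name to its brain region.

    Returns
    -------
    dict
        ``{channel: region}`` with region one of ``frontal``, ``central``,
        ``parietal``, ``occipital``, ``temporal``.  The regions partition the
        30-channel montage (sizes 13 + 7 + 5 + 3 + 2).
    """
    out: dict[str, str] = {}
    for region, names in REGIONS.items():
        for name in names:
            if name in out:  # pragma: no cover - guarded by tests
                raise ValueError(f"channel {name} mapped to two regions")
            out[name] = region
    # preserve montage order for stable iteration
    return {ch: out[ch] for ch in MONTAGE_30}
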