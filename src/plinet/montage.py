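"""The 10-20 electrode montage used throughout the pipeline.

Recordings arrive with up to 21 scalp electrodes of the International
10-20 System.  All network analysis runs on a fixed 16-channel subset:
the reference (Cz), the frontopolar pair (Fp1, Fp2; muscle and eye
artifacts) and the ear electrodes (A1, A2; no brain activity) are
dropped.  Every matrix in the package indexes channels in
``CANONICAL_16`` order.
"""

from __future__ import annotations

# Analysis channels, in canonical order. All connectivity matrices,
# trees and per-node tables use this ordering.
CANONICAL_16: tuple[str, ...] = (
    "F3", "F4", "F7", "F8",
    "T3", "T4", "T5", "T6",
    "C3", "C4", "P3", "P4",
    "O1", "O2", "Fz", "Pz",
)

# Electrodes excluded from all analyses.
DEFAULT_EXCLUDE: tuple[str, ...] = ("Cz", "Fp1", "Fp2", "A1", "A2")

# The full 21-electrode acquisition montage.
FULL_21: tuple[str, ...] = CANONICAL_16 + DEFAULT_EXCLUDE

N_NODES = len(CANONICAL_16)
N_EDGES_MST = N_NODES - 1          # 15 edges in every spanning tree
N_PAIRS = N_NODES * (N_NODES - 1) // 2   # 120 unordered channel pairs

#: Frequency bands analysed by default (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
}


def validate_labels(labels) -> None:
    """Raise ``ValueError`` for labels outside the 21-channel montage."""
    unknown = [lab for lab in labels if lab not in FULL_21]
    if unknown:
        raise ValueError(
            f"unknown channel label(s) {unknown!r}; expected 10-20 labels "
            f"from {FULL_21!r}"
        )
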