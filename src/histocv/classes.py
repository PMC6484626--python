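"""The four-class Gleason label set and its severity order.

Patches are graded into one of four classes: benign tissue, or cancer of
Gleason grade 3 (low-grade), 4, or 5 (high-grade).  The severity order
``benign < G3 < G4 < G5`` defines both the ordinal indices used by the
quadratic-weighted kappa and the deterministic "most severe wins" tie-break
used by majority voting and the classifiers.
"""

from __future__ import annotations

CLASSES: tuple[str, ...] = ("benign", "G3", "G4", "G5")
N_CLASSES: int = len(CLASSES)

#: class name -> ordinal index in severity order (benign=0 ... G5=3)
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}

#: sentinel used in annotation tables for cores an annotator did not grade
MISSING: str = "MISSING"

#: integer code for MISSING in encoded label arrays
MISSING_CODE: int = -1


def encode_labels(labels) -> "np.ndarray":
    """Map an iterable of class names (or MISSING) to integer codes."""
    import numpy as np

    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab == MISSING or lab is None:
            out[i] = MISSING_CODE
        else:
            try:
                out[i] = CLASS_INDEX[lab]
            except KeyError:
                raise ValueError(f"unknown class label: {lab!r}") from None
    return out


def decode_labels(codes) -> list[str]:
    """Inverse of :func:`encode_labels`."""
    return [MISSING if c == MISSING_CODE else CLASSES[c] for c in codes]
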