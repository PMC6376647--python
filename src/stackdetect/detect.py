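"""End-to-end inference: z-stack -> plane triplet -> heatmap -> cell coordinates.

This is a plain composition of the already-tested operations; there is no
hidden post-processing.
"""

from __future__ import annotations

from stackdetect.adapt import find_peaks
from stackdetect.iostack import DetectionSet, ZStack, select_triplet
from stackdetect.model import Heatmap, UNet, predict_heatmap

__all__ = ["detect_cells"]


def detect_cells(
    detector: UNet,
    stack: ZStack,
    triplet_start: int = 13,
    peak_threshold: float = 0.2,
    peak_min_distance: int = 5,
) -> tuple[DetectionSet, Heatmap]:
    """Detect cell centres in a focus stack.

    The triplet of planes ``triplet_start .. triplet_start+2`` (1-based;
    default: the in-focus plane and the two above it) is normalized, run
    through the detector, and the heatmap's local peaks are returned as
    detections.  The unprocessed heatmap is returned alongside for
    inspection or archival.
    """
    triplet = select_triplet(stack, triplet_start, normalize=True)
    heatmap = predict_heatmap(detector, triplet)
    detections = find_peaks(heatmap, threshold=peak_threshold, min_distance=peak_min_distance)
    return detections, heatmap
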