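"""Functional-component summarization of detected anomalies.

Individual ROI-to-ROI "anomalies" (connections with recurrent significant
group differences) are too numerous to interpret one by one, so they are
summarized at the level of 10 large-scale functional components: the seven
canonical resting-state systems collapsed from the Yeo 17-network cortical
parcellation, plus three subcortical additions (brain stem, cerebellum,
basal ganglia) that the cortical atlas does not cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .permutation import FrequencyMatrix

__all__ = [
    "COMPONENTS",
    "SEVENTEEN_TO_TEN",
    "ComponentAtlas",
    "load_atlas",
    "assign_components",
    "anomalies_from_frequency",
    "distribution_matrix",
    "threshold_difference",
    "contribution_histogram",
]

#: Fixed component order used for every serialized 10x10 matrix.
COMPONENTS = ("VIS", "MOT", "DA", "VA", "FP", "LIM", "DMN", "BS", "CRB", "BG")
_COMP_INDEX = {c: i for i, c in enumerate(COMPONENTS)}

#: Collapse of the Yeo 17-network ids onto the 7 cortical components:
#: 1-2 visual, 3-4 and 14 sensorimotor, 5-6 dorsal attention, 7 ventral
#: attention, 8 and 11-13 frontoparietal, 9-10 limbic, 15-17 default mode.
SEVENTEEN_TO_TEN: dict[int, str] = {
    1: "VIS", 2: "VIS",
    3: "MOT", 4: "MOT", 14: "MOT",
    5: "DA", 6: "DA",
    7: "VA",
    8: "FP", 11: "FP", 12: "FP", 13: "FP",
    9: "LIM", 10: "LIM",
    15: "DMN", 16: "DMN", 17: "DMN",
}


@dataclass
class ComponentAtlas:
    """Map from ROI index to one of the 10 functional components.

    Cortical ROIs may be given by their Yeo-17 network id (collapsed via
    :data:`SEVENTEEN_TO_TEN`); subcortical ROIs carry an explicit BS, CRB
    or BG label.
    """

    roi_to_component: dict[int, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.roi_to_component.values()
               if v not in COMPONENTS}
        if bad:
            raise ValueError(f"unknown component labels: {sorted(bad)}")

    def component(self, roi: int) -> str:
        try:
            return self.roi_to_component[roi]
        except KeyError:
            raise KeyError(f"ROI {roi} has no component assignment") from None


def assign_components(
    roi_labels: Mapping[int, int | str],
    seventeen_to_ten: Mapping[int, str] | None = None,
) -> ComponentAtlas:
    """Build an atlas from per-ROI labels.

    Each ROI carries either a Yeo-17 integer id (collapsed to its
    component) or an explicit component string (passthrough, required for
    the subcortical components absent from the cortical parcellation).
    """
    table = dict(seventeen_to_ten) if seventeen_to_ten else SEVENTEEN_TO_TEN
    out: dict[int, str] = {}
    for roi, label in roi_labels.items():
        if isinstance(label, str) and not label.isdigit():
            if label not in COMPONENTS:
                raise ValueError(f"ROI {roi}: unknown component {label!r}")
            out[roi] = label
        else:
            yeo = int(label)
            if yeo not in table:
                raise ValueError(f"ROI {roi}: Yeo-17 id {yeo} out of range")
            out[roi] = table[yeo]
    return ComponentAtlas(out)


def load_atlas(path: str | Path) -> ComponentAtlas:
    """Read an atlas TSV with columns ``roi_index`` and ``label``
    (Yeo-17 id or explicit component string)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"roi_index", "label"}.issubset(df.columns):
        raise ValueError("atlas TSV needs columns: roi_index, label")
    return assign_components(
        {int(r.roi_index): r.label for r in df.itertuples(index=False)})


def anomalies_from_frequency(F: FrequencyMatrix | np.ndarray,
                             threshold: int) -> list[tuple[int, int]]:
    """Unordered ROI pairs with frequency >= threshold (upper triangle)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = F.counts if isinstance(F, FrequencyMatrix) else np.asarray(F)
    iu, ju = np.triu_indices(counts.shape[0], k=1)
    keep = counts[iu, ju] >= threshold
    return [(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])]


def distribution_matrix(anomalies: Sequence[tuple[int, int]],
                        atlas: ComponentAtlas) -> np.ndarray:
    """10x10 anomaly-distribution matrix with two-stage normalization.

    Raw counts are accumulated symmetrically (entry ``(a, b)`` = number of
    anomalies joining components ``a`` and ``b``; the diagonal holds
    intra-component anomalies). Each row's off-diagonal is then divided by
    that component's total number of inter-component anomalies, and the
    diagonal is divided by the total number of intra-component anomalies —
    so each row's off-diagonal sums to 1 (where nonzero) and the diagonal
    sums to 1 (where nonzero). Row normalization makes the result
    asymmetric in general: entry (DMN, FP) is the share of DMN's
    inter-network anomalies that connect to FP, not the reverse.
    """
    raw = np.zeros((10, 10))
    for i, j in anomalies:
        if i == j:
            raise ValueError(f"anomaly ({i}, {j}) is a self-connection")
        a = _COMP_INDEX[atlas.component(i)]
        b = _COMP_INDEX[atlas.component(j)]
        if a == b:
            raw[a, a] += 1
        else:
            raw[a, b] += 1
            raw[b, a] += 1
    out = np.zeros_like(raw)
    off = raw.copy()
    np.fill_diagonal(off, 0.0)
    row_totals = off.sum(axis=1)
    for r in range(10):
        if row_totals[r] > 0:
            out[r, :] = off[r, :] / row_totals[r]
    diag_total = np.trace(raw)
    if diag_total > 0:
        for r in range(10):
            out[r, r] = raw[r, r] / diag_total
    return out


def threshold_difference(A: np.ndarray, B: np.ndarray,
                         cutoff: float = 0.15) -> np.ndarray:
    """Binarized absolute difference of two distribution matrices:
    1 where ``|A - B| >= cutoff`` (inclusive)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return (np.abs(A - B) >= cutoff).astype(int)


def contribution_histogram(anomalies: Sequence[tuple[int, int]],
                           atlas: ComponentAtlas) -> dict[str, float]:
    """Relative contribution of each component to the detected anomalies.

    Every anomaly contributes one count to each *distinct* endpoint
    component: an inter-component anomaly splits its weight across its two
    components, an intra-component anomaly counts once for its single
    component. Returned fractions sum to 1.
    """
    if len(anomalies) == 0:
        raise ValueError("contribution histogram of an empty anomaly list")
    counts = {c: 0 for c in COMPONENTS}
    for i, j in anomalies:
        comps = {atlas.component(i), atlas.component(j)}
        for c in comps:
            counts[c] += 1
    total = sum(counts.values())
    return {c: counts[c] / total for c in COMPONENTS}
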