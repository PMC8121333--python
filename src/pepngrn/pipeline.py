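"""High-level inference pipeline: discretize -> evidence -> score -> sign-select -> threshold."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

from .datatypes import DiscretizedDataset, ScoredEdge, TimeSeriesDataset
from .discretize import DiscretizationConfig, discretize
from .evidence import EvidenceTable, build_state_pairs, extract_evidence
from .scoring import (
    DecayProfile,
    ThresholdConfig,
    decay_probability,
    score_v1,
    score_v2,
    select_signs,
    threshold_edges,
)


@dataclass
class InferenceResult:
    edges: List[ScoredEdge]          # sign-selected (and thresholded) ranking
    table: EvidenceTable
    decay: DecayProfile
    discretized: DiscretizedDataset


def infer_network(
    data: Union[TimeSeriesDataset, DiscretizedDataset],
    variant: str = "v1",
    discretization: Optional[DiscretizationConfig] = None,
    regulators: Optional[Sequence[str]] = None,
    thresholds: Optional[ThresholdConfig] = None,
    sign_tolerance: float = 1e-12,
) -> InferenceResult:
    """Run the unsupervised variants (v1/v2) end to end.

    ``data`` may be continuous (discretized per ``discretization``, default
    equal-frequency 2-bin) or already discrete.  ``regulators`` restricts
    candidate regulators to a known TF list.  When ``thresholds`` is given,
    the per-target regulator cap and score floor are applied after sign
    selection; otherwise the full sign-selected ranking is returned.
    """
    if variant not in ("v1", "v2"):
        raise ValueError(f"variant must be 'v1' or 'v2', got {variant!r}")
    if isinstance(data, DiscretizedDataset):
        disc = data
    else:
        disc = discretize(data, discretization or DiscretizationConfig())
    pairs = build_state_pairs(disc)
    table = extract_evidence(pairs, regulators=regulators)
    scored = score_v1(table) if variant == "v1" else score_v2(table)
    edges = select_signs(scored, tolerance=sign_tolerance)
    if thresholds is not None:
        edges = threshold_edges(edges, thresholds)
    return InferenceResult(edges=edges, table=table,
                           decay=decay_probability(disc), discretized=disc)
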