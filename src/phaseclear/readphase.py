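"""Quality-weighted read-backed phase calling for a variant pair.

Each supporting fragment is weighted by one minus the average of its two
per-site mean base-error probabilities (so perfect bases weigh 1.0).
The pair confidence is

    |TransSubscore - CisSubscore| / (n + 2)

with TransSubscore the sum of trans fragment weights, CisSubscore the
sum of cis fragment weights doubled and capped at n, and n the total
number of fragments overlapping both positions (including fragments that
match the reference at both sites).  The score lies in [0, 1); calls
below the low-quality threshold (default 0.34) are still emitted, the
threshold only labels them.
"""

from __future__ import annotations

from typing import Optional

from phaseclear.datamodel import EvidenceSummary, FragmentEvidence, PhaseEdge

#: Default confidence threshold separating high- from low-quality calls.
LOW_QUALITY_THRESHOLD = 0.34


def fragment_weight(ev: FragmentEvidence) -> float:
    """Weight of one supporting fragment: 1 - mean of the two per-site
    mean base-error probabilities (in [0, 1], 1.0 for perfect bases)."""
    return 1.0 - (ev.corrected_v1 + ev.corrected_v2) / 2.0


def _subscores(es: EvidenceSummary) -> tuple[float, float]:
    trans = sum(fragment_weight(f) for f in es.fragments if f.kind == "trans")
    cis_raw = sum(fragment_weight(f) for f in es.fragments if f.kind == "cis")
    cis = min(2.0 * cis_raw, float(es.n))
    return trans, cis


def confidence_score(es: EvidenceSummary) -> float:
    """Pair confidence |TransSubscore - CisSubscore| / (n + 2)."""
    trans, cis = _subscores(es)
    return abs(trans - cis) / (es.n + 2)


def call_direct_phase(es: EvidenceSummary) -> Optional[PhaseEdge]:
    """Direct cis/trans call from the subscores, or None.

    Orientation follows the larger subscore; an exact tie (including the
    no-evidence case) yields no call — abstaining is the safe clinical
    choice where no tie-break is defined.
    """
    trans, cis = _subscores(es)
    if trans == cis:
        return None
    return PhaseEdge(
        endpoints=frozenset(),  # filled by the caller with site identities
        orientation="cis" if cis > trans else "trans",
        confidence=confidence_score(es),
        source="read",
    )
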