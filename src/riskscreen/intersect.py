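"""Direction-consistent intersection of per-cohort DEG lists (the Venn stage).

A gene is common only if it is significant with the SAME direction in every
cohort.  Genes significant everywhere but with mixed directions are reported
as ``conflicted``, never silently merged or dropped.  The intersection is
computed over the common gene universe; genes missing from some cohort
(platform differences) are excluded with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .deg import DegScreenResult

logger = logging.getLogger(__name__)


@dataclass
class IntersectionResult:
    up_common: set[str]
    down_common: set[str]
    conflicted: set[str]
    per_cohort_membership: dict[str, dict[str, str]] = field(repr=False)

    @property
    def common(self) -> set[str]:
        return self.up_common | self.down_common

    def direction_of(self, gene: str) -> str | None:
        if gene in self.up_common:
            return "up"
        if gene in self.down_common:
            return "down"
        return None


def intersect_degs(results: list[DegScreenResult]) -> IntersectionResult:
    """Intersect ≥2 per-cohort screens with direction consistency required."""
    if not results:
        raise ValueError("no DEG screen results to intersect")
    if len(results) < 2:
        raise ValueError("need at least 2 cohorts to intersect")

    universes = [set(r.gene for r in res.records) for res in results]
    universe = set.intersection(*universes)
    dropped = len(set.union(*universes)) - len(universe)
    if dropped:
        logger.warning(
            "intersection universe excludes %d gene(s) absent from at "
            "least one cohort", dropped)

    up_sets = [res.up_genes & universe for res in results]
    down_sets = [res.down_genes & universe for res in results]

    up_common = set.intersection(*up_sets)
    down_common = set.intersection(*down_sets)
    # significant in every cohort but not direction-consistent
    sig_everywhere = set.intersection(
        *[(u | d) for u, d in zip(up_sets, down_sets)])
    conflicted = sig_everywhere - up_common - down_common

    membership = {
        g: {res.dataset_id: res.direction_of(g) for res in results}
        for g in sorted(up_common | down_common | conflicted)
    }
    return IntersectionResult(up_common=up_common, down_common=down_common,
                              conflicted=conflicted,
                              per_cohort_membership=membership)
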