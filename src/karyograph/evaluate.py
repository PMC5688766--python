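"""Solution-quality measures comparing a reconstruction against the true karyotype.

Five measures of decreasing stringency:

* **correct** -- the reconstruction is *equivalent* to the truth: same integer
  CN profile and the same set of bridges used (orientation and chromosome
  order are ignored; equivalent karyotypes typically differ only in those).
* **ECN** (equal copy number) -- the CN profiles match.
* **EBS** (equal-or-better score) -- the reconstruction's discordance score on
  the noisy graph is no worse than the truth's.
* **EOB** (equivalent for observed bridges) -- equivalence after discounting
  bridges the observation missed: every observed bridge is used and the CN
  matches on every interval not flanking a missed bridge.
* **CN score** -- the length-weighted fraction of intervals with the correct CN.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import BridgeGraph
from .reconstruct import (
    EdgeMultiplicities,
    Solution,
    discordance_score,
    karyotype_multiplicities,
)
from .segments import (
    Extremity,
    Karyotype,
    KaryographError,
    ReferenceSegmentation,
    canonical_pair,
)

_TOL = 1e-9


@dataclass
class EvalReport:
    correct: bool
    ecn: bool
    ebs: bool
    eob: bool
    cn_score: float
    score_solution: float
    score_truth: float

    def as_dict(self) -> dict:
        return {
            "correct": self.correct,
            "ecn": self.ecn,
            "ebs": self.ebs,
            "eob": self.eob,
            "cn_score": self.cn_score,
            "score_solution": self.score_solution,
            "score_truth": self.score_truth,
        }


def _solution_cn(sol: Solution, g: BridgeGraph) -> dict[tuple[str, int], int]:
    em = sol.multiplicities
    return {(c.u.chrom, c.u.index): em.f(c) for c in g.interval_connections()}


def _bridges_used(sol: Solution, g: BridgeGraph) -> set[tuple[Extremity, Extremity]]:
    em = sol.multiplicities
    return {
        canonical_pair(c.u, c.v) for c in g.bridge_connections() if em.f(c) >= 1
    }


def _check_same_segmentation(g: BridgeGraph, seg: ReferenceSegmentation) -> None:
    if g.segmentation.chromosomes != seg.chromosomes:
        raise KaryographError("solution and truth use different segmentations")


def equal_cn_profile(
    cn_solution: dict[tuple[str, int], int], cn_truth: dict[tuple[str, int], int]
) -> bool:
    """ECN: exact equality of the integer CN vectors."""
    return cn_solution == cn_truth


def is_equivalent(
    sol: Solution,
    g: BridgeGraph,
    cn_truth: dict[tuple[str, int], int],
    bridges_truth: set[tuple[Extremity, Extremity]],
) -> bool:
    """Equivalence: identical CN profile and identical set of bridges used."""
    return (
        equal_cn_profile(_solution_cn(sol, g), cn_truth)
        and _bridges_used(sol, g) == bridges_truth
    )


def equal_or_better_score(
    sol: Solution, g: BridgeGraph, truth: Karyotype, alpha: float
) -> tuple[bool, float, float]:
    """EBS: score both karyotypes on the same noisy graph.  Truth junctions
    whose bridge went unobserved contribute nothing (they have no connection)."""
    em_truth = karyotype_multiplicities(g, truth, on_missing="skip")
    score_truth = discordance_score(g, em_truth, alpha)
    return sol.score <= score_truth + _TOL, sol.score, score_truth


def equivalent_observed_bridges(
    sol: Solution,
    g: BridgeGraph,
    cn_truth: dict[tuple[str, int], int],
    bridges_truth: set[tuple[Extremity, Extremity]],
) -> bool:
    """EOB: every observed bridge is used, and the CN profile matches the truth
    on every interval that does not own an extremity of a missed bridge."""
    observed = {canonical_pair(c.u, c.v) for c in g.bridge_connections()}
    if not observed <= bridges_truth:
        raise KaryographError("observed bridges are not a subset of true bridges")
    if not observed <= _bridges_used(sol, g):
        return False
    dropped = bridges_truth - observed
    affected = {e.interval for pair in dropped for e in pair}
    cn_sol = _solution_cn(sol, g)
    return all(
        cn_sol[key] == cn_truth[key] for key in cn_truth if key not in affected
    )


def cn_score(
    cn_solution: dict[tuple[str, int], int],
    cn_truth: dict[tuple[str, int], int],
    seg: ReferenceSegmentation,
) -> float:
    """Length-weighted fraction of intervals whose CN is exactly right."""
    L = seg.total_length
    agree = sum(
        l for c, j, l in seg.intervals() if cn_solution[(c, j)] == cn_truth[(c, j)]
    )
    return agree / L


def evaluate_solution(
    sol: Solution,
    g: BridgeGraph,
    truth: Karyotype,
    cn_truth: dict[tuple[str, int], int],
    bridges_truth: set[tuple[Extremity, Extremity]],
    seg: ReferenceSegmentation,
    alpha: float,
) -> EvalReport:
    """Compute all five measures for one reconstruction."""
    _check_same_segmentation(g, seg)
    cn_sol = _solution_cn(sol, g)
    ecn = equal_cn_profile(cn_sol, cn_truth)
    correct = ecn and _bridges_used(sol, g) == bridges_truth
    ebs, s_sol, s_truth = equal_or_better_score(sol, g, truth, alpha)
    eob = equivalent_observed_bridges(sol, g, cn_truth, bridges_truth)
    return EvalReport(
        correct=correct,
        ecn=ecn,
        ebs=ebs,
        eob=eob,
        cn_score=cn_score(cn_sol, cn_truth, seg),
        score_solution=s_sol,
        score_truth=s_truth,
    )
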