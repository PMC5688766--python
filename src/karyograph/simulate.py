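"""Tumor karyotype simulation: random rearrangement operations plus noise.

The generator starts from a diploid genome of ``C`` chromosomes, each a run of
300 equal-size atomic segments (the smallest unit at which a breakpoint can
fall), applies ``N`` rearrangement operations drawn uniformly among deletion,
inversion, tandem duplication and translocation, then derives the exact
segmentation, CN profile and bridge set, and finally corrupts them the way real
short-read data is corrupted: i.i.d. Gaussian noise on each interval CN,
exponential read support per bridge, and a per-bridge probability of being
missed entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segments import (
    Bridge,
    Extremity,
    Karyotype,
    KaryographError,
    ObservedData,
    ReferenceSegmentation,
    SignedUnit,
    derive_breakpoints,
    derive_bridges,
    derive_cn_profile,
)

DELETION = "deletion"
INVERSION = "inversion"
TANDEM_DUPLICATION = "tandem_duplication"
TRANSLOCATION = "translocation"
CHROMOSOME_GAIN = "chromosome_gain"
CHROMOSOME_LOSS = "chromosome_loss"

STRUCTURAL_OPS = (DELETION, INVERSION, TANDEM_DUPLICATION, TRANSLOCATION)

_INTRA_OPS = frozenset({DELETION, INVERSION, TANDEM_DUPLICATION})


class DegenerateKaryotypeError(KaryographError):
    """No rearrangement operation can be applied to the current karyotype."""


@dataclass(frozen=True)
class ScenarioParams:
    """Simulation scenario.

    Defaults are the base scenario: 5 chromosomes, 5 operations, CN noise
    s.d. 0.28 (estimated from real tumor segments), bridge drop probability
    0.05, support rate λ=0.1866 (mean support 1/λ ≈ 5.4), diploid, 300 atomic
    segments per chromosome, intra-chromosomal span limited to 30 segments.
    """

    n_chromosomes: int = 5  # C
    n_operations: int = 5  # N
    cn_noise: float = 0.28  # ε, s.d. of Gaussian CN noise
    drop_prob: float = 0.05  # p, probability a bridge goes unobserved
    support_rate: float = 0.1866  # λ of the exponential support distribution
    segments_per_chromosome: int = 300
    max_span: int = 30
    op_weights: dict[str, float] = field(
        default_factory=lambda: {op: 0.25 for op in STRUCTURAL_OPS}
    )
    ploidy: int = 2
    normal_fraction: float = 0.0  # healthy-tissue contamination weight
    round_support: bool = False  # round Exp(λ) draws to nearest positive integer
    preserve_telomeres: bool = False  # restrict operations to chromosome interiors
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_prob <= 1.0:
            raise KaryographError("drop_prob must be in [0, 1]")
        if self.cn_noise < 0:
            raise KaryographError("cn_noise must be >= 0")
        if self.support_rate <= 0:
            raise KaryographError("support_rate must be > 0")
        if not 0.0 <= self.normal_fraction < 1.0:
            raise KaryographError("normal_fraction must be in [0, 1)")
        total = sum(self.op_weights.values())
        if not np.isclose(total, 1.0):
            raise KaryographError("op_weights must sum to 1")
        if any(w < 0 for w in self.op_weights.values()):
            raise KaryographError("op_weights must be nonnegative")

    def with_(self, **kwargs) -> "ScenarioParams":
        return replace(self, **kwargs)


@dataclass
class SimulatedInstance:
    """A simulated tumor with its noiseless ground truth."""

    params: ScenarioParams
    reference_chromosomes: dict[str, int]  # chromosome -> number of atoms
    tumor_atoms: Karyotype
    segmentation: ReferenceSegmentation
    tumor: Karyotype  # re-expressed over intervals
    cn_true: dict[tuple[str, int], int]
    bridges_true: set[tuple[Extremity, Extremity]]


# ---------------------------------------------------------------------------
# Rearrangement operations
# ---------------------------------------------------------------------------

def _draw_run(
    length: int, max_span: int, rng: np.random.Generator, interior: bool
) -> tuple[int, int]:
    """Draw a contiguous run [i, j] (0-based, inclusive) of a chromosome.

    Start is uniform over the allowed positions, then the span uniform in
    [1, min(max_span, remaining)], so operations may reach (and disrupt) the
    chromosome end unless ``interior``.
    """
    if interior:
        # keep the first and last element untouched
        if length < 3:
            raise DegenerateKaryotypeError("chromosome too short for interior run")
        i = int(rng.integers(1, length - 1))
        span = int(rng.integers(1, min(max_span, length - 1 - i) + 1))
        return i, i + span - 1
    i = int(rng.integers(0, length))
    span = int(rng.integers(1, min(max_span, length - i) + 1))
    return i, i + span - 1


def _op_feasible(op: str, chroms: list[list[SignedUnit]], interior: bool) -> bool:
    if op in _INTRA_OPS:
        need = 3 if interior else 1
        return any(len(c) >= need for c in chroms)
    if op == TRANSLOCATION:
        need = 2 if interior else 1
        return sum(1 for c in chroms if len(c) >= need) >= 2
    if op == CHROMOSOME_GAIN:
        return len(chroms) >= 1
    if op == CHROMOSOME_LOSS:
        return len(chroms) >= 1
    raise KaryographError(f"unknown operation type {op!r}")


def apply_operation(
    k: Karyotype,
    op_type: str,
    rng: np.random.Generator,
    max_span: int = 30,
    preserve_telomeres: bool = False,
) -> Karyotype:
    """Apply one rearrangement operation at a uniformly drawn position.

    Deletion removes a run of at most ``max_span`` units from one chromosome
    copy, inversion reverses it in place (flipping signs), tandem duplication
    inserts a copy of the run immediately after itself, and translocation swaps
    the suffixes of two distinct chromosomes ((A,B),(C,D) -> (A,D),(C,B)).
    """
    chroms = [list(c) for c in k.chromosomes]
    if not _op_feasible(op_type, chroms, preserve_telomeres):
        raise DegenerateKaryotypeError(f"{op_type} not applicable")

    if op_type in _INTRA_OPS:
        need = 3 if preserve_telomeres else 1
        eligible = [ci for ci, c in enumerate(chroms) if len(c) >= need]
        ci = int(eligible[rng.integers(0, len(eligible))])
        chrom = chroms[ci]
        i, j = _draw_run(len(chrom), max_span, rng, preserve_telomeres)
        run = chrom[i : j + 1]
        if op_type == DELETION:
            chroms[ci] = chrom[:i] + chrom[j + 1 :]
            if not chroms[ci]:
                del chroms[ci]
        elif op_type == INVERSION:
            chroms[ci] = (
                chrom[:i]
                + [(c, p, -s) for (c, p, s) in reversed(run)]
                + chrom[j + 1 :]
            )
        else:  # tandem duplication
            chroms[ci] = chrom[: j + 1] + run + chrom[j + 1 :]
    elif op_type == TRANSLOCATION:
        need = 2 if preserve_telomeres else 1
        eligible = [ci for ci, c in enumerate(chroms) if len(c) >= need]
        pick = rng.choice(len(eligible), size=2, replace=False)
        a, b = eligible[int(pick[0])], eligible[int(pick[1])]
        ca, cb = chroms[a], chroms[b]
        if preserve_telomeres:
            cut_a = int(rng.integers(1, len(ca)))
            cut_b = int(rng.integers(1, len(cb)))
        else:
            cut_a = int(rng.integers(0, len(ca) + 1))
            cut_b = int(rng.integers(0, len(cb) + 1))
        chroms[a] = ca[:cut_a] + cb[cut_b:]
        chroms[b] = cb[:cut_b] + ca[cut_a:]
        chroms = [c for c in chroms if c]
    elif op_type == CHROMOSOME_GAIN:
        ci = int(rng.integers(0, len(chroms)))
        chroms.append(list(chroms[ci]))
    elif op_type == CHROMOSOME_LOSS:
        ci = int(rng.integers(0, len(chroms)))
        del chroms[ci]
    else:
        raise KaryographError(f"unknown operation type {op_type!r}")

    return Karyotype(chroms)


# ---------------------------------------------------------------------------
# Simulation protocol
# ---------------------------------------------------------------------------

def _normal_karyotype(params: ScenarioParams) -> tuple[dict[str, int], Karyotype]:
    ref = {
        f"chr{c}": params.segments_per_chromosome
        for c in range(1, params.n_chromosomes + 1)
    }
    chroms = [
        [(name, p, 1) for p in range(1, n + 1)]
        for name, n in ref.items()
        for _ in range(params.ploidy)
    ]
    return ref, Karyotype(chroms)


def simulate_tumor(
    params: ScenarioParams, rng: np.random.Generator | None = None
) -> SimulatedInstance:
    """Steps 1-3 of the protocol: normal karyotype, N operations, exact truth."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ref, k = _normal_karyotype(params)
    ops = list(params.op_weights)
    weights = np.array([params.op_weights[o] for o in ops], dtype=float)

    for _ in range(params.n_operations):
        allowed = [
            oi
            for oi, o in enumerate(ops)
            if weights[oi] > 0 and _op_feasible(o, k.chromosomes, params.preserve_telomeres)
        ]
        if not allowed:
            raise DegenerateKaryotypeError("no operation applicable")
        w = weights[allowed] / weights[allowed].sum()
        op = ops[int(rng.choice(allowed, p=w))]
        k = apply_operation(
            k, op, rng, max_span=params.max_span,
            preserve_telomeres=params.preserve_telomeres,
        )

    seg, tumor = derive_breakpoints(ref, k)
    return SimulatedInstance(
        params=params,
        reference_chromosomes=ref,
        tumor_atoms=k,
        segmentation=seg,
        tumor=tumor,
        cn_true=derive_cn_profile(tumor, seg),
        bridges_true=derive_bridges(tumor, seg),
    )


def add_noise(
    instance: SimulatedInstance,
    params: ScenarioParams | None = None,
    rng: np.random.Generator | None = None,
) -> ObservedData:
    """Step 4: Gaussian CN noise, bridge dropout, exponential support.

    With ``normal_fraction`` m > 0 the tumor CN is first mixed with the normal
    ploidy, ``(1-m)*cn + m*ploidy``, emulating healthy-tissue contamination.
    Observed CN is deliberately not clipped at 0: the discordance score uses
    absolute deviations and clipping would bias it.
    """
    if params is None:
        params = instance.params
    if rng is None:
        rng = np.random.default_rng(params.seed)

    m = params.normal_fraction
    cn_obs: dict[tuple[str, int], float] = {}
    for key, cn in instance.cn_true.items():
        base = (1.0 - m) * cn + m * params.ploidy if m > 0 else float(cn)
        cn_obs[key] = base + rng.normal(0.0, params.cn_noise)

    bridges: list[Bridge] = []
    for pair in sorted(instance.bridges_true):
        if rng.random() < params.drop_prob:
            continue
        support = rng.exponential(1.0 / params.support_rate)
        if params.round_support:
            support = max(1.0, round(support))
        bridges.append(Bridge(pair[0], pair[1], support))
    return ObservedData(cn=cn_obs, bridges=bridges)


def simulate_instance(
    params: ScenarioParams, seed: int | None = None
) -> tuple[SimulatedInstance, ObservedData]:
    """One full simulated run (truth + noisy observation) from a single RNG."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    inst = simulate_tumor(params, rng)
    return inst, add_noise(inst, params, rng)
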