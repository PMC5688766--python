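"""Reference segmentations, rearranged karyotypes, and the observables they induce.

A reference genome is a set of chromosomes, each partitioned by breakpoints into
an ordered list of intervals.  A (tumor) karyotype is a multiset of chromosomes,
each an ordered sequence of signed intervals: ``+I`` traverses the interval
tail-to-head, ``-I`` head-to-tail.  Comparing a karyotype against its reference
yields the two observables the reconstruction works from: the per-interval copy
number (how many times each interval occurs in the tumor, in either orientation)
and the set of *bridges* -- extremity pairs adjacent in the tumor but not in the
reference, i.e. novel adjacencies / SV junctions.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field
from itertools import accumulate
from typing import Iterable, Iterator, NamedTuple

TAIL = "T"
HEAD = "H"

#: a signed unit (atomic segment or interval): (chromosome, 1-based index, sign)
SignedUnit = tuple[str, int, int]


class KaryographError(ValueError):
    """Base class for invalid-input errors raised by this package."""


class Extremity(NamedTuple):
    """A tail or head of a reference interval."""

    chrom: str
    index: int
    side: str  # TAIL or HEAD

    def __repr__(self) -> str:  # t1/h1 style, compact for debugging and DOT
        return f"{self.side.lower()}_{self.chrom}:{self.index}"

    @property
    def interval(self) -> tuple[str, int]:
        return (self.chrom, self.index)


def _extremity_key(e: Extremity) -> tuple:
    return (e.chrom, e.index, 0 if e.side == TAIL else 1)


def canonical_pair(a: Extremity, b: Extremity) -> tuple[Extremity, Extremity]:
    """Order an unordered extremity pair canonically so {a,b} == {b,a}."""
    return (a, b) if _extremity_key(a) <= _extremity_key(b) else (b, a)


@dataclass(frozen=True)
class Bridge:
    """An unordered pair of extremities adjacent in the tumor but not in the
    reference, with its read support.  Fold-backs ({h,h} self-pairs) are legal."""

    first: Extremity
    second: Extremity
    support: float = 0.0

    @staticmethod
    def make(a: Extremity, b: Extremity, support: float = 0.0) -> "Bridge":
        a, b = canonical_pair(a, b)
        return Bridge(a, b, support)

    @property
    def pair(self) -> tuple[Extremity, Extremity]:
        return (self.first, self.second)

    def __post_init__(self) -> None:
        if self.support < 0:
            raise KaryographError(f"negative bridge support: {self.support}")
        if _extremity_key(self.first) > _extremity_key(self.second):
            raise KaryographError("bridge pair not in canonical order; use Bridge.make")


@dataclass
class ReferenceSegmentation:
    """Chromosomes partitioned into ordered intervals with lengths.

    ``chromosomes`` maps chromosome name to the ordered list of interval
    lengths; interval ``(c, j)`` (1-based j) has length ``lengths[j-1]``.
    """

    chromosomes: dict[str, list[int]]

    def __post_init__(self) -> None:
        for chrom, lengths in self.chromosomes.items():
            if not lengths:
                raise KaryographError(f"chromosome {chrom} has no intervals")
            if any(l <= 0 for l in lengths):
                raise KaryographError(f"non-positive interval length on {chrom}")

    # -- interval accessors ------------------------------------------------
    def intervals(self) -> Iterator[tuple[str, int, int]]:
        """Yield (chrom, index, length) in reference order."""
        for chrom, lengths in self.chromosomes.items():
            for j, l in enumerate(lengths, start=1):
                yield chrom, j, l

    def length(self, chrom: str, index: int) -> int:
        return self.chromosomes[chrom][index - 1]

    @property
    def total_length(self) -> int:
        """L, the summed length of all intervals."""
        return sum(sum(lengths) for lengths in self.chromosomes.values())

    @property
    def n_intervals(self) -> int:
        return sum(len(lengths) for lengths in self.chromosomes.values())

    def boundaries(self, chrom: str) -> list[int]:
        """Cumulative start coordinates (0-based, half-open) of each interval."""
        return [0, *accumulate(self.chromosomes[chrom])][:-1]

    # -- extremities -------------------------------------------------------
    def extremities(self) -> Iterator[Extremity]:
        for chrom, j, _ in self.intervals():
            yield Extremity(chrom, j, TAIL)
            yield Extremity(chrom, j, HEAD)

    def telomeres(self) -> set[Extremity]:
        """S: the tail of the first and the head of the last interval per chromosome."""
        s: set[Extremity] = set()
        for chrom, lengths in self.chromosomes.items():
            s.add(Extremity(chrom, 1, TAIL))
            s.add(Extremity(chrom, len(lengths), HEAD))
        return s

    def has_extremity(self, e: Extremity) -> bool:
        lengths = self.chromosomes.get(e.chrom)
        return (
            lengths is not None
            and 1 <= e.index <= len(lengths)
            and e.side in (TAIL, HEAD)
        )

    def is_reference_adjacency(self, a: Extremity, b: Extremity) -> bool:
        """True iff {a,b} = {h_i, t_{i+1}} of consecutive intervals on one chromosome."""
        a, b = canonical_pair(a, b)
        return (
            a.chrom == b.chrom
            and a.side == HEAD
            and b.side == TAIL
            and b.index == a.index + 1
        )


@dataclass
class Karyotype:
    """A multiset of chromosomes, each an ordered sequence of signed units.

    Units may be atomic segments (simulation substrate) or reference intervals;
    the class is agnostic.  Empty chromosomes are never stored.
    """

    chromosomes: list[list[SignedUnit]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(not c for c in self.chromosomes):
            raise KaryographError("empty chromosome in karyotype")

    @property
    def n_units(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def reversed(self) -> "Karyotype":
        """The same genome with every chromosome read in the opposite direction."""
        return Karyotype(
            [[(c, i, -s) for (c, i, s) in reversed(chrom)] for chrom in self.chromosomes]
        )

    def unit_counts(self) -> Counter:
        """Occurrences of each unit, both orientations pooled."""
        return Counter((c, i) for chrom in self.chromosomes for (c, i, _) in chrom)

    # -- adjacency geometry --------------------------------------------------
    @staticmethod
    def out_extremity(u: SignedUnit) -> Extremity:
        """The extremity a traversal of u exits through (head if +, tail if -)."""
        c, i, s = u
        return Extremity(c, i, HEAD if s > 0 else TAIL)

    @staticmethod
    def in_extremity(u: SignedUnit) -> Extremity:
        """The extremity a traversal of u enters through (tail if +, head if -)."""
        c, i, s = u
        return Extremity(c, i, TAIL if s > 0 else HEAD)

    def adjacencies(self) -> Iterator[tuple[Extremity, Extremity]]:
        """All (out-extremity, in-extremity) junctions between consecutive units."""
        for chrom in self.chromosomes:
            for u, v in zip(chrom, chrom[1:]):
                yield self.out_extremity(u), self.in_extremity(v)


@dataclass
class ObservedData:
    """What the reconstruction sees: a real-valued CN per interval and bridges
    with support.  ``mu`` is the total support score over all bridges."""

    cn: dict[tuple[str, int], float]
    bridges: list[Bridge]

    @property
    def mu(self) -> float:
        return sum(b.support for b in self.bridges)

    def validate_against(self, seg: ReferenceSegmentation) -> None:
        for chrom, j, _ in seg.intervals():
            if (chrom, j) not in self.cn:
                raise KaryographError(f"CN missing for interval {chrom}:{j}")
        for b in self.bridges:
            for e in b.pair:
                if not seg.has_extremity(e):
                    raise KaryographError(f"bridge extremity {e} not in segmentation")
            if seg.is_reference_adjacency(*b.pair):
                raise KaryographError(
                    f"bridge {b.pair} duplicates a reference adjacency"
                )


# ---------------------------------------------------------------------------
# Deriving the segmentation and observables from an atomic-level karyotype
# ---------------------------------------------------------------------------

def _is_reference_atomic_adjacency(u: SignedUnit, v: SignedUnit) -> bool:
    """Whether the junction u|v reproduces a reference adjacency between atoms
    (forward: +a,+(a+1); or the same adjacency traversed in reverse: -a,-(a-1))."""
    cu, pu, su = u
    cv, pv, sv = v
    if cu != cv or su != sv:
        return False
    return pv == pu + 1 if su > 0 else pv == pu - 1


def derive_breakpoints(
    reference_chromosomes: dict[str, int],
    tumor: Karyotype,
) -> tuple[ReferenceSegmentation, Karyotype]:
    """Detect breakpoints by comparing tumor to reference and partition each
    reference chromosome into intervals.

    ``reference_chromosomes`` maps chromosome name to its number of atomic
    segments (atoms are implicitly numbered 1..n).  Returns the coarsest
    segmentation under which the tumor can be re-expressed over whole intervals,
    together with the re-expressed tumor.  Cuts are forced by (a) every tumor
    junction that is not a reference adjacency and (b) every tumor chromosome
    end that is not a reference chromosome end.
    """
    for chrom in tumor.chromosomes:
        for (c, p, s) in chrom:
            n = reference_chromosomes.get(c)
            if n is None or not (1 <= p <= n):
                raise KaryographError(f"unknown atomic segment {c}:{p}")
            if s not in (1, -1):
                raise KaryographError(f"invalid sign {s} for {c}:{p}")

    # cuts[c] = set of atom indices q such that the reference is cut after atom q
    cuts: dict[str, set[int]] = {c: set() for c in reference_chromosomes}

    def cut_at(e: Extremity) -> None:
        q = e.index if e.side == HEAD else e.index - 1
        if 0 < q < reference_chromosomes[e.chrom]:
            cuts[e.chrom].add(q)

    for chrom in tumor.chromosomes:
        cut_at(Karyotype.in_extremity(chrom[0]))
        cut_at(Karyotype.out_extremity(chrom[-1]))
        for u, v in zip(chrom, chrom[1:]):
            if not _is_reference_atomic_adjacency(u, v):
                cut_at(Karyotype.out_extremity(u))
                cut_at(Karyotype.in_extremity(v))

    lengths: dict[str, list[int]] = {}
    starts: dict[str, list[int]] = {}  # 1-based atom index starting each interval
    for c, n in reference_chromosomes.items():
        bounds = sorted(cuts[c])
        edges = [0, *bounds, n]
        lengths[c] = [b - a for a, b in zip(edges, edges[1:])]
        starts[c] = [a + 1 for a in edges[:-1]]
    seg = ReferenceSegmentation(lengths)

    # re-express the tumor over intervals
    def interval_of(c: str, p: int) -> int:
        return bisect_left(starts[c], p + 1)  # 1-based interval index

    new_chroms: list[list[SignedUnit]] = []
    for chrom in tumor.chromosomes:
        out: list[SignedUnit] = []
        k = 0
        while k < len(chrom):
            c, p, s = chrom[k]
            j = interval_of(c, p)
            start = starts[c][j - 1]
            span = seg.length(c, j)
            run = chrom[k : k + span]
            if s > 0:
                expected = [(c, start + t, 1) for t in range(span)]
            else:
                expected = [(c, start + span - 1 - t, -1) for t in range(span)]
            if run != expected:
                raise KaryographError(
                    f"tumor chromosome does not thread through interval {c}:{j} intact"
                )
            out.append((c, j, s))
            k += span
        new_chroms.append(out)
    return seg, Karyotype(new_chroms)


def derive_cn_profile(
    tumor: Karyotype, seg: ReferenceSegmentation
) -> dict[tuple[str, int], int]:
    """Integer CN profile: occurrences of each interval in the tumor, counting
    both orientations.  Intervals absent from the tumor get CN 0."""
    counts = tumor.unit_counts()
    return {(c, j): counts.get((c, j), 0) for c, j, _ in seg.intervals()}


def derive_bridges(
    tumor: Karyotype, seg: ReferenceSegmentation
) -> set[tuple[Extremity, Extremity]]:
    """The set of extremity pairs adjacent in the tumor but not in the
    reference, each reported once.  Reference adjacencies traversed in reverse
    are not bridges; fold-back self-pairs are."""
    out: set[tuple[Extremity, Extremity]] = set()
    for a, b in tumor.adjacencies():
        if not seg.is_reference_adjacency(a, b):
            out.add(canonical_pair(a, b))
    return out
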