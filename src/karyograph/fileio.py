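"""Readers and writers for the package's plain-text formats.

* CN profile: BED-like TSV ``chrom  start  end  interval_id  cn`` (0-based,
  half-open, cn real-valued; intervals must tile each chromosome contiguously).
* Bridges: BEDPE-like TSV ``chrom1 pos1 side1 chrom2 pos2 side2 support``.
  Standard BEDPE has no notion of which side of a breakpoint an extremity is
  on, so an explicit side column (H = head, T = tail) is the minimal extension;
  positions are interval-boundary coordinates (tail -> interval start, head ->
  interval end).
* Karyotypes: one chromosome per line, comma-separated signed interval ids of
  the form ``[-]chrom:index``.
* Solutions: a directory with the reconstructed karyotype, the per-connection
  edge multiplicities (TSV), any detached cycles, and a JSON score record.

Lines starting with ``#`` are comments.  Parse errors name the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

from .graph import BRIDGE, BridgeGraph, Connection, INTERVAL, REFERENCE
from .reconstruct import EdgeMultiplicities, Solution
from .segments import (
    Bridge,
    Extremity,
    HEAD,
    Karyotype,
    KaryographError,
    ObservedData,
    ReferenceSegmentation,
    SignedUnit,
    TAIL,
)


class FormatError(KaryographError):
    """A malformed input file."""


def _rows(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# CN profile (BED-like)
# ---------------------------------------------------------------------------

def write_cn_bed(seg: ReferenceSegmentation, cn: dict, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tinterval_id\tcn\n")
        for chrom, lengths in seg.chromosomes.items():
            start = 0
            for j, l in enumerate(lengths, start=1):
                fh.write(
                    f"{chrom}\t{start}\t{start + l}\t{chrom}:{j}\t"
                    f"{cn[(chrom, j)]!r}\n"
                )
                start += l


def read_cn_bed(path) -> tuple[ReferenceSegmentation, dict]:
    path = Path(path)
    lengths: dict[str, list[int]] = {}
    ends: dict[str, int] = {}
    cn: dict[tuple[str, int], float] = {}
    for lineno, fields in _rows(path):
        if len(fields) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns")
        chrom, start_s, end_s, _id, cn_s = fields
        try:
            start, end, value = int(start_s), int(end_s), float(cn_s)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        expected = ends.get(chrom, 0)
        if start != expected:
            raise FormatError(
                f"{path}:{lineno}: segments on {chrom} not contiguous "
                f"(start {start}, expected {expected})"
            )
        if end <= start:
            raise FormatError(f"{path}:{lineno}: empty or inverted segment")
        lengths.setdefault(chrom, []).append(end - start)
        ends[chrom] = end
        cn[(chrom, len(lengths[chrom]))] = value
    if not lengths:
        raise FormatError(f"{path}: no CN segments")
    return ReferenceSegmentation(lengths), cn


# ---------------------------------------------------------------------------
# Bridges (BEDPE-like)
# ---------------------------------------------------------------------------

def _extremity_coord(seg: ReferenceSegmentation, e: Extremity) -> int:
    bounds = seg.boundaries(e.chrom)
    start = bounds[e.index - 1]
    return start if e.side == TAIL else start + seg.length(e.chrom, e.index)


def _coord_extremity(
    seg: ReferenceSegmentation, chrom: str, pos: int, side: str, where: str
) -> Extremity:
    if side not in (HEAD, TAIL):
        raise FormatError(f"{where}: side must be H or T, got {side!r}")
    if chrom not in seg.chromosomes:
        raise FormatError(f"{where}: unknown chromosome {chrom!r}")
    bounds = seg.boundaries(chrom)
    if side == TAIL:
        if pos not in bounds:
            raise FormatError(f"{where}: {pos} is not an interval start on {chrom}")
        return Extremity(chrom, bounds.index(pos) + 1, TAIL)
    ends = [b + l for b, l in zip(bounds, seg.chromosomes[chrom])]
    if pos not in ends:
        raise FormatError(f"{where}: {pos} is not an interval end on {chrom}")
    return Extremity(chrom, ends.index(pos) + 1, HEAD)


def write_bridges_bedpe(seg: ReferenceSegmentation, bridges, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#chrom1\tpos1\tside1\tchrom2\tpos2\tside2\tsupport\n")
        for b in bridges:
            a, c = b.pair
            fh.write(
                f"{a.chrom}\t{_extremity_coord(seg, a)}\t{a.side}\t"
                f"{c.chrom}\t{_extremity_coord(seg, c)}\t{c.side}\t{b.support!r}\n"
            )


def read_bridges_bedpe(path, seg: ReferenceSegmentation) -> list[Bridge]:
    path = Path(path)
    out: list[Bridge] = []
    for lineno, fields in _rows(path):
        if len(fields) != 7:
            raise FormatError(f"{path}:{lineno}: expected 7 columns")
        c1, p1, s1, c2, p2, s2, sup = fields
        where = f"{path}:{lineno}"
        try:
            a = _coord_extremity(seg, c1, int(p1), s1, where)
            b = _coord_extremity(seg, c2, int(p2), s2, where)
            support = float(sup)
        except ValueError as exc:
            raise FormatError(f"{where}: {exc}") from None
        out.append(Bridge.make(a, b, support))
    return out


def read_observed(cn_path, bridges_path) -> tuple[ReferenceSegmentation, ObservedData]:
    """Load a segmentation + observed data pair; validates consistency."""
    seg, cn = read_cn_bed(cn_path)
    bridges = read_bridges_bedpe(bridges_path, seg)
    obs = ObservedData(cn=cn, bridges=bridges)
    obs.validate_against(seg)
    return seg, obs


# ---------------------------------------------------------------------------
# Karyotypes
# ---------------------------------------------------------------------------

def _unit_str(u: SignedUnit) -> str:
    c, i, s = u
    return f"{'-' if s < 0 else ''}{c}:{i}"


def _parse_unit(token: str, where: str) -> SignedUnit:
    token = token.strip()
    sign = 1
    if token.startswith("-"):
        sign, token = -1, token[1:]
    try:
        chrom, idx = token.rsplit(":", 1)
        return (chrom, int(idx), sign)
    except ValueError:
        raise FormatError(f"{where}: malformed unit {token!r}") from None


def write_karyotype(k: Karyotype, path) -> None:
    with open(path, "w") as fh:
        for chrom in k.chromosomes:
            fh.write(",".join(_unit_str(u) for u in chrom) + "\n")


def read_karyotype(path) -> Karyotype:
    path = Path(path)
    chroms: list[list[SignedUnit]] = []
    for lineno, fields in _rows(path):
        tokens = fields[0].split(",")
        chroms.append([_parse_unit(t, f"{path}:{lineno}") for t in tokens])
    return Karyotype(chroms)


# ---------------------------------------------------------------------------
# Solutions
# ---------------------------------------------------------------------------

def _ext_fields(e: Extremity) -> str:
    return f"{e.chrom}\t{e.index}\t{e.side}"


def write_solution(sol: Solution, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_karyotype(sol.karyotype, out / "karyotype.txt")
    if sol.cycles:
        write_karyotype(Karyotype([list(c) for c in sol.cycles]), out / "cycles.txt")
    with open(out / "multiplicities.tsv", "w") as fh:
        fh.write(
            "#kind\tchrom1\tindex1\tside1\tchrom2\tindex2\tside2\tweight\t"
            "x_fwd\tx_rev\n"
        )
        for c, (xf, xr) in sol.multiplicities.items():
            w = "" if c.weight is None else repr(c.weight)
            fh.write(
                f"{c.kind}\t{_ext_fields(c.u)}\t{_ext_fields(c.v)}\t{w}\t{xf}\t{xr}\n"
            )
    with open(out / "score.json", "w") as fh:
        json.dump(
            {
                "score": sol.score,  # json round-trips the full double
                "alpha": sol.alpha,
                "n_paths": len(sol.paths),
                "n_cycles": len(sol.cycles),
                "n_stray_junctions": len(sol.stray_junctions),
                "warnings": sol.warnings,
                "solver_status": sol.solver_status,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def read_solution(out_dir) -> Solution:
    out = Path(out_dir)
    karyotype = read_karyotype(out / "karyotype.txt")
    cycles_path = out / "cycles.txt"
    cycles = (
        [list(c) for c in read_karyotype(cycles_path).chromosomes]
        if cycles_path.exists()
        else []
    )
    counts: dict[Connection, tuple[int, int]] = {}
    path = out / "multiplicities.tsv"
    for lineno, fields in _rows(path):
        if len(fields) != 10:
            raise FormatError(f"{path}:{lineno}: expected 10 columns")
        kind, c1, i1, s1, c2, i2, s2, w, xf, xr = fields
        if kind not in (INTERVAL, REFERENCE, BRIDGE):
            raise FormatError(f"{path}:{lineno}: unknown connection kind {kind!r}")
        conn = Connection(
            kind,
            Extremity(c1, int(i1), s1),
            Extremity(c2, int(i2), s2),
            None if w == "" else float(w),
        )
        counts[conn] = (int(xf), int(xr))
    with open(out / "score.json") as fh:
        meta = json.load(fh)
    return Solution(
        multiplicities=EdgeMultiplicities(counts),
        paths=[list(c) for c in karyotype.chromosomes],
        cycles=cycles,
        score=float(meta["score"]),
        alpha=float(meta["alpha"]),
        warnings=list(meta.get("warnings", [])),
        solver_status=meta.get("solver_status", "optimal"),
    )


def write_metadata(path, metadata: dict) -> None:
    """JSON run-metadata header (version, seed, params, solver) for provenance."""
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, default=str)
        fh.write("\n")
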