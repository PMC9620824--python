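"""Detection of pure and impure homorepeat (polyX) regions.

A *pure* region is a maximal run of the target residue (alanine by
default) of at least ``min_len`` residues.  An *impure* region is a
stretch mostly composed of the target: every window of ``window``
residues containing at least ``window_min_count`` target residues
qualifies; qualifying windows are unioned, merged spans are trimmed so
they start and end on the target residue, and spans shorter than 5
residues or with fewer than ``window_min_count`` targets are dropped.
Windows shorter than ``window`` at the sequence termini also qualify if
they hold enough target residues, so a repeat at the C-terminus is
called exactly as its mirror image at the N-terminus would be.

The two searches run independently: a protein may contribute regions to
both lists, and a pure region may lie inside an impure one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import ProteinRecord, as_mapping

PURE_LENGTH_CLASSES = ("4", ">4")
IMPURE_LENGTH_CLASSES = ("5", "6", ">6")

#: Minimum length of an impure region after trimming.
IMPURE_MIN_LEN = 5


@dataclass(frozen=True)
class RepeatRegion:
    """A detected homorepeat region, 1-based inclusive coordinates.

    ``impurities`` lists the non-target residues as (offset, residue)
    pairs where offset 1 is the first residue of the region.
    """

    protein_id: str
    start: int
    end: int
    purity: str
    target: str = "A"
    impurities: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad coordinates {self.start}..{self.end}")
        if self.purity not in ("pure", "impure"):
            raise ValueError(f"bad purity {self.purity!r}")
        if self.purity == "pure" and self.impurities:
            raise ValueError("pure region cannot carry impurities")
        if self.purity == "impure" and not self.impurities:
            raise ValueError("impure region must carry at least one impurity")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_target(self) -> int:
        return self.length - len(self.impurities)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def detect_pure(
    record: ProteinRecord, target: str = "A", min_len: int = 4
) -> list[RepeatRegion]:
    """Maximal runs of ``target`` with length >= ``min_len``, in order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    regions: list[RepeatRegion] = []
    pos = 1
    for is_target, group in groupby(record.sequence, key=lambda c: c == target):
        run = sum(1 for _ in group)
        if is_target and run >= min_len:
            regions.append(
                RepeatRegion(record.id, pos, pos + run - 1, "pure", target)
            )
        pos += run
    return regions


def detect_impure(
    record: ProteinRecord,
    target: str = "A",
    window: int = 6,
    window_min_count: int = 4,
    require_impurity: bool = True,
    min_len: int = IMPURE_MIN_LEN,
) -> list[RepeatRegion]:
    """Window-union search for target-rich (impure) regions.

    With ``require_impurity`` (the default) all-target spans are dropped;
    those are the pure regions and are reported by :func:`detect_pure`.
    Setting it to ``False`` gives the inclusive variant.
    """
    if window_min_count > window:
        raise ValueError("window_min_count must be <= window")
    if window_min_count < 1:
        raise ValueError("window_min_count must be >= 1")
    seq = record.sequence
    L = len(seq)
    is_t = [1 if c == target else 0 for c in seq]
    pref = [0]
    for v in is_t:
        pref.append(pref[-1] + v)

    covered = bytearray(L)

    def mark(s: int, e: int) -> None:  # 0-based inclusive span
        if pref[e + 1] - pref[s] >= window_min_count:
            covered[s : e + 1] = b"\x01" * (e - s + 1)

    for s in range(0, L - window + 1):
        mark(s, s + window - 1)
    # terminal windows shorter than `window`
    for k in range(window_min_count, window):
        if k > L:
            break
        mark(0, k - 1)
        mark(L - k, L - 1)

    regions: list[RepeatRegion] = []
    i = 0
    while i < L:
        if not covered[i]:
            i += 1
            continue
        j = i
        while j + 1 < L and covered[j + 1]:
            j += 1
        s, e = i, j
        i = j + 1
        # trim so the span begins and ends on the target residue
        while s <= e and seq[s] != target:
            s += 1
        while e >= s and seq[e] != target:
            e -= 1
        if s > e:
            continue
        length = e - s + 1
        n_target = pref[e + 1] - pref[s]
        if length < min_len or n_target < window_min_count:
            continue
        imps = tuple(
            (k - s + 1, seq[k]) for k in range(s, e + 1) if seq[k] != target
        )
        if not imps and require_impurity:
            continue
        regions.append(
            RepeatRegion(
                record.id,
                s + 1,
                e + 1,
                "impure" if imps else "pure",
                target,
                imps,
            )
        )
    return regions


def detect_all(
    proteome,
    target: str = "A",
    pure_min_len: int = 4,
    window: int = 6,
    window_min_count: int = 4,
    require_impurity: bool = True,
) -> list[RepeatRegion]:
    """Run both searches over a whole proteome; pure then impure per protein."""
    out: list[RepeatRegion] = []
    for rec in as_mapping(proteome).values():
        out.extend(detect_pure(rec, target=target, min_len=pure_min_len))
        out.extend(
            detect_impure(
                rec,
                target=target,
                window=window,
                window_min_count=window_min_count,
                require_impurity=require_impurity,
            )
        )
    return out


def _length_class(region: RepeatRegion) -> str:
    if region.purity == "pure":
        return "4" if region.length == 4 else ">4"
    if region.length == 5:
        return "5"
    if region.length == 6:
        return "6"
    return ">6"


@dataclass
class CountTable:
    """Region and hosting-protein counts per length class.

    Pure regions are classed by length {4, >4}; impure by {5, 6, >6}.
    """

    pure: dict[str, tuple[int, int]] = field(default_factory=dict)
    impure: dict[str, tuple[int, int]] = field(default_factory=dict)
    pure_total: tuple[int, int] = (0, 0)
    impure_total: tuple[int, int] = (0, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for purity, classes, totals in (
            ("pure", self.pure, self.pure_total),
            ("impure", self.impure, self.impure_total),
        ):
            for cls, (nr, np_) in classes.items():
                rows.append((purity, cls, nr, np_))
            rows.append((purity, "total", totals[0], totals[1]))
        return pd.DataFrame(rows, columns=["purity", "length_class", "regions", "proteins"])


def summarize_counts(regions: Iterable[RepeatRegion], proteome=None) -> CountTable:
    """Tabulate regions and distinct hosting proteins per length class."""
    regions = list(regions)
    table = CountTable()
    for purity, classes in (("pure", PURE_LENGTH_CLASSES), ("impure", IMPURE_LENGTH_CLASSES)):
        counts = {cls: [0, set()] for cls in classes}
        total_n = 0
        total_p: set[str] = set()
        for r in regions:
            if r.purity != purity:
                continue
            cls = _length_class(r)
            counts[cls][0] += 1
            counts[cls][1].add(r.protein_id)
            total_n += 1
            total_p.add(r.protein_id)
        packed = {cls: (n, len(p)) for cls, (n, p) in counts.items()}
        if purity == "pure":
            table.pure = packed
            table.pure_total = (total_n, len(total_p))
        else:
            table.impure = packed
            table.impure_total = (total_n, len(total_p))
    return table


def most_nterminal_region(
    regions: Iterable[RepeatRegion],
) -> dict[str, RepeatRegion]:
    """Per protein, the region with the smallest start coordinate.

    Ties (e.g. a pure run starting exactly where the impure span it sits
    in starts) are broken in favour of the longer region.
    """
    best: dict[str, RepeatRegion] = {}
    for r in regions:
        cur = best.get(r.protein_id)
        if cur is None or (r.start, -r.length) < (cur.start, -cur.length):
            best[r.protein_id] = r
    return best


# ---------------------------------------------------------------------------
# Region table (TSV) round trip

REGION_COLUMNS = ["protein_id", "start", "end", "length", "purity", "target", "n_target", "impurities"]


def regions_to_frame(regions: Sequence[RepeatRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        imp = ";".join(f"{k}:{aa}" for k, aa in r.impurities)
        rows.append((r.protein_id, r.start, r.end, r.length, r.purity, r.target, r.n_target, imp))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def write_regions(regions: Sequence[RepeatRegion], path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def read_regions(path) -> list[RepeatRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"impurities": str}, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        imp_field = row.get("impurities", "")
        imps = tuple(
            (int(part.split(":")[0]), part.split(":")[1])
            for part in str(imp_field).split(";")
            if part
        )
        out.append(
            RepeatRegion(
                protein_id=str(row["protein_id"]),
                start=int(row["start"]),
                end=int(row["end"]),
                purity=str(row["purity"]),
                target=str(row.get("target", "A")),
                impurities=imps,
            )
        )
    return out
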