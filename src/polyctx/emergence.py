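"""Did a repeat emerge by insertion or by substitution?

Given a multiple sequence alignment containing the reference protein and
a (typically distant) ortholog, the alignment columns spanned by a
repeat region are inspected in the ortholog row.  If the ortholog is
mostly gapped under the repeat, the repeat is new sequence — an
insertion.  If the ortholog aligns residues there, the repeat arose by
point substitutions of pre-existing residues.  Intermediate gap
fractions are called mixed.  The thresholds are operational knobs (the
distinction is narrative in the literature) and are reported with every
call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio import SeqIO

from .detect import RepeatRegion

GAP_CHARS = frozenset("-.")


def load_alignment(path) -> dict[str, str]:
    """Aligned FASTA as an id -> aligned (gapped, upper-case) string map."""
    rows: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in rows:
            raise ValueError(f"duplicate id {entry.id!r} in alignment")
        rows[entry.id] = str(entry.seq).upper()
    if not rows:
        raise ValueError(f"no alignment rows found in {path}")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    return rows


@dataclass(frozen=True)
class EmergenceCall:
    region: RepeatRegion
    ortholog_id: str
    gap_fraction: float
    nontarget_fraction: float
    target_fraction: float
    call: str  # insertion | substitution | mixed
    t_ins: float
    t_sub: float


def map_region_to_columns(
    msa: Mapping[str, str], ref_id: str, region: RepeatRegion
) -> tuple[int, ...]:
    """1-based alignment columns whose reference residue lies in the region."""
    if ref_id not in msa:
        raise KeyError(f"reference id {ref_id!r} not in alignment")
    row = msa[ref_id]
    cols = []
    residue_idx = 0  # ungapped position, 1-based once incremented
    for col, ch in enumerate(row, start=1):
        if ch in GAP_CHARS:
            continue
        residue_idx += 1
        if region.start <= residue_idx <= region.end:
            cols.append(col)
    if residue_idx < region.end:
        raise ValueError(
            f"region extends past ungapped reference length ({residue_idx})"
        )
    return tuple(cols)


def classify_emergence(
    msa: Mapping[str, str],
    ref_id: str,
    region: RepeatRegion,
    ortholog_id: str,
    t_ins: float = 0.8,
    t_sub: float = 0.2,
) -> EmergenceCall:
    """Classify a repeat as insertion, substitution or mixed.

    gap_fraction is the fraction of the region's columns gapped in the
    ortholog; insertion if >= t_ins, substitution if <= t_sub, mixed
    otherwise.
    """
    if not (0 <= t_sub < t_ins <= 1):
        raise ValueError("thresholds must satisfy 0 <= t_sub < t_ins <= 1")
    if ortholog_id not in msa:
        raise KeyError(f"ortholog id {ortholog_id!r} not in alignment")
    cols = map_region_to_columns(msa, ref_id, region)
    if not cols:
        raise ValueError("region maps to no alignment columns")
    orth = msa[ortholog_id]
    n = len(cols)
    gaps = sum(1 for c in cols if orth[c - 1] in GAP_CHARS)
    target = sum(
        1 for c in cols if orth[c - 1] not in GAP_CHARS and orth[c - 1] == region.target
    )
    nontarget = n - gaps - target
    gap_fraction = gaps / n
    if gap_fraction >= t_ins:
        call = "insertion"
    elif gap_fraction <= t_sub:
        call = "substitution"
    else:
        call = "mixed"
    return EmergenceCall(
        region=region,
        ortholog_id=ortholog_id,
        gap_fraction=gap_fraction,
        nontarget_fraction=nontarget / n,
        target_fraction=target / n,
        call=call,
        t_ins=t_ins,
        t_sub=t_sub,
    )
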