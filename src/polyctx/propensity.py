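"""Tripeptide-based local secondary-structure propensity profiles.

A propensity table maps each tripeptide to a probability vector over 27
structural classes — the ordered triples over the alpha, beta and gamma
regions of Ramachandran space.  A sequence is split into overlapping
tripeptides (two residues shared between neighbours) and each interior
residue i receives the renormalised weighted average of the class
vectors of the tripeptides centred at i-2..i+2, acknowledging that the
local structure of a tripeptide depends on its sequence context.  The
27-vector is then reduced to three numbers: all-helical (aaa),
all-extended (bbb), and Others (the remaining 25 classes).

Profiles over repeat regions are aggregated by relative position: 0 for
residues inside the region, -1..-10 / +1..+10 for the flanks.  The
prediction window extends 12 residues beyond the region on each side so
the reported +/-10 positions are free of terminal artefacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import RepeatRegion
from .io import as_mapping

logger = logging.getLogger(__name__)

#: The 27 class labels: ordered triples over the alpha/beta/gamma regions.
CLASS_LABELS: tuple[str, ...] = tuple(
    "".join(t) for t in product("αβγ", repeat=3)
)
ALPHA_IDX = CLASS_LABELS.index("ααα")
BETA_IDX = CLASS_LABELS.index("βββ")

REDUCED_LABELS = ("aaa", "bbb", "others")

DEFAULT_CONTEXT_WEIGHTS = (1.0, 2.0, 4.0, 2.0, 1.0)


@dataclass
class PropensityTable:
    """Tripeptide -> 27-class probability vectors, with a uniform fallback.

    Lookups are case-insensitive.  Tripeptides absent from the table fall
    back to the uniform 1/27 vector; the number of such misses is counted
    and logged once per table.
    """

    probs: dict[str, np.ndarray]
    provenance: str = ""
    misses: int = field(default=0, compare=False)

    def lookup(self, tripeptide: str) -> np.ndarray:
        key = tripeptide.upper()
        vec = self.probs.get(key)
        if vec is None:
            if self.misses == 0:
                logger.warning(
                    "tripeptide %r not in propensity table; using uniform fallback", key
                )
            self.misses += 1
            return np.full(27, 1 / 27)
        return vec


def load_propensity_table(path) -> PropensityTable:
    """Read a TSV propensity table: column ``tripeptide`` plus 27 class columns.

    Rows whose probabilities do not sum to 1 within 1e-6 are a hard
    error; surviving rows are renormalised exactly.
    """
    df = pd.read_csv(path, sep="\t")
    if "tripeptide" not in df.columns or len(df.columns) != 28:
        raise ValueError(
            f"propensity table must have a 'tripeptide' column plus 27 class columns, got {len(df.columns)}"
        )
    value_cols = [c for c in df.columns if c != "tripeptide"]
    probs: dict[str, np.ndarray] = {}
    for _, row in df.iterrows():
        tri = str(row["tripeptide"]).upper()
        vec = row[value_cols].to_numpy(dtype=float)
        if (vec < 0).any():
            raise ValueError(f"negative probability for tripeptide {tri!r}")
        total = vec.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"probabilities for tripeptide {tri!r} sum to {total}, not 1")
        probs[tri] = vec / total
    return PropensityTable(probs=probs, provenance=str(path))


def write_propensity_table(table: PropensityTable, path) -> None:
    df = pd.DataFrame.from_dict(
        {tri: vec for tri, vec in table.probs.items()}, orient="index", columns=list(CLASS_LABELS)
    )
    df.index.name = "tripeptide"
    df.reset_index().to_csv(path, sep="\t", index=False)


def _reduce(vec: np.ndarray) -> np.ndarray:
    aaa = vec[ALPHA_IDX]
    bbb = vec[BETA_IDX]
    return np.array([aaa, bbb, 1.0 - aaa - bbb])


def predict_profile(
    sequence: str,
    table: PropensityTable,
    context_weights: Sequence[float] = DEFAULT_CONTEXT_WEIGHTS,
) -> np.ndarray:
    """Per-residue (aaa, bbb, Others) fractions, shape (L, 3).

    Residue i (1-based, 2 <= i <= L-1) averages the class vectors of the
    tripeptides centred at i-2..i+2 with ``context_weights``; weights of
    out-of-range neighbours are dropped and the rest renormalised.  The
    terminal residues carry no prediction (NaN rows).
    """
    sequence = sequence.upper()
    L = len(sequence)
    if L < 3:
        raise ValueError("sequence must be at least 3 residues long")
    w = np.asarray(context_weights, dtype=float)
    if w.shape != (5,) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("context_weights must be 5 non-negative values with positive sum")

    centre_vecs = [None] * L  # tripeptide vector for each valid centre (0-based 1..L-2)
    for c in range(1, L - 1):
        centre_vecs[c] = table.lookup(sequence[c - 1 : c + 2])

    out = np.full((L, 3), np.nan)
    for i in range(1, L - 1):
        acc = np.zeros(27)
        wsum = 0.0
        for k, j in enumerate(range(i - 2, i + 3)):
            if w[k] == 0 or not (1 <= j <= L - 2):
                continue
            acc += w[k] * centre_vecs[j]
            wsum += w[k]
        out[i] = _reduce(acc / wsum)
    return out


@dataclass
class PropensityProfile:
    """Mean (aaa, bbb, Others) fractions per relative position.

    Position 0 is the mean over all residues of all regions; -1..-10 and
    +1..+10 are the flanks.  Positions with no contributing residues
    have n = 0 and NaN fractions.
    """

    fractions: pd.DataFrame  # index: relative positions; columns aaa, bbb, others
    n: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = self.fractions.copy()
        df["n"] = self.n
        return df.reset_index(names="position")


def aggregate_region_profiles(
    regions: Sequence[RepeatRegion],
    proteome,
    table: PropensityTable,
    flank_computed: int = 12,
    flank_reported: int = 10,
    context_weights: Sequence[float] = DEFAULT_CONTEXT_WEIGHTS,
) -> PropensityProfile:
    """Aggregate per-residue predictions over regions by relative position.

    Predictions run on each region extended by ``flank_computed``
    residues (clipped to the protein), but only positions within
    ``flank_reported`` of the region are reported, keeping the outer
    flank free of end-of-window artefacts.
    """
    if flank_reported > flank_computed:
        raise ValueError("flank_reported cannot exceed flank_computed")
    proteins = as_mapping(proteome)
    positions = list(range(-flank_reported, flank_reported + 1))
    sums = np.zeros((len(positions), 3))
    counts = np.zeros(len(positions), dtype=int)
    pos_index = {p: k for k, p in enumerate(positions)}
    for r in regions:
        rec = proteins[r.protein_id]
        a = max(1, r.start - flank_computed)
        b = min(rec.length, r.end + flank_computed)
        sub = rec.sequence[a - 1 : b]
        if len(sub) < 3:
            continue
        pred = predict_profile(sub, table, context_weights)
        for absolute in range(a, b + 1):
            row = pred[absolute - a]
            if np.isnan(row[0]):
                continue
            if absolute < r.start:
                rel = absolute - r.start  # negative flank
            elif absolute > r.end:
                rel = absolute - r.end
            else:
                rel = 0
            k = pos_index.get(rel)
            if k is None:
                continue
            sums[k] += row
            counts[k] += 1
    with np.errstate(invalid="ignore"):
        means = sums / counts[:, None]
    fractions = pd.DataFrame(means, index=positions, columns=list(REDUCED_LABELS))
    return PropensityProfile(fractions=fractions, n=pd.Series(counts, index=positions))
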