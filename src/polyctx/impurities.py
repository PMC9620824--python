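"""Composition and position of impurities inside impure homorepeat regions.

Impure regions are stratified by region length into the classes 5, 6 and
>6 residues, plus the pooled class "All".  For every amino-acid letter
the frequency among impurity occurrences is reported per class, and the
pooled frequency is divided by the proteome background frequency to give
the enrichment ratio (the All/Bg ratio).  An impurity at 1-based offset
k in a region of length L sits at relative position (k - 0.5)/L, so the
centre of any region is exactly 0.5 and "second half" means > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detect import RepeatRegion
from .io import BackgroundComposition, STANDARD_AA

IMPURITY_CLASSES = ("5", "6", ">6", "All")


def _length_class(region: RepeatRegion) -> str:
    if region.length == 5:
        return "5"
    if region.length == 6:
        return "6"
    return ">6"


@dataclass
class ImpurityStats:
    """Per-letter, per-length-class impurity statistics.

    frequencies : DataFrame, letters x classes, frequency among impurities
        within that class (0 for letters never observed).
    ratios : Series, pooled ("All") frequency / background frequency per
        letter (0 for letters never observed).
    counts : Series, number of impurity occurrences per class.
    positions : long DataFrame (letter, length_class, rel_pos), one row per
        impurity occurrence; empty until filled by
        :func:`impurity_relative_positions`.
    """

    frequencies: pd.DataFrame
    ratios: pd.Series
    counts: pd.Series
    positions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["letter", "length_class", "rel_pos"])
    )

    def position_summary(self) -> pd.DataFrame:
        """Median and quartiles of relative position per letter and class."""
        if self.positions.empty:
            return pd.DataFrame(columns=["letter", "length_class", "n", "q1", "median", "q3"])
        rows = []
        pooled = self.positions.copy()
        pooled["length_class"] = "All"
        both = pd.concat([self.positions, pooled], ignore_index=True)
        for (letter, cls), grp in both.groupby(["letter", "length_class"], sort=True):
            q1, med, q3 = np.percentile(grp["rel_pos"], [25, 50, 75])
            rows.append((letter, cls, len(grp), q1, med, q3))
        return pd.DataFrame(rows, columns=["letter", "length_class", "n", "q1", "median", "q3"])


def _letters_universe(extra: Iterable[str]) -> list[str]:
    letters = list(STANDARD_AA)
    for aa in extra:
        if aa not in letters:
            letters.append(aa)
    return letters


def impurity_frequencies(
    regions: Sequence[RepeatRegion], background: BackgroundComposition
) -> ImpurityStats:
    """Frequency of each letter among impurities, per length class, and the
    pooled ratio to background."""
    regions = [r for r in regions if r.purity == "impure"]
    all_letters = [aa for r in regions for _, aa in r.impurities]
    if not all_letters:
        raise ValueError("no impurities found in the supplied regions")
    letters = _letters_universe(all_letters)

    counts = pd.DataFrame(0, index=letters, columns=list(IMPURITY_CLASSES), dtype=int)
    for r in regions:
        cls = _length_class(r)
        for _, aa in r.impurities:
            counts.loc[aa, cls] += 1
            counts.loc[aa, "All"] += 1
    totals = counts.sum(axis=0)
    freq = counts / totals.replace(0, np.nan)
    freq = freq.fillna(0.0)

    ratios = pd.Series(0.0, index=letters, name="ratio")
    for aa in letters:
        bg = background.freq.get(aa, 0.0)
        if counts.loc[aa, "All"] > 0:
            if bg <= 0:
                raise ValueError(f"letter {aa!r} observed as impurity but absent from background")
            ratios[aa] = freq.loc[aa, "All"] / bg
    return ImpurityStats(frequencies=freq, ratios=ratios, counts=totals)


def relative_position(offset: int, length: int) -> float:
    """Relative position (offset - 0.5)/length of a 1-based offset in a region."""
    if not (1 <= offset <= length):
        raise ValueError("offset outside region")
    return (offset - 0.5) / length


def impurity_relative_positions(
    regions: Sequence[RepeatRegion], background: BackgroundComposition
) -> ImpurityStats:
    """Impurity statistics with the per-occurrence relative positions filled."""
    stats = impurity_frequencies(regions, background)
    rows = []
    for r in regions:
        if r.purity != "impure":
            continue
        cls = _length_class(r)
        for offset, aa in r.impurities:
            rows.append((aa, cls, relative_position(offset, r.length)))
    stats.positions = pd.DataFrame(rows, columns=["letter", "length_class", "rel_pos"])
    return stats
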