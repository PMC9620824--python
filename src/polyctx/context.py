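"""Positional composition and enrichment of repeat flanking regions.

For every detected region the ten residues before the repeat occupy
positions -1..-10 (counting away from the repeat) and the ten after
occupy +1..+10.  Per position, the frequency of each of the 20 standard
amino acids is computed over all regions; flank positions falling
outside the protein are simply excluded from that position's
denominator, as are ambiguity letters.  Flanks are not masked against
other repeats — the residues around a polyA stretch are themselves
alanine-rich, and that signal is part of the measurement.

Enrichment divides each positional frequency by the amino acid's
background frequency in the proteome.  The marker summary extracts the
single cells the field reads off these profiles (G+1, M-1, S+/-1,
V+/-1) plus the mean enrichment of proline and glycine over all 20
flank positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import RepeatRegion
from .io import BackgroundComposition, STANDARD_AA, as_mapping


def flank_positions(flank: int = 10) -> list[int]:
    return list(range(-flank, 0)) + list(range(1, flank + 1))


@dataclass
class CompositionProfile:
    """Frequencies per flank position (rows) and letter (columns)."""

    freq: pd.DataFrame
    denominators: pd.Series
    subset: str = "all"

    @property
    def positions(self) -> list[int]:
        return list(self.freq.index)


@dataclass
class EnrichmentProfile:
    """Positional frequency divided by background frequency, elementwise."""

    ratio: pd.DataFrame
    background: BackgroundComposition
    subset: str = "all"


def positional_composition(
    regions: Sequence[RepeatRegion],
    proteome,
    flank: int = 10,
    subset: str = "all",
) -> CompositionProfile:
    """Amino-acid composition of the -flank..-1 / +1..+flank positions.

    ``subset`` selects ``pure``, ``impure`` or ``all`` regions and is
    recorded in the output.
    """
    proteins = as_mapping(proteome)
    if subset not in ("pure", "impure", "all"):
        raise ValueError("subset must be pure, impure or all")
    positions = flank_positions(flank)
    counts = pd.DataFrame(0, index=positions, columns=list(STANDARD_AA), dtype=float)
    denom = pd.Series(0, index=positions, dtype=int)
    for r in regions:
        if subset != "all" and r.purity != subset:
            continue
        rec = proteins.get(r.protein_id)
        if rec is None:
            raise ValueError(f"region refers to unknown protein {r.protein_id!r}")
        if r.end > rec.length:
            raise ValueError(
                f"region {r.start}..{r.end} outside protein {r.protein_id!r} (length {rec.length})"
            )
        for j in range(1, flank + 1):
            for pos, absolute in ((-j, r.start - j), (j, r.end + j)):
                if not (1 <= absolute <= rec.length):
                    continue
                aa = rec.sequence[absolute - 1]
                if aa not in counts.columns:
                    continue  # ambiguity letter: skipped, denominator untouched
                counts.loc[pos, aa] += 1
                denom[pos] += 1
    freq = counts.div(denom.replace(0, np.nan), axis=0)
    return CompositionProfile(freq=freq, denominators=denom, subset=subset)


def positional_enrichment(
    profile: CompositionProfile, background: BackgroundComposition
) -> EnrichmentProfile:
    """Elementwise ratio of positional frequency to background frequency."""
    bg = profile.freq.columns.map(lambda aa: background.freq.get(aa, 0.0))
    bg = pd.Series(bg, index=profile.freq.columns, dtype=float)
    zero_bg = bg[bg <= 0].index
    if len(zero_bg) and np.nansum(profile.freq[zero_bg].to_numpy()) > 0:
        raise ValueError(
            f"letters {list(zero_bg)} have zero background but nonzero flank frequency"
        )
    ratio = profile.freq.div(bg.replace(0, np.nan), axis=1)
    return EnrichmentProfile(ratio=ratio, background=background, subset=profile.subset)


MARKERS = ("G+1", "M-1", "S-1", "S+1", "V-1", "V+1", "P", "G")


def marker_summary(enrichment: EnrichmentProfile) -> dict[str, float]:
    """The single-cell and windowed enrichment markers.

    ``G+1`` etc. are single cells of the enrichment matrix; ``P`` and
    ``G`` are the mean enrichment of that letter over all flank
    positions.
    """
    ratio = enrichment.ratio
    if 10 not in ratio.index or -10 not in ratio.index:
        raise ValueError("marker summary needs an enrichment profile with flank >= 10")
    out: dict[str, float] = {}
    for marker in MARKERS[:6]:
        letter, pos = marker[0], int(marker[1:])
        out[marker] = float(ratio.loc[pos, letter])
    for letter in ("P", "G"):
        out[letter] = float(ratio[letter].mean())
    return out


def profile_to_frame(
    profile: CompositionProfile, enrichment: EnrichmentProfile | None = None
) -> pd.DataFrame:
    """Long-format table: position, letter, frequency, denominator[, ratio]."""
    rows = []
    for pos in profile.positions:
        for aa in profile.freq.columns:
            row = [pos, aa, profile.freq.loc[pos, aa], profile.denominators[pos]]
            if enrichment is not None:
                row.append(enrichment.ratio.loc[pos, aa])
            rows.append(row)
    cols = ["position", "letter", "frequency", "denominator"]
    if enrichment is not None:
        cols.append("ratio")
    return pd.DataFrame(rows, columns=cols)
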