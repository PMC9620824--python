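"""Where repeats sit within proteins, and what that predicts.

The relative position of a region is its midpoint (default) or start
coordinate divided by protein length, a value in (0, 1].  Position
samples can be stratified by subcellular location and compared with a
Mann-Whitney U test, and the most-N-terminal repeat per protein drives
the transit-peptide/signal-peptide enrichment table: proteins are
classed by that repeat's start coordinate (2; 3-20; >20), mirroring the
observation that repeats right after the initial methionine behave as
parts of mitochondrial transit peptides while those a little further
downstream fall in signal peptides.

A region starting at coordinate 1 has no initial methionine before it;
it gets its own class "1" and is never counted in class "2".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, sqrt
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .detect import RepeatRegion, most_nterminal_region
from .io import AnnotationTable, LOCATION_LABELS, as_mapping


@dataclass(frozen=True)
class PositionSample:
    protein_id: str
    region: RepeatRegion
    rel_pos: float
    start: int
    group: str | None = None


def relative_positions(
    regions: Sequence[RepeatRegion], proteome, mode: str = "midpoint"
) -> list[PositionSample]:
    """Relative position of each region within its protein.

    midpoint mode: ((start+end)/2) / L;  start mode: start / L.
    """
    if mode not in ("midpoint", "start"):
        raise ValueError("mode must be 'midpoint' or 'start'")
    proteins = as_mapping(proteome)
    samples = []
    for r in regions:
        rec = proteins[r.protein_id]
        if r.end > rec.length:
            raise ValueError(f"region outside protein {r.protein_id!r}")
        coord = (r.start + r.end) / 2 if mode == "midpoint" else r.start
        samples.append(
            PositionSample(r.protein_id, r, coord / rec.length, r.start)
        )
    return samples


class MannWhitneyResult(NamedTuple):
    statistic: float  # U for the first sample
    pvalue: float
    method: str  # "exact" or "asymptotic"


def _exact_u_counts(n1: int, n2: int) -> list[int]:
    """Null distribution of U as integer counts for u = 0..n1*n2.

    The number of arrangements with U = u is the coefficient of q^u in
    the Gaussian binomial [n1+n2 choose n1]_q, built by polynomial
    multiplication by (1 - q^(n2+i)) and exact division by (1 - q^i).
    """
    size = n1 * n2 + 1
    coef = [0] * size
    coef[0] = 1
    for i in range(1, n1 + 1):
        p = n2 + i
        for k in range(size - 1, p - 1, -1):
            coef[k] -= coef[k - p]
        for k in range(i, size):
            coef[k] += coef[k - i]
    return coef


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is the rank-sum statistic for ``sample_a`` with average ranks for
    ties.  When min(n_a, n_b) <= 8 and there are no ties the two-sided
    p-value comes from the exact null distribution (twice the smaller
    tail, capped at 1); otherwise from the normal approximation with
    tie-corrected variance and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if min(n1, n2) <= 8 and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = comb(n1 + n2, n1)
        u_int = int(round(u1))
        lower = sum(counts[: u_int + 1])
        upper = sum(counts[u_int:])
        p = min(1.0, 2 * min(lower, upper) / total)
        return MannWhitneyResult(u1, p, "exact")

    N = n1 + n2
    mu = n1 * n2 / 2
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return MannWhitneyResult(u1, 1.0, "asymptotic")
    diff = u1 - mu
    z = (diff - 0.5 * np.sign(diff)) / sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2 * float(norm.sf(abs(z))))
    return MannWhitneyResult(u1, p, "asymptotic")


@dataclass
class LocationStratification:
    summaries: pd.DataFrame  # group, n, q1, median, q3
    pvalues: pd.DataFrame  # pairwise two-sided p-values (NaN on the diagonal)
    omitted: tuple[str, ...] = ()


def stratify_by_location(
    samples: Sequence[PositionSample],
    annotations: AnnotationTable,
    holm: bool = False,
) -> LocationStratification:
    """Group relative positions by subcellular location and test all pairs.

    Proteins without a location annotation are assigned to "Other/Mixed".
    Groups with no samples are omitted (and listed).  ``holm`` applies a
    Holm step-down adjustment to the pairwise p-values; the unadjusted
    matrix is the default presentation.
    """
    groups: dict[str, list[float]] = {lab: [] for lab in LOCATION_LABELS}
    for s in samples:
        label = annotations.location(s.protein_id) or "Other/Mixed"
        groups[label].append(s.rel_pos)
    omitted = tuple(lab for lab, vals in groups.items() if not vals)
    groups = {lab: vals for lab, vals in groups.items() if vals}

    rows = []
    for lab, vals in groups.items():
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append((lab, len(vals), q1, med, q3))
    summaries = pd.DataFrame(rows, columns=["group", "n", "q1", "median", "q3"])

    labs = list(groups)
    pmat = pd.DataFrame(np.nan, index=labs, columns=labs)
    pairs = list(itertools.combinations(labs, 2))
    pvals = []
    for la, lb in pairs:
        p = mann_whitney_u(groups[la], groups[lb]).pvalue
        pvals.append(p)
    if holm and pvals:
        order = np.argsort(pvals)
        m = len(pvals)
        adjusted = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * pvals[idx]))
            adjusted[idx] = running
        pvals = adjusted
    for (la, lb), p in zip(pairs, pvals):
        pmat.loc[la, lb] = pmat.loc[lb, la] = p
    return LocationStratification(summaries=summaries, pvalues=pmat, omitted=omitted)


TP_CLASSES = ("no polyA", "any", "1", "2", "3-20", ">20")


def start_class(start: int) -> str:
    """Start-coordinate class of a most-N-terminal repeat."""
    if start == 1:
        return "1"
    if start == 2:
        return "2"
    if start <= 20:
        return "3-20"
    return ">20"


@dataclass
class TPTable:
    """Targeting-peptide enrichment table keyed by repeat start class."""

    table: pd.DataFrame  # index TP_CLASSES; columns proteins, mTP, SP, pct_mTP, pct_SP

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index(names="start_class")


def tp_enrichment_table(
    proteome, regions: Iterable[RepeatRegion], annotations: AnnotationTable
) -> TPTable:
    """Count mTP and SP calls per start class of the most-N-terminal repeat.

    Proteins missing from the annotation table count as peptide call
    "other".  The "any" row is the sum of the start classes and together
    with "no polyA" partitions the proteome.
    """
    proteins = as_mapping(proteome)
    leading = most_nterminal_region(regions)
    counts = {cls: [0, 0, 0] for cls in TP_CLASSES}  # proteins, mTP, SP
    for pid in proteins:
        region = leading.get(pid)
        cls = "no polyA" if region is None else start_class(region.start)
        call = annotations.peptide_call(pid) or "other"
        for key in ((cls,) if region is None else (cls, "any")):
            counts[key][0] += 1
            if call == "mTP":
                counts[key][1] += 1
            elif call == "SP":
                counts[key][2] += 1
    df = pd.DataFrame.from_dict(
        counts, orient="index", columns=["proteins", "mTP", "SP"]
    ).loc[list(TP_CLASSES)]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["pct_mTP"] = 100 * df["mTP"] / df["proteins"].replace(0, np.nan)
        df["pct_SP"] = 100 * df["SP"] / df["proteins"].replace(0, np.nan)
    return TPTable(table=df)
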