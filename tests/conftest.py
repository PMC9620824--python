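import numpy as np
import pytest

from polyctx.io import ProteinRecord, STANDARD_AA


@pytest.fixture
def rng():
    return np.random.default_rng(20220915)


@pytest.fixture
def toy_proteome():
    return [
        ProteinRecord("p1", "MAAAAGLLKK"),
        ProteinRecord("p2", "MKLVAAAGAAMKLV"),
        ProteinRecord("p3", "MKLNQRSTVWYFHED"),
    ]


def random_sequence(rng, length, a_freq, target="A"):
    """Random protein sequence with the target at frequency ``a_freq``."""
    others = [aa for aa in STANDARD_AA if aa != target]
    p = [a_freq] + [(1 - a_freq) / len(others)] * len(others)
    return "".join(rng.choice([target] + others, size=length, p=p))


# --- independent detection oracles (brute force, kept free of package logic) ---

def oracle_pure(sequence, target="A", min_len=4):
    """Maximal-run enumeration: spans (start, end), 1-based inclusive."""
    spans = []
    i = 0
    L = len(sequence)
    while i < L:
        if sequence[i] == target:
            j = i
            while j + 1 < L and sequence[j + 1] == target:
                j += 1
            if j - i + 1 >= min_len:
                spans.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return spans


def oracle_impure(sequence, target="A", window=6, window_min_count=4,
                  require_impurity=True, min_len=5):
    """Window-union brute force: enumerate every window (full windows of
    exactly `window` residues plus shorter terminal windows), union the
    qualifying ones, trim to target termini, filter."""
    L = len(sequence)
    windows = [(s, s + window - 1) for s in range(L - window + 1)]
    for k in range(1, window):
        if k <= L:
            windows.append((0, k - 1))
            windows.append((L - k, L - 1))
    covered = set()
    for s, e in windows:
        if sum(1 for i in range(s, e + 1) if sequence[i] == target) >= window_min_count:
            covered.update(range(s, e + 1))
    spans = []
    for i in sorted(covered):
        if spans and i == spans[-1][1] + 1:
            spans[-1][1] = i
        else:
            spans.append([i, i])
    out = []
    for s, e in spans:
        while s <= e and sequence[s] != target:
            s += 1
        while e >= s and sequence[e] != target:
            e -= 1
        if s > e:
            continue
        n_target = sum(1 for i in range(s, e + 1) if sequence[i] == target)
        length = e - s + 1
        if length < min_len or n_target < window_min_count:
            continue
        if require_impurity and n_target == length:
            continue
        out.append((s + 1, e + 1))
    return out
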